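"""Diagnostic signatures: ordered GC-oriented gene pairs plus the vote rule.

A signature is an ordered list of oriented gene pairs.  Each pair states the
ordering expected in cancer tissue (``gene_high > gene_low``); a sample is
called GC when at least half of the pairs show that ordering within the
sample (``at_least_half``), or — under the stricter optional rule — when all
of them do (``all_pairs``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

VOTE_RULES = ("at_least_half", "all_pairs")

FILE_VERSION = 1


@dataclass(frozen=True)
class SignaturePair:
    """One oriented pair: ``gene_high`` exceeds ``gene_low`` in cancer."""

    gene_high: str
    gene_low: str

    def __post_init__(self) -> None:
        if self.gene_high == self.gene_low:
            raise ValueError(f"pair cannot relate a gene to itself: {self.gene_high}")

    @property
    def unordered(self) -> frozenset[str]:
        return frozenset((self.gene_high, self.gene_low))


@dataclass
class Signature:
    """An ordered list of GC-oriented pairs with the vote rule.

    ``k`` (the signature size) is the number of pairs; ``training_accuracy``
    is recorded when the signature was selected on training data.
    """

    pairs: list[SignaturePair] = field(default_factory=list)
    vote_rule: str = "at_least_half"
    training_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.pairs = [
            p if isinstance(p, SignaturePair) else SignaturePair(*p)
            for p in self.pairs
        ]
        if not self.pairs:
            raise ValueError("signature must contain at least one pair")
        if self.vote_rule not in VOTE_RULES:
            raise ValueError(f"unknown vote rule {self.vote_rule!r}; use {VOTE_RULES}")
        seen: set[frozenset[str]] = set()
        for p in self.pairs:
            if p.unordered in seen:
                raise ValueError(
                    f"duplicate pair {p.gene_high}/{p.gene_low} in signature"
                )
            seen.add(p.unordered)

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            for g in (p.gene_high, p.gene_low):
                if g not in out:
                    out.append(g)
        return out

    def to_dict(self) -> dict:
        d = {
            "version": FILE_VERSION,
            "pairs": [
                {"gene_high": p.gene_high, "gene_low": p.gene_low} for p in self.pairs
            ],
            "vote_rule": self.vote_rule,
        }
        if self.training_accuracy is not None:
            d["training_accuracy"] = self.training_accuracy
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        version = d.get("version")
        if version != FILE_VERSION:
            raise ValueError(f"unknown signature file version: {version!r}")
        pairs = [SignaturePair(p["gene_high"], p["gene_low"]) for p in d["pairs"]]
        return cls(
            pairs=pairs,
            vote_rule=d.get("vote_rule", "at_least_half"),
            training_accuracy=d.get("training_accuracy"),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Signature):
            return NotImplemented
        return (
            self.pairs == other.pairs
            and self.vote_rule == other.vote_rule
            and self.training_accuracy == other.training_accuracy
        )


def write_signature(s: Signature, path) -> None:
    with open(path, "w") as fh:
        json.dump(s.to_dict(), fh, indent=2)
        fh.write("\n")


def read_signature(path) -> Signature:
    with open(path) as fh:
        return Signature.from_dict(json.load(fh))


def load_gc_signature() -> Signature:
    """The published two-pair gastric-cancer signature.

    Pair 1 is CYR61 over MMP28, pair 2 is CYR61 over ACOX1; in cancer tissue
    CYR61 is the more abundant gene of each pair.  Three genes, two pairs,
    majority vote (so one concordant pair suffices at k = 2).
    """
    text = resources.files("reosig.data").joinpath("gc_signature.json").read_text()
    return Signature.from_dict(json.loads(text))
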