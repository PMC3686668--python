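"""Domain types, FASTA/TSV I/O, and classification metrics.

The positive class is always the miRNA (hairpin) class; sensitivity is the
true-positive rate on miRNAs and specificity the true-negative rate on
pseudo hairpins.  SE/SP/Gm are reported on the percent scale (0-100)
throughout the public API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

RNA_ALPHABET = frozenset("ACGUN")


class ParseError(ValueError):
    """Raised for malformed FASTA input or illegal sequence characters."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified RNA sequence.

    DNA input is accepted: ``T`` is mapped to ``U`` at construction.
    ``N`` is tolerated (genome windows may contain assembly gaps) but
    records containing it are flagged via :attr:`has_n` and excluded from
    feature extraction by default, since folding is undefined on N.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("empty record id")
        if not self.seq:
            raise ParseError(f"record {self.id!r}: empty sequence")
        seq = self.seq.upper().replace("T", "U")
        for pos, ch in enumerate(seq):
            if ch not in RNA_ALPHABET:
                raise ParseError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )
        object.__setattr__(self, "seq", seq)

    @property
    def has_n(self) -> bool:
        return "N" in self.seq

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved."""
    records: list[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise ParseError(f"entry {i}: missing header id")
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"entry {i} ({rec.id!r}): empty sequence")
        try:
            records.append(SequenceRecord(id=rec.id, seq=seq))
        except ParseError as exc:
            raise ParseError(f"entry {i}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity and their geometric mean, percent scale."""

    se: float
    sp: float
    gm: float


def confusion(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Tabulate a confusion matrix from binary label vectors (1 = miRNA)."""
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if p not in (0, 1) or t not in (0, 1):
            raise ValueError("labels must be binary (0/1)")
        if t == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> Metrics:
    """SE = 100*TP/(TP+FN), SP = 100*TN/(TN+FP), Gm = sqrt(SE*SP)."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("metric undefined for single-class sample")
    se = 100.0 * c.tp / (c.tp + c.fn)
    sp = 100.0 * c.tn / (c.tn + c.fp)
    return Metrics(se=se, sp=sp, gm=math.sqrt(se * sp))


def gm(se: float, sp: float) -> float:
    """Geometric mean of sensitivity and specificity (percent scale)."""
    if not (0 <= se <= 100 and 0 <= sp <= 100):
        raise ValueError("se and sp must lie in [0, 100]")
    return math.sqrt(se * sp)


def imbalance_ratio(n_pos: int, n_neg: int) -> float:
    """Class imbalance: negatives per positive."""
    if n_pos <= 0:
        raise ValueError("imbalance ratio undefined without positives")
    return n_neg / n_pos
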