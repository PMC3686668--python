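"""Negative (pseudo-hairpin) training-set construction from genomic sequence.

Negatives are genome windows whose start positions are drawn at random and
whose lengths are resampled from the empirical length distribution of the
positive (known precursor) set, so that length gives the classifier no
artificial signal.  Windows resembling known precursors are removed by a
homology filter — an external BLASTN at E <= 1e-2 when configured, or a
built-in deterministic seed-and-extend scan otherwise — and the result is
characterised by a structural QC report: the fractions of windows with
length-normalised minimum free energy below -0.05 and pairing density
above 0.15, the two criteria genuine hairpins almost always satisfy.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import SequenceRecord, write_fasta
from .folding import FoldingBackend, get_backend

MFE_PER_LEN_MAX = -0.05
PAIRINGS_PER_LEN_MIN = 0.15
BLAST_EVALUE_CUTOFF = 1e-2


@dataclass(frozen=True)
class NegativeSamplingConfig:
    n_samples: int
    seed: int = 0
    max_retries_per_sample: int = 200
    reverse_complement: bool = False  # sample either strand with p=0.5

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")


@dataclass(frozen=True)
class QCReport:
    fraction_mfe_pass: float
    fraction_pairing_pass: float
    fraction_both_pass: float
    n_records: int
    n_fold_failures: int


_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sample_negatives(
    genome: Sequence[SequenceRecord],
    positive_lengths: Sequence[int],
    cfg: NegativeSamplingConfig,
) -> list[SequenceRecord]:
    """Random genome windows with the positives' length distribution.

    Per sample: a target length is drawn with replacement from the
    positive lengths, a chromosome proportionally to its length, and a
    start uniformly; windows containing N are rejected and redrawn.
    Emitted ids encode ``source:start-end`` with 1-based inclusive
    coordinates.
    """
    if not positive_lengths:
        raise ValueError("positive length list must be non-empty")
    max_len = max(positive_lengths)
    usable = [g for g in genome if len(g) >= max_len]
    if not usable:
        raise ValueError(
            f"no genome sequence is at least {max_len} nt (longest requested window)"
        )
    rng = np.random.default_rng(cfg.seed)
    weights = np.array([len(g) for g in usable], dtype=float)
    weights /= weights.sum()
    lengths = np.asarray(positive_lengths, dtype=int)
    out: list[SequenceRecord] = []
    for _ in range(cfg.n_samples):
        for _attempt in range(cfg.max_retries_per_sample):
            target = int(lengths[rng.integers(len(lengths))])
            chrom = usable[rng.choice(len(usable), p=weights)]
            if len(chrom) < target:
                continue
            start = int(rng.integers(0, len(chrom) - target + 1))
            window = chrom.seq[start : start + target]
            if "N" in window:
                continue
            strand = "+"
            if cfg.reverse_complement and rng.random() < 0.5:
                window = reverse_complement(window)
                strand = "-"
            ident = f"{chrom.id}:{start + 1}-{start + target}"
            if strand == "-":
                ident += "(-)"
            out.append(SequenceRecord(id=ident, seq=window))
            break
        else:
            raise RuntimeError(
                "failed to sample an N-free window within the retry budget"
            )
    return out


# ---------------------------------------------------------------------------
# homology filtering
# ---------------------------------------------------------------------------

def _kmer_index(references: Sequence[SequenceRecord], k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, ref in enumerate(references):
        for i in range(len(ref.seq) - k + 1):
            index.setdefault(ref.seq[i : i + k], []).append((ri, i))
    return index


def _longest_shared_run(cand: str, ref: str, ci: int, ri: int) -> int:
    """Length of the maximal exact match through the seed at (ci, ri)."""
    left = 0
    while ci - left - 1 >= 0 and ri - left - 1 >= 0 and cand[ci - left - 1] == ref[ri - left - 1]:
        left += 1
    right = 0
    while ci + right < len(cand) and ri + right < len(ref) and cand[ci + right] == ref[ri + right]:
        right += 1
    return left + right


def homology_filter(
    candidates: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    min_run: int = 20,
    k: int = 11,
    blast_path: str | None = None,
) -> tuple[list[SequenceRecord], list[tuple[str, str, str]]]:
    """Remove candidates similar to known precursors.

    Default mode: deterministic seed-and-extend over shared k-mers (k=11);
    a candidate sharing a maximal exact run of >= ``min_run`` nucleotides
    with any reference is removed.  With ``blast_path`` set, an external
    nucleotide BLAST is run instead and candidates with E <= 1e-2 are
    removed; a configured-but-missing executable is an error, never a
    silent mode switch.

    Returns ``(kept, removal_log)`` with log rows
    ``(candidate_id, matched_reference_id, statistic)``.
    """
    if not references:
        raise ValueError("references must be non-empty")
    if blast_path is not None:
        return _blast_filter(candidates, references, blast_path)
    index = _kmer_index(references, k)
    kept: list[SequenceRecord] = []
    removed: list[tuple[str, str, str]] = []
    for cand in candidates:
        hit: tuple[int, str] | None = None
        seen_seeds: set[tuple[int, int, int]] = set()
        for i in range(len(cand.seq) - k + 1):
            for ri, rpos in index.get(cand.seq[i : i + k], ()):
                diag = (ri, i - rpos, 0)
                if diag in seen_seeds:
                    continue
                seen_seeds.add(diag)
                run = _longest_shared_run(
                    cand.seq, references[ri].seq, i, rpos
                )
                if run >= min_run and (hit is None or run > hit[0]):
                    hit = (run, references[ri].id)
            if hit is not None and hit[0] >= len(cand.seq):
                break
        if hit is None:
            kept.append(cand)
        else:
            removed.append((cand.id, hit[1], f"run={hit[0]}"))
    return kept, removed


def _blast_filter(
    candidates: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    blast_path: str,
) -> tuple[list[SequenceRecord], list[tuple[str, str, str]]]:
    blastn = shutil.which(blast_path)
    if blastn is None:
        raise FileNotFoundError(
            f"configured BLAST executable {blast_path!r} not found on PATH"
        )
    makeblastdb = shutil.which("makeblastdb")
    if makeblastdb is None:
        raise FileNotFoundError("makeblastdb not found next to configured blastn")
    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp)
        ref_fa = tmp_path / "refs.fasta"
        cand_fa = tmp_path / "cands.fasta"
        write_fasta(references, ref_fa)
        write_fasta(candidates, cand_fa)
        subprocess.run(
            [makeblastdb, "-in", str(ref_fa), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        res = subprocess.run(
            [
                blastn, "-query", str(cand_fa), "-db", str(ref_fa),
                "-evalue", str(BLAST_EVALUE_CUTOFF),
                "-outfmt", "6 qseqid sseqid evalue",
            ],
            check=True, capture_output=True, text=True,
        )
    hits: dict[str, tuple[str, str]] = {}
    for line in res.stdout.splitlines():
        qid, sid, evalue = line.split("\t")
        if qid not in hits or float(evalue) < float(hits[qid][1]):
            hits[qid] = (sid, evalue)
    kept = [c for c in candidates if c.id not in hits]
    removed = [
        (c.id, hits[c.id][0], f"evalue={hits[c.id][1]}")
        for c in candidates
        if c.id in hits
    ]
    return kept, removed


# ---------------------------------------------------------------------------
# structural QC and positive filtering
# ---------------------------------------------------------------------------

def structural_qc(
    records: Sequence[SequenceRecord],
    backend: FoldingBackend | None = None,
) -> QCReport:
    """Fractions of records meeting the hairpin-likeness criteria.

    Criteria: mfe/L below -0.05 and base pairs per length above 0.15.
    Fold failures count as failing both criteria.
    """
    if not records:
        raise ValueError("structural QC undefined on empty input")
    if backend is None:
        backend = get_backend()
    from .folding import parse_structure  # local import avoids cycle at top

    mfe_pass = pairing_pass = both_pass = failures = 0
    for rec in records:
        try:
            fr = backend.fold(rec.seq)
            stats = parse_structure(fr)
        except Exception:
            failures += 1
            continue
        ok_mfe = fr.mfe / len(rec.seq) < MFE_PER_LEN_MAX
        ok_pair = stats.pairings_per_len > PAIRINGS_PER_LEN_MIN
        mfe_pass += ok_mfe
        pairing_pass += ok_pair
        both_pass += ok_mfe and ok_pair
    n = len(records)
    return QCReport(
        fraction_mfe_pass=100.0 * mfe_pass / n,
        fraction_pairing_pass=100.0 * pairing_pass / n,
        fraction_both_pass=100.0 * both_pass / n,
        n_records=n,
        n_fold_failures=failures,
    )


def filter_positives(
    records: Sequence[SequenceRecord],
    evidence_flags: dict[str, bool],
) -> list[SequenceRecord]:
    """Keep records flagged as experimentally confirmed.

    ``evidence_flags`` is the sidecar id -> flag mapping; a record missing
    from it is an error (silent inclusion could poison the positive set).
    """
    kept = []
    for rec in records:
        if rec.id not in evidence_flags:
            raise KeyError(f"record {rec.id!r} missing from evidence sidecar")
        if evidence_flags[rec.id]:
            kept.append(rec)
    return kept


def read_evidence_tsv(path) -> dict[str, bool]:
    """Sidecar TSV with header columns ``id`` and ``evidence`` (0/1/true/false)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns or "evidence" not in df.columns:
        raise ValueError("evidence sidecar needs 'id' and 'evidence' columns")
    truthy = {"1", "true", "yes", "y"}
    return {
        str(r.id): str(r.evidence).strip().lower() in truthy
        for r in df.itertuples(index=False)
    }
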