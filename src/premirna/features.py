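"""Sequence/structure feature extraction for hairpin candidates.

Seven dedicated attributes are computed for every sequence when extended
mode is on:

* ``tri_A``/``tri_U``/``tri_G``/``tri_C`` — frequencies of the
  structure-sequence triplets "A(((", "U(((", "G(((", "C(((" (the middle
  nucleotide with the paired/unpaired state of three adjacent positions,
  after mapping ')' to '('), the four triplets with the highest
  information gain for hairpin discrimination;
* ``orf`` — the longest run of stop-free codons over the three forward
  reading frames, in codons;
* ``loops`` — the cumulative number of unpaired bases in internal loops
  and bulges of the predicted structure;
* ``dm`` — the percentage of the sequence masked as low-complexity by a
  symmetric DUST scan (window 64, subwindow score threshold 15).

The base representation is tiered: tier A holds thermodynamic/pairing
ratios computable from any MFE structure, tier B adds partition-function
(ensemble) quantities, tier C adds z-scores against dinucleotide-
preserving shuffles.  The tier-A names follow the literature's MFE-index
nomenclature (MFEI1 = dG/GC, MFEI2 = dG/#stems, MFEI4 = MFE/#pairs,
dP = pairs per length).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SequenceRecord
from .folding import FoldingBackend, FoldResult, StructureStats, get_backend, parse_structure

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

TIER_A = (
    "gc_content",
    "dg",
    "mfei1",
    "mfei2",
    "mfei4",
    "dp",
    "au_per_len",
    "gc_per_len",
    "gu_per_len",
    "avg_bp_per_stem",
)
TIER_B = (
    "dg_ensemble_per_len",
    "mfe_structure_freq",
    "ensemble_diversity_per_len",
    "positional_entropy",
)
TIER_C = ("z_dg", "z_dp")
NEW_FEATURES = ("tri_A", "tri_U", "tri_G", "tri_C", "orf", "loops", "dm")


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# the seven dedicated attributes
# ---------------------------------------------------------------------------

def triplet_features(seq: str, structure: str) -> tuple[float, float, float, float]:
    """Frequencies of "A(((", "U(((", "G(((", "C((("; denominator L-2."""
    if len(seq) != len(structure):
        raise FeatureError("sequence/structure length mismatch")
    if len(seq) < 3:
        raise FeatureError("triplet features need length >= 3")
    mapped = structure.replace(")", "(")
    counts = {"A": 0, "U": 0, "G": 0, "C": 0}
    for i in range(1, len(seq) - 1):
        if mapped[i - 1 : i + 2] == "(((":
            nt = seq[i]
            if nt in counts:
                counts[nt] += 1
    denom = len(seq) - 2
    return tuple(counts[nt] / denom for nt in "AUGC")  # type: ignore[return-value]


def orf_feature(seq: str) -> int:
    """Longest run of consecutive non-stop codons over the 3 forward frames."""
    best = 0
    for frame in range(3):
        run = 0
        for k in range(frame, len(seq) - 2, 3):
            if seq[k : k + 3] in STOP_CODONS:
                run = 0
            else:
                run += 1
                best = max(best, run)
    return best


def loops_feature(stats: StructureStats) -> int:
    """Cumulative unpaired bases in internal loops/bulges."""
    return stats.internal_loop_total


def _dust_perfect_intervals(triplets: list[int], threshold: int, window: int):
    """Perfect low-complexity intervals of the triplet sequence.

    An interval of l triplets with per-triplet counts c_t has raw score
    sum c_t(c_t-1)/2; it is high-scoring when 10*score > threshold*(l-1)
    and perfect when additionally no proper subinterval beats its
    normalised score.  Only intervals fitting in a `window`-base window
    are considered, which makes the scan symmetric (direction-free).
    """
    n = len(triplets)
    max_len = window - 2  # triplets per window
    if n < 2:
        return []
    norm = [[0.0] * n for _ in range(n)]
    for i in range(n):
        counts: dict[int, int] = {}
        s = 0
        row = norm[i]
        for j in range(i, min(n, i + max_len)):
            c = counts.get(triplets[j], 0)
            s += c
            counts[triplets[j]] = c + 1
            if j > i:
                row[j] = s / (j - i)
    # best[i][j] = max normalised score over subintervals of [i, j]
    best = [row[:] for row in norm]
    out = []
    for length in range(2, min(n, max_len) + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            sub_best = max(best[i + 1][j], best[i][j - 1])
            score = norm[i][j]
            if 10.0 * score > threshold and score >= sub_best:
                out.append((i, j))
            best[i][j] = max(score, sub_best)
    return out


def dust_fraction(seq: str, threshold: int = 15, window: int = 64) -> float:
    """Percent of bases in low-complexity regions (symmetric DUST).

    Operates on the DNA spelling (U→T) of the sequence; triplets
    containing N never match each other and thus never score.
    """
    if not seq:
        raise FeatureError("dust undefined for empty sequence")
    dna = seq.upper().replace("U", "T")
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    triplets = []
    for i in range(len(dna) - 2):
        tri = dna[i : i + 3]
        if all(ch in code for ch in tri):
            t = code[tri[0]] * 16 + code[tri[1]] * 4 + code[tri[2]]
        else:
            t = 64 + i  # unique token: never repeats, never scores
        triplets.append(t)
    intervals = _dust_perfect_intervals(triplets, threshold, window)
    if not intervals:
        return 0.0
    # triplet interval [i, j] covers bases i .. j+2; merge the union
    masked = np.zeros(len(dna), dtype=bool)
    for i, j in intervals:
        masked[i : j + 3] = True
    # discard merged masked runs shorter than 3 bases (cannot occur from
    # whole triplets, but guards merged-edge arithmetic)
    return 100.0 * int(masked.sum()) / len(dna)


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (tier C)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide count multiset.

    Altschul–Erickson Euler-path scheme: the dinucleotides form a
    multigraph; a random spanning arborescence toward the final vertex
    fixes each vertex's last outgoing edge, the remaining edges are
    permuted, and the Euler walk from the first vertex spells the
    shuffled sequence.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = sorted(edges)
    for _ in range(1000):
        last_edge = {}
        for v in vertices:
            if v == last and not edges[v]:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # all vertices with outgoing edges must reach `last` via last edges
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - bounded retry on tiny graphs
        raise FeatureError("dinucleotide shuffle failed to find an Euler order")
    order: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        order[v] = [rest[k] for k in perm]
        if v in last_edge:
            order[v].append(last_edge[v])
    out = [seq[0]]
    idx = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = order[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    shuffled = "".join(out)
    if _dinuc_counts(shuffled) != _dinuc_counts(seq):  # invariant, always checked
        raise FeatureError("shuffle violated dinucleotide counts")
    return shuffled


def _dinuc_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# base feature set and assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """Ordered feature names plus the flags that produced them."""

    tiers: str = "A"  # "A", "AB", or "ABC"
    extended: bool = True  # include the seven dedicated attributes
    backend: str = "vienna"
    n_shuffle: int = 100
    names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.tiers not in ("A", "AB", "ABC"):
            raise FeatureError("tiers must be 'A', 'AB' or 'ABC'")
        names: list[str] = list(TIER_A)
        if "B" in self.tiers:
            names += TIER_B
        if "C" in self.tiers:
            names += TIER_C
        if self.extended:
            names += NEW_FEATURES
        if len(set(names)) != len(names):
            raise FeatureError("duplicate feature names")
        object.__setattr__(self, "names", tuple(names))

    def to_dict(self) -> dict:
        return {
            "tiers": self.tiers,
            "extended": self.extended,
            "backend": self.backend,
            "n_shuffle": self.n_shuffle,
            "names": list(self.names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(
            tiers=d["tiers"],
            extended=d["extended"],
            backend=d["backend"],
            n_shuffle=d["n_shuffle"],
        )


def base_features(
    seq: str,
    fold: FoldResult,
    backend: FoldingBackend,
    tiers: str = "A",
    rng: np.random.Generator | None = None,
    n_shuffle: int = 100,
) -> dict[str, float]:
    """Tiered base representation for one folded sequence.

    Degenerate structures (no pairs or no stems) set the stem- and
    pair-normalised ratios to 0 so genome-window negatives never fail
    extraction.
    """
    L = len(seq)
    stats = parse_structure(fold)
    gc = (seq.count("G") + seq.count("C")) / L
    dg = fold.mfe / L
    dp = stats.n_bp / L
    vals: dict[str, float] = {
        "gc_content": gc,
        "dg": dg,
        "mfei1": dg / gc if gc > 0 else 0.0,
        "mfei2": dg / stats.n_stems if stats.n_stems else 0.0,
        "mfei4": fold.mfe / stats.n_bp if stats.n_bp else 0.0,
        "dp": dp,
        "au_per_len": stats.bp_type_counts["AU"] / L,
        "gc_per_len": stats.bp_type_counts["GC"] / L,
        "gu_per_len": stats.bp_type_counts["GU"] / L,
        "avg_bp_per_stem": stats.n_bp / stats.n_stems if stats.n_stems else 0.0,
    }
    if "B" in tiers:
        ens = backend.ensemble_stats(seq)  # raises on incapable backend
        vals["dg_ensemble_per_len"] = ens["dg_ensemble"] / L
        vals["mfe_structure_freq"] = ens["mfe_structure_freq"]
        vals["ensemble_diversity_per_len"] = ens["ensemble_diversity"] / L
        vals["positional_entropy"] = ens["positional_entropy"]
    if "C" in tiers:
        if rng is None:
            raise FeatureError("tier C needs a seeded random generator")
        dgs, dps = [], []
        for _ in range(n_shuffle):
            sh = dinucleotide_shuffle(seq, rng)
            fr = backend.fold(sh)
            st = parse_structure(fr)
            dgs.append(fr.mfe / L)
            dps.append(st.n_bp / L)
        vals["z_dg"] = _zscore(dg, dgs)
        vals["z_dp"] = _zscore(dp, dps)
    return vals


def _zscore(x: float, ref: Sequence[float]) -> float:
    mu = float(np.mean(ref))
    sd = float(np.std(ref, ddof=1)) if len(ref) > 1 else 0.0
    return (x - mu) / sd if sd > 0 else 0.0


def feature_vector(
    rec: SequenceRecord,
    spec: FeatureSpec,
    backend: FoldingBackend,
    seed: int = 0,
) -> dict[str, float]:
    """All features for one record, in :class:`FeatureSpec` order."""
    if rec.has_n:
        raise FeatureError(f"record {rec.id!r} contains N; excluded from extraction")
    rng = np.random.default_rng([seed, zlib.crc32(rec.id.encode())])
    fold = backend.fold(rec.seq)
    vals = base_features(
        rec.seq, fold, backend, tiers=spec.tiers, rng=rng, n_shuffle=spec.n_shuffle
    )
    if spec.extended:
        tri = triplet_features(rec.seq, fold.structure)
        vals.update(zip(("tri_A", "tri_U", "tri_G", "tri_C"), tri))
        vals["orf"] = float(orf_feature(rec.seq))
        vals["loops"] = float(loops_feature(parse_structure(fold)))
        vals["dm"] = dust_fraction(rec.seq)
    ordered = {name: vals[name] for name in spec.names}
    if not all(math.isfinite(v) for v in ordered.values()):
        raise FeatureError(f"record {rec.id!r}: non-finite feature value")
    return ordered


def extract(
    records: Sequence[SequenceRecord],
    spec: FeatureSpec,
    seed: int = 0,
    backend: FoldingBackend | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Feature table for a batch of records.

    Returns ``(table, failures)``: the table has one row per successfully
    processed record in input order (index = record id, columns in spec
    order); failures collects ``(record_id, reason)`` pairs — records
    containing N land there by default — and never aborts the batch.
    """
    if backend is None:
        backend = get_backend(spec.backend)
    if backend.name != spec.backend:
        raise FeatureError(
            f"backend mismatch: spec declares {spec.backend!r}, got {backend.name!r}"
        )
    rows: list[dict[str, float]] = []
    index: list[str] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            rows.append(feature_vector(rec, spec, backend, seed=seed))
            index.append(rec.id)
        except Exception as exc:  # per-record isolation by contract
            failures.append((rec.id, str(exc)))
    table = pd.DataFrame(rows, index=pd.Index(index, name="id"), columns=spec.names)
    return table, failures


def write_feature_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
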