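"""Synthetic data generators: hairpins, background sequences, score problems.

Every generator is a pure function of its seed.  Each call derives its own
random stream from ``(seed, call-site tag)`` via the NumPy seed-sequence
mechanism, so adding a generator call in one place never perturbs the
sequences another call produces.

The hairpin generator writes an explicit stem-loop: a random 5' arm, a
random loop, and a 3' arm that is the reverse complement of the 5' arm
with a configurable number of point mismatches and single-base bulge
insertions.  These rules make test expectations derivable (a mismatch-free
stem of s pairs folds into at least ~0.75*s pairs under any folder) while
random background sequences of the same length are overwhelmingly
unlikely to satisfy the hairpin QC criteria.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import SequenceRecord, write_fasta
from .dataset_builder import reverse_complement
from .roc_select import ScoredInstance

NUCLEOTIDES = np.array(list("AUGC"))


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(tag.encode())])


@dataclass(frozen=True)
class HairpinConfig:
    stem_len: int = 20
    loop_len: int = 4
    n_mismatches: int = 0
    n_bulges: int = 0
    gc_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_len < 4:
            raise ValueError("stem_len must be >= 4")
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3")
        if not 0 <= self.n_mismatches < self.stem_len:
            raise ValueError("n_mismatches must be < stem_len")
        if not 0.0 <= self.gc_bias <= 1.0:
            raise ValueError("gc_bias must lie in [0, 1]")


@dataclass(frozen=True)
class ScoreProblemConfig:
    n_pos: int
    n_neg: int
    pos_loc: float = 1.0
    pos_scale: float = 1.0
    neg_loc: float = 0.0
    neg_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one instance")


def _random_seq(n: int, gc_bias: float, rng: np.random.Generator) -> str:
    # P(G) = P(C) = gc_bias/2, P(A) = P(U) = (1-gc_bias)/2
    p = np.array(
        [(1 - gc_bias) / 2, (1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2]
    )
    return "".join(rng.choice(NUCLEOTIDES, size=n, p=p))


def make_hairpin(cfg: HairpinConfig, ident: str = "hairpin") -> SequenceRecord:
    """One synthetic stem-loop of length 2*stem_len + loop_len + n_bulges."""
    rng = _rng(cfg.seed, f"hairpin:{ident}")
    arm5 = _random_seq(cfg.stem_len, cfg.gc_bias, rng)
    loop = _random_seq(cfg.loop_len, cfg.gc_bias, rng)
    arm3 = list(reverse_complement(arm5))
    if cfg.n_mismatches:
        for pos in rng.choice(len(arm3), size=cfg.n_mismatches, replace=False):
            current = arm3[pos]
            choices = [nt for nt in "AUGC" if nt != current]
            arm3[pos] = choices[rng.integers(3)]
    for _ in range(cfg.n_bulges):
        pos = int(rng.integers(len(arm3) + 1))
        arm3.insert(pos, str(rng.choice(NUCLEOTIDES)))
    return SequenceRecord(id=ident, seq=arm5 + loop + "".join(arm3))


def make_negative_seq(
    length: int, gc_bias: float = 0.5, seed: int = 0, ident: str = "neg"
) -> SequenceRecord:
    """I.i.d. background sequence with the given GC bias."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed, f"negative:{ident}")
    return SequenceRecord(id=ident, seq=_random_seq(length, gc_bias, rng))


def make_score_problem(cfg: ScoreProblemConfig) -> list[ScoredInstance]:
    """Two-Gaussian labelled score sample for exercising ROC-select."""
    rng = _rng(cfg.seed, "score-problem")
    pos = rng.normal(cfg.pos_loc, cfg.pos_scale, size=cfg.n_pos)
    neg = rng.normal(cfg.neg_loc, cfg.neg_scale, size=cfg.n_neg)
    out = [ScoredInstance(score=float(s), label=1, id=f"p{i}") for i, s in enumerate(pos)]
    out += [ScoredInstance(score=float(s), label=0, id=f"n{i}") for i, s in enumerate(neg)]
    return out


def make_gaussian_features(
    n_pos: int,
    n_neg: int,
    n_features: int = 4,
    separation: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping-class Gaussian feature matrix (positives shifted by
    ``separation`` on every axis); the workhorse for imbalance experiments."""
    rng = _rng(seed, "gaussian-features")
    X_pos = rng.normal(separation, 1.0, size=(n_pos, n_features))
    X_neg = rng.normal(0.0, 1.0, size=(n_neg, n_features))
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def make_dataset(
    n_pos: int,
    n_neg: int,
    out_dir: str | Path,
    seed: int = 0,
    stem_range: tuple[int, int] = (15, 30),
    loop_range: tuple[int, int] = (4, 10),
    mismatch_range: tuple[int, int] = (0, 3),
    gc_bias: float = 0.5,
) -> tuple[Path, Path]:
    """Write a labelled FASTA pair: hairpins vs background sequences.

    Negatives are length-matched to the generated positives (lengths are
    drawn from the same stem/loop arithmetic) so length alone cannot
    separate the classes.  Ids are assigned from one shuffled namespace so
    they carry no class signal.  Returns (positives_path, negatives_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed, "dataset")
    ids = [f"seq{n:06d}" for n in rng.permutation(n_pos + n_neg)]
    positives = []
    pos_lengths = []
    for i in range(n_pos):
        cfg = HairpinConfig(
            stem_len=int(rng.integers(stem_range[0], stem_range[1] + 1)),
            loop_len=int(rng.integers(loop_range[0], loop_range[1] + 1)),
            n_mismatches=int(rng.integers(mismatch_range[0], mismatch_range[1] + 1)),
            gc_bias=gc_bias,
            seed=seed,
        )
        rec = make_hairpin(cfg, ident=ids[i])
        positives.append(rec)
        pos_lengths.append(len(rec))
    negatives = [
        make_negative_seq(
            length=int(pos_lengths[int(rng.integers(n_pos))]) if n_pos else 60,
            gc_bias=gc_bias,
            seed=seed,
            ident=ids[n_pos + j],
        )
        for j in range(n_neg)
    ]
    pos_path = out_dir / "positives.fasta"
    neg_path = out_dir / "negatives.fasta"
    write_fasta(positives, pos_path)
    write_fasta(negatives, neg_path)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("id\tlabel\tlength\n")
        for rec in positives:
            fh.write(f"{rec.id}\t1\t{len(rec)}\n")
        for rec in negatives:
            fh.write(f"{rec.id}\t0\t{len(rec)}\n")
    return pos_path, neg_path
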