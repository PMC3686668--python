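"""RNA secondary-structure prediction backends and dot-bracket parsing.

Two backends implement the same contract:

* ``vienna`` — minimum-free-energy folding through the ViennaRNA Python
  bindings (thermodynamic nearest-neighbour model); also provides the
  partition-function quantities needed by ensemble features.
* ``nussinov`` — a built-in maximum base-pairing folder (Nussinov-style
  dynamic programme, minimum hairpin loop 3, canonical plus G-U wobble
  pairs, energy proxy of -1 kcal/mol per pair) so the package runs with no
  external thermodynamics library.

Feature values depend on the backend, so every backend carries a ``name``
tag that is recorded in trained model bundles; mixing backends between
training and classification is refused at the model layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator

PAIRABLE = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)
MIN_HAIRPIN_LOOP = 3


class FoldingError(RuntimeError):
    pass


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class FoldResult:
    """A sequence with its predicted MFE structure (dot-bracket) and energy."""

    seq: str
    structure: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.structure):
            raise StructureError("sequence/structure length mismatch")
        _pair_map(self.structure)  # validates balance
        if "(" not in self.structure and abs(self.mfe) > 1e-9:
            raise StructureError("unpaired structure must have mfe = 0")


@dataclass(frozen=True)
class StructureStats:
    n_bp: int
    n_stems: int
    n_loops: int
    internal_loop_total: int
    bp_type_counts: dict  # keys "AU", "GC", "GU"
    pairings_per_len: float


def _pair_map(structure: str) -> dict[int, int]:
    """Map each paired index to its partner; raises on unbalanced input."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at index {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise StructureError(f"illegal structure character {ch!r} at index {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at index {stack[0]}")
    return pairs


def parse_structure(fr: FoldResult) -> StructureStats:
    """Derive base-pair, stem and loop statistics from a dot-bracket string.

    Loop decomposition is the standard tree decomposition by enclosing
    pairs.  A loop enclosing exactly one inner helix with at least one
    unpaired base (a bulge or a two-sided internal loop) contributes all
    its unpaired bases to ``internal_loop_total``; hairpin loops,
    multiloops and exterior bases do not.
    """
    structure, seq = fr.structure, fr.seq
    pairs = _pair_map(structure)
    opening = sorted(i for i, j in pairs.items() if i < j)
    n_bp = len(opening)

    bp_type_counts = {"AU": 0, "GC": 0, "GU": 0}
    for i in opening:
        j = pairs[i]
        key = "".join(sorted((seq[i], seq[j])))
        if key == "AU":
            bp_type_counts["AU"] += 1
        elif key == "CG":
            bp_type_counts["GC"] += 1
        elif key == "GU":
            bp_type_counts["GU"] += 1
        # non-canonical pairs (possible in user-supplied structures) are
        # counted in n_bp but not in the per-type tallies

    # stems: maximal runs of directly stacked pairs (i,j),(i+1,j-1),...
    n_stems = 0
    opening_set = set(opening)
    for i in opening:
        j = pairs[i]
        if (i - 1) in opening_set and pairs[i - 1] == j + 1:
            continue  # continuation of the stem opened further out
        n_stems += 1

    # loop tree: each pair whose interior is not a single stacked pair
    # closes a loop
    n_loops = 0
    internal_loop_total = 0
    for i in opening:
        j = pairs[i]
        if (i + 1) in pairs and pairs[i + 1] == j - 1:
            continue  # stacked pair, interior of a stem
        children: list[tuple[int, int]] = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in pairs:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                unpaired += 1
                k += 1
        n_loops += 1
        if len(children) == 1 and unpaired >= 1:
            internal_loop_total += unpaired

    return StructureStats(
        n_bp=n_bp,
        n_stems=n_stems,
        n_loops=n_loops,
        internal_loop_total=internal_loop_total,
        bp_type_counts=bp_type_counts,
        pairings_per_len=n_bp / len(structure) if structure else 0.0,
    )


class FoldingBackend:
    """Contract: deterministic single-structure MFE folding."""

    name: str = "abstract"
    supports_ensemble: bool = False

    def fold(self, seq: str) -> FoldResult:
        raise NotImplementedError

    def ensemble_stats(self, seq: str) -> dict:
        raise FoldingError(
            f"backend {self.name!r} has no partition function; "
            "ensemble (tier B) features need the 'vienna' backend"
        )

    def _check(self, seq: str) -> None:
        if "N" in seq:
            raise FoldingError("cannot fold a sequence containing N")
        if len(seq) < 10:
            raise FoldingError("sequence too short to fold (< 10 nt)")
        bad = set(seq) - {"A", "C", "G", "U"}
        if bad:
            raise FoldingError(f"non-RNA characters: {sorted(bad)}")


class ViennaBackend(FoldingBackend):
    """ViennaRNA MFE folding (thermodynamic model)."""

    name = "vienna"
    supports_ensemble = True

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - present in CI image
            raise FoldingError(
                "ViennaRNA Python bindings not importable; "
                "select the 'nussinov' fallback backend"
            ) from exc
        self._rna = __import__("RNA")

    def fold(self, seq: str) -> FoldResult:
        self._check(seq)
        structure, mfe = self._rna.fold(seq)
        if "(" not in structure:
            mfe = 0.0
        return FoldResult(seq=seq, structure=structure, mfe=float(mfe))

    def ensemble_stats(self, seq: str) -> dict:
        """Partition-function quantities for tier-B features."""
        import math

        self._check(seq)
        RNA = self._rna
        fc = RNA.fold_compound(seq)
        structure, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        _, dg_ensemble = fc.pf()
        params = fc.exp_params
        if callable(params):  # binding-version tolerance
            params = params()
        kT = params.kT / 1000.0  # kcal/mol
        mfe_freq = math.exp((dg_ensemble - mfe) / kT)
        diversity = fc.mean_bp_distance()
        # positional Shannon entropy of the pair-probability matrix
        n = len(seq)
        bpp = fc.bpp()
        p_pair = [0.0] * (n + 1)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                p = bpp[i][j]
                p_pair[i] += p
                p_pair[j] += p
        entropy = 0.0
        for i in range(1, n + 1):
            for p in (p_pair[i], 1.0 - p_pair[i]):
                if p > 1e-12:
                    entropy -= p * math.log2(p)
        return {
            "dg_ensemble": float(dg_ensemble),
            "mfe_structure_freq": float(min(mfe_freq, 1.0)),
            "ensemble_diversity": float(diversity),
            "positional_entropy": entropy / n,
        }


class NussinovBackend(FoldingBackend):
    """Maximum base-pairing fallback folder (no thermodynamics).

    Energy proxy: -1 per pair, so mfe/L equals -(pairing density).
    Deterministic: the traceback prefers leaving position i unpaired only
    when pairing cannot increase the count, and pairs i with the smallest
    admissible partner k maximising the objective.
    """

    name = "nussinov"
    supports_ensemble = False

    def fold(self, seq: str) -> FoldResult:
        self._check(seq)
        structure = _nussinov_structure(seq)
        n_bp = structure.count("(")
        return FoldResult(seq=seq, structure=structure, mfe=float(-n_bp))


@lru_cache(maxsize=4096)
def _nussinov_structure(seq: str) -> str:
    n = len(seq)
    # dp[i][j] = max pairs in seq[i..j]
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if (seq[i], seq[k]) in PAIRABLE:
                    inner = dp[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            dp[i][j] = best
    structure = ["."] * n
    stack: list[tuple[int, int]] = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_HAIRPIN_LOOP:
            continue
        if dp[i][j] == dp[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in PAIRABLE:
                inner = dp[i + 1][k - 1] if k - 1 > i + 1 else 0
                right = dp[k + 1][j] if k + 1 <= j else 0
                if dp[i][j] == 1 + inner + right:
                    structure[i] = "("
                    structure[k] = ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    return "".join(structure)


_BACKENDS = {"vienna": ViennaBackend, "nussinov": NussinovBackend}


def get_backend(name: str = "vienna") -> FoldingBackend:
    """Instantiate a folding backend by tag name."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise FoldingError(
            f"unknown folding backend {name!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return cls()


def read_structures(path) -> Iterator[tuple[str, FoldResult]]:
    """Read precomputed structures as 3-line records: id / sequence / structure.

    The structure line may carry a trailing free energy in parentheses
    (RNAfold output style); absent that, the pairing count proxy is used.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3:
        raise StructureError("structure file must hold 3-line records")
    for k in range(0, len(lines), 3):
        ident = lines[k].lstrip(">")
        seq = lines[k + 1].upper().replace("T", "U")
        parts = lines[k + 2].split(None, 1)
        struct = parts[0]
        if len(parts) == 2:  # trailing "(-8.70)" energy annotation
            mfe = float(parts[1].strip().strip("()"))
        else:
            mfe = float(-struct.count("("))
        yield ident, FoldResult(seq=seq, structure=struct, mfe=mfe)
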