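"""Global protein alignment with affine gaps (Needleman-Wunsch/Gotoh).

The aligner is the workhorse behind globin classification, fold-position
mapping and percent-identity phenetics.  Scoring model: a substitution
matrix (BLOSUM62 by default) plus affine gap penalties where a gap of
length k costs ``gap_open + (k - 1) * gap_extend``.  End gaps are
penalized (true global alignment).

Two code paths share one scoring model:

* :func:`global_align` - a NumPy Gotoh implementation with a deterministic
  traceback (diagonal preferred over up, up over left) that returns the
  full alignment.
* :func:`align_score` - score-only evaluation delegated to Biopython's
  C ``PairwiseAligner`` configured with identical parameters, used where
  only the optimal score is needed (e.g. permutation null distributions).
  Tests assert that both paths produce identical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align as _bio_align
from Bio.Align import substitution_matrices as _submat

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_NEG = -1e30  # effectively -inf but arithmetic-safe


@dataclass(frozen=True)
class AlignParams:
    """Substitution matrix name and affine gap penalties (positive costs)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def substitution_matrix(self):
        return _load_matrix(self.matrix)


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return _submat.load(name)


@lru_cache(maxsize=8)
def _matrix_as_dense(name: str):
    """Return (alphabet string, dense ndarray) for fast indexing."""
    mat = _load_matrix(name)
    alphabet = str(mat.alphabet)
    dense = np.asarray(mat, dtype=float)
    lookup = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lookup[ord(ch)] = i
    return dense, lookup


@lru_cache(maxsize=8)
def _pairwise_aligner(params: AlignParams):
    aligner = _bio_align.PairwiseAligner()
    aligner.substitution_matrix = _load_matrix(params.matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


@dataclass
class Alignment:
    """A global pairwise alignment.

    ``pairs`` holds 1-based (index_a, index_b) tuples for columns where both
    sequences carry a residue; gapped columns are absent from ``pairs`` but
    present in the gapped strings.
    """

    a: str
    b: str
    score: float
    aligned_a: str
    aligned_b: str
    pairs: list = field(repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )

    def identity_pct(self, denominator: str = "aligned") -> float:
        """Percent identity.

        denominator="aligned": columns where both rows are non-gap (default).
        denominator="shorter": length of the shorter input sequence.
        """
        ident = self.n_identical
        if denominator == "aligned":
            den = len(self.pairs)
        elif denominator == "shorter":
            den = min(len(self.a), len(self.b))
        else:
            raise ValueError(f"unknown identity denominator: {denominator!r}")
        if den == 0:
            raise ValueError("empty alignment: no aligned residue columns")
        return 100.0 * ident / den

    def query_index_for_ref(self, ref_index: int):
        """1-based index in ``a`` aligned to 1-based ``ref_index`` in ``b``.

        Returns None when the reference column is aligned to a gap.
        """
        if not 1 <= ref_index <= len(self.b):
            raise IndexError(
                f"reference index {ref_index} outside 1..{len(self.b)}"
            )
        for ia, ib in self.pairs:
            if ib == ref_index:
                return ia
        return None


def _validate_protein(seq: str, who: str) -> None:
    if not seq:
        raise ValueError(f"empty sequence for {who}")
    for pos, ch in enumerate(seq, start=1):
        if ch not in AA_ALPHABET and ch != "X":
            raise ValueError(
                f"non-standard residue {ch!r} at position {pos} in {who}"
            )


def align_score(a: str, b: str, params: AlignParams = AlignParams()) -> float:
    """Optimal global alignment score only (fast C path)."""
    _validate_protein(a, "sequence a")
    _validate_protein(b, "sequence b")
    return float(_pairwise_aligner(params).score(a, b))


def gotoh_dp(sub: np.ndarray, go: float, ge: float) -> tuple:
    """Gotoh DP on a precomputed (n, m) column-score matrix.

    Returns ``(score, moves)`` where moves is the optimal path from the
    origin as a string over {M, X, Y}: M consumes one row and one column,
    X one row only ("up", gap in the column sequence), Y one column only
    ("left").  Ties are broken diagonal > up > left, and within a gap
    state by preferring the M predecessor, so the path is deterministic.
    """
    n, m = sub.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = -(go + np.arange(n) * ge)
    if m:
        Y[0, 1:] = -(go + np.arange(m) * ge)

    jj = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        h_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = sub[i - 1] + h_prev[:-1]
        X[i] = np.maximum(
            np.maximum(M[i - 1], Y[i - 1]) - go, X[i - 1] - ge
        )
        # Y[i, j] = max_{k<j} max(M[i,k], X[i,k]) - go - (j-1-k)*ge
        opener = np.maximum(M[i], X[i]) + jj * ge
        run = np.maximum.accumulate(opener[:-1])
        Y[i, 1:] = run - go - (jj[1:] - 1.0) * ge
        Y[i, 0] = _NEG

    # deterministic traceback
    moves: list = []
    i, j = n, m
    finals = (M[i, j], X[i, j], Y[i, j])
    score = max(finals)
    state = [k for k, f in enumerate(finals) if f == score][0]  # M > X > Y
    while i > 0 or j > 0:
        if state == 0:  # M: consumed row i-1 vs column j-1
            moves.append("M")
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand, val in ((0, M[i, j]), (1, X[i, j]), (2, Y[i, j])):
                if abs(val - target) < 1e-6:
                    state = cand
                    break
        elif state == 1:  # X: consumed row i-1 over gap
            moves.append("X")
            opened = X[i, j] + go
            extended = X[i, j] + ge
            i -= 1
            if abs(M[i, j] - opened) < 1e-6:
                state = 0
            elif abs(X[i, j] - extended) < 1e-6:
                state = 1
            else:
                state = 2
        else:  # Y: consumed column j-1 over gap
            moves.append("Y")
            opened = Y[i, j] + go
            extended = Y[i, j] + ge
            j -= 1
            if abs(M[i, j] - opened) < 1e-6:
                state = 0
            elif abs(X[i, j] - opened) < 1e-6:
                state = 1
            else:
                state = 2
    moves.reverse()
    return float(score), "".join(moves)


def global_align(a: str, b: str, params: AlignParams = AlignParams()) -> Alignment:
    """Optimal global affine-gap alignment with deterministic traceback.

    Three-state Gotoh recursion (see :func:`gotoh_dp`); ties broken
    diagonal > up > left so the returned alignment is unique.
    """
    _validate_protein(a, "sequence a")
    _validate_protein(b, "sequence b")
    dense, lookup = _matrix_as_dense(params.matrix)
    ai = lookup[np.frombuffer(a.encode(), dtype=np.uint8)]
    bi = lookup[np.frombuffer(b.encode(), dtype=np.uint8)]
    if (ai < 0).any() or (bi < 0).any():
        raise ValueError("residue absent from substitution matrix")
    sub = dense[np.ix_(ai, bi)]  # (n, m)
    score, moves = gotoh_dp(sub, params.gap_open, params.gap_extend)

    out_a: list = []
    out_b: list = []
    pairs: list = []
    i = j = 0
    for mv in moves:
        if mv == "M":
            out_a.append(a[i])
            out_b.append(b[j])
            pairs.append((i + 1, j + 1))
            i += 1
            j += 1
        elif mv == "X":
            out_a.append(a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(b[j])
            j += 1
    return Alignment(
        a=a,
        b=b,
        score=score,
        aligned_a="".join(out_a),
        aligned_b="".join(out_b),
        pairs=pairs,
    )
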