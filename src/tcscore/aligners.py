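"""Built-in deterministic MSA backends for the proxy-library mode.

Each backend is a progressive aligner: pairwise identity distances feed a
neighbor-joining guide tree (Bio.Phylo), profiles are merged bottom-up with
a global affine-gap (Gotoh) profile-profile alignment.  Three shipped
settings differ in substitution matrix and gap penalties, so their MSAs
disagree exactly where the alignment is genuinely ambiguous — which is what
the consensus library measures.  External aligners can be plugged in as any
callable ``backend(names, ungapped_seqs) -> Alignment``.
"""

from __future__ import annotations

from typing import Sequence as Seq

import numpy as np
from numba import njit

from .alignment import Alignment

_MATRIX_CACHE: dict[str, tuple[dict[str, int], np.ndarray]] = {}


def _load_matrix(name: str) -> tuple[dict[str, int], np.ndarray]:
    if name not in _MATRIX_CACHE:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load(name)
        letters = "".join(mat.alphabet)
        arr = np.asarray(mat, dtype=np.float64)
        _MATRIX_CACHE[name] = ({c: i for i, c in enumerate(letters)}, arr)
    return _MATRIX_CACHE[name]


@njit(cache=True)
def _gotoh(score, gap_open, gap_extend):
    """Global affine alignment over a precomputed column-score matrix.

    Returns pointer matrices and the final best state for traceback.
    States: 0 = match, 1 = gap in second profile (consume row), 2 = gap in
    first profile (consume column).  Ties break deterministically 0 > 1 > 2.
    """
    n, m = score.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        ptr_x[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        ptr_y[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best, arg = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, arg = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, arg = Y[i - 1, j - 1], 2
            M[i, j] = best + score[i - 1, j - 1]
            ptr_m[i, j] = arg
            a = M[i - 1, j] + gap_open
            b = X[i - 1, j] + gap_extend
            if a >= b:
                X[i, j] = a
                ptr_x[i, j] = 0
            else:
                X[i, j] = b
                ptr_x[i, j] = 1
            a = M[i, j - 1] + gap_open
            b = Y[i, j - 1] + gap_extend
            if a >= b:
                Y[i, j] = a
                ptr_y[i, j] = 0
            else:
                Y[i, j] = b
                ptr_y[i, j] = 2
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best, state = X[n, m], 1
    if Y[n, m] > best:
        best, state = Y[n, m], 2
    return ptr_m, ptr_x, ptr_y, state, best


def _traceback(ptr_m, ptr_x, ptr_y, state, n, m):
    """Recover the merge path as (consume_row, consume_col) steps."""
    path = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            path.append((True, True))
            state = ptr_m[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            path.append((True, False))
            state = ptr_x[i, j]
            i -= 1
        else:
            path.append((False, True))
            state = ptr_y[i, j]
            j -= 1
    path.reverse()
    return path


class ProgressiveAligner:
    """Deterministic progressive MSA over an NJ guide tree.

    Parameters
    ----------
    matrix:
        Name of a Biopython substitution matrix (e.g. ``BLOSUM62``).
    gap_open, gap_extend:
        Affine penalties (negative).
    """

    def __init__(self, matrix: str = "BLOSUM62", gap_open: float = -11.0,
                 gap_extend: float = -1.0) -> None:
        self.matrix_name = matrix
        self.gap_open = float(gap_open)
        self.gap_extend = float(gap_extend)

    def __repr__(self) -> str:
        return (f"ProgressiveAligner({self.matrix_name}, "
                f"{self.gap_open}/{self.gap_extend})")

    # -- profiles ----------------------------------------------------------
    def _profile(self, rows: list[str]) -> np.ndarray:
        index, arr = _load_matrix(self.matrix_name)
        k = arr.shape[0]
        wildcard = index.get("X", index.get("N", 0))
        L = len(rows[0])
        prof = np.zeros((L, k))
        for row in rows:
            for i, ch in enumerate(row):
                if ch != "-":
                    prof[i, index.get(ch, wildcard)] += 1.0
        return prof / len(rows)

    def _merge(self, rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
        _index, arr = _load_matrix(self.matrix_name)
        fa = self._profile(rows_a)
        fb = self._profile(rows_b)
        score = fa @ arr @ fb.T
        ptr_m, ptr_x, ptr_y, state, _ = _gotoh(score, self.gap_open,
                                               self.gap_extend)
        path = _traceback(ptr_m, ptr_x, ptr_y, state, len(fa), len(fb))
        out_a = ["" for _ in rows_a]
        out_b = ["" for _ in rows_b]
        i = j = 0
        for take_a, take_b in path:
            for r, row in enumerate(rows_a):
                out_a[r] += row[i] if take_a else "-"
            for r, row in enumerate(rows_b):
                out_b[r] += row[j] if take_b else "-"
            i += take_a
            j += take_b
        return out_a, out_b

    # -- guide tree --------------------------------------------------------
    def _pairwise_identity(self, a: str, b: str) -> float:
        (ra,), (rb,) = self._merge([a], [b])
        matches = sum(x == y and x != "-" for x, y in zip(ra, rb))
        return matches / max(1, len(ra))

    def _merge_order(self, names: Seq[str], seqs: Seq[str]) -> list[tuple[int, int]]:
        """Pairs of cluster indices to merge, from an NJ guide tree."""
        n = len(seqs)
        if n == 2:
            return [(0, 1)]
        from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

        lower = [[1.0 - self._pairwise_identity(seqs[i], seqs[j])
                  for j in range(i)] + [0.0] for i in range(n)]
        # DistanceMatrix requires unique names; use positional labels
        labels = [f"s{i}" for i in range(n)]
        tree = DistanceTreeConstructor().nj(DistanceMatrix(labels, lower))
        order: list[tuple[int, int]] = []
        cluster_of: dict = {}
        next_cluster = n

        def resolve(clade) -> int:
            nonlocal next_cluster
            if clade.is_terminal():
                return int(clade.name[1:])
            children = [resolve(ch) for ch in clade.clades]
            cur = children[0]
            for other in children[1:]:
                order.append((cur, other))
                cur = next_cluster
                next_cluster += 1
            return cur

        resolve(tree.root)
        return order

    # -- entry point -------------------------------------------------------
    def __call__(self, names: Seq[str], seqs: Seq[str]) -> Alignment:
        seqs = [s.upper() for s in seqs]
        if len(seqs) < 2:
            raise ValueError("need at least two sequences")
        clusters: dict[int, tuple[list[int], list[str]]] = {
            i: ([i], [s]) for i, s in enumerate(seqs)}
        next_id = len(seqs)
        for a, b in self._merge_order(names, seqs):
            ids_a, rows_a = clusters.pop(a)
            ids_b, rows_b = clusters.pop(b)
            out_a, out_b = self._merge(rows_a, rows_b)
            clusters[next_id] = (ids_a + ids_b, out_a + out_b)
            next_id += 1
        (ids, rows), = clusters.values()
        ordered = [rows[ids.index(i)] for i in range(len(seqs))]
        return Alignment(list(names), ordered)


def builtin_backends(alphabet: str = "protein") -> list[ProgressiveAligner]:
    """The three shipped proxy-MSA backends (distinct matrix/penalty settings)."""
    if alphabet == "nucleotide":
        return [ProgressiveAligner("NUC.4.4", -10.0, -1.0),
                ProgressiveAligner("NUC.4.4", -16.0, -4.0),
                ProgressiveAligner("NUC.4.4", -6.0, -2.0)]
    return [ProgressiveAligner("BLOSUM62", -11.0, -1.0),
            ProgressiveAligner("BLOSUM45", -13.0, -2.0),
            ProgressiveAligner("PAM250", -14.0, -2.0)]
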