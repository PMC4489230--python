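"""Transitive consistency scoring.

The score of one aligned residue pair (x_i, y_j) measures how strongly the
residue-pair library supports placing the two residues in the same column.
Support flows through intermediates: a residue z_k of a third sequence with
library links to both x_i and y_j forms a triplet whose contribution is the
lower of its two link weights.  The direct (x_i, y_j) entry, when present,
contributes its own weight.  The normaliser accumulates, for the same
intermediates, the larger of the two link weights, plus the full weight of
every unmatched link of x_i or y_j (including links to other positions of
the partner sequence).  The ratio lies in [0, 1], equals 1 exactly when
every link of both residues agrees, and shrinks whenever either residue
carries conflicting evidence.  A residue pair with no library support at
all scores 0.

Residue, column, sequence and whole-alignment scores are plain averages of
pair scores (per column neighbour, per column, per sequence, over all
residues).  Display, filtering, column duplication and replicate weighting
use the integer projection ``scale_to_0_9``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, column_residue_table
from .errors import TcsError
from .library import Library, Residue

PairKey = tuple[Residue, Residue]


def scale_to_0_9(score: float) -> int:
    """Project a [0, 1] score onto the 0-9 display/filter scale.

    ``min(9, floor(10 * s))``, with a 1e-9 guard so exact decimals stored as
    binary floats land in their intended bin (0.7 -> 7, 0.39999 -> 3).
    """
    if not 0.0 <= score <= 1.0:
        raise TcsError(f"score {score!r} outside [0, 1]")
    return min(9, int(score * 10.0 + 1e-9))


def pair_tcs(lib: Library, x: int, i: int, y: int, j: int) -> float:
    """Transitive consistency of the aligned residue pair (x_i, y_j).

    Coordinates are (sequence index, 1-based ungapped position); ``x != y``.
    Returns 0 when neither residue has any library support.
    """
    if x == y:
        raise TcsError("pair score requires residues from two sequences")
    for s, p in ((x, i), (y, j)):
        if not (0 <= s < len(lib.sequences) and 1 <= p <= len(lib.sequences[s])):
            raise TcsError(f"residue coordinate ({s}, {p}) outside the MSA")
    nx = lib.neighbors(x, i)
    ny = lib.neighbors(y, j)
    direct = nx.get((y, j), 0.0)
    num = direct
    den = direct
    for k, wx in nx.items():
        ks = k[0]
        if ks == y:
            if k[1] != j:  # link to a conflicting position of y
                den += wx
            continue
        if ks == x:
            den += wx
            continue
        wy = ny.get(k, 0.0)
        num += min(wx, wy)
        den += max(wx, wy)
    for k, wy in ny.items():
        ks = k[0]
        if ks == x:
            if k[1] != i:
                den += wy
            continue
        if ks == y:
            den += wy
            continue
        if k not in nx:
            den += wy
    return num / den if den > 0.0 else 0.0


@dataclass
class TcsScores:
    """Score bundle for one target MSA.

    ``pair_scores`` maps canonical ((x, i), (y, j)) keys (x < y) of residue
    pairs actually aligned in the MSA to their score; ``None`` when pair
    retention was disabled.  ``residue_scores`` is keyed by (sequence index,
    1-based ungapped position); gapped cells carry no entry.  Column and
    sequence scores are dense arrays; ``alignment_score`` is the mean over
    all residues (authoritative even when sequences differ in length).
    """

    pair_scores: dict[PairKey, float] | None
    pair_columns: dict[PairKey, int] | None
    residue_scores: dict[Residue, float]
    column_scores: np.ndarray
    sequence_scores: np.ndarray
    alignment_score: float

    def scaled_column_scores(self) -> np.ndarray:
        return np.array([scale_to_0_9(s) for s in self.column_scores])

    def scaled_residue_digit(self, seq: int, pos: int) -> int:
        return scale_to_0_9(self.residue_scores[(seq, pos)])


def residue_tcs(pair_scores: dict[PairKey, float], aln: Alignment,
                x: int, i: int) -> float:
    """Mean pair score of residue (x, i) against its column co-residues."""
    positions = aln.residue_positions(x)
    try:
        col = positions.index(i)
    except ValueError:
        raise TcsError(f"residue {i} of sequence {x} not found") from None
    if aln.rows[x][col] == "-":
        raise TcsError("gap coordinates carry no residue score")
    total, count = 0.0, 0
    for y, j in column_residue_table(aln)[col]:
        if y == x:
            continue
        key = ((x, i), (y, j)) if x < y else ((y, j), (x, i))
        total += pair_scores[key]
        count += 1
    return total / count if count else 0.0


def column_tcs(pair_scores: dict[PairKey, float], aln: Alignment,
               col: int) -> float:
    """Mean pair score over the unordered residue pairs of 1-based column."""
    if not 1 <= col <= aln.length:
        raise TcsError(f"column {col} outside [1, {aln.length}]")
    residues = column_residue_table(aln)[col - 1]
    pairs = list(itertools.combinations(residues, 2))
    if not pairs:
        return 0.0
    return sum(pair_scores[p] for p in pairs) / len(pairs)


def compute_scores(aln: Alignment, lib: Library,
                   keep_pairs: bool = True) -> TcsScores:
    """Score every aligned residue pair of the MSA and derive all averages.

    Only pairs actually aligned in the target MSA are scored.  With
    ``keep_pairs=False`` the (potentially large) pair map is discarded after
    the averages are computed; pair-level reports then become unavailable.
    """
    if list(lib.names) != list(aln.names):
        raise TcsError("library was built over a different sequence set")
    table = column_residue_table(aln)
    pair_scores: dict[PairKey, float] = {}
    pair_columns: dict[PairKey, int] = {}
    res_sum: dict[Residue, float] = {}
    res_cnt: dict[Residue, int] = {}
    column_scores = np.zeros(aln.length)
    for c, residues in enumerate(table):
        col_sum, col_cnt = 0.0, 0
        for (x, i), (y, j) in itertools.combinations(residues, 2):
            s = pair_tcs(lib, x, i, y, j)
            key: PairKey = ((x, i), (y, j))
            pair_scores[key] = s
            pair_columns[key] = c + 1
            col_sum += s
            col_cnt += 1
            for r in ((x, i), (y, j)):
                res_sum[r] = res_sum.get(r, 0.0) + s
                res_cnt[r] = res_cnt.get(r, 0) + 1
        column_scores[c] = col_sum / col_cnt if col_cnt else 0.0
        for r in residues:  # singleton residues score 0 but still count
            res_sum.setdefault(r, 0.0)
            res_cnt.setdefault(r, 0)
    residue_scores = {r: (res_sum[r] / res_cnt[r] if res_cnt[r] else 0.0)
                      for r in res_sum}
    sequence_scores = np.zeros(aln.n)
    for s in range(aln.n):
        vals = [v for (seq, _pos), v in residue_scores.items() if seq == s]
        sequence_scores[s] = float(np.mean(vals)) if vals else 0.0
    all_vals = list(residue_scores.values())
    alignment_score = float(np.mean(all_vals)) if all_vals else 0.0
    return TcsScores(
        pair_scores=pair_scores if keep_pairs else None,
        pair_columns=pair_columns if keep_pairs else None,
        residue_scores=residue_scores,
        column_scores=column_scores,
        sequence_scores=sequence_scores,
        alignment_score=alignment_score)


def sequence_tcs(scores: TcsScores, seq: int) -> float:
    return float(scores.sequence_scores[seq])


def alignment_tcs(scores: TcsScores) -> float:
    return scores.alignment_score
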