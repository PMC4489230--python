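"""Score-driven alignment post-processing.

Four transformations, all driven by the 0-9 scaled scores:

* column filtering — drop (or blank) columns scoring below a threshold
  (default 4, the server default);
* residue masking — gap individual low-scoring residues instead, preserving
  row synchrony, then drop columns left empty;
* column duplication — emit each column as many times as its scaled score
  ("tcs_weighted"), an up-weighting usable by tree programs;
* weighted bootstrap replicates — resample L columns i.i.d. with
  probability proportional to the scaled column score, ``count`` times
  (default 100), deterministically from a seed.

Sequence names and order are preserved throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, Alignment
from .errors import EmptyAlignmentError, TcsError
from .tcs import TcsScores, scale_to_0_9

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Filtering parameters; defaults mirror the server defaults."""

    mode: str = "column"  # or "residue"
    threshold: int = 4
    keep_empty_columns: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("column", "residue"):
            raise TcsError(f"unknown filter mode {self.mode!r}")
        if not 0 <= int(self.threshold) <= 9:
            raise TcsError("filter threshold must lie in [0, 9]")
        self.threshold = int(self.threshold)


@dataclass
class ReplicateSet:
    """Bootstrap replicates plus the metadata needed to regenerate them."""

    replicates: list[Alignment]
    seed: int
    weights: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self):
        return iter(self.replicates)


def _take_columns(aln: Alignment, cols: list[int]) -> Alignment:
    rows = ["".join(row[c] for c in cols) for row in aln.rows]
    return Alignment(aln.names, rows, aln.alphabet)


def filter_columns(aln: Alignment, scores: TcsScores,
                   cfg: FilterConfig | None = None) -> Alignment:
    """Remove columns whose scaled column score falls below the threshold.

    With ``keep_empty_columns`` the removed columns are blanked to all-gap
    instead, so column coordinates are preserved.
    """
    cfg = cfg or FilterConfig()
    if cfg.mode != "column":
        raise TcsError("filter_columns requires mode='column'")
    scaled = scores.scaled_column_scores()
    keep = [c for c in range(aln.length) if scaled[c] >= cfg.threshold]
    if cfg.keep_empty_columns:
        keep_set = set(keep)
        rows = ["".join(ch if c in keep_set else GAP
                        for c, ch in enumerate(row)) for row in aln.rows]
        return Alignment(aln.names, rows, aln.alphabet)
    if not keep:
        logger.warning("filtering removed every column (threshold %d)",
                       cfg.threshold)
        raise EmptyAlignmentError(
            "all columns fall below the threshold; rerun with a lower "
            "threshold or keep_empty_columns")
    return _take_columns(aln, keep)


def mask_residues(aln: Alignment, scores: TcsScores,
                  cfg: FilterConfig | None = None) -> Alignment:
    """Gap residues whose scaled residue score falls below the threshold.

    Masking replaces the residue with a gap (rows stay synchronised);
    columns left entirely gapped are then removed unless
    ``keep_empty_columns``.
    """
    cfg = cfg or FilterConfig(mode="residue")
    if cfg.mode != "residue":
        raise TcsError("mask_residues requires mode='residue'")
    rows = []
    for s, row in enumerate(aln.rows):
        out, pos = [], 0
        for ch in row:
            if ch == GAP:
                out.append(GAP)
                continue
            pos += 1
            digit = scale_to_0_9(scores.residue_scores[(s, pos)])
            out.append(ch if digit >= cfg.threshold else GAP)
        rows.append("".join(out))
    masked = Alignment(aln.names, rows, aln.alphabet)
    if cfg.keep_empty_columns:
        return masked
    keep = [c for c in range(masked.length)
            if any(row[c] != GAP for row in masked.rows)]
    if not keep:
        raise EmptyAlignmentError("masking removed every residue")
    return _take_columns(masked, keep)


def weighted_alignment(aln: Alignment, scores: TcsScores) -> Alignment:
    """Duplicate each column scaled-score times (0 drops the column)."""
    scaled = scores.scaled_column_scores()
    cols: list[int] = []
    for c in range(aln.length):
        cols.extend([c] * int(scaled[c]))
    if not cols:
        raise EmptyAlignmentError("every column scales to 0; nothing to weight")
    return _take_columns(aln, cols)


def bootstrap_replicates(aln: Alignment, scores: TcsScores,
                         count: int = 100, seed: int = 0,
                         raw_weights: bool = False) -> ReplicateSet:
    """Column-resampled replicates weighted by scaled column scores.

    Each replicate draws L columns i.i.d. with replacement with probability
    proportional to the scaled (0-9) column score — or the raw [0, 1] score
    with ``raw_weights``.  Bit-identical given the same seed.
    """
    if count < 1:
        raise TcsError("replicate count must be positive")
    weights = (np.asarray(scores.column_scores, dtype=float) if raw_weights
               else scores.scaled_column_scores().astype(float))
    total = weights.sum()
    if total <= 0:
        raise EmptyAlignmentError("all column weights are zero")
    p = weights / total
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(count):
        cols = rng.choice(aln.length, size=aln.length, replace=True, p=p)
        replicates.append(_take_columns(aln, [int(c) for c in cols]))
    return ReplicateSet(replicates=replicates, seed=seed, weights=weights)
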