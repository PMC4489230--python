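"""Synthetic protein families with known homology.

``simulate_family`` mutates a random ancestor independently along a star
tree: every sequence is an independently substituted/indel-edited copy of
the same ancestor, so column homology of the true alignment is known by
construction.  This is deliberately simpler than a real phylogeny — tests
need ground-truth homology, not realistic evolution; rate heterogeneity,
tree shape and realistic indel length distributions are out of scope.

``corrupt_alignment`` destroys homology inside a column window by cyclically
rotating each row's window content by a random per-row offset, leaving
composition untouched — a controlled "misaligned region" for testing that
low consistency scores track misalignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import GAP, Alignment
from .errors import TcsError
from .hmm import _PROTEIN_BG, PROTEIN_ALPHABET

_AA = PROTEIN_ALPHABET[:20]


@dataclass
class FamilySpec:
    """Parameters of one simulated family.

    substitution_rate / indel_rate are per-site event probabilities in
    [0, 1]; indel lengths are geometric with mean ``indel_mean_length``.
    """

    n_sequences: int = 8
    ancestor_length: int = 120
    substitution_rate: float = 0.1
    indel_rate: float = 0.02
    indel_mean_length: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise TcsError("a family needs at least 2 sequences")
        if self.ancestor_length < 1:
            raise TcsError("ancestor length must be positive")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise TcsError("rates must lie in [0, 1]")
        if self.indel_mean_length < 1.0:
            raise TcsError("mean indel length must be >= 1")


def _draw_indel_length(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(1.0 / mean))


def simulate_family(spec: FamilySpec) -> tuple[Alignment, list[str]]:
    """Generate one family; returns (true alignment, ungapped sequences).

    Deterministic given ``spec.seed``.  With zero rates all sequences equal
    the ancestor and the true alignment is gapless.
    """
    rng = np.random.default_rng(spec.seed)
    bg = _PROTEIN_BG / _PROTEIN_BG.sum()
    ancestor = "".join(rng.choice(list(_AA), size=spec.ancestor_length, p=bg))
    n, A = spec.n_sequences, spec.ancestor_length
    # per sequence: site -> residue or None (deleted); insertions[slot] with
    # slot s meaning "before ancestral site s" (slot A = after the last).
    residues: list[list[str | None]] = []
    insertions: list[dict[int, str]] = []
    for _ in range(n):
        row: list[str | None] = []
        ins: dict[int, str] = {}
        for s in range(A):
            ch = ancestor[s]
            if rng.random() < spec.substitution_rate:
                others = [a for a in _AA if a != ch]
                ch = others[int(rng.integers(len(others)))]
            if rng.random() < spec.indel_rate / 2.0:
                row.append(None)  # deletion
            else:
                row.append(ch)
            if rng.random() < spec.indel_rate / 2.0:
                length = _draw_indel_length(rng, spec.indel_mean_length)
                ins[s + 1] = "".join(
                    rng.choice(list(_AA), size=length, p=bg))
        residues.append(row)
        insertions.append(ins)
    # assemble true alignment columns: insertions are sequence-private
    rows = ["" for _ in range(n)]
    for slot in range(A + 1):
        for r in range(n):
            frag = insertions[r].get(slot, "")
            for ch in frag:
                for r2 in range(n):
                    rows[r2] += ch if r2 == r else GAP
        if slot < A:
            for r2 in range(n):
                ch = residues[r2][slot]
                rows[r2] += ch if ch is not None else GAP
    names = [f"seq{r + 1}" for r in range(n)]
    keep = [c for c in range(len(rows[0]))
            if any(row[c] != GAP for row in rows)]
    rows = ["".join(row[c] for c in keep) for row in rows]
    # guard against a fully deleted sequence at extreme rates
    for r, row in enumerate(rows):
        if set(row) == {GAP}:
            raise TcsError(f"sequence {names[r]} lost every residue; "
                           "lower the indel rate")
    aln = Alignment(names, rows, "protein")
    return aln, [aln.ungapped(i) for i in range(n)]


def corrupt_alignment(aln: Alignment, window: tuple[int, int],
                      seed: int = 0) -> Alignment:
    """Rotate each row's content inside 1-based column window [lo, hi].

    Per-row random cyclic shifts destroy cross-sequence homology inside the
    window while preserving each row's content.  An empty window (hi < lo)
    returns the alignment unchanged.
    """
    lo, hi = window
    if hi < lo:
        return aln
    if not (1 <= lo and hi <= aln.length):
        raise TcsError(f"window {window} outside [1, {aln.length}]")
    rng = np.random.default_rng(seed)
    rows = []
    for row in aln.rows:
        chunk = row[lo - 1 : hi]
        shift = int(rng.integers(1, len(chunk))) if len(chunk) > 1 else 0
        rotated = chunk[shift:] + chunk[:shift]
        rows.append(row[: lo - 1] + rotated + row[hi:])
    return Alignment(aln.names, rows, aln.alphabet)
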