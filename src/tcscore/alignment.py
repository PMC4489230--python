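"""In-memory alignment containers.

An :class:`Alignment` is an ordered set of equal-length gapped rows.  Columns
are 1-based in user-facing coordinates; residue positions are 1-based indices
into the ungapped sequence — the convention used by every report and by the
residue-pair library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import MalformedAlignmentError

GAP = "-"

_NUC_CHARS = set("ACGTUN-")


@dataclass(frozen=True)
class Sequence:
    """A named sequence; residues may or may not contain gap characters."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.name:
            raise MalformedAlignmentError("sequence name must be non-empty")
        if not self.residues:
            raise MalformedAlignmentError(f"sequence {self.name!r} is empty")

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


def detect_alphabet(rows: Iterable[str]) -> str:
    """Classify rows as 'nucleotide' or 'protein' by symbol content."""
    chars = set()
    for row in rows:
        chars.update(row)
    return "nucleotide" if chars <= _NUC_CHARS else "protein"


class Alignment:
    """A multiple sequence alignment of N >= 2 equal-length rows.

    Parameters
    ----------
    names:
        Unique, non-empty sequence identifiers, in display order.
    rows:
        Gapped sequences, all of identical length >= 1, uppercase,
        '-' as the only gap character.
    alphabet:
        'protein' or 'nucleotide'; sniffed from content when omitted.
    """

    def __init__(self, names: Iterable[str], rows: Iterable[str],
                 alphabet: str | None = None) -> None:
        self.names: list[str] = list(names)
        self.rows: list[str] = [r.upper() for r in rows]
        if len(self.names) != len(self.rows):
            raise MalformedAlignmentError("names and rows differ in count")
        if len(self.rows) < 2:
            raise MalformedAlignmentError("an alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise MalformedAlignmentError(
                f"rows have unequal lengths: {sorted(lengths)}")
        if lengths == {0}:
            raise MalformedAlignmentError("alignment has zero columns")
        seen: set[str] = set()
        for name in self.names:
            if not name:
                raise MalformedAlignmentError("empty sequence name")
            if name in seen:
                raise MalformedAlignmentError(f"duplicate sequence name {name!r}")
            seen.add(name)
        self.alphabet = alphabet or detect_alphabet(self.rows)

    # -- basic geometry ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, col: int) -> str:
        """Column as a string; ``col`` is 0-based here (internal)."""
        return "".join(row[col] for row in self.rows)

    def sequences(self) -> list[Sequence]:
        return [Sequence(n, r) for n, r in zip(self.names, self.rows)]

    def ungapped(self, idx: int) -> str:
        return self.rows[idx].replace(GAP, "")

    # -- coordinate maps ---------------------------------------------------
    def residue_positions(self, idx: int) -> list[int]:
        """Per alignment column: 1-based ungapped position, or 0 at gaps."""
        out, pos = [], 0
        for ch in self.rows[idx]:
            if ch == GAP:
                out.append(0)
            else:
                pos += 1
                out.append(pos)
        return out

    def column_residues(self, col: int) -> list[tuple[int, int]]:
        """Non-gap residues of 0-based column ``col`` as (seq_idx, 1-based pos)."""
        out = []
        for s in range(self.n):
            if self.rows[s][col] != GAP:
                out.append((s, col + 1 - self.rows[s][: col + 1].count(GAP)))
        return out

    def with_rows(self, rows: Iterable[str]) -> "Alignment":
        return Alignment(self.names, rows, self.alphabet)

    # -- dunder ------------------------------------------------------------
    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences())

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Alignment) and self.names == other.names
                and self.rows == other.rows)

    def __repr__(self) -> str:
        return f"<Alignment N={self.n} L={self.length} {self.alphabet}>"


def column_residue_table(aln: Alignment) -> list[list[tuple[int, int]]]:
    """For each 0-based column, the list of (seq_idx, 1-based ungapped pos).

    Computed in one pass; prefer this over repeated ``column_residues`` calls.
    """
    table: list[list[tuple[int, int]]] = [[] for _ in range(aln.length)]
    for s, row in enumerate(aln.rows):
        pos = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                pos += 1
                table[c].append((s, pos))
    return table
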