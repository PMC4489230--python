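import numpy as np
import pytest

from tcscore import Alignment, Library
from tcscore.alignment import column_residue_table


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(
        ["seq1", "seq2", "seq3"],
        ["ACDEF", "AC-EF", "ACDEW"])


@pytest.fixture
def identical_alignment() -> Alignment:
    row = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
    return Alignment(["a", "b", "c", "d"], [row] * 4)


def intra_column_library(aln: Alignment, weight: float = 1.0) -> Library:
    """The fully consistent library: every intra-column residue pair at 1."""
    import itertools

    lib = Library(aln.names, [aln.ungapped(i) for i in range(aln.n)],
                  source="test")
    for residues in column_residue_table(aln):
        for (a, i), (b, j) in itertools.combinations(residues, 2):
            lib.add(a, i, b, j, weight)
    return lib


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     gap_frac: float = 0.15) -> Alignment:
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    rows = []
    for _ in range(n):
        while True:
            row = "".join(
                "-" if rng.random() < gap_frac else aa[int(rng.integers(20))]
                for _ in range(length))
            if row.strip("-"):
                break
        rows.append(row)
    return Alignment([f"s{i}" for i in range(n)], rows)


def random_library(rng: np.random.Generator, aln: Alignment,
                   n_entries: int = 40) -> Library:
    lib = Library(aln.names, [aln.ungapped(i) for i in range(aln.n)],
                  source="test")
    for _ in range(n_entries):
        a, b = rng.choice(aln.n, size=2, replace=False)
        la, lb = len(lib.sequences[a]), len(lib.sequences[b])
        if la == 0 or lb == 0:
            continue
        lib.add(int(a), int(rng.integers(1, la + 1)),
                int(b), int(rng.integers(1, lb + 1)),
                float(rng.uniform(0.05, 1.0)))
    return lib
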