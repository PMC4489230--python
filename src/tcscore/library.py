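"""The weighted residue-pair library.

A library is a set of cross-sequence residue pairs, each weighted by the
evidence that the two residues belong together in the final alignment.
Pairs need not be mutually consistent.  Two builders are provided:

* ``build_proba_pair_library`` (the default): pair-HMM posterior decoding of
  every sequence pair, keeping pairs whose posterior is strictly greater
  than the cutoff (default 0.9), weight = posterior.
* ``build_proxy_msa_library`` (fast consensus mode): several pluggable MSA
  backends re-align the ungapped sequences; every residue pair aligned in
  any backend MSA enters the library with weight = supporting backends /
  total backends.

Residue coordinates are (sequence index, 1-based ungapped position).
Duplicate pairs merge by keeping the maximum weight, which makes merging
commutative, associative and idempotent.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable, Iterator, Mapping, Sequence as Seq

from .alignment import Alignment
from .errors import BackendIntegrityError, LibraryError
from .hmm import PairHmmParams, pair_posteriors, default_params

Residue = tuple[int, int]  # (sequence index, 1-based ungapped position)


class Library:
    """Symmetric store of weighted residue pairs over a fixed sequence set."""

    def __init__(self, names: Seq[str], sequences: Seq[str],
                 source: str = "custom", params: object | None = None) -> None:
        if len(names) != len(sequences):
            raise LibraryError("names and sequences differ in count")
        self.names = tuple(names)
        self.sequences = tuple(s.upper() for s in sequences)
        self.source = source
        self.params = params
        self._nbrs: dict[Residue, dict[Residue, float]] = {}

    # -- mutation ----------------------------------------------------------
    def add(self, seq_a: int, pos_a: int, seq_b: int, pos_b: int,
            weight: float) -> None:
        if seq_a == seq_b:
            raise LibraryError("library pairs must span two sequences")
        for s, p in ((seq_a, pos_a), (seq_b, pos_b)):
            if not 0 <= s < len(self.sequences):
                raise LibraryError(f"sequence index {s} out of range")
            if not 1 <= p <= len(self.sequences[s]):
                raise LibraryError(
                    f"position {p} out of range for sequence {self.names[s]}")
        if not weight > 0.0:
            raise LibraryError("pair weight must be positive")
        a, b = (seq_a, pos_a), (seq_b, pos_b)
        w = min(float(weight), 1.0)
        cur = self._nbrs.get(a, {}).get(b)
        if cur is not None and cur >= w:
            return
        self._nbrs.setdefault(a, {})[b] = w
        self._nbrs.setdefault(b, {})[a] = w

    # -- queries -----------------------------------------------------------
    def weight(self, seq_a: int, pos_a: int, seq_b: int, pos_b: int) -> float:
        return self._nbrs.get((seq_a, pos_a), {}).get((seq_b, pos_b), 0.0)

    def neighbors(self, seq: int, pos: int) -> Mapping[Residue, float]:
        return self._nbrs.get((seq, pos), {})

    def entries(self) -> Iterator[tuple[int, int, int, int, float]]:
        """Canonical entries (seq_a < seq_b), sorted, each pair once."""
        for a in sorted(self._nbrs):
            for b, w in sorted(self._nbrs[a].items()):
                if a < b:
                    yield a[0], a[1], b[0], b[1], w

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self._nbrs.values()) // 2

    def __len__(self) -> int:
        return self.n_entries

    def __repr__(self) -> str:
        return (f"<Library {self.n_entries} pairs over {len(self.sequences)} "
                f"sequences, source={self.source}>")

    # -- merging -----------------------------------------------------------
    def merge(self, other: "Library") -> "Library":
        if self.sequences != other.sequences:
            raise LibraryError("cannot merge libraries over different sequences")
        out = Library(self.names, self.sequences,
                      source=f"merge({self.source},{other.source})")
        for lib in (self, other):
            for sa, pa, sb, pb, w in lib.entries():
                out.add(sa, pa, sb, pb, w)
        return out

    # -- T-Coffee text format ----------------------------------------------
    def to_text(self) -> str:
        """Serialise in the T-Coffee plain-text library format.

        Weights are stored as the conventional integer ``round(w * 100)``;
        round-tripping therefore quantises weights to 1/100.
        """
        lines = ["! TC_LIB_FORMAT_01", str(len(self.sequences))]
        for name, seq in zip(self.names, self.sequences):
            lines.append(f"{name} {len(seq)} {seq}")
        by_pair: dict[tuple[int, int], list[tuple[int, int, float]]] = {}
        for sa, pa, sb, pb, w in self.entries():
            by_pair.setdefault((sa, sb), []).append((pa, pb, w))
        for (sa, sb), rows in sorted(by_pair.items()):
            lines.append(f"#{sa + 1} {sb + 1}")
            for pa, pb, w in rows:
                lines.append(f"{pa} {pb} {max(1, round(w * 100))}")
        lines.append("! SEQ_1_TO_N")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Library":
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("! TC_LIB_FORMAT"):
            raise LibraryError("not a T-Coffee library file")
        nseq = int(lines[1])
        names, seqs = [], []
        for ln in lines[2 : 2 + nseq]:
            name, _length, seq = ln.split()
            names.append(name)
            seqs.append(seq)
        lib = cls(names, seqs, source="file")
        sa = sb = -1
        for ln in lines[2 + nseq:]:
            if ln.startswith("!"):
                continue
            if ln.startswith("#"):
                sa, sb = (int(tok) - 1 for tok in ln[1:].split())
                continue
            pa, pb, w = ln.split()
            lib.add(sa, int(pa), sb, int(pb), int(w) / 100.0)
        return lib


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

PosteriorFn = Callable[[str, str], "object"]


def build_proba_pair_library(aln: Alignment,
                             params: PairHmmParams | None = None,
                             cutoff: float = 0.9,
                             posterior_fn: PosteriorFn | None = None,
                             ) -> Library:
    """Build the default library from pair-HMM posteriors.

    For every unordered sequence pair, residue pairs whose posterior
    alignment probability is strictly greater than ``cutoff`` enter the
    library with the posterior as weight — the optimal alignment plus
    high-scoring suboptimal ones.  ``posterior_fn(x, y)`` may replace the
    HMM (a test seam and a hook for external posterior sources).
    """
    import logging

    if not 0.0 <= cutoff < 1.0:
        raise ValueError("cutoff must lie in [0, 1)")
    if params is None and posterior_fn is None:
        params = default_params(aln.alphabet)
        if aln.alphabet == "nucleotide":
            logging.getLogger(__name__).warning(
                "nucleotide input: TCS has only been validated on proteins")
    seqs = [aln.ungapped(i) for i in range(aln.n)]
    lib = Library(aln.names, seqs, source="proba_pair",
                  params={"cutoff": cutoff,
                          "hmm": getattr(params, "version", "external")})
    for a, b in itertools.combinations(range(aln.n), 2):
        post = (posterior_fn(seqs[a], seqs[b]) if posterior_fn is not None
                else pair_posteriors(seqs[a], seqs[b], params))
        values = getattr(post, "values", post)
        n, m = values.shape
        for i in range(n):
            row = values[i]
            for j in range(m):
                if row[j] > cutoff:
                    lib.add(a, i + 1, b, j + 1, float(row[j]))
    return lib


AlignerBackend = Callable[[Seq[str], Seq[str]], Alignment]


def build_proxy_msa_library(aln: Alignment,
                            aligners: Seq[AlignerBackend] | None = None,
                            ) -> Library:
    """Build the consensus library from several proxy MSAs (fast mode).

    Each backend maps the ungapped input sequences to an MSA over the same
    sequences; every residue pair aligned in any backend MSA is added with
    weight = (number of supporting backends) / (number of backends).
    """
    from .aligners import builtin_backends

    if aligners is None:
        aligners = builtin_backends(aln.alphabet)
    if not aligners:
        raise LibraryError("at least one proxy aligner is required")
    seqs = [aln.ungapped(i) for i in range(aln.n)]
    counts: dict[tuple[Residue, Residue], int] = {}
    for backend in aligners:
        proxy = backend(aln.names, seqs)
        if list(proxy.names) != list(aln.names):
            raise BackendIntegrityError("backend changed sequence names/order")
        for i in range(proxy.n):
            if proxy.ungapped(i) != seqs[i]:
                raise BackendIntegrityError(
                    f"backend mutated residues of {aln.names[i]!r}")
        from .alignment import column_residue_table
        for residues in column_residue_table(proxy):
            for ra, rb in itertools.combinations(residues, 2):
                counts[(ra, rb)] = counts.get((ra, rb), 0) + 1
    lib = Library(aln.names, seqs, source="proxy_msa",
                  params={"n_backends": len(aligners)})
    for (ra, rb), c in counts.items():
        lib.add(ra[0], ra[1], rb[0], rb[1], c / len(aligners))
    return lib


def merge_libraries(a: Library, b: Library) -> Library:
    """Union of two libraries over the same sequences; max weight on clashes."""
    return a.merge(b)
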