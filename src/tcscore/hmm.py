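"""Pair hidden Markov model posterior decoding.

A 3-state pair HMM (Match, InsertX, InsertY) aligns two ungapped sequences;
forward-backward decoding yields, for every residue pair (i, j), the
posterior probability that the two residues are aligned, summed over all
global alignments.  These posteriors are the weights of the default
residue-pair library.

The model is parameterised by a joint match-emission matrix over symbol
pairs, a background insert-emission vector, gap open/extend transition
probabilities and an initial state distribution.  The shipped protein
defaults derive the joint emissions from BLOSUM62 log-odds scores and
published background amino-acid frequencies (p_ab proportional to
q_a*q_b*2^(S_ab/2), renormalised); transition constants are artifact
constants chosen in the range used by probabilistic consistency aligners.
Parameters serialise to a versioned JSON document so alternative trained
sets can be swapped in.

All recursions run in log space: lengths up to several thousand residues
neither overflow nor underflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO

import numpy as np
from numba import njit

from .errors import AlphabetError

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
NUCLEOTIDE_ALPHABET = "ACGTN"

# BLOSUM62 background amino-acid frequencies (order = PROTEIN_ALPHABET[:20]).
_PROTEIN_BG = np.array([
    0.0787, 0.0512, 0.0448, 0.0536, 0.0205, 0.0343, 0.0540, 0.0708, 0.0243,
    0.0599, 0.0967, 0.0590, 0.0240, 0.0396, 0.0418, 0.0580, 0.0541, 0.0134,
    0.0324, 0.0703])
_UNKNOWN_BG = 5e-4  # pseudo-frequency of the ambiguity symbol


@dataclass
class PairHmmParams:
    """Emission and transition parameters of the 3-state pair HMM.

    ``match[a, b]`` is the joint probability of emitting symbol pair (a, b)
    from the Match state; ``insert[a]`` the background probability of
    emitting ``a`` from either insert state.  ``gap_open``/``gap_extend``
    are the M->Insert and Insert->Insert transition probabilities; the
    remaining mass closes each row.  ``init`` is the distribution over the
    state emitting the first symbol(s).
    """

    alphabet: str
    match: np.ndarray
    insert: np.ndarray
    gap_open: float
    gap_extend: float
    init: np.ndarray = field(default_factory=lambda: np.array([0.976, 0.012, 0.012]))
    version: str = "tcscore-hmm-1"

    def __post_init__(self) -> None:
        self.match = np.asarray(self.match, dtype=np.float64)
        self.insert = np.asarray(self.insert, dtype=np.float64)
        self.init = np.asarray(self.init, dtype=np.float64)
        k = len(self.alphabet)
        if self.match.shape != (k, k) or self.insert.shape != (k,):
            raise ValueError("emission shapes do not match alphabet size")
        if abs(self.match.sum() - 1.0) > 1e-9:
            raise ValueError("match emission matrix must sum to 1")
        if abs(self.insert.sum() - 1.0) > 1e-9:
            raise ValueError("insert emission vector must sum to 1")
        if abs(self.init.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if not (0.0 < self.gap_open < 0.5 and 0.0 < self.gap_extend < 1.0):
            raise ValueError("transition probabilities out of range")
        self._index = {c: i for i, c in enumerate(self.alphabet)}

    # -- transition table --------------------------------------------------
    @property
    def transitions(self) -> np.ndarray:
        """Row-stochastic 3x3 matrix over states (M, X, Y); X<->Y forbidden."""
        d, e = self.gap_open, self.gap_extend
        return np.array([
            [1.0 - 2.0 * d, d, d],
            [1.0 - e, e, 0.0],
            [1.0 - e, 0.0, e]])

    # -- encoding ----------------------------------------------------------
    def encode(self, seq: str) -> np.ndarray:
        if not seq:
            raise AlphabetError("empty sequence")
        wildcard = self.alphabet[-1]  # 'X' / 'N' ambiguity bucket
        out = np.empty(len(seq), dtype=np.int64)
        for i, ch in enumerate(seq.upper()):
            if ch == "-":
                raise AlphabetError("gapped sequence passed where ungapped expected")
            out[i] = self._index.get(ch, self._index[wildcard])
        return out

    # -- serialization -----------------------------------------------------
    def to_json(self, sink: IO[str] | str | None = None) -> str:
        doc = {
            "version": self.version,
            "alphabet": self.alphabet,
            "match": self.match.tolist(),
            "insert": self.insert.tolist(),
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "init": self.init.tolist(),
        }
        text = json.dumps(doc, indent=1)
        if sink is not None:
            if hasattr(sink, "write"):
                sink.write(text)
            else:
                with open(sink, "w") as fh:
                    fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: IO[str] | str) -> "PairHmmParams":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(alphabet=doc["alphabet"], match=np.array(doc["match"]),
                   insert=np.array(doc["insert"]), gap_open=doc["gap_open"],
                   gap_extend=doc["gap_extend"], init=np.array(doc["init"]),
                   version=doc.get("version", "unversioned"))


def default_protein_params() -> PairHmmParams:
    """Protein defaults: BLOSUM62-derived joint emissions, background inserts."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    core = PROTEIN_ALPHABET[:20]
    k = len(PROTEIN_ALPHABET)
    q = np.empty(k)
    q[:20] = _PROTEIN_BG
    q[20] = _UNKNOWN_BG
    q /= q.sum()
    joint = np.empty((k, k))
    for i, a in enumerate(core):
        for j, b in enumerate(core):
            joint[i, j] = q[i] * q[j] * 2.0 ** (blosum[a, b] / 2.0)
    joint[20, :] = q[20] * q  # ambiguity symbol: odds ratio 1
    joint[:, 20] = q * q[20]
    joint /= joint.sum()
    return PairHmmParams(alphabet=PROTEIN_ALPHABET, match=joint,
                         insert=q, gap_open=0.012, gap_extend=0.886)


def default_nucleotide_params() -> PairHmmParams:
    """Nucleotide defaults: identity-biased joint emissions over ACGT(+N)."""
    k = len(NUCLEOTIDE_ALPHABET)
    q = np.array([0.25, 0.25, 0.25, 0.25, 4e-4])
    q /= q.sum()
    joint = np.empty((k, k))
    for i in range(4):
        for j in range(4):
            joint[i, j] = 0.2125 if i == j else 0.0125
    joint[4, :] = q[4] * q
    joint[:, 4] = q * q[4]
    joint /= joint.sum()
    return PairHmmParams(alphabet=NUCLEOTIDE_ALPHABET, match=joint,
                         insert=q, gap_open=0.02, gap_extend=0.85)


def default_params(alphabet: str = "protein") -> PairHmmParams:
    if alphabet == "protein":
        return default_protein_params()
    if alphabet == "nucleotide":
        return default_nucleotide_params()
    raise ValueError(f"unknown alphabet {alphabet!r}")


# ---------------------------------------------------------------------------
# forward-backward kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lse2(a, b):
    if a < b:
        a, b = b, a
    if b == -np.inf:
        return a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True)
def _lse3(a, b, c):
    return _lse2(_lse2(a, b), c)


@njit(cache=True)
def _forward_backward(lm, lx, ly, lt, lpi):
    """Log-space forward-backward over the 3-state pair HMM.

    lm: (n, m) log match emissions for this sequence pair
    lx: (n,) / ly: (m,) log insert emissions
    lt: log transitions [mm, mx, my, xm, xx, ym, yy]
    lpi: log initial distribution over (M, X, Y)
    Returns the (n, m) posterior match matrix and the log-likelihood.
    """
    n, m = lm.shape
    NEG = -np.inf
    F_M = np.full((n + 1, m + 1), NEG)
    F_X = np.full((n + 1, m + 1), NEG)
    F_Y = np.full((n + 1, m + 1), NEG)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = _lse3(lt[0] + F_M[i - 1, j - 1],
                          lt[3] + F_X[i - 1, j - 1],
                          lt[5] + F_Y[i - 1, j - 1])
                if i == 1 and j == 1:
                    s = _lse2(s, lpi[0])
                F_M[i, j] = lm[i - 1, j - 1] + s
            if i > 0:
                s = _lse2(lt[1] + F_M[i - 1, j], lt[4] + F_X[i - 1, j])
                if i == 1 and j == 0:
                    s = _lse2(s, lpi[1])
                F_X[i, j] = lx[i - 1] + s
            if j > 0:
                s = _lse2(lt[2] + F_M[i, j - 1], lt[6] + F_Y[i, j - 1])
                if i == 0 and j == 1:
                    s = _lse2(s, lpi[2])
                F_Y[i, j] = ly[j - 1] + s
    logz = _lse3(F_M[n, m], F_X[n, m], F_Y[n, m])

    B_M = np.full((n + 1, m + 1), NEG)
    B_X = np.full((n + 1, m + 1), NEG)
    B_Y = np.full((n + 1, m + 1), NEG)
    B_M[n, m] = 0.0
    B_X[n, m] = 0.0
    B_Y[n, m] = 0.0
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            to_m = lm[i, j] + B_M[i + 1, j + 1] if (i < n and j < m) else NEG
            to_x = lx[i] + B_X[i + 1, j] if i < n else NEG
            to_y = ly[j] + B_Y[i, j + 1] if j < m else NEG
            B_M[i, j] = _lse3(lt[0] + to_m, lt[1] + to_x, lt[2] + to_y)
            B_X[i, j] = _lse2(lt[3] + to_m, lt[4] + to_x)
            B_Y[i, j] = _lse2(lt[5] + to_m, lt[6] + to_y)

    post = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            v = F_M[i + 1, j + 1] + B_M[i + 1, j + 1] - logz
            p = math.exp(v) if v < 0.0 else 1.0
            post[i, j] = p
    return post, logz


class PosteriorMatrix:
    """Posterior match probabilities for one ungapped sequence pair.

    ``values[i, j]`` is P(residue i+1 of x aligns residue j+1 of y); every
    row and column sums to at most 1 (a residue aligns at most one partner
    per alignment path).
    """

    def __init__(self, values: np.ndarray, log_likelihood: float) -> None:
        self.values = values
        self.log_likelihood = log_likelihood

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __getitem__(self, key):
        return self.values[key]


def pair_posteriors(x: str, y: str, params: PairHmmParams) -> PosteriorMatrix:
    """Posterior-decode the pair HMM on two ungapped sequences.

    Raises :class:`AlphabetError` on empty input or gap characters; symbols
    outside the parameter alphabet map to its ambiguity bucket.
    """
    xi = params.encode(x)
    yi = params.encode(y)
    with np.errstate(divide="ignore"):
        log_match = np.log(params.match)
        log_insert = np.log(params.insert)
        lt_full = np.log(params.transitions)
        lpi = np.log(params.init)
    lm = np.ascontiguousarray(log_match[np.ix_(xi, yi)])
    lx = np.ascontiguousarray(log_insert[xi])
    ly = np.ascontiguousarray(log_insert[yi])
    lt = np.array([lt_full[0, 0], lt_full[0, 1], lt_full[0, 2],
                   lt_full[1, 0], lt_full[1, 1],
                   lt_full[2, 0], lt_full[2, 2]])
    post, logz = _forward_backward(lm, lx, ly, lt, lpi)
    return PosteriorMatrix(post, float(logz))
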