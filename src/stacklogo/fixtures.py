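"""Synthetic alignments and toy profile HMMs with known ground truth.

Every generator is seeded and column-independent: alignments are sampled
one column at a time from a stated letter distribution and occupancy, toy
HMMs are assembled from explicit per-node emission and transition choices.
That is deliberately simpler than real sequence evolution (no phylogeny,
no indel length process), but it gives exact ground truth against which
estimators, the occupancy recursion and the renderers can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import Alphabet, MultipleAlignment
from .errors import StackLogoError
from .hmm_io import ProfileHMM


@dataclass(frozen=True)
class ColumnSpec:
    """Ground truth for one sampled column: letter distribution + occupancy."""

    true_p: np.ndarray
    occupancy_target: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.true_p, float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise StackLogoError("true_p must be a probability vector")
        if not 0.0 <= self.occupancy_target <= 1.0:
            raise StackLogoError("occupancy_target must lie in [0, 1]")
        object.__setattr__(self, "true_p", p)


def sample_alignment(
    specs: list[ColumnSpec],
    nseq: int,
    seed: int,
    alphabet: Alphabet | None = None,
) -> MultipleAlignment:
    """Sample an alignment column-by-column from ``specs``.

    Each sequence independently bears a gap with probability
    ``1 - occupancy_target``, otherwise a letter drawn from ``true_p``.
    Deterministic for a fixed seed.
    """
    if nseq < 1:
        raise StackLogoError("nseq must be at least 1")
    if not specs:
        raise StackLogoError("need at least one column spec")
    if alphabet is None:
        alphabet = Alphabet.dna() if specs[0].true_p.size == 4 else Alphabet.amino()
    for spec in specs:
        if spec.true_p.size != alphabet.size:
            raise StackLogoError("column spec width does not match alphabet")
    rng = np.random.default_rng(seed)
    letters = alphabet.letters
    cols = []
    for spec in specs:
        gaps = rng.random(nseq) >= spec.occupancy_target
        draws = rng.choice(alphabet.size, size=nseq, p=spec.true_p)
        cols.append(["-" if g else letters[d] for g, d in zip(gaps, draws)])
    rows = ["".join(col[s] for col in cols) for s in range(nseq)]
    ids = [f"seq{s + 1:04d}" for s in range(nseq)]
    return MultipleAlignment(ids=ids, rows=rows, alphabet=alphabet)


@dataclass
class HmmSpec:
    """Explicit parameters for a toy profile HMM of length M.

    Arrays are indexed by match node 1..M: ``eps[k-1]`` is the insert
    self-transition after node k, ``m_to_i``/``m_to_d`` the match exits.
    The terminal node structurally has m->d = 0 and d->m = 1.  The begin
    node's exits (B->M1, B->I0, B->D1) default to (1, 0, 0).
    """

    match_p: np.ndarray                    # (M, L)
    eps: np.ndarray                        # (M,)
    m_to_i: np.ndarray                     # (M,)
    m_to_d: np.ndarray                     # (M,)
    d_to_m: np.ndarray | None = None       # (M,), default 0.5 everywhere
    begin: tuple[float, float, float] = (1.0, 0.0, 0.0)
    map_columns: list[int] | None = None

    def __post_init__(self) -> None:
        self.match_p = np.atleast_2d(np.asarray(self.match_p, float))
        M = self.match_p.shape[0]
        self.eps = np.asarray(self.eps, float)
        self.m_to_i = np.asarray(self.m_to_i, float)
        self.m_to_d = np.asarray(self.m_to_d, float)
        if self.d_to_m is None:
            self.d_to_m = np.full(M, 0.5)
        self.d_to_m = np.asarray(self.d_to_m, float)
        for name, arr in (("eps", self.eps), ("m_to_i", self.m_to_i),
                          ("m_to_d", self.m_to_d), ("d_to_m", self.d_to_m)):
            if arr.shape != (M,):
                raise StackLogoError(f"{name} must have length M={M}")
            if np.any(arr < 0) or np.any(arr > 1):
                raise StackLogoError(f"{name} entries must lie in [0, 1]")
        if np.any(self.eps >= 1.0):
            raise StackLogoError("eps must be < 1 (finite expected insert length)")
        if np.any(self.m_to_i + self.m_to_d > 1.0 + 1e-12):
            raise StackLogoError("m_to_i + m_to_d must not exceed 1")
        if self.m_to_d[-1] != 0.0:
            raise StackLogoError("terminal node must have m_to_d = 0")
        if abs(sum(self.begin) - 1.0) > 1e-9:
            raise StackLogoError("begin transitions must sum to 1")
        sums = self.match_p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise StackLogoError("each match distribution must sum to 1")
        if self.map_columns is not None and len(self.map_columns) != M:
            raise StackLogoError("map_columns must have length M")

    @property
    def M(self) -> int:
        return self.match_p.shape[0]


def make_toy_hmm(spec: HmmSpec, alphabet: Alphabet | None = None,
                 name: str = "toy") -> ProfileHMM:
    """Materialize ``spec`` as a ProfileHMM (insert emissions = background)."""
    if alphabet is None:
        alphabet = Alphabet.dna() if spec.match_p.shape[1] == 4 else Alphabet.amino()
    M = spec.M
    t = np.zeros((M + 1, 7))
    b_m, b_i, b_d = spec.begin
    t[0] = [b_m, b_i, b_d, 1.0, 0.0, 1.0, 0.0]
    for k in range(1, M + 1):
        mi, md, eps, dm = (spec.m_to_i[k - 1], spec.m_to_d[k - 1],
                           spec.eps[k - 1], spec.d_to_m[k - 1])
        if k == M:
            md, dm = 0.0, 1.0
        t[k] = [1.0 - mi - md, mi, md, 1.0 - eps, eps, dm, 1.0 - dm]
    insert = np.tile(alphabet.default_background, (M, 1))
    return ProfileHMM(
        name=name,
        alphabet=alphabet,
        match_emissions=spec.match_p.copy(),
        insert_emissions=insert,
        transitions=t,
        map_annotation=list(spec.map_columns) if spec.map_columns else None,
    )


def random_hmm_spec(M: int, L: int, seed: int, with_map: bool = True) -> HmmSpec:
    """A random but valid HmmSpec, reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    match_p = rng.dirichlet(np.ones(L), size=M)
    eps = rng.uniform(0.0, 0.9, M)
    exits = rng.dirichlet(np.ones(3), size=M)  # (m->m, m->i, m->d)
    m_to_i = exits[:, 1]
    m_to_d = exits[:, 2].copy()
    m_to_d[-1] = 0.0
    d_to_m = rng.uniform(0.1, 1.0, M)
    begin = rng.dirichlet(np.ones(3))
    map_cols = None
    if with_map:
        gaps = rng.integers(1, 4, M)
        map_cols = [int(c) for c in np.cumsum(gaps)]
    return HmmSpec(match_p=match_p, eps=eps, m_to_i=m_to_i, m_to_d=m_to_d,
                   d_to_m=d_to_m, begin=tuple(begin), map_columns=map_cols)
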