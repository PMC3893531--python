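"""Per-column letter distributions, sequence weighting, priors, consensus.

Three estimation regimes are supported for alignment columns:

``observed``
    Maximum-likelihood frequencies from raw counts (every sequence weight 1).
``weighted``
    Henikoff & Henikoff position-based weights: in a column with ``r``
    distinct letters where a sequence's letter occurs ``s`` times, that
    sequence receives increment ``1/(r*s)``; per-sequence totals are averaged
    over the columns in which the sequence bears a residue and normalized to
    mean 1.  Redundant near-duplicate sequences are thereby down-weighted.
``weighted_prior``
    Henikoff weights combined with a Dirichlet prior: the reported
    probabilities are posterior means, which pull sparse columns toward the
    background and so lower their information content.

Occupancy of a column is the (weighted) fraction of sequences showing any
residue there — ambiguity codes included — and drives consensus-column
selection: a column is consensus when its occupancy reaches ``symfrac``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import numpy as np
from scipy.special import gammaln, logsumexp

from .alignment_io import Alphabet, MultipleAlignment
from .errors import EmptyInputError, PriorError

__all__ = [
    "WeightVector",
    "DirichletPrior",
    "ColumnDistribution",
    "count_column",
    "henikoff_weights",
    "unit_weights",
    "apply_prior",
    "estimate_columns",
    "consensus_columns",
]


@dataclass(frozen=True)
class WeightVector:
    """Per-sequence relative weights, normalized to mean 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a nonempty 1-D vector")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.mean() - 1.0) > 1e-9:
            raise ValueError(f"weights must have mean 1 (got {w.mean():.12f})")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size


def unit_weights(nseq: int) -> WeightVector:
    return WeightVector(np.ones(nseq))


@dataclass(frozen=True)
class DirichletPrior:
    """A (mixture) Dirichlet prior over column distributions.

    ``components`` is a list of ``(mixture_coefficient, alpha_vector)``
    pairs; a single component gives the classic pseudocount rule
    ``p_i = (c_i + alpha_i) / (n + sum(alpha))``.
    """

    components: tuple[tuple[float, np.ndarray], ...]

    def __post_init__(self) -> None:
        comps = []
        for coef, alpha in self.components:
            a = np.asarray(alpha, dtype=float)
            if coef < 0:
                raise PriorError("mixture coefficients must be nonnegative")
            if np.any(a <= 0):
                raise PriorError("all Dirichlet alphas must be positive")
            comps.append((float(coef), a))
        total = sum(c for c, _ in comps)
        if abs(total - 1.0) > 1e-9:
            raise PriorError(f"mixture coefficients sum to {total:.12f}, not 1")
        widths = {a.size for _, a in comps}
        if len(widths) != 1:
            raise PriorError("all alpha vectors must have the same length")
        object.__setattr__(self, "components", tuple(comps))

    @classmethod
    def background_scaled(cls, alphabet: Alphabet, concentration: float = 1.0) -> "DirichletPrior":
        """Single-component prior with alphas proportional to the background.

        The prior mean equals the background distribution, so columns with
        no observations fall back to q exactly.
        """
        if concentration <= 0:
            raise PriorError("concentration must be positive")
        return cls(((1.0, concentration * alphabet.default_background),))

    @classmethod
    def uniform(cls, L: int, concentration: float = 1.0) -> "DirichletPrior":
        return cls(((1.0, np.full(L, concentration / L)),))

    @classmethod
    def from_file(cls, handle: IO[str], L: int) -> "DirichletPrior":
        """Parse a plain-text prior: one line per component, coefficient then L alphas."""
        comps = []
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [float(t) for t in line.split()]
            if len(fields) != L + 1:
                raise PriorError(
                    f"line {lineno}: expected 1 coefficient + {L} alphas, got {len(fields)} fields"
                )
            comps.append((fields[0], np.array(fields[1:])))
        if not comps:
            raise PriorError("prior file contains no components")
        return cls(tuple(comps))


@dataclass
class ColumnDistribution:
    """Estimated letter distribution of one alignment column.

    ``occupancy`` is the weighted fraction of sequences bearing a residue
    (ambiguity codes included) at the column; ``column_index`` is 1-based.
    """

    p: np.ndarray
    raw_counts: np.ndarray
    occupancy: float
    column_index: int


def count_column(
    msa: MultipleAlignment, col: int, weights: WeightVector | None = None
) -> tuple[np.ndarray, float]:
    """Weighted letter counts and occupancy of 1-based column ``col``.

    Canonical letters add their sequence's weight to ``counts``; ambiguity
    codes add to occupancy only; gaps add to neither.  An empty column
    yields zero counts and occupancy 0.
    """
    if weights is None:
        weights = unit_weights(msa.nseq)
    w = weights.weights
    if w.size != msa.nseq:
        raise ValueError("weight vector length != number of sequences")
    alpha = msa.alphabet
    counts = np.zeros(alpha.size)
    residue_weight = 0.0
    for row, wi in zip(msa.rows, w):
        ch = row[col - 1]
        if alpha.is_gap(ch):
            continue
        idx = alpha.index_of(ch)
        if idx is not None:
            counts[idx] += wi
        residue_weight += wi  # degenerate symbols still occupy the column
    total = w.sum()
    occupancy = residue_weight / total if total > 0 else 0.0
    return counts, occupancy


def henikoff_weights(msa: MultipleAlignment) -> WeightVector:
    """Position-based sequence weights (mean 1).

    Column rule: with r distinct canonical letters in a column, a sequence
    whose letter occurs s times there receives 1/(r*s).  Each sequence's
    increments are averaged over the columns where it bears a canonical
    letter, then the vector is scaled to mean 1.  Identical sequences get
    identical weights; duplicated sequence sets split their weight evenly.
    """
    alpha = msa.alphabet
    raw = np.zeros(msa.nseq)
    ncounted = np.zeros(msa.nseq)
    any_column = False
    for c in range(msa.ncols):
        idxs = [alpha.index_of(row[c]) if not alpha.is_gap(row[c]) else None
                for row in msa.rows]
        present = [i for i in idxs if i is not None]
        if not present:
            continue
        any_column = True
        occ_counts = np.bincount(present, minlength=alpha.size)
        r = int(np.count_nonzero(occ_counts))
        for s_idx, letter_idx in enumerate(idxs):
            if letter_idx is None:
                continue
            raw[s_idx] += 1.0 / (r * occ_counts[letter_idx])
            ncounted[s_idx] += 1
    if not any_column:
        raise EmptyInputError("no residue-bearing columns; cannot weight sequences")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_col = np.where(ncounted > 0, raw / np.maximum(ncounted, 1), 0.0)
    mean = per_col.mean()
    if mean <= 0:
        raise EmptyInputError("all sequences are residue-free")
    return WeightVector(per_col / mean)


def apply_prior(
    counts: np.ndarray, prior: DirichletPrior, total: float | None = None
) -> np.ndarray:
    """Posterior-mean letter distribution given (weighted) counts and a prior.

    Single component: ``p_i = (counts_i + alpha_i) / (total + sum(alpha))``.
    Mixture: component responsibilities come from Bayes' rule with
    Dirichlet-multinomial marginal likelihoods, and the result is the
    responsibility-weighted average of component posterior means.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    n = c.sum() if total is None else float(total)
    if len(prior.components) == 1:
        _, a = prior.components[0]
        p = (c + a) / (n + a.sum())
    else:
        log_marg = np.empty(len(prior.components))
        means = np.empty((len(prior.components), c.size))
        for j, (coef, a) in enumerate(prior.components):
            if coef == 0.0:
                log_marg[j] = -np.inf
            else:
                log_marg[j] = (
                    np.log(coef)
                    + gammaln(a.sum()) - gammaln(c.sum() + a.sum())
                    + np.sum(gammaln(c + a) - gammaln(a))
                )
            means[j] = (c + a) / (n + a.sum())
        resp = np.exp(log_marg - logsumexp(log_marg))
        p = resp @ means
    return p / p.sum()


def estimate_columns(
    msa: MultipleAlignment,
    method: str = "weighted_prior",
    prior: DirichletPrior | None = None,
    symfrac: float | None = None,
) -> list[ColumnDistribution]:
    """Estimate a :class:`ColumnDistribution` for every retained column.

    Empty columns are always dropped; when ``symfrac`` is given, columns
    below that occupancy threshold are dropped too (consensus-only logos).
    ``method`` selects observed counts, Henikoff-weighted counts, or
    weighted counts blended with ``prior`` (default: background-matched
    single-component Dirichlet with concentration 1).
    """
    if method not in ("observed", "weighted", "weighted_prior"):
        raise ValueError(f"unknown estimation method {method!r}")
    if method == "observed":
        weights = unit_weights(msa.nseq)
    else:
        weights = henikoff_weights(msa)
    if method == "weighted_prior" and prior is None:
        prior = DirichletPrior.background_scaled(msa.alphabet)

    if symfrac is not None and not 0.0 <= symfrac <= 1.0:
        raise ValueError("symfrac must lie in [0, 1]")
    keep = consensus_columns(msa, weights, symfrac if symfrac is not None else 0.0)

    out: list[ColumnDistribution] = []
    for col in range(1, msa.ncols + 1):
        if not keep[col - 1]:
            continue
        counts, occupancy = count_column(msa, col, weights)
        csum = counts.sum()
        if method == "weighted_prior":
            p = apply_prior(counts, prior)
        else:
            if csum == 0:
                # residues present but all degenerate: fall back to background
                p = msa.alphabet.default_background.copy()
            else:
                p = counts / csum
        out.append(ColumnDistribution(p=p, raw_counts=counts, occupancy=occupancy,
                                      column_index=col))
    return out


def consensus_columns(
    msa: MultipleAlignment,
    weights: WeightVector | None = None,
    symfrac: float = 0.5,
) -> np.ndarray:
    """Boolean mask of consensus columns.

    A column is consensus when its weighted occupancy is at least
    ``symfrac``; empty columns are never consensus, so ``symfrac=0`` marks
    exactly the non-empty columns.
    """
    if not 0.0 <= symfrac <= 1.0:
        raise ValueError("symfrac must lie in [0, 1]")
    if weights is None:
        weights = unit_weights(msa.nseq)
    mask = np.zeros(msa.ncols, dtype=bool)
    for col in range(1, msa.ncols + 1):
        _, occ = count_column(msa, col, weights)
        mask[col - 1] = occ > 0.0 and occ >= symfrac
    return mask
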