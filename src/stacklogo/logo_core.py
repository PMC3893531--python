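"""Logo assembly: information content, letter stacks, gap parameters.

The conservation of a column with estimated letter distribution p against
background q is its information content (relative entropy)

    D(p||q) = sum_i p_i * log2(p_i / q_i)    [bits]

which is zero when p equals q and maximal, -log2(q_i), for a column
invariant in the letter that is rarest in the background.  Three letter
height modes are offered:

``info_all``
    Every letter with p_i > 0 gets height p_i * D (the conventional logo).
``info_above_bg``
    Stack height is still D, but it is divided only among letters whose
    log-odds score s_i = log2(p_i/q_i) is positive, in proportion to their
    probabilities — the below-background "smear" is suppressed.
``score``
    Each positive-scoring letter is drawn with height s_i.  The stack total
    is then just a sum of scores with no conservation interpretation.

For profile HMMs, per-position gap parameters are derived from the
transition table: occupancy is the probability of visiting match state k
(a two-term recursion over match/delete), the insert probability is the
m->i transition at k, and insert lengths are geometric with mean 1/(1-eps)
where eps is the insert self-transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment_io import Alphabet, MultipleAlignment
from .column_stats import DirichletPrior, estimate_columns
from .errors import EmptyInputError, LogoError
from .hmm_io import DM, II, MI, MM, ProfileHMM

NEG_INF = float("-inf")

HEIGHT_MODES = ("info_all", "info_above_bg", "score")
PROCESSING_TAGS = ("observed", "weighted", "weighted_prior", "hmm")


def information_content(p, q) -> float:
    """Relative entropy D(p||q) in bits; terms with p_i = 0 contribute 0."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    # 1e-4 tolerance: probabilities read back from 5-decimal -ln storage
    # carry O(1e-5) rounding in their sums
    if abs(p.sum() - 1.0) > 1e-4 or abs(q.sum() - 1.0) > 1e-4:
        raise ValueError("p and q must each sum to 1")
    if np.any((p > 0) & (q <= 0)):
        raise LogoError("divergence undefined: p_i > 0 where q_i = 0")
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def letter_score(p_i: float, q_i: float) -> float:
    """Log-odds score log2(p_i/q_i); -inf when p_i = 0."""
    if q_i <= 0:
        raise LogoError("letter score undefined for zero background probability")
    if p_i < 0:
        raise ValueError("probabilities must be nonnegative")
    if p_i == 0.0:
        return NEG_INF
    return math.log2(p_i / q_i)


def letter_scores(p, q) -> np.ndarray:
    """Vector of log-odds scores; entries are -inf where p_i = 0."""
    return np.array([letter_score(pi, qi) for pi, qi in zip(p, q)])


def _sorted_stack(entries: list[tuple[str, float]]) -> list[tuple[str, float]]:
    # bottom-to-top ascending height; ties put the alphabetically earlier
    # letter closer to the top (later in the list)
    return sorted(entries, key=lambda e: (e[1], [-ord(c) for c in e[0]]))


def letter_heights(p, q, mode: str = "info_all", letters=None) -> list[tuple[str, float]]:
    """Ordered letter stack for one column.

    Returns (letter, height-in-bits) pairs ordered bottom to top; the top
    entry is the tallest letter.  See the module docstring for the three
    modes.  Letters absent from the stack (p_i = 0, or non-positive score
    in the filtered modes) are simply not listed.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if letters is None:
        letters = [chr(ord("A") + i) for i in range(p.size)]
    if mode not in HEIGHT_MODES:
        raise ValueError(f"unknown height mode {mode!r}")

    if mode == "info_all":
        D = information_content(p, q)
        entries = [(a, float(pi * D)) for a, pi in zip(letters, p) if pi > 0]
        return _sorted_stack(entries)

    s = letter_scores(p, q)
    pos = s > 0
    if mode == "score":
        entries = [(a, float(si)) for a, si, keep in zip(letters, s, pos) if keep]
        return _sorted_stack(entries)

    # info_above_bg: same total height D, spread over positive-scoring letters
    D = information_content(p, q)
    p_pos = float(p[pos].sum())
    if D == 0.0 or p_pos == 0.0:
        return []
    entries = [(a, float(D * pi / p_pos))
               for a, pi, keep in zip(letters, p, pos) if keep]
    return _sorted_stack(entries)


def max_theoretical_height(alphabet: Alphabet | None = None, q=None) -> float:
    """Largest possible information content: max_i -log2(q_i).

    Achieved by a column invariant in the letter rarest under the
    background — 2 bits for uniform DNA, about 6.2 bits (tryptophan) under
    the BLOSUM62-associated amino background.
    """
    if q is None:
        if alphabet is None:
            raise ValueError("provide an alphabet or a background vector")
        q = alphabet.default_background
    q = np.asarray(q, float)
    if np.any(q <= 0):
        raise LogoError("background entries must be positive")
    return float(np.max(-np.log2(q)))


def match_occupancy(hmm: ProfileHMM) -> np.ndarray:
    """Probability of visiting each match state, positions 1..M.

    occ(1) = t0(m->m) + t0(m->i)  (everything out of the begin node except
    B->D1 eventually reaches M1), and

    occ(k) = occ(k-1) * (t_{k-1}(m->m) + t_{k-1}(m->i))
             + (1 - occ(k-1)) * t_{k-1}(d->m).
    """
    t = hmm.transitions
    occ = np.empty(hmm.M)
    occ[0] = t[0, MM] + t[0, MI]
    for k in range(1, hmm.M):
        occ[k] = occ[k - 1] * (t[k, MM] + t[k, MI]) + (1.0 - occ[k - 1]) * t[k, DM]
    return np.clip(occ, 0.0, 1.0)


def gap_parameters_from_hmm(hmm: ProfileHMM, k: int) -> tuple[float, float, float]:
    """(occupancy, insert probability, expected insert length) at position k.

    The insert length distribution is geometric with parameter eps (the
    i->i self-transition after k), so its mean is 1/(1-eps).
    """
    if not 1 <= k <= hmm.M:
        raise LogoError(f"position {k} outside 1..{hmm.M}")
    eps = float(hmm.transitions[k, II])
    if eps >= 1.0:
        raise LogoError(f"position {k}: insert self-transition is 1; expected length diverges")
    expected_len = 1.0 / (1.0 - eps)
    insert_prob = float(hmm.transitions[k, MI])
    occ = float(match_occupancy(hmm)[k - 1])
    return occ, insert_prob, expected_len


@dataclass
class LogoPosition:
    """One logo position: the letter stack plus its underlying numbers.

    ``stack`` is ordered bottom to top.  ``insert_probability`` and
    ``expected_insert_length`` are None for alignment logos, where every
    non-empty column already has its own position.
    """

    position: int
    stack: list[tuple[str, float]]
    info_content: float
    occupancy: float
    source_column: int
    full_distribution: np.ndarray
    scores: np.ndarray
    insert_probability: float | None = None
    expected_insert_length: float | None = None

    @property
    def stack_height(self) -> float:
        return float(sum(h for _, h in self.stack))


@dataclass
class Logo:
    """An assembled logo ready for serialization or rendering."""

    positions: list[LogoPosition]
    alphabet: Alphabet
    height_mode: str
    processing: str
    max_height: float
    background: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def is_profile(self) -> bool:
        return self.processing == "hmm"


def _make_position(
    k: int,
    p: np.ndarray,
    q: np.ndarray,
    mode: str,
    letters,
    occupancy: float,
    source_column: int,
    insert_probability: float | None = None,
    expected_insert_length: float | None = None,
) -> LogoPosition:
    return LogoPosition(
        position=k,
        stack=letter_heights(p, q, mode, letters),
        info_content=information_content(p, q),
        occupancy=occupancy,
        source_column=source_column,
        full_distribution=np.asarray(p, float),
        scores=letter_scores(p, q),
        insert_probability=insert_probability,
        expected_insert_length=expected_insert_length,
    )


def build_logo(
    source: MultipleAlignment | ProfileHMM,
    mode: str = "info_all",
    background=None,
    method: str = "weighted_prior",
    symfrac: float | None = 0.5,
    prior: DirichletPrior | None = None,
) -> Logo:
    """Build a logo from either an alignment or a profile HMM.

    Profile source: one position per match state, distributions taken
    straight from the match emissions, gap rows from the transition table,
    source columns from the MAP annotation when present.

    Alignment source: per-column distributions estimated under ``method``
    (see :mod:`stacklogo.column_stats`); only columns passing ``symfrac``
    occupancy become positions (``symfrac=0`` or None keeps every non-empty
    column); insert rows are absent, not zero.
    """
    if mode not in HEIGHT_MODES:
        raise ValueError(f"unknown height mode {mode!r}")

    if isinstance(source, ProfileHMM):
        hmm = source
        alphabet = hmm.alphabet
        q = alphabet.default_background if background is None else np.asarray(background, float)
        letters = alphabet.letters
        occ = match_occupancy(hmm)
        positions = []
        for k in range(1, hmm.M + 1):
            _, ins_p, ins_len = gap_parameters_from_hmm(hmm, k)
            src = hmm.map_annotation[k - 1] if hmm.map_annotation else k
            positions.append(
                _make_position(k, hmm.match_emissions[k - 1], q, mode, letters,
                               float(occ[k - 1]), src, ins_p, ins_len)
            )
        processing = "hmm"
    elif isinstance(source, MultipleAlignment):
        msa = source
        alphabet = msa.alphabet
        q = alphabet.default_background if background is None else np.asarray(background, float)
        letters = alphabet.letters
        cols = estimate_columns(msa, method=method, prior=prior, symfrac=symfrac)
        if not cols:
            raise EmptyInputError("no columns pass the occupancy threshold")
        positions = [
            _make_position(k, cd.p, q, mode, letters, cd.occupancy, cd.column_index)
            for k, cd in enumerate(cols, start=1)
        ]
        processing = method
    else:
        raise TypeError("source must be a MultipleAlignment or a ProfileHMM")

    return Logo(
        positions=positions,
        alphabet=alphabet,
        height_mode=mode,
        processing=processing,
        max_height=max_theoretical_height(q=q),
        background=np.asarray(q, float),
    )
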