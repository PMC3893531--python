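"""HMMER3 plain-text profile HMM reading and writing.

The save-file convention stores every probability as its negative natural
log, with ``*`` standing in for probability zero.  A model of length M has a
begin node (node 0, insert emissions + transitions only) followed by M match
nodes; each node carries a 7-way transition line in the fixed order

    m->m  m->i  m->d  i->m  i->i  d->m  d->d

This module parses those files into :class:`ProfileHMM` (probabilities, not
logs), keeps the MAP alignment-column annotation when present, and writes
models back out in the HMMER3/f dialect.
"""

from __future__ import annotations

import gzip
import io
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterator

import numpy as np

from .alignment_io import Alphabet
from .errors import EmptyInputError, HMMFormatError

TRANSITIONS = ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")
MM, MI, MD, IM, II, DM, DD = range(7)

_ALPH_MAP = {"DNA": "dna", "RNA": "rna", "AMINO": "amino"}


@dataclass
class ProfileHMM:
    """A profile HMM: per-node emissions and transitions, in probability space.

    ``transitions`` has shape (M+1, 7); row 0 is the begin node (its m->m,
    m->i, m->d entries are the B->M1, B->I0, B->D1 transitions), row k the
    transitions out of node k.  ``map_annotation``, when present, gives the
    1-based source alignment column of each match state.
    """

    name: str
    alphabet: Alphabet
    match_emissions: np.ndarray     # (M, L)
    insert_emissions: np.ndarray    # (M, L)
    transitions: np.ndarray         # (M+1, 7)
    map_annotation: list[int] | None = None
    compo: np.ndarray | None = None
    consensus: str | None = None
    header_extra: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, float)
        self.insert_emissions = np.asarray(self.insert_emissions, float)
        self.transitions = np.asarray(self.transitions, float)
        M, L = self.match_emissions.shape
        if M == 0:
            raise EmptyInputError("zero-length profile HMM")
        if L != self.alphabet.size:
            raise HMMFormatError(f"emission width {L} != alphabet size {self.alphabet.size}")
        if self.insert_emissions.shape != (M, L):
            raise HMMFormatError("insert emission matrix shape mismatch")
        if self.transitions.shape != (M + 1, 7):
            raise HMMFormatError("transition matrix must have M+1 rows of 7")

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, tol: float = 1e-4) -> None:
        """Check the probability-sum invariants of every node."""
        for label, mat in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            sums = mat.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > tol)[0]
            if bad.size:
                raise HMMFormatError(
                    f"{label} emissions of state {bad[0] + 1} sum to {sums[bad[0]]:.6f}"
                )
        t = self.transitions
        for k in range(self.M + 1):
            m_sum = t[k, MM] + t[k, MI] + t[k, MD]
            i_sum = t[k, IM] + t[k, II]
            d_sum = t[k, DM] + t[k, DD]
            # terminal node: m->d and d->d are structurally zero (written '*')
            if abs(m_sum - 1.0) > tol:
                raise HMMFormatError(f"node {k}: match transitions sum to {m_sum:.6f}")
            if abs(i_sum - 1.0) > tol:
                raise HMMFormatError(f"node {k}: insert transitions sum to {i_sum:.6f}")
            if k > 0 and abs(d_sum - 1.0) > tol:
                raise HMMFormatError(f"node {k}: delete transitions sum to {d_sum:.6f}")
        if self.map_annotation is not None:
            m = self.map_annotation
            if len(m) != self.M:
                raise HMMFormatError("MAP annotation length != model length")
            if any(b <= a for a, b in zip(m, m[1:])):
                raise HMMFormatError("MAP annotation is not strictly increasing")


# ---------------------------------------------------------------------------
# parsing


def _prob(token: str) -> float:
    if token == "*":
        return 0.0
    try:
        return math.exp(-float(token))
    except ValueError:
        raise HMMFormatError(f"bad probability field {token!r}") from None


def _logval(p: float) -> str:
    return "*" if p <= 0.0 else f"{-math.log(p):.5f}"


def _text_handle(source) -> IO[str]:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            if data[:2] == b"\x1f\x8b":
                data = gzip.decompress(data)
            return io.StringIO(data.decode())
        return io.StringIO(data)
    path = os.fspath(source)
    with open(path, "rb") as fh:
        if fh.read(2) == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def iter_hmms(source) -> Iterator[ProfileHMM]:
    """Yield every model in a (possibly multi-model) HMMER3 text file."""
    handle = _text_handle(source)
    lines = iter(handle.read().splitlines())
    while True:
        header = None
        for line in lines:
            if line.strip():
                header = line
                break
        if header is None:
            return
        if not header.startswith("HMMER3"):
            raise HMMFormatError(
                f"expected an HMMER3 format tag, found {header.split()[0]!r}"
            )
        yield _parse_model(lines)


def read_hmm(source) -> ProfileHMM:
    """Read the first profile HMM from ``source`` (path, stream, or text).

    A warning is issued if the file contains further models; use
    :func:`iter_hmms` to get all of them.
    """
    it = iter_hmms(source)
    try:
        hmm = next(it)
    except StopIteration:
        raise EmptyInputError("no HMM model found in input") from None
    try:
        next(it)
    except (StopIteration, HMMFormatError):
        pass
    else:
        warnings.warn("input contains multiple models; returning the first",
                      stacklevel=2)
    return hmm


def _parse_model(lines: Iterator[str]) -> ProfileHMM:
    name = ""
    leng: int | None = None
    alph: str | None = None
    has_map = False
    header_extra: list[tuple[str, str]] = []
    compo: np.ndarray | None = None

    line = None
    for line in lines:
        if line.startswith("HMM "):
            break
        if not line.strip():
            continue
        key, _, value = line.partition(" ")
        value = value.strip()
        if key == "NAME":
            name = value
        elif key == "LENG":
            leng = int(value)
        elif key == "ALPH":
            alph = value.upper()
        elif key == "MAP":
            has_map = value.lower() == "yes"
        else:
            header_extra.append((key, value))
    else:
        raise HMMFormatError("truncated file: no 'HMM' state-table header")

    if leng is None:
        raise HMMFormatError("missing LENG header")
    if alph is None:
        raise HMMFormatError("missing ALPH header")
    if alph not in _ALPH_MAP:
        raise HMMFormatError(f"unknown ALPH {alph!r}")
    alphabet = Alphabet.from_kind(_ALPH_MAP[alph])
    L = alphabet.size

    def next_line() -> str:
        for raw in lines:
            if raw.strip():
                return raw
        raise HMMFormatError("truncated file: missing '//' terminator")

    next_line()  # transition-name header row

    row = next_line()
    tokens = row.split()
    if tokens[0] == "COMPO":
        compo = np.array([_prob(t) for t in tokens[1 : 1 + L]])
        row = next_line()
        tokens = row.split()

    # begin node: insert emission line, then transition line
    insert0 = [_prob(t) for t in tokens[:L]]
    t0 = [_prob(t) for t in next_line().split()[:7]]

    match_emissions = np.zeros((leng, L))
    insert_emissions = np.zeros((leng, L))
    transitions = np.zeros((leng + 1, 7))
    transitions[0] = t0
    map_annotation: list[int] | None = [] if has_map else None
    consensus_chars: list[str] = []

    for k in range(1, leng + 1):
        tokens = next_line().split()
        if tokens[0] == "//":
            raise HMMFormatError(
                f"LENG is {leng} but the state table ends after node {k - 1}"
            )
        try:
            idx = int(tokens[0])
        except ValueError:
            raise HMMFormatError(f"expected match state {k}, found {tokens[0]!r}") from None
        if idx != k:
            raise HMMFormatError(f"match states out of order: expected {k}, found {idx}")
        match_emissions[k - 1] = [_prob(t) for t in tokens[1 : 1 + L]]
        annot = tokens[1 + L :]
        if map_annotation is not None:
            if not annot or annot[0] == "-":
                raise HMMFormatError(f"MAP yes but node {k} carries no map value")
            map_annotation.append(int(annot[0]))
            annot = annot[1:]
        consensus_chars.append(annot[0] if annot else "-")
        insert_emissions[k - 1] = [_prob(t) for t in next_line().split()[:L]]
        transitions[k] = [_prob(t) for t in next_line().split()[:7]]

    term = next_line().split()[0]
    if term != "//":
        raise HMMFormatError(f"expected '//' terminator, found {term!r}")
    # insert emissions of the begin node are not retained per match state;
    # HMMER's node-0 insert row is re-emitted from insert_emissions[0] on write
    del insert0

    consensus = "".join(consensus_chars)
    if set(consensus) <= {"-"}:
        consensus = None
    return ProfileHMM(
        name=name or "unnamed",
        alphabet=alphabet,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        map_annotation=map_annotation,
        compo=compo,
        consensus=consensus,
        header_extra=header_extra,
    )


# ---------------------------------------------------------------------------
# writing


def write_hmm(hmm: ProfileHMM, handle: IO[str] | None = None) -> str:
    """Serialize ``hmm`` as HMMER3/f text; returns the text.

    Probabilities are written as negative natural logs with five decimal
    places (``*`` for zero), so a read-back agrees with the original to
    better than 1e-4 per value.
    """
    hmm.validate()
    L = hmm.alphabet.size
    out = io.StringIO()
    out.write("HMMER3/f [stacklogo]\n")
    out.write(f"NAME  {hmm.name}\n")
    out.write(f"LENG  {hmm.M}\n")
    out.write(f"ALPH  {hmm.alphabet.kind.upper() if hmm.alphabet.kind != 'amino' else 'amino'}\n")
    out.write(f"MAP   {'yes' if hmm.map_annotation is not None else 'no'}\n")
    for key, value in hmm.header_extra:
        out.write(f"{key}  {value}\n")

    display = [a for a in hmm.alphabet.letters]
    out.write("HMM     " + "".join(f"     {a}    " for a in display).rstrip() + "\n")
    out.write("        " + "  ".join(f"{t:>7s}" for t in TRANSITIONS) + "\n")
    if hmm.compo is not None:
        out.write("  COMPO " + " ".join(f"{_logval(p):>8s}" for p in hmm.compo) + "\n")

    def emit_insert(k: int) -> None:
        row = hmm.insert_emissions[min(k, hmm.M - 1)]
        out.write("        " + " ".join(f"{_logval(p):>8s}" for p in row) + "\n")

    def emit_trans(k: int) -> None:
        vals = list(hmm.transitions[k])
        toks = [_logval(p) for p in vals]
        if k == hmm.M:  # terminal node: m->d and d->d are structural zeros
            toks[MD] = "*"
            toks[DD] = "*"
        out.write("        " + " ".join(f"{t:>8s}" for t in toks) + "\n")

    emit_insert(0)
    emit_trans(0)
    for k in range(1, hmm.M + 1):
        cons = hmm.consensus[k - 1] if hmm.consensus else "-"
        annot = f" {cons} - - -"  # CONS RF MM CS annotation columns
        if hmm.map_annotation is not None:
            annot = f" {hmm.map_annotation[k - 1]:6d}" + annot
        out.write(
            f"{k:7d} "
            + " ".join(f"{_logval(p):>8s}" for p in hmm.match_emissions[k - 1])
            + annot
            + "\n"
        )
        emit_insert(k)
        emit_trans(k)
    out.write("//\n")
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text
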