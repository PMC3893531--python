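"""Multiple sequence alignment input/output and alphabet handling.

Reads Stockholm 1.0 and aligned FASTA (plain or gzip-compressed) into a
rectangular :class:`MultipleAlignment`, detects whether the sequences are
DNA, RNA or protein, and defines the residue/gap/ambiguity character policy
used by every downstream estimator:

* ``-``, ``.``, ``_`` and ``~`` are gap characters;
* case is preserved in storage but ignored when counting (Stockholm marks
  insert-state residues with lower case);
* ambiguity codes (``N``, ``X``, IUPAC nucleotide codes, ``B/Z/J/U/O`` for
  protein) count toward column occupancy but contribute no letter counts.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, AlphabetError, EmptyInputError

GAP_CHARS = frozenset("-._~")

_DNA_LETTERS = tuple("ACGT")
_RNA_LETTERS = tuple("ACGU")
_AMINO_LETTERS = tuple("ACDEFGHIKLMNPQRSTVWY")

_NT_DEGENERATE = frozenset("RYSWKMBDHVN")
_AA_DEGENERATE = frozenset("BZJXUO")

# Robinson-Robinson amino acid frequencies, the background distribution
# conventionally paired with the BLOSUM62 scoring matrix.  Tryptophan is the
# rarest letter, so an invariant W column carries the most information.
ROBINSON_ROBINSON = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


@dataclass(frozen=True)
class Alphabet:
    """A biological alphabet with its gap policy and background distribution.

    Parameters
    ----------
    kind:
        ``"dna"``, ``"rna"`` or ``"amino"``.
    letters:
        The ordered canonical symbols (4 nucleotides or 20 amino acids).
    gap_chars, degenerate_chars:
        Characters treated as gaps, and ambiguity symbols that occupy a
        column without contributing letter counts.
    default_background:
        Background probability vector q over ``letters`` (sums to 1).
    """

    kind: str
    letters: tuple[str, ...]
    gap_chars: frozenset[str]
    degenerate_chars: frozenset[str]
    default_background: np.ndarray

    def __post_init__(self) -> None:
        expected = 4 if self.kind in ("dna", "rna") else 20
        if self.kind not in ("dna", "rna", "amino"):
            raise AlphabetError(f"unknown alphabet kind {self.kind!r}")
        if len(self.letters) != expected:
            raise AlphabetError(
                f"{self.kind} alphabet needs {expected} letters, got {len(self.letters)}"
            )
        q = np.asarray(self.default_background, dtype=float)
        if q.shape != (len(self.letters),) or np.any(q < 0):
            raise AlphabetError("background must be a nonnegative vector over letters")
        if abs(q.sum() - 1.0) > 1e-9:
            raise AlphabetError(f"background sums to {q.sum():.12f}, not 1")
        object.__setattr__(self, "default_background", q)

    # -- constructors ------------------------------------------------------

    @classmethod
    def dna(cls, background: np.ndarray | None = None) -> "Alphabet":
        q = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls("dna", _DNA_LETTERS, GAP_CHARS, _NT_DEGENERATE, q)

    @classmethod
    def rna(cls, background: np.ndarray | None = None) -> "Alphabet":
        q = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls("rna", _RNA_LETTERS, GAP_CHARS, _NT_DEGENERATE | {"T"}, q)

    @classmethod
    def amino(cls, background: np.ndarray | None = None) -> "Alphabet":
        if background is None:
            q = np.array([ROBINSON_ROBINSON[a] for a in _AMINO_LETTERS])
            q = q / q.sum()
        else:
            q = np.asarray(background, float)
        return cls("amino", _AMINO_LETTERS, GAP_CHARS, _AA_DEGENERATE, q)

    @classmethod
    def from_kind(cls, kind: str, background: np.ndarray | None = None) -> "Alphabet":
        try:
            return {"dna": cls.dna, "rna": cls.rna, "amino": cls.amino}[kind](background)
        except KeyError:
            raise AlphabetError(f"unknown alphabet kind {kind!r}") from None

    # -- character classification -----------------------------------------

    @property
    def size(self) -> int:
        return len(self.letters)

    def index_of(self, char: str) -> int | None:
        """Canonical letter index for ``char`` (case-insensitive), else None.

        For DNA, U is accepted as T; for RNA, T is accepted as U.
        """
        c = char.upper()
        if self.kind == "dna" and c == "U":
            c = "T"
        elif self.kind == "rna" and c == "T":
            c = "U"
        try:
            return self.letters.index(c)
        except ValueError:
            return None

    def is_gap(self, char: str) -> bool:
        return char in self.gap_chars

    def is_degenerate(self, char: str) -> bool:
        return char.upper() in self.degenerate_chars

    def validate_char(self, char: str) -> None:
        if self.is_gap(char):
            return
        if self.index_of(char) is None and not self.is_degenerate(char):
            raise AlphabetError(
                f"character {char!r} is neither a {self.kind} residue, an "
                f"ambiguity code, nor a gap"
            )


@dataclass
class MultipleAlignment:
    """A rectangular multiple sequence alignment.

    ``rows`` keeps the characters exactly as read (case preserved); all
    counting goes through :meth:`Alphabet.index_of`, which is
    case-insensitive.  ``reference_line`` keeps a Stockholm ``#=GC RF``
    annotation when one was present.
    """

    ids: list[str]
    rows: list[str]
    alphabet: Alphabet
    reference_line: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyInputError("alignment has no sequences")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dup = next(i for i in self.ids if self.ids.count(i) > 1)
            raise AlignmentError(f"duplicate sequence identifier {dup!r}")
        n = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise AlignmentError(
                    f"sequence {sid!r} has aligned length {len(row)}, expected {n}"
                )
        for sid, row in zip(self.ids, self.rows):
            for ch in row:
                try:
                    self.alphabet.validate_char(ch)
                except AlphabetError as e:
                    raise AlphabetError(f"sequence {sid!r}: {e}") from None

    @property
    def nseq(self) -> int:
        return len(self.rows)

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.ncols:
            raise AlignmentError(f"column {col} outside 1..{self.ncols}")
        return "".join(row[col - 1] for row in self.rows)


# ---------------------------------------------------------------------------
# reading / writing


def _open_maybe_gzip(source) -> IO[str]:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            if data[:2] == b"\x1f\x8b":
                data = gzip.decompress(data)
            return io.StringIO(data.decode())
        return io.StringIO(data)
    path = os.fspath(source)
    with open(path, "rb") as fh:
        head = fh.read(2)
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def detect_alphabet(rows: Iterable[str], threshold: float = 0.95) -> Alphabet:
    """Classify raw aligned rows as DNA, RNA or protein.

    Nucleic if at least ``threshold`` of the non-gap characters fall in
    ``{A,C,G,T,U,N}`` (case-insensitive); RNA if U is observed and T is not,
    DNA otherwise; protein in all remaining cases.
    """
    counts: dict[str, int] = {}
    total = 0
    for row in rows:
        for ch in row:
            if ch in GAP_CHARS:
                continue
            c = ch.upper()
            counts[c] = counts.get(c, 0) + 1
            total += 1
    if total == 0:
        raise EmptyInputError("no residues present; alphabet is undecidable")
    nt = sum(counts.get(c, 0) for c in "ACGTUN")
    if nt / total >= threshold:
        if counts.get("U", 0) > 0 and counts.get("T", 0) == 0:
            return Alphabet.rna()
        return Alphabet.dna()
    return Alphabet.amino()


def read_alignment(
    source,
    format: str = "afa",
    alphabet: Alphabet | None = None,
) -> MultipleAlignment:
    """Read a multiple alignment from a path or open stream.

    Parameters
    ----------
    source:
        Path or text/binary stream; gzip input is detected automatically.
    format:
        ``"afa"`` (aligned FASTA) or ``"stockholm"`` (``"sto"`` accepted).
    alphabet:
        Force an alphabet; by default it is detected from the residues.
    """
    fmt = {"afa": "fasta", "fasta": "fasta", "stockholm": "stockholm",
           "sto": "stockholm"}.get(format)
    if fmt is None:
        raise AlignmentError(f"unsupported alignment format {format!r}")
    handle = _open_maybe_gzip(source)

    ids: list[str] = []
    rows: list[str] = []
    reference_line: str | None = None
    if fmt == "fasta":
        try:
            for rec in SeqIO.parse(handle, "fasta"):
                ids.append(rec.id)
                rows.append(str(rec.seq))
        except ValueError as e:
            raise AlignmentError(f"malformed FASTA input: {e}") from None
    else:
        try:
            aln = AlignIO.read(handle, "stockholm")
        except ValueError as e:
            msg = str(e)
            if "No records found" in msg or "Empty file" in msg:
                raise EmptyInputError("empty alignment input") from None
            raise AlignmentError(f"malformed Stockholm input: {e}") from None
        ids = [rec.id for rec in aln]
        rows = [str(rec.seq) for rec in aln]
        reference_line = aln.column_annotations.get("reference_annotation")
    if not rows:
        raise EmptyInputError("empty alignment input")

    n = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != n:
            raise AlignmentError(
                f"sequence {sid!r} has aligned length {len(row)}, expected {n}"
            )
    if alphabet is None:
        alphabet = detect_alphabet(rows)
    return MultipleAlignment(ids=ids, rows=rows, alphabet=alphabet,
                             reference_line=reference_line)


def write_alignment(msa: MultipleAlignment, handle: IO[str], format: str = "afa") -> None:
    """Write ``msa`` as aligned FASTA or Stockholm."""
    fmt = {"afa": "fasta", "fasta": "fasta", "stockholm": "stockholm",
           "sto": "stockholm"}.get(format)
    if fmt is None:
        raise AlignmentError(f"unsupported alignment format {format!r}")
    if fmt == "fasta":
        for sid, row in zip(msa.ids, msa.rows):
            handle.write(f">{sid}\n{row}\n")
        return
    records = [
        SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(msa.ids, msa.rows)
    ]
    aln = MultipleSeqAlignment(records)
    if msa.reference_line is not None:
        aln.column_annotations["reference_annotation"] = msa.reference_line
    AlignIO.write(aln, handle, "stockholm")
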