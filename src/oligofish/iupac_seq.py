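"""Degenerate nucleotide sequences over the 15-letter IUPAC alphabet.

A degenerate oligo is synthesized as a pool: each ambiguity code (R, Y, S,
W, K, M, B, D, H, V, N) stands for a set of bases, and the pool contains
every fixed sequence obtained by choosing one base per position.  This
module provides the sequence model used throughout the package: validation,
expansion of the pool, GC-content bounds (which drive melting-temperature
ranges), reverse complementation, and FASTA I/O.

Input is case-insensitive and RNA-style ``U`` is accepted (mapped to ``T``),
since ribosomal-DNA records in public databases are frequently annotated as
RNA.  Sequences are stored uppercase.
"""

from __future__ import annotations

import itertools
from math import prod
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_BASES",
    "DEFAULT_EXPANSION_CAP",
    "DegenerateSeq",
    "FixedSeq",
    "DegeneracyOverflowError",
    "FastaFormatError",
    "degeneracy",
    "expand_degenerate",
    "gc_bounds",
    "revcomp",
    "read_fasta",
    "write_fasta",
]

#: Base set for each IUPAC nucleotide code.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: IUPAC code for each base set (inverse of IUPAC_BASES).
CODE_FOR_BASES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}

_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Complement of each IUPAC code (complement of the underlying base set).
IUPAC_COMPLEMENT: dict[str, str] = {
    code: CODE_FOR_BASES[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_BASES.items()
}

#: Above this pool size :meth:`DegenerateSeq.expand` refuses and only the
#: degeneracy count remains available.
DEFAULT_EXPANSION_CAP = 4096

_GC = frozenset("GC")


class DegeneracyOverflowError(ValueError):
    """Expansion refused because the pool would exceed the cap.

    The offending pool size is carried in :attr:`degeneracy` so callers can
    still report the count without materializing the pool.
    """

    def __init__(self, degeneracy: int, cap: int):
        self.degeneracy = degeneracy
        self.cap = cap
        super().__init__(
            f"degeneracy {degeneracy} exceeds expansion cap {cap}; "
            "only the count is available"
        )


class FastaFormatError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class DegenerateSeq:
    """Immutable nucleotide string over the 15-letter IUPAC alphabet.

    Parameters
    ----------
    letters:
        Sequence letters; case-insensitive, ``U`` accepted as ``T``.

    Raises
    ------
    ValueError
        If the string is empty or contains a non-IUPAC letter.
    """

    __slots__ = ("_letters",)

    def __init__(self, letters: str):
        s = str(letters).upper().replace("U", "T")
        if not s:
            raise ValueError("sequence must contain at least one letter")
        for i, ch in enumerate(s):
            if ch not in IUPAC_BASES:
                raise ValueError(
                    f"invalid nucleotide letter {ch!r} at position {i + 1}"
                )
        self._letters = s

    @property
    def letters(self) -> str:
        return self._letters

    def __str__(self) -> str:
        return self._letters

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self._letters!r})"

    def __len__(self) -> int:
        return len(self._letters)

    def __iter__(self) -> Iterator[str]:
        return iter(self._letters)

    def __getitem__(self, item) -> "DegenerateSeq":
        return DegenerateSeq(self._letters[item])

    def __eq__(self, other) -> bool:
        if isinstance(other, DegenerateSeq):
            return self._letters == other._letters
        if isinstance(other, str):
            return self._letters == other.upper()
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._letters)

    @property
    def degeneracy(self) -> int:
        """Pool size: product of per-letter base-set sizes."""
        return prod(len(IUPAC_BASES[c]) for c in self._letters)

    @property
    def is_fixed(self) -> bool:
        """True iff the sequence contains only A/C/G/T (degeneracy 1)."""
        return self.degeneracy == 1

    def expand(self, cap: int = DEFAULT_EXPANSION_CAP) -> set["FixedSeq"]:
        """Materialize the pool of fixed sequences this oligo stands for.

        Refuses with :class:`DegeneracyOverflowError` when the pool exceeds
        ``cap`` (guarding combinatorial blow-up); the count itself is always
        available via :attr:`degeneracy`.
        """
        d = self.degeneracy
        if d > cap:
            raise DegeneracyOverflowError(d, cap)
        choices = [sorted(IUPAC_BASES[c]) for c in self._letters]
        return {FixedSeq("".join(p)) for p in itertools.product(*choices)}

    def gc_bounds(self) -> tuple[int, int]:
        """Minimum and maximum G+C count attainable over the pool.

        A letter contributes 1 to the minimum iff its base set lies inside
        {G, C}, and 1 to the maximum iff it intersects {G, C}; the bounds are
        attained because positions vary independently.
        """
        lo = hi = 0
        for c in self._letters:
            bases = IUPAC_BASES[c]
            if bases <= _GC:
                lo += 1
            if bases & _GC:
                hi += 1
        return lo, hi

    def reverse_complement(self) -> "DegenerateSeq":
        rc = "".join(IUPAC_COMPLEMENT[c] for c in reversed(self._letters))
        return type(self)(rc)


class FixedSeq(DegenerateSeq):
    """Plain A/C/G/T sequence — a degeneracy-1 :class:`DegenerateSeq`."""

    __slots__ = ()

    def __init__(self, letters: str):
        super().__init__(letters)
        for i, ch in enumerate(self._letters):
            if ch not in "ACGT":
                raise ValueError(
                    f"FixedSeq letter {ch!r} at position {i + 1} is degenerate"
                )


# ---------------------------------------------------------------------------
# Functional wrappers (the operation surface used by the rest of the package)


def degeneracy(seq: DegenerateSeq | str) -> int:
    return _as_seq(seq).degeneracy


def expand_degenerate(
    seq: DegenerateSeq | str, cap: int = DEFAULT_EXPANSION_CAP
) -> set[FixedSeq]:
    return _as_seq(seq).expand(cap)


def gc_bounds(seq: DegenerateSeq | str) -> tuple[int, int]:
    return _as_seq(seq).gc_bounds()


def revcomp(seq: DegenerateSeq | str) -> DegenerateSeq:
    return _as_seq(seq).reverse_complement()


def _as_seq(seq: DegenerateSeq | str) -> DegenerateSeq:
    return seq if isinstance(seq, DegenerateSeq) else DegenerateSeq(seq)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[tuple[str, DegenerateSeq]]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file.

    Returns ``(id, sequence)`` pairs in file order.  A malformed record
    raises :class:`FastaFormatError` naming the offending line.
    """
    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - SeqIO is lenient
        raise FastaFormatError(f"{path}: {exc}") from exc
    if not parsed:
        raise FastaFormatError(f"{path}: no FASTA records found")
    for rec in parsed:
        try:
            seq = DegenerateSeq(str(rec.seq))
        except ValueError as exc:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} (line {_record_line(path, rec.id)}): {exc}"
            ) from exc
        records.append((rec.id, seq))
    return records


def _record_line(path: Path, rec_id: str) -> int:
    """1-based line number of the header of record ``rec_id``."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[:1] == [rec_id]:
                return lineno
    return 0


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, DegenerateSeq | str]]
) -> None:
    """Write ``(id, sequence)`` pairs as FASTA; inverse of :func:`read_fasta`."""
    out = [
        SeqRecord(Seq(str(seq)), id=str(name), description="")
        for name, seq in records
    ]
    SeqIO.write(out, str(path), "fasta")
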