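"""FASTA input, alphabet handling, strands, and MAW output.

Sequences are processed per record: a multi-FASTA file yields one
independent MAW computation per record, never a concatenation, since
concatenating would manufacture factors that span record boundaries.
Residues are uppercased on read (genome FASTA uses lowercase for
soft-masking, which carries no meaning for absent-word analysis).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "infer_alphabet",
    "read_fasta",
    "reverse_complement",
    "write_maws",
    "write_maw_tuples",
]

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: identifier, free-text description, residues."""

    identifier: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("record identifier must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.identifier!r} has no residues")


@dataclass(frozen=True)
class Alphabet:
    """An ordered alphabet; the order defines the lexicographic order of suffixes.

    ``letters`` are distinct, strictly increasing symbols; ``index`` maps a
    symbol to its rank in ``[0, size)``.
    """

    letters: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError("alphabet must contain at least one letter")
        if any(a >= b for a, b in zip(self.letters, self.letters[1:])):
            raise ValueError("alphabet letters must be strictly increasing")
        object.__setattr__(self, "index", {c: k for k, c in enumerate(self.letters)})

    @property
    def size(self) -> int:
        return len(self.letters)

    @classmethod
    def from_text(cls, text: str) -> "Alphabet":
        return cls(tuple(sorted(set(text))))

    def encode(self, residues: str) -> list[int]:
        """Map residues to letter indices; raises on symbols outside the alphabet."""
        idx = self.index
        try:
            return [idx[c] for c in residues]
        except KeyError as exc:
            raise ValueError(f"symbol {exc.args[0]!r} is not in the alphabet") from None


def _as_text_stream(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "rt", encoding="ascii"), True
    return source, False


def read_fasta(source: str | Path | IO[str]) -> list[SequenceRecord]:
    """Read a (multi-)FASTA stream or path into :class:`SequenceRecord` objects.

    Sequence lines are concatenated across wrapping and uppercased; record
    order is preserved.  An empty stream, or sequence data appearing before
    the first ``>`` header, is a format error.
    """
    handle, owned = _as_text_stream(source)
    try:
        text = handle.read()
    finally:
        if owned:
            handle.close()

    stripped_lines = [ln.strip() for ln in text.splitlines()]
    meaningful = [ln for ln in stripped_lines if ln]
    if not meaningful:
        raise ValueError("FASTA input contains no records")
    if not meaningful[0].startswith(">"):
        raise ValueError("FASTA format error: sequence data before the first '>' header")

    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(
            SequenceRecord(
                identifier=rec.id,
                description=rec.description,
                residues=str(rec.seq).upper(),
            )
        )
    if not records:
        raise ValueError("FASTA input contains no records")
    return records


def infer_alphabet(records: Iterable[SequenceRecord]) -> Alphabet:
    """Ordered alphabet of all distinct residues across ``records``.

    Letters sort in natural character order, so for plain DNA the result is
    ``(A, C, G, T)``.  Deterministic for a fixed input.
    """
    seen: set[str] = set()
    empty = True
    for rec in records:
        empty = False
        seen.update(rec.residues)
    if empty:
        raise ValueError("cannot infer an alphabet from zero records")
    return Alphabet(tuple(sorted(seen)))


def reverse_complement(residues: str) -> str:
    """Reverse complement of a DNA string over ``{A, C, G, T, N}``.

    ``N`` is self-complementary.  Any other symbol raises, naming the
    offending character and its 0-based position.
    """
    out = []
    for pos, c in enumerate(residues):
        comp = _DNA_COMPLEMENT.get(c)
        if comp is None:
            raise ValueError(
                f"cannot reverse-complement symbol {c!r} at position {pos}: not a DNA letter"
            )
        out.append(comp)
    return "".join(reversed(out))


def write_maws(sink: IO[str], record: SequenceRecord, maws: Iterable[str]) -> None:
    """Write one record's MAWs: a ``>identifier`` line, then one word per line.

    Words are emitted in lexicographic order so output is deterministic and
    diffable; total line count is ``1 + len(maws)``.
    """
    sink.write(f">{record.identifier}\n")
    for word in sorted(maws):
        sink.write(word + "\n")


def write_maw_tuples(
    sink: IO[str], record: SequenceRecord, tuples: Iterable[Sequence]
) -> None:
    """Tuple-mode output: per MAW one ``a<TAB>i<TAB>j`` line.

    ``(i, j)`` is the 0-based inclusive interval of the record's residues
    spelling the MAW's tail; ``a`` is its first letter.
    """
    sink.write(f">{record.identifier}\n")
    for a, i, j in tuples:
        sink.write(f"{a}\t{i}\t{j}\n")
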