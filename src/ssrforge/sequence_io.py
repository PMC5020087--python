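"""Sequence input/output, overlap chunking and coordinate lift-back.

Long chromosomes are sliced into overlapping chunks before repeat mining so
that memory stays bounded; the small overlap lets tandem runs that straddle a
chunk boundary be re-assembled afterwards.  All user-facing coordinates are
1-based inclusive; chunk offsets are internal 0-based.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Tuple, Union

from Bio import SeqIO

PathLike = Union[str, Path]

#: Default chunk size in bp: sequences longer than this are sliced.
DEFAULT_CHUNK_SIZE = 2_000_000
#: Default overlap between consecutive chunks, in bp.
DEFAULT_OVERLAP = 20


class SequenceFormatError(ValueError):
    """Malformed or empty sequence input."""


class DuplicateIdError(SequenceFormatError):
    """Two records in one collection share an identifier."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence.

    The identifier is the FASTA header token up to the first whitespace;
    the description, if any, is dropped.  Case of the sequence is preserved
    (soft-masked lowercase stays lowercase).
    """

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence record has an empty id")


@dataclass(frozen=True)
class Chunk:
    """A slice of a parent sequence carrying the offset for lift-back.

    ``offset`` is the 0-based start of this chunk within its parent, so a
    1-based local position ``p`` corresponds to parent position
    ``offset + p``.
    """

    parent_id: str
    index: int
    offset: int
    sequence: str
    overlap: int

    @property
    def length(self) -> int:
        return len(self.sequence)


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: PathLike) -> List[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into a list of records.

    Multi-line sequences are concatenated, CR/LF line endings tolerated,
    case preserved.  Raises :class:`SequenceFormatError` on an empty file or
    a file with no header line, :class:`DuplicateIdError` on repeated ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as handle:
        text_start = handle.read(1)
        if text_start == "":
            raise SequenceFormatError(f"{path}: empty file")
        if text_start not in (">", ";"):
            raise SequenceFormatError(f"{path}: not FASTA (no '>' header line)")
    with _open_text(path) as handle:
        records = [
            SequenceRecord(id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise SequenceFormatError(f"{path}: no sequence records found")
    _check_unique_ids(records, path)
    return records


def _check_unique_ids(records: Sequence[SequenceRecord], path: PathLike) -> None:
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def fastq_to_fasta(path: PathLike) -> List[SequenceRecord]:
    """Read FASTQ and return the sequences as FASTA-style records.

    Quality lines are discarded; ids are taken from the ``@`` lines.  A
    truncated trailing record raises an error naming its (1-based) index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[SequenceRecord] = []
    with _open_text(path) as handle:
        if handle.read(1) == "":
            raise SequenceFormatError(f"{path}: empty file")
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise SequenceFormatError(
                    f"{path}: malformed FASTQ record {index + 1}: {exc}"
                ) from exc
            index += 1
            records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise SequenceFormatError(f"{path}: no FASTQ records found")
    _check_unique_ids(records, path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    """Write records as multi-line FASTA with the given line width."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def chunk_sequence(
    record: SequenceRecord,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    overlap: int = DEFAULT_OVERLAP,
) -> List[Chunk]:
    """Slice a sequence into overlapping chunks.

    Chunk ``k`` covers parent positions
    ``[k*(chunk_size-overlap), k*(chunk_size-overlap)+chunk_size)`` (0-based,
    clipped to the parent end), so consecutive chunks share exactly
    ``overlap`` bases and every parent base lies in at least one chunk.
    Sequences no longer than ``chunk_size`` yield a single chunk.
    """
    if chunk_size <= 0:
        raise ValueError("chunk_size must be positive")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    if chunk_size <= 2 * overlap:
        raise ValueError(
            f"chunk_size ({chunk_size}) must exceed twice the overlap ({overlap})"
        )
    seq = record.sequence
    n = len(seq)
    if n <= chunk_size:
        return [Chunk(record.id, 0, 0, seq, overlap)]
    step = chunk_size - overlap
    chunks: List[Chunk] = []
    k = 0
    while True:
        start = k * step
        if start >= n:
            break
        piece = seq[start : start + chunk_size]
        chunks.append(Chunk(record.id, k, start, piece, overlap))
        if start + chunk_size >= n:
            break
        k += 1
    return chunks


def lift_to_parent(chunk: Chunk, local_pos: int) -> int:
    """Map a 1-based position inside a chunk to the parent sequence."""
    if not 1 <= local_pos <= chunk.length:
        raise ValueError(
            f"local position {local_pos} outside chunk of length {chunk.length}"
        )
    return chunk.offset + local_pos


def extract_flank(
    record: SequenceRecord, start: int, end: int, flank: int
) -> Tuple[str, int]:
    """Extract a window of ``flank`` bp on either side of [start, end].

    Coordinates are 1-based inclusive.  The window is clipped silently at the
    sequence ends.  Returns ``(window_sequence, window_start)`` where
    ``window_start`` is the 1-based parent position of the first window base,
    allowing positions within the window to be lifted back.
    """
    if not (1 <= start <= end <= record.length):
        raise ValueError(
            f"invalid interval {start}-{end} on {record.id} (length {record.length})"
        )
    if flank < 0:
        raise ValueError("flank must be >= 0")
    win_start = max(1, start - flank)
    win_end = min(record.length, end + flank)
    return record.sequence[win_start - 1 : win_end], win_start


def reassemble(chunks: Sequence[Chunk]) -> str:
    """Concatenate chunks with overlaps removed; inverse of chunking."""
    out: List[str] = []
    for i, chunk in enumerate(sorted(chunks, key=lambda c: c.index)):
        if i == 0:
            out.append(chunk.sequence)
        else:
            out.append(chunk.sequence[chunk.overlap :])
    return "".join(out)


def iter_chunks(
    records: Iterable[SequenceRecord],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    overlap: int = DEFAULT_OVERLAP,
) -> Iterator[Chunk]:
    for record in records:
        yield from chunk_sequence(record, chunk_size, overlap)
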