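"""Streaming FASTQ input/output for single-end sequencing reads.

Reads are carried as :class:`ReadRecord` objects (Phred+33 qualities decoded to
integer scores). Parsing is streaming — memory use does not depend on file
size — and gzip compression is autodetected from the magic bytes unless the
caller states it explicitly.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["ReadRecord", "FastqParseError", "read_fastq", "write_fastq"]

VALID_BASES = frozenset("ACGTN")
_GZIP_MAGIC = b"\x1f\x8b"


class FastqParseError(ValueError):
    """A FASTQ record violated the 4-line format or the record invariants."""


@dataclass
class ReadRecord:
    """One single-end sequencing read.

    Parameters
    ----------
    read_id : str
        Record identifier (the FASTQ title line without the leading ``@``).
    sequence : str
        Bases over ``{A, C, G, T, N}``; lowercase input is uppercased.
    qualities : list[int]
        Phred scores, one per base (Phred+33 on disk).
    """

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("read %r has an empty sequence" % self.read_id)
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                "read %r contains invalid bases %s (alphabet is A/C/G/T/N)"
                % (self.read_id, sorted(bad))
            )
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                "read %r: %d quality scores for %d bases"
                % (self.read_id, len(self.qualities), len(self.sequence))
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _is_gzipped(path: Path) -> bool:
    with open(path, "rb") as handle:
        return handle.read(2) == _GZIP_MAGIC


def read_fastq(
    path: Union[str, Path], expect_gzip: Optional[bool] = None
) -> Iterator[ReadRecord]:
    """Lazily parse a FASTQ file into validated :class:`ReadRecord` objects.

    Parameters
    ----------
    path : path-like
        A 4-line-per-record FASTQ file, plain or gzip-compressed.
    expect_gzip : bool, optional
        Force (de)compression; when omitted the gzip magic bytes decide.

    Yields
    ------
    ReadRecord
        Records in file order. Qualities are decoded assuming Phred+33 and
        never re-encoded or filtered.

    Raises
    ------
    FastqParseError
        On a malformed record (missing ``+`` line, sequence/quality length
        mismatch, invalid alphabet); the message names the 0-based record
        index.
    """
    path = Path(path)
    if expect_gzip is None:
        expect_gzip = _is_gzipped(path)
    opener = gzip.open if expect_gzip else open
    with opener(path, "rt") as handle:  # type: ignore[operator]
        parser = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"malformed FASTQ record at index {index} in {path}: {exc}"
                ) from exc
            try:
                record = ReadRecord(
                    read_id=title,
                    sequence=seq,
                    qualities=[ord(c) - 33 for c in qual],
                )
            except ValueError as exc:
                raise FastqParseError(
                    f"invalid FASTQ record at index {index} in {path}: {exc}"
                ) from exc
            yield record
            index += 1


def write_fastq(
    records: Iterable[ReadRecord],
    path: Union[str, Path],
    gzip_output: bool = False,
) -> int:
    """Write records as 4-line FASTQ (Phred+33); returns the record count.

    Output round-trips through :func:`read_fastq` to an identical stream.
    Gzip output pins the header mtime to 0 so identical inputs produce
    byte-identical files.
    """
    path = Path(path)
    count = 0
    if gzip_output:
        raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        handle: _stdio.TextIOBase = _stdio.TextIOWrapper(gz, encoding="ascii")
    else:
        handle = open(path, "wt", encoding="ascii")
    try:
        for record in records:
            qual = "".join(chr(q + 33) for q in record.qualities)
            handle.write(f"@{record.read_id}\n{record.sequence}\n+\n{qual}\n")
            count += 1
    finally:
        handle.close()
        if gzip_output:
            raw.close()
    return count
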