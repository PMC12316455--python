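"""Strand-aware telomeric read classification.

END-seq sequences the first base of a blunted DNA end, so strand identity is
read directly off the sequenced orientation: a read from a natural chromosome
terminus carries the C-rich strand (CCCTAA repeats), a read from the
telomere-distal side of an internal break carries the G-rich strand (TTAGGG
repeats). A read is called telomeric when it contains at least ``min_repeats``
exact, consecutive copies of the repeat unit anywhere in the read; reads
containing runs of both units are flagged ambiguous and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Iterator, Optional, Tuple

from .io import ReadRecord

__all__ = [
    "StrandClass",
    "ClassifierParams",
    "StrandCounts",
    "has_repeat_run",
    "classify_read",
    "classify_stream",
    "tally_library",
]

G_UNIT = "TTAGGG"
C_UNIT = "CCCTAA"


class StrandClass(str, Enum):
    G_RICH = "G_RICH"
    C_RICH = "C_RICH"
    AMBIGUOUS = "AMBIGUOUS"
    NON_TELOMERIC = "NON_TELOMERIC"


@dataclass(frozen=True)
class ClassifierParams:
    """Repeat units and run-length threshold for telomeric classification.

    Defaults are the human telomeric hexamers with a minimum of four
    consecutive repeats. The machinery is motif-generic: any complementary
    unit pair (e.g. a centromeric consensus) can be substituted.
    """

    unit_g: str = G_UNIT
    unit_c: str = C_UNIT
    min_repeats: int = 4

    def __post_init__(self) -> None:
        if not self.unit_g or not self.unit_c:
            raise ValueError("repeat units must be non-empty")
        if self.min_repeats < 1:
            raise ValueError("min_repeats must be >= 1")
        object.__setattr__(self, "unit_g", self.unit_g.upper())
        object.__setattr__(self, "unit_c", self.unit_c.upper())


DEFAULT_PARAMS = ClassifierParams()


def has_repeat_run(
    sequence: str, unit: str, k: int
) -> Tuple[bool, Optional[int]]:
    """Test for ``k`` exact consecutive copies of ``unit`` in ``sequence``.

    Matching is literal: mismatches and ``N`` break a run. Returns
    ``(found, start)`` where ``start`` is the 0-based position of the leftmost
    occurrence of the concatenated run (``None`` when absent). Sequences
    shorter than ``k * len(unit)`` simply return ``(False, None)``.
    """
    if not unit:
        raise ValueError("unit must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    start = sequence.find(unit * k)
    return (start != -1, start if start != -1 else None)


def classify_read(
    read: ReadRecord, params: ClassifierParams = DEFAULT_PARAMS
) -> StrandClass:
    """Assign one of the four strand classes to a read.

    No reverse-complement search is performed: END-seq's sequenced orientation
    is the strand identity.
    """
    g_found, _ = has_repeat_run(read.sequence, params.unit_g, params.min_repeats)
    c_found, _ = has_repeat_run(read.sequence, params.unit_c, params.min_repeats)
    if g_found and c_found:
        return StrandClass.AMBIGUOUS
    if g_found:
        return StrandClass.G_RICH
    if c_found:
        return StrandClass.C_RICH
    return StrandClass.NON_TELOMERIC


def classify_stream(
    reads: Iterable[ReadRecord], params: ClassifierParams = DEFAULT_PARAMS
) -> Iterator[Tuple[ReadRecord, StrandClass]]:
    """Lazily classify a read stream, yielding ``(read, strand_class)``."""
    for read in reads:
        yield read, classify_read(read, params)


@dataclass(frozen=True)
class StrandCounts:
    """Per-library tallies of the four strand classes.

    RPM values are normalised to the total number of reads in the library
    (telomeric or not), matching how END-seq telomeric signal is reported.
    """

    total_reads: int
    g_rich: int
    c_rich: int
    ambiguous: int
    non_telomeric: int

    def __post_init__(self) -> None:
        parts = self.g_rich + self.c_rich + self.ambiguous + self.non_telomeric
        if parts != self.total_reads:
            raise ValueError(
                f"class counts sum to {parts}, not total_reads={self.total_reads}"
            )
        if self.total_reads <= 0:
            raise ValueError("empty library: RPM is undefined for 0 reads")

    @property
    def rpm_g(self) -> float:
        return 1e6 * self.g_rich / self.total_reads

    @property
    def rpm_c(self) -> float:
        return 1e6 * self.c_rich / self.total_reads

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "g_rich": self.g_rich,
            "c_rich": self.c_rich,
            "ambiguous": self.ambiguous,
            "non_telomeric": self.non_telomeric,
            "rpm_g": self.rpm_g,
            "rpm_c": self.rpm_c,
        }


def tally_library(
    reads: Iterable[ReadRecord],
    params: ClassifierParams = DEFAULT_PARAMS,
    sink: Optional[Callable[[ReadRecord, StrandClass], None]] = None,
) -> StrandCounts:
    """Classify a whole library and tally the four classes.

    ``sink``, when given, receives every ``(read, strand_class)`` pair as it
    is classified — the pass-through channel downstream stages (terminal-end
    extraction, VTR scanning) use so the library is only streamed once.

    Raises
    ------
    ValueError
        If the stream is empty (RPM normalisation is undefined).
    """
    totals = {cls: 0 for cls in StrandClass}
    n = 0
    for read, cls in classify_stream(reads, params):
        totals[cls] += 1
        n += 1
        if sink is not None:
            sink(read, cls)
    if n == 0:
        raise ValueError("empty library: no reads to tally")
    return StrandCounts(
        total_reads=n,
        g_rich=totals[StrandClass.G_RICH],
        c_rich=totals[StrandClass.C_RICH],
        ambiguous=totals[StrandClass.AMBIGUOUS],
        non_telomeric=totals[StrandClass.NON_TELOMERIC],
    )
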