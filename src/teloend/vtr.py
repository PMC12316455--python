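"""Variant telomeric repeat (VTR) scanning in the terminal read window.

Variant repeats are counted at the repeat-unit level within the first W
nucleotides of each telomeric read (default 30 nt = 5 tiled hexamers). For
each read the tiling phase offset in {0..5} maximising exact canonical-unit
matches is chosen first, so a rotated terminal phase — which shifts every
unit boundary but changes no repeat — does not flag the whole read. A
complete tiled unit differing from the canonical unit in at least one
position counts as variant; units containing N are dropped from numerator
and denominator, and partial units at the window edge are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

from .classifier import C_UNIT, G_UNIT, StrandClass
from .io import ReadRecord

__all__ = ["VtrParams", "VtrResult", "vtr_frequency", "count_units"]


@dataclass(frozen=True)
class VtrParams:
    """Scanning window and canonical units for VTR counting.

    ``window`` must be a positive multiple of the unit length; the canonical
    unit is chosen per read from its strand class (CCCTAA for C-rich reads,
    TTAGGG for G-rich reads).
    """

    window: int = 30
    unit_c: str = C_UNIT
    unit_g: str = G_UNIT

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % len(self.unit_c) != 0:
            raise ValueError(
                f"window must be a positive multiple of {len(self.unit_c)}, "
                f"got {self.window}"
            )


@dataclass
class VtrResult:
    """Aggregate unit tallies; ``frequency`` is variant units / total units."""

    units_total: int = 0
    units_variant: int = 0
    reads_skipped: int = 0

    @property
    def frequency(self) -> float:
        if self.units_total == 0:
            raise ValueError("no complete repeat units scanned")
        return self.units_variant / self.units_total

    def to_dict(self) -> dict:
        return {
            "units_total": self.units_total,
            "units_variant": self.units_variant,
            "frequency": self.frequency if self.units_total else None,
            "reads_skipped": self.reads_skipped,
        }


def count_units(sequence: str, canonical: str, window: int) -> Tuple[int, int]:
    """Count (total, variant) complete units in ``sequence[:window]``.

    The phase offset maximising canonical matches is selected (ties to the
    smallest offset); N-containing units are excluded from both counts.
    """
    step = len(canonical)
    best_offset, best_matches = 0, -1
    for offset in range(step):
        matches = 0
        for start in range(offset, window - step + 1, step):
            if sequence[start : start + step] == canonical:
                matches += 1
        if matches > best_matches:
            best_offset, best_matches = offset, matches
    total = variant = 0
    for start in range(best_offset, window - step + 1, step):
        unit = sequence[start : start + step]
        if "N" in unit:
            continue
        total += 1
        if unit != canonical:
            variant += 1
    return total, variant


def vtr_frequency(
    classified_reads: Iterable[Tuple[ReadRecord, StrandClass]],
    params: VtrParams = VtrParams(),
) -> VtrResult:
    """Aggregate VTR unit counts over a stream of classified telomeric reads.

    Reads shorter than the window are skipped (tallied in ``reads_skipped``),
    not an error. Ambiguous or non-telomeric reads are rejected: the caller
    is expected to pass only strand-assigned telomeric reads.
    """
    result = VtrResult()
    for read, strand in classified_reads:
        if strand == StrandClass.C_RICH:
            canonical = params.unit_c
        elif strand == StrandClass.G_RICH:
            canonical = params.unit_g
        else:
            raise ValueError(
                f"read {read.read_id!r} has class {strand.value}; VTR scanning "
                "requires strand-assigned telomeric reads"
            )
        if len(read.sequence) < params.window:
            result.reads_skipped += 1
            continue
        total, variant = count_units(read.sequence, canonical, params.window)
        result.units_total += total
        result.units_variant += variant
    return result
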