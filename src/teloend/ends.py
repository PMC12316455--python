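"""Chromosome 5' terminal-hexamer extraction and information content.

A C-rich END-seq read begins at the chromosome's 5'-terminal base, so its
first six bases are the terminal hexamer. Display convention writes that
hexamer reversed ("-5'" notation, 3'->5' left-to-right toward the terminus):
a read starting ``CTAACC`` terminates in the canonical ``CCAATC-5'`` end
(terminal trinucleotide ATC-5'). End resection of a pure telomeric repeat can
only expose one of the six rotational phases of the repeat, so the category
space is the six cyclic permutations plus an OTHER bin for anything else
(sequencing error, adapter remnants, variant repeats at the terminus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Union

import numpy as np
import pandas as pd

from .io import ReadRecord

__all__ = [
    "PERMUTATION_LABELS",
    "CANONICAL_LABEL",
    "REST_LABELS",
    "OTHER_LABEL",
    "EndMotifDistribution",
    "InformationProfile",
    "terminal_hexamer",
    "end_distribution",
    "position_information",
]

C_UNIT = "CCCTAA"

# label j = reverse of the rotation CCCTAA[j:] + CCCTAA[:j]; the canonical
# terminus CCAATC-5' is rotation j=2 (read prefix CTAACC).
ROTATION_OF_LABEL: Dict[str, int] = {
    (C_UNIT[j:] + C_UNIT[:j])[::-1]: j for j in range(6)
}
CANONICAL_LABEL = "CCAATC"
# canonical first, then by increasing distance from the displayed singletons;
# the last three are the display "Rest" group.
PERMUTATION_LABELS = ("CCAATC", "CAATCC", "AATCCC", "ATCCCA", "TCCCAA", "CCCAAT")
REST_LABELS = ("CCCAAT", "TCCCAA", "ATCCCA")
OTHER_LABEL = "OTHER"

_LABEL_SET = frozenset(PERMUTATION_LABELS)
BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def terminal_hexamer(read: Union[ReadRecord, str]) -> str:
    """Categorise a C-rich read's 5' terminal hexamer.

    The read's first six bases (the chromosome terminus) are reversed into
    "-5'" notation and matched against the six cyclic permutations of the
    C-strand repeat; anything else (including N) is ``OTHER``.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if len(seq) < 6:
        raise ValueError(f"read shorter than 6 nt ({len(seq)} nt): no terminal hexamer")
    label = seq[:6][::-1]
    return label if label in _LABEL_SET else OTHER_LABEL


@dataclass
class EndMotifDistribution:
    """Counts and frequencies over the six terminal-hexamer permutations + OTHER.

    ``counts`` may be fractional (e.g. an in-silico mixture expressed as
    frequencies); invariants only require non-negative cells with a positive
    total.
    """

    counts: Dict[str, float]

    def __post_init__(self) -> None:
        full = {label: 0.0 for label in PERMUTATION_LABELS + (OTHER_LABEL,)}
        for label, value in self.counts.items():
            if label not in full:
                raise ValueError(f"unknown end category {label!r}")
            if value < 0:
                raise ValueError(f"negative count for {label!r}")
            full[label] = value
        self.counts = full
        if self.n_reads <= 0:
            raise ValueError("end-motif distribution has zero total count")

    @property
    def n_reads(self) -> float:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> Dict[str, float]:
        total = self.n_reads
        return {label: value / total for label, value in self.counts.items()}

    @property
    def rest(self) -> float:
        """Frequency of the display 'Rest' group (CCCAAT + TCCCAA + ATCCCA)."""
        freqs = self.frequencies
        return sum(freqs[label] for label in REST_LABELS)

    def display_grouping(self) -> Dict[str, float]:
        """Figure-style grouping: three singleton permutations, Rest, OTHER."""
        freqs = self.frequencies
        grouped = {
            label: freqs[label]
            for label in PERMUTATION_LABELS
            if label not in REST_LABELS
        }
        grouped["Rest"] = self.rest
        grouped[OTHER_LABEL] = freqs[OTHER_LABEL]
        return grouped

    @classmethod
    def from_frequencies(cls, frequencies: Mapping[str, float]) -> "EndMotifDistribution":
        return cls(counts=dict(frequencies))

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        labels = list(PERMUTATION_LABELS) + [OTHER_LABEL]
        return pd.DataFrame(
            {
                "category": labels,
                "count": [self.counts[l] for l in labels],
                "frequency": [freqs[l] for l in labels],
            }
        )


def end_distribution(reads: Iterable[ReadRecord]) -> EndMotifDistribution:
    """Tally terminal-hexamer categories over a stream of C-rich reads."""
    counts: Dict[str, float] = {}
    n = 0
    for read in reads:
        label = terminal_hexamer(read)
        counts[label] = counts.get(label, 0.0) + 1
        n += 1
    if n == 0:
        raise ValueError("no C-rich reads: end distribution undefined")
    return EndMotifDistribution(counts=counts)


@dataclass
class InformationProfile:
    """Per-position information content of the terminal hexamer.

    ``bits[i] = 2 - H_i`` where ``H_i`` is the Shannon entropy (base 2) of the
    observed base frequencies at terminal position ``i`` (terminal-most base
    first). The base-frequency matrix is what standard logo-rendering tools
    consume; no graphics are produced here.
    """

    bits: np.ndarray
    base_frequencies: np.ndarray  # shape (6, 4), columns ordered A C G T
    n_reads: int = 0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.base_frequencies, columns=list(BASES))
        frame.insert(0, "position", np.arange(1, len(self.bits) + 1))
        frame["bits"] = self.bits
        return frame


def position_information(reads: Iterable[ReadRecord]) -> InformationProfile:
    """Information content (bits) of the six terminal positions of C-rich reads.

    Only A/C/G/T are counted; N is skipped per position. No small-sample
    correction is applied.
    """
    counts = np.zeros((6, 4), dtype=float)
    n = 0
    for read in reads:
        seq = read.sequence
        if len(seq) < 6:
            raise ValueError(f"read shorter than 6 nt ({len(seq)} nt)")
        for pos in range(6):
            idx = _BASE_INDEX.get(seq[pos])
            if idx is not None:
                counts[pos, idx] += 1
        n += 1
    if n == 0:
        raise ValueError("no C-rich reads: information profile undefined")
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a terminal position contains only N bases")
    freqs = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    bits = np.clip(2.0 + plogp.sum(axis=1), 0.0, 2.0)
    return InformationProfile(bits=bits, base_frequencies=freqs, n_reads=n)
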