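"""Synthetic END-seq / S1-END-seq library generator with a truth sidecar.

The generator emulates the read-level footprint of the two assays on a
parametric telomere model:

* each telomere is a pure C-strand repeat tract (5-15 kb by default) whose 5'
  terminus sits at one of the six rotational phases of CCCTAA — canonical
  (CCAATC-5', read prefix ``CTAACC``) with probability ``p_canonical``,
  otherwise uniform over the six phases (modelling POT1 depletion or T7
  exonuclease resection);
* the natural terminus yields one C-strand read starting at the terminal
  base (END-seq's first sequenced base is the first base of the blunted end);
* each internal cut — an S1-cleaved ssDNA region in ``s1`` mode, or a
  nuclease-induced DSB in ``endseq`` mode — yields one C-strand read from the
  centromere-proximal fragment and one G-strand read from the
  terminus-proximal fragment, so a library with ``n`` cuts per telomere has
  C:G read counts ``(n+1) : n``;
* variant repeat units are substituted at ``vtr_rate`` per unit, uniform
  sequencing substitution errors at ``error_rate`` per base, and a
  ``background_fraction`` of uniform-random non-telomeric reads is appended.

Fragments shorter than ``min_fragment`` yield no read (library size
selection). Only the sequence windows that can actually be read are ever
materialised, so libraries of tens of thousands of telomeres simulate in
seconds; all randomness derives from ``seed`` and an identical configuration
produces byte-identical FASTQ output.

The :class:`TelomereTruth` sidecar records every telomere's length, terminal
phase and cut positions, plus the emitted read counts, and
:func:`describe_truth` turns it into the closed-form expectations recovery
tests compare against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .ends import CANONICAL_LABEL, PERMUTATION_LABELS, ROTATION_OF_LABEL
from .io import ReadRecord, write_fastq
from .mixture import mixture_distribution

__all__ = [
    "SimulationConfig",
    "TelomereRecord",
    "TelomereTruth",
    "ConfigError",
    "simulate_reads",
    "simulate_library",
    "describe_truth",
    "revcomp",
]

C_UNIT = "CCCTAA"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default variant-unit alphabet: C-strand complements of the common G-strand
#: variant repeats TCAGGG, TGAGGG and TTGGGG.
DEFAULT_VTR_ALPHABET: Tuple[str, ...] = ("CCCTGA", "CCCTCA", "CCCCAA")

_LABELS = list(PERMUTATION_LABELS)


def revcomp(sequence: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message lists offending fields."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic library.

    Defaults reproduce a POT1-proficient human S1-END-seq-style setting:
    75 bp reads, telomere lengths uniform on 5-15 kb, ~70% canonical termini,
    2% variant repeat units, 0.1% per-base substitution error and half the
    library non-telomeric background.

    ``terminal_randomization='none'`` models the unperturbed, precisely
    processed terminus (always canonical); ``'uniform_rotation'`` draws each
    non-canonical terminus uniformly from the six rotational phases, so the
    expected canonical-label frequency is ``p_canonical + (1 - p_canonical)/6``.
    ``cuts_law`` is ``'fixed'`` (exactly ``cuts_per_telomere`` cuts) or
    ``'poisson'`` (mean ``cuts_per_telomere``); ``endseq`` mode reuses the
    same law for nuclease-induced DSBs and defaults to zero cuts.
    """

    n_telomeres: int = 1000
    telomere_length_range: Tuple[int, int] = (5000, 15000)
    p_canonical: float = 0.7
    terminal_randomization: str = "uniform_rotation"  # or "none"
    mode: str = "endseq"  # or "s1"
    cuts_law: str = "fixed"  # or "poisson"
    cuts_per_telomere: float = 0.0
    vtr_rate: float = 0.02
    vtr_alphabet: Tuple[str, ...] = DEFAULT_VTR_ALPHABET
    background_fraction: float = 0.5
    read_length: int = 75
    error_rate: float = 0.001
    min_fragment: int = 36
    g_capture_efficiency: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        problems: List[str] = []
        if self.n_telomeres < 1:
            problems.append(f"n_telomeres must be >= 1 (got {self.n_telomeres})")
        lmin, lmax = self.telomere_length_range
        if lmin > lmax or lmin < 2 * self.min_fragment:
            problems.append(
                "telomere_length_range must satisfy "
                f"2*min_fragment <= min <= max (got {self.telomere_length_range})"
            )
        for name in (
            "p_canonical",
            "vtr_rate",
            "error_rate",
            "g_capture_efficiency",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                problems.append(f"{name} must be in [0, 1] (got {value})")
        if not 0.0 <= self.background_fraction < 1.0:
            problems.append(
                f"background_fraction must be in [0, 1) (got {self.background_fraction})"
            )
        if self.terminal_randomization not in ("none", "uniform_rotation"):
            problems.append(
                f"terminal_randomization must be 'none' or 'uniform_rotation' "
                f"(got {self.terminal_randomization!r})"
            )
        if self.mode not in ("endseq", "s1"):
            problems.append(f"mode must be 'endseq' or 's1' (got {self.mode!r})")
        if self.cuts_law not in ("fixed", "poisson"):
            problems.append(f"cuts_law must be 'fixed' or 'poisson' (got {self.cuts_law!r})")
        if self.cuts_per_telomere < 0:
            problems.append(
                f"cuts_per_telomere must be >= 0 (got {self.cuts_per_telomere})"
            )
        if self.read_length < 6:
            problems.append(f"read_length must be >= 6 (got {self.read_length})")
        if self.min_fragment < 6:
            problems.append(f"min_fragment must be >= 6 (got {self.min_fragment})")
        for unit in self.vtr_alphabet:
            if len(unit) != 6 or unit == C_UNIT:
                problems.append(f"vtr_alphabet unit {unit!r} must be a non-canonical hexamer")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_dict(self) -> dict:
        data = asdict(self)
        data["telomere_length_range"] = list(self.telomere_length_range)
        data["vtr_alphabet"] = list(self.vtr_alphabet)
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "telomere_length_range" in data:
            data["telomere_length_range"] = tuple(data["telomere_length_range"])
        if "vtr_alphabet" in data:
            data["vtr_alphabet"] = tuple(data["vtr_alphabet"])
        return cls(**data)


@dataclass
class TelomereRecord:
    """Ground truth for one telomere."""

    length: int
    terminal_label: str
    cut_positions: List[int]


@dataclass
class TelomereTruth:
    """Library-level ground truth written alongside the FASTQ."""

    config: SimulationConfig
    telomeres: List[TelomereRecord]
    n_c_reads: int
    n_g_reads: int
    n_background: int

    @property
    def expected_c_ends(self) -> int:
        return sum(1 + len(t.cut_positions) for t in self.telomeres)

    @property
    def expected_g_ends(self) -> int:
        return sum(len(t.cut_positions) for t in self.telomeres)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "config": self.config.to_dict(),
            "n_c_reads": self.n_c_reads,
            "n_g_reads": self.n_g_reads,
            "n_background": self.n_background,
            "expected_c_ends": self.expected_c_ends,
            "expected_g_ends": self.expected_g_ends,
            "telomeres": [asdict(t) for t in self.telomeres],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TelomereTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=SimulationConfig.from_dict(payload["config"]),
            telomeres=[TelomereRecord(**t) for t in payload["telomeres"]],
            n_c_reads=payload["n_c_reads"],
            n_g_reads=payload["n_g_reads"],
            n_background=payload["n_background"],
        )


class _Tract:
    """Lazily materialised telomeric C-strand of one telomere.

    The strand is conceptually an infinite concatenation of hexamer units in
    the CCCTAA frame, entered at rotation offset ``j`` so that strand position
    ``p`` maps to tract position ``p + j``. Units are drawn (canonical vs
    variant) only when a window touching them is requested, which keeps the
    cost proportional to the number of reads rather than telomere length.
    """

    def __init__(self, rng: np.random.Generator, cfg: SimulationConfig, rotation: int):
        self.rng = rng
        self.cfg = cfg
        self.j = rotation
        self.units: Dict[int, str] = {}

    def _unit(self, index: int) -> str:
        unit = self.units.get(index)
        if unit is None:
            if self.cfg.vtr_rate > 0 and self.rng.random() < self.cfg.vtr_rate:
                unit = self.cfg.vtr_alphabet[
                    int(self.rng.integers(len(self.cfg.vtr_alphabet)))
                ]
            else:
                unit = C_UNIT
            self.units[index] = unit
        return unit

    def slice(self, start: int, stop: int) -> str:
        """Strand bases in [start, stop) read 5'->3' from the terminus."""
        t0, t1 = start + self.j, stop + self.j
        u0, u1 = t0 // 6, (t1 - 1) // 6
        chunk = "".join(self._unit(u) for u in range(u0, u1 + 1))
        offset = t0 - 6 * u0
        return chunk[offset : offset + (stop - start)]


def _draw_terminal_label(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    if cfg.terminal_randomization == "none":
        return CANONICAL_LABEL
    if rng.random() < cfg.p_canonical:
        return CANONICAL_LABEL
    return _LABELS[int(rng.integers(6))]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        base = chars[i]
        options = [b for b in "ACGT" if b != base]
        chars[i] = options[int(rng.integers(3))]
    return "".join(chars)


def simulate_reads(
    config: SimulationConfig,
) -> Tuple[List[ReadRecord], TelomereTruth]:
    """Generate the library in memory; returns ``(records, truth)``.

    Read order is deterministic: telomeres in index order (terminal read, then
    per-cut C and G reads), followed by background reads. Qualities are a
    constant Q40.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lmin, lmax = config.telomere_length_range
    rl = config.read_length
    records: List[ReadRecord] = []
    telomeres: List[TelomereRecord] = []
    n_c = n_g = 0

    def emit(read_id: str, seq: str) -> None:
        seq = _apply_errors(rng, seq, config.error_rate)
        records.append(ReadRecord(read_id, seq, [40] * len(seq)))

    for t in range(config.n_telomeres):
        length = int(rng.integers(lmin, lmax, endpoint=True))
        label = _draw_terminal_label(rng, config)
        if config.cuts_law == "fixed":
            n_cuts = int(round(config.cuts_per_telomere))
        else:
            n_cuts = int(rng.poisson(config.cuts_per_telomere))
        if n_cuts > 0:
            cuts = sorted(
                int(c)
                for c in rng.integers(
                    config.min_fragment,
                    length - config.min_fragment,
                    size=n_cuts,
                    endpoint=True,
                )
            )
        else:
            cuts = []
        tract = _Tract(rng, config, ROTATION_OF_LABEL[label])
        boundaries = [0] + cuts + [length]

        # natural 5' terminus: one C-strand read (first fragment is always
        # >= min_fragment because cuts keep that distance from the boundary)
        f0_len = boundaries[1]
        emit(f"tel{t:06d}/term/C", tract.slice(0, min(rl, f0_len)))
        n_c += 1

        for i, cut in enumerate(cuts):
            # terminus-proximal fragment ends at the cut: G-strand read
            g_len = cut - boundaries[i]
            if g_len >= config.min_fragment:
                if (
                    config.g_capture_efficiency >= 1.0
                    or rng.random() < config.g_capture_efficiency
                ):
                    emit(
                        f"tel{t:06d}/cut{i}/G",
                        revcomp(tract.slice(cut - min(rl, g_len), cut)),
                    )
                    n_g += 1
            # centromere-proximal fragment starts at the cut: C-strand read
            c_len = boundaries[i + 2] - cut
            if c_len >= config.min_fragment:
                emit(f"tel{t:06d}/cut{i}/C", tract.slice(cut, cut + min(rl, c_len)))
                n_c += 1

        telomeres.append(TelomereRecord(length, label, cuts))

    n_signal = len(records)
    bf = config.background_fraction
    n_background = int(round(bf * n_signal / (1.0 - bf))) if bf > 0 else 0
    bases = np.array(list("ACGT"))
    for k in range(n_background):
        seq = "".join(bases[rng.integers(0, 4, size=rl)])
        records.append(ReadRecord(f"bg{k:06d}", seq, [40] * rl))

    truth = TelomereTruth(
        config=config,
        telomeres=telomeres,
        n_c_reads=n_c,
        n_g_reads=n_g,
        n_background=n_background,
    )
    return records, truth


def simulate_library(
    config: SimulationConfig,
    fastq_path: Union[str, Path],
    truth_path: Optional[Union[str, Path]] = None,
    gzip_output: Optional[bool] = None,
) -> TelomereTruth:
    """Simulate and write a FASTQ library (+ optional JSON truth sidecar).

    Gzip output is inferred from a ``.gz`` suffix unless stated. Identical
    configurations produce byte-identical files.
    """
    records, truth = simulate_reads(config)
    if gzip_output is None:
        gzip_output = str(fastq_path).endswith(".gz")
    write_fastq(records, fastq_path, gzip_output=gzip_output)
    if truth_path is not None:
        truth.to_json(truth_path)
    return truth


def describe_truth(truth: TelomereTruth) -> dict:
    """Closed-form expectations implied by the truth sidecar.

    * ``expected_f`` — C-strand read fraction from the recorded end counts,
      ``sum(1 + cuts) / sum(1 + 2*cuts)`` (assumes no fragment was dropped);
    * ``expected_end_distribution`` — terminal-label frequencies under the
      generating mixture law;
    * ``expected_vtr_rate`` — the per-unit injection rate.
    """
    cfg = truth.config
    c_ends, g_ends = truth.expected_c_ends, truth.expected_g_ends
    p = 1.0 if cfg.terminal_randomization == "none" else cfg.p_canonical
    return {
        "expected_f": c_ends / (c_ends + g_ends),
        "expected_end_distribution": mixture_distribution(p).frequencies,
        "expected_vtr_rate": cfg.vtr_rate,
        "expected_c_ends": c_ends,
        "expected_g_ends": g_ends,
    }
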