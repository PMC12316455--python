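"""Consolidated per-library analysis: classify -> ends -> mixture -> ssDNA -> VTR.

Each library is streamed once: reads are classified and the telomeric ones
retained for the downstream stages. Optional stages that cannot run (e.g. no
C-rich reads for the terminal-end analysis) report a structured
"insufficient data" status instead of failing the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from . import __version__
from .classifier import ClassifierParams, StrandClass, StrandCounts, tally_library
from .ends import (
    EndMotifDistribution,
    InformationProfile,
    end_distribution,
    position_information,
)
from .io import ReadRecord, read_fastq
from .mixture import CanonicalMixtureModel, CanonicalMixtureResults
from .ssdna import SsdnaBreakModel, SsdnaResults
from .vtr import VtrParams, VtrResult, vtr_frequency

__all__ = ["LibraryResult", "PipelineReport", "analyze_library", "run_pipeline", "write_report"]

INSUFFICIENT = "insufficient data"


@dataclass
class LibraryResult:
    """All stage outputs for one library; failed stages carry a status string."""

    name: str
    strand_counts: StrandCounts
    end_motifs: Optional[EndMotifDistribution] = None
    information: Optional[InformationProfile] = None
    mixture: Optional[CanonicalMixtureResults] = None
    ssdna: Optional[SsdnaResults] = None
    vtr: Optional[VtrResult] = None
    statuses: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"name": self.name, "strand_counts": self.strand_counts.to_dict()}
        out["end_motifs"] = (
            {
                "frequencies": self.end_motifs.frequencies,
                "display_grouping": self.end_motifs.display_grouping(),
                "n_reads": self.end_motifs.n_reads,
            }
            if self.end_motifs is not None
            else None
        )
        out["information_bits"] = (
            list(map(float, self.information.bits)) if self.information else None
        )
        out["mixture"] = self.mixture.to_dict() if self.mixture else None
        out["ssdna"] = self.ssdna.to_dict() if self.ssdna else None
        out["vtr"] = self.vtr.to_dict() if self.vtr else None
        out["statuses"] = self.statuses
        return out


@dataclass
class PipelineReport:
    """Per-library results plus provenance (inputs, parameters, version)."""

    libraries: List[LibraryResult]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "libraries": [lib.to_dict() for lib in self.libraries],
        }

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def analyze_library(
    reads,
    name: str,
    classifier_params: ClassifierParams = ClassifierParams(),
    vtr_params: VtrParams = VtrParams(),
) -> LibraryResult:
    """Run every analysis stage on one read stream."""
    telomeric: List[Tuple[ReadRecord, StrandClass]] = []

    def keep_telomeric(read: ReadRecord, cls: StrandClass) -> None:
        if cls in (StrandClass.C_RICH, StrandClass.G_RICH):
            telomeric.append((read, cls))

    counts = tally_library(reads, classifier_params, sink=keep_telomeric)
    result = LibraryResult(name=name, strand_counts=counts)

    c_reads = [r for r, cls in telomeric if cls == StrandClass.C_RICH]
    long_enough = [r for r in c_reads if len(r) >= 6]
    if long_enough:
        result.end_motifs = end_distribution(long_enough)
        result.information = position_information(long_enough)
        result.mixture = CanonicalMixtureModel(result.end_motifs).fit()
    else:
        result.statuses["ends"] = INSUFFICIENT
        result.statuses["mixture"] = INSUFFICIENT

    if counts.c_rich + counts.g_rich > 0:
        result.ssdna = SsdnaBreakModel.from_counts(counts).fit()
    else:
        result.statuses["ssdna"] = INSUFFICIENT

    if telomeric:
        result.vtr = vtr_frequency(telomeric, vtr_params)
        if result.vtr.units_total == 0:
            result.statuses["vtr"] = INSUFFICIENT
            result.vtr = None
    else:
        result.statuses["vtr"] = INSUFFICIENT
    return result


def run_pipeline(
    fastq_paths: List[Union[str, Path]],
    classifier_params: ClassifierParams = ClassifierParams(),
    vtr_params: VtrParams = VtrParams(),
) -> PipelineReport:
    """Analyse one or more FASTQ libraries and assemble the full report."""
    if not fastq_paths:
        raise ValueError("at least one input library is required")
    libraries = [
        analyze_library(
            read_fastq(path), Path(path).name, classifier_params, vtr_params
        )
        for path in fastq_paths
    ]
    provenance = {
        "inputs": [str(p) for p in fastq_paths],
        "tool": "teloend",
        "version": __version__,
        "parameters": {
            "unit_g": classifier_params.unit_g,
            "unit_c": classifier_params.unit_c,
            "min_repeats": classifier_params.min_repeats,
            "vtr_window": vtr_params.window,
        },
    }
    return PipelineReport(libraries=libraries, provenance=provenance)


def write_report(report: PipelineReport, outdir: Union[str, Path]) -> None:
    """Write report.json plus TSV tables for the tabular stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())

    rows = []
    for lib in report.libraries:
        row = {"library": lib.name, **lib.strand_counts.to_dict()}
        if lib.ssdna is not None:
            row.update(
                f=lib.ssdna.f, n_min=lib.ssdna.n_min, alt_call=lib.ssdna.alt_call.value
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "strand_counts.tsv", sep="\t", index=False)

    motif_frames = []
    for lib in report.libraries:
        if lib.end_motifs is not None:
            frame = lib.end_motifs.to_frame()
            frame.insert(0, "library", lib.name)
            motif_frames.append(frame)
    if motif_frames:
        pd.concat(motif_frames).to_csv(outdir / "end_motifs.tsv", sep="\t", index=False)

    info_frames = []
    for lib in report.libraries:
        if lib.information is not None:
            frame = lib.information.to_frame()
            frame.insert(0, "library", lib.name)
            info_frames.append(frame)
    if info_frames:
        pd.concat(info_frames).to_csv(outdir / "information.tsv", sep="\t", index=False)

    vtr_rows = [
        {"library": lib.name, **lib.vtr.to_dict()}
        for lib in report.libraries
        if lib.vtr is not None
    ]
    if vtr_rows:
        pd.DataFrame(vtr_rows).to_csv(outdir / "vtr.tsv", sep="\t", index=False)
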