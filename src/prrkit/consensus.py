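"""Multi-cell-line consensus region building.

A peak is retained when its overlap with a peak from a different cell line
covers at least `min_overlap_fraction` of the peak's own length; retained
peaks are then concatenated, sorted, and merged into disjoint consensus
regions. Retention is asymmetric by default (fraction relative to the
candidate's own length); `reciprocal=True` additionally requires the same
fraction of the partner's length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .intervals import (
    DisjointIntervals,
    GenomicInterval,
    PeakSet,
    merge_intervals,
    overlap_length,
)


@dataclass
class ConsensusConfig:
    min_overlap_fraction: float = 0.5
    min_supporting_cell_lines: int = 2
    merge_bookended: bool = True
    reciprocal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.min_overlap_fraction <= 1.0:
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.min_supporting_cell_lines < 2:
            raise ValueError("min_supporting_cell_lines must be ≥ 2")


@dataclass
class ConsensusRegions:
    """Disjoint sorted consensus regions plus the retained peaks behind them."""

    assay: str
    regions: list[GenomicInterval]
    provenance: list[list[tuple[str, GenomicInterval]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def index(self) -> DisjointIntervals:
        return DisjointIntervals(self.regions)

    @property
    def supporting_cell_lines(self) -> list[set[str]]:
        return [{cl for cl, _ in ev} for ev in self.provenance]


def _check_same_assay(peaks_by_cell_line: Mapping[str, PeakSet]) -> str:
    assays = {ps.assay for ps in peaks_by_cell_line.values()}
    if len(assays) > 1:
        raise ValueError(f"mixed assays in consensus input: {sorted(assays)}")
    return assays.pop() if assays else ""


def _supports(
    peak: GenomicInterval, other: PeakSet, cfg: ConsensusConfig
) -> bool:
    """True if some peak in `other` covers enough of `peak`."""
    threshold = cfg.min_overlap_fraction * peak.length
    for q in other.intervals:
        if q.chrom != peak.chrom or q.end <= peak.start or q.start >= peak.end:
            continue
        ov = overlap_length(peak, q)
        if ov >= threshold and (
            not cfg.reciprocal or ov >= cfg.min_overlap_fraction * q.length
        ):
            return True
    return False


def retain_supported_peaks(
    peaks_by_cell_line: Mapping[str, PeakSet],
    cfg: ConsensusConfig | None = None,
) -> list[tuple[str, GenomicInterval]]:
    """Step (i): keep peaks supported by ≥ (min_supporting_cell_lines − 1)
    other cell lines; each support is an overlap covering at least
    `min_overlap_fraction` of the candidate peak's own length.

    Returns (cell_line, peak) pairs with original coordinates.
    """
    cfg = cfg or ConsensusConfig()
    _check_same_assay(peaks_by_cell_line)
    need = cfg.min_supporting_cell_lines - 1
    retained: list[tuple[str, GenomicInterval]] = []
    for cl in sorted(peaks_by_cell_line):
        others = [
            peaks_by_cell_line[o] for o in sorted(peaks_by_cell_line) if o != cl
        ]
        for peak in peaks_by_cell_line[cl].intervals:
            n_support = 0
            for other in others:
                if _supports(peak, other, cfg):
                    n_support += 1
                    if n_support >= need:
                        break
            if n_support >= need:
                retained.append((cl, peak))
    return retained


def build_consensus(
    peaks_by_cell_line: Mapping[str, PeakSet],
    cfg: ConsensusConfig | None = None,
) -> ConsensusRegions:
    """Steps (i)-(iii): retain, concatenate, sort and merge.

    Provenance lists, per merged region, every retained (cell line, peak)
    contributing bases to it.
    """
    cfg = cfg or ConsensusConfig()
    assay = _check_same_assay(peaks_by_cell_line)
    retained = retain_supported_peaks(peaks_by_cell_line, cfg)
    regions = merge_intervals(
        (peak for _, peak in retained), merge_bookended=cfg.merge_bookended
    )
    provenance: list[list[tuple[str, GenomicInterval]]] = [[] for _ in regions]
    index = DisjointIntervals(regions, merge_bookended=cfg.merge_bookended)
    pos = {iv: i for i, iv in enumerate(index.intervals)}
    for cl, peak in retained:
        region = index.containing(peak.chrom, peak.start)
        assert region is not None  # every retained peak lies in one region
        provenance[pos[region]].append((cl, peak))
    return ConsensusRegions(assay=assay, regions=regions, provenance=provenance)


def write_provenance_tsv(consensus: ConsensusRegions, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_cell_lines\tcell_lines\tpeaks\n")
        for region, evidence in zip(consensus.regions, consensus.provenance):
            lines = sorted({cl for cl, _ in evidence})
            peaks = ",".join(
                f"{cl}:{p.chrom}:{p.start}-{p.end}" for cl, p in evidence
            )
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t"
                f"{len(lines)}\t{','.join(lines)}\t{peaks}\n"
            )
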