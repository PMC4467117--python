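"""SNP annotation against consensus regions and TF peaks.

Classifies SNP chromatin context (enhancer = H3K4me1 without H3K4me3,
promoter = both), attaches bound transcription factors under one of two
intersection semantics, and builds the marker × TF cross-tabulation.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .consensus import ConsensusRegions
from .intervals import DisjointIntervals, GenomicInterval, PeakSet, SNPRecord

log = logging.getLogger(__name__)

MARKER_ROWS = ("H3K4me1", "H3K4me1+H3K4me3", "H3K27ac", "H3K9ac", "DNase", "FAIRE")
UNION_ROW = "Union"


class RegulatoryClass(str, enum.Enum):
    ENHANCER = "enhancer"
    PROMOTER = "promoter"
    OPEN_CHROMATIN = "open_chromatin"
    ACETYLATION = "acetylation"
    UNCLASSIFIED = "unclassified"


@dataclass
class PRRRecord:
    """A SNP inside (or near) consensus regulatory regions."""

    snp: SNPRecord
    markers_hit: set[str]
    region_by_marker: dict[str, GenomicInterval]
    bound_tfs: set[str]
    reg_class: RegulatoryClass
    distance_to_region: int = 0


def _as_index(regions: ConsensusRegions | DisjointIntervals | Iterable[GenomicInterval]) -> DisjointIntervals:
    if isinstance(regions, DisjointIntervals):
        return regions
    if isinstance(regions, ConsensusRegions):
        return regions.index()
    return DisjointIntervals(regions)


def classify_snp_context(
    snp: SNPRecord,
    me1: ConsensusRegions | DisjointIntervals | Iterable[GenomicInterval],
    me3: ConsensusRegions | DisjointIntervals | Iterable[GenomicInterval],
) -> RegulatoryClass:
    """Enhancer if inside H3K4me1 consensus only; promoter if inside both."""
    in_me1 = _as_index(me1).containing(snp.chrom, snp.pos) is not None
    in_me3 = _as_index(me3).containing(snp.chrom, snp.pos) is not None
    if in_me1 and not in_me3:
        return RegulatoryClass.ENHANCER
    if in_me1 and in_me3:
        return RegulatoryClass.PROMOTER
    return RegulatoryClass.UNCLASSIFIED


def annotate_snps(
    snps: Iterable[SNPRecord],
    consensus_by_marker: Mapping[str, ConsensusRegions | DisjointIntervals],
    tf_peaks: Mapping[str, PeakSet] | None = None,
    mode: str = "region_overlap",
    proximity_bp: int = 0,
) -> list[PRRRecord]:
    """Attach markers and bound TFs to every SNP falling in (or within
    `proximity_bp` of) at least one consensus region.

    mode="region_overlap": a TF is bound when one of its peaks shares ≥1 bp
    with a containing consensus region. mode="snp_in_peak": the SNP position
    itself must lie inside a TF peak.
    """
    if mode not in ("region_overlap", "snp_in_peak"):
        raise ValueError(f"unknown mode: {mode!r}")
    if proximity_bp < 0:
        raise ValueError("proximity_bp must be ≥ 0")
    tf_peaks = tf_peaks or {}
    marker_idx = {m: _as_index(r) for m, r in consensus_by_marker.items()}
    tf_idx = {tf: DisjointIntervals(ps.intervals) for tf, ps in tf_peaks.items()}
    known_chroms = set().union(*(idx.chroms for idx in marker_idx.values())) if marker_idx else set()
    unknown_seen: set[str] = set()

    records: list[PRRRecord] = []
    for snp in snps:
        if known_chroms and snp.chrom not in known_chroms:
            if snp.chrom not in unknown_seen:
                log.warning("unknown chromosome %r: records skipped", snp.chrom)
                unknown_seen.add(snp.chrom)
            continue
        markers_hit: set[str] = set()
        region_by_marker: dict[str, GenomicInterval] = {}
        min_dist: Optional[int] = None
        for marker, idx in marker_idx.items():
            region, dist = idx.nearest(snp.chrom, snp.pos)
            if region is None or dist is None or dist > proximity_bp:
                continue
            markers_hit.add(marker)
            region_by_marker[marker] = region
            min_dist = dist if min_dist is None else min(min_dist, dist)
        if not markers_hit:
            continue

        bound_tfs: set[str] = set()
        for tf, idx in tf_idx.items():
            if mode == "snp_in_peak":
                if idx.containing(snp.chrom, snp.pos) is not None:
                    bound_tfs.add(tf)
            else:
                if any(
                    idx.overlaps(r.chrom, r.start, r.end)
                    for r in region_by_marker.values()
                ):
                    bound_tfs.add(tf)

        me1 = marker_idx.get("H3K4me1", DisjointIntervals([]))
        me3 = marker_idx.get("H3K4me3", DisjointIntervals([]))
        records.append(
            PRRRecord(
                snp=snp,
                markers_hit=markers_hit,
                region_by_marker=region_by_marker,
                bound_tfs=bound_tfs,
                reg_class=classify_snp_context(snp, me1, me3),
                distance_to_region=min_dist if min_dist is not None else 0,
            )
        )
    return records


def _row_predicate(row: str):
    if row == "H3K4me1+H3K4me3":
        return lambda r: {"H3K4me1", "H3K4me3"} <= r.markers_hit
    if row == UNION_ROW:
        base = {"H3K4me1", "H3K4me3", "H3K27ac", "H3K9ac", "DNase", "FAIRE"}
        return lambda r: bool(r.markers_hit & base)
    return lambda r: row in r.markers_hit


def crosstab(records: Sequence[PRRRecord], tfs: Sequence[str]) -> pd.DataFrame:
    """Marker × TF table of distinct rsID counts (plus an all-TF
    intersection column and a Union row)."""
    columns = list(tfs) + ["+".join(tfs)] if len(tfs) > 1 else list(tfs)
    rows = list(MARKER_ROWS) + [UNION_ROW]
    table = pd.DataFrame(0, index=rows, columns=columns, dtype=int)
    for row in rows:
        pred = _row_predicate(row)
        in_row = [r for r in records if pred(r)]
        for tf in tfs:
            table.loc[row, tf] = len({r.snp.rsid for r in in_row if tf in r.bound_tfs})
        if len(tfs) > 1:
            table.loc[row, "+".join(tfs)] = len(
                {r.snp.rsid for r in in_row if set(tfs) <= r.bound_tfs}
            )
    return table


def prioritize(
    records: Sequence[PRRRecord],
    min_maf: float = 0.0,
    require_array: bool = False,
) -> list[PRRRecord]:
    """Filter by allele frequency and array membership; sort by descending
    maf then rsid. Records without a maf are dropped whenever min_maf > 0."""
    kept = []
    for r in records:
        if min_maf > 0 and (r.snp.maf is None or r.snp.maf < min_maf):
            continue
        if require_array and not r.snp.on_array:
            continue
        kept.append(r)
    return sorted(kept, key=lambda r: (-(r.snp.maf if r.snp.maf is not None else -1.0), r.snp.rsid))


def records_to_frame(records: Sequence[PRRRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "rsid": r.snp.rsid,
                "chrom": r.snp.chrom,
                "pos0": r.snp.pos,
                "ref": r.snp.ref,
                "alt": r.snp.alt,
                "reg_class": r.reg_class.value,
                "markers": ",".join(sorted(r.markers_hit)),
                "bound_tfs": ",".join(sorted(r.bound_tfs)),
                "distance": r.distance_to_region,
                "maf": r.snp.maf,
                "on_array": int(r.snp.on_array),
            }
        )
    cols = ["rsid", "chrom", "pos0", "ref", "alt", "reg_class", "markers",
            "bound_tfs", "distance", "maf", "on_array"]
    return pd.DataFrame(rows, columns=cols)
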