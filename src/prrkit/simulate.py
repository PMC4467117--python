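"""Seeded synthetic inputs with known ground truth.

Plants disjoint regulatory elements on a toy chromosome, emits per-cell-line
jittered peak landscapes per marker plus noise peaks, TF binding peaks,
SNP catalogs (inside/outside elements), allele-biased count pairs and Ct
tables with planted fold changes — everything needed to exercise the
pipeline end to end without external downloads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .allele import AlleleCounts
from .intervals import (
    GenomicInterval,
    PeakSet,
    SNPRecord,
    write_intervals,
    write_snps_tsv,
    write_snps_vcf,
)

MARKERS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K9ac", "DNase", "FAIRE")
# background SNPs and noise peaks stay this far away from planted elements so
# that jittered peak boundaries cannot silently absorb them
SAFETY_PAD = 100


@dataclass
class SimulationConfig:
    seed: int = 0
    n_cell_lines: int = 5
    chrom: str = "chrS"
    chrom_length: int = 1_000_000
    n_true_regions: int = 20
    region_length_range: tuple[int, int] = (200, 1000)
    peak_jitter_sd: float = 10.0
    peak_detection_prob: float = 0.9
    n_noise_peaks_per_line: int = 20
    n_snps: int = 200
    frac_snps_in_regions: float = 0.5
    tf_names: tuple[str, ...] = ("AR", "ER")
    tf_overlap_prob: float = 0.7
    allele_bias: float = 0.75
    read_depth: int = 200
    ct_noise_sd: float = 0.2
    optional_marker_prob: float = 0.4  # chance of each acetylation/open mark

    def __post_init__(self) -> None:
        for name in ("peak_detection_prob", "frac_snps_in_regions",
                     "tf_overlap_prob", "allele_bias", "optional_marker_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chrom_length <= 0 or self.n_cell_lines < 1 or self.read_depth <= 0:
            raise ValueError("lengths, counts and depth must be positive")
        lo, hi = self.region_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid region_length_range")


@dataclass
class SnpTruth:
    rsid: str
    pos: int
    inside: bool
    markers: set[str]
    bound_tfs: set[str]
    reg_class: str  # enhancer / promoter / unclassified


@dataclass
class TruthTable:
    """Ground truth for one simulated landscape."""

    regions_by_marker: dict[str, list[GenomicInterval]]
    elements: list[GenomicInterval]
    element_markers: list[set[str]]
    element_tfs: list[set[str]]
    snps: list[SnpTruth]

    def to_json(self) -> str:
        def iv(i: GenomicInterval) -> list:
            return [i.chrom, i.start, i.end]

        payload = {
            "regions_by_marker": {
                m: [iv(r) for r in rs] for m, rs in sorted(self.regions_by_marker.items())
            },
            "elements": [iv(e) for e in self.elements],
            "element_markers": [sorted(s) for s in self.element_markers],
            "element_tfs": [sorted(s) for s in self.element_tfs],
            "snps": [
                {
                    "rsid": s.rsid, "pos": s.pos, "inside": s.inside,
                    "markers": sorted(s.markers), "bound_tfs": sorted(s.bound_tfs),
                    "reg_class": s.reg_class,
                }
                for s in self.snps
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class Landscape:
    cfg: SimulationConfig
    peaks: dict[str, dict[str, PeakSet]]  # marker -> cell line -> PeakSet
    tf_peaks: dict[str, PeakSet]
    snps: list[SNPRecord]
    truth: TruthTable


def _place_disjoint(
    rng: np.random.Generator, n: int, lengths: np.ndarray, chrom_length: int, gap: int
) -> list[tuple[int, int]]:
    """n disjoint intervals with ≥gap bp between them, uniformly arranged."""
    total = int(lengths.sum()) + gap * (n + 1)
    slack = chrom_length - total
    if slack < 0:
        raise ValueError("region demand exceeds chromosome length")
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    out = []
    prefix = 0
    for i in range(n):
        start = gap * (i + 1) + prefix + int(cuts[i])
        out.append((start, start + int(lengths[i])))
        prefix += int(lengths[i])
    return out


def simulate_landscape(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> Landscape:
    """Generate the full multi-cell-line peak landscape plus SNPs and truth."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.region_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_true_regions)
    spans = _place_disjoint(rng, cfg.n_true_regions, lengths, cfg.chrom_length, gap=3 * SAFETY_PAD)
    elements = [GenomicInterval(cfg.chrom, s, e) for s, e in spans]

    # marker assignment: every element carries H3K4me1; half also H3K4me3
    # (promoter pattern); acetylation/open marks sprinkled independently
    element_markers: list[set[str]] = []
    for _ in elements:
        marks = {"H3K4me1"}
        if rng.random() < 0.5:
            marks.add("H3K4me3")
        for m in ("H3K27ac", "H3K9ac", "DNase", "FAIRE"):
            if rng.random() < cfg.optional_marker_prob:
                marks.add(m)
        element_markers.append(marks)

    element_tfs = [
        {tf for tf in cfg.tf_names if rng.random() < cfg.tf_overlap_prob}
        for _ in elements
    ]

    regions_by_marker = {
        m: [e for e, marks in zip(elements, element_markers) if m in marks]
        for m in MARKERS
    }

    cell_lines = [f"cell{i:02d}" for i in range(cfg.n_cell_lines)]
    forbidden = [(e.start - SAFETY_PAD, e.end + SAFETY_PAD) for e in elements]

    def sample_background_positions(n: int, width: int) -> list[int]:
        """Starts for width-bp features avoiding the padded elements."""
        out: list[int] = []
        while len(out) < n:
            cand = int(rng.integers(0, cfg.chrom_length - width))
            if all(cand + width <= s or cand >= e for s, e in forbidden):
                out.append(cand)
        return out

    peaks: dict[str, dict[str, PeakSet]] = {}
    for marker in MARKERS:
        peaks[marker] = {}
        for cl in cell_lines:
            ivs: list[GenomicInterval] = []
            for region in regions_by_marker[marker]:
                if rng.random() >= cfg.peak_detection_prob:
                    continue
                s = region.start + rng.normal(0.0, cfg.peak_jitter_sd)
                e = region.end + rng.normal(0.0, cfg.peak_jitter_sd)
                s = int(max(0, round(s)))
                e = int(min(cfg.chrom_length, round(e)))
                if e <= s:
                    s, e = region.start, region.start + 1
                ivs.append(GenomicInterval(cfg.chrom, s, e))
            noise_len = rng.integers(lo, hi + 1, size=cfg.n_noise_peaks_per_line)
            for width in noise_len:
                start = sample_background_positions(1, int(width))[0]
                ivs.append(GenomicInterval(cfg.chrom, start, start + int(width)))
            peaks[marker][cl] = PeakSet(cl, marker, ivs)

    tf_peaks: dict[str, PeakSet] = {}
    for tf in cfg.tf_names:
        ivs = []
        for element, tfs in zip(elements, element_tfs):
            if tf in tfs:
                pad = int(rng.integers(0, 50))
                ivs.append(
                    GenomicInterval(
                        cfg.chrom, max(0, element.start - pad),
                        min(cfg.chrom_length, element.end + pad),
                    )
                )
        for width in rng.integers(lo, hi + 1, size=5):
            start = sample_background_positions(1, int(width))[0]
            ivs.append(GenomicInterval(cfg.chrom, start, start + int(width)))
        tf_peaks[tf] = PeakSet("pooled", tf, ivs)

    # SNPs: a fixed fraction inside elements, the rest in padded background
    n_inside = int(round(cfg.n_snps * cfg.frac_snps_in_regions))
    snps: list[SNPRecord] = []
    truth_snps: list[SnpTruth] = []
    bases = np.array(list("ACGT"))
    for i in range(cfg.n_snps):
        inside = i < n_inside
        if inside:
            k = int(rng.integers(0, len(elements)))
            el = elements[k]
            pos = int(rng.integers(el.start, el.end))
            markers = set(element_markers[k])
            tfs = set(element_tfs[k])
        else:
            pos = sample_background_positions(1, 1)[0]
            markers, tfs = set(), set()
        ref, alt = rng.choice(bases, size=2, replace=False)
        maf = float(rng.uniform(0.0, 0.5))
        snp = SNPRecord(
            rsid=f"rs{i + 1:06d}", chrom=cfg.chrom, pos=pos,
            ref=str(ref), alt=str(alt), maf=round(maf, 4),
            on_array=bool(rng.random() < 0.5),
        )
        snps.append(snp)
        if "H3K4me1" in markers and "H3K4me3" in markers:
            reg_class = "promoter"
        elif "H3K4me1" in markers:
            reg_class = "enhancer"
        else:
            reg_class = "unclassified"
        truth_snps.append(
            SnpTruth(snp.rsid, pos, inside, markers, tfs, reg_class)
        )

    truth = TruthTable(
        regions_by_marker=regions_by_marker,
        elements=elements,
        element_markers=element_markers,
        element_tfs=element_tfs,
        snps=truth_snps,
    )
    return Landscape(cfg=cfg, peaks=peaks, tf_peaks=tf_peaks, snps=snps, truth=truth)


def simulate_allele_counts(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[AlleleCounts, AlleleCounts, float]:
    """(input, ChIP) count pair; input is unbiased binomial, ChIP is
    binomial with the planted allele bias. Returns the bias as truth."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    a_in = int(rng.binomial(cfg.read_depth, 0.5))
    a_chip = int(rng.binomial(cfg.read_depth, cfg.allele_bias))
    return (
        AlleleCounts("input", a_in, cfg.read_depth - a_in),
        AlleleCounts("chip", a_chip, cfg.read_depth - a_chip),
        cfg.allele_bias,
    )


def simulate_ct(
    cfg: SimulationConfig,
    fold_changes: Mapping[str, Mapping[str, float]],
    reference_genes: tuple[str, ...] = ("GAPDH", "B2M"),
    control_condition: str = "control",
    n_replicates: int = 3,
    ct_base: float = 25.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Ct table with planted fold changes: Ct(gene, cond) = base − log2(fold)
    + N(0, ct_noise_sd); reference genes are flat up to noise."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    conditions = sorted({c for per_gene in fold_changes.values() for c in per_gene}
                        | {control_condition})
    rows = []
    for gene, per_cond in fold_changes.items():
        for cond in conditions:
            fold = per_cond.get(cond, 1.0)
            if fold <= 0:
                raise ValueError(f"fold change must be > 0 ({gene}/{cond})")
            mean_ct = ct_base - np.log2(fold)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": gene, "condition": cond, "replicate": rep,
                        "ct": float(mean_ct + rng.normal(0.0, cfg.ct_noise_sd)),
                    }
                )
    for gene in reference_genes:
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": gene, "condition": cond, "replicate": rep,
                        "ct": float(20.0 + rng.normal(0.0, cfg.ct_noise_sd)),
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


def write_landscape(sim: Landscape, outdir: str | Path) -> dict[str, str]:
    """Serialize a landscape as BED/TSV/VCF/JSON text files; returns a
    name → path manifest of everything written."""
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "tf").mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for marker, by_line in sorted(sim.peaks.items()):
        for cl, ps in sorted(by_line.items()):
            path = outdir / "peaks" / f"{marker}.{cl}.bed"
            write_intervals(ps.intervals, path)
            manifest[f"peaks/{marker}/{cl}"] = str(path)
    for tf, ps in sorted(sim.tf_peaks.items()):
        path = outdir / "tf" / f"{tf}.bed"
        write_intervals(ps.intervals, path)
        manifest[f"tf/{tf}"] = str(path)
    snp_tsv = outdir / "snps.tsv"
    write_snps_tsv(sim.snps, snp_tsv)
    manifest["snps_tsv"] = str(snp_tsv)
    snp_vcf = outdir / "snps.vcf"
    write_snps_vcf(sim.snps, snp_vcf, contigs={sim.cfg.chrom: sim.cfg.chrom_length})
    manifest["snps_vcf"] = str(snp_vcf)
    truth_path = outdir / "truth.json"
    truth_path.write_text(sim.truth.to_json())
    manifest["truth"] = str(truth_path)
    cfg_path = outdir / "sim_config.json"
    cfg_path.write_text(json.dumps(dataclasses.asdict(sim.cfg), indent=1, sort_keys=True))
    manifest["config"] = str(cfg_path)
    return manifest
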