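"""Allele-specific binding and qPCR statistics.

Covers the allele-fraction normalization (A/(A+G))·100, the two-sided
Fisher exact test of ChIP versus input allele counts, relative expression
by the delta-delta-Ct method with multiple reference genes, and
percent-of-input ChIP-qPCR enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class AlleleCounts:
    """Integer quantification units for the two alleles of one sample."""

    label: str
    units_a: int
    units_g: int

    def __post_init__(self) -> None:
        for v in (self.units_a, self.units_g):
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(
                    f"{self.label}: allele units must be integers; scale "
                    "continuous areas with scale_areas() first"
                )
            if v < 0:
                raise ValueError(f"{self.label}: negative allele units")

    @property
    def total(self) -> int:
        return self.units_a + self.units_g


@dataclass(frozen=True)
class AlleleSpecificResult:
    fraction_a_pct: Mapping[str, float]  # per-sample (A/(A+G))·100
    p_value: float
    odds_ratio: float
    table: tuple[tuple[int, int], tuple[int, int]]


def scale_areas(label: str, area_a: float, area_g: float, scale: float = 1.0) -> AlleleCounts:
    """Convert continuous peak areas to integer units (rounded after scaling).

    The Fisher p-value depends on this scale; it is a declared choice, not
    part of the measurement.
    """
    return AlleleCounts(label, round(area_a * scale), round(area_g * scale))


def allele_fraction(c: AlleleCounts) -> float:
    """(A/(A+G))·100 for one sample."""
    if c.total <= 0:
        raise ValueError(f"{c.label}: zero total units")
    return 100.0 * c.units_a / c.total


def _fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p with fixed margins, probability ordering.

    Works on the integer pmf numerators C(r1,x)·C(r2,c1−x) so that ties
    between equally probable tables are handled exactly; only the final
    division is floating point.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    observed = numerators[a - lo]
    total = sum(n for n in numerators if n <= observed)
    return min(1.0, total / math.comb(r1 + r2, c1))


def fisher_allele_test(input_counts: AlleleCounts, chip_counts: AlleleCounts) -> AlleleSpecificResult:
    """Two-sided Fisher exact test on the 2×2 table
    [[input_A, input_G], [chip_A, chip_G]].

    p sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (probability-ordering definition). The odds ratio is the cross-product
    ratio a·d/(b·c); zero cells yield inf (or nan when 0/0), never an error.
    """
    for c in (input_counts, chip_counts):
        if c.total <= 0:
            raise ValueError(f"{c.label}: zero total units")
    a, b = input_counts.units_a, input_counts.units_g
    c_, d = chip_counts.units_a, chip_counts.units_g
    p = _fisher_two_sided_p(a, b, c_, d)
    if b * c_ > 0:
        oratio = (a * d) / (b * c_)
    elif a * d > 0:
        oratio = math.inf
    else:
        oratio = math.nan
    return AlleleSpecificResult(
        fraction_a_pct={
            input_counts.label: allele_fraction(input_counts),
            chip_counts.label: allele_fraction(chip_counts),
        },
        p_value=float(min(p, 1.0)),
        odds_ratio=oratio,
        table=((a, b), (c_, d)),
    )


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ("gene", "condition", "ct")
CHIP_COLUMNS = ("condition", "sample", "ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated Ct table; Ct values must be finite and > 0."""
    df = pd.read_csv(path, sep="\t")
    if "ct" not in df.columns:
        raise ValueError(f"{path}: missing 'ct' column")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if not (ct.notna() & (ct > 0)).all():
        raise ValueError(f"{path}: Ct values must be finite and > 0")
    df["ct"] = ct
    return df


def _mean_ct(df: pd.DataFrame, gene: str, condition: str) -> float:
    sel = df[(df["gene"] == gene) & (df["condition"] == condition)]["ct"]
    if sel.empty:
        raise ValueError(f"no Ct values for gene {gene!r} in condition {condition!r}")
    return float(sel.mean())


def ddct_expression(
    ct: pd.DataFrame,
    target: str,
    reference_genes: Sequence[str],
    condition: str,
    control_condition: str,
) -> float:
    """Fold change 2^(−ΔΔCt) for `target` in `condition` versus control.

    Replicate Cts are averaged per (gene, condition); the reference Ct is
    the arithmetic mean of the per-reference-gene mean Cts (equivalent to
    the geometric mean of reference quantities).
    """
    if not reference_genes:
        raise ValueError("at least one reference gene required")

    def delta_ct(cond: str) -> float:
        ref = sum(_mean_ct(ct, g, cond) for g in reference_genes) / len(reference_genes)
        return _mean_ct(ct, target, cond) - ref

    ddct = delta_ct(condition) - delta_ct(control_condition)
    return 2.0 ** (-ddct)


def expression_table(
    ct: pd.DataFrame,
    targets: Sequence[str],
    reference_genes: Sequence[str],
    control_condition: str,
) -> pd.DataFrame:
    """Fold changes for every (target, condition) pair versus control."""
    conditions = sorted(ct["condition"].unique())
    rows = []
    for gene in targets:
        for cond in conditions:
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "fold_change": ddct_expression(
                        ct, gene, reference_genes, cond, control_condition
                    ),
                }
            )
    return pd.DataFrame(rows)


def percent_input(
    ct: pd.DataFrame,
    input_fraction: float,
    control_condition: str,
) -> pd.DataFrame:
    """ChIP enrichment as percent of (fraction-adjusted) input per condition.

    %input = 100 · 2^(adjusted_input_Ct − chip_Ct) where adjusted_input_Ct =
    input_Ct − log2(input_fraction). The `relative` column divides each
    condition's %input by the control condition's.
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    conditions = sorted(ct["condition"].unique())
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent from table")
    values = {}
    for cond in conditions:
        sub = ct[ct["condition"] == cond]
        chip = sub[sub["sample"] == "chip"]["ct"]
        inp = sub[sub["sample"] == "input"]["ct"]
        if chip.empty or inp.empty:
            raise ValueError(f"condition {cond!r} needs both chip and input Ct values")
        adjusted_input = float(inp.mean()) - math.log2(input_fraction)
        values[cond] = 100.0 * 2.0 ** (adjusted_input - float(chip.mean()))
    control = values[control_condition]
    return pd.DataFrame(
        [
            {"condition": cond, "percent_input": v, "relative": v / control}
            for cond, v in values.items()
        ]
    )
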