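"""Shared fixtures and independent brute-force oracles.

Oracles here deliberately avoid the package's own algorithms: consensus is
recomputed base-by-base, Fisher p-values by exhaustive hypergeometric
enumeration, and motif scores by positionwise set membership.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

from prrkit.intervals import GenomicInterval, PeakSet


# ---------------------------------------------------------------------------
# consensus oracle: mark every base covered by a peak passing the retention
# predicate, then extract maximal runs (== merged regions with book-ended
# coalescing)
# ---------------------------------------------------------------------------

def brute_force_consensus(
    peaks_by_cell_line: dict[str, list[tuple[int, int]]],
    chrom_length: int,
    min_frac: float = 0.5,
    min_lines: int = 2,
    reciprocal: bool = False,
) -> list[tuple[int, int]]:
    """Single-chromosome base-by-base consensus for integer peak tuples."""
    covered = np.zeros(chrom_length, dtype=bool)
    lines = sorted(peaks_by_cell_line)
    for cl in lines:
        for (s, e) in peaks_by_cell_line[cl]:
            supporters = set()
            for other in lines:
                if other == cl:
                    continue
                for (qs, qe) in peaks_by_cell_line[other]:
                    ov = max(0, min(e, qe) - max(s, qs))
                    ok = ov >= min_frac * (e - s)
                    if reciprocal:
                        ok = ok and ov >= min_frac * (qe - qs)
                    if ok:
                        supporters.add(other)
                        break
            if len(supporters) >= min_lines - 1:
                covered[s:e] = True
    runs = []
    in_run = False
    for i, c in enumerate(covered):
        if c and not in_run:
            start, in_run = i, True
        elif not c and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, chrom_length))
    return runs


def make_peak_sets(
    peaks_by_cell_line: dict[str, list[tuple[int, int]]],
    assay: str = "H3K4me1",
    chrom: str = "chrT",
) -> dict[str, PeakSet]:
    return {
        cl: PeakSet(cl, assay, [GenomicInterval(chrom, s, e) for s, e in tuples])
        for cl, tuples in peaks_by_cell_line.items()
    }


@pytest.fixture
def random_instance_factory():
    """Random multi-cell-line peak instances on a 10 kb toy chromosome."""

    def factory(rng: np.random.Generator, max_intervals: int = 100, max_lines: int = 5):
        n_lines = int(rng.integers(1, max_lines + 1))
        total = int(rng.integers(0, max_intervals + 1))
        out: dict[str, list[tuple[int, int]]] = {f"L{i}": [] for i in range(n_lines)}
        for _ in range(total):
            cl = f"L{int(rng.integers(0, n_lines))}"
            start = int(rng.integers(0, 9_900))
            length = int(rng.integers(1, 400))
            out[cl].append((start, min(10_000, start + length)))
        return out

    return factory


# ---------------------------------------------------------------------------
# Fisher oracle: exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------

def enumerate_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing the probabilities of every table with
    the observed margins whose probability ≤ the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def table_prob(x: int) -> float:
        # x = top-left cell; requires max(0, c1-r2) ≤ x ≤ min(r1, c1)
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-12):  # tolerate float ties
            total += p
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# motif oracle: positionwise degenerate-set scorer
# ---------------------------------------------------------------------------

_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_motif_scan(seq: str, pattern: str) -> list[tuple[int, str, int]]:
    """(offset, strand, matches) for every window on both strands."""
    k = len(pattern)
    out = []
    for i in range(len(seq) - k + 1):
        fwd = seq[i:i + k]
        rev = "".join(_ORACLE_COMP[b] for b in reversed(fwd))
        for strand, window in (("+", fwd), ("-", rev)):
            score = 0
            for base, code in zip(window, pattern):
                if base != "N" and base in _ORACLE_IUPAC[code]:
                    score += 1
                elif base == "N" and code == "N":
                    score += 1
            out.append((i, strand, score))
    return out
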