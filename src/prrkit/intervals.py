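"""Core genomic-interval data model, interval algebra, and flat-file I/O.

Coordinates are 0-based half-open everywhere (BED convention). VCF positions
are converted to 0-based on ingest. Strand is ignored for interval algebra.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals; 0 across chromosomes.

    Book-ended intervals ([100,200) vs [200,300)) share no base.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], merge_bookended: bool = True
) -> list[GenomicInterval]:
    """Merge overlapping (and, optionally, touching) intervals.

    Returns a sorted, pairwise-disjoint list covering exactly the union of
    the input bases. Names/scores are dropped on merged output.
    """
    ivs = sort_intervals(intervals)
    if not ivs:
        return []
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        joins = iv.start <= cur_end if merge_bookended else iv.start < cur_end
        if iv.chrom == cur_chrom and joins:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


class DisjointIntervals:
    """Bisect-backed point/interval queries over disjoint sorted intervals."""

    def __init__(self, intervals: Iterable[GenomicInterval], merge_bookended: bool = True):
        self.intervals = merge_intervals(intervals, merge_bookended=merge_bookended)
        self._by_chrom: dict[str, tuple[list[int], list[int], list[GenomicInterval]]] = {}
        for iv in self.intervals:
            starts, ends, ivs = self._by_chrom.setdefault(iv.chrom, ([], [], []))
            starts.append(iv.start)
            ends.append(iv.end)
            ivs.append(iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def containing(self, chrom: str, pos: int) -> Optional[GenomicInterval]:
        """The interval containing position `pos`, or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, ivs = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return ivs[i]
        return None

    def nearest(self, chrom: str, pos: int) -> tuple[Optional[GenomicInterval], Optional[int]]:
        """Nearest interval and its distance in bp (0 when pos is inside).

        Distance to an interval on the right is start − pos; on the left it is
        pos − (end − 1), i.e. the gap to the last contained base.
        """
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None, None
        starts, ends, ivs = entry
        i = bisect_right(starts, pos) - 1
        best: tuple[int, GenomicInterval] | None = None
        if i >= 0:
            if pos < ends[i]:
                return ivs[i], 0
            best = (pos - (ends[i] - 1), ivs[i])
        if i + 1 < len(ivs):
            cand = (starts[i + 1] - pos, ivs[i + 1])
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:
            return None, None
        return best[1], best[0]

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All stored intervals sharing ≥1 bp with [start, end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, ivs = entry
        lo = bisect_right(ends, start)  # first interval with iv.end > start
        hi = bisect_left(starts, end)   # first interval with iv.start >= end
        return ivs[lo:hi]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.overlapping(chrom, start, end))


@dataclass
class PeakSet:
    """Peaks for one (cell line, assay) pair, sorted on construction."""

    cell_line: str
    assay: str
    intervals: list[GenomicInterval]
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        self.intervals = sort_intervals(self.intervals)
        n_unique = len(set(self.intervals))
        self.n_duplicates = len(self.intervals) - n_unique
        if self.n_duplicates:
            log.warning(
                "%s/%s: %d duplicate peak(s) in input",
                self.cell_line, self.assay, self.n_duplicates,
            )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide variant; `pos` is 0-based."""

    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: Optional[float] = None
    on_array: bool = False

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"{self.rsid}: alleles must be single bases in ACGT")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        if self.pos < 0:
            raise ValueError(f"{self.rsid}: negative position")
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: maf {self.maf} outside [0, 0.5]")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_bed_line(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected ≥3 tab-separated columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
    name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
    score: Optional[float] = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
    try:
        return GenomicInterval(fields[0], start, end, name=name, score=score)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def _parse_narrowpeak_line(fields: list[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) < 10:
        raise ValueError(f"{path}:{lineno}: narrowPeak requires 10 columns")
    iv = _parse_bed_line(fields[:5], lineno, path)
    # signalValue (col 7) replaces the integer display score when present
    try:
        signal = float(fields[6])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-numeric signalValue") from exc
    return GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name, score=signal)


def read_intervals(path: str | Path, format: Optional[str] = None) -> list[GenomicInterval]:
    """Read a BED3+ or narrowPeak file into a sorted interval list.

    `format` is "bed3", "narrowPeak", or None (inferred from the extension).
    """
    path = Path(path)
    if format is None:
        format = "narrowPeak" if path.suffix.lower() == ".narrowpeak" else "bed3"
    if format not in ("bed3", "bed", "narrowPeak"):
        raise ValueError(f"unknown peak format: {format!r}")
    parse = _parse_narrowpeak_line if format == "narrowPeak" else _parse_bed_line
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            out.append(parse(line.split("\t"), lineno, str(path)))
    return sort_intervals(out)


def read_peaks(
    path: str | Path,
    cell_line: str,
    assay: str,
    format: Optional[str] = None,
) -> PeakSet:
    return PeakSet(cell_line, assay, read_intervals(path, format=format))


def write_intervals(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    one_based: bool = False,
) -> None:
    """Write intervals as BED (or 1-based inclusive when `one_based`)."""
    shift = 1 if one_based else 0
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start + shift), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(iv.score))
            fh.write("\t".join(cols) + "\n")


def _read_snps_vcf(path: Path) -> list[SNPRecord]:
    import pysam

    out: list[SNPRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(rec.ref or "") != 1 or len(alts) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            if rec.ref not in VALID_BASES or alts[0] not in VALID_BASES:
                skipped += 1
                continue
            maf = rec.info.get("MAF") if "MAF" in rec.info else None
            if isinstance(maf, tuple):
                maf = maf[0]
            out.append(
                SNPRecord(
                    rsid=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos - 1,  # pysam .pos is 1-based
                    ref=rec.ref,
                    alt=alts[0],
                    maf=float(maf) if maf is not None else None,
                    on_array="ARRAY" in rec.info,
                )
            )
    if skipped:
        log.warning("%s: skipped %d non-SNV record(s)", path, skipped)
    return out


def _read_snps_tsv(path: Path) -> list[SNPRecord]:
    out: list[SNPRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("rsid\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected ≥5 columns")
            rsid, chrom, pos_s, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
                skipped += 1
                continue
            maf = None
            if len(fields) > 5 and fields[5] not in ("", "."):
                maf = float(fields[5])
            on_array = len(fields) > 6 and fields[6] in ("1", "true", "True")
            try:
                out.append(SNPRecord(rsid, chrom, int(pos_s), ref, alt, maf, on_array))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if skipped:
        log.warning("%s: skipped %d non-SNV record(s)", path, skipped)
    return out


def read_snps(path: str | Path) -> list[SNPRecord]:
    """Read a SNP catalog from VCF (by extension) or a rsid/chrom/pos0 TSV."""
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        return _read_snps_vcf(path)
    return _read_snps_tsv(path)


def write_snps_tsv(snps: Sequence[SNPRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos0\tref\talt\tmaf\ton_array\n")
        for s in snps:
            maf = "" if s.maf is None else f"{s.maf:.6g}"
            fh.write(
                f"{s.rsid}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{maf}\t{int(s.on_array)}\n"
            )


def write_snps_vcf(snps: Sequence[SNPRecord], path: str | Path, contigs: dict[str, int]) -> None:
    """Write SNPs as a minimal VCF v4.2 with MAF/ARRAY INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in sorted(contigs.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=ARRAY,Number=0,Type=Flag,Description="On genotyping array">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            info_parts = []
            if s.maf is not None:
                info_parts.append(f"MAF={s.maf:.6g}")
            if s.on_array:
                info_parts.append("ARRAY")
            info = ";".join(info_parts) or "."
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.rsid}\t{s.ref}\t{s.alt}\t.\t.\t{info}\n")
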