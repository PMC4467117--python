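"""IUPAC degenerate consensus-motif scanning and per-allele impact scoring.

Plain match/mismatch counting against a consensus string on both strands —
no position-weight matrices. A query base matches a pattern position when it
belongs to the degeneracy set of the IUPAC code; a query 'N' matches only a
pattern 'N'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# motifs the package ships by default: androgen-response-element half site
# and the estrogen response element
DEFAULT_MOTIFS = {"ARE": "RGNACR", "ERE": "RGGTCANNNTGASCY"}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusMotif:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"{self.name}: empty pattern")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC code(s) {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifMatch:
    """One scored window; offset is 0-based on the query's forward strand."""

    offset: int
    strand: str  # "+" or "-"
    matches: int
    mismatch_positions: tuple[int, ...]  # pattern coordinates
    covers_snp: bool = False
    snp_offset_in_site: Optional[int] = None


def _base_matches(query_base: str, code: str) -> bool:
    # query N is an unknown base: it satisfies nothing except pattern N
    if query_base == "N":
        return code == "N"
    return query_base in IUPAC[code]


def _score_window(window: str, pattern: str) -> tuple[int, tuple[int, ...]]:
    mismatches = tuple(
        i for i, (b, code) in enumerate(zip(window, pattern))
        if not _base_matches(b, code)
    )
    return len(pattern) - len(mismatches), mismatches


def iupac_scan(
    seq: str,
    motif: ConsensusMotif,
    min_matches: int = 0,
    snp_offset: Optional[int] = None,
) -> list[MotifMatch]:
    """Score every window of `seq` on both strands against the motif.

    A minus-strand match at offset i means the reverse complement of
    seq[i:i+len] fits the pattern; mismatch positions are reported in
    pattern coordinates. Results are sorted by (matches desc, offset asc,
    '+' before '-'). When `snp_offset` is given, windows covering that
    query position are annotated with the SNP's position within the site.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid sequence character(s): {sorted(bad)}")
    k = len(motif)
    if len(seq) < k:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {k})")
    pattern = motif.pattern
    out: list[MotifMatch] = []
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        for strand, oriented in (("+", window), ("-", reverse_complement(window))):
            score, mism = _score_window(oriented, pattern)
            if score < min_matches:
                continue
            covers = snp_offset is not None and i <= snp_offset < i + k
            site_off = None
            if covers:
                site_off = (snp_offset - i) if strand == "+" else (i + k - 1 - snp_offset)
            out.append(
                MotifMatch(
                    offset=i, strand=strand, matches=score,
                    mismatch_positions=mism,
                    covers_snp=covers, snp_offset_in_site=site_off,
                )
            )
    out.sort(key=lambda m: (-m.matches, m.offset, 0 if m.strand == "+" else 1))
    return out


@dataclass(frozen=True)
class AlleleImpact:
    motif: str
    ref_match: Optional[MotifMatch]
    alt_match: Optional[MotifMatch]
    delta: Optional[int]  # matches(alt) − matches(ref) at the shared site


def allele_impact(
    flank: str,
    snp_offset: int,
    ref: str,
    alt: str,
    motif: ConsensusMotif,
) -> AlleleImpact:
    """Best SNP-covering site for each allele and the match-count delta.

    Both allelic sequences are scanned; the reported site is the
    (offset, strand) window covering the SNP with the highest match count
    for either allele (ties: smaller offset, then '+'). A positive delta
    means the alternate allele improves the consensus fit.
    """
    flank = flank.upper()
    if not 0 <= snp_offset < len(flank):
        raise ValueError(f"snp_offset {snp_offset} outside sequence of length {len(flank)}")
    seqs = {
        allele: flank[:snp_offset] + allele + flank[snp_offset + 1:]
        for allele in (ref.upper(), alt.upper())
    }
    covering: dict[str, dict[tuple[int, str], MotifMatch]] = {}
    for allele, seq in seqs.items():
        hits = iupac_scan(seq, motif, min_matches=0, snp_offset=snp_offset)
        covering[allele] = {
            (m.offset, m.strand): m for m in hits if m.covers_snp
        }
    shared = sorted(covering[ref.upper()].keys() & covering[alt.upper()].keys())
    if not shared:
        return AlleleImpact(motif=motif.name, ref_match=None, alt_match=None, delta=None)

    def site_rank(site: tuple[int, str]) -> tuple[int, int, int]:
        best = max(
            covering[ref.upper()][site].matches, covering[alt.upper()][site].matches
        )
        return (-best, site[0], 0 if site[1] == "+" else 1)

    site = min(shared, key=site_rank)
    ref_m = covering[ref.upper()][site]
    alt_m = covering[alt.upper()][site]
    return AlleleImpact(
        motif=motif.name,
        ref_match=ref_m,
        alt_match=alt_m,
        delta=alt_m.matches - ref_m.matches,
    )
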