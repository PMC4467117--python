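# prrkit

Discovery of **polymorphic regulatory regions (PRRs)** — SNPs lying inside
consensus enhancer/promoter elements bound by transcription factors — from
multi-cell-line peak data, together with the downstream allele-specific
statistics and IUPAC consensus-motif impact scoring.

## What it does

- **Consensus regions** (`prrkit.consensus`): three-step retain / concatenate /
  sort-and-merge construction across cell lines. A peak is retained when a
  peak from a different cell line covers ≥ 50 % of its own length
  (asymmetric by default; `--reciprocal` for the stricter variant); retained
  peaks are merged into disjoint regions with per-region provenance.
- **SNP annotation** (`prrkit.discovery`): chromatin-state classification
  (enhancer = H3K4me1 without H3K4me3, promoter = both), TF binding under
  `region_overlap` or `snp_in_peak` semantics, optional proximity windows,
  marker × TF cross-tabulation of distinct rsIDs, and MAF/array filtering.
- **Allele statistics** (`prrkit.allele`): (A/(A+G))·100 allele fractions, an
  exact-arithmetic two-sided Fisher test of ChIP vs input allele counts,
  ΔΔCt relative expression with multiple reference genes, and
  percent-of-input ChIP-qPCR enrichment relative to a control condition.
- **Motif scanning** (`prrkit.motifs`): IUPAC degenerate consensus matching
  on both strands (ships ARE half-site `RGNACR` and ERE
  `RGGTCANNNTGASCY`) and per-allele impact of a SNP on the best covering
  site.
- **Synthetic data** (`prrkit.simulate`): fully seeded landscapes with known
  ground truth — planted regulatory elements, jittered per-cell-line peaks,
  noise peaks, TF peaks, SNP catalogs, allele-biased counts, Ct tables —
  so the entire pipeline is testable offline.
- **Interval core** (`prrkit.intervals`): 0-based half-open interval model
  and algebra; BED3+/narrowPeak, VCF and TSV I/O.

## CLI

All stages are subcommands of `prr` (`prr --help` for the full list):

```sh
# synthetic landscape with ground truth
prr simulate --seed 17 -o outdir/

# consensus per marker
prr consensus --assay H3K4me1 --peaks cellA=a.bed --peaks cellB=b.bed \
    --min-frac 0.5 --min-lines 2 -o consensus/H3K4me1.bed

# SNP annotation and cross-tab
prr discover --consensus-dir consensus/ --tf AR=ar.bed --tf ER=er.bed \
    --snps snps.vcf -o prr.tsv
prr crosstab prr.tsv --tfs AR,ER -o table1.tsv

# allele-specific binding, expression, ChIP enrichment, motif impact
prr allele --input A=632,G=368 --chip A=850,G=150
prr expression --ct ct.tsv --target RAB20 --refs GAPDH,B2M --control EtOH
prr chip-enrich --ct chip_ct.tsv --input-fraction 0.10 --control EtOH
prr motif --fasta flanks.fa --snp-offset 25 --ref G --alt A -o motif.tsv

# everything at once on synthetic data, with a hashed artifact manifest
prr run-all --seed 5 -o run/
```

## Conventions

- Coordinates are 0-based half-open everywhere; VCF positions are converted
  on ingest and output is BED-style unless `--one-based` options say
  otherwise.
- Only SNVs are kept from SNP catalogs; indels are skipped with a warning.
- All randomness flows through a single seed; identical configurations
  reproduce byte-identical outputs.
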