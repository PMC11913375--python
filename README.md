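# intronret

Genome-wide intron-retention analysis from splice-junction reads, built for
short-intron-rich transcriptomes such as the basidiomycete yeast
*Cryptococcus neoformans* (average intron length ~56 nt, multiple introns
per transcript). The package quantifies per-intron splicing efficiency
under a splicing-factor perturbation (e.g. a promoter-shutdown knockdown of
the DEAH-box helicase Prp16) from standard RNA-seq alignments, and relates
the splicing defect to splice-site sequence features and intron length.

It is aimed at transcriptomics researchers who have a genome FASTA, a GTF
annotation and spliced alignments (SAM/BAM) for two conditions with
replicates — or who want to prototype against the bundled synthetic-data
generator, which produces a toy short-intron genome with known per-intron
retention ground truth.

## The score and the test

For each annotated intron, three junction read classes are counted per
sample:

* **EEJR** — exon–exon junction reads: gapped alignments whose `N` CIGAR
  operation spans the intron exactly (spliced mRNA evidence);
* **EIJR / IEJR** — exon–intron / intron–exon junction reads: contiguous
  alignments crossing the donor / acceptor boundary with a minimum anchor
  on both sides (retained pre-mRNA evidence).

With pseudocount α (default 1), the intron retention score per sample is

    IRS = log2 [ (EIJR + IEJR + 2α) / (2 · (EEJR + α)) ]

Introns with fewer than 10 junction reads in either condition are removed.
Per intron, `IRSdiff = mean IRS(KD) − mean IRS(WT)` and a two-sample Z
score `Z = IRSdiff / SE` are computed; the default standard error combines
the per-intron replicate variances with a delta-method counting-noise
floor, while `var_mode="pooled"` gives the classical calibrated Z test
(see `docs/methods.md`). Introns are then categorised:
negative-IRSdiff/negative-Z introns are set aside,
the minimum IRSdiff among introns above the first Z-quartile becomes the
affected/unaffected cutoff, and affected introns split into strongly
(IRSdiff > 2) and mildly affected.

Downstream analyses: splice-site sequence logos (position probability /
information matrices), differential logos (per-position Jensen–Shannon
divergence with signed base differences), per-position Fisher exact tests,
exonic signature groups AAG-G / AAG-H / BBH-H / NNN-N (last three 5'-exon
nt plus first 3'-exon nt; IUPAC B = C/G/T, H = A/C/T), a U5 snRNA loop1
complementarity score for the 5'-exon terminus, and intron-length-stratified
IRS/IRSdiff profiles (bins 20–40 / 40–60 / 60–100 / 100–500 / ≥500 nt, plus
a 10-nt scan) with Wilcoxon rank-sum comparisons.

## Worked example

Run the full pipeline on simulated data (40 genes, ~150 introns, wild type
vs knockdown, 3 replicates each):

```python
import intronret as ir

cfg = ir.RunConfig(outdir="demo_run", seed=7,
                   simulate=ir.SimConfig(n_genes=40, coverage_mean=60.0))
result = ir.run_pipeline(cfg)
print(open("demo_run/summary.txt").read())
```

which prints

```
pipeline summary
================
category counts:
  STRONGLY_AFFECTED: 111
  MILDLY_AFFECTED: 0
  UNAFFECTED: 40
  EXCLUDED_NEGATIVE: 0
  LOW_COVERAGE: 0
signature group counts:
  AAG-G: 4
  AAG-H: 10
  BBH-H: 20
  NNN-N: 117
per-bin median IRSdiff:
  40-60: 2.695
  60-100: 2.687
  20-40: 2.667
  100-500: 2.937
```

Reading: of 151 introns passing the coverage filter, 111 show a strong
retention increase under knockdown (IRSdiff > 2) and 40 are unaffected —
matching the generator's defaults, in which most introns respond strongly
to the knockdown while introns with the U5-friendly AAG-G exonic signature
respond least. The stage tables (`junction_counts.tsv`, `irs_summary.tsv`,
`intron_categories.tsv`, `signature_groups.tsv`, `length_profiles.tsv`, …)
and a manifest with parameters and input checksums are written next to the
summary. The same run is available from the shell as
`intronret run-all --config config.yaml` (see `intronret --help` for the
per-stage subcommands `simulate`, `count`, `irs`, `classify`, `motifs`,
`lengths`).

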