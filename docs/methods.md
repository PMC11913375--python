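# Methods

## Analysis model

The unit of analysis is the annotated intron: the gap between consecutive
exons of a transcript, deduplicated within a gene across transcripts.
Coordinates are 0-based half-open internally; GTF input is treated as
1-based inclusive and SAM as 1-based, with conversions confined to the I/O
layer. On the plus strand the donor sits at the intron start, on the minus
strand at the intron end; intron indices count from the transcript 5' end.

Splicing efficiency is measured purely from junction-traversing reads.
A gapped alignment supports splicing of intron *i* iff one of its `N` gaps
equals the intron exactly and both flanking aligned blocks cover at least
`min_anchor` nt (default 5 — large enough to suppress 1–2 nt spurious
overlaps, permissive for ≥50 nt reads). A contiguous aligned block supports
retention iff it covers the donor window `[start − a, start + a)` (EIJR) or
the acceptor window `[end − a, end + a)` (IEJR). One read contributes at
most one junction type per intron, with deterministic priority
EEJR > EIJR > IEJR; for ultra-short introns a single contiguous read can
cover both boundary windows, and the priority rule resolves it to the
donor side. Because the retention score only ever uses EIJR + IEJR, this
tie-break does not affect any downstream quantity. Deletions (`D`) extend a
block — a small deletion does not break retention evidence — while only `N`
splits blocks; reads with CIGAR operations outside M/I/D/N/S/H/=/X are
skipped and tallied. Counting ignores read strand and uses primary, mapped
alignments only.

Introns need at least 10 junction reads in *each* condition (summed over
that condition's replicates) to enter the analysis; requiring the threshold
per condition rather than overall guarantees the retention score is
estimable on both sides of the comparison.

## Retention score and the two-sample Z test

Per intron and sample, with pseudocount α = 1:

    retention_level = (EIJR + IEJR + 2α) / (2 · (EEJR + α))
    IRS = log2(retention_level)

The two retained junctions play symmetric roles and are averaged; the
pseudocount keeps the score finite for all counts. IRS is computed per
replicate, then averaged per condition — the replicate-level scores are
what gives the Z test its variance estimate.
`IRSdiff = mean IRS(KD) − mean IRS(WT)` and

    Z = IRSdiff / sqrt(V_KD / n_KD + V_WT / n_WT + 1e-6)

Two variance estimators are provided, because no single estimator can both
be calibrated at the nominal level and provide the heteroscedastic
per-intron ranking the classification procedure relies on when only three
replicates per condition exist:

* `var_mode="per_intron"` (default): V is the intron's own replicate
  variance plus a delta-method counting-noise floor,
  `var(IRS) ≥ [1/(EIJR+IEJR+2α) + 1/(EEJR+α)] / ln(2)²` per replicate
  (averaged over replicates). With three replicates, discrete counts
  regularly produce sample variances near zero; without the floor such
  introns reach |Z| in the hundreds and corrupt any quantile-based
  downstream step. The floor caps every Z at the information the counts
  actually contain. This Z is a *ranking* statistic: conservative as a
  test (null |Z| > 1.96 in roughly 1% of introns rather than 5%), but
  heteroscedastic across introns, which the cutoff-derivation below needs.
* `var_mode="pooled"`: the per-condition replicate variances are averaged
  across all tested introns. With thousands of introns this is an
  effectively known variance, the statistic is close to standard normal,
  and the nominal 5% level at |Z| > 1.96 is reproduced (verified by the
  acceptance suite within 3-sigma binomial bounds). Use this mode whenever
  calibrated significance statements are the goal. Note that with a single
  intron the pooled variance reduces to that intron's own variance, i.e.
  the classical Welch formula.

A Welch Z with per-intron variances alone is t-distributed with ~4 degrees
of freedom at n = 3 + 3, rejecting ~12% at 1.96 — neither calibrated nor
stable; it is available only implicitly (per-intron mode on data without
count columns, where the floor cannot be computed).

## Classification

On tested introns: (1) introns with IRSdiff < 0 and Z < 0 are set aside as
likely false positives (`EXCLUDED_NEGATIVE`) before anything else is
derived; (2) quartile thresholds of the remaining Z scores are taken under
the descending-sort convention with midpoint interpolation (the convention
is a parameter); (3) the minimum IRSdiff among introns above the first
quartile becomes the affected/unaffected cutoff; (4) affected introns with
IRSdiff strictly greater than `strong_cut` (default 2; ties are mild) are
strongly affected. Independently, `high_confidence_z` records membership
in the top Z-quartile — the high-confidence affected set consumed by the
sequence-feature analyses. Categories partition the tested introns; introns
failing the coverage filter are reported as `LOW_COVERAGE`.

## Sequence features

Splice-site windows default to 3 exonic + 6 intronic nt at the donor and
6 intronic + 1 exonic nt at the acceptor — covering every position the
downstream analyses use (5'-exon −3…−1, intronic positions 3–4, 3'-exon
+1) — and are extracted in transcript orientation (reverse-complemented on
minus-strand introns). Position probability matrices report per-column
information `2 + Σ p log2 p` bits with ambiguous bases excluded per column;
differential logos report the per-position Jensen–Shannon divergence in
bits (0…1) with signed per-base probability differences. Per-position
enrichment uses the two-sided Fisher exact test on the 2×2 table
[base ∈ set vs not] × [group A vs B], reporting the sample odds ratio.

Signature groups are assigned with precedence AAG-G → AAG-H → BBH-H →
NNN-N, so the four groups are disjoint and partition every intron; NNN-N is
defined as the complement of the first three rules, and ambiguous bases
fall through to NNN-N.

The U5 loop1 score counts base pairs when the 5'-exon terminal 3-mer
(5'→3') is laid antiparallel against a loop register given 5'→3' (wild
type CUU, mutant GAA). Watson–Crick pairs always count; G·U wobbles only on
request (off by default, matching the Watson–Crick framing of the exon–U5
interaction). AAG/CUU scores 3, UUC/CUU scores 0, and UUC/GAA scores 3 —
the complementarity logic behind the loop1-mutant rescue.

## Length analysis

Default bins 20–40, 40–60, 60–100, 100–500, ≥500 nt are lower-inclusive /
upper-exclusive so shared printed edges are not double-counted; introns
below 20 nt are reported separately. A 10-nt preset over [20, 100) serves
the fine scan. Pairwise bin comparisons use the two-sided Wilcoxon
rank-sum test: for pooled samples of at most 20 values, exact enumeration
of all splits with mid-ranks for ties; otherwise the tie-corrected normal
approximation. No multiplicity correction is applied to the pairwise
matrix.

## Synthetic data generator

The generator emulates the study design the pipeline targets: a
promoter-shutdown knockdown versus wild type, three biological replicates
each, on a genome whose introns concentrate at short and ultra-short
lengths. Defaults: 120 single-transcript genes, 3–7 exons of 60–300 nt,
intron lengths from a mixture with mean ≈56 nt (22% in 20–40, 55% in
40–60, 19% in 60–100, remainder up to 500), GT…AG termini, exonic
signature composition 3.0% / 6.5% / 19.3% / 71.2% for AAG-G / AAG-H /
BBH-H / NNN-N (the observed group frequencies), basal retention
ρ_WT = 0.05 for all introns, and knockdown retention ordered by signature
group (AAG-G 0.10 < AAG-H 0.18 < NNN-N 0.35 < BBH-H 0.45), optionally
modulated by intron length. Replicate totals are negative binomial
(default mean 100 junction-spanning reads per intron, size 10); retained
reads are a Binomial(N, ρ) thinning, split evenly between donor- and
acceptor-crossing placements. A deterministic mode replaces draws by
rounded expectations for exact round-trip tests.

Reads are the minimal sufficient data for junction counting: spliced
molecules become single-gap alignments spanning the intron exactly;
retained molecules become contiguous 100 nt alignments crossing one
boundary with at least the minimum anchor on both sides, placed uniformly
over feasible offsets but constrained to the two flanking exons plus the
intron, so every read touches only its own intron's junctions and the
generator's realized-count table is exactly what the counter must return.
Deliberately not modelled: sequencing errors and quality strings, paired
ends, intron-internal coverage, multi-isoform genes, expression differences
between genes, and antisense transcription. Passing recovery tests
therefore demonstrate correctness of the counting/scoring/classification
machinery under idealised alignments — not robustness to alignment
artefacts, overlapping genes or isoform complexity in real data.

## Problem sizes and numerical choices

The validation suite uses 2,000-intron simulations at coverage 100 for the
calibration and recovery experiments, 1,800 introns for the length
ordering, ~500 introns for composition checks, and 20-gene genomes for the
end-to-end byte-determinism run — sizes at which the binomial 3-sigma
bounds used by the tests are meaningful while the whole suite stays fast.
All randomness flows from explicit seeds through `numpy.random.default_rng`;
reruns with identical config and seed are byte-identical, which the
acceptance suite asserts file by file. TSV floats are written with a fixed
`%.6g` format for that reason. Quantile interpolation for Z-quartiles is
midpoint by default and parameterised; the variance floor under the Z
denominator is 1e-6 beyond the counting floor; Fisher tests report the
unconditional sample odds ratio.

## Known limitations

* The exact-match rule for gapped reads (both gap edges must equal the
  intron) ignores alternative 5'/3' splice-site isoforms; junction
  discovery is out of scope.
* Counting is unstranded; overlapping antisense genes would conflate
  counts.
* The per-intron Z mode is conservative as a significance test (by
  design); the pooled mode assumes variance homogeneity across introns and
  is miscalibrated per intron when coverage varies strongly.
* The classification cutoff is the minimum IRSdiff over the top Z-quartile
  — a single extreme intron can move it; the quartile flag
  (`high_confidence_z`) is the more stable set definition.
* Multi-isoform annotations are reduced to deduplicated introns; relative
  isoform usage is not modelled.
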