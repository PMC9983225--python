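# Methods

## Data model and coordinates

All genomic intervals are 0-based, half-open (BED convention); overlap
means at least one shared base. Coverage files (Bismark-style TSV:
chrom, start, end, methylation %, methylated count, unmethylated count)
are converted at the read boundary; both the 1-based `start == end`
flavor and the BED-like `end == start + 1` flavor are accepted, sniffed
per row. The percentage column is always recomputed from the counts. A
CpG missing from a sample is stored with total count 0 and excluded
from that sample's level computation — never imputed. The methylation
level is β = methylated/total; sites below the per-sample coverage
floor (default 5 reads) are masked to NaN, not reported as 0.

## DMR calling

The caller is a deliberately simple segmentation method in the family
of CpG-run segmenters, not a re-implementation of any specific tool's
exact statistics. Its contract is governed by three thresholds —
maximum CpG gap 300 bp, minimum 5 CpGs, minimum absolute group mean
difference 0.2 — plus a coverage floor (5 reads) and a q-value cutoff
(0.05):

1. **Presegmentation.** Sorted CpGs are split into maximal runs whose
   consecutive gaps are ≤ 300 bp; runs with fewer than 5 usable CpGs
   are dropped. CpGs lacking a finite mean in either group are removed
   before the gap scan.
2. **Segmentation.** Within a run, the per-CpG difference profile
   d_i = mean_A(β_i) − mean_B(β_i) is recursively split at the point
   maximizing the size-weighted contrast
   |mean(left) − mean(right)|·√(n_L n_R / n). A segment is a leaf when
   its best split clears neither the raw mean-gap threshold
   (min_diff/2 = 0.1) nor the weighted-contrast threshold (min_diff =
   0.2). The second trigger matters when a short near-baseline stretch
   separates two long shifted blocks: the raw gap is diluted by the
   block lengths while the weighted contrast is not.
3. **Merging.** Adjacent leaves whose means clear |Δβ| ≥ 0.2 with a
   common sign are merged, so one underlying region yields one
   candidate rather than several fragments.
4. **Testing.** Candidates with ≥ 5 CpGs are tested with a two-sided
   Mann–Whitney U of {d_i} against {−d_i} — a zero-centred symmetric
   null — and BH-adjusted across all candidates of the comparison;
   survivors require q ≤ 0.05.

Degenerate 1-vs-1 designs (a de novo/CR pair, or the cell line pair)
carry no within-group replication: candidates pass on the
threshold criteria alone and `q_value` is reported as NaN. Replication
for these comparisons comes from cross-pair recurrence in the cascade,
which is why per-pair false positives are tolerable — they must recur
with a consistent direction across pairs *and* intersect the tested
patient-level signature to survive.

Region coordinates span the first to last CpG of the candidate
(half-open, last position + 1). Reported `delta` is the unweighted mean
of d_i across the region's CpGs; `direction` is hyper iff delta > 0.
A delta of exactly 0 is classified neither hyper nor hypo and the
segment is discarded.

## Interval algebra and the cascade

All set operations use `-wa` semantics: the output consists of the
query set's own regions, unchanged (coordinates, delta, direction are
never modified by any operation), deduplicated when one query region
overlaps several subjects. Direction-aware intersection keeps query
regions with a same-direction (or, in "opposite" mode,
opposite-direction) overlap. Subtraction removes query regions with a
same-direction overlap; regions retained despite an opposite-direction
overlap are flagged rather than silently kept, because the cascade
reports such conflicts narratively. Recurrence across de novo/CR pairs
anchors coordinates to the first pair's call set and requires a
same-direction overlap in every other pair; conflicts with any
opposite-direction partner are recorded separately.

The subtraction order fixing directions is: t(8;21) minus non-t(8;21)
for the karyotype comparisons, and de novo minus CR for the treatment
comparisons — so a "hypermethylated" treatment region is one whose
methylation *fell* after therapy. DMR7 therefore collects regions that
are simultaneously t(8;21)-associated (DMR3) and t(8;21)-specifically
treatment-responsive (DMR6) with consistent directions;
opposite-direction overlaps at this step are eliminated and counted in
the report. The hypermethylated DMR7 subset is the clinically
actionable one (hypermethylation is easy to assay) and feeds
annotation.

## Annotation

The promoter window spans 2200 bp upstream to 500 bp downstream of the
TSS in transcription orientation: for a + strand gene with TSS t this
is [t−2200, t+500); for a − strand gene the TSS is tx_end−1 and the
window is the exact mirror, [TSS−499, TSS+2201), clipped at the
chromosome start. The minus-strand convention (TSS at tx_end−1 under
half-open coordinates) is a documented choice; coordinates reflected
genome-wide with strands flipped produce identical category
assignments, which the tests check.

Per gene, the "gene body" is the transcript interval minus the
promoter window, so the promoter's downstream 500 bp count as promoter
and the per-gene categories form a true partition: Promoter (promoter
window only), GeneBody (body only), P/Gb (both). Across genes the
precedence is P/Gb > Promoter > GeneBody, with Other for regions
touching no gene. Both Promoter- and P/Gb-class regions feed the gene
funnel, since a P/Gb region still covers promoter sequence.
Percentages in distribution tables are rounded half-up to two decimals
to match conventional printed tables; raw fractions are retained in
the JSON report.

## Expression integration

The differential-expression stage is a declared stand-in: per-gene
Welch t-test on log2 expression with BH correction; "down" requires
q < 0.05 and log2FC < 0. No empirical-Bayes variance moderation is
attempted — the funnel consumes only the down-gene set, and a
precomputed gene list from any external DE tool can be supplied in its
place. Gene identifiers are matched exactly (case-sensitive).
The final candidates are the promoter-hypermethylated genes that are
also down-regulated, sorted by q-value. Array-probe overlap against a
region set uses the same any-overlap, half-open rule.

## The synthetic cohort generator

The generator emulates the structure of a capture-bisulfite AML
cohort, not any particular dataset's values:

* **Cohort shape (defaults).** 3 t(8;21) vs 25 non-t(8;21) de novo
  patients; 2 t(8;21) and 3 non-t(8;21) de novo/CR pairs (paired de
  novo samples are part of the de novo groups); one AML1-ETO-positive/
  -silenced cell line pair. The expression cohort is separate and
  larger (7 vs 121 samples), mirroring the common design in which
  methylation comes from a small sequencing study and expression from
  a public transcriptome resource.
* **Genome.** 2 chromosomes × 2 Mb, 200 non-overlapping genes on both
  strands, 20k background CpGs with exponential gaps (mean 150 bp).
  CpG density is increased five-fold inside gene promoter windows and
  planted regions, emulating CpG islands; this also guarantees every
  callable planted region contains at least its required CpG count.
* **Counts.** Per CpG and sample, coverage is Poisson (mean 30) and
  methylated counts are beta-binomial around a latent level μ with
  intra-class dispersion ρ = 0.02 (s = (1−ρ)/ρ concentration), because
  real bisulfite data is overdispersed relative to binomial. Baselines
  are Beta(0.5, 0.5) (bimodal, as in real methylomes); inside planted
  regions the baseline is drawn uniformly from the range that leaves
  headroom for every sample class's shift, and all latent levels are
  clipped to [0.01, 0.99].
* **Planted effects.** Each planted region carries one signed β-scale
  effect and a contrast set: *group* elevates the t(8;21) lineage
  (patients and the AE-positive cell line); *t(8;21)-treatment* /
  *non-t(8;21)-treatment* elevate the de novo samples of that
  karyotype and are reverted in the corresponding CR samples. For
  regions carrying both group and treatment contrasts the CR reversal
  wins, so the de novo − CR delta equals the planted effect — the CR
  sample represents the post-therapy demethylated state. Effects of
  ±0.4 (demo) and ±0.3–0.5 (caller recovery) are used: strong but
  within the range of biologically meaningful promoter methylation
  shifts.
* **Expression.** Log2 expression is normal around per-gene baselines
  (mean 6, between-gene SD 2, within-gene SD 0.5); genes linked to a
  planted promoter region lose 2 log2 units in the t(8;21) group.

What the generator does **not** model: read-level errors and bisulfite
conversion failure, copy-number and mutational heterogeneity, cell-type
admixture, spatially correlated background methylation, batch effects,
and realistic genome scale. Passing recovery tests therefore
demonstrate the pipeline's logic and statistics on well-specified
signals, not performance on real, noisy, confounded cohorts.

## Problem sizes and determinism

The shipped configurations are desk-scale by design: the demo cohort
(~39k CpGs × 35 samples) runs the full cascade in about a second; the
caller-recovery and 20-seed null-calibration suites each finish in a
few seconds. All randomness flows through `numpy.random.default_rng`
seeded from the configuration, so identical configurations produce
byte-identical fixtures, and the acceptance script derives every
sub-seed from its `--seed` argument.

## Known limitations

* The caller is not bit-compatible with established DMR tools; its
  p-values are per-CpG-difference ranks, not read-level likelihoods,
  and neighbouring-CpG correlation is ignored by the test.
* 1-vs-1 comparisons are threshold-only; their error control lives
  entirely in the cascade's recurrence and intersection steps.
* Distribution-table percentages depend on the category partition
  conventions above; other tools' promoter/body attributions will
  differ in edge cases (e.g. the downstream 500 bp of a promoter).
* The expression stand-in assumes roughly normal log-scale expression
  and unpaired groups; count-based models are out of scope.
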