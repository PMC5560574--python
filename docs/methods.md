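# Methods

## Data model

Ct tables are long-format: one row per (primer pair, sample, technical
replicate), with per-sample metadata (plant, organ ∈ {bud, leaf, root,
pollen}, gender ∈ {F, H}, cDNA priming ∈ {oligo_dT, random}, dataset tag).
Missing Ct values stay as explicit NaN rows so no observation disappears
silently; cells missing after replicate aggregation exclude the affected
sample pairwise (per statistic), never the whole gene. Ct must lie in
(0, 50] — the cycling programme runs 50 cycles, so larger values cannot be
observations.

Two replicate-handling modes are exposed. `mean` (default for BestKeeper /
ΔCt-style use) collapses the technical replicates of each (primer pair,
sample) cell; `none` promotes every replicate to a pseudo-sample, matching
the practice of feeding all technical Ct replicates to the ranking tools as
independent observations. Which mode a run used is recorded in its
manifest. No plate term is modelled: replicates are split across plates for
run-to-run monitoring but are treated as exchangeable, which slightly
understates technical variance if plates differ systematically.

Relative quantities use RQ(g,s) = (1+E_g)^(Ct_min,g − Ct_{g,s}). The
per-gene minimum is taken over the samples of the analysis subset (dataset
tag and priming), so each ranking column is self-contained and per-gene
maxima equal exactly 1. Efficiencies are consumed as inputs (fractions in
[0, 1]; values below 0.95 warn, as they fall outside the usual assay
inclusion envelope).

Distribution summaries use linear-interpolation (type-7) quantiles; the
convention is stated because published box plots rarely name one.

## Stability statistics

All standard deviations use the n−1 (sample) denominator, everywhere.

* **geNorm.** M_j is the mean over k ≠ j of SD(log₂(RQ_j/RQ_k)).
  Ranking eliminates the highest-M gene iteratively; exact M ties eliminate
  the lexicographically greatest primer-pair id, making runs deterministic.
  The two surviving finalists cannot be ordered by the criterion and both
  receive rank 1, with the next gene at rank 3 (competition ranking). This
  convention is what makes an all-method-unanimous comprehensive value of
  exactly 1.00 attainable; a flag restores strict ordering of the finalists
  by their final-round M. V(n/n+1) is the SD over samples of
  log₂(NF_n/NF_{n+1}) with NF_n the geometric mean RQ of the top-n genes.
* **NormFinder.** The additive genes + samples model is fitted by double
  centering; the default stability is the root mean square residual
  √(Σ_j r_ij²/(n−1)). The unbiased gene-variance estimator
  σ̂_i² = (z_i − S/k²)·k/(k−2), z_i = Σ_j r_ij²/(n−1), S = k·Σz/(k−1),
  floored at zero, is available behind a flag; it is an increasing affine
  map of the plain statistic, so rankings agree. The grouped mode scores
  each gene by mean_g(|d_ig| + √(γ̂²_ig/n_g)) — inter-group deviation plus
  intra-group sampling error — without the Bayesian shrinkage of the group
  deviations used by the original tool; the mode used is recorded in the
  result's extras.
* **BestKeeper.** Descriptive: per-gene Ct mean, SD, mean absolute
  deviation and CV% = SD/mean·100, plus Pearson r against the BestKeeper
  index (per-sample geometric-mean Ct). Ranking uses the Ct SD; the index
  correlations are reported but not ranked on, since the descriptive SD is
  the only quantity defined for every input (correlations are undefined for
  constant genes, which are flagged).
* **Comparative ΔCt.** stability_j = mean over k ≠ j of
  SD over samples of (Ct_j − Ct_k). With all efficiencies equal to 2 this
  is numerically identical to geNorm's M (both are mean pairwise ΔCt SDs on
  the log₂ scale), a property the test suite asserts.

Input scales follow each method's native definition: geNorm consumes RQ,
NormFinder log₂ RQ, BestKeeper and ΔCt raw Ct.

## Comprehensive ranking

Each method's stability values are ranked ascending with average ties
(geNorm's finalist convention passes through unchanged); the comprehensive
stability of a gene is the geometric mean of its four ranks, and the final
order sorts it ascending with ties broken by mean rank, then id. The value
is bounded by the extreme ranks and hits a bound only under unanimity.
Exports round half-up to 2 decimals, matching the print convention of
published ranking tables; tied (non-integer) ranks enter the geometric mean
unrounded.

## Amplicon coverage validation

For each primer pair the mappable reference is the pair of segments
(≤30-nt up-flank + primer + ≤30-nt down-flank) around the two primer sites
(reverse primer located as its reverse complement; each site must be unique
on the template). Inter-primer sequence is excluded — it would attract
reads from alternative transcripts not specific to the assay. Polymorphic
flanks are handled by additional template variants per primer pair.

Alignment demands an exact, full-length, within-segment match on either
strand, so an internal exact substring matcher implements the contract
directly — with zero mismatches and full-length alignment required, it is
behaviourally identical to running a general aligner in that mode, and
removes external-tool dependencies. A read is counted once per primer pair
at its first match in declared variant order; a flag restores plain
per-variant counting.

A fully interior position of a segment can be covered by read_length
overlapping reads, but positions within read_length−1 of a segment end
cannot; for 50-nt reads on an 80-nt segment the primer bases (positions
30–49) form the full-depth plateau and the flank depth ramps 1…30,
averaging exactly half the plateau. Flank bases therefore count 0.5 in the
edge-adjusted length: adjusted = Σ primer + 0.5·Σ flank = 100 nt for the
standard 160-nt reference. The normalized value is

    rpkm_eq = (total_depth / read_length) · 1e9 / (adjusted_length · total_reads)

i.e. aligned reads per kilobase of effective length per million total
reads: summed per-base depth divided by read length is the aligned-read
count, so this is an RPKM on the edge-adjusted length (interpreting the
coverage as a per-base average over the 160-nt reference instead would
divide by length twice). Variant values of one primer pair are summed,
each normalized by its own adjusted length. Candidates are ranked by
CV = SD/mean of rpkm_eq across samples (fractions, not percentages, with a
flag marking rows whose mean is zero); mfc is reported as max/min but is a
descriptive extra only — published values of it are not internally
consistent enough to pin the definition.

## Relative expression

Per sample, target/reference ratio = (1+E_t)^(−Ct_t) divided by the
geometric mean over references of (1+E_r)^(−Ct_r), computed in log2 space
for numerical hygiene. Ratios are rescaled so the calibrator group — by
default leaf samples, an arbitrary but fixed choice since published
figures leave the y-axis scaling unstated — has grand mean exactly 1.
Mean ± SE are reported per (organ, gender, priming) with SE across
biological replicates (plants), not technical replicates. Samples missing
the target or any reference are excluded with a warning.

## Synthetic data

The Ct generator draws
Ct = baseline + organ effect + gender effect + priming shift + biological
noise + technical noise, with biological noise normal on the Ct scale
(multiplicative on expression — the conventional qPCR error model) per
(gene, plant, organ) and shared between the two primings of the same RNA,
and technical noise per replicate. Defaults mirror the emulated study
design: the pollen group has 4 hermaphrodite plants × 4 organs, the
pollen-free group 3 F + 3 H plants × 3 organs; both primings with a
+4-cycle shift under random priming ("several cycles": random hexamers
dilute mRNA-derived cDNA with rRNA-derived material); 4 technical
replicates at 0.15-cycle noise; panel efficiencies 0.96–1.0; an
rRNA assay measurable only in random-primed cDNA. Designed-stable genes
get small organ effects (≤0.3 cycles) and 0.10–0.15-cycle biological
noise; variable genes get up to 2.5-cycle pollen effects and
0.35–1.6-cycle noise, chosen once as a realistic spread between
housekeeping candidates and poorly behaved ones.

The recovery benchmark (`recovery_config`) isolates noise as the only
stability driver: nine genes, one at 0.1-cycle noise and eight from 0.5 to
2.0, on the pollen-free sampling frame (18 biological samples). Under
these conditions the designed-stable gene tops the comprehensive ranking
in ≈97% of draws; the margin against the 0.5-cycle competitor is
intrinsically modest because large-noise partners dominate both genes'
pairwise statistics.

The read generator picks a transcript per read proportional to abundance
and a start position uniform along it, giving closed-form expectations for
aligned-read counts (eligible starts / total starts) used by the recovery
tests. Reads are written as FASTQ with uniform quality.

What the generators do **not** emulate: plate effects, inter-run
calibration, replicate outliers, primer-dimer artifacts, degraded-RNA
bias, sequencing errors, non-uniform (fragmentation- or GC-biased)
read coverage, and polymorphism between plants. Passing tests therefore
demonstrate correctness of the statistics and pipelines under clean
study-shaped data, not robustness to these artifacts.

## Numerical choices and degenerate inputs

* SD denominator n−1 everywhere; geometric means via log-space averages.
* Rank ties: average ranks; residual ordering ties broken
  lexicographically by primer-pair id, so outputs are deterministic.
* geNorm requires ≥2 complete samples per gene pair and strictly positive
  RQ; NormFinder requires a complete matrix (no imputation is attempted).
* BestKeeper flags constant genes (correlation undefined) but still ranks
  by SD; zero-mean Ct raises rather than emitting an infinite CV.
* Export rounding is half-up at 2 decimals and applied only at export;
  internal tables keep full precision.
* All simulation randomness flows from a single `numpy` Generator seeded
  explicitly; identical seeds give byte-identical outputs.

## Problem sizes in the test suite

Statistical assertions use 100-seed repetitions of the 9-gene recovery
design, 1000-sample priming-shift checks, 50 random instances for oracle
equivalence, and 20–30k-read coverage simulations — sizes at which the
asserted effects are comfortably resolved while the whole suite runs in
well under a minute.
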