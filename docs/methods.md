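# Methods

## The measurement model

Input amounts are normalized mass-spectral signal per mg leaf dry weight
(a value of 1 ≙ the intensity of 1 nmol of internal standard), one value
per sample and analyte, with explicit zeros for below-detection cells
(missing cells are rejected on read). Species names follow shorthand
nomenclature; the parser accepts sum compositions (`PC 34:2`), resolved
chains (`TG 18:3_18:3_18:2`, underscore order preserved, no sn-position
claim), oxidized chains (`;O`/`;On` binding to the chain they follow),
and sterol conjugates (`sitosterol 18:2` = SE, `Sitosterol-Glc` = SG,
`Sitosterol-Glc 16:0` = ASG, sterol names matched case-insensitively).
The headgroup taxonomy (22 classes: acyl positions, compartment,
membrane-diacyl status) ships as a TSV and is user-overridable; GSL has
an unknown chain count and is excluded from chain-based statistics.

Whether an unresolved diacyl species "contains" a chain is answerable
only through an explicit user-supplied lookup (e.g. 36:6 → di-18:3);
nothing is inferred silently. The one exception is deductive: inside the
synthetic generator a 36:6 diacyl species is treated as di-18:3 because
two 18-carbon chains cannot carry more than three double bonds each.

## Quality control

An analyte is removed when its mean amount over experimental samples is
strictly below the limit of detection (default 5·10⁻⁵; `lod_mode`
switches the statistic to any-/all-sample) or when its QC-pool
coefficient of variation (sample SD with the n−1 denominator divided by
the mean; +∞ when the mean is zero) is strictly above 0.3. Boundary
values are retained. The removal report carries one row per removed
analyte; LOD takes precedence when both rules fire.

## The factorial model and LS-means

All treatment comparisons fit, by ordinary least squares,

    y = μ + genotype + treatment + genotype:treatment + block (+ run) + ε

with every term fixed. Replication entered the original analyses as a
random effect; fitting block as fixed leaves the LS-means identical on
the balanced design and can shift the error stratum slightly — the model
matrix is exposed (`FactorialFit.X`) for audit. Runs are pooled by
default (`include_run=True` adds the run main effect). Treatment and
genotype×treatment LS-means are predictions averaged over the remaining
factor levels, so they stay meaningful under mild imbalance. Fisher's
LSD is t(1−α/2, df_error)·SE(difference) at α = 0.05, with no
multiple-testing correction (per-comparison inference is the convention
this reproduces); percent change is reported on the LS-mean scale,
100·(HT−OT)/OT, and requires a positive OT reference.

## Remodeling statistics

* Species unsaturation index: total double-bond equivalents divided by
  the headgroup's acyl-position count (oxidized-chain extra oxygens are
  ignored; their DBEs count).
* Class unsaturation index: amount-weighted mean of member species
  indices; weights default to mean amounts over the chosen samples, or
  treatment LS-means in `unsaturation_by_treatment`. A zero-total class
  is an error, not 0.
* Class totals/shares are sums of per-analyte treatment LS-means;
  shares sum to 1 within a treatment. Species-level shares
  (`structural_species_shares`) default to the diacyl membrane classes
  plus DG as the denominator population.
* The acyl fold-change matrix uses only acyl-resolved species. Per
  sample, each (class, chain) cell accumulates amount × occurrence
  count (oxidized chains are separate columns, never merged); the cell's
  fold change is the ratio of HT to OT LS-means of that sum, and its
  significance flag comes from the LSD test on the per-sample sums
  (testing the underlying sums, not the ratio, is the resolution chosen
  for an ambiguity in the source analysis). A cell whose OT sum is zero
  — or below 10⁻⁹ of the column's data scale, the floating-point floor
  of the OLS solve — is undefined (NaN with a recorded reason), not 0.

## Multivariate structure

PCA centers columns (unit-scales on request; a constant column with
scaling on is an error naming the analyte) and uses the SVD, components
ordered by variance explained with the largest-magnitude loading of each
component made positive, so signs are reproducible.

Co-occurrence is pairwise Spearman ρ (average-rank ties) across
genotype×treatment LS-means — 108 observations per analyte in the
default design, so both treatments inform the correlation; a
raw-replicate option exists. Constant analytes yield NaN ρ, are flagged,
and are dropped (greedily, most-NaN first) before clustering. Lipid
clustering is complete linkage on Euclidean distances between rows of
the ρ matrix — the standard correlation-heatmap construction, chosen
over a literal "match each analyte to its best correlate" reading — cut
into k=6 clusters. Cluster labels are ordered by size (descending, ties
by lexicographically smallest member), so they are invariant to input
row order. Dendrograms export to newick via scikit-bio.

Genotype classification: z-score per analyte of the HT genotype
LS-means of the DGDG/MGDG/PG/TG/SE panel (the source display does not
state scaling; without z-scores high-abundance classes dominate), Ward
linkage (the incremental sum-of-squares criterion on Euclidean
distances, "Ward.D2"), cut at k=6. The tolerant label goes to the
cluster containing the tolerant anchor genotype when anchors are given,
else to the cluster maximizing the remodeling score
mean z(18:3-containing TG and SE) − mean z(18:3-containing
DGDG/MGDG/PG); the susceptible rule is symmetric. k=1 yields no labels.

## Marker distribution

Expected counts assume uniform density: per chromosome, subgenome
density × chromosome Mb; per bin, chromosome density × bin width, with
the final truncated bin scaled by its actual width. Positions are
1-based (VCF convention); bins index (pos−1)/10⁶ into half-open
[start, start+bin) intervals. The deviation test is a two-sided exact
binomial test of the observed count against p = expected/total — an
interpretation, documented as such, since the original arithmetic names
no significance procedure. Expectations sum exactly to the subgenome
(resp. chromosome) totals.

## The synthetic world

`generate_lipidome` draws

    amount = base · exp(e_g) · M^(1[HT]·g_i) · exp(run + block) · noise

* 54 genotypes × {OT, HT} × 2 runs × 3 blocks + 8 QC-pool samples.
* 192-species roster built from the classes and chains reported for
  heat-stressed peanut leaves (including the 25 oxidized species forms:
  DGDG 12, MGDG 5, SQDG 1, PC 4, PE 3; 2 SE + 3 SG + 9 ASG sterol
  species). The exact published roster is only partially enumerable, so
  this one is representative, not identical.
* base = total signal (10/mg) × class share (MGDG 0.49, DGDG 0.29,
  PC 0.075, PE 0.04, PG 0.035, PI 0.02, the rest spread over the minor
  classes, summing to 1) × within-class weight (a 0.6-weight leading
  di-18:3 species in MGDG/DGDG plus a harmonic tail — the harmonic decay
  keeps every roster species above the detection limit, so the planted
  LOD violations are the only ones).
* HT multipliers M per analyte: U(0.53, 0.75) for 18:3-containing
  membrane-diacyl species, U(1.9, 2.2) for 18:3-containing TGs,
  U(2.5, 5.4) SE, U(1.05, 1.4) SG, U(0.4, 0.8) oxidized species,
  U(0.4, 0.9) ASG, U(0.9, 1.1) otherwise — the reported effect ranges.
* Genotype tolerance g_i scales every multiplier as M^g: g=1 full
  remodeling, g=0 none. Five planted strong remodelers (g=1) and five
  weak (g=0) sit against a U(0.3, 0.7) background; the gaps are what
  make "programmed tolerant/susceptible" recoverable categories for the
  classification test. Ground truth stores, besides M and g, the exact
  population-level expected fold Σ_g e^{e_g}·M^{g_i} / Σ_g e^{e_g} —
  the right comparator for fold-change recovery, since tolerance
  scaling means the population never expresses the raw M.
* Noise is multiplicative lognormal (all reported effects are folds or
  percents): residual sd 0.15 (log scale), run and block effects sd
  0.05, genotype global-abundance effect sd 0.02 (small because
  internal-standard and dry-weight normalization cancel most
  genotype-level global variation; a larger value buries the tolerance
  signal under a nuisance common mode). Log-normal draws are
  mean-corrected (μ = ln E − σ²/2), so expectations match the stated
  world exactly.
* QC pools draw around the grand-mean composition at CV 0.1. Planted
  violations hold by construction in the realized table: the three CV
  violators' QC vectors are rescaled to an exact sample CV of 0.5, and
  the two LOD violators' base abundance is LOD/10 — so "the filter
  removes exactly the planted analytes" is deterministic, not merely
  likely.

`generate_markers` allocates n markers multinomially ∝ chromosome size ×
enrichment factor, uniform positions within chromosomes.

### What a green test does and does not establish

The generator reproduces the design, composition, effect directions and
magnitudes, and noise scale of real leaf-lipidome data, but not:
correlated per-genotype lipid profiles beyond the single tolerance axis,
run×analyte batch structure, censoring at the detection limit,
heteroscedasticity across abundance, or real linkage between genotypes
and markers (`generate_markers` is independent of the lipidome). Green
recovery tests establish that the estimators are consistent with the
stated world at its noise level — not that real data meet the model.

## Known limitations

* No mixed-model (REML) error stratum; the LSD can differ slightly from
  a replication-as-random fit on unbalanced data.
* Fold-change uncertainty is a significance flag, not an interval.
* The tolerance score needs 18:3-resolved species on both panel sides.
* Reproducing the originally published values needs the study's
  supplementary species table as input; it is not redistributable here,
  so the acceptance layer exercises the synthetic world only.
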