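# Methods

This note documents the models and estimators implemented in `refstab`,
the parameter choices that matter, what the synthetic data emulate, and
known limitations.

## Quantification model

A qPCR assay amplifies template by a factor E per cycle (the
*amplification factor*; E = 2 is perfect doubling, reported as 100%
efficiency). The efficiency-corrected comparative Ct method expresses
each sample's relative quantity of gene g as

    Q_sg = E_g^(Ctmin_g − Ct_sg)

calibrated to the gene's minimum Ct over samples, so Q ∈ (0, 1] with the
most concentrated sample at exactly 1. The calibrator is a per-gene
constant: any other common calibrator rescales each gene's Q column by a
constant, which cancels in every downstream ratio (geNorm M and V,
NormFinder's centred statistics, normalized fold changes) — asserted by
test.

E is estimated per assay by ordinary least squares of Ct on
log10(relative concentration) over a dilution series (≥ 3 distinct
concentrations; the standard design is ten-fold steps over five orders of
magnitude, each point in triplicate):

    E = 10^(−1/slope),  percent efficiency = (E − 1) × 100

A slope of −3.32 cycles/decade gives 100%. Assays are accepted when the
percent efficiency lies in [90, 110]; the interval is closed at both ends,
consistent with 90.3 and 107.6 counting as acceptable while 89.8 does
not in the packaged screening table.

## Triplicate quality control

Wells are run in technical triplicate and analysed as the replicate mean,
subject to the deviation rule with tolerance 0.5 cycles:

* all pairwise gaps ≤ 0.5 → accept the mean of all replicates;
* exactly one replicate > 0.5 cycles from *both* others while those two
  agree → drop it, accept the mean of the concordant pair;
* otherwise → the well set fails and must be re-measured.

A failed well becomes a missing value. Cts at or beyond the cycle limit
(40 by default) and the `ND` file sentinel mark non-detection. A gene is
excluded from analysis when its fraction of undetected samples exceeds
`detection_exclusion_fraction` (default 0, i.e. any undetected sample
excludes the gene — the conservative behaviour appropriate for a gene
near the assay's detection limit, and deliberately strict for missing
wells of well-expressed genes, where the remedy is re-running the well).

## geNorm

For genes j, k the pairwise variation V_jk is the sample standard
deviation (n − 1 denominator) of log2(Q_j/Q_k); the stability
M_j = mean_k≠j V_jk. The gene with the highest M is removed and M
recomputed until two genes remain; these cannot be separated and share
rank 1 (subsequent genes rank 3, 4, ...). Ties at the maximum M are
broken by excluding the gene later in input order (deterministic,
logged). Missing values are handled pairwise-complete.

The gene-count recommendation compares normalization factors
NF_n (per-sample geometric mean of the n most stable genes' Q):
V_n/n+1 = SD_s log2(NF_n,s/NF_n+1,s). The smallest n (from 2) with
V_n/n+1 < 0.15 is recommended; if none qualifies, all genes are
recommended with a warning. The 0.15 cutoff is the conventional guideline
and is configurable.

geNorm's known blind spot applies: co-regulated genes reward each other
with low M. The algorithm sees only ratios, so it cannot detect a shift
common to the whole panel.

## NormFinder-style model

Each sample's log2-quantity vector is centred by its across-gene mean,
removing the common RNA-input effect. Per gene i and group g the centred
values give a mean d_ig and sample variance s²_ig. The estimator then
separates:

* **intergroup component** z_ig = d_ig − mean_g'(d_ig'), shrunk toward 0
  by τ²_g/(τ²_g + s²_ig/n_g), where τ²_g is the across-gene variance of
  the raw components less the mean sampling variance (clamped at 0) — an
  empirical-Bayes guard against rewarding noisy estimates of "no shift";
* **intragroup variance** v_ig = s²_ig minus the variance injected by the
  shared centring (the across-gene mean variance divided by the gene
  count), clamped at 0.

Stability of gene i = mean over groups of |z̃_ig| + sqrt(v_ig/n_g); lower
is better. With one group the intergroup term vanishes and the ranking
reduces to the corrected intragroup variance. Group sizes may be unequal.

The recommended pair minimizes the stability of the two genes' *average*
signal: intergroup components are averaged and intragroup variances
combined as (v_i + v_j)/4 — the variance of a mean of two independent
genes — then recombined as above. Opposite-sign group shifts cancel in
the average, so the best pair need not contain the two individually best
genes. In single-group mode the pair falls back to the two lowest
individual values.

The original NormFinder publication leaves several estimator constants
open and published reimplementations differ in detail; this implementation
follows the decomposition above and is validated by parameter-recovery
properties (a simulated group-shifted gene ranks worst; a cancelling pair
is found; exhaustive pair search matches an independent oracle), not by
decimal agreement with any specific spreadsheet tool. Only shifts
*relative to the panel average* are identifiable: if most of the panel
moves with the condition, the centring attributes the movement to the
stable genes.

## BestKeeper

Descriptors are computed on raw Cts over complete samples: per-gene
sample SD and CV (100·SD/mean), and the Pearson correlation r of the
gene's Cts with the BestKeeper index (per-sample geometric mean of all
candidates' Cts). Genes with SD > 1.5 cycles carry a warning flag but are
never removed — in heterogeneous material (e.g. microbiopsies with
variable RNA yield) the entire panel can exceed the guideline.

The consensus ranks genes per measure (SD and CV ascending, r by
*descending signed value* — a reference gene should co-vary positively
with the index, so negative r ranks last; this choice is logged and the
magnitude alternative is noted), averages the three ranks (mid-ranks on
ties) and ranks the means. A tie on mean rank prefers the gene whose
three per-measure ranks have the smallest spread (max − min): a gene
equally stable in all three measures beats one excellent in some and poor
in others. Remaining ties fall back to input order. A zero-variance gene
has undefined r and is excluded from the consensus (reported, never
coerced to r = 0).

Note the three measures are not independent — SD and CV nearly share
ordering when mean Cts are similar, and r is computed against an index
that contains the gene itself. The mean-of-ranks consensus is a
pragmatic aggregation, not a probabilistic model.

## Normalization and group testing

A target's normalized expression is Q_target/NF with NF the geometric
mean of the reference pair's quantities. Groups are compared with the
two-sided Mann–Whitney U test: exact null distribution when both groups
have ≤ 10 samples and the pooled data are tie-free, mid-rank normal
approximation with tie correction otherwise; min(U_a, U_b) is reported.
The headline fold change is the ratio of group medians (consistent with
the rank-based test); the mean-based ratio is always reported alongside,
since either convention is defensible. Significance labels use 0.05 (\*)
and 0.01 (\*\*). No multiple-testing correction is applied across targets
by default (a Bonferroni option exists), matching common practice for
small confirmatory panels.

## Synthetic data

The generator draws raw triplicate tables from

    Ct_sgr = baseline_g − effect_{g,group(s)}/log2(E_g)
             + shift_s + noise_sg + rep_noise_sgr

with group effects specified in log2 expression units and converted to
cycles through each gene's own amplification factor, so downstream
efficiency handling is genuinely exercised. Per-well outliers displace
one replicate by a uniform 0.6–3.0 cycles, always enough to trip the
0.5-cycle QC rule.

The song preset encodes the singing-vs-silent Area X design: 5 + 7
samples; nine reference candidates whose amplification factors are the
zebra finch screening efficiencies (1.935–2.036); EGR1 and CFOS with a
+3 log2 (8-fold) effect in the singing group and FOXP2 with none.
Parameter choices, with rationale:

* `sample_scaling_sd` = 1.5 cycles — microbiopsy RNA yield varies
  strongly between animals; this shared per-sample shift dominates raw-Ct
  variance and reproduces the observed regime in which the whole panel
  exceeds BestKeeper's SD > 1.5 guideline while normalized comparisons
  stay tight (normalization removes the shift entirely).
* per-gene biological noise 0.12 cycles and triplicate noise 0.10
  cycles — typical technical scatter for a well-running SYBR assay; these
  set the residual spread of normalized values (≈ 0.16 log2 units per
  sample), under which the median-based fold change recovers an 8-fold
  effect above the 7-fold mark in ≈ 95% of replicates.
* `outlier_rate` = 0.02 per well — occasional pipetting/evaporation
  artefacts, exercising the replicate-deviation rule at a realistic rate.

What the simulation does **not** model: inter-run/plate batch effects,
amplification-curve shape (a single E per assay is assumed across the
dynamic range), gene–gene expression correlation beyond the shared input
shift, RNA-quality covariates, and truncation of Cts at the cycle limit
for moderately expressed genes. Passing recovery tests therefore shows
the estimators behave correctly under the stated generative model, not
that any particular biological panel is stable.

## Numerical choices and degenerate inputs

Sample SDs use the n − 1 denominator throughout. Variance estimates that
go negative after correction clamp to 0 (logged). Negative-slope
enforcement rejects dilution series with no amplification trend; fewer
than three distinct concentrations is an error. Exact tie-break orders
(input order after all stated criteria) make every ranking deterministic;
reruns of the pipeline with the same configuration are byte-identical.
All simulation randomness flows from a single integer seed through
numpy's Generator.

## Problem sizes

The validation suite runs the full pipeline on 100 seeded replicates of
the 12-sample × 12-gene song design (plus 100 null replicates), checks
estimator implementations against brute-force oracles on 200 random
tables of up to 5 genes × 8 samples, and verifies exact rank-sum
p-values against full enumeration for all group sizes up to 8 — sizes at
which exhaustive enumeration is itself cheap and trustworthy.
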