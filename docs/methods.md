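# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## Statistical engine (`statcore`)

**Permutation t-test.** The differential-abundance test permutes sample
labels and compares two-sided |t| values: p is the proportion of
permutations (including the identity arrangement) whose |t| meets or
exceeds the observed one. Including the identity guarantees p > 0 and is
standard practice for sampled permutation tests. The statistic is
Welch's t by default because group variances in load data differ by
construction (copy numbers span orders of magnitude); `equal_var=True`
switches to the pooled statistic. Default 10,000 permutations, seedable;
exhaustive enumeration over all C(n1+n2, n1) assignments is available
and practical up to roughly 12 per group. Degenerate constant input
returns p = 1 with a warning rather than failing.

**PERMANOVA.** One-factor, Anderson-style: SS_total = (1/N) Σ_{i<j}
d²_ij, SS_within the analogous per-group sums, pseudo-F =
(SS_b/(a−1))/(SS_w/(N−a)); the p-value permutes group labels with the
identity counted. Default 999 permutations (lighter than the
differential-abundance test because each evaluation touches the whole
matrix). R² = SS_b/SS_total. A zero SS_within (perfect separation)
reports pseudo-F = +inf with a permutation p. The implementation is
cross-checked in the tests against scikit-bio's `permanova` on random
matrices; scikit-bio is never used as the implementation.

**Classical tests.** Welch t (Satterthwaite df), Mann–Whitney U
(tie-corrected, two-sided), one-way ANOVA with Tukey HSD (Tukey–Kramer
for unbalanced layouts) and Holm–Bonferroni correction all delegate to
scipy/statsmodels behind the module's surface. Identical samples are
short-circuited to p = 1 for the rank test, where scipy's normal
approximation would otherwise return a tie-degenerate value.

## qPCR (`qpcr`)

Relative load is ΔCq = 2^(Cq_host − Cq_target) against the host 28S
reference; absolute copies are n = E^(intercept − Cq) with intercept
38.23 by default and per-primer efficiencies carried in config
(total-16S 1.86, *Pseudomonas* 2.00, host 28S 1.87). Efficiency is
estimated from a serial dilution by OLS of Cq on log10 concentration,
E = 10^(−1/slope); a nonnegative slope is an error. Fold changes between
design cells are ratios of geometric means of ΔCq (equivalently
differences of mean log2 ΔCq) — the geometric mean is the natural
location parameter for a quantity defined on a log (cycle) scale.
Technical replicates are averaged per target before the ratio. A target
reaction that never amplified is censored at the 45-cycle ceiling
(configurable) instead of being treated as zero load.

## Microbiome (`microbiome`)

The prevalence rule keeps ASVs with ≥1% within-sample relative
abundance (inclusive) in ≥5 samples, counted over all samples; both
thresholds are arguments. The module assumes a clean ASV table
(denoising, classification, and contaminant removal happen upstream).
Absolute abundance multiplies each sample's ASV proportions by its total
16S copy number, so columns sum to the measured totals exactly; genus
aggregation sums member ASVs and conserves mass. Differential abundance
runs the permutation t-test per genus within each timepoint, with Holm
applied across the genera of that timepoint (each timepoint is its own
testing family, mirroring per-timepoint reporting). PERMANOVA and PCoA
operate on Bray–Curtis dissimilarities of the absolute table.

Note on compositional coupling: because absolute abundances are
proportions × totals, a bloom of one genus mechanically depresses the
absolute abundance of others unless the measured total rises to match.
The synthetic generator therefore lets the configured total-copy shifts
(10×/100× for infected samples at 2 h/11 h, matching the load ratios the
pipeline recovers from the qPCR stage) be set independently of the
genus-level perturbations; under that default, non-pathogen genera also
shift in absolute terms, which is the expected behavior of the
transformation, not an artifact. The test of the "single perturbed
genus" property is run on a genus copy-number table constructed
directly, where the notion is well defined.

## Survival (`survival`)

Kaplan–Meier product-limit estimation with right censoring; survivors
are administratively censored at 36 h; hourly checks are treated as
exact right-continuous event times at the observation hour (the
conventional KM plotting treatment of interval-censored checks).
Mortality at the horizon is 100·(1 − S(36)).

Pairwise group contrasts fit, per pair, a Cox proportional-hazards model
with a single group indicator, Breslow tie handling, and a separate
baseline hazard per colony (stratification). This replaces a
colony-random-effect (frailty) Cox model: at these design sizes the
fixed-effect contrast is essentially identical while avoiding iterative
variance-component estimation; the degrees-of-freedom bookkeeping of a
mixed-model least-squares-means analysis is not reproduced, so contrasts
are reported as Wald z with Holm correction. A pair in which one group
has no events is reported with an `infinite_coefficient` flag (the
partial-likelihood estimate diverges) rather than failing.

## Behavior (`behavior`)

Events occupy [start, start + duration) and mark every 10-min bin they
overlap; 24 h gives 144 bins per ant and event type. The care-probability
smoother is a penalized cubic B-spline logistic regression: 20 basis
functions over [0, 24] h, second-difference coefficient penalty,
penalized IRLS, λ selected by GCV (n·dev/(n − edf)²) over a log-spaced
grid with a fixed-λ override, and a pointwise 95% band from the
Bayesian-style posterior covariance (A⁻¹ with A = BᵀWB + λP) mapped
through the inverse logit. This simplifies the study's hierarchical
binomial GAM: ants are pooled as replicate Bernoulli bins per group, so
between-ant variance is not partitioned — adequate for interval
detection on synthetic data, and a documented divergence. As λ → ∞ the
fit shrinks onto the penalty's null space (an affine logit), and as
λ → 0 it approaches the unpenalized spline fit. All-zero or all-one
responses fall back to a constant fit with a warning (complete
separation guard). Group differences are screened bin-wise by a Wald
test on the link-scale difference (two-sided or directional) and
contiguous rejected bins are merged into intervals; no multiplicity
correction is applied across bins, matching the pointwise-band
convention of GAM difference plots.

The MG-care fraction is reported as a percent rounded half-up to one
decimal (43/411 = 10.4623…% → 10.5%), with MG-care events counted as a
subset of all care interactions. Care durations are compared by Welch's
t on per-event durations, treating events as independent (the study's
individual-level random effect is not modeled).

## Growth (`growth`)

The logistic model N(t) = K/(1 + ((K − N0)/N0)e^(−rt)) is fit per well
by bounded nonlinear least squares with multi-start: N0 initialized from
the first reading, K from the maximum, r from the early-phase log-slope,
plus jittered restarts (deterministic given the seed); the best
converged solution wins and non-convergence raises an error carrying the
best-so-far parameters. Before fitting, the mean blank trajectory is
subtracted from every well (clipped at zero). Group comparison uses the
Mann–Whitney U test on per-well r, and inhibition is
100·(r_control − r_treat)/r_control on the median rates. The generator's
OD window for the inoculum (0.2–0.5) treats the source description's
"02–0.5" as a typo for 0.2.

## Secretome (`secretome`)

Detection is a nonmissing, nonzero iBAQ value. The cascade: (1) drop
proteins not detected in any atrium replicate (detection in ≥1 replicate
passes, with the detection count carried on the hit); (2) proteins never
detected in hemolymph are hits (`atrium_only`) regardless of abundance;
(3) remaining proteins are hits (`enriched`) iff the ratio of replicate
means, atrium over hemolymph, is ≥1.5 (inclusive). Means are taken over
all replicates of a compartment with non-detected values contributing 0,
so a protein seen in one of six atrium samples is credited one-sixth of
its observed intensity — a conservative abundance estimate; a log-scale
variant (means of log2 over detected replicates) is available. Percent
of total iBAQ is column-normalized over detected proteins per sample.
The headline hit counts of any particular dataset are data-dependent and
not a fixed property of the filter.

## CHC (`chc`)

Profiles arrive as integrated relative peak areas summing to 1 per
sample (validated to 1e-6); peak calling and compound identification are
out of scope. Class fractions sum member compounds; whole-profile
divergence uses PERMANOVA on Bray–Curtis dissimilarities of the
compound matrix; per-class contrasts use ANOVA + Tukey. When a family of
pairwise PERMANOVAs is run across timepoints, Holm correction across the
family is the recommended (and tested) usage.

## Synthetic generators (`synthgen`)

All generators are fully determined by their seed and return tidy
DataFrames matching the TSV schemas. Defaults encode the study's designs
and printed effect sizes:

- qPCR: 10 samples per treatment × timepoint cell; host Cq ~
  N(18, 0.5²); target Cq = host Cq − log2(relative load) + N(0, 0.3²)
  cycles of technical noise; relative loads 10× (2 h) and 100× (11 h)
  above the sterile baseline (0.01).
- Survival: exponential event times with per-group hazards
  λ = −ln(1 − m)/36 from 36-h mortality targets m = 93% (infected,
  isolation), 8% (infected, nest), 33% (infected, MG accessible), 22%
  (soil, nest), 90% (soil, isolation); event times rounded up to the
  observation hour; administrative censoring at 36 h. The sterile-group
  baseline mortality is not published; the default 0.20 is an assumption
  and a config key.
- Behavior: 6 ants per group; per-bin care probability 0.05 baseline,
  elevated to 0.30 for infected ants in the arrival (0–1 h) and
  infection-peak (10–12 h) windows — window probabilities are not
  published and were chosen as plausible magnitudes consistent with the
  reported care time-courses; each event is MG care with probability
  43/411; durations are lognormal, moment-matched to 85 ± 53 s (MG) and
  53 ± 36 s (plain), or parameterized directly on the log scale.
- Microbiome: 18 ASVs in 11 genera, 40 samples, multinomial counts at
  depth 20,000 over lognormal genus abundances (log-sd 0.5); pathogen
  genera (*Pseudomonas*, *Klebsiella*, *Burkholderia*) multiplied in
  infected samples; total 16S copies 5×10⁴ baseline with 10×/100×
  infected shifts and log-sd 0.3.
- Growth: logistic wells (K = 1, N0 = 0.05, r = 0.6/h control) with a
  30% treated rate reduction, 6 control / 9 treated / 3 blank wells,
  10-min cadence over 8 h, Gaussian OD noise sd 0.005, between-well
  rate log-sd 0.05.
- Proteome: 6 replicate samples per compartment; planted atrium-only,
  3-fold-enriched, flat, and hemolymph-only protein sets around a 10⁶
  iBAQ base with log-sd 0.4 (the planted truth is attached in
  `DataFrame.attrs`).
- CHC: class shares 45/30/15/10% (alkane/methyl-branched/alkene/
  alkadiene), 8 compounds per class, lognormal compound noise
  (log-sd 0.25) renormalized per sample; infected ants at 11 h multiply
  the alkadiene share by 1.8 before renormalization; 12 samples per
  cell.

What the generators do **not** emulate: overdispersion beyond lognormal
× multinomial in counts, batch/plate effects, non-constant hazards
(survival shapes are exponential, not digitized from observed curves),
within-ant behavioral autocorrelation, missing-at-random structure in
proteomics, or chromatographic artifacts. Passing tests therefore
demonstrate correctness of the statistical machinery under these clean
models, not robustness to every pathology of real field data.

## Problem sizes and tolerances

Simulation-based checks use desk-scale sizes chosen to keep Monte-Carlo
error well below the tested tolerances: survival parameter recovery uses
cohorts of 1,500 (binomial SE ≤ 1.2 points for the mortalities tested,
against a ±2-point band), duration recovery uses 10,000 draws (SE ≈
0.5 s against a ±3% band), type-I calibration uses 2,500 replicate
datasets (SE ≈ 0.44 points against a ±2-point band), and power-style
checks run 5–10 replicate datasets at the study's published group sizes.
Exhaustive permutation oracles are limited to ≤6 samples per group.

## Known limitations

- No frailty/random-effect variance estimation anywhere; colony enters
  only through stratification, individual only through pooling.
- The behavioral smoother's bands are pointwise; interval detection
  inherits pointwise (not simultaneous) coverage.
- PERMANOVA is one-factor; crossed or nested designs must be encoded as
  a single grouping factor.
- The qPCR stage assumes one host reference gene and a shared intercept
  across plates; multi-plate calibration is out of scope.
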