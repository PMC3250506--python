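# Methods

## The blend model and its estimation

The central quantity is the per-gene heterotypic interaction factor. Writing
`e_A`, `e_B`, `e_co` for the linear-scale expression ratios of the two
monocultures and their mixed co-culture (each the ratio of the sample to a
common reference RNA), the model is

    e_co[n] = (a · e_A[n] + (1 − a) · e_B[n]) · I[n],   I[n] > 0,  a ∈ (0, 1).

The blend term captures the passive, additive contribution of each cell
type's mRNA to the pooled lysate; `I[n]` is the multiplicative deviation
caused by the interaction. The model is unidentified per gene (one equation,
two unknowns shared unevenly), so identification comes from a population
assumption: *the average gene is not affected by the interaction*
(`I = 1`). Operationally, `a` is fitted by a regression of `e_co` on the two
monoculture profiles **without any per-gene terms**, and the equations are
then solved for `I[n] = e_co[n] / (a·e_A[n] + (1−a)·e_B[n])`.

### Why Gamma errors with identity link

Linear-scale expression ratios are strictly positive and right-skewed, with
noise approximately proportional to the signal (a roughly constant
coefficient of variation). A Gamma error family captures exactly this
mean–variance relation (Var ∝ μ²), while the identity link preserves the
additive blend structure — a log link would turn the blend into a product
and misstate the model. Fitting must therefore happen on the linear scale;
log2 is applied only afterwards, for display, clustering and scoring.

### Numerical strategy

The fit is a one-parameter problem, so rather than iteratively reweighted
least squares (which with an identity-link Gamma can step outside the
positive-mean region), `InteractionModel.fit()` minimizes the Gamma deviance

    D(a) = 2 Σ_n [ (y_n − μ_n(a)) / μ_n(a) − log(y_n / μ_n(a)) ]

directly by bounded Brent search on `a ∈ [0.001, 0.999]` (`xatol = 1e-10`).
For fixed dispersion this is exactly the Gamma maximum-likelihood estimate.
μ is a convex combination of positive vectors, hence positive on the whole
interval, so the objective is smooth everywhere the optimizer can go.
Estimates at the interval boundary trigger a warning (a mixture that is
essentially one pure monoculture is biologically implausible). The standard
error comes from the observed information of the identity-link Gamma
likelihood, `Var(â) ≈ φ / Σ (e_A−e_B)²/μ²`, with the dispersion φ estimated
by the Pearson statistic. The test suite checks the optimizer against an
independent exhaustive grid search (step 0.001) and against statsmodels'
Gamma/identity GLM with the second monoculture as offset.

Preconditions: at least 10 genes after exclusions, and monoculture profiles
with |Pearson r| ≤ 0.999 — proportional predictors make `a` unidentifiable
and raise an explicit error.

### Replicate handling

Biological replicates are averaged **in log space** within each role before
transformation to linear scale (equivalently, a geometric mean of linear
ratios). This matches the convention for two-channel log-ratio data and
damps multiplicative noise symmetrically. Genes missing in any role are
excluded from the triplet and counted.

### Cross-co-culture profiles

`log2 I` values from several co-culture pairings are assembled into a
gene × co-culture matrix (missing where a gene was not fitted) and treated
like any expression matrix. Two screens follow the analysis being
reproduced: genes missing in more than 20% of the arrays are removed
(strict inequality, so exactly 20% survives), and genes are kept when their
`log2 I` lies at least 2 column standard deviations from the column mean in
at least 2 co-cultures (boundary inclusive). The source description of the
SD screen is ambiguous between "eliminate genes within 2 SD in ≥2
co-cultures" and "retain genes beyond 2 SD in ≥2 co-cultures"; these differ
for genes extreme in exactly one co-culture. Both are implemented
(`mode="eliminate_within"` / `"retain_extreme"`); the default is
`retain_extreme`, which keeps only genes with a *reproducible* interaction
response. Whether `a` should be fitted on the filtered or unfiltered gene
set is likewise unstated upstream; the default here fits on all genes
passing the missingness filter, since the I=1 assumption is a statement
about the unfiltered population.

## QC and filtering choices

* Background-signal filter: keep a spot iff unflagged and foreground ≥
  1.5 × background in **both** channels ("50% above background"),
  boundary inclusive. With zero background the foreground must be
  positive — a dark spot on a dark background carries no signal; this
  degenerate case is a package convention.
* Log ratios are defined only where both background-corrected intensities
  are strictly positive; anything else is missing, never clamped.
* The fold-variation filter works in log2 space: "3-fold deviation from
  the mean in 2 samples" → `|x − mean| ≥ log2 3` in ≥ 2 samples, mean over
  valid entries, genes with < 2 valid entries removed. Because deviations
  are taken about the per-gene mean, the filter is invariant to per-gene
  constants (tested).
* Missing values are carried as NaN and never imputed; every per-gene
  statistic uses valid entries only.

## Clustering and signatures

Similarity is the uncentered correlation `Σxy / √(Σx²·Σy²)` (the Eisen
convention — no mean subtraction, so magnitude relative to the reference
matters, not just shape), computed over pairwise-valid entries; a vector
that is all zeros on the shared support gets similarity 0 by definition.
Distance is `1 − similarity` with average linkage (scipy), which is
monotone, so merge heights never invert. Items with fewer than two valid
values are excluded with a warning. Cohorts are stratified by the two
subtrees of the root, the branch with the larger mean expression labeled
"high"; the score-sign split (below/above the zero reference) is available
as an alternative stratification and the choice is recorded in the run
manifest.

Induced-gene extraction uses a margin rule standing in for what may have
been a visual cluster selection upstream: a gene is "induced" when its
minimum across all co-culture replicates exceeds its maximum across all
monoculture replicates of both cell types by at least `delta` (default 0).
Signature scores are signed sums of log2 ratios (directions ±1 — the
upstream description of direction weighting is not formalized beyond sign);
missing entries contribute 0 rather than rescaling, so scores remain
comparable as sums, and the per-sample count of contributing genes is
returned for transparency. Centroids are per-patient means of mapped-gene
values; signature–signature association is the signed Pearson r (the
upstream figures label these values "r²" yet report negative numbers; this
package computes and names the signed correlation). Probe mapping collapses
to one probe per unique gene, first match wins, with the full multimap in
the report.

## Survival endpoints

DMFP treats the first distant metastasis or ipsilateral supraclavicular
recurrence as the event (the latter because it is, with rare exception,
followed immediately by distant disease); a preceding local recurrence,
axillary recurrence, contralateral cancer or second primary censors the
patient at that time, since such lesions could themselves seed later
metastases. OS is death from any cause. BMFS applies the DMFP censoring
rules with bone metastasis as the event (the upstream bone-metastasis times
come from an external source without a stated formula; restricting the DMFP
logic is this package's choice). Kaplan–Meier estimation and the two-group
Cox model are delegated to lifelines; ties use the Efron approximation (the
less biased default; upstream is silent). "Survival at t years" reads the
right-continuous step function, i.e. the post-drop value at an event time.
The log-rank test — reported alongside the Cox hazard ratio — is the score
test of the two-group Cox model. When one group has no events the partial
likelihood is monotone; the comparison is flagged `degenerate`, the hazard
ratio reported as 0/∞ by direction, and the log-rank result remains valid.

## Synthetic data: what it emulates, what it does not

`simulate_coculture` draws per-gene monoculture baselines log-normally
(log2 SD 1.5, matching the large intrinsic between-cell-type variation that
dwarfs interaction effects), builds the co-culture mean exactly by the
blend equation with planted `I`, and multiplies each replicate by
independent noise. Gamma noise with mean 1 and shape `1/cv²` is the default
so that the generator's error law matches the fitting model and
oracle-equivalence/recovery tests are well posed; a log-normal mode with
matched CV exercises misspecification. Defaults — 2000 genes, two
replicates, CV 10% — mirror the scale of a filtered two-channel experiment
with duplicate hybridizations.

`simulate_cohort` assigns patients 50/50 to high/low signature groups,
shifts signature genes by ±`group_shift`/2 along each gene's direction
(within-group SD 1, shift 2 — a clear but not trivial two-group structure),
and adds unstructured background genes. Event times are exponential with
hazard `baseline · exp(log_hr · z)` where `z` is the signature score
standardized so the two planted group means sit one unit apart (±0.5). This
standardization makes `log_hr_per_score_sd` equal to the true between-group
log hazard ratio — with naive unit-SD standardization the realized group
effect would scale with signature size and shift, making the nominal
parameter meaningless as a group contrast — while the hazard still varies
continuously with each patient's actual score. With `group_shift = 0` the
score collapses to noise and the generator falls back to unit-SD
standardization. Censoring is an independent exponential whose rate is
calibrated by root-finding so the expected censored fraction equals
`censor_rate` given the realized hazards. Defaults: 300 patients, baseline
hazard 0.05/year, HR 2, 30% censoring.

What the generators do **not** emulate: probe-level artifacts and spatial
effects, dye bias, the many-to-many gene/probe ambiguity of real array
annotation, correlated noise between replicates, non-proportional hazards,
and clinical covariates. Passing the recovery tests therefore shows the
estimators are correct *under the stated model*, not that the model
captures every failure mode of real arrays; conclusions about any specific
published cohort additionally require that cohort's data.

## Problem sizes and tolerances

The shipped test and acceptance runs use 2000-gene experiments (100
replicate simulations per mixing-proportion setting), 50 instances for
grid-search agreement (grid step 0.001, agreement required to the grid
resolution), 300-patient cohorts with 200 replicates for Cox recovery
(mean log HR within ±0.25 of log 2) and 500 label permutations for the
null-uniformity check (Kolmogorov–Smirnov at α = 0.01) — sizes chosen to
sit at desk scale while keeping Monte-Carlo error well inside each
tolerance. Round-trip matrix I/O is exact to 6 decimals (the TSV write
precision); mean-centering is checked to 1e-12.

## Known limitations

* `a` is a single global scalar per co-culture; gradients in mixing across
  the culture are absorbed into `I`.
* No per-gene uncertainty on `I` is reported (one observation per gene per
  co-culture; upstream reports none either).
* Two-cell-type mixtures only; no multi-way blends.
* The Cox comparison is univariate by design — no clinical covariates,
  no competing-risks machinery (censoring, not competing risks, matches
  the endpoint definitions).
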