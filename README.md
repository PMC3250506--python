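# hetint

**Heterotypic interaction effects on gene expression from co-culture
transcriptomics.**

When two cell types — say a breast cancer line and primary osteoblasts — are
mixed in co-culture, the expression profile of the mixture is, for most
genes, just the proportionally weighted blend of the two monoculture
profiles. The biologically interesting part is the deviation from that
blend: genes induced or repressed *because* the two cell types are talking
to each other. `hetint` is a library (plus a thin CLI) for isolating,
quantifying and clinically evaluating those deviations. It is aimed at
computational biologists working with two-channel (reference-design)
microarray or similar ratio-scale expression data.

## The model

For gene *n*, with linear-scale expression ratios `e_A`, `e_B` in the two
monocultures and `e_co` in the co-culture:

```
e_co[n] = (a · e_A[n] + (1 − a) · e_B[n]) · I[n]
```

* `a ∈ (0, 1)` — the mixing proportion, the fraction of the co-culture
  mRNA attributable to cell type A;
* `I[n] > 0` — the per-gene **interaction factor**, the fold change of the
  observed co-culture expression relative to the additive blend.

The identifying assumption is that the *average* gene is unaffected by the
interaction (`I = 1`), so `a` is estimated by a single one-parameter
regression of `e_co` on the monoculture profiles — Gamma errors with
identity link, since ratio data are positive and right-skewed — and the
equations are then solved per gene for `I`. A matrix of `log2 I` across
several co-culture pairings can be filtered and clustered exactly like an
ordinary expression matrix.

Around this core the package provides:

* **QC and filtering** (`hetint.io`) — spot-level background-signal
  filtering (foreground ≥ 1.5× background in both channels), presence
  (≥80% measured), fold-variation (≥3-fold from the gene mean in ≥2
  samples) and missingness (≤20%) filters, PCL-like TSV matrix I/O.
* **The blend model** (`hetint.interaction`) — `InteractionModel.fit()` →
  `InteractionResults` with `a`, its standard error, deviance, per-gene
  interaction factors, `summary()`; cross-co-culture profile assembly and
  the 2-SD interaction-responsiveness filter.
* **Signatures** (`hetint.signatures`) — Eisen-style average-linkage
  clustering with uncentered correlation, extraction of
  co-culture-induced gene sets, probe mapping, signed signature scores,
  high/low cohort stratification and centroid (Pearson) correlation.
* **Survival** (`hetint.survival`) — OS / distant-metastasis-free /
  bone-metastasis-free endpoints from event streams (with censoring at
  local or contralateral recurrences), Kaplan–Meier curves and two-group
  Cox comparison (via lifelines).
* **Synthetic data** (`hetint.simulate`) — generators for blend-model
  co-culture triplets with planted interaction factors and for tumor
  cohorts with group-structured signature expression and a
  proportional-hazards signature effect, with full ground-truth records.

## Worked example

Simulate a co-culture experiment (2000 genes, true mixing proportion 0.6,
80 genes induced 4-fold, 10% multiplicative noise), fit the blend model and
inspect the interaction factors:

```python
import numpy as np
from hetint import (CoCultureSimSpec, simulate_coculture,
                    make_triplet, InteractionModel)

rng = np.random.default_rng(11)
induced = tuple(int(i) for i in rng.choice(2000, 80, replace=False))
spec = CoCultureSimSpec(n_genes=2000, a_true=0.6, noise_cv=0.1,
                        induced_sets=((induced, 4.0),), seed=11)
sim = simulate_coculture(spec)
fit = InteractionModel(make_triplet(sim.matrix, sim.design)).fit()
print(fit.summary())
```

```
Heterotypic interaction blend model (Gamma errors, identity link)
==================================================================
genes fit                  2000
mixing proportion a      0.5723  (SE 0.0126, 95% CI [0.5476, 0.5969])
deviance               277.8701
dispersion (Pearson)     0.3762
converged                  True  (11 objective evaluations)
------------------------------------------------------------------
interaction factors I = e_co / (a*e_A + (1-a)*e_B):
  geometric mean 1.0515, median 0.9964, max 4.8450
```

The mixing proportion comes back near the planted 0.6 (the 80 strongly
induced genes pull the naive blend slightly, which the Gamma fit largely
absorbs), the median interaction factor sits at 1 — the "average gene" is
untouched — and the top of `fit.log2_interaction_factors` is dominated by
the planted induced set (log2 I ≈ 2, i.e. ~4-fold).

The same flow from the shell, end to end on synthetic data:

```sh
hetint pipeline --seed 3 --out-dir runs/demo
```

which simulates a co-culture, fits it, extracts the induced signature,
simulates a 300-patient cohort carrying the signature, stratifies the
patients and compares their survival, writing `pipeline_report.json` and a
reproducibility manifest.

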