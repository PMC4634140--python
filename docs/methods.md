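# Methods

## Statistical model

A plate seeding N cells after dose d yields a colony count y that is
treated as Poisson with mean N·S, where S is the modelled survival
probability. All maximum-likelihood (ML) fits are therefore Poisson
log-link GLMs with offset log N:

- **LQ curve**: log E[y] = log N + c̃_j − α·d − β·d², with one free
  intercept c̃_j = log PE_j per replicate experiment j (`pe_method="fit"`),
  or with log PE_j moved into the offset at its observed dose-0 value
  (`pe_method="fix"`). The design uses a full one-hot block for the
  experiments and no global intercept, so every intercept *is* a log
  plating efficiency. Under `fix` the dose-0 plates are kept in the
  response by default (they still carry residual information when an
  experiment has several control plates; a `drop_controls` flag removes
  them) and the residual d.f. are n − 2 since only α and β are estimated.
- **2×2 factorial**: log E[y] = log N + c̃_j + A·x₁ + B·x₂ + D·x₁x₂.
  The nested report B₀ = B, B₁ = B + D is derived from the fitted
  coefficients; SE(B₁)² = Var(B) + Var(D) + 2·Cov(B, D). Both codings of
  the interaction are linear reparametrizations and give identical fitted
  means (checked to 1e−10 in the tests).

### IRLS

The ML equations are solved by iteratively reweighted least squares with
working weights μ and working response η + (y − μ)/μ − offset. Starting
values μ⁰ = y + 0.5 guard zero counts; convergence is a relative deviance
change below 1e−8 within 25 iterations (the customary GLM defaults);
non-convergence is flagged on the result, not raised. Zero counts enter
the deviance with the standard convention (a y = 0 plate contributes 2μ).
The design matrix is required to have full column rank; rank deficiency
is an error, not silently aliased.

### Dispersion and quasi-likelihood

The dispersion is estimated as φ = Pearson χ² / (n − p), the
quasi-Poisson convention (Pearson rather than deviance; the deviance is
exposed on every fit for comparison). φ ≈ 1 under pure Poisson scatter;
clonogenic data typically give φ > 1 because replicate experiments vary
beyond counting statistics even after plating-efficiency correction. All
reported standard errors are scaled by √φ. A one-sided χ²(n−p) tail
probability of the Pearson statistic tests φ = 1. As a rule of thumb a
dispersion beyond 9 — three Poisson standard deviations — deserves a look
at the replicate diagnostics; this threshold is only a configurable
warning (`--dispersion-warn`), never an automatic exclusion.

### Nested-model F-test

Model comparisons (one common curve vs per-group curves; interaction vs
no interaction) use F = [(D_red − D_full)/Δdf] / φ_full with φ_full from
the richer model, referred to F(Δdf, n − p_full). This is the standard
ANOVA test for GLMs with estimated dispersion; with Δdf = 1 it is
approximately the squared Wald statistic, which is also reported. In the
curve comparison the plating efficiencies are always separate per
(group, experiment), so the test isolates the shape parameters (α, β).

### Least squares

The LS path minimizes Σ(log(y/N) − log S)² with the same design matrices
(log PE intercepts estimated as free coefficients, or subtracted for
fixed PE). R² = 1 − RSS/TSS about the (weighted) grand mean. The weighted
variant uses case weights equal to the observed colony count of each
plate: by the delta method Var(log y) ≈ 1/y under Poisson sampling, so
weighting by y is inverse-variance weighting on the log scale — this is
our reading of the weighted-LS recipe that circulates in the
clonogenic-assay protocol literature. Zero-colony plates have no defined
log fraction; they are excluded from LS/WLS fits with a warning (the ML
path keeps them). LS nested tests are classical ANOVA on residual sums
of squares.

## Replicate diagnostics

Each experiment's share of the total weighted residual sum of squares is
computed from the pooled fit's per-plate contributions — Pearson-weighted
squared residuals for ML, (weighted) squared log-residuals for LS, so the
share decomposition is always consistent with the fit's own objective —
and sums to 1 by construction; under exchangeability each of k
experiments expects 1/k. Single-experiment refits use the same method and
PE handling as the pooled fit and need ≥ 3 distinct doses (3 free
parameters); their within-experiment dispersion separates internal noise
from a shifted-but-clean experiment. Outlier removal is left to the
analyst. Diagnostic plots draw log surviving fraction (observations
normalized by each experiment's PE) against dose, pooled curve solid,
single-experiment curve dashed, share annotated to one decimal.

## Synthetic data generator

`simulate_curve_data` draws y ~ Poisson(N · g · PE · exp(−αd − βd²)) per
plate, `simulate_twoway_data` the analogous 2×2 layout. Defaults describe
a typical radiation study: α = 0.5/Gy, β = 0.02/Gy², PE = 0.5, 8
replicate experiments at doses 0–6 Gy in 1-Gy steps, one plate per dose,
with the cells-seeded schedule growing with dose so that every plate
expects ≈ 50 colonies (rounded up to multiples of 50), as labs do to keep
high-dose plates countable. Two-way defaults: 4 experiments, 500
cells/plate, PE = 0.3, log-effects A = −0.348, B₀ = −0.976, B₁ = −1.343
(≈ 71 %, 38 %, 26 % survival — typical knockdown/chemosensitivity
magnitudes). All draws flow from one `numpy` generator seeded by the
spec, so tables are byte-reproducible.

**Heterogeneity mechanism.** g ~ lognormal(0, `replicate_sd`) is drawn
*per plate*, i.e. Poisson-lognormal mixing. A tempting alternative — one
multiplier per experiment acting on its plating efficiency — turns out to
be inert: the fitted per-experiment intercepts absorb any
experiment-level PE shift exactly, leaving dispersion ≈ 1, so it cannot
emulate the overdispersion the model machinery exists to handle. The
per-plate mechanism raises the expected Pearson ratio by roughly
1 + μ·(e^{σ²} − 1) and reproduces the qualitative behaviour of real
assays (dispersion > 1, scaled intervals needed for correct coverage).
What the generator does **not** emulate: systematic curve-shape
(α, β) variation between experiments, counting/measurement error beyond
Poisson, spatial plate effects, or colony-merging at high density.
Passing calibration tests on these data therefore demonstrates the
correctness of the estimators and tests under the stated mixed
Poisson model, not robustness to every failure mode of real assays.

## Numerical and design choices

- Dispersion uses the Pearson statistic; χ² dispersion test likewise.
- F-test denominator dispersion comes from the full model.
- Deviance drops are clamped at 0 (IRLS round-off can make a nested
  reduction marginally negative).
- Two-level factors read from files are coerced to {0, 1} with the
  lexicographically first level as 0; doses are real numbers, grouping
  labels strings; plates are never aggregated — the Poisson law applies
  per plate.
- Multi-group tables must be subset before single-curve fitting;
  `compare_curves` handles ≥ 2 groups jointly.
- Report precision: 3–4 significant digits in CLI reports, full
  precision in TSV outputs.

## Problem sizes used in the validation suite

Oracle-equivalence checks run 20+ simulated tables against a generic
trust-region/score-root Newton maximizer (agreement 1e−6); parameter
recovery and dispersion calibration use 200 replications of the default
curve design; type-I error of the curve comparison and the interaction
test use 500 replications each, judged against the 99 % binomial band
around the nominal 0.05.

## Known limitations

- Only the LQ dose-response shape is implemented (no single-hit
  multi-target or other cell-survival models); only 2×2 factorial
  designs, no multi-level factors or three-way interactions.
- Only the log link and (quasi-)Poisson family; no model selection.
- The F-test's dispersion estimate is noisy at small residual d.f. (e.g.
  9 in a 4-replicate two-way design); p-values there are approximate, as
  for any quasi-likelihood analysis.
- Fixed plating efficiencies treat the dose-0 ratio as known, ignoring
  its sampling error; fitting the PE (the default) is statistically
  cleaner.
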