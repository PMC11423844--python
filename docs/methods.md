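# Methods

`deapanel` measures the technical efficiency of decision-making units
(DMUs) observed as a jurisdiction-year panel, corrects the estimates for
frontier-estimation bias, and explains the corrected scores with a
random-forest determinants analysis. This note documents the models, the
numerical choices, and what the synthetic test bed does and does not
establish.

## Output-oriented BCC efficiency

Each DMU converts inputs `x ∈ R^p_+` into outputs `y ∈ R^q_+`. Under
variable returns to scale (VRS, the Banker–Charnes–Cooper model), the
Farrell output distance of unit *o* is

    θ_o = max { θ : Yᵀλ ≥ θ y_o,  Xᵀλ ≤ x_o,  Σλ = 1,  λ ≥ 0 },

solved as an explicit envelopment LP with `scipy.optimize.linprog`
(HiGHS). θ ≥ 1 always, because λ = e_o is feasible with θ = 1. The
reported **efficiency score is 1/θ ∈ (0, 1]**, matching the convention
in which published yearly means lie between 0.4 and 0.7. Dropping the
convexity constraint gives the CRS (CCR) variant, used only for the
nesting check VRS ≥ CRS.

Choices:

* **One frontier per calendar year.** The panel is scored as 12
  independent cross-sections, since the efficiency series and its
  confidence band are reported year by year. A pooled intertemporal
  frontier is a different estimand and is out of scope.
* **All 16 input rates enter.** With p + q = 18 dimensions, a yearly
  cross-section of a few hundred DMUs violates the common n ≥ 3(p+q)
  rule of thumb; the scorer logs a warning but does not prune variables,
  because the variable set is part of the design being reproduced.
* **All-zero input columns within a year are dropped** (with a warning):
  they are vacuous constraints and destabilise the solver. This happens
  naturally for input categories that disappear over the study window.
* Tolerances: LP feasibility 1e-9; oracle-equality assertions 1e-6;
  units-invariance drift 1e-8. A failed solve is retried once with
  columns rescaled to unit mean.

Two independent oracles guard the LP. For one input and one output the
VRS frontier is the least concave monotone envelope of the data, so θ is
computable by elementary geometry (single points and pair chords). For
small multi-dimensional instances, brute-force enumeration of the
envelopment polytope's vertices (solving every maximal active-constraint
system with `numpy.linalg.solve`) gives the exact optimum without any LP
machinery.

## Smoothed homogeneous bootstrap

DEA scores are biased toward the frontier: the frontier is estimated
from the best performers of a finite sample and therefore lies inside
the true technology. The smoothed homogeneous bootstrap (Simar–Wilson)
estimates this bias:

1. Estimate distances θ̂_1..θ̂_n for the year.
2. Bandwidth: Silverman's rule on the sample reflected about the
   boundary 1, `h = 0.9 · min(sd, IQR/1.34) · (2n)^(-1/5)`; a
   zero-variance year degenerates to h = 0.
3. For each of B resamples: draw with replacement from
   {θ̂_i} ∪ {2 − θ̂_i}, add N(0, h²) kernel noise, shrink centred draws
   by 1/√(1 + h²/σ̂²_θ) to preserve the sample variance, and fold values
   below 1 back across the boundary.
4. Build the pseudo data set y*_i = (θ̂_i/θ*_i) y_i (inputs unchanged)
   and re-solve the DEA for every original unit against the pseudo
   reference set.
5. On the score scale, `bias_i = mean_b(1/θ_i^(b)) − 1/θ̂_i`;
   `corrected_i = 1/θ̂_i − bias_i`. Per-draw corrected values
   `2/θ̂_i − 1/θ_i^(b)` give a percentile confidence interval, clipped
   to (0, 1] and widened, if ever necessary, to contain the point
   estimate.

Defaults: B = 100 (the reproduced design; a warning notes that smaller
B makes CIs unstable), 95% percentile CIs. The yearly confidence band
on the *mean* corrected score is a normal approximation across
jurisdictions (mean ± 1.96·SE), since that is how yearly bands are
conventionally reported; whether the original band was bootstrap-based
is not stated anywhere, so the simpler convention is used. The
homogeneous (unconditional) variant is used; no conditioning structure
is modelled. RNG streams are derived per year from the master seed, so
any single year reproduces identically in isolation.

## Random-forest determinants

A random-forest regressor predicts the bias-corrected efficiency from
seven contextual covariates plus the calendar year (numeric, capturing
secular change). Configuration mirrors the reproduced design: 500
trees, 5 candidate variables per split, repeated 10-fold
cross-validation with 3 repeats, 50 importance subsamples, 500 partial-
dependence observations. Trees use `min_samples_leaf = 5`, the standard
regression-forest node size.

* **Fit metrics** (MSE, RMSE, R², median absolute error) are computed on
  held-out predictions pooled over all folds and repeats — never on the
  training fit. "MAD" is read as the median absolute error of the CV
  residuals; the median absolute deviation about the residual median is
  reported alongside.
* **Perturbation importance**: for each variable and each of 50
  bootstrap subsamples (size n, drawn with replacement), the variable is
  permuted within the subsample and the RMSE increase over the intact
  subsample is recorded; variables are ranked by the mean increase.
  "Eliminating" a variable is implemented as permutation, not
  drop-and-refit: the subsample structure of the procedure is only
  coherent for a fixed model, and refitting 8 × 50 forests would be a
  different (and far costlier) estimand. Rows are scored **out of
  fold** — each row by the first-repeat CV model that did not train on
  it. In-sample scoring charges part of the forest's memorized noise to
  whichever variable is permuted, which visibly inflates the importance
  of a provably irrelevant feature; out-of-fold scoring restores the
  property that an independent noise column scores ≈ 0.
* **Partial dependence**: min(500, n) rows sampled without replacement;
  ~20 grid points spanning the variable's observed 1st–99th percentile
  range; the variable is set to each grid value in all sampled rows and
  predictions are averaged.
* **Regional refits**: the same configuration fit independently within
  each socio-economic region; regions with fewer rows than CV folds are
  skipped with a warning and listed in the run manifest.

## Summaries and tests

* Yearly summary: mean raw and corrected scores, SE = sd/√n and a
  mean ± 1.96·SE band. SDs use the population convention (ddof = 0),
  which is the convention the module's worked arithmetic examples pin
  down. A single-estimate year is flagged degenerate (CI collapses).
* Growth rate over the window: `100·(end − start)/start`, **truncated**
  toward zero at two decimals. Truncation, not rounding, is the
  convention that reproduces all seven published two-decimal growth
  rates from their printed anchor means (31.4286 → 31.42,
  66.667 → 66.66).
* Trend test: two-sided p-value of the OLS slope of score on year.
  Between-region test: one-way ANOVA per year. Neither test is named in
  the reproduced design; these are the simplest conventional choices and
  are treated as assumptions. Both hold nominal type-I error within
  Monte-Carlo tolerance in the calibration tests. No multiplicity
  adjustment is applied (matching the unadjusted reporting).
* "All jurisdictions" is region 0 and flows through the same code path
  as regions 1–6.

## Synthetic panel generator

The administrative panel this pipeline was designed around is not
deposited, so the generator emulates its schema and magnitudes with a
known technology:

* **Inputs.** 16 rates per 10,000 inhabitants (4 infrastructure + 12
  staffing categories). Each rate is `base_k(t) · s_j · ε_jkt`, where
  `base_k(t)` interpolates published category means between the 2009,
  2015 and 2020 anchors, `s_j` is a jurisdiction-level lognormal
  resource scale (σ = 0.56, E[s] = 1), and `ε` is idiosyncratic
  lognormal noise (σ = 0.15, mean 1). The split matters: total
  cross-jurisdiction dispersion matches the published SEs (SD/mean
  ≈ 0.6 for the large categories), while the strong common factor —
  resource-rich jurisdictions have more of everything, as real staffing
  and infrastructure rates do — keeps the 16-column technology
  effectively low-dimensional. With mostly idiosyncratic noise instead,
  yearly DEA on 16 inputs rates ~40% of units fully efficient and
  frontier recovery degrades; the chosen split makes recovery checkable,
  which is this module's purpose.
* **Technology.** Cobb–Douglas on two aggregates,
  `g(x) = A · (Σ infra)^0.22 · (Σ staffing)^0.38`; Σα = 0.6 < 1 gives
  genuinely variable returns to scale, so VRS-vs-CRS distinctions are
  meaningful. A = 820 calibrates mean 2009 treated output to its
  published magnitude (~819).
* **Inefficiency.** `treated = g(x)·e^{−u}·e^{v}` with
  `u = m_t · (softplus(β·z) + |N(0, σ_u)|)`, σ_u = 0.12, and
  v ~ N(0, σ_v), σ_v = 0.05 (0 in recovery tests). The true Farrell
  distance is exactly e^u. z are the standardized context columns; the
  default signed links β make marginalization the dominant driver
  (+0.55), with coverage (−0.30), indigenous share (+0.35), demand
  (+0.25), Gini (+0.12), government support (+0.08) and employment
  (−0.10). An all-zero β row contributes exactly zero (no
  context-driven inefficiency), so a fully neutral configuration puts
  every unit on the frontier; for active links, softplus's log 2
  baseline at z = 0 supplies the realistic average inefficiency level.
  The year multiplier m_t falls linearly from 1.0 (2009) to 0.52
  (2016), then rebounds to ~0.71 by 2020, producing the
  rise-then-decline efficiency trajectory.
* **Outputs.** Controlled cases are a jittered ~40% share of treated
  cases (N(0.40, 0.05), clipped), matching the published ratio; the two
  outputs share one latent technology rather than inventing a second.
* **Context.** Drawn from independent scaled Beta/Normal/Gamma marginals
  calibrated to the published 2009 means (marginalization ~N(28.7, 10)
  with regional shifts, coverage following the published year path,
  indigenous share a right-skewed Beta with southern regions higher,
  demand declining over the window, Gini ~N(0.40, 0.03), etc.). Only
  the regional shifts and the inefficiency link induce correlation; the
  cross-correlation structure of the real covariates is unknown and not
  modelled.
* Regions 1–6 are contiguous blocks of jurisdictions with a poverty
  gradient (region 1 poorest), so between-region differences and
  regional refits have signal. Per-region β overrides are available for
  region-specific recovery tests.
* Determinism: one `numpy` generator seeded from the config, fixed draw
  order; identical (config, seed) reproduces the panel byte-for-byte.

**What the synthetic bed does not show.** Real administrative rates are
measured with error, serially correlated within jurisdiction, and their
covariates are mutually correlated; none of that is modelled. Passing
recovery tests demonstrates that the estimators recover the structure
*this* generator encodes at these sample sizes — not that the published
point estimates are correct, which would require the undisclosed data.

## Problem sizes used in the automated checks

The acceptance script and end-to-end tests run scaled study conditions
chosen by this package: the full 242 × 12 default panel for generation
and schema checks; a single noise-free 200-jurisdiction frontier with
B = 100 for bias-correction recovery; an 80-jurisdiction × 12-year
panel with B = 100 for the pipeline, summaries and forest; null
simulations (500 in the tests, 1000 in the acceptance script) for test
calibration. Oracle equivalence uses 52 random
instances (40 single-input/single-output, 12 two-by-two).
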