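# Methods

This note documents the models implemented in `frugicast`, the
assumptions behind the synthetic-data generator, and the numerical and
design choices that were genuinely open.

## Seed dispersal effectiveness

SDE for a frugivore–plant pair is the product of a quantity and a
quality term.

**Quantity (qSDE, seeds per 10 h).** The visitation rate is
`n_visits × 10 / observation_hours`; qSDE multiplies it by the mean seed
load per visit. When a pair has several focal records, visits and hours
are pooled before the rate is formed and the load mean is visit-weighted,
so splitting one watch into two records cannot change the estimate. For
many-seeded infructescences the per-visit load is derived from
morphometrics: beak volume under a cone model (`⅓ π r² h`, `r` = half
beak width between commissures, `h` = culmen length, both mm) divided by
150 mm³ of pulp per viable seed gives seeds per peck for birds; mandible
length divided by 0.9 mm of fruit per seed gives seeds per bite for
primates. Seeds per peck/bite are kept as real numbers: integerizing
would bias small-beaked species downward and nothing in the measurement
model requires whole seeds per handling event.

**Quality.** The proportion of tested gut-passed seeds that germinate.
Germination curves are reported on the check grid (every 2 days by
default); a seed first seen germinated at check *t* counts at *t*. A
frugivore without feeding-trial data has an *absent* quality — not zero —
and is excluded from SDE-weighted maps while remaining in qSDE maps.

**Sampling completeness.** Unique plant–frugivore interactions are
treated as species and interaction events as abundances. Asymptotic
richness uses the Chao lower bound `S_obs + f1²/(2 f2)`; when no
doubletons exist the bias-corrected `S_obs + f1(f1−1)/2` is used (the
estimator family leaves this fallback to the implementation). Coverage is
`1 − (f1/n)·(n−1)f1/((n−1)f1 + 2f2)`, with the 0/0 case at `n = 1` taken
at its limiting factor of 1. Point estimates only; interval estimation is
out of scope.

## Range modelling

The SDM stage is deliberately scaffold-shaped: everything around the
learner is fixed, the learner is pluggable behind `fit(X, y)` /
`predict_suitability(X)`.

- **Thinning**: greedy removal of the point with the most neighbours
  within the minimum distance, seeded random tie-breaks. This targets a
  large retained set without claiming global optimality (tests compare
  against exhaustive search on small instances).
- **Background**: presence bounding box padded 10 units per side, clipped
  to the landscape; pseudo-absences are drawn uniformly over non-presence
  cells of the background, equal in number to presences, placed at cell
  centres.
- **Collinearity**: while any retained layer pair has |Pearson r| > 0.6,
  the member with the larger VIF (regressing it on the other retained
  layers) is dropped; constant layers are removed first since their
  correlation is undefined.
- **Evaluation**: TSS (sensitivity + specificity − 1) and rank-based ROC
  AUC with half-credit ties, both on the 25 % holdout of seeded random
  75/25 splits, 15 replicates per algorithm.
- **Ensemble**: cellwise weighted mean with weights ∝ max(TSS, 0).
  Sub-random members (TSS ≤ 0) carry no information about where the
  species is and are zero-weighted; raw-TSS (not rank) weighting is used.
- **Binarization**: the TSS-maximizing threshold over candidate values
  (observed scores plus 0 and 1), ties broken toward the smallest
  threshold, which favours sensitivity. The threshold is selected once on
  the current-scenario ensemble and applied to every projection, so
  range change between scenarios is never an artefact of re-thresholding.
- **Baseline learner**: logistic regression on standardized predictors
  with linear plus quadratic terms per predictor, L2-regularized. The
  quadratic terms matter: log-suitability of a Gaussian niche is
  quadratic in the predictor, so the baseline can represent unimodal
  responses exactly rather than only monotone ones. Tree ensembles or
  other learners can be registered in `sdm.LEARNERS` without touching the
  rest of the pipeline.

Coordinates are planar grid units; there is no geodesy. Grids are
row-major with the origin at the lower-left corner and half-open cells.

## Forecasts and decoupling

Function per cell is `Σ_f Hs_f,C × w_f` over frugivore presences, with
`w` either qSDE or SDE; maps are masked to the plant's scenario-specific
range (an unmasked variant exists for beyond-range reporting). Richness
maps used alongside SDE-weighted function count only frugivores with
trial data, so both layers describe the same species pool.

Both layers are min–max normalized over the same domain — all cells of
the plant's projected range where both metrics are defined, per scenario
and per metric — and the decoupling index is the per-cell difference
`D = function′ − richness′ ∈ [−1, +1]`. A constant layer normalizes to
all zeros (with a prominent log warning) instead of failing, so a
uniform landscape classifies as agreement. Cells are classified as
richness-overestimates (`D < −ε`), agreement (`|D| ≤ ε`) or
richness-underestimates (`D > ε`); ε defaults to 0.05, a value chosen as
a visually negligible twentieth of the index's half-range, and is
configurable.

Change analysis restricts to stable cells (plant present under both
climates). Per-cell percentage change is undefined where the current
value is 0; such cells are excluded rather than imputed. The coupling
regression is OLS of % change in function on % change in richness with
HC3 standard errors (`(XᵀX)⁻¹ Xᵀ diag(e²/(1−h)²) X (XᵀX)⁻¹`), two-sided
t-tests on n − 2 df. Note the HC3 and classical covariances agree only in
the balanced homoskedastic *limit*: in an equal-leverage design with
equal-magnitude residuals the two differ by exactly `n/(n − p)`, which
tends to 1 — the test suite verifies the exact finite-sample relation.
No spatial-autocorrelation correction is applied.

## The synthetic world

The generator exists to make every stage verifiable with known truth,
not to mimic any real geography.

- **Landscape**: 100×100 cells by default, two climate layers.
  Temperature rises 12 → 24 °C south to north (planar gradient, smooth
  noise SD 0.4 °C, correlation length 5 cells); precipitation rises
  800 → 1200 mm west to east (noise SD 25 mm). Future scenarios shift
  the layers additively/multiplicatively: +2.1 °C with 3 % drying
  (moderate) and +2.4 °C with 6 % drying (business-as-usual), matching
  the mid-century warming spread between a moderate and a high-emission
  pathway.
- **Species**: Gaussian niche per layer; suitability is the product of
  `exp(−(x − opt)²/(2σ²))` terms; the true range is suitability ≥ 0.5.
- **Observation models**: presences sampled ∝ suitability (jittered
  within cells); visits Poisson with mean `rate × hours/10`; seed loads
  Poisson; germination binomial with geometric delays on the 2-day check
  grid. Defaults: 300 presences per species, 240 focal hours per
  frugivore, 50 seeds per treatment — effort at which the qSDE and
  germination estimators are precise to a few percent, verified unbiased
  by Monte-Carlo tests.
- **Presets**: `even_contributions` (10 interchangeable dispersers,
  equal weights), `skewed_resilient_key` (a dominant holding ~75 % of
  total qSDE weight with a broad, cool-shifted thermal niche) and
  `skewed_sensitive_key` (the dominant is also the narrowest-niche
  species). The two skewed presets realize the contrast between an
  assemblage buffered by a climate-resilient keystone disperser
  (richness underestimates function; median D > 0) and one whose
  keystone is the first to go (median D < 0). The dominant's niche is
  placed so that its range covers most — but deliberately not all — of
  the plant's future range; if it covered everything, its contribution
  would be constant over the normalization domain and min–max rescaling
  would absorb it, collapsing the contrast by construction.

What the generator does *not* emulate: real geography and fragmentation,
observation biases (roads, detectability varying with habitat),
interaction rewiring under climate change, dispersal limitation and
demography, and niche shapes beyond separable Gaussians. Passing tests
therefore demonstrate that the estimators and maps recover known truth
under a well-specified sampling model — not that any particular real
landscape behaves this way.

## Problem sizes and determinism

Every stochastic routine takes a seed or `numpy` Generator and is
bit-reproducible given one. The shipped studies run at desk scale —
100×100 grids, ~12 species, 15 SDM replicates of the bundled learner,
single-digit seconds per end-to-end study — sizes chosen so the spatial
patterns are resolved while a full multi-seed analysis stays
interactive. The pipeline CLI writes a manifest of output checksums;
identical config and seed reproduce identical checksums.

## Known limitations

- The bundled learner is additive-quadratic; strongly interacting or
  asymmetric niches need a registered external learner.
- Percentage-change regressions inherit the instability of % change near
  small current values; cells with zero current value are dropped, which
  can remove the very cells where functional collapse is sharpest.
- Min–max normalization ties the index to the per-scenario range extremes,
  so D values are comparable within a scenario and metric, not across
  plants with different weight distributions.
- The thinning heuristic is greedy; for pathological point configurations
  it may retain fewer points than the true maximum independent set.
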