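# Methods

This note records the models, defaults and numerical choices behind
`drpeval`, and what the synthetic benchmarks do and do not demonstrate.

## Dose–response model

Viability at molar concentration *c* is modelled by the four-parameter
logistic (4PL)

    f(c) = lower + (upper − lower) / (1 + (c / EC50)^h)

with upper/lower asymptotes in viability units (fraction of untreated
control), EC50 in molar, and Hill slope *h*. Fitting is plain least
squares on the observed viabilities with the curve evaluated in
log10-concentration space, using `scipy.optimize.least_squares` (TRF,
box constraints) with tight tolerances (1e−15) so that noiseless data is
recovered essentially to machine precision.

**Initialization.** Optimizers for sigmoids are sensitive to the EC50
start. We use ≥ 5 deterministic starts: EC50 at quantiles of the observed
log-concentration range, asymptotes at the extreme viabilities, Hill
slope alternating 1 and 2. No RNG is involved, so a fit is a pure
function of its data. The lowest-RSS converged start wins; if none
converges the best attempt is returned flagged `converged=False`.

**Bounds.** Hill slope defaults to [0.1, 10] — unbounded slopes diverge
on sparse or flat curves; asymptotes may range over [−1, 3] because
control-normalized viabilities legitimately exceed 1; the EC50 bound is
widened to 3 decades beyond the observed concentration range. All bounds
are user-configurable (`FitBounds`).

**Degenerate input.** A perfectly flat response carries no concentration
information: the fit returns `upper = lower = value`, `hill = 0`,
`identifiable=False`, rather than raising — downstream AUDRC is then the
clamped constant.

## Standardized AUDRC / AADRC

The area under the dose–response curve is computed on the log10 axis over
a *fixed* window, by default 100 pM to 100 μM (6 orders of magnitude — a
span that covers the therapeutic window of most approved oncology drugs
and is wide enough for robust sigmoid fitting at the typical 8–10
measured doses; defaults are 9):

    AUDRC = (1 / (log10 cmax − log10 cmin)) ∫ clamp(f(10^x), 0, 1) dx

integrated by adaptive quadrature (`scipy.integrate.quad`,
absolute tolerance 1e−8) with the clamp-crossing abscissae passed as
breakpoints, since clamping introduces kinks. The log10 axis and
window-width normalization are deliberate choices: dose–response curves
are conventionally analysed on log concentration, and the normalization
puts AUDRC in [0, 1] (1 = no effect, 0 = complete killing). AADRC is
defined as 1 − AUDRC, so the complement identity is exact by
construction. Clamping the *fitted* curve (not the raw observations used
for fitting) keeps the area within its bounds even when fitted asymptotes
drift outside [0, 1].

`audrc_trapezoid_experimental` implements the older convention —
trapezoids over each experiment's own concentration range — solely to
demonstrate its failure mode: identical underlying curves sampled over
different windows receive different values, whereas the standardized
fitted AUDRC agrees across windows to fit tolerance.

**IC50 conventions.** The absolute IC50 is the concentration where the
fitted curve crosses a viability threshold (0.5 by default), solved in
closed form; it is undefined (NaN) when the asymptotes do not bracket the
threshold. It is distinct from the EC50 parameter (curve midpoint); both
are reported because public datasets conflate them. `ln_ic50` is the
natural log of the molar IC50; source datasets differ in their unit
conventions, so response values are otherwise treated as opaque reals.

## Normalization and binarization

Min-max modes map each group (whole dataset or per drug) linearly onto
[0, 1]; centering modes subtract the group mean, which zero-centers each
drug and highlights differential response across cells. Zero-variance
groups map to 0.5 (min-max) or 0 (centering) with a warning. Centered
values necessarily leave any nominal [0, 1] range; such outputs skip the
range validation and keep their response-type tag.

Percentile binarization labels responses at or below the low percentile
(default 25) *sensitive*, at or above the high percentile (default 75)
*resistant*, and everything between *undefined*; percentiles use linear
interpolation. Groups with fewer than 4 records are skipped; a constant
group satisfies both rules simultaneously and is labelled entirely
undefined.

## Cross-validation strategies

All five splitters are seeded (`numpy.random.default_rng`) and operate on
sorted unique entities, so assignments are reproducible and independent
of input row order. Defaults: k = 5 (the field's convention),
validation fraction 0.

* **random** — pairs dealt into k folds, sizes differing by ≤ 1.
* **cell-blind / drug-blind** — entities dealt into k groups balanced by
  entity count (≤ 1 imbalance); a fold's test set is every measured pair
  of its group. Balancing by entity rather than pair count is the
  simplest contract with a provable guarantee; pair-balanced variants are
  out of scope. k = number of entities gives leave-one-cell-line-out /
  leave-one-drug-out.
* **completely-blind** — cells and drugs both grouped; fold f tests
  cell-group f × drug-group f and trains on pairs touching neither.
  The diagonal pairing yields exactly k folds; pairs mixing groups are
  *discarded* for that fold and reported explicitly (on a full grid,
  per-fold test ≈ 1/k² and train ≈ ((k−1)/k)² of pairs). Discarded pairs
  are never silently dropped from accounting.
* **cancer-type-blind** — all cells of a type share a fold; types are
  placed largest-first into the currently smallest fold (cell-count
  greedy, seeded tie-break). Cells without a type annotation are excluded
  and counted.

The validation carve-out is taken from training *pairs* under random
splitting but from training *entities* under the blind strategies, so the
blind guarantee extends to hyperparameter selection.

`verify_assignment` re-derives the applicable invariants (coverage,
balance, cell/drug disjointness, type cohesion) from the assignment
itself, making the guarantees machine-checkable; balance is checked on
the dealt entity groups, which is where the ≤ 1 guarantee holds on sparse
screens.

## Metrics

Overall metrics are computed over the inner join of truth and prediction
pairs: Pearson and Spearman (average-rank ties, via scipy), RMSE, MAE and
R². Per-drug and per-cell tables repeat these within each entity; a floor
of `min_pairs = 3` applies because a two-point Spearman is always ±1.
Undefined values (too few pairs, zero variance, single-class truths)
propagate as NaN and are excluded from summary denominators — never
coerced to zero, which would silently deflate waterfall fractions. The
waterfall summary counts entities whose metric *strictly* exceeds the
threshold (default 0.5).

Binary metrics (ACC, SEN, SPC, PRE, F1, FPR, GM = √(SEN·SPC), MCC,
AUROC, AUPRC) score continuous predictions against sensitive/resistant
calls; undefined calls are excluded and counted. The diagnostic odds
ratio uses a Haldane 0.5 continuity correction when any contingency cell
is zero. AUROC/AUPRC come from scikit-learn; the test suite cross-checks
every metric against independent brute-force implementations (explicit
rank construction, pairwise win counting) to 1e−12.

## Cross-dataset harmonization

Pairs are matched across datasets after canonicalizing identifiers
(uppercase, strip non-alphanumerics) and applying optional alias tables;
ambiguous aliases (one raw id to two targets) are rejected. The pairwise
Spearman matrix is reported together with matched-pair counts; a
correlation is only reported at ≥ 10 matched pairs (configurable), and
datasets with different response types are refused unless explicitly
allowed (rank invariance makes the comparison defensible, but it should
be a conscious choice). Replicates are aggregated (median) before
correlating.

## Synthetic screens

The generator draws r_cd = μ + α_d + β_c + γ_cd + ε_cd with independent
zero-mean Gaussian components. Defaults — 50 cells × 20 drugs,
σ_drug = 2, σ_cell = σ_interaction = σ_noise = 0.1, no missingness —
put essentially all variance between drugs, the regime in which overall
correlation is uninformative about per-drug skill. Missingness is uniform
at random; missing pairs are absent rows, never imputed. Cancer types are
assigned round-robin. Latent effects are returned so tests can use the
generator as its own oracle.

What this model does *not* emulate: heavy-tailed responses, structured
missingness (drug panels), correlated drugs (chemical similarity), batch
effects, or realistic cell-lineage structure. Passing tests on these
screens therefore demonstrate the correctness of the *evaluation
machinery* — splits, metrics, areas — not the real-world accuracy of any
predictor.

Curve sets draw 4PL parameters from uniform priors (upper 0.9–1.1, lower
0–0.15, log10 EC50 −9 to −5, Hill 0.5–3) at 9 log-spaced doses across the
standard window with Gaussian viability noise (sd 0.02 by default),
clipped at 0 from below.

### Reference predictors

* **drug-mean baseline** — predicts each drug's training mean (grand mean
  for unseen drugs). Its per-drug predictions are constant, so per-drug
  rank correlations are undefined; for demonstrations that need defined
  within-drug ranks, an optional small seeded jitter (`jitter_sd`,
  independent of the truth) is added, leaving per-drug correlations near
  zero while the overall correlation stays driven by the drug means. The
  pathology demonstrations use jitter sd 0.1, the same scale as the
  screen's measurement noise.
* **oracle predictor** — the noiseless latent response plus Gaussian
  noise, which dials per-drug accuracy continuously. When given the
  training set, it only uses effect components of entities seen in
  training (unseen components are replaced by their prior mean, 0),
  mimicking how a learned model degrades under entity-blind evaluation;
  this is what produces the random ≥ cell-blind ≥ drug-blind ordering on
  interaction-dominated screens.

## Problem sizes and tolerances in the validation suite

The shipped checks use: 200 random sparse screens (5–60 cells/drugs, up
to 40% missing) × 5 strategies for split verification; 100-point random
4PL grids against a 10,001-point trapezoid oracle (agreement ≤ 1e−6);
100 seeded noisy curves for EC50 recovery (median |log10 ratio| < 0.05);
20 seeds for the split-ordering majority; 100 random instances for
metric-oracle agreement (≤ 1e−12). These sizes were chosen to give
comfortable statistical margins while keeping the whole suite fast on a
single CPU.

## Known limitations

* No GR metrics, synergy scores, Bayesian curve fits, or per-well QC.
* No parsers for native GDSC/CTRP/PharmacoGx dumps; I/O is generic
  triplet and long-format CSV/TSV.
* Identifier canonicalization is lexical only; full resolution against
  cell-line registries is out of scope.
* No significance testing or confidence intervals on metric differences.
* The config pipeline covers the simulate/split/evaluate/harmonize/plot
  stages; model training is external by design — predictions enter as
  tables.
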