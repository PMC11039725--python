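# Methods

This note records the modelling and numerical choices behind `fleetdea`,
in the order the pipeline runs them.

## Synthetic fleet generator

The generator emulates the operational footprint of a small hospital MRI
fleet at event level. Defaults describe a busy tertiary-care service:
4 scanners observed for 24 months from 2022-01, 18 exams per device-day,
mean scan time 28 min (SD 8, truncated at 10 min) plus a fixed 2-minute
preparation slot, appointment lead times with mean 1.5 days and report
delays with mean 1 day (both gamma, shape 2), a tariff of 600 currency
units per exam with 10% lognormal spread, operating costs of 150 000/month
with 15% lognormal noise, depreciation 80 000/month, and 11 h of energized
(powered-on) time per day. Start month is configurable.

Distributions are deliberately simple: truncated normal for durations,
gamma for waits, lognormal for money — positive, right-skewed, one or two
parameters each. Daily exam counts are Poisson but floored at one, so
every device-month is scoreable. All draws flow from a single
`numpy.random.default_rng(seed)`, making the output a pure function of the
configuration.

One device may be flagged high-efficiency with a multiplier g > 1
(default 1.3 on device A): its daily exam intensity is multiplied by g and
its scan durations, appointment leads and report delays divided by g.
Tariffs and cost parameters are untouched — the efficient device earns
more because it does more work faster, not because it charges more. A
scheduling cursor guarantees exams on one device never overlap, and
energized time is floored at 105% of realized scan minutes so the
utilization ratio stays below saturation.

What the generator does **not** emulate: case-mix differences between
scan protocols, scheduled maintenance windows, demand seasonality,
referral dynamics, or cost heterogeneity from different purchase years.
Passing tests on this data therefore demonstrate that the pipeline's
mathematics behaves as specified and recovers a planted efficiency signal
of realistic magnitude — not that the model is validated on real hospital
operations.

## Indicator panel

The eight indicators are computed per device-month from events whose scan
start falls in that calendar month. Units: X1 and X7 dimensionless, X2 in
hours/day (monthly scan hours over calendar days), X3 and X5 in currency,
X4 in currency/exam, X6 and X8 in minutes. X1 uses the 2-minute
preparation constant so that (τ+2)·n is the occupied machine time; with τ
and σ_b both in minutes the ratio is a dimensionless load factor near 1 at
saturation. Device-months with zero exams are excluded with a warning
because DEA requires strictly positive inputs. The Pearson correlation
screen is descriptive only; it never filters indicators.

## Weighting

**AHP.** Weights are row geometric means normalized to sum 1; λ_max is
estimated as the mean of (Aw)ᵢ/wᵢ over the rows, i.e. Σᵢ (Aw)ᵢ/(n·wᵢ).
A principal-eigenvector mode exists behind `method="eigen"`; both agree on
consistent matrices. RI follows Saaty's table (0.58, 0.90, 1.12, … for
n = 3, 4, 5, …); orders ≤ 2 report CR = 0 by convention. Judgement
matrices are validated for positivity, 1–9 range, unit diagonal and
reciprocity with a relative tolerance of a few percent, since published
matrices carry rounded reciprocals (0.476 ≈ 1/2.1). The residual from such
rounding is also why the consistency ratios of the bundled reference
matrices are reproduced to ±0.001 rather than exactly.

**Improved CRITIC.** Columns are min-max standardized with an explicit
benefit/cost direction per indicator (defaults: X1, X2, X5, X7 benefit;
X3, X4, X6, X8 cost). σⱼ is the information-entropy *value* of the column
(probabilities pᵢ = zᵢ/Σz, entropy −Σp ln p / ln m, with a 1e−12 shift
guarding log 0) — not the entropy weight; this is the reading under which
the decomposition (σ + h)·conflict is internally consistent on the
bundled reference case. hⱼ is the sample standard deviation (ddof 1),
conflict is Σᵢ(1 − |rᵢⱼ|) with |r| so that positive and negative
correlation of equal strength count equally. Weights are normalized
separately within the input group (X1–X4) and output group (X5–X8), since
each group feeds its own multiplier cone. A matrix whose columns are all
mutually |r| = 1 has zero total volume and is rejected.

**Game combination.** For two weight vectors the stationarity conditions
of the deviation-minimizing combination form the Gram system
[[W₁·W₁, W₁·W₂], [W₂·W₁, W₂·W₂]]λ = [W₁·W₁, W₂·W₂]; its solution makes the
combined vector's projection onto each method's vector equal that vector's
own squared norm (the deviation from each method is orthogonal to it).
If the unconstrained solution has a negative coefficient, the constrained
minimum lies on the boundary of λ ≥ 0: the offending coefficient is zeroed
and the remaining one solved in closed form, keeping the combination
convex so the fused weights are always a valid weight vector. λ is then
normalized to sum 1. A variant right-hand side ([W₁·W₁, W₁·W₂]), seen in
parts of the combination-weighting literature, is selectable via
`rhs="as_printed"` for comparison; the symmetric form is the default.
Identical inputs short-circuit to λ = (½, ½).

## Cone-constrained DEA

The CCR multiplier LP is solved per DMU with `scipy.optimize.linprog`
(HiGHS), decision vector (w, μ), objective max μᵀy₀, constraints
μᵀyⱼ − wᵀxⱼ ≤ 0, wᵀx₀ = 1, w, μ ≥ 0. Orientation is input-oriented under
constant returns to scale; no variable-returns variant is provided.
Scores within 1e−7 above 1 are clipped to 1; ties are reported to
6 decimals.

The cone matrices are built from the combined weight vector w* as
B = W_A − m·I with W_A[i][j] = w*ᵢ/w*ⱼ. W_A is consistent, so its
principal eigenvalue is exactly its order and no eigensolver is needed.
A consequence worth stating: for this construction the region
{Bw ≥ 0, w ≥ 0} degenerates to the ray through w* (summing the m
inequalities gives equality, forcing every wᵢ/w*ᵢ to its mean), so the
cone-constrained score has the closed form
(μ*ᵀy₀/w*ᵀx₀) / maxⱼ(μ*ᵀyⱼ/w*ᵀxⱼ). The LP is retained as the
implementation — it is the general mechanism and stays correct for any
polyhedral B — and the closed form serves as an independent oracle in the
tests. The generator vector itself is always feasible, so the cone LP
cannot be infeasible on valid data; a relaxed retry (constraint tolerance
1e−9) guards numerical edge cases.

Undesirable outputs (the two waiting times) are reversed by
v′ = (max v + ε) − v with ε = 1% of the column range, preserving
positivity and strict anti-monotonicity; a reciprocal transform can be
substituted in the `prepare_dea_data` call. Scoring offers a pooled
frontier over all device-months (default — with 4 devices and 8
indicators, a monthly cross-section of 4 DMUs would make nearly every unit
efficient) and a per-month mode for cross-sectional fidelity; months with
fewer than two DMUs in per-month mode score 1 by convention with a
warning.

## Forecaster

Architecture: one bidirectional LSTM layer (32 units per direction),
scalar input, attention over the encoder states with the final
concatenated state as query, and a linear head on H′ = c + s. The
attention score is scaled dot product by default; an additive
(tanh-bottleneck) score and an attention-off ablation are selectable.
Windows of length 6 predict the next month; the split is chronological
80/20; min-max normalization is fitted on the training portion only;
interior gaps are linearly interpolated. Training is full-batch Adam
(β = 0.9/0.999, ε = 1e−8), learning rate 0.01, 200 epochs, MSE loss; all
initialization flows from one seed (default 7), so runs are bit
reproducible. Divergence (non-finite loss, or loss exploding by six
orders of magnitude) raises an error citing the learning rate.

The entire network is implemented on numpy arrays with hand-derived
backpropagation through time; the test-suite checks every parameter
block's gradient against central finite differences for all three
attention modes. Sizes are small enough (windows of 6, tens of training
pairs, 64-unit state) that full-batch float64 training takes well under a
second per series.

Metrics follow the standard definitions: R² = 1 − Σ(M−P)²/Σ(M−M̄)²,
RMSE = √MSE, MAPE averages |M−P|/M over points with M ≠ 0 (zeros are
excluded with a warning), MAE and per-point relative errors (P−M)/M are
reported as diagnostics. R² is undefined for constant actuals and the
evaluator rejects that case explicitly.

## Problem sizes and benchmarks

The default demonstration fleet is 4 devices × 24 months (≈55 000 events,
96 DMUs, 192 LPs for CCR + cone), which runs end to end in well under a
minute. The forecaster's reference benchmark is a noiseless seasonal
series x_t = 0.5 + 0.3·sin(2πt/12) of length 96 with window 6 — a clean
signal on which a correctly implemented network must achieve held-out
R² ≥ 0.85 and MSE ≤ 0.01; the tests assert exactly that, and nothing
about real hospital data. DEA correctness is established against a
brute-force multiplier-grid oracle on instances small enough to
enumerate (≤ 4 DMUs, ≤ 3 total indicators) plus closed forms for the
single-ratio and ray-cone cases.

## Known limitations

- The cone construction intentionally follows the consistent-ratio-matrix
  recipe, which pins multiplier proportions rather than bounding them in
  an interval; analysts wanting looser assurance regions can pass any
  polyhedral B to the LP layer.
- Efficiency scores are relative to the observed pool; adding a
  device-month can lower others' scores. Cross-period comparability in
  pooled mode assumes a stable technology over the window.
- The forecaster is univariate per device; it does not share information
  across devices or ingest exogenous covariates.
- With 24-month series the test split is 4 points; reported held-out
  metrics on real fleets of this size carry wide uncertainty and should
  be read as orientation, not validation.
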