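# Methods

This note records the models implemented in `whey2xanthin`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Response-surface arm

**Design.** A full central composite design over n factors has the 2^n
factorial corners at ±1 coded units, 2n axial points at ±α and replicated
centre points, N = 2^n + 2n + n_C runs in total. For the four-factor medium
screen (yeast extract, peptone, cheese whey dose, initial pH) this is
16 + 8 + 6 = 30 runs with α = 2. Coding uses `z = (x − center)/step` with
centres (10 g/l, 5 g/l, 10 % v/v, pH 7.75) and steps (5, 2.5, 5, 0.75):
these follow directly from the packaged design's five levels per factor
(the axial runs sit at the ±2 levels, e.g. yeast extract 0 and 20 g/l).

**Fit and ANOVA.** The full quadratic (15 terms for n = 4) is fitted by
ordinary least squares in coded units (statsmodels OLS). Per-term sums of
squares are partial (type III), computed as `SS_j = b_j² / c_jj` with
`c_jj = [(X'X)⁻¹]_jj`, each tested against the residual mean square on
(1, df_res); this matches the convention of the commercial DoE packages
practitioners use for such tables. The residual splits into pure error
(centre replicates about their mean, df = n_C − 1) and lack of fit. PRESS
uses the leave-one-out hat-matrix identity `e_i/(1 − h_ii)`; predicted
R² = 1 − PRESS/SS_total. Adequate precision is the spread of fitted values
divided by the average prediction standard error `sqrt(p·MS_res/N)`.
Standardized effects are `|b_j|/SE(b_j)` with the two-sided 5% t critical
value at the residual df as the significance line; t² equals the partial F.

**Optimization.** "In range" optimization is over the factorial box
[−1, 1]^4. Desirability mode maximizes the geometric mean of per-response
Derringer–Suich maximize-ramps with equal weights. The ramp anchors are the
exact min/max of each surface over the box (found by multi-start L-BFGS-B
from a 3-per-axis grid, the same start grid used for the desirability
search itself). Anchoring at the exact extrema matters: a grid-scan anchor
leaves the ramps clipped at 1 over a plateau and the argmax degenerate.
Ties break to the first-found start, so results are deterministic. On the
packaged design this lands at coded (0.29, 0.11, 0.41, 0.10) — a medium of
≈11.4 g/l yeast extract, 5.3 g/l peptone, 12.0% whey, pH 7.83 — predicting
≈16.95 mg/l product and ≈5.23 g/l biomass.

## Batch kinetics

Three unstructured models, assuming no oxygen or nitrogen limitation and
biomass as the only state that feeds back:

- logistic growth `dX/dt = μX(1 − X/Xm)`, closed form
  `X(t) = Xm / (1 + ((Xm − X0)/X0) e^{−μt})`;
- lactose balance `−dS/dt = (1/Y_XS) dX/dt + m_C X`, whose integral against
  the logistic X has an explicit log-term closed form;
- delayed Luedeking–Piret product formation, integrating
  `dP/dt = α dX/dt + βX` with the biomass trajectory shifted by Δt so that
  P(0) = 0 identically.

All exponentials are evaluated through `e^{−μt}` so trajectories stay
finite for arbitrarily large μt. The closed forms are verified in the test
suite against a high-order ODE integration of the growth law (< 1e−6 g/l
over 0–120 h) and adaptive quadrature of the substrate/product balances
(< 1e−5). The model lactose curve may cross zero at long times (the
maintenance term is unbounded); values are returned raw with an optional
negativity flag rather than clipped, so the fitted curve is exactly the
closed form.

**Fitting** is two-stage, as such data are conventionally analysed: growth
parameters first, then substrate and product parameters conditional on the
fitted growth curve. Each stage minimizes the residual sum of squares with
scipy's trust-region-reflective least squares from 16 Latin-hypercube
starts (X0 ∈ (1e−3, 0.2), Xm ∈ (0.5, 2)·max X, μ ∈ (0.01, 1) for growth;
data-scaled brackets for the other stages; Δt box-bounded to 0–12 h, a
small fraction of a batch). Ties in SS break toward the smaller parameter
norm. Each stage charges 3 parameters to the degrees of freedom. Goodness
statistics: SS, R² = 1 − SS/SS_total, σ = sample sd of the observed series,
S_y.x = sqrt(SS/df), MSE% = 100·SS/n. Defining σ as the sd of the
observations is an interpretation; it is the only definition consistent
with the magnitudes reported alongside such fits.

## Substrate inhibition

The specific growth rate peaks at the 12% (v/v) whey dose and declines
beyond it, so μ(S) is fitted with the standard inhibition set: Monod,
Andrews (Haldane), Aiba, Webb, Luong and Han–Levenspiel. S is the initial
cheese-whey dose in % v/v — the variable actually manipulated — not lactose
in g/l. Bounded models (Luong, Han–Levenspiel) return μ = 0 beyond the
critical dose Sm. With both exponents zero, Han–Levenspiel reduces exactly
to Monod, which gives the nesting property used in the tests (its best SS
can never exceed Monod's).

Fitting uses 200 Latin-hypercube starts over data-scaled brackets
(μ_max ∈ (0.5, 5)·max μ, Ks up to 5·max S, Sm ∈ (max S, 3·max S],
exponents ∈ (0.05, 5]) and — deliberately — box-bounds the fit to the same
regime: without upper bounds the five-parameter Han–Levenspiel form drifts
along a ridge (Sm and the exponents growing together) that improves SS
negligibly while destroying interpretability. On seven data points the
fitted curve is far better determined than the individual constants;
model comparison therefore ranks on fit quality (R², with SS as
tie-break), not on parameter values.

## Neural surrogate

A 4-9-2 feed-forward network (65 weights) with sigmoid hidden and linear
output units maps the coded factors to both responses. The 30 designed runs
are augmented with 200 points generated noise-free from the fitted
quadratic surfaces, sampled uniformly over the ±1 coded box (a ±2 box is a
config switch); the 230 rows are split 160/35/35 into train/validation/test
at random per seed, stratified so the six centre replicates stay in
training (they carry the only replicate information). Inputs and outputs
are affinely scaled to [−1, 1] per channel.

Training is Levenberg–Marquardt: each epoch solves
`(J'J + μI) d = −J'r` on the training residuals with the analytic Jacobian,
multiplying the damping μ by 10 (and retrying) after a failed step and
dividing by 10 after a success (initial μ = 1e−3). Early stopping restores
the lowest-validation-MSE weights after 6 consecutive validation increases;
the cap is 1000 epochs. Weight initialization is uniform (−0.5, 0.5) from
the seed. Because single runs depend on the split and initialization, all
reported surrogate numbers are averaged over ≥10 seeds; over seeds 0–9 the
surrogate predicts 16.97 ± 0.03 mg/l and 5.25 ± 0.01 g/l at the optimum
medium and stays within 0.4 mg/l of the generating quadratic across the
design box. A hidden-width sweep shows test error dropping from 2 hidden
units and plateauing by ~9, the reference width.

## Synthetic data

The generators emulate exactly the study conditions the fitted models
describe: batch time courses on a 61-point grid (0–120 h every 2 h — the
density implied by the reported per-curve SS/MSE pairs), with lactose on an
11-point subgrid (likewise implied by its fit statistics); additive
Gaussian noise per channel with defaults (0.17 g/l biomass, 0.07 g/l
lactose, 0.08 mg/l product) chosen so simulated fit statistics resemble the
reported S_y.x magnitudes; CCD response tables from a known surface with
replicate centre noise; μ-vs-S data from any inhibition model. Noisy
observations are clipped at zero (assays cannot report negative
concentrations); mean curves never are. All draws use
`numpy.random.default_rng` (PCG64), so a spec plus seed is reproducible
across platforms.

What the generators do **not** emulate: heteroscedastic or autocorrelated
assay error, calibration-curve nonlinearity, sampling-time jitter, or
biological batch-to-batch variation. Passing round-trip tests therefore
demonstrates that the estimation machinery is correct and well-conditioned
under the stated noise model — not that real fermentation data would be fit
this well.

## Numerical choices and degenerate inputs

- OLS raises an explicit rank error when the design cannot identify the
  quadratic (e.g. axial rows removed).
- ANOVA requires ≥2 centre replicates for the pure-error partition;
  otherwise those rows are omitted with a warning.
- A constant biomass series raises a fit error (μ unidentifiable); fits
  that fail from every start raise a diagnostic error rather than
  returning garbage.
- NLS convergence tolerances are 1e−12 (xtol/ftol/gtol); optimizer ties
  break deterministically (lowest SS, then smallest parameter norm,
  first-found for the desirability search).
- The reproduction driver isolates stage failures: one failing stage is
  reported and the remaining stages still run.

## Limitations

- The kinetic models are unstructured: no intracellular states, no
  oxygen/nitrogen limitation, no temperature or pH dependence of μ, no
  product inhibition (the rate data do not support one for this system).
- Y_XS values in the 12–17 g biomass per g lactose range are treated as
  fitted constants of the lactose balance, not as physically interpretable
  lactose-only yields (whey supplies substantial non-lactose nutrition).
- The product closed form evaluated at 120 h with the packaged 12%-dose
  parameters gives ≈18.8 mg/l, above the ≈17.1 mg/l a real batch reaches;
  endpoint extrapolation of the fitted curve is not a validated use.
- The surrogate is trusted only on the design region; predictions beyond
  ±2 coded units trigger an extrapolation warning.
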