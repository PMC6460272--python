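# Methods

## Survival model

The package models loss of viability under constant UV irradiance as a
single-phase first-order process, `N_t = N_0 exp(−k·x)`, where the dose
variable `x` is either exposure time in minutes or total fluence
`H(t) = T·b·H_0·t`. The fluence expression follows the standard
transmittance-corrected dose model for suspensions irradiated through
their own biomass: the lamp delivers `H_0` W/m² over a bandwidth of `b`
nm, and only the fraction `T` of that light reaches the cell film. The
proportionality constant between `T·b·H_0·t` and physical fluence is
fixed at 1, so fluence-mode rate constants carry units of
(W·m⁻²·nm·min)⁻¹; because `H` is linear in `t` the two modes are exact
re-expressions of one another (`k_time = k_fluence·T·b·H_0`) and the
package defaults to time mode, where `k` has the familiar 1/min units.

Assumptions worth stating: the irradiance field is spatially uniform
and constant in time; the population is kinetically homogeneous (no
shoulder from multi-hit damage, no resistant tail, no spore fraction);
and there is no photoreactivation or dark repair between exposure and
plating. Multi-phase (Weibull, log-logistic, shoulder/tail) models are
deliberately out of scope.

Transmittance is obtained from optical density by the Beer–Lambert
relation `T = 10^(−OD600)`; an OD600 of 1.2 corresponds to 6.3%
transmission. When a caller supplies both an OD and an explicit
transmittance they must agree to within 1e−9, otherwise construction
fails — silently preferring one over the other hides unit mistakes.

## Estimation

The survival constant is estimated by ordinary least squares of
`y = ln(N_t/N_0)` on the dose variable. Both slope and intercept are
fitted: forcing the line through the origin would entangle the rate
estimate with any systematic offset in the control count, and the
reported `R²` would no longer be the conventional coefficient of
determination. `k = −slope`; half-life is `ln 2/k`; the time for the
population to fall to a threshold `N` is `ln(N_0/N)/k`. True extinction
time is undefined under first-order decay (the model only approaches
zero asymptotically), so threshold queries require `0 < N < N_0` and a
practical "time to die" uses `N = 1` CFU.

Zero CFU observations have no logarithm. They are excluded from the
regression and their times recorded on the fit object rather than
replaced by a substitution constant (e.g. 0.5 CFU), because any such
constant biases the slope and no principled value exists for this
design. A fit needs at least two positive counts at distinct times. A
nonnegative fitted slope is reported with a `non_decaying` flag and an
infinite half-life rather than raised as an error: flat or growing
series are legitimate outcomes of a screen.

Natural logarithms are used throughout, matching the e-base decay law;
a constant-`y` series has undefined Pearson correlation and its `R²` is
reported as 0.

## Categorical statistics

The four tests are computed from their defining formulas; only the
chi-square and F reference distributions come from scipy.

* **Pearson chi-square** with expected counts from the margins. The
  Yates continuity correction, `max(|O−E|−0.5, 0)`, is applied to 2×2
  tables only — its standard scope — even when the caller requests
  correction on a larger table. Tables with a zero row or column margin
  are rejected as degenerate.
* **Fisher's exact test**, 2×2 only, two-sided by probability-mass
  ordering: the p-value sums the hypergeometric probabilities of all
  tables with the observed margins that are no more likely than the
  observed table (the R `fisher.test` convention; mid-p and
  tail-doubling variants exist and give different answers). All
  probabilities share the denominator C(N, c₁), so the enumeration is
  carried out on exact integer numerators with a 1e−7 relative
  tie-slack; a full-mass sum is exactly 1.
* **Kruskal–Wallis** with mid-ranks and the usual tie correction
  `1 − Σ(t³−t)/(N³−N)`. When every observation is identical the
  correction denominator vanishes; the statistic is then 0 with p = 1
  (no rank information), not an error. p-values use the chi-square
  approximation with groups−1 degrees of freedom.
* **Two-way ANOVA with interaction**, balanced designs only, via the
  standard decomposition `SS_total = SS_A + SS_B + SS_AB + SS_error`.
  Balance makes the Type I/II/III distinction moot. Unbalanced long-form
  input is rejected with a message directing the caller to balance or
  subsample. Degenerate grids are handled by contract: zero error
  variance with a nonzero effect reports F = +∞ (flagged), an
  all-constant grid reports every F as 0 with p = 1 (flagged).

## Synthetic data

`simulate_survival_series` draws the control population uniformly from
1.5–2.5 × 10⁷ CFU, applies first-order kill across the exposure grid
(default 0/15/30/45/60 min), thins by a single multiplicative plated
fraction, and adds Poisson counting noise — the standard plate-count
model. The default dilution of 1e−5 puts counts from a ~2×10⁷ CFU
culture in the countable 20–250 colony range across a 0.035/min decay;
serial-dilution pipetting error and plate-edge effects are not
modelled. Above a configurable expected-count ceiling (default 1e12)
the Poisson draw is replaced by the rounded expectation, where the
relative sampling error would be below 1e−6 anyway. Each series carries
the known plated control `N₀·dilution` as its `n0`.

`simulate_isolate_table` draws a multinomial over cell probabilities
`p_ij ∝ r_i c_j exp(a·u_i v_j)` with equally spaced scores `u, v` on
[−1, 1]; `a = 0` gives exact independence, which is what makes the
chi-square type-I calibration checkable. `simulate_ae_grid` produces
balanced Poisson replicate grids around user-supplied cell means
(default triplicates, the usual bench design).

Seeding contract: one root `SeedSequence` per spec, one spawned child
stream per replicate, so enlarging `replicates` never changes the
replicates already generated, and a fixed seed reproduces output
byte-for-byte.

What passing tests show — and don't: the generators reproduce the
*statistical structure* the estimators assume (log-linear decay,
Poisson counting error, multinomial tables, balanced grids). Real
plate-count data additionally exhibit overdispersion from pipetting,
plating inhomogeneity, colony merging at high density and shouldered
survival curves; recovery results here bound estimator behaviour only
under the stated model.

## Problem sizes and numerical choices

Monte-Carlo suites use 200 replicates for parameter recovery (median
recovered k within 5% of truth across k ∈ {0.01, 0.035, 0.1}, with the
dilution chosen per rate to keep mid-series counts near 100 CFU), 500
replicates for chi-square type-I calibration (rejection ≤ 7% at nominal
5%) and p-value uniformity (Kolmogorov distance < 0.1), and 1000
replicates for the sampling-envelope check on noisy fits. Exactness
properties are tested tightly: noiseless k-recovery to 1e−10 relative,
`half_life·k = ln 2` to 1e−12 over six orders of magnitude,
time/fluence mode agreement to 1e−9, ANOVA SS identity to 1e−9, and
Fisher p-values against an independent implementation on every 2×2
table with margins ≤ 12.

## Known limitations

Single-phase kinetics only; no r×c exact tests or post-hoc multiple
comparisons; ANOVA requires balance; the fluence model treats
transmittance as constant during exposure although real cultures
photobleach and settle; and CFU counts conflate cells with clumps, so
`k` describes colony-forming ability, not single-cell survival.
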