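# Methods

## Model and assumptions

The package models a gamma-camera head as a single paralyzable element:
every photon stopped by the crystal — recorded or not — extends the dead
period by the resolving time τ, giving the observed/true rate relation
`R' = R_t·exp(−R_t·τ)`. Consequences used throughout:

* the observed rate peaks at `R'_max = (e·τ)⁻¹` for `R_t = 1/τ`; above the
  peak the curve falls, so a single reading cannot reveal which side it is
  on. The correction therefore refuses inputs with `R'·τ > e⁻¹`
  (`AboveMaximumRateError`) instead of clamping, and flags inputs in the
  top 0.1 % sliver below it (`BranchAmbiguityWarning`), where the two
  branches coincide to within floating-point noise.
* dead time is a whole-spectrum property. A narrow window's rate is modelled
  as the open-window observed rate times a window fraction, not by giving
  the window its own paralyzable response. The apparent window dead time
  `τ_EW = τ_OW/w_f^η` is algebra on top of that picture: η = 1 if the
  fraction is rate-independent, η > 1 once pile-up makes the fraction fall
  with rate.
* the window fraction declines **linearly in the open-window observed
  rate**, `w_f(R') = w₀ + s·R'`, clipped to [0, 1]. The slope convention is
  absolute fraction change per cps (a quoted "−9.5 % per 100 kcps" is
  `s = −0.095/10⁵`); the alternative reading — relative to the base
  fraction — was rejected because the quantity is defined as the slope of a
  straight fit of the fraction itself against rate.

τ is treated as a constant of the configuration. Real cameras show mild
drifts of the apparent τ with activity and geometry; that variability is
precisely what the estimators are meant to expose, so it is not baked into
the forward model.

## Numerical choices

* **Lambert W.** `lambert_w0` covers the needed interval [−1/e, 0] with a
  Halley iteration seeded by the branch-point expansion
  (`w ≈ −1 + p − p²/3 + 11p³/72`, `p = √(2(1+ez))`) near −1/e and the
  series `z − z² + 1.5z³ …` elsewhere; points within `p < 10⁻⁸` of the
  branch point are pinned to the expansion. Residual tolerance is relative
  to |z| (default 10⁻¹²). It is deliberately self-contained so the tests
  can validate it against an independent bisection oracle and against
  `scipy.special.lambertw` as a cross-check; the library routine is never
  the shipped path.
* **Truncated series.** Coefficients `n^(n−1)/n!` are evaluated in log
  space (`exp((n−1)ln n − lgamma(n+1))`) so large N stays finite. Default
  N = 10: the relative error of the corrected rate is ≤ 0.11 % while up to
  30 % of true counts are lost, and ≈ 1.14 % at 40 % loss (loss defined as
  `1 − R'/R_t`).
* **Least squares.** Both linear fits (log-linear calibration and window
  fraction) are two-parameter OLS via the normal equations, with the
  parameter covariance `s²(XᵀX)⁻¹` and first-order (delta-method)
  propagation to `C = e^{b₀}` and `τ = −b₁e^{−b₀}`, including the
  intercept–slope covariance. With exactly two points the line is exact and
  standard errors are reported as NaN. The fits are deliberately
  unweighted: that is how the calibration slope is defined in practice, and
  the residual-based error estimate absorbs the mild heteroscedasticity of
  Poisson counts on the log scale.
* **Degenerate inputs.** Background-subtracted rates that fall below zero
  are floored at 0 with a `LowCountWarning`; dual-source triples with
  `R'₁₂ ≥ R'₁+R'₂` return a result flagged invalid rather than raising,
  because Poisson noise at low rates produces them routinely;
  `correction_factor(0)` returns its limit 1.

## Estimation procedures

* **Background** is pooled over all background frames of a detector/window
  (total counts over total duration) and removed by simple subtraction.
  Subtraction is applied to observed rates, which is exact only when the
  ambient rate is negligible against the source rate — the cps-scale
  regime the procedures assume.
* **Triple-source schedule.** Every frame whose source set splits into two
  separately measured disjoint subsets yields one estimate; components are
  matched by nearest acquisition time and their rates decay-aligned to the
  combined frame by the activity ratio of their sources. Scaling an
  *observed* rate by an activity ratio is first-order in the decay between
  frames; for frames minutes apart with a 6 h half-life the residual bias
  on τ is a few tenths of a percent, which is why the algebraic-agreement
  tests use effectively constant sources.
* **Dual-source validity.** For unequal sources the estimator's relative
  error tends to `((R₁−R₂)/(R₁+R₂))²` as rates fall and shrinks with rate.
  The commonly quoted leading-order bound `(R₁−R₂)²/(4(R₁+R₂)²)`
  understates the low-rate limit by a factor 4; `dual_source_error_bound`
  returns the conventional expression, while `dual_source_error_scan`
  computes the exact noiseless worst case (1.18 % over the 44–55 % split,
  35–95 % of `R'_max` band, worst at the most unequal split and lowest
  rate).
* **Validity filtering** is manual: the analyst supplies an activity or
  open-window-rate cutoff and receives both partitions. Automatic
  breakdown detection is deliberately absent — the breakdown is a camera
  artefact whose onset must be established per system.

## Synthetic experiments

The simulator is rate-level: closed-form expected rates plus Poisson counts
per frame (`counts = Poisson(rate·duration)`), fully determined by the
seed; with noise off, counts are rounded expectations, so rates recovered
from *counts* carry an integer-quantization error of order one count per
frame (~10⁻⁶–10⁻⁷ relative at these count levels). Checks of solver-level
exactness therefore read the generator's exact rate output
(`expected_observed_rates`, `noiseless_calibration_points`); checks of the
estimation pipeline use the counts path at its quantization- or
noise-limited tolerance.

The intrinsic preset encodes the canonical calibration: three ⁹⁹ᵐTc
sources (125, 125, 250 MBq; half-life 6.01 h) cycled through the
combinations 1, 2, 1+2, 3, 1+2+3 in ten sessions spaced 11 440 s apart
(~28.6 h total, activities falling to ~4.6/9.2 MBq), 60-s source frames,
300-s background frames before and after each session, 49 source frames
per window; τ = 1.30 µs, C_OW = 0.78 kcps/MBq, photopeak base fraction
0.48/0.78 with −9.5 %/100 kcps slope. Values not fixed by that recipe and
chosen once as realistic: ambient background defaults to 0 cps (a
`background_ow` argument adds it; it then participates in the
dead-time-inducing true rate); breakdown defaults to a 30 % step above
200 kcps open-window rate, which places exactly the highest-activity frame
(500 MBq total) outside the paralyzable regime. The phantom preset uses
τ = 0.92 µs, two 1.4 GBq sources, a collimated sensitivity of
0.075 kcps/MBq (a realistic LEHR system value putting the combined start
near 200 kcps, representative of post-therapy rates), base fraction 0.40
and −5.1 %/100 kcps in scatter.

What the simulator does **not** emulate: spectral physics (energy
resolution, photopeak broadening — pile-up enters only through the linear
fraction model), the window-fraction *increase* observed past breakdown on
real cameras (breakdown here scales all windows equally, so fraction
outliers displace in rate only), detector spatial response, scatter and
attenuation, and event-level dead-time dynamics. Passing tests therefore
demonstrate correctness of the inversion and estimators under the stated
model, not that a particular camera obeys that model at all rates — the
breakdown regime and validity filter exist precisely because real systems
leave the model.

## Known limitations

* Corrections are impossible above `R'_max`, and real cameras typically
  fail earlier; the package requires the analyst to know the validity
  range.
* Photopeak (effective) dead times are geometry- and scatter-dependent
  through the window fraction; a photopeak τ calibrated in air transfers
  poorly to scatter conditions. The recommended workflow is the open-window
  τ plus the window-fraction correction.
* Standard errors come from unweighted-OLS residuals, adequate at
  calibration count levels but optimistic if a series mixes very low-count
  frames with hot ones.
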