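# Methods

## Physical model

An LSPR mode probes its surroundings with an evanescent field whose
intensity falls off as `exp(-2z/l_d)` with height `z` above the metal
surface (`l_d` is the field decay length; the factor 2 converts field to
intensity). For a step index profile — adlayer index `n_a` for
`0 < z < d`, bulk index `n_B` beyond — the intensity-weighted average

```
n_eff = (2/l_d) ∫₀^∞ n(z) exp(-2z/l_d) dz
      = n_B + (n_a − n_B)(1 − exp(−2d/l_d))
```

drives the resonance through the bulk sensitivity: `Δλ = S_B (n_eff −
n_B)`. The model assumes a single homogeneous adlayer, a single
exponential decay constant per mode, and a resonance that responds
linearly to `n_eff` over the observed range. The quantity
`y = ln(1 − Δλ/Δλ_max)` with `Δλ_max = S_B(n_a − n_B)` is exactly
`−(2/l_d) d`, which is what makes a thickness-linear estimation problem
out of a saturating response. Negative contrast (`n_a < n_B`) is
supported throughout with signed shifts.

## Estimation

With k modes, `y_i = C_{d,i} d + ε_i`, `C_{d,i} = −2/l_{d,i}`, and
Gaussian noise with covariance `R_y`, the maximum-likelihood thickness is
the generalized-least-squares solution `d̂ = (CᵀR_y⁻¹C)⁻¹ CᵀR_y⁻¹ y` with
variance `(CᵀR_y⁻¹C)⁻¹`. `R_y` is not directly measured; it is obtained
from the wavelength-noise covariance `R_λ` by the first-order delta
method, `R_y[i,j] = R_λ[i,j]/((Δλ_{i,max}−Δλ_i)(Δλ_{j,max}−Δλ_j))`,
evaluated at the operating shifts. This choice (the transform is not
dictated by the estimator itself) is validated by a Monte-Carlo
cross-check in the test suite: at SNR 10 the first-order σ_d agrees with
the empirical spread of 10⁴ replicate estimates within 5%.

The bulk index change is estimated in a second step from the raw shifts,
`Δλ_i = C_{n,i} Δn + ε_i` with `C_{n,i} = S_i(1 − exp(−2d̂/l_{d,i}))`,
again by GLS under `R_λ`. The reported bulk change is
`Δn̂_B = Δn̂ − (n_a − n_B)`, i.e. the deviation of the estimated total
contrast from the configured analyte contrast. A joint one-step fit of
(d, Δn) is deliberately out of scope; the two-step scheme mirrors how the
method is used in practice and keeps both estimators closed-form.

Numerical policy: all GLS solves use `numpy.linalg.solve` on the
covariance (never an explicit inverse); a covariance condition number
above 10¹² raises an ill-conditioned error; a saturated shift
(`Δλ/Δλ_max ≥ 1`) raises a domain error in the scalar path, while the
Monte-Carlo batch path clamps `1 − Δλ/Δλ_max` at a configurable epsilon
(default 1e-9) and counts the clamped replicates. Noise-driven negative
thickness estimates are flagged but not clipped, so replicate averages
stay unbiased.

## Linear baseline

The classical alternative solves `[Δλ₁; Δλ₂] = S [Δn; d]` with
`S = [[S_B1, S_d1], [S_B2, S_d2]]`, gated on `det(S) ≠ 0` and a 2-norm
condition number of the column-normalized matrix below 100. The 2-norm
(singular-value ratio) is used because it is the standard choice; the
gate, not any particular printed κ value, is what the package asserts.
Uncertainties propagate as `Cov = S⁻¹ R_λ S⁻ᵀ`. The linear model is a
small-thickness approximation: on data generated by the saturating
response its thickness error grows monotonically with true `d`, which the
Monte-Carlo harness demonstrates.

## Calibration

- **Bulk sensitivity** `S_B`: OLS slope of shift vs refractive index over
  calibration solutions (any ≥2 distinct-RI table; no solution set is
  hard-coded). Intercept retained for QC; zero-slope fits are flagged.
- **Decay length** `l_d`: rarely reported by instruments; recovered by
  inverting the response at one worked point,
  `l_d = −2d / ln(1 − Δλ/Δλ_max)`. The recovered values agree within 15%
  with the independent route `l_d = 2 S_B (n_a−n_B)/S_d` from calibrated
  adlayer sensitivities.
- **Adlayer sensitivity relation**: the model derivative at `d = 0` is
  `S_d = 2 S_B (n_a−n_B)/l_d`; the factor-2 form is canonical here
  because it is the actual derivative of the response model. The
  single-factor variant (`model_derivative=False`) is kept for workflows
  that correct simulated sensitivities with that convention, alongside
  the measured/simulated rescaling `S_d' = S_d · S_B,meas / S_B,sim`.
- **Noise**: per-mode σ_λ and between-mode Pearson correlation from ≥3
  replicate baseline readings; correlation defaults to 0 when replicates
  are unavailable, matching the uncorrelated closed forms most
  deployments use.

## Synthetic data

The generator draws `Δλ_i = S_B,i (n_a − n_B + Δn_B)(1 −
exp(−2d/l_{d,i})) + ε` with `ε ~ N(0, R_λ)`, `R_λ = D ρ D`, sampled
through a Cholesky (or eigenvalue, when ρ = ±1) factor of `R_λ`, seeded
with `numpy.random.default_rng`. Default study condition: two modes with
`S_B = (325.25, 787.38)` nm/RIU, contrast 0.1 RIU (`n_B = 1.33`,
`n_a = 1.43`), `d = 6` nm, SNR = Δλ/σ_λ = 10 per mode (equivalently
σ_λ = (0.85, 1.3) nm at the operating point), uncorrelated noise. Decay
lengths follow from the worked-point inversion at that condition
(39.615 and 66.501 nm). A first-order association curve
`d(t) = d_max(1 − e^{−k_obs t})` supplies sensogram-shaped truth for
time-series tests.

What the generator does *not* emulate: spectral line-shape distortion,
correlated drift (thermal or fluidic), mass-transport-limited kinetics,
non-uniform adlayers, and mode-dependent noise statistics beyond a
covariance. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated noise model, not robustness to
every instrumental artefact.

## Monte-Carlo harness sizes

The comparison harness uses 10³ replicates per thickness for the
accuracy/ordering table over `d ∈ {6, 15, 25}` nm and 10⁴ replicates for
precision and coverage checks; both run in seconds because the MLE is
linear in `y` given the weights, so replicate tables are processed with a
single solve. The batch path evaluates `R_y` at the replicate-mean
operating point (the known-covariance treatment); the per-timepoint
pipeline evaluates it at each observed shift vector. Confidence-interval
coverage of `d̂ ± 1.96σ_d` is checked to be 95% ± 1.5% at the SNR-10
operating point.

## Known limitations

- Single adlayer, single decay constant per mode; multilayer stacks and
  wavelength-dependent `l_d` within a mode are out of scope.
- Δλ_max must be supplied (via contrast or directly); estimating it from
  a measured plateau is a calibration-time decision left to the user.
- The thickness estimate is first-order unbiased; near saturation
  (`d ≳ l_d`) the log transform's curvature biases it upward by a few
  percent at SNR 10, visible in the harness output.
- The two-step Δn estimate conditions on d̂ and does not account for d̂'s
  uncertainty in σ_n.
- The linear-model path is strictly 2×2; overdetermined (>2-mode) linear
  fits are not implemented (the nonlinear MLE handles k modes).
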