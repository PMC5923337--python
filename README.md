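# adlayer

Quantitative analysis for multi-resonance localized surface plasmon
resonance (LSPR) biosensors: estimate the thickness of a biomolecular
adlayer and the bulk refractive-index (RI) change, with uncertainties,
from the resonance wavelength shifts of two or more plasmonic modes.

## Who this is for

Label-free biosensing experiments (e.g. streptavidin–biotin binding on
gold nanostructures) read out a resonance wavelength shift that mixes two
effects: growth of the bound molecular adlayer and drift of the bulk
solution index. A sensor with several resonances sees these two effects
through different evanescent decay lengths, which makes them separable.
This package is for experimentalists and modellers who have per-mode
calibration constants and tracked resonance shifts and want thickness and
bulk-RI numbers — not just "response units" — with honest error bars.

## The model and the estimator

The evanescent field intensity decays as `exp(-2z/l_d)` from the metal
surface, so an adlayer of index `n_a` and thickness `d` in a bulk of index
`n_B` produces an effective index

```
n_eff = n_B + (n_a − n_B)(1 − exp(−2d/l_d))
```

and a resonance shift `Δλ = S_B (n_eff − n_B)` for a mode with bulk
sensitivity `S_B` (nm/RIU), saturating at `Δλ_max = S_B (n_a − n_B)`.
The transform `y = ln(1 − Δλ/Δλ_max) = −(2/l_d) d` is exactly linear in
the thickness, so the modes' log-shifts form a Gaussian linear model
`y_i = C_{d,i} d + ε_i` with `C_{d,i} = −2/l_{d,i}`. Maximum likelihood
gives the precision-weighted fusion

```
d̂ = (C_dᵀ R_y⁻¹ C_d)⁻¹ (C_dᵀ R_y⁻¹ y),     σ_d = sqrt((C_dᵀ R_y⁻¹ C_d)⁻¹)
```

with `R_y` the shift-noise covariance propagated to the log scale
(`R_y[i,j] = R_λ[i,j] / ((Δλ_{i,max}−Δλ_i)(Δλ_{j,max}−Δλ_j))`). The bulk
RI change is then estimated the same way from the raw shifts with
coefficients `C_{n,i} = S_i(1 − exp(−2d̂/l_{d,i}))`. The classical linear
baseline — inverting the 2×2 sensitivity matrix `S = [[S_B1, S_d1],
[S_B2, S_d2]]` after a condition-number gate `κ(S′) < 100` — is included
for head-to-head comparison; because the true response saturates in `d`,
its error grows with thickness while the nonlinear MLE stays accurate up
to roughly half the decay length.

## Worked example

Two modes with bulk sensitivities 325.25 and 787.38 nm/RIU, analyte
contrast `n_a − n_B = 1.43 − 1.33 = 0.1` RIU, shift noise 0.85 and 1.3 nm
(SNR 10 at the 6 nm operating point). Decay lengths are recovered from
the saturating response at one worked point each:

```python
import numpy as np
from adlayer import NonlinearMLE, LinearResponseModel, invert_decay_length

l_d = [invert_decay_length(8.5, 32.525, 6.0),
       invert_decay_length(13.0, 78.738, 6.0)]   # [39.615, 66.501] nm

mle = NonlinearMLE(s_bulk=[325.25, 787.38], decay_length=l_d,
                   contrast=0.1, sigma_lambda=[0.85, 1.3]).fit()
print(mle.estimate([[8.5, 13.0]]).round(4).to_string(index=False))
print("sigma_d at operating point:", round(mle.thickness_sigma([8.5, 13.0]), 4))

lm = LinearResponseModel(s_bulk=(325.25, 787.38), s_adlayer=(1.47, 2.2)).fit()
print("kappa:", round(lm.diagnostics_.kappa, 2))
print("LM (sigma_n, sigma_d):",
      np.round(lm.uncertainty(np.diag([0.85**2, 1.3**2])), 4))
```

prints

```
 t  flagged  d_hat  sigma_d  dn_b_hat  sigma_n
 0    False    6.0   0.4795       0.0   0.0071
sigma_d at operating point: 0.4795
kappa: 10.1
LM (sigma_n, sigma_d): [0.0061 1.7915]
```

Reading: a (8.5, 13.0) nm shift pair at this calibration corresponds to a
6.00 nm adlayer with a 0.48 nm first-order standard deviation and no bulk
RI change beyond the configured contrast; the linear model under the same
noise is four times less precise in thickness (1.79 nm). The
command-line interface exposes the same pipeline as `adlayer calibrate`,
`track`, `estimate`, `simulate` and `compare` (see `adlayer --help`).

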