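"""Calibration of sensor modes from measured data.

Turns raw calibration measurements into the per-mode constants the
estimators need: the bulk sensitivity S_B from a shift-vs-refractive-index
regression on solutions of known index, the decay length l_d from a worked
(thickness, shift) point, the simulation-to-measurement correction of the
adlayer sensitivity, and the wavelength-noise level from replicate
baseline readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, InsufficientDataError, InvalidParameterError
from .response import SensorMode, invert_decay_length

__all__ = [
    "CalibrationSeries",
    "BulkSensitivityFit",
    "NoiseEstimate",
    "fit_bulk_sensitivity",
    "correct_adlayer_sensitivity",
    "recover_decay_length",
    "estimate_noise",
]


@dataclass
class CalibrationSeries:
    """Resonance shifts measured against calibration solutions of known RI.

    ``ri_values`` has shape (m,), ``shifts`` shape (m,) for a single mode
    or (m, k) for k modes; ``replicates`` optionally holds repeated
    baseline wavelength readings, shape (n, k), for noise estimation.
    """

    ri_values: np.ndarray
    shifts: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ri_values = np.asarray(self.ri_values, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.shape[0] != self.ri_values.shape[0]:
            raise InvalidParameterError(
                "shifts and ri_values must have the same number of rows"
            )
        if self.ri_values.size < 2:
            raise InvalidParameterError("need at least 2 calibration points")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates, dtype=float)


@dataclass
class BulkSensitivityFit:
    """Per-mode OLS slope of shift vs RI with its standard error.

    The intercept should be ~0 for properly baselined shifts and is kept
    for quality control.  ``degenerate`` flags a zero slope whose relative
    standard error is unbounded.
    """

    s_bulk: np.ndarray
    stderr: np.ndarray
    intercept: np.ndarray
    degenerate: np.ndarray

    def __iter__(self):
        return iter(zip(self.s_bulk, self.stderr, self.intercept))


def fit_bulk_sensitivity(series: CalibrationSeries) -> BulkSensitivityFit:
    """Ordinary-least-squares bulk sensitivity S_B (nm/RIU) per mode.

    Raises
    ------
    CalibrationError
        If all calibration solutions share one refractive index
        (rank-deficient design).
    """
    ri = series.ri_values
    if np.unique(ri).size < 2:
        raise CalibrationError(
            "calibration requires at least two distinct refractive indices"
        )
    shifts = np.atleast_2d(series.shifts.T).T  # (m, k)
    slopes, errs, icepts, degen = [], [], [], []
    for col in shifts.T:
        res = stats.linregress(ri, col)
        slopes.append(res.slope)
        errs.append(res.stderr)
        icepts.append(res.intercept)
        degen.append(res.slope == 0.0)
    return BulkSensitivityFit(
        s_bulk=np.array(slopes),
        stderr=np.array(errs),
        intercept=np.array(icepts),
        degenerate=np.array(degen, dtype=bool),
    )


def correct_adlayer_sensitivity(
    s_d_sim: float, s_b_sim: float, s_b_meas: float
) -> float:
    """Rescale a simulated adlayer sensitivity to the measured device.

    S_d' = S_d * S_B(measured) / S_B(simulated): the adlayer sensitivity
    tracks the bulk sensitivity, so the ratio of measured to simulated
    bulk sensitivities corrects fabrication- and setup-dependent offsets.
    """
    if s_b_sim == 0:
        raise CalibrationError("simulated bulk sensitivity must be nonzero")
    return s_d_sim * s_b_meas / s_b_sim


def recover_decay_length(
    mode: SensorMode, worked_point: tuple[float, float, float]
) -> float:
    """Set a mode's decay length from a worked (d, Δλ, Δλ_max) point.

    Decay lengths are rarely reported directly; this recipe recovers l_d
    by inverting the saturating response at one known thickness and stores
    it on the mode.
    """
    d, delta_lambda, delta_lambda_max = worked_point
    l_d = invert_decay_length(delta_lambda, delta_lambda_max, d)
    mode.decay_length = l_d
    return l_d


@dataclass
class NoiseEstimate:
    """Per-mode wavelength noise σ_λ (nm) and between-mode correlation."""

    sigma_lambda: np.ndarray
    correlation: np.ndarray

    @property
    def covariance(self) -> np.ndarray:
        """The implied shift covariance R_λ = D ρ D with D = diag(σ_λ)."""
        d = np.diag(self.sigma_lambda)
        return d @ self.correlation @ d


def estimate_noise(replicates: np.ndarray | Sequence[Sequence[float]]) -> NoiseEstimate:
    """Sample σ_λ and Pearson correlation from replicate baseline readings.

    ``replicates`` is (n, k): n repeated wavelength readings for k modes.
    With constant readings the correlation is undefined and reported as
    the identity.

    Raises
    ------
    InsufficientDataError
        With fewer than 3 replicate readings.
    """
    replicates = np.atleast_2d(np.asarray(replicates, dtype=float))
    if replicates.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 replicate readings, got {replicates.shape[0]}"
        )
    sigma = replicates.std(axis=0, ddof=1)
    k = replicates.shape[1]
    if np.any(sigma == 0.0) or k == 1:
        corr = np.eye(k)
    else:
        corr = np.corrcoef(replicates, rowvar=False)
    return NoiseEstimate(sigma_lambda=sigma, correlation=np.atleast_2d(corr))
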