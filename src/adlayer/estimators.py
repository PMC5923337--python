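"""Scikit-learn style estimator front-ends.

Two estimators wrap the functional core so sensograms can be processed
with the familiar ``fit``/``predict`` idiom and composed with
scikit-learn model-selection utilities:

``NonlinearMLE``
    The nonlinear-response maximum-likelihood estimator.  ``fit`` takes
    replicate baseline wavelength readings (to estimate the per-mode noise
    and its correlation) or, when noise levels are configured up front,
    may be called with no data.  ``predict`` maps an (n_timepoints,
    n_modes) array of resonance shifts to thickness estimates;
    ``estimate`` returns the full per-timepoint table (d̂, σ_d, Δn̂_B,
    σ_n).

``LinearResponseModel``
    The 2x2 sensitivity-matrix baseline with its conditioning gate.

Both follow the scikit-learn contract: constructor arguments are stored
unmodified, all derived state lives in trailing-underscore attributes set
by ``fit``, and ``get_params``/``set_params`` work for grid search.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .calibration import estimate_noise
from .errors import IllConditionedError, InvalidParameterError
from .io import RunConfig, run_estimation
from .linear import SensitivityMatrix, validate_conditioning
from .mle import thickness_uncertainty
from .response import SensorMode

__all__ = ["NonlinearMLE", "LinearResponseModel"]


def _as_shift_matrix(X, n_modes: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != n_modes:
        raise InvalidParameterError(
            f"X has {X.shape[1]} columns; expected {n_modes} modes"
        )
    return X


class NonlinearMLE(BaseEstimator):
    """Maximum-likelihood adlayer-thickness and bulk-RI estimator.

    Parameters
    ----------
    s_bulk : sequence of float
        Per-mode bulk sensitivities S_B (nm/RIU).
    decay_length : sequence of float
        Per-mode evanescent decay lengths l_d (nm).
    contrast : float
        Analyte index contrast n_a - n_B (RIU); fixes the saturation
        shifts Δλ_max = S_B * contrast.
    n_b : float, default 1.33
        Bulk refractive index (aqueous buffer).
    sigma_lambda : sequence of float or None
        Per-mode shift-noise standard deviations (nm).  When None they
        must be learned from baseline replicates passed to :meth:`fit`.
    correlation : float, default 0.0
        Between-mode noise correlation; overridden by :meth:`fit` when
        baseline replicates are supplied.

    Attributes
    ----------
    modes_ : list of SensorMode
        Calibrated channels assembled by ``fit``.
    noise_covariance_ : ndarray of shape (k, k)
        Wavelength-shift noise covariance R_λ.
    sigma_lambda_ : ndarray of shape (k,)
        Per-mode noise levels actually used.

    Examples
    --------
    >>> est = NonlinearMLE(s_bulk=[325.25, 787.38],
    ...                    decay_length=[39.63, 66.49],
    ...                    contrast=0.1, sigma_lambda=[0.85, 1.3])
    >>> est.fit().predict([[8.5, 13.0]])
    array([5.99...])
    """

    def __init__(
        self,
        s_bulk=(325.25, 787.38),
        decay_length=(39.63, 66.49),
        contrast=0.1,
        n_b=1.33,
        sigma_lambda=None,
        correlation=0.0,
    ):
        self.s_bulk = s_bulk
        self.decay_length = decay_length
        self.contrast = contrast
        self.n_b = n_b
        self.sigma_lambda = sigma_lambda
        self.correlation = correlation

    def fit(self, X=None, y=None):
        """Assemble the calibrated modes; optionally learn the noise.

        Parameters
        ----------
        X : array-like of shape (n_replicates, n_modes), optional
            Replicate baseline wavelength readings.  When given (>= 3
            rows), per-mode noise sigmas and their correlation are
            estimated from them; otherwise ``sigma_lambda`` and
            ``correlation`` from the constructor are used.
        y : ignored
        """
        k = len(self.s_bulk)
        if len(self.decay_length) != k:
            raise InvalidParameterError("s_bulk and decay_length lengths differ")
        if X is not None:
            noise = estimate_noise(_as_shift_matrix(X, k))
            self.sigma_lambda_ = noise.sigma_lambda
            self.noise_covariance_ = noise.covariance
        else:
            if self.sigma_lambda is None:
                raise InvalidParameterError(
                    "either pass baseline replicates to fit() or set sigma_lambda"
                )
            self.sigma_lambda_ = np.asarray(self.sigma_lambda, dtype=float)
            corr = np.full((k, k), self.correlation)
            np.fill_diagonal(corr, 1.0)
            self.noise_covariance_ = corr * np.outer(
                self.sigma_lambda_, self.sigma_lambda_
            )
        self.modes_ = [
            SensorMode(
                label=f"mode{i + 1}",
                s_bulk=float(sb),
                decay_length=float(ld),
                sigma_lambda=float(sig),
            )
            for i, (sb, ld, sig) in enumerate(
                zip(self.s_bulk, self.decay_length, self.sigma_lambda_)
            )
        ]
        self.n_features_in_ = k
        return self

    def _config(self) -> RunConfig:
        return RunConfig(
            modes=self.modes_,
            contrast=self.contrast,
            n_b=self.n_b,
            correlation=self.correlation,
        )

    def estimate(self, X) -> pd.DataFrame:
        """Full per-timepoint estimate table for a shift series.

        Returns a DataFrame with columns ``d_hat``, ``sigma_d``,
        ``dn_b_hat`` (bulk RI change beyond the configured contrast),
        ``sigma_n`` and a ``flagged`` marker for saturated rows.
        """
        check_is_fitted(self, "modes_")
        X = _as_shift_matrix(X, self.n_features_in_)
        config = self._config()
        config.correlation = self._fitted_correlation()
        return run_estimation(config, X)

    def _fitted_correlation(self) -> float:
        cov = self.noise_covariance_
        if cov.shape[0] < 2 or np.any(np.diag(cov) == 0.0):
            return 0.0
        return float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))

    def predict(self, X) -> np.ndarray:
        """Thickness estimates d̂ (nm), one per row of shifts."""
        return self.estimate(X)["d_hat"].to_numpy()

    def thickness_sigma(self, shifts=None) -> float:
        """First-order σ_d (nm) at an operating point.

        ``shifts`` are the per-mode operating shifts Δλ_i; omitted, the
        small-shift (d -> 0) limit is used.  The delta-method headroom
        Δλ_max - Δλ shrinks toward saturation, so σ_d grows with the
        operating thickness.
        """
        check_is_fitted(self, "modes_")
        coeffs = np.array([-2.0 / m.decay_length for m in self.modes_])
        max_shifts = np.array([m.s_bulk * self.contrast for m in self.modes_])
        if shifts is None:
            shifts = np.zeros_like(max_shifts)
        headroom = max_shifts - np.asarray(shifts, dtype=float)
        scale = 1.0 / headroom
        r_y = self.noise_covariance_ * np.outer(scale, scale)
        return thickness_uncertainty(coeffs, r_y)


class LinearResponseModel(BaseEstimator):
    """Sensitivity-matrix (linear response) baseline estimator.

    Solves [Δn; d] = S⁻¹ Δλ per timepoint after checking the conditioning
    gate on the column-normalized matrix.

    Parameters
    ----------
    s_bulk, s_adlayer : sequences of 2 floats
        The two columns of the sensitivity matrix.
    kappa_threshold : float, default 100
        Conditioning gate on κ(S').

    Attributes
    ----------
    S_ : SensitivityMatrix
    diagnostics_ : ConditioningDiagnostics
        det(S), κ(S') and the pass/fail verdict set by ``fit``.
    """

    def __init__(
        self,
        s_bulk=(325.25, 787.38),
        s_adlayer=(1.47, 2.2),
        kappa_threshold=100.0,
    ):
        self.s_bulk = s_bulk
        self.s_adlayer = s_adlayer
        self.kappa_threshold = kappa_threshold

    def fit(self, X=None, y=None):
        """Build the matrix and run the conditioning gate (data unused)."""
        self.S_ = SensitivityMatrix.from_sensitivities(self.s_bulk, self.s_adlayer)
        self.diagnostics_ = validate_conditioning(
            self.S_.matrix, kappa_threshold=self.kappa_threshold
        )
        if not self.diagnostics_.passed:
            raise IllConditionedError(
                f"sensitivity matrix fails conditioning gate: det="
                f"{self.diagnostics_.det:.4g}, kappa={self.diagnostics_.kappa:.4g}"
            )
        self.inv_ = np.linalg.inv(self.S_.matrix)
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        """(n, 2) array of per-timepoint [Δn̂, d̂]."""
        check_is_fitted(self, "S_")
        X = _as_shift_matrix(X, 2)
        return X @ self.inv_.T

    def uncertainty(self, r_lambda) -> tuple[float, float]:
        """(σ_n, σ_d) from propagating R_λ through S⁻¹."""
        check_is_fitted(self, "S_")
        from .linear import lm_uncertainty

        return lm_uncertainty(self.S_, np.asarray(r_lambda, dtype=float))
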