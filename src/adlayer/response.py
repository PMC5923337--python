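"""Closed-form nonlinear response model for evanescent-field sensors.

A localized surface plasmon resonance (LSPR) sensor probes its surroundings
with an evanescent field whose intensity decays as ``exp(-2z/l_d)`` with
distance ``z`` from the metal surface, where ``l_d`` is the field decay
length.  A biomolecular adlayer of thickness ``d`` and refractive index
``n_a`` sitting in a bulk medium of index ``n_B`` therefore produces an
effective refractive index

    n_eff = n_B + (n_a - n_B) * (1 - exp(-2 d / l_d))

which is the intensity-weighted average of the step index profile
``n(z) = n_a`` for ``0 < z < d`` and ``n_B`` beyond.  The resonance
wavelength shift of a mode with bulk sensitivity ``S_B`` (nm/RIU) is
``Δλ = S_B (n_eff - n_B)``, which saturates at ``Δλ_max = S_B (n_a - n_B)``
as the adlayer grows much thicker than the decay length.  The quantity

    y = ln(1 - Δλ/Δλ_max) = -2 d / l_d

is exactly linear in the thickness and is the working variable of the
maximum-likelihood estimators in :mod:`adlayer.mle`.

This module contains only pure functions of the model parameters; nothing
here touches data files or random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import CalibrationError, InvalidParameterError, SaturationError

__all__ = [
    "RIProfile",
    "SensorMode",
    "effective_refractive_index",
    "resonance_shift",
    "max_shift",
    "log_linearize",
    "invert_decay_length",
    "adlayer_sensing_efficiency",
    "adlayer_sensitivity_from_bulk",
]


@dataclass(frozen=True)
class RIProfile:
    """Step refractive-index profile of an adlayer on the sensor surface.

    Parameters
    ----------
    n_a : float
        Refractive index of the adlayer (RIU).
    n_b : float
        Bulk (solution) refractive index beyond the adlayer (RIU).
    d : float
        Adlayer thickness in nm, measured outward from the metal
        surface (z = 0 at the surface).
    """

    n_a: float
    n_b: float
    d: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise InvalidParameterError(f"adlayer thickness d={self.d} must be >= 0")
        if self.n_a <= 0 or self.n_b <= 0:
            raise InvalidParameterError("refractive indices must be positive")

    @property
    def contrast(self) -> float:
        """Signed index contrast n_a - n_B (RIU)."""
        return self.n_a - self.n_b

    def n_of_z(self, z: float) -> float:
        """The step profile n(z): n_a inside the adlayer, n_B beyond."""
        return self.n_a if 0.0 <= z < self.d else self.n_b


@dataclass
class SensorMode:
    """One plasmonic resonance channel and its calibration constants.

    Parameters
    ----------
    label : str
        Channel name, e.g. ``"mode1"``.
    s_bulk : float
        Bulk refractive-index sensitivity S_B in nm/RIU.
    decay_length : float
        Evanescent field decay length l_d in nm (intensity decays as
        exp(-2z/l_d)).
    lambda0 : float, optional
        Baseline resonance wavelength in nm (metadata; not used by the
        estimators).
    s_adlayer : float, optional
        Adlayer sensitivity S_d in nm per nm of adlayer, used by the
        linear response model.
    sigma_lambda : float, optional
        Standard deviation of the wavelength-shift noise in nm.
    dip : bool
        True when the resonance appears as a minimum (dip) of the
        extinction spectrum rather than a peak.
    """

    label: str
    s_bulk: float
    decay_length: float = field(default=float("nan"))
    lambda0: float = field(default=float("nan"))
    s_adlayer: float | None = None
    sigma_lambda: float | None = None
    dip: bool = False

    def __post_init__(self) -> None:
        if self.s_bulk <= 0:
            raise InvalidParameterError(
                f"bulk sensitivity S_B={self.s_bulk} must be > 0"
            )
        if not math.isnan(self.decay_length) and self.decay_length <= 0:
            raise InvalidParameterError(
                f"decay length l_d={self.decay_length} must be > 0"
            )
        if self.sigma_lambda is not None and self.sigma_lambda < 0:
            raise InvalidParameterError("sigma_lambda must be >= 0")


def effective_refractive_index(profile: RIProfile, decay_length: float) -> float:
    """Effective refractive index sensed through the evanescent field.

    Evaluates ``n_B + (n_a - n_B)(1 - exp(-2d/l_d))``, the closed form of
    the intensity-weighted integral ``(2/l_d) ∫ n(z) exp(-2z/l_d) dz`` over
    the step profile.

    Raises
    ------
    InvalidParameterError
        If ``decay_length`` is not positive.
    """
    if decay_length <= 0:
        raise InvalidParameterError(f"decay length l_d={decay_length} must be > 0")
    return profile.n_b + profile.contrast * (
        1.0 - math.exp(-2.0 * profile.d / decay_length)
    )


def resonance_shift(mode: SensorMode, profile: RIProfile) -> float:
    """Resonance wavelength shift Δλ (nm) of one mode for a given adlayer.

    Δλ = S_B (n_a - n_B)(1 - exp(-2d/l_d)).  The sign follows the sign of
    the contrast n_a - n_B and the magnitude is bounded by |Δλ_max|.
    """
    n_eff = effective_refractive_index(profile, mode.decay_length)
    return mode.s_bulk * (n_eff - profile.n_b)


def max_shift(mode: SensorMode, n_a: float, n_b: float) -> float:
    """Saturation shift Δλ_max = S_B (n_a - n_B), reached as d >> l_d."""
    return mode.s_bulk * (n_a - n_b)


def log_linearize(delta_lambda: float, delta_lambda_max: float) -> float:
    """Log-linearised response y = ln(1 - Δλ/Δλ_max).

    For shifts obeying the nonlinear model this equals ``-2d/l_d`` exactly,
    turning the saturating response into a quantity linear in thickness.

    Raises
    ------
    CalibrationError
        If ``delta_lambda_max`` is zero.
    SaturationError
        If ``Δλ/Δλ_max >= 1`` (saturated or super-saturated shift).
    """
    if delta_lambda_max == 0:
        raise CalibrationError("saturation shift Δλ_max must be nonzero")
    ratio = delta_lambda / delta_lambda_max
    if ratio >= 1.0:
        raise SaturationError(
            f"shift {delta_lambda} is at or beyond saturation {delta_lambda_max}"
        )
    return math.log1p(-ratio)


def invert_decay_length(
    delta_lambda: float, delta_lambda_max: float, d: float
) -> float:
    """Recover the decay length from one worked point of the response.

    Solves ``Δλ/Δλ_max = 1 - exp(-2d/l_d)`` for ``l_d`` given a thickness
    ``d`` at which the shift ``Δλ`` was produced.  This is the standard
    route to a decay length when only a calibrated (d, Δλ) pair is
    available.
    """
    if d <= 0:
        raise InvalidParameterError(f"worked-point thickness d={d} must be > 0")
    y = log_linearize(delta_lambda, delta_lambda_max)
    if y == 0.0:
        raise InvalidParameterError("zero shift carries no decay-length information")
    return -2.0 * d / y


def adlayer_sensing_efficiency(s_adlayer: float, s_bulk: float) -> float:
    """Sensing efficiency η = S_d / S_B (RIU per nm of adlayer).

    η is the rate at which adlayer growth moves the effective refractive
    index; it allows modes of very different bulk sensitivity to be
    compared on a common footing.
    """
    if s_bulk == 0:
        raise CalibrationError("bulk sensitivity S_B must be nonzero")
    return s_adlayer / s_bulk


def adlayer_sensitivity_from_bulk(
    s_bulk: float,
    contrast: float,
    decay_length: float,
    *,
    model_derivative: bool = True,
) -> float:
    """Adlayer sensitivity implied by the bulk calibration.

    The derivative of the nonlinear response at zero thickness gives
    ``S_d = 2 S_B (n_a - n_B) / l_d`` — the canonical relation consistent
    with the response model used throughout this package.  Setting
    ``model_derivative=False`` drops the factor of two, giving the
    single-decay-constant variant ``S_B (n_a - n_B) / l_d`` that some
    calibration workflows use; it is provided for reproducing such
    corrections, not as the model derivative.
    """
    if decay_length <= 0:
        raise InvalidParameterError(f"decay length l_d={decay_length} must be > 0")
    factor = 2.0 if model_derivative else 1.0
    return factor * s_bulk * contrast / decay_length
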