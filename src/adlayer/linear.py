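"""Linear response model baseline: sensitivity-matrix inversion.

The established way to decouple bulk refractive-index change from adlayer
growth on a two-resonance sensor treats each shift as linear in both:

    [Δλ_1]   [S_B1  S_d1] [Δn]
    [Δλ_2] = [S_B2  S_d2] [ d ]

and inverts the 2x2 sensitivity matrix S.  The inversion is only
trustworthy when S is nonsingular and its column-normalized form S' is
well conditioned (the conventional gate is a 2-norm condition number below
100).  Because the true response saturates in d, this linear model is a
small-thickness approximation; it is kept here as the head-to-head
baseline for the nonlinear maximum-likelihood estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IllConditionedError, InvalidParameterError
from .mle import ShiftObservation

__all__ = [
    "SensitivityMatrix",
    "ConditioningDiagnostics",
    "normalize_sensitivity_matrix",
    "validate_conditioning",
    "lm_estimate",
    "lm_uncertainty",
]

#: Conventional upper bound on κ(S') for a usable sensitivity matrix.
DEFAULT_KAPPA_THRESHOLD = 100.0


@dataclass(frozen=True)
class ConditioningDiagnostics:
    """Outcome of the sensitivity-matrix conditioning gate."""

    det: float
    kappa: float
    threshold: float
    passed: bool


class SensitivityMatrix:
    """2x2 sensitivity matrix S = [[S_B1, S_d1], [S_B2, S_d2]].

    Column 1 holds the bulk sensitivities (nm/RIU), column 2 the adlayer
    sensitivities (nm/nm).  Exposes the column-normalized matrix, the
    determinant and the 2-norm condition number of the normalized matrix.
    """

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (2, 2):
            raise InvalidParameterError(
                f"sensitivity matrix must be 2x2, got {matrix.shape}"
            )
        self.matrix = matrix

    @classmethod
    def from_sensitivities(cls, s_bulk, s_adlayer) -> "SensitivityMatrix":
        s_bulk = np.asarray(s_bulk, dtype=float)
        s_adlayer = np.asarray(s_adlayer, dtype=float)
        return cls(np.column_stack([s_bulk, s_adlayer]))

    @classmethod
    def from_modes(cls, modes) -> "SensitivityMatrix":
        return cls.from_sensitivities(
            [m.s_bulk for m in modes], [m.s_adlayer for m in modes]
        )

    @property
    def normalized(self) -> np.ndarray:
        return normalize_sensitivity_matrix(self.matrix)

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix))

    @property
    def kappa(self) -> float:
        """2-norm condition number of the column-normalized matrix."""
        return float(np.linalg.cond(self.normalized, 2))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SensitivityMatrix({self.matrix.tolist()})"


def normalize_sensitivity_matrix(matrix: np.ndarray) -> np.ndarray:
    """Divide each column of S by its Euclidean norm.

    Normalization strips the disparate physical units (nm/RIU vs nm/nm) so
    that the condition number reflects the geometry of the two sensing
    channels rather than their scales.
    """
    matrix = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(matrix, axis=0)
    if np.any(norms == 0.0):
        raise IllConditionedError("sensitivity matrix has a zero column")
    return matrix / norms


def validate_conditioning(
    matrix: np.ndarray, kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD
) -> ConditioningDiagnostics:
    """Gate the linear model on det(S) != 0 and κ(S') below threshold.

    Returns a diagnostic record rather than raising: a failed gate is a
    property of the sensor design, not a programming error.
    """
    matrix = np.asarray(matrix, dtype=float)
    det = float(np.linalg.det(matrix))
    if det == 0.0 or np.any(np.linalg.norm(matrix, axis=0) == 0.0):
        return ConditioningDiagnostics(
            det=det, kappa=float("inf"), threshold=kappa_threshold, passed=False
        )
    kappa = float(np.linalg.cond(normalize_sensitivity_matrix(matrix), 2))
    passed = det != 0.0 and kappa < kappa_threshold
    return ConditioningDiagnostics(
        det=det, kappa=kappa, threshold=kappa_threshold, passed=passed
    )


def lm_estimate(
    obs: ShiftObservation | np.ndarray, matrix: np.ndarray | SensitivityMatrix
) -> tuple[float, float]:
    """Solve the 2x2 linear system for (Δn̂, d̂).

    Accepts either a :class:`ShiftObservation` or a bare length-2 shift
    vector.  Refuses singular matrices with a diagnostic.
    """
    if isinstance(matrix, SensitivityMatrix):
        matrix = matrix.matrix
    matrix = np.asarray(matrix, dtype=float)
    shifts = obs.shifts if isinstance(obs, ShiftObservation) else np.asarray(obs, float)
    diag = validate_conditioning(matrix, kappa_threshold=float("inf"))
    if not np.isfinite(diag.kappa) or diag.det == 0.0:
        raise IllConditionedError(
            f"singular sensitivity matrix (det={diag.det}); estimation refused"
        )
    dn_hat, d_hat = np.linalg.solve(matrix, shifts)
    return float(dn_hat), float(d_hat)


def lm_uncertainty(
    matrix: np.ndarray | SensitivityMatrix, r_lambda: np.ndarray
) -> tuple[float, float]:
    """Propagate shift noise through the matrix inverse.

    Cov(Δn̂, d̂) = S⁻¹ R_λ S⁻ᵀ; returns (σ_n, σ_d) as the square roots of
    the diagonal.
    """
    if isinstance(matrix, SensitivityMatrix):
        matrix = matrix.matrix
    matrix = np.asarray(matrix, dtype=float)
    r_lambda = np.asarray(r_lambda, dtype=float)
    if np.linalg.det(matrix) == 0.0:
        raise IllConditionedError("singular sensitivity matrix")
    inv = np.linalg.inv(matrix)
    cov = inv @ r_lambda @ inv.T
    sigma_n, sigma_d = np.sqrt(np.diag(cov))
    return float(sigma_n), float(sigma_d)
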