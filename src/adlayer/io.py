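"""File I/O, resonance tracking and the batch estimation pipeline.

All on-disk formats are plain delimited text (comma or tab, autodetected):
extinction spectra as two-column (wavelength, extinction) blocks,
calibration tables and shift time series as columnar tables with a header
row of mode labels, and run configurations as YAML with a flat top level
plus one section per mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    InvalidParameterError,
    ParseError,
    SaturationError,
    TrackingError,
    UnidentifiableError,
)
from .linear import SensitivityMatrix, lm_estimate, lm_uncertainty
from .mle import (
    ShiftObservation,
    estimate_ri_change,
    estimate_thickness,
    log_transform,
)
from .response import SensorMode

__all__ = [
    "SpectrumRecord",
    "RunConfig",
    "read_spectra",
    "track_resonance",
    "read_table",
    "read_calibration_table",
    "load_config",
    "run_estimation",
]


@dataclass
class SpectrumRecord:
    """One extinction spectrum: strictly increasing wavelengths (nm),
    extinction in arbitrary units, and an optional timestamp."""

    wavelengths: np.ndarray
    extinction: np.ndarray
    timestamp: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.wavelengths.shape != self.extinction.shape:
            raise InvalidParameterError("wavelength and extinction lengths differ")
        if self.wavelengths.size == 0:
            raise ParseError("empty spectrum")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")


_DELIMS = re.compile(r"[,\t;]|\s+")


def _split_row(line: str) -> list[str]:
    return [tok for tok in _DELIMS.split(line.strip()) if tok]


def read_spectra(path: str | Path) -> list[SpectrumRecord]:
    """Read two-column (wavelength, extinction) spectra from delimited text.

    Blank lines separate consecutive spectra (one block per timepoint); a
    single block yields one record.  A leading non-numeric header row per
    block is skipped.  Malformed rows raise :class:`ParseError` with the
    offending line number; non-monotone wavelength grids are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty input")
    records: list[SpectrumRecord] = []
    block_w: list[float] = []
    block_e: list[float] = []

    def flush():
        if block_w:
            records.append(
                SpectrumRecord(
                    wavelengths=np.array(block_w),
                    extinction=np.array(block_e),
                    timestamp=float(len(records)),
                )
            )
            block_w.clear()
            block_e.clear()

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            flush()
            continue
        tokens = _split_row(stripped)
        if len(tokens) != 2:
            raise ParseError(f"expected 2 columns, got {len(tokens)}", line=lineno)
        try:
            w, e = float(tokens[0]), float(tokens[1])
        except ValueError:
            if not block_w:  # header row at block start
                continue
            raise ParseError(f"non-numeric row {tokens!r}", line=lineno) from None
        block_w.append(w)
        block_e.append(e)
    flush()
    if not records:
        raise ParseError(f"{path}: no numeric rows found")
    return records


def track_resonance(
    record: SpectrumRecord,
    window: tuple[float, float],
    dip: bool = False,
) -> float:
    """Locate a resonance wavelength inside a window by parabolic refinement.

    Finds the extremum sample of the extinction within [λ_lo, λ_hi] (a
    minimum when ``dip`` is set) and refines it with a 3-point parabola
    through the extremum and its neighbours, giving sub-grid-resolution
    output that is exact for quadratic line shapes.

    Raises
    ------
    TrackingError
        If the window holds fewer than 5 samples or the extremum sits on
        the window edge (no interior peak to refine).
    """
    lo, hi = window
    mask = (record.wavelengths >= lo) & (record.wavelengths <= hi)
    w = record.wavelengths[mask]
    e = record.extinction[mask]
    if w.size < 5:
        raise TrackingError(f"window [{lo}, {hi}] contains {w.size} samples (< 5)")
    idx = int(np.argmin(e) if dip else np.argmax(e))
    if idx == 0 or idx == w.size - 1:
        raise TrackingError("extremum on window edge; widen or move the window")
    # 3-point parabolic vertex through (w[idx-1..idx+1], e[idx-1..idx+1])
    x0, x1, x2 = w[idx - 1 : idx + 2]
    y0, y1, y2 = e[idx - 1 : idx + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a == 0.0:
        raise TrackingError("flat spectrum in window; no extremum")
    return float(-b / (2.0 * a))


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table (comma/tab autodetected) with a header row."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty input")
    first = text.splitlines()[0]
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    return pd.read_csv(path, sep=sep, engine="python")


def read_calibration_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, list]:
    """Read a calibration table: first column RI, remaining columns one
    shift series per mode (header row holds the mode labels).

    Returns (ri_values, shifts[m, k], mode_labels).
    """
    df = read_table(path)
    if df.shape[1] < 2:
        raise ParseError("calibration table needs an RI column and >=1 mode column")
    ri = df.iloc[:, 0].to_numpy(dtype=float)
    shifts = df.iloc[:, 1:].to_numpy(dtype=float)
    return ri, shifts, list(df.columns[1:])


@dataclass
class RunConfig:
    """Estimation run configuration.

    ``modes`` carries the per-mode calibration; the analyte contrast
    (n_a - n_B in RIU) fixes the per-mode saturation shifts
    Δλ_max = S_B (n_a - n_B) — it must be stated explicitly because the
    estimators cannot infer it from shifts alone.
    """

    modes: list[SensorMode]
    contrast: float
    n_b: float = 1.33
    correlation: float = 0.0
    kappa_threshold: float = 100.0
    saturation_epsilon: float = 1e-9
    baseline_interval: tuple[int, int] | None = None
    run_lm: bool = False
    s_adlayer: list[float] | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kappa_threshold <= 1:
            raise InvalidParameterError("kappa_threshold must exceed 1")
        if not self.modes:
            raise InvalidParameterError("at least one mode must be configured")

    @property
    def n_a(self) -> float:
        return self.n_b + self.contrast

    @property
    def noise_covariance(self) -> np.ndarray:
        sigma = np.array([m.sigma_lambda or 0.0 for m in self.modes])
        k = len(sigma)
        corr = np.full((k, k), self.correlation)
        np.fill_diagonal(corr, 1.0)
        return corr * np.outer(sigma, sigma)


_MODE_KEYS = {
    "s_bulk",
    "decay_length",
    "lambda0",
    "s_adlayer",
    "sigma_lambda",
    "dip",
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration: flat keys plus a ``modes`` mapping
    of per-mode sections, e.g.::

        contrast: 0.1
        n_b: 1.33
        correlation: 0.0
        modes:
          mode1: {s_bulk: 325.25, decay_length: 39.63, sigma_lambda: 0.85}
          mode2: {s_bulk: 787.38, decay_length: 66.49, sigma_lambda: 1.3}
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "modes" not in raw:
        raise ParseError("config must be a mapping with a 'modes' section")
    modes = []
    for label, section in raw["modes"].items():
        unknown = set(section) - _MODE_KEYS
        if unknown:
            raise ParseError(f"unknown mode keys for {label}: {sorted(unknown)}")
        modes.append(SensorMode(label=str(label), **section))
    known = {
        "contrast",
        "n_b",
        "correlation",
        "kappa_threshold",
        "saturation_epsilon",
        "baseline_interval",
        "run_lm",
        "s_adlayer",
        "seed",
    }
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "contrast" not in kwargs:
        raise ParseError("config must state the analyte contrast (n_a - n_B)")
    if kwargs.get("baseline_interval") is not None:
        kwargs["baseline_interval"] = tuple(kwargs["baseline_interval"])
    extra = {k: v for k, v in raw.items() if k not in known and k != "modes"}
    return RunConfig(modes=modes, extra=extra, **kwargs)


def run_estimation(
    config: RunConfig, shift_timeseries: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Estimate (d̂, σ_d, Δn̂_B, σ_n) for every timepoint of a shift series.

    ``shift_timeseries`` holds one column per configured mode, either
    resonance shifts in nm or raw resonance wavelengths when
    ``config.baseline_interval`` is set (the mean wavelength over that
    half-open row interval is subtracted per mode).  Per timepoint the
    pipeline log-linearises the shifts, fuses them into a thickness MLE
    and then estimates the total index contrast; the reported bulk change
    is Δn̂_B = Δn̂ - (n_a - n_B).  Rows whose shifts are saturated or carry
    missing modes are flagged and skipped, not fatal.  When ``run_lm`` is
    set the 2x2 linear-model estimates are appended for comparison.
    """
    values = (
        shift_timeseries.to_numpy(dtype=float)
        if isinstance(shift_timeseries, pd.DataFrame)
        else np.atleast_2d(np.asarray(shift_timeseries, dtype=float))
    )
    k = len(config.modes)
    if values.shape[1] != k:
        raise InvalidParameterError(
            f"series has {values.shape[1]} columns but {k} modes are configured"
        )
    if config.baseline_interval is not None:
        lo, hi = config.baseline_interval
        baseline = values[lo:hi].mean(axis=0)
        values = values - baseline

    r_lambda = config.noise_covariance
    lm_matrix = None
    if config.run_lm:
        s_d = config.s_adlayer or [m.s_adlayer for m in config.modes]
        lm_matrix = SensitivityMatrix.from_sensitivities(
            [m.s_bulk for m in config.modes], s_d
        )
        sigma_n_lm, sigma_d_lm = lm_uncertainty(lm_matrix, r_lambda)

    rows = []
    for t, shifts in enumerate(values):
        row: dict = {"t": t, "flagged": False}
        if np.any(~np.isfinite(shifts)):
            row.update(flagged=True, d_hat=np.nan, sigma_d=np.nan,
                       dn_b_hat=np.nan, sigma_n=np.nan)
            rows.append(row)
            continue
        obs = ShiftObservation(shifts=shifts, covariance=r_lambda)
        try:
            log_obs = log_transform(obs, config.modes, config.n_a, config.n_b)
            est = estimate_thickness(log_obs)
            row.update(d_hat=est.d_hat, sigma_d=est.sigma_d)
            try:
                ri = estimate_ri_change(obs, max(est.d_hat, 0.0), config.modes)
                row.update(
                    dn_b_hat=ri.dn_hat - config.contrast, sigma_n=ri.sigma_n
                )
            except UnidentifiableError:
                # zero thickness carries no bulk-RI information; report
                # no change rather than failing the row
                row.update(dn_b_hat=0.0, sigma_n=np.nan)
        except SaturationError:
            row.update(flagged=True, d_hat=np.nan, sigma_d=np.nan,
                       dn_b_hat=np.nan, sigma_n=np.nan)
        if lm_matrix is not None:
            if np.any(~np.isfinite(shifts)):
                row.update(lm_dn=np.nan, lm_d=np.nan)
            else:
                dn_lm, d_lm = lm_estimate(shifts, lm_matrix)
                row.update(
                    lm_dn=dn_lm - config.contrast,
                    lm_d=d_lm,
                    lm_sigma_d=sigma_d_lm,
                    lm_sigma_n=sigma_n_lm,
                )
        rows.append(row)
    return pd.DataFrame(rows)
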