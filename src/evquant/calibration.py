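"""Spike-in calibration: TFI vs EV concentration, LOD, EV-equivalents.

A dilution series of vesicle spike-ins (particles per mL) is fit by
ordinary least squares on log10(TFI) vs log10(concentration) — the noise
in fluorescence dilution series is multiplicative, so the log-log line is
the natural model.  The limit of detection is the inverse-predicted
concentration at the blank mean + 3 SD (the conventional 3-sigma rule;
the multiplier is configurable, e.g. 3.3 or 10 for an LOQ).  The fitted
line also translates an arbitrary TFI into "EV equivalents per mL",
making cutoffs portable across instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class CalibrationCurve:
    points: list[tuple[float, float]]  # (concentration EV/mL, tfi)
    slope: float
    intercept: float
    fit_r2: float
    blank_mean: float
    blank_sd: float
    lod_concentration: float | None = None


def fit_calibration(
    points: Sequence[tuple[float, float]],
    blanks: Sequence[float],
    tfi_floor: float = 1e-9,
) -> CalibrationCurve:
    """Least-squares log10-log10 line through the dilution points.

    Non-positive TFIs (possible after an aggressive histogram cutoff) are
    floored at ``tfi_floor`` with a warning rather than dropped, so the
    design stays balanced.
    """
    pts = [(float(c), float(t)) for c, t in points]
    if len(pts) < 3:
        raise ValueError("at least 3 calibration points required")
    if len(blanks) < 2:
        raise ValueError("at least 2 blank replicates required")
    conc = np.array([c for c, _ in pts])
    tfi = np.array([t for _, t in pts])
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.any(tfi <= 0):
        warnings.warn("non-positive TFI floored for log fit", stacklevel=2)
        tfi = np.maximum(tfi, tfi_floor)
    x = np.log10(conc)
    y = np.log10(tfi)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    blanks_arr = np.asarray(blanks, dtype=float)
    return CalibrationCurve(
        points=pts,
        slope=float(slope),
        intercept=float(intercept),
        fit_r2=float(r2),
        blank_mean=float(np.mean(blanks_arr)),
        blank_sd=float(np.std(blanks_arr, ddof=1)),
    )


def tfi_to_ev_equivalents(curve: CalibrationCurve, tfi: float) -> float:
    """Invert the fitted map: concentration = 10^((log10 tfi - b) / a)."""
    if tfi <= 0:
        raise ValueError("tfi must be positive")
    if curve.slope == 0:
        raise ValueError("cannot invert a flat calibration curve")
    return float(10.0 ** ((np.log10(tfi) - curve.intercept) / curve.slope))


def predict_tfi(curve: CalibrationCurve, concentration: float) -> float:
    """Forward prediction of TFI at a concentration (EV/mL)."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    return float(10.0 ** (curve.slope * np.log10(concentration) + curve.intercept))


def estimate_lod(curve: CalibrationCurve, n_sd: float = 3.0) -> float:
    """Limit of detection: inverse prediction at blank_mean + n_sd * blank_sd.

    Warns when the critical TFI falls more than one decade below the
    fitted range (extrapolation).
    """
    tfi_star = curve.blank_mean + n_sd * curve.blank_sd
    if tfi_star <= 0:
        raise ValueError("blank statistics give a non-positive critical TFI")
    lod = tfi_to_ev_equivalents(curve, tfi_star)
    conc = np.array([c for c, _ in curve.points])
    if np.log10(lod) < np.log10(conc.min()) - 1.0:
        warnings.warn(
            "LOD is more than one decade below the fitted range (extrapolation)",
            stacklevel=2,
        )
    curve.lod_concentration = lod
    return lod
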