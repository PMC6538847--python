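"""Auxiliary quantitations: protein mass per cell, fluorescence-to-copies
calibration, and doubling times from OD600 growth curves.

The mass-per-cell measurement divides bulk protein mass by viable cell
count. Fluorescence calibration converts background-subtracted mean
pixel intensities of fluorescent-protein fusions to molecules/cell via a
single anchor protein whose absolute copy number is known from
quantitative Western blotting (MipZ in the original study). Doubling
times come from exponential regression of log-phase OD600 points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .quant import CellMassParams


@dataclass(frozen=True)
class CalibrationAnchor:
    """A protein with known copies/cell and measured background-subtracted
    fluorescence intensity, anchoring the intensity-to-copies conversion."""

    name: str
    anchor_copies: float
    anchor_intensity: float

    def __post_init__(self) -> None:
        if self.anchor_copies <= 0:
            raise ValueError("anchor_copies must be positive")
        if self.anchor_intensity <= 0:
            raise ValueError("anchor_intensity must be positive")


@dataclass
class DoublingTimeFit:
    doubling_time_h: float
    slope: float           # 1/h, on ln(OD)
    intercept: float
    r_squared: float
    no_growth: bool = False


def mass_per_cell(total_protein_mass_g: float, viable_cells: float,
                  medium: str = "") -> CellMassParams:
    """Average protein mass per cell from a bulk measurement."""
    if total_protein_mass_g <= 0:
        raise ValueError("protein mass must be positive")
    if viable_cells <= 0:
        raise ValueError("viable cell count must be positive")
    return CellMassParams(total_protein_mass_g / viable_cells, medium=medium)


def mass_per_cell_replicates(masses_g, cell_counts,
                             medium: str = "") -> CellMassParams:
    """Mean +/- sd of per-replicate mass-per-cell values."""
    per_rep = [mass_per_cell(m, n).mass_per_cell
               for m, n in zip(masses_g, cell_counts, strict=True)]
    return CellMassParams(float(np.mean(per_rep)),
                          sd=float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0,
                          medium=medium)


def yfp_to_molecules(intensity, background: float,
                     anchor: CalibrationAnchor):
    """Convert fluorescence intensity to molecules/cell through the anchor.

    molecules = (intensity - background) * anchor_copies / anchor_intensity.
    Intensities that fall below background clip to zero (reported, not
    negative). The anchor intensity must already be background-subtracted
    with the same background.
    """
    net = np.asarray(intensity, dtype=float) - background
    clipped = net < 0
    molecules = np.clip(net, 0.0, None) * anchor.anchor_copies / anchor.anchor_intensity
    if np.isscalar(intensity) or np.ndim(intensity) == 0:
        return float(molecules), bool(clipped)
    return molecules, clipped


def doubling_time(times_h, od600, window: tuple[float, float] | None = None
                  ) -> DoublingTimeFit:
    """Doubling time by least squares on ln(OD600) vs time.

    ``window`` restricts the fit to log-phase time points (inclusive
    bounds, hours); the doubling time is ln(2)/slope. A non-positive
    slope is flagged as no growth rather than raised.
    """
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, od = t[mask], od[mask]
    if t.size < 3:
        raise ValueError("need at least 3 points in the fitted window")
    if np.any(od <= 0):
        raise ValueError("OD600 must be positive within the fitted window")
    fit = stats.linregress(t, np.log(od))
    if fit.slope <= 0:
        return DoublingTimeFit(float("inf"), fit.slope, fit.intercept,
                               fit.rvalue ** 2, no_growth=True)
    return DoublingTimeFit(np.log(2) / fit.slope, fit.slope, fit.intercept,
                           fit.rvalue ** 2)


def pick_log_phase_window(times_h, od600, min_points: int = 4
                          ) -> tuple[float, float]:
    """Automatic log-phase window: the contiguous run of >= ``min_points``
    maximizing R^2 of the exponential fit. Provided as a convenience; by
    default callers choose the window by inspection."""
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    best, best_r2, best_len = None, -np.inf, 0
    for i in range(len(t) - min_points + 1):
        for j in range(i + min_points, len(t) + 1):
            if np.any(od[i:j] <= 0):
                continue
            fit = stats.linregress(t[i:j], np.log(od[i:j]))
            r2 = fit.rvalue ** 2
            if fit.slope <= 0:
                continue
            # prefer the longest window among (numerically) tied fits
            if r2 > best_r2 + 1e-12 or (abs(r2 - best_r2) <= 1e-12
                                        and j - i > best_len):
                best_r2, best_len, best = r2, j - i, (t[i], t[j - 1])
    if best is None:
        raise ValueError("no growing window found")
    return best


def growth_enhancement(t_control_h: float, t_treated_h: float) -> float:
    """Percent faster doubling of the treated culture vs control:
    100 * (t_control - t_treated) / t_control."""
    if t_control_h <= 0 or t_treated_h <= 0:
        raise ValueError("doubling times must be positive")
    return 100.0 * (t_control_h - t_treated_h) / t_control_h
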