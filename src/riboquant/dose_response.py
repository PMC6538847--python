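"""Riboswitch repression curves: reporter intensity vs ligand concentration.

A translational OFF riboswitch shuts down reporter expression as ligand
accumulates. Intensity follows the decreasing hyperbola

    I(c) = i_inf + (i0 - i_inf) * K / (K + c)

with i0 the intensity at zero ligand, i_inf the floor at saturation, and
K the half-repression concentration K_1/2: at c = K the curve passes the
midpoint (i0 + i_inf) / 2. Fitting is nonlinear least squares with a
multi-start grid on K to avoid local minima on shallow curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

#: Multi-start grid for K_1/2 initialization, nM.
K_INIT_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class DoseResponseFit:
    k_half: float
    i0: float
    i_inf: float
    r_squared: float
    converged: bool = True
    increasing: bool = False   # data trend up with ligand: not repression
    degenerate: bool = False   # constant data, R^2 undefined


def repression_model(c, i0, i_inf, k_half):
    c = np.asarray(c, dtype=float)
    return i_inf + (i0 - i_inf) * k_half / (k_half + c)


def _prepare(concentrations, intensities) -> pd.DataFrame:
    df = pd.DataFrame({"conc": np.asarray(concentrations, dtype=float),
                       "intensity": np.asarray(intensities, dtype=float)})
    if np.any(df["conc"] < 0):
        raise ValueError("concentrations must be non-negative")
    means = df.groupby("conc", as_index=False)["intensity"].mean()
    if len(means) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    return means


def fit_repression(concentrations, intensities) -> DoseResponseFit:
    """Fit the repression hyperbola to (concentration, intensity) data.

    Replicates are averaged per concentration before fitting. Returns
    the best multi-start fit with R^2 = 1 - SS_res/SS_tot; monotone
    increasing data are fitted but flagged as not a repression curve,
    and constant data are flagged degenerate.
    """
    means = _prepare(concentrations, intensities)
    c, y = means["conc"].to_numpy(), means["intensity"].to_numpy()

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        logger.warning("constant intensities: R^2 undefined")
        return DoseResponseFit(np.nan, float(y[0]), float(y[0]), np.nan,
                               converged=False, degenerate=True)

    hi, lo = float(y.max()), float(y.min())
    span = max(hi - lo, 1e-12 * max(abs(hi), 1.0))
    best = None
    for k0 in K_INIT_GRID:
        try:
            popt, _ = curve_fit(
                repression_model, c, y, p0=[hi, lo, k0],
                bounds=([lo - span, lo - span, 1e-12],
                        [hi + span, hi + span, np.inf]),
                maxfev=20000)
        except RuntimeError:
            continue
        ss_res = float(np.sum((y - repression_model(c, *popt)) ** 2))
        if best is None or ss_res < best[0]:
            best = (ss_res, popt)
    if best is None:
        raise RuntimeError("dose-response fit failed to converge from any start")
    ss_res, (i0, i_inf, k_half) = best
    increasing = bool(np.polyfit(np.log1p(c), y, 1)[0] > 0 and i0 < i_inf)
    if increasing:
        logger.warning("intensity rises with ligand: not a repression curve")
    return DoseResponseFit(float(k_half), float(i0), float(i_inf),
                           1.0 - ss_res / ss_tot, increasing=increasing)


def predict(fit: DoseResponseFit, concentration):
    """Fitted intensity at a concentration; monotone non-increasing in c."""
    if np.any(np.asarray(concentration, dtype=float) < 0):
        raise ValueError("concentration must be non-negative")
    return repression_model(concentration, fit.i0, fit.i_inf, fit.k_half)


def read_dose_table(path) -> pd.DataFrame:
    """Read a TSV with columns conc_nM, intensity[, replicate]."""
    df = pd.read_csv(path, sep="\t")
    required = {"conc_nM", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"dose table must have columns {sorted(required)}")
    return df
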