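"""Linear R2*-iron calibration and parametric FeMRI map construction.

The relaxation rate of an aqueous iron solution grows linearly with iron
concentration over the working range, R2* = m C + b, so a table of reference
standards ([Fe], R2*) calibrates a line that inverts per-pixel rates into a
concentration map (the parametric FeMRI map).  Maps are then stratified at
the midpoint of the calibration range (0.15 mg/g for the default 0.0-0.3
range) into low- and high-iron pixels; the high stratum is what the
localized cluster analysis counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CalibrationError, DegenerateDesignError, InputError, StateError
from .relaxometry import R2StarMap

__all__ = [
    "IronCalibration",
    "FeMap",
    "STRATUM_UNDEFINED",
    "STRATUM_LOW",
    "STRATUM_HIGH",
    "fit_calibration",
    "apply_calibration",
    "stratify",
    "high_threshold",
]

STRATUM_UNDEFINED = -1
STRATUM_LOW = 0
STRATUM_HIGH = 1


@dataclass(frozen=True)
class IronCalibration:
    """Fitted R2* = m C + b line over a concentration range (mg iron(III)/g)."""

    slope: float  # s^-1 per (mg/g)
    intercept: float  # s^-1
    conc_range: tuple = (0.0, 0.3)
    r_squared: float = float("nan")

    @property
    def high_threshold(self) -> float:
        """Lower bound of the high-iron stratum: midpoint of the range."""
        lo, hi = self.conc_range
        return (lo + hi) / 2.0

    def concentration(self, r2star: np.ndarray) -> np.ndarray:
        """Invert the line: C = (R2* - b)/m, without clamping."""
        return (np.asarray(r2star, dtype=float) - self.intercept) / self.slope


@dataclass
class FeMap:
    """Per-pixel iron concentration raster with tumor mask and strata.

    ``iron`` is in mg iron(III)/g, clamped to ``conc_range`` on defined
    pixels and NaN elsewhere; ``strata`` is filled by :func:`stratify`
    (-1 undefined / 0 low / 1 high).
    """

    iron: np.ndarray
    tumor_mask: np.ndarray
    pixel_size: float  # mm
    conc_range: tuple = (0.0, 0.3)
    strata: Optional[np.ndarray] = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.iron)


def fit_calibration(
    standards: pd.DataFrame | np.ndarray,
    conc_range: tuple = (0.0, 0.3),
) -> IronCalibration:
    """Ordinary least-squares fit of R2* on concentration from standards.

    ``standards`` is a table with columns ``conc_mg_g`` and ``r2star_s``
    (or an (n, 2) array in that column order) holding at least two distinct
    concentrations.  Raises :class:`DegenerateDesignError` when all
    concentrations coincide and :class:`CalibrationError` when the fitted
    slope is not positive (rates must rise with iron).
    """
    if isinstance(standards, pd.DataFrame):
        conc = standards["conc_mg_g"].to_numpy(dtype=float)
        r2 = standards["r2star_s"].to_numpy(dtype=float)
    else:
        arr = np.asarray(standards, dtype=float)
        conc, r2 = arr[:, 0], arr[:, 1]
    if conc.size < 2:
        raise InputError("at least two standards are required")
    if np.ptp(conc) == 0:
        raise DegenerateDesignError("all standard concentrations are identical")
    lo, hi = conc_range
    if not lo < hi:
        raise InputError("conc_range must satisfy lo < hi")
    fit = stats.linregress(conc, r2)
    if fit.slope <= 0:
        raise CalibrationError(f"non-positive calibration slope {fit.slope:.4g}")
    return IronCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        conc_range=(float(lo), float(hi)),
        r_squared=float(fit.rvalue**2),
    )


def apply_calibration(
    r2map: R2StarMap,
    cal: IronCalibration,
    mask: Optional[np.ndarray] = None,
) -> FeMap:
    """Convert an R2* map to a parametric FeMRI concentration map.

    C = (R2* - b)/m on pixels that are inside ``mask`` (default: all) and
    have ``fit_ok``; values are clamped to the calibration range (negative
    concentrations saturate at the range floor, supra-range at the ceiling).
    Other pixels are undefined (NaN).
    """
    if mask is None:
        mask = np.ones(r2map.r2star.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != r2map.r2star.shape:
        raise InputError(
            f"mask shape {mask.shape} does not match map {r2map.r2star.shape}"
        )
    lo, hi = cal.conc_range
    defined = mask & r2map.fit_ok
    iron = np.full(r2map.r2star.shape, np.nan)
    iron[defined] = np.clip(cal.concentration(r2map.r2star[defined]), lo, hi)
    return FeMap(
        iron=iron,
        tumor_mask=mask,
        pixel_size=r2map.pixel_size,
        conc_range=(lo, hi),
    )


def stratify(femap: FeMap) -> FeMap:
    """Fill the low/high stratum labels of a calibrated map.

    The high-iron stratum starts at the midpoint of the concentration range
    (inclusive: a pixel exactly at the threshold is high); pixels below are
    low; undefined pixels stay undefined.  Returns the same map with
    ``strata`` filled.
    """
    threshold = (femap.conc_range[0] + femap.conc_range[1]) / 2.0
    strata = np.full(femap.iron.shape, STRATUM_UNDEFINED, dtype=np.int8)
    defined = femap.defined
    strata[defined & (femap.iron >= threshold)] = STRATUM_HIGH
    strata[defined & (femap.iron < threshold)] = STRATUM_LOW
    femap.strata = strata
    return femap


def high_threshold(conc_range: tuple = (0.0, 0.3)) -> float:
    """Lower bound of the high-iron stratum for a concentration range."""
    lo, hi = conc_range
    if not lo < hi:
        raise InputError("conc_range must satisfy lo < hi")
    return (lo + hi) / 2.0
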