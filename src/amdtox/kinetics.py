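"""Bioremediation kinetics: urease assay calibration, batch growth, and
metal-sequestration accounting.

Ureolytic consortia hydrolyse urea to ammonia and carbonate, raising the pH
of acidic drainage and precipitating dissolved metals as carbonates.  The
quantities tracked here are the ones a batch experiment reports: a
phenol-hypochlorite ammonium standard curve and urease units (1 U = 1 umol
urea hydrolysed per minute; two ammonia equivalents per urea), exponential
growth rate K (h^-1) and doubling time Td = ln 2 / K from ln(OD600) vs
time, sequestration efficiency SE = (MQM - SQ)/MQM * 100, and precipitate
yield as dry mass per culture volume.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "AmmoniumStandardCurve",
    "fit_ammonium_standard_curve",
    "urease_activity",
    "ExponentialGrowthModel",
    "exponential_growth_fit",
    "sequestration_efficiency",
    "precipitate_yield",
]


class AmmoniumStandardCurve(BaseEstimator, RegressorMixin):
    """Ordinary least-squares line through (NH4Cl concentration, absorbance).

    Fitted attributes: ``slope_`` (absorbance per uM), ``intercept_``,
    ``r_squared_``.  ``inverse`` maps an absorbance back to an ammonium
    concentration in uM.
    """

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        absorbance = np.asarray(y, dtype=float).ravel()
        if conc.size < 2:
            raise ValueError("standard curve needs at least two points")
        if np.unique(conc).size < 2:
            raise ValueError("standard concentrations are all identical (rank-deficient)")
        if conc.min() < 50 or conc.max() > 1000:
            warnings.warn(
                "standard concentrations outside the expected 50-1000 uM span",
                stacklevel=2,
            )
        res = stats.linregress(conc, absorbance)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        return self

    def predict(self, X):
        return self.slope_ * np.asarray(X, dtype=float) + self.intercept_

    def inverse(self, absorbance):
        """Absorbance -> ammonium concentration (uM)."""
        return (np.asarray(absorbance, dtype=float) - self.intercept_) / self.slope_


def fit_ammonium_standard_curve(concentrations_uM, absorbances):
    """OLS calibration line; returns (slope, intercept, R^2)."""
    curve = AmmoniumStandardCurve().fit(concentrations_uM, absorbances)
    return curve.slope_, curve.intercept_, curve.r_squared_


def urease_activity(
    absorbance: float,
    curve: AmmoniumStandardCurve,
    incubation_min: float,
    *,
    dilution: float = 1.0,
    ammonia_per_urea: float = 2.0,
) -> float:
    """Urease activity in U per ml of assayed sample.

    The calibration inverse gives ammonium in uM; divided by 1000 this is
    umol per ml of reaction.  Complete urea hydrolysis releases two ammonia
    equivalents per urea, so the urea turnover is ammonium / 2 (the
    stoichiometry is exposed for assays quenched after the first step).
    One unit hydrolyses 1 umol urea per minute.
    """
    if curve.slope_ <= 0:
        raise ValueError("standard-curve slope must be positive")
    if incubation_min <= 0:
        raise ValueError("incubation time must be positive")
    ammonium_uM = float(curve.inverse(absorbance))
    if ammonium_uM < 0:
        warnings.warn(
            "absorbance below the calibration intercept; activity floored at 0",
            stacklevel=2,
        )
        return 0.0
    ammonium_umol_per_ml = ammonium_uM / 1000.0
    urea_umol_per_ml = ammonium_umol_per_ml / ammonia_per_urea
    return urea_umol_per_ml / incubation_min * dilution


class ExponentialGrowthModel(BaseEstimator, RegressorMixin):
    """Exponential-phase growth fit: ln(OD600) regressed on time.

    Parameters
    ----------
    window : (float, float), optional
        Time interval (h) to fit over, e.g. ``(6, 18)`` for a culture with a
        6 h lag.  When omitted, the fit uses the maximum-slope contiguous
        run of at least ``min_points`` observations on the ln(OD) series.
    min_points : int, default 3
        Minimum observations in an automatically selected window.

    Attributes
    ----------
    K_ : float
        Specific growth rate (h^-1): the ln(OD) slope.
    Td_ : float
        Doubling time ln(2)/K (h); NaN when K <= 0 (no growth).
    window_ : (float, float)
        Time span actually fitted, echoed for the report.
    n_points_ : int
    """

    def __init__(self, window=None, min_points: int = 3):
        self.window = window
        self.min_points = min_points

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        od = np.asarray(y, dtype=float).ravel()
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        keep = od > 0
        t, od = t[keep], od[keep]
        if self.window is not None:
            lo, hi = self.window
            inside = (t >= lo) & (t <= hi)
            if inside.sum() < 2:
                raise ValueError("fewer than 2 positive-OD points inside the window")
            sel = np.flatnonzero(inside)
            sel = (sel[0], sel[-1])
        else:
            sel = self._max_slope_window(t, np.log(od))
        i, j = sel
        res = stats.linregress(t[i : j + 1], np.log(od[i : j + 1]))
        self.K_ = float(res.slope)
        self.Td_ = math.log(2) / self.K_ if self.K_ > 0 else math.nan
        if self.K_ <= 0:
            warnings.warn("no growth detected (K <= 0); Td reported as missing", stacklevel=2)
        self.window_ = (float(t[i]), float(t[j]))
        self.n_points_ = j - i + 1
        self.intercept_ = float(res.intercept)
        return self

    def _max_slope_window(self, t, ln_od):
        n = t.size
        m = min(self.min_points, n)
        if n < 2:
            raise ValueError("need at least 2 positive-OD points")
        m = max(m, 2)
        best, best_slope = None, -math.inf
        for i in range(0, n - m + 1):
            for j in range(i + m - 1, n):
                slope = stats.linregress(t[i : j + 1], ln_od[i : j + 1]).slope
                if slope > best_slope:
                    best, best_slope = (i, j), slope
        return best

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        return np.exp(self.intercept_ + self.K_ * t)


def exponential_growth_fit(time_h, od600, window=None) -> tuple[float, float]:
    """Thin wrapper: returns (K in h^-1, Td in h; Td is NaN when K <= 0)."""
    model = ExponentialGrowthModel(window=window).fit(time_h, od600)
    return model.K_, model.Td_


def sequestration_efficiency(mqm: float, sq: float) -> float:
    """SE = (MQM - SQ) / MQM * 100, clamped to [0, 100].

    MQM is the metal concentration in the medium before inoculation and SQ
    the supernatant concentration after incubation (same units).  SQ
    marginally above MQM (assay noise) clamps to 0 with a warning.
    """
    if not mqm > 0:
        raise ValueError(f"MQM must be > 0, got {mqm!r}")
    if sq < 0:
        raise ValueError(f"SQ must be >= 0, got {sq!r}")
    if sq > mqm:
        warnings.warn(
            f"supernatant concentration {sq} exceeds initial {mqm}; SE clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return (mqm - sq) / mqm * 100.0


def precipitate_yield(dry_mass_mg: float, culture_volume_ml: float) -> float:
    """Dry precipitate mass per culture volume (mg per ml)."""
    if not culture_volume_ml > 0:
        raise ValueError(f"culture volume must be > 0, got {culture_volume_ml!r}")
    if dry_mass_mg < 0:
        raise ValueError(f"dry mass must be >= 0, got {dry_mass_mg!r}")
    return dry_mass_mg / culture_volume_ml
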