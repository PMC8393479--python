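"""ELISA standard curves and per-donor CSF hemoglobin concentrations.

The calibrator series (serially diluted pure hemoglobin) is fitted with a
four-parameter logistic (4PL),

    A(c) = d + (a - d) / (1 + (c / c0)^b),

where ``a`` is the zero-concentration asymptote, ``d`` the saturation
asymptote, ``c0`` the inflection concentration and ``b`` the slope. Duplicate
absorbances are averaged before inversion; the inverse curve times the
dilution factor (1:10 by default) gives the sample concentration. Estimates
below the limit of detection (6.25 ng/mL) are censored *at* the LOD with a
flag — not set to zero or LOD/2 — which preserves the rank statistics used in
cohort comparisons while marking the uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LOD_NG_ML",
    "StandardCurve",
    "CsfSample",
    "fit_standard_curve",
    "absorbance_to_conc",
    "normalize_to_protein",
    "process_plate",
]

LOD_NG_ML = 6.25


def _four_pl(c, a, b, c0, d):
    return d + (a - d) / (1.0 + (c / c0) ** b)


@dataclass
class CsfSample:
    """One donor's assay-derived values."""

    donor: str
    group: str = ""
    hb_ng_ml: float = np.nan
    total_protein: float = np.nan
    hb_over_protein: float = np.nan
    censored_low: bool = False
    censored_high: bool = False


@dataclass
class StandardCurve:
    """Fitted calibration curve; use :meth:`fit` to construct one."""

    conc: np.ndarray
    absorbance: np.ndarray
    params: tuple[float, float, float, float]  # (a, b, c0, d)
    method: str = "4pl"
    residual_rms: float = 0.0

    @classmethod
    def fit(cls, conc, absorbance) -> "StandardCurve":
        """Least-squares 4PL fit; falls back to a log-log linear fit when the
        logistic fit fails to converge. Calibrator order is irrelevant.

        Raises if fewer than 4 points are given or if absorbance is not
        strictly monotone in concentration.
        """
        conc = np.asarray(conc, dtype=float)
        absorbance = np.asarray(absorbance, dtype=float)
        if conc.size < 4:
            raise ValueError("need at least 4 calibrator points")
        order = np.argsort(conc)
        c, a = conc[order], absorbance[order]
        if np.any(np.diff(c) <= 0):
            raise ValueError("duplicate calibrator concentrations")
        d = np.diff(a)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("calibrator absorbances are not monotone in "
                             "concentration; cannot build a standard curve")
        try:
            p0 = (a[0], 1.0, float(np.median(c)), a[-1])
            popt, _ = curve_fit(_four_pl, c, a, p0=p0, maxfev=20_000)
            fitted = _four_pl(c, *popt)
            # the fitted curve must stay monotone over the calibrated range
            if not np.all(np.diff(fitted) * np.sign(d[0]) > 0):
                raise RuntimeError("non-monotone 4PL fit")
            rms = float(np.sqrt(np.mean((fitted - a) ** 2)))
            return cls(c, a, tuple(float(x) for x in popt), "4pl", rms)
        except (RuntimeError, ValueError):
            # log-log linear fallback: log A = m log c + q
            m, q = np.polyfit(np.log(c), np.log(a), 1)
            fitted = np.exp(m * np.log(c) + q)
            rms = float(np.sqrt(np.mean((fitted - a) ** 2)))
            return cls(c, a, (float(m), float(q), 0.0, 0.0), "loglog", rms)

    def predict(self, conc):
        """Absorbance at the given concentration(s)."""
        conc = np.asarray(conc, dtype=float)
        if self.method == "4pl":
            return _four_pl(conc, *self.params)
        m, q = self.params[:2]
        return np.exp(m * np.log(conc) + q)

    def inverse(self, absorbance: float) -> float:
        """Concentration at the given absorbance; NaN outside the invertible
        range of the fitted curve."""
        if self.method == "loglog":
            m, q = self.params[:2]
            return float(np.exp((np.log(absorbance) - q) / m))
        a, b, c0, d = self.params
        if b == 0 or absorbance == d:
            return float("nan")
        ratio = (a - d) / (absorbance - d) - 1.0
        if not np.isfinite(ratio) or ratio <= 0:
            return float("nan")
        with np.errstate(invalid="ignore", over="ignore"):
            val = c0 * ratio ** (1.0 / b)
        return float(val) if np.isfinite(val) and val > 0 else float("nan")

    @property
    def inflection_conc(self) -> float:
        return self.params[2] if self.method == "4pl" else float("nan")


def fit_standard_curve(calibrators: pd.DataFrame) -> StandardCurve:
    """Fit from a calibrator table with ``conc`` and ``absorbance`` columns."""
    return StandardCurve.fit(calibrators["conc"], calibrators["absorbance"])


def absorbance_to_conc(duplicates: tuple[float, float], curve: StandardCurve,
                       dilution_factor: float = 10.0,
                       lod: float = LOD_NG_ML) -> tuple[float, bool, bool]:
    """Duplicate absorbances -> (hb_ng_ml, censored_low, censored_high).

    The duplicate pair is averaged first; the inverse-curve estimate times the
    dilution factor is the concentration. A raw estimate below ``lod`` is
    returned *as* ``lod`` with the low-censoring flag; an absorbance outside
    the curve's invertible range sets the high-censoring flag.
    """
    mean_abs = float(np.mean(duplicates))
    est = curve.inverse(mean_abs)
    if not np.isfinite(est):
        upper = float(np.max(curve.conc)) * dilution_factor
        return upper, False, True
    conc = est * dilution_factor
    if conc < lod:
        return lod, True, False
    return conc, False, False


def normalize_to_protein(sample: CsfSample) -> CsfSample:
    """Set ``hb_over_protein = hb / total_protein`` (in place; returned).

    Note: a cohort's median ratio is the median of per-donor ratios, not the
    ratio of the cohort medians — aggregate after normalizing.
    """
    if not np.isfinite(sample.total_protein) or sample.total_protein <= 0:
        raise ValueError("total_protein must be positive")
    sample.hb_over_protein = sample.hb_ng_ml / sample.total_protein
    return sample


def process_plate(plate: pd.DataFrame, calibrators: pd.DataFrame,
                  dilution_factor: float = 10.0,
                  lod: float = LOD_NG_ML) -> pd.DataFrame:
    """Plate readings -> per-donor table.

    ``plate`` columns: ``donor``, ``absorbance`` (two rows per donor =
    duplicates), optional ``group`` and ``total_protein``. Returns one row
    per donor with concentration and censoring flags.
    """
    curve = fit_standard_curve(calibrators)
    rows = []
    for donor, grp in plate.groupby("donor", sort=False):
        dup = tuple(grp["absorbance"].to_numpy()[:2])
        if len(dup) == 1:
            dup = (dup[0], dup[0])
        conc, lo, hi = absorbance_to_conc(dup, curve, dilution_factor, lod)
        row = {"donor": donor, "hb_ng_ml": conc,
               "censored_low": lo, "censored_high": hi}
        if "group" in grp:
            row["group"] = grp["group"].iloc[0]
        if "total_protein" in grp:
            tp = float(grp["total_protein"].iloc[0])
            row["total_protein"] = tp
            row["hb_over_protein"] = conc / tp if tp > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
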