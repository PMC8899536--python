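"""Esterification-assay analytics.

Standard-curve calibration of GC detector responses, conversion-ratio
arithmetic (percent of the initially supplied fatty acid converted to
its ethyl ester), optimization fold-improvements, and relative/residual
activity summaries for pH/temperature profiles and substrate-preference
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "StandardCurve",
    "StandardCurveRegressor",
    "fit_standard_curve",
    "quantify",
    "conversion_ratio",
    "fold_improvement",
    "relative_activity",
    "residual_activity",
    "preference_fold",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` with ties away from zero, as printed reports do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear calibration: response = slope * conc_mM + intercept."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be non-zero for an invertible curve")


class StandardCurveRegressor(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares calibration line for one analyte.

    ``fit`` takes concentrations (mM) and detector responses, with
    replicate measurements averaged per concentration before the fit;
    ``predict`` maps concentrations to expected responses and
    ``quantify`` inverts responses back to concentrations.

    Attributes
    ----------
    slope_, intercept_, r_squared_ : float
    curve_ : StandardCurve
    """

    def __init__(self, analyte: str = ""):
        self.analyte = analyte

    def fit(self, X, y) -> "StandardCurveRegressor":
        conc = np.asarray(X, dtype=float).ravel()
        resp = np.asarray(y, dtype=float).ravel()
        if conc.shape != resp.shape:
            raise ValueError("concentration and response lengths differ")
        # average replicates (repeated concentrations) before fitting
        df = pd.DataFrame({"conc": conc, "resp": resp}).groupby("conc", as_index=False).mean()
        if len(df) < 3:
            raise ValueError(
                f"need >= 3 distinct concentrations, got {len(df)}"
            )
        fit = stats.linregress(df["conc"], df["resp"])
        if fit.slope == 0:
            raise ValueError("degenerate calibration: zero slope")
        self.slope_ = float(fit.slope)
        self.intercept_ = float(fit.intercept)
        self.r_squared_ = float(fit.rvalue**2)
        self.curve_ = StandardCurve(self.analyte, self.slope_, self.intercept_, self.r_squared_)
        return self

    def predict(self, X) -> np.ndarray:
        conc = np.asarray(X, dtype=float)
        return self.slope_ * conc + self.intercept_

    def quantify(self, response) -> np.ndarray | float:
        return quantify(response, self.curve_)


def fit_standard_curve(dilutions, analyte: str = "") -> StandardCurve:
    """Fit a calibration line to (conc_mM, response) pairs.

    Replicates (repeated concentrations) are averaged before the OLS
    fit; at least three distinct concentrations are required.
    """
    arr = np.asarray(list(dilutions), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("dilutions must be (conc_mM, response) pairs")
    reg = StandardCurveRegressor(analyte=analyte).fit(arr[:, 0], arr[:, 1])
    return reg.curve_


def quantify(response, curve: StandardCurve, clip_negative: bool = True):
    """Invert the calibration: concentration = (response - intercept)/slope.

    Blank drift can push quantified concentrations slightly negative;
    those are clipped to 0 by default (disable with
    ``clip_negative=False`` to see the raw inversion).
    """
    if curve.slope == 0:
        raise ValueError("curve with zero slope is not invertible")
    resp = np.asarray(response, dtype=float)
    conc = (resp - curve.intercept) / curve.slope
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return conc.item() if conc.ndim == 0 else conc


def conversion_ratio(ester_mM, initial_acid_mM) -> np.ndarray | float:
    """Percent of the initially supplied acid converted to ester."""
    ester = np.asarray(ester_mM, dtype=float)
    acid = np.asarray(initial_acid_mM, dtype=float)
    if np.any(acid <= 0):
        raise ValueError("initial acid concentration must be positive")
    if np.any(ester < 0):
        raise ValueError("ester concentration must be non-negative")
    out = 100.0 * ester / acid
    return out.item() if out.ndim == 0 else out


def fold_improvement(after_pct: float, before_pct: float, rounded: bool = True) -> float:
    """Ratio of conversion after optimization to before.

    The printed report rounds half-up to two decimals; pass
    ``rounded=False`` for the raw ratio.
    """
    if before_pct <= 0:
        raise ValueError("baseline conversion must be positive")
    if after_pct < 0:
        raise ValueError("conversion must be non-negative")
    fold = after_pct / before_pct
    return round_half_up(fold) if rounded else fold


def relative_activity(activities, uncertainties=None):
    """Scale an activity profile to percent of its maximum.

    Uncertainties, when given, are scaled by the same factor so error
    bars keep their relative size.  Returns the scaled activities, or a
    (activities, uncertainties) pair when uncertainties are supplied.
    """
    act = np.asarray(activities, dtype=float)
    if act.size == 0 or np.all(act == 0):
        raise ValueError("activity profile needs at least one positive value")
    if np.any(act < 0):
        raise ValueError("activities must be non-negative")
    peak = act.max()
    scaled = 100.0 * act / peak
    if uncertainties is None:
        return scaled
    unc = np.asarray(uncertainties, dtype=float)
    if unc.shape != act.shape:
        raise ValueError("uncertainty length must match activity length")
    return scaled, 100.0 * unc / peak


def residual_activity(treated: float, control: float) -> float:
    """Activity after a stability incubation, percent of untreated control."""
    if control <= 0:
        raise ValueError("control activity must be positive")
    if treated < 0:
        raise ValueError("treated activity must be non-negative")
    return 100.0 * treated / control


def preference_fold(enzyme_conc: float, control_conc: float) -> float:
    """Product concentration with enzyme over the no-enzyme control."""
    if control_conc <= 0:
        raise ValueError("control concentration must be positive")
    if enzyme_conc < 0:
        raise ValueError("enzyme concentration must be non-negative")
    return enzyme_conc / control_conc


def analyze_assay(
    curve_table: pd.DataFrame,
    assay_table: pd.DataFrame,
    subtract_control: bool = False,
    control_sample: str = "NG",
) -> pd.DataFrame:
    """Quantify esters and compute conversion ratios for an assay table.

    ``curve_table`` has columns analyte, conc_mM, response (replicates
    as repeated rows); one calibration line is fitted per analyte.
    ``assay_table`` has columns sample_id, substrate_acid, ester,
    initial_acid_mM and either response (quantified through the ester's
    curve) or ester_mM (taken as-is); exactly one of the two per row.

    With ``subtract_control``, the ester concentration of the
    ``control_sample`` rows (enzyme-free blank) is subtracted per ester
    before the ratio, and the control rows are dropped from the output.

    Returns one row per assay measurement: sample_id, ester, ester_mM,
    conversion_pct (full precision) and conversion_pct_rounded.
    """
    curves = {
        analyte: fit_standard_curve(group[["conc_mM", "response"]].to_numpy(), analyte)
        for analyte, group in curve_table.groupby("analyte")
    }

    has_resp = "response" in assay_table.columns
    has_conc = "ester_mM" in assay_table.columns
    if not has_resp and not has_conc:
        raise ValueError("assay table needs a response or ester_mM column")

    rows = []
    for rec in assay_table.itertuples(index=False):
        resp = getattr(rec, "response", None) if has_resp else None
        direct = getattr(rec, "ester_mM", None) if has_conc else None
        resp_ok = resp is not None and not pd.isna(resp)
        direct_ok = direct is not None and not pd.isna(direct)
        if resp_ok == direct_ok:
            raise ValueError(
                f"row for {rec.sample_id}/{rec.ester}: exactly one of "
                "response and ester_mM must be given"
            )
        if direct_ok:
            ester_mM = float(direct)
        else:
            if rec.ester not in curves:
                raise ValueError(f"no standard curve for analyte {rec.ester!r}")
            ester_mM = float(quantify(resp, curves[rec.ester]))
        rows.append(
            {
                "sample_id": rec.sample_id,
                "ester": rec.ester,
                "initial_acid_mM": float(rec.initial_acid_mM),
                "ester_mM": ester_mM,
            }
        )
    out = pd.DataFrame(rows)

    if subtract_control:
        blanks = out[out["sample_id"] == control_sample].set_index("ester")["ester_mM"]
        out = out[out["sample_id"] != control_sample].copy()
        out["ester_mM"] = (
            out["ester_mM"] - out["ester"].map(blanks).fillna(0.0)
        ).clip(lower=0.0)

    out["conversion_pct"] = conversion_ratio(out["ester_mM"], out["initial_acid_mM"])
    out["conversion_pct_rounded"] = [round_half_up(v) for v in out["conversion_pct"]]
    return out.reset_index(drop=True)
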