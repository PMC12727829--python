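"""Weighted linear calibration, LOD/LOQ and the quantifiable range.

Calibration curves relate spiked peptide amount (x, pg or pg/ul) to the
light/heavy response ratio (y) by weighted least squares with 1/x weights,
the standard choice when response variance grows with concentration.  The
limit of detection follows the intercept-dispersion convention
``LOD = 3.3 * sigma / S`` (and ``LOQ = 10 * sigma / S``) with ``sigma`` the
standard deviation of the y-intercepts across replicate curves and ``S``
the mean slope; LLOQ/ULOQ are the lowest/highest levels whose replicate
back-calculation passes the accuracy CV rule (<= 20%, relaxed to <= 40% if
fewer than four levels pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationFit",
    "fit_curve",
    "lod_loq",
    "quant_range",
    "back_calculate",
    "calibrate_peptide",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    r2: float
    n_points: int


@dataclass
class CalibrationResult:
    peptide: str
    slope: float
    intercept: float
    r2: float
    lod: float
    loq: float
    lloq: float
    uloq: float
    flags: list[str] = field(default_factory=list)


def fit_curve(x, y, weighting: str = "one_over_x") -> CalibrationFit:
    """Weighted least-squares line through calibration points.

    With ``weighting="one_over_x"`` each point gets weight 1/x; zero-
    concentration (blank) points are excluded from the weighted fit with a
    warning since their weight is undefined.  r2 is computed on the
    weighted residuals.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if weighting == "one_over_x":
        if (x <= 0).any():
            warnings.warn("blank/zero-concentration points excluded from "
                          "1/x-weighted fit", stacklevel=2)
            y = y[x > 0]
            x = x[x > 0]
        w = 1.0 / x
    elif weighting == "none":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if np.unique(x).size < 2:
        raise ValueError("singular fit: need >= 2 distinct concentrations")

    # weighted normal equations
    sw = w.sum()
    xb = (w * x).sum() / sw
    yb = (w * y).sum() / sw
    sxx = (w * (x - xb) ** 2).sum()
    sxy = (w * (x - xb) * (y - yb)).sum()
    slope = sxy / sxx
    intercept = yb - slope * xb
    resid = y - (intercept + slope * x)
    ss_res = (w * resid**2).sum()
    ss_tot = (w * (y - yb) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationFit(float(slope), float(intercept), float(r2), int(x.size))


def lod_loq(replicate_fits: list[CalibrationFit]) -> tuple[float, float, list[str]]:
    """LOD and LOQ from replicate calibration curves.

    sigma is the sample SD of the y-intercepts, S the mean slope;
    LOD = 3.3 sigma/S, LOQ = 10 sigma/S (so LOQ/LOD = 10/3.3 exactly).
    A non-positive mean slope leaves both undefined, flagged.
    """
    if len(replicate_fits) < 2:
        raise ValueError("need >= 2 replicate curves for LOD/LOQ")
    intercepts = np.array([f.intercept for f in replicate_fits])
    slopes = np.array([f.slope for f in replicate_fits])
    sigma = intercepts.std(ddof=1)
    s_mean = slopes.mean()
    if s_mean <= 0:
        return np.nan, np.nan, ["nonpositive_mean_slope"]
    return (
        float(LOD_FACTOR * sigma / s_mean),
        float(LOQ_FACTOR * sigma / s_mean),
        [],
    )


def quant_range(
    back_calc: pd.DataFrame,
    cv_primary_pct: float = 20.0,
    cv_relaxed_pct: float = 40.0,
    min_levels: int = 4,
) -> tuple[float, float, list[str]]:
    """Accuracy-based LLOQ and ULOQ from replicate back-calculations.

    ``back_calc`` has columns ``level`` (nominal concentration) and
    ``back_calculated`` (one row per replicate).  A level passes when the
    replicate CV of its back-calculated concentrations is <= 20%; if fewer
    than ``min_levels`` levels pass, the rule is relaxed to <= 40%.  The
    LLOQ/ULOQ are the lowest/highest passing levels.
    """
    level_cv = (
        back_calc.groupby("level")["back_calculated"]
        .apply(lambda v: (v.std(ddof=1) / v.mean() * 100.0)
               if v.mean() != 0 and len(v) > 1 else 0.0)
        .sort_index()
    )
    flags: list[str] = []
    passing = level_cv[level_cv <= cv_primary_pct]
    if len(passing) < min_levels:
        passing = level_cv[level_cv <= cv_relaxed_pct]
        flags.append("cv_rule_relaxed_40pct")
    if passing.empty:
        return np.nan, np.nan, flags + ["no_level_passes"]
    return float(passing.index.min()), float(passing.index.max()), flags


def back_calculate(
    response: float,
    fit: CalibrationFit,
    observed_range: tuple[float, float] | None = None,
) -> tuple[float, str | None]:
    """Invert the calibration line: concentration from a response.

    Values outside the observed calibrant range are removed with a reason
    code (``below_range`` / ``above_range``) rather than reported.
    """
    if fit.slope == 0:
        raise ValueError("zero slope: cannot back-calculate")
    conc = (response - fit.intercept) / fit.slope
    if observed_range is not None:
        lo, hi = observed_range
        if conc < lo:
            return np.nan, "below_range"
        if conc > hi:
            return np.nan, "above_range"
    return float(conc), None


def calibrate_peptide(
    series: pd.DataFrame,
    peptide: str = "",
    weighting: str = "one_over_x",
    min_r2: float = 0.98,
) -> CalibrationResult:
    """Full calibration of one peptide from replicate dilution series.

    ``series`` has columns ``replicate``, ``level`` (nominal pg or pg/ul,
    > 0) and ``response`` (L/H ratio).  Fits each replicate curve,
    derives LOD/LOQ from the intercept dispersion, back-calculates every
    point against its own replicate curve and applies the accuracy rule
    for LLOQ/ULOQ.  A curve is reportable when >= 4 levels pass the
    accuracy rule and the pooled fit reaches ``min_r2``.
    """
    flags: list[str] = []
    fits = []
    bc_rows = []
    for _, rdf in series.groupby("replicate"):
        f = fit_curve(rdf["level"], rdf["response"], weighting)
        fits.append(f)
        for _, row in rdf.iterrows():
            if row["level"] <= 0:
                continue
            conc, _ = back_calculate(row["response"], f)
            bc_rows.append({"level": row["level"], "back_calculated": conc})
    pooled = fit_curve(series["level"], series["response"], weighting)
    lod, loq, lflags = lod_loq(fits)
    lloq, uloq, qflags = quant_range(pd.DataFrame(bc_rows))
    flags += lflags + qflags
    if pooled.r2 < min_r2:
        flags.append("low_r2")
    return CalibrationResult(
        peptide=peptide, slope=pooled.slope, intercept=pooled.intercept,
        r2=pooled.r2, lod=lod, loq=loq, lloq=lloq, uloq=uloq, flags=flags,
    )
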