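"""Concentration matching and assembly of the internal-standard mixture.

A dilution series of the heavy standard against a fixed plasma background
gives, per peptide, light/heavy ratios at each spike level; the endogenous-
equivalent concentration is the spike level at which that ratio crosses 1,
interpolated in log-log space.  Each peptide is then assigned to the
nearest concentration tier in log10 space, validated to lie within one
order of magnitude of its endogenous level, and the mixture totals are
book-kept in ng.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TIERS",
    "TierAssignment",
    "estimate_endogenous_level",
    "assign_tier",
    "compose_panel",
    "composition_totals",
]

#: default tier concentrations in pg/ul, covering 10 pg/ul - 2 ng/ul
DEFAULT_TIERS = (10.0, 100.0, 500.0, 2000.0)


@dataclass
class TierAssignment:
    peptide: str
    endogenous_equiv_pg_per_ul: float
    assigned_pg_per_ul: float
    tier: int
    flags: list[str]


def estimate_endogenous_level(
    responses: pd.DataFrame,
    screen_log10_window: float = 2.0,
) -> tuple[float, list[str]]:
    """Endogenous-equivalent concentration (pg/ul) of one peptide.

    ``responses`` has columns ``level_pg_per_ul``, ``light_signal``,
    ``heavy_signal`` (one row per spike level).  The light/heavy ratio is
    computed per level; the returned concentration is where the ratio
    equals 1, interpolated linearly in log10(level) vs log10(ratio) between
    the bracketing levels.  Levels whose ratio lies more than
    ``screen_log10_window`` decades from 1 are screened out first.

    Returns (estimate, flags); flags mark extrapolation at either boundary
    or an undetermined estimate (no detectable heavy signal).
    """
    flags: list[str] = []
    r = responses.dropna(subset=["heavy_signal"])
    r = r[r["heavy_signal"] > 0]
    if r.empty:
        return np.nan, ["undetermined_no_heavy_signal"]
    r = r.sort_values("level_pg_per_ul")
    levels = r["level_pg_per_ul"].to_numpy(float)
    ratio = (r["light_signal"] / r["heavy_signal"]).to_numpy(float)
    ok = np.isfinite(ratio) & (ratio > 0)
    levels, ratio = levels[ok], ratio[ok]
    if levels.size == 0:
        return np.nan, ["undetermined_no_heavy_signal"]

    in_window = np.abs(np.log10(ratio)) <= screen_log10_window
    if in_window.any():
        levels, ratio = levels[in_window], ratio[in_window]

    log_l, log_r = np.log10(levels), np.log10(ratio)
    if np.all(log_r > 0):
        # light exceeds heavy even at the highest spike
        flags.append("extrapolated_above_max_level")
        return float(levels[-1]), flags
    if np.all(log_r < 0):
        flags.append("extrapolated_below_min_level")
        return float(levels[0]), flags
    if np.any(log_r == 0):
        return float(levels[np.argmax(log_r == 0)]), flags
    # first sign change of log-ratio along increasing spike level
    idx = np.nonzero(np.diff(np.sign(log_r)) != 0)[0][0]
    x0, x1 = log_l[idx], log_l[idx + 1]
    y0, y1 = log_r[idx], log_r[idx + 1]
    cross = x0 - y0 * (x1 - x0) / (y1 - y0)
    return float(10.0 ** cross), flags


def assign_tier(
    endogenous_equiv: float,
    tiers: tuple[float, ...] = DEFAULT_TIERS,
    max_log10_mismatch: float = 1.0,
) -> tuple[float, int, list[str]]:
    """Assign the tier concentration nearest in log10 space.

    Ties go to the lower tier.  A flag is raised when the assigned tier is
    more than ``max_log10_mismatch`` decades from the endogenous level.
    Returns (tier concentration pg/ul, 1-based tier index, flags).
    """
    if not tiers:
        raise ValueError("tier list must not be empty")
    tiers = tuple(sorted(tiers))
    dist = np.abs(np.log10(np.asarray(tiers)) - np.log10(endogenous_equiv))
    i = int(np.argmin(dist))  # argmin takes the first = lower tier on ties
    flags = []
    if dist[i] > max_log10_mismatch:
        flags.append("out_of_one_log10")
    return tiers[i], i + 1, flags


def compose_panel(
    responses: pd.DataFrame,
    tiers: tuple[float, ...] = DEFAULT_TIERS,
) -> pd.DataFrame:
    """Estimate endogenous levels and assign tiers for every peptide.

    ``responses`` is a long table with columns ``peptide``,
    ``level_pg_per_ul``, ``light_signal``, ``heavy_signal``.  Returns the
    panel composition with one row per peptide.
    """
    rows = []
    for pep, pdf in responses.groupby("peptide", sort=True):
        est, flags = estimate_endogenous_level(pdf)
        if np.isnan(est):
            rows.append({
                "peptide": pep, "endogenous_equiv_pg_per_ul": np.nan,
                "pg_per_ul": np.nan, "tier": pd.NA,
                "flags": ";".join(flags),
            })
            continue
        conc, tier, tflags = assign_tier(est, tiers)
        rows.append({
            "peptide": pep, "endogenous_equiv_pg_per_ul": est,
            "pg_per_ul": conc, "tier": tier,
            "flags": ";".join(flags + tflags),
        })
    return pd.DataFrame(rows)


def composition_totals(
    comp: pd.DataFrame | None = None,
    equal_conc_pg: float | None = None,
    n_peptides: int | None = None,
    volume_ul: float = 1.0,
) -> float:
    """Total peptide mass (ng) of a standard mixture in ``volume_ul`` ul.

    Either pass a composition table with a ``pg_per_ul`` column, or the
    per-peptide amount of an equal-concentration mixture via
    ``equal_conc_pg`` (pg/ul) and ``n_peptides``.
    """
    if comp is not None:
        if comp.empty:
            return 0.0
        total_pg = float(comp["pg_per_ul"].sum()) * volume_ul
    else:
        if equal_conc_pg is None or n_peptides is None:
            raise ValueError("need a composition table or equal_conc_pg + n_peptides")
        total_pg = equal_conc_pg * n_peptides * volume_ul
    return total_pg / 1000.0
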