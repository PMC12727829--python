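"""Normalization and quality control of SIL-spiked quantification tables.

Two normalization strategies are provided.  ``norm_light`` divides every
endogenous (light) intensity on a platform by one scalar — the median of
all light intensities in that platform's study-pool runs.  ``ratio``
divides each light intensity by its matched heavy internal-standard (SIS)
intensity in the same run, which cancels any per-run multiplicative factor
shared by the two channels and thereby removes platform and injection
effects exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "completeness_filter",
    "median_normalize",
    "ratio_normalize",
    "cv",
    "select_quant_precursor",
    "fragment_distribution",
    "cross_method_foldchange",
    "rt_agreement",
]

#: normal-consistency constant for the scaled MAD
MAD_SCALE = 1.4826


def completeness_filter(
    table: pd.DataFrame,
    threshold: float = 2.0 / 3.0,
    channel: str = "L",
) -> list[str]:
    """Peptides detected in strictly more than ``threshold`` of the samples.

    Detection means a non-missing light intensity in a sample; the sample
    universe is all distinct ``sample_id`` values in the table.
    """
    df = table[table["channel"] == channel]
    n_samples = df["sample_id"].nunique()
    if n_samples == 0:
        raise ValueError("no samples in table")
    det = (
        df.dropna(subset=["intensity"])
        .groupby("modified_seq")["sample_id"]
        .nunique()
    )
    frac = det / n_samples
    return sorted(frac[frac > threshold].index)


def median_normalize(
    table: pd.DataFrame,
    pool_runs: dict[str, list[str]],
) -> pd.DataFrame:
    """Median normalization: one scalar factor per platform.

    The factor is the median of all endogenous (light) intensities in that
    platform's study-pool runs; every light intensity on the platform is
    divided by it.  Returns the light rows with a ``norm_light`` column.
    """
    light = table[table["channel"] == "L"].copy()
    factors = {}
    for platform, runs in pool_runs.items():
        pool = light[(light["platform_id"] == platform)
                     & (light["run_id"].isin(runs))]
        vals = pool["intensity"].dropna()
        if vals.empty:
            raise ValueError(f"no pool intensities for platform {platform!r}")
        factors[platform] = float(vals.median())
    light["norm_light"] = light["intensity"] / light["platform_id"].map(factors)
    return light


def ratio_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """SIL-ratio normalization: light / heavy per (precursor, run).

    The heavy partner is matched on (modified_seq, charge, run_id).  The
    ratio is emitted only where both channels are present and the heavy
    intensity is positive; otherwise it is missing — missingness is data,
    not failure.
    """
    key = ["run_id", "modified_seq", "charge"]
    light = table[table["channel"] == "L"].copy()
    heavy = (
        table[table["channel"] == "H"][key + ["intensity"]]
        .rename(columns={"intensity": "sis"})
        .drop_duplicates(subset=key)
    )
    out = light.merge(heavy, on=key, how="left")
    out["ratio"] = np.where(
        out["sis"].notna() & (out["sis"] > 0) & out["intensity"].notna(),
        out["intensity"] / out["sis"],
        np.nan,
    )
    return out


def cv(values, method: str = "robust") -> float:
    """Coefficient of variation in percent.

    ``robust``: scaled MAD (x1.4826 for normal consistency) over the
    median.  ``classic``: sample SD over the mean.  Returns NaN for fewer
    than two non-missing values.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 2:
        return np.nan
    if method == "robust":
        med = np.median(v)
        if med == 0:
            return np.nan
        return float(MAD_SCALE * np.median(np.abs(v - med)) / med * 100.0)
    if method == "classic":
        mean = v.mean()
        if mean == 0:
            return np.nan
        return float(v.std(ddof=1) / mean * 100.0)
    raise ValueError(f"unknown CV method {method!r}")


def select_quant_precursor(
    candidates: pd.DataFrame,
    cv_gate_pct: float = 40.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pick one quantification precursor per peptide.

    ``candidates`` has one row per candidate precursor with columns
    ``peptide``, ``precursor``, ``protein_group``, ``pool_cv_pct``,
    ``mean_intensity`` and optionally ``sil_profile`` (an array-like of
    the heavy-standard quantities across cohort samples, used for the
    same-protein trend check).

    Candidates with pool CV >= the gate (strictly less than 40% passes)
    are discarded; among survivors of a peptide the most abundant wins.
    For peptides of the same protein, the selected precursors' SIL
    profiles must agree in trend (non-negative Spearman correlation);
    disagreement is flagged, not dropped.  Peptides with no surviving
    candidate are reported unquantifiable.
    """
    passing = candidates[candidates["pool_cv_pct"] < cv_gate_pct]
    chosen = (
        passing.sort_values(["peptide", "mean_intensity"],
                            ascending=[True, False])
        .groupby("peptide", sort=True)
        .head(1)
        .copy()
    )
    chosen["flags"] = ""

    failed = sorted(set(candidates["peptide"]) - set(chosen["peptide"]))
    report = pd.DataFrame({
        "peptide": failed,
        "status": ["unquantifiable_cv_gate"] * len(failed),
    })

    if "sil_profile" in chosen.columns:
        for protein, grp in chosen.groupby("protein_group"):
            if len(grp) < 2:
                continue
            profiles = list(grp["sil_profile"])
            idx = list(grp.index)
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    rho = spearmanr(profiles[a], profiles[b],
                                    nan_policy="omit").statistic
                    if np.isfinite(rho) and rho < 0:
                        for j in (idx[a], idx[b]):
                            chosen.loc[j, "flags"] = "trend_disagreement"
    return chosen.reset_index(drop=True), report


def fragment_distribution(
    fragments: pd.DataFrame,
    max_fragments: int = 12,
) -> pd.Series:
    """Percentage profile of a precursor's fragment ions.

    ``fragments`` has columns ``fragment_id``, ``run_id``,
    ``fragment_intensity``.  The per-fragment median intensity over runs is
    taken, the top ``max_fragments`` fragments are kept and rescaled to
    sum to exactly 100%.
    """
    med = (
        fragments.dropna(subset=["fragment_intensity"])
        .groupby("fragment_id")["fragment_intensity"]
        .median()
        .sort_values(ascending=False)
        .head(max_fragments)
    )
    if med.empty:
        raise ValueError("no fragment intensities")
    return med / med.sum() * 100.0


def cross_method_foldchange(
    a: pd.DataFrame,
    b: pd.DataFrame,
    value_col: str = "ratio",
) -> tuple[pd.Series, float]:
    """Per-peptide median fold change between two normalized tables.

    For every peptide shared by ``a`` and ``b``, the fold change a/b is
    computed sample-wise and its median taken; the cohort summary is the
    median over peptides.  Tables need columns ``sample_id``,
    ``modified_seq`` and ``value_col``.
    """
    key = ["sample_id", "modified_seq"]
    merged = a[key + [value_col]].merge(
        b[key + [value_col]], on=key, suffixes=("_a", "_b")
    )
    merged = merged.dropna()
    if merged.empty:
        raise ValueError("no overlapping (sample, peptide) observations")
    fc = merged[f"{value_col}_a"] / merged[f"{value_col}_b"]
    per_peptide = fc.groupby(merged["modified_seq"]).median()
    return per_peptide, float(per_peptide.median())


def rt_agreement(table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Retention-time QC: light-heavy co-elution and per-platform RT CV.

    Returns (per-peptide median |RT_L - RT_H| in minutes, a per-
    (peptide, platform) RT CV table in percent, and summary medians).
    """
    key = ["run_id", "modified_seq", "charge"]
    light = table[table["channel"] == "L"][key + ["platform_id", "rt"]]
    heavy = table[table["channel"] == "H"][key + ["rt"]].rename(
        columns={"rt": "rt_h"}
    )
    pairs = light.merge(heavy, on=key, how="inner").dropna(subset=["rt", "rt_h"])
    diff = (pairs["rt"] - pairs["rt_h"]).abs()
    per_peptide = diff.groupby(pairs["modified_seq"]).median()

    rt_cv = (
        light.dropna(subset=["rt"])
        .groupby(["modified_seq", "platform_id"])["rt"]
        .apply(lambda v: cv(v, "classic"))
        .rename("rt_cv_pct")
        .reset_index()
    )
    summary = {
        "median_rt_diff_min": float(per_peptide.median()) if len(per_peptide) else np.nan,
        "median_rt_cv_pct": float(rt_cv["rt_cv_pct"].median()) if len(rt_cv) else np.nan,
    }
    return per_peptide, rt_cv, summary
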