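"""Cross-matrix / cross-platform statistical evaluation battery.

Per-peptide trend tests against an ordinal severity factor (Kendall's
tau-b with Benjamini-Hochberg adjustment within each dataset), paired
Wilcoxon signed-rank tests between matrices, agreement statistics between
platforms (two-way ANOVA intraclass correlations, Bland-Altman limits of
agreement with t-based confidence intervals), variance partitioning with
crossed random intercepts for platform and severity, KNN imputation,
composite-dataset construction and per-group regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kendall_trend",
    "bh_adjust",
    "trend_table",
    "paired_wilcoxon",
    "icc",
    "knn_impute",
    "variance_partition",
    "bland_altman",
    "composite_dataset",
    "group_regression",
    "pca_scores",
    "BlandAltmanResult",
]


def kendall_trend(values, groups) -> tuple[float, float]:
    """Kendall tau-b trend of ``values`` against ordinal ``groups``.

    Uses the tie-corrected normal approximation for the two-sided p-value
    at every sample size, matching standard trend-test practice for
    heavily tied ordinal factors.
    """
    v = np.asarray(values, float)
    g = np.asarray(groups, float)
    ok = np.isfinite(v) & np.isfinite(g)
    v, g = v[ok], g[ok]
    if v.size < 3 or np.unique(g).size < 2:
        raise ValueError("need >= 3 observations over >= 2 groups")
    if np.unique(v).size == 1:
        return np.nan, np.nan
    res = stats.kendalltau(g, v, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, float)
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def trend_table(
    table: pd.DataFrame,
    severity_order: list[str] | None = None,
    value_col: str = "ratio",
    group_col: str = "group",
    dataset_col: str | None = None,
) -> pd.DataFrame:
    """Per-peptide Kendall trend tests with within-dataset BH adjustment.

    ``severity_order`` fixes the ordinal coding (e.g. healthy < mild <
    severe < critical); otherwise groups are sorted lexicographically.
    When ``dataset_col`` is given, the FDR adjustment is performed within
    each dataset separately, as platforms are independent experiments.
    """
    df = table.dropna(subset=[value_col]).copy()
    if severity_order is not None:
        coding = {g: i for i, g in enumerate(severity_order)}
        df["_ord"] = df[group_col].map(coding)
    else:
        df["_ord"] = df[group_col].astype("category").cat.codes.astype(float)

    group_keys = ["modified_seq"] if dataset_col is None else [dataset_col, "modified_seq"]
    rows = []
    for keys, pdf in df.groupby(group_keys, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        try:
            tau, p = kendall_trend(pdf[value_col], pdf["_ord"])
        except ValueError:
            tau, p = np.nan, np.nan
        rows.append(dict(zip(group_keys, keys)) | {"tau": tau, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjust"] = np.nan
    adjust_within = [dataset_col] if dataset_col else []
    grouper = out.groupby(adjust_within) if adjust_within else [(None, out)]
    for _, grp in grouper:
        ok = grp["p"].notna()
        if ok.any():
            out.loc[grp.index[ok], "p_adjust"] = bh_adjust(grp.loc[ok, "p"])
    return out


def paired_wilcoxon(a, b, exact_max_n: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; the exact null distribution is used for
    n <= ``exact_max_n`` (without ties), otherwise the normal approximation
    with continuity correction.  All-zero differences leave the test
    undefined (NaN).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    d = d[d != 0]
    if d.size == 0:
        return np.nan
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= exact_max_n and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(res.pvalue)


def icc(matrix: pd.DataFrame | np.ndarray, model: str = "ICC3k") -> float:
    """Intraclass correlation from a samples x raters (platforms) matrix.

    Rows with any missing value are removed (listwise).  Both forms derive
    from the two-way ANOVA decomposition: ICC(3,k) — consistency of the
    average measurement under a mixed-effects model — is
    ``(MS_rows - MS_err) / MS_rows``; ICC(2,1) — absolute agreement of a
    single measurement under a random-effects model — additionally charges
    the rater variance.
    """
    x = np.asarray(matrix, float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 complete rows and >= 2 raters")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if model == "ICC3k":
        if ms_rows == 0:
            return np.nan
        return float((ms_rows - ms_err) / ms_rows)
    if model == "ICC21":
        denom = (ms_rows + (k - 1) * ms_err
                 + k * (ms_cols - ms_err) / n)
        if denom == 0:
            return np.nan
        return float((ms_rows - ms_err) / denom)
    raise ValueError(f"unknown ICC model {model!r}")


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """KNN imputation of a peptides x samples matrix.

    Following the transpose convention of expression-matrix imputation,
    samples are treated as observations and peptides as variables: the
    matrix is transposed, missing entries are replaced by the unweighted
    mean of the k nearest samples (Euclidean distance over co-observed
    coordinates, scaled by the number observed), and the result is
    transposed back.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if matrix.isna().all(axis=1).any():
        raise ValueError("every peptide needs at least one observed value")
    n_samples = matrix.shape[1]
    k_eff = min(k, max(n_samples - 1, 1))
    imputer = KNNImputer(n_neighbors=k_eff, weights="uniform")
    filled = imputer.fit_transform(matrix.T.to_numpy(float)).T
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


@dataclass
class VarianceFractions:
    peptide: str
    frac_platform: float
    frac_severity: float
    frac_residual: float
    flags: list[str]


def _varcomp_moments(y, platform, severity) -> tuple[float, float, float]:
    """Method-of-moments variance components for two crossed factors."""
    df = pd.DataFrame({"y": y, "p": platform, "s": severity})
    total = float(df["y"].var(ddof=1))
    vp = max(float(df.groupby("p")["y"].transform("mean").var(ddof=1)), 0.0)
    vs = max(float(df.groupby("s")["y"].transform("mean").var(ddof=1)), 0.0)
    ve = max(total - vp - vs, 1e-12)
    return vp, vs, ve


def variance_partition(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    platform_col: str = "platform",
    severity_col: str = "severity",
) -> pd.DataFrame:
    """Per-peptide variance fractions for platform and severity.

    For every peptide (row of the complete ``matrix``; impute first) a
    linear mixed model with crossed random intercepts,
    ``value ~ (1 | platform) + (1 | severity)``, is fitted by REML and the
    three variance components are reported as fractions of their sum.
    Non-convergence falls back to a method-of-moments estimate, flagged.
    ``design`` is indexed by the matrix columns (samples).
    """
    design = design.loc[list(matrix.columns)]
    platform = design[platform_col].astype(str).to_numpy()
    severity = design[severity_col].astype(str).to_numpy()
    if len(set(platform)) < 2 or len(set(severity)) < 2:
        raise ValueError("need >= 2 levels of each factor")
    base = pd.DataFrame({
        "platform": platform,
        "severity": severity,
        "g": np.ones(len(platform)),
    })
    vc = {"platform": "0 + C(platform)", "severity": "0 + C(severity)"}

    rows = []
    for pep, vals in matrix.iterrows():
        df = base.copy()
        df["y"] = vals.to_numpy(float)
        flags = []
        try:
            model = sm.MixedLM.from_formula(
                "y ~ 1", groups="g", vc_formula=vc, data=df
            )
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True, method="powell", maxiter=500)
            vp, vs = float(fit.vcomp[0]), float(fit.vcomp[1])
            ve = float(fit.scale)
            if not fit.converged or not np.isfinite([vp, vs, ve]).all():
                raise ValueError("non-converged or non-finite components")
        except Exception:
            vp, vs, ve = _varcomp_moments(df["y"], platform, severity)
            flags.append("moment_fallback")
        tot = vp + vs + ve
        rows.append({
            "peptide": pep,
            "frac_platform": vp / tot,
            "frac_severity": vs / tot,
            "frac_residual": ve / tot,
            "flags": ";".join(flags),
        })
    return pd.DataFrame(rows).set_index("peptide")


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    n: int


def bland_altman(x, y, loa_z: float = 1.96, ci: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements.

    Differences d = x - y give the bias (mean), limits of agreement
    bias +/- 1.96 sd(d), and t-based 95% confidence intervals: the bias CI
    uses SE = sd/sqrt(n); the LoA CIs use the standard
    SE = sd * sqrt(3/n) approximation, both with n-1 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    n = d.size
    if n < 2:
        raise ValueError("need >= 2 complete pairs")
    bias = d.mean()
    sd = d.std(ddof=1)
    loa_low, loa_high = bias - loa_z * sd, bias + loa_z * sd
    t = stats.t.ppf(0.5 + ci / 2, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        bias=float(bias), sd_diff=float(sd),
        loa_low=float(loa_low), loa_high=float(loa_high),
        ci_bias=(float(bias - t * se_bias), float(bias + t * se_bias)),
        ci_loa_low=(float(loa_low - t * se_loa), float(loa_low + t * se_loa)),
        ci_loa_high=(float(loa_high - t * se_loa), float(loa_high + t * se_loa)),
        n=n,
    )


def composite_dataset(
    tables: dict[str, pd.DataFrame],
    holdout: str,
    seed: int,
    value_col: str = "ratio",
) -> pd.DataFrame:
    """Assemble a cross-platform composite cohort, excluding a holdout.

    For each sample one non-holdout platform is drawn uniformly at random
    (seeded) and that platform's normalized values for the sample are
    taken; the sample set — and hence the severity distribution — is
    identical to the source cohort, and the holdout platform contributes
    nothing, avoiding leakage when the composite is later compared to it.
    """
    rng = np.random.default_rng(seed)
    donors = {p: t for p, t in tables.items() if p != holdout}
    if not donors:
        raise ValueError("no non-holdout platforms")
    sample_ids = sorted(
        set().union(*(set(t["sample_id"]) for t in tables.values()))
    )
    pieces = []
    for sid in sample_ids:
        available = sorted(
            p for p, t in donors.items() if (t["sample_id"] == sid).any()
        )
        if not available:
            raise ValueError(f"sample {sid!r} absent from all non-holdout platforms")
        pick = available[rng.integers(len(available))]
        piece = donors[pick][donors[pick]["sample_id"] == sid].copy()
        piece["source_platform"] = pick
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def group_regression(
    merged: pd.DataFrame,
    x_col: str,
    y_col: str,
    group_col: str = "group",
    peptide_col: str = "modified_seq",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-peptide per-group OLS of method B on method A.

    Fits y ~ x for every (peptide, group) cell with >= ``min_pairs``
    complete pairs and non-zero x variance; reports slope and r2.
    """
    rows = []
    for (pep, grp), cell in merged.groupby([peptide_col, group_col], sort=True):
        cell = cell.dropna(subset=[x_col, y_col])
        x = cell[x_col].to_numpy(float)
        y = cell[y_col].to_numpy(float)
        if x.size < min_pairs or np.var(x) == 0:
            rows.append({peptide_col: pep, group_col: grp,
                         "slope": np.nan, "r2": np.nan, "n": x.size})
            continue
        res = stats.linregress(x, y)
        rows.append({peptide_col: pep, group_col: grp,
                     "slope": float(res.slope),
                     "r2": float(res.rvalue**2), "n": x.size})
    return pd.DataFrame(rows)


def pca_scores(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA scores of a samples x peptides matrix via SVD.

    Returns (scores DataFrame indexed like ``matrix``, explained-variance
    fractions, non-increasing and summing to <= 1).  The matrix must be
    complete; impute first.
    """
    x = matrix.to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute first")
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), explained
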