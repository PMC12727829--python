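"""Precursor ranking and panel-selection filters.

A precursor (modified sequence + charge) is scored within each study-pool
series by its weight ``PPres / CV`` — detection frequency over coefficient
of variation, i.e. presence times signal-to-noise.  Weights are ranked
ascending (best precursor gets relative rank 1), relative ranks are averaged
over the studies where the precursor was observed, and the panel keeps
proteotypic precursors with mean relative rank >= 0.5 observed in at least
half the studies and at least two blood matrices, at most three peptides
per protein.  A physicochemical pass then removes peptides that are poor
synthesis / stability candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "study_precursor_stats",
    "weight_and_rank",
    "aggregate_relrank",
    "eligibility_filter",
    "physicochemical_filter",
    "peptide_properties",
    "hydropathy",
    "net_charge",
    "KYTE_DOOLITTLE",
    "MISSED_CLEAVAGE_MOTIFS",
]

#: Kyte-Doolittle hydropathy index per residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Lehninger pKa values for ionizable groups.
PKA = {
    "nterm": 9.69, "cterm": 2.34,
    "K": 10.53, "R": 12.48, "H": 6.0,
    "D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07,
}
_BASIC = {"K", "R", "H"}
_ACIDIC = {"D", "E", "C", "Y"}

#: dipeptide motifs marking likely missed / aberrant tryptic cleavage
MISSED_CLEAVAGE_MOTIFS = ("KK", "KR", "RR", "RK", "KP", "RP")


def _check_canonical(seq: str) -> None:
    bad = set(seq) - set(KYTE_DOOLITTLE)
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)} in {seq!r}")


def hydropathy(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy index (GRAVY) of a peptide."""
    _check_canonical(seq)
    return sum(KYTE_DOOLITTLE[r] for r in seq) / len(seq)


def net_charge(seq: str, pH: float = 7.0) -> float:
    """Peptide net charge at ``pH`` via Henderson-Hasselbalch.

    Sums the fractional charge of the free termini and every ionizable side
    chain using the Lehninger pKa set.
    """
    _check_canonical(seq)
    def frac_pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def frac_neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    charge = frac_pos(PKA["nterm"]) + frac_neg(PKA["cterm"])
    for r in seq:
        if r in _BASIC:
            charge += frac_pos(PKA[r])
        elif r in _ACIDIC:
            charge += frac_neg(PKA[r])
    return charge


# ---------------------------------------------------------------------------
# per-study statistics and ranking


def study_precursor_stats(table: pd.DataFrame, channel: str = "L") -> pd.DataFrame:
    """Per-(precursor, study) presence and CV from a study-pool series.

    ``p_pres`` is the fraction of the study's runs in which the precursor
    has a non-missing intensity; ``cv`` is sample SD / mean over those
    intensities (linear scale).  Precursors never observed in a study are
    omitted.  Requires >= 2 runs per study.
    """
    df = table[table["channel"] == channel].copy()
    df["precursor"] = df["modified_seq"] + "/" + df["charge"].astype(str)

    rows = []
    for study, sdf in df.groupby("study_id", sort=True):
        runs = sdf["run_id"].unique()
        n_runs = len(runs)
        if n_runs < 2:
            raise ValueError(
                f"study {study!r} has {n_runs} run(s); CV needs >= 2"
            )
        matrix = sdf["matrix"].iloc[0]
        obs = sdf.dropna(subset=["intensity"])
        for prec, pdf in obs.groupby("precursor", sort=True):
            vals = pdf["intensity"].to_numpy(float)
            if len(vals) == 0:
                continue
            mean = vals.mean()
            sd = vals.std(ddof=1) if len(vals) > 1 else np.nan
            rows.append({
                "precursor": prec,
                "study_id": study,
                "matrix": matrix,
                "protein_group": pdf["protein_group"].iloc[0],
                "stripped_seq": pdf["stripped_seq"].iloc[0],
                "p_pres": len(vals) / n_runs,
                "cv": sd / mean if mean > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def weight_and_rank(stats: pd.DataFrame) -> pd.DataFrame:
    """Fill weight, rank and relative rank within each study.

    Weight = p_pres / cv (infinite for cv = 0: perfectly reproducible
    precursors must not be discarded).  Ranks ascend with weight — the
    largest weight gets rank = max rank, hence relative rank 1 — with
    average ranks on ties.
    """
    out = stats.copy()
    with np.errstate(divide="ignore"):
        out["weight"] = np.where(
            out["cv"].to_numpy(float) == 0.0,
            np.inf,
            out["p_pres"].to_numpy(float) / out["cv"].to_numpy(float),
        )
    out["rank"] = np.nan
    out["rel_rank"] = np.nan
    for _, idx in out.groupby("study_id").groups.items():
        w = out.loc[idx, "weight"].to_numpy(float)
        # single-observation precursors have undefined CV -> rank lowest
        w = np.where(np.isnan(w), -np.inf, w)
        r = rankdata(w, method="average")
        out.loc[idx, "rank"] = r
        out.loc[idx, "rel_rank"] = r / r.max()
    return out


def aggregate_relrank(
    per_study: pd.DataFrame,
    proteotypic: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Aggregate per-study relative ranks across the study pool.

    The mean relative rank is taken over the studies where the precursor
    appears; absence is handled by the project-count filter, not by
    zero-imputation.  ``proteotypic`` maps stripped sequence -> bool from
    the annotation table (defaults to True when not supplied).
    """
    agg = (
        per_study.groupby("precursor")
        .agg(
            rel_rank_mean=("rel_rank", "mean"),
            n_projects=("study_id", "nunique"),
            n_matrices=("matrix", "nunique"),
            protein_group=("protein_group", "first"),
            stripped_seq=("stripped_seq", "first"),
        )
        .reset_index()
    )
    if proteotypic is None:
        agg["proteotypic"] = True
    else:
        mapping = dict(proteotypic)
        agg["proteotypic"] = agg["stripped_seq"].map(
            lambda s: bool(mapping.get(s, False))
        )
    return agg


def eligibility_filter(
    agg: pd.DataFrame,
    min_relrank: float = 0.5,
    min_projects: int | None = None,
    min_matrices: int = 2,
    max_peptides_per_protein: int = 3,
    n_studies: int | None = None,
) -> pd.DataFrame:
    """Apply the panel eligibility cutoffs and per-protein top-k rule.

    Keeps proteotypic precursors with mean relative rank >= ``min_relrank``
    (inclusive), observed in at least ``min_projects`` studies (default:
    half the studies, rounded up) and ``min_matrices`` blood matrices; then
    retains at most ``max_peptides_per_protein`` peptides per protein group,
    preferring higher mean relative rank, then more projects, then
    lexicographic sequence (deterministic tie-break).
    """
    if min_projects is None:
        if n_studies is None:
            n_studies = int(agg["n_projects"].max())
        min_projects = math.ceil(n_studies / 2)
    keep = agg[
        agg["proteotypic"]
        & (agg["rel_rank_mean"] >= min_relrank)
        & (agg["n_projects"] >= min_projects)
        & (agg["n_matrices"] >= min_matrices)
    ].copy()
    keep = keep.sort_values(
        ["protein_group", "rel_rank_mean", "n_projects", "stripped_seq"],
        ascending=[True, False, False, True],
    )
    keep = keep.groupby("protein_group", sort=False).head(max_peptides_per_protein)
    return keep.reset_index(drop=True)


# ---------------------------------------------------------------------------
# physicochemical filtering


@dataclass
class PeptideProperties:
    stripped_seq: str
    length: int
    hydropathy: float
    net_charge: float
    missed_cleavage_motif: bool
    has_cys: bool
    nterm_gln: bool
    synthesis_score: float | None = None


def peptide_properties(seq: str, pH: float = 7.0) -> PeptideProperties:
    """Compute the filterable physicochemical properties of one peptide."""
    _check_canonical(seq)
    return PeptideProperties(
        stripped_seq=seq,
        length=len(seq),
        hydropathy=hydropathy(seq),
        net_charge=net_charge(seq, pH),
        missed_cleavage_motif=any(m in seq for m in MISSED_CLEAVAGE_MOTIFS),
        has_cys="C" in seq,
        nterm_gln=seq.startswith("Q"),
    )


def physicochemical_filter(
    seqs: list[str],
    exceptions: list[str] | None = None,
    min_length: int = 6,
    max_length: int = 25,
) -> tuple[list[str], pd.DataFrame]:
    """Drop peptides unsuited as synthesis standards; report every flag.

    Exclusion reasons: length outside [6, 25], a missed-cleavage motif
    (KK/KR/RR/RK/KP/RP), cysteine, or N-terminal glutamine — all prone to
    poor synthesis or chemical modification.  Peptides in ``exceptions``
    are retained regardless, with their flags still recorded.
    """
    exceptions = set(exceptions or [])
    kept: list[str] = []
    rows = []
    for seq in seqs:
        p = peptide_properties(seq)
        flags = []
        if not (min_length <= p.length <= max_length):
            flags.append("length")
        if p.missed_cleavage_motif:
            flags.append("missed_cleavage_motif")
        if p.has_cys:
            flags.append("cysteine")
        if p.nterm_gln:
            flags.append("nterm_gln")
        excepted = seq in exceptions
        retained = not flags or excepted
        if retained:
            kept.append(seq)
        rows.append({
            "stripped_seq": seq,
            "flags": ";".join(flags),
            "exception": excepted,
            "retained": retained,
        })
    return kept, pd.DataFrame(rows)
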