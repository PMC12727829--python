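"""Seeded synthetic-data generators with known ground truth.

Three generators mirror the data structures the toolkit consumes:

- multi-study QC-pool series with per-precursor presence probabilities and
  intensity CVs (for the selection workflow),
- a multi-platform clinical cohort with an ordinal severity factor,
  multiplicative monotone severity effects on a subset of peptides,
  per-platform scale/noise, a shared per-run factor, a heavy channel
  spiked at known amounts, and missingness,
- replicate dilution/calibration series with known slope, intercept
  dispersion and noise.

Intensities are log-normal — plasma peptide intensities span several
orders of magnitude — and every generator is bit-reproducible given
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimTruth",
    "simulate_study_pools",
    "simulate_cohort",
    "simulate_calibration",
]

_MATRICES = ("EDTA", "citrate", "heparin", "serum")


@dataclass
class SimTruth:
    """Ground truth underlying a simulated dataset."""

    planted_good: list[str] = field(default_factory=list)
    planted_bad: list[str] = field(default_factory=list)
    presence: dict[str, float] = field(default_factory=dict)
    cv: dict[str, float] = field(default_factory=dict)
    platform_scale: dict[str, float] = field(default_factory=dict)
    severity_effect: dict[str, float] = field(default_factory=dict)
    spike_amount: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0


def _precursor_frame(n_precursors: int, rng: np.random.Generator,
                     n_proteins: int | None = None) -> pd.DataFrame:
    """Deterministic peptide/precursor identities."""
    n_proteins = n_proteins or max(n_precursors // 2, 1)
    residues = np.array(list("ACDEFGHILMNPSTVWY"))  # no K/R/Q internally
    seqs = []
    for i in range(n_precursors):
        body = "".join(rng.choice(residues, size=9))
        seqs.append(body + ("K" if i % 2 == 0 else "R"))
    return pd.DataFrame({
        "stripped_seq": seqs,
        "modified_seq": seqs,
        "charge": np.where(np.arange(n_precursors) % 3 == 0, 3, 2),
        "protein_group": [f"PROT{i % n_proteins:04d}" for i in range(n_precursors)],
    })


def simulate_study_pools(
    n_studies: int = 6,
    n_runs_per_study: int = 8,
    n_precursors: int = 200,
    frac_good: float = 0.3,
    frac_bad: float = 0.3,
    good_presence: float = 0.98,
    good_cv: float = 0.12,
    bad_presence: float = 0.55,
    bad_cv: float = 0.9,
    mid_presence: float = 0.85,
    mid_cv: float = 0.45,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Multi-study QC-pool series with planted good/bad precursors.

    "Good" precursors are near-always detected with low intensity CV,
    "bad" ones are sporadic or noisy, the remainder intermediate; studies
    cycle through the four blood matrices.  Returns a long quantification
    table (light channel) and the ground truth.
    """
    if n_runs_per_study < 2:
        raise ValueError("need >= 2 runs per study")
    if not (0 < frac_good + frac_bad <= 1):
        raise ValueError("invalid planted fractions")
    rng = np.random.default_rng(seed)
    prec = _precursor_frame(n_precursors, rng)
    prec_keys = prec["modified_seq"] + "/" + prec["charge"].astype(str)

    n_good = int(round(frac_good * n_precursors))
    n_bad = int(round(frac_bad * n_precursors))
    kinds = np.array(["mid"] * n_precursors, dtype=object)
    order = rng.permutation(n_precursors)
    kinds[order[:n_good]] = "good"
    kinds[order[n_good:n_good + n_bad]] = "bad"

    presence = np.where(kinds == "good", good_presence,
                        np.where(kinds == "bad", bad_presence, mid_presence))
    cv = np.where(kinds == "good", good_cv,
                  np.where(kinds == "bad", bad_cv, mid_cv))
    base = 10.0 ** rng.uniform(4, 8, size=n_precursors)

    truth = SimTruth(
        planted_good=sorted(prec_keys[kinds == "good"]),
        planted_bad=sorted(prec_keys[kinds == "bad"]),
        presence=dict(zip(prec_keys, presence)),
        cv=dict(zip(prec_keys, cv)),
        seed=seed,
    )

    rows = []
    for s in range(n_studies):
        study = f"study{s:02d}"
        matrix = _MATRICES[s % len(_MATRICES)]
        for r in range(n_runs_per_study):
            run = f"{study}_run{r:02d}"
            # log-normal with sigma chosen so the linear-scale CV matches
            sigma = np.sqrt(np.log1p(cv**2))
            inten = base * np.exp(rng.normal(0, 1, n_precursors) * sigma
                                  - sigma**2 / 2)
            inten = np.where(cv == 0, base, inten)
            present = rng.random(n_precursors) < presence
            for i in np.nonzero(present)[0]:
                rows.append({
                    "run_id": run, "study_id": study, "matrix": matrix,
                    "platform_id": "sim", "sample_id": run, "group": "pool",
                    "protein_group": prec["protein_group"].iloc[i],
                    "stripped_seq": prec["stripped_seq"].iloc[i],
                    "modified_seq": prec["modified_seq"].iloc[i],
                    "charge": int(prec["charge"].iloc[i]),
                    "channel": "L", "intensity": inten[i],
                    "rt": np.nan, "fragment_id": None,
                    "fragment_intensity": np.nan,
                })
    return pd.DataFrame(rows), truth


def simulate_cohort(
    n_samples: int = 40,
    severity_levels: tuple[str, ...] = ("healthy", "mild", "severe", "critical"),
    platforms: tuple[str, ...] = ("A", "B", "C"),
    n_peptides: int = 60,
    frac_effect: float = 0.25,
    effect_per_step: float = 1.6,
    platform_scale_range: tuple[float, float] = (0.2, 5.0),
    platform_response_sd: float = 0.4,
    run_factor_sd: float = 0.4,
    noise_cv: float = 0.15,
    missing_rate: float = 0.05,
    missing_mode: str = "intensity",
    n_pool_runs: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Multi-platform clinical cohort with a spiked heavy channel.

    Per measurement: ``light = baseline * severity_effect^step *
    platform_scale * response * run_factor * noise`` and ``heavy = spike *
    platform_scale * response * run_factor * noise``.  ``platform_scale``
    is a global per-platform factor; ``response`` is a per-(platform,
    peptide) log-normal factor emulating peptide-specific ionization and
    transfer differences between instruments — the component a single
    per-platform median factor cannot remove.  The per-run factor and the
    response are shared by both channels, so the true light/heavy ratio
    is platform-free.  A fraction of peptides carries a multiplicative
    monotone severity effect.  Missingness averages ``missing_rate`` and
    is intensity-dependent by default (logistic in log-intensity,
    emulating detection limits); ``missing_mode="mcar"`` drops entries
    completely at random instead.  Study-pool replicate runs (group
    ``"pool"``) are appended per platform for CV QC.  Returns
    (quant table, design table, truth).
    """
    if len(severity_levels) < 2 or len(platforms) < 2:
        raise ValueError("need >= 2 severity levels and >= 2 platforms")
    if missing_mode not in ("intensity", "mcar"):
        raise ValueError(f"unknown missing_mode {missing_mode!r}")
    rng = np.random.default_rng(seed)
    prec = _precursor_frame(n_peptides, rng)
    peptides = prec["modified_seq"].tolist()

    n_eff = int(round(frac_effect * n_peptides))
    eff_idx = rng.permutation(n_peptides)[:n_eff]
    effect = np.ones(n_peptides)
    # alternate up/down regulation
    effect[eff_idx] = np.where(np.arange(n_eff) % 2 == 0,
                               effect_per_step, 1.0 / effect_per_step)
    baseline = 10.0 ** rng.uniform(4, 7, n_peptides)
    spike = baseline * 10.0 ** rng.uniform(-0.3, 0.3, n_peptides)
    pscale = {p: float(10.0 ** rng.uniform(np.log10(platform_scale_range[0]),
                                           np.log10(platform_scale_range[1])))
              for p in platforms}
    response = {p: np.exp(rng.normal(0, platform_response_sd, n_peptides))
                for p in platforms}

    sev = [severity_levels[i % len(severity_levels)] for i in range(n_samples)]
    design = pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n_samples)],
        "severity": sev,
    })
    truth = SimTruth(
        planted_good=[peptides[i] for i in sorted(eff_idx)],
        severity_effect={peptides[i]: float(effect[i]) for i in eff_idx},
        spike_amount=dict(zip(peptides, spike)),
        platform_scale=pscale,
        noise_sd=noise_cv,
        missing_rate=missing_rate,
        seed=seed,
    )

    sigma = np.sqrt(np.log1p(noise_cv**2))

    def missing_mask(values: np.ndarray) -> np.ndarray:
        if missing_rate <= 0:
            return np.zeros(values.size, dtype=bool)
        if missing_mode == "mcar":
            return rng.random(values.size) < missing_rate
        # logistic dropout in log10 intensity: threshold at the
        # missing_rate quantile so the average rate matches
        logv = np.log10(values)
        c = np.quantile(logv, missing_rate)
        p = 1.0 / (1.0 + np.exp((logv - c) / 0.15))
        return rng.random(values.size) < p

    def emit(rows, run, sample, group, platform, step):
        run_factor = float(np.exp(rng.normal(0, run_factor_sd)))
        scale = pscale[platform] * response[platform] * run_factor
        noise_l = np.exp(rng.normal(0, sigma, n_peptides) - sigma**2 / 2)
        noise_h = np.exp(rng.normal(0, sigma, n_peptides) - sigma**2 / 2)
        light = baseline * effect**step * scale * noise_l
        heavy = spike * scale * noise_h
        miss_l = missing_mask(light)
        miss_h = missing_mask(heavy)
        for i in range(n_peptides):
            common = {
                "run_id": run, "study_id": "cohort", "matrix": "citrate",
                "platform_id": platform, "sample_id": sample, "group": group,
                "protein_group": prec["protein_group"].iloc[i],
                "stripped_seq": prec["stripped_seq"].iloc[i],
                "modified_seq": peptides[i],
                "charge": int(prec["charge"].iloc[i]),
                "rt": np.nan, "fragment_id": None, "fragment_intensity": np.nan,
            }
            if not miss_l[i]:
                rows.append(common | {"channel": "L", "intensity": light[i]})
            if not miss_h[i]:
                rows.append(common | {"channel": "H", "intensity": heavy[i]})

    rows: list[dict] = []
    steps = {g: i for i, g in enumerate(severity_levels)}
    for platform in platforms:
        for _, srow in design.iterrows():
            run = f"{platform}_{srow['sample_id']}"
            emit(rows, run, srow["sample_id"], srow["severity"], platform,
                 steps[srow["severity"]])
        for r in range(n_pool_runs):
            emit(rows, f"{platform}_pool{r:02d}", f"pool{r:02d}", "pool",
                 platform, 0)
    return pd.DataFrame(rows), design, truth


def simulate_calibration(
    levels: tuple[float, ...] = (0.064, 0.32, 1.6, 8.0, 40.0, 200.0, 500.0, 1000.0),
    replicates: int = 3,
    slope: float = 1.0,
    intercept_sd: float = 0.05,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate calibration series with known slope and intercept spread.

    Responses follow ``slope * x + intercept_r + eps`` with a per-replicate
    intercept drawn from Normal(0, intercept_sd) and i.i.d. Normal(0,
    noise_sd) point noise.  Default levels mirror an eight-point serial
    dilution spanning ~2e4-fold.
    """
    if len(levels) < 2:
        raise ValueError("need >= 2 levels")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        intercept = rng.normal(0, intercept_sd) if intercept_sd > 0 else 0.0
        for lv in levels:
            eps = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({
                "replicate": rep, "level": float(lv),
                "response": slope * lv + intercept + eps,
            })
    return pd.DataFrame(rows)
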