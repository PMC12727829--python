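"""Readers/writers for the toolkit's tab-separated tables and SIL label arithmetic.

All tables are UTF-8 TSV with "." as decimal separator and the empty string
as missing value, mirroring the long-format reports emitted by DIA search
engines.  Intensities are linear-scale throughout; no reader or writer ever
log-transforms.

The heavy label is a C-terminal ``13C/15N`` lysine or arginine: six carbons
and two (K) or four (R) nitrogens are replaced by their heavy isotopes, so
the mass shift follows directly from the isotope mass differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "QUANT_COLUMNS",
    "LIBRARY_COLUMNS",
    "LabelScheme",
    "QuantTableError",
    "heavy_mass_shift",
    "read_quant_table",
    "write_quant_table",
    "read_library",
    "write_library",
    "refine_silac_library",
    "read_composition",
    "write_composition",
]

# Monoisotopic isotope mass differences (Da), NIST/CODATA.
DELTA_C13 = 1.0033548378  # 13C - 12C
DELTA_N15 = 0.9970348937  # 15N - 14N

#: heavy-label atom counts per labeled residue: (n_13C, n_15N)
_LABEL_ATOMS = {"K": (6, 2), "R": (6, 4)}

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

MANDATORY_QUANT_COLUMNS = [
    "run_id",
    "study_id",
    "matrix",
    "platform_id",
    "sample_id",
    "group",
    "protein_group",
    "stripped_seq",
    "modified_seq",
    "charge",
    "channel",
    "intensity",
]
OPTIONAL_QUANT_COLUMNS = ["rt", "fragment_id", "fragment_intensity"]
QUANT_COLUMNS = MANDATORY_QUANT_COLUMNS + OPTIONAL_QUANT_COLUMNS

LIBRARY_COLUMNS = [
    "ModifiedSequence",
    "PrecursorCharge",
    "FragmentId",
    "FragmentMz",
    "ExcludeFromAssay",
    "Channel",
]

COMPOSITION_COLUMNS = ["peptide", "pg_per_ul", "tier"]

MATRICES = {"EDTA", "citrate", "heparin", "serum", "other"}


class QuantTableError(ValueError):
    """Raised when a quantification table fails schema or value validation."""


@dataclass(frozen=True)
class LabelScheme:
    """Heavy-label definition: per-residue mass shifts and where they apply.

    Parameters
    ----------
    residue_shifts
        Mapping residue -> heavy mass shift in Da.  Defaults to the
        full ``13C6 15N2``-lysine / ``13C6 15N4``-arginine SILAC shifts.
    position_rule
        ``"c_terminal_only"`` applies the shift only when the labeled
        residue is the final one (tryptic C-terminus); ``"all_KR"``
        labels every K/R.
    """

    residue_shifts: dict[str, float] = field(
        default_factory=lambda: {
            r: n_c * DELTA_C13 + n_n * DELTA_N15
            for r, (n_c, n_n) in _LABEL_ATOMS.items()
        }
    )
    position_rule: str = "c_terminal_only"

    def __post_init__(self) -> None:
        if self.position_rule not in ("c_terminal_only", "all_KR"):
            raise ValueError(f"unknown position_rule {self.position_rule!r}")
        if any(v < 0 for v in self.residue_shifts.values()):
            raise ValueError("label mass shifts must be non-negative")


def heavy_mass_shift(residue: str, scheme: LabelScheme | None = None,
                     channel: str = "H") -> float:
    """Mass shift in Da of the heavy label on ``residue``.

    For the default scheme this is ``6 * (13C-12C) + n_N * (15N-14N)`` with
    ``n_N = 2`` for lysine and ``4`` for arginine, i.e. 8.014199 Da (K) and
    10.008269 Da (R).  The light channel carries no shift.
    """
    if channel == "L":
        return 0.0
    scheme = scheme or LabelScheme()
    try:
        return scheme.residue_shifts[residue]
    except KeyError:
        raise ValueError(
            f"unsupported residue {residue!r}: no heavy label defined"
        ) from None


# ---------------------------------------------------------------------------
# quantification table


def _validate_quant(df: pd.DataFrame) -> pd.DataFrame:
    for col in MANDATORY_QUANT_COLUMNS:
        if col not in df.columns:
            raise QuantTableError(f"missing mandatory column: {col!r}")
    bad_channel = ~df["channel"].isin(["L", "H"])
    if bad_channel.any():
        raise QuantTableError(
            f"invalid channel values: {sorted(df.loc[bad_channel, 'channel'].unique())}"
        )
    df["charge"] = df["charge"].astype(int)
    if ((df["charge"] < 1) | (df["charge"] > 6)).any():
        raise QuantTableError("charge outside [1, 6]")
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
    if (df["intensity"].dropna() < 0).any():
        raise QuantTableError("negative intensity values present")
    bad_seq = df["stripped_seq"].map(
        lambda s: not set(str(s)) <= CANONICAL_RESIDUES
    )
    if bad_seq.any():
        raise QuantTableError(
            f"non-canonical residues in stripped_seq rows {list(df.index[bad_seq][:5])}"
        )
    return df


def read_quant_table(path, dialect: str = "long_tsv") -> pd.DataFrame:
    """Read and validate a long-format precursor quantification TSV.

    Returns a DataFrame with one row per (run, precursor, channel[,
    fragment]) record.  Missing intensities are NaN; validation failures
    raise :class:`QuantTableError` naming the offending column.
    """
    if dialect != "long_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"group": str}, keep_default_na=True,
                     na_values=[""])
    for col in OPTIONAL_QUANT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = _validate_quant(df)
    df["rt"] = pd.to_numeric(df["rt"], errors="coerce")
    df["fragment_intensity"] = pd.to_numeric(df["fragment_intensity"],
                                             errors="coerce")
    return df[QUANT_COLUMNS]


def write_quant_table(df: pd.DataFrame, path) -> None:
    """Write a quantification table as UTF-8 TSV (empty string = missing)."""
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# spectral library


def read_library(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise QuantTableError(f"library missing columns: {missing}")
    df["ExcludeFromAssay"] = df["ExcludeFromAssay"].map(
        {"T": True, "F": False, True: True, False: False}
    )
    return df


def write_library(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["ExcludeFromAssay"] = out["ExcludeFromAssay"].map({True: "T", False: "F"})
    out.to_csv(path, sep="\t", index=False)


def _fragment_series(fragment_id: str) -> str:
    """Ion series letter of a fragment id such as ``y5_1`` or ``b3_2``."""
    return str(fragment_id)[0].lower()


def _fragment_charge(fragment_id: str) -> int:
    fid = str(fragment_id)
    if "_" in fid:
        try:
            return int(fid.rsplit("_", 1)[1])
        except ValueError:
            pass
    return 1


def refine_silac_library(
    lib: pd.DataFrame,
    panel: list[str],
    scheme: LabelScheme | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict heavy channels to panel peptides and exclude b-ions.

    The refined library keeps the heavy (H) channel only for peptides in
    ``panel``; the label mass shift is applied to the C-terminal K/R, so
    y-series fragment m/z values shift by ``shift / fragment_charge`` while
    b-series fragments (which do not contain the C-terminus) are unshifted.
    All b-series fragments are marked ``ExcludeFromAssay`` so quantification
    uses y-ions only, where the light/heavy pair is mass-resolved.

    Returns the refined library and a report of warnings (panel peptides
    absent from the library, peptides not ending in K/R).
    """
    scheme = scheme or LabelScheme()
    report: list[str] = []
    panel_set = set(panel)

    def strip_mods(seq: str) -> str:
        out, depth = [], 0
        for ch in seq:
            if ch in "([":
                depth += 1
            elif ch in ")]":
                depth -= 1
            elif depth == 0:
                out.append(ch)
        return "".join(out)

    light = lib[lib["Channel"] == "L"].copy()
    lib_peptides = set(light["ModifiedSequence"])
    for pep in sorted(panel_set - lib_peptides):
        msg = f"panel peptide {pep!r} absent from library"
        warnings.warn(msg, stacklevel=2)
        report.append(msg)

    heavy_rows = []
    for pep in sorted(panel_set & lib_peptides):
        cterm = strip_mods(pep)[-1]
        if cterm not in scheme.residue_shifts:
            msg = (f"panel peptide {pep!r} ends in {cterm!r}; "
                   "no heavy channel generated")
            warnings.warn(msg, stacklevel=2)
            report.append(msg)
            continue
        shift = scheme.residue_shifts[cterm]
        h = light[light["ModifiedSequence"] == pep].copy()
        h["Channel"] = "H"
        is_y = h["FragmentId"].map(_fragment_series) == "y"
        fz = h["FragmentId"].map(_fragment_charge)
        h.loc[is_y, "FragmentMz"] = h.loc[is_y, "FragmentMz"] + shift / fz[is_y]
        heavy_rows.append(h)

    refined = pd.concat([light] + heavy_rows, ignore_index=True)
    is_b = refined["FragmentId"].map(_fragment_series) == "b"
    refined.loc[is_b, "ExcludeFromAssay"] = True
    return refined, report


# ---------------------------------------------------------------------------
# standard-composition table


def read_composition(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("peptide", "pg_per_ul") if c not in df.columns]
    if missing:
        raise QuantTableError(f"composition table missing columns: {missing}")
    if (df["pg_per_ul"] <= 0).any():
        raise QuantTableError("non-positive concentration in composition table")
    return df


def write_composition(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
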