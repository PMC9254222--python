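"""Domain types and table I/O for dual-luciferase plate screens.

The canonical in-memory container for well-level measurements is a pandas
DataFrame with one row per well and the columns listed in
:data:`WELL_COLUMNS`.  Readers validate against the 384-well grid (rows
A..P, columns 1..24), enforce well uniqueness within a (plate, replicate
day), and normalize concentration units to µM.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel chemical id for solvent-only negative-control wells.
VEHICLE = "VEHICLE"

#: Well roles.
ROLES = ("test", "vehicle", "control_activator", "control_inhibitor")

#: Required columns of a well-level table, in canonical order.
WELL_COLUMNS = [
    "plate_id",
    "well",
    "chemical_id",
    "concentration_uM",
    "firefly",
    "renilla",
    "replicate_day",
    "role",
]

#: Canonical column order for the per-chemical score table.
SCORE_COLUMNS = [
    "chemical_id",
    "mean_log2fc_all_conc",
    "mean_cell_health_all_conc",
    "mean_ch_log2fc_all_conc",
    "response_slope",
    "toxicity_slope",
    "wnt_score",
    "min_p",
    "min_p_cell_health",
    "is_toxic",
    "is_activator",
    "is_inhibitor",
    "hit_class",
]

#: Canonical column order for the per chemical x concentration summary table.
SUMMARY_COLUMNS = [
    "chemical_id",
    "concentration_uM",
    "mean_log2fc",
    "mean_cell_health",
    "mean_ch_log2fc",
    "p_value",
    "p_value_cell_health",
    "n_replicates",
]

_WELL_RE = re.compile(r"^([A-P])([0-9]{1,2})$")

_UNIT_FACTORS = {"uM": 1.0, "µM": 1.0, "um": 1.0, "nM": 1e-3, "nm": 1e-3,
                 "mM": 1e3, "mm": 1e3, "M": 1e6}


class ScreenDataError(ValueError):
    """Raised for malformed or inconsistent screen tables."""


class ConfigurationError(ScreenDataError):
    """Raised when a required column or setting is missing."""


@dataclass(frozen=True)
class WellMeasurement:
    """One well's raw dual-luciferase measurement."""

    plate_id: str
    well: str
    chemical_id: str
    concentration_uM: float
    firefly: float
    renilla: float
    replicate_day: int
    role: str = "test"


@dataclass(frozen=True)
class ChemicalRecord:
    """Chemical annotation: id, display name, registry number, structure."""

    chemical_id: str
    name: str = ""
    casrn: str | None = None
    smiles: str | None = None


def validate_well_position(well: str) -> tuple[int, int]:
    """Parse a letter+number 384-well position into (row, column) indices.

    Raises :class:`ScreenDataError` if the position falls outside the
    16 x 24 grid.
    """
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ScreenDataError(f"invalid 384-well position {well!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    if not (0 <= col < 24):
        raise ScreenDataError(f"well column out of range in {well!r}")
    return row, col


def well_name(row: int, col: int) -> str:
    """Inverse of :func:`validate_well_position` (0-based indices)."""
    return f"{chr(ord('A') + row)}{col + 1}"


def validate_wells(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a well-level DataFrame in place and return it.

    Checks grid positions, well uniqueness per (plate_id, replicate_day),
    non-negative finite luminescence, and vehicle-well consistency.
    """
    missing = [c for c in WELL_COLUMNS if c not in df.columns and c != "role"]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")
    if "role" not in df.columns:
        df = df.copy()
        df["role"] = np.where(df["chemical_id"] == VEHICLE, "vehicle", "test")

    for w in df["well"].unique():
        validate_well_position(w)

    bad_role = set(df["role"].unique()) - set(ROLES)
    if bad_role:
        raise ScreenDataError(f"unknown roles: {sorted(bad_role)}")

    dup = df.duplicated(subset=["plate_id", "replicate_day", "well"])
    if dup.any():
        rows = df.loc[dup, ["plate_id", "replicate_day", "well"]]
        raise ScreenDataError(
            "duplicate well positions within a plate/day:\n"
            + rows.to_string(index=True)
        )

    for col in ("firefly", "renilla"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            idx = df.index[bad].tolist()
            raise ScreenDataError(
                f"non-finite or negative {col} values at rows {idx}"
            )
        df[col] = vals.astype(float)

    veh = df["role"] == "vehicle"
    if (df.loc[veh, "concentration_uM"].astype(float) != 0).any():
        raise ScreenDataError("vehicle wells must have concentration 0")
    return df


def read_plate_table(
    path_or_buf,
    fmt: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a plate-reader measurement table into a validated well DataFrame.

    Parameters
    ----------
    path_or_buf : path or file-like
        CSV/TSV source.
    fmt : {"csv", "tsv"}
        Delimiter convention.
    column_map : mapping, optional
        Maps the file's column names to the canonical :data:`WELL_COLUMNS`
        names, e.g. ``{"Plate": "plate_id"}``.

    A ``concentration_unit`` column, if present, is used to convert each
    row's concentration to µM (accepted units: nM, µM/uM, mM, M).
    Wells whose ``chemical_id`` equals :data:`VEHICLE` are given the
    vehicle role unless an explicit role column says otherwise.
    """
    if fmt is None:
        suffix = Path(str(path_or_buf)).suffix.lower()
        fmt = "tsv" if suffix in (".tsv", ".tab") else "csv"
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise ConfigurationError(f"unknown plate table format {fmt!r}")
    df = pd.read_csv(path_or_buf, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))

    required = [c for c in WELL_COLUMNS if c != "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"plate table missing columns {missing}; present: {list(df.columns)}"
        )

    if df.empty:
        logger.warning("plate table %s is empty", path_or_buf)
        if "role" not in df.columns:
            df["role"] = pd.Series(dtype=str)
        return df[WELL_COLUMNS]

    for col in ("firefly", "renilla", "concentration_uM"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | vals.isna()
        if bad.any():
            # +2: header line plus 1-based numbering, matching the file
            lines = [int(i) + 2 for i in df.index[bad]]
            raise ScreenDataError(
                f"unparseable {col} values at file line(s) {lines}"
            )
        df[col] = vals.astype(float)

    if "concentration_unit" in df.columns:
        factors = df["concentration_unit"].map(_UNIT_FACTORS)
        if factors.isna().any():
            bad_units = df.loc[factors.isna(), "concentration_unit"].unique()
            raise ScreenDataError(f"unknown concentration units: {bad_units}")
        df["concentration_uM"] = df["concentration_uM"] * factors

    if "role" not in df.columns:
        df["role"] = np.where(df["chemical_id"] == VEHICLE, "vehicle", "test")
    else:
        # explicit role wins; fill blanks from the VEHICLE sentinel
        blank = df["role"].isna() | (df["role"].astype(str).str.strip() == "")
        df.loc[blank, "role"] = np.where(
            df.loc[blank, "chemical_id"] == VEHICLE, "vehicle", "test"
        )

    df["replicate_day"] = df["replicate_day"].astype(int)
    df = validate_wells(df)
    return df[WELL_COLUMNS + [c for c in df.columns if c not in WELL_COLUMNS]]


def read_chemical_table(path, fmt: str | None = None) -> pd.DataFrame:
    """Read chemical annotations from CSV, SDF (V2000) or .smi.

    Returns a DataFrame with columns chemical_id, name, casrn, smiles.
    SMILES strings are kept verbatim; no canonicalization is applied at
    read time.  Duplicate chemical ids raise an error.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".sdf": "sdf", ".smi": "smi"}.get(
            path.suffix.lower(), "csv"
        )

    if fmt == "csv":
        df = pd.read_csv(path)
        if "chemical_id" not in df.columns:
            raise ConfigurationError("chemical table needs a chemical_id column")
        for col in ("name", "casrn", "smiles"):
            if col not in df.columns:
                df[col] = None
        if df["smiles"].isna().all():
            logger.warning(
                "chemical table %s has no SMILES; structure-based steps "
                "will skip these chemicals", path,
            )
        df = df[["chemical_id", "name", "casrn", "smiles"]]
    elif fmt == "smi":
        rows = []
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol_{i}"
            rows.append((cid, cid, None, smiles))
        df = pd.DataFrame(rows, columns=["chemical_id", "name", "casrn", "smiles"])
    elif fmt == "sdf":
        from rdkit import Chem

        rows = []
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ScreenDataError(f"unparseable molecule #{i + 1} in {path}")
            cid = mol.GetProp("_Name") or f"mol_{i + 1}"
            casrn = mol.GetProp("CASRN") if mol.HasProp("CASRN") else None
            rows.append((cid, cid, casrn, Chem.MolToSmiles(mol)))
        df = pd.DataFrame(rows, columns=["chemical_id", "name", "casrn", "smiles"])
    else:
        raise ConfigurationError(f"unknown chemical table format {fmt!r}")

    dup = df["chemical_id"][df["chemical_id"].duplicated()].unique()
    if len(dup):
        raise ScreenDataError(f"duplicate chemical ids: {sorted(dup)}")
    return df.reset_index(drop=True)


def records_from_frame(df: pd.DataFrame) -> list[ChemicalRecord]:
    """Convert a chemical annotation DataFrame to ChemicalRecord objects."""
    return [
        ChemicalRecord(
            chemical_id=str(r.chemical_id),
            name=str(r.name) if pd.notna(r.name) else "",
            casrn=r.casrn if pd.notna(r.casrn) else None,
            smiles=r.smiles if pd.notna(r.smiles) else None,
        )
        for r in df.itertuples(index=False)
    ]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    hits_only: bool = False,
) -> dict[str, Path]:
    """Write result tables as TSV with deterministic column order.

    Floats are written at 12 significant digits so read/write round-trips
    are lossless at that precision.  With ``hits_only``, score tables are
    filtered to rows whose hit_class is not "none".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in sorted(tables):
        df = tables[name]
        if hits_only and "hit_class" in df.columns:
            df = df[df["hit_class"] != "none"]
        order = _canonical_order(df.columns)
        path = out_dir / f"{name}.tsv"
        df[order].to_csv(path, sep="\t", index=False, float_format="%.12g")
        written[name] = path
    return written


def read_result_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def _canonical_order(columns: Iterable[str]) -> list[str]:
    cols = list(columns)
    for template in (SCORE_COLUMNS, SUMMARY_COLUMNS, WELL_COLUMNS):
        if set(template) <= set(cols):
            return template + [c for c in cols if c not in template]
    return cols
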