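"""Readers and writers for method configuration, batch design and measurements.

The canonical measurement interchange is a long-format CSV (UTF-8, '.'
decimal separator) with one row per sample x transition:

    sample_id, species_id, transition_role, peak_area, snr, rt

Vendor exports with different headers can be adapted through an explicit
column mapping.  All writers emit a stable column order so outputs can be
golden-file tested.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import pydantic
import yaml

from .model import (
    ConfigurationError,
    MethodConfig,
    SampleRecord,
    SoilMeta,
)

MEASUREMENT_COLUMNS = ["sample_id", "species_id", "transition_role", "peak_area", "snr", "rt"]

DESIGN_COLUMNS = [
    "sample_id",
    "soil_id",
    "role",
    "nominal_level",
    "replicate_id",
    "day_id",
    "operator_id",
    "soil_mass_g",
    "extract_volume_mL",
    "ilis_addition",
]

SOIL_COLUMNS = ["soil_id", "c_org_pct", "ph", "water_content_pct", "texture"]


class ValidationError(ValueError):
    """Measurement or design table violates an input contract."""


# ---------------------------------------------------------------------------
# method configuration
# ---------------------------------------------------------------------------

def write_method_config(config: MethodConfig, path: str | Path) -> None:
    data = config.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_method_config(path: str | Path) -> MethodConfig:
    """Load and fully validate a method configuration (YAML or JSON).

    All catalog invariants are enforced on load: unique species ids,
    resolvable analyte->ILIS references with matching polarity, exactly one
    quantifier and one qualifier transition per species, strictly increasing
    calibration levels.
    """
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return MethodConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


# ---------------------------------------------------------------------------
# batch design and soils
# ---------------------------------------------------------------------------

def design_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = [r.model_dump(mode="json") for r in records]
    df = pd.DataFrame(rows)
    return df[DESIGN_COLUMNS]


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "soil_id": str})
    records = []
    for row in df.to_dict(orient="records"):
        if pd.isna(row.get("nominal_level")):
            row["nominal_level"] = None
        if pd.isna(row.get("soil_id")):
            row["soil_id"] = None
        records.append(SampleRecord.model_validate(row))
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in design: {dupes}")
    return design_frame(records)


def soils_frame(soils: Sequence[SoilMeta]) -> pd.DataFrame:
    return pd.DataFrame([s.model_dump() for s in soils])[SOIL_COLUMNS]


def write_soils(soils: Sequence[SoilMeta], path: str | Path) -> None:
    soils_frame(soils).to_csv(path, index=False)


def read_soils(path: str | Path) -> list[SoilMeta]:
    df = pd.read_csv(path, dtype={"soil_id": str})
    return [SoilMeta.model_validate(r) for r in df.to_dict(orient="records")]


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def validate_measurements(
    table: pd.DataFrame,
    config: MethodConfig,
    design: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"measurement table missing columns {missing}")
    table = table[MEASUREMENT_COLUMNS].copy()
    unknown = set(table["species_id"]) - set(config.species_ids)
    if unknown:
        raise ValidationError(f"unknown species in measurements: {sorted(unknown)[:5]}")
    bad_roles = set(table["transition_role"]) - {"quantifier", "qualifier"}
    if bad_roles:
        raise ValidationError(f"unknown transition roles: {sorted(bad_roles)}")
    if (table["peak_area"] < 0).any():
        raise ValidationError("negative peak areas in measurement table")
    if (table["snr"] < 0).any():
        raise ValidationError("negative S/N in measurement table")
    key = table[["sample_id", "species_id", "transition_role"]]
    if key.duplicated().any():
        first = key[key.duplicated()].iloc[0].tolist()
        raise ValidationError(f"duplicated (sample, species, role) row, e.g. {first}")
    if design is not None:
        orphans = set(table["sample_id"]) - set(design["sample_id"])
        if orphans:
            raise ValidationError(
                f"samples present in measurements but absent from design: {sorted(orphans)[:5]}"
            )
    return table


def read_measurements(
    path: str | Path,
    config: MethodConfig,
    design: Optional[pd.DataFrame] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read a long-format measurement CSV and validate it against the method.

    ``column_map`` maps vendor headers to the canonical ones, e.g.
    ``{"Sample Name": "sample_id"}``.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "species_id": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    return validate_measurements(df, config, design)


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    table[MEASUREMENT_COLUMNS].to_csv(path, index=False)
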