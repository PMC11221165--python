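"""CSV schemas, validation and conversions between tables and domain objects.

All tabular interchange uses plain CSV with documented headers.  Units:
isotope values in ‰ (δ13C vs V-PDB, δ15N vs AIR), lengths in mm, mass in g
(beaks) or mg (subsections), coordinates in decimal degrees, years as
calendar years.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .beak_geometry import BeakSpecimen, Subsection
from .corrections import CorrectedSubsection

__all__ = [
    "SchemaError",
    "BEAKS_COLUMNS",
    "SUBSECTIONS_COLUMNS",
    "CORRECTED_COLUMNS",
    "validate_columns",
    "read_beaks",
    "read_subsections",
    "specimens_from_frame",
    "subsections_from_frame",
    "corrected_frame",
]

BEAKS_COLUMNS = ["individual_id", "species", "time_series", "year",
                 "lat", "lon", "source"]
SUBSECTIONS_COLUMNS = ["individual_id", "index", "start_mm", "end_mm",
                       "d13c_raw", "d15n_raw", "cn_ratio"]
CORRECTED_COLUMNS = ["individual_id", "index", "d13c_corrected",
                     "d15n_muscle_equiv", "trophic_position",
                     "baseline_d15n_used", "d13c_correction_used",
                     "tef_used", "qc_pass"]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def validate_columns(df: pd.DataFrame, required: Sequence[str],
                     name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")


def read_beaks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_columns(df, BEAKS_COLUMNS, "beaks.csv")
    return df


def read_subsections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_columns(df, SUBSECTIONS_COLUMNS, "subsections.csv")
    return df


def _opt(row, key):
    v = row.get(key)
    return None if v is None or pd.isna(v) else float(v)


def specimens_from_frame(beaks: pd.DataFrame) -> list[BeakSpecimen]:
    validate_columns(beaks, BEAKS_COLUMNS, "beaks")
    out = []
    for _, row in beaks.iterrows():
        out.append(BeakSpecimen(
            individual_id=str(row["individual_id"]),
            species=str(row["species"]),
            time_series=str(row["time_series"]),
            year=int(row["year"]),
            lat=float(row["lat"]), lon=float(row["lon"]),
            source=str(row["source"]),
            url_mm=_opt(row, "url_mm"), ucl_mm=_opt(row, "ucl_mm"),
            ml_mm=_opt(row, "ml_mm"), w_g=_opt(row, "w_g"),
        ))
    return out


def subsections_from_frame(subsections: pd.DataFrame,
                           individual_id: str | None = None,
                           ) -> list[Subsection]:
    validate_columns(subsections, SUBSECTIONS_COLUMNS, "subsections")
    if individual_id is not None:
        subsections = subsections[
            subsections["individual_id"] == individual_id]
    out = []
    for _, row in subsections.iterrows():
        out.append(Subsection(
            individual_id=str(row["individual_id"]),
            index=int(row["index"]),
            start_mm=float(row["start_mm"]), end_mm=float(row["end_mm"]),
            d13c_raw=float(row["d13c_raw"]), d15n_raw=float(row["d15n_raw"]),
            cn_ratio=_opt(row, "cn_ratio"),
            mass_mg=_opt(row, "mass_mg"),
        ))
    return out


def corrected_frame(corrected: Iterable[CorrectedSubsection],
                    specimen: BeakSpecimen | None = None) -> pd.DataFrame:
    """Corrected subsections as a table; specimen metadata columns appended."""
    rows = []
    for c in corrected:
        row = {k: getattr(c, k) for k in CORRECTED_COLUMNS}
        if specimen is not None:
            row.update(species=specimen.species,
                       time_series=specimen.time_series,
                       year=specimen.year)
        rows.append(row)
    return pd.DataFrame(rows)
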