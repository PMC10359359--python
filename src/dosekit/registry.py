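"""Scan-record schema and delimited-table I/O.

A "scan table" throughout this package is a :class:`pandas.DataFrame` with
one row per CT scan and the canonical columns in :data:`SCAN_COLUMNS`. The
:class:`ScanRecord` dataclass mirrors one row for row-level interop and
typing; vectorised operations work on the frame directly.

Units are fixed package-wide: DLP in mGy·cm, doses in mSv, lengths and
diameters in cm. There is no unit auto-detection.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError

#: Canonical body regions. Composite or adjacent anatomies fold into these
#: seven: sinus and face exams count as head, cervical spine as neck, and
#: whole-spine exams as combined chest/abdomen/pelvis.
REGIONS = (
    "head",
    "neck",
    "chest",
    "cardiac",
    "abdomen_pelvis",
    "chest_abdomen_pelvis",
    "spine",
)

#: Regions whose reference doses are age-matched only; they never carry a
#: patient-diameter stratification.
HEAD_NECK = ("head", "neck")

REGION_SYNONYMS = {
    "sinus": "head",
    "face": "head",
    "cervical_spine": "neck",
    "cervical spine": "neck",
    "whole_spine": "chest_abdomen_pelvis",
    "whole spine": "chest_abdomen_pelvis",
    "abdomen_and_pelvis": "abdomen_pelvis",
    "abdomen and pelvis": "abdomen_pelvis",
    "combined_chest_abdomen_pelvis": "chest_abdomen_pelvis",
    "combined chest abdomen and pelvis": "chest_abdomen_pelvis",
    "chest_abdomen_and_pelvis": "chest_abdomen_pelvis",
    "thoracic_or_lumbar_spine": "spine",
    "thoracic or lumbar spine": "spine",
    "thoracic_spine": "spine",
    "lumbar_spine": "spine",
}

MANUFACTURERS = ("GE", "Siemens", "Philips", "Canon", "other")
SEXES = ("F", "M", "unknown")
PHANTOMS = ("16cm", "32cm", "unknown")

#: Canonical scan-table columns, in order.
SCAN_COLUMNS = (
    "scan_id",
    "body_region",
    "age",
    "sex",
    "mean_effective_diameter",
    "dlp",
    "ctdi_vol",
    "scan_length",
    "kvp",
    "mas",
    "manufacturer",
    "reporting_phantom",
    "is_perfusion",
    "e_reference",
)

#: Columns that must be present (and parseable) in any input table.
MANDATORY_COLUMNS = ("body_region", "age", "dlp")

NUMERIC_COLUMNS = (
    "age",
    "mean_effective_diameter",
    "dlp",
    "ctdi_vol",
    "scan_length",
    "kvp",
    "mas",
    "e_reference",
)

#: Study age range: enrolment spans birth up to (not including) 22 years.
AGE_RANGE = (0.0, 22.0)


@dataclass
class ScanRecord:
    """One CT scan's patient, technical, and dose fields.

    ``None`` marks an absent optional value; the frame representation uses
    NaN. ``e_reference`` carries the reference (Monte-Carlo-style) effective
    dose in mSv when available.
    """

    scan_id: str
    body_region: str
    age: float
    dlp: Optional[float]
    sex: str = "unknown"
    mean_effective_diameter: Optional[float] = None
    ctdi_vol: Optional[float] = None
    scan_length: Optional[float] = None
    kvp: Optional[float] = None
    mas: Optional[float] = None
    manufacturer: str = "other"
    reporting_phantom: str = "unknown"
    is_perfusion: bool = False
    e_reference: Optional[float] = None

    @classmethod
    def from_row(cls, row: Mapping) -> "ScanRecord":
        def opt(key):
            v = row.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return v

        return cls(
            scan_id=str(row.get("scan_id", "")),
            body_region=normalize_region(row["body_region"]),
            age=float(row["age"]) if opt("age") is not None else np.nan,
            dlp=opt("dlp"),
            sex=row.get("sex", "unknown") or "unknown",
            mean_effective_diameter=opt("mean_effective_diameter"),
            ctdi_vol=opt("ctdi_vol"),
            scan_length=opt("scan_length"),
            kvp=opt("kvp"),
            mas=opt("mas"),
            manufacturer=row.get("manufacturer", "other") or "other",
            reporting_phantom=row.get("reporting_phantom", "unknown") or "unknown",
            is_perfusion=bool(row.get("is_perfusion", False)),
            e_reference=opt("e_reference"),
        )


def normalize_region(value) -> str:
    """Map a raw body-region string onto the seven canonical regions.

    Unknown strings are returned lower-cased/underscored as-is; validation
    against :data:`REGIONS` happens in the exclusion filter, which treats an
    unrecognised region as a missing field rather than raising mid-parse.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    key = str(value).strip().lower().replace("-", "_")
    key_spaced = key.replace("_", " ")
    if key in REGIONS:
        return key
    if key in REGION_SYNONYMS:
        return REGION_SYNONYMS[key]
    if key_spaced in REGION_SYNONYMS:
        return REGION_SYNONYMS[key_spaced]
    return key.replace(" ", "_")


def _normalize_manufacturer(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "other"
    v = str(value).strip()
    lookup = {m.lower(): m for m in MANUFACTURERS}
    aliases = {
        "general electric": "GE",
        "ge healthcare": "GE",
        "toshiba": "Canon",
        "canon medical systems": "Canon",
    }
    low = v.lower()
    return lookup.get(low, aliases.get(low, "other"))


def _normalize_sex(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    v = str(value).strip().upper()
    if v in ("F", "FEMALE"):
        return "F"
    if v in ("M", "MALE"):
        return "M"
    return "unknown"


def read_scan_table(source, column_map: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Read a delimited scan table into the canonical frame.

    Parameters
    ----------
    source : path, stream, or DataFrame
        CSV (``,``) or TSV (``\\t``) with a header row, a ``.parquet`` file,
        or an already-loaded frame to be normalised in place.
    column_map : mapping, optional
        ``{canonical field: source column name}``. Unmapped canonical fields
        are looked up under their own names.

    Unparseable numeric cells become NaN (absent), never silent zeros; row
    order is preserved. Raises :class:`ConfigurationError` if any of
    ``body_region``, ``age`` or ``dlp`` cannot be resolved, and
    :class:`EmptyInputError` on a table with no data rows.
    """
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        raw = _read_any(source)
    if raw.empty:
        raise EmptyInputError("scan table contains no data rows")

    column_map = dict(column_map or {})
    frame = pd.DataFrame(index=raw.index)
    for canon in SCAN_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            frame[canon] = raw[src]
        else:
            frame[canon] = np.nan

    missing = [c for c in MANDATORY_COLUMNS if frame[c].isna().all() and column_map.get(c, c) not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"mandatory column(s) not found in source table: {', '.join(missing)}"
        )

    for col in NUMERIC_COLUMNS:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")

    frame["body_region"] = frame["body_region"].map(normalize_region)
    frame["manufacturer"] = frame["manufacturer"].map(_normalize_manufacturer)
    frame["sex"] = frame["sex"].map(_normalize_sex)
    frame["reporting_phantom"] = frame["reporting_phantom"].where(
        frame["reporting_phantom"].isin(PHANTOMS), "unknown"
    )
    frame["is_perfusion"] = _coerce_bool(frame["is_perfusion"])
    if frame["scan_id"].isna().all():
        frame["scan_id"] = [f"scan-{i}" for i in range(len(frame))]
    frame["scan_id"] = frame["scan_id"].astype(str)
    return frame.reset_index(drop=True)


def _read_any(source) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() in (".parquet", ".pq"):
            return pd.read_parquet(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        return pd.read_csv(path, sep=sep)
    if isinstance(source, (_io.TextIOBase, _io.BufferedIOBase, _io.RawIOBase)):
        return pd.read_csv(source)
    return pd.read_csv(source)


def _coerce_bool(series: pd.Series) -> pd.Series:
    truthy = {"1", "true", "t", "yes", "y"}
    out = series.map(
        lambda v: False
        if v is None or (isinstance(v, float) and np.isnan(v))
        else (v if isinstance(v, (bool, np.bool_)) else str(v).strip().lower() in truthy)
    )
    return out.astype(bool)


def write_scan_table(frame: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a canonical scan table as CSV/TSV (dialect chosen by ``sep``)."""
    frame.to_csv(path, sep=sep, index=False)


def to_records(frame: pd.DataFrame) -> list[ScanRecord]:
    """Materialise a scan table as a list of :class:`ScanRecord`."""
    return [ScanRecord.from_row(row) for row in frame.to_dict("records")]


def frame_from_records(records: Iterable[ScanRecord]) -> pd.DataFrame:
    """Inverse of :func:`to_records`."""
    return pd.DataFrame([vars(r) for r in records], columns=list(SCAN_COLUMNS))
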