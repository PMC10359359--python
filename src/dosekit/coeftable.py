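"""Stratified conversion-coefficient tables.

A :class:`CoefficientTable` maps a stratum key — body region, optionally
crossed with age group, diameter bin, and manufacturer — to the median and
interquartile coefficients (mSv per mGy·cm) and the stratum scan count.

Serialisation is a plain CSV with columns
``region, age_group, diameter_bin, manufacturer, median_k, q25_k, q75_k, n``;
an empty string marks an absent stratification axis. Reference tables
published without per-stratum counts may leave ``n`` blank; tables derived
from data always populate it.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .dose import AGE_GROUPS, DIAMETER_BINS
from .errors import DomainError, MissingStratumError
from .registry import HEAD_NECK, REGIONS

AXIS_COLUMNS = ("age_group", "diameter_bin", "manufacturer")
VALUE_COLUMNS = ("median_k", "q25_k", "q75_k", "n")
ALL_COLUMNS = ("region",) + AXIS_COLUMNS + VALUE_COLUMNS

_AXIS_ORDER = {
    "age_group": {g: i for i, g in enumerate(AGE_GROUPS)},
    "diameter_bin": {b: i for i, b in enumerate(DIAMETER_BINS)},
}


class CoefficientTable:
    """Stratum → (median, q25, q75, n) conversion coefficients.

    Parameters
    ----------
    frame : DataFrame
        Columns per :data:`ALL_COLUMNS`; absent axes as NaN/None/"".
    validate : bool
        Enforce invariants: positive coefficients, q25 ≤ median ≤ q75,
        known regions, and no diameter-stratified head/neck rows.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        df = frame.copy()
        for col in ALL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        for col in AXIS_COLUMNS:
            df[col] = df[col].replace("", np.nan)
            df[col] = df[col].where(df[col].notna(), None).astype(object)
        for col in ("median_k", "q25_k", "q75_k", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        self._df = df[list(ALL_COLUMNS)].reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self._df
        bad_region = ~df["region"].isin(REGIONS)
        if bad_region.any():
            raise DomainError(
                f"unknown region(s): {sorted(df.loc[bad_region, 'region'].unique())}"
            )
        if (df["median_k"] <= 0).any() or df["median_k"].isna().any():
            raise DomainError("median_k must be present and strictly positive")
        has_q = df["q25_k"].notna() & df["q75_k"].notna()
        if ((df.loc[has_q, "q25_k"] > df.loc[has_q, "median_k"])
                | (df.loc[has_q, "median_k"] > df.loc[has_q, "q75_k"])).any():
            raise DomainError("require q25_k <= median_k <= q75_k in every stratum")
        if ((df.loc[has_q, "q25_k"] <= 0)).any():
            raise DomainError("quartile coefficients must be strictly positive")
        hn_diam = df["region"].isin(HEAD_NECK) & df["diameter_bin"].notna()
        if hn_diam.any():
            raise DomainError("head/neck strata must not carry a diameter bin")
        dupes = df.duplicated(subset=["region", *AXIS_COLUMNS])
        if dupes.any():
            raise DomainError("duplicate stratum keys in coefficient table")

    # -- container protocol ------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoefficientTable):
            return NotImplemented
        a = self._df.sort_values(["region", *AXIS_COLUMNS]).reset_index(drop=True)
        b = other._df.sort_values(["region", *AXIS_COLUMNS]).reset_index(drop=True)
        return a.equals(b)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying table (copy)."""
        return self._df.copy()

    @property
    def axes(self) -> tuple:
        """Stratification axes populated anywhere in the table."""
        return tuple(c for c in AXIS_COLUMNS if self._df[c].notna().any())

    def regions(self) -> tuple:
        return tuple(sorted(self._df["region"].unique(), key=REGIONS.index))

    # -- lookup ------------------------------------------------------------

    def lookup(
        self,
        region: str,
        age_group: Optional[str] = None,
        diameter_bin: Optional[str] = None,
        manufacturer: Optional[str] = None,
    ) -> float:
        """Median coefficient for an exact stratum key.

        The key must match the table's axes exactly: axes not supplied must be
        absent in the stored stratum. Missing strata raise
        :class:`MissingStratumError` naming the key.
        """
        row = self.stratum(
            region, age_group=age_group, diameter_bin=diameter_bin,
            manufacturer=manufacturer,
        )
        return float(row["median_k"])

    def stratum(self, region, age_group=None, diameter_bin=None, manufacturer=None) -> pd.Series:
        """Full row (median, quartiles, n) for an exact stratum key."""
        df = self._df
        mask = df["region"] == region
        for col, val in (
            ("age_group", age_group),
            ("diameter_bin", diameter_bin),
            ("manufacturer", manufacturer),
        ):
            mask &= df[col].isna() if val is None else (df[col] == val)
        hits = df[mask]
        if hits.empty:
            key = dict(region=region, age_group=age_group,
                       diameter_bin=diameter_bin, manufacturer=manufacturer)
            raise MissingStratumError(
                "no stratum for "
                + ", ".join(f"{k}={v}" for k, v in key.items() if v is not None)
            )
        return hits.iloc[0]

    def lookup_frame(self, keys: pd.DataFrame) -> pd.Series:
        """Vectorised lookup: one median coefficient per row of ``keys``.

        ``keys`` carries ``region`` plus any of the axis columns; axis columns
        not present are treated as absent. Rows whose stratum is missing get
        NaN (callers decide whether that is an error or an exclusion).
        """
        left = pd.DataFrame({"region": keys["region"].to_numpy(dtype=object)})
        for col in AXIS_COLUMNS:
            left[col] = (
                keys[col].to_numpy(dtype=object) if col in keys.columns else None
            )
        right = self._df[["region", *AXIS_COLUMNS, "median_k"]].copy()
        # merge on sentinel-filled keys: NaN != NaN in joins
        for col in AXIS_COLUMNS:
            left[col] = left[col].where(pd.notna(left[col]), "__none__")
            right[col] = right[col].where(pd.notna(right[col]), "__none__")
        merged = left.merge(right, how="left", on=["region", *AXIS_COLUMNS])
        return pd.Series(merged["median_k"].to_numpy(), index=keys.index, name="median_k")

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, validate: bool = True) -> "CoefficientTable":
        df = pd.read_csv(
            path,
            dtype={c: object for c in ("region",) + AXIS_COLUMNS},
            keep_default_na=True,
        )
        return cls(df, validate=validate)

    def to_csv(self, path) -> None:
        out = self._df.copy()
        for col in AXIS_COLUMNS:
            out[col] = out[col].fillna("")
        out.to_csv(path, index=False)

    @classmethod
    def from_records(cls, records, validate: bool = True) -> "CoefficientTable":
        return cls(pd.DataFrame(list(records)), validate=validate)
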