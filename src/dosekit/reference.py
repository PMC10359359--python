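"""Packaged reference tables.

Published stratified conversion coefficients and the composition (region ×
age × sex × manufacturer counts) of the multicenter pediatric CT registry
they were derived from (128,397 scans, ages 0–21). These ship with the
package as plain CSV and seed both the synthetic-registry defaults and the
relative-coefficient checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coeftable import CoefficientTable
from .errors import ConfigurationError


def _data_path(name: str):
    return resources.files("dosekit.data").joinpath(name)


def load_age_coefficients() -> CoefficientTable:
    """Published coefficients by body region × age group (mSv per mGy·cm).

    The spine ``<1`` stratum is absent: it held fewer than 10 scans in the
    source registry and was suppressed by the minimum-count rule.
    """
    with resources.as_file(_data_path("age_coefficients.csv")) as p:
        table = CoefficientTable.from_csv(p)
    if table.axes != ("age_group",):
        raise ConfigurationError("age coefficient fixture corrupted")
    return table


def load_diameter_coefficients() -> CoefficientTable:
    """Published coefficients by body region × diameter bin.

    Head and neck are absent by construction: their reference doses are
    age-matched only, never size-stratified.
    """
    with resources.as_file(_data_path("diameter_coefficients.csv")) as p:
        table = CoefficientTable.from_csv(p)
    if table.axes != ("diameter_bin",):
        raise ConfigurationError("diameter coefficient fixture corrupted")
    return table


def load_registry_composition() -> pd.DataFrame:
    """Region × (total, sex, age-group, manufacturer) scan counts.

    Indexed by region; used to default the synthetic generator's region,
    age, sex, and manufacturer mixes to the source registry's empirical
    proportions.
    """
    with resources.as_file(_data_path("registry_composition.csv")) as p:
        df = pd.read_csv(p)
    df = df.set_index("region")
    age_cols = ["age_lt1", "age_1_4", "age_5_9", "age_10_14", "age_15_21"]
    checks = (
        df[age_cols].sum(axis=1).eq(df["total"]).all()
        and df[["female", "male"]].sum(axis=1).eq(df["total"]).all()
        and df[["GE", "Siemens", "Philips", "Canon"]].sum(axis=1).eq(df["total"]).all()
    )
    if not checks:
        raise ConfigurationError("registry composition fixture fails internal sums")
    return df
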