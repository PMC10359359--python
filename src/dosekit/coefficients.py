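"""Coefficient-table derivation and relative coefficients.

Thin functional wrappers over :class:`~dosekit.estimators.DoseCoefficientRegressor`
plus the relative-coefficient summary: the ratio of a region's extreme-stratum
median coefficients (youngest/oldest age groups, or smallest/largest diameter
bins), quantifying how strongly the DLP→dose conversion varies across the
pediatric range.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Optional

import pandas as pd

from .coeftable import CoefficientTable
from .dose import AGE_GROUPS, DIAMETER_BINS
from .errors import DomainError, InsufficientStrataError
from .estimators import DoseCoefficientRegressor, StrataSpec


def derive_coefficients(
    scans: pd.DataFrame, spec: Optional[StrataSpec] = None
) -> CoefficientTable:
    """Derive a stratified coefficient table from scans with reference doses.

    Equivalent to fitting a :class:`DoseCoefficientRegressor` with the spec's
    axes/min_n and returning its ``coefficient_table_``.
    """
    spec = spec or StrataSpec()
    est = DoseCoefficientRegressor(
        axes=tuple(spec.axes), min_n=spec.min_n, interpolation=spec.interpolation
    )
    return est.fit(scans).coefficient_table_


class RelativeCoefficient(NamedTuple):
    """Extreme-stratum median ratio for one region along one axis."""

    rounded: float  #: ratio rounded half-away-from-zero to one decimal
    raw: float  #: unrounded ratio
    numerator_stratum: str  #: youngest / smallest populated stratum
    denominator_stratum: str  #: oldest / largest populated stratum


def _round_half_away(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def relative_coefficient(
    table: CoefficientTable, region: str, axis: str = "age_group"
) -> RelativeCoefficient:
    """Ratio of extreme-stratum medians for a region along an axis.

    For the age axis: youngest-available over oldest-available group (a
    suppressed stratum — e.g. spine under 1 year — makes the next group the
    youngest available). For the diameter axis: smallest over largest
    available bin. The rounded value uses half-away-from-zero rounding to one
    decimal; the raw ratio is returned alongside.
    """
    if axis == "age_group":
        order = AGE_GROUPS
    elif axis == "diameter_bin":
        order = DIAMETER_BINS
    else:
        raise DomainError(f"axis must be 'age_group' or 'diameter_bin', got {axis!r}")

    df = table.frame
    rows = df[(df["region"] == region) & df[axis].notna()]
    populated = [g for g in order if g in set(rows[axis])]
    if len(populated) < 2:
        raise InsufficientStrataError(
            f"region {region!r} has {len(populated)} populated {axis} strata; need >= 2"
        )
    lo_label, hi_label = populated[0], populated[-1]
    num = float(rows.loc[rows[axis] == lo_label, "median_k"].iloc[0])
    den = float(rows.loc[rows[axis] == hi_label, "median_k"].iloc[0])
    raw = num / den
    return RelativeCoefficient(_round_half_away(raw), raw, lo_label, hi_label)


def relative_coefficients(table: CoefficientTable, axis: str = "age_group") -> pd.DataFrame:
    """Relative coefficients for every region with >= 2 populated strata."""
    rows = []
    for region in table.regions():
        try:
            rc = relative_coefficient(table, region, axis)
        except InsufficientStrataError:
            continue
        rows.append(
            {"region": region, "axis": axis, "relative_coefficient": rc.rounded,
             "raw_ratio": rc.raw, "numerator_stratum": rc.numerator_stratum,
             "denominator_stratum": rc.denominator_stratum}
        )
    return pd.DataFrame(rows)
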