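"""Dose arithmetic: ICRP-103 effective dose, per-scan conversion coefficients,
age/diameter binning, coefficient lookup, and DLP-derived dose.

Effective dose E is the tissue-weighted sum of organ equivalent doses,

    E = sum_T w_T * H_T   [mSv],

with the ICRP Publication 103 weighting set w_T (sums to 1). For photon
radiation the equivalent dose H_T is numerically equal to the absorbed organ
dose, so organ doses may be supplied in mGy. The "remainder" tissues are
modelled as a single pooled tissue at weight 0.12 applied to a caller-supplied
mean remainder dose.

The DLP-to-effective-dose conversion coefficient (k-factor) is

    k = E_reference / DLP   [mSv per mGy·cm],

and a DLP-derived effective dose is simply DLP * k with k looked up from a
stratified coefficient table.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Union

import numpy as np

from .errors import DomainError, LabelError
from .registry import HEAD_NECK

#: ICRP Publication 103 tissue weighting factors. Remainder tissues pooled.
ICRP103_TISSUE_WEIGHTS: Mapping[str, float] = {
    "red_bone_marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "remainder": 0.12,
    "gonads": 0.08,
    "bladder": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone_surface": 0.01,
    "brain": 0.01,
    "salivary_glands": 0.01,
    "skin": 0.01,
}

#: Five age strata spanning the study range [0, 22) years.
AGE_GROUPS = ("<1", "1-4", "5-9", "10-14", "15-21")
AGE_EDGES = np.array([0.0, 1.0, 5.0, 10.0, 15.0, 22.0])

#: Mean-effective-diameter strata (cm), contiguous half-open integer-edge
#: bins [11,16), [16,21), ... [36,41).
DIAMETER_BINS = ("11-15", "16-20", "21-25", "26-30", "31-35", "36-40")
DIAMETER_EDGES = np.array([11.0, 16.0, 21.0, 26.0, 31.0, 36.0, 41.0])


class DiameterRangeWarning(UserWarning):
    """Diameter outside the tabulated 11–40 cm range; clamped to nearest bin."""


def effective_dose(
    organ_doses: Mapping[str, float],
    weights: Optional[Mapping[str, float]] = None,
) -> float:
    """Tissue-weighted sum of organ equivalent doses, in mSv.

    Organs absent from ``organ_doses`` contribute zero. Unknown organ labels
    raise :class:`LabelError`; negative doses raise :class:`DomainError`.
    """
    w = ICRP103_TISSUE_WEIGHTS if weights is None else weights
    total = 0.0
    for organ, dose in organ_doses.items():
        if organ not in w:
            raise LabelError(f"unknown organ/tissue label: {organ!r}")
        if dose < 0:
            raise DomainError(f"negative equivalent dose for {organ!r}: {dose}")
        total += w[organ] * dose
    return total


def scan_coefficient(e_reference, dlp):
    """Per-scan conversion coefficient k = e_reference / dlp (mSv per mGy·cm).

    Accepts scalars or arrays; ``dlp`` must be strictly positive and
    ``e_reference`` non-negative.
    """
    e = np.asarray(e_reference, dtype=float)
    d = np.asarray(dlp, dtype=float)
    if np.any(d <= 0):
        raise DomainError("dlp must be strictly positive")
    if np.any(e < 0):
        raise DomainError("e_reference must be non-negative")
    out = e / d
    return float(out) if out.ndim == 0 else out


def dlp_derived_dose(dlp, k):
    """DLP-derived effective dose = dlp * k, in mSv. Both inputs > 0."""
    d = np.asarray(dlp, dtype=float)
    kk = np.asarray(k, dtype=float)
    if np.any(d <= 0):
        raise DomainError("dlp must be strictly positive")
    if np.any(kk <= 0):
        raise DomainError("coefficient k must be strictly positive")
    out = d * kk
    return float(out) if out.ndim == 0 else out


def assign_age_group(age: float) -> str:
    """Age-stratum label for an age in years.

    Half-open bins: [0,1) → "<1", [1,5) → "1-4", [5,10) → "5-9",
    [10,15) → "10-14", [15,22) → "15-21". Ages outside [0, 22) raise
    :class:`DomainError` — the study range ends below 22 years.
    """
    if not np.isfinite(age) or age < 0.0 or age >= 22.0:
        raise DomainError(f"age {age!r} outside the study range [0, 22)")
    idx = int(np.searchsorted(AGE_EDGES, age, side="right")) - 1
    return AGE_GROUPS[idx]


def assign_age_groups(ages) -> np.ndarray:
    """Vectorised :func:`assign_age_group`. NaN maps to None (absent)."""
    a = np.asarray(ages, dtype=float)
    finite = np.isfinite(a)
    if np.any((a[finite] < 0) | (a[finite] >= 22.0)):
        raise DomainError("age values outside the study range [0, 22)")
    idx = np.searchsorted(AGE_EDGES, a, side="right") - 1
    out = np.empty(a.shape, dtype=object)
    out[finite] = np.array(AGE_GROUPS, dtype=object)[idx[finite].clip(0, 4)]
    out[~finite] = None
    return out


def assign_diameter_bin(diameter: float, warn: bool = True) -> str:
    """Diameter-stratum label for a mean effective diameter in cm.

    Values below 11 cm or at/above 41 cm clamp to the nearest bin — real
    registries contain such scans — with a :class:`DiameterRangeWarning`.
    Non-positive diameters raise :class:`DomainError`.
    """
    if not np.isfinite(diameter) or diameter <= 0:
        raise DomainError(f"diameter must be positive, got {diameter!r}")
    if diameter < DIAMETER_EDGES[0] or diameter >= DIAMETER_EDGES[-1]:
        if warn:
            warnings.warn(
                f"diameter {diameter:g} cm outside the tabulated 11–40 cm "
                "range; clamped to the nearest bin",
                DiameterRangeWarning,
                stacklevel=2,
            )
        return DIAMETER_BINS[0] if diameter < DIAMETER_EDGES[0] else DIAMETER_BINS[-1]
    idx = int(np.searchsorted(DIAMETER_EDGES, diameter, side="right")) - 1
    return DIAMETER_BINS[idx]


def assign_diameter_bins(diameters, warn: bool = True):
    """Vectorised :func:`assign_diameter_bin`.

    Returns ``(labels, out_of_range)``: an object array of labels (None where
    the diameter is absent) and a boolean mask of clamped values.
    """
    d = np.asarray(diameters, dtype=float)
    finite = np.isfinite(d)
    if np.any(d[finite] <= 0):
        raise DomainError("diameters must be positive")
    clipped = np.clip(d, DIAMETER_EDGES[0], np.nextafter(DIAMETER_EDGES[-1], 0))
    idx = np.searchsorted(DIAMETER_EDGES, clipped, side="right") - 1
    out = np.empty(d.shape, dtype=object)
    out[finite] = np.array(DIAMETER_BINS, dtype=object)[idx[finite].clip(0, 5)]
    out[~finite] = None
    oor = finite & ((d < DIAMETER_EDGES[0]) | (d >= DIAMETER_EDGES[-1]))
    if warn and np.any(oor):
        warnings.warn(
            f"{int(oor.sum())} diameter value(s) outside the tabulated "
            "11–40 cm range; clamped to the nearest bin",
            DiameterRangeWarning,
            stacklevel=2,
        )
    return out, oor


#: Lookup strategies → coefficient-table axes they require.
STRATEGY_AXES = {
    "region": (),
    "age": ("age_group",),
    "diameter": ("diameter_bin",),
    "age_diameter": ("age_group", "diameter_bin"),
    "manufacturer_age": ("manufacturer", "age_group"),
}


def lookup_coefficient(
    table,
    region: str,
    age: Optional[float] = None,
    diameter: Optional[float] = None,
    manufacturer: Optional[str] = None,
    strategy: str = "age",
) -> float:
    """Median conversion coefficient for a scan, from a stratified table.

    ``strategy`` selects the stratification axes (see :data:`STRATEGY_AXES`).
    Head and neck scans are always matched by age: their reference doses are
    never size-stratified, so a diameter-involving strategy silently falls
    back to ``age`` (a notice is emitted via :mod:`warnings`).

    Raises :class:`~dosekit.errors.MissingStratumError` when the stratum is
    absent (suppressed by the minimum-count rule or never tabulated).
    """
    if strategy not in STRATEGY_AXES:
        raise DomainError(f"unknown lookup strategy {strategy!r}")
    if region in HEAD_NECK and "diameter_bin" in STRATEGY_AXES[strategy]:
        warnings.warn(
            f"{region} scans use age-matched coefficients; "
            f"strategy {strategy!r} falls back to 'age'",
            UserWarning,
            stacklevel=2,
        )
        strategy = "age"
    axes = STRATEGY_AXES[strategy]
    key = {}
    if "age_group" in axes:
        if age is None:
            raise DomainError("strategy requires an age")
        key["age_group"] = assign_age_group(age)
    if "diameter_bin" in axes:
        if diameter is None:
            raise DomainError("strategy requires a diameter")
        key["diameter_bin"] = assign_diameter_bin(diameter)
    if "manufacturer" in axes:
        if manufacturer is None:
            raise DomainError("strategy requires a manufacturer")
        key["manufacturer"] = manufacturer
    return table.lookup(region, **key)
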