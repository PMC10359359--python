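"""Agreement between DLP-derived and reference effective doses.

Quantifies how well the simple DLP × k estimate tracks the per-scan reference
(Monte-Carlo-style) effective dose: Pearson correlation with a Fisher-z
confidence interval, and the percentage of scans whose estimate misses the
reference by at least a relative-error threshold (default 50%). The relative
error is always measured against the reference dose, never the estimate.

Also supports applying a legacy single-reference-age coefficient set (such as
older published k-factor tables keyed by "0 year old" ... "adult") to a scan
table for head-to-head comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .coeftable import CoefficientTable
from .dose import STRATEGY_AXES, assign_age_groups
from .errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    MissingMappingError,
)
from .estimators import attach_strata
from .registry import HEAD_NECK

#: Age-group → legacy reference-age label mapping for single-year coefficient
#: sets: each study age group borrows the nearest tabulated reference age.
DEFAULT_LEGACY_AGE_MAP = {
    "<1": "0 year old",
    "1-4": "1 year old",
    "5-9": "5 years old",
    "10-14": "10 years old",
    "15-21": "adult",
}


class PearsonCI(NamedTuple):
    r: float
    ci_low: float
    ci_high: float


def pearson_with_ci(
    x, y, alpha: float = 0.05, method: str = "fisher",
    n_boot: int = 2000, seed: Optional[int] = None,
) -> PearsonCI:
    """Sample Pearson correlation with a (1 - alpha) confidence interval.

    The default interval is the Fisher z-transform interval
    ``tanh(arctanh(r) ± z_{1-alpha/2} / sqrt(n - 3))``; ``method="bootstrap"``
    gives a percentile bootstrap instead. Requires n >= 3, finite values, and
    non-zero variance in both series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("series must have equal length")
    if len(x) < 3:
        raise InsufficientDataError(f"need n >= 3 for a correlation, got n={len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("series must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    if method == "fisher":
        if n <= 3:
            lo, hi = -1.0, 1.0
        else:
            z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
            half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
            lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        rs = np.empty(n_boot)
        for b in range(n_boot):
            xb, yb = x[idx[b]], y[idx[b]]
            if np.std(xb) == 0 or np.std(yb) == 0:
                rs[b] = np.nan
                continue
            rs[b] = np.corrcoef(xb, yb)[0, 1]
        rs = rs[np.isfinite(rs)]
        lo = float(np.quantile(rs, alpha / 2))
        hi = float(np.quantile(rs, 1 - alpha / 2))
    else:
        raise DomainError(f"unknown CI method {method!r}")
    return PearsonCI(r, min(lo, r), max(hi, r))


class ErrorRate(NamedTuple):
    pct: float  #: percentage of evaluable scans at/above the threshold
    n: int  #: evaluable scans
    n_missing: int  #: scans excluded for a missing estimate (absent stratum)


def pct_relative_error_above(
    estimate, reference, threshold: float = 0.5, inclusive: bool = True
) -> ErrorRate:
    """Percentage of scans with |estimate − reference| / reference ≥ threshold.

    ``inclusive=True`` counts errors exactly at the threshold (the "50% or
    greater" convention); set False for a strict > rule. Scans with a missing
    (NaN) estimate are excluded from the denominator and counted separately.
    Reference doses must be strictly positive.
    """
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise DomainError("series must have equal length")
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    if np.any(~np.isfinite(ref)) or np.any(ref <= 0):
        raise DomainError("reference doses must be finite and strictly positive")
    ok = np.isfinite(est)
    n_missing = int((~ok).sum())
    est, ref = est[ok], ref[ok]
    if len(est) == 0:
        return ErrorRate(float("nan"), 0, n_missing)
    rel = np.abs(est - ref) / ref
    hits = rel >= threshold if inclusive else rel > threshold
    return ErrorRate(100.0 * float(np.mean(hits)), int(len(est)), n_missing)


@dataclass
class LegacyCoefficientSet:
    """Single-reference-age coefficient set plus the age-label mapping rule.

    ``coefficients`` maps ``(region, reference age label)`` to a coefficient
    in mSv per mGy·cm; ``age_map`` maps each study age group to the reference
    age label to borrow. A region covered at all must be covered for every
    age group it is asked about.
    """

    coefficients: Mapping[Tuple[str, str], float]
    age_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LEGACY_AGE_MAP)
    )

    def lookup(self, region: str, age_group: str) -> float:
        if age_group not in self.age_map:
            raise MissingMappingError(f"no legacy age label for group {age_group!r}")
        label = self.age_map[age_group]
        key = (region, label)
        if key not in self.coefficients:
            raise MissingMappingError(
                f"legacy set has no coefficient for region={region!r}, age={label!r}"
            )
        return float(self.coefficients[key])


def apply_legacy_coefficients(
    scans: pd.DataFrame, legacy: LegacyCoefficientSet
) -> pd.Series:
    """Per-scan dose = DLP × legacy coefficient mapped through the age rule."""
    groups = assign_age_groups(scans["age"].to_numpy())
    ks = np.array(
        [legacy.lookup(r, g) for r, g in zip(scans["body_region"], groups)],
        dtype=float,
    )
    return pd.Series(
        scans["dlp"].to_numpy(dtype=float) * ks, index=scans.index, name="e_legacy"
    )


def _estimate_doses(
    scans: pd.DataFrame, table: CoefficientTable, strategy: str
) -> pd.Series:
    axes = STRATEGY_AXES[strategy]
    work = attach_strata(scans, axes)
    keys = work[["body_region", *axes]].rename(columns={"body_region": "region"})
    k = table.lookup_frame(keys)
    return pd.Series(scans["dlp"].to_numpy(dtype=float) * k.to_numpy(), index=scans.index)


def agreement_report(
    scans: pd.DataFrame,
    tables: Mapping[str, CoefficientTable],
    legacy: Optional[LegacyCoefficientSet] = None,
    threshold: float = 0.5,
    alpha: float = 0.05,
    regions: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-region, per-strategy agreement of DLP-derived vs reference doses.

    ``tables`` maps a lookup strategy name ("age", "diameter", "age_diameter",
    "manufacturer_age") to the coefficient table to use for it. Head and neck
    rows omit diameter-involving strategies, whose reference doses are
    age-matched only. Scans whose stratum is absent from a table are excluded
    from that cell and counted in ``n_missing_stratum``.

    Returns a tidy frame with one row per region × strategy: Pearson r with a
    Fisher-z 95% interval and the percentage of scans at/above the relative
    error threshold.
    """
    if scans["e_reference"].isna().any():
        raise DomainError("agreement requires a reference dose on every scan")
    region_list = list(regions) if regions is not None else [
        r for r in scans["body_region"].unique()
    ]
    strategies = list(tables.keys())
    rows = []
    estimates = {s: _estimate_doses(scans, t, s) for s, t in tables.items()}
    if legacy is not None:
        estimates["legacy"] = apply_legacy_coefficients(scans, legacy)
        strategies.append("legacy")
    for region in region_list:
        in_region = scans["body_region"] == region
        ref = scans.loc[in_region, "e_reference"].to_numpy(dtype=float)
        for strat in strategies:
            if region in HEAD_NECK and strat != "legacy" and "diameter_bin" in STRATEGY_AXES[strat]:
                continue
            est = estimates[strat].loc[in_region].to_numpy(dtype=float)
            ok = np.isfinite(est)
            err = pct_relative_error_above(est, ref, threshold=threshold)
            if ok.sum() >= 3 and np.std(est[ok]) > 0 and np.std(ref[ok]) > 0:
                r, lo, hi = pearson_with_ci(est[ok], ref[ok], alpha=alpha)
            else:
                r = lo = hi = float("nan")
            rows.append(
                {
                    "region": region,
                    "strategy": strat,
                    "n": err.n,
                    "pearson_r": r,
                    "ci_low": lo,
                    "ci_high": hi,
                    "pct_gt_threshold": err.pct,
                    "n_missing_stratum": err.n_missing,
                    "threshold": threshold,
                }
            )
    return pd.DataFrame(rows)
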