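"""Study-population filters: perfusion/missing-data exclusions, percentile
tail trimming, and age-band subsampling.

The exclusion cascade applies, in order:

1. perfusion scans;
2. records missing body region, age, or DLP, or with "erroneous" values —
   non-positive DLP/CTDI-vol/diameter/scan length, or age outside [0, 22);
3. records strictly outside the [q, 1-q] quantile envelope (default q = 1%)
   of each trim variable, with quantiles computed once on the set surviving
   steps 1–2.

Each excluded record is attributed to the first rule that removes it, so the
:class:`ExclusionLog` counts reconcile exactly with input minus output. A
record missing an optional trim variable is never trimmed on that variable,
and boundary-equal values are retained (only strictly-outside values drop) —
a conservative, deterministic tie rule.

Trim quantiles are computed globally, not per body region (a per-region mode
is available via ``per_region=True``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DomainError, EmptyInputError
from .registry import AGE_RANGE, REGIONS

DEFAULT_TRIM_VARIABLES = (
    "ctdi_vol",
    "dlp",
    "mean_effective_diameter",
    "scan_length",
    "e_reference",
    "mas",
)

_ERRONEOUS_POSITIVE = ("dlp", "ctdi_vol", "mean_effective_diameter", "scan_length")


@dataclass
class ExclusionLog:
    """Per-reason exclusion counts; reconciles exactly with input − output."""

    input_n: int
    retained_n: int
    counts: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.retained_n + sum(self.counts.values()) == self.input_n

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"input_n": self.input_n, "retained_n": self.retained_n,
             "excluded": self.counts},
            **{"indent": 2, **kwargs},
        )

    def __str__(self) -> str:
        lines = [f"input scans: {self.input_n}"]
        lines += [f"excluded [{reason}]: {n}" for reason, n in self.counts.items()]
        lines.append(f"retained: {self.retained_n}")
        return "\n".join(lines)


class ExclusionFilter(TransformerMixin, BaseEstimator):
    """Row filter implementing the study-population exclusion cascade.

    scikit-learn transformer over scan tables: ``fit`` learns the per-variable
    trim bounds from the training table (after its own perfusion/missing
    pass), ``transform`` applies the cascade and records an
    :class:`ExclusionLog` per call.

    Parameters
    ----------
    trim_fraction : float in [0, 0.5)
        Quantile trimmed from each tail of each trim variable. 0 disables
        trimming.
    trim_variables : sequence of column names
        Variables subject to tail trimming.
    per_region : bool
        Compute trim quantiles within each body region instead of globally.

    Attributes
    ----------
    bounds_ : dict
        ``{variable: (low, high)}`` (or ``{(region, variable): ...}`` when
        per-region) learned at fit.
    exclusion_log_ : ExclusionLog
        Log of the most recent ``transform``.
    """

    def __init__(
        self,
        trim_fraction: float = 0.01,
        trim_variables: Sequence[str] = DEFAULT_TRIM_VARIABLES,
        per_region: bool = False,
    ):
        self.trim_fraction = trim_fraction
        self.trim_variables = trim_variables
        self.per_region = per_region

    def _check_params(self) -> None:
        if not (0.0 <= self.trim_fraction < 0.5):
            raise DomainError(
                f"trim_fraction must lie in [0, 0.5), got {self.trim_fraction}"
            )

    def fit(self, X: pd.DataFrame, y=None) -> "ExclusionFilter":
        self._check_params()
        if len(X) == 0:
            raise EmptyInputError("cannot fit exclusion filter on an empty table")
        clean = X[~self._perfusion_mask(X) & ~self._missing_mask(X)]
        bounds = {}
        if self.trim_fraction > 0:
            groups = (
                clean.groupby("body_region", sort=False)
                if self.per_region
                else [(None, clean)]
            )
            for region, grp in groups:
                for var in self.trim_variables:
                    vals = grp[var].dropna()
                    if vals.empty:
                        continue
                    lo = float(vals.quantile(self.trim_fraction))
                    hi = float(vals.quantile(1.0 - self.trim_fraction))
                    key = var if region is None else (region, var)
                    bounds[key] = (lo, hi)
        self.bounds_ = bounds
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_params()
        if not hasattr(self, "bounds_"):
            raise DomainError("ExclusionFilter must be fitted before transform")
        counts: dict = {}
        alive = pd.Series(True, index=X.index)

        perf = self._perfusion_mask(X) & alive
        counts["perfusion"] = int(perf.sum())
        alive &= ~perf

        miss = self._missing_mask(X) & alive
        counts["missing_fields"] = int(miss.sum())
        alive &= ~miss

        for var in self.trim_variables:
            out = self._trim_mask(X, var) & alive
            counts[f"tail_trim:{var}"] = int(out.sum())
            alive &= ~out

        filtered = X[alive].copy()
        self.exclusion_log_ = ExclusionLog(
            input_n=len(X),
            retained_n=len(filtered),
            counts={k: v for k, v in counts.items() if v > 0},
        )
        return filtered

    # -- rule masks ----------------------------------------------------------

    @staticmethod
    def _perfusion_mask(X: pd.DataFrame) -> pd.Series:
        if "is_perfusion" not in X.columns:
            return pd.Series(False, index=X.index)
        return X["is_perfusion"].fillna(False).astype(bool)

    @staticmethod
    def _missing_mask(X: pd.DataFrame) -> pd.Series:
        """Missing mandatory fields or erroneous values."""
        bad = (
            ~X["body_region"].isin(REGIONS)
            | X["age"].isna()
            | (X["age"] < AGE_RANGE[0])
            | (X["age"] >= AGE_RANGE[1])
            | X["dlp"].isna()
        )
        for var in _ERRONEOUS_POSITIVE:
            if var in X.columns:
                bad |= X[var].notna() & (X[var] <= 0)
        return bad.fillna(True)

    def _trim_mask(self, X: pd.DataFrame, var: str) -> pd.Series:
        if var not in X.columns or not self.bounds_:
            return pd.Series(False, index=X.index)
        vals = X[var]
        if self.per_region:
            lo = X["body_region"].map(
                lambda r: self.bounds_.get((r, var), (-np.inf, np.inf))[0]
            )
            hi = X["body_region"].map(
                lambda r: self.bounds_.get((r, var), (-np.inf, np.inf))[1]
            )
        else:
            if var not in self.bounds_:
                return pd.Series(False, index=X.index)
            lo, hi = self.bounds_[var]
        # strictly outside [lo, hi]; boundary-equal values are retained
        return (vals.notna() & ((vals < lo) | (vals > hi))).fillna(False)


def apply_exclusions(
    scans: pd.DataFrame,
    trim_fraction: float = 0.01,
    trim_variables: Sequence[str] = DEFAULT_TRIM_VARIABLES,
    per_region: bool = False,
) -> Tuple[pd.DataFrame, ExclusionLog]:
    """Apply the full exclusion cascade; returns (filtered table, log).

    Thin wrapper over :class:`ExclusionFilter` fitted and applied on the same
    table, matching the study's single-pass usage.
    """
    filt = ExclusionFilter(
        trim_fraction=trim_fraction,
        trim_variables=trim_variables,
        per_region=per_region,
    )
    out = filt.fit(scans).transform(scans)
    return out, filt.exclusion_log_


def subsample_age_band(
    scans: pd.DataFrame,
    band: Tuple[float, float] = (18.0, 22.0),
    fraction: float = 0.05,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Keep each scan in the age band independently with probability ``fraction``.

    Emulates deliberate under-sampling of near-adult patients so they do not
    dominate derived coefficients. Scans outside ``band`` are always kept.
    Per-record Bernoulli draws under a seeded generator; bit-identical for a
    fixed seed.
    """
    if not (0.0 < fraction <= 1.0):
        raise DomainError(f"fraction must lie in (0, 1], got {fraction}")
    if fraction == 1.0:
        return scans.copy()
    lo, hi = band
    in_band = (scans["age"] >= lo) & (scans["age"] < hi)
    rng = np.random.default_rng(seed)
    draws = rng.random(len(scans))
    keep = ~in_band.to_numpy() | (draws < fraction)
    return scans[keep].copy()
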