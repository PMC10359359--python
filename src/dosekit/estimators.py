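"""scikit-learn style estimators for conversion-coefficient modelling.

:class:`DoseCoefficientRegressor` is the package's central object. ``fit``
takes a scan table whose rows carry a reference effective dose (in practice
from Monte Carlo organ-dose simulation) and derives a stratified coefficient
table: within each stratum — body region crossed with the configured axes —
the median and quartiles of the per-scan ratio k = E_reference / DLP.
``predict`` maps new scans to DLP-derived effective doses, DLP × median k of
the matching stratum.

Strata with fewer than ``min_n`` scans are omitted from the fitted table,
never zero-filled; prediction on a scan whose stratum is missing yields NaN
so callers can report such scans separately.

The estimator composes with sklearn model selection and pipelines (it is a
regressor over DataFrame inputs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .coeftable import AXIS_COLUMNS, CoefficientTable
from .dose import STRATEGY_AXES, assign_age_groups, assign_diameter_bins
from .errors import DomainError, EmptyDerivationError
from .registry import HEAD_NECK


@dataclass
class StrataSpec:
    """Stratification plan: axes crossed with body region, and the minimum
    per-stratum scan count below which a stratum is suppressed."""

    axes: Sequence[str] = ("age_group",)
    min_n: int = 10
    interpolation: str = "linear"

    def __post_init__(self):
        bad = [a for a in self.axes if a not in AXIS_COLUMNS]
        if bad:
            raise DomainError(f"unknown stratification axes: {bad}")
        if self.min_n < 1:
            raise DomainError(f"min_n must be >= 1, got {self.min_n}")


def _strategy_for_axes(axes: Sequence[str]) -> str:
    for name, ax in STRATEGY_AXES.items():
        if tuple(sorted(ax)) == tuple(sorted(axes)):
            return name
    return "custom"


def attach_strata(scans: pd.DataFrame, axes: Sequence[str]) -> pd.DataFrame:
    """Return a copy of ``scans`` with the derived axis columns attached.

    ``age_group`` is binned from ``age``; ``diameter_bin`` from
    ``mean_effective_diameter`` (left absent for head/neck scans, whose
    coefficients are never size-stratified); ``manufacturer`` passes through.
    """
    out = scans.copy()
    if "age_group" in axes:
        out["age_group"] = assign_age_groups(out["age"].to_numpy())
    if "diameter_bin" in axes:
        labels, _ = assign_diameter_bins(
            out["mean_effective_diameter"].to_numpy(), warn=False
        )
        labels[out["body_region"].isin(HEAD_NECK).to_numpy()] = None
        out["diameter_bin"] = labels
    return out


class DoseCoefficientRegressor(RegressorMixin, BaseEstimator):
    """Stratified-median DLP→effective-dose estimator.

    Parameters
    ----------
    axes : sequence of {"age_group", "diameter_bin", "manufacturer"}
        Stratification axes crossed with body region. Empty gives a
        region-only table.
    min_n : int
        Minimum scans per stratum; smaller strata are suppressed.
    interpolation : str
        Quantile method passed to :func:`numpy.quantile` (default "linear",
        i.e. interpolation between order statistics).

    Attributes
    ----------
    coefficient_table_ : CoefficientTable
        The fitted stratified coefficients.
    strategy_ : str
        Lookup strategy name matching ``axes`` (e.g. "age", "age_diameter").
    n_used_ : int
        Scans entering derivation after axis-availability drops.
    n_dropped_axis_missing_ : int
        Scans dropped because a required axis value was absent (e.g. no
        diameter on a diameter-axis fit; head/neck scans on any
        diameter-containing fit).
    n_suppressed_strata_ : int
        Strata omitted by the ``min_n`` rule.
    """

    def __init__(
        self,
        axes: Sequence[str] = ("age_group",),
        min_n: int = 10,
        interpolation: str = "linear",
    ):
        self.axes = axes
        self.min_n = min_n
        self.interpolation = interpolation

    # -- fitting -------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "DoseCoefficientRegressor":
        """Derive the stratified coefficient table.

        ``X`` is a scan table; the reference effective dose is taken from
        ``y`` if given, else from ``X["e_reference"]``. Every scan must have
        dlp > 0 and a reference dose.
        """
        spec = StrataSpec(tuple(self.axes), self.min_n, self.interpolation)
        if len(X) == 0:
            raise EmptyDerivationError("cannot derive coefficients from an empty table")
        e_ref = (
            pd.Series(np.asarray(y, dtype=float), index=X.index)
            if y is not None
            else pd.to_numeric(X["e_reference"], errors="coerce")
        )
        if e_ref.isna().any():
            raise DomainError("every scan must carry a reference effective dose")
        dlp = pd.to_numeric(X["dlp"], errors="coerce")
        if dlp.isna().any() or (dlp <= 0).any():
            raise DomainError("every scan must have dlp > 0")

        work = attach_strata(X, spec.axes)
        work = work.assign(_k=e_ref.to_numpy() / dlp.to_numpy())
        keys = ["body_region", *spec.axes]
        usable = np.ones(len(work), dtype=bool)
        for ax in spec.axes:
            usable &= pd.notna(work[ax]).to_numpy()
        self.n_dropped_axis_missing_ = int((~usable).sum())
        work = work[usable]
        self.n_used_ = len(work)
        if self.n_used_ == 0:
            raise EmptyDerivationError(
                "no scans carry the axis values required for this stratification"
            )

        q = work.groupby(keys, sort=True, dropna=False)["_k"].agg(
            n="size",
            median_k=lambda s: float(np.quantile(s, 0.5, method=spec.interpolation)),
            q25_k=lambda s: float(np.quantile(s, 0.25, method=spec.interpolation)),
            q75_k=lambda s: float(np.quantile(s, 0.75, method=spec.interpolation)),
        ).reset_index()
        self.n_suppressed_strata_ = int((q["n"] < spec.min_n).sum())
        q = q[q["n"] >= spec.min_n]
        if q.empty:
            warnings.warn(
                f"no stratum reached min_n={spec.min_n}; fitted table is empty",
                UserWarning,
                stacklevel=2,
            )
        q = q.rename(columns={"body_region": "region"})
        self.coefficient_table_ = CoefficientTable(q) if not q.empty else CoefficientTable(
            pd.DataFrame(columns=["region", "median_k", "q25_k", "q75_k", "n"]),
            validate=False,
        )
        self.strategy_ = _strategy_for_axes(spec.axes)
        self.n_features_in_ = X.shape[1]
        return self

    # -- prediction ------------------------------------------------------------

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """DLP-derived effective dose per scan, in mSv.

        NaN marks scans whose stratum is absent from the fitted table.
        """
        if not hasattr(self, "coefficient_table_"):
            raise DomainError("estimator is not fitted")
        k = self.lookup(X)
        return (pd.to_numeric(X["dlp"], errors="coerce") * k).to_numpy(dtype=float)

    def lookup(self, X: pd.DataFrame) -> pd.Series:
        """Median coefficient per scan (NaN where the stratum is missing)."""
        work = attach_strata(X, tuple(self.axes))
        keys = work[["body_region", *[a for a in AXIS_COLUMNS if a in tuple(self.axes)]]]
        keys = keys.rename(columns={"body_region": "region"})
        return self.coefficient_table_.lookup_frame(keys)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """R² of predictions against the reference dose, over scans whose
        stratum is present."""
        from sklearn.metrics import r2_score

        y_true = (
            np.asarray(y, dtype=float)
            if y is not None
            else pd.to_numeric(X["e_reference"], errors="coerce").to_numpy()
        )
        y_pred = self.predict(X)
        ok = np.isfinite(y_pred) & np.isfinite(y_true)
        return float(r2_score(y_true[ok], y_pred[ok]))
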