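"""Seed-reproducible synthetic CT scan registries.

Emulates the statistical structure of a multicenter pediatric CT dose
registry so that every pipeline stage — exclusion filtering, coefficient
derivation, DLP-derived estimation, agreement analysis — is testable without
proprietary registry data or a Monte Carlo organ-dose engine.

Structure generated per scan:

* body region ~ the registry's empirical region mix; age group ~ the
  region-conditional empirical mix, with age uniform within the group;
* mean effective diameter log-normal around an age-linear median
  (d0 + d1·age), absent for head/neck scans;
* DLP log-normal around a region-specific, age-increasing median (the source
  registry publishes no DLP distributions; the defaults are
  order-of-magnitude plausible and fully config-driven);
* reference effective dose E = k_true(stratum) · DLP · exp(sigma·Z), i.e.
  the true stratified coefficient under multiplicative log-normal error.
  Log-normal noise has median 1, so the per-stratum median of E/DLP is
  k_true in expectation and stratified-median derivation is
  median-unbiased. The default sigma is calibrated so the simulated
  per-scan coefficient IQR ratio q75/q25 matches the published head
  infant stratum (0.045/0.026 ≈ 1.73).

All randomness flows through one seeded generator with a fixed draw order
that depends only on the scan count, so two configs differing only in
``noise_sigma`` share every other random draw (common random numbers) — the
basis for the monotone noise-degradation properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coeftable import CoefficientTable
from .dose import AGE_EDGES, AGE_GROUPS, DIAMETER_BINS, assign_diameter_bins
from .errors import ConfigurationError, DomainError
from .registry import HEAD_NECK, REGIONS, SCAN_COLUMNS
from . import reference

_MISSINGNESS_FIELDS = ("mean_effective_diameter", "scan_length", "ctdi_vol", "mas")

#: Region-median DLP at age 0 (mGy·cm) — plausible scale only, config-driven.
#: Chosen so reference effective doses overlap across regions (as in real
#: registries): a region must not monopolise the global dose tails, or the
#: two-tail percentile trim would concentrate on it.
DEFAULT_DLP_BASE = {
    "head": 500.0, "neck": 100.0, "chest": 60.0, "cardiac": 60.0,
    "abdomen_pelvis": 150.0, "chest_abdomen_pelvis": 150.0, "spine": 200.0,
}
#: Region-median scan length at age 0 (cm).
DEFAULT_SCAN_LENGTH_BASE = {
    "head": 18.0, "neck": 20.0, "chest": 25.0, "cardiac": 18.0,
    "abdomen_pelvis": 35.0, "chest_abdomen_pelvis": 55.0, "spine": 40.0,
}


def _as_prob_vector(d: Mapping[str, float], keys: Sequence[str], name: str) -> np.ndarray:
    v = np.array([float(d.get(k, 0.0)) for k in keys])
    if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} must be a probability vector summing to 1")
    return v


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic registry generator.

    Defaults (see :func:`default_config`) reproduce the source registry's
    region / age / sex / manufacturer composition and its published
    stratified coefficients as the generating truth.
    """

    n_scans: int
    seed: int
    region_mix: Mapping[str, float]
    age_mix_by_region: Mapping[str, Sequence[float]]
    sex_female_by_region: Mapping[str, float]
    manufacturer_mix: Mapping[str, float]
    k_true: CoefficientTable
    noise_sigma: float
    diameter_d0: float = 11.0  # cm at age 0
    diameter_slope: float = 0.8  # cm per year
    diameter_sigma: float = 0.12  # log-scale dispersion
    dlp_base: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DLP_BASE))
    dlp_age_slope: float = 0.08  # relative median increase per year
    dlp_sigma: float = 0.5
    scan_length_base: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCAN_LENGTH_BASE)
    )
    scan_length_age_slope: float = 0.03
    scan_length_sigma: float = 0.15
    mas_median: float = 120.0
    mas_sigma: float = 0.4
    kvp_levels: Sequence[float] = (80.0, 100.0, 120.0)
    kvp_probs: Sequence[float] = (0.25, 0.35, 0.40)
    perfusion_rate: float = 0.005
    missingness_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "mean_effective_diameter": 0.01,
            "scan_length": 0.01,
            "ctdi_vol": 0.01,
            "mas": 0.01,
        }
    )
    head_neck_diameter_missing: float = 1.0

    def validate(self) -> None:
        if self.n_scans < 1:
            raise ConfigurationError("n_scans must be >= 1")
        if self.noise_sigma < 0 or self.diameter_sigma < 0 or self.dlp_sigma < 0:
            raise ConfigurationError("dispersions must be non-negative")
        _as_prob_vector(self.region_mix, REGIONS, "region_mix")
        _as_prob_vector(self.manufacturer_mix, list(self.manufacturer_mix), "manufacturer_mix")
        for region, mix in self.age_mix_by_region.items():
            v = np.asarray(mix, dtype=float)
            if len(v) != len(AGE_GROUPS) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"age mix for {region!r} must be a length-5 probability vector"
                )
        kp = np.asarray(self.kvp_probs, dtype=float)
        if abs(kp.sum() - 1.0) > 1e-9:
            raise ConfigurationError("kvp_probs must sum to 1")
        if not (0.0 <= self.perfusion_rate < 1.0):
            raise ConfigurationError("perfusion_rate must lie in [0, 1)")
        for region, p in self.region_mix.items():
            if p > 0 and region not in self.k_true.regions():
                raise ConfigurationError(
                    f"region {region!r} has sampling mass but no k_true strata"
                )

    # -- (de)serialisation for provenance files -------------------------------

    def to_dict(self) -> dict:
        out = {}
        for key, val in vars(self).items():
            if isinstance(val, CoefficientTable):
                out[key] = val.frame.where(val.frame.notna(), None).to_dict("records")
            elif isinstance(val, Mapping):
                out[key] = {k: (list(map(float, v)) if isinstance(v, (list, tuple, np.ndarray)) else float(v)) for k, v in val.items()}
            elif isinstance(val, (list, tuple, np.ndarray)):
                out[key] = [float(x) for x in val]
            elif isinstance(val, (np.floating, np.integer)):
                out[key] = val.item()
            else:
                out[key] = val
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        d["k_true"] = CoefficientTable.from_records(d["k_true"])
        return cls(**d)


def default_config(
    n_scans: int = 10_000,
    seed: int = 0,
    k_true: Optional[CoefficientTable] = None,
    noise_sigma: Optional[float] = None,
) -> SyntheticConfig:
    """Generator config matching the source registry's published structure.

    Region, region×age, sex, and manufacturer mixes equal the registry's
    empirical proportions; ``k_true`` defaults to the published age-stratified
    coefficient medians; ``noise_sigma`` defaults to the value matching the
    published head infant IQR ratio.
    """
    comp = reference.load_registry_composition()
    total = comp["total"].sum()
    region_mix = {r: comp.loc[r, "total"] / total for r in REGIONS}
    age_cols = ["age_lt1", "age_1_4", "age_5_9", "age_10_14", "age_15_21"]
    age_mix = {
        r: (comp.loc[r, age_cols] / comp.loc[r, "total"]).to_list() for r in REGIONS
    }
    sex_female = {r: comp.loc[r, "female"] / comp.loc[r, "total"] for r in REGIONS}
    manu_cols = ["GE", "Siemens", "Philips", "Canon"]
    manu_mix = {m: comp[m].sum() / total for m in manu_cols}
    table = k_true if k_true is not None else reference.load_age_coefficients()
    if noise_sigma is None:
        row = table.frame
        head_inf = row[(row["region"] == "head") & (row["age_group"] == "<1")]
        if not head_inf.empty and pd.notna(head_inf["q25_k"].iloc[0]):
            iqr_ratio = float(head_inf["q75_k"].iloc[0] / head_inf["q25_k"].iloc[0])
        else:
            iqr_ratio = 1.73
        noise_sigma = float(np.log(iqr_ratio) / (2 * stats.norm.ppf(0.75)))
    return SyntheticConfig(
        n_scans=n_scans,
        seed=seed,
        region_mix=region_mix,
        age_mix_by_region=age_mix,
        sex_female_by_region=sex_female,
        manufacturer_mix=manu_mix,
        k_true=table,
        noise_sigma=noise_sigma,
    )


def _effective_age_mix(config: SyntheticConfig) -> np.ndarray:
    """Region-conditional age mix with strata absent from k_true zeroed.

    A stratum the truth table does not cover (e.g. spine under 1 year,
    suppressed in the published table) is never sampled; remaining mass is
    renormalised within the region. Regions sampled via a non-age truth table
    keep their full mix.
    """
    kf = config.k_true.frame
    has_age = "age_group" in config.k_true.axes
    mix = np.zeros((len(REGIONS), len(AGE_GROUPS)))
    for i, region in enumerate(REGIONS):
        v = np.asarray(config.age_mix_by_region.get(region, [0.2] * 5), dtype=float)
        if has_age:
            rows = kf[kf["region"] == region]
            if rows["age_group"].notna().any():
                present = set(rows.loc[rows["age_group"].notna(), "age_group"])
                v = np.where([g in present for g in AGE_GROUPS], v, 0.0)
        if v.sum() > 0:
            v = v / v.sum()
        mix[i] = v
    return mix


def _k_lookup_maps(table: CoefficientTable):
    """Per-region lookup dicts for the generating truth, with nearest-bin
    fallback along ordered axes so clamped diameters at the table edge take
    the edge stratum's coefficient."""
    kf = table.frame
    axes = table.axes
    maps: dict = {}
    for region, grp in kf.groupby("region"):
        if "age_group" in axes and "diameter_bin" in axes:
            maps[region] = {
                (r["age_group"], r["diameter_bin"]): r["median_k"]
                for _, r in grp.iterrows()
            }
        elif "diameter_bin" in axes:
            maps[region] = {r["diameter_bin"]: r["median_k"] for _, r in grp.iterrows()}
        else:
            maps[region] = {r["age_group"]: r["median_k"] for _, r in grp.iterrows()}
    return maps, axes


def _nearest_key(present: Sequence[str], order: Sequence[str], want: str) -> str:
    if want in present:
        return want
    iw = order.index(want)
    return min(present, key=lambda p: abs(order.index(p) - iw))


def _resolve_k_true(
    config: SyntheticConfig,
    regions: np.ndarray,
    age_groups: np.ndarray,
    diameters: np.ndarray,
) -> np.ndarray:
    maps, axes = _k_lookup_maps(config.k_true)
    if "diameter_bin" in axes:
        bins, _ = assign_diameter_bins(diameters, warn=False)
    k = np.empty(len(regions))
    for i, region in enumerate(regions):
        table = maps.get(region)
        if table is None:
            raise ConfigurationError(f"k_true covers no strata for region {region!r}")
        if "age_group" in axes and "diameter_bin" in axes:
            ags = sorted({a for a, _ in table}, key=AGE_GROUPS.index)
            ag = _nearest_key(ags, AGE_GROUPS, age_groups[i])
            dbs = [d for a, d in table if a == ag]
            db = _nearest_key(sorted(dbs, key=DIAMETER_BINS.index), DIAMETER_BINS, bins[i])
            k[i] = table[(ag, db)]
        elif "diameter_bin" in axes:
            db = _nearest_key(
                sorted(table, key=DIAMETER_BINS.index), DIAMETER_BINS, bins[i]
            )
            k[i] = table[db]
        else:
            if age_groups[i] not in table:
                raise ConfigurationError(
                    f"sampled stratum ({region}, {age_groups[i]}) missing from k_true"
                )
            k[i] = table[age_groups[i]]
    return k


def generate_registry(config: SyntheticConfig) -> pd.DataFrame:
    """Generate ``config.n_scans`` synthetic scan records.

    Deterministic for a fixed seed; records include ``e_reference`` (the
    reference effective dose with multiplicative log-normal error) and
    ``is_perfusion``, so exclusion filters can be exercised.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_scans

    region_p = _as_prob_vector(config.region_mix, REGIONS, "region_mix")
    region_idx = np.searchsorted(np.cumsum(region_p), rng.random(n), side="right")
    region_idx = region_idx.clip(0, len(REGIONS) - 1)

    age_mix = _effective_age_mix(config)
    age_cum = np.cumsum(age_mix, axis=1)
    u_age = rng.random(n)
    group_idx = (u_age[:, None] > age_cum[region_idx]).sum(axis=1).clip(0, 4)

    return _assemble(config, rng, region_idx, group_idx)


def generate_balanced_registry(
    config: SyntheticConfig, n_per_stratum: int
) -> pd.DataFrame:
    """Exactly ``n_per_stratum`` scans in every (region × age group) stratum
    of the truth table. Requires an age-stratified ``k_true``; used for
    parameter-recovery studies where sampling noise per stratum must be
    controlled."""
    config.validate()
    if "age_group" not in config.k_true.axes:
        raise ConfigurationError("balanced generation requires an age-stratified k_true")
    kf = config.k_true.frame
    pairs = [
        (REGIONS.index(r), AGE_GROUPS.index(g))
        for r, g in zip(kf["region"], kf["age_group"])
        if pd.notna(g)
    ]
    region_idx = np.repeat([p[0] for p in pairs], n_per_stratum)
    group_idx = np.repeat([p[1] for p in pairs], n_per_stratum)
    rng = np.random.default_rng(config.seed)
    return _assemble(config, rng, region_idx, group_idx)


def _assemble(
    config: SyntheticConfig,
    rng: np.random.Generator,
    region_idx: np.ndarray,
    group_idx: np.ndarray,
) -> pd.DataFrame:
    """Draw every per-scan field in a fixed order (common random numbers)."""
    n = len(region_idx)
    regions = np.array(REGIONS, dtype=object)[region_idx]

    lo = AGE_EDGES[group_idx]
    hi = AGE_EDGES[group_idx + 1]
    age = lo + rng.random(n) * (hi - lo)
    age_groups = np.array(AGE_GROUPS, dtype=object)[group_idx]

    female_p = np.array(
        [config.sex_female_by_region.get(r, 0.5) for r in REGIONS]
    )[region_idx]
    sex = np.where(rng.random(n) < female_p, "F", "M").astype(object)

    manu_names = list(config.manufacturer_mix)
    manu_p = np.array([config.manufacturer_mix[m] for m in manu_names])
    manu_idx = np.searchsorted(np.cumsum(manu_p), rng.random(n), side="right")
    manufacturer = np.array(manu_names, dtype=object)[manu_idx.clip(0, len(manu_names) - 1)]

    diam_median = config.diameter_d0 + config.diameter_slope * age
    diameter = diam_median * np.exp(config.diameter_sigma * rng.standard_normal(n))
    u_diam_missing = rng.random(n)

    sl_base = np.array([config.scan_length_base[r] for r in REGIONS])[region_idx]
    scan_length = (
        sl_base
        * (1.0 + config.scan_length_age_slope * age)
        * np.exp(config.scan_length_sigma * rng.standard_normal(n))
    )

    dlp_base = np.array([config.dlp_base[r] for r in REGIONS])[region_idx]
    dlp = (
        dlp_base
        * (1.0 + config.dlp_age_slope * age)
        * np.exp(config.dlp_sigma * rng.standard_normal(n))
    )
    ctdi_vol = dlp / scan_length

    mas = config.mas_median * np.exp(config.mas_sigma * rng.standard_normal(n))
    kvp_cum = np.cumsum(np.asarray(config.kvp_probs, dtype=float))
    kvp_idx = np.searchsorted(kvp_cum, rng.random(n), side="right")
    kvp = np.asarray(config.kvp_levels, dtype=float)[kvp_idx.clip(0, len(kvp_cum) - 1)]

    z_noise = rng.standard_normal(n)
    k_true = _resolve_k_true(config, regions, age_groups, diameter)
    e_reference = k_true * dlp * np.exp(config.noise_sigma * z_noise)

    is_perfusion = rng.random(n) < config.perfusion_rate

    # missingness draws: fixed field order
    missing_u = {f: rng.random(n) for f in _MISSINGNESS_FIELDS}

    head_neck = np.isin(regions, HEAD_NECK)
    diam_missing_p = np.where(
        head_neck,
        config.head_neck_diameter_missing,
        config.missingness_rates.get("mean_effective_diameter", 0.0),
    )
    diameter = np.where(u_diam_missing < diam_missing_p, np.nan, diameter)
    scan_length = np.where(
        missing_u["scan_length"] < config.missingness_rates.get("scan_length", 0.0),
        np.nan, scan_length,
    )
    ctdi_vol = np.where(
        missing_u["ctdi_vol"] < config.missingness_rates.get("ctdi_vol", 0.0),
        np.nan, ctdi_vol,
    )
    mas = np.where(
        missing_u["mas"] < config.missingness_rates.get("mas", 0.0), np.nan, mas
    )

    frame = pd.DataFrame(
        {
            "scan_id": [f"syn-{i:06d}" for i in range(n)],
            "body_region": regions,
            "age": age,
            "sex": sex,
            "mean_effective_diameter": diameter,
            "dlp": dlp,
            "ctdi_vol": ctdi_vol,
            "scan_length": scan_length,
            "kvp": kvp,
            "mas": mas,
            "manufacturer": manufacturer,
            "reporting_phantom": np.where(regions == "head", "16cm", "32cm"),
            "is_perfusion": is_perfusion,
            "e_reference": e_reference,
        },
        columns=list(SCAN_COLUMNS),
    )
    return frame
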