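# Methods

## Model

dosekit implements the conversion-coefficient view of CT dosimetry. The
per-scan conversion coefficient is the ratio

    k = E_ref / DLP        [mSv per mGy·cm],

where E_ref is a reference effective dose (in practice, Monte Carlo organ-dose
simulation aggregated with ICRP-103 tissue weights) and DLP the
scanner-reported dose length product. Coefficients are summarised per stratum
— body region crossed with any of age group, diameter bin, and manufacturer —
as the stratum **median** with 25th/75th percentiles, never as a mean: k is a
ratio quantity with right-skewed dispersion, and the median is robust to that
skew. A DLP-derived dose for a new scan is then Ê = DLP × median k of its
stratum.

Effective-dose aggregation uses the ICRP Publication 103 weighting set with
the 13 remainder tissues pooled into a single "remainder" label at weight
0.12 applied to a caller-supplied mean remainder dose; full remainder
arithmetic is out of scope because organ doses enter this package only as
pre-computed inputs. Photon radiation is assumed throughout, so equivalent
dose equals absorbed dose numerically.

### Strata

- Age groups (half-open): [0,1), [1,5), [5,10), [10,15), [15,22) years. The
  upper study edge is 22: enrolment spans 0–21-year-olds, with 18–21-year-olds
  deliberately under-sampled (see subsampling below). An exactly-1-year-old
  falls in "1-4"; the edge convention is half-open upward because no published
  convention states otherwise.
- Diameter bins: contiguous half-open integer-edge bins [11,16) … [36,41) cm.
  Diameters outside 11–40 cm clamp to the nearest bin with a warning rather
  than erroring — real registries contain such scans, and the exclusion
  pipeline already trims distributional tails.
- Head and neck scans are never diameter-stratified: their reference doses are
  age-matched only. A diameter-involving lookup on head/neck falls back to the
  age strategy with a notice.
- Strata with fewer than `min_n` scans (default 10) are omitted from derived
  tables, never zero-filled; lookups on a missing stratum raise (scalar API)
  or yield NaN (vectorised API), and downstream agreement code counts such
  scans separately.
- Coefficients are not stratified by reporting phantom (16 vs 32 cm): phantom
  use is near-uniform within body region in practice, so the field is carried
  for audit only.

### Percentile convention

Stratum quantiles use linear interpolation between order statistics
(`numpy.quantile`, method="linear"). Medians are unaffected by the choice of
convention; quartile differences between conventions are negligible at
registry stratum sizes and the method is configurable
(`StrataSpec.interpolation`).

### Relative coefficients

For a region and axis, the relative coefficient is the ratio of the
extreme-stratum medians: youngest-available over oldest-available age group,
or smallest over largest diameter bin. "Available" matters: a suppressed
stratum (e.g. spine under 1 year) makes the next stratum the extreme. The
ratio is reported both raw and rounded to one decimal with
**half-away-from-zero** rounding (banker's rounding would round a midpoint
ratio like 6.875 to 6.8 instead of 6.9, breaking agreement with the published
one-decimal values, which were rounded half-up). When computed on the packaged
published tables the ratios are of already-rounded printed medians, which is
what reproduces the printed relative coefficients exactly; on derived tables
the ratio is of unrounded medians, and both values are always returned.

## Exclusion cascade

`apply_exclusions` applies, in order, attributing each removal to the first
rule that fires so the log reconciles exactly:

1. perfusion scans;
2. missing body region / age / DLP, or "erroneous" values — operationalised
   as non-positive DLP, CTDI-vol, diameter, or scan length, or age outside
   [0, 22) (no published definition of "erroneous" exists; this is the
   package's own);
3. two-tail percentile trimming (default 1% per tail) on CTDI-vol, DLP,
   diameter, scan length, reference dose, and mAs jointly, with quantile
   bounds computed once on the set surviving steps 1–2. A record missing an
   optional variable is not trimmed on it; records **equal** to a boundary are
   retained (strictly-outside rule — conservative and deterministic under
   ties). Bounds are global across regions by default, matching the
   single-pass phrasing of registry practice; `per_region=True` computes them
   within regions instead.

As a scikit-learn transformer, `ExclusionFilter.fit` learns the trim bounds
and `transform` applies the cascade, so bounds learned on one table can be
applied to another.

Age-band subsampling (`subsample_age_band`) keeps each scan aged 18–22
independently with probability `fraction` (default 0.05) under a seeded
generator — per-record Bernoulli draws rather than an exact-count draw, which
keeps the operation streamable and seed-stable.

## Agreement statistics

Pearson r between DLP-derived and reference doses per region × strategy, with
a Fisher-z interval `tanh(arctanh r ± z_{1-α/2}/√(n−3))` (a percentile
bootstrap is available). The error-rate metric is the percentage of scans with
|Ê − E_ref| / E_ref **≥** threshold (default 0.5). The reference dose is
always the denominator. The ≥ (inclusive) reading is the default and
configurable (`inclusive=False` for strict >).

Legacy coefficient sets keyed by single reference ages ("0 year old" …
"adult") are applied through an explicit age-group→label map (default:
&lt;1→"0 year old", 1-4→"1 year old", 5-9→"5 years old", 10-14→"10 years old",
15-21→"adult"). No legacy values are packaged; they are user-supplied inputs.

The per-strategy report covers age, diameter, age_diameter, manufacturer_age,
and legacy strategies. A single-year age stratification is not implemented;
the five standard pediatric age groups are the package's resolution.

## Synthetic registry generator

The generator's defaults *are* the study conditions the rest of the package is
validated under:

- region / region×age / sex / manufacturer mixes equal the packaged registry
  composition (128,397 scans; head 53.6%, cardiac 0.4%, …);
- k_true defaults to the published region × age coefficient medians; a
  stratum absent from k_true (spine &lt;1) is never sampled — its
  region-conditional age mass is renormalised away;
- E_ref = k_true(stratum) · DLP · exp(σ·Z) with Z standard normal.
  Multiplicative log-normal error is chosen because per-scan coefficients are
  ratio quantities with right-skewed published IQRs, and log-normal noise has
  median 1, making stratum-median recovery exact in expectation. Default
  σ = ln(0.045/0.026)/(2·z₀.₇₅) ≈ 0.407, calibrated so the simulated q75/q25
  coefficient ratio matches the published head infant stratum (≈1.73);
- diameter is log-normal around an age-linear median 11 + 0.8·age cm
  (σ=0.12 log-scale), absent for head/neck; its effect on E_ref enters only
  through k_true stratification, not an independent attenuation model;
- DLP is log-normal (σ=0.5) around region medians rising 8%/year of age.
  No DLP distributions are published, so these are the package's own
  plausible choices; region age-0 medians (head 500, neck 100, chest 60,
  cardiac 60, abdomen/pelvis 150, combined CAP 150, spine 200 mGy·cm) are
  set so reference-dose distributions overlap across regions — in a real
  registry no single region monopolises the global dose tails, and a default
  where one did would let the global 1% trim silently delete a rare region.
  No test depends on DLP locations;
- scan length is log-normal around region medians (+3%/year); CTDI-vol is
  DLP / scan length, keeping the three technical fields consistent;
- perfusion flags (0.5%) and small missingness rates (1% per optional
  technical field) exist to exercise the filters;
- sex follows the registry's per-region proportions but never influences
  dose (no sex-specific coefficients exist);
- 18–21-year-olds are generated at their pre-subsampling share so the
  subsampling operation can be exercised downstream.

All draws flow through one `numpy` generator in a fixed order that depends
only on the scan count, so two configs differing only in `noise_sigma` share
every other draw (common random numbers). This makes noise-monotonicity
properties (raising σ lowers r and raises the error rate) hold pathwise on a
fixed seed, not just in expectation. `generate_balanced_registry` forces an
exact scan count per (region × age group) stratum for parameter-recovery
studies.

During generation, truth lookup falls back to the nearest populated bin along
an ordered axis (age or diameter) when a clamped value lands outside the
truth table's coverage — the true coefficient saturates at the table edge.

### What the generator does not emulate

No anatomy, beam physics, tube-current modulation, scanner-model effects, or
diameter-conditional DLP (size affects dose only through stratified k_true).
Manufacturer is sampled but does not modulate dose, consistent with the
minimal manufacturer differences in published coefficients. Consequently,
passing tests demonstrate that the *pipeline arithmetic* (filtering,
stratified-median derivation, lookup estimation, agreement metrics) is
correct and statistically consistent — not that the packaged coefficients are
accurate for any particular real scanner population.

## Problem sizes and numerical tolerances

- Parameter recovery: 2,000 scans per stratum (34 strata, 68,000 scans),
  default noise → every derived stratum median within 5% of truth (the
  median's relative standard error is ≈ σ·1.2533/√n ≈ 1.1%, so 5% is > 4
  standard errors); noiseless recovery is exact to machine precision.
- Self-consistency: 15,000–20,000-scan registries; noiseless estimation with
  the generating table gives r = 1 within 1e-12 and a 0% error rate.
- The full loop (generate → exclude → derive → estimate → agree) at
  n = 100,000 runs in a few seconds on one CPU.
- ICRP weight-sum check at 1e-12; dose round-trips at relative 1e-12.

## Known limitations

- "Erroneous data" has no published operational definition; ours is explicit
  but necessarily a guess.
- Whether the original trimming was joint or sequential per variable is
  unknown; dosekit trims jointly against bounds from one reference pass, and
  attributes multi-variable outliers to the first variable in the configured
  order.
- Published diameter tables carry no per-stratum counts; the packaged fixture
  leaves `n` blank, and the minimum-count invariant is enforced only on
  derived tables.
- Real-registry agreement values (correlations ~0.5–0.8, ≥50%-error rates
  ~13–31%) depend on proprietary per-scan Monte Carlo doses and cannot be
  reproduced from published material; the synthetic analogues here are
  structural stand-ins with the same report format and qualitative behaviour.
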