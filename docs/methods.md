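# Methods

## Overview

`attanest` chains five stages: solar geometry → irradiance quality control
and daily integration → agreement scoring → chamber geometry → comparison
battery, with a synthetic generator standing in for field inputs. This note
records the models, the parameter choices and their rationale, the numerical
decisions, and what the synthetic closed loop does and does not demonstrate.

## Solar geometry

The extraterrestrial (top-of-atmosphere) irradiance is
`I_E = S0 (1/R) cos Z` with `S0 = 1361 W/m²`. `R` (dimensionless Earth–Sun
distance ratio) and the solar declination `δ` are truncated Fourier series
in the angular fraction of the year `F = 360·D/365` (degrees, `D` the day
of year on 1–365); the hour angle is `ω = (12 − Hd)·15` for decimal hour
`Hd`, and `cos Z = sin δ sin Φ + cos δ cos Φ cos ω`.

Numerical and interface decisions:

* **All trigonometric arguments are degrees** and converted internally.
* **Latitude is signed** (southern hemisphere negative; the default site is
  −22.85°). Declination and hour angle are hemisphere-agnostic; only
  `cos Z` depends on the sign.
* The `2F` harmonic of the distance-ratio series enters as a **sine** term:
  the series alternates sine and cosine harmonics (its neighbours are
  `sin 3F` and `cos 4F`), which fixes the functional form.
* **Night floor:** `cos Z < 0` maps to `I_E = 0` rather than a negative
  irradiance, so `I_E` is a valid non-negative ceiling for measurements.
* `Hd` is taken as the timestamp's clock time; no equation-of-time or
  longitude correction is applied (a few minutes' offset in solar noon,
  irrelevant to limit screening). Day 366 of leap years is clamped to 365.

Coefficient-magnitude bounds (`|δ| ≤ 27.7°`, `R ∈ (0.96, 1.04)`,
`I_E ≤ 1420 W/m²`) are asserted as properties.

## Quality control and integration

Five-minute means are screened against the physically-possible tier only:
GHI accepted iff `0 < value < 1.20·I_E`, DHI iff `0 < value < I_E`. The 20%
GHI headroom exists because cloud multireflection can transiently push
global irradiance above the extraterrestrial value. Decisions:

* **Strict inequalities.** Exactly 0 or exactly at the ceiling is rejected.
  Night samples (I_E = 0, value 0) are therefore rejected as non-positive;
  this costs nothing since their energy contribution would be zero, and it
  keeps one rule instead of a special case.
* **Rejected samples are missing, not interpolated.** The daily total is
  the sum over accepted samples (`value · 300 s / 10⁶` MJ/m² each), with
  coverage = accepted/(accepted+rejected) reported per day. A configurable
  minimum-coverage filter (default 0, i.e. keep all days) records the
  gap-handling decision without guessing; note that with night samples
  always rejected, full-day coverage is structurally below 1, so the filter
  is interpreted against that baseline.
* **Fixed 300 s grid.** Irregular timestamp spacing raises an error rather
  than silently reweighting the integral.

Monthly summaries are arithmetic mean ± sample standard deviation (n−1);
empty months are omitted with a warning.

## Willmott agreement

`d = 1 − Σ(Aᵢ−Bᵢ)² / Σ(|A′ᵢ|+|B′ᵢ|)²` with `A′ᵢ = Aᵢ − B̄`,
`B′ᵢ = Bᵢ − B̄`: the standard potential-error denominator centered on the
reference mean. Term-wise `(Aᵢ−Bᵢ)² ≤ (|A′ᵢ|+|B′ᵢ|)²`, so `d ∈ [0, 1]`,
and `d` is invariant to a common additive shift. If the denominator is
zero (both series constant and equal to B̄) the pair is a degenerate
perfect match and `d = 1`.

A literal variant with denominator `Σ(|Aᵢ|−|Bᵢ|)²` (uncentered,
differenced) circulates in some write-ups; it is undefined (0/0) for any
identical pair, contradicting the index's defining property. It is kept
behind an explicit off-by-default flag for auditability and returns NaN on
a vanishing denominator. Callers must state the reference series (B); the
pipeline uses the shaded plot as reference for cross-environment pairs and
the external series for inside/outside pairs. Pairing is by timestamp
intersection with unpaired observations dropped and counted; months with
fewer than two pairs are omitted with a warning.

## Chamber geometry

`V = πr²((h − r) + 0.67r)`: a cylinder of height `ch = h − r` plus a
rounded cap approximated by the empirical 0.67 factor (a hemisphere would
be 2/3 ≈ 0.667, so at `h = r` the formula is within 0.5% of a hemisphere —
an exact boundary the tests treat with a float-round-off allowance).
Preconditions: `r ≥ 0`, `h ≥ r`.

The field protocol measures width and length, not a radius. The default
conversion is the mean horizontal semi-axis `r = (w + l)/4`, chosen to use
both measured axes while preserving the cylindrical formula; `min`, `max`
and `geometric` rules are selectable and the rule used is recorded in
output metadata. Reported mean volumes are always means of per-nest
volumes, never the volume of mean dimensions (Jensen gap).

## Comparison battery

* **Equal proportions.** Pearson chi-square on the 2×2 deaths table,
  closed form `X² = N(ad−bc)²/(R₁R₂C₁C₂)`, 1 df, two-sided; optional Yates
  correction subtracting N/2 from |ad−bc|. Both variants are reported by
  the pipeline. A zero marginal raises.
* **Routing.** Shapiro–Wilk (scipy) at α = 0.05 on the pooled response:
  p ≥ α → parametric. A constant sample routes nonparametric (W is
  undefined; no normal model can be asserted). Per-variable overrides are
  exposed; the pipeline forces chamber *volume* to the nonparametric
  (median-comparison) branch and gates the linear dimensions. Note the gate
  sees the pooled two-environment sample, so a strong environment effect
  itself produces non-normality and a nonparametric route — a conservative
  and explicit behavior.
* **ANOVA branch.** Two-way factorial ANOVA (statsmodels OLS, type-II sums
  of squares) with F tests for environment, month and interaction; Tukey
  HSD per factor; complete cells required.
* **Scheirer–Ray–Hare.** Pooled mid-ranks; factorial sums of squares on the
  ranks; `H_effect = SS_effect / MS_total` with `MS_total = SS_total/(N−1)`,
  referred to χ² with the effect's df. Mid-ranking makes `MS_total` the
  tie-adjusted rank variance, so no separate tie factor is needed. Balanced
  designs (and designs with one single-level factor) use the exact
  cell-mean decomposition; unbalanced designs use type-II rank sums of
  squares. With one factor constant the other factor's H reduces exactly to
  tie-corrected Kruskal–Wallis — the oracle-equivalence test. All responses
  tied raises (zero rank variance).
* **Dunn.** `z_ij = (R̄ᵢ−R̄ⱼ)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)]`,
  two-sided normal p, Benjamini–Hochberg adjustment by default.
* **Letters.** Insert-and-absorb on the pairwise significance matrix:
  start from one column holding all groups; for each significant pair
  co-resident in a column, split the column; absorb subset columns; assign
  letters by the best group each column contains. Groups are ordered by
  mean (Tukey) or mean rank (Dunn), descending, ties broken by label.

## Synthetic generator

The generator defines the study conditions: 2 plots (sunny = GHI,
shaded = DHI under a screen), 4 study months × 30 days of 288 five-minute
samples, 100 nests per environment with a quarter excavated each month.

* **Irradiance** is multiplicative on the clear-sky envelope:
  `value = I_E(t)·τ(t)` with daily mean transmittance ~N(0.50, 0.15²) and
  within-day noise (sd 0.05), clipped to (0.02, 1]; with probability 0.01
  per daytime sample a multireflection spike replaces the value with
  `I_E·U(1.05, 1.35)`, straddling the 1.20 ceiling so both QC outcomes
  occur. Mean transmittance 0.5 puts sunny daily totals near 20 MJ/m² in
  the southern early summer, inside the observed 17.5–21.3 MJ/m² monthly
  band. The shaded series is additionally scaled by an effective
  transmittance of 0.25 — calibrated to the observed shaded totals
  (2.3–7.5 MJ/m²), not to the screen's nominal 50% rating; the two
  disagree and the measured totals win.
* **Temperatures.** External = plot mean + diurnal half-amplitude (6.0 °C
  sunny, 3.5 °C shaded, peaking mid-afternoon) + irradiance-coupled term
  (1.5–2 °C per kW/m²) + Gaussian noise. Internal (chamber, 15 cm) =
  external mean + offset (2.2 / 1.3 °C) + damping × (2 h-smoothed, 2
  h-lagged external anomaly) + small noise. Damping 0.22 (sunny) and 0.55
  (shaded) reproduce the observed variance pattern — internal sd ≈ 1 vs
  external ≈ 4–6 in the sun, internal ≈ 1.4–1.8 vs external ≈ 3 in the
  shade — and make inside/outside agreement higher in the shade, the
  qualitative signature the analysis is meant to detect.
* **Colonies.** Queen death ~ Bernoulli(0.91 sunny / 0.58 shaded).
  Chamber dimensions ~ Normal around the environment means (depth
  9.21/13.18, width 2.43/3.41, length 3.34/4.52, height 2.62/3.66 cm) with
  field-plausible per-nest sds (1.2/0.45/0.55/0.45 cm); height is clamped
  to ≥ the derived radius so the cap model stays valid. Census counts are
  negative-binomial (k = 8) around monthly mean trajectories (eggs rising
  25 → 115.5 by month 3); sunny counts and fungus are scaled by 0.6
  (poorer development in the sun). Queen mass interpolates 658.5 →
  229.45 mg linearly; fungus biomass grows geometrically 64.5 → 1354.9 mg;
  queen mass is common to both environments (it is observed to be similar).
  The mass/fungus anchor pairing follows the stated order of the source
  values; dispersions are config parameters since only means are reported.

What the closed loop shows: the pipeline's own estimators recover the
generator's parameters (mortality proportions inside exact binomial
intervals, irradiation envelopes, variance ordering, the shade contrast)
and the QC invariants hold under spike injection. What it does not show:
performance on real recordings — the generator has no autocorrelated
multi-day weather regimes, no rainfall, no sensor drift or missing-data
bursts, no within-nest repeated measures, and its independence assumptions
are exactly the test battery's assumptions.

## Problem sizes and calibration checks

Error-rate calibrations run at the study's own design size: the
Scheirer–Ray–Hare null uses 2 × 4 cells of 25 (N = 200, the layout implied
by 100 nests per environment excavated 25% per month) with 2000 replicates;
Dunn/BH null control uses 3 groups of 10 with 2000 replicates; mortality
recovery uses 100 seeded colony simulations at n = 100 per environment.
Unit tests elsewhere use scaled-down studies (4-day months, 40 nests) purely
for speed; the defaults above are the study conditions.

## Known limitations

* The QC implements only the physically-possible tier, not the rare /
  extremely-rare tiers of full BSRN-style screening.
* The Shapiro–Wilk gate on pooled samples conflates treatment effects with
  non-normality; gating on residuals is a reasonable alternative the
  routing overrides can emulate.
* Mortality is modelled as a single end-of-phase Bernoulli, not an
  event-history process; no survival-time analysis is attempted.
* The hour variable is clock time; sites far from their time-zone meridian
  would shift the solar-noon peak by up to ~30 minutes.
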