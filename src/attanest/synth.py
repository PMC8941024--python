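"""Synthetic field study generator.

Emulates the three inputs of a two-environment (sunny vs shaded) nest-
founding experiment so the whole pipeline is testable without the
undeposited field recordings:

* 5-minute irradiance — a clear-sky envelope I_E(t) modulated by bounded
  stochastic cloud transmittance, with rare multireflection spikes that
  exceed I_E so the quality-control rejection paths are exercised.  The
  sunny plot measures GHI; the shaded plot measures DHI under a screen
  whose effective transmittance is calibrated to the observed shaded
  daily totals (2-8 MJ/m^2), not the screen's nominal 50% rating.
* temperatures — external air temperature with a diurnal cycle coupled to
  irradiance, and an internal (chamber, 15 cm deep) series that is a
  damped, lagged, smoothed transform of the external one, so the internal
  sd is always below the external sd.
* colonies — nest founding, Bernoulli queen survival (defaults 0.91 dead
  in the sun, 0.58 in the shade), monthly excavation of a quarter of the
  nests, chamber dimensions around environment-specific means, and
  overdispersed census counts following monthly mean trajectories
  (queen mass declining 658.5 -> 229.45 mg, fungus garden growing
  64.5 -> 1354.9 mg over the four claustral months).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import solar
from .stats import MortalityTable

__all__ = [
    "CloudParams",
    "TemperatureParams",
    "SyntheticConfig",
    "simulate_irradiance_day",
    "simulate_temperatures",
    "simulate_colonies",
    "simulate_study",
]

ENVIRONMENTS = ("sunny", "shaded")
#: irradiance component measured in each plot
ENV_COMPONENT = {"sunny": "GHI", "shaded": "DHI"}

SAMPLES_PER_DAY = 288  # 5-minute cadence
BASE_YEAR = 2019  # nuptial flights late Oct / early Nov


@dataclass(frozen=True)
class CloudParams:
    """Multiplicative cloud field on the clear-sky envelope."""

    mean_transmittance: float = 0.50
    daily_sd: float = 0.15  # day-to-day variation of the daily mean
    within_day_sd: float = 0.05
    spike_probability: float = 0.01  # per daytime sample
    spike_lo: float = 1.05  # spike value as a multiple of I_E
    spike_hi: float = 1.35

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_transmittance <= 1.0:
            raise ValueError("mean transmittance must be in (0, 1]")
        if not 0.0 <= self.spike_probability <= 1.0:
            raise ValueError("spike probability must be in [0, 1]")


@dataclass(frozen=True)
class TemperatureParams:
    """External diurnal cycle and the damped internal (15 cm) response."""

    external_mean: float  # deg C
    diurnal_amplitude: float  # deg C, half peak-to-trough
    irradiance_gain: float = 1.5  # deg C per kW/m^2
    external_noise_sd: float = 0.8
    internal_offset: float = 2.0  # chamber runs warmer than air on average
    damping: float = 0.3  # fraction of the external anomaly reaching 15 cm
    lag_steps: int = 24  # 2 h at 5-min cadence
    smooth_steps: int = 24
    internal_noise_sd: float = 0.2


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    latitude: float = solar.DEFAULT_LATITUDE
    months: int = 4
    days_per_month: int = 30
    start_day_of_year: int = 309  # Nov 5: foundation after the nuptial flight
    nests_per_env: int = 100
    shade_transmittance: float = 0.25
    cloud: CloudParams = field(default_factory=CloudParams)
    temperature: dict = field(
        default_factory=lambda: {
            "sunny": TemperatureParams(
                external_mean=23.4,
                diurnal_amplitude=6.0,
                internal_offset=2.2,
                damping=0.22,
            ),
            "shaded": TemperatureParams(
                external_mean=22.7,
                diurnal_amplitude=3.5,
                irradiance_gain=2.0,
                external_noise_sd=0.6,
                internal_offset=1.3,
                damping=0.55,
            ),
        }
    )
    mortality_p: dict = field(
        default_factory=lambda: {"sunny": 0.91, "shaded": 0.58}
    )
    #: per-variable monthly mean trajectories (shaded plot) and dispersion;
    #: sunny counts and fungus are scaled down by sunny_factor (development
    #: is poorer in the sun), queen mass is common to both environments.
    census_means: dict = field(
        default_factory=lambda: {
            "eggs": [25.0, 70.0, 115.5, 90.0],
            "larvae": [28.0, 30.0, 31.0, 30.0],
            "pupae": [5.0, 25.0, 35.0, 40.0],
            "workers_small_medium": [1.0, 18.0, 55.0, 80.0],
        }
    )
    census_dispersion: float = 8.0  # negative-binomial k
    sunny_factor: float = 0.6
    queen_mass_anchors: tuple = (658.5, 229.45)  # mg, month 1 -> month 4
    queen_mass_sd: float = 40.0
    fungus_anchors: tuple = (64.5, 1354.9)  # mg, geometric growth
    fungus_log_sd: float = 0.2
    #: chamber dimension means (cm) per environment and per-nest sd
    dimension_means: dict = field(
        default_factory=lambda: {
            "sunny": {"depth_cm": 9.21, "width_cm": 2.43, "length_cm": 3.34, "height_cm": 2.62},
            "shaded": {"depth_cm": 13.18, "width_cm": 3.41, "length_cm": 4.52, "height_cm": 3.66},
        }
    )
    dimension_sd: dict = field(
        default_factory=lambda: {
            "depth_cm": 1.2,
            "width_cm": 0.45,
            "length_cm": 0.55,
            "height_cm": 0.45,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.shade_transmittance <= 1.0:
            raise ValueError("shade transmittance must be in (0, 1]")
        for env, p in self.mortality_p.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"mortality probability for {env} must be in [0, 1]")
        if self.nests_per_env <= 0 or self.months <= 0 or self.days_per_month <= 0:
            raise ValueError("counts must be positive")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _study_dates(config: SyntheticConfig) -> list[date]:
    start = date(BASE_YEAR, 1, 1) + timedelta(days=config.start_day_of_year - 1)
    return [start + timedelta(days=i) for i in range(config.months * config.days_per_month)]


def study_month(dates, start: date, days_per_month: int) -> np.ndarray:
    """Study month index (1-based) of each date, in 30-day blocks from start."""
    d = pd.to_datetime(pd.Series(dates))
    return ((d - pd.Timestamp(start)).dt.days // days_per_month + 1).to_numpy()


def simulate_irradiance_day(
    env: str, day: date | int, config: SyntheticConfig, seed
) -> pd.DataFrame:
    """One day of 5-minute irradiance samples for one plot.

    ``day`` is a calendar date (an integer is taken as a day of year in the
    base study year).  Returns columns site, timestamp, component,
    value_wm2.
    """
    if env not in ENVIRONMENTS:
        raise ValueError(f"unknown environment {env!r}")
    if isinstance(day, int):
        day = date(BASE_YEAR, 1, 1) + timedelta(days=day - 1)
    rng = _rng(seed)
    cloud = config.cloud

    hours = np.arange(SAMPLES_PER_DAY) * 5.0 / 60.0
    doy = min(day.timetuple().tm_yday, 365)
    ie = solar.clear_sky_ceiling(doy, hours, config.latitude)

    tau_day = rng.normal(cloud.mean_transmittance, cloud.daily_sd)
    tau = tau_day + rng.normal(0.0, cloud.within_day_sd, SAMPLES_PER_DAY)
    tau = np.clip(tau, 0.02, 1.0)

    value = ie * tau
    if env == "shaded":
        value = value * config.shade_transmittance

    daytime = ie > 0
    spikes = daytime & (rng.random(SAMPLES_PER_DAY) < cloud.spike_probability)
    value[spikes] = ie[spikes] * rng.uniform(cloud.spike_lo, cloud.spike_hi, spikes.sum())

    ts = pd.Timestamp(day) + pd.to_timedelta(np.arange(SAMPLES_PER_DAY) * 5, unit="m")
    return pd.DataFrame(
        {
            "site": env,
            "timestamp": ts,
            "component": ENV_COMPONENT[env],
            "value_wm2": value,
        }
    )


def simulate_temperatures(
    env: str, timestamps, irradiance_wm2, config: SyntheticConfig, seed
) -> pd.DataFrame:
    """External and internal (15 cm) temperature series for one plot.

    ``irradiance_wm2`` must align 1:1 with ``timestamps`` (the external
    series is coupled to it); a length mismatch raises.  Internal
    temperature is a damped, lagged, smoothed transform of the external
    anomaly, so its variance is reduced relative to the external series.
    """
    if env not in ENVIRONMENTS:
        raise ValueError(f"unknown environment {env!r}")
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
    irr = np.asarray(irradiance_wm2, dtype=float)
    if len(ts) != irr.size:
        raise ValueError("irradiance series length does not match timestamps")
    rng = _rng(seed)
    p: TemperatureParams = config.temperature[env]

    hours = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    diurnal = -np.cos(2.0 * np.pi * (hours - 2.0) / 24.0)  # peak mid-afternoon
    external = (
        p.external_mean
        + p.diurnal_amplitude * diurnal
        + p.irradiance_gain * irr / 1000.0
        + rng.normal(0.0, p.external_noise_sd, irr.size)
    )

    ext = pd.Series(external)
    smooth = ext.rolling(max(p.smooth_steps, 1), min_periods=1).mean()
    lagged = smooth.shift(p.lag_steps).bfill()
    anomaly = lagged - ext.mean()
    internal = (
        ext.mean()
        + p.internal_offset
        + p.damping * anomaly.to_numpy()
        + rng.normal(0.0, p.internal_noise_sd, irr.size)
    )
    return pd.DataFrame(
        {"site": env, "timestamp": ts, "external_c": external, "internal_c": internal}
    )


def _negative_binomial(rng, mean, k, size):
    """Overdispersed counts with mean ``mean`` and NB dispersion ``k``."""
    mean = float(mean)
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size)


def simulate_colonies(
    config: SyntheticConfig, seed
) -> tuple[pd.DataFrame, pd.DataFrame, MortalityTable]:
    """Nest founding, survival, excavation and census for both plots.

    Returns (nests, census, mortality): one nest row per founded colony
    with its excavation month, chamber dimensions and queen survival; one
    census row per surviving nest at excavation; and the 2x2 mortality
    table.
    """
    rng = _rng(seed)
    months = np.arange(1, config.months + 1)
    qm_anchor = np.interp(
        months, [1, config.months], list(config.queen_mass_anchors)
    )
    fungus_anchor = np.exp(
        np.interp(months, [1, config.months], np.log(config.fungus_anchors))
    )

    nest_rows, census_rows = [], []
    deaths = {}
    for env in ENVIRONMENTS:
        n = config.nests_per_env
        # quarter of the established nests excavated each month
        excavation = np.tile(months, n // config.months + 1)[:n].copy()
        rng.shuffle(excavation)
        dead = rng.random(n) < config.mortality_p[env]
        deaths[env] = int(dead.sum())

        dims = {}
        for col, mu in config.dimension_means[env].items():
            dims[col] = np.maximum(
                rng.normal(mu, config.dimension_sd[col], n), 0.3
            )
        # the chamber cap model needs height >= base radius
        radius = (dims["width_cm"] + dims["length_cm"]) / 4.0
        dims["height_cm"] = np.maximum(dims["height_cm"], radius)

        scale = config.sunny_factor if env == "sunny" else 1.0
        for i in range(n):
            nest_id = f"{env}-{i + 1:03d}"
            m = int(excavation[i])
            nest_rows.append(
                {
                    "nest_id": nest_id,
                    "environment": env,
                    "month": m,
                    "depth_cm": dims["depth_cm"][i],
                    "width_cm": dims["width_cm"][i],
                    "length_cm": dims["length_cm"][i],
                    "height_cm": dims["height_cm"][i],
                    "queen_alive": not bool(dead[i]),
                }
            )
            if dead[i]:
                continue
            row = {"nest_id": nest_id, "environment": env, "month": m}
            for var, traj in config.census_means.items():
                mean = traj[m - 1] * scale
                row[var] = int(
                    _negative_binomial(rng, mean, config.census_dispersion, 1)[0]
                )
            row["queen_mass_mg"] = max(
                rng.normal(qm_anchor[m - 1], config.queen_mass_sd), 1.0
            )
            row["fungus_biomass_mg"] = float(
                fungus_anchor[m - 1] * scale * rng.lognormal(0.0, config.fungus_log_sd)
            )
            census_rows.append(row)

    nests = pd.DataFrame(nest_rows)
    census = pd.DataFrame(census_rows)
    mortality = MortalityTable(
        deaths_sunny=deaths["sunny"],
        n_sunny=config.nests_per_env,
        deaths_shaded=deaths["shaded"],
        n_shaded=config.nests_per_env,
    )
    return nests, census, mortality


def simulate_study(config: SyntheticConfig, seed=None) -> dict:
    """Full synthetic study: irradiance, temperatures, nests, census.

    Independent child streams are spawned from the seed so each generator
    is deterministic and the whole bundle is reproducible.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    irr_seed, temp_seed, colony_seed = ss.spawn(3)
    irr_rngs = {env: np.random.default_rng(s) for env, s in zip(ENVIRONMENTS, irr_seed.spawn(2))}
    temp_rngs = {env: np.random.default_rng(s) for env, s in zip(ENVIRONMENTS, temp_seed.spawn(2))}

    dates = _study_dates(config)
    irr_frames, temp_frames = [], []
    for env in ENVIRONMENTS:
        env_days = [
            simulate_irradiance_day(env, d, config, irr_rngs[env]) for d in dates
        ]
        env_irr = pd.concat(env_days, ignore_index=True)
        irr_frames.append(env_irr)
        temp_frames.append(
            simulate_temperatures(
                env, env_irr["timestamp"], env_irr["value_wm2"], config, temp_rngs[env]
            )
        )

    nests, census, mortality = simulate_colonies(
        config, np.random.default_rng(colony_seed)
    )
    return {
        "irradiance": pd.concat(irr_frames, ignore_index=True),
        "temperatures": pd.concat(temp_frames, ignore_index=True),
        "nests": nests,
        "census": census,
        "mortality": mortality,
        "start_date": dates[0],
    }
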