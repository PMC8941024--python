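"""Physically-possible-limit quality control and daily integration.

Five-minute pyranometer means (W/m^2) are screened against the
extraterrestrial irradiance I_E at their timestamp:

* GHI (global horizontal) is accepted iff ``0 < value < 1.20 * I_E`` — the
  20% headroom allows short cloud-multireflection spikes above I_E;
* DHI (diffuse horizontal) is accepted iff ``0 < value < I_E``.

Both inequalities are strict: a reading of exactly 0 W/m^2 or exactly at
the ceiling is rejected.  Accepted samples are numerically integrated into
a daily irradiation total in MJ/m^2 (each 5-minute mean contributes
``value * 300 s / 1e6``); rejected samples are treated as missing, never
interpolated, and the fraction of accepted samples is reported as coverage
so that low-coverage days can be filtered downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date
from enum import Enum

import numpy as np
import pandas as pd

from . import solar

__all__ = [
    "Component",
    "QCResult",
    "DailyIrradiation",
    "qc_limit",
    "qc_sample",
    "qc_series",
    "integrate_daily",
    "daily_table",
    "monthly_summary",
    "read_irradiance_csv",
    "SAMPLE_INTERVAL_S",
]

#: Fixed sampling interval of the measurement loggers, seconds.
SAMPLE_INTERVAL_S = 300

GHI_HEADROOM = 1.20  # global ceiling is 1.20 * I_E (cloud multireflection)


class Component(str, Enum):
    GHI = "GHI"
    DHI = "DHI"


@dataclass(frozen=True)
class QCResult:
    accepted: bool
    limit_used: float  # W/m^2 upper ceiling applied
    reason: str  # "ok" | "non_positive" | "exceeds_limit"


@dataclass(frozen=True)
class DailyIrradiation:
    date: _date
    energy_mj_m2: float
    n_accepted: int
    n_rejected: int

    @property
    def coverage(self) -> float:
        total = self.n_accepted + self.n_rejected
        return self.n_accepted / total if total else 0.0


def qc_limit(component, ie_wm2):
    """Upper physically-possible ceiling (W/m^2) for a component."""
    comp = Component(component)
    if comp is Component.GHI:
        return GHI_HEADROOM * ie_wm2
    return 1.0 * ie_wm2


def qc_sample(value_wm2: float, component, ie_wm2: float) -> QCResult:
    """Screen one 5-minute mean against its physically-possible limits."""
    if ie_wm2 < 0:
        raise ValueError("extraterrestrial irradiance must be non-negative")
    limit = qc_limit(component, ie_wm2)
    if not value_wm2 > 0.0:
        return QCResult(False, limit, "non_positive")
    if not value_wm2 < limit:
        return QCResult(False, limit, "exceeds_limit")
    return QCResult(True, limit, "ok")


def _decimal_hours(ts: pd.Series) -> np.ndarray:
    t = pd.DatetimeIndex(ts)
    return (
        t.hour.to_numpy()
        + t.minute.to_numpy() / 60.0
        + t.second.to_numpy() / 3600.0
    )


def qc_series(frame: pd.DataFrame, latitude: float = solar.DEFAULT_LATITUDE) -> pd.DataFrame:
    """Vectorized QC of a long irradiance table.

    ``frame`` needs columns ``timestamp`` (datetime-like), ``component``
    ("GHI"/"DHI") and ``value_wm2``.  Returns a copy with ``ie_wm2``,
    ``limit_wm2``, ``accepted`` and ``reason`` columns appended.
    """
    out = frame.copy()
    ts = pd.to_datetime(out["timestamp"])
    # D is defined on 1..365; Dec 31 of a leap year is clamped to 365
    doy = np.minimum(pd.DatetimeIndex(ts).dayofyear.to_numpy(), 365)
    ie = solar.clear_sky_ceiling(doy, _decimal_hours(ts), latitude)

    comp = out["component"].astype(str)
    unknown = ~comp.isin([c.value for c in Component])
    if unknown.any():
        bad = sorted(comp[unknown].unique())
        raise ValueError(f"unknown irradiance component(s): {bad}")

    limit = np.where(comp.to_numpy() == Component.GHI.value, GHI_HEADROOM * ie, ie)
    value = out["value_wm2"].to_numpy(dtype=float)
    non_positive = ~(value > 0.0)
    exceeds = (value > 0.0) & ~(value < limit)

    out["ie_wm2"] = ie
    out["limit_wm2"] = limit
    out["accepted"] = ~(non_positive | exceeds)
    out["reason"] = np.select(
        [non_positive, exceeds], ["non_positive", "exceeds_limit"], default="ok"
    )
    return out


def integrate_daily(samples: pd.DataFrame) -> DailyIrradiation:
    """Integrate one day's accepted 5-minute means into MJ/m^2.

    ``samples`` must carry ``timestamp``, ``value_wm2`` and ``accepted`` for
    a single calendar day and a single component, on the fixed 300 s grid;
    irregular spacing raises rather than silently reweighting.
    """
    if len(samples) == 0:
        raise ValueError("cannot integrate an empty day")
    if "component" in samples.columns and samples["component"].nunique() > 1:
        raise ValueError("mixed components in one integration window")
    ts = pd.to_datetime(samples["timestamp"]).sort_values()
    days = ts.dt.normalize().unique()
    if len(days) > 1:
        raise ValueError("samples span more than one calendar day")
    if len(ts) > 1:
        gaps = ts.diff().dropna().dt.total_seconds().to_numpy()
        if not np.allclose(gaps, SAMPLE_INTERVAL_S):
            raise ValueError(
                f"timestamps are not on a fixed {SAMPLE_INTERVAL_S} s grid"
            )
    accepted = samples["accepted"].to_numpy(dtype=bool)
    value = samples["value_wm2"].to_numpy(dtype=float)
    energy = float(value[accepted].sum() * SAMPLE_INTERVAL_S / 1e6)
    return DailyIrradiation(
        date=pd.Timestamp(days[0]).date(),
        energy_mj_m2=energy,
        n_accepted=int(accepted.sum()),
        n_rejected=int((~accepted).sum()),
    )


def daily_table(qc_frame: pd.DataFrame) -> pd.DataFrame:
    """Daily irradiation totals per (site, component, day) from a QC'd table.

    Returns columns site (if present), component, date, mj_m2, n_accepted,
    n_rejected, coverage.
    """
    frame = qc_frame.copy()
    frame["date"] = pd.to_datetime(frame["timestamp"]).dt.date
    keys = [c for c in ("site", "component") if c in frame.columns] + ["date"]
    rows = []
    for key, grp in frame.groupby(keys, sort=True):
        di = integrate_daily(grp)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            mj_m2=di.energy_mj_m2,
            n_accepted=di.n_accepted,
            n_rejected=di.n_rejected,
            coverage=di.coverage,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def monthly_summary(
    frame: pd.DataFrame,
    value_col: str,
    month_col: str = "month",
    by: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Arithmetic mean and sample standard deviation per calendar month.

    Groups by ``by + (month_col,)``; months with no finite observations are
    omitted with a warning.  ``sd`` uses the n-1 denominator and is 0 for a
    single observation only if pandas returns NaN (reported as NaN).
    """
    work = frame.dropna(subset=[value_col])
    dropped = frame[month_col].nunique() - work[month_col].nunique()
    if dropped > 0:
        warnings.warn(f"{dropped} month(s) had no data and were omitted")
    keys = list(by) + [month_col]
    out = (
        work.groupby(keys, sort=True)[value_col]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def read_irradiance_csv(path) -> pd.DataFrame:
    """Read the long irradiance schema: site, timestamp, component, value_wm2."""
    frame = pd.read_csv(path)
    required = {"site", "timestamp", "component", "value_wm2"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(
            f"{path}: missing irradiance column(s) {sorted(missing)}; "
            f"expected schema site,timestamp,component,value_wm2"
        )
    if len(frame) == 0:
        raise ValueError(f"{path}: irradiance file is empty")
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame
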