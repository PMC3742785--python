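"""Reading, validating and segmenting sonde and wind records.

Sonde files are delimited text with a header; timestamps are ISO-8601
in local standard time. Records are validated against the 30-minute
native cadence, rows that fail to parse are collected in a rejects
table, and a validated series is cut into sunrise-to-sunrise
``DaySegment`` objects ready for the state-space fit. Missing steps are
never interpolated in the DO series — the filter handles them — but
driver series (temperature) are gap-filled so the state can be
propagated.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gas_exchange import GasParams, k20_from_wind
from .light import LightModel, sunrise_sunset
from .types import DaySegment, Prior, SiteMeta, SondeFormatError, SondeSeries, WindRecord

__all__ = [
    "read_sonde",
    "write_sonde",
    "read_wind",
    "day_boundaries",
    "segment_days",
    "attach_k20_prior",
]

DEFAULT_COLUMNS = {
    "timestamp": "timestamp",
    "do_mgL": "do_mgL",
    "temp_C": "temp_C",
    "turbidity_NTU": "turbidity_NTU",
    "sp_cond": "sp_cond",
}

#: a day is unusable above this fraction of missing steps
MAX_MISSING_FRACTION = 0.10
#: ... or with any contiguous gap longer than this (hours)
MAX_GAP_H = 2.0


def read_sonde(path, dialect: Optional[Mapping[str, str]] = None,
               site_id: str = "site", sep: str = ",",
               cadence_min: float = 30.0) -> SondeSeries:
    """Read a delimited sonde file into a validated :class:`SondeSeries`.

    ``dialect`` maps canonical names (``timestamp``, ``do_mgL``,
    ``temp_C``, optionally ``turbidity_NTU``, ``sp_cond``) to the file's
    column headers. A missing mandatory column raises
    :class:`SondeFormatError`; rows with unparseable timestamps or
    out-of-range values are dropped into ``series.rejects``.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    raw = pd.read_csv(path, sep=sep, skipinitialspace=True, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    for key in ("timestamp", "do_mgL", "temp_C"):
        if cols[key] not in raw.columns:
            raise SondeFormatError(
                f"mandatory column {cols[key]!r} ({key}) missing from {path}"
            )

    ts = pd.to_datetime(raw[cols["timestamp"]], errors="coerce")
    do = pd.to_numeric(raw[cols["do_mgL"]], errors="coerce")
    temp = pd.to_numeric(raw[cols["temp_C"]], errors="coerce")

    reasons = pd.Series("", index=raw.index, dtype=object)
    reasons[ts.isna()] = "unparseable timestamp"
    reasons[(reasons == "") & do.notna() & (do < 0)] = "negative DO"
    reasons[(reasons == "") & temp.notna()
            & ((temp <= 0) | (temp >= 45))] = "temperature out of range"
    dup = ts.duplicated(keep="first") & ts.notna()
    reasons[(reasons == "") & dup] = "duplicate timestamp"

    bad = reasons != ""
    rejects = pd.DataFrame({"row": raw.index[bad], "reason": reasons[bad]})

    data = pd.DataFrame({"do_mgL": do[~bad].values, "temp_C": temp[~bad].values},
                        index=pd.DatetimeIndex(ts[~bad].values, name="timestamp"))
    for key in ("turbidity_NTU", "sp_cond"):
        if cols[key] in raw.columns:
            data[key] = pd.to_numeric(raw[cols[key]], errors="coerce")[~bad].values
    data = data.sort_index()
    return SondeSeries(site_id=site_id, data=data, cadence_min=cadence_min,
                       rejects=rejects.reset_index(drop=True))


def write_sonde(series: SondeSeries, path, float_format: str = "%.4f") -> None:
    """Write a normalised sonde CSV (round-trips through :func:`read_sonde`)."""
    series.data.to_csv(path, float_format=float_format,
                       index_label="timestamp", date_format="%Y-%m-%d %H:%M:%S")


def read_wind(path, sep: str = ",") -> list[WindRecord]:
    """Read a daily wind CSV with columns ``date`` and ``u10_ms``."""
    df = pd.read_csv(path, sep=sep, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    if "date" not in df.columns or "u10_ms" not in df.columns:
        raise SondeFormatError("wind file needs 'date' and 'u10_ms' columns")
    return [WindRecord(date=pd.Timestamp(d).normalize(), u10_ms=float(u))
            for d, u in zip(pd.to_datetime(df["date"]), df["u10_ms"])]


def day_boundaries(site: SiteMeta, start, end) -> list[pd.Timestamp]:
    """Sunrise instants for every calendar date from ``start`` to ``end``."""
    dates = pd.date_range(pd.Timestamp(start).normalize(),
                          pd.Timestamp(end).normalize(), freq="D")
    return [sunrise_sunset(site, d)[0] for d in dates]


def segment_days(series: SondeSeries, site: SiteMeta,
                 light: Optional[LightModel] = None) -> list[DaySegment]:
    """Cut a sonde record into sunrise-to-sunrise model-ready days.

    Each segment owns the regular 30-minute grid slots from one sunrise
    up to (not including) the next; partial leading/trailing spans are
    dropped. A segment is flagged unusable when more than 10% of its
    steps are missing or any contiguous gap exceeds 2 h. DO stays NaN at
    missing steps; temperature is linearly gap-filled as a driver.
    """
    light = light or LightModel(site)
    if len(series) < 2:
        return []
    step = pd.Timedelta(minutes=series.cadence_min)
    t0, t1 = series.data.index[0], series.data.index[-1]
    grid = pd.date_range(t0, t1, freq=step)
    on_grid = series.data.reindex(grid, method="nearest",
                                  tolerance=pd.Timedelta(minutes=2))

    sunrises = day_boundaries(site, t0, t1)
    sunrises = [s for s in sunrises if t0 <= s <= t1 + step]
    segments: list[DaySegment] = []
    step_h = series.cadence_min / 60.0
    for d in range(len(sunrises) - 1):
        lo = int(np.searchsorted(grid.values, np.datetime64(sunrises[d]), side="left"))
        hi = int(np.searchsorted(grid.values, np.datetime64(sunrises[d + 1]), side="left"))
        if hi <= lo or hi > len(grid):
            continue
        times = grid[lo:hi]
        obs = on_grid["do_mgL"].iloc[lo:hi].to_numpy(dtype=float)
        temp = (on_grid["temp_C"].iloc[lo:hi]
                .interpolate(limit_direction="both").to_numpy(dtype=float))
        qp = light.qp_series(times)

        missing = np.isnan(obs)
        flags = []
        frac = missing.mean()
        if frac > MAX_MISSING_FRACTION:
            flags.append(f"missing_fraction={frac:.2f}")
        run = longest = 0
        for m in missing:
            run = run + 1 if m else 0
            longest = max(longest, run)
        if longest * step_h > MAX_GAP_H:
            flags.append(f"gap={longest * step_h:.1f}h")
        if np.isnan(temp).any():
            flags.append("no_temperature")
        segments.append(DaySegment(
            date=pd.Timestamp(sunrises[d]).normalize(),
            times=times, obs_do=obs, temp=temp, qp=qp, step_h=step_h,
            usable=not flags, flags=tuple(flags),
        ))
    return segments


def attach_k20_prior(segment: DaySegment,
                     wind: Union[WindRecord, Mapping, Iterable[WindRecord], None],
                     site: SiteMeta,
                     gas: Optional[GasParams] = None,
                     rel_sd: float = 0.3,
                     min_sd: float = 0.02) -> DaySegment:
    """Attach the day's K₂₀ prior derived from wind, or the default uniform.

    With wind available the prior is normal with mean
    ``k600(u10)/100/z_mix`` and sd ``max(rel_sd·mean, min_sd)`` h⁻¹;
    without wind it is uniform(0, 4) h⁻¹.
    """
    gas = gas or GasParams(mixing_depth_m=site.mixing_depth_m)
    if gas.mixing_depth_m <= 0:
        raise ValueError("mixing depth must be positive")

    u10 = None
    if isinstance(wind, WindRecord):
        u10 = wind.u10_ms if wind.date == segment.date else None
    elif isinstance(wind, Mapping):
        u10 = wind.get(segment.date)
    elif wind is not None:
        for rec in wind:
            if rec.date == segment.date:
                u10 = rec.u10_ms
                break

    if u10 is None:
        prior = Prior.uniform(0.0, 4.0)
    else:
        mean = k20_from_wind(float(u10), gas)
        prior = Prior.normal(mean, max(rel_sd * mean, min_sd))
    segment.k20_prior = prior
    return segment
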