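"""Shared domain types.

Lightweight dataclasses used across the package: site metadata, priors,
the validated sonde record container and the per-day model-ready segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SiteMeta",
    "WindRecord",
    "Prior",
    "SondeSeries",
    "DaySegment",
    "SondeFormatError",
]


class SondeFormatError(ValueError):
    """Raised when a sonde or wind file violates the expected layout."""


@dataclass(frozen=True)
class SiteMeta:
    """Geographic and physical metadata for one monitoring site.

    Parameters
    ----------
    latitude_dd, longitude_dd : float
        Decimal degrees; east and north positive.
    utc_offset_h : float
        Offset of local standard time from UTC in hours. Timestamps in
        sonde files are interpreted in this fixed offset (no DST).
    mixing_depth_m : float
        Assumed vertical mixing depth of the surface layer in metres;
        converts a gas transfer velocity into a volumetric reaeration
        coefficient.
    """

    latitude_dd: float
    longitude_dd: float
    utc_offset_h: float
    mixing_depth_m: float = 0.5
    site_id: str = "site"

    def __post_init__(self) -> None:
        if not abs(self.latitude_dd) <= 90:
            raise ValueError(f"latitude out of range: {self.latitude_dd}")
        if self.mixing_depth_m <= 0:
            raise ValueError("mixing_depth_m must be > 0")


@dataclass(frozen=True)
class WindRecord:
    """Daily mean wind speed at 10 m for one calendar day."""

    date: pd.Timestamp
    u10_ms: float

    def __post_init__(self) -> None:
        if self.u10_ms < 0:
            raise ValueError("u10_ms must be >= 0")


@dataclass(frozen=True)
class Prior:
    """A one-dimensional prior: ``uniform(lo, hi)`` or ``normal(mean, sd)``.

    Normal priors are truncated at zero when used for nonnegative
    parameters (reaeration coefficients, rates, standard deviations).
    """

    kind: str  # "uniform" | "normal"
    a: float   # lo or mean
    b: float   # hi or sd

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "normal"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "uniform" and not self.b > self.a:
            raise ValueError("uniform prior needs hi > lo")
        if self.kind == "normal" and self.b <= 0:
            raise ValueError("normal prior needs sd > 0")

    @staticmethod
    def uniform(lo: float, hi: float) -> "Prior":
        return Prior("uniform", lo, hi)

    @staticmethod
    def normal(mean: float, sd: float) -> "Prior":
        return Prior("normal", mean, sd)


@dataclass
class SondeSeries:
    """A validated 30-minute sonde record for one site.

    ``data`` is indexed by naive local-standard-time timestamps, strictly
    increasing, with columns ``do_mgL``, ``temp_C`` and optionally
    ``turbidity_NTU`` and ``sp_cond``. Rows rejected during parsing are
    kept in ``rejects`` with a reason column.
    """

    site_id: str
    data: pd.DataFrame
    cadence_min: float = 30.0
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )

    def __post_init__(self) -> None:
        idx = self.data.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise SondeFormatError("timestamps must be strictly increasing")
        do = self.data["do_mgL"].dropna()
        if (do < 0).any():
            raise SondeFormatError("dissolved oxygen must be >= 0")
        t = self.data["temp_C"].dropna()
        if ((t <= 0) | (t >= 45)).any():
            raise SondeFormatError("temperature outside (0, 45) degC")
        if len(idx) >= 2:
            diffs = np.diff(idx.view("int64")) / 60e9  # minutes
            # native cadence = modal spacing; gaps are multiples of it
            vals, counts = np.unique(np.round(diffs, 3), return_counts=True)
            native = float(vals[np.argmax(counts)])
            if abs(native - self.cadence_min) > 2.0:
                raise SondeFormatError(
                    f"native cadence {native:.1f} min differs from "
                    f"{self.cadence_min:.0f} min by more than 2 min"
                )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DaySegment:
    """One sunrise-to-sunrise slice of a sonde record, on a regular grid.

    Arrays all have length ``n_steps`` (grid slots from sunrise up to,
    not including, the next sunrise). Missing observations are NaN in
    ``obs_do`` and are skipped by the filtering likelihood; driver
    series (``temp``, ``qp``) are gap-filled so the state can still be
    propagated across missing observations.
    """

    date: pd.Timestamp              # calendar date of the starting sunrise
    times: pd.DatetimeIndex         # grid timestamps, local standard time
    obs_do: np.ndarray              # mg L-1, NaN where missing
    temp: np.ndarray                # degC, gap-filled
    qp: np.ndarray                  # photon flux, relative units, >= 0
    step_h: float = 0.5
    k20_prior: Optional[Prior] = None
    usable: bool = True
    flags: tuple = ()

    @property
    def n_steps(self) -> int:
        return len(self.obs_do)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.obs_do).sum())
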