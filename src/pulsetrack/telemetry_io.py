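"""Read/write GPS fix tables and event tables, align timestamps across
species, and sample raster covariates at points.

Fix tables are CSV with the canonical header
``animal_id,species,sex,timestamp_iso8601,x,y``; coordinates are projected
meters in one shared planar frame.  In memory a fix table is a pandas
DataFrame with columns ``animal_id, species, sex, t, x, y`` where ``t`` is a
timezone-aware UTC Timestamp, sorted by (animal_id, t) and strictly
increasing in time within each animal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .rasters import RasterStack

__all__ = [
    "SPECIES",
    "Standardization",
    "read_fixes",
    "write_fixes",
    "read_events",
    "write_events",
    "validate_fixes",
    "sample_covariates",
    "match_contemporaneous",
    "nearest_fix_indices",
    "times_ns",
]


def times_ns(t) -> np.ndarray:
    """Datetime-like (tz-aware or naive) -> naive UTC ``datetime64[ns]`` array."""
    if isinstance(t, pd.Series):
        idx = pd.DatetimeIndex(t)
    elif isinstance(t, pd.DatetimeIndex):
        idx = t
    else:
        idx = pd.DatetimeIndex(np.atleast_1d(t))
    if idx.tz is not None:
        idx = idx.tz_convert("UTC").tz_localize(None)
    return idx.to_numpy(dtype="datetime64[ns]")

SPECIES = {"cougar", "coyote", "black_bear", "bobcat", "elk", "mule_deer", "other"}
SEXES = {"F", "M", "unknown"}

FIX_COLUMNS = ["animal_id", "species", "sex", "t", "x", "y"]
_CSV_HEADER = ["animal_id", "species", "sex", "timestamp_iso8601", "x", "y"]


def validate_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Check schema, species/sex domains, and per-animal strict time order.

    Returns the table sorted by (animal_id, t).  Raises ``ValueError`` naming
    the offending animal on duplicated or non-monotone timestamps.
    """
    missing = set(FIX_COLUMNS) - set(fixes.columns)
    if missing:
        raise ValueError(f"fix table missing columns: {sorted(missing)}")
    bad_sp = set(fixes["species"].unique()) - SPECIES
    if bad_sp:
        raise ValueError(f"unknown species: {sorted(bad_sp)}")
    bad_sex = set(fixes["sex"].unique()) - SEXES
    if bad_sex:
        raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
    if not np.isfinite(fixes[["x", "y"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite coordinates in fix table")
    out = fixes.sort_values(["animal_id", "t"], kind="stable").reset_index(drop=True)
    for animal, grp in out.groupby("animal_id", sort=False):
        dt = grp["t"].diff().dropna()
        if (dt <= pd.Timedelta(0)).any():
            raise ValueError(f"non-increasing timestamps for animal {animal!r}")
    return out


def read_fixes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "species": str, "sex": str})
    missing = set(_CSV_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"fix CSV missing columns: {sorted(missing)}")
    df["t"] = pd.to_datetime(df["timestamp_iso8601"], utc=True)
    df = df.drop(columns=["timestamp_iso8601"])
    return validate_fixes(df[FIX_COLUMNS])


def write_fixes(fixes: pd.DataFrame, path: str | Path) -> None:
    fixes = validate_fixes(fixes)
    out = fixes.copy()
    out["timestamp_iso8601"] = out["t"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out[_CSV_HEADER].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Event CSV ``animal_id,event_time,method,x,y`` -> DataFrame."""
    df = pd.read_csv(path, dtype={"animal_id": str, "method": str})
    df["event_time"] = pd.to_datetime(df["event_time"], utc=True)
    return df[["animal_id", "event_time", "method", "x", "y"]]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["event_time"] = pd.to_datetime(out["event_time"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out[["animal_id", "event_time", "method", "x", "y"]].to_csv(path, index=False)


@dataclass
class Standardization:
    """Per-column centering/scaling constants for continuous covariates.

    Zero-variance columns are left unscaled (sd set to 1) and recorded in
    ``constant_columns`` so callers can flag them.
    """

    means: dict[str, float]
    sds: dict[str, float]
    constant_columns: tuple[str, ...] = ()

    @classmethod
    def fit(cls, table: pd.DataFrame, columns: list[str]) -> "Standardization":
        means, sds, const = {}, {}, []
        for c in columns:
            v = table[c].to_numpy(dtype=float)
            m = float(np.nanmean(v))
            s = float(np.nanstd(v, ddof=0))
            if s == 0.0 or not np.isfinite(s):
                const.append(c)
                s = 1.0
            means[c], sds[c] = m, s
        return cls(means=means, sds=sds, constant_columns=tuple(const))

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c, m in self.means.items():
            if c in out.columns:
                out[c] = (out[c].astype(float) - m) / self.sds[c]
        return out


def sample_covariates(
    points: pd.DataFrame,
    stack: RasterStack,
    standardization: Standardization | None = None,
) -> pd.DataFrame:
    """Nearest-cell covariates at points ``(x, y)``, one row per point.

    Adds an ``in_bounds`` flag; out-of-bounds rows carry NaN covariates and
    are meant to be excluded downstream.  Categorical layers come back as
    integer class codes (NaN-safe float).  When a :class:`Standardization`
    is supplied it is applied to the continuous layers it names; otherwise
    raw values are returned.
    """
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    out = pd.DataFrame(index=points.index)
    out["in_bounds"] = stack.in_bounds(x, y)
    for name in stack.names():
        out[name] = stack.sample(x, y, name)
    if standardization is not None:
        out = standardization.apply(out)
    return out


def nearest_fix_indices(
    t_queries: np.ndarray, fix_times: np.ndarray, tolerance: pd.Timedelta
) -> np.ndarray:
    """Index of the nearest fix time per query (-1 if none within tolerance).

    Ties between an earlier and a later fix are broken toward the earlier
    fix.  Both inputs are int64 nanosecond arrays or datetime64 arrays;
    ``fix_times`` must be sorted ascending.
    """
    tq = times_ns(t_queries).astype(np.int64)
    tf = times_ns(fix_times).astype(np.int64)
    tol = int(tolerance.value)
    pos = np.searchsorted(tf, tq)
    lo = np.clip(pos - 1, 0, len(tf) - 1)
    hi = np.clip(pos, 0, len(tf) - 1)
    d_lo = np.abs(tq - tf[lo])
    d_hi = np.abs(tq - tf[hi])
    best = np.where(d_lo <= d_hi, lo, hi)  # tie -> earlier fix
    d_best = np.minimum(d_lo, d_hi)
    return np.where(d_best <= tol, best, -1)


def match_contemporaneous(
    t_query: pd.Timestamp, prey_trajectory: pd.DataFrame, tolerance: pd.Timedelta
) -> pd.Series | None:
    """Nearest prey fix to ``t_query`` within ``tolerance``, else ``None``.

    Operationalizes "simultaneous" predator and prey positions: prey are
    sampled several times faster than predators, so the nearest prey fix
    within half the prey fix interval is effectively contemporaneous.
    """
    if tolerance <= pd.Timedelta(0):
        raise ValueError("tolerance must be positive")
    if len(prey_trajectory) == 0:
        return None
    idx = nearest_fix_indices(
        np.array([pd.Timestamp(t_query).to_datetime64()]),
        prey_trajectory["t"].to_numpy(),
        tolerance,
    )[0]
    if idx < 0:
        return None
    return prey_trajectory.iloc[int(idx)]
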