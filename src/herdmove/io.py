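"""Data model, trajectory CSV I/O, and run configuration.

The universal input to every analysis stage is a :class:`TrajectoryTable`:
per-individual 1 Hz time series of planar position (metres) and body heading
(radians, mathematical convention, wrapped to ``[0, 2pi)``). All downstream
stages consume validated tables only; no stage reads raw files directly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

TWO_PI = 2.0 * math.pi

REQUIRED_COLUMNS = ("time_s", "individual_id", "x_m", "y_m", "heading_rad")
OPTIONAL_COLUMNS = ("day_id",)

#: CSV float formats: 6 d.p. for positions, 9 d.p. for headings.
_POS_FMT = "%.6f"
_HEAD_FMT = "%.9f"


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class IntegrityError(ValueError):
    """A table-level invariant (uniqueness, range) is violated."""


def wrap_angle(theta):
    """Wrap angle(s) to ``[0, 2pi)``."""
    return np.mod(theta, TWO_PI)


@dataclass
class TrajectoryTable:
    """Validated per-individual 1 Hz trajectory data.

    Wraps a :class:`pandas.DataFrame` with columns
    ``time_s, individual_id, x_m, y_m, heading_rad, day_id`` sorted by
    ``(individual_id, time_s)``. Construct via :meth:`from_frame` or
    :func:`read_trajectories` so invariants are checked.
    """

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True) -> "TrajectoryTable":
        df = df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if "day_id" not in df.columns:
            df["day_id"] = "d0"
        df = df[list(REQUIRED_COLUMNS) + ["day_id"]]
        df["time_s"] = df["time_s"].astype(np.int64)
        df["individual_id"] = df["individual_id"].astype(str)
        df["day_id"] = df["day_id"].astype(str)
        for c in ("x_m", "y_m", "heading_rad"):
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        df = df.sort_values(["individual_id", "time_s"], kind="mergesort")
        df = df.reset_index(drop=True)
        table = cls(df=df)
        if validate:
            table.validate()
        return table

    def validate(self) -> None:
        df = self.df
        if df.duplicated(subset=["individual_id", "time_s"]).any():
            dup = df[df.duplicated(subset=["individual_id", "time_s"], keep=False)]
            pair = (dup.iloc[0]["individual_id"], int(dup.iloc[0]["time_s"]))
            raise IntegrityError(f"duplicate (individual_id, time_s) pair: {pair}")
        h = df["heading_rad"].to_numpy()
        if not np.all(np.isfinite(h)):
            raise ValueError("non-finite heading values")
        if np.any(h < 0.0) or np.any(h >= TWO_PI):
            raise IntegrityError("heading_rad outside [0, 2pi)")
        if not np.all(np.isfinite(df[["x_m", "y_m"]].to_numpy())):
            raise ValueError("non-finite position values")

    # -- convenience accessors -------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return sorted(self.df["individual_id"].unique())

    @property
    def days(self) -> list[str]:
        return sorted(self.df["day_id"].unique())

    def day(self, day_id: str) -> "TrajectoryTable":
        return TrajectoryTable(self.df[self.df["day_id"] == day_id].reset_index(drop=True))

    def time_gaps(self) -> pd.DataFrame:
        """Flag missing samples: per (day, individual) count of absent seconds
        relative to the day's full time grid. Gaps are allowed but reported."""
        out = []
        for day_id, sub in self.df.groupby("day_id"):
            grid = np.arange(sub["time_s"].min(), sub["time_s"].max() + 1)
            for ind, ss in sub.groupby("individual_id"):
                n_missing = len(grid) - ss["time_s"].nunique()
                out.append({"day_id": day_id, "individual_id": ind, "n_missing": n_missing})
        return pd.DataFrame(out)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrajectoryTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass
class GroupSeries:
    """Per-time-step group aggregates.

    Columns: ``time_s, day_id, centroid_x_m, centroid_y_m, mean_heading_rad,
    mean_speed_mps, polar_order, n_members``. ``mean_heading_rad`` is NaN when
    the heading resultant is degenerate.
    """

    df: pd.DataFrame

    GROUP_COLUMNS = (
        "time_s",
        "day_id",
        "centroid_x_m",
        "centroid_y_m",
        "mean_heading_rad",
        "mean_speed_mps",
        "polar_order",
        "n_members",
    )

    def day(self, day_id: str) -> "GroupSeries":
        return GroupSeries(self.df[self.df["day_id"] == day_id].reset_index(drop=True))

    def to_csv(self, path) -> None:
        cols = [c for c in self.GROUP_COLUMNS if c in self.df.columns]
        self.df[cols].to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RunConfig:
    """All analysis-stage parameters with config-file and CLI override support.

    Change-point penalties and the stationary-phase definition are explicit,
    overridable defaults (not hard-coded constants) because the reference
    values for them are analysis choices, not physical constants.
    """

    # decision windows
    window_pre_s: int = 100
    window_post_s: int = 100
    # bootstrap
    bootstrap_n: int = 1000
    rng_seed: int = 0
    # cross-correlation
    max_lag_s: int = 25
    ccf_normalization: str = "full"  # "full" (classic sample ccf) | "overlap"
    # leadership
    leadership_threshold: float = 0.9
    leadership_window_s: int = 15
    leadership_max_shift_s: int = 10
    min_dyad_steps: int = 10
    n_perm: int = 1000
    # change-point detection
    speed_penalty: float | None = None  # None -> auto (BIC-like)
    heading_penalty: float | None = None
    penalty_scale: float = 1.0  # multiplier for auto penalties (sensitivity sweeps)
    heading_var_window_s: int = 15
    # decision filters
    stationary_speed_mps: float = 0.2
    stationary_min_s: int = 60
    moving_speed_min_mps: float = 0.3
    candidate_post_s: int = 30
    heading_cp_post_s: int = 30
    moving_phase_s: int = 10
    direction_settle_s: int = 6
    travel_min_s: int = 60
    min_event_sep_s: int = 120
    # group aggregation
    min_member_frac: float = 0.8
    group_speed_source: str = "mean_members"  # or "centroid"
    # alignment test
    chance_alignment: float = 2.0 / math.pi

    def __post_init__(self):
        if self.window_pre_s <= 0 or self.window_post_s <= 0:
            raise ValueError("window lengths must be positive")
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap_n must be >= 1")
        if self.max_lag_s <= 0:
            raise ValueError("max_lag_s must be positive")
        if not 0.0 < self.min_member_frac <= 1.0:
            raise ValueError("min_member_frac must be in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_trajectories(path, schema: Mapping[str, str] | None = None,
                      heading_unit: str = "rad") -> TrajectoryTable:
    """Read a trajectory CSV into a validated :class:`TrajectoryTable`.

    Parameters
    ----------
    path:
        CSV file with columns ``time_s,individual_id,x_m,y_m,heading_rad``
        (plus optional ``day_id``), or arbitrary column names mapped via
        ``schema``.
    schema:
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"heading_rad": "bearing_deg"}``.
    heading_unit:
        ``"rad"`` or ``"deg"``; degree input is converted at this boundary so
        everything downstream sees one convention.
    """
    if heading_unit not in ("rad", "deg"):
        raise ValueError(f"heading_unit must be 'rad' or 'deg', got {heading_unit!r}")
    raw = pd.read_csv(path)
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing = [v for v in schema.values() if v not in raw.columns]
        if missing:
            raise SchemaError(f"schema refers to absent columns: {missing}")
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    h = pd.to_numeric(raw["heading_rad"], errors="coerce")
    if h.isna().any():
        raise ValueError("non-numeric heading values")
    if heading_unit == "deg":
        h = np.deg2rad(h)
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite heading values")
    raw = raw.copy()
    raw["heading_rad"] = wrap_angle(h.to_numpy())
    return TrajectoryTable.from_frame(raw)


def write_trajectories(table: TrajectoryTable, path) -> None:
    """Write a trajectory CSV that :func:`read_trajectories` inverts exactly
    at the declared precision (6 d.p. positions, 9 d.p. headings)."""
    df = table.df.copy()
    for c in ("x_m", "y_m"):
        df[c] = df[c].map(lambda v: _POS_FMT % v)
    df["heading_rad"] = df["heading_rad"].map(lambda v: _HEAD_FMT % v)
    cols = list(REQUIRED_COLUMNS) + ["day_id"]
    df[cols].to_csv(path, index=False)


def latlon_to_xy(lat_deg, lon_deg, lat0_deg=None, lon0_deg=None):
    """Equirectangular lat/lon -> local planar metres about the data centroid.

    Adequate at the ~100 m scales of a single herd's daily range; provided for
    real-data users, not used by the synthetic pipeline.
    """
    lat = np.asarray(lat_deg, dtype=float)
    lon = np.asarray(lon_deg, dtype=float)
    if lat0_deg is None:
        lat0_deg = float(np.mean(lat))
    if lon0_deg is None:
        lon0_deg = float(np.mean(lon))
    r_earth = 6_371_000.0
    x = np.deg2rad(lon - lon0_deg) * r_earth * math.cos(math.radians(lat0_deg))
    y = np.deg2rad(lat - lat0_deg) * r_earth
    return x, y
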