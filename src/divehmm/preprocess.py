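"""Dive-level preprocessing: segmentation, batching, turning angles, covariates.

Dive tables are pandas DataFrames with columns ``individual_id, t_start,
t_end, x, y, max_depth, dive_duration, surface_duration`` (timestamps UTC,
positions in projected metres).  Batching collapses consecutive groups of
``batch_size`` dives into one observation row carrying the channel means,
the planar step length across the batch and (after a second pass) the
turning angle between consecutive batch displacements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DIVE_COLUMNS = [
    "individual_id",
    "t_start",
    "t_end",
    "x",
    "y",
    "max_depth",
    "dive_duration",
    "surface_duration",
]

#: observation channels, in model order
GAMMA_CHANNELS = ("max_depth", "dive_duration", "surface_duration", "step_length")
ANGLE_CHANNEL = "turning_angle"
CHANNELS = GAMMA_CHANNELS + (ANGLE_CHANNEL,)

DEFAULT_MAX_GAP = pd.Timedelta(hours=6)
DEFAULT_BATCH_SIZE = 10


# ---------------------------------------------------------------------------
# segmentation and batching
# ---------------------------------------------------------------------------

def drop_initial_period(dives: pd.DataFrame, hours: float = 24.0) -> pd.DataFrame:
    """Discard each individual's first ``hours`` of data after tag deployment."""
    if dives.empty:
        return dives
    cutoff = dives.groupby("individual_id")["t_start"].transform("min") + pd.Timedelta(
        hours=hours
    )
    return dives.loc[dives["t_start"] >= cutoff].reset_index(drop=True)


def segment_track(
    dives: pd.DataFrame, max_gap: pd.Timedelta = DEFAULT_MAX_GAP
) -> list[pd.DataFrame]:
    """Split one individual's dive series at gaps strictly longer than ``max_gap``.

    The gap between dive ``i`` and dive ``i+1`` is ``t_start[i+1] - t_end[i]``;
    a gap exactly equal to ``max_gap`` does not split.  Returns the segments in
    time order; every dive lands in exactly one segment.
    """
    if dives.empty:
        return []
    if dives["individual_id"].nunique() > 1:
        raise ValueError("segment_track expects a single individual's dives")
    t_start = pd.to_datetime(dives["t_start"]).to_numpy()
    if np.any(t_start[1:] < t_start[:-1]):
        raise ValueError("dives must be sorted by t_start")
    t_end = pd.to_datetime(dives["t_end"]).to_numpy()
    gaps = t_start[1:] - t_end[:-1]
    breaks = np.flatnonzero(gaps > np.timedelta64(max_gap.to_timedelta64())) + 1
    pieces = np.split(np.arange(len(dives)), breaks)
    return [dives.iloc[idx].reset_index(drop=True) for idx in pieces]


def batch_dives(
    segment: pd.DataFrame,
    batch_size: int = DEFAULT_BATCH_SIZE,
    segment_id: str = "seg0",
) -> pd.DataFrame:
    """Collapse a dive segment into non-overlapping batches of ``batch_size`` dives.

    The trailing remainder of fewer than ``batch_size`` dives is dropped.
    Depth and the two durations are arithmetic means over the batch;
    ``step_length`` is the planar distance from the position at the start of
    the batch's first dive to the position at the end of its last dive.
    Turning angles are left unset (see :func:`attach_turning_angles`).
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    n = len(segment) // batch_size
    cols = [
        "individual_id",
        "segment_id",
        "batch_index",
        "t_begin",
        "max_depth",
        "dive_duration",
        "surface_duration",
        "step_length",
        "turning_angle",
        "dx",
        "dy",
        "x_begin",
        "y_begin",
    ]
    if n == 0:
        return pd.DataFrame(columns=cols)
    used = segment.iloc[: n * batch_size]
    grp = np.repeat(np.arange(n), batch_size)
    means = used[["max_depth", "dive_duration", "surface_duration"]].groupby(grp).mean()
    first = used.iloc[::batch_size].reset_index(drop=True)
    last = used.iloc[batch_size - 1 :: batch_size].reset_index(drop=True)
    dx = last["x"].to_numpy(float) - first["x"].to_numpy(float)
    dy = last["y"].to_numpy(float) - first["y"].to_numpy(float)
    out = pd.DataFrame(
        {
            "individual_id": first["individual_id"].to_numpy(),
            "segment_id": segment_id,
            "batch_index": np.arange(n),
            "t_begin": pd.to_datetime(first["t_start"]).to_numpy(),
            "max_depth": means["max_depth"].to_numpy(),
            "dive_duration": means["dive_duration"].to_numpy(),
            "surface_duration": means["surface_duration"].to_numpy(),
            "step_length": np.hypot(dx, dy),
            "turning_angle": np.nan,
            "dx": dx,
            "dy": dy,
            "x_begin": first["x"].to_numpy(float),
            "y_begin": first["y"].to_numpy(float),
        }
    )
    return out[cols]


def compute_turning_angle(prev_displacement, curr_displacement) -> float:
    """Signed heading change between two planar displacements, in (-pi, pi].

    Counter-clockwise positive; a full reversal maps to +pi.  Returns NaN
    (MISSING) when either displacement has zero length.
    """
    px, py = float(prev_displacement[0]), float(prev_displacement[1])
    cx, cy = float(curr_displacement[0]), float(curr_displacement[1])
    if (px == 0.0 and py == 0.0) or (cx == 0.0 and cy == 0.0):
        return math.nan
    cross = px * cy - py * cx
    dot = px * cx + py * cy
    ang = math.atan2(cross, dot)
    if ang <= -math.pi:
        ang = math.pi
    return ang


def attach_turning_angles(batches: pd.DataFrame) -> pd.DataFrame:
    """Fill ``turning_angle`` from consecutive batch displacements within segments.

    The first batch of every (individual, segment) keeps a MISSING angle.
    """
    out = batches.copy()
    ang = np.full(len(out), np.nan)
    for _, idx in out.groupby(["individual_id", "segment_id"], sort=False).indices.items():
        idx = np.sort(idx)
        for k in range(1, len(idx)):
            prev = (out["dx"].iat[idx[k - 1]], out["dy"].iat[idx[k - 1]])
            curr = (out["dx"].iat[idx[k]], out["dy"].iat[idx[k]])
            ang[idx[k]] = compute_turning_angle(prev, curr)
    out["turning_angle"] = ang
    return out


def preprocess_dives(
    dives: pd.DataFrame,
    batch_size: int = DEFAULT_BATCH_SIZE,
    max_gap: pd.Timedelta = DEFAULT_MAX_GAP,
    discard_first_hours: float | None = 24.0,
) -> pd.DataFrame:
    """Full dive-to-batch pipeline over all individuals.

    Sorts per individual, optionally discards the first post-deployment day,
    segments at data gaps, batches each segment and attaches turning angles.
    """
    dives = dives.copy()
    dives["t_start"] = pd.to_datetime(dives["t_start"])
    dives["t_end"] = pd.to_datetime(dives["t_end"])
    if discard_first_hours is not None:
        dives = drop_initial_period(dives, discard_first_hours)
    pieces = []
    for ind, sub in dives.groupby("individual_id", sort=False):
        sub = sub.sort_values("t_start").reset_index(drop=True)
        for s, seg in enumerate(segment_track(sub, max_gap)):
            pieces.append(batch_dives(seg, batch_size, segment_id=f"{ind}-s{s}"))
    if not pieces:
        return batch_dives(dives.iloc[:0], batch_size)  # empty frame, right columns
    batches = pd.concat(pieces, ignore_index=True)
    return attach_turning_angles(batches)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

@dataclass
class Covariate:
    """One covariate's kind and (for continuous ones) the fitted transform."""

    name: str
    kind: str = "continuous"  # continuous | binary | categorical
    levels: tuple = ()
    reference: object = None
    mean: float | None = None
    sd: float | None = None
    vmin: float | None = None
    vmax: float | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind in ("binary", "categorical"):
            if not self.levels:
                raise ValueError(f"{self.name}: levels required for {self.kind}")
            if self.reference is None:
                self.reference = self.levels[0]
            if self.reference not in self.levels:
                raise ValueError(f"{self.name}: reference not in levels")

    @property
    def design_columns(self) -> list[str]:
        if self.kind == "continuous":
            return [self.name]
        return [f"{self.name}[{lv}]" for lv in self.levels if lv != self.reference]


@dataclass
class CovariateSpec:
    """Ordered covariate set; after fitting carries the standardization used."""

    covariates: list[Covariate] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @property
    def design_columns(self) -> list[str]:
        cols: list[str] = []
        for c in self.covariates:
            cols.extend(c.design_columns)
        return cols

    @property
    def n_design(self) -> int:
        return len(self.design_columns)

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def destandardize(self, name: str, values):
        c = self[name]
        if c.kind != "continuous" or c.mean is None:
            raise ValueError(f"{name} has no stored standardization")
        return np.asarray(values) * c.sd + c.mean

    def standardize_value(self, name: str, values):
        c = self[name]
        if c.kind != "continuous" or c.mean is None:
            raise ValueError(f"{name} has no stored standardization")
        return (np.asarray(values) - c.mean) / c.sd


def standardize_covariates(
    batches: pd.DataFrame, spec: CovariateSpec
) -> tuple[pd.DataFrame, CovariateSpec]:
    """Standardize continuous covariates and reference-code categorical ones.

    Continuous covariates are centred on the pooled mean and scaled by the
    pooled sample (n-1) standard deviation, computed over all individuals and
    batches; the (mean, sd) pair is stored on the returned spec so natural
    scales can be recovered exactly.  Categorical/binary covariates become
    0/1 indicator columns against their reference level.
    """
    out = batches.copy()
    fitted: list[Covariate] = []
    for cov in spec.covariates:
        if cov.name not in out.columns:
            raise KeyError(f"covariate column {cov.name!r} missing from batches")
        col = out[cov.name]
        if cov.kind == "continuous":
            vals = col.to_numpy(float)
            finite = vals[np.isfinite(vals)]
            if np.unique(finite).size < 2:
                raise ValueError(f"covariate {cov.name!r} is constant; cannot standardize")
            mean = float(np.mean(finite))
            sd = float(np.std(finite, ddof=1))
            out[cov.name] = (vals - mean) / sd
            fitted.append(
                replace(cov, mean=mean, sd=sd, vmin=float(finite.min()), vmax=float(finite.max()))
            )
        else:
            seen = set(col.dropna().unique())
            unknown = seen - set(cov.levels)
            if unknown:
                raise ValueError(f"covariate {cov.name!r}: unexpected levels {unknown}")
            for lv in cov.levels:
                if lv == cov.reference:
                    continue
                out[f"{cov.name}[{lv}]"] = (col == lv).astype(float)
            fitted.append(replace(cov))
    return out, CovariateSpec(fitted)
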