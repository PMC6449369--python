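"""Gillnet fishing-event detection from vessel pings and the net-proximity covariate.

Vessel pings (hourly position/speed reports) are classified by speed into
drifting / fishing / steaming; maximal runs of fishing pings become events
whose set time and location are the run's first ping.  Events without a
reported haul time get one imputed from a default soak duration.  The
dynamic covariate is the planar distance (km) from a query point to the
nearest net whose soak interval covers the query time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

LOWER_SPEED_DEFAULT = 0.5  # knots
FALLBACK_UPPER = 3.0  # knots
DEFAULT_SOAK_DAYS = 0.9
DEFAULT_DISTANCE_CAP_KM = 100.0

PING_COLUMNS = ["vessel_id", "t", "x", "y", "speed_knots"]
EVENT_COLUMNS = ["event_id", "source", "x", "y", "t_set", "t_haul"]


def upper_speed_threshold(speeds, lower: float = LOWER_SPEED_DEFAULT) -> float:
    """Vessel-specific upper fishing-speed threshold (knots).

    Finds the first interior minimum of a Silverman-bandwidth kernel density
    of the speeds in ``(lower, 9]`` — the valley separating the slow fishing
    mode from the fast steaming mode — clamped to [2, 6] knots.  Falls back
    to 3.0 knots (with a warning) when fewer than 50 usable speeds exist or
    the density has no interior minimum.
    """
    speeds = np.asarray(speeds, float)
    usable = speeds[(speeds > lower) & (speeds <= 9.0) & np.isfinite(speeds)]
    if usable.size < 50:
        warnings.warn(
            f"only {usable.size} speeds in ({lower}, 9]; using fallback "
            f"upper threshold {FALLBACK_UPPER} knots",
            stacklevel=2,
        )
        return FALLBACK_UPPER
    if np.ptp(usable) < 1e-9:
        return FALLBACK_UPPER
    kde = gaussian_kde(usable, bw_method="silverman")
    grid = np.linspace(lower, 9.0, 512)
    dens = kde(grid)
    peak = dens.max()
    interior = np.flatnonzero(
        (dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])
    )
    for idx in interior + 1:
        # a genuine valley separates two modes: require a substantial mode on
        # the steaming side and a clear dip relative to it
        later_peak = dens[idx:].max()
        if later_peak >= 0.05 * peak and dens[idx] <= 0.5 * later_peak:
            return float(np.clip(grid[idx], 2.0, 6.0))
    return FALLBACK_UPPER


def detect_fishing_events(
    pings: pd.DataFrame,
    lower: float = LOWER_SPEED_DEFAULT,
    upper: float | None = None,
) -> pd.DataFrame:
    """Detect gillnet set events from one vessel's ping series.

    Pings are labelled drifting (``speed < lower``), fishing
    (``lower <= speed <= upper``) or steaming (``speed > upper``); each
    maximal run of fishing pings yields one event positioned and timed at
    the run's first ping.  ``upper`` defaults to the automatic per-vessel
    threshold.  Returned events have MISSING ``t_haul``.
    """
    if pings.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    if pings["vessel_id"].nunique() > 1:
        raise ValueError("detect_fishing_events expects a single vessel's pings")
    t = pd.to_datetime(pings["t"]).to_numpy()
    if np.any(t[1:] < t[:-1]):
        raise ValueError("pings must be sorted by t")
    if upper is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            upper = upper_speed_threshold(pings["speed_knots"].to_numpy(), lower)
    speed = pings["speed_knots"].to_numpy(float)
    fishing = (speed >= lower) & (speed <= upper)
    starts = np.flatnonzero(fishing & ~np.r_[False, fishing[:-1]])
    vessel = pings["vessel_id"].iloc[0]
    rows = []
    for k, i in enumerate(starts):
        rows.append(
            {
                "event_id": f"{vessel}-e{k}",
                "source": "vms",
                "x": float(pings["x"].iloc[i]),
                "y": float(pings["y"].iloc[i]),
                "t_set": t[i],
                "t_haul": pd.NaT,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def mean_soak(events: pd.DataFrame) -> float:
    """Mean soak time in days over events with a reported haul time."""
    t_set = pd.to_datetime(events["t_set"])
    t_haul = pd.to_datetime(events["t_haul"])
    soak = (t_haul - t_set).dt.total_seconds() / 86400.0
    soak = soak.dropna()
    if soak.empty:
        raise ValueError("no events with t_haul present")
    if (soak <= 0).any():
        raise ValueError("non-positive soak time encountered")
    return float(soak.mean())


def assign_soak(events: pd.DataFrame, default_soak: float = DEFAULT_SOAK_DAYS) -> pd.DataFrame:
    """Impute ``t_haul = t_set + default_soak`` (days) where no haul time exists."""
    if default_soak <= 0:
        raise ValueError("default_soak must be positive")
    out = events.copy()
    if out.empty:
        return out
    t_set = pd.to_datetime(out["t_set"])
    t_haul = pd.to_datetime(out["t_haul"])
    missing = t_haul.isna()
    t_haul = t_haul.where(~missing, t_set + pd.to_timedelta(default_soak, unit="D"))
    if (t_haul <= t_set).any():
        raise ValueError("event with non-positive soak after assignment")
    out["t_haul"] = t_haul
    return out


def distance_to_nearest_active_net(x, y, t, events: pd.DataFrame) -> float:
    """Distance (km) from ``(x, y)`` metres to the nearest net soaking at ``t``.

    A net is active on the closed interval ``[t_set, t_haul]``.  Returns NaN
    (MISSING) when no net is active at ``t``.
    """
    if events.empty:
        return np.nan
    t = pd.Timestamp(t)
    t_set = pd.to_datetime(events["t_set"])
    t_haul = pd.to_datetime(events["t_haul"])
    if t_haul.isna().any():
        raise ValueError("events must have soak intervals assigned")
    active = (t_set <= t) & (t <= t_haul)
    if not active.any():
        return np.nan
    ex = events.loc[active, "x"].to_numpy(float)
    ey = events.loc[active, "y"].to_numpy(float)
    return float(np.hypot(ex - x, ey - y).min() / 1000.0)


def net_distance_covariate(
    batches: pd.DataFrame,
    events: pd.DataFrame,
    cap_km: float = DEFAULT_DISTANCE_CAP_KM,
    column: str = "net_distance",
) -> pd.DataFrame:
    """Attach the active-net distance covariate to a batch table.

    Evaluated at each batch's ``t_begin`` position proxy (the batch table must
    carry ``x``/``y`` columns or ``x_begin``/``y_begin``).  MISSING distances
    (no active net anywhere) and distances above ``cap_km`` are set to
    ``cap_km`` — "no known active net nearby" is informative, not missing.
    """
    out = batches.copy()
    xcol = "x" if "x" in out.columns else "x_begin"
    ycol = "y" if "y" in out.columns else "y_begin"
    dist = np.empty(len(out))
    for i, (px, py, pt) in enumerate(zip(out[xcol], out[ycol], out["t_begin"])):
        d = distance_to_nearest_active_net(px, py, pt, events)
        dist[i] = cap_km if not np.isfinite(d) else min(d, cap_km)
    out[column] = dist
    return out
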