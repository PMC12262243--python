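"""Per-frame velocity and per-encounter kinematic features.

Encounter features feed two classifiers: (log duration, log mean on-patch
velocity) separates explore from exploit; (minimum on-patch velocity,
entry deceleration, maximum velocity change) separates sensing from
non-responding. Deceleration is the least-squares slope of velocity over the
window from 1.5 s before to 6.5 s after encounter entry; the maximum velocity
change subtracts the minimum on-patch velocity from the peak velocity in the
10 s before entry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "instantaneous_velocity",
    "deceleration_at_entry",
    "max_delta_velocity",
    "encounter_features",
]

DECEL_PRE_S = 1.5
DECEL_POST_S = 6.5
MAX_DELTA_PRE_S = 10.0


def instantaneous_velocity(track: pd.DataFrame, smoothing_window: float = 1.0) -> np.ndarray:
    """Instantaneous midpoint speed in um/s.

    Central-difference speed of the (x_mm, y_mm) positions against time_s,
    followed by a moving average over ``smoothing_window`` seconds.
    """
    t = track["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 frames to compute velocity")
    x = track["x_mm"].to_numpy(dtype=float)
    y = track["y_mm"].to_numpy(dtype=float)
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    v = np.hypot(vx, vy) * 1000.0  # mm/s -> um/s
    if smoothing_window > 0:
        dt = np.median(np.diff(t))
        w = max(1, int(round(smoothing_window / dt)))
        if w > 1:
            v = uniform_filter1d(v, size=w, mode="nearest")
    return v


def deceleration_at_entry(times: np.ndarray, velocity: np.ndarray, entry_time: float) -> float:
    """Slope (um/s^2) of velocity over [entry-1.5 s, entry+6.5 s].

    Returns NaN when the window is not fully inside the recording (the
    encounter entry is censored and the feature is unavailable).
    """
    times = np.asarray(times, dtype=float)
    lo, hi = entry_time - DECEL_PRE_S, entry_time + DECEL_POST_S
    if lo < times[0] or hi > times[-1]:
        return np.nan
    m = (times >= lo) & (times <= hi)
    if m.sum() < 2:
        return np.nan
    slope, _ = np.polyfit(times[m], np.asarray(velocity, dtype=float)[m], 1)
    return float(slope)


def max_delta_velocity(
    times: np.ndarray,
    velocity: np.ndarray,
    entry_time: float,
    exit_time: float,
    entry_observed: bool = True,
) -> float:
    """Peak pre-entry velocity minus minimum on-patch velocity, floored at 0.

    The peak is taken over the 10 s before entry; when the entry is not
    observed (left-censored encounter) the feature is NaN and downstream
    classification must marginalize over it.
    """
    times = np.asarray(times, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if not entry_observed:
        return np.nan
    pre = (times >= entry_time - MAX_DELTA_PRE_S) & (times <= entry_time)
    on = (times >= entry_time) & (times <= exit_time)
    if not pre.any() or not on.any():
        return np.nan
    return float(max(0.0, velocity[pre].max() - velocity[on].min()))


def encounter_features(
    track: pd.DataFrame,
    encounters: pd.DataFrame,
    smoothing_window: float = 1.0,
    duration_floor_s: float | None = None,
) -> pd.DataFrame:
    """Append kinematic features to an encounter table.

    Adds duration_s (if absent), mean/min on-patch velocity, deceleration,
    max delta velocity, entry_observed, and the natural-log features
    log_duration and log_mean_velocity used by the explore/exploit
    classifier. Durations are floored at one frame before the log.
    """
    feats = []
    vel_by_worm = {}
    for worm_id, grp in track.groupby("worm_id"):
        grp = grp.reset_index(drop=True)
        vel_by_worm[worm_id] = (
            grp["time_s"].to_numpy(dtype=float),
            instantaneous_velocity(grp, smoothing_window),
        )
    for _, enc in encounters.iterrows():
        t, v = vel_by_worm[enc["worm_id"]]
        dt = float(np.median(np.diff(t)))
        floor = duration_floor_s if duration_floor_s is not None else dt
        entry, exit_ = float(enc["entry_time_s"]), float(enc["exit_time_s"])
        entry_observed = not bool(enc.get("left_censored", False))
        on = (t >= entry) & (t <= exit_)
        v_on = v[on] if on.any() else v[np.argmin(np.abs(t - entry))][None]
        decel = deceleration_at_entry(t, v, entry) if entry_observed else np.nan
        max_dv = max_delta_velocity(t, v, entry, exit_, entry_observed)
        dur = max(exit_ - entry, floor)
        mean_v = float(np.mean(v_on))
        feats.append({
            "duration_s": dur,
            "mean_velocity": mean_v,
            "min_velocity": float(np.min(v_on)),
            "deceleration": decel,
            "max_delta_velocity": max_dv,
            "entry_observed": entry_observed and np.isfinite(decel),
            "log_duration": float(np.log(dur)),
            "log_mean_velocity": float(np.log(max(mean_v, 1e-12))),
        })
    out = encounters.reset_index(drop=True).copy()
    fdf = pd.DataFrame(feats)
    for c in fdf.columns:
        out[c] = fdf[c] if len(fdf) else pd.Series(dtype=float)
    return out
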