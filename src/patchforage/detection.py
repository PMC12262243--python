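"""Patch-encounter detection from midpoint tracks.

A worm's midpoint sits ~0.46 mm from the patch edge when its head first
touches the patch, so an encounter is the interval during which the midpoint
is within 0.46024 mm of the nearest patch edge. Two corrections follow:
near-miss intervals in which the midpoint never came within 0.28758 mm of the
edge are dropped, and consecutive intervals on the same patch are merged when
the intervening "off-patch" excursion has a midpoint-to-edge distance standard
deviation below 0.22221 mm (outstretched feeding postures, not true leaving).
Intervals that abut the start or end of the recording are flagged as left- or
right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .geometry import PatchMap, signed_distances

__all__ = [
    "DetectionConfig",
    "detect_encounters",
    "calibrate_thresholds",
    "CalibrationError",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Calibrated distance thresholds (mm) for encounter detection."""

    encounter_threshold: float = 0.46024
    near_miss_threshold: float = 0.28758
    merge_sd_threshold: float = 0.22221

    def __post_init__(self) -> None:
        if not (0 < self.near_miss_threshold < self.encounter_threshold):
            raise ValueError("need 0 < near_miss_threshold < encounter_threshold")
        if self.merge_sd_threshold <= 0:
            raise ValueError("merge_sd_threshold must be positive")


ENCOUNTER_COLUMNS = [
    "worm_id", "patch_id", "entry_time_s", "exit_time_s", "duration_s",
    "left_censored", "right_censored", "merged_from", "min_signed_distance_mm",
    "max_signed_distance_mm", "entry_frame", "exit_frame",
]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def detect_encounters(
    track: pd.DataFrame,
    patch_map: PatchMap,
    cfg: DetectionConfig = DetectionConfig(),
    on_nan: str = "drop",
    max_missing_frac: float = 0.25,
) -> pd.DataFrame:
    """Detect patch encounters for every worm in a track table.

    Parameters
    ----------
    track
        Columns worm_id, time_s, x_mm, y_mm; time-ordered within worm.
    patch_map
        Arena and patch geometry.
    cfg
        Distance thresholds.
    on_nan
        ``"drop"`` removes frames with NaN positions, ``"error"`` raises.
    max_missing_frac
        Worms with more than this fraction of NaN frames are rejected
        (animals tracked for <75% of the video are excluded).

    Returns
    -------
    DataFrame with one row per encounter (see ``ENCOUNTER_COLUMNS``).
    """
    out = []
    for worm_id, grp in track.groupby("worm_id", sort=True):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"worm {worm_id}: timestamps not strictly increasing")
        xy = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        bad = ~np.isfinite(xy).all(axis=1)
        if bad.any():
            if on_nan == "error":
                raise ValueError(f"worm {worm_id}: NaN positions")
            if bad.mean() > max_missing_frac:
                continue  # tracked for too small a fraction of the video
            t, xy = t[~bad], xy[~bad]
        if len(t) == 0:
            continue
        out.append(_detect_one(worm_id, t, xy, patch_map, cfg))
    if not out:
        return pd.DataFrame(columns=ENCOUNTER_COLUMNS)
    return pd.concat(out, ignore_index=True)


def _detect_one(worm_id, t, xy, patch_map, cfg) -> pd.DataFrame:
    d, pid = signed_distances(xy, patch_map)
    prox = d >= -cfg.encounter_threshold

    # raw intervals; patch identity from the frame of deepest approach
    intervals = []
    for a, b in _runs(prox):
        j = a + int(np.argmax(d[a:b]))
        patch = int(pid[j])
        # distance relative to the assigned patch (needed for merge SDs)
        intervals.append({"a": a, "b": b, "patch": patch, "max_d": float(d[j])})

    # near-miss exclusion: the midpoint must at some point come closer than
    # the near-miss threshold to the patch edge
    intervals = [iv for iv in intervals if iv["max_d"] >= -cfg.near_miss_threshold]

    # merging, transitively left to right: if the gap between consecutive
    # intervals on the same patch has low distance variability, it was not a
    # true leaving event
    p = patch_map.patches
    merged: list[dict] = []
    for iv in intervals:
        iv = dict(iv, merged_from=1)
        if merged and merged[-1]["patch"] == iv["patch"]:
            prev = merged[-1]
            ga, gb = prev["b"], iv["a"]
            patch = p[iv["patch"]]
            gap_d = patch.radius - np.hypot(
                xy[ga:gb, 0] - patch.center[0], xy[ga:gb, 1] - patch.center[1]
            ) if patch.is_circle else np.array(
                [patch.signed_distance(x, y) for x, y in xy[ga:gb]]
            )
            sd = float(np.std(gap_d)) if len(gap_d) > 1 else 0.0
            if sd < cfg.merge_sd_threshold:
                prev["b"] = iv["b"]
                prev["max_d"] = max(prev["max_d"], iv["max_d"])
                prev["merged_from"] += 1
                continue
        merged.append(iv)

    rows = []
    n = len(t)
    for iv in merged:
        a, b = iv["a"], iv["b"]
        patch = p[iv["patch"]]
        if patch.is_circle:
            dd = patch.radius - np.hypot(xy[a:b, 0] - patch.center[0], xy[a:b, 1] - patch.center[1])
        else:
            dd = np.array([patch.signed_distance(x, y) for x, y in xy[a:b]])
        rows.append({
            "worm_id": worm_id,
            "patch_id": iv["patch"],
            "entry_time_s": float(t[a]),
            "exit_time_s": float(t[b - 1]),
            "duration_s": float(t[b - 1] - t[a]),
            "left_censored": a == 0,
            "right_censored": b == n,
            "merged_from": iv["merged_from"],
            "min_signed_distance_mm": float(dd.min()),
            "max_signed_distance_mm": float(dd.max()),
            "entry_frame": int(a),
            "exit_frame": int(b - 1),
        })
    return pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)


class CalibrationError(RuntimeError):
    """Raised when threshold calibration cannot proceed."""


def calibrate_thresholds(
    highres_tracks: pd.DataFrame,
    patch_map: PatchMap,
    edge_tol: float = 0.02,
) -> DetectionConfig:
    """Recover detection thresholds from high-resolution head+midpoint tracks.

    ``highres_tracks`` needs columns worm_id, time_s, x_mm, y_mm (midpoint)
    and head_x_mm, head_y_mm. The encounter threshold is the median
    head-to-midpoint distance over frames where the head is on the patch edge
    (within ``edge_tol`` mm); the near-miss threshold is the magnitude of the
    1st percentile of the signed midpoint-to-edge distance over frames with
    the head on the patch; the merge threshold is the posterior-0.5 crossing
    of a two-component Gaussian mixture fit to off-patch distance standard
    deviations.
    """
    mid = highres_tracks[["x_mm", "y_mm"]].to_numpy(dtype=float)
    head = highres_tracks[["head_x_mm", "head_y_mm"]].to_numpy(dtype=float)
    d_head, _ = signed_distances(head, patch_map)
    d_mid, _ = signed_distances(mid, patch_map)

    on_edge = np.abs(d_head) <= edge_tol
    if not on_edge.any():
        raise CalibrationError("no frames with the head on a patch edge")
    enc_thr = float(np.median(np.hypot(*(head[on_edge] - mid[on_edge]).T)))

    head_on = d_head >= 0
    if not head_on.any():
        raise CalibrationError("no frames with the head on a patch")
    near_thr = float(-np.percentile(d_mid[head_on], 1))
    near_thr = min(near_thr, 0.999 * enc_thr)  # keep the config invariant

    merge_thr = _merge_threshold_from_sds(_off_patch_interval_sds(highres_tracks, patch_map, enc_thr))
    return DetectionConfig(enc_thr, max(near_thr, 1e-6), merge_thr)


def _off_patch_interval_sds(tracks: pd.DataFrame, patch_map: PatchMap, enc_thr: float) -> np.ndarray:
    sds = []
    for _, grp in tracks.groupby("worm_id"):
        xy = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        d, _ = signed_distances(xy, patch_map)
        for a, b in _runs(d < -enc_thr):
            if b - a > 1:
                sds.append(np.std(d[a:b]))
    return np.asarray(sds)


def _merge_threshold_from_sds(sds: np.ndarray, min_separation: float = 1.0) -> float:
    """Posterior-0.5 crossing of a 1-D two-component GMM on off-patch SDs."""
    if len(sds) < 4:
        raise CalibrationError("too few off-patch intervals to fit a mixture")
    gm = GaussianMixture(n_components=2, random_state=0, n_init=5).fit(sds.reshape(-1, 1))
    mu = gm.means_.ravel()
    sig = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(mu)
    if (mu[hi] - mu[lo]) < min_separation * (sig[lo] + sig[hi]):
        raise CalibrationError("off-patch distance SDs are not bimodal; cannot calibrate merging")
    grid = np.linspace(mu[lo], mu[hi], 4096).reshape(-1, 1)
    post_lo = gm.predict_proba(grid)[:, lo]
    j = int(np.argmin(np.abs(post_lo - 0.5)))
    return float(grid[j, 0])
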