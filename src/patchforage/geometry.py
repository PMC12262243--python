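"""Arena and bacterial-patch geometry.

Patches are small circular bacterial lawns pipetted onto an agar arena; the
signed distance from an animal's midpoint to the nearest patch edge (positive
inside the patch) is the primitive that patch-encounter detection is built on.
Relative patch density is estimated from radial fluorescence-intensity
profiles: the patch border is located at the curvature maximum of the outer
edge profile, the border amplitude is the intensity drop from the profile peak
to the border, and per-condition linear models of exposure-normalized border
amplitude versus growth time are scaled so that a 0.5 uL OD600=10 patch grown
for 1 hour has relative density 10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "Patch",
    "PatchMap",
    "RadialProfile",
    "NoBorderError",
    "signed_distance_to_patch_edge",
    "signed_distances",
    "detect_border_and_peak",
    "fit_density_model",
    "scale_to_relative_density",
    "REFERENCE_RELATIVE_DENSITY",
]

#: Relative density assigned to the reference condition
#: (0.5 uL droplet, OD600 = 10, grown 1 h at room temperature).
REFERENCE_RELATIVE_DENSITY = 10.0


@dataclass
class Patch:
    """One circular (or polygonal) bacterial patch."""

    center: tuple[float, float]
    radius: float | None = None
    boundary: Polygon | None = None  # alternative to a circular radius
    rel_density: float = 1.0

    def __post_init__(self) -> None:
        if self.radius is None and self.boundary is None:
            raise ValueError("patch needs a radius or a boundary polygon")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"patch radius must be positive, got {self.radius}")
        if self.rel_density < 0:
            raise ValueError("relative density must be >= 0")

    @property
    def is_circle(self) -> bool:
        return self.radius is not None

    def signed_distance(self, x: float, y: float) -> float:
        """Distance to the patch edge; positive inside the patch."""
        if self.is_circle:
            d = np.hypot(x - self.center[0], y - self.center[1])
            return self.radius - d
        p = Point(x, y)
        d = self.boundary.exterior.distance(p)
        return d if self.boundary.contains(p) else -d

    def outer_radius(self) -> float:
        """Radius of the smallest circle about ``center`` containing the patch."""
        if self.is_circle:
            return self.radius
        cx, cy = self.center
        xs, ys = np.asarray(self.boundary.exterior.coords).T
        return float(np.max(np.hypot(xs - cx, ys - cy)))


@dataclass
class PatchMap:
    """Arena geometry plus the patches it contains."""

    arena_radius: float
    patches: list[Patch] = field(default_factory=list)
    arena_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.arena_radius <= 0:
            raise ValueError("arena radius must be positive")
        for i, p in enumerate(self.patches):
            d = np.hypot(p.center[0] - self.arena_center[0], p.center[1] - self.arena_center[1])
            if d + p.outer_radius() >= self.arena_radius:
                raise ValueError(f"patch {i} overlaps the arena boundary")

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def densities(self) -> np.ndarray:
        return np.array([p.rel_density for p in self.patches], dtype=float)

    # -- JSON round trip (circular patches only; polygons are an in-memory extension)
    def to_json(self, path) -> None:
        obj = {
            "arena_radius_mm": self.arena_radius,
            "arena_center_mm": list(self.arena_center),
            "patches": [
                {
                    "x_mm": p.center[0],
                    "y_mm": p.center[1],
                    "radius_mm": p.radius,
                    "rel_density": p.rel_density,
                }
                for p in self.patches
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PatchMap":
        with open(path) as fh:
            obj = json.load(fh)
        patches = [
            Patch(center=(q["x_mm"], q["y_mm"]), radius=q["radius_mm"], rel_density=q["rel_density"])
            for q in obj["patches"]
        ]
        return cls(
            arena_radius=obj["arena_radius_mm"],
            patches=patches,
            arena_center=tuple(obj.get("arena_center_mm", (0.0, 0.0))),
        )


def signed_distance_to_patch_edge(point: tuple[float, float], patch_map: PatchMap) -> tuple[float, int]:
    """Signed distance from ``point`` to the nearest patch edge.

    Positive inside a patch, negative outside. The nearest patch is the one
    with the largest signed distance (for non-overlapping patches this is the
    containing patch if any, else the patch with the closest edge); ties break
    to the lowest patch id.

    Returns
    -------
    (distance_mm, patch_id)
    """
    if patch_map.n_patches == 0:
        raise ValueError("patch map contains no patches")
    x, y = point
    ds = np.array([p.signed_distance(x, y) for p in patch_map.patches])
    pid = int(np.argmax(ds))  # argmax returns the first (lowest id) maximizer
    return float(ds[pid]), pid


def signed_distances(xy: np.ndarray, patch_map: PatchMap) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized signed distance for an (n, 2) array of positions.

    Returns per-frame signed distance to the nearest patch edge and the
    nearest patch id. Circular patches are evaluated in closed form; polygon
    patches fall back to per-point shapely queries.
    """
    if patch_map.n_patches == 0:
        raise ValueError("patch map contains no patches")
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    all_d = np.empty((patch_map.n_patches, n))
    for j, p in enumerate(patch_map.patches):
        if p.is_circle:
            all_d[j] = p.radius - np.hypot(xy[:, 0] - p.center[0], xy[:, 1] - p.center[1])
        else:
            all_d[j] = [p.signed_distance(x, y) for x, y in xy]
    pid = np.argmax(all_d, axis=0)
    return all_d[pid, np.arange(n)], pid


# ---------------------------------------------------------------------------
# Radial intensity profiles and relative density estimation
# ---------------------------------------------------------------------------


class NoBorderError(ValueError):
    """Raised when a radial profile has no detectable patch border."""


@dataclass
class RadialProfile:
    """Mean fluorescence intensity versus radial distance for one patch."""

    radius_mm: np.ndarray
    intensity: np.ndarray
    exposure_time_s: float = 1.0
    growth_time_h: float = 1.0

    def __post_init__(self) -> None:
        self.radius_mm = np.asarray(self.radius_mm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.radius_mm.ndim != 1 or self.radius_mm.shape != self.intensity.shape:
            raise ValueError("radius and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.radius_mm) <= 0):
            raise ValueError("radius bins must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(y.astype(float), pad, mode="edge")
    out = np.convolve(yp, kernel, mode="same")
    return out[pad : pad + len(y)]


def detect_border_and_peak(
    profile: RadialProfile, smooth_window: int = 3, flat_tol: float = 1e-9
) -> tuple[float, float, float]:
    """Locate the patch border and peak on a radial intensity profile.

    The profile peak is the intensity maximum; the border is placed at the
    maximum of the second difference (discrete curvature) of the lightly
    smoothed profile outside the peak, i.e. the outer kink where the falling
    edge meets the background plateau. Border amplitude is the magnitude of
    the intensity difference between peak and border.

    Returns
    -------
    (border_radius_mm, peak_intensity, border_amplitude)

    Raises
    ------
    NoBorderError
        For flat or monotonically structureless profiles with no edge.
    """
    if len(profile.radius_mm) < 5:
        raise ValueError("profile needs at least 5 bins")
    y = _moving_average(profile.intensity, smooth_window)
    rng = float(np.ptp(y))
    if rng <= flat_tol * max(1.0, float(np.max(np.abs(y)))):
        raise NoBorderError("flat profile: no patch border detectable")

    i_peak = int(np.argmax(y))
    # curvature (second difference) on interior bins beyond the peak
    curv = np.full_like(y, -np.inf)
    curv[1:-1] = y[2:] - 2.0 * y[1:-1] + y[:-2]
    curv[: i_peak + 1] = -np.inf
    if not np.any(np.isfinite(curv)):
        raise NoBorderError("profile has no bins outside the peak")
    cmax = np.max(curv[np.isfinite(curv)])
    # smoothing can tie the curvature across the kink; the border is the
    # outermost bin at the maximum, where the edge meets the background
    ties = np.flatnonzero(np.isfinite(curv) & (curv >= cmax - 1e-9 * max(1.0, abs(cmax))))
    i_border = int(ties[-1])
    if curv[i_border] <= flat_tol * max(1.0, rng):
        raise NoBorderError("no convex kink outside the peak: profile is monotone or flat")

    peak_intensity = float(profile.intensity[i_peak])
    border_intensity = float(profile.intensity[i_border])
    amplitude = abs(peak_intensity - border_intensity)
    return float(profile.radius_mm[i_border]), peak_intensity, amplitude


def fit_density_model(samples: list[tuple[float, float]]) -> tuple[float, float]:
    """OLS fit of relative border amplitude versus bacterial growth time.

    ``samples`` are (growth_time_h, relative_border_amplitude) pairs, where
    relative border amplitude is the border amplitude divided by the imaging
    exposure time. Returns (slope, intercept).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for a linear fit")
    t = np.array([s[0] for s in samples], dtype=float)
    a = np.array([s[1] for s in samples], dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct growth times")
    slope, intercept = np.polyfit(t, a, 1)
    return float(slope), float(intercept)


def scale_to_relative_density(amplitudes: np.ndarray, reference_amplitude: float) -> np.ndarray:
    """Linearly scale amplitudes so the reference condition maps to density 10.

    ``reference_amplitude`` is the (model-estimated) relative border amplitude
    of the reference condition: a 0.5 uL OD600=10 patch grown 1 h.
    """
    if reference_amplitude <= 0:
        raise ValueError("reference amplitude must be positive")
    return np.asarray(amplitudes, dtype=float) * (REFERENCE_RELATIVE_DENSITY / reference_amplitude)
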