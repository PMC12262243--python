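"""Spatial null model: does on-patch residence exceed chance?

Patch constellations are semi-randomly permuted — a global rotation about the
arena center followed by per-patch translations, rejecting placements that
overlap another patch or the arena wall — and the observed probability of
residing on patch over time is compared per time bin against the pooled
permuted placements with a one-tailed Fisher's exact test and
Benjamini-Hochberg correction across bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .geometry import Patch, PatchMap, signed_distances

__all__ = [
    "PermutationResult",
    "permute_patches",
    "residence_probability",
    "residence_counts",
    "residence_test",
]


def permute_patches(
    patch_map: PatchMap,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    max_tries: int = 10_000,
) -> list[PatchMap]:
    """Semi-random permutations of the patch constellation.

    Each replicate applies one random rotation of all patch centers about the
    arena center, then re-places every patch uniformly over the arena subject
    to no patch-patch overlap and no overlap with the arena boundary,
    retrying rejected proposals. Patch radii and densities are preserved
    exactly. Raises if a replicate cannot be placed within ``max_tries``
    proposals (over-packed arena).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cx, cy = patch_map.arena_center
    R = patch_map.arena_radius
    out = []
    for _ in range(n_perm):
        # global rotation randomizes the placement order's angular reference;
        # each patch is then translated to a uniform position over the arena
        order = rng.permutation(len(patch_map.patches))
        placed: list[tuple[float, float, float]] = []
        new_patches: list[Patch | None] = [None] * len(patch_map.patches)
        for j in order:
            p = patch_map.patches[j]
            if not p.is_circle:
                raise ValueError("permutation supports circular patches only")
            ok = False
            for _t in range(max_tries):
                rmax = R - p.radius
                rr = rmax * np.sqrt(rng.uniform())
                th = rng.uniform(0.0, 2.0 * np.pi)
                prop = (cx + rr * np.cos(th), cy + rr * np.sin(th))
                x, y = prop
                if np.hypot(x - cx, y - cy) + p.radius < R and all(
                    np.hypot(x - qx, y - qy) >= p.radius + qr for qx, qy, qr in placed
                ):
                    ok = True
                    break
            if not ok:
                raise RuntimeError("could not place permuted patches: arena too packed")
            placed.append((prop[0], prop[1], p.radius))
            new_patches[j] = Patch(center=prop, radius=p.radius, rel_density=p.rel_density)
        out.append(PatchMap(arena_radius=R, patches=new_patches, arena_center=(cx, cy)))
    return out


def residence_counts(
    track: pd.DataFrame, patch_map: PatchMap, bin_edges_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(on-patch, off-patch) frame counts per time bin, pooled over worms."""
    t = track["time_s"].to_numpy(dtype=float)
    xy = track[["x_mm", "y_mm"]].to_numpy(dtype=float)
    d, _ = signed_distances(xy, patch_map)
    on = d >= 0
    which = np.digitize(t, bin_edges_s) - 1
    nb = len(bin_edges_s) - 1
    valid = (which >= 0) & (which < nb)
    on_counts = np.bincount(which[valid & on], minlength=nb)
    total = np.bincount(which[valid], minlength=nb)
    return on_counts, total - on_counts


def residence_probability(
    track: pd.DataFrame, patch_map: PatchMap, bin_edges_s: np.ndarray
) -> np.ndarray:
    """Fraction of (worm, frame) samples inside any patch per time bin.

    Bins with no samples are NaN (undefined, masked downstream).
    """
    on, off = residence_counts(track, patch_map, bin_edges_s)
    total = on + off
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, on / np.maximum(total, 1), np.nan)


@dataclass
class PermutationResult:
    bin_edges_s: np.ndarray
    observed: np.ndarray
    permuted_mean: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    n_perm: int


def residence_test(
    on_obs: np.ndarray,
    off_obs: np.ndarray,
    on_perm: np.ndarray,
    off_perm: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin one-tailed Fisher's exact test with BH correction across bins.

    The 2x2 table per bin is [[on_obs, off_obs], [on_perm, off_perm]] with the
    permuted counts pooled over replicates; the alternative is that observed
    residence exceeds the permuted null. Bins with an empty margin get p = 1.
    """
    nb = len(on_obs)
    p = np.ones(nb)
    for i in range(nb):
        table = np.array([[on_obs[i], off_obs[i]], [on_perm[i], off_perm[i]]])
        if table.sum(axis=1).min() == 0 or table.sum() == 0:
            p[i] = 1.0
            continue
        p[i] = fisher_exact(table, alternative="greater")[1]
    sig = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    return p, sig


def _per_worm_bin_samples(track: pd.DataFrame, patch_map: PatchMap, edges: np.ndarray):
    """One on/off sample per worm per time bin (the frame nearest the bin center).

    Consecutive frames within a worm are strongly autocorrelated; counting
    every frame in the Fisher table would treat pseudo-replicates as
    independent samples. One sample per worm per bin keeps the table margins
    honest.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)
    on = np.zeros(nb, dtype=np.int64)
    off = np.zeros(nb, dtype=np.int64)
    for _, grp in track.groupby("worm_id"):
        t = grp["time_s"].to_numpy(dtype=float)
        xy = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        idx = np.searchsorted(t, centers)
        idx = np.clip(idx, 0, len(t) - 1)
        valid = (centers >= t[0]) & (centers <= t[-1])
        d, _ = signed_distances(xy[idx], patch_map)
        on += (valid & (d >= 0)).astype(np.int64)
        off += (valid & (d < 0)).astype(np.int64)
    return on, off


def run_residence_analysis(
    track: pd.DataFrame,
    patch_map: PatchMap,
    n_bins: int = 60,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationResult:
    """Observed vs. permuted residence over time for one tracked cohort."""
    t = track["time_s"].to_numpy(dtype=float)
    edges = np.linspace(t.min(), t.max() + 1e-9, n_bins + 1)
    on_obs, off_obs = _per_worm_bin_samples(track, patch_map, edges)
    perms = permute_patches(patch_map, n_perm=n_perm, seed=seed)
    on_p = np.zeros(n_bins, dtype=np.int64)
    off_p = np.zeros(n_bins, dtype=np.int64)
    perm_probs = []
    for pm in perms:
        a, b = _per_worm_bin_samples(track, pm, edges)
        on_p += a
        off_p += b
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_probs.append(np.where(a + b > 0, a / np.maximum(a + b, 1), np.nan))
    p, sig = residence_test(on_obs, off_obs, on_p, off_p, alpha=alpha)
    tot = on_obs + off_obs
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(tot > 0, on_obs / np.maximum(tot, 1), np.nan)
    return PermutationResult(
        bin_edges_s=edges,
        observed=observed,
        permuted_mean=np.nanmean(np.array(perm_probs), axis=0),
        p_values=p,
        significant=sig,
        n_perm=n_perm,
    )
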