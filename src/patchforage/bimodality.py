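"""Silverman's critical-bandwidth test for unimodality.

A Gaussian kernel density estimate gets smoother as its bandwidth grows, and
with a Gaussian kernel the number of modes is non-increasing in the
bandwidth. The critical bandwidth h* is the smallest bandwidth at which the
KDE of a sample has at most k modes (k=1 here); samples drawn from a unimodal
density need little smoothing to look unimodal, so a large h* is evidence of
multimodality. Significance comes from a smoothed bootstrap: resample with
replacement, add kernel noise at h* rescaled to preserve the sample variance,
recompute h* per replicate, and report the fraction of replicate critical
bandwidths at least as large as the observed one.

Multivariate feature matrices are mean-centered and projected onto their
first principal component before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SilvermanResult",
    "rule_of_thumb_bandwidth",
    "count_modes",
    "critical_bandwidth",
    "silverman_test",
    "pc1_projection",
]

_GRID_SIZE = 2048


def rule_of_thumb_bandwidth(data: np.ndarray, d: int = 1) -> float:
    """Silverman's rule-of-thumb bandwidth sigma * (4 / ((d+2) n))^(1/(d+4))."""
    x = np.asarray(data, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        raise ValueError("zero-variance sample has no meaningful bandwidth")
    return sigma * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))


class _BinnedKDE:
    """Linear-binned Gaussian KDE smoothed in the Fourier domain.

    The sample is binned once onto a regular grid padded by ``pad`` times the
    largest bandwidth of interest; each bandwidth evaluation is then a single
    FFT multiply, O(grid log grid) independent of n. Mode counting at
    bandwidths below the bin width is approximate (distinct points that share
    a bin merge), which only matters far below any realistic critical
    bandwidth.
    """

    def __init__(self, x: np.ndarray, h_max: float, grid_size: int = _GRID_SIZE, pad: float = 8.0):
        self._xmin, self._xmax = float(x.min()), float(x.max())
        lo = self._xmin - pad * h_max
        hi = self._xmax + pad * h_max
        if lo == hi:
            lo, hi = lo - 1.0, hi + 1.0
        counts, edges = np.histogram(x, bins=grid_size, range=(lo, hi))
        self._lo = lo
        self.dx = edges[1] - edges[0]
        self._n_grid = grid_size
        self._F = np.fft.rfft(counts.astype(float))
        self._freq = np.fft.rfftfreq(grid_size, d=self.dx)
        self.h_max = h_max

    def density(self, h: float) -> np.ndarray:
        atten = np.exp(-2.0 * (np.pi * self._freq * h) ** 2)
        return np.fft.irfft(self._F * atten, n=self._n_grid)

    def n_modes(self, h: float) -> int:
        dens = self.density(h)
        # the circular FFT wraps the far tails; a Gaussian KDE can have no
        # mode outside the data range + 3h, so only the core is counted
        i0 = max(int((self._xmin - 3.0 * h - self._lo) / self.dx), 0)
        i1 = min(int(np.ceil((self._xmax + 3.0 * h - self._lo) / self.dx)) + 1, len(dens))
        core = dens[i0:i1]
        d = np.diff(core)
        d[np.abs(d) < 1e-10 * max(core.max(), 1e-300)] = 0.0  # FFT ripple
        s = np.sign(d)
        s = s[s != 0]
        if s.size == 0:
            return 1
        return int(np.sum((s[:-1] > 0) & (s[1:] < 0)) + (1 if s[-1] > 0 else 0))


def count_modes(data: np.ndarray, h: float, grid_size: int = _GRID_SIZE) -> int:
    """Number of modes of the Gaussian KDE of ``data`` at bandwidth ``h``.

    The sample is binned onto a regular grid spanning the data range plus 5h
    of padding on each side and smoothed in the Fourier domain; modes are
    strict local maxima of the smoothed histogram (plateaus count once).
    """
    x = np.asarray(data, dtype=float).ravel()
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    return _BinnedKDE(x, h_max=h, grid_size=grid_size).n_modes(h)


def critical_bandwidth(
    data: np.ndarray,
    k_modes: int = 1,
    rel_tol: float = 1e-4,
    grid_size: int = _GRID_SIZE,
) -> float:
    """Minimum bandwidth at which the Gaussian KDE has at most ``k_modes`` modes.

    Bisection over the bandwidth; for Gaussian kernels the mode count is
    non-increasing in the bandwidth, so the crossing is unique. The tolerance
    is ``rel_tol`` times the sample standard deviation.
    """
    x = np.asarray(data, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        return 0.0
    hi = 2.0 * sigma
    kde = _BinnedKDE(x, h_max=hi, grid_size=grid_size)
    while kde.n_modes(hi) > k_modes:
        hi *= 2.0
        kde = _BinnedKDE(x, h_max=hi, grid_size=grid_size)
    lo = hi / 2.0
    while kde.n_modes(lo) <= k_modes and lo > rel_tol * sigma / 4:
        lo /= 2.0
    tol = rel_tol * sigma
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if kde.n_modes(mid) <= k_modes:
            hi = mid
        else:
            lo = mid
    return float(hi)


def pc1_projection(features: np.ndarray) -> np.ndarray:
    """Mean-center a feature matrix and project onto its first principal component."""
    z = np.asarray(features, dtype=float)
    if z.ndim == 1:
        return z - z.mean()
    z = z - z.mean(axis=0)
    if z.shape[1] == 1:
        return z[:, 0]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    return z @ vt[0]


@dataclass
class SilvermanResult:
    h_rot: float
    h_crit: float
    n_boot: int
    p_value: float
    boot_h_crit: np.ndarray
    projection: np.ndarray


def silverman_test(
    features: np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    k_modes: int = 1,
    grid_size: int = _GRID_SIZE,
) -> SilvermanResult:
    """Test the null that the PC1 projection of ``features`` is unimodal.

    Each smoothed-bootstrap replicate resamples the projection with
    replacement and perturbs it as z~ = (z* + h* eps) / sqrt(1 + h*^2/sigma^2)
    with eps standard normal, which preserves the sample variance. The
    p-value is the fraction of replicate critical bandwidths >= the observed
    one; small p rejects unimodality.
    """
    z = pc1_projection(features)
    if z.size < 10:
        raise ValueError("need at least 10 observations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    h_rot = rule_of_thumb_bandwidth(z)
    h_crit = critical_bandwidth(z, k_modes=k_modes, grid_size=grid_size)
    sigma2 = float(np.var(z, ddof=1))
    scale = np.sqrt(1.0 + h_crit**2 / sigma2)

    n = z.size
    boot = np.empty(n_boot)
    for b in range(n_boot):
        zb = rng.choice(z, size=n, replace=True)
        zt = (zb + h_crit * rng.standard_normal(n)) / scale
        boot[b] = critical_bandwidth(zt, k_modes=k_modes, grid_size=grid_size)
    p = float(np.mean(boot >= h_crit))
    return SilvermanResult(h_rot=h_rot, h_crit=h_crit, n_boot=n_boot, p_value=p,
                           boot_h_crit=boot, projection=z)


def smoothed_bootstrap_rescale(z_star: np.ndarray, eps: np.ndarray, h: float, sigma2: float) -> np.ndarray:
    """The smoothed-bootstrap noise rule z~ = (z* + h eps) / sqrt(1 + h^2/sigma^2)."""
    return (np.asarray(z_star, dtype=float) + h * np.asarray(eps, dtype=float)) / np.sqrt(
        1.0 + h**2 / sigma2
    )
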