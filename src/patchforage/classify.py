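"""Behavioral-state classification of patch encounters.

Two classifiers compose into three encounter states:

* explore vs. exploit — a regularized two-component Gaussian mixture on
  z_k = (log duration, log mean on-patch velocity). The ridge term alpha*I on
  the component covariances is tuned on cross-validated replicates to
  minimize the posterior variance sum_k p_k (1 - p_k), i.e. to make the
  posteriors as decisive as possible out of sample.
* sensing vs. non-responding — semi-supervised quadratic discriminant
  analysis on w_k = (min on-patch velocity, entry deceleration, max velocity
  change). Encounters with bacteria-free (density 0) patches are true
  negatives; exploit encounters are included as true positives with
  probability p(y=1|z) across replicates; a self-training loop grows the
  labeled set with high-confidence assignments. Left-censored encounters,
  whose entry kinematics are unobserved, get p(sensed | min velocity) by
  numerically integrating the QDA conditional over a kernel density estimate
  of the unseen features.

Composed states: search = not sensed; sample = sensed but not exploited;
exploit = sensed and exploited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.stats import norm
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold

from .bimodality import rule_of_thumb_bandwidth

__all__ = [
    "ExploitPosterior",
    "SensePosterior",
    "DurationClasses",
    "fit_exploit_gmm",
    "classify_duration_gmm",
    "fit_sensing_qda",
    "marginalize_censored_sensing",
    "compose_states",
    "posterior_variance",
    "near_miss_mask",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 0.1001, 0.005), 4))
NEAR_MISS_P_SENSED = 0.05


def posterior_variance(p: np.ndarray) -> float:
    """Classifier sharpness criterion sum_k p_k (1 - p_k)."""
    p = np.asarray(p, dtype=float)
    return float(np.sum(p * (1.0 - p)))


# ---------------------------------------------------------------------------
# explore / exploit GMM
# ---------------------------------------------------------------------------


@dataclass
class ExploitPosterior:
    p_exploit: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    alpha: float
    cv_scores: dict = field(default_factory=dict)


def _fit_gmm(Z: np.ndarray, alpha: float, seed: int) -> GaussianMixture:
    return GaussianMixture(
        n_components=2,
        covariance_type="full",
        reg_covar=max(alpha, 1e-12),
        n_init=3,
        random_state=seed,
    ).fit(Z)


def fit_exploit_gmm(
    features: np.ndarray,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_reps: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> ExploitPosterior:
    """Two-component GMM posterior of exploitation for each encounter.

    ``features`` is the (n, 2) matrix of (log duration, log mean on-patch
    velocity). The covariance regularization alpha is chosen on a grid by
    ``n_reps`` repeats of ``n_folds``-fold cross-validation, minimizing the
    mean held-out posterior variance. The exploit component is the one with
    the larger mean log duration.
    """
    Z = np.asarray(features, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValueError("features must be (n, 2): log duration, log mean velocity")
    if Z.shape[0] < 20:
        raise ValueError("need at least 20 encounters")

    rng = np.random.default_rng(seed)
    cv_scores: dict[float, float] = {}
    for alpha in alpha_grid:
        scores = []
        failed = False
        for rep in range(n_reps):
            kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
            for tr, te in kf.split(Z):
                try:
                    gm = _fit_gmm(Z[tr], alpha, seed=int(rng.integers(2**31)))
                except Exception:
                    failed = True
                    break
                p = gm.predict_proba(Z[te])[:, 0]
                scores.append(np.mean(p * (1.0 - p)))
            if failed:
                break
        cv_scores[float(alpha)] = np.inf if failed or not scores else float(np.mean(scores))

    alpha_star = min(cv_scores, key=cv_scores.get)
    if not np.isfinite(cv_scores[alpha_star]):
        raise RuntimeError("GMM fit failed at every regularization value")

    try:
        gm = _fit_gmm(Z, alpha_star, seed=seed)
    except Exception:
        # degenerate at the chosen alpha (e.g. alpha=0 with singular clusters)
        finite = sorted(a for a in cv_scores if np.isfinite(cv_scores[a]) and a > alpha_star)
        if not finite:
            raise
        alpha_star = finite[0]
        gm = _fit_gmm(Z, alpha_star, seed=seed)

    exploit_comp = int(np.argmax(gm.means_[:, 0]))  # larger mean log duration
    p = gm.predict_proba(Z)[:, exploit_comp]
    order = [exploit_comp, 1 - exploit_comp]
    return ExploitPosterior(
        p_exploit=p,
        means=gm.means_[order],
        covariances=gm.covariances_[order],
        weights=gm.weights_[order],
        alpha=float(alpha_star),
        cv_scores=cv_scores,
    )


@dataclass
class DurationClasses:
    p_long: np.ndarray
    p_long_refit: np.ndarray | None
    boundary_s: float
    unimodal_warning: bool


def classify_duration_gmm(durations: np.ndarray, censor_flags: np.ndarray | None = None, seed: int = 0) -> DurationClasses:
    """Short/long encounter classes from a 1-D GMM on log duration.

    With ``censor_flags`` (left-censored indicator), the mixture is refit on
    non-censored encounters only and the refit posteriors are reported
    alongside, so the shift due to censoring can be inspected. The class
    boundary is where the long-class posterior crosses 0.5.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 20:
        raise ValueError("need at least 20 encounters")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    x = np.log(d).reshape(-1, 1)
    if np.ptp(x) == 0:
        raise ValueError("all durations identical: degenerate mixture")

    def _fit(xx):
        gm = GaussianMixture(2, reg_covar=1e-9, n_init=5, random_state=seed).fit(xx)
        long_comp = int(np.argmax(gm.means_.ravel()))
        return gm, long_comp

    gm, long_comp = _fit(x)
    mu = np.sort(gm.means_.ravel())
    unimodal = (mu[1] - mu[0]) < np.sqrt(gm.covariances_.ravel()).sum() / 2
    if unimodal:
        warnings.warn("duration distribution looks unimodal; posteriors may be unstable")
    p_long = gm.predict_proba(x)[:, long_comp]

    grid = np.linspace(x.min(), x.max(), 4096).reshape(-1, 1)
    pg = gm.predict_proba(grid)[:, long_comp]
    boundary_s = float(np.exp(grid[np.argmin(np.abs(pg - 0.5)), 0]))

    p_refit = None
    if censor_flags is not None:
        keep = ~np.asarray(censor_flags, dtype=bool)
        if keep.sum() >= 20 and np.ptp(x[keep]) > 0:
            gm2, long2 = _fit(x[keep])
            p_refit = gm2.predict_proba(x)[:, long2]
    return DurationClasses(p_long=p_long, p_long_refit=p_refit,
                           boundary_s=boundary_s, unimodal_warning=bool(unimodal))


# ---------------------------------------------------------------------------
# sensing / non-responding semi-supervised QDA
# ---------------------------------------------------------------------------


@dataclass
class SensePosterior:
    """Replicate-averaged sensing posteriors and the stacked QDA parameters."""

    p_sensed: np.ndarray
    n_replicates: int
    marginalized: np.ndarray  # bool mask of encounters classified via marginalization
    # stacked parameters across replicate models: shape (M, 2, ...)
    _means: np.ndarray = field(repr=False, default=None)
    _precisions: np.ndarray = field(repr=False, default=None)
    _logdets: np.ndarray = field(repr=False, default=None)
    _logpriors: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray, max_models: int | None = None) -> np.ndarray:
        """p(sensed | w) averaged over replicate QDA models for points X (n, 3)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        M = self._means.shape[0] if max_models is None else min(max_models, self._means.shape[0])
        mu = self._means[:M]  # (M, 2, 3)
        prec = self._precisions[:M]  # (M, 2, 3, 3)
        diff = X[None, None, :, :] - mu[:, :, None, :]  # (M, 2, n, 3)
        quad = np.einsum("mcni,mcij,mcnj->mcn", diff, prec, diff)
        g = self._logpriors[:M][:, :, None] - 0.5 * self._logdets[:M][:, :, None] - 0.5 * quad
        # class 1 = sensing
        p = 1.0 / (1.0 + np.exp(np.clip(g[:, 0] - g[:, 1], -500, 500)))
        return p.mean(axis=0)


def _qda_params(model: QuadraticDiscriminantAnalysis):
    means, precs, logdets = [], [], []
    for c in range(2):
        R = model.rotations_[c]
        S = np.maximum(model.scalings_[c], 1e-300)
        precs.append(R @ np.diag(1.0 / S) @ R.T)
        logdets.append(float(np.sum(np.log(S))))
        means.append(model.means_[c])
    return np.array(means), np.array(precs), np.array(logdets), np.log(model.priors_)


def fit_sensing_qda(
    features: np.ndarray,
    labels_neg: np.ndarray,
    p_exploit: np.ndarray,
    n_reps: int = 1000,
    seed: int = 0,
    self_train_threshold: float = 0.95,
    max_iter: int = 50,
    reg_param: float = 1e-4,
) -> SensePosterior:
    """Semi-supervised QDA posterior of sensing for each encounter.

    ``features`` is the (n, 3) matrix w = (min velocity, deceleration, max
    delta velocity); rows with non-finite entries (censored encounters) are
    left NaN here and must be handled by marginalization. ``labels_neg`` is a
    boolean mask of guaranteed non-sensed encounters (bacteria-free patches).
    Per replicate, positives are drawn y ~ Bern(p_exploit); a QDA is fit on
    the labeled subset and grown by self-training (unlabeled points whose
    posterior exceeds ``self_train_threshold`` either way are adopted) until
    assignments stabilize; the final posteriors are averaged over replicates.
    """
    W = np.asarray(features, dtype=float)
    if W.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    neg = np.asarray(labels_neg, dtype=bool)
    pe = np.asarray(p_exploit, dtype=float)
    if not ((pe >= 0) & (pe <= 1)).all():
        raise ValueError("p_exploit must be probabilities")
    ok = np.isfinite(W).all(axis=1)
    if not neg[ok].any():
        raise ValueError("need at least one true-negative (density-0) encounter")

    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(ok)
    Wo = W[ok]
    nego = neg[ok]
    peo = pe[ok]

    acc = np.zeros(len(Wo))
    all_means, all_precs, all_logdets, all_logpriors = [], [], [], []
    for _ in range(n_reps):
        for _retry in range(100):
            pos = (rng.uniform(size=len(Wo)) < peo) & ~nego
            if pos.any():
                break
        else:
            raise RuntimeError("could not draw a replicate with at least one positive label")

        labeled = nego | pos
        y = pos.astype(int)
        prev = None
        model = None
        for _it in range(max_iter):
            model = QuadraticDiscriminantAnalysis(reg_param=reg_param).fit(Wo[labeled], y[labeled])
            p_all = model.predict_proba(Wo)[:, 1]
            conf_pos = (~labeled) & (p_all > self_train_threshold)
            conf_neg = (~labeled) & (p_all < 1.0 - self_train_threshold)
            assign = conf_pos | conf_neg
            key = (assign.sum(), conf_pos.sum())
            if prev == key or not assign.any():
                break
            prev = key
            labeled = labeled | assign
            y = np.where(conf_pos, 1, np.where(conf_neg, 0, y))
        acc += model.predict_proba(Wo)[:, 1]
        m, pr, ld, lp = _qda_params(model)
        all_means.append(m)
        all_precs.append(pr)
        all_logdets.append(ld)
        all_logpriors.append(lp)

    p_sensed = np.full(len(W), np.nan)
    p_sensed[idx] = acc / n_reps
    return SensePosterior(
        p_sensed=p_sensed,
        n_replicates=n_reps,
        marginalized=~ok,
        _means=np.array(all_means),
        _precisions=np.array(all_precs),
        _logdets=np.array(all_logdets),
        _logpriors=np.array(all_logpriors),
    )


def marginalize_censored_sensing(
    s: float,
    conditional,
    reference_features: np.ndarray,
    max_models: int | None = 25,
    epsrel: float = 1e-4,
) -> float:
    """p(sensed | min velocity s) for an entry-censored encounter.

    Integrates p(sensed | s, t, u) against the kernel density estimate of
    (deceleration t, max delta velocity u) conditional on s over the
    reference encounters:

        p(v=1 | s) = integral integral p(v=1 | s,t,u) p(t,u | s) dt du

    ``conditional`` is a ``SensePosterior`` or a callable p(s, t, u). The
    conditional KDE uses Gaussian product kernels with rule-of-thumb
    bandwidths; the double integral is evaluated with adaptive quadrature.
    Values of s outside the reference support are clamped to the nearest
    observed s with a warning.
    """
    ref = np.asarray(reference_features, dtype=float)
    ref = ref[np.isfinite(ref).all(axis=1)]
    if len(ref) == 0:
        raise ValueError("reference feature set is empty")
    sr, tr, ur = ref[:, 0], ref[:, 1], ref[:, 2]
    hs = rule_of_thumb_bandwidth(sr) if np.ptp(sr) > 0 else max(1e-6, abs(sr[0]) * 1e-3 + 1e-6)
    ht = rule_of_thumb_bandwidth(tr) if np.ptp(tr) > 0 else 1e-6
    hu = rule_of_thumb_bandwidth(ur) if np.ptp(ur) > 0 else 1e-6

    lo, hi = sr.min() - 3 * hs, sr.max() + 3 * hs
    if not (lo <= s <= hi):
        warnings.warn("min velocity outside reference support; evaluating at nearest support point")
        s = float(np.clip(s, sr.min(), sr.max()))

    logw = -0.5 * ((s - sr) / hs) ** 2
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()

    if isinstance(conditional, SensePosterior):
        def p_func(t, u):
            return float(conditional.predict(np.array([[s, t, u]]), max_models=max_models)[0])
    else:
        def p_func(t, u):
            return float(conditional(s, t, u))

    t_lo, t_hi = tr.min() - 5 * ht, tr.max() + 5 * ht
    u_lo, u_hi = ur.min() - 5 * hu, ur.max() + 5 * hu

    def kde_tu(t, u):
        return float(np.sum(w * norm.pdf(t, tr, ht) * norm.pdf(u, ur, hu)))

    num, _ = integrate.dblquad(
        lambda u, t: p_func(t, u) * kde_tu(t, u), t_lo, t_hi, u_lo, u_hi, epsrel=epsrel, epsabs=1e-8,
    )
    # mass of the truncated KDE over the same box (analytic for product kernels)
    mass = float(np.sum(
        w
        * (norm.cdf(t_hi, tr, ht) - norm.cdf(t_lo, tr, ht))
        * (norm.cdf(u_hi, ur, hu) - norm.cdf(u_lo, ur, hu))
    ))
    return float(np.clip(num / mass, 0.0, 1.0))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def compose_states(p_sensed: np.ndarray, p_exploit: np.ndarray):
    """Compose sensing and exploitation posteriors into state probabilities.

    search = not sensed; sample = sensed, not exploited; exploit = sensed and
    exploited. The triple sums to one exactly.
    """
    ps = np.asarray(p_sensed, dtype=float)
    pe = np.asarray(p_exploit, dtype=float)
    p_sample = ps * (1.0 - pe)
    p_exploit_final = ps * pe
    # exact complement of the sensed mass so the triple normalizes exactly
    p_search = 1.0 - (p_sample + p_exploit_final)
    return p_search, p_sample, p_exploit_final


def near_miss_mask(max_signed_distance_mm: np.ndarray, p_sensed: np.ndarray) -> np.ndarray:
    """True for residual near-miss encounters to exclude downstream.

    An encounter whose midpoint never entered the patch proper and whose
    sensing probability is below 5% is treated as a near miss.
    """
    return (np.asarray(max_signed_distance_mm, dtype=float) < 0) & (
        np.asarray(p_sensed, dtype=float) < NEAR_MISS_P_SENSED
    )
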