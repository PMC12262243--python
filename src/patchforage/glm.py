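"""Soft-label logistic models of the decision to exploit a patch.

The probability that an animal exploits on sensed encounter k is modeled as
p(y_k=1) = logistic(beta . x_k) with covariates: intercept, rho_k (log
relative density of the current patch), tau_s (hours off food since the last
exploit), rho_h (log density of the previous encounter's patch), rho_e (log
density of the last exploited patch), and optionally tau_t (hours since
transfer). Exploitation is observed only as a classifier posterior q_k =
p(y_k=1|z_k), so the fit minimizes the KL divergence between q_k and the
model probabilities — equivalent to maximizing the logistic log-likelihood
with q_k in place of binary outcomes, and collapsing to ordinary logistic
regression when the labels are hard.

Uncertainty propagates through two resampling layers: "encounter sampling"
(each encounter enters a replicate with probability p(sensed); covariates are
rebuilt over the retained subsequence) and "worm sampling" (hierarchical
bootstrap over animals). Their product forms the replicate set over which
coefficients, bootstrap hypothesis tests, model-selection scores, and
between-strain Z tests are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "COEF_NAMES",
    "FitResult",
    "SeparationError",
    "build_covariates",
    "sample_encounters",
    "bootstrap_worms",
    "fit_soft_logistic",
    "fit_replicated",
    "test_coefficients",
    "compare_strains",
    "optimize_ridge",
    "model_selection",
    "likelihood_ratio_test",
    "simulate_first_exploitation",
    "predict_probability_surface",
    "expand_soft_rows",
    "logistic",
]

COEF_NAMES = ("b0", "bk", "bs", "bh", "be", "bt")
#: density coefficients compared one-sidedly (mutant < wild type) in strain tests
DENSITY_COEFS = {"bk", "bh", "be"}


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


class SeparationError(RuntimeError):
    """Unpenalized fit diverged (perfectly separated data); set ridge > 0."""


# ---------------------------------------------------------------------------
# covariate construction
# ---------------------------------------------------------------------------


def build_covariates(
    encounters: pd.DataFrame,
    acclimation_density: float,
    exploit_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-sensed-encounter covariates for one encounter-sampled replicate.

    ``encounters`` holds the retained (sensed) encounters only, time-ordered
    within worm, with columns worm_id, entry_time_s, exit_time_s, density and
    the soft response q (= p(y=1|z)). Time spent during removed
    non-responding encounters is, by construction, part of the off-patch
    clock: tau_s at encounter k is the time since the end of the last
    exploited encounter minus the on-patch time of retained encounters in
    between (hours); for a worm with no exploit yet it is the time elapsed
    since the start of the recording minus retained on-patch time. rho_h and
    rho_e start at the acclimation-plate density. Exploits are the encounters
    with q > ``exploit_threshold``.
    """
    if acclimation_density <= 0:
        raise ValueError("acclimation density must be positive")
    if (encounters["density"] <= 0).any():
        raise ValueError("density-0 encounters cannot enter the exploitation model")
    log_accl = float(np.log(acclimation_density))
    rows = []
    for worm_id, grp in encounters.groupby("worm_id", sort=True):
        grp = grp.sort_values("entry_time_s")
        rho_h = log_accl
        rho_e = log_accl
        t_ref = 0.0  # end of last exploited encounter (or recording start)
        on_patch_since_ref = 0.0
        for kstar, (_, enc) in enumerate(grp.iterrows()):
            entry = float(enc["entry_time_s"])
            dens = float(enc["density"])
            tau_s = (entry - t_ref - on_patch_since_ref) / 3600.0
            tau_t = entry / 3600.0
            rows.append({
                "worm_id": worm_id,
                "k": int(enc["k"]) if "k" in enc else kstar,
                "k_star": kstar,
                "rho_k": np.log(dens),
                "tau_s": max(tau_s, 0.0),
                "tau_t": tau_t,
                "rho_h": rho_h,
                "rho_e": rho_e,
                "q": float(enc["q"]),
            })
            rho_h = np.log(dens)
            if float(enc["q"]) > exploit_threshold:
                rho_e = np.log(dens)
                t_ref = float(enc["exit_time_s"])
                on_patch_since_ref = 0.0
            else:
                on_patch_since_ref += float(enc["exit_time_s"]) - entry
    return pd.DataFrame(rows, columns=[
        "worm_id", "k", "k_star", "rho_k", "tau_s", "tau_t", "rho_h", "rho_e", "q",
    ])


def sample_encounters(
    p_sensed: np.ndarray, n_reps: int = 100, seed: int | np.random.Generator = 0
) -> list[np.ndarray]:
    """Encounter-sampling replicates: boolean inclusion masks drawn Bern(p_sensed)."""
    p = np.asarray(p_sensed, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_sensed must be probabilities")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masks = [rng.uniform(size=p.size) < p for _ in range(n_reps)]
    return masks


def bootstrap_worms(
    worm_ids, n_reps: int = 500, seed: int | np.random.Generator = 0
) -> list[np.ndarray]:
    """Hierarchical bootstrap: with-replacement worm resamples of original size."""
    ids = np.unique(np.asarray(worm_ids))
    if ids.size == 0:
        raise ValueError("need at least one worm")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [rng.choice(ids, size=ids.size, replace=True) for _ in range(n_reps)]


# ---------------------------------------------------------------------------
# the soft-label fit
# ---------------------------------------------------------------------------


def soft_loglik(beta: np.ndarray, X: np.ndarray, q: np.ndarray, weights=None) -> float:
    """Soft-label logistic log-likelihood sum_k w_k [q ln p + (1-q) ln(1-p)]."""
    eta = X @ beta
    # log p and log(1-p) via logaddexp for numerical stability
    log_p = -np.logaddexp(0.0, -eta)
    log_1mp = -np.logaddexp(0.0, eta)
    ll = q * log_p + (1.0 - q) * log_1mp
    if weights is not None:
        ll = ll * weights
    return float(np.sum(ll))


def fit_soft_logistic(
    X: np.ndarray,
    q: np.ndarray,
    ridge_lam: float = 0.0,
    weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    beta_cap: float = 1e4,
):
    """Newton (IRLS) maximizer of the soft-label logistic objective.

    Maximizes sum_k w_k [q_k log p_k + (1-q_k) log(1-p_k)] - lam * ||beta[1:]||^2
    (the ridge penalty excludes the intercept, assumed in column 0). Returns
    ``(beta, info)`` where info carries the unpenalized log-likelihood, AIC
    and BIC. With hard labels q in {0,1} and lam=0 this is ordinary logistic
    regression.
    """
    X = np.asarray(X, dtype=float)
    q = np.asarray(q, dtype=float)
    n, p = X.shape
    if np.any((q < 0) | (q > 1)):
        raise ValueError("soft labels must lie in [0, 1]")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    pen = np.full(p, 2.0 * ridge_lam)
    pen[0] = 0.0

    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -500, 500)
        mu = logistic(eta)
        grad = X.T @ (w * (q - mu)) - pen * beta
        if np.linalg.norm(grad) < tol:
            # a "converged" unpenalized fit that saturates every probability is
            # perfect separation: the true optimum is at infinity
            if ridge_lam == 0.0 and np.max(np.abs(beta)) > 20 and np.all(np.abs(q - mu) < 1e-8):
                raise SeparationError(
                    "probabilities saturated at a diverging optimum: data are "
                    "perfectly separated; set ridge_lam > 0"
                )
            break
        s = w * mu * (1.0 - mu)
        H = -(X.T * s) @ X - np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular Hessian: data may be separable or collinear; set ridge_lam > 0"
            )
        # backtracking on the penalized objective
        obj0 = soft_loglik(beta, X, q, w) - 0.5 * float(pen @ beta**2)
        t_step = 1.0
        for _half in range(50):
            cand = beta - t_step * step
            obj = soft_loglik(cand, X, q, w) - 0.5 * float(pen @ cand**2)
            if obj >= obj0 - 1e-12:
                break
            t_step /= 2.0
        beta = beta - t_step * step
        if np.max(np.abs(beta)) > beta_cap and ridge_lam == 0.0:
            raise SeparationError(
                "coefficients diverging: data are likely perfectly separated; set ridge_lam > 0"
            )
    else:
        if ridge_lam == 0.0:
            raise SeparationError("did not converge; data may be separated, set ridge_lam > 0")

    ll = soft_loglik(beta, X, q, w)
    n_eff = float(np.sum(w))
    info = {
        "loglik": ll,
        "aic": -2.0 * ll + 2.0 * p,
        "bic": -2.0 * ll + p * np.log(max(n_eff, 1.0)),
        "n": n_eff,
        "n_params": p,
    }
    return beta, info


def expand_soft_rows(X: np.ndarray, q: np.ndarray):
    """Expand soft-label rows into two hard-label rows weighted q and 1-q.

    Independent route to the same optimum as ``fit_soft_logistic``; used for
    cross-checking the KL objective.
    """
    X = np.asarray(X, dtype=float)
    q = np.asarray(q, dtype=float)
    X2 = np.vstack([X, X])
    y2 = np.concatenate([np.ones(len(X)), np.zeros(len(X))])
    w2 = np.concatenate([q, 1.0 - q])
    keep = w2 > 0
    return X2[keep], y2[keep], w2[keep]


# ---------------------------------------------------------------------------
# replicated fits
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Coefficient replicates and summaries for one model fit."""

    beta: np.ndarray  # (n_replicates, n_coefs)
    coef_names: tuple[str, ...]
    loglik: np.ndarray
    aic: np.ndarray
    bic: np.ndarray
    ridge_lam: float = 0.0
    n_failed: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return self.beta.shape[0]

    def summary(self) -> pd.DataFrame:
        b = self.beta
        return pd.DataFrame({
            "coef": list(self.coef_names),
            "mean": b.mean(axis=0),
            "std": b.std(axis=0, ddof=1) if len(b) > 1 else np.zeros(b.shape[1]),
            "q2.5": np.percentile(b, 2.5, axis=0),
            "q50": np.percentile(b, 50, axis=0),
            "q97.5": np.percentile(b, 97.5, axis=0),
        })


def _design(rows: pd.DataFrame, covariates: tuple[str, ...]):
    X = np.column_stack([np.ones(len(rows))] + [rows[c].to_numpy(dtype=float) for c in covariates])
    return X, rows["q"].to_numpy(dtype=float)


_COV_TO_COEF = {"rho_k": "bk", "tau_s": "bs", "rho_h": "bh", "rho_e": "be", "tau_t": "bt"}


def coef_names_for(covariates: tuple[str, ...]) -> tuple[str, ...]:
    return ("b0",) + tuple(_COV_TO_COEF[c] for c in covariates)


def fit_replicated(
    encounters: pd.DataFrame,
    acclimation_density: float,
    covariates: tuple[str, ...] = ("rho_k", "tau_s", "rho_h", "rho_e"),
    n_encounter_reps: int = 100,
    n_worm_reps: int = 500,
    ridge_lam: float = 0.0,
    seed: int = 0,
    shuffle_response: bool = False,
    max_failed_frac: float = 0.01,
) -> FitResult:
    """Fit the soft-label model over the encounter x worm resampling product.

    ``encounters`` is the full encounter table (all worms, time-ordered) with
    columns worm_id, k, entry_time_s, exit_time_s, density, p_sensed, q. Per
    encounter-sampling replicate, encounters are retained Bern(p_sensed) and
    covariates rebuilt on the retained subsequence; per worm-sampling
    replicate, worms are drawn with replacement and enter the likelihood once
    per appearance (frequency weights). ``shuffle_response`` permutes q
    against the covariates within each encounter replicate (the null model).
    """
    rng = np.random.default_rng(seed)
    masks = sample_encounters(encounters["p_sensed"].to_numpy(dtype=float), n_encounter_reps, rng)
    names = coef_names_for(covariates)

    betas, lls, aics, bics = [], [], [], []
    n_failed = 0
    worm_order = np.unique(encounters["worm_id"].to_numpy())
    for mask in masks:
        kept = encounters.loc[mask]
        if kept.empty:
            n_failed += n_worm_reps
            continue
        rows = build_covariates(kept, acclimation_density)
        X, qv = _design(rows, covariates)
        if shuffle_response:
            qv = rng.permutation(qv)
        wid = rows["worm_id"].to_numpy()
        # frequency-weight lookup per worm replicate
        for _ in range(n_worm_reps):
            draw = rng.choice(worm_order, size=worm_order.size, replace=True)
            counts = pd.Series(draw).value_counts()
            wts = counts.reindex(wid).fillna(0.0).to_numpy(dtype=float)
            if not np.any(wts > 0):
                n_failed += 1
                continue
            sel = wts > 0
            try:
                beta, info = fit_soft_logistic(X[sel], qv[sel], ridge_lam, weights=wts[sel])
            except SeparationError:
                n_failed += 1
                continue
            betas.append(beta)
            lls.append(info["loglik"])
            aics.append(info["aic"])
            bics.append(info["bic"])

    total = n_encounter_reps * n_worm_reps
    if n_failed > max_failed_frac * total:
        raise SeparationError(
            f"{n_failed}/{total} replicate fits failed; refit with ridge_lam > 0"
        )
    return FitResult(
        beta=np.array(betas),
        coef_names=names,
        loglik=np.array(lls),
        aic=np.array(aics),
        bic=np.array(bics),
        ridge_lam=ridge_lam,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# hypothesis tests and model comparison
# ---------------------------------------------------------------------------


def test_coefficients(fit: FitResult, bonferroni: bool = False) -> pd.DataFrame:
    """Two-tailed one-sample bootstrap test of each coefficient against zero.

    p = 2 min(P(beta <= 0), P(beta >= 0)) over replicates, floored at
    2/(n_replicates + 1) (an empirical p-value is never exactly zero).
    """
    b = fit.beta
    n = b.shape[0]
    if n < 100:
        raise ValueError("need at least 100 replicates for a bootstrap test")
    p_le = np.mean(b <= 0, axis=0)
    p_ge = np.mean(b >= 0, axis=0)
    p = 2.0 * np.minimum(p_le, p_ge)
    floor = 2.0 / (n + 1)
    p = np.maximum(p, floor)
    if bonferroni:
        p = np.minimum(p * b.shape[1], 1.0)
    return pd.DataFrame({
        "coef": list(fit.coef_names),
        "mean": b.mean(axis=0),
        "p_value": p,
        "at_floor": p <= floor,
    })


def compare_strains(fit_mutant: FitResult, fit_ref: FitResult) -> pd.DataFrame:
    """Between-strain Z test on the replicate coefficient distributions.

    Z = (mu_mutant - mu_ref) / sqrt(sigma_mutant^2 + sigma_ref^2); density
    coefficients (bk, bh, be) use a left-tailed test (is the mutant's density
    sensitivity reduced?), the others a two-tailed test; Benjamini-Hochberg
    across coefficients.
    """
    if fit_mutant.coef_names != fit_ref.coef_names:
        raise ValueError("coefficient sets differ between fits")
    mu_m = fit_mutant.beta.mean(axis=0)
    mu_r = fit_ref.beta.mean(axis=0)
    sd_m = fit_mutant.beta.std(axis=0, ddof=1)
    sd_r = fit_ref.beta.std(axis=0, ddof=1)
    z = (mu_m - mu_r) / np.sqrt(sd_m**2 + sd_r**2)
    p = np.empty_like(z)
    for i, name in enumerate(fit_ref.coef_names):
        if name in DENSITY_COEFS:
            p[i] = stats.norm.cdf(z[i])  # left-tailed
        else:
            p[i] = 2.0 * stats.norm.cdf(-abs(z[i]))  # two-tailed
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "coef": list(fit_ref.coef_names),
        "z": z,
        "p_value": p,
        "p_bh": p_adj,
    })


def optimize_ridge(
    rows: pd.DataFrame,
    covariates: tuple[str, ...],
    lam_grid,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Cross-validated ridge strength: argmax of mean held-out soft log-likelihood.

    Folds are grouped by worm so one animal's encounters never straddle the
    train/test split.
    """
    lam_grid = list(lam_grid)
    if not lam_grid:
        raise ValueError("lambda grid is empty")
    X, q = _design(rows, covariates)
    worms = rows["worm_id"].to_numpy()
    uniq = np.unique(worms)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    folds = np.array_split(perm, min(cv_folds, len(uniq)))

    records = []
    for lam in lam_grid:
        scores = []
        for hold in folds:
            te = np.isin(worms, hold)
            if te.all() or not te.any():
                continue
            try:
                beta, _ = fit_soft_logistic(X[~te], q[~te], ridge_lam=lam)
            except SeparationError:
                scores.append(-np.inf)
                continue
            scores.append(soft_loglik(beta, X[te], q[te]) / te.sum())
        records.append({"lam": lam, "mean_heldout_loglik": float(np.mean(scores))})
    table = pd.DataFrame(records)
    best = float(table.loc[table["mean_heldout_loglik"].idxmax(), "lam"])
    return best, table


def model_selection(
    rows: pd.DataFrame,
    covariate_subsets: dict[str, tuple[str, ...]],
    ridge_lam: float = 0.0,
) -> pd.DataFrame:
    """Log-likelihood / AIC / BIC for a family of covariate subsets on one replicate."""
    records = []
    for name, covs in covariate_subsets.items():
        X, q = _design(rows, covs)
        beta, info = fit_soft_logistic(X, q, ridge_lam=ridge_lam)
        records.append({
            "model": name, "covariates": covs, "n_params": info["n_params"],
            "loglik": info["loglik"], "aic": info["aic"], "bic": info["bic"],
        })
    return pd.DataFrame(records)


def likelihood_ratio_test(rows: pd.DataFrame, null_covs: tuple[str, ...], alt_covs: tuple[str, ...]):
    """LRT of a nested null model within an alternative; returns (stat, df, p)."""
    if not set(null_covs) <= set(alt_covs):
        raise ValueError("null model must be nested in the alternative")
    X0, q = _design(rows, null_covs)
    X1, _ = _design(rows, alt_covs)
    b0, i0 = fit_soft_logistic(X0, q)
    b1, i1 = fit_soft_logistic(X1, q)
    stat = 2.0 * (i1["loglik"] - i0["loglik"])
    df = i1["n_params"] - i0["n_params"]
    return float(stat), int(df), float(stats.chi2.sf(max(stat, 0.0), df))


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------


def simulate_first_exploitation(
    p_sequences: list[np.ndarray], n_sims: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Distribution of the encounter index (1-based) of the first exploit.

    Per simulation, each sequence of per-encounter exploit probabilities is
    walked drawing Bernoulli(p_k); the index of the first success is
    recorded, or the sequence is right-censored at its end.
    """
    if not p_sequences:
        raise ValueError("need at least one probability sequence")
    rng = np.random.default_rng(seed)
    max_len = max(len(p) for p in p_sequences)
    counts = np.zeros(max_len + 1, dtype=np.int64)  # [k=1..max_len], censored at 0
    n_censored = 0
    for p in p_sequences:
        p = np.asarray(p, dtype=float)
        draws = rng.uniform(size=(n_sims, p.size)) < p  # (n_sims, L)
        any_hit = draws.any(axis=1)
        first = np.argmax(draws, axis=1) + 1
        first = first[any_hit]
        np.add.at(counts, first, 1)
        n_censored += int((~any_hit).sum())
    total = counts[1:].sum() + n_censored
    idx = np.arange(1, max_len + 1)
    return pd.DataFrame({
        "k": idx,
        "count": counts[1:],
        "probability": counts[1:] / total,
    }).assign(n_censored=n_censored, n_total=total)


def predict_probability_surface(
    beta: np.ndarray,
    coef_names: tuple[str, ...],
    grid_a: np.ndarray,
    grid_b: np.ndarray,
    vary: tuple[str, str],
    fixed: dict[str, float],
) -> np.ndarray:
    """Logistic probability surface over two covariates, others held fixed.

    ``vary`` names the coefficients for rows (grid_a) and columns (grid_b);
    ``fixed`` supplies values for the remaining non-intercept coefficients
    (typically data means). Returns a (len(grid_a), len(grid_b)) matrix.
    """
    beta = np.asarray(beta, dtype=float)
    names = list(coef_names)
    eta = np.full((len(grid_a), len(grid_b)), beta[names.index("b0")])
    A, B = np.meshgrid(grid_a, grid_b, indexing="ij")
    eta = eta + beta[names.index(vary[0])] * A + beta[names.index(vary[1])] * B
    for name, val in fixed.items():
        eta = eta + beta[names.index(name)] * val
    return logistic(eta)
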