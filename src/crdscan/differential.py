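"""Negative-binomial Wald differential tests and Storey q-value machinery.

The differential core mirrors the standard count-based workflow: library
composition is absorbed by median-of-ratios size factors; each feature gets
an NB GLM with a log link and log-size-factor offset; per-feature dispersion
is estimated by Cox-Reid-adjusted maximum likelihood and shrunk toward a
mean-dispersion trend; the case/control coefficient is tested with a Wald
z.  Multiplicity is handled throughout by Storey's pi0/q-value estimator,
which also provides the pi1 (proportion of true alternatives) statistic used
for replication and covariate screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

log = logging.getLogger("crdscan")


@dataclass
class DifferentialResult:
    feature_id: str
    base_mean: float
    log2_fold_change: float
    se: float
    z: float
    p: float
    q: float
    direction: int


@dataclass
class PiStatistics:
    """Storey pi0/pi1 estimate with the q-values it implies."""

    pi0: float
    pi1: float
    lambdas: np.ndarray
    qvalues: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalue(pvalues, lambdas=None, pi0: float | None = None) -> PiStatistics:
    """Storey q-values with smoothed pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed by a cubic
    polynomial over the lambda grid and evaluated at its upper end.  Inputs
    with fewer than 20 p-values fall back to pi0 = 1 (Benjamini-Hochberg);
    passing ``pi0=1.0`` forces BH exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    if pi0 is None:
        if m < 20:
            pi0 = 1.0
        else:
            pi0_l = np.array(
                [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas]
            )
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas.max()))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 estimate {pi0} outside (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return PiStatistics(pi0=pi0, pi1=1.0 - pi0, lambdas=lambdas, qvalues=q)


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def estimate_size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors for a samples x features count matrix.

    Ratios are taken against the per-feature geometric mean over features
    with all-positive counts; the factors are normalized to geometric mean 1.
    """
    K = np.asarray(counts, dtype=float)
    usable = (K > 0).all(axis=0)
    if not usable.any():
        raise ValueError("no feature with all-positive counts")
    logK = np.log(K[:, usable])
    log_geo = logK.mean(axis=0)
    log_sf = np.median(logK - log_geo, axis=1)
    log_sf -= log_sf.mean()
    return np.exp(log_sf)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def _nb_loglik_grid(y, mu, alphas, X):
    """Cox-Reid-adjusted NB log-likelihood on an alpha grid.

    y, mu: (n,) for one feature; alphas: (g,); X: (n, p) design.
    Returns (g,) adjusted log-likelihoods.
    """
    n = y.size
    out = np.empty(alphas.size)
    for i, a in enumerate(alphas):
        inv = 1.0 / a
        ll = (
            special.gammaln(y + inv)
            - special.gammaln(inv)
            - special.gammaln(y + 1.0)
            + y * np.log(a * mu / (1.0 + a * mu))
            - inv * np.log1p(a * mu)
        ).sum()
        w = mu / (1.0 + a * mu)
        xtwx = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(xtwx)
        out[i] = ll - 0.5 * logdet
    return out


def _estimate_dispersions(Y, Mu, X, shrink_strength: float = 10.0):
    """Per-feature CR-MLE dispersion, shrunk toward a log-mean trend."""
    nf = Y.shape[1]
    grid = np.exp(np.linspace(np.log(1e-4), np.log(10.0), 40))
    alpha_hat = np.empty(nf)
    for j in range(nf):
        ll = _nb_loglik_grid(Y[:, j], Mu[:, j], grid, X)
        i = int(np.argmax(ll))
        # one parabolic refinement in log-alpha
        if 0 < i < grid.size - 1:
            la = np.log(grid[i - 1 : i + 2])
            y3 = ll[i - 1 : i + 2]
            denom = (y3[0] - 2 * y3[1] + y3[2])
            if denom < 0:
                la_star = la[1] - 0.5 * (y3[2] - y3[0]) / denom * (la[1] - la[0])
                alpha_hat[j] = np.exp(np.clip(la_star, np.log(1e-4), np.log(10.0)))
                continue
        alpha_hat[j] = grid[i]
    base_mean = Mu.mean(axis=0)
    la = np.log(alpha_hat)
    lm = np.log(np.maximum(base_mean, 1e-8))
    if nf >= 10 and np.ptp(lm) > 1e-8:
        coef = np.polyfit(lm, la, 1)
        trend = np.polyval(coef, lm)
    else:
        trend = np.full(nf, la.mean())
    n = Y.shape[0]
    w_obs = n / 2.0  # rough precision of the per-feature log-dispersion MLE
    la_shrunk = (w_obs * la + shrink_strength * trend) / (w_obs + shrink_strength)
    return np.exp(la_shrunk), alpha_hat


def _irls_nb(Y, X, offset, alphas, max_iter=50, tol=1e-8):
    """Vectorized NB IRLS across features with a shared design.

    Returns (beta (features x p), mu (n x features), converged (features,)).
    """
    n, p = X.shape
    nf = Y.shape[1]
    beta = np.zeros((nf, p))
    # init: intercept from mean of offset-corrected counts
    beta[:, 0] = np.log(np.maximum((Y / np.exp(offset)[:, None]).mean(axis=0), 1e-8))
    converged = np.zeros(nf, dtype=bool)
    eta = offset[:, None] + X @ beta.T
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu / (1.0 + alphas[None, :] * mu)
        z = (eta - offset[:, None]) + (Y - mu) / np.maximum(mu, 1e-12)
        A = np.einsum("ni,nf,nj->fij", X, W, X)
        b = np.einsum("ni,nf->fi", X, W * z)
        A += 1e-10 * np.eye(p)[None]
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        step = np.abs(new_beta - beta).max(axis=1)
        beta = new_beta
        eta = offset[:, None] + X @ beta.T
        converged |= step < tol
        if converged.all():
            break
    mu = np.exp(np.clip(eta, -30, 30))
    return beta, mu, converged


def nb_wald_test(
    counts,
    status,
    covariates=None,
    size_factors=None,
    feature_ids=None,
    shrink_strength: float = 10.0,
):
    """Two-group NB Wald test per feature.

    ``counts`` is samples x features (non-negative integers); ``status`` is
    the binary case indicator.  Returns a DataFrame with columns
    feature_id, base_mean, log2_fold_change, se, z, p, q, direction; all-zero
    features are excluded with a log message, and non-convergent fits get
    p = NA.
    """
    import pandas as pd

    K = np.asarray(counts, dtype=float)
    s = np.asarray(status, dtype=float)
    n = K.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(K.shape[1])]
    feature_ids = np.asarray(feature_ids, dtype=object)
    if len(np.unique(s)) != 2:
        raise ValueError("status must have two groups")
    if min((s == 1).sum(), (s == 0).sum()) < 5:
        raise ValueError("need >= 5 samples per group")
    keep = K.sum(axis=0) > 0
    if not keep.all():
        log.info("nb_wald_test: excluding %d all-zero features", int((~keep).sum()))
    K = K[:, keep]
    feature_ids = feature_ids[keep]
    if size_factors is None:
        size_factors = estimate_size_factors(np.maximum(K, 0))
    offset = np.log(np.asarray(size_factors, dtype=float))
    cols = [np.ones(n), s]
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cols.extend(C.T)
    X = np.column_stack(cols)
    status_idx = 1

    # initial fit with moment dispersions, then dispersion estimation, refit
    norm = K / np.exp(offset)[:, None]
    mean0 = norm.mean(axis=0)
    var0 = norm.var(axis=0, ddof=1)
    alpha0 = np.clip((var0 - mean0) / np.maximum(mean0, 1e-8) ** 2, 1e-4, 10.0)
    beta, mu, _ = _irls_nb(K, X, offset, alpha0, max_iter=15)
    alpha, _ = _estimate_dispersions(K, mu, X, shrink_strength)
    beta, mu, converged = _irls_nb(K, X, offset, alpha)

    W = mu / (1.0 + alpha[None, :] * mu)
    A = np.einsum("ni,nf,nj->fij", X, W, X)
    cov = np.linalg.inv(A + 1e-10 * np.eye(X.shape[1])[None])
    se_ln = np.sqrt(np.maximum(cov[:, status_idx, status_idx], 0))
    b = beta[:, status_idx]
    z = np.where(converged, b / np.maximum(se_ln, 1e-300), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    qvals = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        qvals[ok] = storey_qvalue(p[ok]).qvalues
    ln2 = np.log(2.0)
    df = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "base_mean": norm.mean(axis=0),
            "log2_fold_change": b / ln2,
            "se": se_ln / ln2,
            "z": z,
            "p": np.where(ok, p, np.nan),
            "q": qvals,
            "direction": np.sign(b).astype(int),
        }
    )
    return df


# ---------------------------------------------------------------------------
# Covariate screening for the differential design
# ---------------------------------------------------------------------------

def select_differential_covariates(
    covariates: np.ndarray,
    names,
    status,
    quantifications,
    pi1_threshold: float = 0.05,
    status_alpha: float = 0.05,
):
    """Pick covariates to include in the differential design.

    A covariate is included if it associates with disease status
    (Mann-Whitney U, p < status_alpha) or with many features (pi1 of its
    per-feature linear-regression p-values above pi1_threshold).
    """
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    s = np.asarray(status)
    Y = np.asarray(quantifications, dtype=float)
    chosen = []
    for j, name in enumerate(names):
        c = C[:, j]
        try:
            p_status = stats.mannwhitneyu(
                c[s == 1], c[s == 0], alternative="two-sided"
            ).pvalue
        except ValueError:
            p_status = 1.0
        cz = (c - c.mean()) / max(c.std(), 1e-12)
        Yz = Y - Y.mean(axis=0)
        sd = Y.std(axis=0)
        okf = sd > 1e-12
        r = (cz @ Yz[:, okf]) / (len(c) * sd[okf])
        r = np.clip(r, -0.999999, 0.999999)
        t = r * np.sqrt((len(c) - 2) / (1 - r**2))
        pvec = 2 * stats.t.sf(np.abs(t), len(c) - 2)
        pi1 = storey_qvalue(pvec).pi1 if pvec.size >= 20 else 0.0
        if p_status < status_alpha or pi1 > pi1_threshold:
            chosen.append(name)
    return chosen
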