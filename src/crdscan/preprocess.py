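"""Covariate regression and normalization applied before correlation and QTL
analysis.

The pipeline order is: regress declared covariates plus genotype-PC (ancestry)
and phenotype-PC (technical) scores out of the quantified values, then
rank-normal-transform the residuals so every feature matches a Normal(0, 1)
across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GenotypeMatrix, PhenotypeMatrix

log = logging.getLogger("crdscan")


@dataclass
class CovariateModel:
    """Named covariates aligned to a sample order (no intercept column)."""

    names: list[str]
    matrix: np.ndarray  # samples x covariates
    n_phenotype_pcs: int = 0

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("covariate names do not match matrix columns")
        design = np.column_stack([np.ones(self.matrix.shape[0]), self.matrix])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate design is rank-deficient with intercept")


def inverse_normal_transform(values) -> np.ndarray:
    """Map values to Normal(0, 1) quantiles, Phi^-1((rank - 0.5) / m).

    Ranks are averaged over ties and then perturbed deterministically by
    input order so tied observations get distinct quantiles; NAs are
    preserved in place; m counts non-NA entries only.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = ~np.isnan(v)
    x = v[mask]
    m = x.size
    if m < 3:
        raise ValueError("need >= 3 non-NA values")
    if np.all(x == x[0]):
        raise ValueError("all non-NA values equal: rank transform degenerate")
    avg = stats.rankdata(x, method="average")
    ordi = stats.rankdata(x, method="ordinal")
    ranks = avg + (ordi - avg) * 1e-8
    out[mask] = stats.norm.ppf((ranks - 0.5) / m)
    return out


def compute_pcs(matrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of a samples x features matrix.

    Columns are centered internally; each component's sign is fixed so its
    largest-|loading| feature has a positive loading.
    """
    X = np.asarray(matrix, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n_samples, n_features)={min(X.shape)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def genotype_pcs(genotypes: GenotypeMatrix, k: int = 2) -> np.ndarray:
    """Ancestry PCs on the dosage matrix centered by 2*MAF-implied means."""
    d = genotypes.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    nan = np.isnan(d)
    if nan.any():
        d[nan] = np.take(col_mean, np.nonzero(nan)[1])
    return compute_pcs(d, k)


def regress_out(matrix, covariates: CovariateModel | np.ndarray | None):
    """Per-feature OLS residuals of value ~ intercept + covariates.

    With no covariates the output is the column-centered input.  Residuals
    are orthogonal to every covariate column; the operation is idempotent.
    NAs are handled per feature on complete cases.
    """
    Y = np.asarray(matrix, dtype=float)
    n = Y.shape[0]
    if covariates is None:
        C = np.empty((n, 0))
    elif isinstance(covariates, CovariateModel):
        C = covariates.matrix
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                bad.append(j - 1)
        raise ValueError(f"rank-deficient covariate design (columns {bad})")
    if not np.isnan(Y).any():
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return Y - X @ beta
    out = np.full_like(Y, np.nan)
    for j in range(Y.shape[1]):
        mask = ~np.isnan(Y[:, j])
        if mask.sum() <= X.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(X[mask], Y[mask, j], rcond=None)
        out[mask, j] = Y[mask, j] - X[mask] @ beta
    return out


def normalize_phenotypes(
    pm: PhenotypeMatrix, covariates: CovariateModel | None = None
) -> PhenotypeMatrix:
    """Regress out covariates, then rank-normal-transform each feature."""
    resid = regress_out(pm.values, covariates)
    out = np.column_stack(
        [inverse_normal_transform(resid[:, j]) for j in range(resid.shape[1])]
    )
    return PhenotypeMatrix(pm.sample_ids, pm.features.copy(), out, "normalized")


def select_pc_count(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    candidate_ks,
    seed: int,
    n_perm: int = 100,
    window: int = 1_000_000,
    fdr: float = 0.05,
    extra_covariates: np.ndarray | None = None,
) -> int:
    """Phenotype-PC count that maximizes cis-QTL discoveries at the given FDR.

    For each candidate k the quantified matrix is residualized on k of its
    own PCs (plus any fixed covariates), rank-normalized, and run through a
    reduced-permutation QTL pass; the k with the most q <= fdr discoveries
    wins, ties going to the smallest k.
    """
    from .qtl import permutation_pass

    ks = list(candidate_ks)
    if not ks:
        raise ValueError("candidate_ks is empty")
    n = phenotypes.n_samples
    if any(k >= n for k in ks):
        raise ValueError("candidate k >= n_samples")
    best_k, best_count = None, -1
    for k in sorted(ks):
        covs = []
        if extra_covariates is not None and extra_covariates.size:
            covs.append(np.atleast_2d(extra_covariates))
        if k > 0:
            covs.append(compute_pcs(phenotypes.values, k))
        cm = None
        if covs:
            C = np.column_stack(covs)
            cm = CovariateModel([f"c{i}" for i in range(C.shape[1])], C, k)
        norm = normalize_phenotypes(phenotypes, cm)
        res = permutation_pass(norm, genotypes, window=window, n_perm=n_perm, seed=seed)
        count = int((res["q"] <= fdr).sum()) if len(res) else 0
        log.info("select_pc_count: k=%d -> %d discoveries", k, count)
        if count > best_count:
            best_k, best_count = k, count
    return best_k
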