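"""Cis-QTL mapping: nominal, permutation (beta-approximated), conditional,
genotype x disease interaction, RTC colocalization and pi1 sharing.

The permutation pass follows the standard population-genetics scheme: per
molecular phenotype, the best nominal association across the +/- 1 Mb cis
window is compared against the minima of the same scan on label-permuted
phenotypes (genotypes fixed, preserving cis LD); a Beta(a, b) distribution
fitted by maximum likelihood to the permutation minima converts the observed
best p into an adjusted p; Storey q-values across phenotypes set the FDR.
Independent signals come from a forward-backward conditional scan at the
phenotype-specific nominal threshold implied by the fitted Beta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .differential import storey_qvalue
from .io_formats import GenotypeMatrix, IntervalSet, PhenotypeMatrix

log = logging.getLogger("crdscan")

DEFAULT_WINDOW = 1_000_000
DEFAULT_MAF_MIN = 0.05


@dataclass
class QTLRecord:
    phenotype_id: str
    variant_id: str
    distance: int
    slope: float
    p_nominal: float
    beta_a: float
    beta_b: float
    p_adjusted: float
    q: float
    rank: int = 0


@dataclass
class RTCRecord:
    qtl_variant: str
    gwas_variant: str
    hotspot: tuple
    n_variants: int
    rank: int
    rtc: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# core helpers
# ---------------------------------------------------------------------------

def _corr_pvalue(r, df):
    r = np.clip(r, -0.9999999999, 0.9999999999)
    t = r * np.sqrt(df / (1.0 - r * r))
    return 2.0 * stats.t.sf(np.abs(t), df)


def _cis_slice(geno: GenotypeMatrix, chrom, anchor0, window, maf_min):
    """Column indices of variants within +/- window of a 0-based anchor."""
    v = geno.variants
    pos0 = v["pos"].to_numpy() - 1
    mask = (
        (v["chrom"].to_numpy() == chrom)
        & (np.abs(pos0 - anchor0) <= window)
        & (v["maf"].to_numpy() >= maf_min)
    )
    return np.nonzero(mask)[0]


def beta_mle(x, max_iter=50, tol=1e-10):
    """Maximum-likelihood Beta(a, b) fit by Newton iterations on the digamma
    equations, initialized from method-of-moments."""
    x = np.clip(np.asarray(x, dtype=float), 1e-300, 1.0 - 1e-12)
    L1 = np.log(x).mean()
    L2 = np.log1p(-x).mean()
    m, v = x.mean(), x.var()
    v = max(v, 1e-12)
    common = max(m * (1.0 - m) / v - 1.0, 1e-6)
    a, b = max(m * common, 1e-6), max((1.0 - m) * common, 1e-6)
    for _ in range(max_iter):
        psi_ab = special.digamma(a + b)
        g = np.array(
            [special.digamma(a) - psi_ab - L1, special.digamma(b) - psi_ab - L2]
        )
        tri_ab = special.polygamma(1, a + b)
        H = np.array(
            [
                [special.polygamma(1, a) - tri_ab, -tri_ab],
                [-tri_ab, special.polygamma(1, b) - tri_ab],
            ]
        )
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        new = np.array([a, b]) - step
        # damped positivity guard
        while (new <= 0).any():
            step *= 0.5
            new = np.array([a, b]) - step
        if np.abs(step).max() < tol * max(a, b, 1.0):
            a, b = new
            break
        a, b = new
    return float(a), float(b)


def permutation_scan(y, X, n_perm, rng):
    """Permutation scan of one phenotype against a candidate matrix.

    ``y``: (n,) phenotype; ``X``: (n, m) candidate predictors (dosages or
    CRD activities).  Returns a dict with the best candidate's index, slope,
    nominal p, the fitted Beta parameters, and the beta-adjusted p.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    mask = ~np.isnan(y)
    y = y[mask]
    X = X[mask]
    n, m = X.shape
    if n < 3 or m == 0:
        return None
    yc = y - y.mean()
    sy = yc.std()
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    ok = sx > 1e-12
    if not ok.any():
        return None
    Xs = Xc[:, ok] / sx[ok]
    r = (yc / max(sy, 1e-300)) @ Xs / n
    df = n - 2
    p_nom = _corr_pvalue(r, df)
    best_local = int(np.argmin(p_nom))
    best = np.nonzero(ok)[0][best_local]
    slope = r[best_local] * sy / sx[ok][best_local]

    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = (yc / max(sy, 1e-300))[perms]  # (n_perm, n), standardized rows
    Rp = Yp @ Xs / n
    r2max = (Rp * Rp).max(axis=1)
    p_min = _corr_pvalue(np.sqrt(r2max), df)
    a, b = beta_mle(p_min)
    p_adj = float(stats.beta.cdf(p_nom[best_local], a, b))
    # direct empirical permutation p, reported for reference
    p_emp = float((1.0 + (p_min <= p_nom[best_local]).sum()) / (1.0 + n_perm))
    return {
        "best_index": best,
        "slope": float(slope),
        "r": float(r[best_local]),
        "p_nominal": float(p_nom[best_local]),
        "beta_a": a,
        "beta_b": b,
        "p_adjusted": p_adj,
        "p_empirical": p_emp,
        "n_candidates": int(ok.sum()),
        "n_used": n,
    }


# ---------------------------------------------------------------------------
# passes
# ---------------------------------------------------------------------------

def nominal_pass(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    window: int = DEFAULT_WINDOW,
    maf_min: float = DEFAULT_MAF_MIN,
) -> pd.DataFrame:
    """All cis phenotype-variant linear associations (slope, two-sided p)."""
    _check_alignment(phenotypes, genotypes)
    anchors = phenotypes.anchors()
    chroms = phenotypes.features["chrom"].to_numpy()
    pids = phenotypes.features["feature_id"].to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    vids = genotypes.variants["variant_id"].to_numpy()
    out = []
    for j in range(phenotypes.n_features):
        cis = _cis_slice(genotypes, chroms[j], anchors[j], window, maf_min)
        if cis.size == 0:
            continue
        y = phenotypes.values[:, j]
        mask = ~np.isnan(y)
        if mask.sum() < 3:
            log.info("nominal_pass: phenotype %s has < 3 complete samples", pids[j])
            continue
        yv = y[mask]
        G = genotypes.dosages[mask][:, cis]
        yc = yv - yv.mean()
        sy = max(yc.std(), 1e-300)
        Gc = G - G.mean(axis=0)
        sx = Gc.std(axis=0)
        keep = sx > 1e-12
        r = (yc / sy) @ (Gc[:, keep] / sx[keep]) / mask.sum()
        p = _corr_pvalue(r, mask.sum() - 2)
        slope = r * sy / sx[keep]
        for k, ci in enumerate(cis[keep]):
            out.append(
                (pids[j], vids[ci], int(pos[ci] - 1 - anchors[j]),
                 float(slope[k]), float(p[k]))
            )
    return pd.DataFrame(
        out, columns=["phenotype_id", "variant_id", "distance", "slope", "p"]
    )


def permutation_pass(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    window: int = DEFAULT_WINDOW,
    n_perm: int = 1000,
    seed: int = 0,
    maf_min: float = DEFAULT_MAF_MIN,
) -> pd.DataFrame:
    """Per-phenotype best cis association with beta-approximated adjusted p.

    Returns one row per phenotype with the best variant, the fitted Beta
    parameters, adjusted p and Storey q across phenotypes.
    """
    _check_alignment(phenotypes, genotypes)
    anchors = phenotypes.anchors()
    chroms = phenotypes.features["chrom"].to_numpy()
    pids = phenotypes.features["feature_id"].to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    vids = genotypes.variants["variant_id"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(phenotypes.n_features):
        cis = _cis_slice(genotypes, chroms[j], anchors[j], window, maf_min)
        if cis.size == 0:
            log.info("permutation_pass: phenotype %s has no cis variants", pids[j])
            continue
        res = permutation_scan(
            phenotypes.values[:, j], genotypes.dosages[:, cis], n_perm, rng
        )
        if res is None:
            continue
        ci = cis[res["best_index"]]
        rows.append(
            {
                "phenotype_id": pids[j],
                "variant_id": vids[ci],
                "distance": int(pos[ci] - 1 - anchors[j]),
                "slope": res["slope"],
                "p_nominal": res["p_nominal"],
                "beta_a": res["beta_a"],
                "beta_b": res["beta_b"],
                "p_adjusted": res["p_adjusted"],
                "p_empirical": res["p_empirical"],
                "n_variants": res["n_candidates"],
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = storey_qvalue(df["p_adjusted"].to_numpy()).qvalues
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def _residualize(M, Z):
    """Residuals of columns of M on covariates Z (with intercept)."""
    X = np.column_stack([np.ones(M.shape[0]), Z]) if Z is not None else np.ones(
        (M.shape[0], 1)
    )
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta, X.shape[1]


def conditional_pass(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    perm_results: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    fdr: float = 0.05,
    maf_min: float = DEFAULT_MAF_MIN,
    max_signals: int = 10,
) -> pd.DataFrame:
    """Forward-backward scan for independent cis signals.

    Phenotypes significant in the permutation pass (q <= fdr) are rescanned;
    the phenotype-specific nominal threshold is the quantile of its fitted
    Beta at the genome-wide adjusted-p bound.  Forward: add the best variant
    as a covariate while one passes the threshold.  Backward: retest each
    selected variant conditioning on the others, dropping non-significant
    ones.  Survivors are ranked by forward selection order (0 = primary).
    """
    _check_alignment(phenotypes, genotypes)
    sig = perm_results[perm_results["q"] <= fdr]
    if not len(sig):
        return pd.DataFrame(
            columns=["phenotype_id", "variant_id", "distance", "slope",
                     "p_nominal", "threshold", "rank"]
        )
    # adjusted-p significance bound: midpoint between the last significant
    # and first non-significant phenotype; when everything is significant any
    # adjusted p up to the FDR level itself would still pass
    insig = perm_results[perm_results["q"] > fdr]
    if len(insig):
        p_adj_bound = float(
            (sig["p_adjusted"].max() + insig["p_adjusted"].min()) / 2.0
        )
    else:
        p_adj_bound = float(max(sig["p_adjusted"].max(), fdr))
    anchors = phenotypes.anchors()
    feats = phenotypes.features.set_index("feature_id")
    pid_to_col = {f: i for i, f in enumerate(phenotypes.features["feature_id"])}
    pos = genotypes.variants["pos"].to_numpy()
    vids = genotypes.variants["variant_id"].to_numpy()
    out = []
    for row in sig.itertuples(index=False):
        pid = row.phenotype_id
        j = pid_to_col[pid]
        thr = float(stats.beta.ppf(p_adj_bound, row.beta_a, row.beta_b))
        cis = _cis_slice(
            genotypes, feats.loc[pid, "chrom"], anchors[j], window, maf_min
        )
        y = phenotypes.values[:, j]
        mask = ~np.isnan(y)
        yv = y[mask]
        G = genotypes.dosages[mask][:, cis]
        n = yv.size

        def scan(yy, GG, sel_cols):
            Z = GG[:, sel_cols] if sel_cols else None
            yr, k = _residualize(yy[:, None], Z)
            Gr, _ = _residualize(GG, Z)
            yr = yr[:, 0]
            sy = yr.std()
            sx = Gr.std(axis=0)
            ok = (sx > 1e-10) & (sy > 1e-12)
            p = np.ones(GG.shape[1])
            slope = np.zeros(GG.shape[1])
            if ok.any():
                r = (yr - yr.mean()) @ ((Gr[:, ok] - Gr[:, ok].mean(axis=0))
                                        / sx[ok]) / (n * max(sy, 1e-300))
                dfree = n - 1 - k
                p[ok] = _corr_pvalue(r, dfree)
                slope[ok] = r * sy / sx[ok]
            return p, slope

        selected: list[int] = []
        while len(selected) < max_signals:
            p, slope = scan(yv, G, selected)
            p[selected] = 1.0
            best = int(np.argmin(p))
            if p[best] > thr:
                break
            selected.append(best)
        # backward
        survivors = []
        for s_idx in selected:
            others = [t for t in selected if t != s_idx]
            p, slope = scan(yv, G, others)
            if p[s_idx] <= thr:
                survivors.append((s_idx, p[s_idx], slope[s_idx]))
        for rank, (s_idx, pval, slope) in enumerate(survivors):
            ci = cis[s_idx]
            out.append(
                (pid, vids[ci], int(pos[ci] - 1 - anchors[j]), float(slope),
                 float(pval), thr, rank)
            )
    return pd.DataFrame(
        out, columns=["phenotype_id", "variant_id", "distance", "slope",
                      "p_nominal", "threshold", "rank"]
    )


def interaction_qtl(
    phenotypes: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    status,
    covariates=None,
    qtl_pairs=None,
) -> pd.DataFrame:
    """Genotype x disease interaction test for a set of QTL pairs.

    Per (phenotype, variant) pair an OLS of phenotype ~ genotype + status +
    covariates + genotype*status is fitted and the interaction coefficient
    tested two-sided; Storey q across the tested pairs.  ``qtl_pairs`` is an
    iterable of (phenotype_id, variant_id) — by design the QTLs discovered in
    the case subset.
    """
    _check_alignment(phenotypes, genotypes)
    s = np.asarray(status, dtype=float)
    if len(np.unique(s)) < 2:
        raise ValueError("interaction test needs both groups")
    if qtl_pairs is None:
        raise ValueError("qtl_pairs required")
    pid_to_col = {f: i for i, f in enumerate(phenotypes.features["feature_id"])}
    vid_to_col = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}
    C = None
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(s):
            C = C.T
    rows = []
    for pid, vid in qtl_pairs:
        y = phenotypes.values[:, pid_to_col[pid]]
        g = genotypes.dosages[:, vid_to_col[vid]]
        mask = ~(np.isnan(y) | np.isnan(g))
        yy, gg, ss = y[mask], g[mask], s[mask]
        cols = [np.ones(mask.sum()), gg, ss]
        if C is not None:
            cols.extend(C[mask].T)
        cols.append(gg * ss)
        X = np.column_stack(cols)
        n, p = X.shape
        if n <= p:
            continue
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ beta
        sigma2 = resid @ resid / (n - p)
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(max(sigma2 * XtX_inv[-1, -1], 1e-300))
        t = beta[-1] / se
        pval = 2.0 * stats.t.sf(abs(t), n - p)
        slope_ctrl = beta[1]
        slope_case = beta[1] + beta[-1]
        rows.append((pid, vid, float(beta[-1]), float(pval),
                     float(slope_case), float(slope_ctrl)))
    df = pd.DataFrame(
        rows, columns=["phenotype_id", "variant_id", "interaction_slope", "p",
                       "slope_case", "slope_control"]
    )
    if len(df):
        df["q"] = storey_qvalue(df["p"].to_numpy()).qvalues
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def rtc(
    phenotype_values,
    genotypes: GenotypeMatrix,
    qtl_variant: str,
    gwas_variant: str,
    hotspots: IntervalSet,
) -> RTCRecord | None:
    """Regulatory trait concordance score for a QTL / GWAS variant pair.

    Both variants must fall in the same recombination-hotspot interval.  For
    each of the N interval variants the phenotype is residualized on that
    variant's dosage and the QTL variant is re-associated with the residual;
    variants are ranked by how completely their removal destroys the QTL
    signal (rank 0 = residual association p is largest).  The GWAS variant's
    rank gives RTC = (N - rank) / N, so RTC near 1 means the two variants
    tag the same functional effect.  The degenerate case where the two
    variants coincide trivially ranks first and is flagged.
    """
    v = genotypes.variants.set_index("variant_id")
    q_chrom, q_pos = v.loc[qtl_variant, ["chrom", "pos"]]
    g_chrom, g_pos = v.loc[gwas_variant, ["chrom", "pos"]]
    iv_q = hotspots.containing(q_chrom, int(q_pos) - 1)
    iv_g = hotspots.containing(g_chrom, int(g_pos) - 1)
    if iv_q is None or iv_q != iv_g or q_chrom != g_chrom:
        return None
    lo, hi = iv_q
    pos0 = v["pos"].to_numpy() - 1
    in_iv = np.nonzero(
        (v["chrom"].to_numpy() == q_chrom) & (pos0 >= lo) & (pos0 < hi)
    )[0]
    vids = v.index.to_numpy()[in_iv]
    y = np.asarray(phenotype_values, dtype=float)
    q_dose = genotypes.dosages[:, v.index.get_loc(qtl_variant)]
    mask = ~(np.isnan(y) | np.isnan(q_dose))
    yv = y[mask]
    qv = q_dose[mask]
    n = int(mask.sum())
    p_destroyed = np.ones(in_iv.size)
    for k, col in enumerate(in_iv):
        d = genotypes.dosages[mask, col]
        ok = ~np.isnan(d)
        yr, _ = _residualize(yv[ok][:, None], d[ok][:, None])
        yr = yr[:, 0]
        qk = qv[ok]
        if qk.std() < 1e-12 or yr.std() < 1e-12:
            continue
        r = np.corrcoef(yr, qk)[0, 1]
        p_destroyed[k] = float(_corr_pvalue(np.array([r]), ok.sum() - 3)[0])
    order = np.argsort(-p_destroyed, kind="stable")  # 0 = most destroyed
    rank = int(np.nonzero(vids[order] == gwas_variant)[0][0])
    N = in_iv.size
    return RTCRecord(
        qtl_variant=qtl_variant,
        gwas_variant=gwas_variant,
        hotspot=(q_chrom, lo, hi),
        n_variants=N,
        rank=rank,
        rtc=float((N - rank) / N),
        degenerate=qtl_variant == gwas_variant,
    )


def sharing_pi1(
    discovery: pd.DataFrame,
    repl_phenotypes: PhenotypeMatrix,
    repl_genotypes: GenotypeMatrix,
):
    """pi1 (proportion of true associations) of discovery QTLs in a
    replication set: each discovery pair's nominal p is recomputed in the
    replication data and fed to the Storey estimator."""
    _check_alignment(repl_phenotypes, repl_genotypes)
    pairs = list(zip(discovery["phenotype_id"], discovery["variant_id"]))
    if len(pairs) < 20:
        raise ValueError("pi1 needs >= 20 discovery pairs")
    pid_to_col = {f: i for i, f in enumerate(repl_phenotypes.features["feature_id"])}
    vid_to_col = {v: i for i, v in enumerate(repl_genotypes.variants["variant_id"])}
    ps = []
    for pid, vid in pairs:
        y = repl_phenotypes.values[:, pid_to_col[pid]]
        g = repl_genotypes.dosages[:, vid_to_col[vid]]
        mask = ~(np.isnan(y) | np.isnan(g))
        yy, gg = y[mask], g[mask]
        if mask.sum() < 3 or gg.std() < 1e-12 or yy.std() < 1e-12:
            ps.append(1.0)
            continue
        r = np.corrcoef(yy, gg)[0, 1]
        ps.append(float(_corr_pvalue(np.array([r]), mask.sum() - 2)[0]))
    st = storey_qvalue(np.asarray(ps))
    return st


def _check_alignment(phenotypes: PhenotypeMatrix, genotypes: GenotypeMatrix):
    if phenotypes.sample_ids != genotypes.sample_ids:
        raise ValueError("phenotype and genotype sample orders differ")
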