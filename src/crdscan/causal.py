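"""Gene-CRD association and causal inference on variant-CRD-gene triplets.

Genes are associated with CRDs whose span falls within +/- 1 Mb of the TSS
using the same permutation/beta machinery as the QTL passes, with CRD
activities playing the role of candidate predictors.  Significant pairs are
collapsed onto their first principal component (PC1 of the standardized
gene/CRD pair, sign-aligned with the gene) and this pseudo-phenotype is
QTL-mapped to find a shared variant (eCRD-QTL), yielding triplets.

Each triplet is scored under three Gaussian linear networks —

  causal:      V -> C -> G   scored as  L(C|V) * L(G|C)
  reactive:    V -> G -> C   scored as  L(G|V) * L(C|G)
  independent: V -> C, V -> G  scored as  L(C|V) * L(G|V)

— with each conditional an OLS Gaussian likelihood, a BIC penalty (equal
across models, so it cancels in the normalization) and a uniform model
prior; posteriors are the softmax of the scores.  The marginal of V is
identical across models and omitted.  Bootstrap accuracy is the fraction of
resamples whose top model matches the full-data top model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_formats import GenotypeMatrix, PhenotypeMatrix
from .differential import storey_qvalue
from .qtl import DEFAULT_MAF_MIN, DEFAULT_WINDOW, _cis_slice, permutation_scan

log = logging.getLogger("crdscan")

MODELS = ("causal", "reactive", "independent")


@dataclass
class Triplet:
    variant_id: str
    crd_id: str
    gene_id: str
    pc1_variance: float
    p_causal: float
    p_reactive: float
    p_independent: float
    top_model: str
    accuracy: float
    passed: bool


# ---------------------------------------------------------------------------
# gene-CRD pairs
# ---------------------------------------------------------------------------

def map_gene_crd_pairs(
    expression: PhenotypeMatrix,
    crd_activity: PhenotypeMatrix,
    window: int = DEFAULT_WINDOW,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-pass association of each gene with its cis CRDs.

    A CRD is a candidate when its span overlaps the +/- window interval
    around the gene TSS.  Returns gene_id, crd_id, r, p_nominal, beta
    parameters, adjusted p, Storey q, TSS-to-CRD distance (0 when the TSS is
    inside the CRD) and the relative TSS position within the span.
    """
    if expression.sample_ids != crd_activity.sample_ids:
        raise ValueError("expression and CRD activity sample orders differ")
    rng = np.random.default_rng(seed)
    tss = expression.anchors()
    gf = expression.features
    cf = crd_activity.features
    rows = []
    for j in range(expression.n_features):
        chrom = gf.at[j, "chrom"]
        lo, hi = tss[j] - window, tss[j] + window
        cand = np.nonzero(
            (cf["chrom"].to_numpy() == chrom)
            & (cf["start"].to_numpy() <= hi)
            & (cf["end"].to_numpy() >= lo)
        )[0]
        if cand.size == 0:
            continue
        res = permutation_scan(
            expression.values[:, j], crd_activity.values[:, cand], n_perm, rng
        )
        if res is None:
            continue
        ci = cand[res["best_index"]]
        c_start, c_end = int(cf.at[ci, "start"]), int(cf.at[ci, "end"])
        t = int(tss[j])
        if c_start <= t < c_end:
            dist, rel = 0, (t - c_start) / (c_end - c_start)
        elif t < c_start:
            dist, rel = t - c_start, np.nan
        else:
            dist, rel = t - (c_end - 1), np.nan
        rows.append(
            {
                "gene_id": gf.at[j, "feature_id"],
                "crd_id": cf.at[ci, "feature_id"],
                "r": res["r"],
                "p_nominal": res["p_nominal"],
                "beta_a": res["beta_a"],
                "beta_b": res["beta_b"],
                "p_adjusted": res["p_adjusted"],
                "distance": dist,
                "tss_relative_position": rel,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = storey_qvalue(df["p_adjusted"].to_numpy()).qvalues
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def cross_qtl_effect(
    qtl_records: pd.DataFrame,
    partner: PhenotypeMatrix,
    pairs: pd.DataFrame,
    genotypes: GenotypeMatrix,
    qtl_side: str,
):
    """Test QTL variants of one phenotype class against the paired phenotype
    of the other class.

    ``qtl_side`` is 'gene' when qtl_records are eQTLs (partner = CRD
    activity) and 'crd' when they are aCRD-QTLs (partner = expression).
    Returns (per-pair table, fraction with partner p < 0.05, pi1 estimate).
    """
    if qtl_side not in ("gene", "crd"):
        raise ValueError("qtl_side must be 'gene' or 'crd'")
    own_col = "gene_id" if qtl_side == "gene" else "crd_id"
    other_col = "crd_id" if qtl_side == "gene" else "gene_id"
    link = pairs.set_index(own_col)[other_col].to_dict()
    pid_to_col = {f: i for i, f in enumerate(partner.features["feature_id"])}
    vid_to_col = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}
    from .qtl import _corr_pvalue

    rows = []
    for rec in qtl_records.itertuples(index=False):
        other = link.get(rec.phenotype_id)
        if other is None or other not in pid_to_col:
            continue
        y = partner.values[:, pid_to_col[other]]
        g = genotypes.dosages[:, vid_to_col[rec.variant_id]]
        mask = ~(np.isnan(y) | np.isnan(g))
        if mask.sum() < 3 or g[mask].std() < 1e-12 or y[mask].std() < 1e-12:
            continue
        r = np.corrcoef(y[mask], g[mask])[0, 1]
        p = float(_corr_pvalue(np.array([r]), mask.sum() - 2)[0])
        rows.append((rec.phenotype_id, other, rec.variant_id, float(r), p))
    df = pd.DataFrame(
        rows, columns=[own_col, other_col, "variant_id", "r", "p"]
    )
    if not len(df):
        log.warning("cross_qtl_effect: no linkable QTLs")
        return df, np.nan, np.nan
    frac = float((df["p"] < 0.05).mean())
    pi1 = (
        storey_qvalue(df["p"].to_numpy()).pi1 if len(df) >= 20 else np.nan
    )
    return df, frac, pi1


# ---------------------------------------------------------------------------
# triplets
# ---------------------------------------------------------------------------

def pc1_pseudophenotype(gene_values, crd_values):
    """PC1 scores of one standardized gene/CRD pair.

    Returns (scores, variance_explained); the variance explained equals
    (1 + |r|)/2 for a standardized pair.  The sign is aligned so the scores
    correlate positively with gene expression.
    """
    g = np.asarray(gene_values, dtype=float)
    c = np.asarray(crd_values, dtype=float)
    mask = ~(np.isnan(g) | np.isnan(c))
    gz = np.full(g.shape, np.nan)
    cz = np.full(c.shape, np.nan)
    gz[mask] = (g[mask] - g[mask].mean()) / g[mask].std()
    cz[mask] = (c[mask] - c[mask].mean()) / c[mask].std()
    r = float(np.mean(gz[mask] * cz[mask]))
    scores = (gz + np.sign(r) * cz) / np.sqrt(2.0)
    var_explained = (1.0 + abs(r)) / 2.0
    return scores, var_explained, r


def build_triplets(
    pairs: pd.DataFrame,
    expression: PhenotypeMatrix,
    crd_activity: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    window: int = DEFAULT_WINDOW,
    n_perm: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
    maf_min: float = DEFAULT_MAF_MIN,
    min_abs_r: float = 0.05,
) -> pd.DataFrame:
    """QTL-map PC1 pseudo-phenotypes of significant gene-CRD pairs.

    Pairs whose pseudo-phenotype has a significant cis variant (Storey
    q <= fdr over the tested pairs) become variant-CRD-gene triplets.
    Pairs with |r(gene, CRD)| < min_abs_r are skipped (PC1 ill-defined for
    the purpose of aggregating the two signals).
    """
    rng = np.random.default_rng(seed)
    gid_to_col = {f: i for i, f in enumerate(expression.features["feature_id"])}
    cid_to_col = {f: i for i, f in enumerate(crd_activity.features["feature_id"])}
    tss = expression.anchors()
    gf = expression.features.set_index("feature_id")
    pos = genotypes.variants["pos"].to_numpy()
    vids = genotypes.variants["variant_id"].to_numpy()
    rows = []
    for pair in pairs.itertuples(index=False):
        gcol = gid_to_col[pair.gene_id]
        ccol = cid_to_col[pair.crd_id]
        scores, var_expl, r = pc1_pseudophenotype(
            expression.values[:, gcol], crd_activity.values[:, ccol]
        )
        if abs(r) < min_abs_r:
            log.info("build_triplets: skipping %s-%s, |r|=%.3f too small",
                     pair.gene_id, pair.crd_id, abs(r))
            continue
        anchor = tss[gcol]
        cis = _cis_slice(genotypes, gf.loc[pair.gene_id, "chrom"], anchor,
                         window, maf_min)
        if cis.size == 0:
            continue
        res = permutation_scan(scores, genotypes.dosages[:, cis], n_perm, rng)
        if res is None:
            continue
        ci = cis[res["best_index"]]
        rows.append(
            {
                "variant_id": vids[ci],
                "crd_id": pair.crd_id,
                "gene_id": pair.gene_id,
                "pc1_variance": var_expl,
                "gene_crd_r": r,
                "distance": int(pos[ci] - 1 - anchor),
                "slope": res["slope"],
                "p_nominal": res["p_nominal"],
                "p_adjusted": res["p_adjusted"],
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = storey_qvalue(df["p_adjusted"].to_numpy()).qvalues
        df = df[df["q"] <= fdr].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Bayesian-network scoring
# ---------------------------------------------------------------------------

def _gauss_cond_ll(y, x):
    """Gaussian log-likelihood of y | x under OLS y ~ intercept + x."""
    n = y.size
    vx = x.var()
    if vx < 1e-24:
        resid_var = y.var()
    else:
        b = np.cov(y, x, bias=True)[0, 1] / vx
        resid_var = np.mean((y - y.mean() - b * (x - x.mean())) ** 2)
    resid_var = max(resid_var, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * resid_var) + 1.0)


def bn_posteriors(dosage, crd_values, gene_values):
    """Posterior probabilities of the three causal models for one triplet.

    Requires >= 30 complete observations and a non-constant dosage; raises
    on constant C or G.  Returns (p_causal, p_reactive, p_independent)
    summing to 1.
    """
    v = np.asarray(dosage, dtype=float)
    c = np.asarray(crd_values, dtype=float)
    g = np.asarray(gene_values, dtype=float)
    mask = ~(np.isnan(v) | np.isnan(c) | np.isnan(g))
    v, c, g = v[mask], c[mask], g[mask]
    n = v.size
    if n < 30:
        raise ValueError("bn_posteriors needs >= 30 complete observations")
    if v.std() < 1e-12:
        raise ValueError("constant dosage")
    if c.std() < 1e-12 or g.std() < 1e-12:
        raise ValueError("constant CRD or gene values")
    # per-model score: sum of conditional Gaussian log-likelihoods minus a
    # BIC penalty; all three models have 6 free parameters so the penalty
    # cancels in the softmax but is kept for interpretable absolute scores
    penalty = 0.5 * 6 * np.log(n)
    scores = np.array(
        [
            _gauss_cond_ll(c, v) + _gauss_cond_ll(g, c),  # causal
            _gauss_cond_ll(g, v) + _gauss_cond_ll(c, g),  # reactive
            _gauss_cond_ll(c, v) + _gauss_cond_ll(g, v),  # independent
        ]
    ) - penalty
    post = np.exp(scores - logsumexp(scores))
    return tuple(float(p) for p in post)


def bootstrap_accuracy(dosage, crd_values, gene_values, B: int = 100,
                       threshold: float = 0.55, seed: int = 0):
    """Confidence of a triplet's top model under case resampling.

    ``accuracy`` is the fraction of B bootstrap resamples (with replacement)
    whose top model matches the full-data top model; resamples with a
    constant dosage are redrawn up to 10 times, then counted as a mismatch.
    Returns (accuracy, passed) with passed = accuracy >= threshold.
    """
    v = np.asarray(dosage, dtype=float)
    c = np.asarray(crd_values, dtype=float)
    g = np.asarray(gene_values, dtype=float)
    mask = ~(np.isnan(v) | np.isnan(c) | np.isnan(g))
    v, c, g = v[mask], c[mask], g[mask]
    full = int(np.argmax(bn_posteriors(v, c, g)))
    rng = np.random.default_rng(seed)
    n = v.size
    hits = 0
    for _ in range(B):
        for _retry in range(10):
            idx = rng.integers(0, n, size=n)
            if v[idx].std() > 1e-12:
                break
        else:
            continue  # counted as mismatch
        if c[idx].std() < 1e-12 or g[idx].std() < 1e-12:
            continue
        if int(np.argmax(bn_posteriors(v[idx], c[idx], g[idx]))) == full:
            hits += 1
    acc = hits / B
    return acc, acc >= threshold


def score_triplets(
    triplets: pd.DataFrame,
    expression: PhenotypeMatrix,
    crd_activity: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    sample_ids=None,
    B: int = 100,
    threshold: float = 0.55,
    seed: int = 0,
) -> pd.DataFrame:
    """BN posteriors + bootstrap accuracy for every triplet, optionally on a
    sample subset (per-group scoring)."""
    expr = expression if sample_ids is None else expression.subset_samples(sample_ids)
    act = (
        crd_activity if sample_ids is None
        else crd_activity.subset_samples(sample_ids)
    )
    geno = genotypes if sample_ids is None else genotypes.subset_samples(sample_ids)
    gid_to_col = {f: i for i, f in enumerate(expr.features["feature_id"])}
    cid_to_col = {f: i for i, f in enumerate(act.features["feature_id"])}
    vid_to_col = {x: i for i, x in enumerate(geno.variants["variant_id"])}
    out = []
    for i, t in enumerate(triplets.itertuples(index=False)):
        v = geno.dosages[:, vid_to_col[t.variant_id]]
        c = act.values[:, cid_to_col[t.crd_id]]
        g = expr.values[:, gid_to_col[t.gene_id]]
        try:
            post = bn_posteriors(v, c, g)
        except ValueError as e:
            log.info("score_triplets: skipping %s/%s/%s (%s)",
                     t.variant_id, t.crd_id, t.gene_id, e)
            continue
        acc, passed = bootstrap_accuracy(
            v, c, g, B=B, threshold=threshold, seed=seed + i
        )
        out.append(
            Triplet(
                variant_id=t.variant_id,
                crd_id=t.crd_id,
                gene_id=t.gene_id,
                pc1_variance=float(getattr(t, "pc1_variance", np.nan)),
                p_causal=post[0],
                p_reactive=post[1],
                p_independent=post[2],
                top_model=MODELS[int(np.argmax(post))],
                accuracy=acc,
                passed=bool(passed),
            )
        )
    return pd.DataFrame([vars(t) for t in out], columns=[
        "variant_id", "crd_id", "gene_id", "pc1_variance", "p_causal",
        "p_reactive", "p_independent", "top_model", "accuracy", "passed",
    ])


def compare_mechanisms(
    triplets_cases: pd.DataFrame, triplets_controls: pd.DataFrame
) -> pd.DataFrame:
    """Mechanism-change table for triplets scored in both groups.

    Triplets are matched on (variant, CRD, gene) and must pass the accuracy
    filter in both groups; reactive and independent are collapsed into
    'different', so the classes are same | causal_to_different |
    different_to_causal (direction controls -> cases).
    """
    key = ["variant_id", "crd_id", "gene_id"]
    a = triplets_cases.loc[
        triplets_cases["passed"].astype(bool), key + ["top_model"]
    ]
    b = triplets_controls.loc[
        triplets_controls["passed"].astype(bool), key + ["top_model"]
    ]
    merged = a.merge(b, on=key, suffixes=("_case", "_control"))
    unmatched = len(triplets_cases) + len(triplets_controls) - 2 * len(merged)
    if unmatched:
        log.info("compare_mechanisms: %d triplets unmatched or filtered",
                 unmatched)

    def classify(row):
        case_causal = row["top_model_case"] == "causal"
        ctrl_causal = row["top_model_control"] == "causal"
        if case_causal == ctrl_causal:
            return "same"
        return "causal_to_different" if ctrl_causal else "different_to_causal"

    if len(merged):
        merged["change"] = merged.apply(classify, axis=1)
    else:
        merged["change"] = pd.Series(dtype=object)
    return merged
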