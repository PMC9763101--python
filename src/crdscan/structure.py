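"""Characterization of condition-specific CRDs.

Condition-specific domains are those called in one group whose member peaks
regroup into no domain of the other group.  Their formation is probed two
ways: per-peak differential activity (Mann-Whitney U on quantifications
uncorrected for covariates) and a per-domain correlation shift (mean pairwise
member correlation per group, compared globally across domains with a
Mann-Whitney U on the per-domain estimates).  Annotation overlap is scored
with a two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crd import CRD
from .differential import storey_qvalue
from .io_formats import IntervalSet, PhenotypeMatrix

log = logging.getLogger("crdscan")


@dataclass
class EnrichmentResult:
    """2x2 annotation-overlap table with odds ratio and Fisher p.

    Cells: a = foreground & overlapping, b = foreground & not, c = background
    & overlapping, d = background & not.  A zero cell makes the plain OR
    inf/0; ``odds_ratio_haldane`` adds 0.5 to every cell and is always finite.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    odds_ratio_haldane: float
    p: float
    foreground_label: str = "foreground"
    annotation_label: str = "annotation"


def find_specific_crds(crds_a: list[CRD], crds_b: list[CRD],
                       peak_universe=None) -> list[CRD]:
    """CRDs of set A none of whose member peaks appear in any CRD of set B."""
    if peak_universe is not None:
        universe = set(peak_universe)
        for c in list(crds_a) + list(crds_b):
            missing = set(c.member_peaks) - universe
            if missing:
                raise ValueError(
                    f"CRD {c.crd_id} references peaks outside the universe: "
                    f"{sorted(missing)[:3]}"
                )
    peaks_b = set()
    for c in crds_b:
        peaks_b.update(c.member_peaks)
    return [c for c in crds_a if not (set(c.member_peaks) & peaks_b)]


def per_peak_differential(
    raw_quantifications: PhenotypeMatrix, status, peak_ids=None
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per peak between cases and controls.

    Uses quantifications uncorrected for covariates (kind must not be
    'normalized').  Returns feature_id, u_stat, p, q, median_diff
    (median(case) - median(control)); constant peaks get p = 1 and a flag.
    """
    if raw_quantifications.kind == "normalized":
        raise ValueError("per-peak differential uses uncorrected quantifications")
    s = np.asarray(status)
    if min((s == 1).sum(), (s == 0).sum()) < 5:
        raise ValueError("need >= 5 samples per group")
    V = raw_quantifications.values
    feats = raw_quantifications.features["feature_id"].to_numpy()
    if peak_ids is not None:
        idx = raw_quantifications.feature_index(peak_ids)
        V = V[:, idx]
        feats = feats[idx]
    rows = []
    for j in range(V.shape[1]):
        x = V[s == 1, j]
        y = V[s == 0, j]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            rows.append((feats[j], np.nan, 1.0, 0.0, True))
            continue
        # exact U distribution when there are no ties (scipy caches the
        # null distribution per group-size pair), normal approximation with
        # tie correction otherwise
        method = (
            "exact"
            if pooled.size <= 500 and np.unique(pooled).size == pooled.size
            else "asymptotic"
        )
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            (feats[j], float(res.statistic), float(res.pvalue),
             float(np.median(x) - np.median(y)), False)
        )
    df = pd.DataFrame(rows, columns=["feature_id", "u_stat", "p", "median_diff",
                                     "constant"])
    df["q"] = storey_qvalue(df["p"].to_numpy()).qvalues
    return df[["feature_id", "u_stat", "p", "q", "median_diff", "constant"]]


def per_crd_correlation_shift(
    corrected: PhenotypeMatrix, specific_crds: list[CRD], status
) -> tuple[pd.DataFrame, float]:
    """Mean pairwise member correlation per CRD and group, plus the global
    Mann-Whitney p comparing the per-CRD case vs control estimates.

    The global test treats the two sets of per-CRD estimates as independent
    samples (not paired by CRD).  Domains with an undefined correlation in
    either group are dropped with a log message.
    """
    s = np.asarray(status)
    if min((s == 1).sum(), (s == 0).sum()) < 10:
        raise ValueError("need >= 10 samples per group")
    rows = []
    dropped = 0
    for c in specific_crds:
        idx = corrected.feature_index(c.member_peaks)
        est = {}
        for g, lab in ((1, "case"), (0, "control")):
            M = corrected.values[s == g][:, idx]
            ok = ~np.isnan(M).any(axis=1)
            M = M[ok]
            if M.shape[0] < 3 or np.any(M.std(axis=0) < 1e-12):
                est[lab] = np.nan
                continue
            R = np.corrcoef(M, rowvar=False)
            iu = np.triu_indices(R.shape[0], 1)
            est[lab] = float(R[iu].mean())
        if np.isnan(est["case"]) or np.isnan(est["control"]):
            dropped += 1
            continue
        rows.append((c.crd_id, est["case"], est["control"],
                     est["case"] - est["control"]))
    if dropped:
        log.info("per_crd_correlation_shift: dropped %d CRDs with undefined r",
                 dropped)
    df = pd.DataFrame(rows, columns=["crd_id", "mean_r_case", "mean_r_control",
                                     "shift"])
    if len(df) < 2:
        raise ValueError("global test needs >= 2 CRDs with defined estimates")
    p = float(
        stats.mannwhitneyu(
            df["mean_r_case"], df["mean_r_control"], alternative="two-sided"
        ).pvalue
    )
    return df, p


def annotation_overlap_enrichment(
    foreground: PhenotypeMatrix | pd.DataFrame,
    background: PhenotypeMatrix | pd.DataFrame,
    annotation: IntervalSet,
    foreground_label: str = "foreground",
) -> EnrichmentResult:
    """Fisher exact test of foreground-vs-background annotation overlap.

    A peak overlaps the annotation iff the intersection is >= 1 bp.
    Foreground and background must be disjoint peak sets (background =
    universe minus foreground).
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")

    def _rows(x):
        feats = x.features if isinstance(x, PhenotypeMatrix) else x
        return feats[["feature_id", "chrom", "start", "end"]]

    fg = _rows(foreground)
    bg = _rows(background)
    shared = set(fg["feature_id"]) & set(bg["feature_id"])
    if shared:
        raise ValueError("foreground and background overlap")

    def _count(rows):
        hits = sum(
            annotation.overlaps(r.chrom, r.start, r.end)
            for r in rows.itertuples(index=False)
        )
        return hits, len(rows) - hits

    a, b = _count(fg)
    c, d = _count(bg)
    return enrichment_from_table(a, b, c, d, foreground_label,
                                 annotation.label or "annotation")


def enrichment_from_table(a, b, c, d, foreground_label="foreground",
                          annotation_label="annotation") -> EnrichmentResult:
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a == 0 or d == 0 else np.nan)
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return EnrichmentResult(
        a=int(a), b=int(b), c=int(c), d=int(d),
        odds_ratio=float(odds), odds_ratio_haldane=float(haldane), p=float(p),
        foreground_label=foreground_label, annotation_label=annotation_label,
    )
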