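"""Cis-regulatory domain (CRD) calling from interindividual peak correlation.

The caller measures the Pearson correlation between all pairs of chromatin
peaks on a chromosome within a sliding window of 250 peaks, agglomerates
genomically adjacent peaks/clusters into a binary tree by mean inter-cluster
correlation, and accepts a tree node as a CRD when three empirical criteria
hold:

(i)   mean pairwise correlation of the members >= factor x background,
(ii)  mean correlation between each boundary (first/last) member and the
      rest of the members >= factor x background,
(iii) at least two mutually non-overlapping member intervals.

``background`` is the chromosome-wide mean of the banded off-diagonal
correlations, floored by a sampling-noise guard (see
:func:`background_noise_floor`) so that on data with no shared structure the
criteria are not satisfied by chance.  Accepted nodes are maximal: the
search stops descending once a node qualifies, so nested sub-domains are
never emitted.  Signed correlations are used throughout — anti-correlated
peaks do not build domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PhenotypeMatrix

log = logging.getLogger("crdscan")

DEFAULT_WINDOW = 250
DEFAULT_FACTOR = 2.0


@dataclass
class CorrelationMap:
    """Banded Pearson correlations between peaks of one chromosome."""

    chrom: str
    peak_ids: list[str]
    corr: np.ndarray  # dense (n, n); NaN beyond the band or when undefined
    window: int
    background: float
    n_samples: int
    peak_starts: np.ndarray = field(repr=False, default=None)
    peak_ends: np.ndarray = field(repr=False, default=None)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    def filled(self) -> np.ndarray:
        """Correlations with out-of-band/undefined entries set to background
        and unit diagonal; used by the clustering and the criteria."""
        C = self.corr.copy()
        C[np.isnan(C)] = self.background
        np.fill_diagonal(C, 1.0)
        return C


@dataclass
class TreeNode:
    """Node of the adjacency-constrained clustering tree.

    Members are the contiguous peak-index range [lo, hi]; ``mean_corr`` is
    the mean pairwise correlation over members (out-of-band pairs contribute
    the background) and ``edge_corr`` the mean correlation between the two
    boundary peaks and all other members.
    """

    lo: int
    hi: int
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    mean_corr: float = 1.0
    edge_corr: float = 1.0
    pair_sum: float = 0.0  # sum of pairwise correlations among members

    @property
    def size(self) -> int:
        return self.hi - self.lo + 1

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class CRD:
    """A called cis-regulatory domain with its criteria statistics."""

    crd_id: str
    chrom: str
    start: int
    end: int
    member_peaks: list[str]
    n_members: int
    mean_corr: float
    edge_corr: float
    n_nonoverlapping: int
    background: float


def build_correlation_map(
    peaks: PhenotypeMatrix, window: int = DEFAULT_WINDOW, min_pairs: int = 10
) -> dict[str, CorrelationMap]:
    """Per-chromosome banded correlation maps of normalized peak activity.

    Correlations use pairwise-complete samples; a pair with fewer than
    ``min_pairs`` complete samples gets NaN (treated as background later) and
    is logged.  ``background`` is the mean banded off-diagonal correlation.
    """
    if peaks.kind != "normalized":
        raise ValueError("build_correlation_map requires kind='normalized'")
    maps = {}
    feats = peaks.features
    for chrom, idx in feats.groupby("chrom", sort=True).groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            continue
        sub = peaks.values[:, idx]
        ids = feats.loc[idx, "feature_id"].tolist()
        n_peak = idx.size
        if np.isnan(sub).any():
            C, n_bad = _pairwise_complete_corr(sub, window, min_pairs)
            if n_bad:
                log.warning(
                    "correlation map %s: %d pairs with < %d complete samples",
                    chrom, n_bad, min_pairs,
                )
        else:
            C = np.corrcoef(sub, rowvar=False)
        i, j = np.indices((n_peak, n_peak))
        band = np.abs(i - j) <= window
        C = np.where(band, C, np.nan)
        off = band & (i < j)
        background = float(np.nanmean(C[off]))
        maps[str(chrom)] = CorrelationMap(
            chrom=str(chrom),
            peak_ids=ids,
            corr=C,
            window=window,
            background=background,
            n_samples=peaks.n_samples,
            peak_starts=feats.loc[idx, "start"].to_numpy(),
            peak_ends=feats.loc[idx, "end"].to_numpy(),
        )
    return maps


def _pairwise_complete_corr(M, window, min_pairs):
    n_peak = M.shape[1]
    C = np.full((n_peak, n_peak), np.nan)
    n_bad = 0
    for a in range(n_peak):
        for b in range(a, min(a + window + 1, n_peak)):
            mask = ~(np.isnan(M[:, a]) | np.isnan(M[:, b]))
            if mask.sum() < min_pairs:
                n_bad += 1
                continue
            x, y = M[mask, a], M[mask, b]
            sx, sy = x.std(), y.std()
            if sx < 1e-12 or sy < 1e-12:
                n_bad += 1
                continue
            r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
            C[a, b] = C[b, a] = r
    return C, n_bad


def build_tree(cmap: CorrelationMap) -> TreeNode:
    """Adjacency-constrained agglomerative clustering of one chromosome.

    At each step the two genomically adjacent clusters with the highest mean
    inter-cluster correlation are merged (ties to the leftmost pair); pairs
    outside the correlation band contribute the background value.  Returns
    the root node; every node's member set is a contiguous index range.
    """
    C = cmap.filled()
    n = cmap.n_peaks
    clusters: list[TreeNode] = [TreeNode(i, i) for i in range(n)]
    # cached merge score between cluster k and k+1
    scores = [float(C[i, i + 1]) for i in range(n - 1)]

    def cross_sum(a: TreeNode, b: TreeNode) -> float:
        return float(C[a.lo : a.hi + 1, b.lo : b.hi + 1].sum())

    while len(clusters) > 1:
        k = int(np.argmax(scores))  # first max -> leftmost tie
        a, b = clusters[k], clusters[k + 1]
        cs = cross_sum(a, b)
        node = TreeNode(a.lo, b.hi, left=a, right=b)
        node.pair_sum = a.pair_sum + b.pair_sum + cs
        m = node.size
        node.mean_corr = node.pair_sum / (m * (m - 1) / 2.0)
        row_lo = C[node.lo, node.lo + 1 : node.hi + 1].sum()
        row_hi = C[node.hi, node.lo : node.hi].sum()
        node.edge_corr = float((row_lo + row_hi - C[node.lo, node.hi]) / (2 * m - 3))
        clusters[k : k + 2] = [node]
        del scores[k]
        if k > 0:
            scores[k - 1] = cross_sum(clusters[k - 1], node) / (
                clusters[k - 1].size * node.size
            )
        if k < len(scores):
            scores[k] = cross_sum(node, clusters[k + 1]) / (
                node.size * clusters[k + 1].size
            )
    return clusters[0]


def count_nonoverlapping(starts, ends) -> int:
    """Maximum number of mutually non-overlapping intervals (greedy by end)."""
    order = np.argsort(ends, kind="stable")
    count, last_end = 0, -np.inf
    for i in order:
        if starts[i] >= last_end:
            count += 1
            last_end = ends[i]
    return count


def background_noise_floor(n_samples: int, n_candidates: int, alpha: float = 0.01,
                           factor: float = DEFAULT_FACTOR) -> float:
    """Sampling-noise floor for the background correlation.

    Under no shared structure, pairwise correlations fluctuate around zero
    with Fisher-z scale 1/sqrt(n-3); with ``n_candidates`` candidate merges a
    Bonferroni-style bound r* = tanh(z_{1-alpha/n_candidates}/sqrt(n-3)) is
    the largest spurious correlation expected.  The floor is chosen so that
    ``factor x floor = r*``, making chance-level domains fail criterion (i).
    """
    if n_samples <= 4 or n_candidates < 1:
        return 0.01
    z = stats.norm.ppf(1.0 - alpha / n_candidates)
    r_star = float(np.tanh(z / np.sqrt(n_samples - 3)))
    return r_star / factor


def call_crds(
    tree: TreeNode,
    cmap: CorrelationMap,
    peak_intervals=None,
    factor: float = DEFAULT_FACTOR,
    background_floor: float | None = None,
    id_prefix: str = "crd",
) -> list[CRD]:
    """Depth-first acceptance of maximal tree nodes passing the three criteria.

    ``peak_intervals`` is an (n_peaks, 2) array of member start/end
    coordinates; defaults to the ones stored on the map.  A non-positive or
    chance-level background is floored (see :func:`background_noise_floor`).
    """
    if peak_intervals is None:
        peak_intervals = np.column_stack([cmap.peak_starts, cmap.peak_ends])
    starts = np.asarray(peak_intervals)[:, 0]
    ends = np.asarray(peak_intervals)[:, 1]
    if background_floor is None:
        background_floor = background_noise_floor(
            cmap.n_samples, max(cmap.n_peaks - 1, 1), factor=factor
        )
    bg = cmap.background
    if bg <= 0:
        log.warning(
            "chromosome %s: background %.4g <= 0, flooring to %.4g",
            cmap.chrom, bg, background_floor,
        )
    bg = max(bg, background_floor)
    threshold = factor * bg
    accepted: list[CRD] = []

    def qualify(node: TreeNode) -> bool:
        if node.is_leaf or node.size < 2:
            return False
        if node.mean_corr < threshold or node.edge_corr < threshold:
            return False
        rng = slice(node.lo, node.hi + 1)
        return count_nonoverlapping(starts[rng], ends[rng]) >= 2

    stack = [tree]
    while stack:
        node = stack.pop()
        if qualify(node):
            rng = slice(node.lo, node.hi + 1)
            accepted.append(
                CRD(
                    crd_id="",
                    chrom=cmap.chrom,
                    start=int(starts[rng].min()),
                    end=int(ends[rng].max()),
                    member_peaks=cmap.peak_ids[node.lo : node.hi + 1],
                    n_members=node.size,
                    mean_corr=float(node.mean_corr),
                    edge_corr=float(node.edge_corr),
                    n_nonoverlapping=int(
                        count_nonoverlapping(starts[rng], ends[rng])
                    ),
                    background=bg,
                )
            )
        elif not node.is_leaf:
            stack.append(node.right)
            stack.append(node.left)
    accepted.sort(key=lambda c: c.start)
    for i, c in enumerate(accepted):
        c.crd_id = f"{id_prefix}_{cmap.chrom}_{i:04d}"
    return accepted


def call_crds_genomewide(
    peaks: PhenotypeMatrix,
    window: int = DEFAULT_WINDOW,
    factor: float = DEFAULT_FACTOR,
    background_floor: float | None = None,
    id_prefix: str = "crd",
) -> list[CRD]:
    """Correlation map + tree + calling for every chromosome of a matrix."""
    crds: list[CRD] = []
    for chrom, cmap in build_correlation_map(peaks, window=window).items():
        tree = build_tree(cmap)
        crds.extend(
            call_crds(
                tree, cmap, factor=factor, background_floor=background_floor,
                id_prefix=id_prefix,
            )
        )
    return crds


def quantify_crds(peaks: PhenotypeMatrix, crds: list[CRD]) -> PhenotypeMatrix:
    """Mean member-peak quantification per individual for each CRD.

    NA-aware: a sample with every member missing gets NA.  Output features
    carry the CRD span coordinates.
    """
    cols, rows = [], []
    for c in crds:
        idx = peaks.feature_index(c.member_peaks)
        sub = peaks.values[:, idx]
        n_ok = (~np.isnan(sub)).sum(axis=1)
        total = np.nansum(sub, axis=1)
        cols.append(np.where(n_ok > 0, total / np.maximum(n_ok, 1), np.nan))
        rows.append((c.crd_id, c.chrom, c.start, c.end, "+", c.crd_id))
    feats = pd.DataFrame(
        rows, columns=["feature_id", "chrom", "start", "end", "strand", "group_id"]
    )
    values = np.column_stack(cols) if cols else np.zeros((peaks.n_samples, 0))
    order = feats.sort_values(["chrom", "start"], kind="stable").index.to_numpy()
    return PhenotypeMatrix(
        peaks.sample_ids, feats.iloc[order].reset_index(drop=True),
        values[:, order], "quantified",
    )


def sum_crd_counts(raw_counts: PhenotypeMatrix, crds: list[CRD]) -> PhenotypeMatrix:
    """Integer sums of member-peak counts per CRD (input kind must be
    raw_count); feeds the differential-activity test."""
    if raw_counts.kind != "raw_count":
        raise ValueError("sum_crd_counts requires kind='raw_count'")
    cols, rows = [], []
    for c in crds:
        idx = raw_counts.feature_index(c.member_peaks)
        cols.append(raw_counts.values[:, idx].sum(axis=1))
        rows.append((c.crd_id, c.chrom, c.start, c.end, "+", c.crd_id))
    feats = pd.DataFrame(
        rows, columns=["feature_id", "chrom", "start", "end", "strand", "group_id"]
    )
    values = np.column_stack(cols) if cols else np.zeros((raw_counts.n_samples, 0))
    order = feats.sort_values(["chrom", "start"], kind="stable").index.to_numpy()
    return PhenotypeMatrix(
        raw_counts.sample_ids, feats.iloc[order].reset_index(drop=True),
        values[:, order], "raw_count",
    )


def crds_to_frame(crds: list[CRD]) -> pd.DataFrame:
    """BED-style table of called CRDs (member ids as a comma list)."""
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "crd_id": c.crd_id,
                "n_members": c.n_members,
                "mean_corr": c.mean_corr,
                "edge_corr": c.edge_corr,
                "background": c.background,
                "member_ids": ",".join(c.member_peaks),
            }
            for c in crds
        ],
        columns=[
            "chrom", "start", "end", "crd_id", "n_members", "mean_corr",
            "edge_corr", "background", "member_ids",
        ],
    )


def frame_to_crds(df: pd.DataFrame) -> list[CRD]:
    out = []
    for r in df.itertuples(index=False):
        members = r.member_ids.split(",")
        out.append(
            CRD(
                crd_id=r.crd_id, chrom=r.chrom, start=int(r.start), end=int(r.end),
                member_peaks=members, n_members=len(members),
                mean_corr=float(r.mean_corr), edge_corr=float(r.edge_corr),
                n_nonoverlapping=len(members), background=float(r.background),
            )
        )
    return out
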