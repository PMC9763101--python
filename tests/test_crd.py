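import numpy as np
import pytest

from crdscan.crd import (
    build_correlation_map,
    build_tree,
    call_crds,
    call_crds_genomewide,
    background_noise_floor,
    count_nonoverlapping,
    quantify_crds,
    sum_crd_counts,
)
from tests.conftest import make_phenotypes


def collect_nodes(node):
    out = [node]
    if not node.is_leaf:
        out += collect_nodes(node.left) + collect_nodes(node.right)
    return out


def oracle_called_set(values, starts, ends, tree, window, factor=2.0):
    """Independent recomputation of the caller's result.

    Recomputes banded correlations, background (with the same noise floor),
    and the three criteria for every tree node directly from the data, then
    returns the maximal qualifying nodes (no qualifying ancestor).
    """
    n = values.shape[1]
    R = np.corrcoef(values, rowvar=False)
    band = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) <= window
    iu = np.triu_indices(n, 1)
    in_band = band[iu]
    bg = R[iu][in_band].mean()
    bg = max(bg, background_noise_floor(values.shape[0], n - 1, factor=factor))
    Rb = np.where(band, R, bg)

    def qualifies(lo, hi):
        if hi == lo:
            return False
        idx = np.arange(lo, hi + 1)
        sub = Rb[np.ix_(idx, idx)]
        pairs = sub[np.triu_indices(len(idx), 1)]
        mean_corr = pairs.mean()
        m = len(idx)
        edge_pairs = np.concatenate([sub[0, 1:], sub[-1, 1:-1]]) if m > 2 else sub[0, 1:]
        edge_corr = edge_pairs.mean()
        n_no = count_nonoverlapping(starts[idx], ends[idx])
        return (mean_corr >= factor * bg and edge_corr >= factor * bg
                and n_no >= 2)

    nodes = collect_nodes(tree)
    qual = {(nd.lo, nd.hi) for nd in nodes if qualifies(nd.lo, nd.hi)}

    def has_qualifying_ancestor(node, ancestors):
        return any(a in qual for a in ancestors)

    maximal = set()

    def walk(node, ancestors):
        key = (node.lo, node.hi)
        if key in qual and not has_qualifying_ancestor(node, ancestors):
            maximal.add(key)
            return
        if not node.is_leaf:
            walk(node.left, ancestors + [key])
            walk(node.right, ancestors + [key])

    walk(tree, [])
    return maximal, bg


class TestCorrelationMap:
    def test_identical_and_inverted_peaks(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        pm = make_phenotypes(np.column_stack([x, x, -x]))
        cmap = build_correlation_map(pm)["chr1"]
        assert cmap.corr[0, 1] == pytest.approx(1.0)
        assert cmap.corr[0, 2] == pytest.approx(-1.0)

    def test_band_boundary(self):
        """With a 250-peak window, index distance 250 is kept, 251+ is not."""
        rng = np.random.default_rng(1)
        pm = make_phenotypes(rng.normal(size=(30, 300)))
        cmap = build_correlation_map(pm, window=250)["chr1"]
        assert np.isfinite(cmap.corr[0, 250])
        assert np.isnan(cmap.corr[0, 299])

    def test_requires_normalized_kind(self):
        pm = make_phenotypes(np.random.default_rng(2).normal(size=(10, 5)),
                             kind="quantified")
        with pytest.raises(ValueError, match="normalized"):
            build_correlation_map(pm)


class TestBuildTree:
    def test_two_peaks_single_root(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        pm = make_phenotypes(np.column_stack([x, x + rng.normal(size=40)]))
        cmap = build_correlation_map(pm)["chr1"]
        tree = build_tree(cmap)
        assert (tree.lo, tree.hi) == (0, 1)
        assert tree.mean_corr == pytest.approx(cmap.corr[0, 1])
        assert tree.edge_corr == pytest.approx(cmap.corr[0, 1])

    def test_four_peak_merge_order(self):
        """r(0,1)=r(2,3) high, cross-block r ~ 0: blocks merge first."""
        rng = np.random.default_rng(4)
        n = 500
        f1, f2 = rng.normal(size=(2, n))
        vals = np.column_stack(
            [f1 + 0.3 * rng.normal(size=n), f1 + 0.3 * rng.normal(size=n),
             f2 + 0.3 * rng.normal(size=n), f2 + 0.3 * rng.normal(size=n)]
        )
        tree = build_tree(build_correlation_map(make_phenotypes(vals))["chr1"])
        child_ranges = {(tree.left.lo, tree.left.hi),
                        (tree.right.lo, tree.right.hi)}
        assert child_ranges == {(0, 1), (2, 3)}

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(60, 8))
        perm = rng.permutation(60)
        t1 = build_tree(build_correlation_map(make_phenotypes(vals))["chr1"])
        t2 = build_tree(build_correlation_map(make_phenotypes(vals[perm]))["chr1"])
        r1 = sorted((n.lo, n.hi) for n in collect_nodes(t1))
        r2 = sorted((n.lo, n.hi) for n in collect_nodes(t2))
        assert r1 == r2

    def test_contiguous_ranges(self):
        rng = np.random.default_rng(6)
        tree = build_tree(
            build_correlation_map(make_phenotypes(rng.normal(size=(50, 20))))["chr1"]
        )
        for node in collect_nodes(tree):
            if not node.is_leaf:
                assert node.left.hi + 1 == node.right.lo
                assert (node.lo, node.hi) == (node.left.lo, node.right.hi)


class TestCallCrds:
    def _planted_block(self, seed=0, n=500, block=range(7, 12), n_peaks=30):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(n, n_peaks)) * np.sqrt(2.0)
        f = rng.normal(size=n)
        for j in block:
            vals[:, j] = f + rng.normal(size=n)
        return make_phenotypes(vals), list(block)

    def test_planted_block_called(self):
        """One domain is called; it contains the planted block, matches it at
        Jaccard >= 0.5, and its stored criteria hold."""
        pm, block = self._planted_block()
        crds = call_crds_genomewide(pm)
        assert len(crds) == 1
        members = set(crds[0].member_peaks)
        planted = {f"p{j:04d}" for j in block}
        assert planted <= members
        assert len(planted & members) / len(planted | members) >= 0.5
        assert crds[0].mean_corr >= 2 * crds[0].background
        assert crds[0].edge_corr >= 2 * crds[0].background

    def test_planted_block_delimited_on_long_chromosome(self):
        """With enough peaks the noise guard tightens and the called domain
        is exactly the planted block."""
        pm, block = self._planted_block(seed=12, n=200, block=range(80, 86),
                                        n_peaks=200)
        crds = call_crds_genomewide(pm)
        assert len(crds) == 1
        assert crds[0].member_peaks == [f"p{j:04d}" for j in block]

    def test_fully_overlapping_pair_rejected(self):
        """A correlated pair occupying one shared interval fails the
        non-overlap criterion; with distinct intervals it is called."""
        rng = np.random.default_rng(7)
        n = 300
        vals = rng.normal(size=(n, 10))
        f = rng.normal(size=n)
        vals[:, 4] = f + 0.3 * rng.normal(size=n)
        vals[:, 5] = f + 0.3 * rng.normal(size=n)
        pm = make_phenotypes(vals)
        cmap = build_correlation_map(pm)["chr1"]
        tree = build_tree(cmap)
        distinct = np.column_stack(
            [pm.features["start"], pm.features["end"]]
        ).astype(int)
        called = call_crds(tree, cmap, peak_intervals=distinct)
        assert len(called) == 1
        assert {"p0004", "p0005"} <= set(called[0].member_peaks)
        # every peak on one shared interval: criterion (iii) rejects all nodes
        same = np.repeat([[1000, 2000]], 10, axis=0)
        assert call_crds(tree, cmap, peak_intervals=same) == []

    def test_disjoint_membership_and_recomputable_criteria(self):
        pm, _ = self._planted_block(seed=8, block=range(3, 8))
        crds = call_crds_genomewide(pm)
        seen = set()
        for c in crds:
            assert not (seen & set(c.member_peaks))
            seen.update(c.member_peaks)
            idx = pm.feature_index(c.member_peaks)
            R = np.corrcoef(pm.values[:, idx], rowvar=False)
            iu = np.triu_indices(len(idx), 1)
            assert R[iu].mean() == pytest.approx(c.mean_corr, abs=1e-9)

    def test_oracle_equivalence_small_chromosomes(self):
        """Called set == maximal tree nodes passing brute-force criteria."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_peaks = int(rng.integers(4, 13))
            n = 60
            vals = rng.normal(size=(n, n_peaks))
            if seed % 2:  # plant one block half the time
                f = rng.normal(size=n)
                lo = int(rng.integers(0, n_peaks - 2))
                hi = min(lo + int(rng.integers(2, 5)), n_peaks)
                vals[:, lo:hi] = f[:, None] + 0.6 * rng.normal(size=(n, hi - lo))
            pm = make_phenotypes(vals)
            cmap = build_correlation_map(pm)["chr1"]
            tree = build_tree(cmap)
            called = call_crds(tree, cmap)
            starts = pm.features["start"].to_numpy()
            ends = pm.features["end"].to_numpy()
            expected, _ = oracle_called_set(vals, starts, ends, tree,
                                            cmap.window)
            got = set()
            for c in called:
                idx = pm.feature_index(c.member_peaks)
                got.add((int(idx.min()), int(idx.max())))
            assert got == expected, f"seed {seed}"


class TestQuantify:
    def test_mean_activity(self):
        pm, block = self._block()
        crds = call_crds_genomewide(pm)
        act = quantify_crds(pm, crds)
        idx = pm.feature_index(crds[0].member_peaks)
        assert np.allclose(act.values[:, 0], pm.values[:, idx].mean(axis=1))

    def _block(self):
        rng = np.random.default_rng(9)
        n = 400
        vals = rng.normal(size=(n, 12)) * np.sqrt(2.0)
        f = rng.normal(size=n)
        for j in range(4, 9):
            vals[:, j] = f + rng.normal(size=n)
        return make_phenotypes(vals), list(range(4, 9))

    def test_all_na_sample_gives_na(self):
        pm, _ = self._block()
        crds = call_crds_genomewide(pm)
        idx = pm.feature_index(crds[0].member_peaks)
        pm.values[0, idx] = np.nan
        act = quantify_crds(pm, crds)
        assert np.isnan(act.values[0, 0])
        assert not np.isnan(act.values[1:, 0]).any()

    def test_activity_tracks_latent_factor(self):
        """r(activity, factor) = sqrt(k l^2/(k l^2 + s^2)) ~ 0.91 for k=5."""
        rng = np.random.default_rng(10)
        n = 500
        f = rng.normal(size=n)
        vals = f[:, None] + rng.normal(size=(n, 5))
        pm = make_phenotypes(vals)
        act = vals.mean(axis=1)
        r = np.corrcoef(act, f)[0, 1]
        assert r > 0.9

    def test_missing_member_rejected(self):
        pm, _ = self._block()
        crds = call_crds_genomewide(pm)
        crds[0].member_peaks.append("p9999")
        with pytest.raises(KeyError):
            quantify_crds(pm, crds)


class TestSumCounts:
    def _counts_and_crds(self):
        rng = np.random.default_rng(11)
        pm = make_phenotypes(rng.normal(size=(300, 10)))
        f = rng.normal(size=300)
        pm.values[:, 2:6] = f[:, None] + 0.5 * rng.normal(size=(300, 4))
        crds = call_crds_genomewide(pm)
        counts = make_phenotypes(
            rng.poisson(50, size=(300, 10)).astype(float), kind="raw_count"
        )
        return counts, crds

    def test_member_sum(self):
        counts, crds = self._counts_and_crds()
        summed = sum_crd_counts(counts, crds)
        idx = counts.feature_index(crds[0].member_peaks)
        assert np.array_equal(summed.values[:, 0],
                              counts.values[:, idx].sum(axis=1))

    def test_conservation(self):
        counts, crds = self._counts_and_crds()
        summed = sum_crd_counts(counts, crds)
        assert np.all(summed.values.sum(axis=1) <= counts.values.sum(axis=1))

    def test_non_integer_rejected(self):
        counts, crds = self._counts_and_crds()
        bad = make_phenotypes(counts.values + 0.5, kind="quantified")
        with pytest.raises(ValueError, match="raw_count"):
            sum_crd_counts(bad, crds)
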