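"""Disparity bootstrap, Holm correction, PERMANOVA and hull occupation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleomorph.disparity_stats import (
    bootstrap_disparity,
    classify_tempo,
    holm_bonferroni,
    hull_measure,
    pairwise_permanova,
    permanova,
    sequential_disparity_ttests,
    sum_of_variances,
)
from paleomorph.errors import DegenerateDataError


class TestSumOfVariances:
    def test_hand_computed_square(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        assert sum_of_variances(pts, axes=2) == pytest.approx(2 / 3)

    def test_identical_points_zero(self):
        assert sum_of_variances(np.ones((5, 4))) == 0.0

    def test_translation_invariance(self, rng):
        X = rng.normal(size=(30, 4))
        shifted = X + np.array([5.0, -3.0, 2.0, 100.0])
        assert sum_of_variances(X) == pytest.approx(sum_of_variances(shifted))

    def test_single_row_raises(self):
        with pytest.raises(DegenerateDataError):
            sum_of_variances(np.ones((1, 4)))


class TestBootstrapDisparity:
    def test_constant_group_all_draws_zero(self, rng):
        X = np.vstack([np.ones((10, 4)), rng.normal(size=(10, 4))])
        groups = np.repeat(["const", "noisy"], 10)
        res = bootstrap_disparity(X, groups, n_boot=50, seed=1)
        assert np.all(res.bootstrap_draws["const"] == 0.0)

    def test_planted_trace_recovered(self):
        """Bootstrap mean tracks the planted trace of covariance (2.0) at n=200.

        The sampling sd of one n=200 disparity estimate is itself ~5%, so the
        bootstrap mean is averaged over replicate datasets of that size.
        """
        means = []
        for rep in range(25):
            r = np.random.default_rng(700 + rep)
            X = r.normal(scale=np.sqrt(0.5), size=(200, 4))  # trace = 4*0.5 = 2
            res = bootstrap_disparity(X, np.repeat(["g"], 200), axes=4,
                                      n_boot=200, seed=rep)
            means.append(res.bootstrap_draws["g"].mean())
        assert np.mean(means) == pytest.approx(2.0, rel=0.05)

    def test_uses_exactly_requested_axes(self, rng):
        X = np.hstack([rng.normal(size=(50, 4)), np.full((50, 1), 1e6)])
        X[:, 4] += rng.normal(size=50) * 100  # huge 5th axis must be ignored
        groups = np.repeat(["g"], 50)
        res = bootstrap_disparity(X, groups, axes=4, n_boot=20, seed=0)
        assert res.point_estimates["g"] == pytest.approx(
            sum_of_variances(X[:, :4], axes=4)
        )

    def test_seed_reproducible_and_row_order_invariant(self, rng):
        X = rng.normal(size=(40, 4))
        ids = np.array([f"s{i:02d}" for i in range(40)])
        groups = np.repeat(["a", "b"], 20)
        table = pd.DataFrame(X, columns=["PC1", "PC2", "PC3", "PC4"])
        table.insert(0, "specimen_id", ids)
        r1 = bootstrap_disparity(table, groups, n_boot=30, seed=11)
        perm = rng.permutation(40)
        r2 = bootstrap_disparity(
            table.iloc[perm].reset_index(drop=True), groups[perm], n_boot=30,
            seed=11, group_order=["a", "b"],
        )
        for g in ("a", "b"):
            np.testing.assert_array_equal(
                r1.bootstrap_draws[g], r2.bootstrap_draws[g]
            )

    def test_bootstrap_sd_shrinks_with_group_size(self):
        """Bootstrap spread scales roughly as 1/sqrt(n) on planted data."""
        r = np.random.default_rng(5)
        sds = {}
        for n in (50, 800):
            X = r.normal(size=(n, 4))
            res = bootstrap_disparity(X, np.repeat(["g"], n), n_boot=400, seed=2)
            sds[n] = res.bootstrap_draws["g"].std()
        ratio = sds[50] / sds[800]
        assert ratio == pytest.approx(4.0, rel=0.35)

    def test_singleton_group_excluded_with_warning(self, rng, caplog):
        X = rng.normal(size=(11, 4))
        groups = np.array(["a"] * 10 + ["b"])
        import logging

        with caplog.at_level(logging.WARNING):
            res = bootstrap_disparity(X, groups, n_boot=10, seed=0)
        assert res.excluded == ["b"]
        assert "b" not in res.bootstrap_draws


def holm_by_definition(p):
    """Brute-force Holm: sort, adjusted_i = max_j<=i (m-j+1) p_(j), cap at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_bonferroni([0.03]), [0.03])

    def test_worked_example(self):
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(holm_bonferroni([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(holm_bonferroni(p), holm_by_definition(p), atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8), st.integers(0, 1000))
    def test_order_invariance(self, p, seed):
        """Permuting the inputs permutes the outputs identically."""
        perm = np.random.default_rng(seed).permutation(len(p))
        a = holm_bonferroni(p)
        b = holm_bonferroni(np.asarray(p)[perm])
        np.testing.assert_allclose(a[perm], b, atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        p = [0.001, 0.2, 0.05, 0.5]
        adj = holm_bonferroni(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])


class TestSequentialTTests:
    def test_identical_distributions_large_p(self):
        r = np.random.default_rng(3)
        X = r.normal(size=(400, 4))
        groups = np.array(["a"] * 200 + ["b"] * 200)
        # same generating distribution: expect no significant difference
        res = bootstrap_disparity(X, groups, n_boot=300, seed=4)
        res.bootstrap_draws["b"] = res.bootstrap_draws["a"].copy()
        res.point_estimates["b"] = res.point_estimates["a"]
        res = sequential_disparity_ttests(res, order=["a", "b"])
        assert res.pairwise["p_raw"].iloc[0] > 0.9

    def test_adjacent_mode_three_comparisons_for_four_bins(self, rng):
        X = rng.normal(size=(80, 4))
        groups = np.repeat(["wetland", "shallow", "deep", "modern"], 20)
        res = bootstrap_disparity(X, groups, n_boot=30, seed=0)
        res = sequential_disparity_ttests(
            res, order=["wetland", "shallow", "deep", "modern"]
        )
        assert len(res.pairwise) == 3
        all_pairs = sequential_disparity_ttests(
            res, order=["wetland", "shallow", "deep", "modern"], mode="all-pairs"
        )
        assert len(all_pairs.pairwise) == 6

    def test_planted_jump_detected(self):
        """A 3-sampling-SD disparity jump is flagged in >= 95% of replicates."""
        n, axes = 100, 4
        rel_jump = 3 * np.sqrt(2 / (n - 1)) / np.sqrt(axes)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            a = r.normal(size=(n, axes))
            b = r.normal(size=(n, axes))
            c = r.normal(scale=np.sqrt(1 + rel_jump), size=(n, axes))
            X = np.vstack([a, b, c])
            groups = np.repeat(["t1", "t2", "t3"], n)
            res = bootstrap_disparity(X, groups, n_boot=200, seed=rep)
            res = sequential_disparity_ttests(res, order=["t1", "t2", "t3"])
            row = res.pairwise.iloc[1]
            hits += row["p_holm"] < 0.05 and row["estimate_b"] > row["estimate_a"]
        assert hits >= 95

    def test_degenerate_pair_flagged(self):
        X = np.vstack([np.ones((5, 2)), np.ones((5, 2))])
        groups = np.repeat(["a", "b"], 5)
        res = bootstrap_disparity(X, groups, axes=2, n_boot=20, seed=0)
        res = sequential_disparity_ttests(res, order=["a", "b"])
        assert res.pairwise["degenerate"].iloc[0]
        assert res.pairwise["p_raw"].iloc[0] == 1.0


class TestClassifyTempo:
    def make_result(self, disparities, n=150, seed=0):
        r = np.random.default_rng(seed)
        X = np.vstack(
            [r.normal(scale=np.sqrt(d / 4), size=(n, 4)) for d in disparities]
        )
        groups = np.repeat([f"t{i}" for i in range(len(disparities))], n)
        res = bootstrap_disparity(X, groups, n_boot=300, seed=seed)
        return sequential_disparity_ttests(
            res, order=[f"t{i}" for i in range(len(disparities))]
        )

    def test_plateau_reads_early_burst(self):
        res = self.make_result([0.2, 1.0, 1.1])
        assert classify_tempo(res) == "early-burst"

    def test_late_rise_reads_constant_rate(self):
        res = self.make_result([0.2, 0.4, 1.6])
        assert classify_tempo(res) == "constant-rate"

    def test_no_change_reads_flat(self):
        res = self.make_result([1.0, 1.0, 1.0])
        # force equality of draws so nothing is significant
        for g in res.bootstrap_draws:
            res.bootstrap_draws[g] = res.bootstrap_draws["t0"]
            res.point_estimates[g] = res.point_estimates["t0"]
        res.pairwise = None
        assert classify_tempo(res, order=["t0", "t1", "t2"]) == "flat"


def permanova_by_enumeration(X, groups):
    """Exhaustive PERMANOVA oracle: recompute F for every distinct labeling
    directly from group centroids (independent of the distance identity)."""

    def F_of(labels):
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        grand = X.mean(axis=0)
        ssb = sum(
            (labels == g).sum() * np.sum((X[labels == g].mean(axis=0) - grand) ** 2)
            for g in uniq
        )
        ssw = sum(
            np.sum((X[labels == g] - X[labels == g].mean(axis=0)) ** 2) for g in uniq
        )
        return (ssb / (len(uniq) - 1)) / (ssw / (len(X) - len(uniq)))

    obs = F_of(groups)
    perms = set(itertools.permutations(groups))
    count = sum(F_of(p) >= obs - 1e-12 for p in perms)
    return obs, count / len(perms)


class TestPermanova:
    def test_identical_groups_F_zero_p_one(self):
        base = np.random.default_rng(0).normal(size=(5, 3))
        X = np.vstack([base, base])
        groups = np.repeat(["a", "b"], 5)
        res = permanova(X, groups, n_perm=99, seed=1)
        assert res.pseudo_F == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_exact_enumeration_matches_oracle(self, rng):
        """2 groups x 3 observations: p equals the exhaustive enumeration value."""
        X = rng.normal(size=(6, 2))
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(X, groups, exact=True)
        obs, p_oracle = permanova_by_enumeration(X, groups)
        assert res.n_perm == 20
        assert res.pseudo_F == pytest.approx(obs, rel=1e-9)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_min_attainable_p_with_999_perms(self, rng):
        """Well-separated groups reach exactly p = 1/(999+1) = 0.001."""
        X = np.vstack(
            [rng.normal(size=(20, 3)), rng.normal(size=(20, 3)) + 50.0]
        )
        groups = np.repeat(["a", "b"], 20)
        res = permanova(X, groups, n_perm=999, seed=0)
        assert res.p == pytest.approx(0.001)
        assert res.R2 > 0.9

    def test_matches_scikit_bio(self, rng):
        """Independent cross-check of pseudo-F against scikit-bio's PERMANOVA."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        X = rng.normal(size=(30, 4))
        X[15:] += 0.8
        groups = np.repeat(["a", "b"], 15)
        res = permanova(X, groups, n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(squareform(pdist(X)))
        ref = skbio_stats.permanova(dm, grouping=list(groups), permutations=999)
        assert res.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)
        assert abs(res.R2 - (1 - 1 / (1 + ref["test statistic"] * 1 / 28))) < 0.2

    def test_seed_reproducible(self, rng):
        X = rng.normal(size=(20, 3))
        groups = np.repeat(["a", "b"], 10)
        r1 = permanova(X, groups, n_perm=199, seed=42)
        r2 = permanova(X, groups, n_perm=199, seed=42)
        assert r1.p == r2.p

    def test_single_group_raises(self, rng):
        with pytest.raises(DegenerateDataError):
            permanova(rng.normal(size=(5, 2)), np.repeat(["a"], 5))


class TestPairwisePermanova:
    def test_identical_groups_p_one(self):
        base = np.random.default_rng(1).normal(size=(5, 2))
        X = np.vstack([base, base, base])
        groups = np.repeat(["a", "b", "c"], 5)
        table = pairwise_permanova(X, groups, n_perm=49, seed=0)
        assert np.all(table["p_raw"] == 1.0)

    def test_pair_count_18_groups(self, rng):
        """18 guilds produce 153 pairwise comparisons."""
        X = rng.normal(size=(18 * 4, 2))
        groups = np.repeat([f"g{i:02d}" for i in range(18)], 4)
        table = pairwise_permanova(X, groups, n_perm=19, seed=0)
        assert len(table) == 153
        assert np.all(table["p_adjusted"] >= table["p_raw"] - 1e-15)

    def test_planted_cluster_pair_detected(self):
        """The separated pair attains minimum p; the similar pair stays ns."""
        wins, ns_ok = 0, 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(500 + rep)
            a = r.normal(size=(15, 3))
            b = r.normal(size=(15, 3))          # same distribution as a
            c = r.normal(size=(15, 3)) + 6.0    # far cluster
            X = np.vstack([a, b, c])
            groups = np.repeat(["a", "b", "c"], 15)
            table = pairwise_permanova(X, groups, n_perm=99, seed=rep,
                                       correction="none")
            by_pair = table.set_index(["group_a", "group_b"])["p_raw"]
            sep_p = min(by_pair[("a", "c")], by_pair[("b", "c")])
            wins += sep_p == by_pair.min()
            ns_ok += by_pair[("a", "b")] > 0.05
        assert wins >= 18
        assert ns_ok >= 18


def monte_carlo_hull_area(points, n_samples=1_000_000, seed=0):
    """Rejection-sampling area estimate inside the bounding box."""
    from shapely.geometry import MultiPoint, Point

    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    r = np.random.default_rng(seed)
    samples = r.uniform(lo, hi, size=(n_samples, 2))
    from shapely import contains_xy

    inside = contains_xy(hull, samples[:, 0], samples[:, 1])
    box_area = np.prod(hi - lo)
    return inside.mean() * box_area


class TestHullMeasure:
    def test_unit_square_area_one(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        hm = hull_measure(pts, dims=2)
        assert hm.measure == pytest.approx(1.0)
        assert not hm.degenerate
        assert {tuple(v) for v in hm.vertices} == {tuple(p) for p in pts}

    def test_collinear_points_zero(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        hm = hull_measure(pts, dims=2)
        assert hm.measure == 0.0
        assert hm.degenerate

    def test_too_few_points_flagged(self):
        hm = hull_measure(np.array([[0.0, 0.0], [1.0, 1.0]]), dims=2)
        assert hm.measure == 0.0 and hm.degenerate

    def test_matches_monte_carlo(self, rng):
        """Hull area agrees with a 10^6-sample rejection estimate within 2%."""
        pts = rng.normal(size=(200, 2))
        hm = hull_measure(pts, dims=2)
        mc = monte_carlo_hull_area(pts)
        assert hm.measure == pytest.approx(mc, rel=0.02)

    def test_monotone_under_point_addition(self, rng):
        pts = rng.normal(size=(40, 2))
        base = hull_measure(pts, dims=2).measure
        grown = hull_measure(np.vstack([pts, rng.normal(size=(10, 2)) * 2]), dims=2)
        assert grown.measure >= base - 1e-12

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(50, 2))
        theta = 0.9
        R = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
        moved = pts @ R + np.array([3.0, -7.0])
        assert hull_measure(pts).measure == pytest.approx(
            hull_measure(moved).measure, rel=1e-9
        )

    def test_four_dims_hypervolume(self, rng):
        hm = hull_measure(rng.normal(size=(60, 4)), dims=4)
        assert hm.measure > 0 and hm.dims == 4
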