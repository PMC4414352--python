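"""Baseline clustering: minpts=1 DBSCAN, epsilon sweep, Poisson selection,
K-means scree, and local-range extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

import isoprov as ip
from isoprov.baseline import SweepResult, largest_cluster

rng_points = st.integers(0, 2**31 - 1)


def partition_sets(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


def fauna(sample_id, sr, pb):
    return ip.IsotopeSample(sample_id=sample_id, site="T", kind="fauna",
                            sr87_86=sr, pb206_204=pb)


class TestNormalize:
    def test_zscore_definition(self, harappa_study):
        norm = ip.normalize(harappa_study["fauna"])
        assert np.allclose(norm.points.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(norm.points.std(axis=0, ddof=1), 1, atol=1e-12)
        assert np.allclose(norm.inverse(norm.points),
                           np.array([[s.pb206_204, s.sr87_86]
                                     for s in norm.samples]))

    def test_two_points_error(self):
        with pytest.raises(ip.DegenerateInputError):
            ip.normalize([fauna("a", 0.711, 18.0), fauna("b", 0.712, 18.1)])

    def test_constant_axis_error(self):
        pts = [fauna(f"s{i}", 0.715, 18.0 + i) for i in range(4)]
        with pytest.raises(ip.DegenerateInputError, match="constant"):
            ip.normalize(pts)

    def test_samples_missing_axis_excluded(self, harappa_study):
        import dataclasses
        broken = dataclasses.replace(harappa_study["fauna"][0],
                                     sample_id="broken", pb206_204=None)
        norm = ip.normalize(list(harappa_study["fauna"]) + [broken])
        assert "broken" not in {s.sample_id for s in norm.samples}


class TestDBSCANComponents:
    def test_coincident_points_one_cluster(self):
        pts = np.zeros((3, 2))
        assert len(set(ip.dbscan_components(pts, 0.5))) == 1

    def test_epsilon_below_min_distance_all_singletons(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0]])
        assert len(set(ip.dbscan_components(pts, 0.5))) == 4

    def test_chain_merging_1d_example(self):
        # {0,1,2} chain-connected at eps=1.5; {10} isolated
        pts = np.array([[0.0], [1.0], [2.0], [10.0]])
        labels = ip.dbscan_components(pts, 1.5)
        assert partition_sets(labels) == frozenset(
            {frozenset({0, 1, 2}), frozenset({3})})

    @given(seed=rng_points, n=st.integers(4, 30), eps_q=st.floats(0.01, 0.99))
    @settings(max_examples=60)
    def test_equals_single_linkage_cut(self, seed, n, eps_q):
        """minpts=1 DBSCAN is a single-linkage dendrogram cut at height eps."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        d = pdist(pts)
        eps = float(np.quantile(d, eps_q))
        ours = ip.dbscan_components(pts, eps)
        ref = fcluster(linkage(pts, method="single"), t=eps,
                       criterion="distance")
        assert partition_sets(ours) == partition_sets(ref)


class TestEpsilonBounds:
    def test_1d_example_mst_breakpoints(self):
        # points {0,1,3}: MST edges {1,2} -> bounds (1, 2*(1-1e-9))
        pts = np.array([[0.0], [1.0], [3.0]])
        lo, hi = ip.epsilon_bounds(pts)
        assert lo == 1.0
        assert hi == pytest.approx(2.0 * (1 - 1e-9), rel=0, abs=1e-15)

    def test_agrees_with_brute_force_grid(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(12, 2))
        lo, hi = ip.epsilon_bounds(pts)
        n = len(pts)
        # fine grid straddling each bound: non-trivial inside, trivial outside
        for eps, expect_nontrivial in [
            (lo * 0.999, False), (lo, True),
            (hi, True), (hi / (1 - 1e-9) * 1.001, False),
        ]:
            k = len(set(ip.dbscan_components(pts, eps)))
            assert (1 < k < n) == expect_nontrivial

    def test_two_points_error(self):
        with pytest.raises(ip.DegenerateInputError):
            ip.epsilon_bounds(np.array([[0.0], [1.0]]))

    def test_all_coincident_error(self):
        with pytest.raises(ip.DegenerateInputError):
            ip.epsilon_bounds(np.zeros((5, 2)))

    def test_equilateral_has_no_nontrivial_window(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        with pytest.raises(ip.DegenerateInputError):
            ip.epsilon_bounds(pts)


class TestSweep:
    def test_k_monotone_nonincreasing_and_nontrivial(self, harappa_report):
        ks = harappa_report.sweep.k_counts
        n = len(harappa_report.normalized.points)
        assert np.all(np.diff(ks) <= 0)
        assert np.all((ks > 1) & (ks < n))

    def test_breakpoints_are_mst_edges(self):
        """k(eps) only changes when eps crosses an MST edge weight."""
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import squareform
        mst_edges = np.sort(minimum_spanning_tree(
            csr_matrix(squareform(pdist(pts)))).data)
        eps_grid = np.linspace(0, mst_edges[-1] * 1.05, 400)
        ks = [len(set(ip.dbscan_components(pts, e))) for e in eps_grid]
        changes = [eps_grid[i] for i in range(1, len(ks)) if ks[i] != ks[i - 1]]
        for c in changes:
            assert np.any((mst_edges > eps_grid[0]) &
                          (np.abs(mst_edges - c) <= np.diff(eps_grid)[0]))
        # number of merges equals number of MST edges
        assert ks[0] - ks[-1] == len(mst_edges) - \
            np.searchsorted(mst_edges, 0, side="right")

    def test_plateau_at_three_well_separated_pairs(self):
        pts = np.array([[0, 0], [0.01, 0], [5, 0], [5.01, 0],
                        [10, 0], [10.01, 0]], dtype=float)
        sweep = ip.sweep_dbscan(pts, ip.SweepConfig(n_intervals=200))
        ks, counts = np.unique(sweep.k_counts, return_counts=True)
        assert counts[ks == 3][0] > 0.9 * sweep.k_counts.size

    def test_grid_inclusive_endpoints(self, harappa_report):
        sweep = harappa_report.sweep
        assert sweep.epsilons[0] == sweep.epsilon_low
        assert sweep.epsilons[-1] == sweep.epsilon_high
        assert len(sweep.epsilons) == 1000
        assert np.allclose(np.diff(sweep.epsilons),
                           np.diff(sweep.epsilons)[0])


def make_sweep(k_counts):
    k = np.asarray(k_counts)
    return SweepResult(epsilon_low=0.1, epsilon_high=1.0,
                       epsilons=np.linspace(0.1, 1.0, k.size),
                       partitions=np.zeros((k.size, 1), dtype=int),
                       k_counts=k)


class TestPoissonSelect:
    def test_constant_counts_closed_form(self):
        sel = ip.poisson_select(make_sweep([4] * 10))
        assert sel.lambda_hat == 4
        assert sel.ranked_k[0] == 4
        # e^-4 * 4^4 / 4!
        assert sel.likelihood_by_k[4] == pytest.approx(
            np.exp(-4) * 4**4 / 24, rel=1e-12)

    def test_pmf_normalizes(self):
        sel = ip.poisson_select(make_sweep([3, 4, 5, 6] * 25))
        lam = sel.lambda_hat
        from scipy.stats import poisson
        assert abs(poisson.pmf(np.arange(0, 201), lam).sum() - 1) < 1e-12

    def test_lambda_is_sweep_mean(self, harappa_report):
        sel = harappa_report.selection
        assert sel.lambda_hat == pytest.approx(
            float(np.mean(harappa_report.sweep.k_counts)), rel=1e-12)
        for k, lik in sel.likelihood_by_k.items():
            from scipy.stats import poisson
            assert lik == pytest.approx(float(poisson.pmf(k, sel.lambda_hat)),
                                        rel=1e-12)
            assert 0 < lik < 1

    def test_ranking_descending(self, harappa_report):
        liks = [harappa_report.selection.likelihood_by_k[k]
                for k in harappa_report.selection.ranked_k]
        assert all(a >= b for a, b in zip(liks, liks[1:]))


class TestRepresentativePartition:
    def test_modal_partition_on_plateau(self):
        pts = np.array([[0, 0], [0.01, 0], [5, 0], [5.01, 0],
                        [10, 0], [10.01, 0]], dtype=float)
        sweep = ip.sweep_dbscan(pts, ip.SweepConfig(n_intervals=100))
        part = ip.representative_partition(sweep, 3)
        assert partition_sets(part) == frozenset({
            frozenset({0, 1}), frozenset({2, 3}), frozenset({4, 5})})

    def test_absent_k_errors(self, harappa_report):
        with pytest.raises(ValueError):
            ip.representative_partition(harappa_report.sweep, 9999)

    def test_tie_broken_at_smaller_epsilon(self):
        # two distinct k=2 partitions each on one grid point
        pts = np.array([[0.0], [1.0], [2.5]])
        sweep = ip.sweep_dbscan(pts, ip.SweepConfig(n_intervals=2))
        ks = sweep.k_counts.tolist()
        assert ks[0] == 2
        part = ip.representative_partition(sweep, 2)
        assert (part == sweep.partitions[0]).all()


class TestKMeansScree:
    def test_sse_nonincreasing_and_zero_at_n(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        scree = ip.kmeans_scree(pts, k_max=8, restarts=20, seed=1)
        sse = [scree.sse_by_k[k] for k in sorted(scree.sse_by_k)]
        assert all(a >= b - 1e-9 for a, b in zip(sse, sse[1:]))
        assert scree.sse_by_k[8] == pytest.approx(0, abs=1e-12)

    def test_elbow_finds_three_blobs(self):
        rng = np.random.default_rng(42)
        blobs = [rng.normal(loc=c, scale=1.0, size=(20, 2))
                 for c in ([0, 0], [30, 0], [0, 30])]  # separation 30 SD
        pts = np.vstack(blobs)
        scree = ip.kmeans_scree(pts, k_max=8, restarts=20, seed=2)
        assert scree.elbow_k == 3


class TestLocalRange:
    def test_box_is_coordinatewise_minmax(self):
        samples = [fauna(f"s{i}", sr, pb) for i, (sr, pb) in enumerate(
            [(0.7180, 18.7), (0.7182, 18.8), (0.7179, 18.75),
             (0.7190, 18.72), (0.7185, 18.9)])]
        part = np.zeros(5, dtype=int)
        lr = ip.local_range(part, samples)
        assert lr.bounds["sr87_86"] == (0.7179, 0.7190)
        assert lr.bounds["pb206_204"] == (18.7, 18.9)
        assert set(lr.member_ids) == {f"s{i}" for i in range(5)}

    def test_singleton_cluster_degenerate_box(self):
        samples = [fauna("a", 0.718, 18.7), fauna("b", 0.711, 17.0),
                   fauna("c", 0.712, 17.1)]
        part = np.array([0, 1, 1])
        lr = ip.local_range(np.array([0, 1, 2]), samples)  # all singletons
        assert lr.bounds["sr87_86"][0] == lr.bounds["sr87_86"][1]

    def test_size_tie_broken_by_smaller_sr_sd(self):
        tight = [fauna("t1", 0.71800, 18.7), fauna("t2", 0.71801, 18.8)]
        loose = [fauna("l1", 0.71100, 17.0), fauna("l2", 0.71400, 17.1)]
        part = np.array([0, 0, 1, 1])
        lr = ip.local_range(part, tight + loose)
        assert set(lr.member_ids) == {"t1", "t2"}

    def test_members_classify_local_against_own_range(self, harappa_report):
        for sid in harappa_report.local.member_ids:
            s = next(s for s in harappa_report.normalized.samples
                     if s.sample_id == sid)
            call = ip.classify_local(s, harappa_report.local)
            assert call.is_local and call.box_distance == 0


class TestPoolBaseline:
    def test_idempotent(self, farmana_study):
        seds = farmana_study["sediments"]
        once = ip.pool_baseline([seds])
        twice = ip.pool_baseline([seds, seds])
        assert once.bounds == twice.bounds

    def test_envelope_of_disjoint_boxes(self):
        g1 = [fauna("a", 0.711, 17.0), fauna("b", 0.712, 17.5)]
        g2 = [fauna("c", 0.718, 18.7), fauna("d", 0.719, 18.9)]
        lr = ip.pool_baseline([g1, g2])
        assert lr.bounds["sr87_86"] == (0.711, 0.719)
        assert lr.bounds["pb206_204"] == (17.0, 18.9)

    def test_empty_union_errors(self):
        with pytest.raises(ValueError):
            ip.pool_baseline([[], []])
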