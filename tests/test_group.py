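"""Group t-test, thresholding, clustering, sign-flip permutation, FWE."""

import numpy as np
import pytest
from scipy import sparse, stats

import surflight as sl
from surflight.group import signflip_null_subject


@pytest.fixture(scope="module")
def sphere4_adj():
    low = sl.subdivide(sl.base_icosahedron(), 4)
    return low, sl.build_adjacency(low)


class TestGroupTtest:
    def test_all_at_chance_gives_zero(self):
        maps = [np.full(10, 0.5) + 0.1 * np.array([1, -1, 0, 1, -1, 0, 1, -1, 0, 0]) * s
                for s in (1, -1, 0)]
        # vertex 2, 5, 8, 9 exactly chance in every map -> t = 0 there
        t = sl.group_ttest(maps, chance=0.5)
        assert t.t[2] == 0.0 and t.t[9] == 0.0
        assert t.df == 2

    def test_textbook_value(self):
        t = sl.group_ttest([np.array([0.6]), np.array([0.7]),
                            np.array([0.8])], chance=0.5)
        assert t.t[0] == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-12)
        assert t.t[0] == pytest.approx(3.4641016, abs=1e-6)

    def test_agrees_with_reference_routine(self, rng):
        maps = rng.uniform(0.3, 0.9, size=(12, 80))
        t = sl.group_ttest(list(maps), chance=0.5)
        ref = stats.ttest_1samp(maps, 0.5, axis=0)
        assert np.abs(t.t - ref.statistic).max() < 1e-9

    def test_zero_variance_infinities(self):
        maps = [np.array([1.0, 0.2, 0.5])] * 4
        t = sl.group_ttest(maps, chance=0.5)
        assert t.t[0] == np.inf
        assert t.t[1] == -np.inf
        assert t.t[2] == 0.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            sl.group_ttest([np.zeros(5)], chance=0.5)


class TestThresholdMap:
    def test_marks_p_below_cutoff(self, rng):
        t = sl.TMap(t=rng.normal(0, 3, size=200), df=9, chance=0.5)
        marked = sl.threshold_map(t, vertexwise=3.0)
        p = stats.t.sf(t.t, df=9)
        assert np.array_equal(marked, p < 1e-3)

    def test_zero_tmap_empty(self):
        t = sl.TMap(t=np.zeros(50), df=7, chance=0.5)
        assert not sl.threshold_map(t, 3.0).any()

    def test_monotone_in_threshold(self, rng):
        t = sl.TMap(t=rng.normal(0, 3, size=300), df=9, chance=0.5)
        loose = sl.threshold_map(t, 2.0)
        strict = sl.threshold_map(t, 3.0)
        assert np.all(loose[strict])  # strict is a subset of loose

    def test_infinite_t_always_marked(self):
        t = sl.TMap(t=np.array([np.inf, -np.inf, 0.0]), df=5, chance=0.5)
        assert sl.threshold_map(t, 3.0).tolist() == [True, False, False]


def _unionfind_sizes(binary, adjacency):
    """Independent oracle: connected components via sparse graph labelling."""
    n = len(binary)
    rows, cols = [], []
    for i in range(n):
        if not binary[i]:
            continue
        for j in adjacency[i]:
            if binary[j]:
                rows.append(i)
                cols.append(j)
    g = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, lab = sparse.csgraph.connected_components(g, directed=False)
    sizes = [int(np.sum((lab == c) & binary)) for c in range(n_comp)]
    return sorted(s for s in sizes if s > 0)


class TestFindClusters:
    def test_empty_map(self, sphere4_adj):
        low, adj = sphere4_adj
        assert sl.find_clusters(np.zeros(low.n_vertices, bool), adj) == []

    def test_all_marked_single_cluster(self, sphere4_adj):
        low, adj = sphere4_adj
        clusters = sl.find_clusters(np.ones(low.n_vertices, bool), adj)
        assert len(clusters) == 1
        assert clusters[0].size == low.n_vertices

    def test_matches_unionfind_on_random_maps(self, sphere4_adj):
        low, adj = sphere4_adj
        rng = np.random.default_rng(99)
        for _ in range(1000):
            binary = rng.random(low.n_vertices) < rng.uniform(0.05, 0.5)
            got = sorted(c.size for c in sl.find_clusters(binary, adj))
            assert got == _unionfind_sizes(binary, adj)

    def test_every_marked_vertex_in_exactly_one_cluster(self, sphere4_adj):
        low, adj = sphere4_adj
        rng = np.random.default_rng(5)
        binary = rng.random(low.n_vertices) < 0.3
        clusters = sl.find_clusters(binary, adj)
        covered = np.concatenate([c.vertices for c in clusters])
        assert sorted(covered.tolist()) == np.flatnonzero(binary).tolist()

    def test_peak_within_cluster(self, sphere4_adj):
        low, adj = sphere4_adj
        rng = np.random.default_rng(6)
        tmap = sl.TMap(t=rng.normal(size=low.n_vertices), df=9, chance=0.5)
        binary = tmap.t > 0.5
        for c in sl.find_clusters(binary, adj, tmap):
            assert c.peak_vertex in c.vertices
            assert c.peak_t == tmap.t[c.vertices].max()


class TestSignflipNull:
    def test_reproducible(self, sphere4_adj, rng):
        low, adj = sphere4_adj
        tmap = sl.TMap(t=rng.normal(0, 3, low.n_vertices), df=9, chance=0.5)
        spec = sl.ThresholdSpec(n_perm=100, fwe_alpha=0.05, seed=12)
        a = sl.signflip_null(tmap, adj, spec)
        b = sl.signflip_null(tmap, adj, spec)
        assert np.array_equal(a.max_sizes, b.max_sizes)

    def test_subthreshold_tmap_all_zero(self, sphere4_adj):
        low, adj = sphere4_adj
        tmap = sl.TMap(t=np.full(low.n_vertices, 0.5), df=9, chance=0.5)
        null = sl.signflip_null(tmap, adj,
                                sl.ThresholdSpec(n_perm=50, fwe_alpha=0.1))
        assert np.all(null.max_sizes == 0)

    def test_identity_permutation_hook(self, sphere4_adj, rng):
        low, adj = sphere4_adj
        tmap = sl.TMap(t=rng.normal(0, 4, low.n_vertices), df=9, chance=0.5)
        observed = sl.threshold_map(tmap, 3.0)
        obs_max = max((c.size for c in sl.find_clusters(observed, adj)),
                      default=0)
        null = sl.signflip_null(tmap, adj,
                                sl.ThresholdSpec(n_perm=20, fwe_alpha=0.1),
                                flip_prob=0.0)
        assert np.all(null.max_sizes == obs_max)

    def test_sorted_descending(self, sphere4_adj, rng):
        low, adj = sphere4_adj
        tmap = sl.TMap(t=rng.normal(0, 3, low.n_vertices), df=9, chance=0.5)
        null = sl.signflip_null(tmap, adj,
                                sl.ThresholdSpec(n_perm=80, fwe_alpha=0.05))
        assert np.all(np.diff(null.max_sizes.astype(int)) <= 0)

    def test_global_sign_inversion_symmetry(self, sphere4_adj, rng):
        # flipping every t sign leaves the null distribution statistically
        # unchanged; compare means across many permutations
        low, adj = sphere4_adj
        t = rng.normal(0, 4, low.n_vertices)
        spec = sl.ThresholdSpec(n_perm=400, fwe_alpha=0.05, seed=7)
        a = sl.signflip_null(sl.TMap(t, 9, 0.5), adj, spec)
        b = sl.signflip_null(sl.TMap(-t, 9, 0.5), adj, spec)
        assert abs(a.max_sizes.mean() - b.max_sizes.mean()) < 0.5


class TestFweFilter:
    def test_rank_arithmetic(self):
        spec = sl.ThresholdSpec(fwe_alpha=0.01, n_perm=2000)
        assert spec.threshold_rank == 20

    def test_alpha_nperm_too_small(self):
        with pytest.raises(ValueError):
            sl.ThresholdSpec(fwe_alpha=0.001, n_perm=100)

    def test_strict_inequality_retention(self):
        null = sl.NullDistribution(
            max_sizes=np.array(sorted([7] * 30 + [0] * 70, reverse=True)),
            threshold_rank=10)
        assert null.threshold_size == 7
        clusters = [sl.Cluster(np.arange(s), 1.0, 0) for s in (7, 8, 3)]
        surviving = sl.fwe_filter(clusters, null)
        assert [c.size for c in surviving] == [8]

    def test_zero_null_everything_survives(self):
        null = sl.NullDistribution(max_sizes=np.zeros(100, int),
                                   threshold_rank=5)
        clusters = [sl.Cluster(np.arange(2), 1.0, 0)]
        assert sl.fwe_filter(clusters, null) == clusters


class TestClusterReport:
    def test_single_cluster_row(self, sphere4_adj, rng):
        low, adj = sphere4_adj
        tmap = sl.TMap(t=rng.normal(size=low.n_vertices), df=9, chance=0.5)
        c = sl.Cluster(np.array([3, 4, 5]), float(tmap.t[[3, 4, 5]].max()),
                       int([3, 4, 5][np.argmax(tmap.t[[3, 4, 5]])]))
        df = sl.cluster_report([c], tmap)
        assert len(df) == 1
        assert df.loc[0, "peak_t"] == tmap.t[[3, 4, 5]].max()

    def test_sizes_sum_and_mm2_additivity(self, sphere4_adj, rng):
        low, adj = sphere4_adj
        tmap = sl.TMap(t=rng.normal(0, 3, low.n_vertices), df=9, chance=0.5)
        binary = sl.threshold_map(tmap, 1.0)
        clusters = sl.find_clusters(binary, adj, tmap)
        areas = rng.uniform(1.0, 3.0, low.n_vertices)
        df = sl.cluster_report(clusters, tmap, coords=None,
                               area_per_vertex=areas)
        assert df["size_vertices"].sum() == int(binary.sum())
        for _, row in df.iterrows():
            members = next(c.vertices for c in clusters
                           if c.peak_vertex == row["peak_vertex"])
            assert row["size_mm2"] == pytest.approx(areas[members].sum())

    def test_sorted_by_size(self, sphere4_adj, rng):
        low, adj = sphere4_adj
        tmap = sl.TMap(t=rng.normal(0, 2, low.n_vertices), df=9, chance=0.5)
        clusters = sl.find_clusters(sl.threshold_map(tmap, 1.0), adj, tmap)
        df = sl.cluster_report(clusters, tmap)
        if len(df) > 1:
            assert np.all(np.diff(df["size_vertices"]) <= 0)


class TestClusterPermutationEstimator:
    def test_full_chain_and_modes(self, sphere4_adj, rng):
        low, adj = sphere4_adj
        maps = [np.clip(0.5 + rng.normal(0, 0.05, low.n_vertices), 0, 1)
                for _ in range(8)]
        # inject a coherent bump around vertex 0
        bump = np.arccos(np.clip(low.vertices @ low.vertices[0], -1, 1)) < 0.5
        maps = [m + 0.4 * bump for m in maps]
        for mode in ("tmap", "subject"):
            est = sl.ClusterPermutation(adj, vertexwise=3.0, fwe_alpha=0.05,
                                        n_perm=200, mode=mode,
                                        random_state=1)
            est.fit(maps, chance=0.5)
            assert est.tmap_.df == 7
            assert len(est.surviving_) >= 1
            assert any(0 in c.vertices for c in est.surviving_)

    def test_subject_mode_null_distribution(self, sphere4_adj, rng):
        low, adj = sphere4_adj
        maps = [0.5 + rng.normal(0, 0.05, low.n_vertices) for _ in range(10)]
        spec = sl.ThresholdSpec(vertexwise=2.0, fwe_alpha=0.05, n_perm=100,
                                seed=3)
        null = signflip_null_subject(maps, adj, spec, chance=0.5)
        assert len(null.max_sizes) == 100
        assert np.all(np.diff(null.max_sizes.astype(int)) <= 0)
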