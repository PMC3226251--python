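import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from assaynet import (
    DistanceProfiler,
    bfs_distances,
    degree_cdf,
    enrichment,
    fraction_profile,
    map_symbols,
    ranksum,
)


class TestMapSymbols:
    def test_all_present(self, ppi_small):
        symbols = sorted(ppi_small.nodes)[:5]
        mapped, unmapped = map_symbols(symbols, ppi_small)
        assert mapped == set(symbols) and unmapped == []

    def test_empty_input(self, ppi_small):
        assert map_symbols([], ppi_small) == (set(), [])

    def test_unmapped_reported_in_order(self, ppi_small):
        present = sorted(ppi_small.nodes)[:3]
        symbols = [present[0], "ZZZ2", present[1], "ZZZ1", present[2]]
        mapped, unmapped = map_symbols(symbols, ppi_small)
        assert len(mapped) == 3
        assert unmapped == ["ZZZ2", "ZZZ1"]


class TestBfs:
    def test_path_distances(self):
        g = nx.path_graph(["a", "b", "c"])
        assert bfs_distances(g, "a") == {"a": 0, "b": 1, "c": 2}

    def test_isolated_source(self):
        g = nx.Graph()
        g.add_node("x")
        assert bfs_distances(g, "x") == {"x": 0}

    def test_unknown_source_raises(self, ppi_small):
        with pytest.raises(KeyError):
            bfs_distances(ppi_small, "NOT_A_GENE")

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_floyd_warshall(self, seed):
        g = nx.gnp_random_graph(30, 0.1, seed=seed)
        fw = nx.floyd_warshall(g)
        src = seed % 30
        d = bfs_distances(g, src)
        for node in g:
            if math.isinf(fw[src][node]):
                assert node not in d
            else:
                assert d[node] == fw[src][node]


class TestFractionProfile:
    def test_all_markers(self, ppi_small):
        seed = sorted(ppi_small.nodes)[0]
        prof = fraction_profile(ppi_small, seed, set(ppi_small.nodes))
        assert all(v == 1.0 for v in prof.values())

    def test_no_markers(self, ppi_small):
        seed = sorted(ppi_small.nodes)[0]
        prof = fraction_profile(ppi_small, seed, set())
        assert all(v == 0.0 for v in prof.values())

    def test_star_hand_count(self):
        g = nx.star_graph(8)  # center 0, leaves 1..8
        assert fraction_profile(g, 0, {1, 2, 3}) == {1: 3 / 8}

    def test_seed_excluded_from_own_shells(self):
        g = nx.path_graph(4)
        prof = fraction_profile(g, 0, {0})
        assert all(v == 0.0 for v in prof.values())

    def test_shell_totals_cover_reachable_nodes(self, ppi_small):
        seed = sorted(ppi_small.nodes)[10]
        dist = bfs_distances(ppi_small, seed)
        prof = DistanceProfiler(ppi_small)
        totals, _ = prof.shell_counts(seed, prof.marker_mask([]))
        assert totals[1:].sum() == len(dist) - 1

    def test_profiler_agrees_with_direct_profile(self, ppi_small):
        """The cached vectorised path must equal the plain BFS one."""
        nodes = sorted(ppi_small.nodes)
        markers = set(nodes[::7])
        prof = DistanceProfiler(ppi_small)
        mask = prof.marker_mask(markers)
        for seed in nodes[:10]:
            totals, hits = prof.shell_counts(seed, mask)
            direct = fraction_profile(ppi_small, seed, markers)
            derived = {d: hits[d] / totals[d]
                       for d in range(1, len(totals)) if totals[d] > 0}
            assert derived == pytest.approx(direct)


class TestDegreeCdf:
    def test_uniform_degree(self):
        g = nx.circulant_graph(12, [1, 2])  # all degrees 4... use complete
        g = nx.complete_graph(6)            # all degrees 5
        cdf = degree_cdf(g, list(g.nodes), range(1, 8))
        for k in range(1, 6):
            assert cdf[k] == 100.0
        assert cdf[6] == 0.0 and cdf[7] == 0.0

    def test_hand_count(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("c", "a")])
        # degrees: a=2, b=2, c=3, d=1
        cdf = degree_cdf(g, {"b", "c", "d"}, range(1, 5))
        assert cdf[1] == 100.0
        assert cdf[2] == pytest.approx(200 / 3)
        assert cdf[3] == pytest.approx(100 / 3)
        assert cdf[4] == 0.0

    def test_non_increasing(self, ppi_small):
        cdf = degree_cdf(ppi_small, set(list(ppi_small.nodes)[:50]))
        vals = [cdf[k] for k in sorted(cdf)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_empty_set_raises(self, ppi_small):
        with pytest.raises(ValueError):
            degree_cdf(ppi_small, set())


class TestRanksum:
    def test_exact_small_sample(self):
        # enumeration over all 6 rank assignments gives P = 1/3
        assert ranksum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples(self):
        assert ranksum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_large_shift_vanishing_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        assert ranksum(x, x + 2.0) < 1e-10

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])

    def test_agrees_with_exact_mannwhitney_all_4_4_partitions(self):
        """Exact-enumeration path vs scipy's exact Mann-Whitney over every
        partition of 8 distinct values into two samples of 4."""
        values = [1.0, 2.5, 3.0, 4.7, 5.1, 6.0, 7.2, 9.9]
        for idx in itertools.combinations(range(8), 4):
            x = [values[i] for i in idx]
            y = [values[i] for i in range(8) if i not in idx]
            expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="exact").pvalue
            assert ranksum(x, y) == pytest.approx(expected)

    def test_normal_approximation_tracks_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.4, 1, 55)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert ranksum(x, y) == pytest.approx(expected, rel=1e-6)


class TestEnrichment:
    def test_empty_inputs_rejected(self, ppi_small):
        some = set(list(ppi_small.nodes)[:5])
        with pytest.raises(ValueError):
            enrichment(ppi_small, set(), some, n_random=10, rng_seed=0)
        with pytest.raises(ValueError):
            enrichment(ppi_small, some, set(), n_random=10, rng_seed=0)

    def test_fractions_within_unit_interval(self, ppi_small):
        nodes = sorted(ppi_small.nodes)
        res = enrichment(ppi_small, nodes[:20], nodes[::5],
                         n_random=200, rng_seed=1)
        for d in res.distances:
            assert 0.0 <= res.mean_fraction[d] <= 1.0
            assert 0.0 < res.p_value[d] <= 1.0

    def test_uniform_markers_mean_approaches_global_fraction(self, ppi_large):
        """With markers drawn uniformly, the seed-averaged shell fraction
        converges on the global marker fraction as seeds are added."""
        nodes = sorted(ppi_large.nodes)
        rng = np.random.default_rng(12)
        markers = set(rng.choice(nodes, size=200, replace=False))
        global_frac = len(markers) / len(nodes)
        prof = DistanceProfiler(ppi_large)
        errs = []
        for n_seeds in (20, 400):
            rep = []
            for _ in range(10):
                seeds = rng.choice(nodes, size=n_seeds, replace=False)
                res = enrichment(ppi_large, seeds, markers, n_random=10,
                                 rng_seed=5, profiler=prof)
                rep.append(abs(res.mean_fraction[2] - global_frac))
            errs.append(np.mean(rep))
        assert errs[1] < errs[0]
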