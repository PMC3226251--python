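import networkx as nx
import numpy as np
import pytest

from assaynet import (
    ConfigError,
    SyntheticConfig,
    degree_distribution,
    fit_power_law,
    gen_activity,
    gen_markers,
    gen_ppi,
    jaccard,
    project,
    build_bipartite,
)


class TestConfig:
    def test_defaults_valid(self):
        SyntheticConfig()

    @pytest.mark.parametrize("kwargs", [
        {"n_proteins": 0},
        {"n_proteins": 3, "attach_m": 3},
        {"proximity_rho": 0.5},
        {"p_in": 1.5},
        {"p_in": 0.1, "p_out": 0.2},
        {"n_clusters": 100, "n_assays": 10},
        {"n_essential": 1500, "n_drug_targets": 600},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SyntheticConfig(**kwargs)


class TestGenPPI:
    def test_size_and_connectivity(self):
        g = gen_ppi(100, 2, rng_seed=1)
        assert g.number_of_nodes() == 100
        assert nx.is_connected(g)
        assert not any(u == v for u, v in g.edges())

    def test_determinism(self):
        a = gen_ppi(100, 2, rng_seed=1)
        b = gen_ppi(100, 2, rng_seed=1)
        assert set(a.edges()) == set(b.edges())

    def test_symbols_zero_padded(self):
        g = gen_ppi(10, 2, rng_seed=0)
        assert sorted(g.nodes)[0] == "G000001"

    def test_heavy_tail_slope(self, ppi_large):
        """Preferential attachment at n=2000, m=3 yields a log-log degree
        slope in the known heavy-tail range."""
        fit = fit_power_law(degree_distribution(ppi_large))
        assert -3.5 < fit.exponent < -1.5

    def test_invalid_sizes_raise(self):
        with pytest.raises(ConfigError):
            gen_ppi(2, 2, rng_seed=0)


def _distance1_fraction(ppi, markers):
    near = set(markers.essential)
    for e in markers.essential:
        near.update(ppi.neighbors(e))
    if not markers.bioassay_targets:
        return 0.0
    return len(markers.bioassay_targets & near) / len(markers.bioassay_targets)


class TestGenMarkers:
    def test_rho_one_matches_uniform_null(self, ppi_large):
        """With rho = 1 the mean near-essential fraction of bioassay
        targets over 50 seeds must sit within 3 binomial SD of the pool
        fraction (the exact uniform expectation)."""
        fracs, expected = [], []
        for seed in range(50):
            cfg = SyntheticConfig(proximity_rho=1.0, rng_seed=seed)
            m = gen_markers(ppi_large, cfg)
            near = set(m.essential)
            for e in m.essential:
                near.update(ppi_large.neighbors(e))
            pool = set(ppi_large.nodes) - m.drug_targets
            expected.append(len(near & pool) / len(pool))
            fracs.append(_distance1_fraction(ppi_large, m))
        n_draws = 50 * len(m.bioassay_targets)
        p = np.mean(expected)
        sd = np.sqrt(p * (1 - p) / n_draws)
        assert abs(np.mean(fracs) - p) < 3 * sd

    def test_rho_ten_enriches_near_essential(self, ppi_large):
        """rho = 10 puts bioassay targets inside distance 1 of essential
        genes more often than rho = 1, in ≥95% of 100 seeded replicates."""
        wins = 0
        for seed in range(100):
            null = gen_markers(ppi_large,
                               SyntheticConfig(proximity_rho=1.0, rng_seed=seed))
            plant = gen_markers(ppi_large,
                                SyntheticConfig(proximity_rho=10.0, rng_seed=seed))
            if _distance1_fraction(ppi_large, plant) > \
               _distance1_fraction(ppi_large, null):
                wins += 1
        assert wins >= 95

    def test_zero_bioassay_targets_ok(self, ppi_small):
        cfg = SyntheticConfig(n_proteins=300, n_essential=30,
                              n_drug_targets=20, n_disease=20,
                              n_bioassay_targets=0, rng_seed=0)
        m = gen_markers(ppi_small, cfg)
        assert m.bioassay_targets == frozenset()

    def test_disjoint_from_drug_targets_by_default(self, ppi_small):
        cfg = SyntheticConfig(n_proteins=300, n_essential=30,
                              n_drug_targets=50, n_disease=20,
                              n_bioassay_targets=40, rng_seed=3)
        m = gen_markers(ppi_small, cfg)
        assert not (m.bioassay_targets & m.drug_targets)

    def test_essential_genes_favour_hubs(self, ppi_large):
        cfg = SyntheticConfig(rng_seed=5)
        m = gen_markers(ppi_large, cfg)
        deg_essential = np.mean([ppi_large.degree(n) for n in m.essential])
        deg_all = np.mean([d for _, d in ppi_large.degree()])
        assert deg_essential > deg_all

    def test_oversized_request_raises(self, ppi_small):
        cfg = SyntheticConfig(n_proteins=300, n_essential=10,
                              n_drug_targets=290, n_disease=5,
                              n_bioassay_targets=50, rng_seed=0)
        with pytest.raises(ConfigError):
            gen_markers(ppi_small, cfg)

    def test_determinism(self, ppi_small):
        cfg = SyntheticConfig(n_proteins=300, n_essential=30,
                              n_drug_targets=20, n_disease=20,
                              n_bioassay_targets=15, rng_seed=9)
        assert gen_markers(ppi_small, cfg) == gen_markers(ppi_small, cfg)


class TestGenActivity:
    def test_block_structure_gives_two_components(self):
        cfg = SyntheticConfig(n_assays=10, n_compounds=40, n_clusters=2,
                              p_in=1.0, p_out=0.0, rng_seed=0)
        table = gen_activity(cfg)
        g = project(build_bipartite(table), min_jaccard=0.01)
        assert nx.number_connected_components(g) == 2

    def test_all_zero_probabilities_give_no_pairs(self):
        cfg = SyntheticConfig(n_assays=10, n_compounds=40, n_clusters=2,
                              p_in=0.0, p_out=0.0, rng_seed=0)
        assert gen_activity(cfg).pairs == []

    def test_within_cluster_jaccard_exceeds_between(self):
        cfg = SyntheticConfig(n_assays=50, n_compounds=500, n_clusters=5,
                              p_in=0.3, p_out=0.005, rng_seed=3)
        table = gen_activity(cfg)
        sets: dict[str, set] = {}
        for a, c in table.pairs:
            sets.setdefault(a, set()).add(c)
        assays = sorted(sets)
        cluster = {a: (int(a[1:]) - 1) % cfg.n_clusters for a in assays}
        within, between = [], []
        for i, u in enumerate(assays):
            for v in assays[i + 1:]:
                j = jaccard(sets[u], sets[v])
                (within if cluster[u] == cluster[v] else between).append(j)
        assert np.mean(within) > np.mean(between)

    def test_metadata_consistent(self, ppi_small):
        cfg = SyntheticConfig(n_proteins=300, n_essential=30,
                              n_drug_targets=20, n_disease=20,
                              n_bioassay_targets=15, rng_seed=4)
        markers = gen_markers(ppi_small, cfg)
        table = gen_activity(cfg, markers)
        for info in table.assay_meta.values():
            if info.assay_type == "target_based":
                assert info.target_symbol in markers.bioassay_targets
            else:
                assert info.target_symbol is None

    def test_determinism(self):
        cfg = SyntheticConfig(rng_seed=6)
        assert gen_activity(cfg).pairs == gen_activity(cfg).pairs
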