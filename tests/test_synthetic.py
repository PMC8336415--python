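import numpy as np
import pytest

from clockscape import (SimulationConfig, default_pair_table,
                        default_species_table, global_align, make_order_b,
                        percent_identity, simulate_divergences,
                        simulate_gc_garp, simulate_orders, simulate_rates,
                        simulate_sequences)
from clockscape.acceleration import subtelomere_labels
from clockscape.synthetic_data import pair_multiplier


@pytest.fixture(scope="module")
def default_truth():
    config = SimulationConfig()
    rng = np.random.default_rng(0)
    return config, simulate_rates(config, rng)


class TestDesignTables:
    def test_times_follow_clade_structure(self, pairs120):
        by_class = pairs120.groupby("pair_class")["t"]
        assert set(by_class.get_group("Eutherian-Metatherian")) == {158.5}
        assert set(by_class.get_group("intra-Metatherian")) == {60.0}
        assert set(by_class.get_group("intra-Eutherian")) == {70.0, 96.0, 104.0}

    def test_times_are_ultrametric_consistent(self, species16, pairs120):
        # cross-clade times exceed within-clade times for every triple level
        clade = dict(zip(species16["species_id"], species16["clade"]))
        for row in pairs120.itertuples(index=False):
            same_clade = clade[row.species_a] == clade[row.species_b]
            assert (row.t <= 70.0) == same_clade or row.pair_class != "intra-Eutherian"


class TestOrders:
    def test_human_like_partition(self, default_truth):
        _, truth = default_truth
        assert truth.order_a.n_genes == 15727
        assert len(truth.order_a.chromosomes) == 23

    def test_opossum_like_partition(self, default_truth):
        _, truth = default_truth
        assert truth.order_b.n_genes == 15727
        assert len(truth.order_b.chromosomes) == 9

    def test_orders_are_permutations_of_one_gene_set(self, default_truth):
        _, truth = default_truth
        assert set(truth.order_a.gene_ids) == set(truth.order_b.gene_ids)

    def test_identity_mode_preserves_everything(self, default_truth):
        _, truth = default_truth
        rng = np.random.default_rng(1)
        same = make_order_b(truth.order_a, "identity", rng)
        assert same.gene_ids == truth.order_a.gene_ids
        assert same.chromosomes == truth.order_a.chromosomes

    def test_preserving_mode_keeps_subtelomeric_genes_subtelomeric(
            self, default_truth):
        _, truth = default_truth
        rng = np.random.default_rng(2)
        order_c = make_order_b(truth.order_a, "subtelomere-preserving", rng)
        sub_a = subtelomere_labels(truth.order_a, 50)
        sub_c = subtelomere_labels(order_c, 50)
        genes_a = {truth.order_a.gene_ids[i] for i in np.flatnonzero(sub_a)}
        genes_c = {order_c.gene_ids[i] for i in np.flatnonzero(sub_c)}
        kept = len(genes_a & genes_c) / len(genes_a)
        assert kept >= 0.8

    def test_reshuffled_mode_overlap_matches_uniform_expectation(
            self, default_truth):
        _, truth = default_truth
        sub_a = subtelomere_labels(truth.order_a, 50)
        sub_b = subtelomere_labels(truth.order_b, 50)
        genes_a = {truth.order_a.gene_ids[i] for i in np.flatnonzero(sub_a)}
        genes_b = {truth.order_b.gene_ids[i] for i in np.flatnonzero(sub_b)}
        observed = len(genes_a & genes_b)
        expected = len(genes_a) * len(genes_b) / truth.order_a.n_genes
        # hypergeometric SD ~ sqrt(expected)
        assert abs(observed - expected) < 5 * np.sqrt(expected)


class TestRates:
    def test_same_seed_identical_rates(self):
        config = SimulationConfig()
        a = simulate_rates(config, np.random.default_rng(3))
        b = simulate_rates(config, np.random.default_rng(3))
        np.testing.assert_array_equal(a.k, b.k)
        assert a.accelerated == b.accelerated

    def test_sigma_zero_degenerates_to_single_rate(self):
        config = SimulationConfig(sigma_log_rate=0.0)
        truth = simulate_rates(config, np.random.default_rng(4))
        np.testing.assert_allclose(truth.k, config.mean_clock)

    def test_default_spread_is_about_two_orders_of_magnitude(
            self, default_truth):
        _, truth = default_truth
        p1, p99 = np.percentile(truth.k, [1, 99])
        assert 50 <= p99 / p1 <= 500

    def test_planted_blocks_raise_only_their_lineage(self, default_truth):
        config, truth = default_truth
        idx = truth.order_a.rank
        e_idx = [idx[g] for g in truth.accelerated["Eutheria"]]
        assert (truth.multiplier["Eutheria"][e_idx] > 1).all()
        others = np.setdiff1d(np.arange(truth.order_a.n_genes), e_idx)
        assert (truth.multiplier["Eutheria"][others] == 1).all()

    def test_cross_lineage_multiplier_is_branch_average(self, default_truth):
        _, truth = default_truth
        cross = pair_multiplier(truth, "Eutheria", "Metatheria")
        np.testing.assert_allclose(
            cross, 0.5 * (truth.multiplier["Eutheria"]
                          + truth.multiplier["Metatheria"]))


class TestDivergences:
    def test_zero_time_gives_zero_pd(self, species16):
        config = SimulationConfig(n_genes=200, chrom_weights_a=(1, 1),
                                  chrom_names_a=("chr1", "chr2"),
                                  chrom_weights_b=(1,), chrom_names_b=("chr1",),
                                  acceleration_blocks=[])
        rng = np.random.default_rng(5)
        truth = simulate_rates(config, rng)
        pairs = default_pair_table().copy()
        pairs["t"] = 1e-12
        matrix = simulate_divergences(truth, pairs, config, rng, species16)
        np.testing.assert_array_equal(matrix.values, 0.0)

    def test_pd_increases_with_divergence_time(self, small_sim_config,
                                               species16):
        rng = np.random.default_rng(6)
        truth = simulate_rates(small_sim_config, rng)
        pairs = default_pair_table()
        matrix = simulate_divergences(truth, pairs, small_sim_config, rng,
                                      species16)
        mean_by_t = {t: matrix.values[:, (pairs["t"] == t).to_numpy()].mean()
                     for t in sorted(pairs["t"].unique())}
        times = sorted(mean_by_t)
        assert all(mean_by_t[a] < mean_by_t[b]
                   for a, b in zip(times, times[1:]))

    def test_full_design_has_1887240_cells(self, default_truth, species16,
                                           pairs120):
        config, truth = default_truth
        rng = np.random.default_rng(7)
        matrix = simulate_divergences(truth, pairs120, config, rng, species16)
        assert matrix.values.size == 15727 * 120 == 1887240


class TestGcGarp:
    def test_default_coupling_lands_near_rho(self, default_truth, species16):
        config, truth = default_truth
        rng = np.random.default_rng(8)
        gc, garp = simulate_gc_garp(config, truth, rng, species16)
        r = np.corrcoef(gc["Felis_catus"], garp["Felis_catus"])[0, 1]
        assert abs(r - 0.93) < 0.03

    def test_lineage_blocks_elevate_gc_for_own_lineage_only(
            self, default_truth, species16):
        config, truth = default_truth
        rng = np.random.default_rng(9)
        gc, _ = simulate_gc_garp(config, truth, rng, species16)
        e_genes = sorted(truth.accelerated["Eutheria"])
        bg = sorted(set(truth.gene_ids) - truth.accelerated["Eutheria"]
                    - truth.accelerated["Metatheria"])
        cat_boost = gc.loc[e_genes, "Felis_catus"].mean() - gc.loc[bg, "Felis_catus"].mean()
        koala_boost = (gc.loc[e_genes, "Phascolarctos_cinereus"].mean()
                       - gc.loc[bg, "Phascolarctos_cinereus"].mean())
        assert cat_boost > 2.0
        assert abs(koala_boost) < 1.0


class TestSequences:
    def _tiny(self):
        return SimulationConfig(n_genes=20, chrom_weights_a=(1,),
                                chrom_names_a=("chr1",), chrom_weights_b=(1,),
                                chrom_names_b=("chr1",),
                                acceleration_blocks=[])

    def test_rate_zero_keeps_all_species_identical(self, species16):
        config = self._tiny()
        rng = np.random.default_rng(10)
        truth = simulate_rates(config, rng)
        truth.k[:] = 0.0
        seqs = simulate_sequences(truth, config, rng, n_genes=3, length=60)
        for gene in ("g00001", "g00002", "g00003"):
            unique = {seqs[sp][gene] for sp in seqs}
            assert len(unique) == 1

    def test_zero_rate_pd_through_full_aligner(self, species16):
        config = self._tiny()
        rng = np.random.default_rng(11)
        truth = simulate_rates(config, rng)
        truth.k[:] = 0.0
        seqs = simulate_sequences(truth, config, rng, n_genes=1, length=80)
        a = seqs["Felis_catus"]["g00001"]
        b = seqs["Monodelphis_domestica"]["g00001"]
        assert percent_identity(global_align(a, b)) == 100.0

    def test_end_to_end_divergence_tracks_expected_kt(self, species16):
        # aligner-measured PD against k*t across genes: origin-anchored slope
        # near 1 at moderate divergence (multiple hits stay negligible)
        config = SimulationConfig(n_genes=60, chrom_weights_a=(1,),
                                  chrom_names_a=("chr1",),
                                  chrom_weights_b=(1,), chrom_names_b=("chr1",),
                                  acceleration_blocks=[])
        rng = np.random.default_rng(12)
        truth = simulate_rates(config, rng)
        truth.k[:] = np.linspace(0.02, 0.15, 60)
        seqs = simulate_sequences(truth, config, rng, n_genes=60, length=500)
        t = 70.0  # Felis vs Equus: same clade
        expected, observed = [], []
        for i, gene in enumerate(truth.gene_ids):
            a = seqs["Felis_catus"][gene]
            b = seqs["Equus_asinus"][gene]
            pd_obs = 100.0 - percent_identity(global_align(a, b))
            expected.append(truth.k[i] * t)
            observed.append(pd_obs)
        expected, observed = np.array(expected), np.array(observed)
        slope = np.dot(expected, observed) / np.dot(expected, expected)
        assert slope == pytest.approx(1.0, abs=0.1)
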