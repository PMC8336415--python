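import textwrap

import numpy as np
import pandas as pd
import pytest

from clockscape import (Landscape, RunConfig, build_pair_table,
                        make_species_table, read_gene_order,
                        read_landscape_tsv, read_ortholog_fastas,
                        write_gene_order, write_landscape_tsv)
from clockscape.core_io import (read_heatmap_tsv, read_pair_table,
                                write_heatmap_tsv, write_pair_table)


def _write(path, text):
    path.write_text(textwrap.dedent(text))


class TestGeneOrder:
    def test_ranks_by_position_within_chromosome(self, tmp_path):
        _write(tmp_path / "order.tsv", """\
            gene_id\tchromosome\tstart
            a\tchr1\t100
            b\tchr1\t50
            c\tchr1\t200
            """)
        order = read_gene_order(tmp_path / "order.tsv")
        assert order.gene_ids == ("b", "a", "c")

    def test_equal_start_ties_break_by_gene_id(self, tmp_path):
        _write(tmp_path / "order.tsv", """\
            gene_id\tchromosome\tstart
            zeta\tchr1\t10
            alpha\tchr1\t10
            """)
        assert read_gene_order(tmp_path / "order.tsv").gene_ids == ("alpha", "zeta")

    def test_chromosome_order_is_file_order_not_lexicographic(self, tmp_path):
        _write(tmp_path / "order.tsv", """\
            gene_id\tchromosome\tstart
            a\tchr2\t1
            b\tchr10\t1
            c\tchr1\t1
            """)
        order = read_gene_order(tmp_path / "order.tsv")
        assert list(order.chromosomes) == ["chr2", "chr10", "chr1"]

    def test_23_chromosomes_of_100_genes(self, tmp_path):
        rows = ["gene_id\tchromosome\tstart"]
        for c in range(23):
            for i in range(100):
                rows.append(f"g{c:02d}_{i:03d}\tchr{c + 1}\t{i + 1}")
        (tmp_path / "order.tsv").write_text("\n".join(rows) + "\n")
        order = read_gene_order(tmp_path / "order.tsv")
        assert order.n_genes == 2300
        assert len(order.chromosomes) == 23

    def test_duplicate_gene_errors(self, tmp_path):
        _write(tmp_path / "order.tsv", """\
            gene_id\tchromosome\tstart
            a\tchr1\t1
            a\tchr2\t2
            """)
        with pytest.raises(ValueError, match="duplicate gene_id"):
            read_gene_order(tmp_path / "order.tsv")

    def test_missing_column_errors(self, tmp_path):
        _write(tmp_path / "order.tsv", """\
            gene_id\tchromosome
            a\tchr1
            """)
        with pytest.raises(ValueError, match="missing column"):
            read_gene_order(tmp_path / "order.tsv")

    def test_round_trip_is_identity(self, tmp_path, order_500):
        write_gene_order(order_500, tmp_path / "order.tsv")
        back = read_gene_order(tmp_path / "order.tsv")
        assert back.gene_ids == order_500.gene_ids
        assert back.chromosomes == order_500.chromosomes


class TestSpeciesAndPairs:
    def test_16_species_make_120_classified_pairs(self, species16, pairs120):
        assert len(species16) == 16
        counts = pairs120["pair_class"].value_counts()
        assert len(pairs120) == 120
        assert counts["intra-Eutherian"] == 66
        assert counts["Eutherian-Metatherian"] == 48
        assert counts["intra-Metatherian"] == 6

    def test_lineage_follows_clade(self, species16):
        eutheria = species16[species16["clade"] != "Metatheria"]
        assert (eutheria["lineage"] == "Eutheria").all()

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate species_id"):
            make_species_table([("cat", "Laurasiatheria"), ("cat", "Afrotheria")])

    def test_nonpositive_time_rejected(self):
        sp = make_species_table([("a", "Laurasiatheria"), ("b", "Metatheria")])
        with pytest.raises(ValueError, match="must be > 0"):
            build_pair_table(sp, {frozenset({"a", "b"}): 0.0})

    def test_pair_table_round_trip(self, tmp_path, pairs120):
        write_pair_table(pairs120, tmp_path / "pairs.tsv")
        back = read_pair_table(tmp_path / "pairs.tsv")
        pd.testing.assert_frame_equal(back, pairs120)


class TestOrthologFastas:
    def _species(self):
        return make_species_table(
            [("cat", "Laurasiatheria"), ("koala", "Metatheria")])

    def test_shared_genes_are_kept(self, tmp_path):
        (tmp_path / "cat.fa").write_text(">g1\nMKV\n>g2\nMAA\n")
        (tmp_path / "koala.fa").write_text(">g1\nMKV\n>g2\nMAV\n")
        orthologs = read_ortholog_fastas(tmp_path, self._species())
        assert orthologs.gene_ids == ["g1", "g2"]
        assert orthologs.species_with("g1") == ["cat", "koala"]

    def test_lineage_specific_gene_excluded(self, tmp_path):
        (tmp_path / "cat.fa").write_text(">g1\nMKV\n>only_eutherian\nMW\n")
        (tmp_path / "koala.fa").write_text(">g1\nMKV\n")
        orthologs = read_ortholog_fastas(tmp_path, self._species())
        assert orthologs.gene_ids == ["g1"]

    def test_duplicate_gene_in_species_errors(self, tmp_path):
        (tmp_path / "cat.fa").write_text(">g1\nMKV\n>g1\nMAA\n")
        (tmp_path / "koala.fa").write_text(">g1\nMKV\n")
        with pytest.raises(ValueError, match="duplicate gene id"):
            read_ortholog_fastas(tmp_path, self._species())

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(ValueError, match="no species FASTAs found"):
            read_ortholog_fastas(tmp_path, self._species())


class TestLandscapeTsv:
    def test_round_trip(self, tmp_path, tiny_order):
        values = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        write_landscape_tsv(Landscape(tiny_order, values, "gc"), tmp_path / "l.tsv")
        back = read_landscape_tsv(tmp_path / "l.tsv", tiny_order)
        np.testing.assert_array_equal(back.values, values)

    def test_length_mismatch_errors(self, tiny_order):
        with pytest.raises(ValueError, match="does not match"):
            Landscape(tiny_order, np.zeros(5))

    def test_heatmap_round_trip_with_chromosomes(self, tmp_path, tiny_order):
        matrix = np.arange(18, dtype=float).reshape(2, 9)
        write_heatmap_tsv(matrix, tiny_order, ["p1", "p2"], tmp_path / "h.tsv")
        back, order, names = read_heatmap_tsv(tmp_path / "h.tsv")
        np.testing.assert_array_equal(back, matrix)
        assert names == ["p1", "p2"]
        assert order.chromosomes == tiny_order.chromosomes


class TestRunConfig:
    def test_defaults_are_study_values(self):
        config = RunConfig()
        assert config.window_half_width == 50
        assert config.identity_floor == 30.0
        assert config.n_random_orders == 3
        assert config.threshold_sd_multiplier == 3.0
        assert config.subtelomere_margin == 50

    def test_yaml_round_trip(self, tmp_path):
        config = RunConfig(window_half_width=10, rng_seed=7)
        config.to_yaml(tmp_path / "run.yaml")
        assert RunConfig.from_yaml(tmp_path / "run.yaml") == config

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "run.yaml").write_text("window: 5\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            RunConfig.from_yaml(tmp_path / "run.yaml")

    @pytest.mark.parametrize("kwargs", [
        {"window_half_width": 0},
        {"identity_floor": 0.0},
        {"n_random_orders": 0},
        {"edge_policy": "wrap"},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RunConfig(**kwargs)
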