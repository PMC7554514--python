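"""Synthetic-data generators: determinism, truth consistency, structure."""

import numpy as np
import pandas as pd
import pytest

from heatscreen import phylo, quant, simulate
from heatscreen.simulate import SimConfig


class TestConfig:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(de_fraction=1.5)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(dispersion=-0.1)

    def test_nonpositive_library_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(library_sizes=(0, 100))


class TestTagLibraries:
    def test_null_simulation_has_no_de_genes(self):
        cfg = SimConfig(n_genes=1000, de_fraction=0.0, seed=1)
        _, truth = simulate.sim_tag_libraries(cfg)
        assert truth["is_de"].sum() == 0
        assert (truth["true_log2fc"] == 0).all()

    def test_de_count_near_binomial_expectation(self):
        cfg = SimConfig(n_genes=1000, de_fraction=0.1, effect_log2=2.0, seed=2)
        _, truth = simulate.sim_tag_libraries(cfg)
        n_de = truth["is_de"].sum()
        sigma = np.sqrt(1000 * 0.1 * 0.9)
        assert abs(n_de - 100) <= 3 * sigma

    def test_truth_flags_consistent_with_effects(self):
        cfg = SimConfig(n_genes=500, de_fraction=0.2, seed=3)
        _, truth = simulate.sim_tag_libraries(cfg)
        assert ((truth["true_log2fc"].abs() > 0) == truth["is_de"]).all()

    def test_same_seed_reproduces_byte_identical_tables(self):
        cfg = SimConfig(n_genes=300, de_fraction=0.1, seed=4)
        pair1, truth1 = simulate.sim_tag_libraries(cfg)
        pair2, truth2 = simulate.sim_tag_libraries(cfg)
        pd.testing.assert_frame_equal(pair1.counts, pair2.counts)
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_realized_totals_are_column_sums(self):
        cfg = SimConfig(n_genes=300, seed=5)
        pair, _ = simulate.sim_tag_libraries(cfg)
        assert pair.N1 == pair.counts["x"].sum()
        assert pair.N2 == pair.counts["y"].sum()

    def test_two_library_sizes_required(self):
        with pytest.raises(ValueError):
            simulate.sim_tag_libraries(SimConfig(library_sizes=(100,)))


class TestCountMatrix:
    def test_null_groups_equal_in_expectation(self):
        cfg = SimConfig(
            n_genes=400, de_fraction=0.0, library_sizes=(300_000,), seed=6
        )
        cm, _ = simulate.sim_count_matrix(cfg)
        a = cm.counts[[s for s, g in cm.groups.items() if g == "A"]].mean(axis=1)
        b = cm.counts[[s for s, g in cm.groups.items() if g == "B"]].mean(axis=1)
        # overall means match closely; per-gene ratios are noisy
        assert a.sum() == pytest.approx(b.sum(), rel=0.02)

    def test_planted_effect_recovered_on_average(self):
        cfg = SimConfig(
            n_genes=300,
            de_fraction=0.2,
            effect_log2=1.0,
            library_sizes=(2_000_000,),
            seed=7,
        )
        cm, truth = simulate.sim_count_matrix(cfg)
        groups = cm.group_samples()
        mean_a = cm.counts[groups["A"]].mean(axis=1)
        mean_b = cm.counts[groups["B"]].mean(axis=1)
        de_up = truth[truth["true_log2fc"] > 0].set_index("gene_id").index
        big = mean_a.loc[de_up] > 50
        ratios = np.log2(mean_b.loc[de_up][big] / mean_a.loc[de_up][big])
        assert ratios.mean() == pytest.approx(1.0, abs=0.1)

    def test_lengths_attached_and_positive(self):
        cm, _ = simulate.sim_count_matrix(SimConfig(n_genes=50, seed=8))
        assert (cm.lengths > 0).all()
        assert cm.lengths.index.equals(cm.counts.index)

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_genes=50, seed=9)
        cm1, _ = simulate.sim_count_matrix(cfg)
        cm2, _ = simulate.sim_count_matrix(cfg)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)


class TestPromoters:
    def test_zero_promoters_empty_output(self):
        seqs, truth = simulate.sim_promoters(n=0, length=100, seed=1)
        assert seqs == {} and truth.empty

    def test_planted_element_recorded_and_present(self):
        seqs, truth = simulate.sim_promoters(
            n=3, length=300, planted=("GACCGACGA", 50, "-"), seed=2
        )
        for row in truth.itertuples(index=False):
            segment = seqs[row.seq_id][row.start : row.end]
            # '-' strand: the forward strand carries the reverse complement
            assert segment == "TCGTCGGTC"

    def test_element_must_fit(self):
        with pytest.raises(ValueError):
            simulate.sim_promoters(n=1, length=10, planted=("GACCGACGA", 5, "+"))

    def test_background_core_rate_matches_combinatorics(self):
        """Per strand, E[core matches] = (L-5) * (2/4) * (1/4)^5 per promoter."""
        seqs, _ = simulate.sim_promoters(n=10_000, length=100, seed=3)
        import re

        total = 0
        for seq in seqs.values():
            total += len(re.findall("(?=[AG]CCGAC)", seq))
        windows = 95 * 10_000
        p = (2 / 4) * (1 / 4) ** 5
        expected = windows * p
        sigma = np.sqrt(windows * p * (1 - p))
        assert abs(total - expected) <= 3 * sigma


class TestProteins:
    def test_exact_copies_have_consensus_substring(self, domain_consensus):
        seqs, truth = simulate.sim_proteins(
            domain_copies=[1, 2], consensus=domain_consensus, seed=4
        )
        assert seqs["prot0000"].count(domain_consensus) == 1
        assert seqs["prot0001"].count(domain_consensus) == 2

    def test_seed_reproducibility(self, domain_consensus):
        a, _ = simulate.sim_proteins([1, 0], domain_consensus, seed=5)
        b, _ = simulate.sim_proteins([1, 0], domain_consensus, seed=5)
        assert a == b

    def test_mutation_rate_bounds(self, domain_consensus):
        with pytest.raises(ValueError):
            simulate.sim_proteins([1], domain_consensus, mutation_rate=0.9)


class TestCtTable:
    def test_noise_free_encoding(self):
        table = simulate.sim_ct_table(
            {"ctl": 1.0, "trt": 8.0}, calibrator="ctl", noise_sd=0.0, seed=6
        )
        mean = table.groupby(["sample", "gene"])["ct"].mean().unstack()
        shift = mean.loc["trt", "target"] - mean.loc["ctl", "target"]
        assert shift == pytest.approx(-3.0)  # -log2(8)
        assert mean["reference"].nunique() == 1

    def test_nonpositive_rq_rejected(self):
        with pytest.raises(ValueError):
            simulate.sim_ct_table({"ctl": 1.0, "trt": -2.0}, calibrator="ctl")

    def test_three_replicates_per_cell(self):
        table = simulate.sim_ct_table({"ctl": 1.0}, calibrator="ctl", seed=7)
        assert (table.groupby(["sample", "gene"]).size() == 3).all()


class TestInjuryTallies:
    def test_counts_sum_to_cohort_size(self):
        counts = simulate.sim_injury_tallies(30, [0.25, 0.25, 0.25, 0.25], seed=8)
        assert counts.sum() == 30

    def test_all_mass_on_zero_gives_hii_zero(self):
        counts = simulate.sim_injury_tallies(30, [1.0, 0, 0, 0], seed=9)
        assert quant.heat_injury_index(counts) == 0.0

    def test_all_mass_on_max_gives_hii_hundred(self):
        counts = simulate.sim_injury_tallies(30, [0, 0, 0, 1.0], seed=10)
        assert quant.heat_injury_index(counts) == 100.0

    def test_expected_hii_of_even_mixture(self):
        """Mass split between levels 1 and 3 gives HII near 66.7%."""
        counts = simulate.sim_injury_tallies(
            3000, [0, 0.5, 0, 0.5], max_level=3, seed=11
        )
        assert quant.heat_injury_index(counts) == pytest.approx(66.67, abs=2.0)


class TestAlignment:
    def test_zero_branch_lengths_identical_sequences(self):
        tree = phylo.from_newick("(a:0,b:0,c:0);")
        aln = simulate.sim_alignment(tree, seq_len=200, seed=12)
        assert len(set(aln.values())) == 1

    def test_star_tree_distances_roughly_equal(self):
        tree = phylo.from_newick("(a:0.2,b:0.2,c:0.2,d:0.2);")
        aln = simulate.sim_alignment(tree, seq_len=5000, seed=13)
        _, d = phylo.p_distance(aln)
        off = d[np.triu_indices(4, k=1)]
        assert off.std() / off.mean() < 0.15

    def test_seed_reproducibility(self):
        tree = phylo.from_newick("(a:0.1,b:0.1,c:0.1);")
        a = simulate.sim_alignment(tree, seq_len=100, seed=14)
        b = simulate.sim_alignment(tree, seq_len=100, seed=14)
        assert a == b
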