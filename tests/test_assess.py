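"""Substitution/permutation robustness protocol and synthetic fixtures."""

import numpy as np
import pytest
from scipy import stats

from tmcomplexity.assess import (HeatMap, PerturbationGrid, heatmap,
                                 permute_blocks, read_fasta, substitute,
                                 synth_dna, synth_step_string, write_fasta)
from tmcomplexity.markov import best_order_nc


class TestStepString:
    def test_default_is_500_zeros_then_500_ones(self):
        x = synth_step_string()
        assert x.size == 1000
        assert (x[:500] == 0).all() and (x[500:] == 1).all()

    def test_degenerate_segments(self):
        assert (synth_step_string(n0=0) == 1).all()
        with pytest.raises(ValueError):
            synth_step_string(0, 0)

    def test_low_statistical_complexity(self):
        assert best_order_nc(synth_step_string(), alphabet_size=2).nc < 0.2


class TestSubstitute:
    def test_zero_probability_is_identity(self):
        x = synth_step_string()
        assert np.array_equal(substitute(x, 0.0, seed=1), x)

    def test_full_fixed_substitution_is_constant(self):
        x = synth_dna(500, seed=2)
        y = substitute(x, 1.0, mode="fixed", target="A", seed=3)
        assert (y == 0).all() and y.size == x.size

    def test_uniform_hamming_distance_binomial(self):
        x = synth_step_string()
        y = substitute(x, 0.5, mode="uniform", alphabet_size=2, seed=4)
        # each position flips with probability p (|A|-1)/|A| = 0.25
        dist = int((y != x).sum())
        sigma = np.sqrt(1000 * 0.25 * 0.75)
        assert abs(dist - 250) < 3 * sigma

    def test_fixed_mode_requires_target(self):
        with pytest.raises(ValueError):
            substitute([0, 1], 0.5, mode="fixed")

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            substitute([0, 1], 1.5)


class TestPermuteBlocks:
    def test_single_block_is_identity(self):
        x = synth_step_string()
        assert np.array_equal(permute_blocks(x, 1, seed=5), x)

    @pytest.mark.parametrize("n_blocks", [2, 7, 64, 1000])
    def test_symbol_multiset_preserved(self, n_blocks):
        x = synth_dna(1000, seed=6)
        y = permute_blocks(x, n_blocks, seed=7)
        assert np.array_equal(np.bincount(y, minlength=4),
                              np.bincount(x, minlength=4))

    def test_block_sizes_differ_by_at_most_one(self):
        # 10 symbols in 3 blocks: sizes 4,3,3 — recover them by inverting a
        # known permutation of distinguishable symbols
        x = np.arange(10, dtype=np.int8)
        y = permute_blocks(x, 3, seed=8)
        blocks = sorted((list(y).index(b[0]), len(b)) for b in
                        ([0, 1, 2, 3], [4, 5, 6], [7, 8, 9]))
        assert sorted(size for _, size in blocks) == [3, 3, 4]

    def test_shuffling_step_string_raises_nc(self):
        x = synth_step_string()
        base = best_order_nc(x, alphabet_size=2).nc
        wins = sum(
            best_order_nc(permute_blocks(x, 64, seed=s), alphabet_size=2).nc
            > base for s in range(20))
        assert wins >= 18

    def test_bad_block_count_rejected(self):
        with pytest.raises(ValueError):
            permute_blocks([0, 1], 3)


class TestHeatmap:
    def test_unperturbed_cell_equals_plain_nc(self):
        x = synth_step_string()
        grid = PerturbationGrid(substitution_probabilities=(0.0,),
                                block_counts=(1,))
        hm = heatmap(x, grid, alphabet_size=2, seed=0)
        assert hm.values.shape == (1, 1)
        assert hm.values[0, 0] == pytest.approx(
            best_order_nc(x, alphabet_size=2).nc)

    def test_corner_cell_stable_across_master_seeds(self):
        x = synth_step_string()
        grid = PerturbationGrid(substitution_probabilities=(0.0, 0.4),
                                block_counts=(1, 4))
        v1 = heatmap(x, grid, alphabet_size=2, seed=1).values
        v2 = heatmap(x, grid, alphabet_size=2, seed=2).values
        assert v1[0, 0] == v2[0, 0]  # (p=0, 1 block) is deterministic

    def test_uniform_substitution_raises_nc_on_step_string(self):
        x = synth_step_string()
        grid = PerturbationGrid(
            substitution_probabilities=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
            block_counts=(1,))
        rhos = []
        for seed in range(20):
            vals = heatmap(x, grid, alphabet_size=2, seed=seed).values[:, 0]
            rhos.append(stats.spearmanr(np.arange(6), vals).statistic)
        assert np.mean(rhos) > 0.9

    def test_fixed_substitution_lowers_nc_on_complex_dna(self):
        x = synth_dna(2000, seed=3, sharpness=0.0)
        grid = PerturbationGrid(
            substitution_probabilities=(0.0, 0.25, 0.5, 0.75, 1.0),
            block_counts=(1,), substitution_mode="fixed", target_symbol="A")
        rhos = []
        for seed in range(20):
            vals = heatmap(x, grid, alphabet_size=4, seed=seed).values[:, 0]
            rhos.append(stats.spearmanr(np.arange(5), vals).statistic)
        assert np.mean(rhos) < -0.9

    def test_full_uniform_substitution_looks_iid(self):
        x = synth_step_string()
        grid = PerturbationGrid(substitution_probabilities=(1.0,),
                                block_counts=(1,))
        hm = heatmap(x, grid, alphabet_size=2, seed=4)
        iid = np.random.default_rng(5).integers(0, 2, x.size)
        assert hm.values[0, 0] == pytest.approx(
            best_order_nc(iid, alphabet_size=2).nc, abs=0.05)

    def test_tsv_matrix_shape(self):
        x = synth_step_string()
        grid = PerturbationGrid(substitution_probabilities=(0.0, 0.5),
                                block_counts=(1, 2, 4))
        text = heatmap(x, grid, alphabet_size=2, seed=6).to_tsv()
        lines = text.strip().splitlines()
        assert len(lines) == 3
        assert lines[0].split("\t")[1:] == ["1", "2", "4"]

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            PerturbationGrid(substitution_probabilities=(0.5, 0.1))
        with pytest.raises(ValueError):
            PerturbationGrid(block_counts=(0,))


class TestFasta:
    def toy(self, tmp_path, body):
        p = tmp_path / "toy.fasta"
        p.write_text(body)
        return str(p)

    def test_two_records_with_lengths(self, tmp_path):
        path = self.toy(tmp_path, ">a desc\nACGT\nAC\n>b\nGGGG\n")
        recs = read_fasta(path)
        assert [h for h, _ in recs] == ["a desc", "b"]
        assert recs[0][1].tolist() == [0, 1, 2, 3, 0, 1]
        assert recs[1][1].tolist() == [2, 2, 2, 2]

    def test_lowercase_equals_uppercase(self, tmp_path):
        up = read_fasta(self.toy(tmp_path, ">x\nACGT\n"))
        lo = read_fasta(self.toy(tmp_path, ">x\nacgt\n"))
        assert np.array_equal(up[0][1], lo[0][1])

    def test_roundtrip(self, tmp_path):
        recs = [("r1", synth_dna(150, seed=9)), ("r2", synth_dna(33, seed=10))]
        path = tmp_path / "rt.fasta"
        write_fasta(str(path), recs)
        back = read_fasta(str(path))
        for (h1, s1), (h2, s2) in zip(recs, back):
            assert h1 == h2 and np.array_equal(s1, s2)

    def test_ambiguity_reject_and_random(self, tmp_path):
        path = self.toy(tmp_path, ">x\nACGNT\n")
        with pytest.raises(ValueError):
            read_fasta(path)
        recs = read_fasta(path, ambiguity="random", seed=11)
        assert recs[0][1].size == 5
        assert 0 <= recs[0][1][3] <= 3

    def test_bad_inputs(self, tmp_path):
        with pytest.raises(ValueError):
            read_fasta(self.toy(tmp_path, ""))
        with pytest.raises(ValueError):
            read_fasta(self.toy(tmp_path, ">x\nAC!T\n"))


class TestSynthDna:
    def test_near_uniform_chain_has_nc_near_one(self):
        x = synth_dna(10_000, seed=12, sharpness=0.0)
        assert abs(best_order_nc(x, alphabet_size=4).nc - 1.0) <= 0.03

    def test_peaked_chain_is_nearly_periodic(self):
        x = synth_dna(10_000, seed=13, sharpness=1.0)
        assert best_order_nc(x, alphabet_size=4).nc < 0.05

    def test_reproducible_and_validated(self):
        assert np.array_equal(synth_dna(100, seed=14), synth_dna(100, seed=14))
        with pytest.raises(ValueError):
            synth_dna(0)
        with pytest.raises(ValueError):
            synth_dna(10, sharpness=1.5)
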