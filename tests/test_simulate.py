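"""Generator behaviour: Markov genotypes, planted structure, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bxdnet.datatypes import ConfigurationError, MarkerMap, TruthRecord
from bxdnet.simulate import (default_truth, make_annotation, make_dataset,
                             make_expression, make_genotypes, make_phenotypes,
                             module_factors)


class TestGenotypes:
    def test_no_recombination_gives_one_state_per_chromosome(self, small_map):
        panel = make_genotypes(30, small_map, 0.0, seed=1)
        for idx in small_map.chromosome_slices().values():
            block = panel.calls[:, idx]
            assert (block == block[:, [0]]).all()

    def test_free_recombination_halves_adjacent_agreement(self, small_map):
        panel = make_genotypes(200, small_map, 0.5, seed=2)
        agree = 0
        total = 0
        for idx in small_map.chromosome_slices().values():
            block = panel.calls[:, idx]
            agree += (block[:, 1:] == block[:, :-1]).sum()
            total += block[:, 1:].size
        # binomial 99.9% band around 0.5
        p = stats.binomtest(int(agree), total, 0.5).pvalue
        assert p > 1e-3

    def test_allele_frequency_near_half(self, small_map):
        panel = make_genotypes(200, small_map, 0.25, seed=3)
        freq = panel.calls.mean(axis=0)
        assert np.all(np.abs(freq - 0.5) < 0.1)

    def test_recombination_length_mismatch_raises(self, small_map):
        with pytest.raises(ConfigurationError):
            make_genotypes(10, small_map, [0.1] * 3, seed=0)

    def test_reproducible(self, small_map):
        a = make_genotypes(25, small_map, 0.2, seed=9)
        b = make_genotypes(25, small_map, 0.2, seed=9)
        assert a == b


class TestExpression:
    def test_null_generator_arms_differ_only_by_noise(self, small_map):
        panel = make_genotypes(20, small_map, 0.25, seed=4)
        annot = make_annotation(100, small_map, seed=4)
        truth = TruthRecord(seed=4)
        sal, eth, _ = make_expression(panel, annot, truth, noise_sd=0.3,
                                      seed=5, probes_per_set=0)
        diff = (eth - sal).to_numpy()
        assert abs(diff.mean()) < 0.01
        assert diff.std() < 0.25  # only the two arm-noise components

    def test_planted_module_produces_high_pairwise_correlation(self, small_map):
        panel = make_genotypes(27, small_map, 0.25, seed=6)
        annot = make_annotation(60, small_map, seed=6)
        genes = list(annot.index[:50])
        truth = TruthRecord(seed=6, modules={"M": {
            "genes": genes, "loadings": {g: 1.0 for g in genes},
            "factor_sd": 3.0, "arm": "both"}})
        sal, _, _ = make_expression(panel, annot, truth, noise_sd=0.3,
                                    seed=7, probes_per_set=0)
        r = np.corrcoef(sal.loc[genes].to_numpy())
        pairs = np.abs(r[np.triu_indices(len(genes), k=1)])
        assert (pairs > 0.7).mean() > 0.9

    def test_truth_validation_rejects_unknown_gene(self, small_map):
        panel = make_genotypes(12, small_map, 0.25, seed=8)
        annot = make_annotation(20, small_map, seed=8)
        truth = TruthRecord(seed=8, cis_effects={"nope": ("m01_000", 1.0)})
        with pytest.raises(ConfigurationError):
            make_expression(panel, annot, truth, noise_sd=0.3, seed=8,
                            probes_per_set=0)

    def test_non_positive_noise_rejected(self, small_map):
        panel = make_genotypes(12, small_map, 0.25, seed=8)
        annot = make_annotation(20, small_map, seed=8)
        with pytest.raises(ConfigurationError):
            make_expression(panel, annot, TruthRecord(), noise_sd=0.0, seed=1)


class TestPhenotypes:
    def test_includes_pure_noise_negative_control(self, small_map):
        panel = make_genotypes(20, small_map, 0.25, seed=10)
        truth = TruthRecord(seed=10)
        ph = make_phenotypes(panel, truth, 3, seed=11)
        assert ph.shape == (3, 20)
        assert all(name.startswith("noise_") for name in ph.index)

    def test_two_phenotypes_from_same_factor_correlate(self, small_map):
        panel = make_genotypes(27, small_map, 0.25, seed=12)
        truth = TruthRecord(seed=12, modules={"M": {
            "genes": [], "loadings": {}, "factor_sd": 1.0, "arm": "both"}},
            phenotype_coefficients={"a": {"M": 1.0}, "b": {"M": 1.0}})
        # attenuation: corr = var_f / (var_f + var_noise) = 1 / 1.25 = 0.8
        rs = []
        for s in range(12):
            ph = make_phenotypes(panel, truth, 3, seed=100 + s, noise_sd=0.5)
            rs.append(np.corrcoef(ph.loc["a"], ph.loc["b"])[0, 1])
        assert np.mean(rs) > 0.5

    def test_factors_shared_with_expression_stage(self, small_map):
        panel = make_genotypes(15, small_map, 0.25, seed=13)
        truth = TruthRecord(seed=13, modules={"M": {
            "genes": [], "loadings": {}, "factor_sd": 1.0, "arm": "both"}})
        f1 = module_factors(panel, truth)["M"]
        f2 = module_factors(panel, truth)["M"]
        np.testing.assert_array_equal(f1, f2)

    def test_n_phenotypes_validated(self, small_map):
        panel = make_genotypes(10, small_map, 0.25, seed=14)
        with pytest.raises(ConfigurationError):
            make_phenotypes(panel, TruthRecord(), 0, seed=1)


class TestDataset:
    def test_same_seed_is_bit_identical(self):
        a = make_dataset(77, n_probe_sets=400, with_probe_level=False)
        b = make_dataset(77, n_probe_sets=400, with_probe_level=False)
        pd.testing.assert_frame_equal(a.saline, b.saline)
        pd.testing.assert_frame_equal(a.ethanol, b.ethanol)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert a.panel == b.panel

    def test_truth_consistent_with_annotation_and_map(self):
        d = make_dataset(78, n_probe_sets=400, with_probe_level=False)
        d.truth.validate(d.annotation.index, d.panel.map)
        regulators = set(d.truth.cis_effects) & set(d.truth.response_effects)
        assert len(regulators) == 1
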