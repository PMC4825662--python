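"""Synthetic-data generators: cross, meiosis, MSAP and expression."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from polyploidkit import msap
from polyploidkit import segregation as seg
from polyploidkit.simulate import (
    DiploidParent,
    SimulationConfig,
    TetraploidIndividual,
    default_parents,
    progeny_genotype_table,
    simulate_bsp_cross,
    simulate_expression_matrix,
    simulate_marker_counts,
    simulate_msap_profiles,
    simulate_tetraploid_meiosis,
)


class TestBspCross:
    def test_forced_tetraploids(self):
        p1, p2 = default_parents(n_chromosomes=2, two_n_egg_rate=1.0, two_n_pollen_rate=1.0)
        progeny = simulate_bsp_cross(p1, p2, SimulationConfig(n_progeny=50, seed=1))
        assert all(ind.ploidy == 4 for ind in progeny)

    def test_forced_diploids(self):
        p1, p2 = default_parents(n_chromosomes=2, two_n_egg_rate=0.0, two_n_pollen_rate=0.0)
        progeny = simulate_bsp_cross(p1, p2, SimulationConfig(n_progeny=50, seed=1))
        assert all(ind.ploidy == 2 for ind in progeny)

    def test_tetraploid_fraction_binomial(self):
        # P(4x) = P(2n egg) * P(2n pollen) = 0.6 * 0.1 = 0.06
        n = 10_000
        p1, p2 = default_parents(n_chromosomes=1)
        progeny = simulate_bsp_cross(p1, p2, SimulationConfig(n_progeny=n, seed=42))
        frac = sum(ind.ploidy == 4 for ind in progeny) / n
        se = np.sqrt(0.06 * 0.94 / n)
        assert abs(frac - 0.06) < 3 * se

    def test_mismatched_locus_catalogues_rejected(self):
        p1, _ = default_parents(n_chromosomes=2)
        _, p2 = default_parents(n_chromosomes=3)
        with pytest.raises(ValueError, match="locus catalogue"):
            simulate_bsp_cross(p1, p2, SimulationConfig(n_progeny=5))

    def test_fdr_cross_transmits_all_alleles(self):
        """An FDR 2n gamete carries both parental homologs, so 4x progeny
        inherit every parental allele: allele accounting shows no deficit."""
        p1, p2 = default_parents(n_chromosomes=3, two_n_egg_rate=1.0, two_n_pollen_rate=1.0)
        progeny = simulate_bsp_cross(p1, p2, SimulationConfig(n_progeny=10, seed=3))
        table = progeny_genotype_table(progeny, p1, p2)
        parental = {
            locus: {a for hom_map in (p1.alleles[locus], p2.alleles[locus]) for a in hom_map.values()}
            for locus in p1.alleles
        }
        for pid, sub in table.groupby("progeny_id"):
            observed = {
                locus: set(grp.loc[grp["present"] == 1, "allele"])
                for locus, grp in sub.groupby("locus")
            }
            report = seg.allele_accounting(parental, {}, observed)
            assert (report["deficit"] == 0).all()

    def test_determinism(self):
        p1, p2 = default_parents(n_chromosomes=2)
        cfg = SimulationConfig(n_progeny=30, seed=9)
        t1 = progeny_genotype_table(simulate_bsp_cross(p1, p2, cfg), p1, p2)
        t2 = progeny_genotype_table(simulate_bsp_cross(p1, p2, cfg), p1, p2)
        pd.testing.assert_frame_equal(t1, t2)


def _bsp_tetraploid():
    return TetraploidIndividual(
        id="S29",
        homologs={
            "chr1": (("a", "seed"), ("b", "seed"), ("c", "pollen"), ("d", "pollen"))
        },
    )


class TestTetraploidMeiosis:
    def test_random_pairing_uniform_over_six_pairs(self):
        n = 60_000
        gametes = simulate_tetraploid_meiosis(
            _bsp_tetraploid(), SimulationConfig(n_progeny=1, pairing_preference=0.0, seed=5), n
        )
        counts = Counter(frozenset(g["chr1"]) for g in gametes)
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        assert len(counts) == 6
        for pair, c in counts.items():
            assert abs(c / n - 1 / 6) < 3 * se, pair

    def test_preferential_pairing_never_joins_a_preferred_pair(self):
        gametes = simulate_tetraploid_meiosis(
            _bsp_tetraploid(), SimulationConfig(n_progeny=1, pairing_preference=1.0, seed=6), 5000
        )
        forbidden = ({"a", "b"}, {"c", "d"})
        assert not any(set(g["chr1"]) in forbidden for g in gametes)

    def test_double_reduction_rate(self):
        n = 60_000
        gametes = simulate_tetraploid_meiosis(
            _bsp_tetraploid(),
            SimulationConfig(n_progeny=1, double_reduction_alpha=1 / 6, seed=7),
            n,
        )
        frac = sum(g["chr1"][0] == g["chr1"][1] for g in gametes) / n
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        assert abs(frac - 1 / 6) < 3 * se

    @pytest.mark.parametrize("b", [0.0, 0.5, 1.0])
    def test_marginal_inclusion_probability_half(self, b):
        """Each bivalent contributes one chromosome, so every homolog has
        inclusion probability 1/2 regardless of the pairing preference."""
        n = 40_000
        gametes = simulate_tetraploid_meiosis(
            _bsp_tetraploid(), SimulationConfig(n_progeny=1, pairing_preference=b, seed=8), n
        )
        se = np.sqrt(0.25 / n)
        for hom in "abcd":
            frac = sum(hom in g["chr1"] for g in gametes) / n
            assert abs(frac - 0.5) < 3 * se

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_progeny=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_progeny=1, pairing_preference=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_progeny=1, double_reduction_alpha=0.5)


class TestMarkerCountSimulation:
    def test_counts_follow_model_expectation(self, rng):
        config = seg.LocusConfiguration(
            "L", "I", (("A", frozenset({0})), ("B", frozenset({2})))
        )
        from polyploidkit.pairing import TETRASOMIC

        exp = seg.joint_class_expectation(config, TETRASOMIC)
        n = 60_000
        counts = simulate_marker_counts(
            config, SimulationConfig(n_progeny=n, pairing_preference=0.0), rng
        )
        for c, p in zip(counts, exp.probabilities):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(c / n - p) < 3 * se


class TestMsapSimulation:
    def test_no_events_means_no_nonparental_sites(self):
        sim = simulate_msap_profiles(
            300, {"de_novo": 0.0, "demethylation": 0.0}, n_hybrids=2, seed=11
        )
        states = msap.score_band_matrix(sim.bands)
        classes = msap.classify_hybrid_sites(states, "P1", "P2")
        flat = classes.to_numpy().ravel()
        assert not {"de_novo_methylation", "demethylation"} & set(flat)

    def test_classifier_recovers_simulated_classes_exactly(self):
        sim = simulate_msap_profiles(
            1000,
            {"de_novo": 0.14, "demethylation": 0.10, "parental_P1_like": 0.2},
            n_hybrids=3,
            seed=12,
        )
        states = msap.score_band_matrix(sim.bands)
        classes = msap.classify_hybrid_sites(states, "P1", "P2")
        for hyb in sim.hybrids:
            assert (classes[hyb].to_numpy() == sim.truth["class"].to_numpy()).all()

    def test_determinism_byte_identical(self):
        a = simulate_msap_profiles(200, {"de_novo": 0.1}, seed=13)
        b = simulate_msap_profiles(200, {"de_novo": 0.1}, seed=13)
        assert a.bands.to_csv() == b.bands.to_csv()
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_msap_profiles(10, {"de_novo": 0.9, "demethylation": 0.6})
        with pytest.raises(ValueError, match="unknown site class"):
            simulate_msap_profiles(10, {"hyperspace": 0.1})
        with pytest.raises(ValueError, match="negative"):
            simulate_msap_profiles(10, {"de_novo": -0.1})


class TestExpressionSimulation:
    def test_noise_free_limit_recovers_effect(self):
        study, truth = simulate_expression_matrix(
            200, frac_nonadditive=0.2, effect_log2fc=2.0, sigma=1e-9, seed=21
        )
        from polyploidkit.expression import contrast

        res = contrast(study, "hybrid4x", "parent")
        true_fc = truth.loc[truth["nonadditive"], "true_log2fc"]
        recovered = res.loc[true_fc.index, "log2fc"]
        assert np.allclose(recovered, true_fc, atol=1e-6)
        additive = res.loc[~truth["nonadditive"], "log2fc"]
        assert np.allclose(additive, 0.0, atol=1e-6)

    def test_group_structure(self):
        study, truth = simulate_expression_matrix(50, seed=22)
        assert study.matrix.shape == (50, 24)
        assert sorted(study.samples["group"].unique()) == [
            "hybrid2x",
            "hybrid4x",
            "parent",
        ]
        assert (study.samples.groupby("genotype").size() == 3).all()

    def test_degenerate_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            simulate_expression_matrix(10, n_replicates=1)
        with pytest.raises(ValueError, match="sigma"):
            simulate_expression_matrix(10, sigma=0.0)

    def test_determinism(self):
        a, ta = simulate_expression_matrix(40, seed=23)
        b, tb = simulate_expression_matrix(40, seed=23)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)
        pd.testing.assert_frame_equal(ta, tb)
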