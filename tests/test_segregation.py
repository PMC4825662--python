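"""Segregation expectations, χ² testing and inheritance calls."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyploidkit import segregation as seg
from polyploidkit.pairing import DISOMIC, TETRASOMIC, PairingModel

ALL_PARTITIONS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def brute_force_distribution(config, model):
    """Independent oracle: weighted enumeration of all partitions × draws."""
    pref = frozenset(frozenset(p) for p in config.preferred_partition())
    b = Fraction(model.preference)
    dist = {}
    for part in ALL_PARTITIONS:
        w = b + (1 - b) / 3 if frozenset(frozenset(p) for p in part) == pref else (1 - b) / 3
        for pick in itertools.product(part[0], part[1]):
            pat = tuple(
                bool(set(pick) & carriers) for _, carriers in config.tracked_alleles
            )
            dist[pat] = dist.get(pat, Fraction(0)) + w * Fraction(1, 4)
    return dist


def locus(*carrier_sets, chromosome="I"):
    alleles = tuple(
        (chr(ord("A") + i), frozenset(c)) for i, c in enumerate(carrier_sets)
    )
    return seg.LocusConfiguration("L", chromosome, alleles)


carrier_set = st.sets(st.integers(0, 3), min_size=1, max_size=4).map(frozenset)


class TestGameteDistribution:
    @pytest.mark.parametrize(
        "carriers, model, expected",
        [
            ({0}, TETRASOMIC, Fraction(1, 2)),  # simplex: 3 of 6 pairs carry it
            ({0, 1}, TETRASOMIC, Fraction(5, 6)),  # duplex: only 1 pair lacks both
            ({0, 1, 2, 3}, TETRASOMIC, Fraction(1)),
            ({0, 1, 2, 3}, DISOMIC, Fraction(1)),
            ({0, 1}, DISOMIC, Fraction(1)),  # both carriers in one preferred pair
            ({0, 2}, DISOMIC, Fraction(3, 4)),  # split across preferred pairs
            ({0}, DISOMIC, Fraction(1, 2)),
        ],
    )
    def test_presence_probability(self, carriers, model, expected):
        assert seg.presence_probability(locus(carriers), model) == expected

    @given(
        carriers=st.lists(carrier_set, min_size=1, max_size=4),
        b=st.sampled_from([0.0, 0.25, 0.5, 1.0]),
    )
    def test_matches_brute_force_enumeration(self, carriers, b):
        config = locus(*carriers)
        model = PairingModel(preference=b)
        dist = seg.gamete_distribution(config, model)
        oracle = brute_force_distribution(config, model)
        assert dist == oracle  # exact rational agreement

    @given(carriers=st.lists(carrier_set, min_size=2, max_size=3))
    def test_marginal_consistency(self, carriers):
        """Joint classes marginalized over the other alleles give the presence prob."""
        config = locus(*carriers)
        for model in (DISOMIC, TETRASOMIC):
            dist = seg.gamete_distribution(config, model)
            for idx, allele in enumerate(config.allele_ids):
                marginal = sum(p for pat, p in dist.items() if pat[idx])
                assert marginal == seg.presence_probability(config, model, allele)

    def test_symmetry_within_preferred_pair(self):
        """Relabeling homologs within a preferred pair leaves expectations unchanged."""
        for model in (DISOMIC, TETRASOMIC):
            a = seg.joint_class_expectation(locus({0}, {2}), model)
            b = seg.joint_class_expectation(locus({1}, {2}), model)
            assert a.probabilities == b.probabilities

    def test_double_reduction_requires_opt_in(self):
        model = PairingModel(preference=0.0, double_reduction=1 / 6)
        with pytest.raises(ValueError, match="double reduction"):
            seg.gamete_distribution(locus({0}), model)
        dist = seg.gamete_distribution(locus({0}), model, allow_double_reduction=True)
        # simplex presence drops below 1/2: the DR branch favours pure pairs
        expected = (5 / 6) * (1 / 2) + (1 / 6) * (1 / 4)
        assert float(dist[(True,)]) == pytest.approx(expected)


class TestJointExpectation:
    def test_repulsion_disomic_is_uniform(self):
        exp = seg.joint_class_expectation(locus({0}, {2}), DISOMIC)
        assert exp.probabilities == (0.25, 0.25, 0.25, 0.25)
        assert exp.class_labels == ("A+ B+", "A+ B-", "A- B+", "A- B-")

    def test_repulsion_tetrasomic_1221(self):
        exp = seg.joint_class_expectation(locus({0}, {2}), TETRASOMIC)
        assert exp.exact == (
            Fraction(1, 6),
            Fraction(1, 3),
            Fraction(1, 3),
            Fraction(1, 6),
        )

    @pytest.mark.parametrize("model", [DISOMIC, TETRASOMIC])
    def test_colocated_alleles_cosegregate(self, model):
        exp = seg.joint_class_expectation(locus({0}, {0}), model)
        by_label = dict(zip(exp.class_labels, exp.exact))
        assert by_label["A+ B+"] == Fraction(1, 2)
        assert by_label["A- B-"] == Fraction(1, 2)
        assert by_label["A+ B-"] == 0 and by_label["A- B+"] == 0


class TestChiSquare:
    def test_perfect_fit(self):
        exp = seg.joint_class_expectation(locus({0}), TETRASOMIC)
        t = seg.chi_square_gof([30, 30], exp)
        assert t.chi2 == 0.0 and t.p_value == 1.0 and t.verdict == "NS"

    def test_five_to_one_hand_arithmetic(self):
        # duplex tetrasomic expectation is 5:1; (45,15) on n=60 gives
        # chi2 = 25/50 + 25/10 = 3.0, df=1, p ~ 0.083 -> NS at 0.05
        exp = seg.joint_class_expectation(locus({0, 1}), TETRASOMIC)
        t = seg.chi_square_gof([45, 15], exp)
        assert t.chi2 == pytest.approx(3.0)
        assert t.df == 1
        assert t.p_value == pytest.approx(0.0833, abs=5e-4)
        assert t.verdict == "NS"

    def test_observed_in_zero_probability_class_is_nontestable(self):
        exp = seg.joint_class_expectation(locus({0, 1}), DISOMIC)  # presence prob 1
        t = seg.chi_square_gof([55, 5], exp)
        assert t.verdict == "NT" and t.chi2 is None and not t.testable

    def test_unobserved_impossible_class_is_dropped(self):
        exp = seg.joint_class_expectation(locus({0}, {0}), TETRASOMIC)
        t = seg.chi_square_gof({(True, True): 28, (False, False): 32}, exp)
        assert t.verdict == "NS" and t.df == 1

    def test_single_class_is_nontestable(self):
        exp = seg.joint_class_expectation(locus({0, 1, 2, 3}), TETRASOMIC)
        assert seg.chi_square_gof([60, 0], exp).verdict == "NT"

    def test_all_zero_counts_rejected(self):
        exp = seg.joint_class_expectation(locus({0}), TETRASOMIC)
        with pytest.raises(ValueError, match="all-zero"):
            seg.chi_square_gof([0, 0], exp)

    def test_simplex_models_coincide(self):
        """A lone simplex allele segregates 1:1 under both models."""
        mt = seg.test_marker(locus({0}), [27, 33])
        assert mt.disomic.verdict == mt.tetrasomic.verdict
        assert mt.disomic.chi2 == pytest.approx(mt.tetrasomic.chi2)


def _fake_test(model, verdict):
    chi2 = None if verdict == "NT" else 1.0
    p = None if verdict == "NT" else {"NS": 0.5, "*": 0.03, "**": 0.005}[verdict]
    return seg.SegregationTest(model, (30, 30), (30.0, 30.0), chi2, 1, p, verdict)


def _marker(dis, tet, locus_id="m1", chromosome="I"):
    return seg.MarkerTest(locus_id, chromosome, _fake_test("disomic", dis), _fake_test("tetrasomic", tet))


class TestClassifyChromosome:
    @pytest.mark.parametrize(
        "dis, tet, call",
        [
            ("**", "NS", "tetrasomic"),
            ("*", "NS", "tetrasomic"),
            ("NS", "**", "disomic"),
            ("NS", "NS", "ambiguous"),
            ("**", "**", "distorted"),
            ("NT", "NS", "tetrasomic"),
            ("NT", "**", "distorted"),
            ("NT", "NT", "untestable"),
        ],
    )
    def test_single_marker_rule_table(self, dis, tet, call):
        assert seg.classify_chromosome([_marker(dis, tet)]).call == call

    def test_disagreeing_markers_are_intermediate(self):
        call = seg.classify_chromosome(
            [_marker("**", "NS", "m1"), _marker("NS", "**", "m2")]
        )
        assert call.call == "intermediate"

    def test_ambiguous_markers_defer_to_decisive_one(self):
        call = seg.classify_chromosome(
            [_marker("NS", "NS", "m1"), _marker("**", "NS", "m2")]
        )
        assert call.call == "tetrasomic"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            seg.classify_chromosome([])


class TestAlleleAccounting:
    def test_full_transmission(self):
        report = seg.allele_accounting(
            {"L1": {"A", "B"}}, {"L1": {"C", "D"}}, {"L1": {"A", "B", "C", "D"}}
        )
        assert report.loc[0, "deficit"] == 0 and not report.loc[0, "flagged"]

    def test_missing_allele_flagged(self):
        report = seg.allele_accounting(
            {"L1": {"A", "B"}}, {"L1": {"C", "D"}}, {"L1": {"A", "C", "D"}}
        )
        assert report.loc[0, "deficit"] == 1 and bool(report.loc[0, "flagged"])


class TestPowerProperties:
    @pytest.mark.parametrize("b, fitting, rejected", [(0.0, "tetrasomic", "disomic"), (1.0, "disomic", "tetrasomic")])
    def test_wrong_model_rejected_more_often(self, b, fitting, rejected, rng):
        """Repulsion-phase data simulated under one extreme reject the other more."""
        from polyploidkit.simulate import SimulationConfig, simulate_marker_counts

        config = locus({0}, {2})
        n_rej = {"disomic": 0, "tetrasomic": 0}
        for _ in range(300):
            counts = simulate_marker_counts(
                config, SimulationConfig(n_progeny=60, pairing_preference=b), rng
            )
            mt = seg.test_marker(config, counts)
            n_rej["disomic"] += mt.disomic.significant
            n_rej["tetrasomic"] += mt.tetrasomic.significant
        assert n_rej[rejected] > n_rej[fitting]
        assert n_rej[rejected] > 100  # clear power, not a tie
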