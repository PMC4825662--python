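"""Marker segregation analysis in a 4x × 4x test cross.

A neotetraploid produced by bilateral sexual polyploidization (BSP)
carries two seed-parent-derived and two pollen-parent-derived homologs
of each chromosome.  Crossing it to a tetraploid tester that carries
none of the tracked parent-specific SSR alleles makes progeny band
presence a direct readout of the BSP parent's gametes, so the observed
segregation discriminates disomic (preferential pairing) from
tetrasomic (random pairing) inheritance.

Expected class probabilities are derived by exhaustive enumeration over
bivalent partitions and chromosome draws, assuming no double reduction:
the tetrasomic model is uniform over all C(4,2) = 6 homolog pairs, the
disomic model uniform over the 4 one-from-each-preferred-pair
combinations.  Observed counts are tested by Pearson's χ² goodness of
fit, and per-chromosome inheritance mode is called from the pattern of
verdicts under the two models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pairing import DISOMIC, TETRASOMIC, PairingModel

__all__ = [
    "LocusConfiguration",
    "SegregationExpectation",
    "SegregationTest",
    "MarkerTest",
    "ChromosomeInheritanceCall",
    "gamete_distribution",
    "presence_probability",
    "joint_class_expectation",
    "chi_square_gof",
    "test_marker",
    "classify_chromosome",
    "allele_accounting",
    "observed_pattern_counts",
]

#: Homolog slots of a tetraploid locus; 0,1 are seed-parent derived,
#: 2,3 pollen-parent derived in the default BSP layout.
DEFAULT_ORIGINS = ("seed", "seed", "pollen", "pollen")

#: The three ways to split four homologs into two bivalents.
PARTITIONS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass(frozen=True)
class LocusConfiguration:
    """Which homologs of a 4x individual carry which parent-specific alleles.

    ``tracked_alleles`` maps allele identifiers to their carrier homolog
    slots (subsets of {0, 1, 2, 3}).  Dosage is the carrier-set size:
    1 = simplex, 2 = duplex, etc.  All tracked alleles must be absent
    from the tetraploid tester.
    """

    locus_id: str
    chromosome: str
    tracked_alleles: tuple[tuple[str, frozenset[int]], ...]
    origins: tuple[str, str, str, str] = DEFAULT_ORIGINS

    def __post_init__(self) -> None:
        if not self.tracked_alleles:
            raise ValueError(f"locus {self.locus_id}: at least one tracked allele required")
        for allele, carriers in self.tracked_alleles:
            if not carriers or not carriers <= {0, 1, 2, 3}:
                raise ValueError(
                    f"locus {self.locus_id}, allele {allele}: carrier set must be a "
                    f"nonempty subset of the 4 homolog slots, got {set(carriers)}"
                )
        if len(self.origins) != 4:
            raise ValueError("exactly four homolog origin tags required")
        if sorted(set(self.origins)) and any(self.origins.count(o) != 2 for o in set(self.origins)):
            raise ValueError("origin tags must partition the homologs 2 + 2")

    @property
    def allele_ids(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.tracked_alleles)

    def dosage(self, allele_id: str) -> int:
        for a, carriers in self.tracked_alleles:
            if a == allele_id:
                return len(carriers)
        raise KeyError(allele_id)

    def preferred_partition(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Origin-wise bivalent partition (seed homologs pair together)."""
        groups: dict[str, list[int]] = {}
        for idx, origin in enumerate(self.origins):
            groups.setdefault(origin, []).append(idx)
        pair_a, pair_b = (tuple(v) for v in groups.values())
        return pair_a, pair_b  # type: ignore[return-value]


@dataclass(frozen=True)
class SegregationExpectation:
    """Expected progeny class probabilities under one inheritance model."""

    model: str
    patterns: tuple[tuple[bool, ...], ...]
    class_labels: tuple[str, ...]
    probabilities: tuple[float, ...]
    exact: tuple[Fraction, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        total = sum(self.probabilities)
        if any(p < 0 for p in self.probabilities) or abs(total - 1.0) > 1e-12:
            raise ValueError("class probabilities must be >= 0 and sum to 1")


@dataclass(frozen=True)
class SegregationTest:
    """One χ² goodness-of-fit test of observed counts against a model."""

    model: str
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float | None
    df: int
    p_value: float | None
    verdict: str  # 'NS', '*', '**' or 'NT'

    @property
    def testable(self) -> bool:
        return self.verdict != "NT"

    @property
    def significant(self) -> bool:
        return self.verdict in ("*", "**")


@dataclass(frozen=True)
class MarkerTest:
    """Paired tests of one marker under the disomic and tetrasomic models."""

    locus_id: str
    chromosome: str
    disomic: SegregationTest
    tetrasomic: SegregationTest


@dataclass(frozen=True)
class ChromosomeInheritanceCall:
    chromosome: str
    call: str  # tetrasomic | disomic | ambiguous | intermediate | distorted | untestable
    marker_calls: tuple[tuple[str, str], ...]  # (locus_id, per-marker call)


def _partition_order(
    config: LocusConfiguration,
) -> tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]:
    """All three partitions, preferred one first."""
    pref = tuple(tuple(sorted(p)) for p in config.preferred_partition())
    pref_set = frozenset(frozenset(p) for p in pref)
    others = [p for p in PARTITIONS if frozenset(frozenset(q) for q in p) != pref_set]
    return (pref, *others)  # type: ignore[return-value]


def _pattern(config: LocusConfiguration, gamete: tuple[int, int]) -> tuple[bool, ...]:
    members = set(gamete)
    return tuple(bool(members & carriers) for _, carriers in config.tracked_alleles)


def gamete_distribution(
    config: LocusConfiguration,
    model: PairingModel,
    *,
    allow_double_reduction: bool = False,
) -> dict[tuple[bool, ...], Fraction]:
    """Exact distribution over joint allele-presence patterns in gametes.

    Enumerates the three bivalent partitions (weighted by the pairing
    preference) and, within each, the four equally likely
    one-homolog-per-bivalent gametes.  With double reduction rate
    ``alpha`` the gamete is instead two copies of a uniformly chosen
    homolog with probability ``alpha`` (disabled by default: the
    standard expectations assume ``alpha = 0``).
    """
    if model.double_reduction > 0 and not allow_double_reduction:
        raise ValueError(
            "expectations assume no double reduction; pass allow_double_reduction=True "
            "to enumerate with alpha > 0"
        )
    alpha = Fraction(model.double_reduction)
    weights = model.partition_weights()
    partitions = _partition_order(config)

    dist: dict[tuple[bool, ...], Fraction] = {}
    for part, w in zip(partitions, weights):
        for i, j in itertools.product(*part):
            pat = _pattern(config, (i, j))
            dist[pat] = dist.get(pat, Fraction(0)) + (1 - alpha) * w * Fraction(1, 4)
    if alpha > 0:
        for h in range(4):
            pat = _pattern(config, (h, h))
            dist[pat] = dist.get(pat, Fraction(0)) + alpha * Fraction(1, 4)
    assert sum(dist.values()) == 1
    return dist


def presence_probability(
    config: LocusConfiguration, model: PairingModel, allele_id: str | None = None
) -> Fraction:
    """Marginal probability that a gamete carries the given tracked allele."""
    if allele_id is None:
        allele_id = config.allele_ids[0]
    idx = config.allele_ids.index(allele_id)
    dist = gamete_distribution(config, model)
    return sum((p for pat, p in dist.items() if pat[idx]), Fraction(0))


def _class_label(allele_ids: Sequence[str], pattern: Sequence[bool]) -> str:
    return " ".join(f"{a}{'+' if present else '-'}" for a, present in zip(allele_ids, pattern))


def joint_class_expectation(
    config: LocusConfiguration, model: PairingModel
) -> SegregationExpectation:
    """Expected probabilities of all 2^k joint presence/absence classes.

    Structurally impossible classes keep an explicit probability of 0 so
    the χ² step can apply the nontestability rule when such a class is
    observed.
    """
    dist = gamete_distribution(config, model)
    k = len(config.tracked_alleles)
    patterns = tuple(itertools.product((True, False), repeat=k))
    exact = tuple(dist.get(pat, Fraction(0)) for pat in patterns)
    return SegregationExpectation(
        model=model.label or f"b={model.preference}",
        patterns=patterns,
        class_labels=tuple(_class_label(config.allele_ids, pat) for pat in patterns),
        probabilities=tuple(float(p) for p in exact),
        exact=exact,
    )


def chi_square_gof(
    observed: Sequence[int] | Mapping[tuple[bool, ...], int],
    expectation: SegregationExpectation,
) -> SegregationTest:
    """Pearson χ² goodness of fit of observed class counts to a model.

    The statistic is Σ(O−E)²/E over classes with E > 0 and
    df = (#classes with E > 0) − 1, with no continuity correction and no
    pooling.  The test is nontestable (NT) when a class with expected
    count exactly 0 is observed, or when fewer than two classes have
    positive expectation.
    """
    if isinstance(observed, Mapping):
        obs = np.array([int(observed.get(pat, 0)) for pat in expectation.patterns])
    else:
        obs = np.asarray(observed, dtype=int)
        if obs.shape != (len(expectation.patterns),):
            raise ValueError(
                f"observed counts must align with the {len(expectation.patterns)} "
                f"expectation classes, got shape {obs.shape}"
            )
    if (obs < 0).any():
        raise ValueError("observed counts must be nonnegative")
    total = int(obs.sum())
    if total == 0:
        raise ValueError("all-zero observed counts")

    probs = np.asarray(expectation.probabilities)
    expected = probs * total
    support = probs > 0
    df = int(support.sum()) - 1

    if (obs[~support] > 0).any() or df < 1:
        return SegregationTest(
            model=expectation.model,
            observed=tuple(int(o) for o in obs),
            expected=tuple(float(e) for e in expected),
            chi2=None,
            df=df,
            p_value=None,
            verdict="NT",
        )

    chi2 = float(((obs[support] - expected[support]) ** 2 / expected[support]).sum())
    p = float(stats.chi2.sf(chi2, df))
    verdict = "**" if p <= 0.01 else "*" if p <= 0.05 else "NS"
    return SegregationTest(
        model=expectation.model,
        observed=tuple(int(o) for o in obs),
        expected=tuple(float(e) for e in expected),
        chi2=chi2,
        df=df,
        p_value=p,
        verdict=verdict,
    )


def test_marker(
    config: LocusConfiguration,
    observed: Sequence[int] | Mapping[tuple[bool, ...], int],
) -> MarkerTest:
    """Test one marker's observed class counts under both pairing extremes."""
    return MarkerTest(
        locus_id=config.locus_id,
        chromosome=config.chromosome,
        disomic=chi_square_gof(observed, joint_class_expectation(config, DISOMIC)),
        tetrasomic=chi_square_gof(observed, joint_class_expectation(config, TETRASOMIC)),
    )


def _marker_call(disomic: SegregationTest, tetrasomic: SegregationTest) -> str:
    """Inheritance-mode call for one marker from its verdict pair.

    Rejecting one model while the other fits is evidence for the
    fitting model.  Rejecting both indicates segregation distortion
    rather than a pairing regime.  A model whose expectation puts zero
    probability on an observed class is nontestable; the marker is then
    read against the testable model alone.
    """
    if not disomic.testable and not tetrasomic.testable:
        return "untestable"
    if not disomic.testable:
        return "distorted" if tetrasomic.significant else "tetrasomic"
    if not tetrasomic.testable:
        return "distorted" if disomic.significant else "disomic"
    if disomic.significant and tetrasomic.significant:
        return "distorted"
    if disomic.significant:
        return "tetrasomic"
    if tetrasomic.significant:
        return "disomic"
    return "ambiguous"


def classify_chromosome(
    tests: Sequence[MarkerTest], chromosome: str | None = None
) -> ChromosomeInheritanceCall:
    """Combine all marker tests of one chromosome into an inheritance call.

    Untestable markers are dropped; a chromosome with none left is
    untestable.  Ambiguous markers (both models fit) defer to any
    decisive marker; decisive markers that disagree yield an
    intermediate call.
    """
    if not tests:
        raise ValueError("at least one marker test required")
    if chromosome is None:
        chromosome = tests[0].chromosome
    marker_calls = tuple((t.locus_id, _marker_call(t.disomic, t.tetrasomic)) for t in tests)
    calls = [c for _, c in marker_calls if c != "untestable"]
    if not calls:
        call = "untestable"
    else:
        decisive = {c for c in calls if c != "ambiguous"}
        if not decisive:
            call = "ambiguous"
        elif len(decisive) == 1:
            call = decisive.pop()
        else:
            call = "intermediate"
    return ChromosomeInheritanceCall(chromosome=chromosome, call=call, marker_calls=marker_calls)


def allele_accounting(
    parent1: Mapping[str, Iterable[str]],
    parent2: Mapping[str, Iterable[str]],
    progeny: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-locus comparison of parental vs progeny allele inventories.

    For each locus, counts the distinct alleles found across the two
    parents and the distinct alleles observed in the progeny
    (individual); ``deficit = max(0, parental − observed)`` flags
    apparent allele loss (which may reflect segregation in restitutional
    meiosis rather than physical loss).
    """
    loci = sorted(set(parent1) | set(parent2) | set(progeny))
    rows = []
    for locus in loci:
        parental = set(parent1.get(locus, ())) | set(parent2.get(locus, ()))
        observed = set(progeny.get(locus, ()))
        deficit = max(0, len(parental) - len(observed))
        rows.append(
            {
                "locus": locus,
                "sum_of_parents": len(parental),
                "observed_in_progeny": len(observed),
                "deficit": deficit,
                "flagged": deficit > 0,
            }
        )
    return pd.DataFrame(rows)


def observed_pattern_counts(
    presence: pd.DataFrame, config: LocusConfiguration
) -> np.ndarray:
    """Tally progeny joint presence patterns aligned with the expectation classes.

    ``presence`` must have columns ``progeny_id``, ``allele`` and
    ``present`` (0/1) for one locus; progeny missing a tracked allele row
    are treated as lacking it.
    """
    k = len(config.allele_ids)
    patterns = tuple(itertools.product((True, False), repeat=k))
    index = {pat: i for i, pat in enumerate(patterns)}
    wide = (
        presence.pivot_table(
            index="progeny_id", columns="allele", values="present", aggfunc="first"
        )
        .reindex(columns=list(config.allele_ids))
        .fillna(0)
        .astype(int)
    )
    counts = np.zeros(len(patterns), dtype=int)
    for _, row in wide.iterrows():
        counts[index[tuple(bool(v) for v in row)]] += 1
    return counts


def marker_test_table(tests: Sequence[MarkerTest]) -> pd.DataFrame:
    """Flat per-marker report with both models' statistics and verdicts."""
    rows = []
    for t in tests:
        rows.append(
            {
                "locus": t.locus_id,
                "chromosome": t.chromosome,
                "chi2_disomic": t.disomic.chi2 if t.disomic.chi2 is not None else math.nan,
                "df_disomic": t.disomic.df,
                "p_disomic": t.disomic.p_value if t.disomic.p_value is not None else math.nan,
                "verdict_disomic": t.disomic.verdict,
                "chi2_tetrasomic": t.tetrasomic.chi2
                if t.tetrasomic.chi2 is not None
                else math.nan,
                "df_tetrasomic": t.tetrasomic.df,
                "p_tetrasomic": t.tetrasomic.p_value
                if t.tetrasomic.p_value is not None
                else math.nan,
                "verdict_tetrasomic": t.tetrasomic.verdict,
            }
        )
    return pd.DataFrame(rows)
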