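"""Synthetic data generators emulating a bilateral sexual polyploidization study.

The generators reproduce the statistical structure the downstream
analyses assume, so the whole pipeline is testable without any external
download:

* a 2x × 2x cross in which both diploid parents produce a mixture of n
  and 2n gametes (the seed parent at a high rate, emulating a plant
  with 55–70% 2n eggs), yielding full-sib 2x, 3x and 4x hybrids — the
  4x ones by union of two 2n gametes (BSP);
* tetraploid meiosis of a BSP individual under a configurable pairing
  preference and double-reduction rate, feeding the 4x × 4x test-cross
  marker segregation analysed by :mod:`polyploidkit.segregation`;
* MSAP band matrices for two heterozygous parents plus hybrids with
  stated de novo methylation / demethylation site-class frequencies;
* log2 expression matrices for parents + 2x + 3 × 4x hybrid genotypes
  with three replicates each and a configurable fraction of
  nonadditive genes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import GROUPS, ExpressionStudy
from .msap import SITE_CLASSES, classify_site, state_to_bands
from .pairing import MAX_DOUBLE_REDUCTION, PairingModel
from .segregation import LocusConfiguration, joint_class_expectation

__all__ = [
    "DiploidParent",
    "TetraploidIndividual",
    "Individual",
    "SimulationConfig",
    "simulate_bsp_cross",
    "simulate_tetraploid_meiosis",
    "simulate_marker_counts",
    "simulate_msap_profiles",
    "MsapSimulation",
    "simulate_expression_matrix",
    "progeny_genotype_table",
    "default_parents",
]

RestitutionMode = Literal["FDR_no_crossover", "SDR_no_crossover"]


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs of the meiosis/cross simulators.

    ``pairing_preference`` is the probability b that tetraploid meiosis
    adopts the origin-wise bivalent partition outright (b = 1: complete
    preferential pairing; b = 0: random among all three partitions).
    ``double_reduction_alpha`` is the per-chromosome rate of gametes
    carrying two copies of one homolog (theoretical maximum 1/6,
    default 0 as assumed by the segregation expectations).
    """

    n_progeny: int
    pairing_preference: float = 0.0
    double_reduction_alpha: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be positive")
        if not 0.0 <= self.pairing_preference <= 1.0:
            raise ValueError("pairing_preference must be in [0, 1]")
        if not 0.0 <= self.double_reduction_alpha <= MAX_DOUBLE_REDUCTION + 1e-12:
            raise ValueError("double_reduction_alpha must be in [0, 1/6]")

    def pairing_model(self, label: str = "") -> PairingModel:
        return PairingModel(self.pairing_preference, self.double_reduction_alpha, label)


@dataclass(frozen=True)
class DiploidParent:
    """A diploid meiotic mutant producing a mixture of n and 2n gametes.

    ``genome`` maps each chromosome to its two homolog labels;
    ``alleles`` maps each locus to {homolog label: allele id}.  Under
    first-division restitution without crossover (FDR) a 2n gamete
    carries both homologs of every chromosome, transmitting the
    parent's full heterozygosity; under SDR it carries two copies of
    one homolog.
    """

    id: str
    genome: Mapping[str, tuple[str, str]]
    alleles: Mapping[str, Mapping[str, str]]
    locus_chromosome: Mapping[str, str]
    two_n_gamete_rate: float = 0.0
    restitution_mode: RestitutionMode = "FDR_no_crossover"

    def __post_init__(self) -> None:
        if not 0.0 <= self.two_n_gamete_rate <= 1.0:
            raise ValueError("two_n_gamete_rate must be in [0, 1]")
        for chrom, homs in self.genome.items():
            if len(homs) != 2:
                raise ValueError(f"chromosome {chrom}: exactly 2 homologs required")
        for locus, chrom in self.locus_chromosome.items():
            if chrom not in self.genome:
                raise ValueError(f"locus {locus} maps to unknown chromosome {chrom}")

    def gamete(self, rng: np.random.Generator) -> tuple[dict[str, tuple[str, ...]], bool]:
        """One gamete: {chromosome: homolog labels}, and whether it is 2n."""
        unreduced = bool(rng.random() < self.two_n_gamete_rate)
        out: dict[str, tuple[str, ...]] = {}
        for chrom, (h1, h2) in self.genome.items():
            if not unreduced:
                out[chrom] = (h1 if rng.random() < 0.5 else h2,)
            elif self.restitution_mode == "FDR_no_crossover":
                out[chrom] = (h1, h2)
            else:  # SDR: homozygose one homolog
                h = h1 if rng.random() < 0.5 else h2
                out[chrom] = (h, h)
        return out, unreduced


@dataclass(frozen=True)
class Individual:
    """A cross progeny: homolog copies per chromosome, tagged by parental origin."""

    id: str
    ploidy: int
    homologs: Mapping[str, tuple[tuple[str, str], ...]]  # chrom -> ((label, origin), ...)


@dataclass(frozen=True)
class TetraploidIndividual:
    """A 4x individual with 2 seed-parent- and 2 pollen-parent-derived homologs."""

    id: str
    homologs: Mapping[str, tuple[tuple[str, str], ...]]

    def __post_init__(self) -> None:
        for chrom, homs in self.homologs.items():
            if len(homs) != 4:
                raise ValueError(f"chromosome {chrom}: exactly 4 homolog copies required")
            origins = [o for _, o in homs]
            if any(origins.count(o) != 2 for o in set(origins)):
                raise ValueError(
                    f"chromosome {chrom}: origin tags must partition the homologs 2 + 2"
                )

    @classmethod
    def from_individual(cls, ind: Individual) -> "TetraploidIndividual":
        if ind.ploidy != 4:
            raise ValueError(f"individual {ind.id} has ploidy {ind.ploidy}, not 4")
        return cls(id=ind.id, homologs=ind.homologs)


def simulate_bsp_cross(
    p1: DiploidParent, p2: DiploidParent, cfg: SimulationConfig
) -> list[Individual]:
    """Cross two diploids producing n/2n gamete mixtures.

    Each progeny unites one egg (from ``p1``) and one pollen grain
    (from ``p2``); tetraploids arise exactly when both gametes are 2n,
    triploids from one 2n gamete, diploids otherwise.  Parents must
    share the locus catalogue and chromosome set.
    """
    if set(p1.genome) != set(p2.genome) or set(p1.locus_chromosome) != set(
        p2.locus_chromosome
    ):
        raise ValueError("parents must share chromosome set and locus catalogue")
    rng = np.random.default_rng(cfg.seed)
    progeny = []
    for i in range(cfg.n_progeny):
        egg, _ = p1.gamete(rng)
        pollen, _ = p2.gamete(rng)
        homologs = {
            chrom: tuple((h, "seed") for h in egg[chrom])
            + tuple((h, "pollen") for h in pollen[chrom])
            for chrom in p1.genome
        }
        ploidy = len(next(iter(homologs.values())))
        progeny.append(Individual(id=f"S{i + 1}", ploidy=ploidy, homologs=homologs))
    return progeny


def progeny_genotype_table(
    progeny: Sequence[Individual], p1: DiploidParent, p2: DiploidParent
) -> pd.DataFrame:
    """Long-format allele presence table (progeny_id, ploidy, locus, allele, present)."""
    allele_universe: dict[str, set[str]] = {}
    carrier: dict[tuple[str, str], set[str]] = {}
    for parent in (p1, p2):
        for locus, hom_map in parent.alleles.items():
            for hom, allele in hom_map.items():
                allele_universe.setdefault(locus, set()).add(allele)
                carrier.setdefault((locus, allele), set()).add(hom)
    rows = []
    for ind in progeny:
        for locus, alleles in sorted(allele_universe.items()):
            chrom = p1.locus_chromosome[locus]
            labels = {h for h, _ in ind.homologs[chrom]}
            for allele in sorted(alleles):
                present = int(bool(labels & carrier[(locus, allele)]))
                rows.append(
                    {
                        "progeny_id": ind.id,
                        "ploidy": ind.ploidy,
                        "locus": locus,
                        "allele": allele,
                        "present": present,
                    }
                )
    return pd.DataFrame(rows)


def _partition_index(origins: Sequence[str]) -> tuple[tuple[tuple[int, int], tuple[int, int]], ...]:
    """The three bivalent partitions of slots 0-3, origin-wise partition first."""
    groups: dict[str, list[int]] = {}
    for idx, origin in enumerate(origins):
        groups.setdefault(origin, []).append(idx)
    pref = tuple(tuple(g) for g in groups.values())
    pref_set = frozenset(frozenset(g) for g in pref)
    all_parts = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))
    others = [p for p in all_parts if frozenset(frozenset(q) for q in p) != pref_set]
    return (pref, *others)  # type: ignore[return-value]


def _sample_gamete_slots(
    origins: Sequence[str], b: float, alpha: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n gametes as (n, 2) arrays of homolog slot indices (equal slots = double reduction)."""
    partitions = _partition_index(origins)
    weights = [b + (1 - b) / 3, (1 - b) / 3, (1 - b) / 3]
    part_idx = rng.choice(3, size=n, p=weights)
    sides = rng.integers(0, 2, size=(n, 2))
    gametes = np.empty((n, 2), dtype=int)
    for pi, part in enumerate(partitions):
        mask = part_idx == pi
        pair_a, pair_b = np.asarray(part[0]), np.asarray(part[1])
        gametes[mask, 0] = pair_a[sides[mask, 0]]
        gametes[mask, 1] = pair_b[sides[mask, 1]]
    if alpha > 0:
        dr = rng.random(n) < alpha
        dup = rng.integers(0, 4, size=n)
        gametes[dr, 0] = dup[dr]
        gametes[dr, 1] = dup[dr]
    return gametes


def simulate_tetraploid_meiosis(
    parent: TetraploidIndividual, cfg: SimulationConfig, n_gametes: int
) -> list[dict[str, tuple[str, str]]]:
    """Gametes of a tetraploid: per chromosome, two homolog labels each.

    Meiosis picks a bivalent partition per chromosome (the origin-wise
    one with probability b + (1−b)/3) and one homolog per bivalent;
    with probability alpha the gamete instead carries two copies of one
    uniformly chosen homolog (double reduction).
    """
    if n_gametes < 1:
        raise ValueError("n_gametes must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    per_chrom = {}
    for chrom, homs in parent.homologs.items():
        origins = [o for _, o in homs]
        slots = _sample_gamete_slots(
            origins, cfg.pairing_preference, cfg.double_reduction_alpha, n_gametes, rng
        )
        labels = np.array([h for h, _ in homs], dtype=object)
        per_chrom[chrom] = np.stack([labels[slots[:, 0]], labels[slots[:, 1]]], axis=1)
    return [
        {chrom: (arr[i, 0], arr[i, 1]) for chrom, arr in per_chrom.items()}
        for i in range(n_gametes)
    ]


def simulate_marker_counts(
    config: LocusConfiguration,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Observed joint-class counts of one marker in a simulated test cross.

    Simulates ``cfg.n_progeny`` gametes of the BSP parent under the
    configured pairing regime; since the tester carries none of the
    tracked alleles, each progeny's presence pattern is the gamete's.
    Counts align with the class order of
    :func:`polyploidkit.segregation.joint_class_expectation`.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    slots = _sample_gamete_slots(
        config.origins,
        cfg.pairing_preference,
        cfg.double_reduction_alpha,
        cfg.n_progeny,
        rng,
    )
    k = len(config.tracked_alleles)
    patterns = list(itertools.product((True, False), repeat=k))
    index = {pat: i for i, pat in enumerate(patterns)}
    counts = np.zeros(len(patterns), dtype=int)
    carrier_sets = [carriers for _, carriers in config.tracked_alleles]
    for g0, g1 in slots:
        members = {int(g0), int(g1)}
        pat = tuple(bool(members & c) for c in carrier_sets)
        counts[index[pat]] += 1
    return counts


# --- MSAP profile generator -------------------------------------------------

_ALL_STATES = ("U", "H", "F", "X")

#: All (parent1, parent2, hybrid) state triples grouped by the class the
#: scorer assigns them, so generated data are consistent by construction.
_TRIPLES_BY_CLASS: dict[str, list[tuple[str, str, str]]] = {}
for _t in itertools.product(_ALL_STATES, repeat=3):
    _TRIPLES_BY_CLASS.setdefault(classify_site(*_t), []).append(_t)

_CLASS_ALIASES = {
    "de_novo": "de_novo_methylation",
    "parental_p1": "parental_P1_like",
    "parental_p2": "parental_P2_like",
}


@dataclass
class MsapSimulation:
    """Simulated MSAP assay: band matrices plus ground-truth labels."""

    bands: pd.DataFrame  # (individual, lane) x sites, 0/1
    truth: pd.DataFrame  # site x (class, state_p1, state_p2)
    parents: tuple[str, str]
    hybrids: tuple[str, ...]


def simulate_msap_profiles(
    n_sites: int,
    event_rates: Mapping[str, float],
    n_hybrids: int = 6,
    seed: int = 0,
) -> MsapSimulation:
    """MSAP band matrices for two parents plus hybrids with known site classes.

    ``event_rates`` gives the fraction of sites per inheritance class
    (keys among parental_P1_like, parental_P2_like, de_novo_methylation
    / de_novo, demethylation, ambiguous, excluded); the remainder is
    monomorphic.  One class is drawn per site and shared by all
    hybrids — the two parents have a single band pattern per site, so
    it must stay compatible with every hybrid's class — while each
    hybrid's state is drawn independently among the states realizing
    that class given the parents' states.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    rates: dict[str, float] = {}
    for key, frac in event_rates.items():
        cls = _CLASS_ALIASES.get(key, key)
        if cls not in SITE_CLASSES or cls == "monomorphic":
            raise ValueError(f"unknown site class {key!r}")
        if frac < 0:
            raise ValueError(f"negative fraction for class {key!r}")
        rates[cls] = rates.get(cls, 0.0) + float(frac)
    if sum(rates.values()) > 1.0 + 1e-12:
        raise ValueError("class fractions must sum to <= 1")
    rates["monomorphic"] = max(0.0, 1.0 - sum(rates.values()))

    rng = np.random.default_rng(seed)
    classes = list(rates)
    probs = np.array([rates[c] for c in classes])
    site_classes = rng.choice(len(classes), size=n_sites, p=probs / probs.sum())

    # Group admissible triples by parent-state pair per class.
    by_class: dict[str, list[tuple[tuple[str, str], list[str]]]] = {}
    for cls, triples in _TRIPLES_BY_CLASS.items():
        pairs: dict[tuple[str, str], list[str]] = {}
        for p1, p2, h in triples:
            pairs.setdefault((p1, p2), []).append(h)
        by_class[cls] = sorted(pairs.items())

    hybrids = tuple(f"H{i + 1}" for i in range(n_hybrids))
    parents = ("P1", "P2")
    state_rows: dict[str, list[str]] = {ind: [] for ind in parents + hybrids}
    truth_rows = []
    for s in range(n_sites):
        cls = classes[site_classes[s]]
        options = by_class[cls]
        (p1, p2), hyb_states = options[rng.integers(len(options))]
        state_rows["P1"].append(p1)
        state_rows["P2"].append(p2)
        for hyb in hybrids:
            state_rows[hyb].append(hyb_states[rng.integers(len(hyb_states))])
        truth_rows.append({"site": f"site_{s + 1}", "class": cls, "state_p1": p1, "state_p2": p2})

    sites = [f"site_{s + 1}" for s in range(n_sites)]
    band_rows = {}
    for ind, states in state_rows.items():
        pairs = [state_to_bands(st) for st in states]
        band_rows[(ind, "HpaII")] = [p[0] for p in pairs]
        band_rows[(ind, "MspI")] = [p[1] for p in pairs]
    bands = pd.DataFrame.from_dict(band_rows, orient="index", columns=sites)
    bands.index = pd.MultiIndex.from_tuples(bands.index, names=["individual", "lane"])
    truth = pd.DataFrame(truth_rows).set_index("site")
    return MsapSimulation(bands=bands, truth=truth, parents=parents, hybrids=hybrids)


# --- Expression matrix generator --------------------------------------------

DEFAULT_GENOTYPES: dict[str, str] = {
    "PG-F9": "parent",
    "12P": "parent",
    "S8-2x": "hybrid2x",
    "S16-2x": "hybrid2x",
    "S24-2x": "hybrid2x",
    "S29-4x": "hybrid4x",
    "S48-4x": "hybrid4x",
    "S60-4x": "hybrid4x",
}


def simulate_expression_matrix(
    n_genes: int,
    frac_nonadditive: float = 0.1,
    effect_log2fc: float = 2.0,
    sigma: float = 0.5,
    n_replicates: int = 3,
    seed: int = 0,
    genotypes: Mapping[str, str] | None = None,
    affected_groups: Sequence[str] = ("hybrid2x", "hybrid4x"),
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Log2 expression matrix with a known set of nonadditive genes.

    The default design mirrors the study layout: two parents, three 2x
    and three 4x hybrid genotypes, three biological replicates each
    (24 samples).  Additive genes share one mean across all groups;
    nonadditive genes have the hybrid-group means of ``affected_groups``
    shifted by ±``effect_log2fc`` from the parental mean.  Replicate
    noise is Gaussian on the log2 scale (log-normal on the linear
    scale) with standard deviation ``sigma``.  Returns the study and a
    per-gene truth table (``nonadditive``, ``true_log2fc``).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not 0.0 <= frac_nonadditive <= 1.0:
        raise ValueError("frac_nonadditive must be in [0, 1]")
    if effect_log2fc <= 0 and frac_nonadditive > 0:
        raise ValueError("effect_log2fc must be > 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n_replicates < 2:
        raise ValueError("at least 2 replicates per genotype required")
    genotypes = dict(genotypes or DEFAULT_GENOTYPES)
    unknown = set(genotypes.values()) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    baseline = rng.normal(8.0, 1.5, size=n_genes)
    n_true = int(round(frac_nonadditive * n_genes))
    true_idx = rng.choice(n_genes, size=n_true, replace=False)
    signs = rng.choice((-1.0, 1.0), size=n_true)
    shift = np.zeros(n_genes)
    shift[true_idx] = signs * effect_log2fc

    samples = []
    columns = {}
    for genotype, group in genotypes.items():
        mean = baseline + (shift if group in affected_groups else 0.0)
        for rep in range(1, n_replicates + 1):
            name = f"{genotype}_r{rep}"
            columns[name] = mean + rng.normal(0.0, sigma, size=n_genes)
            samples.append(
                {"sample": name, "genotype": genotype, "group": group, "replicate": rep}
            )
    genes = pd.Index([f"gene_{i + 1}" for i in range(n_genes)], name="gene")
    matrix = pd.DataFrame(columns, index=genes)
    sheet = pd.DataFrame(samples).set_index("sample")
    truth = pd.DataFrame(
        {"nonadditive": shift != 0.0, "true_log2fc": shift}, index=genes
    )
    return ExpressionStudy(matrix=matrix, samples=sheet), truth


def default_parents(
    n_chromosomes: int = 8,
    two_n_egg_rate: float = 0.6,
    two_n_pollen_rate: float = 0.1,
) -> tuple[DiploidParent, DiploidParent]:
    """A pair of heterozygous diploid parents with one SSR locus per chromosome.

    Every homolog carries a distinct allele, so allele transmission is
    fully traceable through the cross.  The default 2n-gamete rates put
    the seed parent in the reported 55–70% 2n-egg range and keep the 4x
    progeny fraction near the few-percent level observed for this type
    of cross.
    """
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    genome1 = {c: (f"{c}.F9a", f"{c}.F9b") for c in chroms}
    genome2 = {c: (f"{c}.12Pa", f"{c}.12Pb") for c in chroms}
    loci = {f"ssr_{c}": c for c in chroms}
    alleles1 = {
        locus: {h: f"{locus}:{h.split('.')[1]}" for h in genome1[chrom]}
        for locus, chrom in loci.items()
    }
    alleles2 = {
        locus: {h: f"{locus}:{h.split('.')[1]}" for h in genome2[chrom]}
        for locus, chrom in loci.items()
    }
    p1 = DiploidParent(
        id="PG-F9",
        genome=genome1,
        alleles=alleles1,
        locus_chromosome=loci,
        two_n_gamete_rate=two_n_egg_rate,
        restitution_mode="FDR_no_crossover",
    )
    p2 = DiploidParent(
        id="12P",
        genome=genome2,
        alleles=alleles2,
        locus_chromosome=loci,
        two_n_gamete_rate=two_n_pollen_rate,
        restitution_mode="FDR_no_crossover",
    )
    return p1, p2
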