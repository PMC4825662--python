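"""Nonadditive gene-expression analysis of a BSP cross.

The transcriptome design behind this module contrasts three groups of
samples from one diploid × diploid cross that yielded both diploid and
tetraploid (bilateral sexual polyploidization) full-sib hybrids: the
two parents, the 2x hybrids and the 4x hybrids.  Three two-class
unpaired contrasts partition the differentially expressed genes:

* HS  (hybridization-sensitive)                    = DE(parents, 2x)
* HPS (hybridization- and polyploidization-sensitive) = DE(parents, 4x)
* PS  (polyploidization-sensitive)                 = DE(2x, 4x) \\ DE(parents, 4x)

A gene is differentially expressed when |log2FC| > 1 and the
Benjamini–Hochberg adjusted p-value is < 0.05.  Per-gene testing uses
Welch's t on the normalized log2 matrix; the test is pluggable so a
moderated statistic can be substituted.  The module also provides the
over/under-expression summary of per-genotype vs parental-mean
contrasts, hypergeometric term enrichment, and 2^-ΔΔCt relative
quantification for qPCR validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionStudy",
    "GenePartition",
    "contrast",
    "build_partition",
    "nonadditive_partition",
    "ou_summary",
    "ou_counts_from_contrasts",
    "percent_of_universe",
    "term_enrichment",
    "ddct",
]

GROUPS = ("parent", "hybrid2x", "hybrid4x")


@dataclass
class ExpressionStudy:
    """Normalized log2 expression matrix plus its sample annotations.

    ``matrix`` is genes × samples; ``samples`` is indexed by sample name
    with columns ``genotype``, ``group`` (parent / hybrid2x / hybrid4x)
    and ``replicate``.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.matrix.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)}")
        for col in ("genotype", "group"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks required column {col!r}")
        unknown = set(self.samples["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}; expected {GROUPS}")

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.samples.index[self.samples["group"] == group]
        return [s for s in self.matrix.columns if s in set(sel)]

    def samples_of_genotype(self, genotype: str) -> list[str]:
        sel = self.samples.index[self.samples["genotype"] == genotype]
        return [s for s in self.matrix.columns if s in set(sel)]


@dataclass(frozen=True)
class GenePartition:
    """HS/HPS/PS gene sets with the underlying DE sets."""

    hs: frozenset[str]
    hps: frozenset[str]
    ps: frozenset[str]
    de_parents_2x: frozenset[str]
    de_parents_4x: frozenset[str]
    de_2x_4x: frozenset[str]


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Welch t and p with explicit zero-variance handling."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        fallback_t = np.zeros_like(diff)
        fallback_t[diff > 0] = np.inf
        fallback_t[diff < 0] = -np.inf
        t = np.where(degenerate, fallback_t, t)
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def contrast(
    study: ExpressionStudy,
    class_a: str | Sequence[str],
    class_b: str | Sequence[str],
    *,
    log2fc_cutoff: float = 1.0,
    fdr: float = 0.05,
    test: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Two-class unpaired contrast of all genes (first minus second class).

    ``class_a``/``class_b`` are group labels or explicit sample lists.
    Returns a per-gene table with ``log2fc``, ``t``, raw and
    BH-adjusted p, the joint significance flag (|log2FC| > cutoff and
    adjusted p < fdr) and the direction in the first class.
    """
    samples_a = study.samples_in_group(class_a) if isinstance(class_a, str) else list(class_a)
    samples_b = study.samples_in_group(class_b) if isinstance(class_b, str) else list(class_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each contrasted class needs at least 2 samples")
    a = study.matrix[samples_a].to_numpy(dtype=float)
    b = study.matrix[samples_b].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t, p = (test or _welch_t)(a, b)
    p_adj = multipletests(p, method="fdr_bh")[1]
    significant = (np.abs(log2fc) > log2fc_cutoff) & (p_adj < fdr)
    direction = np.where(log2fc > 0, "over", np.where(log2fc < 0, "under", "none"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index(study.matrix.index, name="gene"),
    )


def significant_genes(result: pd.DataFrame) -> frozenset[str]:
    return frozenset(result.index[result["significant"]])


def build_partition(
    de_p2x: Iterable[str], de_p4x: Iterable[str], de_2x4x: Iterable[str]
) -> GenePartition:
    """HS/HPS/PS partition from the three DE gene sets.

    PS genes differ between 2x and 4x hybrids but not between parents
    and 4x hybrids, so they respond to the ploidy change alone.
    """
    de_p2x, de_p4x, de_2x4x = frozenset(de_p2x), frozenset(de_p4x), frozenset(de_2x4x)
    return GenePartition(
        hs=de_p2x,
        hps=de_p4x,
        ps=de_2x4x - de_p4x,
        de_parents_2x=de_p2x,
        de_parents_4x=de_p4x,
        de_2x_4x=de_2x4x,
    )


def nonadditive_partition(
    study: ExpressionStudy, *, log2fc_cutoff: float = 1.0, fdr: float = 0.05
) -> tuple[GenePartition, dict[str, pd.DataFrame]]:
    """Run the three group contrasts and build the HS/HPS/PS partition."""
    kw = dict(log2fc_cutoff=log2fc_cutoff, fdr=fdr)
    results = {
        "parents_vs_2x": contrast(study, "parent", "hybrid2x", **kw),
        "parents_vs_4x": contrast(study, "parent", "hybrid4x", **kw),
        "2x_vs_4x": contrast(study, "hybrid2x", "hybrid4x", **kw),
    }
    partition = build_partition(
        significant_genes(results["parents_vs_2x"]),
        significant_genes(results["parents_vs_4x"]),
        significant_genes(results["2x_vs_4x"]),
    )
    return partition, results


def percent_of_universe(count: int, universe: int, ndigits: int = 1) -> float:
    """Percentage of the gene universe, rounded from full precision."""
    if universe <= 0:
        raise ValueError("universe size must be positive")
    return round(100.0 * count / universe, ndigits)


def ou_summary(counts: pd.DataFrame, universe: int) -> pd.DataFrame:
    """Over/under-expressed summary of per-genotype vs parental-mean contrasts.

    ``counts`` needs columns ``genotype``, ``ploidy`` and the
    ``overexpressed``/``underexpressed`` gene counts of each progeny
    genotype against the parental mean.  Adds per-genotype O/U ratio,
    O+U and percent of the gene universe (two decimals each), plus one
    mean row per ploidy: counts are averaged at full precision, while
    the mean ratio averages the rounded per-genotype ratios — the
    convention consistent with the reference summaries this layout
    mirrors.
    """
    if universe <= 0:
        raise ValueError("universe size must be positive")
    rows = []
    for _, rec in counts.iterrows():
        o, u = int(rec["overexpressed"]), int(rec["underexpressed"])
        rows.append(
            {
                "genotype": rec["genotype"],
                "ploidy": rec["ploidy"],
                "overexpressed": float(o),
                "underexpressed": float(u),
                "ratio_ou": round(o / u, 2) if u else np.nan,
                "de_total": float(o + u),
                "pct_de": round(100.0 * (o + u) / universe, 2),
            }
        )
    table = pd.DataFrame(rows)
    means = []
    for ploidy, grp in table.groupby("ploidy", sort=False):
        o_mean = grp["overexpressed"].mean()
        u_mean = grp["underexpressed"].mean()
        total_mean = grp["de_total"].mean()
        means.append(
            {
                "genotype": "Mean",
                "ploidy": ploidy,
                "overexpressed": o_mean,
                "underexpressed": u_mean,
                "ratio_ou": round(grp["ratio_ou"].mean(), 2),
                "de_total": total_mean,
                "pct_de": round(100.0 * total_mean / universe, 2),
            }
        )
    return pd.concat([table, pd.DataFrame(means)], ignore_index=True)


def ou_counts_from_contrasts(
    study: ExpressionStudy,
    progeny_genotypes: Mapping[str, str],
    *,
    log2fc_cutoff: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """O/U counts per progeny genotype contrasted against the parental group.

    ``progeny_genotypes`` maps genotype name to its ploidy label
    (e.g. ``{"S8-2x": "2x"}``).
    """
    parent_samples = study.samples_in_group("parent")
    rows = []
    for genotype, ploidy in progeny_genotypes.items():
        res = contrast(
            study,
            study.samples_of_genotype(genotype),
            parent_samples,
            log2fc_cutoff=log2fc_cutoff,
            fdr=fdr,
        )
        sig = res[res["significant"]]
        rows.append(
            {
                "genotype": genotype,
                "ploidy": ploidy,
                "overexpressed": int((sig["direction"] == "over").sum()),
                "underexpressed": int((sig["direction"] == "under").sum()),
            }
        )
    return pd.DataFrame(rows)


def term_enrichment(
    test_set: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of terms in a gene set.

    For a term carried by K of the N universe genes, observing k
    carriers in a test set of n genes has over-representation tail
    P(X >= k) and under-representation tail P(X <= k) under
    Hypergeometric(N, K, n).  Unannotated genes count toward N and n.
    BH adjustment is applied to the over-representation p-values.
    """
    test = frozenset(test_set)
    genes = frozenset(universe)
    if not test:
        raise ValueError("empty test set")
    if not test <= genes:
        raise ValueError("test set must be a subset of the universe")
    if isinstance(annotation, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for gene, term in zip(annotation["gene"], annotation["term"]):
            mapping.setdefault(gene, set()).add(term)
    else:
        mapping = {g: set(ts) for g, ts in annotation.items()}
    term_carriers: dict[str, set[str]] = {}
    for gene in genes:
        for term in mapping.get(gene, ()):
            term_carriers.setdefault(term, set()).add(gene)
    n_univ, n_test = len(genes), len(test)
    rows = []
    for term in sorted(term_carriers):
        carriers = term_carriers[term]
        big_k = len(carriers)
        k = len(carriers & test)
        p_over = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_test))
        p_under = float(stats.hypergeom.cdf(k, n_univ, big_k, n_test))
        fold = (k / n_test) / (big_k / n_univ)
        rows.append(
            {
                "term": term,
                "universe_carriers": big_k,
                "test_carriers": k,
                "fold": fold,
                "p_over": p_over,
                "p_under": p_under,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_over_adj"] = multipletests(table["p_over"], method="fdr_bh")[1]
    return table


def ddct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Relative expression by the 2^-ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_reference) in the test sample minus the same
    difference in the calibrator sample; the result is the fold change
    of the target gene relative to the calibrator, normalized to the
    endogenous reference gene.
    """
    values = (ct_target_test, ct_ref_test, ct_target_cal, ct_ref_cal)
    if not all(np.isfinite(v) for v in values):
        raise ValueError("Ct values must be finite")
    ddct_value = (ct_target_test - ct_ref_test) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct_value))
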