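"""Reference summary counts from the alfalfa BSP study this package models.

Two diploid *Medicago sativa* meiotic mutants (PG-F9 × 12P) were
crossed to produce full-sib diploid (S8, S16, S24) and tetraploid
(S29, S48, S60) hybrids, the tetraploids by bilateral sexual
polyploidization.  These tables carry the published per-genotype
summaries used as worked examples and reference inputs: MSAP
site-class counts (from which the MR statistic is recomputed) and the
numbers of genes over-/under-expressed relative to the parental mean
(from which the over/under summary table is recomputed).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "msap_site_class_counts",
    "nonadditive_gene_counts",
    "GENE_UNIVERSE",
    "PARENT_DE_GENES",
]

#: Number of genes probed on the expression array (the universe used
#: for all percentage-of-genes figures).
GENE_UNIVERSE = 41_538

#: Genes differentially expressed between the two parental genotypes.
PARENT_DE_GENES = 4_839

_MSAP_ROWS = [
    # genotype, ploidy, total scored, monomorphic, PG-F9-like, 12P-like,
    # demethylation, de novo methylation, ambiguous
    ("S8", "2x", 221, 100, 41, 28, 24, 22, 6),
    ("S16", "2x", 235, 101, 54, 21, 26, 27, 6),
    ("S24", "2x", 234, 87, 43, 39, 16, 46, 3),
    ("S29", "4x", 250, 90, 63, 30, 30, 33, 4),
    ("S48", "4x", 242, 79, 50, 42, 42, 28, 1),
    ("S60", "4x", 250, 87, 41, 43, 43, 32, 4),
]

_OU_ROWS = [
    # genotype, ploidy, overexpressed, underexpressed (vs parental mean)
    ("S8-2x", "2x", 236, 74),
    ("S16-2x", "2x", 240, 117),
    ("S24-2x", "2x", 562, 490),
    ("S29-4x", "4x", 432, 299),
    ("S48-4x", "4x", 818, 680),
    ("S60-4x", "4x", 393, 404),
]


def msap_site_class_counts() -> pd.DataFrame:
    """MSAP site-class counts per hybrid genotype.

    ``total`` is the number of scored sites; the class columns sum to
    it row-wise.  MR for a genotype is its de novo methylation count
    over its demethylation count (equal denominators cancel).
    """
    return pd.DataFrame(
        _MSAP_ROWS,
        columns=[
            "genotype",
            "ploidy",
            "total",
            "monomorphic",
            "parental_P1_like",
            "parental_P2_like",
            "demethylation",
            "de_novo_methylation",
            "ambiguous",
        ],
    )


def nonadditive_gene_counts() -> pd.DataFrame:
    """Genes over-/under-expressed in each progeny genotype vs the parental mean."""
    return pd.DataFrame(
        _OU_ROWS, columns=["genotype", "ploidy", "overexpressed", "underexpressed"]
    )
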