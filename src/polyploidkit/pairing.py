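"""Chromosome-pairing models for tetraploid meiosis.

A tetraploid forms two bivalents per chromosome at meiosis.  The four
homologs can be split into two pairs in three ways; which partition is
used determines the segregation model:

* complete preferential pairing (homologs pair strictly by parental
  origin) gives disomic inheritance, the hallmark of allopolyploids;
* random choice among all three partitions gives tetrasomic
  inheritance, the hallmark of autopolyploids.

``PairingModel`` interpolates between the extremes with a preference
coefficient ``b``: the origin-wise partition is used with probability
``b + (1 - b)/3`` and each alternative partition with probability
``(1 - b)/3``, so ``b = 0`` is fully random and ``b = 1`` fully
preferential.  Double reduction — a gamete receiving two copies of the
same homolog, possible only via multivalents — is modeled as a
per-chromosome event rate ``alpha`` with the theoretical maximum 1/6.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

MAX_DOUBLE_REDUCTION = 1.0 / 6.0


@dataclass(frozen=True)
class PairingModel:
    """Meiotic pairing regime of a tetraploid.

    Parameters
    ----------
    preference:
        Probability ``b`` in [0, 1] that meiosis adopts the preferred
        (origin-wise) bivalent partition outright; the residual mass is
        spread uniformly over all three partitions.
    double_reduction:
        Per-chromosome probability ``alpha`` in [0, 1/6] that a gamete
        carries two copies of one homolog.
    label:
        Free-text name used in reports (e.g. ``"disomic"``).
    """

    preference: float
    double_reduction: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.preference <= 1.0:
            raise ValueError(f"pairing preference must be in [0, 1], got {self.preference}")
        if not 0.0 <= self.double_reduction <= MAX_DOUBLE_REDUCTION + 1e-12:
            raise ValueError(
                f"double reduction rate must be in [0, 1/6], got {self.double_reduction}"
            )

    def partition_weights(self) -> tuple[Fraction, Fraction, Fraction]:
        """Exact probabilities (preferred, alt1, alt2) of the three partitions."""
        b = Fraction(self.preference)
        pref = b + (1 - b) / 3
        alt = (1 - b) / 3
        return pref, alt, alt


#: Complete preferential pairing: strict origin-wise bivalents.
DISOMIC = PairingModel(preference=1.0, double_reduction=0.0, label="disomic")

#: Complete random pairing among the three partitions.
TETRASOMIC = PairingModel(preference=0.0, double_reduction=0.0, label="tetrasomic")
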