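# polyploidkit

Analysis toolkit for **sexual polyploidization** experiments in plants —
crosses in which unreduced (2n) gametes from two diploid parents unite to
form neotetraploids (bilateral sexual polyploidization, BSP). It was built
around an alfalfa (*Medicago sativa*) study design in which two diploid
meiotic mutants produced full-sib 2x and 4x hybrids, and answers three
questions about such material:

1. **Are the neotetraploids true autopolyploids?** In a 4x × 4x test cross,
   parent-specific SSR alleles segregate differently under *disomic*
   inheritance (complete preferential chromosome pairing, the allopolyploid
   hallmark) and *tetrasomic* inheritance (random pairing, the autopolyploid
   hallmark). `polyploidkit.segregation` derives the expected class
   probabilities by exhaustive enumeration — e.g. a simplex allele is
   transmitted with probability 1/2 under both models, a duplex allele with
   5/6 (tetrasomic) vs 1 or 3/4 (disomic), and two alleles in repulsion
   segregate 1:1:1:1 (disomic) vs 1:2:2:1 (tetrasomic) — tests observed
   counts by Pearson's χ² (no double reduction assumed), and calls each
   chromosome's inheritance mode.
2. **Does polyploidization remodel cytosine methylation?**
   `polyploidkit.msap` scores MSAP (HpaII/MspI isoschizomer) band patterns
   into methylation states (1-1 unmethylated, 1-0 hemi-methylated, 0-1 fully
   methylated CmCGG, 0-0 uninformative), classifies each hybrid site against
   the parents (monomorphic / parental / de novo methylation / demethylation
   / ambiguous), and computes methylation levels, one-way ANOVA between
   groups, PCoA of profiles, and the **MR statistic** — percent de novo
   methylation over percent demethylation.
3. **Which genes respond nonadditively?** `polyploidkit.expression` runs
   two-class unpaired contrasts (|log2FC| > 1 and BH-adjusted p < 0.05) and
   partitions genes into **HS** (hybridization-sensitive: parents vs 2x),
   **HPS** (parents vs 4x) and **PS** (polyploidization-sensitive: 2x vs 4x
   but not parents vs 4x), with over/under-expression summaries,
   hypergeometric term enrichment and 2^-ΔΔCt qPCR quantification.

`polyploidkit.simulate` generates all three data types — the BSP cross with
configurable 2n-gamete rates, tetraploid meiosis with a pairing-preference
coefficient b and double-reduction rate α, MSAP site profiles with known
event rates, and expression matrices with a known nonadditive gene set — so
every stage is testable end to end without external data.

## Worked example

```python
from polyploidkit import segregation as seg
from polyploidkit.pairing import DISOMIC, TETRASOMIC

# An SSR locus on chromosome V of a BSP tetraploid: allele A on one
# seed-parent homolog (slot 0), allele B on one pollen-parent homolog (slot 2).
locus = seg.LocusConfiguration(
    "MTIC153", "V", (("A", frozenset({0})), ("B", frozenset({2})))
)
for model in (DISOMIC, TETRASOMIC):
    exp = seg.joint_class_expectation(locus, model)
    print(model.label, dict(zip(exp.class_labels, exp.probabilities)))

observed = [8, 22, 21, 9]   # A+B+, A+B-, A-B+, A-B- in 60 test-cross progeny
mt = seg.test_marker(locus, observed)
print(f"disomic:    chi2={mt.disomic.chi2:.2f}  p={mt.disomic.p_value:.4f}  {mt.disomic.verdict}")
print(f"tetrasomic: chi2={mt.tetrasomic.chi2:.2f}  p={mt.tetrasomic.p_value:.4f}  {mt.tetrasomic.verdict}")
print("chromosome call:", seg.classify_chromosome([mt]).call)

from polyploidkit.msap import methylation_ratio
print("MR(S24) =", methylation_ratio(46, 16, 234))
```

prints

```
disomic {'A+ B+': 0.25, 'A+ B-': 0.25, 'A- B+': 0.25, 'A- B-': 0.25}
tetrasomic {'A+ B+': 0.16666666666666666, 'A+ B-': 0.3333333333333333, 'A- B+': 0.3333333333333333, 'A- B-': 0.16666666666666666}
disomic:    chi2=11.33  p=0.0101  *
tetrasomic: chi2=0.75  p=0.8614  NS
chromosome call: tetrasomic
MR(S24) = 2.9
```

The observed counts sit close to the tetrasomic 1:2:2:1 expectation
(10:20:20:10 on n = 60) and far from the disomic 15:15:15:15, so the disomic
model is rejected at p ≤ 0.05 while the tetrasomic model fits: this
chromosome segregates tetrasomically, i.e. the plant behaves as an
autotetraploid there. The last line is the MR of the 2x hybrid genotype S24:
46 de novo methylation sites over 16 demethylation sites among 234 scored
sites gives MR = 2.9 — de novo methylation strongly predominates in that
hybrid.

A full synthetic pipeline (simulate → analyze → report) runs from the shell:

```sh
polyploidkit run --out demo_out --seed 17
```

See `polyploidkit --help` for the individual subcommands
(`simulate-cross`, `test-segregation`, `msap-classify`, `expr-partition`,
`enrich`, `ddct`).

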