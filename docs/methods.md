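# Methods

This note documents the models, parameter choices and numerical
conventions behind `polyploidkit`, and what the synthetic-data
generators do and do not emulate.

## Tetraploid segregation model

A tetraploid carries four homologs per chromosome; at meiosis these form
two bivalents, and each gamete receives one homolog from each bivalent.
The four homologs can be split into two bivalents in three ways. The
**pairing preference** `b ∈ [0, 1]` is the probability that meiosis
adopts the origin-wise partition (the two seed-parent-derived homologs
pairing together, likewise the pollen-derived pair) outright; the
remaining probability mass is spread uniformly over all three
partitions, so a partition is chosen with probability `b + (1−b)/3`
(preferred) or `(1−b)/3` (each alternative). The two extremes reproduce
the classical hypotheses:

* `b = 1` — complete preferential pairing, **disomic** inheritance:
  gametes are the 4 equally likely one-from-each-preferred-pair
  combinations;
* `b = 0` — complete random pairing, **tetrasomic** inheritance: all
  C(4,2) = 6 unordered homolog pairs are equally likely (each pair can
  arise from two of the three partitions, with probability
  2 × 1/3 × 1/4 = 1/6).

The preferred partition for the disomic hypothesis is fixed to parental
origin because BSP individuals carry origin-tagged 2+2 homolog sets; a
different partition can be requested by relabeling the carrier slots of
the `LocusConfiguration`.

**Double reduction** (a gamete carrying two copies of one homolog,
requiring multivalent formation and a proximal crossover) is modeled as
a per-chromosome gamete-level rate `α ∈ [0, 1/6]`: with probability `α`
the gamete is two copies of a uniformly chosen homolog. Expectations
used for testing fix `α = 0` — the standard assumption for this kind of
segregation analysis — and enumerating with `α > 0` requires an explicit
opt-in; the simulator-side `α` exists for robustness studies only.

Expected class probabilities are computed by exhaustive enumeration over
partitions × draws using exact rational arithmetic (`fractions`), so
closed-form values (simplex 1/2; duplex 5/6 tetrasomic, 1 or 3/4
disomic; repulsion 1:1:1:1 vs 1:2:2:1) are reproduced exactly, not to
floating tolerance. With k tracked alleles all 2^k joint
presence/absence classes are kept, including structurally impossible
ones with probability 0 — these drive the nontestability rule below.

### χ² testing and inheritance calls

Pearson's χ² = Σ(O−E)²/E is computed over classes with E > 0, with
df = (#classes with E > 0) − 1, no continuity correction and no pooling
(an explicit choice: pooling would mask the nontestability rule).
Verdicts: `**` at p ≤ 0.01, `*` at p ≤ 0.05, `NS` otherwise; `NT`
(nontestable) when a class with expected count exactly 0 is observed, or
when fewer than two classes have positive expectation. An impossible
class that is also unobserved is dropped silently — the model is not
contradicted by data that never hits it.

Marker-level calls combine the two verdicts: rejecting exactly one model
supports the other; rejecting both indicates segregation distortion
rather than a pairing regime; both fitting is ambiguous. When one model
is NT the marker is read against the testable model alone (NT + NS →
that model, weakly; NT + significant → distorted, since the rejection
cannot be attributed to pairing when the alternative is untestable).
Chromosome-level calls drop untestable markers, let decisive markers
override ambiguous ones, and report `intermediate` when decisive markers
disagree.

Allele dosage is taken from the input configuration (assumed known from
parental genotypes), not inferred from progeny. The allele-accounting
report counts *distinct* alleles across the two parents (a shared allele
is counted once), so `deficit > 0` means alleles genuinely absent from
the progeny inventory.

## MSAP scoring and the MR statistic

The band-pair → state map ((1,1) → U, (1,0) → H, (0,1) → F, (0,0) → X)
follows the standard isoschizomer logic; 0-0 is uninformative (mutation
vs hypermethylation cannot be separated) and excludes the site. Hybrid
sites are classified against the two parents with the methylation order
U < H < F: equal triples are monomorphic; a hybrid matching exactly one
of two discordant parents shows parental-pattern inheritance; a hybrid
strictly above (below) both parents shows de novo methylation
(demethylation); a hybrid strictly between discordant parents — the only
remaining case, e.g. (U, F, H) — is ambiguous. The full decision table
is what the literature's scoring schemes leave partly implicit, so it is
exported with results and the classifier is total on {U,H,F,X}³; the
seven class counts always partition the site total.

MR = (percent de novo methylation) / (percent demethylation); with a
shared denominator this reduces to the count ratio, reported to one
decimal and undefined (missing) when no demethylation site was seen.

Group methylation levels are offered both pooled and per-individual
(the reference figures do not state which averaging was used); one-way
ANOVA of per-individual levels uses the standard between/within
decomposition with a degenerate guard (identical data → F = 0, p = 1).
PCoA uses Jaccard distance on the concatenated HpaII+MspI binary lanes
(no distance is canonical for MSAP; Jaccard ignores shared absences,
which is appropriate for dominant markers) with classical metric
scaling via scikit-bio; negative eigenvalues of non-Euclidean inputs are
truncated to zero with a warning. Post-hoc multiple-range testing of
ANOVA means is out of scope; p-values are reported unadjusted.

## Expression contrasts and the HS/HPS/PS partition

The module starts from a normalized log2 matrix (raw-array processing is
out of scope). Each two-class unpaired contrast computes per-gene
log2FC as the difference of class means and tests it with **Welch's t**
(Satterthwaite df) plus Benjamini–Hochberg adjustment across the genes
of the contrast — a documented, simpler stand-in for a moderated
empirical-Bayes statistic; the test is a pluggable callable so a
moderated backend can be swapped in without touching the partition
logic. Zero-variance genes get p = 1 when the means agree and p = 0
otherwise. Differential expression requires |log2FC| > 1 **and**
adjusted p < 0.05.

The partition identities are set algebra over the three DE sets:
HS = DE(parents, 2x), HPS = DE(parents, 4x),
PS = DE(2x, 4x) \ DE(parents, 4x), hence PS ∩ HPS = ∅ by construction.

The over/under summary rounds per-genotype O/U ratios and percentages
to two decimals from full precision. Per-ploidy mean *counts* are
arithmetic means reported at full precision; the per-ploidy mean
*ratio* averages the two-decimal per-genotype ratios, the only
convention consistent with both reference mean ratios (full-precision
averaging reproduces one of them but yields 1.21 instead of 1.20 for
the tetraploid group; one reference mean count, 547 vs 547.67, appears
truncated rather than rounded — full precision is reported instead of
matching it). Percentages use the 41,538-gene universe of the reference
experiment by default when its counts are analyzed; synthetic analyses
default to the matrix row count.

Term enrichment is the exact hypergeometric over-representation tail
P(X ≥ k) (and the P(X ≤ k) under-representation tail) with BH
adjustment; unannotated genes stay in the totals. 2^-ΔΔCt is the
textbook computation with finiteness checks.

## Synthetic-data generators

The generators define the conditions under which the pipeline is
validated; their defaults mirror the study design.

* **BSP cross** — the seed parent produces 2n eggs at rate 0.6 (within
  the reported 55–70% range) and the pollen parent 2n pollen at rate
  0.1, giving ≈ 6% tetraploid progeny, near the few-percent level
  reported for this material; the 2n pollen transmission rate is not
  published, so both rates are exposed as parameters. Restitution
  defaults to **FDR without crossover** (a 2n gamete carries both
  parental homologs), because FDR transmits parental heterozygosity,
  matching the observed multi-allelic BSP genotypes; SDR (two copies of
  one homolog) is available as an option. Mixed n + 2n fertilizations
  yield triploids, which are kept and ploidy-tagged. Crossovers are not
  simulated: loci travel rigidly with their homolog, which suffices for
  whole-chromosome marker configurations but means the generator cannot
  emulate recombination between linked loci.
* **Tetraploid meiosis** — the partition/draw model above, vectorized;
  the default test-cross size is 60 progeny, the study's family size.
* **MSAP profiles** — one inheritance class is drawn per site from the
  configured event rates (remainder monomorphic), then a
  (parent1, parent2) state pair compatible with that class and, per
  hybrid, an independent hybrid state realizing it. Admissible state
  triples are derived *from the classifier itself* by enumeration, so
  generated data are consistent with the scorer by construction and the
  classifier recovers the simulated class labels exactly; sampling
  variation in recovered fractions comes only from the per-site class
  draw. Because the two parents have a single band pattern per site,
  the class label is shared by all hybrids at a site — real hybrids
  vary independently per site, so per-hybrid class *differences* (as in
  the reference per-genotype tables) are not emulated.
* **Expression matrices** — 2 parents + three 2x + three 4x genotypes,
  3 replicates each (24 samples); gene baselines ~ N(8, 1.5) log2
  units; a fraction of genes (default 0.1) is nonadditive, with both
  hybrid groups' means shifted ±effect (default 2 log2 units) from the
  parental mean; replicate noise is Gaussian on the log2 scale
  (log-normal on the linear scale, default σ = 0.5). The generator does
  not emulate the large parental divergence of the real cross, probe-
  level structure, or intensity-dependent variance — so passing
  recovery tests demonstrate the contrast/partition logic, not
  microarray-specific robustness.

All generators take a seed and are exactly reproducible; the pipeline
derives stage seeds deterministically from the run seed.

## Validation problem sizes

The statistical properties are checked at the sizes the analysis is
meant for: segregation closure at 1000 replicate test crosses of 60
progeny per pairing extreme (type-I error within 3 binomial SE of the
nominal 0.05; majority rejection of the wrong extreme for the repulsion
configuration), MSAP recovery at 5000 sites with 14% de novo / 10%
demethylation (class fractions within 3 binomial SE; MR near the 1.4
design ratio within a delta-method interval), and expression properties
at 1000–2000 genes (null FDR control; ≥ 95% detection at 4 log2FC with
σ = 0.1). Enumeration-based expectations are asserted exactly, and the
hypergeometric tails are checked against full enumeration of all draws
on universes up to 12 genes.

## Known limitations

* Inheritance-mode calling follows a fixed rule table; it does not
  estimate a continuous preferential-pairing coefficient or the double
  reduction rate from data.
* The ambiguous MSAP class absorbs all non-orderable parent/hybrid
  combinations; band loss from allele segregation vs methylation change
  is not disambiguated (heterozygous parents make the two
  indistinguishable in a dominant assay).
* Welch's t loses power relative to a moderated statistic at 3
  replicates per genotype; contrasts at the genotype level (n = 3 vs 6)
  should be read accordingly.
* Term enrichment treats annotations as flat labels; ontology-graph
  propagation is not performed.
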