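# Methods

This note documents the models, decision rules and numerical choices
behind `vmiap`, and what the synthetic-data generator does and does not
emulate.

## Breeding simulator

Chromosomes are tracked as *ancestry paintings*: run-length encoded
segments tagged with the founder strain of origin, which tile each
chromosome exactly (checked after every meiosis). Meiosis draws a Poisson
number of crossovers per chromosome with mean equal to the chromosome's
genetic length in Morgans, places breakpoints uniformly on physical
length (a linear genetic↔physical map), and alternates between the two
parental haplotypes — a no-interference model, the simplest sufficient
for interval-recovery testing. No obligate crossover is enforced, so
chromosomes may transmit intact; this keeps the crossover count exactly
Poisson and testable. Sex chromosomes are not modelled (the mapped locus
is autosomal) and there is no selection or lethality.

The default genome has two chromosomes (a 195-Mb unlinked control and a
156-Mb chromosome 4 analogue, 0.98/0.84 Morgans), informative markers
every 2 Mb, and the hidden dominant modifier at chr4:145,000,000 with a
marker placed at that exact position. With the modifier inside the marker
map and error-free phenotyping, containment of the true locus in the
mapped outer interval is a structural guarantee, verified by simulation.
Genotypes (BB/BC/CC) are deterministically recoverable from the two
paintings; all generators derive from one top-level seed via
`numpy.random.SeedSequence.spawn`, so fixed-seed runs are byte-identical.

## Methylation model

Each locus has a baseline Beta distribution rescaled to 0–100% and a
modifier-induced high state. Defaults are Beta(9, 11) (mean 45%) for the
variable baseline and Beta(24, 6) (mean 80%) for the high state, with
Gaussian per-CpG pyrosequencing noise (sd 2 percentage points, 6 CpGs).
Effect modes: *zygotic* (high iff ≥1 modifier allele), *maternal* (high
iff the dam is of the modifier strain), *maternal+zygotic* (high under
either condition), *none*.

Two deliberate refinements:

* **Maternal boost.** In maternal+zygotic mode an individual satisfying
  *both* conditions draws from the high state plus a boost (default +8
  points). Without it the BC and CB reciprocal cohorts would be
  identically distributed and the maternal+zygotic category — defined by
  a significant BC–CB difference on top of two significant vs-B6
  differences — could never be recovered, contradicting the observed
  four-way typology the classifier implements.
* **Non-overlapping index locus.** Beta(9, 11) places ~8% of its mass
  above the 60% cutoff and Beta(24, 6) ~0.8% below it, which is fine for
  distribution-level comparisons but would corrupt the all-or-nothing
  SNP-intersection filter (a single misphenotyped individual vetoes every
  true candidate marker). The mapping index locus is therefore modelled
  with tighter shapes at the same means — baseline Beta(54, 66), high
  state Beta(96, 24) — reflecting the fact that a locus is chosen as a
  mapping phenotype precisely because its two states do not overlap the
  cutoff. The broad defaults remain in force for the GBE cohort loci.

## Decision rules and statistics

* **Variability**: a locus is variable when the range (max − min) of
  per-individual means exceeds 10 percentage points. The criterion is
  interpretable as either range or variance of means; range matches
  visual inspection of per-individual dot plots and is the default, with
  variance available via configuration. Non-variable loci are subtyped
  hyper-/hypo-methylated at group means ≥80 / ≤20 (package conveniences).
* **Phenotype cutoff**: high iff mean > 60%; a value exactly at 60 is
  low, so "high" means strictly above the cutoff.
* **Kruskal–Wallis** uses midranks with tie correction (scipy); the
  all-identical degenerate case returns H = 0, p = 1. **Dunn's test**
  uses z = (r̄ᵢ − r̄ⱼ)/√(S²(1/nᵢ + 1/nⱼ)) with the tie-corrected pooled
  variance S² = N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided normal p-values,
  Bonferroni ×3 by default (holm/none configurable). The GBE decision
  table works on adjusted p at α = 0.05; figure-style significance stars
  are a display convention, not the decision rule. Direction is the sign
  of the pooled-hybrid median minus the B6 median.
* **Mapping filter**: a marker is a candidate iff heterozygous in all
  high and homozygous-B6 in all low individuals; any missing call among
  labelled individuals vetoes candidacy (conservative), and a
  missing-bearing marker only serves as an outer-interval bound if its
  non-missing calls already violate the filter. Homozygous-CAST calls in
  a B6 backcross are impossible and reported as genotyping errors, not
  dropped silently. Coordinates are 0-based half-open internally and
  printed 1-based inclusive; Mb lengths are rounded half-up to one
  decimal. Both the inner (candidate-span) and outer (flanking-failing-
  marker) intervals are reported, since either convention can be meant by
  a printed interval size.
* **Pedigree consistency** tests each high-sire family for 1:1
  segregation and each low-sire family for all-low offspring. The
  per-family binomial tests are Bonferroni-corrected: at a plain
  per-family α = 0.05 a perfectly consistent 12-family pedigree would be
  flagged inconsistent almost half the time.
* **Percent identity** uses a deterministic global aligner (match +1,
  mismatch −1, gap open −2, extend −1) rather than a heuristic local
  mapper; on near-identical LTRs the local/global distinction is
  immaterial and determinism aids testing. Arguments are canonically
  ordered before alignment so the reported identity is symmetric even
  when co-optimal alignments differ. Identity is computed over the full
  sequence, not a trimmed region.
* **Multiple alignment** is progressive: a UPGMA guide tree built from
  pairwise identities, then profile–profile Needleman–Wunsch with
  expected-pair column scores and affine gaps (open −12, extend −0.5 per
  merged column). The strong opening cost keeps an indel as one
  contiguous gap block; weaker settings let blocks split or slide inside
  divergent segments, scrambling window boundaries. Input order does not
  matter (sequences are processed in lexicographic id order).
* **Divergent-window scan**: a column scores 1 when all target rows share
  one state (gap included) and every nontarget row differs from it,
  otherwise the clamped difference of between- and within-group mismatch
  rates. Columns scoring ≥0.55 seed windows (above the ≈0.45 score of a
  single stray nontarget mutation, below the ≥0.58 of group-level
  divergence); seeds separated by fewer than 6 low columns merge; merged
  windows are kept at mean score ≥0.35 and consensus-frame length ≥8 and
  ranked by length × score. The consensus frame counts columns in which
  >50% of target rows are ungapped. The merge distance of 6 bridges the
  low-score runs produced by conserved anchor columns and single
  reversion mutations inside a genuinely divergent segment.
* **BKY FDR**: stage 1 runs a linear step-up at q′ = q/(1+q) to estimate
  the number of true nulls m₀, stage 2 a linear step-up at q·m/m₀
  (statsmodels `fdr_tsbky`). The per-locus test is the classic
  pooled-variance unpaired t (Welch configurable); zero-variance
  equal-mean comparisons return p = 1.
* **Neighbor joining**: Saitou–Nei with the Studier–Keppler Q-criterion,
  first-minimum (lowest index pair) tie break, standard limb-length
  formulas with negative estimates clamped to 0 and flagged. Distances
  are raw p-distances with pairwise deletion of gap/N columns
  (Jukes–Cantor optional). The returned tree is unrooted (final
  trifurcation at the root).
* **Clade enrichment**: the tree is midpoint-rooted solely to enumerate
  clades; the best clade minimises the hypergeometric tail probability
  (ties → smaller clade, then lexicographic). The primary statistic is a
  label-permutation p (the full clade search repeated per permutation,
  10,000 by default, seeded); the hypergeometric p is descriptive. The
  clustering test itself is package-defined.
* **Anchored matrices** rescale element bodies by area-weighted binning
  of the coverage step function, so the mean of the body bins equals the
  element's mean raw coverage exactly (to float tolerance); flanks are
  copied at 1-bp resolution and minus-strand rows reversed. 1-bp bins are
  used for exactness. Elements shorter than 2 bp are rejected. The 95% CI
  multiplier is fixed at 1.96.

## LTR family generator

A random 420-bp consensus carries a 28-bp recognition segment starting at
position 150. Targets and nontargets descend from a shared VM-clade
ancestor (2% substitutions outside the segment), each leaf adding 0.5%
terminal substitutions; nontargets additionally carry the disruption — a
4-bp insertion at segment offset 12 plus substitutions at every third
segment position — so the disrupted region is divergent along its length
while conserved anchor columns keep the alignment stable. Background
leaves diverge 15% directly from the consensus, placing them below the
90% identity filter while the VM clade stays above it. A random 30% of
records are emitted reverse-complemented with an orientation flag.
Coverage tracks are Poisson background (mean 5) plus an additive block
(height 20) over the 3′-proximal 40% of enriched elements, strand-aware.

## What the simulator does not emulate

Real genetic maps and recombination interference; X-linkage, selection
and litter structure; read-level bisulphite chemistry or pyrogram
artefacts (noise is Gaussian on percentages); indel evolution outside the
planted disruption; alignment uncertainty of truly repetitive DNA;
ChIP-seq library normalisation, fragment-length effects or peak calling.
Passing tests therefore demonstrate the correctness and calibration of
the inference chain under its stated model, not robustness to every
artefact of real mouse data.

## Problem sizes

Defaults mirror the study design: 47 N3 individuals genotyped on a
2-Mb-spaced marker panel (23–25 high vs 22–24 low splits arise naturally),
reciprocal-F1 cohorts of 40–50 per group, families of 7 targets + 2
nontargets (+24 background for the tree), 200-replicate recovery checks
and 1,000-replicate calibration checks. The full pipeline runs in a few
seconds; the complete test suite in a few minutes on one CPU.
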