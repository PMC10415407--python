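# Methods

`riboprofiler` reimplements, end to end and on synthetic data, a benchtop
workflow for characterizing intragenomic 45S rDNA variation from noisy
long-read amplicons and for turning the resulting profiles into a
species-identification assay. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## The profiling model

The 45S rDNA cassette (ETS–18S–ITS1–5.8S–ITS2–28S) is tandemly repeated at
high copy number. Repeat copies within one individual are not identical:
a *ribotype* is a fixed intragenomic variant — in this package, a biallelic
site at which a substantial fraction of repeat copies carry the minor
allele. The profiling goal is a consensus sequence whose only degenerate
(IUPAC) positions are genuine ribotypes, with sequencing error and
transient low-frequency variation removed.

The pipeline stages mirror the benchtop procedure:

1. **Size selection.** Reads are kept inside an expected-amplicon window
   (default ±5% around the amplicon length, reflecting gel-based size
   selection). Off-target fragments fall outside it.
2. **Seed consensus.** The highest-quality reads (lowest mean per-base
   error probability; default 12) are progressively aligned, best first,
   into a column profile whose majority call is the initial reference.
3. **Polishing.** Greedy progressive alignment tears columns around indels,
   so the seed consensus retains roughly 1% error concentrated at
   homopolymers. The reference is therefore refined by remapping a read
   subsample (default 300 reads, 2 rounds) and taking the deep majority,
   with two non-standard repairs:
   - *Homopolymer run-length repair.* When the reference's run is one base
     short, about half the reads emit an insertion — never a strict
     majority — because elevated in-run error erodes read run lengths.
     Each run of ≥2 identical bases is resized to
     `round(mean observed run bases per read / (1 − w·ē))`, where `ē` is
     the mean per-base error probability observed in the run's columns and
     `w = 0.75` the fraction of errors that shorten a run (substitutions
     and deletions shorten; insertions of the run base lengthen). Reads
     carry their own error probabilities, so the erosion correction needs
     no knowledge of the generator.
   - *Junction-pooled insertion voting.* A deleted base next to a shared
     base splits the two allele populations' insertion evidence across the
     two flanking junctions, each just below majority; those junction pairs
     are pooled before voting. Run-base insertions anywhere adjacent to a
     run are credited to the run-length estimate instead.
4. **Mapping.** Every read is aligned globally to the polished reference in
   both orientations (banded edit-distance alignment via edlib) and
   rejected above 15% divergence — the tolerance appropriate for noisy
   long-read amplicon data.
5. **Pool consensus and merging.** Reads are pooled (default 500 per pool
   at this scale); each pool's column-majority consensus is computed, and
   pools are merged column-wise: disagreements involving gaps or Ns
   resolve to the majority canonical base (sequencing error), two canonical
   bases each carried by ≥25% of pools become an IUPAC-coded *candidate*
   ribotype, and three-way canonical splits are flagged `N`.

## The ribotype caller

At every position with depth ≥10, the caller tests the null hypothesis that
all non-major observations are errors. The p-value is the exact
Poisson-binomial tail `P(X ≥ k)` for the observed minor count `k`, where
`X` sums independent Bernoulli draws with each read's own per-base error
probability at the position. The tail is computed by convolving the
binomial PMFs of groups of reads sharing an error probability, truncated at
`k` — algebraically identical to the textbook per-read dynamic-programming
convolution, exact, and fast because Phred values are discrete. Bonferroni
correction uses the number of depth-qualified positions. Gap observations
carry the read's mean error probability (a deleted base has no quality of
its own), quantized to the integer-Phred grid.

Confirmed variants are classified:

- **fixed ribotype** — both alleles canonical and minor frequency ≥ 0.25;
- **sequencing error** — a gap or N allele (indel ambiguity), a canonical
  split touching a homopolymer run of the same base (see below), or the
  weaker member of a pair of adjacent fixed calls;
- **transient** — everything else, including sites demoted for having more
  than two canonical alleles.

Two artifact filters deserve explanation. Long-read chemistry misreads
G strings (runs of ≥3 G), and when the reference mis-sizes such a run the
reads split between a mismatch column and an indel path, manufacturing a
canonical ~50/50 split at the run boundary that no orthogonal (Sanger-type)
check would confirm. Any would-be fixed site whose allele matches an
overlapping or bordering run of ≥3 identical bases is therefore demoted to
sequencing error. Similarly, one biallelic site torn across two adjacent
alignment columns produces two adjacent fixed calls; the weaker is demoted.
The corollary is a documented blind spot: a *real* ribotype inside or
immediately beside a homopolymer run is not callable by this method — the
same limitation the underlying bench workflow has, where such candidate
sites remained inconclusive under verification.

Variants whose non-reference frequency reaches 50% are flagged for external
(Sanger-style) verification; `apply_ribotypes` accepts an optional
confirmation mask so externally rejected calls are demoted before the final
profile is written. The final profile's degenerate symbols correspond
one-to-one to confirmed fixed ribotypes, and `enumerate_combinations`
expands `k` biallelic sites into the `2^k` resolvable repeat variants.

## Synthetic data

The generators define the study conditions; every stage is testable without
any external download.

- **Repeat family.** A random unit template (~6.5 kb; region lengths
  ETS 650, 18S 1900, ITS1 560, 5.8S 160, ITS2 380, 28S 2850; coding regions
  GC-richer than spacers) with biallelic ribotypic loci applied as
  independent Bernoulli draws per copy. Realized minor counts are recorded
  as the recovery target. `choose_ribotypic_loci` places loci away from
  homopolymer runs and never lets the minor allele extend a neighboring
  run — ribotypic variation at such sites is indistinguishable from
  basecalling error in this kind of data, so planting it there would make
  the truth unknowable to any method, not just this one. Minor alleles are
  transversions (the complement of the template base).
- **Reads.** Per-base substitution/insertion/deletion events (defaults
  0.03/0.02/0.03, at most one event per template base) with all rates
  multiplied (default ×3) inside runs of ≥3 G; insertions copy a uniform
  random base; qualities encode the effective per-base error probability.
  Half the reads are reverse-complemented; an off-target fraction draws
  random sequences with lengths in [200, 3000] ∪ [9000, 12000], cleanly
  separated from the amplicon size window.
- **qPCR plates.** Per-channel sigmoid curves
  `baseline + (plateau−baseline)/(1+exp(−k(c−m)))` with the midpoint `m`
  placed so the threshold crossing lands exactly at
  `Cq = intercept + slope·log10(concentration)` (slope default −3.32, i.e.
  ~100% efficiency); Gaussian RFU noise (sd 20); channel–class response per
  the assay design (FAM→first target class, HEX→second, control→any
  non-blank); and an explicit per-channel detection floor (default
  10⁻³ ng/µL for FAM, 10⁻⁴ for HEX and control) below which a channel never
  amplifies, giving the plate a defined limit of detection.

What the generator does **not** emulate: pore-level signal, chimeric reads,
PCR duplicates, context-dependent error beyond the G-run multiplier,
between-run basecaller differences, baseline drift in qPCR, or competition
between targets in multiplex. Passing tests therefore demonstrate the
correctness of the algorithms under the stated error model, not performance
on any particular instrument run.

## Phylogenetics and delimitation

- **Distances.** Tamura–Nei (1993) closed form with base frequencies pooled
  from the two sequences over comparable columns; gap/ambiguous columns
  pairwise-deleted; saturation (non-positive log argument) returns
  infinity. In the equal-frequency, equal-rate regime the formula collapses
  analytically to Jukes–Cantor.
- **Trees.** Standard Saitou–Nei neighbor joining, lowest-index pair on
  ties, negative branch estimates clamped to zero; additive matrices are
  recovered exactly. Jackknife support deletes 50% of columns per replicate
  (1000 replicates by default) and reports integer-percent bipartition
  recovery; zero-length internal edges are treated as unresolved, so
  identical sequences yield no supported bipartitions.
- **Networks.** Pairwise differences count each contiguous gap run as one
  event. The statistical-parsimony connection limit is the largest step
  count `j` whose parsimony probability is ≥95%, computed with a
  Jukes–Cantor correction: with per-site divergence `q = j/L`, the expected
  substitutions per site solve `(3/4)(1−e^{−4μ/3}) = q`, and the
  probability that one observed difference reflects exactly one
  substitution is `μe^{−μ}/q`; the parsimony probability for `j` steps is
  that ratio to the `j`-th power. Pairs one step apart are always joined;
  longer connections are added in increasing distance order only between
  unconnected components, inserting unsampled median nodes so each edge is
  one mutation.
- **Reciprocal monophyly (P_AB).** The probability that groups of sizes
  `a` and `b` are both monophyletic on a uniformly random labeled
  coalescent history, by the exact recursion
  `P(i,j) = [C(i,2)P(i−1,j) + C(j,2)P(i,j−1)] / C(i+j,2)`, `P(1,1)=1`.
- **Random distinctiveness (P(RD)).** The original plugin's statistic is
  not restated in accessible form, so this package uses a documented
  stand-in: the clade's stem length divided by the tree's mean edge length,
  compared against Kingman coalescent trees of the same tip count
  (size-matched random clade selection), with the add-one Monte-Carlo
  p-value. It is validated by null calibration (p-values uniform under the
  null) and by sensitivity to extreme stems — not against the original
  implementation.

## Assay design and qPCR interpretation

Diagnostic windows are ranked by the count of columns where the target
profile differs from *every* contrast profile; any window overlapping a
degenerate (ribotypic) position in any input profile is excluded, since an
oligo over such a site would bind only part of the template population.
Candidate oligos satisfy length (default 18–26 nt), GC (0.30–0.70) and
melting-temperature constraints, probes additionally avoiding a 5′ G
(quencher adjacency). Two Tm calculations are provided: nearest-neighbor
thermodynamics (unified 1998 duplex parameters, terminal initiation terms,
entropy salt correction `0.368(N−1)ln[Na⁺]`, divalents folded in as
`Na⁺ + 120√(Mg²⁺ − dNTP)` mM, `Tm = 1000ΔH/(ΔS′ + R ln(C_T/4)) − 273.15`)
and the composition-only salt-adjusted formula
`100.5 + 41(G+C)/N − 820/N + 16.6 log₁₀[Na⁺]`. Specificity screening scans
both strands of every non-target for sites where all three oligos bind with
at most 2 mismatches in amplifiable orientation and spacing (amplicon ≤400
bp, a practical hydrolysis-probe cap).

Plate interpretation reduces each well to per-channel Cq values (first
upward crossing of the 1000-RFU threshold, linearly interpolated; a curve
whose final-cycle RFU is below threshold counts as not detected) and
applies the triplex rule set with ΔCq = Cq(control) − Cq(diagnostic):
no control → inconclusive (insufficient/poor DNA); both diagnostics valid →
inconclusive (contamination/artifact/unsampled genotype), taking precedence
over a species verdict; exactly one diagnostic not lagging the control by
more than 8 cycles → species verdict (the HEX verdict requires CO1
barcoding follow-up to separate the two sibling species); a diagnostic
lagging beyond 8 cycles, or none detected → negative. Standard curves are
ordinary least squares of mean Cq on log₁₀(concentration); efficiency is
`10^(−1/slope) − 1`; the limit of detection is the lowest concentration at
which every replicate was detected.

## Problem sizes used by the test suite and acceptance script

Parameter recovery runs 20 seeded pipelines at the study scale the workflow
was designed around: a 6.5 kb unit, 4 loci at minor frequency 0.5, 1500
reads at ~5% error with 10% off-target. Caller calibration uses 20 random
pileups (depth ≤50) against 10⁵-draw Monte-Carlo and 200 null profiles of
100 positions at depth 50. Jackknife support uses 1000 replicates over
494 columns; Rosenberg enumeration covers all splits of up to 6 tips;
the network check uses the 16-sequence combination set. These sizes were
chosen as the smallest that exercise each claim at full fidelity.

## Not reproducible at desk scale

Quantities that require the original specimens, instruments, or sequence
archives are out of reach of a synthetic rerun and are deliberately not
asserted anywhere: the real-run Cq means and spreads (e.g. 15.77 ± 2.59 for
the FAM channel), real-specimen tree topologies and haplogroup structure,
the 28-SNV / 4-SNV CO1 separation counts (which require the public barcode
specimen sets), and the published primer-table Tm values — the latter match
neither the nearest-neighbor evaluation at the stated salt conditions nor
the salt-adjusted closed form exactly, so they are treated as ±2 °C
plausibility references only. The synthetic plate reproduces the *patterns*
(ΔCq sign and magnitude, the −3.32 slope, the 10⁻³ ng/µL LOD for the FAM
channel) because its generator encodes them as study conditions, not
because the real instrument data were re-analyzed.

## Known limitations

- Ribotypes inside or adjacent to homopolymer runs are by design not
  callable (demoted as indistinguishable from basecalling artifacts).
- The profile retains ~1–3 per-kb residual *indel* wobble at long
  homopolymers after polishing; substitution accuracy is effectively exact
  (zero substitution errors in the end-to-end checks).
- The connection-limit statistic and P(RD) are documented
  operationalizations, validated by internal properties rather than against
  the original closed-source implementations.
- `classify_sample` trusts its Cq inputs; baseline drift and multicomponent
  correction are out of scope.
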