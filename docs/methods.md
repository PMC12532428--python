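# Methods

This note documents the statistical model behind each stage, the
defaults that matter, the choices made where the design was genuinely
open, and what the synthetic cohort generator does and does not emulate.

## Coordinate and genotype conventions

All in-memory coordinates are 1-based inclusive; the BED export is the
only 0-based half-open surface (start = pos − 1). TE insertions are
stored as breakpoint pairs and their length is `end − start`: the
inserted sequence occupies the gap between the two junction coordinates,
which reproduces both catalogued insertion lengths (1227 bp and 79 bp)
from their breakpoints. Genotypes are alt-allele dosage codes 0/1/2 with
−1 for missing, the Axiom calls-file convention; phased separators and
half-calls are normalised on VCF import, and any allele index above 1 at
a multi-allelic site becomes missing for array-style analyses (counted
and logged).

## Array content design

**Variant filter.** A site survives when it is a bi-allelic SNP, not an
A/T or C/G (strand-ambiguous "W/S") pair — those need twice the probes
under ligation chemistry — its alternate-allele frequency lies strictly
inside (0.1, 0.9), and *every* sample's depth lies strictly inside
(5, 30). The all-sample reading of the depth window is deliberate: it is
the strictest interpretation of a per-sample FORMAT filter, and the
attrition table makes its cost visible. Each rejected site is charged to
the first failing rule, so the counts telescope
(input = output + Σ rejected).

**Spacing.** Per scaffold, a greedy scan accepts the first site and then,
repeatedly, the first site at least `spacing_target` (3000 bp) beyond the
last accepted one — equivalently the candidate closest to
`last + target`, ties resolving to the smaller coordinate. Greedy
closest-to-target is deterministic and order-free, which is what a
reproducible design pipeline needs; no claim of global optimality is
made.

**Trimming.** Loci with MAF = 0.5 (within 1e−9; at 0.5 the minor allele
is undefined and downstream A/B labelling unstable) are dropped first,
then a single left-to-right pass removes any locus closer than `min_gap`
(3150 bp) to the nearest *retained* predecessor on the same scaffold.
Only genome-wide loci are trimmed; sex-locus categories pass through.

**Sex-locus categories.** (a) every bi-allelic SNP inside the *gsdf*
region; (b) SNPs homozygous in every labelled female and heterozygous in
every labelled male — strict because the category exists to verify
already-known markers, not to discover tolerant ones; (c) candidate probe
positions tiled over ±100 bp of each of the four TE breakpoints whose
35-mer footprint (centred on the interrogated junction) contains no
variant site. A SNP inside *gsdf* that is also strictly dimorphic is
categorised (a): the categories partition the panel. Category (c)
candidates usually outnumber what an array accepts, so a
`te_probe_budget` (default 334) evenly down-samples them; the
thermodynamic screening a vendor would apply is represented by a
pluggable conversion scorer whose default accepts everything.

## Genotyping QC

Samples are gated on Dish QC ≥ 0.82 — a raw-signal attribute that cannot
be derived from calls and therefore arrives as an input — and call rate
≥ 97 %. The Hardy–Weinberg test is a plain 1-df χ² goodness-of-fit
against p², 2pq, q² at the observed allele frequency, without continuity
correction; monomorphic markers return p = 1 by convention. χ² screening
is the standard choice at array scale; an exact test adds nothing at the
p < 0.01 screening threshold used here and the simpler statistic has a
closed form (χ² = n when heterozygotes are absent at p̂ = 0.5) that the
tests exploit.

The six-class SNP classification approximates a vendor's 2-D cluster
model with one-dimensional rules, applied in order: call rate < 97 % →
CRbT; a low-signal sub-cluster (≥ 5 % of called samples below an absolute
floor, default 500) → OTV; minimum adjacent-genotype-class separation
(|Δ mean| / pooled within-class SD) below 3.6 — the published FLD
default — → Other; one genotype class → MHR; heterozygotes but no minor
homozygote → NMH; all three classes with ≥ 2 minor homozygotes → PHR.
Residual shapes (two homozygote classes with no heterozygote; a lone
minor homozygote) land in Other. The classification is invariant to
sample order and to A/B relabelling, and every marker receives exactly
one class.

## Concordance accounting

Overall per-category concordance is
`100 · (1 − discordant genotypes / (n_markers · n_samples))`, with
comparisons counted only where both calls are non-missing and array
samples below an 80 % call rate excluded. This is the definition under
which the per-category worked examples reproduce their published
overall-concordance column from the row inputs alone. Duplicate-pair
inconsistencies split into missing-type (exactly one call missing) and
discordant-type (both called, unequal); both-missing counts as
consistent, since no comparison of reported genotypes is possible.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (composite LD, matching PLINK `--r2` on
unphased data). Pairs that are monomorphic in the complete subset, or
have fewer than 2 complete samples, are dropped with a logged count. The
independent cross-check is a haplotype-frequency r² with the
double-heterozygote cell resolved by EM under random mating. The two
estimators coincide *exactly* only on all-homozygous data, where each
sample contributes two identical gametes and phase is trivial; fixtures
with single-locus heterozygotes already separate them, so the
cross-oracle tests use all-homozygous fixtures and the decay analyses use
the dosage estimator throughout. Distance bins are left-closed
(`floor(d / width)`), 100 kb wide genome-wide (20 kb optionally) up to
10 Mb, and 10 × 1 Mb for per-chromosome curves; genome-wide summaries are
available both pooled over chromosomes and as equal-weight averages of
per-chromosome means, labelled accordingly.

## Genetic-sex calling

Three evidence classes vote per sample: homozygosity proportion over the
sex-segregating SNP panel, homozygosity over *gsdf*-region SNPs retained
by a data-driven scan (|female hom-rate − male hom-rate| ≥ 0.5), and mean
intensity over TE-breakpoint probes whose female-minus-male differential
is ≤ −400 (absent template in females → reduced female signal; probes
with *elevated* female signal are never selected, whatever the
magnitude). Homozygosity votes use thresholds ≥ 0.85 → female and ≤ 0.65
→ male: under the model, genetic females are fully homozygous at
sex-linked loci and genetic males fully heterozygous, so the thresholds
sit far from both expectations and a panel of ≥ 40 SNPs crosses them only
under gross error. The intensity vote compares each sample to the
midpoint of labelled-male and labelled-female training means with a ±10 %
ambiguity band; neomales are excluded from training because they are
genetic females and would bias the male mean. The final call is the
majority of informative votes; a tie or no informative evidence gives
`ambiguous`. Reconciliation against phenotype yields `concordant`,
`candidate_misassignment` (e.g. a phenotypic male called female),
`neomale_consistent` (a neomale called female — the expected state), or
`unresolved` when the genetic call is ambiguous or the phenotype unknown.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume: a
24-chromosome genome plus unplaced scaffolds; site MAF uniform on
[0.01, 0.5]; genotypes drawn per site from HWE with inbreeding F
(P(het) = 2pq(1 − F)); sex-linked SNPs heterozygous in genetic males and
fixed-homozygous in genetic females (which allele is female-fixed is
random per site); sequencing depth negative-binomial (mean 20, size 100 —
chosen so the strict all-sample depth window keeps a realistic fraction
of sites); array error as uniform misassignment at rate 0.5 % and
missingness at 0.36 % (a 99.64 % mean call rate); TE-breakpoint probe
intensities Normal(1500, 150) where template is present and
Normal(700, 150) where absent, a −800 differential that leaves the −400
rule generous headroom; per-sample Dish QC Normal(0.95, 0.02). The
cohort comprises 40 sequenced broodstock (20 per sex, phenotype = truth)
plus a validation set phenotyped 114 females / 22 males / 18 neomales,
with 6 sex-reversed phenotypic males and 1 masculinised neomale planted
as mislabels; duplicates are re-genotyped copies with independent 2 %
missingness and 0.4 % flips, with the planted per-pair difference counts
recorded for exact verification. All randomness flows from one seed and
identical configs give byte-identical outputs.

What it does **not** emulate: linkage disequilibrium (sites are drawn
independently, so LD decay summaries on simulated data measure the
finite-sample null level ≈ 1/(n − 1), not a decay curve), allele-specific
probe chemistry or two-channel cluster geometry, population structure,
reference/genotyping bias shared between platforms, and per-individual
variation in TE breakpoint position. Passing tests therefore demonstrate
the correctness of the accounting and the separability logic under the
stated model — not the field performance of any physical array.

## Problem sizes

The genome is scaled: chromosomes default to 9 Mb (chromosome 13 keeps
the real sex-locus coordinates near 8.51 Mb, so it must reach past them)
at ~1 site / 3 kb, giving ~72 k sites — the scale of the array itself.
The test and acceptance runs shrink further (4 chromosomes × 1 Mb, 97 or
1000 samples; a 2-chromosome, 1152-sample cohort for the QC-gate check;
13 × 9 Mb for the sex-assay bookkeeping), sizes chosen so the full suite
runs in seconds while the checked properties — exact counts, calibration
bands, separability margins — are scale-free or carry explicit binomial
tolerances.

## Known limitations

* The greedy spacing rule and the one-dimensional class separation
  statistic are documented simplifications of proprietary tools; they
  preserve decision structure, not numerics.
* The HWE χ² is asymptotic; below ~10 expected counts per genotype class
  its type-I error drifts, which is why calibration tests sample MAF
  ≥ 0.2 at n = 200+.
* The TE-probe evidence needs labelled samples of both sexes for
  training; a cohort without reliable phenotypes cannot use that vote.
* Dosage r² on small pairwise-complete subsets is noisy and upward
  biased (≈ 1/(n − 1)); bins report pair counts so users can weigh them.
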