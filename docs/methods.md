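# Methods

`hybridhallmarks` implements the population-genetic diagnostics used to
establish that a butterfly population is a *hybrid species* — a daughter
species founded by interbreeding between two parental species — and a
simulator of that demography so every diagnostic can be exercised and
validated without access to real specimens.  The motivating system is
the North American tiger swallowtail complex (*Papilio glaucus*,
*P. canadensis*, and the putative hybrid species *P. appalachiensis*),
but nothing in the code is specific to it beyond default locus names and
the packaged trait table.

## The hybrid-speciation scenario

The simulator (`simdata`) models three demes under a structured
coalescent (msprime): two parental species split from a common ancestor
`T_parent_split` generations ago; a hybrid deme is founded much later
(`T_hybrid_origin`) by a single admixture pulse in which each founding
lineage derives from parentA with probability `alpha`.  After founding,
migration flows only *into* the hybrid deme (unidirectional
introgression); nothing leaves the parents.

Inheritance modes differ in transmitted copy number relative to a
diploid autosomal locus (2·Ne copies): Z-linked loci have 1.5·Ne copies
(ZZ males carry two, ZW females one) and mitochondria Ne/2 (females
only, strictly maternal).  In Lepidoptera the W chromosome is
co-inherited with the mitochondrion, so mtDNA ancestry is the W proxy.
Because matings at contact are strongly asymmetric by sex, the founding
mixture need not be the same for every compartment: `alpha_maternal`
and `alpha_z` override `alpha` for mitochondrial and Z-linked loci.
This is how the genomic mosaic is expressed: e.g. `alpha = 0.5`,
`alpha_maternal = 1.0` (all founding mothers from parentA),
`alpha_z = 0.1` (Z mostly from parentB).

Key defaults (desk scale, chosen once):

| parameter | default | why |
|---|---|---|
| Ne (all demes) | 1,000 diploids | desk-scale drift; times scale with it |
| T_parent_split | 4,000 gen (4·Ne) | deep parental divergence |
| T_hybrid_origin | 700 gen (0.7·Ne) | preserves the real ≈0.17 age ratio between hybrid origin and parental split |
| alpha | 0.5 | near-equal founding contributions |
| m_A_to_H, m_B_to_H | 1.15e-4, 9e-5 per gen | see below |
| theta_per_locus | 5 | a handful of SNPs per 500-bp locus |
| loci | 1 mtDNA + 19 Z, 500–600 bp | mirrors an mtDNA + Z-panel design |
| generation time | 1 year | these butterflies are uni/bivoltine |

**Migration defaults.** Isolation-with-migration analyses of such
systems report historical-average population migration rates of order
2Nm ≈ 2 into the hybrid species.  Converting that literally into a
*constant* per-generation rate m = 2Nm/(2·Ne) over the hybrid's whole
lifetime would replace ≈ 75% of hybrid ancestry (the product
2Nm · t/(2·Ne) is scale-free), washing out the hybrid's genetic
distinctness — which contradicts the burst-founding, little-backcrossing
scenario this package simulates.  The defaults therefore use one tenth
of the literal conversion, for a cumulative immigrant replacement of
≈ 13%.  Both halves of the admixture diagnostic then hold
simultaneously: hybrid individuals show ≈ 50:50 ancestry at K = 2 and a
distinct cluster at K = 3.

**Mutation.**  Infinite-sites at rate θ/4Ne per lineage per generation
per locus, projected onto finite sequences; a variant claims the
alignment column under its continuous coordinate, and collisions
re-draw among free columns.  No recombination within loci, no
selection.

**Dominant markers.**  Each AFLP-style marker is an unlinked autosomal
biallelic locus: one mutation is placed uniformly on the marker's
coalescent genealogy (conditioning on the marker being variant), and
the mutant class is declared the band-presence allele with probability
1/2.  A band is present iff the individual carries ≥ 1 presence allele
(dominance).

**Crosses and swarms.**  Laboratory F1/F2 crosses and the
forward-simulated recent hybrid swarm operate on diploid genotype
arrays.  Markers sit on linkage groups (default 31, the lepidopteran
karyotype) with Markov recombination between adjacent markers (default
r = 0.1 per interval).  Linkage matters: genotypes at truly unlinked
loci are independent in an F1/F2 (independent assortment), so the
elevated linkage disequilibrium that diagnoses *recent* hybridization
exists only between physically linked markers.  Fully unlinked
behaviour is recovered by giving each marker its own linkage group.
Desk-scale LD experiments use a reduced genome (6 linkage groups ×
20 markers, adjacent r = 0.02) that preserves the *marker density* of a
real genome-wide AFLP panel rather than its chromosome count, because
density is what controls the fraction of testable linked pairs.

**What the generator does not emulate.**  Real AFLP data have peak-calling
noise, size homoplasy, and non-independent restriction sites; real
alignments have sequencing error, alignment ambiguity, and intralocus
recombination; real demography has population growth, range shifts, and
selection (the very thing hypothesized to maintain the hybrid species).
Passing tests therefore validate the *statistical machinery and its
expected behaviour under the stated neutral demography*, not the
robustness of the diagnostics to those artifacts.

## AMOVA Φ_ST (`popdiff`)

Squared pairwise distances are decomposed into among/within-group
variance components; Φ_ST = σ²_a/(σ²_a+σ²_w).  Sequence distance counts
differing polymorphic sites (a multi-base indel counts one), with
pairwise deletion of missing calls; haploid (mtDNA, female Z) and
diploid (male Z) sequences enter the same haplotype-level analysis.
Significance is by random label permutation with the plus-one
correction (default 10,000 permutations), or by exhaustive enumeration
of all distinct label arrangements for small samples.  Negative
variance components are reported as computed and flagged, never
truncated — truncation would break permutation exchangeability.  For a
single binary marker the permutation distribution is heavily tied, so
those p-values are valid but conservative (super-uniform); multi-site
statistics are effectively continuous and their null p-values are
uniform.

## Marker and genotype classification (`markers`)

Ancestry-informative markers are those with parental-contrast
permutation p ≤ 0.05.  The four-way classification of a hybrid's
marker frequencies follows the significance pattern of the two
hybrid-vs-parent tests; *intermediate* additionally requires the hybrid
frequency to lie inside the closed parental interval.  The residual
case — significant versus neither parent but frequency outside the
interval — is flagged `outside_nonsignificant` and counted with
*intermediate* in headline totals, because the four published categories
do not cover it and silently folding it in would hide information.  At
frequency ties with a parental value the significance pattern alone
decides.

Sequence genotypes are classified at sites with parental-contrast
p ≤ 0.001: each allele is assigned to the parent where it is more
frequent; an individual's call is its allele's class, `heterozygote`
when a diploid male carries one allele of each class, `missing`
otherwise (alleles seen in neither parent are counted and reported).
Note that even with strictly single-parent inheritance, shared ancestral
polymorphism leaves a minority of diagnostic-site calls associated with
the other parent — observed ≈ 15% in simulation — so "fixed for one
parent's mtDNA" manifests as a strong majority, not unanimity.

## Linkage disequilibrium (`ld`)

All unordered polymorphism pairs are tested with a two-sided Fisher
exact test on the 2×2 band/allele table (pairwise deletion; pairs
monomorphic after deletion are excluded from the denominator).  An
EM-based genotypic exact test for unphased diploid data is deliberately
not implemented: dominant bands and haploid/phased sequences give
unambiguous tables.  The headline summary is the percentage of pairs
significant at α = 0.01; per-polymorphism significant fractions (mean ±
SD across polymorphisms) are also emitted and feed the one-way ANOVA
comparisons between populations.  Both figures are reported because the
phrase "percentage of polymorphisms significantly associated" is
ambiguous between them.

## Species-specific diversity (`divstats`)

Per gene and species: polymorphisms segregating within the species;
species-specific polymorphisms (the within-species minor allele occurs
in no other species; frequency ties break toward the globally rarer
allele); haplotypes as greedy compatibility classes of full sequences
with `N` mismatch-neutral; species-specific haplotypes compatible with
no other species' sequence.  Proportions are exact fractions and feed
the one-way ANOVA untransformed — an arcsine or logit transform is
available in principle but not applied, as the untransformed analysis
reproduces the published F statistics.  The mtDNA clock calibration is
T = divergence / (2 × per-lineage rate): 3.17% at 1.15%/lineage/Myr
gives 1.38 ≈ 1.4 Myr.  The suspected-hybrid fraction divides hybrids by
the phenotypically pure individuals (16/286 ≈ 5.6%); dividing by all
individuals (16/302 ≈ 5.3%) is the noted alternative reading.

## Phylogenetics (`phylo`)

Distances between AFLP profiles default to the mean character
difference (mismatches over comparable markers; Jaccard available).
Neighbor joining uses the Saitou–Nei Q-criterion with deterministic
tie-breaking on the smallest index pair; additive matrices are
recovered exactly.  Negative branch lengths are clamped to zero with
the deficit moved to the sibling edge and flagged.  Bootstrap resamples
marker columns with replacement; an internal edge's support is the
percentage of replicate trees containing its leaf bipartition.

Binary traits are mapped by Fitch parsimony (unit-cost Sankoff) on a
tree rooted at a declared outgroup; *all* most-parsimonious
reconstructions are enumerated, so genuinely ambiguous histories
(parallel gains versus basal gain plus losses) are reported as the full
set rather than a single arbitrary choice.  A hybrid taxon is excluded
from the parsimony pass and attached post hoc, since parsimony on a
tree cannot represent reticulation.

## Admixture estimation (`admix`)

A Gibbs sampler over per-individual-per-marker ancestry assignments z,
cluster band frequencies p (Beta(1,1) prior), and admixture vectors q
(Dirichlet(α = 1) prior, α fixed).  Bands are modelled as haploid
binary observations — the dominant genotype is treated as the allele
itself.  This keeps all full conditionals conjugate; the cost is a
modest downward bias in minor-allele frequencies under dominance, and a
dominance-aware genotype likelihood is an explicit non-goal.  Label
switching is resolved after the fact by greedy correlation matching of
q columns across runs, never inside the sampler.  Scaled-down defaults
(burn-in 5,000, 20,000 collection sweeps) are desk-scale stand-ins for
production-length chains (hundreds of thousands of sweeps), which are
reachable through configuration.

## Pipeline and reproducibility

`pipeline.run_all` drives simulate → analyze → report from one config
and one mandatory seed.  The global seed expands into named per-stage
substreams (SeedSequence over a CRC of the stage name), so each stage
is individually reproducible and manifests are byte-identical across
reruns.  Stage failures are isolated: dependents are skipped, the
manifest records the failure, and the CLI exits non-zero.

## Problem sizes

Validation experiments run at desk scale, chosen to finish a full suite
in minutes on one core: 20–40 samples per population, 20 sequence loci
of 300–600 bp, a few hundred dominant markers, permutation counts of
500–10,000, Gibbs chains of a few thousand sweeps, and 100 replicate
datasets for ordering properties.  The acceptance experiments mirror
real study shapes where they matter: ≈ 250 ancestry-informative markers
surviving a screen, 40 individuals per species, 23 laboratory hybrids.

## Known limitations

* The haploid-band admixture likelihood ignores dominance; q estimates
  on real dominant data would be mildly biased toward the band-present
  cluster.
* Indel scoring collapses only *identical* gap patterns; overlapping
  but unequal deletions count as separate events.
* Haplotype compatibility grouping is greedy in input order; with
  heavy missingness the class count can depend on sequence order.
* The permutation test for a single binary marker is conservative
  (discrete statistic); screens at a given α therefore select slightly
  fewer than α of null markers.
* The coalescent marker simulator draws each marker independently, so
  parental populations carry no linked-marker background LD; only the
  forward simulators (crosses, swarms) generate linkage signal.
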