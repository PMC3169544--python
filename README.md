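# hybridhallmarks

Population-genetic diagnostics of **hybrid speciation** — the origin of a
reproductively distinct daughter species from interbreeding between two
parental species — plus a coalescent/forward simulator of the
admixture-founding demography so the whole battery of diagnostics can be
exercised and validated end to end.

The package grew out of the classic tiger swallowtail problem: is
*Papilio appalachiensis* a hybrid species derived from *P. glaucus* and
*P. canadensis*, with a mosaic genome (glaucus-like mitochondria/W,
canadensis-like Z chromosome, genome-wide admixed AFLPs)?  The tools are
generic: they apply to any system with per-gene sequence alignments, a
dominant binary marker matrix, and a sample→population map.

## What it computes

| module | diagnostic |
|---|---|
| `popdiff` | locus-by-locus AMOVA fixation index Φ_ST = σ²_among/(σ²_among+σ²_within) with label-permutation p-values (plus-one corrected; exact enumeration for small n) |
| `markers` | ancestry-informative marker screen (parental contrast p ≤ 0.05), four-way hybrid marker classification (parentA-like / parentB-like / intermediate / different), per-individual genotype mosaics at strongly differentiated sites (p ≤ 0.001) |
| `admix` | Bayesian admixture proportions q for dominant markers via a conjugate Gibbs sampler (Dirichlet prior on q, Beta on cluster band frequencies), with post-hoc label alignment across runs |
| `ld` | pairwise Fisher exact tests of association; percent of pairs significant at α = 0.01 per population; across-population ANOVA — elevated LD flags *recent* hybrids, background LD an old hybrid species |
| `divstats` | species-specific (private) polymorphism and haplotype proportions per gene, across-gene means/SDs, one-way ANOVA; molecular-clock split-time calibration T = divergence/(2·rate); bimodal-hybrid-zone fraction |
| `phylo` | mean-character-difference distances, Saitou–Nei neighbor joining (exact on additive matrices), column-bootstrap supports, Fitch parsimony trait mapping with full enumeration of most-parsimonious reconstructions |
| `simdata` | structured-coalescent simulation (msprime) of two old parental species and a young admixture-founded hybrid with unidirectional introgression; mitochondrial (maternal, Ne/2) and Z-linked (1.5·Ne; ZZ males, ZW females) inheritance; dominant markers; lab F1/F2 crosses and recent hybrid swarms with linked markers |
| `seqio` | FASTA alignments with `sample|population|sex|allele` headers, polymorphism tables (multi-base indels collapse to one site), AFLP/population-map TSV, Newick |
| `pipeline` | one-config, one-seed orchestration with per-stage seed substreams and a deterministic results manifest |

## Worked example

Simulate the mosaic scenario — autosomal founding 50:50, *all* founding
mothers from parentA, Z chromosome 90% from parentB — and ask each
compartment which parent the hybrid resembles:

```python
from hybridhallmarks import simdata, seqio, popdiff, divstats, datasets

params = simdata.default_scenario(seed=42, alpha_maternal=1.0, alpha_z=0.1)
loci = simdata.simulate_sequences(params)
for name in ("COI", "KET"):
    locus = next(l for l in loci if l.locus_name == name)
    table = seqio.extract_polymorphisms(locus)
    D = popdiff.pairwise_distances(table)
    groups = table.populations.loc[table.calls.index].to_numpy()
    print(name, "pairwise Phi_ST:")
    print(popdiff.pairwise_fst(D, groups).round(3))
```

```
COI pairwise Phi_ST:
         parentA  parentB  hybrid
parentA    0.000    0.964   0.539
parentB    0.964    0.000   0.988
hybrid     0.539    0.988   0.000

KET pairwise Phi_ST:
         parentA  parentB  hybrid
parentA    0.000    0.845   0.651
parentB    0.845    0.000   0.310
hybrid     0.651    0.310   0.000
```

The mitochondrial gene (COI) ties the hybrid to parentA (Φ_ST 0.54
versus 0.99 against parentB), while the Z-linked gene (KET) ties it to
parentB (0.31 versus 0.65) — opposite ancestry on the two sex-linked
compartments, the signature of a mosaic hybrid genome.  (The nonzero
hybrid-vs-maternal-parent Φ_ST is post-founding drift: the hybrid is a
real population with its own history, not a carbon copy of a parent.)

The packaged per-gene diversity counts for the three swallowtail species
reproduce the published summary statistics:

```python
counts = datasets.diversity_counts()
print(divstats.proportion_summary(counts, "polymorphisms").round(3))
an = divstats.anova_oneway(counts["proportion_specific_polys"], counts["species"])
print(f"ANOVA: F({an.df_between},{an.df_within}) = {an.F:.2f}, p = {an.p:.3f}")
cal = divstats.calibrate_split_time(3.17, 1.15)
print(f"split time: {cal.split_time_Myr:.2f} Myr")
```

```
                 mean     sd  n_genes
species
appalachiensis  0.408  0.192        7
canadensis      0.575  0.221        7
glaucus         0.587  0.158        7
ANOVA: F(2,18) = 1.90, p = 0.179
split time: 1.38 Myr
```

The hybrid species carries the lowest proportion of private
polymorphisms (0.41), as expected from its younger age, but the
difference is not significant — it is an established species, not a
transient hybrid swarm.  The calibration converts 3.17% mtDNA
divergence at 1.15% per lineage per Myr into a ≈ 1.4 Myr outgroup split.

A full run (simulate → Φ_ST → genotype mosaic → marker classification →
admixture at K = 2..4 → LD → diversity → NJ tree → trait mapping) is one
command:

```bash
hybridhallmarks run --seed 7 --out results/
```

which writes per-stage TSV/JSON tables, figures, and a deterministic
`manifest.json` (same seed ⇒ byte-identical).

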