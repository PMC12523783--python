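# Methods

`panmixsel` is a forward-in-time simulator of recurrent selection in a
panmictic (random-mating) population, built around three ideas: linkage
disequilibrium (LD) engineered by crossing two founder populations with
contrasting allele frequencies, a quantitative trait with additive, dominance
and classical digenic-epistatic gene action, and per-cycle genetic evaluation
by genomic or pedigree BLUP. This note records the model, its assumptions,
the defaults and why they were chosen, and what the synthetic data do and do
not capture.

## Genome and founder populations

The default genome mimics a commercial broiler chicken panel: 10 chromosomes
from 199.4 cM down to 25.7 cM, carrying 38,500 SNPs (10,000 on chromosome 1
down to 1,250 on chromosome 10) and 1,000 QTL (260 down to 30), all placed
uniformly at random. Only the endpoint chromosomes and the totals are pinned;
intermediate lengths follow a power-law interpolation whose exponent is solved
so the total map is exactly 770 cM, which reproduces the average marker
spacing of 0.02 cM and gene spacing of 0.77 cM. Intermediate locus counts are
proportional to chromosome length.

Allele frequencies in the two parental populations are drawn per locus from
Beta(mu*nu, (1-mu)*nu). The concentration nu defaults to 10 — enough spread
that loci differ meaningfully in frequency, but with negligible mass at
fixation. The stated frequency means are interpreted as the mean of the
sampled allele-1 frequency; for means at or below 0.5 this coincides with the
minor-allele-frequency reading up to sampling tolerance.

The reference population (generation 0) is created by crossing the two
parental populations (each in linkage equilibrium) and randomly mating the F1
once, which restores Hardy-Weinberg proportions. The gametic pool of
generation 0 then carries LD

    Delta_ab = (1 - 2 theta_ab) / 4 * (p_a1 - p_a2)(p_b1 - p_b2),

so LD is controlled entirely by the frequency contrast between the parents:

* **low-LD design** — SNP means 0.3/0.3, favorable-QTL means 0.6/0.6;
  expected LD is zero at every pair (individual pairs fluctuate);
* **high-LD design** — SNP means 0.1/0.5, favorable-QTL means 0.3/0.9; every
  frequency difference has the same sign, so pairwise LD is predominantly
  positive and the LD covariance dominates the genotypic variance.

Every generation-0 allele copy carries a unique founder-origin label
(2*individual + haplotype), distinguishing identical-by-state copies, so
identity by descent can be counted exactly downstream.

## Trait

The simulated trait is feed conversion ratio (FCR) — lower is better. Per-QTL
effects derive from the homozygote genotypic bounds (defaults 1.1 and 2.9):
with equal allocation each QTL gets midpoint m_i and half-range a_i such that
sum(m+a) and sum(m-a) hit the bounds exactly (a geometric-series allocation is
available). Dominance is positive toward the FCR-raising allele with degree
of dominance Uniform(0, 1.2) (mean 0.6), which makes the favorable alleles
recessive. Phenotypes add a normal error whose variance is re-derived each
generation from the cohort's realized genotypic variance so broad-sense
heritability stays at H2 = 0.30, then truncate into [1.0, 3.5] to avoid
outliers.

### Digenic epistasis

A configurable fraction of QTL (default 0.5 when enabled) is paired into
disjoint interacting pairs. Each pair gets one of the seven classical types,
named by the F2 phenotypic ratio it produces: complementary (9:7), duplicate
(15:1), dominant (12:3:1), recessive (9:3:4), dominant-and-recessive (13:3),
duplicate genes with cumulative effects (9:6:1), and a four-distinct-class
interaction type (the 9:3:3:1 pattern with all four classes distinct). The
two-locus value is G_xy = m_i + m_j + alpha_x + alpha_y + I_xy and the nine
epistatic effects are solved from the type's class structure: G is constant
within each phenotypic class; the class containing the double homozygote
(2,2) is pinned by a random draw

    I22 ~ N(0, k (sigma_A^2 + sigma_D^2 + 2 sigma_AD)),   k = 1.5,

with the variances computed from the pair's generation-0 allele frequencies
(sigma_AD = 0 under random mating); every other class is anchored by zeroing
the epistatic effect of its lowest-coded member, which perturbs the
non-epistatic surface minimally. Tables are solved once at generation 0 and
fixed thereafter: epistatic effects are properties of genotypes, not of
frequencies. Variances are partitioned by the Kempthorne orthogonal-contrast
decomposition (additive, dominance, AxA, AxD+DxA, DxD under HWE and linkage
equilibrium); the implementation is checked against a brute-force weighted
regression over the nine genotypes to 1e-10.

## Population machinery

Meiosis uses the Haldane map function: crossover counts are Poisson(L/100)
per chromosome with uniform positions and no interference. Allele states and
founder-origin labels travel together. One mating design is used for every
generation including the first: each cycle takes the selected (or, for
generation 1, randomly drawn) n_sires males and n_dams = 5*n_sires females,
allocates five dams per sire at random while avoiding matings between
individuals that share a parent (full or half sibs; the rule relaxes with a
warning only if no allocation exists), and produces 10 offspring per dam with
Bernoulli(1/2) sexes.

Three inbreeding coefficients are tracked: pedigree F from a
generation-layered kinship recursion (identical to the tabular
numerator-relationship result, verified to machine precision); genomic F as
the diagonal of the VanRaden matrix minus one; and realized F as the fraction
of SNP loci at which an individual's two alleles carry the same
founder-origin label.

## Evaluation and selection schemes

The mixed model is y = Xb + sum_k u_k + e with independent random effects
per relationship kernel: VanRaden (method 1) additive G and Su et al.
dominance D by default, optionally the Hadamard products G#G, G#D, D#D
(rescaled to unit mean diagonal) for AxA, AxD+DxA and DxD covariances, or the
pedigree numerator matrix A for pedigree BLUP. Kernel reference frequencies
come from the currently genotyped set (training plus candidates) at each
evaluation. Variance components are estimated by average-information REML
with an EM-type multiplicative fallback, convergence at a maximum relative
component change of 1e-6 or 200 iterations, variance floors at 1e-8 of the
phenotypic variance, and a 1e-6 diagonal ridge on each kernel. Components
that collapse onto the floor are pinned there and removed from the update —
with realistic trait architectures the dominance component is a ~1e-3 share
of the phenotypic variance, and without pinning a vanishing component never
satisfies a relative-change criterion. When the training set exceeds 1,500
records the components are estimated on a random subset of that size (they
are population parameters, so a subset estimates them consistently); the BLUP
step always uses every phenotyped record, and candidate predictions come from
the marginal-covariance projection, which equals the joint mixed-model
solution for non-phenotyped individuals.

Eight schemes share founders, genome and trait architecture within a
replicate and differ only in criterion and phenotyping policy: GS (GBLUP,
training = founders plus a random 20% of every generation, cumulative), GS1
(founders only — no model updating), GS2 (10% per generation), GS3 (half the
parents, double progeny — higher intensity), GV (true genotypic value), pbB
(pedigree BLUP, all phenotyped), pbB1 (pedigree BLUP, 20% phenotyped) and NS
(random parents, same numbers, preserving effective size). Selection is
within-sex truncation on the predicted additive value (FCR: lowest first),
400 females (20%) and 80 males (4%) at full scale, ties broken by id.

## Scale presets

* **full** — the reference design above: 400+400 founders, 4,000 candidates
  per generation, 7 cycles, 10 replicates.
* **desk** — used by the acceptance script and the heavier tests. It
  preserves every dimensionless quantity (selection fractions 20%/4%, five
  dams per sire, progeny 10, training fractions, H2, trait bounds, k, the
  dominance-degree distribution, founder-frequency designs) and the two
  anchors that set the genetic-variance scale: the total map length (770 cM
  over 3 chromosomes of 320/260/190 cM — the LD covariance contributed by the
  founder cross is proportional to map length and its decay kernel depends
  only on pair distances) and the QTL count (1,000 — per-locus effects scale
  as 1/n_QTL, so the non-LD additive variance does too). Only the marker
  panel (3,000 SNPs) and the cohort sizes shrink: 180+180 founders, 180 dams
  and 36 sires selected from 1,800 candidates. Effective population size is
  therefore about 2.2 times smaller than at full scale, which proportionally
  inflates inbreeding coefficients and drift effects; this is the one
  dimension the desk scale cannot preserve.
* **toy** — a seconds-scale smoke configuration for tests.

## What the desk scale shows and what it cannot

High-LD results transfer well: the genotypic variance, its erosion (driven by
recombination decaying the predominantly positive LD), the realized gains and
the prediction accuracies are comparable to full scale by construction of the
two anchors. Inbreeding levels are inflated by the smaller effective size.
The low-LD no-selection variance trajectory deserves a caveat: the expected
decrease is small (heterozygosity loss of order F, a few percent) and at desk
effective size it is partly offset by a positive variance contribution from
identity disequilibrium interacting with directional dominance (heterozygosity
becomes correlated across loci as ancestry variance accumulates, and all
dominance deviations share a sign), while drift-realized LD adds a
per-replicate noise of several percentage points. The sign of a single
replicate's change is therefore uninformative at this scale; the acceptance
script averages over many replicates and the methods here document the
mechanism.

## Numerical choices and degenerate inputs

Monomorphic markers contribute zero to both numerator and denominator of the
genomic matrices and are effectively dropped (an all-monomorphic panel is an
error). Exact position ties in genome construction are resampled. An empty
mating plan yields an empty generation. A cohort with zero genotypic variance
reuses the last positive error variance, with a warning. Phenotype truncation
beyond 1% of records warns. Zero-length chromosomes transmit unrecombined
haplotypes. Pedigree routines require non-overlapping generations, which the
design guarantees. Genomic kernels are assembled from cached Gram matrices
(M M' and the heterozygosity analogue), which makes the per-cycle
recentering at current frequencies a rank-one correction instead of a full
matrix product; the assembled kernels match the direct definitions to
machine precision.

## Known limitations

No mutation, no sex chromosomes, no crossover interference, no overlapping
generations, no genotype-by-environment interaction, no maternal or litter
effects, no higher-order (>2 locus) epistasis. The simulator is not a
single-step evaluator: genotypes are available for every candidate by design.
Pedigree BLUP with full phenotyping accumulates every record, so at full
scale its mixed-model solves grow cubically and dominate runtime; the desk
and toy presets are the practical scales for that scheme.
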