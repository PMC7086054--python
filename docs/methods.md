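# Methods

This note documents the statistical models implemented in `mhcdiv`, the
choices made where conventions genuinely differ, and what the synthetic
data generator does and does not emulate.

## Data model

Genotypes are presence/absence sets of allele identifiers per individual
and sampling site. This is deliberate: in duplicated MHC gene families,
amplicon genotyping yields 2–6 sequence variants per individual that
cannot be assigned to loci, so homozygosity and copy number are
unobservable. Every statistic in the package is defined on sets, and the
only frequency notion used is the *incidence frequency*: the share of
individuals carrying an allele. Allele nucleotide sequences must be
equal-length, gap-free and stop-free in the configured reading frame;
`frame_offset` (0–2, default 0) is an explicit input because a PCR
fragment's frame is a property of the primer design, not of the data
file, and a trailing incomplete codon is silently trimmed.

## Supertype clustering

Each allele is encoded by the five z-scale descriptors (hydrophilicity,
steric bulk, polarity and two electronic scales) of its residues at the
positively selected sites, concatenated in PSS order into a 5·|PSS|
vector. Clustering is plain k-means on these raw descriptors with
best-of-`n_starts` restarts (default 20) under a fixed seed; no PCA or
discriminant-analysis reduction is applied, because the allele counts
involved (tens) do not warrant it and raw-space clustering is
deterministic and transparent. PSS positions are an *input*: inferring
them requires phylogenetically controlled selection tests that are out
of scope here.

Model selection uses `BIC(k) = n ln(WSS_k/n) + k ln(n)` with `n` the
allele count. The WSS inside the logarithm is floored at 10⁻³ of the
total sum of squares: when k reaches the number of distinct descriptor
rows, WSS collapses to zero, and an absolute floor near machine epsilon
would make that single drop dominate the curve's range and defeat any
relative elbow rule. The elbow itself is operationalised explicitly:
the chosen k is the smallest one whose BIC decrease to k+1 is less than
`drop_threshold` (default 0.01) of the curve's total range. "Negligible
decrease" is a judgement call in the literature; making the threshold a
logged, configurable number keeps the judgement reproducible. A manual
`k_override` is supported and logged. Flat curves return the smallest k;
monotone-increasing curves do too, with a warning. k-means ties are
resolved by scikit-learn's deterministic assignment; final labels are
renumbered 1..k by first appearance in catalog order so that the
partition, not the arbitrary label, is the output.

## Index of association

For alleles a, b scored over n individuals, the mismatch indicator
`d_a(i,j)` is 1 iff individuals i and j differ in presence of a. With
population (divide-by-N) moments over all n(n−1)/2 pairs,

    I_A = Var(d_a + d_b) / (Var(d_a) + Var(d_b)) − 1
        = 2 Cov(d_a, d_b) / (Var(d_a) + Var(d_b)).

The moments depend only on the 2×2 carrier table, which the
implementation exploits; the test suite pins the formula to an
exhaustive enumeration oracle over all individual pairs. I_A is
undefined (an error, never 0) when either allele is monomorphic in the
sample, and such pairs are excluded from the Bonferroni denominator.
Note that a pair and its complement yield the same I_A — the statistic
sees co-*segregation*, not co-occurrence direction.

The permutation test permutes one column across individuals (sufficient
under exchangeability). Under a uniform permutation the carrier overlap
is exactly hypergeometric in the two margins, and I_A given the margins
is a function of the overlap alone, so the null is sampled directly from
that distribution rather than by materialising permutations; the test
suite verifies the equivalence against literal column permutation.
P-values use the add-one estimator `p = (1 + #{I_A* ≥ I_A})/(n_perm+1)`
(default `n_perm` 99,999), so `p ≥ 1/(n_perm+1)` and p = 0 is
impossible. Because the null is discrete, p-values are conservative
(super-uniform), which the calibration tests assert; exact uniformity is
not attainable for any exact test on this statistic.

## Null genotype simulation

The question is whether individuals carry more functionally distinct
supertypes than random assembly of the observed alleles would produce.
The default assembly includes each allele independently with its
observed incidence frequency (preserving marginals) and rejects/redraws
all-zero genotypes; the rejection count is logged and the resulting
marginal is `p_a/(1 − Π(1−p_i))`, which the tests check analytically. An
alternative `fixed_counts` assembly draws the per-genotype allele count
from the observed count distribution and samples that many distinct
alleles with probability proportional to incidence; both are exposed
because the mechanism behind "random occurrence" admits either reading.
In linked mode, Bonferroni-significant pairs enter as all-or-none units
whose inclusion probability is the arithmetic mean of the members'
incidences (members of significant pairs have near-identical incidences
by construction, and the choice is logged per pair); a `proportional`
mode softens the unit by a per-pair strength. Overlapping pairs are an
error — merging into larger cliques is not attempted. Ensembles default
to 50,000 genotypes and are bit-reproducible given a seed.

Observed and simulated supertype-count distributions are compared with a
one-sample Kolmogorov–Smirnov statistic against the ensemble's empirical
CDF treated as a fixed discrete null. Because the support is a handful
of small integers, the asymptotic continuous KS p-value would be badly
mis-calibrated; instead p is Monte-Carlo — resample observed-size
samples from the null CDF (default 100,000 replicates) and apply the
add-one estimator. A two-sided mean-based empirical p (how often a null
resample's mean deviates from the null mean by at least the observed
amount) is reported alongside, since a location shift is the
scientifically interesting alternative and the two tests answer
slightly different questions.

## Diversity statistics

All sequence statistics are computed over *unique* alleles, unweighted
by incidence, because copy numbers are unknown; an incidence-weighted π
would silently assume one copy per carrier. Rarefied allelic richness
operates on individual-allele presence records (one record per carrier),
`A_R = Σ_a [1 − C(N−n_a, g)/C(N, g)]`, with the draw size `g` defaulting
to the smallest per-site record total. Rarefaction over gene copies
under an assumed ploidy — what diploid-marker tools do — is not
expressible for presence data, so richness values are comparable within
an analysis but not across conventions.

The synonymous/nonsynonymous partition uses unweighted Nei–Gojobori
counting with no multiple-hit correction (proportions, matching how
small MHC fragments are usually reported): per codon, each position
contributes one site split by the fraction of non-stop single-base
changes that are synonymous; per codon pair, differences are averaged
with equal weight over the minimal mutational pathways, excluding
pathways through stop codons (falling back to all pathways only if
every one is blocked — possible only for artificial inputs). Sites are
averaged between the two sequences of a pair. Pairs whose averaged site
count for a component is zero are excluded from that component's mean
with a logged count, not zero-filled. The pathway logic is pinned to an
independent enumeration oracle in the tests, and a conservation check
asserts that syn + nonsyn differences reproduce the raw mismatch count.

## Differentiation

Rho is reconstructed from between-individual gene identity: the
probability that one allele drawn uniformly from one individual's set
equals one drawn from another's (`|g₁∩g₂|/(|g₁||g₂|)` for presence
sets; averaged over loci of the two-draw match probability for diploid
panels). With Q2 the mean identity for same-site pairs and Q3 for
cross-site pairs, `Rho = (Q2 − Q3)/(1 − Q3)`. Within-individual identity
never enters, which is exactly what makes the statistic indifferent to
ploidy and to per-individual allele counts. Pairwise Rho averages the
two sites' within-site means for Q2; global Rho pools all within-site
pairs with equal weight. Two estimator artefacts are worth knowing:
literally identical site compositions give a small *negative* Rho of
order 1/n (cross-site pairs include each individual's twin, within-site
pairs do not), and an all-heterozygous diploid locus fixed for disjoint
allele pairs gives Rho = 0.5, not 1, because Q2 is 0.5 by definition.
Permutation significance shuffles individuals between the two sites;
since identity does not depend on labels, the identity matrix is
computed once and permutations only re-partition it.

Mantel tests correlate upper-triangle entries (Pearson), permuting rows
and columns of the first matrix simultaneously, one-tailed upper,
add-one estimator, 719 permutations by default. The partial Mantel uses
the standard first-order partial correlation and permutes the raw first
matrix (residual-based permutation); the method label is recorded in
outputs because partial-Mantel conventions differ between packages. A
constant covariate reduces to the simple Mantel; a covariate collinear
with a tested matrix is reported undefined. Geographic distances are
Euclidean for planar coordinates and great-circle (Earth radius
6371.0088 km) for lon/lat.

## Synthetic data generator

The generator produces data shaped like a two-range MHC survey: an
89-allele catalog of 184-nt alleles with 10 planted supertypes at 5 PSS;
one native site (n = 21) drawing from a 32-allele pool and seven
invasive sites (n = 16, 7, 35, 27, 107, 36, 89) sharing a 20-allele pool
with 6 alleles common to both pools; 2–6 alleles per individual
(distribution {2: .20, 3: .40, 4: .25, 5: .10, 6: .05}); one fully
linked allele pair planted in the invasive pool; linear site
coordinates.

Planted supertypes are residue pools at the PSS chosen by greedy maximin
in z-space; by default each supertype uses a single anchor residue per
PSS (alleles of one supertype share their binding residues exactly —
the sharpest form of functional equivalence), with a `pool_size` knob to
soften the structure and `separation = 0` as a negative control. Outside
the PSS, alleles descend from one ancestral sequence with a 6% per-codon
replacement rate, placing pairwise π near 0.1–0.15 — the right order for
MHC exon-2 data — without any substitution-model realism. Site structure
enters as logit-scale perturbations of per-allele base incidences
(Beta(0.8, 1.6): a few common, many rare alleles), independent per site
or as a Brownian walk along site order (`spatial=True`) so divergence
grows with distance; individuals draw an allele count and then alleles
weighted by site frequency; linked pairs are enforced all-or-none with a
configurable strength. The diploid microsatellite generator is an
island model: site frequencies are Dirichlet draws around a common
ancestral frequency vector with concentration monotone in the
divergence knob.

What the generator does **not** emulate — and hence what passing tests
do and do not show about real data: no coalescent or mating-system
structure (allele co-occurrence within individuals is random apart from
planted pairs, so there is no planted divergent-allele advantage and the
observed-vs-null comparisons are null by construction); mutations are
uniform across non-PSS positions, so segregating-site counts run higher
than in real conserved exons at matched π; all sites share one allele
support, so realised Rho/(1 − Rho) (~0.02–0.06) sits below the ~0.2 that
surveys with partially disjoint allele pools report; and allele dosage
does not exist, by design. Recovery tests therefore demonstrate
correctness of the estimators under their own assumptions, not power on
any particular real dataset.

## Problem sizes and determinism

Default analysis sizes are the ones the methods were designed around:
99,999 association permutations, 50,000-genotype ensembles, 100,000 KS
resamples, 999 Rho permutations, 719 Mantel permutations. The test suite
and the acceptance script scale some of these down (they state their
sizes inline) — the statistics are estimator-exact at any permutation
count, only the p-value granularity changes. Every random stage takes an
explicit seed; identical configuration yields bit-identical outputs,
which the pipeline tests assert.
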