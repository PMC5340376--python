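# Methods

`mtphylogeo` implements the standard mitochondrial phylogeography workflow
for structured populations: collapse aligned mtDNA sequences to haplotypes,
summarise within-group diversity, test for departures from neutrality,
characterise demographic history from mismatch distributions, partition
molecular variance hierarchically, and visualise relationships as trees and
haplotype networks. This note records the models, conventions and numerical
choices behind each stage, and what the synthetic-data generator does and
does not emulate.

## Site handling

All statistics share a single *complete-deletion* site set: any alignment
column containing a gap (`-`) or an `N` in any sequence is excluded once,
up front. Haplotype identity, diversity, distances and mismatch spectra are
all computed on this set, so a haplotype table is always consistent with
the diversity values computed from it. The number of excluded sites is
logged. IUPAC ambiguity codes other than `N` are mapped to `N` on input by
default (configurable to reject). When two loci are concatenated, specimen
ids must match exactly between loci; an optional regex can strip locus
suffixes first.

## Diversity

Gene (haplotype) diversity uses the small-sample-corrected estimator
h = n(1 − Σp²)/(n − 1) and nucleotide diversity the mean per-site
proportion of raw pairwise differences (p-differences, not model-corrected
— the convention of DnaSP and most mtDNA surveys). Sampling standard
deviations follow Nei (1987): eq. 8.12 for h and the no-recombination form
of eq. 10.7 for π. Mean pairwise differences k̄ always satisfy k̄ = π·L on
the retained length L; a brute-force double-loop oracle enforces this in
the tests.

## Distances

Raw Hamming counts, p-distances and Kimura two-parameter distances are
supported. K2P separates transitions (within {A,G} or {C,T}) from
transversions: d = ½ln(1/(1−2P−Q)) + ¼ln(1/(1−2Q)). Saturated pairs
(non-positive logarithm argument) are flagged `NaN` rather than truncated;
tree building refuses matrices containing them. Global matrices use the
complete-deletion set so one L underlies every pair.

## Neutrality tests

Tajima's D is computed from (n, S, k̄) with the usual a₁…e₂ constants.
S = 0 yields a flagged undefined result, not zero. Fu's Fs evaluates
S′ = Pr(K ≥ k_obs) under the Ewens sampling distribution at θ = k̄ (the
estimator Fu recommended), with Pr(K = k) = |s(n,k)|θᵏ/(θ)ₙ. Unsigned
Stirling numbers of the first kind are built by the standard recursion
carried entirely in log space, and both tails of S′ are log-sum-exp
accumulations, so n in the hundreds (the scale of a pooled mtDNA survey)
is numerically safe; Fs = ln S′ − ln(1 − S′) is formed as the difference
of the two tail log-masses. k_obs = 1 gives S′ = 1 and a flagged +∞.

Significance comes from neutral constant-size coalescent simulation
conditioned on θ̂ = k̄ (1000 replicates by default, seedable): genealogies
with exponential coalescence times, Poisson mutations on branches,
infinite sites. p_D is two-tailed empirical; p_Fs = Pr(Fs_sim ≤ Fs_obs).
Empirical p-values use the (count + 1)/(reps + 1) estimator throughout the
package. The simulator reports S, k̄ and the haplotype count per replicate
directly from the genealogy (a branch with m mutations separates
c(n − c) pairs; tips share a haplotype iff no mutation lies between them),
avoiding sequence construction. Its E[S] = θa₁ and E[k̄] = θ identities
are tested against both the closed forms and msprime as an independent
oracle. A calibration experiment (400 neutral datasets at n = 20, θ = 5,
null of 150 replicates each — sizes chosen to make the binomial error
small at desk scale) checks that p_D rejects at the nominal 5% level.

## Mismatch distributions and dating

The sudden-expansion model (Rogers & Harpending 1992): a population at
scaled size θ₀ jumps to θ₁ at mutational time τ = 2μT before present. The
expected spectrum is

F_i(τ,θ₀,θ₁) = F̂_i(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{j≤i} (τʲ/j!)[F̂_{i−j}(θ₀) − F̂_{i−j}(θ₁)]

with F̂_i(θ) = θⁱ/(1+θ)^{i+1}, renormalised over the observed support
0…i_max. Two limits anchor the implementation: τ = 0 returns the
equilibrium spectrum at θ₀, and θ₀ → 0, θ₁ → ∞ collapses to Poisson(τ)
(tested to 1e−3).

Fitting minimises SSD = Σ(f_i − F_i)² with a 5×5×5 log-spaced multi-start
grid (τ additionally seeded at the spectrum mean) followed by Nelder-Mead
refinement of the five best seeds; parameters are clamped to τ ∈ [0, 50],
θ₀ ∈ [0, 20], θ₁ ∈ [θ₀, 10⁴] (the fit is parametrised in θ₁ − θ₀ so the
ordering constraint cannot be violated). The fitted optimum is verified to
beat every grid seed. The SSD goodness-of-fit p-value is a parametric
bootstrap (default 200 replicates): coalescent samples under the fitted
parameters — the constant-size engine with a single ancestral size change
at scaled time τ/θ₁ and rate ratio θ₁/θ₀ — are refitted (moment seed plus
the generating parameters, one local refinement each) and replicate SSDs
≥ observed are counted.

**Dating.** τ converts to years through τ = 2μT, where 2μ is twice the
whole-sequence divergence rate: T = τ·g/(2·d·L) with d the per-site
divergence rate per year (default 1.42e−8, i.e. 1.42%/Myr, the midpoint of
the 1.17–1.66%/Myr range commonly applied to decapod mtDNA), g the
generation time (1 year) and L the sites sequenced (792 for the two
concatenated fragments). Dates are truncated (floored) to whole years:
with τ = 4.713 this convention yields 209,533 years, which rounding would
miss by one. Lineage ages use A = π/d — the dimensional reading of the
"A = μπ" shorthand that reproduces the published lineage ages from
unrounded π — and are linear in π. The reported dating table propagates
the rate range into earliest/latest bounds.

## Population structure

AMOVA follows Excoffier, Smouse & Quattro (1992) on squared
inter-individual distances (squared raw difference counts by default, the
ARLEQUIN convention; squared K2P optional and recorded in the run config).
Sums of squares are partitioned into among-group, among-populations-
within-group and within-population pieces with df (G−1, P−G, N−P);
variance components come from the standard unequal-sample-size
n-coefficients, and negative components are retained (not truncated) when
forming Φ_CT = σa²/σ_T², Φ_SC = σb²/(σb²+σc²), Φ_ST = (σa²+σb²)/σ_T².
Three permutation schemes match the statistics: individuals among
populations (Φ_ST), individuals among populations within groups (Φ_SC),
and whole populations among groups (Φ_CT); 10,000 permutations by default.
Pairwise Φ_ST is exactly the two-population one-group AMOVA (an identity
the tests enforce to 1e−12), with the same permutation scheme. The
grouping search evaluates user-supplied candidate partitions and ranks by
Φ_CT; no simulated-annealing search is attempted.

UPGMA on the pairwise Φ_ST matrix uses average-linkage agglomeration
(negative Φ values clamped to zero with a warning) with node heights at
half the merge distance, emitted as Newick. The Mantel test correlates the
off-diagonal entries of the genetic and great-circle geographic distance
matrices, permuting rows/columns of one matrix jointly (1000 permutations
default, seedable; exhaustive enumeration available for small matrices).
It is implemented in-package so that permutations are reproducibly seeded,
and is cross-checked against scikit-bio's implementation in the tests.

## Trees and networks

Neighbour joining (on K2P distances by default) is delegated to
scikit-bio; negative branch lengths are clamped to zero and logged.
Bootstrap support resamples alignment columns with replacement, rebuilds
the tree, and reports bipartition recovery percentages. Lineage assignment
for downstream per-lineage statistics takes the two clades flanking the
midpoint root of the haplotype NJ tree, labelling the clade with higher
nucleotide diversity "A" (older lineages retain more variation); explicit
specimen lists override the tree rule for exact reproduction of a
published split.

The median-joining network implements Bandelt et al. (1999) with ε = 0 and
unit site weights by default: iterate minimum-spanning-network
construction (all edges joining components still separate at the previous
distance level; ties broken lexicographically for determinism) with
quasi-median addition (majority state per site over feasible triplets,
three-way ties resolved toward the first sequence; a median is added only
when it strictly shortens the two-link path it replaces), then prune
obsolete medians (degree ≤ 1, or degree 2 adding no shortcut) to a fixed
point. Median vectors never duplicate observed haplotypes, and re-running
the construction on a network's own vertex set reproduces it.

## Synthetic data

The generator's defaults are the study conditions the pipeline targets:
ten populations of sizes 26, 24, 22, 30, 20, 24, 25, 22, 15 and 31
(239 specimens), loci of 421 + 371 sites, two maternal lineages mixed
within four of the populations (A/B totals 118/121), founders separated by
12 fixed differences, per-lineage expansion parameters τ_A = 4.713 and
τ_B = 1.108, transition:transversion bias κ = 4 (so K2P ≠ p-distance in
tests) and an AT-biased ancestral composition (GC ≈ 36%, between the two
loci's published values). Approximate site coordinates support geographic
distance matrices.

Each lineage is generated under a *star-genealogy approximation*: every
specimen receives Poisson(τ/2) mutations from its lineage founder at
uniform random sites, so within-lineage pairwise differences are
approximately Poisson(τ) and τ is directly interpretable as the
within-lineage mismatch mean. This reproduces the qualitative structure
the analysis assumes — star-like post-expansion clusters, unimodal
per-lineage and bimodal pooled mismatch distributions — and makes
parameter recovery exact in expectation. It does **not** emulate residual
pre-expansion coalescent structure (θ₀ is effectively 0), recombination
(absent in mtDNA anyway), selection, or the precise haplotype-sharing
pattern of the real data (a star model produces more singleton haplotypes
than a correlated genealogy, so published haplotype counts are not
reproduced by simulation). Passing tests therefore demonstrate correctness
of the estimators under their own model assumptions, not agreement with
any field dataset. The full two-epoch coalescent engine is available as an
alternative generator where genealogical correlation matters.

Same seed and config give byte-identical FASTA output; every stochastic
stage of the pipeline takes an independent named seed recorded in the run
log.

## Degenerate inputs and tie-breaking

Monomorphic alignments: S = 0 flags Tajima's D undefined; all-zero AMOVA
variance flags Φ as NaN; a single haplotype cannot form a network.
Haplotype ordering is by decreasing total count with ties broken by first
occurrence. MST/link selection ties break lexicographically. Permutation
p-values can never be zero by construction.

## Problem sizes used in checks

The stochastic acceptance experiments run at desk scale by design: τ
recovery uses 10 seeds of n = 120 sequences (median within ±25% of
τ = 4.7); the neutrality calibration uses 400 datasets with 150-replicate
nulls; bootstrap and permutation defaults (1000 / 10,000) apply to real
analyses, while the test suite uses smaller, seeded counts.

## Known limitations

Only the K2P substitution model is offered (with raw/p-distances); no
model selection or likelihood trees — the NJ bootstrap carries the
lineage-split question. The mismatch model is the demographic
sudden-expansion form, not the spatial-expansion variant. The Ewens-based
Fs assumes neutrality and no recombination. Geographic distances are
great-circle, not watercourse or least-cost paths.
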