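# mtphylogeo

Mitochondrial-DNA phylogeography for structured populations: from aligned
multi-locus mtDNA sequences and a population map to haplotype tables,
diversity and neutrality statistics, mismatch-distribution demography with
expansion dating, hierarchical AMOVA and pairwise Φ_ST, NJ/UPGMA trees,
and median-joining haplotype networks.

The package targets the common design of freshwater/coastal mtDNA surveys
— e.g. the oriental river prawn (*Macrobrachium nipponense*) sampled at
ten East Asian sites (239 specimens, concatenated 16S rRNA + COI
fragments of 421 + 371 bp), where two deeply diverged maternal lineages
mix within several populations. A synthetic-data generator reproduces
exactly this structure so that the whole pipeline is testable at desk
scale, with truth records for parameter-recovery experiments.

## What it computes

* **Haplotypes & sites** — exact-identity haplotype collapsing over a
  complete-deletion site set; variable and parsimony-informative sites;
  base composition.
* **Diversity** — gene diversity h = n(1 − Σp²)/(n − 1) and nucleotide
  diversity π (mean per-site p-differences), with Nei (1987) sampling
  variances.
* **Neutrality** — Tajima's D and Fu's Fs, the latter via the Ewens
  sampling distribution Pr(K = k) = |s(n,k)|θᵏ/(θ)ₙ evaluated in log
  space; p-values by seeded neutral coalescent simulation conditioned on
  θ̂ = k̄.
* **Demography** — observed mismatch spectra; the Rogers–Harpending
  sudden-expansion model F_i(τ, θ₀, θ₁) fitted by multi-start least
  squares with a parametric-bootstrap SSD test; dating via τ = 2μT
  (T = τ·g / (2·d·L)) and lineage ages via A = π/d.
* **Structure** — AMOVA variance components and Φ_CT / Φ_SC / Φ_ST with
  the three matching permutation schemes; pairwise Φ_ST matrices; UPGMA
  on Φ_ST; Mantel tests against great-circle distances.
* **Trees & networks** — neighbour joining on K2P distances with
  site-resampling bootstrap; median-joining haplotype networks
  (Bandelt et al. 1999) with median vectors flagged.

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

```python
from mtphylogeo import (SimulationConfig, simulate_dataset_object, collapse_haplotypes,
                        diversity_summary, neutrality_test, mismatch_distribution,
                        fit_expansion, expansion_time, DatingConvention, amova)

dataset, truth = simulate_dataset_object(SimulationConfig(seed=1))
table = collapse_haplotypes(dataset)
div = diversity_summary(dataset.alignment)
print(f"n = {dataset.alignment.n}, haplotypes = {table.n_haplotypes}")
print(f"h = {div.h:.3f} +/- {div.h_sd:.3f}, pi = {div.pi:.5f} +/- {div.pi_sd:.5f}")

neut = neutrality_test(dataset.alignment, reps=1000, seed=0)
print(f"Tajima's D = {neut.D:.3f} (p = {neut.p_D:.3f}), Fu's Fs = {neut.Fs:.3f} (p = {neut.p_Fs:.3f})")

lineage_a = dataset.subset_by_lineage("A")
fit = fit_expansion(mismatch_distribution(lineage_a.alignment))
years = expansion_time(fit.tau, DatingConvention(L=792))
print(f"lineage A: tau = {fit.tau:.3f} -> expansion {years:,} years ago")

res = amova(dataset, n_perm=999, seed=0)
print(f"AMOVA: Phi_ST = {res.phi_st:.4f} (p = {res.p_values['phi_st']:.4f})")
```

prints

```
n = 239, haplotypes = 157
h = 0.906 +/- 0.018, pi = 0.01122 +/- 0.00574
Tajima's D = -2.559 (p = 0.002), Fu's Fs = -226.095 (p = 0.001)
lineage A: tau = 3.756 -> expansion 167,008 years ago
AMOVA: Phi_ST = 0.7226 (p = 0.0010)
```

Reading the output: the pooled sample is highly diverse (h near 1) with
strongly negative, significant D and Fs — the signature of demographic
expansion; the fitted within-lineage expansion parameter τ converts to an
expansion date through the 1.42%/Myr divergence rate over 792 sites; and
most molecular variance lies among populations (Φ_ST ≈ 0.72 here, where
the generator's lineage sorting is sharper than in field data). The fitted
τ = 3.76 sits within sampling error of the generator's 4.713 for a single
seed; the test suite checks the median over ten seeds.

The same pipeline runs from the shell on FASTA + TSV inputs:

```bash
mtphylogeo simulate --seed 7 --out sim/          # or bring your own data
mtphylogeo run --config run.yaml                 # full report bundle
mtphylogeo stats --fasta sim/16S.fasta --fasta sim/COI.fasta --map sim/populations.tsv
mtphylogeo date --tau 4.713                      # -> expansion time: 209533 years
```

`run` writes TSV tables (per-group diversity/neutrality, pairwise Φ_ST
with p-values, AMOVA per candidate grouping, mismatch fits, dating with
rate-range bounds), Newick trees, a GraphML network and a YAML run log
recording seeds and versions.

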