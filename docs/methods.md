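# Methods

This package re-implements, as a self-contained analysis pipeline, the
population-genetic machinery behind a demographic study of Norway spruce
(*Picea abies*) and its relatives Siberian spruce (*P. obovata*) and Serbian
spruce (*P. omorika*): summary statistics from SNP genotypes, joint
site-frequency-spectrum (SFS) construction, coalescent simulation of the
fitted three-species demographic model, composite-likelihood estimation
with parametric bootstrap / goodness of fit / Akaike model choice, and
admixture and geographic-origin screening (f₃, drift-covariance tree,
PCA + tree-ensemble assignment).

## Data model

Genotypes are diploid alt-allele dosages in {0, 1, 2} (or missing) at
biallelic SNPs (`GenotypeMatrix`), read from VCF 4.x via cyvcf2.
Genotypes with any uncalled allele (`./.` and half calls like `./1`) are
treated as missing, which keeps dosages well-defined without imputation.
The site missingness filter keeps a site only when *strictly more than* a
fraction (default 0.5) of individuals are called, a literal reading of the
"more than half" rule; read-depth filtering is upstream of this data model
and out of scope.  A `PopulationMap` carries sample → population → cluster
assignments with a known-origin flag, and a `SiteAnnotation` labels sites
as 0-fold / 4-fold / other with a coding/intron/intergenic region class.

## Summary statistics

* **π** — per-site pairwise heterozygosity 2k(n−k)/(n(n−1)) from called
  allele copies, averaged over the supplied SNPs.  Because the matrix holds
  variant sites only, π is *per SNP* by default; π₀/π₄ comparisons on the
  classical per-bp rate scale require class denominators (total surveyed
  sites per class), which the cohort generator provides
  (`class_sizes` argument of `pi_by_degeneracy`).  Without them, thinned
  panels show a ratio near 1 even under strong purifying selection —
  thinning removes sites, not per-site diversity.
* **Tajima's D** — standard constants with the effective sample size fixed
  at the median called allele count across used segregating sites; π is
  accumulated per site from complete-case copies.  S = 0 raises instead of
  returning 0.
* **Hudson F_ST** — the ratio-of-averages (Bhatia-style) estimator with
  finite-sample heterozygosity corrections; negative per-site components
  are retained.  Chosen for robustness to unequal sample sizes; the
  estimator choice is recorded in outputs.
* **LD** — composite r² (squared Pearson correlation of dosages on
  complete cases; no phasing).  Pruning drops the later site of any pair
  within a 10 kb window with r² ≥ 0.2 whose Benjamini–Hochberg-adjusted
  χ²₁ p-value (n·r²) is ≤ 0.05, via a deterministic left-to-right greedy
  scan.

## Joint SFS

Outgroup polarization assigns the ancestral allele as the allele fixed in
the outgroup; sites polymorphic in the outgroup are unusable (shared
target/outgroup polymorphism is tallied separately, mirroring the
stringency filter), and fixed derived differences enter the spectrum at
count n.  Per-site variation in call numbers is handled by hypergeometric
projection to user-chosen haploid sizes, each usable site contributing
total weight 1.  The invariant corners are always masked; folding to
minor-allele polarity sums each entry with its vectorwise complement into
the smaller-total representative (lexicographic tie-break, self-
complementary entries once).  Spectra round-trip through a dadi-style text
format.

## Coalescent simulator

A hand-written structured coalescent over up to three sampled populations
embedded in an arbitrary demography of piecewise-constant diploid sizes,
backward-time joins, pulse admixture (lineage reassignment with the pulse
probability) and symmetric continuous migration (per-generation lineage
probabilities treated as exponential rates; rates here are ≤ 1e-6, where
the discrete/continuous distinction is negligible).  Event times are
quantized to whole generations (floor of years/generation-time).  Joins
that target an already-merged population are redirected to its current
representative, so single event times can be moved freely during fitting
without invalidating the schedule.  Sites are unlinked — one independent
genealogy per site — justified by the very fast within-gene LD decay
(~200 bp) of the emulated exome panel.

Each lineage's subtended sample configuration is fixed at its creation, so
branch lengths are recorded per lineage at death:

* **branch mode** accumulates expected branch length per SFS entry; the
  normalized spectrum is the entry-probability vector used in likelihoods
  (the per-site mutation rate cancels when only segregating entries are
  scored);
* **mutation mode** drops Poisson(rate·L_total) mutations per genealogy —
  rate calibrated by a 100-genealogy pilot batch to ~0.25 sites per
  genealogy — and simulates genealogies until the requested number of
  segregating sites is collected.  Sampling exactly one site per genealogy
  would weight configurations by E[L_e/L_total] instead of E[L_e] and
  systematically inflate singletons; the Poisson scheme is the honest
  sparse infinite-sites limit (a small fraction of sites share a
  genealogy).
* **genotype mode** keeps child pointers, places each mutation
  branch-length-uniformly, and emits diploid dosages by pairing
  consecutive gene copies, with i.i.d. per-genotype missingness.

Kernels are numba-jitted; a single integer seed drives deterministic
per-genealogy child streams, so results are independent of evaluation
order and identical across runs.  The simulator is validated against
msprime (constant size, two-population split, pulse admixture) within
Monte Carlo error, and against closed forms (E[T₂] = 2N, E[ξᵢ] ∝ 1/i).

## The fitted three-spruce model (preset)

`spruce_model()` encodes the published point estimates: present sizes
N_OMO = 78, N_OBO = 35,498, N_HYB = 390, N_ALP = 5,982, N_CAR = 8,043,
N_FEN = 7,540; splits at 22,875,400 y (root), 17,600,050 y (OBO/ABIES),
15,274,375 y (FEN vs ALP+CAR), 15,272,700 y (ALP/CAR); a shared
*P. abies* bottleneck at 12,850 y (pre-bottleneck size default 2.5e5,
configurable over the published 2.5e5–5.7e5 bracket); a *P. omorika*
bottleneck at 2,775 y (3,200-fold); a pulse of 17% from *P. obovata* into
the Fennoscandian domain at 103,150 y, when the donor/recipient sizes were
5.6e6 / 6e5; the hybrid population founded 1,600 y ago with equal parental
contributions; migration 1e-6 among the *P. abies* domains; μ = 1.1e-9 per
site per year and generation time 25 y.  Where the source tables' two
admixture-time labels conflict with the running text, the preset follows
the text (pulse at ~103 ky, hybrid founding at 1.6 ky).  The root
ancestral size is not printed; it is set to the *P. omorika*
pre-bottleneck size (≈2.5e5), consistent with the described pre-decline
stability of that species.  Changing the generation time rescales all
diploid sizes by 25/g while leaving year-denominated event times unchanged
— the published generation-time sensitivity behaviour.

## Composite-likelihood inference

The multinomial composite log₁₀-likelihood is summed over unmasked SFS
entries with expected probabilities renormalized over those entries and
zero cells floored at 1e-20 of the mass; the multinomial constant is
omitted (it cancels in every comparison).  CLR = CL_O − CL_E in log₁₀
units, the only dimensionally coherent reading of the published
G-statistic convention.  The expected spectrum at a candidate parameter
vector comes from branch mode with *common random numbers* — the same
genealogy seed streams at every evaluation — which makes the objective
deterministic and smooth along the parameter axis.

Optimization works in log₁₀ parameter space.  With one free parameter the
search is a deterministic 13-point coarse grid followed by golden-section
refinement (relative log-tolerance 5e-4) — cheaper than multi-start
Nelder–Mead and immune to local trapping given the bracketing pass; with
two or more free parameters, multi-start Nelder–Mead (default 20 starts
uniform in the log bounds) is used.  Defaults: 1e5 genealogies per
branch-mode evaluation.

A note on identifiability: because invariant corners are masked, the
likelihood sees only the *shape* of the spectrum.  A lone constant-size
population is therefore unidentifiable (its shape is ∝ 1/i for every N);
sizes and times become identifiable through their effect on the joint
spectrum of two or more populations, which is the form every recovery
check takes.

* **Parametric bootstrap** — resimulate the observed spectrum (mutation
  mode, same site count) under the fitted model, re-fit, take 2.5/97.5
  percentiles; flagged unreliable if >20% of replicate fits fail, and the
  point estimate falling outside its CI is flagged, not hidden.
* **Goodness of fit** — the CLR null distribution is built by simulating
  datasets under the fitted model and scoring each against its own
  saturated likelihood; p is the fraction of null CLRs at or above the
  observed one.  The type-I rate is checked by simulation.
* **Model choice** — Akaike weights from AIC = 2k − 2·ln(10)·CL_E.
  Composite likelihoods over linked or dependent sites do not give a true
  AIC; the weights are reported with that caveat, matching their original
  use for the m = 0 vs m = 1e-6 comparison.
* **Rescaling** — re-expresses size estimates under a different generation
  time (N_e ∝ 1/g at fixed per-year coalescent rate) while keeping
  year-denominated times fixed.

## Admixture and origin assignment

* **f₃(target; s1, s2)** — per-site (c−a)(c−b) minus the target's
  finite-sample heterozygosity correction h_c/n_c, averaged, with a
  delete-one-block jackknife over blocks of 100 consecutive SNPs;
  "significantly negative" means Z < −3 (field convention; configurable).
* **Drift-covariance tree** — pairwise drift distances
  E[(p_i−p_j)²]/(p̄(1−p̄)) feed neighbor joining (scikit-bio); the tree is
  rooted at the outgroup's attachment and branch lengths are refit by
  non-negative least squares to the outgroup-referenced covariance, whose
  tree expectation is the shared root-path length.  Variance explained is
  1 − ‖W−Ŵ‖²/‖W−mean(W)‖²; admixture between non-sister clusters lowers
  it, which is what the 95% stopping rule exploits.
* **PCA** — smartpca scaling (center 2p̂, scale √(p̂(1−p̂)), mean-imputed
  missing dosages), SVD scores, deterministic sign (largest-|score|
  coordinate positive).
* **Assignment** — a hand-written bagged CART ensemble (Gini splits,
  per-node feature subsampling of ⌈√f⌉ of the five PCs, 200 trees),
  trained on bootstrap resamples of the reference panel; repeating the
  whole procedure (default 1,000 repetitions; analysis scripts use fewer
  for speed) yields a per-individual confidence as the modal-class
  fraction.  An established forest implementation (scikit-learn) is kept
  strictly as a test oracle, preserving an implementation-vs-oracle check.
  Stratified k-fold cross-validation reports the misassignment rate.

## Synthetic cohort

The generator emulates the study design: seven *P. abies* clusters — the
three core domains ALP/CAR/FEN drawn from the preset demography, plus four
derived clusters built as per-individual two-way mixtures (Russian–Baltic
= CAR/FEN 50:50, Northern Poland = CAR/FEN 75:25, Central Europe = ALP/CAR
50:50, Central/Southern Sweden = ALP/FEN 50:50; cluster means jittered per
individual with a truncated normal, sd 0.05).  Each gene copy draws its
source domain independently with the individual's weights.  Defaults: 40
individuals per cluster, 5% per-genotype missingness, ~2e4 SNPs after
0-fold thinning (retention 0.4, a crude purifying-selection proxy that
drives the per-bp π₀/π₄ toward 0.4), degeneracy fractions matching the
emulated capture panel (22.7% 0-fold, 13.5% 4-fold, the rest noncoding),
and an optional fraction of individuals with hidden origin labels (truth
retained).

What the cohort does *not* emulate: linkage between nearby SNPs,
sequencing or genotype-calling error, ascertainment of the capture probes,
spatially continuous sampling, and unequal cluster sizes.  Passing tests
therefore demonstrate the statistical machinery under the fitted model's
own conditions, not performance on the original empirical data —
quantities tied to that dataset (SNP totals, the empirical Table of
diversity values, empirical assignment counts) are outside what synthetic
data can reproduce.

## Problem sizes and numerical choices

Recovery checks use 10 diploids per population (8 for the three-domain 3D
spectrum), 5e4 segregating sites, and 1e5 genealogies per expected-SFS
evaluation; the assignment benchmark uses 40 references per cluster and
~2e4 pruned SNPs; the model-choice replication uses 20 replicates of 2e4
sites scored against 5e4-genealogy expected spectra.  These sizes make
each recovery a sub-minute computation while leaving every estimate within
a few percent of its generating value.  Bootstrap-coverage and GOF
type-I simulations in the test suite run at deliberately small scale
(3-4 diploids, ~1.5e3 sites) with the same code paths.  Tolerances
follow the Monte Carlo error of the check itself (3 SE bands for
simulator oracles); optimizer tie-breaks and degenerate inputs (S = 0,
empty spectra, monomorphic panels) raise explicit errors rather than
returning silent defaults.

## Interfaces

The library modules are the interface, driven by the numbered scripts
under `analysis/` (each accepts `--seed`); there is no separate CLI
binary.  Models serialize to YAML; spectra to dadi-style text; popmaps,
annotations and all results to TSV.

## Known limitations

Composite likelihood treats SFS entries as independent multinomial cells;
CIs from the parametric bootstrap inherit that approximation.  Branch-mode
spectra are Monte Carlo estimates — two fits agree only when seeded
identically (common random numbers are the supported workflow).  The
migration treatment is symmetric and constant per epoch pair; TreeMix-style
migration-edge search, unsupervised ADMIXTURE clustering and haplotype
phasing are intentionally out of scope.
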