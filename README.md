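# spruce-demog

Demographic inference and translocation screening for Eurasian spruce from
genome-wide SNP genotypes.

Norway spruce (*Picea abies*) in Western Europe is structured into three
ancient domains (Alpine, Carpathian, Fennoscandian) with derived, admixed
clusters between them, deep splits from Siberian spruce (*P. obovata*) and
Serbian spruce (*P. omorika*), glacial bottlenecks, and — in southern
Sweden — extensive 20th-century transfer of forest reproductive material
whose origin must be inferred from genotype similarity.  This package
implements the full analysis stack such a study needs, as a library under
`src/spruce_demog/` with numbered drivers under `analysis/`:

* genotype/popmap data model with VCF 4.x I/O, missingness filtering
  (sites kept only when more than half the individuals are called);
* diversity and differentiation statistics: π (overall and at 0-fold vs
  4-fold sites, with the π₀/π₄ ratio), Tajima's *D*, Hudson's *F*_ST
  (ratio of averages), composite-LD r² and LD pruning
  (r² ≥ 0.2, BH-FDR ≤ 0.05);
* joint site-frequency spectra (1–3 populations): outgroup polarization,
  hypergeometric projection, folding, dadi-style text I/O;
* a numba-accelerated structured-coalescent simulator (splits,
  bottlenecks, pulse admixture, migration) with the fitted three-species
  demographic model as a preset, in branch (expected-SFS), mutation
  (sampled-SFS) and genotype modes;
* fastsimcoal-style composite-likelihood fitting with common random
  numbers, parametric-bootstrap CIs, a likelihood-ratio *G*-statistic
  goodness-of-fit test, Akaike-weight model choice and generation-time
  rescaling;
* admixture screening (f₃ with block jackknife, drift-covariance tree
  with residual variance explained) and geographic-origin assignment
  (PCA scores → bagged classification trees → repetition-frequency
  confidence, with k-fold cross-validation).

## The model at the core

For populations with joint SFS **ξ** over unmasked entries *e*, parameters
θ of the demography are estimated by maximizing the multinomial composite
log-likelihood

    CL(θ) = Σ_e ξ_e · log₁₀ p_e(θ),

where p_e(θ) is the normalized expected branch length subtending
configuration *e* under the structured coalescent at θ (Monte Carlo, common
random numbers).  Goodness of fit uses CLR = log₁₀(CL_O/CL_E) — the
saturated minus the maximized composite likelihood — with its null
distribution simulated under the fitted model.  The preset demography
(`spruce_model()`) encodes the published fit: a root split at ~22.9 Mya
(*P. omorika*), *P. obovata* vs *P. abies* at ~17.6 Mya, the three
*P. abies* domains separating ~15.3 Mya, a shared end-glacial bottleneck
~12,850 years ago, a pulse of ~17% *P. obovata* ancestry into Fennoscandia
~103,000 years ago, a recent hybrid population (~1,600 years, equal
parental shares), migration 10⁻⁶ among domains, μ = 1.1×10⁻⁹ /site/year,
generation time 25 years.

## Worked example

Recover the *P. obovata*→Fennoscandia admixture proportion from data
simulated under the preset (10 diploids per population, 5×10⁴ segregating
sites), freeing only that parameter:

```python
from spruce_demog import spruce_model, simulate_sfs
from spruce_demog.inference import fit_model

obs = simulate_sfs(spruce_model(), {"OBO": 10, "FEN": 10},
                   50_000, mode="mutation", seed=101)
fit = fit_model(obs, spruce_model, {"alpha_adm": (0.01, 0.99)},
                {"OBO": 10, "FEN": 10}, seed=11)
print(fit.estimates)
```

prints

```
{'alpha_adm': 0.16669202282246956}
```

an estimated pulse proportion of 16.7% against the generating value of
17% — the composite likelihood pins the ancient admixture fraction from
the two-population joint SFS alone.  The same machinery drives the
numbered analyses:

```bash
python analysis/01_simulate_cohort.py --seed 1     # synthetic study cohort
python analysis/02_diversity_stats.py --seed 1     # pi, pi0/pi4, D, F_ST
python analysis/03_origin_assignment.py --seed 1   # PCA + forest assignment
python analysis/04_admixture_tests.py --seed 1     # f3 + drift tree
python analysis/05_fit_demography.py --seed 1      # parameter recovery
python analysis/06_model_choice.py --seed 1        # m=1e-6 vs m=0
```

Each writes its tables under `results/`.  On the default cohort the
5-fold cross-validated misassignment rate is well under the 8% bound, the
admixed derived clusters give strongly negative f₃ (Z ≪ −3) while the
core domains are tree-like, and the drift tree explains >95% of the
frequency covariance.

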