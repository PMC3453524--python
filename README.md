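# gsmix

Bayesian genomic selection with marker-mixture priors for full-sib
populations: polygenic, genomic and combined mixed models fitted by Gibbs
sampling, pedigree relationship matrices, within/between-family
cross-validation, and Bayes-factor marker evidence — plus a synthetic
population generator so the whole pipeline is testable end to end without
external data.

## Who this is for

Quantitative geneticists and animal-breeding researchers comparing
pedigree-based (BLUP-style) and marker-based prediction of breeding
values, studying how the assumed fraction of trait-affecting markers
changes variance partitioning, predictive ability and QTL evidence in
populations of full-sib families (the layout of heterogeneous-stock mouse
resources and many livestock designs).

## Models

Three model classes share the structure
`y = mu + X1 b + X2 c + (genetic terms) + e`, with fixed effects `b`,
cage effects `c ~ N(0, I sigma2_c)` and residuals `e ~ N(0, I sigma2_e)`:

| model     | genetic term | prior |
|-----------|--------------|-------|
| polygenic | `Z u`        | `u ~ N(0, A sigma2_u)`, `A` from the pedigree |
| genomic   | `Q (a o s)`  | base effects `a ~ N(0,1)`; scaling `s` carries the mixture |
| combined  | both         | both |

Per marker the scaling factor has the two-component mixture prior
`s ~ N(0, sigma2_g0)` with probability `pi0` (near-null; `sigma2_g0` fixed
at 1% of the phenotypic variance over the marker count) and
`s ~ TN>0(0, sigma2_g1)` with probability `pi1` (substantial effects);
`pi1 = 1` gives the non-mixture model. Downstream the package reports
variance components with 95% credible intervals, heritabilities
`h2_u = sigma2_u/sigma2_p` and `h2_a = sigma2_a/sigma2_p` (with `sigma2_a`
the variance of genomic values `g = Q beta`, LD covariances included),
cross-validated predictive ability (Pearson correlation of predicted
breeding values with fixed-effect-corrected phenotypes on held-out
animals), and per-marker prior-to-posterior odds ratios
`PPOR = (p1/(1-p1)) / (pi1/(1-pi1))` classified as substantial (>3.2),
strong (>10) or decisive (>100) evidence.

See `docs/methods.md` for the update cycle, priors, numerical choices and
the synthetic-data model.

## Worked example

```python
from gsmix import (ChainSettings, ModelSpec, encode_design, fit, make_splits,
                   marker_inclusion_probability, ppor, run_cv, summarize)
from gsmix.evidence import classify
from gsmix.simulate import SimulationConfig, simulate_population

config = SimulationConfig(n_families=60, n_markers=200, n_qtl=20,
                          h2_qtl=0.4, h2_polygenic=0.1, cage_fraction=0.2,
                          n_burnin_generations=30, burnin_population=120)
pop = simulate_population(config, seed=7)
panel = pop.panel.subset_animals(list(pop.phenotypes.animal_ids))
enc = encode_design(panel, "dosage-centered")

draws = fit(ModelSpec(model="genomic", pi1=0.1), pop.phenotypes, encoding=enc,
            chain=ChainSettings(6000, 2000, 4, seed=1))
print(summarize(draws))

plan = make_splits(pop.phenotypes, "between-family", seed=2)
res = run_cv(ModelSpec(model="genomic", pi1=0.1), pop.phenotypes, plan,
             encoding=enc, chain=ChainSettings(800, 300, 5, seed=3))
print(f"between-family predictive ability: {res.mean_pa:.3f} +/- {res.se_pa:.3f}")

p1 = marker_inclusion_probability(draws)
table, counts = classify(ppor(p1, 0.1), panel.marker_map, p1_hat=p1)
print("evidence classes:", counts)
```

Output:

```
sigma2_a:   40.454  [32.811, 48.670]
sigma2_c:   27.300  [19.473, 37.259]
sigma2_e:   33.907  [29.184, 38.536]
sigma2_p:  101.662  [90.389, 113.777]
    h2_a:    0.398  [0.338, 0.461]
between-family predictive ability: 0.595 +/- 0.019
evidence classes: {'none': 189, 'substantial': 2, 'strong': 5, 'decisive': 4}
```

The population was simulated with 20 QTLs explaining 40% of the
phenotypic variance plus a 10% polygenic background and 20% cage
variance. The 10%-mixture genomic model attributes `h2_a = 0.40` of the
variance (~100 total) to the markers — it also absorbs most of the
polygenic background, since the same families carry both — predicts
held-out whole families at r = 0.60, and flags 11 of 200 markers with
substantial-or-better evidence, 9 of them strong or decisive, clustered
at the planted QTLs.

The same stages are available from a shell:

```sh
gsmix simulate --seed 1 --out pop/
gsmix fit --model genomic --pi1 0.1 --genotypes pop/genotypes.ped \
      --phenotypes pop/phenotypes.csv --out fit/
gsmix cv --model genomic --pi1 0.1 --mode between --genotypes pop/genotypes.ped \
      --phenotypes pop/phenotypes.csv --out cv.csv
gsmix evidence --pi1 0.025 --genotypes pop/genotypes.ped \
      --phenotypes pop/phenotypes.csv --out evidence.csv
```

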