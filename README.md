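# plumagevar

Genetic and environmental variance partitioning of avian plumage color.

Melanin-based plumage color is a sexually selected signal in North American
barn swallows (*Hirundo rustica erythrogaster*): females allocate paternity
to darker, more saturated males. How much of the color variation among
nestlings is heritable, and how much is stamped on by the environment they
grow up in? `plumagevar` implements the full analysis chain used to answer
that question in a colony study design, together with a synthetic-data
generator so every stage is testable with known ground truth:

1. **Color quantification** (`plumagevar.colorspace`): reflectance spectra
   (300–700 nm, triplicate scans) are mapped into the avian tetrahedral
   color space. Relative cone quantum catches (u, s, m, l) place each
   sample in a regular tetrahedron; hue is the direction (θ, φ), chroma is
   the distance r from the achromatic center, and achieved chroma
   r_A = r / r_max rescales by the maximum chroma possible in that hue
   direction. Average brightness is mean percent reflectance. Measurement
   repeatability is the one-way-ANOVA intraclass correlation.
2. **Paternity exclusion** (`plumagevar.paternity`): offspring are called
   extra-pair young (EPY) when ≥ 2 of 7 microsatellite loci carry no
   paternal allele matching the social father (one mismatching locus is
   tolerated as mutation/typing error). Per-locus first-parent exclusion
   probabilities use the standard polynomial in allele-frequency power
   sums, P1 = 1 − 4a₂ + 4a₃ − 3a₄ + 2a₂², combined across loci as
   1 − Π(1 − P1).
3. **Pedigree relatedness** (`plumagevar.pedigree`): the analysis pedigree
   (dam = social mother; sire = social father, assigned extra-pair sire, or
   unknown) yields the additive relationship matrix **A** by the tabular
   method, with a Henderson-rule sparse inverse as a fast path.
4. **Animal model** (`plumagevar.animal_model`): a Bayesian multivariate
   animal model fitted by Gibbs sampling partitions each trait's
   phenotypic variance as V_P = V_A + V_CE (+ V_ME) + V_R — additive
   genetic, common (nest) environment, maternal, residual — with
   inverse-Wishart priors on all covariance matrices. Reported per trait
   and per posterior sample: h² = V_A/V_P, ce² = V_CE/V_P, me² = V_ME/V_P,
   genetic correlations r_g = G_ij/√(G_ii G_jj), fixed effects, posterior
   modes with 95% HPD intervals, effective sample sizes, and DIC.
5. **Stage comparisons** (`plumagevar.stage_compare`): sex × developmental
   stage two-way ANOVAs with Tukey contrasts, Welch t-tests for recruitment
   comparisons, the nestling → adult ANCOVA (does juvenile color predict
   the adult signal within individuals?), and Spearman checks.
6. **Synthetic studies** (`plumagevar.simulate`): a generator emulating the
   study design — ~24 colonies, ~108 mothers, ~95 fathers, ~500 offspring,
   ~41% extra-pair young clustered within nests (beta-binomial) so that
   roughly two thirds of nests hold at least one EPY, Mendelian gene
   dropping at 7 microsatellite loci, four correlated color traits with
   configurable G/C/M/R covariance components, and spectrometer-style
   triplicate spectra from a two-parameter melanin reflectance family.

The core estimators follow scikit-learn conventions (`fit`/`transform`/
`predict`, `get_params`, fitted attributes with trailing underscores):
`TetraColorMapper`, `PaternityClassifier`, and `AnimalModel`.

## Worked example

```python
from plumagevar import (SimulationParams, simulate_study, PaternityClassifier,
                        build_pedigree, AnimalModel)
from plumagevar.paternity import epy_summary

study = simulate_study(SimulationParams(seed=11))          # ~500 offspring
calls = PaternityClassifier().fit(study.genotypes).predict(study.social)
summary, _ = epy_summary(calls)
print(summary[summary.year == "all"][["n_offspring", "pct_epy",
                                      "pct_nests_with_epy"]])

ped = build_pedigree(calls, study.social)
data = study.phenotypes.query("stage == 'nestling'").merge(
    study.social, on=["individual", "sex"])
model = AnimalModel(traits=("theta",), random_terms=("additive", "nest"),
                    n_iter=20_000, burn_in=1_000, thin=10, seed=1).fit(data, ped)
print(model.summary_.query("component in ('V_P', 'h2', 'ce2')")
      [["component", "mode", "lower", "upper"]].round(3))
```

Output:

```
 n_offspring   pct_epy  pct_nests_with_epy
         514 38.715953           67.132867
component  mode  lower  upper
      V_P 0.962  0.861  1.165
       h2 0.345  0.158  0.639
      ce2 0.290  0.181  0.433
```

Of 514 simulated offspring, 38.7% are called extra-pair (generating rate
41%) and 67.1% of nests contain at least one extra-pair chick. The animal
model, fitted to hue (θ) with the paternity-derived pedigree, recovers a
posterior-mode heritability of 0.35 with 95% HPD (0.16, 0.64) — the
generating value is 0.33 — and a nest-environment share of 0.29 (generating
value 0.29). On the z-scored trait the total phenotypic variance sits near
1, so components are directly readable as proportions.

## Command line

Every stage runs standalone on a plain-CSV study bundle, and `pipeline`
chains them:

```bash
plumagevar simulate --seed 1 --out bundle/
plumagevar colormetrics --spectra bundle/spectra.csv --out metrics.csv
plumagevar paternity --bundle bundle/ --out reports/
plumagevar pipeline --seed 1 --out run1/
```

Pedigree CSVs use the 3-column convention `id, dam, sire` with an empty
field for an unknown parent.

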