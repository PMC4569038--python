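# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Tetrahedral color space

A reflectance spectrum R(λ) on a strictly increasing grid covering
300–700 nm is reduced to quantum catches Q_i = ∫ R(λ) C_i(λ) dλ for the
four avian single-cone classes, by trapezoidal quadrature on the native
grid (spectrometer output is already finely gridded; at a 0.2 nm step the
quadrature error is below 1e-6 relative). The illuminant is uniform
(ideal); no receptor-noise or adaptation model is applied. Catches are
normalized to sum to one and mapped to Cartesian coordinates

    x = ((1 − 2s − m − u)/2)·√(3/2)
    y = (−1 + 3m + u)/(2√2)
    z = u − 1/4,

which places the four pure-stimulation points at the vertices of a regular
tetrahedron of circumradius 0.75 centered on the achromatic point. Hue is
(θ, φ) = (atan2(y, x), arcsin(z/r)); chroma is r = ‖(x, y, z)‖; r_max is
the distance from the origin to the tetrahedron boundary along the hue
direction, found as the smallest positive ray–face intersection over the
four faces; achieved chroma is r_A = r/r_max. At r = 0 hue is undefined
and is returned as NaN together with an explicit `hue_defined = False`
flag, so that downstream averaging cannot silently absorb undefined
angles. Brightness is the mean percent reflectance over 300–700 nm.

**Cone templates.** The defaults are unnormalized Gaussian sensitivities
with peaks 372/456/544/609 nm and common SD 50 nm. These are generic
violet-type songbird values, fully configurable via `ConeSensitivitySet`;
results should always be reported together with the cone set used, and no
attempt is made to numerically reproduce metric values computed with other
templates or illuminants.

**Replicates.** Replicate scans are averaged pointwise before metrics are
computed (matching a measure-three-times-and-average protocol);
repeatability is instead computed on per-replicate metrics, as the one-way
ANOVA intraclass correlation with the standard unequal-group-size
correction k₀ = (N − Σn_i²/N)/(G − 1), clamped to [−1, 1].

## Paternity exclusion

A locus mismatches a candidate male when none of the offspring's candidate
paternal alleles is carried by the male. When the mother's genotype is
available, the paternal candidate set is the offspring allele not
attributable to the mother; when both or neither offspring allele could be
maternal, both are retained (conservative). A locus contributes at most
one mismatch, so the "two or more alleles" rule means two or more loci.
Offspring are called extra-pair at ≥ 2 mismatching loci: a single
mismatching locus is tolerated, absorbing mutation and genotyping error.
Classification requires ≥ 4 loci typed in both offspring and social father
(missing loci are skipped). Extra-pair sires are assigned only when
exactly one candidate male is compatible (zero mismatches at every typed
locus); ambiguity is never resolved by likelihood — likelihood-based
assignment is out of scope.

First-parent (no known parent) exclusion probability per locus, with
allele-frequency power sums a_k = Σ p_i^k:

    P1 = 1 − 4a₂ + 4a₃ − 3a₄ + 2a₂²,

verified in the tests against brute-force enumeration over HWE-weighted
(mother, father, offspring, random male) genotype configurations. Combined
exclusion over independent loci is 1 − Π(1 − P1). The default simulated
panel (7 loci × 8 equifrequent alleles) gives a combined exclusion of
99.8%; real allele frequencies for the study's loci are not published, so
the panel is a stated default, not a reconstruction.

## Pedigree and relatedness

Dams are the social mothers (maternity is not questioned); sires are
social fathers for within-pair young, assigned extra-pair sires when
identified (a flag disables this), and unknown otherwise. Unknown parents
contribute nothing to the recursion (founder-by-absence), and all breeding
adults are treated as mutually unrelated, non-inbred founders. The
additive relationship matrix A (twice the kinship) is built by the tabular
method; A⁻¹ is computed by dense Cholesky at study scale (n ≈ 700), with
`henderson_inverse` as an equivalent sparse-rule construction using the
Mendelian-sampling variance d_i = 1 − 0.25·(A_dd + A_ss) over known
parents. Correctness is checked against gene-dropping simulation (A within
0.01 of 2× Monte-Carlo kinship at 200,000 drops) and the identity
‖A·A⁻¹ − I‖_max < 1e-8.

## The animal model

For t traits (default: θ, φ, r_A, brightness, z-scored so V_P ≈ 1 and
components read as proportions):

    y_i = X_i β + a_i + c_nest(i) + m_mother(i) + e_i

with a ~ MVN(0, G ⊗ A), c ~ MVN(0, C), m ~ MVN(0, M), e ~ MVN(0, R), and
inverse-Wishart priors on G, C, M, R. Fixed terms available: intercept,
year (factor), sampling date nested within year (year-specific centered
slopes), mass, sex (±1/2 coding). Maternal effects are estimable only when
some mothers have ≥ 2 nests; if none does, the sampler warns that V_ME and
V_CE are confounded. The two standard model configurations are the
all-families model (additive + nest) and the multibrood model
(additive + nest + maternal, restricted to offspring of mothers with ≥ 2
broods within or across seasons).

**Sampler.** Blocked Gibbs with exact Gaussian full conditionals per
location block. The additive block is whitened through the Cholesky factor
L of A (a = Lu, u ~ MVN(0, I ⊗ G)); with W the record rows of L, the
conditional precision (W'W) ⊗ R⁻¹ + I ⊗ G⁻¹ is block-diagonalized once and
for all by the eigendecomposition W'W = QΛQ', so the whole additive vector
is drawn jointly each iteration at O(nq) cost. Nest and maternal blocks
have diagonal incidence crossproducts (batched t×t solves); fixed effects
are drawn as a matrix-normal under a flat prior. Covariances follow their
inverse-Wishart full conditionals — for the additive term the scale
quadratic form u'u equals a'A⁻¹a. Each fit is reproducible from its seed.

**Priors.** Default V = I_t·(V_P/#components) and ν = t + 0.002 per
component: proper, weakly informative, and centered on an even split of
the observed variance. A sensitivity test varies V and ν; posterior means
of h²/ce² move by < 0.05. (Posterior *modes* of these broad, plateau-shaped
ratio posteriors are numerically unstable under any KDE argmax — measured
swings of ~0.15 with posterior-mean swings of ~0.01 — so the stability
property is asserted on means.)

**Summaries.** Per component, trait, and ratio: posterior mode by Gaussian
KDE (Silverman bandwidth, argmax on a 512-point grid), 95% HPD as the
shortest interval of sorted samples (equal-tailed available by flag), and
ESS by Geyer's initial-positive-sequence truncation, capped at the stored
sample count. Ratios (h², ce², me²) are computed per stored sample from the
covariance diagonals, so each component's uncertainty propagates into the
ratio intervals; the headline percentage is the cross-trait mean of the
per-trait ratio modes. Genetic correlations r_g = G_ij/√(G_ii·G_jj) per
sample, flagged significant when the 95% HPD excludes zero. DIC is
2·mean(deviance) − deviance at the posterior mean of the location effects
and residual covariance, with deviance = −2 log MVN(Y | fitted, R).

**Chain settings.** The documented full-run reference is 1,002,000
iterations, burn-in 2000, thinning 500 (exactly 2000 stored samples).
Desk-scale fits in tests and the acceptance script use 20,000 / 1,000 / 10,
which recovers generating parameters reliably at study scale (h² HPD
coverage 18–20 of 20 in calibration runs) while keeping a single-trait fit
under ~20 s on one CPU.

## Stage comparisons

Two-way ANOVA (sex × stage, type-II F tests) per color metric, with Tukey
HSD contrasts computed cellwise on the four sex-stage means via the
studentized-range distribution and the pooled within-cell error. Welch
t-tests (Satterthwaite df) for all recruitment comparisons, as group sizes
are strongly unequal. The nestling → adult ANCOVA regresses adult color on
nestling color on within-stage z-scores with a sex intercept offset; both
with- and without-sex fits are computed and the sex term is retained when
significant at 0.05 (hue metrics typically retain it; saturation and
brightness typically do not). Standardization is per stage, since the two
stages are measured years apart on different plumage. Spearman rank
correlations use midranks for ties.

## Synthetic-data generator

The generator defines the study conditions; defaults are fixed, not tuned:

- **Population**: 24 sites, 108 mothers, 95 fathers; broods per mother
  {1: 0.70, 2: 0.25, 3: 0.05}; brood size {2: .15, 3: .30, 4: .35, 5: .15,
  6: .05} (mean ≈ 3.65), giving ≈ 500–540 offspring; two seasons.
- **Extra-pair paternity**: per-nest EP probability from a Beta with mean
  0.41 and intraclass correlation 0.37 (beta-binomial clustering), chosen
  analytically so that ~67% of nests hold ≥ 1 EPY at the default brood-size
  mix; EP sires drawn uniformly from other males at the same site (any-site
  fallback only when the site has no other male). With clustering the
  per-nest EPY-proportion histogram piles up at 0 and 1 relative to the
  binomial with the same mean.
- **Genotypes**: 7 unlinked loci, 8 equifrequent alleles (configurable
  frequencies); founders i.i.d. from the frequencies, offspring by
  Mendelian gene dropping; no genotyping error by default.
- **Phenotypes**: founders' breeding values MVN(0, G); offspring =
  midparent + MVN(0, G/2) Mendelian deviate (no inbreeding; founders
  unrelated); c ~ MVN(0, C) per nest, m ~ MVN(0, M) per mother,
  e ~ MVN(0, R) per record. Default diagonals follow the all-families
  variance-component pattern (G: .34/.297/.332/.297; C: .303/.304/.177/
  .293; R: .393/.459/.512/.489; M = 0), with a `multibrood()` preset adding
  a maternal component (M diag ≈ .14). Fixed-effect defaults: year 0.082,
  date-within-year ±0.02, mass 0.013 on all traits; sex effects reproduce
  the dimorphism pattern (nestlings dimorphic only in saturation and
  brightness, adults in all four metrics).
- **Adult stage**: same breeding value and maternal effect, fresh residual,
  no nest effect — adult feathers are grown far from the natal nest, so the
  within-individual nestling → adult persistence share is (V_A + V_ME)/V_P.
- **Spectra**: R(λ) = 70%·exp(−c·(1 + b·(1 − w))), w the position in the
  300–700 nm window: pigment concentration c darkens all wavelengths,
  melanin-balance b tilts the long-vs-short slope; three replicates with
  Gaussian noise (SD 0.5% reflectance, clipped at 0). Concentration and
  balance are tied monotonically to the simulated brightness and θ traits
  so that the colorspace stage has signal to recover.

**What it does not emulate**: feather nanostructure optics, genotyping
error and allele dropout, survival/recruitment processes, brood
parasitism (social mother = genetic mother always), inbreeding, and
between-year environmental trends beyond a constant year effect. Passing
tests therefore demonstrate correctness of the estimators under the stated
generating model, not robustness to those real-data complications.

## Numerical choices and limitations

- All randomness flows through one seeded `numpy` Generator per operation;
  identical parameters and seed give bit-identical studies and chains.
- A gets a 1e-10 diagonal jitter before Cholesky whitening; eigenvalues of
  W'W are clipped at zero.
- The KDE posterior mode is a noisy point estimate (slow-converging mode
  estimation); intervals and means are the stable summaries.
- Record-order permutation changes floating-point summation order inside
  the sampler, so chains are equal in distribution, not bitwise, under
  reordering.
- Problem sizes in tests and the acceptance script (20,000-iteration
  single-trait fits, 20-study calibration, 200,000 gene drops, 5,000-
  offspring misclassification runs) were chosen as the smallest at which
  the checked quantities are stable; the reference full-run MCMC settings
  remain available through `MCMCSettings` defaults.
- REML fitting, parent–offspring regression heritabilities, genomic
  relatedness, LOD-based paternity, and non-Gaussian traits are out of
  scope.
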