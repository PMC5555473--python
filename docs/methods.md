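# Methods

`ssgp` studies one question from the genomic-evaluation literature: when a
population is under selection and genotypes exist only for selected
animals, how should genotype covariates be centered in a single-step
analysis, and what does fitting the founder genotypic mean `mu_g` as a
fixed effect buy?  This note records the models, the synthetic-data
design, and the numerical and design choices the package makes.

## Genetic model

The trait is additive.  For individual *i* with genotype row `m_i'`
(allele counts 0/1/2 at the causal loci) the genotypic value is

    g_i = beta + m_i' alpha

with substitution effects `alpha` and intercept `beta` (0 in all
simulations).  Writing `k' = E[m_i']` in the unselected founders, the
breeding value is `u_i = (m_i' - k') alpha` and `mu_g = k' alpha` is the
founder mean of the linear genotypic component.  Under selection the
genotype means of later generations drift away from `k'`, which is why
centering observed genotypes by their sample means is not innocent: the
sample mean no longer estimates `k'`.

## Single-step regression

Individuals are split into genotyped (g) and nongenotyped (n).  Missing
marker covariates are imputed by best linear prediction from the
pedigree, `Mhat_n = Ang Agg^-1 Mg`, where `A` is the numerator
relationship matrix.  The founder-mean terms of the conditional
expectation collect into a covariate `J` (`-1` for genotyped
individuals, `Ang Agg^-1 (-1)` for nongenotyped ones) whose coefficient
is `mu_g`.  The fitted model is

    y = 1 mu + Z J mu_g + Z M alpha + U eps + e

with imputation residuals `eps` for nongenotyped individuals,
`Var(eps) = (Ann - Ang Agg^-1 Agn) sigma_g^2`, whose inverse is exactly
the nn-block of `A^-1` divided by `sigma_g^2` — so the prior precision of
`eps` is sparse and no dense relationship block is ever formed.

Six variants differ in whether `J` is fitted and how `M` is centered:

| variant | J fitted | centering |
|---------|----------|-----------|
| J  | yes | none |
| N  | no  | none |
| JC | yes | whole matrix (observed + imputed) |
| C  | no  | whole matrix |
| JC* | yes | observed covariates only, by their own means |
| C*  | no  | observed covariates only |

Whole-matrix centering only shifts every GEBV by a constant (`1 m-bar'
alpha-hat`), so JC and J (and C and N) are metrically identical; this is
asserted to numerical precision in the tests.  Observed-only centering is
the single-step GBLUP convention; it reparameterizes the mean to
`mu_g* = mu_g - v' alpha` (`v` = observed-genotype column means), which
the tests verify as an exact identity of the fits.  Fitting the model
with every marker effect Gaussian (BayesC with `pi = 0`) and fixed
variances makes the posterior mean the solution of a ridge-type
mixed-model system; predictions are equivalent to single-step GBLUP.

Two fitting routes are provided and cross-checked:

- **`method="mme"`** — exact sparse solve.  The (mu, mu_g, alpha) block is
  small and dense; the eps block has the sparsity of the nn-block of
  `A^-1` and is eliminated by a Schur complement after one sparse LU
  factorization, which is cached on the `RelationshipOperator` and reused
  across the J computation and every imputed marker column.
- **`method="gibbs"`** — single-site Gibbs sampling with fixed variances,
  adjusted-residual bookkeeping (a sweep is linear in the nonzeros), batch-
  means Monte Carlo standard errors, defaults 50,000 samples / 5,000
  burn-in.  The two routes agree within Monte Carlo error; all replicated
  evaluations use the deterministic MME route.

Pedigree BLUP (`y = 1 mu + Z u + e`, `Var(u) = A sigma_g^2`) is the
baseline, solved exactly from the sparse mixed-model equations.

### Numerical choices

- `A^-1` is assembled by Henderson's rules with Mendelian-sampling
  variances that account for parental inbreeding; inbreeding coefficients
  come from a Meuwissen–Luo-style ancestor-tracing pass (numba-accelerated
  when available, identical pure-Python fallback otherwise).  The
  simulated population does accumulate mild inbreeding through the sire
  bottleneck, so the zero-inbreeding shortcut is deliberately avoided.
- Unknown parents are unrelated founders; no genetic groups (the models
  fit a single overall mean).
- Per-marker prior variance defaults to `sigma_g^2 / sum_j 2 p_j (1-p_j)`
  with allele frequencies from the observed genotypes of the fitted panel
  (`marker_variance_rule="sum2pq"`); `"per_marker"` (`sigma_g^2 / m`) is
  available because the choice shifts shrinkage.
- Variances are fixed at their simulation values — `sigma_g^2` is the
  sample variance of TBV in G0 and `sigma_e^2` follows from the target
  heritability — never re-estimated.
- When every phenotyped individual is genotyped, `J` is collinear with the
  intercept; the fit refuses with an explicit error rather than
  regularizing silently.
- Truncation selection breaks phenotype ties deterministically by
  position, so identical seeds give bitwise-identical studies.

## Synthetic data

The generator emulates a livestock design: a base of 721 diplotypes
(360 male, 361 female) on ten 0.1 Morgan chromosomes, 200 loci
(20 per chromosome; 5 QTL + 15 markers each) or 2000 loci (50 QTL per
chromosome), all loci with MAF >= 0.01 and mean adjacent-locus LD
(r^2) near 0.30.  Because no real haplotypes ship with the package, the
base is synthesized: an ancestral pool starts at linkage equilibrium with
allele frequencies uniform on (0.1, 0.9) and drifts through
small-population random mating (pool of 100, shrunk adaptively if LD
stalls) until the delivered statistic — mean adjacent r^2 of the sampled,
MAF-filtered base — reaches the target; the accepted sample is the base
returned, so the statistic holds by construction.  The pool carries a
4x oversampled candidate locus set so the MAF filter can discard drifted
loci, mirroring how a real SNP panel is thinned.  Measured LD lands in
[0.30, 0.33] across seeds.

The base is expanded by sampling male–female pairs with replacement into
a generation of `2 * n_dams` offspring, followed by four nonoverlapping
random-mating generations, ending in the founders G0.  Meiosis is
Poisson crossovers (mean 0.1 per chromosome), uniform positions, no
interference, no mutation; recombination fractions follow the Haldane map
function (verified by Monte Carlo).  Five selection rounds follow: the
top 5% of males on own phenotype become sires (200 of 4000 at full
scale), each dam leaves one male and one female offspring, sires drawn
independently per offspring (a `same_sire_per_dam` switch covers the
other reading of "each female mated twice").  Training data are the
phenotypes of G0–G4; genotypes are observed for the selected sires and
the whole of G5, which is the validation set.

**QTL effects.**  Effects are `Normal(mu_alpha, sigma_alpha^2)` with
`mu_alpha = 0.2` and default `sigma_alpha = 0.05`.  The scale of
`sigma_alpha` is otherwise absorbed by the heritability calibration, but
its ratio to `mu_alpha` is substantive: the regime of interest has an
essentially all-positive effect vector, so that `mu_g = k' alpha` is an
order of magnitude larger than `sigma_g` and selection moves genotype
means materially.  With the default, the simulated G0→G5 advance in mean
TBV is ~0.5 per generation on a G0 mean near 10 — the regime the
centering question is about.  Setting `sigma_alpha` large relative to
`mu_alpha` (mixed-sign effects) shrinks `mu_g` toward zero and the
J-vs-N contrast largely disappears; both regimes are reachable through
`SimulationConfig`.

**Analysis pedigree.**  G0 is treated as the founder generation of the
relationship matrix (parents unknown); the pre-G0 expansion exists to
give G0 realistic LD and relatedness but is not carried into `A`.  The
full expansion pedigree is retained on the dataset for inspection.

**What the generator does not emulate.**  Real linkage maps (loci are
evenly spaced), mutation, genotyping error, overlapping generations,
female selection, and the long-range LD structure of real cattle
haplotypes.  Passing tests therefore demonstrate the selection/centering
phenomena and the correctness of the algebra, not calibration against any
real population.

## Scales and the replicated grid

Two population scales are built in: the full design (4000 dams, 200
sires, 40,000 training phenotypes, 8000 validation animals) and a
reduced desk scale (800 dams, 40 sires, same 5% selected proportion,
8,000 training phenotypes, 1600 validation animals).  The package's
default evaluation grid (`ssgp.evaluation.study_grid`) runs the reduced
scale with 3 replicates and the exact MME route — small enough to rerun
routinely, large enough that the qualitative contrasts (J vs N on
QTL-containing panels, C* vs JC*, monotonicity in h^2, PBLUP far below
all genomic variants) are stable across seeds.  Absolute accuracies at
the reduced scale run a few points below the full design (one fifth the
training data); the full scale is available via
`ScenarioConfig(scale="full")` and `SimulationConfig()` defaults.

Aggregation follows the study convention: metrics are computed per
replicate on the validation generation (Pearson correlation of TBV and
GEBV in percent; OLS slope of TBV on GEBV), then averaged, with the SE of
the replicate means.

## Known limitations

- The Gibbs route is a readable reference sampler (Python loops over
  markers and residuals); it is meant for instances up to a few thousand
  individuals, not the full grid.
- `pi > 0` variable selection, variance re-estimation (REML/sampled
  variances), H-matrix single-step GBLUP, genetic groups and metafounders
  are out of scope.
- With the 2000-locus panel at full scale the dense covariate block of
  the MME (~48,000 x 1,850) is memory-hungry; the reduced scale is
  recommended for that panel.
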