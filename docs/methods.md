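# Methods

This note documents the models behind `crossplan`: how family means and
within-family variances are predicted for arbitrary breeding pipelines under
dominance, how linkage disequilibrium (LD) is propagated from parents to a
prospective family, how the expected loss of additive standard deviation
(PropSD) is estimated without marker effects, and how mating plans are
searched under constraints.  It also states the assumptions of the synthetic
data generator and the numerical choices that matter.

## Genotypic model

A trait is controlled by `nj` loci.  Individual `i`'s genotypic value is

    g_i = sum_j m(M[i,j]) a_j + w(M[i,j]) d_j

where `M[i,j]` is the dosage of the effect allele (0..ploidy), `a_j` and
`d_j` are per-locus additive and dominance effects, `m(k)` is the additive
class score (default `m(k) = k`) and `w(k)` the dominance score.  For diploids
the default `w = (0, 1, 0)` is the heterozygosity indicator.  For
autotetraploids no canonical dominance score exists (digenic, duplex-specific
and indicator conventions are all in use), so `w` must be supplied explicitly;
the synthetic-data generator uses the indicator `w(k) = 1{0 < k < 4}`.
The same machinery serves the genotypic parameterization (strictly additive +
dominance components, correlated within a locus) and the breeding
parameterization (breeding values + dominance deviations), provided scores and
effects are given on the same convention; with `d = 0` the two coincide.

## Per-locus class distributions

Every pipeline is composed from four exact per-locus operators on genotype-
class probability vectors:

* **Gametes.**  Diploid: a parent of dosage `m` transmits the effect allele
  with probability `m/2`.  Tetraploid: 2 of the 4 homologs are drawn without
  double reduction, `P(g = k) = C(m,k) C(4-m, 2-k) / C(4,2)` (polysomic,
  random bivalent pairing).
* **F1**: convolution of the two parental gamete distributions.
* **Selfing** (t generations): each class selfs through its own gamete
  distribution; the class mixture is propagated by the resulting Markov
  matrix.  This matches single-seed-descent (each line traces one F1 plant).
* **Doubled haploids** (diploids only): all mass moves to dosages {0, 2} with
  `P(2)` equal to the family's mean gamete allele probability.
* **Testcross**: the family's gamete mixture is convolved with the tester's
  gamete distribution; multi-tester schemes are predicted per tester and
  averaged (unweighted).

The family mean is the sum over loci of class-probability-weighted locus
values; per-locus total/additive/dominance variances and the within-locus
additive-dominance correlation `rho_j` come from the same distributions.
Loci are treated independently here; all cross-locus structure enters through
the LD models below.

## LD propagation

The genome-wide variance couples per-locus standard deviations through a
correlation matrix of locus effects.  Recombination fractions come from map
distances via Haldane's function `c = (1 - e^(-2d))/2` (no interference),
matching the meiosis simulator, with `c = 1/2` across chromosomes.

The cross-locus additive dosage covariance of the evaluated generation
decomposes into two elementwise-propagated paths:

* the **within-parent path**, carrying `Gamma = gamma_k + gamma_l`, where
  `gamma_p[i,j] = (1/phi) sum_r (H_p[r,i] - p_i)(H_p[r,j] - p_j)` is the
  parent-centred haplotype covariance of parent `p`, and
* the **between-parent path**, carrying `Delta Delta^T` with
  `Delta_j = p_kj - p_lj` the parental allele-frequency difference — the
  segregation LD created by the cross itself.

Writing `u = 1 - 2c` elementwise, the two-locus recursions give closed-form
coefficients.  For diploids, the F1 state is

    E[gamma_F1]   = (u Gamma + Delta Delta^T) / 4
    cov(p_ind)_F1 = u Gamma / 4

and each selfing generation updates

    cov(p_ind) += (u/2) E[gamma],     E[gamma] *= u/2 .

For autotetraploids (bivalent pairing, no double reduction; gamete covariance
given an individual is `(4/3) u gamma`):

    E[gamma_F1]   = (5/12 - c/2) Gamma + Delta Delta^T / 4
    cov(p_ind)_F1 = u Gamma / 12
    cov(p_ind)   += (u/6) E[gamma],    E[gamma] *= (5/6 - c)

(the within-individual decay `5/6 - c` at `c = 0` reproduces the classical
5/6-per-generation heterozygosity decay of selfed autotetraploids).  The
dosage covariance of a line generation is `phi^2 cov(p_ind)`; doubled
haploids give `4 (u E[gamma_F1] + cov(p_ind)_F1)`; testcross families add the
family-side gamete covariance `lambda u E[gamma] + (phi/2)^2 cov(p_ind)`
(`lambda` = 1 diploid, 4/3 tetraploid) to the tester's own `lambda u gamma_T`.
All coefficients were validated against the meiosis simulator for every
pipeline and both ploidies (predicted covariances within Monte-Carlo error).

Three models consume this machinery:

1. **independent** — identity correlation; the variance is the sum of
   per-locus variances.
2. **approx** — no phased data: pool-level LD stands in for parental LD.
   The covariance of parent allele frequencies in each source population
   provides the between-parent path; the within-parent path uses the pool's
   average haplotype LD (recovered through a method-of-moments inbreeding
   estimate) reshaped per parent as `sqrt(w_ki w_kj) R_pool[i,j]` with
   `w_ki = (dos/phi)(1 - dos/phi)` the parent's exact within-locus allele
   variance.  Fully homozygous parents therefore contribute no within-parent
   LD, and each pair still receives its own correlation matrix.
3. **full** — phased haplotypes give `gamma_k`, `gamma_l` and `Delta`
   exactly.  Dominance enters through the path rule: with per-locus additive
   and dominance SDs `sa_j`, `sd_j`, their correlation `rho_j`, and the
   additive correlation matrix `Ca`,

       Var(g_F) = v^T Ca v + sum_j sd_j^2 (1 - rho_j^2),   v = sa + rho*sd,

   which reduces exactly to the single-locus total variance for one locus.

Per-locus variance vectors enter the quadratic form as standard deviations
(so the form equals the sum of covariances); correlations of zero-variance
loci are zeroed; negative propagated variances (possible with estimated
effects) are clipped to zero and counted (`CrossPredictor.clip`).

## Usefulness and mating-plan optimization

Usefulness of a family is `U_F = E(g_F) + i_F r sd(g_F)` with `r` the
prediction accuracy and `i_F = phi(z)/p`, `z = Phi^{-1}(1-p)`, the normal
selection intensity at within-family selected proportion `p` (a literal
variance mode is exposed for comparison but the SD convention is the
default).  A mating plan is a multiset of parent pairs with per-family cross
counts; replicating a cross enlarges the family, raises `i_F`, and couples
the objective to the plan, making the problem non-convex.  Fitness is the
unweighted mean of `U_F` over families (a count-weighted option exists).

Constraints (total crosses, repeats on/off, family count, per-parent bounds,
allowed/forbidden pairs, testers, and the PropSD cutoff) are enforced by a
penalty sentinel: infeasible plans receive a large negative fitness, keeping
the search space connected.  The search is a genetic algorithm with elite
retention, three mutation operators (replace a family, swap one parent,
shift a replication) and family-exchange crossover, hybridized with
simulated annealing (geometrically cooled acceptance of inferior candidates).
Runs are deterministic under a seed.  An exhaustive enumerator (guarded to
1e6 plans) serves as the optimality oracle in tests.

## PropSD

Additive values are modelled as `u ~ N(0, G sigma*^2)` with `G` the
ploidy-generalized VanRaden relationship matrix
(`Z = M - phi p`, `G = Z Z^T / (phi sum_j p_j (1-p_j))`).  The expected
sample SD of `u` has no elementary closed form, so the sample variance is
moment-matched to a gamma distribution:

    E(s^2)  = [tr(G)/n - 1'G1/n^2] n/(n-1)
    var(s^2)= 1' (2 Sigma1 o Sigma1) 1 / (n-1)^2,
    Sigma1  = G + SEM^2 - rowmeans - colmeans,    SEM = sqrt(1'G1)/n
    alpha   = E(s^2)^2/var(s^2),  beta = var(s^2)/E(s^2)
    E(s)    = beta^(1/2) Gamma(alpha + 1/2)/Gamma(alpha).

For `G = I` this is *exact*: it reproduces the classical `c4(n)` small-sample
bias constant of the sample SD to machine precision, which also pins down the
`alpha`/`beta` convention.  PropSD of a selected multiset is
`1 - E(s_am)/E(s_a)` with `G_m` the submatrix on the selected parents, each
repeated once per mating it takes part in (a unique-parent mode is
available); the variance-component scale cancels.  The degenerate cases are
defined explicitly: fewer than two selected entries mean complete loss
(PropSD = 1) and `var(s^2) = 0` falls back to `sqrt(E(s^2))`.

PropSD predicts the loss under *random* transmission.  Directional selection
additionally builds negative LD among loci (the Bulmer effect), so realized
losses of *genetic* SD (which include LD covariances) exceed the prediction
in unselected base populations, while losses of *genic* SD (per-locus
variances only) track it closely — the package exposes both via
`genetic_sd` / `genic_sd` and reproduces the direction in its tests.

## Synthetic data generator

The generator emulates LD-structured crop panels:

* 1,000 loci, evenly spaced on 8 chromosomes of 150 cM (defaults).
* Founder haplotypes: per chromosome, allele frequencies are sampled
  independently and haplotypes follow a first-order Markov chain whose
  adjacent-locus correlation is min(0.95, Frechet bound given the two
  frequencies).
* Diploid panel: two independent heterotic pools; per pool, 200 founder
  haplotypes are paired into 100 founders, 50 random crosses are made and
  each progeny is converted to a doubled haploid (50 fully homozygous phased
  lines per pool).  A clonal variant stops before DH conversion, keeping
  heterozygous phased clones — used for clonal-crop scenarios, because an F1
  family of two fully homozygous lines has zero within-family variance.
* Tetraploid panel: 400 founders, 100 random crosses, 100 heterozygous
  phased genotypes in one pool.
* Effects: 250 QTL sampled at random; additive and dominance effects for two
  traits (YLD, MAT) from a multivariate normal with cross-trait correlation
  0.3; dominance effects at half the additive scale (moderate partial
  dominance); non-QTL loci carry zero effect.

Estimated-effect sets reproduce the benchmark's calibration settings:
`QTL_true` (identity); `QTL_1` (a null-space perturbation of the parental
QTL design: parents' genome-wide values are reproduced exactly while
per-locus effects differ — requires more effect columns than parents);
`QTL_0.7` and `Markers_0.7` (ridge/SNP-BLUP effects fitted to noisy parental
phenotypes `y = TGV + e`, with `var(e)` bisected until the parental GEGV-TGV
correlation is 0.700 +- 0.005, on the true QTL columns and on the 750
non-QTL markers respectively — this mirrors how sub-unit accuracy arises in
practice and gives the effect errors realistic LD/relationship structure).

What the generator does *not* emulate: real marker ascertainment, mutation,
selection history (the base populations are unselected, which is exactly why
the Bulmer gap appears in the selection experiment), genotyping error,
missing data, crossover interference, or double reduction in tetraploids.
Passing tests therefore demonstrate internal consistency of the equations
with the stated meiosis model and the reported accuracy levels under these
idealized conditions, not performance on any particular real crop.

## Validation harness and problem sizes

The cross-validation harness draws random parent pairs per scheme (within a
pool for line/clonal schemes; for hybrid schemes pairs come from the first
pool with one random opposite-pool tester per cross, the
reciprocal-recurrent layout), simulates progeny with the *true* QTL effects
as the Monte-Carlo truth, and scores each effect-set x LD-model combination
by Pearson accuracy and NRMSE (RMSE / SD of truth).  Every scheme is scored
under both additive-only and additive+dominance trait values (the same
progeny genotypes, two value maps), and summary accuracies pool both rows.  Default desk-scale replication is 200
crosses x 2,000 progeny per scheme (acceptance script and criterion tests);
scaled runs preserve the method ordering (full >= approx >=
independent for SD accuracy under true effects).  Whole-genome meioses are
simulated by placing Poisson crossovers on the genetic map (rate = map
length in Morgans), so analytic and simulated LD share the same no-
interference model.

## Numerical choices

* Haldane mapping for `c`; positions in cM; chromosomes assort freely.
* Distribution invariants enforced to 1e-12; chi-square goodness-of-fit
  tests run at alpha = 0.001 with a <= 2% rejection budget across loci.
* `rho_j := 0` whenever `sa_j sd_j = 0` (removes 0/0 without affecting any
  covariance term).
* Bisection tolerances: calibration accuracy +- 0.005, <= 100 iterations.
* Missing genotypes are rejected rather than imputed: every downstream
  formula assumes complete data.
* Unphased heterozygous parents get a seeded uniform random phase (with a
  warning) only inside the simulator; the full LD model refuses them.
* GA defaults: population 100, elite 10, mutation 0.2, crossover 0.8,
  geometric cooling 0.98, patience 60 of 300 iterations.

## Known limitations

* The approx model's within-parent path relies on a pool-level inbreeding
  estimate and a shared LD correlation shape; in strongly structured or
  recently admixed pools the per-pair correlation matrices are coarse, and
  clonal-scheme SD accuracy sits below the line-scheme range.
* Tetraploid meiosis ignores double reduction and preferential pairing;
  quadrivalent formation would perturb both the gamete distributions and the
  LD-transfer coefficients.
* Multi-trait prediction and epistasis are out of scope; testers capture
  GCA/SCA implicitly rather than as named variance components.
* PropSD does not anticipate selection-induced (Bulmer) LD; near Bulmer
  equilibrium the gap shrinks, but in fresh base populations realized
  genetic-SD losses exceed the prediction.
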