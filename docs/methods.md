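# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic benchmarks do and do not show.

## Demographic model and simulator

Two present-day demes of diploid effective sizes `n1`, `n2` merge
(backwards in time) into one ancestral deme of size `n_anc` at the split
time `t2`.  Gene flow is active on a scenario-specific backward window:
none (CI), `[t1, t2]` (AM), `[0, t1]` (SC), or `[0, t2]` (CM).  The four
scenarios therefore share one parameterisation and differ only in the
migration schedule; AM with `t1 = t2`, SC with `t1 = 0` and CM with zero
rates all reduce to CI — by construction they then consume the random
stream identically and produce bit-identical data under a shared seed,
which the tests exploit as an exact equivalence check alongside the
distributional (KS) one.

Within a deme, each pair of gene copies coalesces at rate `1/(2N)` per
generation.  The forward-time migration parameters `m12`, `m21` are
immigrant fractions (the fraction of a deme's individuals replaced by
immigrants each generation); the backward lineage-migration rate is set
equal to the forward fraction, the standard identification that is exact
in the low-migration limit and conventional at the rates used here.
Time is measured in generations and no generation-time conversion is
applied: the study organisms are annual herbs, so generations and years
coincide.

Mutation is the generalised stepwise model: Poisson numbers of mutations
per branch, each mutation moving the allele state by ±k repeat units,
`k ~ Geometric(1 − p_geom)` (`p_geom = 0` gives the strict single-step
model, the default).  The allele ladder is unbounded and anchored at 100
repeat units; range constraints of fragment-length assays are not
modelled, a deliberate fidelity caveat since every downstream statistic
uses only allele identities and differences.  The calibration target is
the classical single-population identity `E[V] = θ/2 = 2Nμ` for the
sample allele-size variance, which the simulator reproduces within
Monte-Carlo error (acceptance benchmark: 8,000 replicate loci, within
5%).

Inbreeding is emulated at sampling: with probability `f_is` an
individual's second gene copy is replaced by a duplicate of its first at
all loci.  This reproduces the genome-wide heterozygote deficit of
selfing lineages with a single parameter (fixation index ≈ `f_is`), but
is not a partial-selfing coalescent: it does not change the genealogy,
so it slightly understates the coalescent-rate effects of selfing.

The event loop is JIT-compiled (numba); all randomness is seeded
explicitly and every dataset is a pure function of (scenario, n_loci,
seed).

## Priors for ABC

The study's prior table is not available, so the package declares its
own, chosen once to bracket the study system's scale: log-uniform
effective sizes on [100, 2000] (heterozygosities of 0.23–0.37 with
microsatellite mutation rates of 10⁻⁴–10⁻³ imply effective sizes of a
few hundred to a few thousand), uniform split time on [2×10⁴, 4×10⁵]
generations (bracketing a late-Pleistocene divergence of ~10⁵
generations), `t1` uniform on [0, t2], log-uniform migration fractions
on [10⁻³, 0.15] (bracketing the ~0.1 scale of interest), and log-uniform
mutation rate on [10⁻⁴, 10⁻³], shared across loci.

Reference tables for competing models are generated with **common random
numbers**: every model re-uses the same prior stream and the same
per-row simulation seeds.  Where two scenarios are equivalent for a
particular draw (e.g. SC with `t1` beyond the sample's coalescence
time equals CM), they then produce bit-identical rows, and the model
comparison is decided by the rows where the scenarios genuinely differ
rather than by simulation noise.

## ABC machinery

Summary statistics (50 for the five-population design): per population
the mean allele count, expected heterozygosity, allele-size variance and
Garza–Williamson `M = K/(range+1)`; per population pair the AMOVA-type
`F_ST` (ratio of summed variance components across loci), `(δμ)²` and
the shared-allele proportion (Jaccard over allele sets, averaged across
loci).

Each statistic is Box-Cox transformed (λ fitted per statistic on the
pooled reference, with a shift for non-positive values), standardised,
and reduced by PLS regression of the parameters on the statistics —
fitted on the pooled all-model reference so that all models live in one
comparison space; five components by default.  Rejection keeps the
Euclidean-closest simulations (ties broken by row order).

The ABC-GLM step fits `scores = c + B·θ + ε` on the retained rows of one
model, with the residual covariance Σ as the Gaussian error (ridge
jitter if singular, logged).  The marginal density of the model is the
average of `N(obs; c + B·θ_i, Σ)` over the model's **full prior
sample**, with non-retained draws contributing zero.  Averaging over the
full prior rather than the retained subset preserves the Occam penalty:
a model that spreads its prior over parameter regions unable to produce
the observed statistics is penalised by exactly the wasted prior mass.
Relative densities normalise the marginal densities across models;
Bayes factors are their ratios.  Posterior summaries are computed from
the retained draws weighted by their GLM likelihood: the mode is the
argmax of a weighted Gaussian KDE on a 512-point grid (Scott bandwidth
with a floor of 0.2× the weighted sd — an unfloored Scott factor at very
large samples makes the argmax wander between noise peaks), the median
and HPD intervals come from the weighted empirical distribution.

### Which scenarios are identifiable here

Under the declared priors and the study's parameter regime (deep
divergence relative to the effective size, `t2/2N ≫ 1`), the four
scenarios are not mutually identifiable: SC is exactly CM whenever `t1`
exceeds the sample's coalescence time (most draws), and AM reproduces
the complete-isolation signature with divergence dated at `t1` instead
of `t2`, with comparable prior mass at any observed divergence time.
Measured four-model recovery therefore splits ~evenly within each
equivalent pair while separating pairs by hundreds of log-units.  The
scenario-recovery benchmark consequently poses the model choice between
the distinguishable extremes — complete isolation versus continuous
gene flow — where recovery is essentially deterministic, and checks
AM-versus-SC separately in the regime where they do differ (`t1 ≪ t2`
with strong migration, so that the migration epochs overlap the
coalescent history differently).  A real analysis should interpret
relative densities among AM/SC/CM with this near-equivalence in mind.

Benchmark scale: 5,000 reference simulations per model, retaining the
best 1,000 for the GLM (a 20% acceptance rate; the GLM is a local
approximation, and retaining everything would force one global linear
fit).  Pseudo-observed datasets use a mid-prior generating point
(`N = 800`, `t2 = 1.1×10⁵`, `μ = 3×10⁻⁴`, and `m = 0` or `0.1`).

## Diversity statistics and AMOVA

Per-locus definitions: `Na` observed alleles, `Ne = 1/Σp²`, Shannon
`I = −Σ p ln p`, `Ho` the observed heterozygote fraction,
`He = 1 − Σp²`, `uHe = (2N/(2N−1))·He` with that locus's scored `N`, and
`F = 1 − Ho/He` averaged over polymorphic loci only (the published
fixation indices are not reproducible from the table's mean Ho and He,
which is consistent with per-locus averaging).  Standard errors are
across-locus `sd/√L`.

AMOVA is the two-level nested gene-copy analysis with the identity
distance by default (a squared allele-size distance is available).
Closed forms avoid explicit distance matrices: for a set of copies with
allele counts `c_a`, the within-set sum of squares is
`(n − Σc_a²/n)/2` for the identity distance and the ordinary ANOVA
`Σa² − (Σa)²/n` for the squared-size distance.  Variance components use
the unequal-sample-size expected-mean-square coefficients; degrees of
freedom use nominal copy counts (2 per individual), matching the
published 1/3/157/161 layout for 81 diploids in 5 populations, while
per-locus sums of squares drop missing copies.  Negative components are
reported raw and flagged, never truncated, so published-table arithmetic
stays exact.  Permutation tests permute (a) populations among species
for `F_CT`, (b) individuals among populations within species for
`F_SC`, (c) individuals among all populations for `F_ST`; p-values are
`(hits+1)/(n_perm+1)`.  With five populations the among-species
permutation space is tiny, which is why that test's p-values are coarse
(≈0.1 steps) — the same granularity the published table shows.

## Outlier scan

The multinomial-Dirichlet (Polya) likelihood of the allele counts given
ancestral frequencies `p_l` and precision `θ_lj = 1/F_lj − 1`, with
`logit(F_lj) = α_l δ_l + β_j`.  Priors: uniform Dirichlet on ancestral
frequencies, Normal(0, 1) on α and β (tunable), prior odds for
neutrality 10 (inclusion probability 1/11), matching the "posterior
odds > 10" decision calibration.  Moves per sweep: a Dirichlet proposal
on each locus's ancestral frequencies (concentration 60, with a +0.5
baseline so proposals stay interior; Hastings-corrected), a random walk
on included α's, a reversible jump that toggles inclusion proposing α
from its prior (so the proposal density cancels the prior in the
acceptance ratio), and a random walk on each β.  Posterior odds are
`P(δ=1)/(1−P(δ=1))`, capped at 9999 when a locus is never excluded; the
q-value of a locus is the running mean of the posterior neutrality
probabilities of all loci with at least its evidence.  Default run
length follows the 10⁵-iteration/thinning-1000 convention; tests and
benchmarks use a reduced scale (2,500 iterations, thinning 5) that the
planted-truth checks show is sufficient at 50-locus problems.

## Clustering and DAPC

The admixture Gibbs sampler alternates (i) per-copy cluster assignments
given memberships Q and cluster frequencies, (ii) cluster frequencies
from their Dirichlet full conditional under the correlated-frequency
prior (concentration `anc·(1−F_k)/F_k` plus counts; ancestral
frequencies are fixed at their λ=1-smoothed empirical estimate, a
point-estimate simplification of the hierarchical prior), a Metropolis
step on each drift parameter `F_k` (log-scale proposal, uniform prior on
(0.001, 0.99)), (iii) Q rows from Dirichlet(α + counts) with a
Metropolis step on the admixture α (uniform prior on (0, 10)).
`lnP(K)` is the deviance-based `mean(logL) − var(logL)/2` over the
post-burn-in trace.  A monotone trend in that trace (|Spearman ρ| > 0.5,
p < 0.01) flags non-convergence.  Label switching within a chain is not
corrected; on the strongly structured fixtures used here chains do not
switch, and across-run alignment is handled by the greedy
column-permutation matcher (maximising matched-column dot products
against the first run).  Benchmarks run 10 replicate chains per K over
K = 1..4 at 200 + 500 sweeps; the conventional full scale (10⁵ burn-in +
10⁶ sweeps) remains available through the parameters.

DAPC: PCA of the centred individuals×alleles count matrix (missing
genotypes mean-imputed), retention of the first PCs (two by default),
then linear discriminant analysis; membership probabilities are the
LDA posteriors.

## Environment association

VIF pruning drops the largest-VIF variable (`1/(1−R²)` against the
others; infinite for exact collinearity) until all fall below 10, ties
broken by column order.  The niche PCA is on the correlation matrix.
Species differences along PCs use the tie-corrected Kruskal–Wallis test.
The multivariate logistic regression is a maximum-likelihood fit with
Wald tests; (near-)separation or singular-Hessian fits fall back to a
ridge-stabilised IRLS and are flagged rather than silently returned.

dbRDA takes the genetic response (the first two PCs of the allele-count
matrix), forms Euclidean distances, and — because principal-coordinate
analysis of a Euclidean distance recovers the centred response up to
rotation — is implemented and tested as an RDA of the centred response
on the standardised predictors (least-squares projection, robust to
rank-deficient predictor sets such as site-level variables repeated per
individual).  Inertia is partitioned exactly (constrained +
unconstrained = total); adjusted R² is Ezekiel's.  Per-variable type II
(marginal) tests compute the F of each variable given all others and
permute the residuals of the reduced model.  The Mantel test correlates
off-diagonal entries and permutes one matrix's rows and columns jointly.

## Synthetic fixtures: what they emulate, and what not

The genotype fixture reproduces the study design — five labelled
populations of 10/19/22/15/15 diploids on two demes, 15 neutral loci
from the AM scenario at the printed scale (`t2 = 1.1×10⁵`,
`t1 = 5.5×10⁴`, `m = 0.1`, `μ = 1.5×10⁻⁴`, `f_is = 0.6`), targeting mean
expected heterozygosity in 0.23–0.37 and fixation index in 0.39–0.73
(redrawn with a warning, then an error, if a draw misses the band).
Positive-outlier loci are planted as species-private fixed homozygous
alleles (the maximal-divergence pattern of the study's detected
outliers), the balancing outlier by shuffling a locus's copies across
all individuals.  Outliers are planted by frequency manipulation, not
by simulating selection — they are labels with known truth.

The environment fixture draws the five variables as noisy proxies of one
shared latent axis (factor loading 35) and shifts species means along
that axis by 11 latent sd (≈1.85 sd of separation on the axis).  This
realises the generator's contract — the integrated axis (PC1) separates
the species while each variable's partial effect stays individually
undetectable at n = 23+16 — as a deliberate power balance: the 1-df PC1
tests are powered, the per-variable Wald tests are not.  Because the
pattern is a finite-sample significance event (each sub-test sits near
its threshold, as the study's own PC1 Z = 2.6 does), any single fixture
realises the full qualitative conjunction with probability ~0.85; the
benchmark therefore evaluates five independent fixtures and requires the
pattern in a majority.

Passing these benchmarks shows the stack recovers planted truths under
its own generating model at study scale; it does not validate
performance under real-data complications the generator omits — allele
size homoplasy and range constraints, genotyping error, null alleles,
population substructure within demes, or non-equilibrium demography
beyond the four scenarios.

## Numerical conventions

All permutation p-values are `(hits+1)/(n_perm+1)` and reproducible
under a fixed seed; every stochastic component takes an explicit seed
and the pipeline expands one global seed into per-stage seeds by a fixed
rule.  Frequency vectors are renormalised after clipping at 10⁻¹²;
singular covariance fits are ridge-jittered with a logged magnitude;
undefined pairwise `F_ST` entries (monomorphic pairs) are replaced by 0
with a warning in the ABC statistic vector, and left NaN elsewhere.
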