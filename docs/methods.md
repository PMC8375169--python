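# Methods

`ratelink` detects genotype–phenotype associations across species by relating
*rates* of molecular and phenotypic evolution along a time-calibrated
phylogeny, rather than only trait values.  This note documents the models,
the priors and numerical choices, the synthetic data that the test suite and
acceptance script run on, and the known limitations.

## The three per-species quantities

Every analysis reduces to three per-species root-to-tip sums:

* **R_phen** — the summed rate-scaled branch lengths (rt = time × rate
  scalar) of the phenotypic variable-rates model: the total amount of
  relative-testes-mass change a species' lineage has experienced.
* **R_dN**, **R_dS** — the summed branch-wise non-synonymous and synonymous
  substitution rates of a gene along the same lineage.

Because lineages share history, all regressions of these quantities on each
other use phylogenetic GLS with the time tree's shared-path covariance.

## Variable-rates regression (phenotype side)

log10 testes mass is regressed on log10 body mass with a separate intercept
and slope per clade.  The residual follows Brownian motion with background
rate σ²_b (trait²/Myr); a subset of branches additionally carries rate
scalars r that multiply their lengths (r > 1 faster, r < 1 slower than
background).  The posterior over (β, σ²_b, scalar placement and values) is
sampled by reversible-jump MCMC: random-scan Metropolis updates of β
(preconditioned by (XᵀX)⁻¹), log σ²_b, and the log of each active scalar,
plus birth/death moves for scalar placement.

Priors, which the source analysis leaves unstated, are: β flat on a wide box
(±100 per coefficient), log σ²_b uniform on [log 1e−8, log 1e3], the number
of scaled branches uniform on 0..B, scalar values ln r ~ Normal(0, 1.5²).
With the birth proposal drawn from the scalar prior and the uniform prior on
the count, the reversible-jump acceptance reduces to the likelihood ratio
times a boundary correction at k = 0 and k = B.  Unassigned branches have
r = 1 exactly, which, with the ln r prior centred at 0, anchors σ²_b against
the global level of the scalars.  Clades with fewer than three species get
an intercept but no clade-specific slope (the slope is not identifiable).

Proposal scales adapt toward 30 % acceptance during burn-in only.  The
covariance V(r) = A diag(t·r) Aᵀ (A the species×branch path indicator
matrix) is refactorised by Cholesky at every rate move; a relative jitter of
1e−10 × mean(diag V) keeps the factorisation stable after pruning produces
zero-length branches.  The chain kernel is compiled (numba), at roughly
30–60 µs per single-parameter update at 48–64 species.

Defaults: 2×10⁶ single-parameter updates, 10 % burn-in, 1 000 retained
samples.  Analyses in the test-suite and acceptance script use 10⁴–8×10⁵
updates depending on problem size; those sizes are stated where used.

The **rate-scaled tree** uses the per-branch posterior *median* r, with a
branch counted as r = 1 in samples where it carries no scalar.  At desk
sample sizes this median is a deliberately conservative detector: branches
are stretched only when the posterior insists, so R_phen spreads are
compressed relative to truth (the acceptance script measures this as a
correlation, not an equality).

## Marginal likelihoods and the Bayes factor

Support for rate heterogeneity is a stepping-stone estimate of
log m₁ (variable rates) minus log m₀ (single rate), reported as
BF = 2(log m₁ − log m₀) and read against Raftery's scale (<2 weak, 2–6
positive, 6–10 strong, >10 very strong).  The printed formula in the source
analysis ("−2 log_e[m₁/m₀]") is negative whenever m₁ > m₀ and contradicts
its own reported positive values; the sign convention here makes positive
values favour the variable-rates model.  Powers sit at Beta(α = 0.40, β = 1)
quantiles; stone 0 samples the prior directly (the priors are proper — the
boxes above — so the marginal likelihood is well defined), and each
subsequent stone warm-starts from the previous one.  Desk defaults are
32–100 stones × 2 000–10 000 updates; the published-scale 500 stones × 10⁶
is a configuration choice, not a code property.

## MG94xREV codon models (molecular side)

Only single-nucleotide codon changes have non-zero rate, weighted by GTR
exchangeabilities ρ (AG fixed to 1), the F3x4 position-specific target
nucleotide frequency, and dS (synonymous) or dN (non-synonymous).  No
site-to-site rate variation.  The generator is normalised so dS_b and dN_b
are expected synonymous/non-synonymous substitutions per codon on branch b —
time-independent branch values, as required for rate trees.  Equilibrium
codon frequencies are F3x4 with zero-frequency flooring at 1e−6; gaps and
ambiguous codons are missing data (partial likelihood 1); the genetic code
is the universal code (configurable).

Likelihoods use Felsenstein pruning over the 61 sense codons with per-site
scaling and alignment-column compression.  Transition matrices come from a
symmetric eigendecomposition of the π-similarity-transformed generator;
Q(dS, dN) = c·M(u) with u = dN/(dS+dN), so one decomposition per mix u
serves every branch scale, and decompositions are cached on a quantised grid
of u (0.04 in logit space) shared across branches and optimisation sweeps.

Fitting is cyclic rather than one joint quasi-Newton run:

* **global model** (shared ω, free branch scales t_b; dS_b = t_b,
  dN_b = ω t_b): per-branch Brent line searches against cached outside
  partial-likelihood messages, a Brent search for ω, and one L-BFGS-B pass
  for ρ; outer cycles stop when the log-likelihood gains < 1e−3.
* **local model** (free (dS_b, dN_b) per branch): initialised from the
  global fit, nested Brent searches per branch (outer over the mix u, inner
  over the scale), messages refreshed every 8 branch updates, up to 4–5
  sweeps with a 0.02 log-likelihood stopping gain.  ρ is held at the
  global-model estimate: it is shared between the two models, so this can
  only shrink the likelihood-ratio statistic slightly (conservative).

D = 2(lnL_local − lnL_global), clipped at zero, is tested against χ² with
df = the explicit parameter-count difference (2B+5 vs B+6, i.e. B−1 for a
binary unrooted tree), since the source reports only significance levels.
Null simulations (16 taxa × 200 codons) give mean D/df ≈ 1.0 and a 5 %
rejection rate within binomial error — the measured values are in the
acceptance report.

The per-branch dN and dS values are exported as two trees, rooted at the
outgroup's attachment point with the outgroup removed, and summed root-to-tip
for R_dN and R_dS.

## Bayesian PGLS with Pagel's λ

Residual covariance σ²·V(λ), where V(λ) multiplies off-diagonal entries of
the time-tree covariance by λ ∈ [0, 1].  Sampling is Metropolis-within-Gibbs:
exact Gaussian conditional for β (flat prior), conjugate inverse-gamma for
σ² (log-uniform prior), reflected random walk for λ (uniform prior).

Two models per gene, all variables log10:

* model i: testes ~ R_dN + R_dS + body
* model ii: R_phen ~ R_dN + R_dS + testes + body

Significance is **p_x**: the fraction of a coefficient's posterior on the
minority side of zero (exact zeros count as crossing), significant when
< 0.05.  Note the frequentist character of this rule: with flat priors,
p_x < 0.05 corresponds to a two-sided test at roughly the 10 % level, so a
null-calibration experiment is expected to "reject" about 10 % of the time —
the acceptance script measures exactly this rate.  The stated desk default
is 5×10⁵ updates with 1 000 retained samples; the pipeline uses 1.5×10⁴ per
model at n ≤ 64, which pilot runs showed reproduces p_x to within ±0.01.

## Gene classification

A gene is analysed only when the codon LRT shows branch-to-branch rate
variation at p < 0.001.  The R_dN coefficient of model ii (the *rate* axis)
and of model i (the *phenotype* axis) then map onto six categories:

| rate axis (ii)   | phenotype axis (i) | label                        |
|------------------|--------------------|------------------------------|
| sig, positive    | ns                 | bidirectional_rapid_driver   |
| sig, positive    | sig                | directional_rapid_driver     |
| sig, negative    | ns                 | moderator                    |
| sig, negative    | sig                | directional_moderator        |
| ns               | sig                | directional_nonrapid_driver  |
| ns               | ns                 | no_association               |

The map is total and deterministic over the significance/sign grid.  No
multiple-testing correction is applied across genes; the design's guard is
rerunning the identical pipeline on control genes and expecting
no_association.  Leave-one-species-out robustness reruns both PGLS models
once per species with the molecular and phenotypic rate estimates held
fixed; the reruns are regression-level only (rates are not re-estimated per
exclusion, which would multiply the cost by the species count for little
information gain at these sample sizes).

## Synthetic data

The generator stands in for the real inputs (a ~2000-species time tree and
trait table, per-gene orthologue alignments) at desk scale:

* **Tree**: pure-birth, rescaled to 300 Myr depth, ultrametric; a basal
  outgroup diverging 1.3× the root age is attached for codon simulations.
* **Traits**: body mass by Brownian motion (0.004 log10-units²/Myr from a
  root of 2.0 log10 g); testes mass from clade-specific allometries
  (intercepts −1.4..−1.0, slopes 0.62..0.78 across five clades) plus a
  Brownian residual with σ²_b = 0.001 and planted rate scalars.
* **Fast branches**: either one clade, or (default) several scattered
  subtrees of 4–10 tips covering ~30 % of species.  Units of this size span
  enough branch time for a rate burst to be statistically detectable at desk
  sample sizes, while remaining spread over independent parts of the tree so
  the planted shift is not confounded with any single clade's trait drift.
  The alternate (unchosen) subtrees form the complementary *slow set* used
  by moderator archetypes: elevating dN on a similarly sized scattered
  subset gives a moderator the same log-contrast magnitude as a driver,
  which multiplying the entire fast-set complement does not.
* **Genes**: Gillespie simulation under MG94xREV (so true per-branch
  substitution counts are available as a counting oracle), with baseline
  branch-rate noise (lognormal — every gene shows real rate heterogeneity,
  as in the study's controls), plus archetype couplings: dN multiplied on
  the fast set (drivers) or the slow set (moderators), and/or multiplied by
  exp(±d) according to the *sign* of the trait innovation on the branch
  (directional archetypes).  Sign coupling is used deliberately: coupling to
  step magnitudes — raw or standardised — leaks a spurious rate association
  through the mean or the variance of the multiplier, whereas a sign-based
  multiplier has identical magnitude on every branch and is rate-free by
  construction.
* **Benchmark bundle**: one 64-species tree and trait table shared by six
  gene archetypes, each gene alignment keeping every 2nd species (32 + the
  outgroup) — mirroring the real study, where phenotypic rates come from a
  much larger species table than any gene's sequence set.  210 codons per
  gene; trait bursts ×32; coupling ×32; directional strength 1.4; baseline
  branch-rate noise sd 0.55.  These effect sizes were fixed by pilot
  simulation runs exploring the trade-off described under Limitations, and
  frozen before the test thresholds.

## Numerical and policy choices

* Branch identity everywhere is the set of tip labels below the branch, so
  per-branch maps survive serialisation and re-reading.
* Species names are normalised (spaces → underscores); an unmatched trait
  species may bind to a single congeneric tip (ambiguity refuses, never
  guesses).
* Polytomies are treated as hard; zero-length branches are allowed and
  contribute zero to sums and covariances.
* Optimiser restarts for codon fits default to 1 (configurable); the
  cyclic scheme with shared-eigendecomposition line searches was observed in
  pilots to land within <0.01 lnL across random starts.
* All randomness flows through numpy Generators seeded from a single
  integer; seeded reruns are byte-identical.

## Limitations

* The synthetic phenotype generator plants discrete rate classes (r = 1 or
  r_fast); real phenotypic rate variation is continuous and autocorrelated.
  Passing recovery tests shows the estimators find planted structure, not
  that real testes-mass data have that structure.
* The codon generator matches the fitted model family (no alignment error,
  no orthology error, no site-to-site variation), so fit quality on real
  alignments will be worse than recovery tests suggest.
* At desk sample sizes (32–64 species) the median-rate tree under-detects
  rate bursts, compressing R_phen; end-to-end classification accuracy is
  therefore majority-level, not near-perfect — matching the statistical
  reality of the method at these sizes rather than the published scale
  (hundreds of species, 10⁹-iteration chains).
* The benchmark exposes a genuine trade-off in the method itself: larger
  trait-rate bursts make R_phen estimable (powering the rate axis) but also
  make the PGLS residual covariance — a λ-scaled *time* tree — more
  misspecified, inflating phenotype-axis false positives beyond the nominal
  ~10 % of p_x < 0.05.  Archetypes that require two simultaneous detections
  (the directional moderator especially) sit near the power boundary at 32
  overlapping species, and their recovery rate in the end-to-end test is
  expected to be only moderately above chance.
* p_x-based significance is not calibrated to 5 % type-I error (see above);
  it is reported as the source analysis defines it.
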