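# Methods

## The model family

`coaldiv` treats a rooted ultrametric phylogeny of `n` species, sampled at the
present from a clade of known richness `N0`, as the outcome of a coalescent
process running backwards in time. Nine diversification scenarios are
supported, spanning three binary contrasts — saturated vs. expanding
diversity, constant vs. time-varying rates, extinction present vs. absent:

| model | diversity | rates     | extinction | free parameters |
|-------|-----------|-----------|------------|-----------------|
| M1    | saturated | constant  | implied    | τ0 |
| M2    | saturated | varying   | implied    | τ0, γ |
| M3    | expanding | constant  | yes        | λ0, μ0 |
| M4a   | expanding | varying λ | yes        | λ0, α, μ0 |
| M4b   | expanding | varying μ | yes        | λ0, μ0, β |
| M4c   | expanding | varying both, fixed μ/λ | yes | λ0, α, ε |
| M4d   | expanding | varying both | yes     | λ0, α, μ0, β |
| M5    | expanding (pure birth) | constant | no | λ0 |
| M6    | expanding (pure birth) | varying  | no | λ0, α |

Time `t` runs backwards from the present (`t = 0` at the tips). Time-varying
rates are exponential: λ(t) = λ0·e^{αt}, μ(t) = μ0·e^{βt}, τ(t) = τ0·e^{γt},
so a positive coefficient means the rate was higher in the past and has
decayed toward the present. Fits may return either sign. The saturated models
couple every extinction to an immediate speciation (a Moran process on
species), so clade size stays at N0 and the extinction fraction at present is
1 by construction; the pure-birth models have extinction fraction 0.

The stochastic number of coexisting species is approximated by its
deterministic expectation N(t) = N0·exp(−∫₀ᵗ (λ−μ) ds), evaluated in closed
form per model (`models.expected_diversity`), with |coefficient| < 1e−8
switched to the constant-rate limit to avoid catastrophic cancellation. All
likelihood expressions assume λ(t) ≥ μ(t) throughout the tree's history;
because every rate curve is log-linear in t, λ−μ changes sign at most once
and `validate_constraint` checks the two endpoints exactly (no grid needed).

## Likelihood of internode distances

Number the internal nodes from the root (depth t₁) to the most recent node
(depth t_{n−1}); during the interval g_j = t_{j−1} − t_j exactly j sampled
lineages coexist. While j lineages remain, pairs merge at rate

    ρ_j(t) = κ · [j(j−1)/2] · λ(t) / N(t),

the Kingman rate with population size N(t) and generation time 1/λ(t) (the
time for one complete turnover of species when each of the N lineages
speciates at rate λ). Each internode distance contributes
log ρ_j(t_{j−1}) − Λ_j(t_j, t_{j−1}) to the log-likelihood, with
Λ_j(a,b) = ∫ₐᵇ ρ_j(s) ds. The terminal interval (most recent node to
present) is not a waiting time between speciation events and contributes no
factor; the likelihood conditions on it and on n. Because the expression
depends on τ0 (or λ0) and N0 only through λ/N, clade size must be supplied —
it cannot be estimated jointly.

**The convention constant κ = 2.** In both generating processes implemented
here the pair that merges at an event is a uniformly random pair among the
N(t) coexisting species: in the Moran-style turnover process a specific pair
merges with probability 2/(N(N−1)) per event at total event rate N·τ, and in
a birth–death process each speciation (total rate N·λ) merges a specific pair
with probability 1/C(N,2). Both give a pair-merger rate ≈ 2λ/N, twice the
naive Wright–Fisher rate of C(j,2)/N per generation — the familiar factor-two
difference between Moran and Wright–Fisher effective sizes. We therefore set
κ = 2 (`coalescent.DEFAULT_KAPPA`), i.e. ρ_j = j(j−1)·λ(t)/N(t), and verify
it two ways in the test suite: a Monte-Carlo estimate of the simulator's
pair-coalescence rate, and bias-free recovery of τ0 when fitting the
constant-turnover model to its own simulations. κ rescales every rate
estimate by a constant and cancels from all AICc/weight comparisons.

**Integration.** Λ_j factors as κ·C(j,2)·∫λ/N, and the j-independent integral
has elementary closed forms for M1, M2, M3, M4c, M5 and M6. For M4a, M4b and
M4d the likelihood integrates λ(s)·e^{∫(λ−μ)}/N0 by fixed-order
Gauss–Legendre quadrature (32 nodes per internode interval, node positions
precomputed once per tree and reused across all optimizer iterations). The
integrands are smooth exponentials; agreement with a 10⁶-point trapezoid
oracle is ~1e−7 in absolute log-likelihood, and the public
`cumulative_rate` API offers an adaptive-quadrature route (absolute tolerance
1e−10 relative to scale) used to cross-check every closed form.

**Degenerate inputs and optimizer-facing behavior.** Inadmissible parameters
(constraint violated, N(t) underflowing, overflow in the intensity) return
−∞ rather than raising, so a derivative-free optimizer can traverse them;
inside the optimizer −∞ becomes a graded penalty sloped toward the feasible
region. Zero-length internode distances (from epsilon-resolved polytomies)
are admissible: they contribute log ρ with a null integral.

## Fitting and model selection

Each model is fitted by multi-start Nelder–Mead (10 starts by default) on
transformed coordinates: rates on a log scale, the extinction fraction on a
logit scale, variation coefficients untransformed. Two deterministic
heuristic starts anchor the search — one at the Hey-model closed-form MLE
τ̂0 = (n−2)·N0/(κ·ΣC(j,2)g_j) with extinction set so that N(root) ≈ 1 (the
"grew from a single ancestor" configuration), one nearly extinction-free —
and the remaining starts draw rates log-uniformly within a factor 10 and
variation coefficients uniformly within ±2/root-age. The second anchor
matters: on trees whose root age is many net-diversification half-lives, the
admissible extinction rates sit close to λ0 − ln(N0)/t₁ and random starts
rarely land there.

Goodness of fit is the small-sample Akaike criterion
AICc = −2logL + 2k + 2k(k+1)/(n_obs−k−1) with n_obs = n−2 internode
distances; a model needs n_obs > k+1. Akaike weights are
exp(−Δ_l/2)/Σexp(−Δ_m/2) with the max-shift trick; models with no admissible
parameters anywhere get AICc = +∞ and weight 0 with a logged notice. Ties
for "best model" break by fewer parameters, then fixed model order. Three
hypothesis pairs are evaluated by selecting the lowest-AICc model inside each
subset and renormalizing the two winners' weights: expanding {M3–M6} vs.
saturated {M1,M2}; time-varying {M2,M4a–d,M6} vs. constant {M1,M3,M5};
extinction {M1–M4d} vs. none {M5,M6}. The extinction fraction at present is
1 for M1/M2, 0 for M5/M6, ε̂ for M4c and μ̂(0)/λ̂(0) otherwise.

## Simulators

`simulate_saturated` implements the turnover process: N0 lineages joined by a
root polytomy, exponential waiting times at total rate N0·τ evaluated at the
previous event, one uniform-random lineage removed and another bifurcated per
event. For constant τ the event stream is a homogeneous Poisson process and
is generated exactly (count Poisson, times uniform); for γ ≠ 0 the times are
generated sequentially. The genealogy of the N0 extant species is then
reconstructed by a single backward sweep over the events, stopping at the
sample MRCA. The default run length is 10·N0/τ0 ≈ 10·E[TMRCA]; if the root
polytomy has not resolved the simulation re-runs with doubled duration (up to
three times) before flagging the result.

`simulate_birth_death` starts from one lineage and draws events at total rate
N·(λ+μ) evaluated at the previous event, bifurcating with probability
λ/(λ+μ). Evaluating rates at the previous event rather than exact thinning
of the inhomogeneous process follows the generating scheme the models
describe; it is exact for constant rates and a good approximation when
per-event rate changes are small (the regimes used here). Extinct clades are
flagged; the `_conditioned` wrapper discards and resimulates, i.e.
conditions on survival. Reconstructed trees prune extinct subtrees and are
exactly ultrametric. `simulate_yule(n, λ)` grows a pure-birth tree to exactly
n tips and places the present a fresh Exp(nλ) after the last split, so every
inter-node interval keeps its textbook exponential law — the configuration
under which the gamma statistic is standard normal.

`sample_tips` retains ⌈f·n⌉ tips uniformly without replacement (the rounding
is a choice; nothing downstream is sensitive to it) and suppresses
pass-through nodes, lengthening terminal branches exactly as incomplete
taxon sampling does.

### What the generators do and do not emulate

The simulators generate the study conditions for every validation experiment:
equal diversification chances for all lineages, exponential-in-time rates,
uniform taxon sampling, exact ultrametry. Real phylogenies violate several of
these — rate heterogeneity across lineages (real trees are more imbalanced
than any of the nine models predicts), non-uniform taxon sampling,
branch-length estimation error and rounding. Passing the validation suite
therefore shows the inference machinery is correct and well calibrated for
the model class, not that the model class captures every feature of real
data.

### Study conditions used by the validation experiments

* **Saturated-diversity classification** (the headline experiment and the
  quantity `scripts/acceptance.py` recomputes): 100 replicates of Model 1
  with N0 = 100 and τ0 = 1 (the classification is invariant to time
  rescaling), subsampled at f = 0.75, all nine models fitted.
* **Decaying-speciation experiments** (classification and parameter
  recovery): Model 4a with λ0 = 0.5, α = 0.5, μ0 = 0.25 over 4 time units —
  extinction fraction 0.5 at present, ~7-fold speciation decay across the
  clade's history, expected present-day richness of a few hundred species so
  that even 10% sampling leaves a usable tree. Parameter recovery uses 200
  replicates per sampling fraction f ∈ {0.1, 0.75, 1.0} (4 optimizer starts
  per fit, which the restart-consistency checks show is ample for a 3-
  parameter model); the classification check uses 25 replicates at f = 0.75.
* **Gamma calibration**: 10⁴ pure-birth trees of 50 tips.
* **Kernel calibration**: pair-coalescence Monte Carlo at N0 = 50 (8000
  pairs) plus τ0 recovery on 50 Model-1 trees (N0 = 100, f = 0.75).

These sizes keep the full validation suite within a desk-scale run while
leaving Monte-Carlo error well below every tolerance asserted.

## Summary statistics and the branch-length comparator

The Pybus–Harvey gamma statistic is computed from all inter-node intervals
*including* the terminal one (unlike the likelihood — the two uses are kept
explicit in the API): with T_i = Σ_{k≤i} k·g_k and T = T_n,
γ = [mean(T_2..T_{n−1}) − T/2] / [T·√(1/(12(n−2)))]. It is scale-invariant,
standard normal under the pure-birth model, and negative when nodes crowd
toward the root.

The branch-length comparator fits exponential, Weibull, lognormal and normal
distributions to the *internal* branch lengths (terminal and root branches
excluded — neither is delimited by two speciation events) and ranks them by
the same AICc. Closed-form MLEs are used for the exponential, normal and
lognormal; the Weibull is fitted by Nelder–Mead started from its exponential
(shape = 1) special case. Of the four, only the Weibull implies speciation
rates that change with lineage age; the validation suite shows constant-rate
families keep winning on trees whose speciation rate decays in *absolute*
time, i.e. this comparator is blind to the signal the coalescent likelihood
detects. A fifth, "variable rates" family from the same literature is defined
only in an external reference and is not implemented.

A posterior-predictive check (`gamma_posterior_quantile`) simulates from a
fitted model — for expanding-diversity fits the clade age is set where the
fitted N(t) contracts to a single ancestor — and returns the quantile of the
observed gamma within the simulated gamma distribution.

## Tree handling

Newick I/O, tree cloning and pruning go through dendropy. Ultrametricity is
validated with a relative tolerance of 1e−4 of tree depth by default
(configurable): empirical trees carry rounding noise, and the tolerance used
by any given published study is rarely stated. Polytomies are resolved into
random bifurcations spaced 1e−6 time units apart (configurable), preserving
every original node depth exactly; the new nodes receive strictly increasing
offsets ε, 2ε, … below the polytomy node regardless of how the random joins
nest, so every random resolution yields the same multiset of internode
distances and hence the same likelihood. Tied node depths in input trees are
never perturbed silently. Zero-length terminal branches are allowed (they
never enter the likelihood).

## Known limitations

* Diversity that *declines* toward the present (μ > λ) is outside the model
  class; the constraint is enforced, not relaxed.
* No rate variation across lineages; empirical trees are typically more
  imbalanced than anything these models generate.
* The deterministic-N(t) approximation slightly overestimates extinction
  rates (visible in the parameter-recovery experiment as a positive median
  bias of μ̂0 that is small relative to the sampling band).
* The waiting-time scheme updates rates only at events; for very fast
  exponential rate change within a single waiting time the simulators would
  drift from the exact inhomogeneous process.
* Confidence intervals on fitted parameters are not provided; uncertainty is
  quantified across simulation replicates only.
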