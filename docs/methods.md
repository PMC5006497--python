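# Methods

## The model

A plumage patch is a discrete character with state space a subset of
{absence, scales, bars, spots}, evolving along a rooted phylogeny with
branch lengths taken as supplied, under a continuous-time Markov chain with
rate matrix `Q`.  The object of inference is not a single `Q` but a *rate
configuration*: each ordered state pair is either fixed to zero (the
transition does not occur) or assigned to a rate class, and pairs sharing a
class share one positive rate.  Two configurations are the same *model*
exactly when they share the zero set and the partition of free pairs; the
model space for `n` pairs therefore has `Σ_z C(n, z)·B(n−z) = B(n+1)`
members.  States never observed in a patch are dropped from its modeled
space (a three-state patch has 6 ordered pairs), mirroring how such patches
are analyzed with smaller model spaces.

Likelihood: Felsenstein pruning with per-branch `P(t) = exp(Qt)`.  A taxon
carries a non-empty *set* of allowed states — a singleton for a clean
observation, the full set for mottled/unknown plumage, an intermediate set
for twigs — and contributes partial likelihood 1 to each allowed state.
The root prior is uniform over the modeled space by default (configurable
to the stationary distribution); root-state marginals are the normalized
product of prior and root conditional likelihoods.

## Sampling over models

The RJMCMC state is (configuration, class rates, gamma hyperparameters).
The target is

    L(data | Q) × Π_c Gamma(r_c; a, b) × 1/B(n+1) × Uniform(a, μ over box)

Moves: a log-scale rate walk (Hastings ratio `r'/r`), sending a free pair
to ZERO / reviving a zero pair into an existing or fresh class, reassigning
a pair between classes, and splitting/merging classes.  Every rate created
by a dimension-changing move is drawn from the current gamma prior, which
makes each Metropolis–Hastings–Green ratio exact (the prior density of the
created/destroyed rate cancels against the proposal); move-type
probabilities are renormalized over the feasible set (0.5 rate walk, 0.5
split evenly across feasible structural moves) and enter the ratio
explicitly.  Exactness is verified two ways in the test suite: with
uninformative data the sampled configuration frequencies match the uniform
prior over the five 2-state models (chi-square), and on a two-tip problem
the RJ frequencies match a brute-force quadrature posterior over all five
configurations.

Hyperprior.  Class rates get a Gamma(shape a, rate b) prior.  An
empirical-Bayes interval is computed by fitting the saturated model (every
pair its own class) by maximum likelihood and summarizing the fitted rates:
rates pushed to the optimizer's lower boundary are excluded (they describe
transitions the data reject outright, not the magnitude of rates that do
occur), and the (mean m, sd s) of the rest define the box.  Per generation
a Metropolis step proposes a ∼ U(1, 5) and gamma mean μ ∼ U(max(m−s, m/2),
m+s), with b = a/μ.  Two deliberate exclusions guard the reversible jump's
ability to distinguish "occurs" from "does not occur": shapes below 1 are
out (their density spike at rate → 0 would let a free rate imitate the
nested zero model), and the gamma mean cannot collapse far below the
empirical-Bayes center for the same reason.

Chain management follows the production protocol in structure: several
independent runs (default 4, seeds base+index), convergence declared when
the harmonic-mean log marginal likelihoods of all runs agree within 1 lnHM;
the pooled post-burn-in sample is screened with a lag-1 Ljung–Box test on
the log-likelihood series and thinned to every 10th draw when it rejects at
5 %.  The harmonic-mean estimator is used only as this cross-run agreement
statistic — its instability as an absolute marginal-likelihood estimate is
well known.  `ChainConfig.paper_scale()` records the production-fidelity
settings (500 000 burn-in, sampling every 100 000th generation, four runs);
the plain defaults (20 000 generations, burn-in 4 000, sample every 100)
are desk-scale values chosen so a full analysis of a 200-tip patch runs in
well under a minute per chain, which is what the examples and tests use —
the target being distributional correctness, not byte-compatibility with
any particular production run.

## Multimodel statistics

Each unique model's posterior probability is its visit fraction.  Prior
odds take the model's *complexity class* share of the uniform configuration
prior, `C(n, z)·B(n−z)/B(n+1)` for a model with `z` zero transitions —
binomial counting for the transitions that do not occur combined with Bell
counting for those that do — so the Bayes factor asks whether a model is
visited more than its complexity class warrants.  (A strict
one-configuration prior `1/B(n+1)` is available as `prior_mode="uniform"`;
with 12 pairs it makes every visited model's BF astronomically large and
renders the top model set non-selective, which is why the complexity-class
form is the default.)  The full model is judged qualitatively: all
configurations with an empty zero set, prior `B(n)/B(n+1)`.

Marginal probabilities are visit-weighted.  Over the full posterior,
MP(occurs) + MP(not) = 1 per pair and ancestral MPs sum to 1 over states.
The "final" MPs additionally reported for the top model set cumulate only
models with BF ≥ 2 while keeping the full sample size as denominator, so
the two need not sum to 1 — posterior mass on models outside the top set
supports neither verdict.  A model's ancestral state is the argmax of its
mean sampled root vector; exact ties split the tally fractionally (two tied
states count 0.5 each).  "Average probability" is the plain posterior mean
of the root-state vector, and the average rate of a pair mixes zeros in
(a model with the pair at ZERO contributes 0).

Patch verdicts compare MP(occurs) against MP(not): larger by more than the
tolerance (default 0, i.e. any difference) → occurs / absent; otherwise
equivocal.  Cross-patch summary counts add 1 per occurring patch and 0.5
per equivocal patch, over the patches whose modeled space contains both
states.  The order of first evolution is the breadth-first layering of the
occurring-transition digraph from the inferred ancestral state; ties at a
depth yield a partial order whose linear extensions are enumerated exactly
(4! brute force), and each candidate order drives one whole-body recoding —
a species' representative state is the latest, in that order, among its
unambiguous patch states; species mottled everywhere become missing.

## Synthetic data

The generator is the package's study-condition definition, not a fixture.
Trees: forward Yule/birth–death simulation conditioned on the extant tip
count (dendropy), tips relabeled `sp1..spN`; internal supports are drawn
U(0.96, 1) except for a configurable fraction drawn U(0.5, 0.95] — only the
0.95 collapse threshold is scientifically meaningful, so the support
distribution is a modeling convenience.  Traits: exact jump-chain
simulation along branches from a fixed root state (a transition-matrix
sampler exists as an internal cross-check; the two agree in distribution).
Missingness: each taxon independently becomes fully ambiguous with the
missing rate.

The `constraint_chain` preset encodes the sparse truth of interest —
absence → bars → scales → spots with bidirectional bars ↔ scales, direct
absence ↔ spots impossible — on 200-tip unit-birth-rate Yule trees with
10 % missing tips and 10 % low-support branches.  Rates (0.15 entry into
patterning, 0.3 motif switching, 0.35 scales → spots) were calibrated
against forward-simulated tip frequencies only, so that the ancestral state
stays a plurality and each derived pattern segregates at a realistic
minority frequency; since a pattern that never evolves cannot inform the
transitions involving it, generation redraws (deterministically in the
seed) until every state has at least 20 unambiguous tips, emulating
empirical frequency tables in which all modeled states are represented.
What the generator does not emulate: correlated evolution between patches,
clade-specific rate variation, state-dependent diversification, or
phylogenetic error beyond the support-value/twig mechanism — so passing
recovery tests demonstrate internal consistency of the inference under the
model's own assumptions, not robustness to their violation.

## Numerical choices

- `exp(Qt)` in bulk via one eigendecomposition per proposal and a
  vectorized reconstruction across branches, validated by positivity and
  row-sum checks with automatic per-branch scaling-and-squaring (Padé)
  fallback whenever the eigenbasis is ill-conditioned (cond > 1e8) or the
  reconstruction is inaccurate; single-branch calls use scaling-and-squaring
  directly.  Entries are clipped at −1e−9 tolerance and rows renormalized.
- Pruning rescales partials by their maximum at each internal node,
  accumulating the log scale, so 200-tip likelihoods do not underflow.
- ML rates are optimized on log scale (L-BFGS-B, bounds e−15..e8,
  multi-start at 0.1×/1×/10× a tree-length-based scale), making boundary
  optima at rate → 0 reachable.
- Majority/modal ties in trait coding break deterministically by the
  canonical state order (absence < scales < bars < spots) with a logged
  warning; equivocal transition verdicts require an exact tie by default.
- Twig terminals keep the collapsed clade's subtending branch length plus
  its mean root-to-tip depth, preserving expected tip depth; branches
  without annotated support are treated as trusted.

## Known limitations

- Under the uniform configuration prior, a transition pair is free in
  ≈ 84.8 % of configurations a priori (1 − B(12)/B(13)).  For a transition
  out of a state occupying little total branch length, the marginal Bayes
  factor against freeing it is bounded by `E_Γ[e^{−rT}]` (T the occupied
  length), so MP(not occurring) cannot approach 1 at moderate sample sizes
  no matter how long the chain runs; and a fast two-step pathway completed
  within a single branch is likelihood-equivalent to a direct shortcut
  edge.  Truth-recovery of *zero* transitions at desk scale is therefore
  imperfect for transitions out of minority states, while recovery of
  occurring transitions and rejection of the full model are robust.  This
  is a property of the model space and data regime, not of the sampler.
- The harmonic-mean convergence criterion inherits the estimator's high
  variance; it is a pragmatic cross-run agreement check, not a model-choice
  statistic.
- Tests of the whole pipeline run at desk scale (tens of thousands of
  generations); they validate correctness of the algorithms, not the
  mixing behaviour of production-length runs.
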