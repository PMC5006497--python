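"""Reversible-jump MCMC over zero/rate-class configurations.

The chain state is a :class:`~plumevol.ctmc.RateConfiguration` — each
ordered state pair fixed to ZERO or grouped into a rate class — together
with gamma hyperprior parameters on the class rates.  The target is

    posterior  ∝  likelihood(data | Q(config))
                × Π_classes Gamma(rate_c; shape, rate)
                × uniform prior over configurations
                × uniform hyperprior over the empirical-Bayes box.

Dimension-changing moves (send a pair to ZERO / revive it, reassign between
classes, split and merge classes) draw any newly created class rate from
the current gamma prior, so every Metropolis–Hastings–Green ratio is exact;
with uninformative data the chain provably targets the uniform prior over
configurations, which the test suite checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .ctmc import (
    PruningContext,
    RateConfiguration,
    build_rate_matrix,
    empirical_bayes_interval,
    ml_rates,
    ordered_pairs,
)
from .phylo import Phylogeny
from .traits import TraitColumn

logger = logging.getLogger(__name__)

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------
# hyperprior


@dataclass
class GammaHyper:
    """Gamma prior on class rates with resampled hyperparameters.

    The mean of the gamma is confined to ``mean_bounds`` (centered on the
    empirical-Bayes mean ± sd of the per-pair ML rates) and the shape to
    ``shape_bounds``; both are updated by a Metropolis step with uniform
    independent proposals over the box.

    Shapes below 1 are excluded: a gamma with shape < 1 piles density at
    rate → 0, so a free rate class could imitate the nested zero model and
    the reversible jump would no longer separate "occurs" from "does not
    occur".  A free class stands for a transition that genuinely happens,
    so its rate is kept bounded away from zero in distribution.
    """

    mean_bounds: tuple[float, float]
    shape_bounds: tuple[float, float] = (1.0, 5.0)
    shape: float = 1.0
    rate: float = 1.0

    @classmethod
    def from_interval(
        cls,
        mean: float,
        sd: float,
        shape_bounds: tuple[float, float] = (1.0, 5.0),
    ) -> "GammaHyper":
        # the box stays centered on the empirical-Bayes mean: letting the
        # gamma mean collapse far below it would defeat the estimator
        lo = max(mean - sd, mean * 0.5, 1e-6)
        hi = max(mean + sd, lo)
        hyper = cls(mean_bounds=(lo, hi), shape_bounds=shape_bounds)
        mu = 0.5 * (lo + hi)
        hyper.shape = 0.5 * (shape_bounds[0] + shape_bounds[1])
        hyper.rate = hyper.shape / mu
        return hyper

    def log_pdf(self, r: float) -> float:
        a, b = self.shape, self.rate
        return a * math.log(b) - gammaln(a) + (a - 1.0) * math.log(r) - b * r

    def log_prior_rates(self, config: RateConfiguration) -> float:
        return sum(self.log_pdf(r) for r in config.class_rates.values())

    def draw_rate(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape) / self.rate)

    def metropolis_update(
        self, config: RateConfiguration, rng: np.random.Generator
    ) -> bool:
        a_new = float(rng.uniform(*self.shape_bounds))
        mu_new = float(rng.uniform(*self.mean_bounds))
        b_new = a_new / mu_new
        if not config.class_rates:
            self.shape, self.rate = a_new, b_new
            return True
        cand = GammaHyper(self.mean_bounds, self.shape_bounds, a_new, b_new)
        delta = cand.log_prior_rates(config) - self.log_prior_rates(config)
        if math.log(rng.uniform()) < delta:
            self.shape, self.rate = a_new, b_new
            return True
        return False


# ---------------------------------------------------------------------
# move machinery


MOVE_WALK = "rate_walk"
MOVE_KILL = "kill"
MOVE_REVIVE = "revive"
MOVE_REASSIGN = "reassign"
MOVE_SPLIT = "split"
MOVE_MERGE = "merge"

STRUCTURAL_MOVES = (MOVE_KILL, MOVE_REVIVE, MOVE_REASSIGN, MOVE_SPLIT, MOVE_MERGE)


def _splittable(config: RateConfiguration) -> list[int]:
    return [c for c, mem in sorted(config.class_members().items()) if len(mem) >= 2]


def move_probabilities(config: RateConfiguration) -> dict[str, float]:
    """Normalized probability of drawing each feasible move type.

    Rate walks get half the mass and the feasible dimension-changing moves
    split the other half evenly; when a category is entirely infeasible its
    mass is renormalized away.
    """
    feasible: dict[str, float] = {}
    if config.n_classes >= 1:
        feasible[MOVE_WALK] = 0.5
    struct = []
    if config.free_pairs:
        struct.append(MOVE_KILL)
        struct.append(MOVE_REASSIGN)
    if config.zero_pairs:
        struct.append(MOVE_REVIVE)
    if _splittable(config):
        struct.append(MOVE_SPLIT)
    if config.n_classes >= 2:
        struct.append(MOVE_MERGE)
    for m in struct:
        feasible[m] = 0.5 / len(struct)
    total = sum(feasible.values())
    return {m: w / total for m, w in feasible.items()}


def _log_lognormal(x_to: float, x_from: float, sigma: float) -> float:
    z = (math.log(x_to) - math.log(x_from)) / sigma
    return -0.5 * z * z - LOG_SQRT_2PI - math.log(sigma) - math.log(x_to)


def _new_class_id(config: RateConfiguration) -> int:
    return max(config.class_rates, default=-1) + 1


def propose_move(
    current: RateConfiguration,
    rng: np.random.Generator,
    hyper: GammaHyper,
    sigma: float = 0.6,
) -> tuple[RateConfiguration | None, float, str]:
    """One reversible-jump proposal.

    Returns ``(proposed, log_hastings, move_name)`` where ``log_hastings``
    is ``log q(current | proposed) - log q(proposed | current)`` including
    move-type probabilities and the gamma densities of any rates drawn or
    (in reverse) regenerated.  ``proposed is None`` signals an auto-rejected
    draw (e.g. a trivial split).
    """
    probs = move_probabilities(current)
    names = sorted(probs)
    move = str(rng.choice(names, p=[probs[n] for n in names]))
    pair_order = ordered_pairs(current.states)
    F = len(current.free_pairs)
    Z = len(current.zero_pairs)
    C = current.n_classes

    if move == MOVE_WALK:
        cids = sorted(current.class_rates)
        cid = int(rng.choice(cids))
        r = current.class_rates[cid]
        r_new = r * math.exp(sigma * rng.normal())
        prop = current.copy()
        prop.class_rates[cid] = r_new
        log_fwd = math.log(probs[move] / C) + _log_lognormal(r_new, r, sigma)
        log_rev = math.log(move_probabilities(prop)[move] / C) + _log_lognormal(
            r, r_new, sigma
        )
        return prop, log_rev - log_fwd, move

    if move == MOVE_KILL:
        free = [p for p in pair_order if current.assignment[p] is not None]
        pair = free[int(rng.integers(len(free)))]
        cid = current.assignment[pair]
        singleton = len(current.class_members()[cid]) == 1
        prop = current.copy()
        prop.assignment[pair] = None
        destroyed = None
        if singleton:
            destroyed = prop.class_rates.pop(cid)
        log_fwd = math.log(probs[move] / F)
        C_after = prop.n_classes
        rev = math.log(move_probabilities(prop)[MOVE_REVIVE] / ((Z + 1) * (C_after + 1)))
        if destroyed is not None:
            rev += hyper.log_pdf(destroyed)
        return prop, rev - log_fwd, move

    if move == MOVE_REVIVE:
        zeros = [p for p in pair_order if current.assignment[p] is None]
        pair = zeros[int(rng.integers(len(zeros)))]
        target = int(rng.integers(C + 1))
        prop = current.copy()
        log_fwd = math.log(probs[move] / (Z * (C + 1)))
        if target == C:  # fresh singleton class with a prior-drawn rate
            cid = _new_class_id(current)
            r_new = hyper.draw_rate(rng)
            prop.class_rates[cid] = r_new
            prop.assignment[pair] = cid
            log_fwd += hyper.log_pdf(r_new)
        else:
            cid = sorted(current.class_rates)[target]
            prop.assignment[pair] = cid
        log_rev = math.log(move_probabilities(prop)[MOVE_KILL] / (F + 1))
        return prop, log_rev - log_fwd, move

    if move == MOVE_REASSIGN:
        free = [p for p in pair_order if current.assignment[p] is not None]
        pair = free[int(rng.integers(len(free)))]
        src = current.assignment[pair]
        singleton_src = len(current.class_members()[src]) == 1
        others = [c for c in sorted(current.class_rates) if c != src]
        n_opt = len(others) + 1  # existing classes other than src, plus "new"
        choice = int(rng.integers(n_opt))
        prop = current.copy()
        log_fwd = math.log(probs[move] / (F * n_opt))
        log_rev_extra = 0.0
        if choice == len(others):  # target: new class
            r_new = hyper.draw_rate(rng)
            cid = _new_class_id(current)
            prop.assignment[pair] = cid
            prop.class_rates[cid] = r_new
            log_fwd += hyper.log_pdf(r_new)
            if singleton_src:
                destroyed = prop.class_rates.pop(src)
                log_rev_extra += hyper.log_pdf(destroyed)
        else:
            prop.assignment[pair] = others[choice]
            if singleton_src:
                destroyed = prop.class_rates.pop(src)
                log_rev_extra += hyper.log_pdf(destroyed)
        n_opt_rev = prop.n_classes  # (C' - 1 existing) + new
        log_rev = (
            math.log(move_probabilities(prop)[move] / (F * n_opt_rev))
            + log_rev_extra
        )
        return prop, log_rev - log_fwd, move

    if move == MOVE_SPLIT:
        cands = _splittable(current)
        cid = int(rng.choice(cands))
        members = current.class_members()[cid]
        bits = rng.integers(0, 2, size=len(members))
        if bits.min() == bits.max():  # trivial split: auto-reject
            return None, 0.0, move
        prop = current.copy()
        new_id = _new_class_id(current)
        r_new = hyper.draw_rate(rng)
        prop.class_rates[new_id] = r_new
        for p, b in zip(members, bits):
            if b == 1:
                prop.assignment[p] = new_id
        log_fwd = (
            math.log(probs[move] / len(cands))
            - len(members) * math.log(2.0)
            + hyper.log_pdf(r_new)
        )
        C_after = C + 1
        log_rev = math.log(
            move_probabilities(prop)[MOVE_MERGE] / (C_after * (C_after - 1))
        )
        return prop, log_rev - log_fwd, move

    if move == MOVE_MERGE:
        cids = sorted(current.class_rates)
        keep = int(rng.choice(cids))
        absorb = int(rng.choice([c for c in cids if c != keep]))
        prop = current.copy()
        destroyed = prop.class_rates.pop(absorb)
        for p, c in prop.assignment.items():
            if c == absorb:
                prop.assignment[p] = keep
        m = len(prop.class_members()[keep])
        log_fwd = math.log(probs[move] / (C * (C - 1)))
        log_rev = (
            math.log(move_probabilities(prop)[MOVE_SPLIT] / len(_splittable(prop)))
            - m * math.log(2.0)
            + hyper.log_pdf(destroyed)
        )
        return prop, log_rev - log_fwd, move

    raise AssertionError(f"unknown move {move}")


# ---------------------------------------------------------------------
# chain driver


@dataclass
class ChainConfig:
    """Chain-management settings.

    Defaults mirror the production-scale protocol (500 000 burn-in
    generations, sampling every 100 000th) only through the documented
    ``paper_scale`` constructor; the plain defaults are desk-scale values
    suitable for tests and examples.
    """

    n_generations: int = 20_000
    burn_in: int = 4_000
    sample_interval: int = 100
    n_chains: int = 4
    seed: int = 0
    hyper_interval: tuple[float, float] | None = None
    shape_bounds: tuple[float, float] = (1.0, 5.0)
    proposal_sigma: float = 0.6
    convergence_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_generations):
            raise ValueError("need 0 <= burn_in < n_generations")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @classmethod
    def paper_scale(cls, **overrides) -> "ChainConfig":
        """Production-fidelity settings: 500k burn-in, sample every 100k."""
        base = dict(
            n_generations=5_500_000,
            burn_in=500_000,
            sample_interval=100_000,
            n_chains=4,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class ModelSample:
    """One recorded posterior draw."""

    config: RateConfiguration
    log_likelihood: float
    root_probs: np.ndarray
    generation: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_likelihood):
            raise ValueError("sampled log-likelihood must be finite")
        if abs(float(np.sum(self.root_probs)) - 1.0) > 1e-6:
            raise ValueError("root probability vector must sum to 1")

    @property
    def signature(self) -> str:
        return self.config.signature()


@dataclass
class ChainResult:
    samples: list[ModelSample]
    ln_hm: float
    acceptance: dict[str, float]
    seed: int


def _initial_configuration(
    ctx: PruningContext,
    tree: Phylogeny,
    column: TraitColumn,
    root_prior: np.ndarray | None,
    seed: int,
) -> RateConfiguration:
    """Single-class all-free start at the single-rate ML value."""
    skeleton = RateConfiguration.single_class(ctx.states, 1.0)
    rates, _ = ml_rates(tree, column, skeleton, root_prior=root_prior, seed=seed,
                        n_starts=3)
    rate = max(rates[0], 1e-6)
    return RateConfiguration.single_class(ctx.states, rate)


def run_chain(
    tree: Phylogeny,
    column: TraitColumn,
    config: ChainConfig,
    states: Sequence[str] | None = None,
    root_prior: np.ndarray | None = None,
    _context: PruningContext | None = None,
    _initial: RateConfiguration | None = None,
) -> ChainResult:
    """Run one Metropolis–Hastings–Green chain and record thinned samples."""
    from .states import STATE_ORDER

    states = tuple(states) if states is not None else STATE_ORDER
    ctx = _context or PruningContext(tree, column, states)
    rng = np.random.default_rng(config.seed)

    if config.hyper_interval is None:
        mean, sd = empirical_bayes_interval(
            tree, column, states, root_prior=root_prior, seed=config.seed
        )
    else:
        mean, sd = config.hyper_interval
    hyper = GammaHyper.from_interval(mean, sd, shape_bounds=config.shape_bounds)

    current = (_initial or _initial_configuration(
        tree=tree, ctx=ctx, column=column, root_prior=root_prior, seed=config.seed
    )).copy()
    prior = ctx._check_prior(root_prior)
    cur_ll = ctx.log_likelihood(build_rate_matrix(current), prior)
    retries = 0
    while not math.isfinite(cur_ll):
        retries += 1
        if retries > 20:
            raise RuntimeError("could not find a finite-likelihood starting model")
        current = RateConfiguration.single_class(
            ctx.states, float(rng.gamma(hyper.shape) / hyper.rate)
        )
        cur_ll = ctx.log_likelihood(build_rate_matrix(current), prior)
    cur_rate_prior = hyper.log_prior_rates(current)

    samples: list[ModelSample] = []
    proposed_counts: dict[str, int] = {}
    accepted_counts: dict[str, int] = {}
    for gen in range(1, config.n_generations + 1):
        if hyper.metropolis_update(current, rng):
            cur_rate_prior = hyper.log_prior_rates(current)
        prop, log_hastings, move = propose_move(
            current, rng, hyper, sigma=config.proposal_sigma
        )
        proposed_counts[move] = proposed_counts.get(move, 0) + 1
        if prop is not None:
            prop_ll = ctx.log_likelihood(build_rate_matrix(prop), prior)
            if math.isfinite(prop_ll):
                prop_rate_prior = hyper.log_prior_rates(prop)
                log_alpha = (
                    (prop_ll - cur_ll)
                    + (prop_rate_prior - cur_rate_prior)
                    + log_hastings
                )
                if log_alpha >= 0.0 or math.log(rng.uniform()) < log_alpha:
                    current, cur_ll, cur_rate_prior = prop, prop_ll, prop_rate_prior
                    accepted_counts[move] = accepted_counts.get(move, 0) + 1
        if gen > config.burn_in and (gen - config.burn_in) % config.sample_interval == 0:
            roots = ctx.root_marginals(build_rate_matrix(current), prior)
            samples.append(
                ModelSample(current.copy(), cur_ll, roots, generation=gen)
            )
    acceptance = {
        m: accepted_counts.get(m, 0) / n for m, n in proposed_counts.items()
    }
    ln_hm = harmonic_mean_logml([s.log_likelihood for s in samples])
    return ChainResult(samples=samples, ln_hm=ln_hm, acceptance=acceptance,
                       seed=config.seed)


@dataclass
class MultiChainResult:
    chains: list[ChainResult]
    converged: bool
    max_lnhm_diff: float
    ljung_box_p: float | None = None
    thinned: bool = False
    pooled: list[ModelSample] = field(default_factory=list)


def run_chains(
    tree: Phylogeny,
    column: TraitColumn,
    config: ChainConfig,
    states: Sequence[str] | None = None,
    root_prior: np.ndarray | None = None,
    screen_autocorrelation: bool = True,
) -> MultiChainResult:
    """Run ``n_chains`` independent chains (seed = base seed + index).

    Cross-run agreement of the harmonic-mean marginal likelihood (< 1 lnHM)
    is the convergence criterion; the pooled post-burn-in sample is screened
    for lag-1 autocorrelation of the log-likelihood series and thinned to
    every 10th draw when the Ljung–Box test rejects at 5 %.
    """
    from .states import STATE_ORDER

    states = tuple(states) if states is not None else STATE_ORDER
    ctx = PruningContext(tree, column, states)
    if config.hyper_interval is None:
        mean, sd = empirical_bayes_interval(
            tree, column, states, root_prior=root_prior, seed=config.seed
        )
        config = ChainConfig(**{**config.__dict__, "hyper_interval": (mean, sd)})
    initial = _initial_configuration(ctx, tree, column, root_prior, config.seed)
    chains = []
    for i in range(config.n_chains):
        cfg_i = ChainConfig(**{**config.__dict__, "seed": config.seed + i})
        chains.append(
            run_chain(tree, column, cfg_i, states=states, root_prior=root_prior,
                      _context=ctx, _initial=initial)
        )
    if len(chains) >= 2:
        converged, diff = check_convergence(
            [c.ln_hm for c in chains], threshold=config.convergence_threshold
        )
    else:
        logger.warning("single chain: convergence check skipped")
        converged, diff = True, 0.0
    pooled = [s for c in chains for s in c.samples]
    lb_p: float | None = None
    thinned = False
    if screen_autocorrelation and len(pooled) > 2:
        series = np.array([s.log_likelihood for s in pooled])
        if np.ptp(series) > 0:
            _, lb_p = ljung_box(series, lag=1)
            if lb_p <= 0.05:
                pooled = thin(pooled, 10)
                thinned = True
    return MultiChainResult(
        chains=chains, converged=converged, max_lnhm_diff=diff,
        ljung_box_p=lb_p, thinned=thinned, pooled=pooled,
    )


# ---------------------------------------------------------------------
# chain statistics


def harmonic_mean_logml(logliks: Sequence[float]) -> float:
    """Harmonic-mean estimate of the log marginal likelihood.

    lnHM = -(logsumexp(-lnL) - log n), computed in log space.  Known to be
    unstable in general; used here as the cross-run convergence statistic.
    """
    if len(logliks) == 0:
        raise ValueError("no log-likelihood samples")
    arr = np.asarray(logliks, dtype=float)
    return float(-(logsumexp(-arr) - math.log(len(arr))))


def check_convergence(
    ln_hms: Sequence[float], threshold: float = 1.0
) -> tuple[bool, float]:
    """Converged iff all pairwise lnHM differences are below ``threshold``."""
    if len(ln_hms) < 2:
        raise ValueError("need at least 2 runs to assess convergence")
    arr = np.asarray(ln_hms, dtype=float)
    diff = float(arr.max() - arr.min())
    return diff < threshold, diff


def ljung_box(series: Sequence[float], lag: int = 1) -> tuple[float, float]:
    """Ljung–Box portmanteau test for autocorrelation up to ``lag``.

    Q = n(n+2) Σ_{h<=lag} r_h^2 / (n-h), compared to chi-square(lag).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if lag < 1 or n <= lag:
        raise ValueError("need series length > lag >= 1")
    centered = x - x.mean()
    denom = float(centered @ centered)
    if denom == 0.0:
        raise ValueError("autocorrelation undefined for a constant series")
    q = 0.0
    for h in range(1, lag + 1):
        r_h = float(centered[h:] @ centered[:-h]) / denom
        q += r_h * r_h / (n - h)
    q *= n * (n + 2.0)
    return q, float(chi2.sf(q, df=lag))


def thin(samples: Sequence, k: int) -> list:
    """Every k-th sample, preserving visit order."""
    if k < 1:
        raise ValueError("thinning factor must be >= 1")
    return list(samples)[::k]
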