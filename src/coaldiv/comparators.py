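"""Summary statistics and branch-length-distribution comparators.

Contains the Pybus-Harvey gamma statistic (standard normal under the Yule
process; negative when nodes crowd toward the root) and a comparator that
fits classical distributions (exponential, Weibull, lognormal, normal) to the
internal branch lengths of a tree. Of these families only the Weibull implies
a speciation rate that changes with lineage age, so the comparator serves as a
benchmark for how much signal about time-varying rates survives in branch
lengths alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .inference import FitResult, aicc
from .treeio import CoalescentTimes, PhyloTree, coalescent_times

__all__ = [
    "BranchLengthSample",
    "DistFit",
    "FAMILIES",
    "gamma_statistic",
    "extract_internal_branch_lengths",
    "fit_branch_length_distribution",
    "venditti_model_selection",
    "gamma_posterior_quantile",
]

FAMILIES = ("exponential", "weibull", "lognormal", "normal")

#: families under which speciation is effectively constant-rate
CONSTANT_RATE_FAMILIES = frozenset({"exponential", "lognormal", "normal"})


def gamma_statistic(
    times: CoalescentTimes, terminal_interval: Optional[float] = None
) -> float:
    """Pybus-Harvey gamma of an ultrametric tree.

    Unlike the model likelihood, gamma uses every inter-node interval
    including the terminal one (most recent node to present); pass
    ``terminal_interval`` to override the value stored on *times*.

    With g_k the interval during which k lineages exist (k = 2..n) and
    T_i = sum_{k<=i} k*g_k, T = T_n:

        gamma = [ mean_{i=2..n-1} T_i - T/2 ] / [ T * sqrt(1/(12(n-2))) ]
    """
    n = times.n
    if n < 3:
        raise ValueError("gamma requires n >= 3 tips")
    term = times.terminal_interval if terminal_interval is None else terminal_interval
    g = np.concatenate([times.internode_distances, [term]])  # g_2 .. g_n
    ks = np.arange(2, n + 1)
    t_cum = np.cumsum(ks * g)  # T_2 .. T_n
    total = t_cum[-1]
    inner = t_cum[:-1].mean()  # mean of T_2 .. T_{n-1}
    return float((inner - total / 2.0) / (total * math.sqrt(1.0 / (12 * (n - 2)))))


@dataclass
class BranchLengthSample:
    """Internal branch lengths of a tree (terminal and root branches excluded,
    since neither is delimited by two speciation events)."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths <= 0):
            raise ValueError("internal branch lengths must be positive")

    @property
    def count(self) -> int:
        return len(self.lengths)


def extract_internal_branch_lengths(tree: PhyloTree) -> BranchLengthSample:
    lengths = [
        e.length
        for e in tree.tree.preorder_edge_iter()
        if e.tail_node is not None and not e.head_node.is_leaf()
    ]
    return BranchLengthSample(np.asarray(lengths))


@dataclass
class DistFit:
    family: str
    params: Dict[str, float]
    log_likelihood: float
    k: int
    n_obs: int
    aicc: float


def _weibull_negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    shape, scale = math.exp(theta[0]), math.exp(theta[1])
    return -float(np.sum(stats.weibull_min.logpdf(x, shape, scale=scale)))


def fit_branch_length_distribution(
    sample: BranchLengthSample, family: str
) -> DistFit:
    """ML fit of one distribution family to internal branch lengths.

    Closed-form MLEs are used where they exist (exponential, normal,
    lognormal); the Weibull is fitted by Nelder-Mead on log-transformed
    shape and scale, started from the exponential special case.
    """
    x = sample.lengths
    n = sample.count
    if family == "exponential":
        k = 1
        rate = 1.0 / x.mean()
        ll = float(n * math.log(rate) - rate * x.sum())
        params = {"rate": rate}
    elif family == "normal":
        k = 2
        mu, sigma = float(x.mean()), float(x.std(ddof=0))
        ll = float(np.sum(stats.norm.logpdf(x, loc=mu, scale=sigma)))
        params = {"mean": mu, "sd": sigma}
    elif family == "lognormal":
        k = 2
        logs = np.log(x)
        mu, sigma = float(logs.mean()), float(logs.std(ddof=0))
        ll = float(np.sum(stats.lognorm.logpdf(x, sigma, scale=math.exp(mu))))
        params = {"meanlog": mu, "sdlog": sigma}
    elif family == "weibull":
        k = 2
        x0 = np.array([0.0, math.log(x.mean())])  # shape=1: the exponential
        res = optimize.minimize(
            _weibull_negloglik,
            x0,
            args=(x,),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        ll = -float(res.fun)
        params = {"shape": math.exp(res.x[0]), "scale": math.exp(res.x[1])}
    else:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if n <= k + 1:
        raise ValueError(f"too few branches ({n}) for a {k}-parameter family")
    return DistFit(
        family=family,
        params=params,
        log_likelihood=ll,
        k=k,
        n_obs=n,
        aicc=aicc(ll, k, n),
    )


def venditti_model_selection(
    tree: PhyloTree,
) -> Tuple[str, Dict[str, DistFit]]:
    """Best-fitting branch-length distribution family by AICc.

    Extracts the internal branch lengths and fits all four families;
    deterministic given the tree (the only optimizer involved starts from a
    fixed point). Requires at least 5 internal branches.
    """
    sample = extract_internal_branch_lengths(tree)
    if sample.count < 5:
        raise ValueError(
            f"need >= 5 internal branches, found {sample.count}"
        )
    table = {
        fam: fit_branch_length_distribution(sample, fam) for fam in FAMILIES
    }
    best = min(table, key=lambda fam: (table[fam].aicc, table[fam].k))
    return best, table


def gamma_posterior_quantile(
    times: CoalescentTimes,
    fit: FitResult,
    f: float = 1.0,
    reps: int = 100,
    seed: Optional[int] = None,
) -> float:
    """Posterior-predictive check of a fitted model via the gamma statistic.

    Simulates ``reps`` phylogenies from the fitted model (clade size n0 from
    the fit, subsampled at the empirical sampling fraction f) and returns the
    quantile of the observed gamma within the simulated gamma distribution.
    Values near 0 or 1 flag a best-fit model whose branch-length patterns are
    unrealistic; mid-range values mean the model reproduces the observed
    node-depth profile.
    """
    # imported here to avoid a circular import at module load
    from . import simulate as _sim
    from .models import net_diversification_integral

    rng = np.random.default_rng(seed)
    spec = fit.spec
    n0 = spec.n0
    obs = gamma_statistic(times)
    sims = []
    if spec.model_id in ("M1", "M2"):
        duration = None
    else:
        # clade age under the fitted model: expected diversity reaches one
        # species at the root
        target = math.log(n0)

        def shortfall(t: float) -> float:
            return float(net_diversification_integral(spec, t)) - target

        hi = times.root_age
        while shortfall(hi) < 0 and hi < 1e3 * times.root_age:
            hi *= 2.0
        if shortfall(hi) < 0:
            raise ValueError(
                "fitted model never contracts to a single ancestor; "
                "no natural clade age for simulation"
            )
        duration = float(optimize.brentq(shortfall, 1e-12, hi))
    while len(sims) < reps:
        s = int(rng.integers(0, 2**31 - 1))
        if spec.model_id in ("M1", "M2"):
            sim = _sim.simulate_saturated(
                int(round(n0)), spec.tau0, gamma=spec.gamma, seed=s
            )
        else:
            sim = _sim.simulate_birth_death_conditioned(
                spec, duration, seed=s, min_tips=max(3, math.ceil(3 / f))
            )
        sub = _sim.sample_tips(sim.tree, f, seed=s)
        sims.append(gamma_statistic(coalescent_times(sub)))
    sims_arr = np.asarray(sims)
    return float(np.mean(sims_arr < obs))
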