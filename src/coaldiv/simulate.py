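"""Forward-time simulation of phylogenies under the nine diversification models.

Two simulators are provided, following the generating processes the models
describe:

* a Moran-style turnover simulator for the saturated-diversity models (M1,
  M2): N0 lineages, turnover events (one uniform-random lineage dies, another
  uniform-random lineage bifurcates) at total rate N0 * tau(t), waiting times
  drawn from the exponential distribution with the rate evaluated at the
  previous event;
* a birth-death simulator for the expanding-diversity models (M3-M6): starting
  from a single lineage, events at total rate N * (lambda + mu) evaluated at
  the previous event, each event a bifurcation with probability
  lambda/(lambda+mu) and an extinction otherwise.

Evaluating rates at the previous event (rather than exact thinning of the
inhomogeneous process) is a deliberate fidelity trade-off: per-event rate
changes are small in the parameter ranges used, and the scheme is exact for
the constant-rate models.

Reconstructed trees (extinct lineages pruned) are exactly ultrametric, with
all tips at the stop time. Random tip subsampling emulates incompletely
sampled phylogenies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from . import models as _m
from .coalescent import DEFAULT_KAPPA
from .inference import compare_models
from .models import ModelSpec
from .treeio import PhyloTree, coalescent_times, tree_from_string

__all__ = [
    "SimTree",
    "ExperimentConfig",
    "simulate_saturated",
    "simulate_birth_death",
    "simulate_birth_death_conditioned",
    "simulate_yule",
    "sample_tips",
    "moran_pair_coalescence_times",
    "run_classification_experiment",
    "summarize_classification",
    "DECAYING_SPECIATION",
]

logger = logging.getLogger("coaldiv.simulate")

#: models featuring a speciation rate that decays toward the present
DECAYING_SPECIATION = frozenset({"M4a", "M4c", "M4d", "M6"})


@dataclass
class SimTree:
    """A simulated phylogeny with its true generating parameters attached."""

    spec: ModelSpec
    seed: Optional[int]
    tree: Optional[PhyloTree]  # reconstructed (extinct lineages pruned)
    n_extant: int
    duration: float
    extinct: bool = False
    polytomy_unresolved: bool = False
    subsampled: Optional[PhyloTree] = None
    sampling_fraction: float = 1.0
    n_events: int = 0
    history: Optional[np.ndarray] = None  # event times, if requested


class _Chain:
    """Lineage node used during backward reconstruction of the Moran genealogy."""

    __slots__ = ("depth", "children", "label")

    def __init__(self, depth: float, children=None, label: Optional[str] = None):
        self.depth = depth  # time before present
        self.children = children or []
        self.label = label


def _newick_from_chain(root: _Chain) -> str:
    """Iterative post-order Newick rendering (avoids deep recursion)."""
    out: Dict[int, str] = {}
    stack: List = [(root, False)]
    while stack:
        node, visited = stack.pop()
        if node.children and not visited:
            stack.append((node, True))
            stack.extend((c, False) for c in node.children)
            continue
        if not node.children:
            out[id(node)] = node.label
        else:
            parts = [
                f"{out.pop(id(c))}:{c_depth_fmt(node.depth - c.depth)}"
                for c in node.children
            ]
            out[id(node)] = "(" + ",".join(parts) + ")"
    return out[id(root)] + ";"


def c_depth_fmt(x: float) -> str:
    return format(max(float(x), 0.0), ".17g")


def simulate_saturated(
    n0: int,
    tau0: float,
    gamma: float = 0.0,
    duration: Optional[float] = None,
    seed: Optional[int] = None,
    max_extensions: int = 3,
    keep_history: bool = False,
) -> SimTree:
    """Simulate the Moran-style turnover process (Models 1 and 2).

    N0 lineages hang from a root polytomy; turnover events (extinction
    immediately followed by a speciation) occur at total rate N0 * tau(t),
    with tau(t) = tau0 * exp(gamma * t) in time before present. The default
    run length is 10 * N0 / tau0 (about ten expected times to the sample's
    common ancestor); if the initial polytomy has not fully resolved within
    the run the simulation is re-run with doubled duration, up to
    ``max_extensions`` times, after which the result is flagged.

    The reconstructed tree of the N0 extant species is returned; the lineage
    count is exactly N0 at all times by construction.
    """
    if n0 < 2:
        raise ValueError("N0 must be >= 2")
    if tau0 <= 0 or (duration is not None and duration <= 0):
        raise ValueError("tau0 and duration must be positive")
    if duration is None:
        duration = 10.0 * n0 / tau0
    rng = np.random.default_rng(seed)

    # forward event times on [0, duration]
    if gamma == 0.0:
        # homogeneous Poisson process: exact vectorized generation
        n_events = rng.poisson(n0 * tau0 * duration)
        event_times = np.sort(rng.uniform(0.0, duration, n_events))
    else:
        ts = []
        t = 0.0
        while True:
            tbp_prev = duration - t
            rate = n0 * tau0 * math.exp(gamma * tbp_prev)
            t += rng.exponential(1.0 / rate)
            if t > duration:
                break
            ts.append(t)
        event_times = np.asarray(ts)
        n_events = len(ts)

    dies = rng.integers(0, n0, n_events)
    parents = (dies + 1 + rng.integers(0, n0 - 1, n_events)) % n0

    # walk events backwards from the present, merging lineages; stop at MRCA
    active: List[Optional[_Chain]] = [
        _Chain(0.0, label=f"t{i + 1}") for i in range(n0)
    ]
    n_anc = n0
    root: Optional[_Chain] = None
    for i in range(n_events - 1, -1, -1):
        d, p = int(dies[i]), int(parents[i])
        a, b = active[d], active[p]
        if a is not None and b is not None:
            node = _Chain(duration - event_times[i], [a, b])
            active[p] = node
            n_anc -= 1
            if n_anc == 1:
                root = node
                break
        elif a is not None:
            active[p] = a
        active[d] = None

    unresolved = root is None
    if unresolved and max_extensions > 0:
        logger.info(
            "root polytomy unresolved after duration %.3g; extending", duration
        )
        return simulate_saturated(
            n0,
            tau0,
            gamma=gamma,
            duration=2.0 * duration,
            seed=seed,
            max_extensions=max_extensions - 1,
            keep_history=keep_history,
        )
    if unresolved:
        remaining = [c for c in active if c is not None]
        root = _Chain(duration, remaining)

    tree = tree_from_string(_newick_from_chain(root))
    tree.n0 = float(n0)
    spec = ModelSpec("M1" if gamma == 0.0 else "M2", n0=n0, tau0=tau0, gamma=gamma)
    return SimTree(
        spec=spec,
        seed=seed,
        tree=tree,
        n_extant=n0,
        duration=duration,
        polytomy_unresolved=unresolved,
        n_events=int(n_events),
        history=event_times if keep_history else None,
    )


class _Lineage:
    __slots__ = ("start", "end", "children", "survived")

    def __init__(self, start: float):
        self.start = start  # forward time of birth
        self.end: Optional[float] = None
        self.children: List["_Lineage"] = []
        self.survived = False


def _render_reconstructed(node: _Lineage, duration: float):
    """Prune extinct subtrees and suppress pass-through lineages.

    Returns (newick fragment, forward time of the fragment's top event) or
    None when no descendant survives. Iterative to tolerate long event chains.
    """
    # post-order over the lineage tree
    result: Dict[int, Optional[tuple]] = {}
    stack: List = [(node, False)]
    counter = [0]
    while stack:
        nd, visited = stack.pop()
        if nd.children and not visited:
            stack.append((nd, True))
            stack.extend((c, False) for c in nd.children)
            continue
        if not nd.children:
            if nd.survived:
                counter[0] += 1
                result[id(nd)] = (f"t{counter[0]}", duration)
            else:
                result[id(nd)] = None
        else:
            kept = [
                r for r in (result.pop(id(c)) for c in nd.children) if r is not None
            ]
            if not kept:
                result[id(nd)] = None
            elif len(kept) == 1:
                result[id(nd)] = kept[0]
            else:
                (f1, e1), (f2, e2) = kept
                s = nd.end
                result[id(nd)] = (
                    f"({f1}:{c_depth_fmt(e1 - s)},{f2}:{c_depth_fmt(e2 - s)})",
                    s,
                )
    return result[id(node)]


def simulate_birth_death(
    spec: ModelSpec,
    duration: float,
    seed: Optional[int] = None,
    keep_history: bool = False,
) -> SimTree:
    """Simulate a birth-death phylogeny (Models 3-6) forward in time.

    Starts from a single lineage; waiting times are exponential with total
    rate N * (lambda + mu) evaluated at the previous event; each event
    bifurcates a uniform-random lineage with probability lambda/(lambda+mu)
    and kills one otherwise. Extinct subtrees are pruned from the returned
    reconstructed tree. A clade that dies out (or leaves a single species) is
    returned with ``extinct=True`` and no tree; callers conditioning on
    survival should discard and resimulate (see
    :func:`simulate_birth_death_conditioned`).
    """
    if spec.model_id not in ("M3", "M4a", "M4b", "M4c", "M4d", "M5", "M6"):
        raise ValueError(
            "birth-death simulation applies to the expanding-diversity models"
        )
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    root = _Lineage(0.0)
    active = [root]
    t = 0.0
    n_events = 0
    times = [] if keep_history else None
    while active:
        tbp_prev = duration - t
        lam = float(_m.rates_at(spec, tbp_prev)[0])
        mu = float(_m.rates_at(spec, tbp_prev)[1])
        total = len(active) * (lam + mu)
        if total <= 0:
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next > duration:
            break
        idx = int(rng.integers(len(active)))
        nd = active[idx]
        nd.end = t_next
        n_events += 1
        if times is not None:
            times.append(t_next)
        if rng.random() < lam / (lam + mu):
            c1, c2 = _Lineage(t_next), _Lineage(t_next)
            nd.children = [c1, c2]
            active[idx] = c1
            active.append(c2)
        else:
            active[idx] = active[-1]
            active.pop()
        t = t_next

    for nd in active:
        nd.end = duration
        nd.survived = True
    n_extant = len(active)

    if n_extant < 2:
        return SimTree(
            spec=spec,
            seed=seed,
            tree=None,
            n_extant=n_extant,
            duration=duration,
            extinct=True,
            n_events=n_events,
            history=np.asarray(times) if times is not None else None,
        )
    frag, e_top = _render_reconstructed(root, duration)
    tree = tree_from_string(frag + ";")
    tree.n0 = float(n_extant)
    return SimTree(
        spec=spec,
        seed=seed,
        tree=tree,
        n_extant=n_extant,
        duration=duration,
        n_events=n_events,
        history=np.asarray(times) if times is not None else None,
    )


def simulate_birth_death_conditioned(
    spec: ModelSpec,
    duration: float,
    seed: Optional[int] = None,
    min_tips: int = 3,
    max_tries: int = 1000,
) -> SimTree:
    """Resimulate until the clade survives with at least ``min_tips`` species.

    Mirrors the usual conditioning on survival to the present; the number of
    discarded replicates is logged.
    """
    rng = np.random.default_rng(seed)
    discarded = 0
    for _ in range(max_tries):
        sim = simulate_birth_death(
            spec, duration, seed=int(rng.integers(0, 2**31 - 1))
        )
        if not sim.extinct and sim.n_extant >= min_tips:
            if discarded:
                logger.debug("discarded %d extinct/small replicates", discarded)
            return sim
        discarded += 1
    raise RuntimeError(
        f"no surviving clade with >= {min_tips} tips in {max_tries} tries"
    )


def simulate_yule(
    n_tips: int, lam0: float, seed: Optional[int] = None
) -> SimTree:
    """Pure-birth tree with exactly ``n_tips`` tips.

    Grown forward at per-lineage rate lam0; the present is placed a fresh
    Exp(n * lam0) waiting time after the last split (the memoryless residual
    before the next, unobserved, split), so every inter-node interval has its
    textbook exponential law.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if lam0 <= 0:
        raise ValueError("lam0 must be positive")
    rng = np.random.default_rng(seed)
    root = _Lineage(0.0)
    active = [root]
    t = 0.0
    for k in range(1, n_tips):
        t += rng.exponential(1.0 / (k * lam0))
        idx = int(rng.integers(len(active)))
        nd = active[idx]
        nd.end = t
        c1, c2 = _Lineage(t), _Lineage(t)
        nd.children = [c1, c2]
        active[idx] = c1
        active.append(c2)
    duration = t + rng.exponential(1.0 / (n_tips * lam0))
    for nd in active:
        nd.end = duration
        nd.survived = True
    frag, _ = _render_reconstructed(root, duration)
    tree = tree_from_string(frag + ";")
    tree.n0 = float(n_tips)
    return SimTree(
        spec=ModelSpec("M5", n0=n_tips, lam0=lam0),
        seed=seed,
        tree=tree,
        n_extant=n_tips,
        duration=duration,
        n_events=n_tips - 1,
    )


def sample_tips(tree: PhyloTree, f: float, seed: Optional[int] = None) -> PhyloTree:
    """Retain a uniform random fraction f of tips (ceil(f*n), no replacement).

    Unsampled lineages are pruned and pass-through nodes suppressed, which
    lengthens the surviving terminal branches, exactly as incomplete taxon
    sampling does to real phylogenies.
    """
    if not 0 < f <= 1:
        raise ValueError("sampling fraction f must be in (0, 1]")
    n = tree.n_tips
    m = math.ceil(f * n)
    if m < 3:
        raise ValueError(f"subsampled tree would have {m} < 3 tips")
    if m == n:
        work = tree.tree.clone(depth=1)
        return PhyloTree(
            tree=work,
            n0=tree.n0,
            sampling_fraction=1.0,
            is_binary=tree.is_binary,
            depth_discrepancy=tree.depth_discrepancy,
        )
    rng = np.random.default_rng(seed)
    leaves = tree.tree.leaf_nodes()
    keep_idx = rng.choice(n, size=m, replace=False)
    keep_taxa = [leaves[i].taxon for i in keep_idx]
    work = tree.tree.clone(depth=1)
    keep_labels = {tx.label for tx in keep_taxa}
    work.retain_taxa_with_labels(list(keep_labels))
    return PhyloTree(
        tree=work,
        n0=tree.n0,
        sampling_fraction=m / n if tree.n0 is None else m / tree.n0,
        is_binary=True,
        depth_discrepancy=tree.depth_discrepancy,
    )


def moran_pair_coalescence_times(
    n0: int,
    tau0: float,
    reps: int = 10_000,
    seed: Optional[int] = None,
    max_steps: int = 10_000_000,
) -> np.ndarray:
    """Monte-Carlo coalescence times of a lineage pair in the turnover process.

    Generates the (time-reversible, for constant tau) event stream of the
    Moran-style simulator backwards from the present and tracks two sampled
    lineages until they merge. Used to calibrate the kernel convention
    constant: the empirical pair-merger rate is 2*tau0/(N0-1), which the
    kernel's rho_2 = kappa * tau0/N0 matches with kappa = 2 (up to the
    O(1/N0) finite-size factor).
    """
    if n0 < 3:
        raise ValueError("need N0 >= 3")
    rng = np.random.default_rng(seed)
    a = np.zeros(reps, dtype=np.int64)
    b = np.ones(reps, dtype=np.int64)
    t = np.zeros(reps)
    out = np.full(reps, np.nan)
    alive = np.ones(reps, dtype=bool)
    steps = 0
    while alive.any():
        if steps > max_steps:
            raise RuntimeError("pair coalescence did not complete")
        t = t + rng.exponential(1.0 / (n0 * tau0), reps)
        d = rng.integers(0, n0, reps)
        p = (d + 1 + rng.integers(0, n0 - 1, reps)) % n0
        hit_a = alive & (d == a)
        hit_b = alive & (d == b)
        a = np.where(hit_a, p, a)
        b = np.where(hit_b, p, b)
        merged = alive & (a == b)
        out[merged] = t[merged]
        alive &= ~merged
        steps += 1
    return out


@dataclass
class ExperimentConfig:
    """Configuration of a batch model-classification experiment."""

    model_id: str
    params: Dict[str, float]
    n0: int = 100  # clade size for saturated models
    duration: Optional[float] = None
    reps: int = 100
    f: float = 1.0
    seed: Optional[int] = None
    restarts: int = 10
    kappa: float = DEFAULT_KAPPA
    fit_models: Iterable[str] = _m.MODEL_IDS


def run_classification_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate, subsample, fit all candidate models and tabulate winners.

    Returns one row per replicate with the generating seed, tip counts, the
    lowest-AICc model, and the three partition outcomes. Fit failures are
    recorded per replicate (best_model = None), not raised.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.reps):
        sim_seed = int(rng.integers(0, 2**31 - 1))
        if config.model_id in ("M1", "M2"):
            sim = simulate_saturated(
                n0=config.n0,
                tau0=config.params.get("tau0", 1.0),
                gamma=config.params.get("gamma", 0.0),
                duration=config.duration,
                seed=sim_seed,
            )
        else:
            spec = ModelSpec(config.model_id, n0=1, **config.params)
            # after subsampling, the largest candidate model (4 parameters)
            # needs n - 2 > 5 internode distances, i.e. at least 8 tips
            sim = simulate_birth_death_conditioned(
                spec,
                duration=config.duration,
                seed=sim_seed,
                min_tips=math.ceil(8 / config.f),
            )
        tree = sim.tree
        n_clade = sim.n_extant
        sub_seed = int(rng.integers(0, 2**31 - 1))
        subtree = sample_tips(tree, config.f, seed=sub_seed)
        times = coalescent_times(subtree)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        row = {
            "rep": rep,
            "sim_seed": sim_seed,
            "n_clade": n_clade,
            "n_tips": subtree.n_tips,
        }
        try:
            comp = compare_models(
                times,
                n0=n_clade,
                model_ids=config.fit_models,
                seed=fit_seed,
                restarts=config.restarts,
                kappa=config.kappa,
            )
        except Exception as exc:  # record, don't abort the batch
            logger.warning("replicate %d fit failed: %s", rep, exc)
            row.update(
                best_model=None,
                saturated=None,
                constant_rates=None,
                with_extinction=None,
                decaying_speciation=None,
                extinction_fraction=None,
            )
            rows.append(row)
            continue
        best = comp.best_id
        row.update(
            best_model=best,
            saturated=best in _m.SATURATED,
            constant_rates=best in _m.CONSTANT_RATES,
            with_extinction=best in _m.WITH_EXTINCTION,
            decaying_speciation=best in DECAYING_SPECIATION,
            extinction_fraction=comp.extinction_fraction,
        )
        rows.append(row)
    columns = [
        "rep",
        "sim_seed",
        "n_clade",
        "n_tips",
        "best_model",
        "saturated",
        "constant_rates",
        "with_extinction",
        "decaying_speciation",
        "extinction_fraction",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_classification(df: pd.DataFrame) -> Dict:
    """Best-model counts and partition-winner counts from an experiment table."""
    ok = df[df["best_model"].notna()] if len(df) else df
    best_counts = (
        ok["best_model"].value_counts().to_dict() if len(ok) else {}
    )
    return {
        "replicates": int(len(df)),
        "fitted": int(len(ok)),
        "best_counts": {mid: int(best_counts.get(mid, 0)) for mid in _m.MODEL_IDS},
        "saturated": int(ok["saturated"].sum()) if len(ok) else 0,
        "constant_rates": int(ok["constant_rates"].sum()) if len(ok) else 0,
        "with_extinction": int(ok["with_extinction"].sum()) if len(ok) else 0,
        "decaying_speciation": int(ok["decaying_speciation"].sum())
        if len(ok)
        else 0,
    }
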