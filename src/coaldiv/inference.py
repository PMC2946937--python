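"""Maximum-likelihood fitting and AICc-based model selection.

Each of the nine diversification models is fitted to the internode distances
of one tree by multi-start Nelder-Mead on transformed parameters (rates on a
log scale, the extinction fraction on a logit scale, exponential-variation
coefficients untransformed). Model support is summarized by AICc and Akaike
weights, and three competing hypothesis pairs are evaluated by comparing the
best model within each subset: expanding vs. saturated diversity, time-varying
vs. constant rates, and extinction present vs. absent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from . import models as _m
from .coalescent import DEFAULT_KAPPA, log_likelihood
from .models import MODEL_IDS, MODEL_PARAMS, ModelSpec
from .treeio import CoalescentTimes

__all__ = [
    "FitResult",
    "ModelComparison",
    "FitError",
    "aicc",
    "akaike_weights",
    "fit_model",
    "compare_models",
    "hypothesis_probability",
    "extinction_fraction_at_present",
    "tau0_mle_hey",
    "PARTITIONS",
]

logger = logging.getLogger("coaldiv.inference")

#: the three hypothesis partitions, each (name, subset_A, subset_B)
PARTITIONS: Dict[str, Tuple[frozenset, frozenset]] = {
    "diversity": (_m.EXPANDING, _m.SATURATED),
    "rates": (_m.VARYING_RATES, _m.CONSTANT_RATES),
    "extinction": (_m.WITH_EXTINCTION, _m.WITHOUT_EXTINCTION),
}

_PENALTY = 1e8
_LOG_BOUND = 50.0  # |transformed parameter| beyond this is treated as divergent


class FitError(RuntimeError):
    """Raised when no optimizer restart produced a finite likelihood."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass
class FitResult:
    """Maximized likelihood of one model on one tree."""

    model_id: str
    spec: ModelSpec
    log_likelihood: float
    k: int
    n_obs: int
    aicc: float
    diagnostics: Dict = field(default_factory=dict)

    @property
    def params(self) -> Dict[str, float]:
        return self.spec.params()


def aicc(logL: float, k: int, n_obs: int) -> float:
    """Second-order Akaike Information Criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n_obs - k - 1), where n_obs is the number
    of observations entering the likelihood (here, internode distances).
    """
    if n_obs <= k + 1:
        raise ValueError(
            f"AICc undefined: n_obs={n_obs} must exceed k+1={k + 1}"
        )
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Normalized exp(-ΔAICc/2); infinite AICc values receive weight 0."""
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("all AICc values are infinite")
    best = a[finite].min()
    with np.errstate(over="ignore"):
        raw = np.where(finite, np.exp(-(a - best) / 2.0), 0.0)
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# parameter transforms


def _to_spec(model_id: str, theta: np.ndarray, n0: float) -> Optional[ModelSpec]:
    """Map transformed optimizer coordinates to a ModelSpec, or None if the
    coordinates are out of numeric range."""
    if np.any(np.abs(theta) > _LOG_BOUND):
        return None
    kwargs: Dict[str, float] = {}
    for name, x in zip(MODEL_PARAMS[model_id], theta):
        if name in ("tau0", "lam0", "mu0"):
            kwargs[name] = math.exp(x)
        elif name == "eps":
            kwargs[name] = float(expit(x))
        else:  # alpha, beta, gamma
            kwargs[name] = float(x)
    return ModelSpec(model_id=model_id, n0=n0, **kwargs)


def _from_params(model_id: str, params: Dict[str, float]) -> np.ndarray:
    out = []
    for name in MODEL_PARAMS[model_id]:
        v = params[name]
        if name in ("tau0", "lam0", "mu0"):
            out.append(math.log(v))
        elif name == "eps":
            out.append(float(logit(min(max(v, 1e-12), 1 - 1e-12))))
        else:
            out.append(v)
    return np.asarray(out, dtype=float)


def tau0_mle_hey(
    times: CoalescentTimes, n0: float, kappa: float = DEFAULT_KAPPA
) -> float:
    """Closed-form MLE of the turnover rate under the Hey/Moran model.

    The internode distances are independent exponentials with rates
    kappa*C(j,2)*tau0/N0, so tau0_hat = (n-2) * N0 / (kappa * sum C(j,2) g_j).
    """
    js = np.arange(2, times.n)
    pairs = js * (js - 1) / 2.0
    denom = kappa * float(np.sum(pairs * times.internode_distances))
    return (times.n - 2) * n0 / denom


def _mu_from_net(lam0: float, net: float, rng=None) -> float:
    """Extinction rate giving the requested net diversification, if admissible."""
    mu = lam0 - net
    if mu <= 0:
        frac = 0.5 if rng is None else float(rng.uniform(0.1, 0.9))
        mu = lam0 * frac
    return mu


def _initial_points(
    model_id: str,
    times: CoalescentTimes,
    n0: float,
    kappa: float,
    restarts: int,
    rng: np.random.Generator,
) -> list:
    """Heuristic starts plus log-uniform random restarts.

    Two rate scales anchor the starts: the Hey-model MLE r0 (the scale of the
    per-lineage coalescence rate the data imply) and the net diversification
    rate ln(N0)/root_age that a clade growing from one ancestor to N0 species
    over the observed root age would need. The latter matters because for
    models with extinction the likelihood is only finite while N(t) stays
    above zero over the whole tree: admissible extinction rates live close to
    lam0 - ln(N0)/root_age.
    """
    r0 = tau0_mle_hey(times, n0, kappa)
    t_scale = 1.0 / times.root_age
    r_net = math.log(n0) / times.root_age
    base = {"alpha": 0.0, "beta": 0.0, "gamma": 0.0}
    heuristics = [
        # growth from a single ancestor at the observed net rate
        {
            **base,
            "tau0": r0,
            "lam0": r0,
            "mu0": _mu_from_net(r0, r_net),
            "eps": min(max(1.0 - r_net / r0, 0.01), 0.99),
        },
        # extinction-free start
        {**base, "tau0": r0, "lam0": max(r_net, 0.1 * r0), "mu0": 1e-8 * r0,
         "eps": 0.01},
    ]
    points = [_from_params(model_id, h) for h in heuristics[: max(restarts, 1)]]
    for _ in range(max(restarts - len(points), 0)):
        lam0 = r0 * 10 ** rng.uniform(-1, 1)
        net = r_net * 10 ** rng.uniform(-1, 1)
        draw = {
            "tau0": lam0,
            "lam0": lam0,
            "mu0": _mu_from_net(lam0, net, rng),
            "alpha": rng.uniform(-2, 2) * t_scale,
            "beta": rng.uniform(-2, 2) * t_scale,
            "gamma": rng.uniform(-2, 2) * t_scale,
            "eps": min(max(1.0 - net / lam0, 0.01), 0.99),
        }
        points.append(_from_params(model_id, draw))
    return points


def fit_model(
    model_id: str,
    times: CoalescentTimes,
    n0: float,
    seed: Optional[int] = None,
    restarts: int = 10,
    kappa: float = DEFAULT_KAPPA,
) -> FitResult:
    """Fit one model to one tree by multi-start Nelder-Mead.

    The speciation>=extinction constraint is enforced through a penalty so the
    simplex can recover from infeasible regions. Raises FitError if every
    restart diverges, and ValueError when n_obs <= k+1 (too few internode
    distances to support the model's parameter count).
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    if n0 < times.n:
        raise ValueError("N0 must be at least the number of sampled tips")
    k = len(MODEL_PARAMS[model_id])
    n_obs = times.n - 2
    if n_obs <= k + 1:
        raise ValueError(
            f"insufficient data for model {model_id}: "
            f"n_obs={n_obs} <= k+1={k + 1}"
        )
    rng = np.random.default_rng(seed)
    root_age = times.root_age

    def objective(theta: np.ndarray) -> float:
        spec = _to_spec(model_id, theta, n0)
        if spec is None:
            return _PENALTY * (1.0 + float(np.sum(np.abs(theta))))
        ll = log_likelihood(spec, times, kappa=kappa)
        if math.isfinite(ll):
            return -ll
        # graded penalty: slope toward the feasible region
        lam, mu = _m.rates_at(spec, np.array([0.0, root_age]))
        viol = float(np.max(mu - lam))
        if math.isfinite(viol) and viol > 0:
            return _PENALTY * (1.0 + min(viol, _PENALTY))
        return _PENALTY * (1.0 + float(np.sum(np.abs(theta))))

    best = None
    best_i = -1
    funs = []
    for i, x0 in enumerate(_initial_points(model_id, times, n0, kappa, restarts, rng)):
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 300 * len(x0)},
        )
        funs.append(res.fun)
        if best is None or res.fun < best.fun:
            best = res
            best_i = i
    if best is None or best.fun >= _PENALTY:
        raise FitError(
            f"all restarts diverged for model {model_id}", partial=best
        )
    spec = _to_spec(model_id, best.x, n0)
    ll = -best.fun
    finite_funs = [f for f in funs if f < _PENALTY]
    diag = {
        "restarts": restarts,
        "best_restart": best_i,
        "fun_spread": float(max(finite_funs) - min(finite_funs))
        if finite_funs
        else math.inf,
    }
    return FitResult(
        model_id=model_id,
        spec=spec,
        log_likelihood=ll,
        k=k,
        n_obs=n_obs,
        aicc=aicc(ll, k, n_obs),
        diagnostics=diag,
    )


@dataclass
class ModelComparison:
    """AICc comparison of several fitted models on one tree."""

    fits: Dict[str, FitResult]
    best_id: str
    weights: Dict[str, float]
    delta_aicc: Dict[str, float]

    @property
    def best(self) -> FitResult:
        return self.fits[self.best_id]

    @property
    def extinction_fraction(self) -> float:
        return extinction_fraction_at_present(self.best)

    def hypothesis(self, partition: str) -> Tuple[float, float]:
        return hypothesis_probability(self, partition)


def _rank_key(model_id: str, a: float):
    # ties broken by fewer parameters, then fixed model order
    return (a, len(MODEL_PARAMS[model_id]), MODEL_IDS.index(model_id))


def compare_models(
    times: CoalescentTimes,
    n0: float,
    model_ids: Iterable[str] = MODEL_IDS,
    seed: Optional[int] = None,
    restarts: int = 10,
    kappa: float = DEFAULT_KAPPA,
) -> ModelComparison:
    """Fit every requested model and summarize support by Akaike weights.

    Models for which no admissible parameters exist are recorded with
    AICc = +inf and excluded from the weights (with a logged notice).
    """
    model_ids = list(model_ids)
    rng = np.random.default_rng(seed)
    fits: Dict[str, FitResult] = {}
    for mid in model_ids:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fits[mid] = fit_model(
                mid, times, n0, seed=sub_seed, restarts=restarts, kappa=kappa
            )
        except FitError:
            logger.warning(
                "model %s admitted no feasible parameters; excluded from weights",
                mid,
            )
            fits[mid] = FitResult(
                model_id=mid,
                spec=ModelSpec(model_id=mid, n0=n0, tau0=1.0, lam0=1.0),
                log_likelihood=-math.inf,
                k=len(MODEL_PARAMS[mid]),
                n_obs=times.n - 2,
                aicc=math.inf,
                diagnostics={"failed": True},
            )
    aiccs = np.array([fits[mid].aicc for mid in model_ids])
    w = akaike_weights(aiccs)
    weights = {mid: float(wi) for mid, wi in zip(model_ids, w)}
    best_finite = min(a for a in aiccs if math.isfinite(a))
    delta = {mid: fits[mid].aicc - best_finite for mid in model_ids}
    best_id = min(model_ids, key=lambda mid: _rank_key(mid, fits[mid].aicc))
    return ModelComparison(
        fits=fits, best_id=best_id, weights=weights, delta_aicc=delta
    )


def hypothesis_probability(
    comparison: ModelComparison,
    partition: Union[str, Tuple[Iterable[str], Iterable[str]]],
) -> Tuple[float, float]:
    """Relative probability of the best model in each half of a partition.

    The lowest-AICc model is selected within each subset, and the two winners'
    Akaike weights (computed over the full fitted set) are renormalized:
    returns (w_A/(w_A+w_B), w_B/(w_A+w_B)).

    ``partition`` is one of "diversity" (expanding, saturated), "rates"
    (varying, constant), "extinction" (present, absent), or an explicit pair
    of model-id collections.
    """
    if isinstance(partition, str):
        subset_a, subset_b = PARTITIONS[partition]
    else:
        subset_a, subset_b = (frozenset(s) for s in partition)
    fitted = set(comparison.fits)
    sub_a = sorted(subset_a & fitted)
    sub_b = sorted(subset_b & fitted)
    if not sub_a or not sub_b:
        raise ValueError("each subset of the partition needs >= 1 fitted model")
    win_a = min(sub_a, key=lambda mid: _rank_key(mid, comparison.fits[mid].aicc))
    win_b = min(sub_b, key=lambda mid: _rank_key(mid, comparison.fits[mid].aicc))
    wa = comparison.weights[win_a]
    wb = comparison.weights[win_b]
    tot = wa + wb
    if tot == 0:
        return (0.5, 0.5)
    return (wa / tot, wb / tot)


def extinction_fraction_at_present(best_fit: FitResult) -> float:
    """Extinction fraction mu(0)/lambda(0) implied by the best-fit model.

    Saturated-diversity models couple every extinction to a speciation, so the
    fraction is 1 by construction; pure-birth models have no extinction, so 0;
    otherwise the ratio of the fitted rates at the present.
    """
    mid = best_fit.model_id
    if mid in ("M1", "M2"):
        return 1.0
    if mid in ("M5", "M6"):
        return 0.0
    if mid == "M4c":
        return float(best_fit.spec.eps)
    return float(best_fit.spec.mu0 / best_fit.spec.lam0)
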