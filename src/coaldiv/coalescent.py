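"""Coalescent likelihood of internode distances under a diversification model.

Going backwards in time, while j lineages of the sample remain, pairs merge at
rate ``rho_j(t) = kappa * [j(j-1)/2] * lambda(t) / N(t)``, where N(t) is the
deterministic expected clade size and 1/lambda(t) plays the role of the
generation time (the time for a complete turnover of species). Each internode
distance g_j (the interval between node j and node j-1, during which exactly j
lineages exist) therefore contributes

    log rho_j(t_{j-1}) - int_{t_j}^{t_{j-1}} rho_j(s) ds

to the log-likelihood. The terminal interval, between the most recent node and
the present, is not a waiting time between cladogenesis events and contributes
no factor. Because the merging pair at an event is a uniformly random pair of
the N(t) coexisting species, two tracked lineages merge at twice the naive
per-generation Kingman rate C(j,2)/N, hence the convention constant kappa = 2
(verified empirically against the forward simulators; see the simulate
module). kappa rescales all rate estimates by a constant factor and cancels
from every model comparison.
"""

from __future__ import annotations

import math


import numpy as np
from scipy import integrate

from .models import ModelSpec, expected_diversity, rates_at, validate_constraint
from .treeio import CoalescentTimes

__all__ = [
    "DEFAULT_KAPPA",
    "log_likelihood",
    "log_likelihood_hey",
    "cumulative_rate",
    "unit_intensity",
]

#: lineage-pair merger rate convention: rho_j = kappa * C(j,2) * lambda/N.
#: kappa = 2 matches both the Moran-style turnover simulator and the
#: birth-death simulators (see module docstring).
DEFAULT_KAPPA = 2.0

# models whose integrated intensity has an elementary closed form
_CLOSED_FORM = frozenset({"M1", "M2", "M3", "M4c", "M5", "M6"})
_COEF_EPS = 1e-8
_GL_ORDER = 32
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_GL_ORDER)


def _exp_diff_over(r: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(e^{r b} - e^{r a}) / r with the r -> 0 limit."""
    if abs(r) < _COEF_EPS:
        return b - a
    return (np.exp(r * b) - np.exp(r * a)) / r


def _closed_unit_intensity(spec: ModelSpec, a, b) -> np.ndarray:
    """Closed-form int_a^b lambda(s)/N(s) ds for the dispatchable models."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = spec.model_id
    n0 = spec.n0
    if m == "M1":
        return spec.tau0 * (b - a) / n0
    if m == "M2":
        return spec.tau0 * _exp_diff_over(spec.gamma, a, b) / n0
    if m == "M3":
        return spec.lam0 * _exp_diff_over(spec.lam0 - spec.mu0, a, b) / n0
    if m == "M5":
        return spec.lam0 * _exp_diff_over(spec.lam0, a, b) / n0
    if m == "M6":
        if abs(spec.alpha) < _COEF_EPS:
            return spec.lam0 * _exp_diff_over(spec.lam0, a, b) / n0
        u = (spec.lam0 / spec.alpha) * np.expm1(spec.alpha * np.stack([a, b]))
        return (np.exp(u[1]) - np.exp(u[0])) / n0
    if m == "M4c":
        c = (1.0 - spec.eps) * spec.lam0  # net diversification coefficient
        if abs(spec.alpha) < _COEF_EPS:
            return spec.lam0 * _exp_diff_over(c, a, b) / n0
        if abs(1.0 - spec.eps) < 1e-12:
            # lambda == mu: N(t) stays at N0, lambda grows exponentially
            return spec.lam0 * _exp_diff_over(spec.alpha, a, b) / n0
        u = (c / spec.alpha) * np.expm1(spec.alpha * np.stack([a, b]))
        return (np.exp(u[1]) - np.exp(u[0])) / ((1.0 - spec.eps) * n0)
    raise ValueError(f"no closed-form intensity for model {m}")


def _integrand(spec: ModelSpec, s: np.ndarray) -> np.ndarray:
    lam, _ = rates_at(spec, s)
    return lam / expected_diversity(spec, s)


def unit_intensity(spec: ModelSpec, a, b, method: str = "auto") -> np.ndarray:
    """int_a^b lambda(s)/N(s) ds, the j-independent part of the merger rate.

    ``method``: "auto" dispatches to the closed form where one exists and to
    adaptive quadrature otherwise; "closed" or "quad" force one path.
    """
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    b_arr = np.atleast_1d(np.asarray(b, dtype=float))
    if np.any(a_arr < 0) or np.any(b_arr < a_arr):
        raise ValueError("require 0 <= a <= b")
    if method == "auto":
        method = "closed" if spec.model_id in _CLOSED_FORM else "quad"
    if method == "closed":
        out = _closed_unit_intensity(spec, a_arr, b_arr)
    elif method == "quad":
        out = np.empty_like(a_arr)
        for i, (lo, hi) in enumerate(zip(a_arr, b_arr)):
            if hi == lo:
                out[i] = 0.0
                continue
            scale = max(abs(_integrand(spec, np.array([lo]))[0]) * (hi - lo), 1.0)
            val, _err = integrate.quad(
                lambda s: float(_integrand(spec, np.array([s]))[0]),
                lo,
                hi,
                epsabs=1e-10 * scale,
                epsrel=1e-10,
                limit=200,
            )
            if val < 0 or not math.isfinite(val):
                raise ValueError(
                    f"intensity integral failed on [{lo}, {hi}] for "
                    f"{spec.model_id} (value {val})"
                )
            out[i] = val
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.isscalar(a) and np.isscalar(b):
        return float(out[0])
    return out


def cumulative_rate(
    spec: ModelSpec,
    j: int,
    a: float,
    b: float,
    kappa: float = DEFAULT_KAPPA,
    method: str = "auto",
) -> float:
    """Integrated merger rate Lambda_j(a, b) for j concurrent lineages."""
    if j < 2:
        raise ValueError("need at least 2 lineages to coalesce")
    pairs = j * (j - 1) / 2.0
    return float(kappa * pairs * unit_intensity(spec, a, b, method=method))


def _gl_nodes(times: CoalescentTimes):
    """Gauss-Legendre nodes/weights per internode interval, cached per tree.

    The node positions depend only on the interval endpoints, so they are
    computed once per tree and reused across every likelihood evaluation
    during optimization.
    """
    cache = getattr(times, "_gl_cache", None)
    if cache is not None:
        return cache
    upper = times.node_depths[:-1]
    lower = times.node_depths[1:]
    half = 0.5 * (upper - lower)
    mid = 0.5 * (upper + lower)
    s = mid[:, None] + half[:, None] * _GL_X[None, :]
    w = half[:, None] * _GL_W[None, :]
    times._gl_cache = (s, w)
    return times._gl_cache


def log_likelihood(
    spec: ModelSpec,
    times: CoalescentTimes,
    kappa: float = DEFAULT_KAPPA,
    method: str = "auto",
) -> float:
    """Log-likelihood (nats) of the n-2 internode distances under *spec*.

    Returns -inf (rather than raising) for inadmissible parameters: the
    speciation-not-less-than-extinction constraint violated anywhere on
    [0, root age], N(t) underflowing to zero, or overflow in the intensity.
    This lets derivative-free optimizers traverse bad regions.

    ``method="quad"`` forces the numerical-quadrature path for every model
    (used to cross-check the closed forms).
    """
    n = times.n
    root_age = times.root_age
    if not validate_constraint(spec, root_age):
        return -math.inf

    js = np.arange(2, n)  # j = 2..n-1, one per internode distance
    pairs = js * (js - 1) / 2.0
    upper = times.node_depths[:-1]  # t_{j-1}: the older end of interval j
    lower = times.node_depths[1:]  # t_j

    with np.errstate(over="ignore", under="ignore", divide="ignore", invalid="ignore"):
        lam_up, _ = rates_at(spec, upper)
        n_up = expected_diversity(spec, upper)
        if np.any(~np.isfinite(n_up)) or np.any(n_up <= 0) or np.any(lam_up <= 0):
            return -math.inf
        log_rho = np.log(kappa * pairs * lam_up / n_up)

        use_quad = method == "quad" or (
            method == "auto" and spec.model_id not in _CLOSED_FORM
        )
        if use_quad:
            s, w = _gl_nodes(times)
            lam_s, _ = rates_at(spec, s)
            n_s = expected_diversity(spec, s)
            if np.any(~np.isfinite(n_s)) or np.any(n_s <= 0):
                return -math.inf
            unit = np.sum(w * lam_s / n_s, axis=1)
        else:
            unit = _closed_unit_intensity(spec, lower, upper)

        total = float(np.sum(log_rho) - kappa * np.sum(pairs * unit))
    if math.isnan(total):
        return -math.inf
    return total


def log_likelihood_hey(
    tau0: float,
    n0: float,
    times: CoalescentTimes,
    kappa: float = DEFAULT_KAPPA,
) -> float:
    """Closed-form log-likelihood under the constant-turnover Hey/Moran model.

    Each internode distance is exponential with constant rate
    ``kappa * C(j,2) * tau0/N0``; the expression depends on tau0 and N0 only
    through their ratio, which is why N0 must be supplied externally.
    """
    if tau0 <= 0 or n0 <= 0:
        raise ValueError("tau0 and N0 must be positive")
    n = times.n
    js = np.arange(2, n)
    rates = kappa * (js * (js - 1) / 2.0) * tau0 / n0
    g = times.internode_distances
    return float(np.sum(np.log(rates) - rates * g))
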