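"""Diversification scenarios: rate functions and deterministic expected diversity.

Nine scenarios are supported, falling into two families:

* saturated diversity (M1, M2): every extinction is immediately followed by a
  speciation, so clade size stays at ``N0``; the single rate is the turnover
  rate ``tau(t) = tau0 * exp(gamma * t)``.
* expanding diversity (M3, M4a-M4d, M5, M6): independent speciation and
  extinction with rates ``lambda(t)`` and ``mu(t)``; diversity is approximated
  by its deterministic expectation ``N(t) = N0 * exp(-int_0^t (lambda-mu))``.

Time ``t`` is measured backwards from the present (t=0 at the tips), so a
positive variation coefficient (alpha, beta, gamma) means the rate was higher
in the past and has decayed toward the present.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "MODEL_IDS",
    "MODEL_PARAMS",
    "ModelSpec",
    "rates_at",
    "expected_diversity",
    "validate_constraint",
]

MODEL_IDS = ("M1", "M2", "M3", "M4a", "M4b", "M4c", "M4d", "M5", "M6")

#: free parameters of each model (N0 is always a known input, never fitted)
MODEL_PARAMS: Dict[str, Tuple[str, ...]] = {
    "M1": ("tau0",),
    "M2": ("tau0", "gamma"),
    "M3": ("lam0", "mu0"),
    "M4a": ("lam0", "alpha", "mu0"),
    "M4b": ("lam0", "mu0", "beta"),
    "M4c": ("lam0", "alpha", "eps"),
    "M4d": ("lam0", "alpha", "mu0", "beta"),
    "M5": ("lam0",),
    "M6": ("lam0", "alpha"),
}

#: model subsets used for the three hypothesis partitions
SATURATED = frozenset({"M1", "M2"})
EXPANDING = frozenset({"M3", "M4a", "M4b", "M4c", "M4d", "M5", "M6"})
CONSTANT_RATES = frozenset({"M1", "M3", "M5"})
VARYING_RATES = frozenset({"M2", "M4a", "M4b", "M4c", "M4d", "M6"})
WITH_EXTINCTION = frozenset({"M1", "M2", "M3", "M4a", "M4b", "M4c", "M4d"})
WITHOUT_EXTINCTION = frozenset({"M5", "M6"})

# below this magnitude an exponential-variation coefficient is treated as zero
# (constant-rate limit) to avoid catastrophic cancellation in (e^{at}-1)/a
_COEF_EPS = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """One diversification scenario with its parameter vector.

    Only the parameters listed in ``MODEL_PARAMS[model_id]`` are meaningful;
    the rest are ignored. ``n0`` is the known present-day clade richness.
    """

    model_id: str
    n0: float
    tau0: float = 0.0
    gamma: float = 0.0
    lam0: float = 0.0
    alpha: float = 0.0
    mu0: float = 0.0
    beta: float = 0.0
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.n0 <= 0:
            raise ValueError("N0 must be positive")
        for name in ("tau0", "lam0", "mu0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError("extinction fraction eps must lie in [0, 1]")

    @property
    def k(self) -> int:
        """Number of free parameters (for AICc)."""
        return len(MODEL_PARAMS[self.model_id])

    def params(self) -> Dict[str, float]:
        return {p: getattr(self, p) for p in MODEL_PARAMS[self.model_id]}

    def with_params(self, **kwargs) -> "ModelSpec":
        return replace(self, **kwargs)


def rates_at(spec: ModelSpec, t) -> Tuple[np.ndarray, np.ndarray]:
    """Speciation and extinction rates (lambda(t), mu(t)) at time t before present.

    For the saturated models M1/M2 the turnover rate plays both roles
    (every extinction is coupled to a speciation).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (time before present)")
    m = spec.model_id
    if m in ("M1", "M2"):
        tau = spec.tau0 * np.exp(spec.gamma * t if m == "M2" else np.zeros_like(t))
        return tau, tau
    if m == "M3":
        one = np.ones_like(t)
        return spec.lam0 * one, spec.mu0 * one
    if m == "M4a":
        return spec.lam0 * np.exp(spec.alpha * t), spec.mu0 * np.ones_like(t)
    if m == "M4b":
        return spec.lam0 * np.ones_like(t), spec.mu0 * np.exp(spec.beta * t)
    if m == "M4c":
        lam = spec.lam0 * np.exp(spec.alpha * t)
        return lam, spec.eps * lam
    if m == "M4d":
        return spec.lam0 * np.exp(spec.alpha * t), spec.mu0 * np.exp(spec.beta * t)
    if m == "M5":
        return spec.lam0 * np.ones_like(t), np.zeros_like(t)
    # M6
    return spec.lam0 * np.exp(spec.alpha * t), np.zeros_like(t)


def _expm1_over(a: float, t: np.ndarray) -> np.ndarray:
    """(e^{a t} - 1)/a, with the a -> 0 limit handled."""
    if abs(a) < _COEF_EPS:
        return np.asarray(t, dtype=float)
    return np.expm1(a * t) / a


def net_diversification_integral(spec: ModelSpec, t) -> np.ndarray:
    """R(t) = int_0^t [lambda(s) - mu(s)] ds, in closed form.

    The expected diversity is ``N(t) = N0 * exp(-R(t))``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (time before present)")
    m = spec.model_id
    if m in ("M1", "M2"):
        return np.zeros_like(t)
    if m == "M3":
        return (spec.lam0 - spec.mu0) * t
    if m == "M4a":
        return spec.lam0 * _expm1_over(spec.alpha, t) - spec.mu0 * t
    if m == "M4b":
        return spec.lam0 * t - spec.mu0 * _expm1_over(spec.beta, t)
    if m == "M4c":
        return (1.0 - spec.eps) * spec.lam0 * _expm1_over(spec.alpha, t)
    if m == "M4d":
        return spec.lam0 * _expm1_over(spec.alpha, t) - spec.mu0 * _expm1_over(
            spec.beta, t
        )
    if m == "M5":
        return spec.lam0 * t
    # M6
    return spec.lam0 * _expm1_over(spec.alpha, t)


def expected_diversity(spec: ModelSpec, t) -> np.ndarray:
    """Deterministic expected clade size N(t) at time t before present.

    N(t) = N0 under the saturated models; otherwise
    N(t) = N0 * exp(-int_0^t (lambda - mu) ds), evaluated in closed form.
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        out = spec.n0 * np.exp(-net_diversification_integral(spec, t))
    return out


def validate_constraint(spec: ModelSpec, horizon: float) -> bool:
    """True iff lambda(t) >= mu(t) for all t in [0, horizon].

    All nine models have log lambda(t) - log mu(t) affine in t, so the sign of
    lambda - mu changes at most once and checking both endpoints is exact.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    ends = np.array([0.0, horizon])
    lam, mu = rates_at(spec, ends)
    return bool(np.all(lam >= mu))
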