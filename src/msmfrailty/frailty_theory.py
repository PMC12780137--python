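"""Closed-form gamma-frailty mathematics.

A frailty Z is an unobserved multiplicative effect on the hazard,
conditionally ``h(t|Z) = Z h(t)`` and ``S(t|Z) = exp(-Z H(t))``.  We use the
one-parameter gamma frailty with mean 1 and variance sigma^2 (shape = rate =
1/sigma^2), whose Laplace transform ``L(s) = E[exp(-Zs)]`` has the closed
form ``(1 + sigma^2 s)^(-1/sigma^2)``.  Marginal (population-averaged)
quantities follow from L:

* marginal survival   S(t) = L(H(t))
* marginal hazard     h'(t) = h(t) * [-L'(H)/L(H)] = h(t) / (1 + sigma^2 H)
* posterior frailty mean among survivors  E[Z|T>=t] = (1 + sigma^2 H)^(-1)
* posterior frailty variance              V[Z|T>=t] = sigma^2 (1 + sigma^2 H)^(-2)

The within-cluster dependence induced by a shared gamma frailty with
variance theta has Kendall's tau = theta / (theta + 2).

sigma^2 = 0 is treated as the degenerate (no-frailty) analytic limit,
``L(s) = exp(-s)``, not as a numerical division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GammaFrailtySpec",
    "HazardCurve",
    "gamma_laplace",
    "conditional_survival",
    "conditional_frailty_mean",
    "conditional_frailty_variance",
    "marginal_hazard",
    "joint_marginal_survival",
    "kendalls_tau",
]


@dataclass(frozen=True)
class GammaFrailtySpec:
    """Gamma frailty with unit mean and variance ``variance``; shape = rate = 1/variance."""

    variance: float = 1.0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"frailty variance must be >= 0, got {self.variance}")

    @property
    def shape(self) -> float:
        if self.variance == 0:
            raise ValueError("degenerate frailty (variance 0) has no gamma shape")
        return 1.0 / self.variance

    @property
    def rate(self) -> float:
        return self.shape

    def density(self, z):
        """Gamma density f(z; sigma^2) with shape = rate = 1/sigma^2."""
        from scipy import stats

        return stats.gamma.pdf(z, a=self.shape, scale=self.variance)


@dataclass(frozen=True)
class HazardCurve:
    """A hazard evaluated on an increasing grid, with its cumulative integral.

    ``cumulative`` is the running trapezoidal integral of ``hazard`` with
    H(grid[0]) anchored via an implied origin at t=0, H(0)=0.
    """

    grid: np.ndarray
    hazard: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        haz = np.asarray(self.hazard, dtype=float)
        if grid.ndim != 1 or grid.shape != haz.shape:
            raise ValueError("grid and hazard must be equal-length 1-d arrays")
        if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
            raise ValueError("grid must be nonnegative and strictly increasing")
        if np.any(haz < 0):
            raise ValueError("hazard must be nonnegative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "hazard", haz)

    @property
    def cumulative(self) -> np.ndarray:
        # prepend t=0 with h(0)=h(grid[0]) held constant on [0, grid[0]]
        t = np.concatenate([[0.0], self.grid])
        h = np.concatenate([[self.hazard[0]], self.hazard])
        H = np.concatenate([[0.0], np.cumsum(np.diff(t) * (h[:-1] + h[1:]) / 2.0)])
        return H[1:]


def _check_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


def gamma_laplace(s, spec: GammaFrailtySpec):
    """Laplace transform ``E[exp(-Zs)] = (1 + sigma^2 s)^(-1/sigma^2)``.

    Decreasing in s, equal to 1 at s=0; tends to ``exp(-s)`` as sigma^2 -> 0.
    """
    s = _check_nonneg("s", s)
    if spec.variance == 0:
        return np.exp(-s)
    return (1.0 + spec.variance * s) ** (-1.0 / spec.variance)


def conditional_survival(H, z):
    """Survival given frailty: ``S(t|Z=z) = exp(-z H(t))``."""
    H = _check_nonneg("H", H)
    z = _check_nonneg("z", z)
    return np.exp(-z * H)


def conditional_frailty_mean(H, spec: GammaFrailtySpec):
    """Mean frailty among survivors to cumulative hazard H: ``-L'(H)/L(H)``.

    For gamma frailty this is ``(1 + sigma^2 H)^(-1)``: survivors are a
    progressively less frail selection of the population.
    """
    H = _check_nonneg("H", H)
    return 1.0 / (1.0 + spec.variance * H)


def conditional_frailty_variance(H, spec: GammaFrailtySpec):
    """Frailty variance among survivors: ``L''/L - (L'/L)^2 = sigma^2 (1+sigma^2 H)^-2``."""
    H = _check_nonneg("H", H)
    return spec.variance / (1.0 + spec.variance * H) ** 2


def marginal_hazard(h, H, spec: GammaFrailtySpec):
    """Population-averaged hazard ``h'(t) = h(t) E[Z | T >= t] = h/(1 + sigma^2 H)``."""
    h = _check_nonneg("h", h)
    H = _check_nonneg("H", H)
    return h * conditional_frailty_mean(H, spec)


def joint_marginal_survival(H_terms, spec: GammaFrailtySpec) -> float:
    """Marginal joint survival of a cluster sharing one gamma frailty.

    ``H_terms`` are the per-member conditional cumulative hazards
    ``H0(t_k) exp(beta' x_k)``.  The marginal joint survival is the Laplace
    transform at their sum,

        L(sum_k H_k) = (1 + sigma^2 sum_k H_k)^(-1/sigma^2),

    equivalently, in terms of the marginal per-member survivals
    ``S_k = L(H_k)``,

        (sum_k S_k^(-sigma^2) - (n - 1))^(-1/sigma^2).
    """
    terms = _check_nonneg("H_terms", H_terms)
    if terms.size == 0:
        raise ValueError("H_terms must be non-empty")
    return float(gamma_laplace(terms.sum(), spec))


def kendalls_tau(theta: float) -> float:
    """Kendall's tau of a shared gamma frailty with variance theta: theta/(theta+2)."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    return theta / (theta + 2.0)
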