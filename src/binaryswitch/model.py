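"""Continuum growth law for threshold-regulated birth-death dynamics.

A population lives on (or is idealised as living on) a hexagonal lattice in
which each individual senses its number of occupied nearest-neighbour sites,
``n``, out of six.  Proliferation and death rates may depend on ``n``; the
mean-field (well-mixed) limit of that individual-based process is a scalar
ODE for the scaled density ``C(t)`` in ``[0, 1]``::

    (1/C) dC/dt = (1 - C) * sum_{n=0..5} gamma_n * binom(5, n) * C**n * (1 - C)**(5 - n)
                  - gamma_6 * C**6

with net growth coefficients ``gamma_n = p_n - 6 d_n / (6 - n)`` for
``n <= 5`` and ``gamma_6 = d_6``.  ``C = 1`` is the maximum packing density.

The *binary switch* closure collapses the thirteen per-neighbour rates to
five interpretable parameters: individuals at or below a threshold local
density ``M`` proliferate at rate ``r`` and die at rate ``r * alpha``; above
the threshold the rates are ``R`` and ``R * beta``.  Depending on
``(r, R, alpha, beta, M)`` the resulting growth law reproduces logistic
growth, Weak/Strong Allee effects, extinction, and several less familiar
regimes (see :mod:`binaryswitch.equilibria`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.integrate import solve_ivp

__all__ = [
    "BinarySwitchParams",
    "NeighbourRates",
    "GammaCoefficients",
    "ClassicParams",
    "Trajectory",
    "IntegrationError",
    "switch_rates",
    "gamma_coefficients",
    "per_capita_rate",
    "per_capita_from_gamma",
    "growth_rate",
    "polynomial_coefficients",
    "classic_rate",
    "solve_trajectory",
    "solve_trajectories",
]

#: binomial coefficients binom(5, n), n = 0..5
_BINOM5 = np.array([math.comb(5, n) for n in range(6)], dtype=float)

_DOMAIN_TOL = 1e-9


@dataclass(frozen=True)
class BinarySwitchParams:
    """Five-parameter threshold growth model.

    Parameters
    ----------
    r : float
        Low-density proliferation rate (per unit time, >= 0).
    R : float
        High-density proliferation rate (per unit time, >= 0).
    alpha : float
        Ratio of low-density death rate to ``r``; in ``[0, 1]``.
    beta : float
        Ratio of high-density death rate to ``R``; in ``[0, 1]``.
    M : int
        Threshold local density (occupied neighbours) in ``{0, ..., 5}``.
        Rates switch when an individual senses *more* than ``M`` neighbours.
    validate : bool
        If False, skip range checks (escape hatch for exploratory use with
        out-of-range ratios).  The ranges above are part of the model
        definition, so validation is on by default.
    """

    r: float
    R: float
    alpha: float
    beta: float
    M: int
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if int(self.M) != self.M or not 0 <= int(self.M) <= 5:
            raise ValueError(f"M must be an integer in 0..5, got {self.M!r}")
        object.__setattr__(self, "M", int(self.M))
        if not self.validate:
            return
        if self.r < 0 or self.R < 0:
            raise ValueError(f"rates must be non-negative: r={self.r}, R={self.R}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")

    def to_dict(self) -> dict:
        return {"r": self.r, "R": self.R, "alpha": self.alpha,
                "beta": self.beta, "M": self.M}

    @classmethod
    def from_dict(cls, d: dict, validate: bool = True) -> "BinarySwitchParams":
        return cls(r=float(d["r"]), R=float(d["R"]), alpha=float(d["alpha"]),
                   beta=float(d["beta"]), M=int(d["M"]), validate=validate)


@dataclass(frozen=True)
class NeighbourRates:
    """Per-neighbour-count rates: ``p[n]`` (n = 0..5) and ``d[n]`` (n = 0..6)."""

    p: tuple
    d: tuple

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.p)
        d = tuple(float(x) for x in self.d)
        if len(p) != 6 or len(d) != 7:
            raise ValueError("need 6 proliferation rates (n=0..5) and 7 death rates (n=0..6)")
        if any(x < 0 for x in p) or any(x < 0 for x in d):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class GammaCoefficients:
    """Net growth coefficients ``gamma_n``, n = 0..6 (``gamma_6 = d_6 >= 0``)."""

    gamma: tuple

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.gamma)
        if len(g) != 7:
            raise ValueError("need 7 coefficients (n=0..6)")
        if g[6] < 0:
            raise ValueError("gamma_6 equals the 6-neighbour death rate and must be >= 0")
        object.__setattr__(self, "gamma", g)


@dataclass(frozen=True)
class ClassicParams:
    """Textbook growth laws used as qualitative references.

    ``logistic``:    dC/dt = r C (1 - C/K)
    ``weak_allee``:  dC/dt = r C (1 - C/K)(1 + C/A),  A > 0
    ``strong_allee``: dC/dt = r C (1 - C/K)(C/B - 1),  0 < B < K
    """

    model: str
    r: float
    K: float
    A: float | None = None
    B: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("logistic", "weak_allee", "strong_allee"):
            raise ValueError(f"unknown classic model {self.model!r}")
        if self.r <= 0 or self.K <= 0:
            raise ValueError("need r > 0 and K > 0")
        if self.model == "weak_allee" and (self.A is None or self.A <= 0):
            raise ValueError("weak Allee form needs A > 0")
        if self.model == "strong_allee" and (
                self.B is None or not 0 < self.B < self.K):
            raise ValueError("strong Allee form needs 0 < B < K")


@dataclass(frozen=True)
class Trajectory:
    """A solved density time course ``C(t)`` for one initial condition."""

    times: np.ndarray
    densities: np.ndarray
    params: BinarySwitchParams
    C0: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "density": self.densities})


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the solver's status message."""


def switch_rates(params: BinarySwitchParams) -> NeighbourRates:
    """Expand the five switch parameters into per-neighbour-count rates.

    ``p_n = r`` for ``n <= M`` else ``R`` (n = 0..5); ``d_n = r*alpha`` for
    ``n <= M`` else ``R*beta`` (n = 0..6).
    """
    M = params.M
    p = tuple(params.r if n <= M else params.R for n in range(6))
    d = tuple(params.r * params.alpha if n <= M else params.R * params.beta
              for n in range(7))
    return NeighbourRates(p=p, d=d)


def gamma_coefficients(rates: NeighbourRates) -> GammaCoefficients:
    """Net growth coefficients: ``gamma_n = p_n - 6 d_n/(6-n)`` (n<=5), ``gamma_6 = d_6``."""
    g = [rates.p[n] - 6.0 * rates.d[n] / (6 - n) for n in range(6)]
    g.append(rates.d[6])
    return GammaCoefficients(gamma=tuple(g))


def _check_domain(C: np.ndarray) -> None:
    if np.any(C < -_DOMAIN_TOL) or np.any(C > 1.0 + _DOMAIN_TOL):
        bad = np.asarray(C)[(np.asarray(C) < -_DOMAIN_TOL)
                            | (np.asarray(C) > 1.0 + _DOMAIN_TOL)]
        raise ValueError(f"density outside [0, 1]: {bad[:5]!r}")


def per_capita_from_gamma(C, gamma: GammaCoefficients):
    """Per-capita growth rate evaluated from the general neighbour-rate law.

    This is the thirteen-parameter form; the local density of an individual
    in a well-mixed population at global density ``C`` is binomial, which is
    where the ``binom(5, n) C^n (1-C)^(5-n)`` weights come from.
    """
    C = np.asarray(C, dtype=float)
    _check_domain(C)
    g = gamma.gamma
    acc = np.zeros_like(C)
    for n in range(6):
        acc += g[n] * _BINOM5[n] * C**n * (1.0 - C)**(5 - n)
    return (1.0 - C) * acc - g[6] * C**6


def per_capita_rate(C, params: BinarySwitchParams):
    """Per-capita growth rate ``(1/C) dC/dt`` of the binary switch model.

    Implemented directly from the switch form (two binomial partial sums,
    the high-density one empty when ``M = 5``), independently of
    :func:`per_capita_from_gamma`; the two paths agree to rounding error.
    Accepts scalars or arrays in ``[0, 1]``.
    """
    C = np.asarray(C, dtype=float)
    _check_domain(C)
    r, R, a, b, M = params.r, params.R, params.alpha, params.beta, params.M
    out = np.zeros_like(C)
    for j in range(0, M + 1):
        out += r * _BINOM5[j] * C**j * (1.0 - C)**(6 - j) * (1.0 - 6.0 * a / (6 - j))
    for j in range(M + 1, 6):  # empty when M = 5
        out += R * _BINOM5[j] * C**j * (1.0 - C)**(6 - j) * (1.0 - 6.0 * b / (6 - j))
    out -= R * b * C**6
    if np.isscalar(C) or C.ndim == 0:
        return float(out)
    return out


def growth_rate(C, params: BinarySwitchParams):
    """Density growth rate ``dC/dt = C * per_capita_rate(C)``; exactly 0 at C = 0."""
    C = np.asarray(C, dtype=float)
    out = C * per_capita_rate(C, params)
    if C.ndim == 0:
        return float(out)
    return out


def polynomial_coefficients(params: BinarySwitchParams) -> np.ndarray:
    """Expand ``dC/dt`` as a degree-7 polynomial in ``C``.

    Returns ascending coefficients (length 8); the constant term is exactly
    zero because ``C = 0`` is always an equilibrium.
    """
    g = gamma_coefficients(switch_rates(params)).gamma
    C = Polynomial([0.0, 1.0])
    one_minus = Polynomial([1.0, -1.0])
    poly = Polynomial([0.0])
    for n in range(6):
        poly = poly + g[n] * _BINOM5[n] * C**(n + 1) * one_minus**(6 - n)
    poly = poly - g[6] * C**7
    coef = np.zeros(8)
    coef[: len(poly.coef)] = poly.coef
    coef[0] = 0.0
    return coef


def classic_rate(C, cp: ClassicParams):
    """Growth rate ``dC/dt`` of a classic logistic / weak-Allee / strong-Allee law."""
    C = np.asarray(C, dtype=float)
    base = cp.r * C * (1.0 - C / cp.K)
    if cp.model == "logistic":
        out = base
    elif cp.model == "weak_allee":
        out = base * (1.0 + C / cp.A)
    else:
        out = base * (C / cp.B - 1.0)
    if C.ndim == 0:
        return float(out)
    return out


def solve_trajectory(params: BinarySwitchParams, C0: float,
                     t_grid: Sequence[float],
                     rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate ``dC/dt`` from ``C(0) = C0`` and sample at ``t_grid``.

    Uses adaptive Runge-Kutta 4(5).  Densities stay in ``[0, 1]`` because
    both endpoints repel or absorb under the dynamics; no post-hoc clamping
    is applied.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D sequence")
    if not 0.0 <= C0 <= 1.0:
        raise ValueError(f"C0 must lie in [0, 1], got {C0}")
    dens = solve_trajectories(params, [C0], t_grid, rtol=rtol, atol=atol)[:, 0]
    return Trajectory(times=t_grid, densities=dens, params=params, C0=float(C0))


def solve_trajectories(params: BinarySwitchParams, C0s: Sequence[float],
                       t_grid: Sequence[float],
                       rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Vectorised :func:`solve_trajectory` over several initial densities.

    Returns an array of shape ``(len(t_grid), len(C0s))``.  The densities for
    different initial conditions are integrated as one uncoupled system,
    which is markedly cheaper than repeated scalar solves during calibration.
    """
    coef = polynomial_coefficients(params)[::-1]  # descending, for polyval
    t_grid = np.asarray(t_grid, dtype=float)
    C0s = np.asarray(C0s, dtype=float)
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at or after t = 0")
    if t_grid[-1] == 0.0:
        return np.tile(C0s, (len(t_grid), 1))

    def rhs(_t, y):
        y = np.clip(y, 0.0, 1.0)  # guard round-off excursions inside the solver
        return np.polyval(coef, y)

    sol = solve_ivp(rhs, (0.0, t_grid[-1]), C0s,
                    t_eval=t_grid, method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"ODE solver failed (status {sol.status}): {sol.message}")
    return np.clip(sol.y.T, 0.0, 1.0)
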