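"""Bifurcation structure of the threshold growth law.

Three one-parameter slices of the ``(r, R, alpha, beta, M)`` space have
closed-form equilibrium relations, transcribed here as rational functions
and cross-validated (in the test suite) against independent numeric
solutions of the defining conditions:

* **No low-density turnover** (``r = 0``): a single interior equilibrium
  ``C1`` exists iff ``beta < (5 - M)/6`` and ``M <= 4``; the map
  ``beta = case1_beta_of_C1(M, C1)`` and its inverse are one-to-one.
* **No high-density turnover** (``R = 0``): ``C = 1`` is always an
  equilibrium; a third equilibrium in ``(0, 1)`` appears iff
  ``alpha > (6 - M)/6``, via ``alpha = case2_alpha_of_C1(M, C1)``.
* **Both rates positive** (``r`` normalised to 1): the boundary between
  single- and triple-equilibrium regions is the *tangential manifold*,
  where the growth polynomial has a double root ``C_hat``.  It is
  parametrised as ``R = tangential_R(M, C_hat, beta)``,
  ``alpha = tangential_alpha(M, C_hat, beta)``.  The double root becomes a
  stable triple root at the *triple point* (``beta = triple_point_beta``)
  and meets ``alpha = 1`` at the *junction point*
  (``beta = junction_point_beta``), which separates the Extinction and
  Strong-Allee regions.

The manifold exists only for ``M`` in ``{1, 2, 3, 4}``; at the extreme
thresholds the entire ``(alpha, R)`` plane shows only Weak-Allee or
Extinction behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq

from .equilibria import DegenerateGrowthError, RegimeLabel, classify_regime
from .model import BinarySwitchParams

__all__ = [
    "TangentialPoint",
    "TriplePoint",
    "JunctionPoint",
    "RegimeMap",
    "case1_beta_of_C1",
    "case1_C1_of_beta",
    "case2_alpha_of_C1",
    "case2_C1_of_alpha",
    "tangential_R",
    "tangential_alpha",
    "tangential_point",
    "triple_point_beta",
    "triple_point",
    "junction_point_beta",
    "junction_point",
    "case3_polynomials",
    "regime_map",
]

_INV_XTOL = 1e-12

# --- r = 0 slice: beta as a rational function of the interior equilibrium ---
# ascending numerator / denominator coefficients, keyed by threshold M
_CASE1 = {
    0: ([-5.0, 15, -20, 15, -6, 1], [-6.0, 15, -20, 15, -6, 1]),
    1: ([10.0, -30, 35, -19, 4], [15.0, -40, 45, -24, 5]),
    2: ([10.0, -25, 21, -6], [20.0, -45, 36, -10]),
    3: ([5.0, -9, 4], [15.0, -24, 10]),
    4: ([1.0, -1], [6.0, -5]),
}

# --- R = 0 slice: alpha as a rational function of the interior equilibrium ---
_CASE2 = {
    1: ([1.0, 4], [1.0, 5]),
    2: ([1.0, 3, 6], [1.0, 4, 10]),
    3: ([1.0, 2, 3, 4], [1.0, 3, 6, 10]),
    4: ([1.0, 1, 1, 1, 1], [1.0, 2, 3, 4, 5]),
    5: ([1.0], [1.0, 1, 1, 1, 1, 1]),
}

# --- tangential manifold: R = F(C, beta) as (numerator(C), den_poly(C), den_beta_coef, C_power) ---
# R = num(C) / (C**k * (den0(C) + den_b * beta))
_TANGENTIAL_R = {
    1: ([1.0, -6, 15, -20, 15, -6, 1],          # (C-1)**6
        [20.0, -10, -20, 15, -6, 1], -30.0, 1),
    2: (np.polynomial.polynomial.polymul([-1.0, 5, -10, 10, -5, 1], [1.0, 8, 6]),
        [-30.0, 10, 15, 21, -22, 6], 60.0, 2),
    3: (np.polynomial.polynomial.polymul([1.0, -4, 6, -4, 1], [1.0, 6, 21, 16, 6]),
        [20.0, -5, -6, -7, -8, 6], -60.0, 3),
    4: (np.polynomial.polynomial.polymul([-1.0, 3, -3, 1], [1.0, 4, 10, 20, 10, 4, 1]),
        [-5.0, 1, 1, 1, 1, 1], 30.0, 4),
}

# --- tangential manifold: alpha = G(C, beta) as (num0(C), num_beta(C), den0(C), den_beta) ---
# alpha = (num0(C) + beta * num_b(C)) / (den0(C) + den_b * beta)
_TANGENTIAL_ALPHA = {
    1: ([20.0, -20], [-30.0, 15, -20, 15, -6, 1],
        [20.0, -10, -20, 15, -6, 1], -30.0),
    2: ([-30.0, 30], [60.0, -40, 15, 21, -22, 6],
        [-30.0, 10, 15, 21, -22, 6], 60.0),
    3: ([20.0, -20], [-60.0, 45, -6, -7, -8, 6],
        [20.0, -5, -6, -7, -8, 6], -60.0),
    4: ([-5.0, 5], [30.0, -24, 1, 1, 1, 1],
        [-5.0, 1, 1, 1, 1, 1], 30.0),
}

# --- triple point: beta = H(C) as (numerator, denominator), ascending ---
_TRIPLE = {
    1: ([2.0, -2], [3.0]),
    2: (np.polynomial.polynomial.polymul([1.0, -1], [1.0, 2]), [2.0, 3]),
    3: (np.polynomial.polynomial.polymul([1.0, -1], [1.0, 2, 2]), [3.0, 4, 3]),
    4: (np.polynomial.polynomial.polymul([1.0, 0, -1], [2.0, 1, 2]), [12.0, 9, 6, 3]),
}

# --- junction point: beta = J(C) as (numerator, denominator), ascending ---
_JUNCTION = {
    1: (np.polynomial.polynomial.polymul([-1.0, 1], [-10.0, 10, -5, 1]),
        [15.0, -20, 15, -6, 1]),
    2: (np.polynomial.polynomial.polymul([-1.0, 1], [20.0, 5, -16, 6]),
        [-40.0, 15, 21, -22, 6]),
    3: (np.polynomial.polynomial.polymul([-1.0, 1], [-15.0, -9, -2, 6]),
        [45.0, -6, -7, -8, 6]),
    4: (np.polynomial.polynomial.polymul([-1.0, 1], [4.0, 3, 2, 1]),
        [-24.0, 1, 1, 1, 1]),
}


@dataclass(frozen=True)
class TangentialPoint:
    """A double-root (semi-stable) equilibrium and the parameters producing it."""

    M: int
    C_hat: float
    beta: float
    R: float
    alpha: float
    branch: str  # "positive" (C_hat below the triple point) or "negative"


@dataclass(frozen=True)
class TriplePoint:
    """Degenerate point where the double root becomes a stable triple root."""

    M: int
    C_triple: float
    beta: float
    residual: float  # second-derivative defect of the growth law at C_triple


@dataclass(frozen=True)
class JunctionPoint:
    """Point where the negative tangential branch reaches ``alpha = 1``.

    ``R_junction`` is the critical high-density rate: with ``alpha = 1``, all
    densities go extinct below it, while above it the model shows a Strong
    Allee effect.
    """

    M: int
    C_junction: float
    beta: float
    R_junction: float


@dataclass(frozen=True)
class RegimeMap:
    """Qualitative regime at each cell of an ``(alpha, R)`` grid."""

    M: int
    beta: float
    alpha_grid: np.ndarray
    R_grid: np.ndarray
    labels: np.ndarray  # shape (len(alpha_grid), len(R_grid)), dtype object

    def to_frame(self):
        import pandas as pd

        a, r = np.meshgrid(self.alpha_grid, self.R_grid, indexing="ij")
        return pd.DataFrame({"alpha": a.ravel(), "R": r.ravel(),
                             "label": [l.value if l is not None else "Degenerate"
                                       for l in self.labels.ravel()]})


def _ratio(table, M, x, what):
    if M not in table:
        raise ValueError(f"{what} is undefined for M = {M}")
    num, den = table[M]
    return (np.polynomial.polynomial.polyval(x, num)
            / np.polynomial.polynomial.polyval(x, den))


def case1_beta_of_C1(M: int, C1: float) -> float:
    """High-density death ratio placing the interior equilibrium at ``C1`` when ``r = 0``."""
    if not 0.0 < C1 <= 1.0:
        raise ValueError(f"C1 must lie in (0, 1], got {C1}")
    return float(_ratio(_CASE1, M, C1, "the r = 0 equilibrium relation"))


def case1_C1_of_beta(M: int, beta: float) -> float | None:
    """Interior equilibrium for ``r = 0``; ``None`` if only extinction remains.

    A root in ``(0, 1]`` exists iff ``M <= 4`` and ``beta < (5 - M)/6``.
    """
    if not 0 <= M <= 5:
        raise ValueError(f"M must be in 0..5, got {M}")
    if M == 5 or beta >= (5 - M) / 6 or beta < 0:
        return None
    if beta == 0.0:
        return 1.0
    return float(brentq(lambda c: case1_beta_of_C1(M, c) - beta,
                        1e-14, 1.0, xtol=_INV_XTOL))


def case2_alpha_of_C1(M: int, C1: float) -> float:
    """Low-density death ratio placing a second interior equilibrium at ``C1`` when ``R = 0``."""
    if not 0.0 < C1 < 1.0:
        raise ValueError(f"C1 must lie in (0, 1), got {C1}")
    return float(_ratio(_CASE2, M, C1, "the R = 0 equilibrium relation"))


def case2_C1_of_alpha(M: int, alpha: float) -> float | None:
    """Interior equilibrium in ``(0, 1)`` for ``R = 0``; exists iff ``alpha > (6 - M)/6``."""
    if not 0 <= M <= 5:
        raise ValueError(f"M must be in 0..5, got {M}")
    if M == 0 or alpha <= (6 - M) / 6 or alpha >= 1.0:
        return None
    return float(brentq(lambda c: case2_alpha_of_C1(M, c) - alpha,
                        1e-14, 1.0 - 1e-14, xtol=_INV_XTOL))


def _check_tangential_args(M: int, C_hat: float, beta: float) -> None:
    if M not in (1, 2, 3, 4):
        raise ValueError(
            f"the tangential manifold exists only for M in 1..4, got M = {M}")
    if not 0.0 < C_hat < 1.0:
        raise ValueError(f"C_hat must lie in (0, 1), got {C_hat}")
    if not 0.0 <= beta < (5 - M) / 6:
        raise ValueError(
            f"beta must lie in [0, (5-M)/6) = [0, {(5 - M) / 6:.4g}), got {beta}")


def _polyval_ld(x, coef):
    """Polynomial evaluation in extended precision.

    The tangential closed forms have denominators that nearly cancel close
    to the junction point at small beta; float64 evaluation noise there is
    of order 1e-8 relative, which extended precision pushes below 1e-11.
    """
    return np.polynomial.polynomial.polyval(
        np.longdouble(x), np.asarray(coef, dtype=np.longdouble))


def tangential_R(M: int, C_hat: float, beta: float) -> float:
    """Closed-form high-density rate ``R`` on the tangential manifold."""
    _check_tangential_args(M, C_hat, beta)
    num, den0, den_b, k = _TANGENTIAL_R[M]
    b = np.longdouble(beta)
    den = np.longdouble(C_hat)**k * (_polyval_ld(C_hat, den0) + den_b * b)
    return float(_polyval_ld(C_hat, num) / den)


def tangential_alpha(M: int, C_hat: float, beta: float) -> float:
    """Closed-form low-density death ratio ``alpha`` on the tangential manifold."""
    _check_tangential_args(M, C_hat, beta)
    num0, num_b, den0, den_b = _TANGENTIAL_ALPHA[M]
    b = np.longdouble(beta)
    num = _polyval_ld(C_hat, num0) + b * _polyval_ld(C_hat, num_b)
    den = _polyval_ld(C_hat, den0) + den_b * b
    return float(num / den)


def case3_polynomials(M: int, beta: float):
    """Decompose the per-capita law (r = 1) as ``V(C) = a(C) + R*b(C) + alpha*c(C)``.

    Returns three :class:`numpy.polynomial.Polynomial` objects.  ``V`` is
    linear in ``R`` and ``alpha`` separately, which is what makes the
    tangential manifold solvable as a 2x2 linear system.
    """
    C = Polynomial([0.0, 1.0])
    one_minus = Polynomial([1.0, -1.0])
    a = Polynomial([1.0, -1.0])
    b = Polynomial([0.0] * 6 + [-beta])
    c = Polynomial([-1.0] + [0.0] * 5 + [1.0])
    for j in range(M + 1, 6):
        w = math.comb(5, j) * C**j * one_minus**(6 - j)
        a = a - w
        b = b + w * (1.0 - 6.0 * beta / (6 - j))
        c = c + w * (6.0 / (6 - j))
    return a, b, c


def tangential_point(M: int, C_hat: float, beta: float) -> TangentialPoint:
    """Parameters ``(R, alpha)`` making ``C_hat`` a double root of the growth law.

    Solved from the 2x2 linear system "growth rate and its slope both vanish
    at ``C_hat``" (the per-capita law is linear in ``R`` and ``alpha``); the
    closed forms :func:`tangential_R` / :func:`tangential_alpha` agree to
    rounding error.  Points beyond the junction (``alpha > 1``) are rejected
    as they leave the admissible parameter ranges.
    """
    _check_tangential_args(M, C_hat, beta)
    a, b, c = case3_polynomials(M, beta)

    # Cramer's rule in extended precision: the system turns singular on a
    # curve in (C_hat, beta) and float64 loses ~6 digits nearby
    ld = np.longdouble
    x = ld(C_hat)

    def ev(p):
        return np.polynomial.polynomial.polyval(x, p.coef.astype(ld))

    ax, bx, cx = ev(a), ev(b), ev(c)
    apx, bpx, cpx = ev(a.deriv()), ev(b.deriv()), ev(c.deriv())
    det = bx * cpx - cx * bpx
    scale = max(abs(bx), abs(cx), abs(bpx), abs(cpx), ld(1.0))
    if abs(det) < 1e-14 * scale * scale:
        raise ValueError(
            f"singular tangency system at C_hat={C_hat}, beta={beta}, M={M}")
    R = float((-ax * cpx + cx * apx) / det)
    alpha = float((-bx * apx + ax * bpx) / det)
    if R < -1e-9 or alpha < -1e-9 or alpha > 1.0 + 1e-9:
        raise ValueError(
            f"C_hat={C_hat} is not on the admissible manifold for beta={beta}, "
            f"M={M}: it maps to R={R:.6g}, alpha={alpha:.6g} outside the "
            "parameter ranges (the negative branch ends at the junction point)")
    C_triple = triple_point(M, beta).C_triple
    branch = "positive" if C_hat <= C_triple else "negative"
    return TangentialPoint(M=M, C_hat=float(C_hat), beta=float(beta),
                           R=float(R), alpha=float(alpha), branch=branch)


def triple_point_beta(M: int, C: float) -> float:
    """Closed-form ``beta`` at which ``C`` is the triple-root location."""
    if M not in (1, 2, 3, 4):
        raise ValueError(f"triple point exists only for M in 1..4, got {M}")
    return float(_ratio(_TRIPLE, M, C, "the triple-point relation"))


def triple_point(M: int, beta: float) -> TriplePoint | None:
    """Triple-root location for given ``beta``; ``None`` outside ``[0, (5-M)/6]``.

    The location decreases monotonically from 1 (at ``beta = 0``) to 0 (at
    ``beta = (5-M)/6``).  The returned ``residual`` is the second derivative
    of the growth law at the point with ``(R, alpha)`` taken on the
    tangential manifold — zero up to round-off by construction.
    """
    if M not in (1, 2, 3, 4):
        raise ValueError(f"triple point exists only for M in 1..4, got {M}")
    bmax = (5 - M) / 6
    if not 0.0 <= beta <= bmax:
        return None
    if beta == 0.0:
        C = 1.0
    elif beta == bmax:
        C = 0.0
    else:
        C = float(brentq(lambda c: triple_point_beta(M, c) - beta, 0.0, 1.0,
                         xtol=_INV_XTOL))
    if 0.0 < C < 1.0:
        a, b, c_ = case3_polynomials(M, beta)
        R = tangential_R(M, C, beta)
        alpha = tangential_alpha(M, C, beta)
        x = Polynomial([0.0, 1.0])
        growth = x * (a + R * b + alpha * c_)
        residual = float(growth.deriv(2)(C))
    else:
        residual = 0.0
    return TriplePoint(M=M, C_triple=C, beta=float(beta), residual=residual)


def junction_point_beta(M: int, C: float) -> float:
    """Closed-form ``beta`` at which ``C`` is the junction-point location."""
    if M not in (1, 2, 3, 4):
        raise ValueError(f"junction point exists only for M in 1..4, got {M}")
    return float(_ratio(_JUNCTION, M, C, "the junction-point relation"))


def junction_point(M: int, beta: float) -> JunctionPoint | None:
    """Junction-point location and critical rate ``R`` for given ``beta``.

    Solves ``junction_point_beta(M, C) = beta`` on ``[0, 1]``; ``None``
    outside ``[0, (5-M)/6]``.  At the returned point the tangential-manifold
    ``alpha`` equals 1 exactly (checked by the test suite to 1e-9).
    """
    if M not in (1, 2, 3, 4):
        raise ValueError(f"junction point exists only for M in 1..4, got {M}")
    bmax = (5 - M) / 6
    if not 0.0 <= beta <= bmax:
        return None
    if beta == 0.0:
        C = 1.0
    elif beta == bmax:
        C = 0.0
    else:
        C = float(brentq(lambda c: junction_point_beta(M, c) - beta, 0.0, 1.0,
                         xtol=_INV_XTOL))
        # polish on the defining identity G(C, beta) = 1 written pole-free:
        # num(C) - den(C) = 0.  At small beta the junction point approaches a
        # pole of the rational closed forms (root-pole distance ~ beta**2),
        # so the identity must be polished on the polynomial difference, in
        # extended precision.
        ld = np.longdouble
        num0, num_b, den0, den_b = _TANGENTIAL_ALPHA[M]
        width = max(len(num0), len(num_b), len(den0))
        q = np.zeros(width, dtype=ld)
        q[: len(num0)] += np.asarray(num0, dtype=ld)
        q[: len(num_b)] += ld(beta) * np.asarray(num_b, dtype=ld)
        q[: len(den0)] -= np.asarray(den0, dtype=ld)
        q[0] -= ld(den_b) * ld(beta)
        dq = np.polynomial.polynomial.polyder(q)
        x = ld(C)
        for _ in range(6):
            slope = np.polynomial.polynomial.polyval(x, dq)
            if slope == 0.0:
                break
            step = np.polynomial.polynomial.polyval(x, q) / slope
            x -= step
            if abs(step) < 1e-18:
                break
        if 0.0 < x < 1.0:
            C = float(x)
    if 0.0 < C < 1.0:
        R = tangential_R(M, C, beta)
    else:
        # degenerate endpoints: fall back to the linear tangency system limit
        R = float("nan")
    return JunctionPoint(M=M, C_junction=C, beta=float(beta), R_junction=R)


def regime_map(M: int, beta: float, alpha_grid=None, R_grid=None,
               r: float = 1.0) -> RegimeMap:
    """Classify the growth regime over an ``(alpha, R)`` grid at fixed ``M, beta``.

    ``r`` defaults to 1; other values only rescale time and are rescaled
    internally, so they do not change the map.
    """
    if alpha_grid is None:
        alpha_grid = np.linspace(0.0, 1.0, 201)
    if R_grid is None:
        R_grid = np.linspace(0.0, 3.0, 201)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    R_grid = np.asarray(R_grid, dtype=float)
    labels = np.empty((len(alpha_grid), len(R_grid)), dtype=object)
    for i, alpha in enumerate(alpha_grid):
        for j, R in enumerate(R_grid):
            params = BinarySwitchParams(r=1.0, R=R / r, alpha=alpha,
                                        beta=beta, M=M)
            try:
                labels[i, j] = classify_regime(params)
            except DegenerateGrowthError:
                # growth vanishes identically (e.g. M=0, alpha=1, R=0):
                # no regime label applies
                labels[i, j] = None
    return RegimeMap(M=M, beta=float(beta), alpha_grid=alpha_grid,
                     R_grid=R_grid, labels=labels)
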