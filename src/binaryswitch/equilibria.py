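"""Equilibria, stability, and qualitative regime classification.

The growth law is a degree-7 polynomial in the density ``C`` with a
structural root at ``C = 0``, so all equilibria are polynomial roots in
``[0, 1]``.  Beyond the zero state the model admits at most three distinct
equilibria in ``(0, 1]``; their number, multiplicity and stability determine
which member of the Allee-effect family the parameters produce:

========================  ==========================  =====================
regime                    equilibria (ascending)      stability
========================  ==========================  =====================
Extinction                {0}                         {S}
Logistic                  {0, C1}                     {U, S}   (r=R, a=b)
Weak Allee                {0, C1}                     {U, S}
Triple Point              {0, C1 (triple root)}       {U, S}
Junction Point            {0, C1 (double root)}       {S, SS}
Strong Allee              {0, C1, C2}                 {S, U, S}
Reverse Allee             {0, C1, 1}                  {U, S, U}
Positive Tangential M.    {0, C1 (double), C2}        {U, SS, S}
Negative Tangential M.    {0, C1, C2 (double)}        {U, S, SS}
Hyper-Allee               {0, C1, C2, C3}             {U, S, U, S}
========================  ==========================  =====================

Boundary equilibria (0 and 1) are classified one-sidedly from the sign of
the growth rate on the interior side; interior equilibria follow the usual
odd/even-multiplicity derivative rule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .model import BinarySwitchParams, polynomial_coefficients

__all__ = [
    "Stability",
    "Equilibrium",
    "EquilibriumSet",
    "RegimeLabel",
    "DegenerateGrowthError",
    "RootFindingError",
    "UnrecognisedRegimeError",
    "find_equilibria",
    "stability_of_root",
    "classify_regime",
]

#: a root below this counts as the structural zero equilibrium
ZERO_CUTOFF = 1e-9
#: default clustering tolerance for multiplicity detection
CLUSTER_TOL = 1e-6
# eigen-roots of an m-fold root scatter like eps**(1/m) into the complex
# plane (~1e-5 for a triple root), so near-real detection must be looser
# than the clustering tolerance
_IMAG_TOL = 2e-5
_RESIDUAL_TOL = 1e-9
_DERIV_TOL = 1e-7


class Stability(str, enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    SEMI_STABLE = "semi-stable"


class RegimeLabel(str, enum.Enum):
    EXTINCTION = "Extinction"
    LOGISTIC = "Logistic"
    WEAK_ALLEE = "WeakAllee"
    TRIPLE_POINT = "TriplePoint"
    JUNCTION_POINT = "JunctionPoint"
    STRONG_ALLEE = "StrongAllee"
    REVERSE_ALLEE = "ReverseAllee"
    POSITIVE_TANGENTIAL = "PositiveTangentialManifold"
    NEGATIVE_TANGENTIAL = "NegativeTangentialManifold"
    HYPER_ALLEE = "HyperAllee"


class DegenerateGrowthError(ValueError):
    """The growth rate vanishes identically (all rates zero)."""


class RootFindingError(RuntimeError):
    """Root residuals failed to meet tolerance; diagnostics in the message."""


class UnrecognisedRegimeError(RuntimeError):
    """Equilibrium signature matches no known regime (bug sentinel)."""

    def __init__(self, signature):
        self.signature = signature
        super().__init__(f"unrecognised equilibrium signature: {signature}")


@dataclass(frozen=True)
class Equilibrium:
    value: float
    multiplicity: int
    stability: Stability

    def to_dict(self) -> dict:
        return {"value": self.value, "multiplicity": self.multiplicity,
                "stability": self.stability.value}


@dataclass(frozen=True)
class EquilibriumSet:
    equilibria: tuple
    params: BinarySwitchParams

    @property
    def values(self) -> np.ndarray:
        return np.array([e.value for e in self.equilibria])

    @property
    def interior(self) -> tuple:
        """Equilibria in (0, 1] (i.e. excluding the structural zero state)."""
        return tuple(e for e in self.equilibria if e.value > ZERO_CUTOFF)

    def signature(self) -> tuple:
        return tuple(e.stability.value for e in self.equilibria)

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(),
                "equilibria": [e.to_dict() for e in self.equilibria]}


def stability_of_root(coef, root: float, multiplicity: int) -> Stability:
    """Stability of an interior equilibrium from the multiplicity rule.

    For a root of multiplicity ``m``, the sign of the ``m``-th derivative of
    the growth polynomial decides: odd ``m`` with negative derivative is
    stable, positive unstable; even ``m`` is semi-stable regardless of sign.
    ``coef`` are ascending polynomial coefficients.
    """
    poly = Polynomial(np.asarray(coef, dtype=float))
    d = poly
    for _ in range(multiplicity):
        d = d.deriv()
    val = d(root)
    if abs(val) < 1e-12:
        raise DegenerateGrowthError(
            f"derivative of order {multiplicity} vanishes at root {root}; "
            "multiplicity is higher than claimed or the polynomial is degenerate")
    if multiplicity % 2 == 0:
        return Stability.SEMI_STABLE
    return Stability.STABLE if val < 0 else Stability.UNSTABLE


def _one_sided_stability(poly: Polynomial, at: float, side: str,
                         multiplicity: int) -> Stability:
    """Boundary equilibria: classify from the growth-rate sign on the interior side.

    For an m-fold root the leading local behaviour is
    ``p(at + h) ~ p^(m)(at) h**m / m!``, so the sign on the interior side is
    read off the m-th derivative — pointwise evaluation next to a high-order
    root is dominated by cancellation noise.
    """
    val = poly.deriv(multiplicity)(at)
    if val == 0.0:
        raise DegenerateGrowthError(
            f"growth rate vanishes to order {multiplicity + 1} at {at}")
    if side == "left":
        val *= (-1.0) ** multiplicity
    if side == "right":
        return Stability.UNSTABLE if val > 0 else Stability.STABLE
    return Stability.STABLE if val > 0 else Stability.UNSTABLE


def _polish(poly: Polynomial, x0: float, order: int) -> float:
    """Newton-polish a root of the ``order``-th derivative (order 0 = poly itself)."""
    f = poly
    for _ in range(order):
        f = f.deriv()
    fp = f.deriv()
    x = x0
    for _ in range(40):
        fx = f(x)
        fpx = fp(x)
        if fpx == 0.0:
            break
        step = fx / fpx
        x -= step
        if abs(step) < 1e-15:
            break
    # keep the polish honest: reject a Newton escape far from the cluster
    if abs(x - x0) > 1e-3:
        return x0
    return min(max(x, 0.0), 1.0)


def _deflate_at_one(coef_ascending: list) -> tuple:
    """Synthetic division by ``(C - 1)``; returns (quotient ascending, remainder)."""
    d = coef_ascending[::-1]
    b = [d[0]]
    for di in d[1:]:
        b.append(di + b[-1])
    return b[:-1][::-1], b[-1]


def _tangency_ok(poly: Polynomial, cluster: list) -> bool:
    """Would treating ``cluster`` as one m-fold root satisfy the tangency residuals?"""
    m = len(cluster)
    x = _polish(poly, float(np.mean(cluster)), m - 1)
    if abs(poly(x)) > _RESIDUAL_TOL:
        return False
    d = poly
    for _ in range(m - 1):
        d = d.deriv()
        if abs(d(x)) > _DERIV_TOL * max(1.0, abs(d.deriv()(x))):
            return False
    return True


def find_equilibria(params: BinarySwitchParams,
                    tol: float = CLUSTER_TOL) -> EquilibriumSet:
    """All equilibria of the growth law in ``[0, 1]`` with multiplicity and stability.

    Roots come from companion-matrix eigenvalues of the expanded degree-7
    polynomial, are clustered within ``tol`` to detect double/triple roots,
    Newton-polished, and residual-checked.  The zero equilibrium is always
    reported first.  ``C = 1`` is an equilibrium exactly when ``beta = 0``
    and is handled through that exact condition rather than numerically.
    """
    coef = polynomial_coefficients(params)
    scale = float(np.max(np.abs(coef)))
    if scale == 0.0:
        raise DegenerateGrowthError("all rates are zero; every density is an equilibrium")
    poly = Polynomial(coef)

    # deflate the structural roots exactly before the eigen-solve: C = 0 is
    # always an equilibrium (possibly multiple when low-density turnover
    # vanishes), and the packed state C = 1 is one exactly when the
    # high-density death rate R*beta vanishes.  Eigenvalues of an m-fold
    # root scatter like eps**(1/m), so these must not go through `roots()`.
    work = list(coef)
    m0 = 0
    while len(work) > 1 and abs(work[0]) < 1e-13 * scale:
        work.pop(0)
        m0 += 1
    m1 = 0
    if params.R * params.beta == 0.0:
        while len(work) > 1:
            quotient, rem = _deflate_at_one(work)
            if abs(rem) < 1e-10 * scale:
                work = quotient
                m1 += 1
            else:
                break

    q = Polynomial(np.asarray(work))
    q_roots = q.roots() if q.degree() >= 1 else np.array([])
    real = q_roots[np.abs(q_roots.imag) < _IMAG_TOL].real
    real = real[(real > -tol) & (real < 1.0 + tol)]
    real = np.clip(real, 0.0, 1.0)

    # cluster; structural roots are prepended so nearby eigen-roots merge in
    pts = np.sort(np.concatenate(([0.0] * m0, [1.0] * m1, real)))
    clusters: list[list[float]] = [[float(pts[0])]]
    for x in pts[1:]:
        if x - clusters[-1][-1] < tol:
            clusters[-1].append(float(x))
        else:
            clusters.append([float(x)])

    # companion-matrix eigenvalues of an m-fold root scatter like eps**(1/m),
    # wider than `tol` for m >= 3; merge adjacent clusters when the combined
    # cluster genuinely passes the tangency (vanishing-derivative) checks
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        for i in range(len(clusters) - 1):
            gap = clusters[i + 1][0] - clusters[i][-1]
            if gap >= 100 * tol:
                continue
            cand = clusters[i] + clusters[i + 1]
            if cand[0] == 0.0 or cand[-1] == 1.0:
                continue  # never absorb interior roots into a boundary state
            if _tangency_ok(poly, cand):
                clusters[i: i + 2] = [cand]
                merged = True
                break

    reps: list[tuple[float, int]] = []
    for cl in clusters:
        m = len(cl)
        x0 = float(np.mean(cl))
        if x0 <= ZERO_CUTOFF or cl[0] == 0.0:
            reps.append((0.0, m))
            continue
        if cl[-1] == 1.0:
            reps.append((1.0, m))
            continue
        if m == 1:
            reps.append((_polish(poly, x0, 0), 1))
            continue
        x = _polish(poly, x0, m - 1)
        if m == 2 and abs(poly.deriv()(x)) > _DERIV_TOL:
            # eigen-roots merely close, not tangent: keep them as simple roots
            for xi in cl:
                reps.append((_polish(poly, xi, 0), 1))
        else:
            reps.append((x, m))

    reps.sort()
    eqs = []
    for x, m in reps:
        if x <= ZERO_CUTOFF:
            stab = _one_sided_stability(poly, 0.0, "right", m)
        elif x >= 1.0 - ZERO_CUTOFF:
            stab = _one_sided_stability(poly, 1.0, "left", m)
        else:
            if abs(poly(x)) > _RESIDUAL_TOL:
                raise RootFindingError(
                    f"root {x} of multiplicity {m} has residual {poly(x):.3e} "
                    f"(params {params.to_dict()})")
            stab = stability_of_root(coef, x, m)
        eqs.append(Equilibrium(value=x, multiplicity=m, stability=stab))
    return EquilibriumSet(equilibria=tuple(eqs), params=params)


_SIGNATURES = {
    ("stable",): RegimeLabel.EXTINCTION,
    ("stable", "unstable", "stable"): RegimeLabel.STRONG_ALLEE,
    ("unstable", "stable", "unstable"): RegimeLabel.REVERSE_ALLEE,
    ("unstable", "semi-stable", "stable"): RegimeLabel.POSITIVE_TANGENTIAL,
    ("unstable", "stable", "semi-stable"): RegimeLabel.NEGATIVE_TANGENTIAL,
    ("unstable", "stable", "unstable", "stable"): RegimeLabel.HYPER_ALLEE,
}


def classify_regime(params: BinarySwitchParams,
                    tol: float = CLUSTER_TOL) -> RegimeLabel:
    """Map a parameter set to its qualitative growth regime.

    Logistic growth is reported only on the exact no-switch condition
    ``r = R`` and ``alpha = beta`` (with a surviving carrying state); the
    manifold/point labels require a non-simple root detected within ``tol``.
    """
    eqset = find_equilibria(params, tol=tol)
    sig = eqset.signature()
    interior = eqset.interior

    if (params.r == params.R and params.alpha == params.beta
            and sig == ("unstable", "stable")):
        return RegimeLabel.LOGISTIC
    if sig == ("unstable", "stable"):
        # A stable triple root marks the triple point.  Higher-order or
        # triple contact at the packed state C=1 with R=0 is structural to
        # the no-high-density-turnover slice, not a bifurcation point.
        if interior[0].multiplicity == 3 and (
                interior[0].value < 1.0 - ZERO_CUTOFF or params.R > 0):
            return RegimeLabel.TRIPLE_POINT
        return RegimeLabel.WEAK_ALLEE
    if sig == ("stable", "semi-stable"):
        return RegimeLabel.JUNCTION_POINT
    if sig == ("stable", "unstable") and interior[-1].value >= 1.0 - ZERO_CUTOFF:
        # growth is non-positive everywhere below the (repelling) packed state
        return RegimeLabel.EXTINCTION
    label = _SIGNATURES.get(sig)
    if label is None:
        raise UnrecognisedRegimeError(sig)
    return label
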