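"""Closed-form bifurcation structure against its defining conditions."""

import numpy as np
import pytest

from binaryswitch import (
    BinarySwitchParams,
    RegimeLabel,
    classify_regime,
    case1_beta_of_C1,
    case1_C1_of_beta,
    case2_alpha_of_C1,
    case2_C1_of_alpha,
    junction_point,
    junction_point_beta,
    per_capita_rate,
    regime_map,
    tangential_alpha,
    tangential_point,
    tangential_R,
    triple_point,
    triple_point_beta,
)
from binaryswitch.manifolds import case3_polynomials


def case1_residual(M, C1, beta):
    """Defining condition of the r=0 slice: per-capita rate vanishes at C1."""
    return per_capita_rate(C1, BinarySwitchParams(0.0, 1.0, 0.0, beta, M))


def case2_residual(M, C1, alpha):
    return per_capita_rate(C1, BinarySwitchParams(1.0, 0.0, alpha, 0.0, M))


class TestCase1:
    @pytest.mark.parametrize("M, C1, expected", [
        (4, 0.8, 0.1),
        (0, 1.0, 0.0),
        (2, 1e-9, 0.5),
    ])
    def test_known_values(self, M, C1, expected):
        assert case1_beta_of_C1(M, C1) == pytest.approx(expected, abs=1e-6)

    def test_undefined_for_top_threshold(self):
        with pytest.raises(ValueError):
            case1_beta_of_C1(5, 0.5)

    @pytest.mark.parametrize("M", range(5))
    def test_defining_residual_and_monotone(self, M):
        C = np.linspace(1e-3, 1.0, 500)
        beta = np.array([case1_beta_of_C1(M, c) for c in C])
        assert np.all(np.diff(beta) < 0)  # one-to-one
        for c, b in zip(C[::25], beta[::25]):
            assert abs(case1_residual(M, c, b)) < 1e-10
        assert beta[0] == pytest.approx((5 - M) / 6, abs=1e-2)

    @pytest.mark.parametrize("M, beta, expected", [
        (4, 0.1, 0.8), (4, 1 / 6, None), (5, 0.05, None), (1, 2 / 3, None),
    ])
    def test_inverse(self, M, beta, expected):
        got = case1_C1_of_beta(M, beta)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-9)


class TestCase2:
    @pytest.mark.parametrize("M, C1, expected", [
        (5, 1 - 1e-9, 1 / 6),
        (1, 1e-9, 1.0),
        (1, 1 - 1e-9, 5 / 6),
    ])
    def test_range_endpoints(self, M, C1, expected):
        assert case2_alpha_of_C1(M, C1) == pytest.approx(expected, abs=1e-6)

    def test_undefined_for_zero_threshold(self):
        with pytest.raises(ValueError):
            case2_alpha_of_C1(0, 0.5)

    @pytest.mark.parametrize("M", range(1, 6))
    def test_defining_residual_and_monotone(self, M):
        C = np.linspace(1e-3, 1 - 1e-3, 500)
        alpha = np.array([case2_alpha_of_C1(M, c) for c in C])
        assert np.all(np.diff(alpha) < 0)
        for c, a in zip(C[::25], alpha[::25]):
            assert abs(case2_residual(M, c, a)) < 1e-10

    def test_inverse_round_trip(self):
        for M in range(1, 6):
            alpha = 0.5 * ((6 - M) / 6 + 1.0)
            c = case2_C1_of_alpha(M, alpha)
            assert case2_alpha_of_C1(M, c) == pytest.approx(alpha, abs=1e-10)
            assert case2_C1_of_alpha(M, (6 - M) / 6) is None


class TestTangentialManifold:
    def test_closed_forms_match_linear_system(self):
        """The printed rational functions agree with an independent solve of
        the 2x2 tangency system (growth rate and slope vanish)."""
        for M in (1, 2, 3, 4):
            for C_hat in np.linspace(0.05, 0.95, 19):
                for beta in np.linspace(0.0, (5 - M) / 6 * 0.9, 5):
                    try:
                        tp = tangential_point(M, C_hat, beta)
                    except ValueError:
                        continue  # beyond the junction point
                    F = tangential_R(M, C_hat, beta)
                    G = tangential_alpha(M, C_hat, beta)
                    assert tp.R == pytest.approx(F, rel=1e-9, abs=1e-9)
                    assert tp.alpha == pytest.approx(G, rel=1e-9, abs=1e-9)

    def test_defining_residuals(self):
        for M in (1, 2, 3, 4):
            beta = 0.3 * (5 - M) / 6
            a, b, c = case3_polynomials(M, beta)
            for C_hat in (0.2, 0.5, 0.7):
                try:
                    tp = tangential_point(M, C_hat, beta)
                except ValueError:
                    continue
                V = a(C_hat) + tp.R * b(C_hat) + tp.alpha * c(C_hat)
                dV = (a.deriv()(C_hat) + tp.R * b.deriv()(C_hat)
                      + tp.alpha * c.deriv()(C_hat))
                scale = max(1.0, abs(tp.R))
                assert abs(V) < 1e-9 * scale and abs(dV) < 1e-9 * scale

    def test_undefined_for_extreme_thresholds(self):
        for M in (0, 5):
            with pytest.raises(ValueError):
                tangential_point(M, 0.5, 0.05)

    def test_no_negative_branch_at_beta_zero(self):
        """At beta=0 the triple point sits at C=1, so every double root lies
        on the positive branch."""
        for M in (1, 2, 3, 4):
            assert triple_point(M, 0.0).C_triple == 1.0
            for C_hat in (0.3, 0.6, 0.9):
                try:
                    tp = tangential_point(M, C_hat, 0.0)
                except ValueError:
                    continue
                assert tp.branch == "positive"

    def test_branch_stability_signatures(self):
        """Positive branch: {0 U, double SS, S}; negative: {0 U, S, double SS}."""
        tp = tangential_point(4, 0.4, 0.06)
        lbl = classify_regime(BinarySwitchParams(1, tp.R, tp.alpha, 0.06, 4))
        assert lbl == RegimeLabel.POSITIVE_TANGENTIAL
        tn = tangential_point(4, 0.83, 0.06)
        assert tn.branch == "negative"
        lbl = classify_regime(BinarySwitchParams(1, tn.R, tn.alpha, 0.06, 4))
        assert lbl == RegimeLabel.NEGATIVE_TANGENTIAL


class TestTriplePoint:
    @pytest.mark.parametrize("M", (1, 2, 3, 4))
    def test_beta_zero_gives_packed_state(self, M):
        assert triple_point(M, 0.0).C_triple == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_value(self):
        # H_1(C) = 2(1-C)/3, so C=0.25 pairs with beta=0.5
        assert triple_point_beta(1, 0.25) == pytest.approx(0.5)
        assert triple_point(1, 0.5).C_triple == pytest.approx(0.25, abs=1e-9)

    @pytest.mark.parametrize("M", (1, 2, 3, 4))
    def test_collapse_at_maximal_beta(self, M):
        assert triple_point(M, (5 - M) / 6).C_triple == pytest.approx(0.0)

    @pytest.mark.parametrize("M", (1, 2, 3, 4))
    def test_second_derivative_residual(self, M):
        for beta in (0.1 * (5 - M) / 6, 0.6 * (5 - M) / 6):
            tp = triple_point(M, beta)
            assert abs(tp.residual) < 1e-8

    def test_out_of_range_beta(self):
        assert triple_point(4, 0.5) is None


class TestJunctionPoint:
    @pytest.mark.parametrize("M, C, expected", [
        (4, 1.0, 0.0), (4, 0.0, 1 / 6),
    ])
    def test_closed_form_endpoints(self, M, C, expected):
        assert junction_point_beta(M, C) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("M", (1, 2, 3, 4))
    def test_alpha_is_one_at_junction(self, M):
        """The junction point is exactly where the tangential-manifold death
        ratio alpha reaches 1."""
        for C in (0.3, 0.5, 0.8):
            beta = junction_point_beta(M, C)
            assert tangential_alpha(M, C, beta) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("M", (1, 2, 3, 4))
    def test_round_trip_and_critical_R(self, M):
        beta = junction_point_beta(M, 0.5)
        jp = junction_point(M, beta)
        assert jp.C_junction == pytest.approx(0.5, abs=1e-9)
        assert jp.R_junction == pytest.approx(
            tangential_R(M, 0.5, beta), rel=1e-9)


class TestRegimeMap:
    def test_extreme_threshold_map_weak_or_extinct(self):
        """For M=0 (with beta past the r=0-slice cutoff 5/6) every admissible
        cell is Weak Allee below alpha=1 and Extinction at alpha=1."""
        rm = regime_map(0, 0.9, np.linspace(0, 1, 11), np.linspace(0, 2, 9))
        for i, alpha in enumerate(rm.alpha_grid):
            for j in range(len(rm.R_grid)):
                lbl = rm.labels[i, j]
                if lbl is None:
                    continue  # identically-zero growth at (alpha=1, R=0)
                if alpha == 1.0:
                    assert lbl == RegimeLabel.EXTINCTION
                elif alpha == rm.beta and rm.R_grid[j] == 1.0:
                    # the exact no-switch line r=R, alpha=beta inside the grid
                    assert lbl == RegimeLabel.LOGISTIC
                else:
                    assert lbl == RegimeLabel.WEAK_ALLEE

    def test_no_bistability_when_beta_too_large(self):
        rm = regime_map(4, 1 / 6, np.linspace(0, 1, 11), np.linspace(0, 3, 11))
        labels = {l for l in rm.labels.ravel() if l is not None}
        assert RegimeLabel.HYPER_ALLEE not in labels
        assert RegimeLabel.STRONG_ALLEE not in labels

    def test_hyper_allee_region_bounded_by_manifold(self):
        """Crossing the positive tangential branch from outside to inside the
        wedge switches Weak Allee -> Hyper Allee."""
        beta, M = 0.06, 4
        for C_hat in (0.3, 0.45, 0.6):
            tp = tangential_point(M, C_hat, beta)
            labels = {
                classify_regime(BinarySwitchParams(1, tp.R * s, tp.alpha,
                                                   beta, M))
                for s in (0.98, 1.02)}
            assert labels == {RegimeLabel.HYPER_ALLEE, RegimeLabel.WEAK_ALLEE}
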