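"""Combined least-squares calibration and the synthetic-data generator."""

import numpy as np
import pytest

from binaryswitch import (
    BinarySwitchParams,
    CalibrationTheta,
    GrowthCurveModel,
    GrowthDataset,
    fit_for_M,
    generate_synthetic_growth,
    load_reference_fits,
    model_select,
    solve_trajectory,
    sum_sq_error,
)
from binaryswitch.calibration import (
    datasets_from_frame,
    datasets_to_frame,
    predict_densities,
)
from binaryswitch.model import solve_trajectories


def naive_sse(theta, datasets):
    """Loop re-implementation of the combined objective (same integrator)."""
    total = 0.0
    for i, ds in enumerate(datasets):
        pred = predict_densities(
            CalibrationTheta(M=theta.M, r=theta.r, R=theta.R,
                             alpha=theta.alpha, beta=theta.beta,
                             C0=(theta.C0[i],)), ds.times)[:, 0]
        for c_model, c_obs in zip(pred, ds.densities):
            total += (c_model - c_obs) ** 2
    return total


class TestSumSqError:
    def test_noise_free_self_consistency(self, reference_truth):
        ds = generate_synthetic_growth(reference_truth, sigma=0.0, seed=0)
        assert sum_sq_error(reference_truth, ds) <= 1e-10

    def test_single_point_arithmetic(self):
        theta = CalibrationTheta(M=2, r=1, R=1, alpha=0.1, beta=0.1, C0=(0.5,))
        ds = [GrowthDataset("x", np.array([0.0]), np.array([0.3]))]
        assert sum_sq_error(theta, ds) == pytest.approx(0.04, abs=1e-12)

    def test_additivity_over_datasets(self, reference_truth):
        ds = generate_synthetic_growth(reference_truth, sigma=0.01, seed=3)
        total = sum_sq_error(reference_truth, ds)
        parts = 0.0
        for i, d in enumerate(ds):
            theta_i = CalibrationTheta(
                M=reference_truth.M, r=reference_truth.r, R=reference_truth.R,
                alpha=reference_truth.alpha, beta=reference_truth.beta,
                C0=(reference_truth.C0[i],))
            parts += sum_sq_error(theta_i, [d])
        assert total == pytest.approx(parts, abs=1e-12)

    def test_matches_naive_loop(self, reference_truth):
        ds = generate_synthetic_growth(reference_truth, sigma=0.01, seed=5)
        assert sum_sq_error(reference_truth, ds) == pytest.approx(
            naive_sse(reference_truth, ds), abs=1e-12)

    def test_fast_integrator_matches_adaptive(self, reference_truth):
        """The compiled fixed-step integrator used inside the objective agrees
        with the adaptive reference solver far below observation noise."""
        t = np.arange(0.0, 121.0, 3.0)
        fast = predict_densities(reference_truth, t)
        ref = solve_trajectories(reference_truth.params(),
                                 reference_truth.C0, t)
        assert np.max(np.abs(fast - ref)) < 1e-6

    def test_mismatched_c0_count(self, reference_truth):
        ds = generate_synthetic_growth(reference_truth, sigma=0.0, seed=0)
        bad = CalibrationTheta(M=1, r=0.02, R=0.03, alpha=0.1, beta=0.1,
                               C0=(0.02,))
        with pytest.raises(ValueError):
            sum_sq_error(bad, ds[:3])


class TestSyntheticGenerator:
    def test_zero_noise_exact_model_curves(self, reference_truth):
        ds = generate_synthetic_growth(reference_truth, sigma=0.0, seed=1)
        assert len(ds) == 3
        for i, d in enumerate(ds):
            ref = solve_trajectory(reference_truth.params(),
                                   reference_truth.C0[i], d.times)
            assert np.max(np.abs(d.densities - ref.densities)) < 1e-7

    def test_seed_determinism(self, reference_truth):
        a = generate_synthetic_growth(reference_truth, sigma=0.01, seed=42)
        b = generate_synthetic_growth(reference_truth, sigma=0.01, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.densities, y.densities)

    def test_residual_sd_matches_sigma(self, reference_truth):
        sigma = 0.01
        resid = []
        for seed in range(5):
            for i, d in enumerate(generate_synthetic_growth(
                    reference_truth, sigma=sigma, seed=seed)):
                clean = solve_trajectory(reference_truth.params(),
                                         reference_truth.C0[i],
                                         d.times).densities
                keep = (clean > 3 * sigma) & (clean < 1 - 3 * sigma)  # unclipped
                resid.extend((d.densities - clean)[keep])
        resid = np.asarray(resid)
        se = sigma / np.sqrt(2 * (len(resid) - 1))  # sd-estimator spread
        assert abs(resid.std(ddof=1) - sigma) < 3 * se


class TestFitting:
    def test_fixed_point_recovery_from_truth(self, reference_truth):
        """Noise-free data with the optimiser started at the generating
        parameters: the optimum stays there with (near-)zero objective."""
        ds = generate_synthetic_growth(reference_truth, sigma=0.0, seed=0)
        entry = fit_for_M(ds, 1, start=reference_truth, restarts=1, seed=0)
        assert entry.sse <= 1e-9
        assert entry.theta.r == pytest.approx(reference_truth.r, rel=0.05)

    def test_descent_property(self, reference_truth):
        ds = generate_synthetic_growth(reference_truth, sigma=0.01, seed=2)
        start = CalibrationTheta(M=1, r=0.05, R=0.05, alpha=0.3, beta=0.3,
                                 C0=(0.03, 0.05, 0.15))
        entry = fit_for_M(ds, 1, start=start, restarts=1, seed=0, maxfev=800)
        assert entry.sse <= sum_sq_error(start, ds)

    def test_model_select_structure(self, reference_truth):
        ds = generate_synthetic_growth(reference_truth, sigma=0.005, seed=0)
        res = model_select(ds, restarts=1, seed=0, maxfev=200)
        assert len(res.per_M) == 6
        assert [e.M for e in res.per_M] == list(range(6))
        assert res.sse == min(e.sse for e in res.per_M)
        assert res.theta_star.M == min(res.per_M, key=lambda e: e.sse).M

    def test_logistic_data_degenerate_across_thresholds(self):
        """Growth without a switch is nested in every M (r=R, alpha=beta), so
        each per-M fit started from the logistic truth reaches ~zero SSE."""
        truth = CalibrationTheta(M=0, r=0.03, R=0.03, alpha=0.1, beta=0.1,
                                 C0=(0.05, 0.2))
        ds = generate_synthetic_growth(truth, sigma=0.0, seed=0)
        for M in range(6):
            entry = fit_for_M(ds, M, start=truth, restarts=1, seed=0)
            assert entry.sse < 1e-8

    def test_noise_never_improves_noise_free_optimum(self, reference_truth):
        clean = generate_synthetic_growth(reference_truth, sigma=0.0, seed=0)
        noisy = generate_synthetic_growth(reference_truth, sigma=0.01, seed=0)
        assert (sum_sq_error(reference_truth, noisy)
                >= sum_sq_error(reference_truth, clean))


class TestModelResultsApi:
    def test_reference_table_forward_simulates_increasing(self):
        """Every published per-M parameter row yields monotone increasing
        curves from the three printed seeding densities."""
        table = load_reference_fits()
        assert list(table["M"]) == list(range(6))
        t = np.linspace(0.0, 120.0, 41)
        for _, row in table.iterrows():
            params = BinarySwitchParams(r=row["r"], R=row["R"],
                                        alpha=row["alpha"], beta=row["beta"],
                                        M=int(row["M"]))
            for c0 in row["C0"]:
                traj = solve_trajectory(params, c0, t)
                assert np.all(np.diff(traj.densities) > -1e-12)
                assert traj.densities[-1] > traj.densities[0]

    def test_results_object_round_trip(self, reference_truth):
        ds = generate_synthetic_growth(reference_truth, sigma=0.005, seed=1)
        df = datasets_to_frame(ds)
        model = GrowthCurveModel.from_dataframe(df)
        res = model.fit(M=1, start=reference_truth, restarts=1, seed=0,
                        maxfev=400)
        assert res.M == 1
        assert res.sse >= 0
        text = res.summary()
        assert "combined SSE" in text and "threshold M" in text
        pred = res.predict()
        assert set(pred["dataset"]) == {d.label for d in ds}
        back = datasets_from_frame(df)
        for orig, rt in zip(sorted(ds, key=lambda d: d.label),
                            sorted(back, key=lambda d: d.label)):
            assert np.array_equal(orig.densities, rt.densities)
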