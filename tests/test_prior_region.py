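import numpy as np
import pytest

from b2bsample.prior_region import (
    Box,
    CalibrationError,
    PriorSpec,
    RotatedRegion,
    build_box,
    calibrate_all_deltas,
    calibrate_delta,
    find_seed_point,
    lhs_sample,
    local_box,
    pca_region,
    samples_from_csv,
    samples_to_csv,
    volume_ratio,
)
from b2bsample.synthetic_model import N_PARAMS, coefficient_box, lp_feasibility_oracle


class _ToyModel:
    """Scalar response depending on a single coordinate."""

    def __init__(self, fn, nominal=None):
        self.fn = fn
        self.nominal = nominal if nominal is not None else np.zeros(N_PARAMS)

    def evaluate(self, x, n):
        return self.fn(np.asarray(x))


class TestCalibrateDelta:
    def test_linear_inversion(self):
        model = _ToyModel(lambda x: -30.10 + 2.0 * x[0])
        delta, achieved = calibrate_delta(model, 0, target=10.0, tol=1e-6)
        assert delta == pytest.approx(5.0, abs=1e-5)
        assert achieved == pytest.approx(10.0, abs=1e-6)

    def test_quadratic_closed_form(self):
        model = _ToyModel(lambda x: x[0] ** 2)
        delta, achieved = calibrate_delta(model, 0, target=9.0, tol=1e-6)
        assert delta == pytest.approx(3.0, abs=1e-5)
        assert achieved == pytest.approx(9.0, abs=1e-6)

    def test_no_bracket_within_cap(self):
        model = _ToyModel(lambda x: 0.01 * np.tanh(x[0]))  # bounded response
        with pytest.raises(CalibrationError, match="USS_H"):
            calibrate_delta(model, 0, target=10.0)

    def test_synthetic_all_parameters_hit_target(self, model):
        deltas, achieved = calibrate_all_deltas(model, n=4, target=10.0, tol=1e-3)
        assert np.all(deltas > 0)
        assert np.max(np.abs(achieved - 10.0)) <= 1e-3

    def test_recalibration_consistent(self, model):
        # re-applying the returned perturbation reproduces the target change
        delta, _ = calibrate_delta(model, 3, target=10.0, tol=1e-3)
        x = np.asarray(model.nominal.values).copy()
        base = model.evaluate(x, 4)
        x[3] += delta
        assert abs(model.evaluate(x, 4) - base) == pytest.approx(10.0, abs=1e-3)


class TestPriorBox:
    def test_full_and_scaled(self):
        spec = PriorSpec(np.zeros(3), np.array([1.0, 2.0, 4.0]), k=1.0)
        box = build_box(spec)
        assert np.allclose(box.lower, [-1, -2, -4]) and np.allclose(box.upper, [1, 2, 4])
        shrunk = build_box(PriorSpec(spec.x_nom, spec.delta, k=0.4))
        assert np.allclose(shrunk.upper, 0.4 * box.upper)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(np.zeros(2), np.ones(2), k=0.0)
        with pytest.raises(ValueError):
            PriorSpec(np.zeros(2), np.ones(2), k=1.5)


class TestVolumeRatio:
    def test_shrink_to_0p4_in_27d(self):
        # the k = 0.4 shrink is ~5.5e10-fold smaller by volume in 27 dims
        ratio = volume_ratio(0.4, 27)
        assert ratio == pytest.approx((1 / 0.4) ** 27, rel=1e-14)
        assert 5.4e10 < ratio < 5.7e10

    @pytest.mark.parametrize("k,d,expected", [(1.0, 27, 1.0), (0.5, 2, 4.0)])
    def test_analytic_cases(self, k, d, expected):
        assert volume_ratio(k, d) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("k", [0.1, 0.25, 0.4, 0.9, 1.0])
    @pytest.mark.parametrize("d", [1, 5, 27])
    def test_inverse_identity(self, k, d):
        assert volume_ratio(k, d) * k**d == pytest.approx(1.0, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            volume_ratio(0.0, 27)


class TestSeedSearch:
    def test_objective_at_nominal(self, model, table):
        res = find_seed_point(model, table, (5, 6), budget=1)
        # best-found with budget 1 is essentially the nominal start
        assert res.objective <= 17.58

    def test_finds_feasible_seed(self, model, table, cfg):
        res = find_seed_point(model, table, (5, 6), budget=5000)
        assert res.feasible
        # the LP oracle confirms a witness exists for this subset
        assert lp_feasibility_oracle(table, (5, 6), coefficient_box(cfg)).feasible
        for e in (5, 6):
            assert abs(model.evaluate(res.x_opt, e) - table[e].value) <= table[e].uncertainty

    def test_feasible_start_stays_feasible(self, model, table):
        first = find_seed_point(model, table, (5, 6), budget=5000)
        again = find_seed_point(model, table, (5, 6), start=first.x_opt, budget=200)
        assert again.feasible
        assert again.objective <= first.objective + 1e-15


class TestLocalBox:
    def test_multiplicative_rule(self):
        x = np.full(N_PARAMS, 10.0)
        box = local_box(x, rel=1e-3)
        assert np.allclose(box.lower, 9.99) and np.allclose(box.upper, 10.01)

    def test_sign_safe(self):
        x = np.full(N_PARAMS, -4.0)
        box = local_box(x, rel=1e-3)
        assert box.lower[0] == pytest.approx(-4.004)
        assert box.upper[0] == pytest.approx(-3.996)

    def test_zero_vector_fallback(self):
        box = local_box(np.zeros(N_PARAMS), rel=1e-3)
        assert np.all(box.upper - box.lower > 0)


class TestLHS:
    def test_one_point_per_stratum_1d(self):
        box = Box(np.array([0.0]), np.array([1.0]))
        pts = lhs_sample(box, 4, seed=3).ravel()
        counts, _ = np.histogram(pts, bins=np.linspace(0, 1, 5))
        assert np.all(counts == 1)

    def test_deterministic(self, design_box):
        a = lhs_sample(design_box, 100, seed=11)
        b = lhs_sample(design_box, 100, seed=11)
        assert np.array_equal(a, b)

    def test_samples_inside_box(self, design_box):
        X = lhs_sample(design_box, 500, seed=0)
        assert design_box.contains(X).all()

    def test_samples_inside_rotated_region(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((N_PARAMS, N_PARAMS)))
        region = RotatedRegion(rng.standard_normal(N_PARAMS), q,
                               rng.uniform(0.5, 2.0, N_PARAMS))
        X = lhs_sample(region, 400, seed=5)
        Z = region.unmap(X)
        assert np.all(np.abs(Z) <= 1 + 1e-12)
        # vertex mapping check: all unit-cube vertices of a 2-point grid map inside
        corners = region.map_unit(np.array([np.ones(N_PARAMS), -np.ones(N_PARAMS)]))
        assert region.bounding_box().contains(corners).all()

    def test_invalid_n(self, design_box):
        with pytest.raises(ValueError):
            lhs_sample(design_box, 0, seed=1)


class TestPCARegion:
    def test_extension_scales_half_widths(self, rng):
        X = rng.standard_normal((100, N_PARAMS))
        r1 = pca_region(X, extension=1.0)
        r10 = pca_region(X, extension=10.0)
        assert np.allclose(r10.half_widths, 10.0 * r1.half_widths)
        assert np.allclose(r10.axes, r1.axes)

    def test_orthonormal_axes(self, rng):
        X = rng.standard_normal((60, N_PARAMS)) * rng.uniform(0.1, 3.0, N_PARAMS)
        region = pca_region(X)
        assert np.allclose(region.axes.T @ region.axes, np.eye(N_PARAMS), atol=1e-10)

    def test_equivariance_under_rotation(self, rng):
        X = rng.standard_normal((120, N_PARAMS)) * np.linspace(3.0, 0.1, N_PARAMS)
        Q, _ = np.linalg.qr(rng.standard_normal((N_PARAMS, N_PARAMS)))
        r0 = pca_region(X)
        r1 = pca_region(X @ Q.T)
        assert np.allclose(r1.center, Q @ r0.center, atol=1e-10)
        # axes agree up to per-column sign
        overlap = np.abs(np.diag(r1.axes.T @ (Q @ r0.axes)))
        assert np.allclose(overlap, 1.0, atol=1e-8)
        assert np.allclose(np.sort(r1.half_widths), np.sort(r0.half_widths), atol=1e-8)

    def test_degenerate_direction(self):
        X = np.zeros((40, N_PARAMS))
        X[:, 0] = np.linspace(-1, 1, 40)
        region = pca_region(X, extension=1.0, floor=1e-12)
        assert abs(abs(region.axes[0, 0]) - 1.0) < 1e-12
        assert region.half_widths[0] == pytest.approx(1.0)
        assert np.all(region.half_widths[1:] == 1e-12)

    def test_deficient_error_mode(self, rng):
        with pytest.raises(ValueError):
            pca_region(rng.standard_normal((5, N_PARAMS)), on_deficient="error")


def test_samples_csv_round_trip(tmp_path, rng):
    X = rng.standard_normal((7, N_PARAMS))
    path = tmp_path / "samples.csv"
    samples_to_csv(X, path)
    assert np.array_equal(samples_from_csv(path), X)
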