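"""The frequency-distribution transform: normalize, sort, rotate, fit."""

import numpy as np
import pytest

from fdbdrill.fdb import (
    ROTATION_MATRIX,
    FitOptions,
    RotatedCurve,
    SilentFrameError,
    UnitCurve,
    fdb_model,
    fdb_jacobian,
    fdb_transform,
    fit_fdb,
    fit_quality,
    normalize_amplitudes,
    rotate_to_c2,
    sort_ascending,
)
from fdbdrill.pipeline import FAST_FIT_OPTIONS

from conftest import make_band_spectrum


class TestNormalize:
    def test_divides_by_maximum(self):
        np.testing.assert_allclose(
            normalize_amplitudes([1.0, 2.0, 4.0]), [0.25, 0.5, 1.0]
        )

    def test_constant_vector_becomes_all_ones(self):
        np.testing.assert_allclose(normalize_amplitudes([3.0] * 5), np.ones(5))

    def test_invariant_under_global_scaling(self, rng):
        amps = rng.random(58) + 0.01
        np.testing.assert_allclose(
            normalize_amplitudes(amps), normalize_amplitudes(1e6 * amps)
        )

    def test_silent_frame_rejected(self):
        with pytest.raises(SilentFrameError):
            normalize_amplitudes(np.zeros(58))

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            normalize_amplitudes([-1.0, 2.0])


class TestSortAscending:
    def test_sorts_and_grids(self):
        curve = sort_ascending([0.5, 1.0, 0.25])
        np.testing.assert_allclose(curve.ys, [0.25, 0.5, 1.0])
        np.testing.assert_allclose(curve.xs, [0.0, 0.5, 1.0])

    def test_idempotent_on_sorted_input(self):
        ys = np.linspace(0.1, 1.0, 20)
        np.testing.assert_allclose(sort_ascending(ys).ys, ys)

    def test_uniform_ramp_lies_on_original_line(self):
        curve = sort_ascending(np.linspace(0, 1, 30))
        np.testing.assert_allclose(curve.ys, curve.xs)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            sort_ascending([1.0])


class TestRotation:
    def test_matrix_is_orthogonal(self):
        np.testing.assert_allclose(
            ROTATION_MATRIX @ ROTATION_MATRIX.T, np.eye(2), atol=1e-12
        )

    def test_norm_preserved_on_random_points(self, rng):
        pts = rng.standard_normal((2, 500))
        rotated = ROTATION_MATRIX @ pts
        np.testing.assert_allclose(
            np.linalg.norm(rotated, axis=0), np.linalg.norm(pts, axis=0),
            atol=1e-12,
        )

    @pytest.mark.parametrize(
        "point,expected",
        [((1.0, 1.0), (1.0, 0.0)), ((0.0, 1.0), (0.5, 0.5)), ((0.0, 0.0), (0.0, 0.0))],
    )
    def test_known_points_after_rescaling(self, point, expected):
        curve = UnitCurve(xs=np.array([point[0]]), ys=np.array([point[1]]))
        rot = rotate_to_c2(curve)
        assert (rot.xs[0], rot.ys[0]) == pytest.approx(expected, abs=1e-15)

    def test_identity_curve_maps_to_zero(self):
        xs = np.linspace(0, 1, 58)
        rot = rotate_to_c2(UnitCurve(xs=xs, ys=xs.copy()))
        np.testing.assert_allclose(rot.ys, 0.0, atol=1e-15)
        np.testing.assert_allclose(rot.xs, xs, atol=1e-15)


FIG9_RANGES = {"a": (0.03, 0.20), "b": (-1.0, 2.0), "c": (-7.0, -2.0), "d": (0.4, 0.8)}


def draw_coeffs(rng, n):
    return np.column_stack([
        rng.uniform(*FIG9_RANGES[k], n) for k in "abcd"
    ])


class TestModel:
    def test_endpoints_vanish_for_random_coefficients(self, rng):
        for a, b, c, d in draw_coeffs(rng, 1000):
            assert fdb_model(0.0, a, b, c, d) == pytest.approx(0.0, abs=1e-12)
            assert fdb_model(1.0, a, b, c, d) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_point_closed_form(self):
        # phase = 2*pi*0.25 = pi/2 when b=c=0, d=1
        assert fdb_model(0.25, 1.0, 0.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            fdb_model(-0.1, 0.1, 1.0, -4.0, 0.6)

    def test_jacobian_matches_finite_differences(self):
        x = np.linspace(0.01, 1, 25)
        p = np.array([0.1, 1.0, -4.0, 0.6])
        jac = fdb_jacobian(x, *p)
        eps = 1e-7
        for j in range(4):
            dp = np.zeros(4)
            dp[j] = eps
            fd = (fdb_model(x, *(p + dp)) - fdb_model(x, *(p - dp))) / (2 * eps)
            np.testing.assert_allclose(jac[:, j], fd, rtol=1e-5, atol=1e-8)

    def test_coefficient_roles_are_monotone(self):
        """a scales amplitude, b tilts the below/above ratio, c and d move
        the interior root."""
        x = np.linspace(1e-4, 1, 2000)

        amps = [np.max(np.abs(fdb_model(x, a, 0.5, -4.5, 0.6)))
                for a in np.linspace(0.03, 0.20, 7)]
        assert np.all(np.diff(amps) > 0)

        ratios = []
        for b in np.linspace(-1, 2, 7):
            y = fdb_model(x, 0.1, b, -4.5, 0.6)
            ratios.append(-y.min() / y.max())
        assert np.all(np.diff(ratios) > 0)

        def interior_root(c, d):
            y = fdb_model(x, 0.1, 0.5, c, d)
            sign_flips = np.flatnonzero(np.diff(np.sign(y)) != 0)
            return x[sign_flips[0]]

        roots_c = [interior_root(c, 0.6) for c in np.linspace(-7, -2, 7)]
        assert np.all(np.diff(roots_c) < 0)  # less negative c -> earlier root
        roots_d = [interior_root(-4.5, d) for d in np.linspace(0.4, 0.8, 7)]
        assert np.all(np.diff(roots_d) > 0)  # larger d -> later root


class TestFitQuality:
    def test_perfect_fit(self):
        assert fit_quality([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]) == (0.0, 1.0, 0.0)

    def test_mean_prediction_gives_zero_r_square(self):
        obs = np.array([0.0, 1.0, 2.0])
        sse, r2, rmse = fit_quality(obs, np.full(3, obs.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        sse, r2, rmse = fit_quality([0.0, 1.0, 2.0], [0.0, 1.0, 1.0])
        assert sse == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt(1 / 3))

    def test_zero_variance_reports_missing_r_square(self):
        sse, r2, rmse = fit_quality([1.0, 1.0], [1.0, 0.5])
        assert np.isnan(r2)


TRUE_COEFFS = (0.1, 1.0, -4.0, 0.6)


class TestFitRecovery:
    def test_noiseless_recovery(self):
        xs = np.linspace(0, 1, 58)
        ys = fdb_model(xs, *TRUE_COEFFS)
        fit = fit_fdb(RotatedCurve(xs=xs, ys=ys))
        for got, want in zip(fit.as_array(), TRUE_COEFFS):
            assert abs(got - want) / abs(want) < 1e-3
        assert fit.sse <= 1e-10
        assert fit.r_square == pytest.approx(1.0)

    def test_noisy_recovery_fraction(self):
        xs = np.linspace(0, 1, 58)
        clean = fdb_model(xs, *TRUE_COEFFS)
        hits = 0
        n_rep = 20
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            fit = fit_fdb(RotatedCurve(xs=xs, ys=clean + rng.normal(0, 0.005, 58)))
            rel = np.abs((fit.as_array() - TRUE_COEFFS) / TRUE_COEFFS)
            hits += np.all(rel < 0.10)
        assert hits >= 0.9 * n_rep

    def test_flat_curve_degenerate_fit(self):
        xs = np.linspace(0, 1, 58)
        fit = fit_fdb(RotatedCurve(xs=xs, ys=np.zeros(58)))
        assert fit.a == FitOptions().bounds_lo[0]
        assert fit.sse == 0.0

    def test_too_few_points_rejected(self):
        xs = np.linspace(0, 1, 7)
        with pytest.raises(ValueError, match=">= 8 points"):
            fit_fdb(RotatedCurve(xs=xs, ys=np.zeros(7)))

    def test_reduced_start_grid_matches_full_grid(self, rng):
        """The pipeline's single-start profile must land in the same
        minimum as the full 27-point grid on drilling-like spectra."""
        for trial in range(6):
            w = np.ones(58) if trial % 2 else np.where(np.arange(58) >= 39, 1.0, 0.1)
            spec = make_band_spectrum(rng.rayleigh(1.0, 58) * np.sqrt(w))
            full = fdb_transform(spec)
            fast = fdb_transform(spec, options=FAST_FIT_OPTIONS)
            assert fast.sse <= full.sse * 1.001 + 1e-12


class TestTransform:
    def test_scale_invariance(self, rng):
        amps = rng.random(58) + 0.05
        c1 = fdb_transform(make_band_spectrum(amps))
        c2 = fdb_transform(make_band_spectrum(amps * 37.5))
        np.testing.assert_allclose(c1.as_array(), c2.as_array(), rtol=1e-9)

    def test_concentrated_vs_uniform_pattern(self):
        """Concentrated spectra: smaller a and d, larger b and c than
        near-uniform spectra (the transition-region signature)."""
        wins = np.zeros(4)
        n_pairs = 20
        for i in range(n_pairs):
            rng = np.random.default_rng(2000 + i)
            conc_amps = np.where(np.arange(58) >= 39, 1.0, 0.1) * np.exp(
                0.7 * rng.standard_normal(58)
            )
            uni_amps = np.exp(0.12 * rng.standard_normal(58))
            conc = fdb_transform(make_band_spectrum(conc_amps)).as_array()
            uni = fdb_transform(make_band_spectrum(uni_amps)).as_array()
            wins += [uni[0] > conc[0], uni[1] < conc[1],
                     uni[2] < conc[2], uni[3] > conc[3]]
        assert np.all(wins >= 0.9 * n_pairs)

    def test_carries_frame_time(self):
        fit = fdb_transform(make_band_spectrum(np.ones(58) + 0.1, time=3.25))
        assert fit.time == 3.25
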