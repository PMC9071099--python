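import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddrquant import (
    AbsoluteIC50Model,
    LoessConfig,
    PointOfDepartureModel,
    ResponseCurve,
    ResponseModel,
    compute_ic50,
    compute_pod,
    fit_loess,
    fold_change,
    geometric_series,
    min_max_normalize,
)
from ddrquant.errors import DegenerateControlError, InsufficientDataError


def _curve(series, mean_fn, noise=0.0, reps=3, controls=1000.0, n_controls=6, seed=0):
    rng = np.random.default_rng(seed)
    responses = [mean_fn(c) + rng.normal(0, noise, reps) for c in series]
    ctrl = controls + rng.normal(0, noise, n_controls)
    return ResponseCurve(series, responses, ctrl)


def loess_oracle_at_data(x, y, frac):
    """Brute-force Cleveland loess (degree 1, tricube) evaluated at the data
    points: contiguous k-nearest window, bandwidth = farthest point in window,
    weighted least squares with tricube weights."""
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    k = int(frac * n)
    out = []
    for x0 in x:
        d = np.abs(x - x0)
        idx = np.sort(np.argsort(d, kind="stable")[:k])
        h = max(x0 - x[idx[0]], x[idx[-1]] - x0)
        w = (1 - np.clip(np.abs(x[idx] - x0) / h, 0, 1) ** 3) ** 3 if h > 0 else np.ones(len(idx))
        sw = np.sqrt(w)
        A = np.column_stack([np.ones(len(idx)), x[idx]])
        beta = np.linalg.lstsq(A * sw[:, None], sw * y[idx], rcond=None)[0]
        out.append(beta[0] + beta[1] * x0)
    return x, np.array(out)


class TestFoldChange:
    def test_control_level_maps_to_one(self, series8):
        curve = _curve(series8, lambda c: 1000.0)
        fc = fold_change(curve)
        assert fc.control_mean == pytest.approx(1.0)
        assert all(np.allclose(r, 1.0) for r in fc.responses)

    def test_direct_division(self, series8):
        curve = ResponseCurve(series8, [[5.0]] * 8, [2.0, 2.0, 2.0])
        fc = fold_change(curve)
        assert fc.responses[0][0] == pytest.approx(2.5)

    @given(scale=st.floats(0.01, 1e4))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        series = geometric_series(0.1, 21.54, 8)
        curve = _curve(series, lambda c: 1000.0 + 50 * np.log10(c), noise=20.0, seed=3)
        scaled = ResponseCurve(
            curve.concentrations, [r * scale for r in curve.responses],
            curve.control_values * scale,
        )
        for a, b in zip(fold_change(curve).responses, fold_change(scaled).responses):
            np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_nonpositive_control_rejected(self, series8):
        curve = ResponseCurve(series8, [[1.0]] * 8, [0.0])
        with pytest.raises(DegenerateControlError):
            fold_change(curve)


class TestMinMaxNormalize:
    def test_basic(self):
        out, flag = min_max_normalize([1, 2, 3])
        np.testing.assert_allclose(out, [0, 0.5, 1])
        assert not flag

    def test_constant_collection_flagged(self):
        out, flag = min_max_normalize([4.0, 4.0])
        np.testing.assert_array_equal(out, [0.0, 0.0])
        assert flag

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_extremes_attained(self, values):
        out, flag = min_max_normalize(values)
        assert not flag
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.all((out >= 0) & (out <= 1))


class TestFitLoess:
    def test_collinear_data_full_span_reproduces_line(self, series8):
        curve = _curve(series8, lambda c: 100.0 + 25.0 * np.log10(c), reps=3)
        f = fit_loess(curve, LoessConfig(span=1.0))
        x = np.log10(series8)
        np.testing.assert_allclose(f(x), 100.0 + 25.0 * x, rtol=1e-6)

    def test_constant_responses_constant_fit(self, series8):
        curve = _curve(series8, lambda c: 77.0)
        f = fit_loess(curve)
        np.testing.assert_allclose(f(np.log10(series8)), 77.0, rtol=1e-9)

    def test_noiseless_hill_curve_within_5pct_at_design_points(self, series8):
        # unit Hill slope: the canonical moderate induction shape; steeper
        # curves accumulate more local-linear smoothing bias (see methods note)
        rm = ResponseModel(1000.0, 4.0, None, 1.0, 2.0, 0.0)
        curve = _curve(series8, lambda c: rm.mean_response(np.array([c]))[0])
        f = fit_loess(curve)
        fitted = f(np.log10(series8))
        truth = rm.mean_response(series8)
        np.testing.assert_allclose(fitted, truth, rtol=0.05)

    def test_matches_brute_force_tricube_oracle(self):
        # single-replicate curve -> distinct x values, no window-tie ambiguity
        rng = np.random.default_rng(8)
        series = np.sort(10 ** rng.uniform(-1, 1.3, 16))
        curve = ResponseCurve(series, [[v] for v in 100 + 40 * np.sin(np.log10(series) * 4)],
                              [100.0, 101.0])
        f = fit_loess(curve, LoessConfig(span=0.5))
        x, expected = loess_oracle_at_data(*curve.flat_xy(), frac=0.5)
        np.testing.assert_allclose(f(x), expected, rtol=1e-8, atol=1e-8)

    def test_too_few_concentrations_rejected(self):
        curve = ResponseCurve([1.0, 2.0, 4.0], [[1.0]] * 3, [1.0])
        with pytest.raises(InsufficientDataError):
            fit_loess(curve)


class TestComputePod:
    def test_flat_curve_undefined(self, flat_curve):
        result = compute_pod(flat_curve)
        assert not result.defined
        assert result.direction == "none"

    def test_recovery_of_known_onset(self, series8):
        rm = ResponseModel.from_onset(1000.0, 3.0, onset_concentration=1.0,
                                      hill_slope=2.0, noise_sd=100.0)
        curve = _curve(series8, lambda c: rm.mean_response(np.array([c]))[0], seed=2)
        # spread controls so the band has the calibrated width
        rng = np.random.default_rng(12)
        curve = ResponseCurve(series8, curve.responses, 1000.0 + rng.normal(0, 100.0, 40))
        result = compute_pod(curve)
        assert result.defined and result.direction == "positive"
        assert abs(np.log10(result.pod) - np.log10(1.0)) < 1 / 3  # within one dilution step

    def test_mirrored_curve_same_pod_negative_direction(self, series8):
        rng = np.random.default_rng(4)
        controls = 1000.0 + rng.normal(0, 50.0, 30)
        mean = lambda c: 1000.0 * (1 + 2 * (c**2 / (c**2 + 4.0**2)))
        up = ResponseCurve(series8, [[mean(c)] * 3 for c in series8], controls)
        # mirror responses about the control mean
        m = up.control_mean
        down = ResponseCurve(series8, [2 * m - np.asarray(r) for r in up.responses],
                             up.control_values)
        r_up, r_down = compute_pod(up), compute_pod(down)
        assert r_up.direction == "positive" and r_down.direction == "negative"
        assert r_down.pod == pytest.approx(r_up.pod, rel=1e-6)

    def test_censored_when_curve_starts_outside_band(self, series8):
        # strong effect already at the lowest tested concentration
        curve = ResponseCurve(series8, [[5000.0] * 3 for _ in series8],
                              [1000.0, 1010.0, 990.0])
        result = compute_pod(curve)
        assert result.censored
        assert result.pod == pytest.approx(series8[0])

    def test_affine_invariance(self, series8):
        rng = np.random.default_rng(6)
        controls = 1000.0 + rng.normal(0, 80.0, 20)
        curve = _curve(series8, lambda c: 1000.0 * (1 + c / (c + 3.0)), noise=50.0, seed=6)
        curve = ResponseCurve(series8, curve.responses, controls)
        a, b = 3.7, 250.0
        shifted = ResponseCurve(series8, [a * np.asarray(r) + b for r in curve.responses],
                                a * curve.control_values + b)
        r1 = compute_pod(curve, use_fold_change=False)
        r2 = compute_pod(shifted, use_fold_change=False)
        assert r2.pod == pytest.approx(r1.pod, rel=1e-9)

    def test_wider_band_cannot_decrease_pod(self, series8):
        rng = np.random.default_rng(9)
        curve = _curve(series8, lambda c: 1000.0 * (1 + 2 * c / (c + 2.0)), noise=30.0, seed=9)
        pods = []
        for sd in (30.0, 100.0, 300.0):
            # controls engineered to an exact sample SD of `sd`
            ctrl = 1000.0 + sd * np.sqrt(19 / 20) * np.resize([-1.0, 1.0], 20)
            c = ResponseCurve(series8, curve.responses, ctrl)
            r = compute_pod(c)
            pods.append(r.pod if r.defined else np.inf)
        assert pods[0] <= pods[1] <= pods[2]

    def test_model_results_summary(self, series8):
        rm = ResponseModel.from_onset(1000.0, 4.0, 2.0, 2.0, 100.0)
        curve = _curve(series8, lambda c: rm.mean_response(np.array([c]))[0],
                       noise=50.0, seed=1)
        res = PointOfDepartureModel(curve).fit()
        text = res.summary()
        assert "PoD" in text and "control band" in text


class TestComputeIC50:
    def test_full_viability_undefined(self, series8):
        curve = ResponseCurve(series8, [[100.0] * 3 for _ in series8], [100.0] * 6)
        assert not compute_ic50(curve).defined

    def test_noiseless_recovery_within_one_percent(self, series8):
        true_ic50 = 1.0
        mean = lambda c: 100.0 / (1.0 + (c / true_ic50) ** 1.5)
        curve = _curve(series8, mean, controls=100.0)
        result = compute_ic50(curve)
        assert result.defined
        assert result.ic50 == pytest.approx(true_ic50, rel=0.01)

    def test_declining_but_above_half_everywhere_undefined(self, series8):
        # declines from 100 to 70: never reaches the absolute 50% line
        mean = lambda c: 70.0 + 30.0 / (1.0 + c / 1.0)
        curve = _curve(series8, mean, controls=100.0)
        assert not compute_ic50(curve).defined

    def test_crossing_outside_tested_range_undefined(self, series8):
        # true IC50 far above the highest tested concentration
        mean = lambda c: 100.0 / (1.0 + (c / 1e4) ** 1.5)
        curve = _curve(series8, mean, controls=100.0)
        assert not compute_ic50(curve).defined

    def test_summary_reports_fit(self, series8):
        mean = lambda c: 100.0 / (1.0 + (c / 2.0) ** 2)
        res = AbsoluteIC50Model(_curve(series8, mean, controls=100.0)).fit()
        assert "IC50" in res.summary()
        assert res.ic50 == pytest.approx(2.0, rel=0.01)
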