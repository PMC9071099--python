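import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddrquant import (
    PlateDesign,
    ResponseModel,
    default_plate_design,
    generate_monolayer_images,
    generate_response_table,
    generate_spheroid_stack,
    geometric_series,
)
from ddrquant.errors import ConfigurationError, InvalidRangeError, InvalidStackError, PackingError
from ddrquant.synthetic import _hill


class TestGeometricSeries:
    def test_eight_point_aflatoxin_range(self):
        s = geometric_series(0.10, 21.54, 8)
        # equal log10 spacing between the printed endpoints
        expected = [0.100, 0.2154, 0.4642, 1.000, 2.154, 4.642, 10.00, 21.54]
        np.testing.assert_allclose(s, expected, rtol=5e-4)
        assert s[0] == 0.10 and s[-1] == 21.54

    def test_decade_spacing(self):
        np.testing.assert_allclose(geometric_series(1, 100, 3), [1, 10, 100])

    def test_gemcitabine_range_closed_form_ratio(self):
        s = geometric_series(0.0037, 0.80, 8)
        assert s[0] == 0.0037 and s[-1] == 0.80
        ratio = (0.80 / 0.0037) ** (1 / 7)
        np.testing.assert_allclose(np.diff(np.log(s)), np.log(ratio), rtol=1e-9)

    @pytest.mark.parametrize("lo,hi,n", [(-1, 10, 8), (0, 10, 8), (10, 1, 8), (1, 10, 1)])
    def test_invalid_ranges_raise(self, lo, hi, n):
        with pytest.raises(InvalidRangeError):
            geometric_series(lo, hi, n)

    @given(
        lo=st.floats(1e-4, 10.0),
        ratio=st.floats(1.5, 1e4),
        n=st.integers(2, 12),
    )
    @settings(max_examples=50, deadline=None)
    def test_log_spacing_property(self, lo, ratio, n):
        s = geometric_series(lo, lo * ratio, n)
        assert len(s) == n and np.all(np.diff(s) > 0)
        np.testing.assert_allclose(np.diff(np.log10(s)), np.log10(ratio) / (n - 1), rtol=1e-6)


class TestMonolayerGenerator:
    def test_empty_field(self):
        channels, truth = generate_monolayer_images(0, image_size=64, seed=0, noise_sd=0.0)
        assert channels["hoechst"].pixels.max() == 0
        assert truth.nucleus_masks.n_objects == 0
        assert truth.pi_positive_ids == set()

    def test_requested_counts_and_consecutive_labels(self, monolayer):
        _, truth = monolayer
        assert truth.nucleus_masks.n_objects == 30
        truth.nucleus_masks.validate()
        assert len(truth.pi_positive_ids) == round(0.3 * 30)

    def test_full_pi_fraction(self):
        _, truth = generate_monolayer_images(10, image_size=256, seed=3, pi_fraction=1.0)
        assert truth.pi_positive_ids == set(range(1, 11))

    def test_seed_determinism_bitwise(self):
        a, _ = generate_monolayer_images(20, image_size=128, seed=42, pi_fraction=0.5)
        b, _ = generate_monolayer_images(20, image_size=128, seed=42, pi_fraction=0.5)
        for name in ("hoechst", "gfp", "pi"):
            np.testing.assert_array_equal(a[name].pixels, b[name].pixels)

    def test_packing_error_when_overcrowded(self):
        with pytest.raises(PackingError):
            generate_monolayer_images(500, image_size=64, seed=0)

    def test_partial_pi_fraction_is_exact_per_object(self):
        _, truth = generate_monolayer_images(
            5, image_size=256, seed=9, pi_fraction=1.0, pi_partial_fraction=0.5, noise_sd=0.0
        )
        for lab, frac in truth.pi_fraction_by_id.items():
            area = int(np.sum(truth.nucleus_masks.labels == lab))
            assert frac == round(0.5 * area) / area


class TestSpheroidGenerator:
    def test_projected_mask_is_equatorial_disk(self):
        stacks, truth = generate_spheroid_stack(
            1, seed=2, noise_sd=0.0, radius_um_range=(100.0, 100.0), pixel_size=2.0
        )
        # sphere center sits on the middle plane: max projection of the stack
        # equals the equatorial disk stored in the ground truth
        proj = stacks["hoechst"].as_array().max(axis=0) > 0
        np.testing.assert_array_equal(proj, truth.spheroid_masks.labels > 0)
        area = proj.sum()
        assert abs(area - np.pi * 50**2) / (np.pi * 50**2) < 0.02

    def test_empty_scene(self):
        stacks, truth = generate_spheroid_stack(0, seed=0, noise_sd=0.0)
        assert truth.spheroid_masks.n_objects == 0
        assert stacks["hoechst"].as_array().max() == 0

    def test_two_spheres_do_not_overlap(self, spheroid_stack):
        _, truth = spheroid_stack
        labels = truth.spheroid_masks.labels
        # brute-force pixel scan: each pixel carries at most one label
        assert truth.spheroid_masks.n_objects == 2
        m1, m2 = labels == 1, labels == 2
        assert not np.any(m1 & m2)
        assert m1.sum() > 0 and m2.sum() > 0

    def test_invalid_plane_count(self):
        with pytest.raises(InvalidStackError):
            generate_spheroid_stack(1, n_planes=0, seed=0)

    def test_stack_shape_and_step(self, spheroid_stack):
        stacks, _ = spheroid_stack
        assert len(stacks["hoechst"].planes) == 9
        assert stacks["hoechst"].step == 30.0
        assert stacks["gfp"].shape == stacks["hoechst"].shape


class TestResponseModel:
    def test_hill_midpoint_identity(self):
        for slope in (0.5, 1.0, 2.0, 4.0):
            assert _hill(np.array([3.0]), 3.0, slope)[0] == pytest.approx(0.5)

    def test_from_onset_crosses_band_at_onset(self):
        rm = ResponseModel.from_onset(1000.0, 4.0, onset_concentration=1.0, hill_slope=2.0, noise_sd=100.0)
        at_onset = rm.mean_response(np.array([1.0]))[0]
        assert at_onset == pytest.approx(1000.0 + 2 * 100.0)
        assert rm.ec50 >= rm.onset_concentration

    def test_from_ec50_round_trips_onset(self):
        rm = ResponseModel.from_ec50(1000.0, 3.0, ec50=5.0, hill_slope=1.5, noise_sd=50.0)
        rm2 = ResponseModel.from_onset(1000.0, 3.0, rm.onset_concentration, 1.5, 50.0)
        assert rm2.ec50 == pytest.approx(5.0)

    def test_decrease_direction_clips_at_zero(self):
        rm = ResponseModel(100.0, 2.0, None, 2.0, 1.0, 0.0, direction="decrease")
        resp = rm.mean_response(np.array([1e6]))
        assert resp[0] == pytest.approx(0.0, abs=1e-6)

    def test_true_ic50_is_half_baseline_crossing(self):
        rm = ResponseModel(100.0, 2.0, None, 1.5, 2.0, 0.0, direction="decrease")
        ic50 = rm.true_ic50()
        assert rm.mean_response(np.array([ic50]))[0] == pytest.approx(50.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ResponseModel(100.0, 0.5, None, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            ResponseModel(100.0, 2.0, 5.0, 1.0, 1.0, 0.0)  # ec50 < onset, increase


class TestResponseTable:
    @staticmethod
    def _tiny_design():
        return PlateDesign(
            models=["2D-DMEM"],
            reporters=["BTG2"],
            compounds={"cisplatin": geometric_series(0.10, 21.54, 8)},
            durations=["24h"],
            n_replicates=3,
            solvent_control_wells=4,
        )

    def test_noiseless_table_matches_deterministic_curve(self):
        design = self._tiny_design()
        rm = ResponseModel(1000.0, 3.0, None, 2.0, 2.0, 0.0)
        key = ("2D-DMEM", "BTG2", "cisplatin", "24h")
        table, truth = generate_response_table(design, {key: rm}, seed=0)
        treated = table[table.well_type == "treated"]
        for c, grp in treated.groupby("concentration_uM"):
            expected = rm.mean_response(np.array([c]))[0]
            np.testing.assert_allclose(grp.value, expected)
        assert np.isnan(truth.true_pod.iloc[0])  # zero-noise band is degenerate

    def test_null_condition_wells_match_controls(self):
        design = self._tiny_design()
        rm = ResponseModel(1000.0, 1.0, None, 1.0, 1.0, 100.0)
        key = ("2D-DMEM", "BTG2", "cisplatin", "24h")
        table, truth = generate_response_table(design, {key: rm}, seed=1)
        treated = table[table.well_type == "treated"].value
        controls = table[table.well_type == "solvent"].value
        assert np.isnan(truth.true_pod.iloc[0])
        # treated wells are statistically indistinguishable from controls
        se_diff = 100.0 * np.sqrt(1 / len(treated) + 1 / len(controls))
        assert abs(treated.mean() - controls.mean()) < 4 * se_diff

    def test_missing_condition_model_raises(self):
        design = self._tiny_design()
        with pytest.raises(ConfigurationError):
            generate_response_table(design, {}, seed=0)

    def test_control_noise_calibration(self):
        # with noise_sd = sigma, the empirical control SD over >= 500 wells
        # lands within 10% of sigma
        design = PlateDesign(
            models=["2D-DMEM"],
            reporters=["BTG2"],
            compounds={"cisplatin": geometric_series(0.10, 21.54, 8)},
            durations=["24h"],
            n_replicates=3,
            solvent_control_wells=600,
        )
        rm = ResponseModel(1000.0, 1.0, None, 1.0, 1.0, 80.0)
        key = ("2D-DMEM", "BTG2", "cisplatin", "24h")
        table, _ = generate_response_table(design, {key: rm}, seed=2)
        sd = table[table.well_type == "solvent"].value.std(ddof=1)
        assert abs(sd - 80.0) / 80.0 < 0.10

    def test_design_invariants(self):
        with pytest.raises(ValueError):
            PlateDesign(["m"], ["r"], {"c": np.arange(1, 8)}, ["24h"])  # 7 points
        with pytest.raises(ValueError):
            PlateDesign(
                ["m"], ["r"], {"c": geometric_series(1, 10, 8)}, ["24h"], n_replicates=2
            )

    def test_default_design_matches_protocol(self):
        d = default_plate_design()
        assert len(d.models) == 4 and len(d.reporters) == 3 and len(d.compounds) == 5
        assert all(len(s) == 8 for s in d.compounds.values())
        assert d.compounds["gemcitabine"][0] == 0.0037
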