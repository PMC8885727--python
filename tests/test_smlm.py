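"""Pairing, photon-ratio demixing, drift correction and rendering."""

import numpy as np
import pytest

from synapse_corr import (
    ContractError,
    DemixingError,
    DriftEstimationError,
    EmptyResultError,
    apply_drift,
    classify,
    compute_photon_ratio,
    estimate_drift,
    fit_demix_model,
    make_localizations,
    pair_detections,
    render,
    simulate_two_camera_emitters,
)


class TestPairing:
    def test_identical_tables_pair_completely(self, rng):
        n = 50
        t1 = make_localizations(
            x=rng.uniform(0, 5000, n), y=rng.uniform(0, 5000, n),
            frame=np.arange(n) % 5, I_cam1=np.full(n, 100.0),
        )
        t2 = t1.copy()
        t2["I_cam2"] = 40.0
        paired = pair_detections(t1, t2, tol=100.0)
        assert len(paired) == n
        assert (paired["I_cam2"] == 40.0).all()

    def test_empty_table_gives_zero_pairs(self, rng):
        t1 = make_localizations(x=[1.0], y=[2.0])
        empty = make_localizations(x=np.empty(0), y=np.empty(0))
        assert len(pair_detections(t1, empty, tol=100.0)) == 0

    def test_mutual_nn_keeps_exactly_one_pair(self):
        # two cam1 records flank one cam2 record: only the closer pairs
        t1 = make_localizations(x=[0.0, 30.0], y=[0.0, 0.0], frame=[0, 0])
        t2 = make_localizations(x=[20.0], y=[0.0], frame=[0])
        paired = pair_detections(t1, t2, tol=100.0)
        assert len(paired) == 1
        assert paired["x"].iloc[0] == 30.0

    def test_frame_mismatch_blocks_pairing(self):
        t1 = make_localizations(x=[0.0], y=[0.0], frame=[0])
        t2 = make_localizations(x=[0.0], y=[0.0], frame=[1])
        assert len(pair_detections(t1, t2, tol=100.0)) == 0

    def test_non_positive_tolerance_rejected(self):
        t = make_localizations(x=[0.0], y=[0.0])
        with pytest.raises(ContractError):
            pair_detections(t, t, tol=0.0)


class TestPhotonRatio:
    @pytest.mark.parametrize(
        "i1,i2,expected", [(300.0, 100.0, 0.75), (0.0, 50.0, 0.0), (120.0, 0.0, 1.0)]
    )
    def test_ratio_arithmetic(self, i1, i2, expected):
        t = make_localizations(x=[0.0], y=[0.0], I_cam1=[i1], I_cam2=[i2])
        out = compute_photon_ratio(t)
        assert out["ratio"].iloc[0] == expected

    def test_zero_total_intensity_rejected_record(self):
        t = make_localizations(x=[0.0], y=[0.0], I_cam1=[0.0], I_cam2=[0.0])
        out = compute_photon_ratio(t)
        assert out["fluor"].iloc[0] == "rejected"
        assert np.isnan(out["ratio"].iloc[0])

    def test_missing_intensities_block_demixing(self):
        t = make_localizations(x=[0.0, 1.0], y=[0.0, 1.0])
        with pytest.raises(DemixingError):
            compute_photon_ratio(t)

    def test_ratio_invariant_to_global_intensity_rescale(self):
        table, _ = simulate_two_camera_emitters((300, 300), seed=1)
        a = compute_photon_ratio(table)["ratio"]
        scaled = table.copy()
        scaled[["I_cam1", "I_cam2"]] *= 7.5
        b = compute_photon_ratio(scaled)["ratio"]
        np.testing.assert_allclose(a, b, rtol=1e-12)
        assert ((b >= 0) & (b <= 1)).all()


class TestDemixModel:
    def test_fitted_means_close_to_truth_symmetric_components(self):
        table, _ = simulate_two_camera_emitters(
            (5000, 5000), ratio_means=(0.7, 0.3), seed=21
        )
        table = compute_photon_ratio(table)
        model = fit_demix_model(table["ratio"].to_numpy())
        assert model.mu_a == pytest.approx(0.7, abs=0.01)
        assert model.mu_b == pytest.approx(0.3, abs=0.01)

    def test_single_component_is_degenerate(self, rng):
        ratios = rng.normal(0.5, 0.05, 1000).clip(0, 1)
        with pytest.raises(DemixingError, match="degenerate"):
            fit_demix_model(ratios)

    def test_too_few_ratios_rejected(self, rng):
        with pytest.raises(ContractError):
            fit_demix_model(rng.random(50))

    def test_classification_with_posterior_guard(self):
        table, labels = simulate_two_camera_emitters((2000, 2000), seed=22)
        table = compute_photon_ratio(table)
        model = fit_demix_model(table["ratio"].to_numpy())
        out = classify(table, model)
        assigned = out["fluor"].to_numpy()
        wrong = (
            ((assigned == "fluorA") & (labels == "fluorB"))
            | ((assigned == "fluorB") & (labels == "fluorA"))
        ).mean()
        assert wrong < 0.001
        assert (assigned == "rejected").mean() < 0.02


class TestDrift:
    @staticmethod
    def _clustered_table(rng, n=20000, n_frames=6000, drift_per_frame=(0.0, 0.0)):
        centres = rng.uniform(500, 4500, (25, 2))
        idx = rng.integers(0, 25, n)
        frames = rng.integers(0, n_frames, n)
        xy = centres[idx] + rng.normal(0, 30, (n, 2))
        x = xy[:, 0] + drift_per_frame[0] * frames
        y = xy[:, 1] + drift_per_frame[1] * frames
        return make_localizations(x=x, y=y, frame=frames), frames

    def test_zero_drift_recovered_as_zero(self, rng):
        table, _ = self._clustered_table(rng)
        traj = estimate_drift(table, bin_frames=2000, grid=20.0)
        assert np.abs(traj.dx).max() <= 2.0  # grid / 10
        assert np.abs(traj.dy).max() <= 2.0

    def test_linear_drift_endpoint_recovered(self, rng):
        table, frames = self._clustered_table(rng, drift_per_frame=(100 / 6000, 0.0))
        traj = estimate_drift(table, bin_frames=2000, grid=20.0)
        true_dx = 100 / 6000 * frames
        bins = frames // 2000
        true_rel = np.array([true_dx[bins == b].mean() for b in range(3)])
        true_rel -= true_rel[0]
        assert abs(traj.dx[-1] - true_rel[-1]) <= 10.0
        # correction is idempotent: re-estimated drift within grid/10
        corrected = apply_drift(table, traj)
        traj2 = estimate_drift(corrected, bin_frames=2000, grid=20.0)
        assert np.abs(traj2.dx).max() <= 2.0
        assert np.abs(traj2.dy).max() <= 2.0

    def test_correction_restores_cluster_width(self, rng):
        table, frames = self._clustered_table(rng, drift_per_frame=(100 / 6000, 0.0))
        clean, _ = self._clustered_table(np.random.default_rng(12345))
        traj = estimate_drift(table, bin_frames=2000, grid=20.0)
        corrected = apply_drift(table, traj)
        # drift-free width oracle from the identically-seeded clean table
        sd_clean = clean["x"].to_numpy().std()
        sd_corr = corrected["x"].to_numpy().std()
        assert sd_corr <= 1.1 * sd_clean

    def test_single_bin_table_rejected(self, rng):
        table, _ = self._clustered_table(rng, n=500, n_frames=100)
        with pytest.raises(DriftEstimationError):
            estimate_drift(table, bin_frames=2000)

    def test_z_left_untouched(self, rng):
        table, _ = self._clustered_table(rng, drift_per_frame=(0.05, 0.0))
        table["z"] = rng.normal(0, 50, len(table))
        traj = estimate_drift(table, bin_frames=2000)
        corrected = apply_drift(table, traj)
        np.testing.assert_array_equal(corrected["z"], table["z"])


class TestRender:
    def test_single_localisation_lands_in_expected_pixel(self):
        t = make_localizations(x=[105.0], y=[55.0])
        img, origin = render(t, pixel=10.0, origin=(0.0, 0.0), shape=(6, 11))
        assert origin == (0.0, 0.0)
        assert img.sum() == 1
        assert img[5, 10] == 1  # row from y=55, col from x=105

    def test_count_conservation(self, rng):
        n = 500
        t = make_localizations(x=rng.uniform(0, 2000, n), y=rng.uniform(0, 2000, n))
        img, _ = render(t, pixel=10.0)
        assert img.sum() == n

    def test_doubling_pixel_size_quarters_area(self, rng):
        n = 300
        t = make_localizations(x=rng.uniform(0, 3000, n), y=rng.uniform(0, 1500, n))
        img1, _ = render(t, pixel=10.0)
        img2, _ = render(t, pixel=20.0)
        ratio = img1.size / img2.size
        assert 3.3 <= ratio <= 4.8

    def test_empty_after_filter_rejected(self):
        t = make_localizations(x=[1.0], y=[1.0])
        with pytest.raises(EmptyResultError):
            render(t, fluor="fluorA")
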