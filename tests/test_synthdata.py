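import numpy as np
import pandas as pd
import pytest

from smlmdiff import (
    PopulationSpec,
    SimulationConfig,
    render_frames,
    simulate_intensity_trace,
    simulate_trajectories,
)
from smlmdiff.synthdata import gradient_D


def cfg(**kw):
    base = dict(
        populations=[PopulationSpec(0.1, 1.0, "p")],
        sigma_loc=30.0,
        dt=0.03,
        mean_track_len=8.0,
        n_molecules=500,
        fov=(20.0, 20.0),
        n_frames=1000,
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateTrajectories:
    def test_immobile_noiseless_molecules_do_not_move(self):
        locs, _ = simulate_trajectories(
            cfg(populations=[PopulationSpec(0.0, 1.0)], sigma_loc=0.0, n_molecules=50)
        )
        for _, g in locs.groupby("molecule_id"):
            assert g["x_nm"].nunique() == 1
            assert g["y_nm"].nunique() == 1

    def test_step_variance_matches_2_D_dt(self):
        # per-axis variance of a Brownian step is 2*D*dt; the mean squared
        # 2-D frame-to-frame displacement is 4*D*dt = 0.012 um^2
        D, dt = 0.1, 0.03
        locs, _ = simulate_trajectories(
            cfg(populations=[PopulationSpec(D, 1.0)], sigma_loc=0.0, n_molecules=30_000, fov=(200.0, 200.0))
        )
        locs = locs.sort_values(["molecule_id", "frame"], kind="stable")
        same = locs["molecule_id"].to_numpy()[1:] == locs["molecule_id"].to_numpy()[:-1]
        dx = np.diff(locs["x_nm"].to_numpy())[same] / 1000.0
        dy = np.diff(locs["y_nm"].to_numpy())[same] / 1000.0
        sq = dx**2 + dy**2
        assert len(sq) >= 1e5
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - 4 * D * dt) < 3 * se

    def test_seeded_runs_are_bit_reproducible(self):
        a, ta = simulate_trajectories(cfg(seed=123))
        b, tb = simulate_trajectories(cfg(seed=123))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)
        assert a.to_csv() == b.to_csv()

    def test_mean_trajectory_length(self):
        locs, _ = simulate_trajectories(cfg(n_molecules=20_000, fov=(200.0, 200.0), n_frames=100_000))
        lengths = locs.groupby("molecule_id").size().to_numpy()
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 8.0) < 2 * se + 0.05  # fov truncation trims a little

    def test_frames_contiguous_per_molecule(self):
        _, truth = simulate_trajectories(cfg(n_molecules=200))
        for _, g in truth.groupby("molecule_id"):
            f = np.sort(g["frame"].to_numpy())
            assert (np.diff(f) == 1).all()

    def test_gradient_assigns_D_by_initial_radius(self):
        c = cfg(
            populations=[PopulationSpec(0.0, 1.0)],
            lesion_center=(10.0, 10.0),
            gradient=(0.029, 3.7, 0.014),
            n_molecules=2_000,
        )
        _, truth = simulate_trajectories(c)
        first = truth.drop_duplicates("molecule_id")
        r = np.hypot(first["x_um"] - 10.0, first["y_um"] - 10.0)
        expected = gradient_D(r, 0.029, 3.7, 0.014)
        np.testing.assert_allclose(first["D_true"], expected, rtol=1e-9)
        # D0 + Dinf at the lesion center, non-increasing with distance
        assert np.isclose(gradient_D(0.0, 0.029, 3.7, 0.014), 0.043)
        order = np.argsort(r.to_numpy())
        assert (np.diff(expected[order]) <= 1e-12).all()

    @pytest.mark.parametrize(
        "bad",
        [
            dict(populations=[]),
            dict(populations=[PopulationSpec(0.1, 0.5)]),  # fractions != 1
            dict(dt=0.0),
            dict(sigma_loc=-1.0),
            dict(mean_track_len=0.5),
            dict(gradient=(0.029, 3.7, 0.014)),  # gradient without center
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_trajectories(cfg(**bad))


class TestRenderFrames:
    def test_empty_frame_is_offset_plus_shot_noise(self):
        c = cfg(fov=(3.0, 3.0), n_molecules=1)
        empty = pd.DataFrame(
            {"x_nm": [], "y_nm": [], "frame": [], "sigma_loc_nm": [], "spot_sd_nm": [], "intensity": [], "molecule_id": []}
        )
        stack = render_frames(empty, c, offset=100, bg_photons=2.0, seed=0)
        assert stack.dtype == np.uint16
        assert stack.min() >= 100
        assert stack.mean() == pytest.approx(102.0, abs=1.0)

    def test_brightest_pixel_contains_emitter(self):
        c = cfg(fov=(3.0, 3.0))
        locs = pd.DataFrame(
            {"x_nm": [1530.0], "y_nm": [980.0], "frame": [0], "sigma_loc_nm": [30.0],
             "spot_sd_nm": [140.0], "intensity": [50_000.0], "molecule_id": [0]}
        )
        stack = render_frames(locs, c, seed=1)
        i, j = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert j == int(1530.0 / 109.0)
        assert i == int(980.0 / 109.0)

    def test_out_of_fov_emitter_rejected(self):
        c = cfg(fov=(3.0, 3.0))
        locs = pd.DataFrame(
            {"x_nm": [5000.0], "y_nm": [100.0], "frame": [0], "sigma_loc_nm": [30.0],
             "spot_sd_nm": [140.0], "intensity": [500.0], "molecule_id": [0]}
        )
        with pytest.raises(ValueError, match="field of view"):
            render_frames(locs, c)


class TestIntensityTrace:
    def test_single_exponential_when_A_is_one(self):
        tr = simulate_intensity_trace(1.0, 30.0, 300.0, 100.0, BG=0.0, noise_sd=0.0, n_frames=50, dt=5.0)
        t = tr["t_s"].to_numpy()
        np.testing.assert_allclose(tr["I_raw"], 100.0 * np.exp(-t / 30.0), rtol=1e-12)

    def test_flat_response_traces_bleach_curve(self):
        tr = simulate_intensity_trace(0.6, 30.0, 300.0, 100.0, BG=0.0, noise_sd=0.0, n_frames=50, dt=5.0)
        t = tr["t_s"].to_numpy()
        bl = 0.6 * np.exp(-t / 30.0) + 0.4 * np.exp(-t / 300.0)
        np.testing.assert_allclose(tr["I_raw"], 100.0 * bl, rtol=1e-12)
        assert tr["I_raw"].iloc[0] == pytest.approx(100.0)  # BL(0) = 1 exactly

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            simulate_intensity_trace(0.5, -1.0, 300.0, 100.0, 0.0, 0.0, 50, 5.0)
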