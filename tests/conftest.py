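import numpy as np
import pandas as pd
import pytest

from smlmdiff import PopulationSpec, SimulationConfig, simulate_trajectories


@pytest.fixture(scope="session")
def single_pop_estimates():
    """Eligible-length trajectories from a single-population simulation
    (D = 0.1 um^2/s, sigma_loc = 30 nm, dt = 30 ms, lengths capped at 15),
    grouped by ground-truth molecule identity."""
    from smlmdiff import estimate_all

    cfg = SimulationConfig(
        populations=[PopulationSpec(0.1, 1.0, "p")],
        sigma_loc=30.0,
        dt=0.03,
        mean_track_len=8.0,
        n_molecules=30_000,
        fov=(200.0, 200.0),
        n_frames=5_000,
        seed=1,
    )
    locs, _ = simulate_trajectories(cfg)
    locs = (
        locs.rename(columns={"molecule_id": "traj_id"})
        .sort_values(["traj_id", "frame"], kind="stable")
        .groupby("traj_id")
        .head(15)
    )
    return estimate_all(locs, 0.03)


@pytest.fixture(scope="session")
def gradient_estimates():
    """Diffusion estimates from a lesion-gradient simulation
    (D(r) = 0.029*exp(-r/3.7) + 0.014 um^2/s, lesion at the fov center),
    grouped by ground-truth molecule identity; sized so every 2-um annulus
    out to 10 um holds >= 2000 eligible trajectories."""
    from smlmdiff import estimate_all

    cfg = SimulationConfig(
        populations=[PopulationSpec(0.0, 1.0, "g")],
        sigma_loc=30.0,
        dt=0.03,
        mean_track_len=8.0,
        n_molecules=240_000,
        fov=(22.0, 22.0),
        n_frames=20_000,
        seed=3,
        lesion_center=(11.0, 11.0),
        gradient=(0.029, 3.7, 0.014),
    )
    locs, _ = simulate_trajectories(cfg)
    locs = locs.rename(columns={"molecule_id": "traj_id"})
    return estimate_all(locs, 0.03)


def make_loc_table(x, y, frame, precision=30.0, spot_sd=140.0):
    n = len(x)
    return pd.DataFrame(
        {
            "x_nm": np.asarray(x, dtype=float),
            "y_nm": np.asarray(y, dtype=float),
            "frame": np.asarray(frame, dtype=np.int64),
            "sigma_loc_nm": np.broadcast_to(precision, n).astype(float),
            "spot_sd_nm": np.broadcast_to(spot_sd, n).astype(float),
            "intensity": np.full(n, 500.0),
        }
    )
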