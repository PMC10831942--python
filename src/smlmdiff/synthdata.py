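"""Synthetic single-molecule and intensity-trace generators.

Produces ground-truth-annotated localization tables, rendered camera frame
stacks and bleaching intensity traces with the statistical structure the
downstream analysis assumes: 2-D Brownian motion of a small number of
populations with log-separated diffusion coefficients, isotropic localization
noise, geometrically distributed (photobleaching-limited) trajectory lengths,
an optional lesion-centered diffusivity gradient D(r) = D0*exp(-r/r0) + Dinf,
and biexponential photobleaching of bulk fluorescence.

All file-facing positions are in nm; internal dynamics are computed in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "simulate_trajectories",
    "render_frames",
    "simulate_intensity_trace",
    "LOC_COLUMNS",
]

#: column order of the localization-table interchange format
LOC_COLUMNS = [
    "x_nm",
    "y_nm",
    "frame",
    "sigma_loc_nm",
    "spot_sd_nm",
    "intensity",
    "molecule_id",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One diffusing population.

    Parameters
    ----------
    D_true
        Ground-truth diffusion coefficient, um^2/s (>= 0).
    fraction
        Fraction of simulated molecules drawn from this population; fractions
        across a :class:`SimulationConfig` must sum to 1.
    label
        Free-text population name carried into the ground-truth table.
    """

    D_true: float
    fraction: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.D_true) or self.D_true < 0:
            raise ValueError(f"D_true must be finite and >= 0, got {self.D_true}")
        if not np.isfinite(self.fraction) or self.fraction < 0:
            raise ValueError(f"fraction must be finite and >= 0, got {self.fraction}")


@dataclass
class SimulationConfig:
    """Conditions of a synthetic SMLM experiment.

    Defaults mirror the imaging conditions the analysis was designed for:
    30 ms camera dwell time, ~30 nm localization precision, 109 nm pixels and
    photobleaching-limited trajectories of ~8 frames on average.
    """

    populations: Sequence[PopulationSpec]
    sigma_loc: float = 30.0  # nm, SD of isotropic localization noise
    dt: float = 0.03  # s, frame interval
    mean_track_len: float = 8.0  # frames, mean of the geometric length law
    n_molecules: int = 1000
    fov: tuple[float, float] = (20.0, 20.0)  # um
    n_frames: int = 10_000
    seed: int = 0
    lesion_center: tuple[float, float] | None = None  # um
    gradient: tuple[float, float, float] | None = None  # (D0, r0, Dinf)
    pixel_size: float = 109.0  # nm

    def validate(self) -> None:
        if len(self.populations) == 0:
            raise ValueError("at least one population is required")
        fractions = np.array([p.fraction for p in self.populations], dtype=float)
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {fractions.sum()!r}, not 1")
        for name, value in (
            ("dt", self.dt),
            ("mean_track_len", self.mean_track_len),
            ("pixel_size", self.pixel_size),
        ):
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not np.isfinite(self.sigma_loc) or self.sigma_loc < 0:
            raise ValueError(f"sigma_loc must be finite and >= 0, got {self.sigma_loc}")
        if self.mean_track_len < 1:
            raise ValueError("mean_track_len must be >= 1")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not all(np.isfinite(self.fov)) or min(self.fov) <= 0:
            raise ValueError(f"fov must be positive and finite, got {self.fov}")
        if self.gradient is not None:
            d0, r0, dinf = self.gradient
            if not (np.isfinite(d0) and np.isfinite(r0) and np.isfinite(dinf)):
                raise ValueError("gradient parameters must be finite")
            if r0 <= 0 or d0 < 0 or dinf < 0:
                raise ValueError("gradient requires r0 > 0 and D0, Dinf >= 0")
            if self.lesion_center is None:
                raise ValueError("gradient mode requires lesion_center")


def gradient_D(r: np.ndarray, D0: float, r0: float, Dinf: float) -> np.ndarray:
    """Lesion-distance diffusivity profile D(r) = D0*exp(-r/r0) + Dinf."""
    return D0 * np.exp(-np.asarray(r, dtype=float) / r0) + Dinf


def simulate_trajectories(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Brownian molecules and return (localizations, ground truth).

    Each molecule starts uniformly in the field of view at a uniformly chosen
    start frame, lives for a geometrically distributed number of frames
    (memoryless photobleaching with the configured mean), and performs 2-D
    Brownian motion with per-axis per-step displacement variance ``2*D*dt``.
    The observed position is the true position plus isotropic Gaussian noise
    of SD ``sigma_loc``. A molecule whose true position leaves the field of
    view is truncated there (it leaves the evanescent excitation field).

    In gradient mode the molecule's D is evaluated once, at its initial
    radial distance from ``lesion_center``; population ``D_true`` values are
    then ignored (fractions still set the population labels).

    Returns
    -------
    localizations : DataFrame
        Columns :data:`LOC_COLUMNS`; per-localization quality columns are
        drawn as ``|N(30, 8)|`` nm precision and ``N(140, 15)`` nm spot SD so
        that downstream quality filters act on realistic inputs.
    ground_truth : DataFrame
        molecule_id, population label, frame, true x/y (um), D_true (um^2/s).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    fov = np.asarray(config.fov, dtype=float)

    fractions = np.array([p.fraction for p in config.populations], dtype=float)
    pop_idx = rng.choice(len(fractions), size=n, p=fractions / fractions.sum())

    # geometric(p) on {1, 2, ...} has mean 1/p
    lengths = rng.geometric(1.0 / config.mean_track_len, size=n)
    start_frames = rng.integers(0, config.n_frames, size=n)
    lengths = np.minimum(lengths, config.n_frames - start_frames)

    start_xy = rng.uniform(0.0, 1.0, size=(n, 2)) * fov

    D_pop = np.array([p.D_true for p in config.populations], dtype=float)
    if config.gradient is not None:
        cx, cy = config.lesion_center
        r_init = np.hypot(start_xy[:, 0] - cx, start_xy[:, 1] - cy)
        D_mol = gradient_D(r_init, *config.gradient)
    else:
        D_mol = D_pop[pop_idx]

    total = int(lengths.sum())
    mol_of_row = np.repeat(np.arange(n), lengths)
    first_rows = np.concatenate(([0], np.cumsum(lengths)[:-1]))

    step_sd = np.sqrt(2.0 * D_mol * config.dt)  # um, per axis per frame
    steps = rng.normal(size=(total, 2)) * step_sd[mol_of_row, None]
    steps[first_rows] = 0.0
    cum = np.cumsum(steps, axis=0)
    pos = cum - cum[first_rows][mol_of_row] + start_xy[mol_of_row]

    # truncate trajectories at the first excursion outside the fov
    inside = (pos >= 0.0).all(axis=1) & (pos <= fov).all(axis=1)
    cum_bad = np.cumsum(~inside)
    bad_before = cum_bad - (cum_bad[first_rows] - (~inside)[first_rows])[mol_of_row]
    keep = bad_before == 0

    mol_of_row = mol_of_row[keep]
    pos = pos[keep]
    # frame index = start frame + within-trajectory offset
    row_idx = np.arange(total)[keep]
    kept_first = np.concatenate(([0], np.cumsum(np.bincount(mol_of_row, minlength=n))[:-1]))
    offset = np.arange(len(mol_of_row)) - kept_first[mol_of_row]
    frames = start_frames[mol_of_row] + offset
    del row_idx

    noise = rng.normal(0.0, config.sigma_loc, size=pos.shape)  # nm
    obs_nm = pos * 1000.0 + noise

    precision = np.abs(rng.normal(30.0, 8.0, size=len(pos)))
    precision = np.maximum(precision, 1e-3)
    spot_sd = np.maximum(rng.normal(140.0, 15.0, size=len(pos)), 1e-3)
    intensity = np.maximum(rng.normal(500.0, 100.0, size=len(pos)), 50.0)

    labels = np.array([p.label or f"pop{i + 1}" for i, p in enumerate(config.populations)])

    locs = pd.DataFrame(
        {
            "x_nm": obs_nm[:, 0],
            "y_nm": obs_nm[:, 1],
            "frame": frames.astype(np.int64),
            "sigma_loc_nm": precision,
            "spot_sd_nm": spot_sd,
            "intensity": intensity,
            "molecule_id": mol_of_row.astype(np.int64),
        }
    )
    truth = pd.DataFrame(
        {
            "molecule_id": mol_of_row.astype(np.int64),
            "population": labels[pop_idx[mol_of_row]],
            "frame": frames.astype(np.int64),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "D_true": D_mol[mol_of_row],
        }
    )
    # file/frame order: sort by frame, stable so per-molecule order survives
    order = np.argsort(locs["frame"].to_numpy(), kind="stable")
    return locs.iloc[order].reset_index(drop=True), truth.iloc[order].reset_index(drop=True)


def render_frames(
    localizations: pd.DataFrame,
    config: SimulationConfig,
    *,
    psf_sd_px: float = 1.3,
    offset: int = 100,
    bg_photons: float = 2.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render localizations as a 16-bit camera frame stack.

    Each emitter is drawn as an integrated 2-D Gaussian PSF of SD
    ``psf_sd_px`` pixels scaled to its ``intensity`` (photons); Poisson shot
    noise is applied to the expected photon image and a constant camera
    offset added. Pixel (i, j) covers [j, j+1) x [i, i+1) in pixel units with
    the origin at the top-left corner, x rightward, y downward.
    """
    px = config.pixel_size
    shape = (
        int(round(config.fov[1] * 1000.0 / px)),
        int(round(config.fov[0] * 1000.0 / px)),
    )
    x_px = localizations["x_nm"].to_numpy(dtype=float) / px
    y_px = localizations["y_nm"].to_numpy(dtype=float) / px
    if len(localizations) and (
        x_px.min() < 0 or y_px.min() < 0 or x_px.max() > shape[1] or y_px.max() > shape[0]
    ):
        raise ValueError("localizations fall outside the configured field of view")

    frames_idx = localizations["frame"].to_numpy(dtype=np.int64) if len(localizations) else np.array([], dtype=np.int64)
    n_frames = int(frames_idx.max()) + 1 if len(frames_idx) else 1
    photons = (
        localizations["intensity"].to_numpy(dtype=float)
        if "intensity" in localizations
        else np.full(len(localizations), 500.0)
    )

    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    half = int(np.ceil(5 * psf_sd_px))
    stack = np.empty((n_frames, *shape), dtype=np.uint16)
    expected_bg = np.full(shape, bg_photons, dtype=float)
    for f in range(n_frames):
        expected = expected_bg.copy()
        for k in np.flatnonzero(frames_idx == f):
            cx, cy = x_px[k], y_px[k]
            j0, j1 = max(int(cx) - half, 0), min(int(cx) + half + 1, shape[1])
            i0, i1 = max(int(cy) - half, 0), min(int(cy) + half + 1, shape[0])
            jj = np.arange(j0, j1) + 0.5
            ii = np.arange(i0, i1) + 0.5
            g = np.exp(-((ii[:, None] - cy) ** 2 + (jj[None, :] - cx) ** 2) / (2 * psf_sd_px**2))
            expected[i0:i1, j0:j1] += photons[k] * g / (2 * np.pi * psf_sd_px**2)
        frame = rng.poisson(expected) + offset
        stack[f] = np.clip(frame, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return stack


def simulate_intensity_trace(
    A: float,
    tau1: float,
    tau2: float,
    response_profile: Callable[[np.ndarray], np.ndarray] | np.ndarray | float,
    BG: float,
    noise_sd: float,
    n_frames: int,
    dt: float,
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a raw fluorescence trace with biexponential photobleaching.

    The raw signal is ``response(t) * BL(t) + BG + N(0, noise_sd)`` with the
    normalized bleaching law ``BL(t) = A*exp(-t/tau1) + (1-A)*exp(-t/tau2)``
    (so BL(0) = 1 for any parameters). Returns a table with columns
    ``t_s`` and ``I_raw``.
    """
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"A must be in [0, 1], got {A}")
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("tau1 and tau2 must be > 0")
    if n_frames < 1 or dt <= 0:
        raise ValueError("n_frames >= 1 and dt > 0 required")
    t = np.arange(n_frames) * dt
    bl = A * np.exp(-t / tau1) + (1.0 - A) * np.exp(-t / tau2)
    if callable(response_profile):
        resp = np.asarray(response_profile(t), dtype=float)
    else:
        resp = np.broadcast_to(np.asarray(response_profile, dtype=float), t.shape)
    rng = np.random.default_rng(seed)
    raw = resp * bl + BG + (rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else 0.0)
    return pd.DataFrame({"t_s": t, "I_raw": raw})
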