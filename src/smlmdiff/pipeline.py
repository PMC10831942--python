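"""End-to-end pipeline: simulate -> filter -> link -> MSD -> mixture -> annuli.

A single master seed deterministically derives independent per-stage random
streams (simulation, mixture restarts), so running the same configuration
twice yields identical outputs and toggling one stage does not perturb the
randomness of the others. Every run directory receives all intermediate
tables, the fitted model, a machine-readable ``summary.json``, a copy of the
configuration and a log with every parameter and rejection count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffusion, io, linking, localize, mixtures, spatial
from .synthdata import PopulationSpec, SimulationConfig, simulate_trajectories

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the standard analysis settings
    (30 ms dwell time, 500 nm search radius, 5-frame minimum, 9-frame MSD
    eligibility, 0.2 log-bin width, 2-um annuli out to 10 um)."""

    seed: int = 0
    out_dir: str = "run"
    # simulation stage (skipped when input_locs is given)
    input_locs: str | None = None
    populations: str = "0.0023:0.4,0.014:0.35,0.072:0.25"  # D:fraction pairs
    n_molecules: int = 20_000
    sigma_loc: float = 30.0
    mean_track_len: float = 8.0
    fov: float = 20.0
    n_frames: int = 10_000
    lesion_center: str | None = None  # "x,y" in um
    gradient: str | None = None  # "D0,r0,Dinf"
    # analysis stages
    dt: float = 0.03
    search_radius_nm: float = 500.0
    min_len: int = 5
    min_traj_len: int = 9
    max_lag: int | None = None
    bin_width: float = 0.2
    J: int = 3
    shared_centers: bool = True
    shared_width: bool = True
    log_level: str = "INFO"

    def parse_populations(self) -> list[PopulationSpec]:
        pops = []
        for i, item in enumerate(self.populations.split(",")):
            d, _, f = item.partition(":")
            pops.append(PopulationSpec(D_true=float(d), fraction=float(f), label=f"pop{i + 1}"))
        return pops

    def parse_center(self) -> tuple[float, float] | None:
        if self.lesion_center is None:
            return None
        x, y = (float(v) for v in self.lesion_center.split(","))
        return (x, y)

    def parse_gradient(self) -> tuple[float, float, float] | None:
        if self.gradient is None:
            return None
        d0, r0, dinf = (float(v) for v in self.gradient.split(","))
        return (d0, r0, dinf)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = io.read_keyvalues(path)
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - set(known))
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            f = known[key]
            if value.lower() in ("none", ""):
                kwargs[key] = None
            elif f.type in ("int", int):
                kwargs[key] = int(value)
            elif f.type in ("float", float):
                kwargs[key] = float(value)
            elif f.type in ("bool", bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif f.type in ("int | None",):
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        io.write_keyvalues(dataclasses.asdict(self), path)


def _stage_seed(master: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the master seed."""
    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("smlmdiff")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    config.to_file(out / "config.txt")
    logger.info("pipeline start: %s", dataclasses.asdict(config))
    summary: dict = {"seed": config.seed}

    try:
        if config.input_locs is not None:
            locs = io.read_table(config.input_locs, schema="localizations")
        else:
            sim = SimulationConfig(
                populations=config.parse_populations(),
                sigma_loc=config.sigma_loc,
                dt=config.dt,
                mean_track_len=config.mean_track_len,
                n_molecules=config.n_molecules,
                fov=(config.fov, config.fov),
                n_frames=config.n_frames,
                seed=_stage_seed(config.seed, "simulate"),
                lesion_center=config.parse_center(),
                gradient=config.parse_gradient(),
            )
            locs, truth = simulate_trajectories(sim)
            io.write_table(locs, out / "locs.csv", schema="localizations")
            io.write_table(truth, out / "ground_truth.csv")
            summary["n_molecules"] = config.n_molecules
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/input' failed: {exc}") from exc

    try:
        filtered = localize.filter_localizations(locs)
        io.write_table(filtered, out / "locs.filtered.csv", schema="localizations")
        summary["n_localizations"] = len(locs)
        summary["n_filtered"] = len(filtered)
        density = len(filtered) / (config.fov**2 * max(int(filtered["frame"].max()) + 1, 1)) if len(filtered) else 0.0
        summary["mean_spot_density_per_um2_frame"] = density
        logger.info("spot density: %.4g per um^2 per frame", density)
    except Exception as exc:
        raise RuntimeError(f"stage 'filter' failed: {exc}") from exc

    try:
        trajs = linking.link_trajectories(filtered, config.search_radius_nm, config.min_len)
        io.write_table(trajs, out / "trajs.csv", schema="trajectories")
        summary["n_trajectories"] = int(trajs["traj_id"].nunique()) if len(trajs) else 0
    except Exception as exc:
        raise RuntimeError(f"stage 'link' failed: {exc}") from exc

    try:
        estimates = diffusion.estimate_all(
            trajs, config.dt, min_traj_len=config.min_traj_len, max_lag=config.max_lag
        )
        io.write_table(estimates, out / "D.csv", schema="estimates")
        summary["n_estimates"] = len(estimates)
    except Exception as exc:
        raise RuntimeError(f"stage 'msd' failed: {exc}") from exc

    try:
        if len(estimates):
            pdf = mixtures.build_pdf(estimates["D_log"].to_numpy(), config.bin_width)
            io.write_table(
                pd.DataFrame(
                    {"bin_left": pdf.edges[:-1], "bin_right": pdf.edges[1:], "density": pdf.density}
                ),
                out / "pdf.csv",
            )
            model = mixtures.fit_mixture_global(
                [pdf],
                config.J,
                shared_centers=config.shared_centers,
                shared_width=config.shared_width,
                seed=_stage_seed(config.seed, "fitpdf"),
            )
            io.write_keyvalues(
                {
                    "J": model.J,
                    "shared_centers": model.shared_centers,
                    "shared_width": model.shared_width,
                    "centers": model.centers[0],
                    "widths": model.widths[0],
                    "fractions": model.fractions[0],
                    "fraction_stderr": model.stderr[0] if model.stderr is not None else "nan",
                    "sse": model.sse[0],
                },
                out / "model.txt",
            )
            peak = mixtures.find_peak_D(pdf)
            summary["fractions"] = model.fractions[0].tolist()
            summary["centers_Dlog"] = model.centers[0].tolist()
            summary["width_Dlog"] = float(model.widths[0, 0])
            summary["D_pk_um2_s"] = peak.D_pk
    except Exception as exc:
        raise RuntimeError(f"stage 'fitpdf' failed: {exc}") from exc

    try:
        center = config.parse_center()
        if center is not None and len(estimates):
            profile = spatial.annulus_profile(estimates, center)
            io.write_table(profile.to_frame(), out / "profile.csv", schema="profile")
            if np.isfinite(profile.D_geo).sum() >= 3:
                fit = spatial.fit_distance_profile(profile, "exponential")
                io.write_keyvalues({**fit.params, "R2": fit.r_squared, "model": fit.model}, out / "profile_fit.txt")
                summary["profile_fit"] = {**fit.params, "R2": fit.r_squared}
    except Exception as exc:
        raise RuntimeError(f"stage 'spatial' failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline done: %s", summary)
    return out
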