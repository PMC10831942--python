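"""MSD curves and diffusion-coefficient estimation for short trajectories.

For a 2-D Brownian trajectory observed with localization noise sigma_loc the
mean square displacement at lag time t = n*dt is

    MSD(t) = <(x_{i+n} - x_i)^2> + <(y_{i+n} - y_i)^2> = 4*D*t + 4*sigma_loc^2

so an ordinary least-squares line through the MSD curve yields D from the
slope while the (possibly negative) intercept absorbs the localization-error
offset. Because photobleaching keeps trajectories short, individual D
estimates are noisy and the estimate of a slow molecule can come out with a
negative slope; such events are kept by taking the modulus of D, and the
per-trajectory log-diffusivity D_log = log10(D / 1 um^2 s^-1) is the quantity
analyzed downstream (it is approximately Gaussian for short tracks).

Eligibility rules: trajectories must extend over at least ``min_traj_len``
(default 9) frames; the MSD keeps only lags averaged over at least 4
displacement pairs (n = 1 .. L-4) and the regression needs at least
``min_points`` (default 4) lag points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MSDCurve", "DiffusionEstimate", "compute_msd", "estimate_D", "estimate_all"]

MIN_PAIRS = 4  # displacement pairs needed for a lag to be retained


@dataclass(frozen=True)
class MSDCurve:
    """MSD values per retained lag for one trajectory."""

    lags: np.ndarray  # lag index n
    t: np.ndarray  # lag time n*dt, s
    msd: np.ndarray  # um^2
    pairs: np.ndarray  # displacement pairs averaged per lag
    dt: float  # s
    traj_len: int  # frames


@dataclass(frozen=True)
class DiffusionEstimate:
    """Per-trajectory diffusion estimate from the MSD regression."""

    D: float  # um^2/s, modulus of slope/4
    D_log: float  # log10(D / 1 um^2 s^-1)
    intercept: float  # um^2, reported as fitted (may be negative)
    traj_id: int
    traj_len: int
    r_lesion: float | None = None  # um, distance to lesion if known


def compute_msd(xy_um: np.ndarray, dt: float, *, min_pairs: int = MIN_PAIRS) -> MSDCurve:
    """Time-averaged MSD of one trajectory.

    ``xy_um`` is an (L, 2) array of positions in um at consecutive frames.
    For each lag n the MSD is the mean squared 2-D displacement over all
    (i, i+n) pairs; only lags with at least ``min_pairs`` pairs (n <= L - 4
    by default) are retained.
    """
    xy = np.asarray(xy_um, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("trajectory needs at least 2 localizations of shape (L, 2)")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    L = xy.shape[0]
    max_lag = L - min_pairs
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    pairs = np.empty(len(lags), dtype=int)
    for k, n in enumerate(lags):
        d = xy[n:] - xy[:-n]
        msd[k] = np.mean(np.einsum("ij,ij->i", d, d))
        pairs[k] = L - n
    return MSDCurve(lags=lags, t=lags * dt, msd=msd, pairs=pairs, dt=dt, traj_len=L)


def estimate_D(
    curve: MSDCurve,
    *,
    min_traj_len: int = 9,
    min_points: int = 4,
    max_lag: int | None = None,
    traj_id: int = -1,
    r_lesion: float | None = None,
) -> DiffusionEstimate | None:
    """OLS fit msd = 4*D*t + c; returns None for ineligible trajectories.

    Ineligible means: trajectory shorter than ``min_traj_len`` frames, fewer
    than ``min_points`` retained lags, or an exactly zero slope (D_log would
    be undefined). ``max_lag`` optionally restricts the regression to the
    first lags only.
    """
    if curve.traj_len < min_traj_len:
        return None
    t, msd = curve.t, curve.msd
    if max_lag is not None:
        sel = curve.lags <= max_lag
        t, msd = t[sel], msd[sel]
    if len(t) < min_points:
        return None
    slope, intercept = np.polyfit(t, msd, 1)
    if slope == 0.0:
        return None
    D = abs(slope) / 4.0
    return DiffusionEstimate(
        D=D,
        D_log=np.log10(D),
        intercept=float(intercept),
        traj_id=traj_id,
        traj_len=curve.traj_len,
        r_lesion=r_lesion,
    )


def estimate_all(
    trajs: pd.DataFrame,
    dt: float,
    *,
    min_traj_len: int = 9,
    min_points: int = 4,
    max_lag: int | None = None,
    traj_col: str = "traj_id",
) -> pd.DataFrame:
    """Vectorized per-trajectory D estimation for a trajectory table.

    ``trajs`` must carry ``x_nm, y_nm, frame`` and a trajectory id column;
    rows of one trajectory must be at consecutive frames. Trajectories are
    grouped by length and the MSD/OLS computation is done per length group,
    which keeps the estimator fast for 10^4-10^5 trajectories.

    Returns a table with traj_id, D_um2_s, D_log, intercept_um2, traj_len and
    the trajectory's mean position (mean_x_um, mean_y_um) for spatial
    analysis. Ineligible trajectories are omitted.
    """
    if len(trajs) == 0:
        return pd.DataFrame(
            columns=["traj_id", "D_um2_s", "D_log", "intercept_um2", "traj_len", "mean_x_um", "mean_y_um"]
        )
    trajs = trajs.sort_values([traj_col, "frame"], kind="stable")
    ids, counts = np.unique(trajs[traj_col].to_numpy(), return_counts=True)
    xy = trajs[["x_nm", "y_nm"]].to_numpy(dtype=float) / 1000.0  # um
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))

    out: list[pd.DataFrame] = []
    for L in np.unique(counts):
        if L < max(min_traj_len, MIN_PAIRS + min_points):
            continue
        sel = counts == L
        seg_starts = starts[sel]
        block = np.stack([xy[s : s + L] for s in seg_starts])  # (m, L, 2)
        lags = np.arange(1, L - MIN_PAIRS + 1)
        if max_lag is not None:
            lags = lags[lags <= max_lag]
        if len(lags) < min_points:
            continue
        msd = np.empty((block.shape[0], len(lags)))
        for k, n in enumerate(lags):
            d = block[:, n:, :] - block[:, :-n, :]
            msd[:, k] = (d**2).sum(axis=2).mean(axis=1)
        t = lags * dt
        tc = t - t.mean()
        slope = (msd * tc).sum(axis=1) / (tc**2).sum()
        intercept = msd.mean(axis=1) - slope * t.mean()
        D = np.abs(slope) / 4.0
        ok = D > 0
        out.append(
            pd.DataFrame(
                {
                    "traj_id": ids[sel][ok],
                    "D_um2_s": D[ok],
                    "D_log": np.log10(D[ok]),
                    "intercept_um2": intercept[ok],
                    "traj_len": L,
                    "mean_x_um": block.mean(axis=1)[ok, 0],
                    "mean_y_um": block.mean(axis=1)[ok, 1],
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["traj_id", "D_um2_s", "D_log", "intercept_um2", "traj_len", "mean_x_um", "mean_y_um"]
        )
    return pd.concat(out, ignore_index=True).sort_values("traj_id", kind="stable").reset_index(drop=True)
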