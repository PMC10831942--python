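"""Frame-to-frame trajectory linking.

Localizations in successive camera frames are associated by a one-to-one
assignment that minimizes the total squared displacement among candidate
pairs within a search radius (500 nm by default, the maximum plausible
single-frame displacement). There is no gap closing: a molecule missing in
one frame terminates its trajectory. Trajectories shorter than ``min_len``
frames (5 by default) are discarded.

At the low emitter densities of sparse photoactivation this per-frame-pair
optimal assignment (Hungarian algorithm with infeasible pairs masked out)
is equivalent to global multi-frame optimization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["link_trajectories"]


def _match_frame_pair(
    xy0: np.ndarray, xy1: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Max-cardinality, min-total-squared-displacement matching within radius.

    Returns (index in frame f, index in frame f+1) pairs. Infeasible pairs
    get a penalty cost just above the largest possible feasible total, so the
    solver first maximizes the number of feasible links, then minimizes their
    summed squared displacement, without losing cost resolution to rounding.
    """
    if len(xy0) == 0 or len(xy1) == 0:
        return []
    cost = cdist(xy0, xy1, "sqeuclidean")
    feasible = cost <= radius**2
    if not feasible.any():
        return []
    big = radius**2 * (min(len(xy0), len(xy1)) + 1.0)
    cost = np.where(feasible, cost, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if feasible[r, c]]


def link_trajectories(
    locs: pd.DataFrame,
    search_radius_nm: float = 500.0,
    min_len: int = 5,
) -> pd.DataFrame:
    """Assemble localizations into trajectories.

    Parameters
    ----------
    locs
        Localization table with at least ``x_nm, y_nm, frame``; extra columns
        are carried through to the output unchanged.
    search_radius_nm
        Maximum displacement between successive frames.
    min_len
        Minimum trajectory length in frames; shorter chains are dropped.

    Returns
    -------
    DataFrame
        Input rows that belong to a retained trajectory, with a ``traj_id``
        column, sorted by (traj_id, frame). Frames within a trajectory are
        strictly consecutive and every consecutive displacement is within the
        search radius.
    """
    if len(locs) == 0:
        out = locs.copy()
        out["traj_id"] = pd.Series(dtype=np.int64)
        return out

    locs = locs.reset_index(drop=True)
    frames = locs["frame"].to_numpy()
    xy = locs[["x_nm", "y_nm"]].to_numpy(dtype=float)

    # next_of[i] = row index linked in the following frame, -1 if none
    next_of = np.full(len(locs), -1, dtype=np.int64)
    has_prev = np.zeros(len(locs), dtype=bool)

    frame_rows = {f: np.flatnonzero(frames == f) for f in np.unique(frames)}
    for f in sorted(frame_rows):
        if f + 1 not in frame_rows:
            continue
        r0, r1 = frame_rows[f], frame_rows[f + 1]
        for a, b in _match_frame_pair(xy[r0], xy[r1], search_radius_nm):
            next_of[r0[a]] = r1[b]
            has_prev[r1[b]] = True

    traj_of = np.full(len(locs), -1, dtype=np.int64)
    traj_id = 0
    order = np.argsort(frames, kind="stable")
    for start in order:
        if has_prev[start]:
            continue
        chain = []
        i = start
        while i != -1:
            chain.append(i)
            i = next_of[i]
        if len(chain) >= min_len:
            traj_of[chain] = traj_id
            traj_id += 1

    keep = traj_of >= 0
    out = locs.loc[keep].copy()
    out["traj_id"] = traj_of[keep]
    return out.sort_values(["traj_id", "frame"], kind="stable").reset_index(drop=True)
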