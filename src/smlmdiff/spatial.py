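"""Lesion-centered annulus analysis of diffusivities.

Trajectories are grouped into contiguous 2-um-wide annuli around the lesion
site (outer radii 2, 4, 6, 8, 10 um) by the radial distance of their mean
position, with the interval convention (inner, outer]; trajectories beyond
the outermost radius are excluded. Per annulus the diffusion coefficient is
averaged on a logarithmic scale (the geometric mean of D). The resulting
distance profile is fit either with an exponential recovery,
D(r) = D0*exp(-r/r0) + Dinf, or with a line, D(r) = m*r + D0, using the
annulus midpoint (outer radius minus 1 um) as the abscissa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DEFAULT_OUTER_RADII",
    "AnnulusProfile",
    "DistanceFitResult",
    "assign_annuli",
    "log_average_D",
    "annulus_profile",
    "fit_distance_profile",
]

DEFAULT_OUTER_RADII = (2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class AnnulusProfile:
    """Geometric-mean diffusivity per 2-um annulus around the lesion."""

    r_inner: np.ndarray  # um
    r_outer: np.ndarray  # um
    D_geo: np.ndarray  # um^2/s, log-averaged
    n: np.ndarray  # trajectories per annulus
    lesion_center: tuple[float, float]  # um

    @property
    def r_mid(self) -> np.ndarray:
        return self.r_outer - 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r_inner_um": self.r_inner, "r_outer_um": self.r_outer, "D_geo_um2_s": self.D_geo, "n": self.n}
        )


@dataclass(frozen=True)
class DistanceFitResult:
    """Fit of the diffusivity-versus-distance profile."""

    model: str  # "exponential" or "linear"
    params: dict[str, float]
    r_squared: float


def assign_annuli(
    estimates: pd.DataFrame,
    lesion_center: tuple[float, float],
    outer_radii: tuple[float, ...] = DEFAULT_OUTER_RADII,
) -> pd.DataFrame:
    """Attach lesion distance and annulus index to a diffusion-estimate table.

    ``estimates`` must carry ``mean_x_um, mean_y_um``. Returns a copy with
    ``r_um`` (distance of the trajectory's mean position to the lesion) and
    ``annulus`` (0-based index; -1 for excluded trajectories with r beyond
    the largest outer radius). Annulus k covers (outer[k-1], outer[k]]; r = 0
    falls in the innermost annulus.
    """
    if lesion_center is None:
        raise ValueError("lesion_center is required")
    for col in ("mean_x_um", "mean_y_um"):
        if col not in estimates.columns:
            raise ValueError(f"estimates table lacks column {col!r}")
    outer = np.asarray(outer_radii, dtype=float)
    cx, cy = lesion_center
    r = np.hypot(estimates["mean_x_um"] - cx, estimates["mean_y_um"] - cy).to_numpy()
    idx = np.searchsorted(outer, r, side="left")
    idx[r > outer[-1]] = -1
    out = estimates.copy()
    out["r_um"] = r
    out["annulus"] = idx
    return out


def log_average_D(D: np.ndarray) -> float:
    """Geometric mean: 10**(mean of log10 D)."""
    D = np.asarray(D, dtype=float)
    if D.size == 0:
        raise ValueError("empty group")
    if (D <= 0).any():
        raise ValueError("D must be positive for log averaging")
    return float(10.0 ** np.mean(np.log10(D)))


def annulus_profile(
    estimates: pd.DataFrame,
    lesion_center: tuple[float, float],
    outer_radii: tuple[float, ...] = DEFAULT_OUTER_RADII,
) -> AnnulusProfile:
    """Log-averaged D per annulus. Empty annuli get NaN D and n = 0."""
    assigned = assign_annuli(estimates, lesion_center, outer_radii)
    outer = np.asarray(outer_radii, dtype=float)
    inner = np.concatenate(([0.0], outer[:-1]))
    D_geo = np.full(len(outer), np.nan)
    n = np.zeros(len(outer), dtype=int)
    for k in range(len(outer)):
        grp = assigned.loc[assigned["annulus"] == k, "D_um2_s"]
        n[k] = len(grp)
        if n[k]:
            D_geo[k] = log_average_D(grp.to_numpy())
    return AnnulusProfile(r_inner=inner, r_outer=outer, D_geo=D_geo, n=n, lesion_center=tuple(lesion_center))


def _r_squared(y: np.ndarray, fit: np.ndarray) -> float:
    ss_res = float(((y - fit) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0  # constant data: no variance to explain, by convention
    return 1.0 - ss_res / ss_tot


def fit_distance_profile(profile: AnnulusProfile, model: str = "exponential") -> DistanceFitResult:
    """Fit the distance profile at annulus midpoints.

    ``model="exponential"`` fits D(r) = D0*exp(-r/r0) + Dinf by nonlinear
    least squares (initialized with Dinf at the profile minimum, D0 at the
    range and r0 at half the radial span); ``model="linear"`` fits
    D(r) = m*r + D0 by OLS. NaN annuli (empty) are dropped.
    """
    ok = np.isfinite(profile.D_geo)
    r, y = profile.r_mid[ok], profile.D_geo[ok]
    if len(np.unique(r)) < 2:
        raise ValueError("degenerate abscissa: fewer than 2 distinct radii")
    if model == "linear":
        if len(r) < 2:
            raise ValueError("linear fit needs >= 2 annuli")
        m, d0 = np.polyfit(r, y, 1)
        return DistanceFitResult(
            model="linear", params={"m": float(m), "D0": float(d0)}, r_squared=_r_squared(y, m * r + d0)
        )
    if model != "exponential":
        raise ValueError(f"unknown model {model!r}")
    if len(r) < 3:
        raise ValueError("exponential fit needs >= 3 annuli")

    def f(r, d0, r0, dinf):
        return d0 * np.exp(-r / r0) + dinf

    p0 = [max(y.max() - y.min(), 1e-6), (r.max() - r.min()) / 2.0, y.min()]
    popt, _ = optimize.curve_fit(
        f, r, y, p0=p0, bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20_000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    d0, r0, dinf = popt
    return DistanceFitResult(
        model="exponential",
        params={"D0": float(d0), "r0": float(r0), "Dinf": float(dinf)},
        r_squared=_r_squared(y, f(r, *popt)),
    )
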