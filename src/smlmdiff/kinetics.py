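"""Bleach-corrected fluorescence intensity kinetics.

Lesion-site fluorescence is quantified from ROI mean-intensity traces as

    I(t) = (I_raw(t) - BG) / BL(t)

where BG is the background level and BL(t) the photobleaching decay measured
in a reference ROI far from the lesion, normalized to its initial value and
fit heuristically with a biexponential,

    BL(t) = A*exp(-t/tau1) + (1 - A)*exp(-t/tau2),  BL(0) = 1.

ROI extraction and lesion re-centering are upstream annotation; this module
consumes already-extracted traces. Traces can be normalized to 100 at t = 0
or at an explicit reference value (e.g. the pre-wound sarcolemma signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "BleachModel",
    "IntensityTrace",
    "fit_bleach",
    "correct_intensity",
    "normalize_trace",
    "zline_sarcolemma_ratio",
]


@dataclass(frozen=True)
class BleachModel:
    """Normalized biexponential photobleaching law."""

    A: float  # fractional amplitude of the fast component, in [0, 1]
    tau1: float  # s
    tau2: float  # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.A <= 1.0:
            raise ValueError(f"A must be in [0, 1], got {self.A}")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tau1 and tau2 must be > 0")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * np.exp(-t / self.tau1) + (1.0 - self.A) * np.exp(-t / self.tau2)


@dataclass(frozen=True)
class IntensityTrace:
    """Background- and bleach-corrected ROI intensity trace."""

    times: np.ndarray  # s
    I_raw: np.ndarray
    BG: float | np.ndarray
    BL: np.ndarray
    I: np.ndarray  # (I_raw - BG) / BL


def fit_bleach(times: np.ndarray, reference: np.ndarray) -> BleachModel:
    """Fit the biexponential bleaching law to a reference ROI trace.

    The trace is divided by its t = 0 value before fitting, so BL(0) = 1 by
    construction. Bounds: A in [0, 1], tau in [dt, 100 x trace duration];
    deterministic initialization (A = 0.5, tau1 = duration/10,
    tau2 = duration). For a constant trace the taus run into the upper bound
    and the correction is the identity to within ~1%.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(reference, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and reference must be 1-D arrays of equal length")
    if len(t) < 6:
        raise ValueError("need at least 6 time points to fit a biexponential")
    if y[0] <= 0:
        raise ValueError("reference trace must start positive")
    yn = y / y[0]
    duration = t[-1] - t[0]
    dt = np.min(np.diff(t))
    if duration <= 0 or dt <= 0:
        raise ValueError("times must be strictly increasing")

    def resid(p):
        a, tau1, tau2 = p
        return a * np.exp(-t / tau1) + (1 - a) * np.exp(-t / tau2) - yn

    res = optimize.least_squares(
        resid,
        x0=[0.5, duration / 10.0, duration],
        bounds=([0.0, dt, dt], [1.0, 100.0 * duration, 100.0 * duration]),
        method="trf",
    )
    if not res.success:
        raise RuntimeError("biexponential bleach fit did not converge")
    a, tau1, tau2 = res.x
    return BleachModel(A=float(a), tau1=float(tau1), tau2=float(tau2))


def correct_intensity(
    times: np.ndarray,
    I_raw: np.ndarray,
    BG: float | np.ndarray,
    model: BleachModel,
) -> IntensityTrace:
    """Apply I(t) = (I_raw(t) - BG)/BL(t).

    BG may be a scalar (mean of the background ROI) or a per-frame trace.
    Values below background pass through as negative intensities — they are
    data, not errors. Raises if BL is not strictly positive over the trace.
    """
    t = np.asarray(times, dtype=float)
    raw = np.asarray(I_raw, dtype=float)
    bl = model(t)
    if (bl <= 0).any():
        raise ValueError("bleaching curve is non-positive over the trace")
    bg = np.asarray(BG, dtype=float)
    corrected = (raw - bg) / bl
    return IntensityTrace(times=t, I_raw=raw, BG=BG if np.ndim(BG) else float(bg), BL=bl, I=corrected)


def normalize_trace(
    values: np.ndarray, mode: str = "t0", reference: float | None = None
) -> np.ndarray:
    """Scale a trace so its reference equals 100.

    ``mode="t0"`` uses the first sample as the reference; ``mode="reference"``
    uses the explicit ``reference`` value (e.g. pre-wound sarcolemma signal).
    """
    v = np.asarray(values, dtype=float)
    if mode == "t0":
        if v.size == 0:
            raise ValueError("empty trace")
        ref = v[0]
    elif mode == "reference":
        if reference is None:
            raise ValueError("mode='reference' requires a reference value")
        ref = float(reference)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref == 0:
        raise ValueError("reference value is zero; cannot normalize")
    return v * (100.0 / ref)


def zline_sarcolemma_ratio(zline_means: np.ndarray, sarcolemma_means: np.ndarray) -> float:
    """Ratio of Z-line to sarcolemma fluorescence for one cell.

    Each input is the set of per-position ROI mean intensities (the
    measurement protocol uses 10 positions per cell); the ratio is the mean
    of the Z-line means over the mean of the sarcolemma means.
    """
    z = np.asarray(zline_means, dtype=float)
    s = np.asarray(sarcolemma_means, dtype=float)
    if z.size == 0 or s.size == 0:
        raise ValueError("both ROI sets must be non-empty")
    if not (np.isfinite(z).all() and np.isfinite(s).all()):
        raise ValueError("ROI means must be finite")
    denom = s.mean()
    if denom == 0:
        raise ValueError("sarcolemma mean intensity is zero")
    return float(z.mean() / denom)
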