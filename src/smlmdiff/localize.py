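"""Spot detection, sub-pixel Gaussian fitting and localization quality filters.

The localizer is a plain least-squares 2-D Gaussian fit on 7x7-pixel windows
around local maxima. It returns sub-pixel centers (nm), the fitted PSF SD and
a precision estimate proportional to ``spot_sd / sqrt(photons)`` — the
shot-noise-limited scaling of the uncertainty of a Gaussian-spot centroid.

Quality filtering applies two rejection rules to localization tables:
spots with fitted SD below one camera pixel (109 nm) are rejected (too sharp
to be a focused single emitter), as are spots with localization precision
worse than 70 nm. Both comparisons are strict, so precision exactly 70 nm and
spot SD exactly 109 nm are retained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = ["localize_spots", "filter_localizations"]

logger = logging.getLogger(__name__)

#: reject spots sharper than one pixel
MIN_SPOT_SD_NM = 109.0
#: reject localizations less precise than this
MAX_PRECISION_NM = 70.0

_WIN = 3  # half-width of the 7x7 fit window


def _fit_window(win: np.ndarray, psf_sd_guess: float) -> tuple[float, float, float, float, float] | None:
    """Fit offset + amplitude Gaussian to a (2w+1)^2 window.

    Returns (x0, y0, sd, amplitude, baseline) in window pixel coordinates
    (pixel centers at half-integers), or None if the fit fails.
    """
    size = win.shape[0]
    yy, xx = np.mgrid[0:size, 0:size] + 0.5
    z = win.ravel().astype(float)

    def model(p):
        b, a, x0, y0, s = p
        return b + a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2).ravel() / (2 * s**2))

    c = size / 2.0
    p0 = np.array([np.percentile(z, 20), max(win.max() - np.percentile(z, 20), 1.0), c, c, psf_sd_guess])
    lb = [0.0, 0.0, 0.0, 0.0, 0.3]
    ub = [np.inf, np.inf, size, size, size]
    try:
        res = optimize.least_squares(lambda p: model(p) - z, p0, bounds=(lb, ub), method="trf")
    except Exception:  # pragma: no cover - degenerate windows
        return None
    if not res.success:
        return None
    b, a, x0, y0, s = res.x
    return x0, y0, s, a, b


def localize_spots(
    stack: np.ndarray,
    detection_threshold: float,
    *,
    pixel_size_nm: float = 109.0,
    psf_sd_guess_px: float = 1.3,
) -> pd.DataFrame:
    """Detect and fit single-molecule spots in a frame stack.

    Local maxima (3x3 neighborhood) whose pixel value exceeds
    ``detection_threshold`` are fit with a 2-D Gaussian on a 7x7 window.
    Candidates closer than the window half-width to the frame edge are
    skipped. Returns a localization table with ``x_nm, y_nm, frame,
    sigma_loc_nm, spot_sd_nm, intensity`` where intensity is the integrated
    photon count ``2*pi*A*sd^2`` of the fitted Gaussian and ``sigma_loc_nm``
    the precision proxy ``spot_sd_nm / sqrt(intensity)``.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("stack must be a non-empty (n_frames, h, w) array")
    if not np.isfinite(detection_threshold):
        raise ValueError("detection_threshold must be finite")

    rows: list[tuple] = []
    for f, frame in enumerate(stack):
        frame = frame.astype(float)
        is_max = frame == ndimage.maximum_filter(frame, size=3, mode="nearest")
        cand = np.argwhere(is_max & (frame > detection_threshold))
        for i, j in cand:
            if not (_WIN <= i < frame.shape[0] - _WIN and _WIN <= j < frame.shape[1] - _WIN):
                continue
            win = frame[i - _WIN : i + _WIN + 1, j - _WIN : j + _WIN + 1]
            fit = _fit_window(win, psf_sd_guess_px)
            if fit is None:
                continue
            x0, y0, s, a, _b = fit
            photons = 2 * np.pi * a * s**2
            if photons <= 0:
                continue
            x_nm = (j - _WIN + x0) * pixel_size_nm
            y_nm = (i - _WIN + y0) * pixel_size_nm
            spot_sd_nm = s * pixel_size_nm
            rows.append((x_nm, y_nm, f, spot_sd_nm / np.sqrt(photons), spot_sd_nm, photons))

    return pd.DataFrame(
        rows, columns=["x_nm", "y_nm", "frame", "sigma_loc_nm", "spot_sd_nm", "intensity"]
    )


def filter_localizations(
    locs: pd.DataFrame,
    *,
    max_precision_nm: float = MAX_PRECISION_NM,
    min_spot_sd_nm: float = MIN_SPOT_SD_NM,
) -> pd.DataFrame:
    """Apply the two quality rules to a localization table.

    Keeps rows with ``spot_sd_nm >= min_spot_sd_nm`` AND
    ``sigma_loc_nm <= max_precision_nm`` (rejection is strict on both sides),
    preserving row order. Rejection counts per rule are logged.
    """
    required = {"sigma_loc_nm", "spot_sd_nm"}
    missing = sorted(required - set(locs.columns))
    if missing:
        raise ValueError(f"localization table is missing columns: {', '.join(missing)}")

    too_sharp = locs["spot_sd_nm"] < min_spot_sd_nm
    too_imprecise = locs["sigma_loc_nm"] > max_precision_nm
    keep = ~(too_sharp | too_imprecise)
    logger.info(
        "filter_localizations: %d/%d retained (%d spot_sd < %g nm, %d precision > %g nm)",
        int(keep.sum()),
        len(locs),
        int(too_sharp.sum()),
        min_spot_sd_nm,
        int(too_imprecise.sum()),
        max_precision_nm,
    )
    return locs.loc[keep].copy()
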