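"""Log-scale diffusivity histograms and global log-Gaussian mixture fits.

Per-trajectory log-diffusivities D_log = log10(D / 1 um^2 s^-1) are compiled
into histograms with fixed bin width 0.2 on the log axis, area-normalized to
probability density functions. Because individual D estimates from short
trajectories scatter log-normally around the true diffusivity, distinct
classes of diffusing entities appear as Gaussian components on the log axis
and the PDF is modeled as

    PDF(D_log) = sum_j f_j / (sigma_j * sqrt(2*pi))
                 * exp(-(D_log - c_j)^2 / (2*sigma_j^2))

with fractional populations f_j >= 0, sum f_j = 1, centers c_j and widths
sigma_j. Several datasets (e.g. before/after membrane lesioning) can be fit
in a single run with centers and widths shared between them, so that only the
per-dataset fractions differ — the population-shift readout of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm as _norm

__all__ = [
    "HistogramPDF",
    "MixtureModel",
    "PeakFit",
    "build_pdf",
    "eval_mixture",
    "fit_mixture_global",
    "find_peak_D",
    "population_shift",
]

DEFAULT_BIN_WIDTH = 0.2


@dataclass(frozen=True)
class HistogramPDF:
    """Area-normalized histogram of D_log values."""

    edges: np.ndarray  # bin edges, multiples of the bin width
    density: np.ndarray  # probability density per bin
    n: int  # number of trajectories compiled
    label: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class MixtureModel:
    """Fitted sum of log-Gaussians, possibly shared across datasets.

    ``centers`` has shape (n_datasets, J) — rows are identical when centers
    are shared; likewise ``widths``. ``fractions`` is (n_datasets, J) with
    rows on the simplex. ``stderr`` holds asymptotic 1-sigma uncertainties
    for the fraction estimates (same shape), NaN where unavailable.
    """

    centers: np.ndarray
    widths: np.ndarray
    fractions: np.ndarray
    labels: list[str]
    shared_centers: bool
    shared_width: bool
    sse: np.ndarray = field(default_factory=lambda: np.array([]))  # per dataset
    stderr: np.ndarray | None = None

    @property
    def J(self) -> int:
        return self.centers.shape[1]


@dataclass(frozen=True)
class PeakFit:
    """Gaussian fit to the upper part of the dominant histogram peak."""

    D_pk: float  # um^2/s
    center: float  # fitted center on the D_log axis
    width: float  # fitted SD on the D_log axis
    n_points: int  # histogram bins used


def build_pdf(
    d_log: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH, label: str = ""
) -> HistogramPDF:
    """Histogram D_log values on a fixed grid and area-normalize.

    Bin edges are anchored at integer multiples of ``bin_width`` (…, -0.4,
    -0.2, 0, …) so histograms from different datasets share a common grid.
    The density integrates to 1: sum(density) * bin_width = 1.
    """
    v = np.asarray(d_log, dtype=float)
    if v.size == 0:
        raise ValueError("cannot build a PDF from an empty sample")
    if not np.isfinite(v).all():
        raise ValueError("D_log values must be finite")
    lo = np.floor(v.min() / bin_width)
    hi = np.ceil(v.max() / bin_width)
    if hi == v.max() / bin_width:  # top value exactly on an edge: open one more bin
        hi += 1
    edges = np.arange(int(lo), int(hi) + 1) * bin_width
    counts, _ = np.histogram(v, bins=edges)
    density = counts / (v.size * bin_width)
    return HistogramPDF(edges=edges, density=density, n=int(v.size), label=label)


def _gauss(x: np.ndarray, c: float, s: float) -> np.ndarray:
    return np.exp(-((x - c) ** 2) / (2.0 * s**2)) / (s * np.sqrt(2.0 * np.pi))


def eval_mixture(model: MixtureModel, d_log: np.ndarray, dataset: int = 0) -> np.ndarray:
    """Mixture density at points ``d_log`` for one dataset."""
    f = model.fractions[dataset]
    if abs(f.sum() - 1.0) > 1e-9 or (f < -1e-12).any():
        raise ValueError("fractions must be non-negative and sum to 1")
    x = np.asarray(d_log, dtype=float)
    out = np.zeros_like(x, dtype=float)
    for j in range(model.J):
        out += f[j] * _gauss(x, model.centers[dataset, j], model.widths[dataset, j])
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.concatenate([logits, [0.0]])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _unpack(params: np.ndarray, J: int, n_ds: int, shared_centers: bool, shared_width: bool):
    k = 0
    if shared_centers:
        centers = np.tile(params[k : k + J], (n_ds, 1))
        k += J
    else:
        centers = params[k : k + J * n_ds].reshape(n_ds, J)
        k += J * n_ds
    if shared_width:
        widths = np.full((n_ds, J), params[k])
        k += 1
    else:
        widths = np.tile(params[k : k + J], (n_ds, 1))
        k += J
    fracs = np.empty((n_ds, J))
    for d in range(n_ds):
        fracs[d] = _softmax(params[k : k + J - 1])
        k += J - 1
    return centers, widths, fracs


def fit_mixture_global(
    pdfs: list[HistogramPDF] | HistogramPDF,
    J: int,
    *,
    shared_centers: bool = True,
    shared_width: bool = True,
    init_centers: np.ndarray | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    loss: str = "density",
) -> MixtureModel:
    """Global fit of a sum of J log-Gaussians to one or more PDFs.

    All histograms are fit simultaneously; with ``shared_centers`` /
    ``shared_width`` the component centers / the single common width take one
    value across all datasets ("Occam's razor" global fit), while fractional
    populations are free per dataset, constrained to the simplex by a softmax
    reparameterization.

    ``loss="density"`` (default) minimizes the unweighted squared residual
    between the mixture density evaluated at the bin centers and the observed
    density; it is robust to the mildly skewed tails that per-trajectory
    diffusivity estimates carry in practice. ``loss="ml"`` maximizes the
    multinomial likelihood of the bin counts under bin-integrated mixture
    probabilities — statistically more efficient when the data truly are a
    log-Gaussian mixture, but sensitive to tail misfit.

    Optimization is deterministic: a quantile-spread start plus
    ``n_restarts`` seeded random perturbations; the best objective wins.
    Raises RuntimeError if no start converges, ValueError if J exceeds the
    number of occupied bins.
    """
    if loss not in ("ml", "density"):
        raise ValueError(f"unknown loss {loss!r}; use 'ml' or 'density'")
    if isinstance(pdfs, HistogramPDF):
        pdfs = [pdfs]
    if J < 1:
        raise ValueError("J must be >= 1")
    occupied = max(int((p.density > 0).sum()) for p in pdfs)
    if J > occupied:
        raise ValueError(f"J={J} exceeds the {occupied} occupied bins")
    n_ds = len(pdfs)

    all_centers = np.concatenate([p.centers for p in pdfs])
    all_density = np.concatenate([p.density for p in pdfs])
    lo, hi = all_centers.min(), all_centers.max()
    pad = pdfs[0].bin_width

    # weighted quantile spread of the pooled histogram as the base start
    w = all_density / all_density.sum()
    order = np.argsort(all_centers)
    cw = np.cumsum(w[order])
    q = (np.arange(J) + 0.5) / J
    base_centers = (
        np.asarray(init_centers, dtype=float)
        if init_centers is not None
        else np.interp(q, cw, all_centers[order])
    )
    mean = (all_centers * w).sum()
    sd = max(np.sqrt(((all_centers - mean) ** 2 * w).sum()), pdfs[0].bin_width)
    base_width = max(sd / max(J, 1), 0.05)

    def pack(centers_j, width, logits_per_ds):
        parts = [np.sort(centers_j)] if shared_centers else [np.tile(np.sort(centers_j), n_ds)]
        parts.append([width] if shared_width else np.full(J, width))
        for d in range(n_ds):
            parts.append(logits_per_ds)
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])

    def residuals(params):
        centers, widths, fracs = _unpack(params, J, n_ds, shared_centers, shared_width)
        res = []
        for d, p in enumerate(pdfs):
            m = np.zeros_like(p.centers)
            for j in range(J):
                m += fracs[d, j] * _gauss(p.centers, centers[d, j], widths[d, j])
            res.append(m - p.density)
        return np.concatenate(res)

    bin_counts = [np.rint(p.density * p.n * p.bin_width) for p in pdfs]

    def neg_loglik(params):
        centers, widths, fracs = _unpack(params, J, n_ds, shared_centers, shared_width)
        nll = 0.0
        for d, p in enumerate(pdfs):
            probs = np.zeros(len(p.centers))
            for j in range(J):
                cdf = _norm.cdf(p.edges, centers[d, j], widths[d, j])
                probs += fracs[d, j] * np.diff(cdf)
            probs = np.maximum(probs, 1e-300)
            nll -= float(bin_counts[d] @ np.log(probs))
        return nll

    n_center = J if shared_centers else J * n_ds
    n_width = 1 if shared_width else J
    lower = np.concatenate(
        [np.full(n_center, lo - pad), np.full(n_width, 1e-3), np.full((J - 1) * n_ds, -20.0)]
    )
    upper = np.concatenate(
        [np.full(n_center, hi + pad), np.full(n_width, hi - lo + 2 * pad), np.full((J - 1) * n_ds, 20.0)]
    )

    rng = np.random.default_rng(seed)
    starts = [pack(base_centers, base_width, np.zeros(J - 1))]
    for _ in range(n_restarts):
        c = np.clip(base_centers + rng.normal(0, 2 * pad, J), lo, hi)
        wdt = float(np.clip(base_width * rng.lognormal(0, 0.4), 1e-3, hi - lo + pad))
        logits = rng.normal(0, 1, J - 1)
        starts.append(pack(c, wdt, logits))

    best = None
    if loss == "density":
        for x0 in starts:
            try:
                res = optimize.least_squares(
                    residuals, np.clip(x0, lower, upper), bounds=(lower, upper), method="trf"
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost - 1e-14):
                best = res
        if best is not None:
            cov = _ls_covariance(best)
    else:
        bnds = list(zip(lower, upper))
        for x0 in starts:
            try:
                res = optimize.minimize(
                    neg_loglik, np.clip(x0, lower, upper), method="L-BFGS-B", bounds=bnds
                )
            except Exception:
                continue
            if res.success and (best is None or res.fun < best.fun - 1e-12):
                best = res
        if best is not None:
            cov = _nll_covariance(neg_loglik, best.x, lower, upper)
    if best is None:
        raise RuntimeError("global mixture fit did not converge from any start")

    centers, widths, fracs = _unpack(best.x, J, n_ds, shared_centers, shared_width)
    # sort components by center (per shared ordering)
    order = np.argsort(centers[0])
    centers, widths, fracs = centers[:, order], widths[:, order], fracs[:, order]

    sse = np.empty(n_ds)
    r = residuals(best.x)
    pos = 0
    for d, p in enumerate(pdfs):
        k = len(p.centers)
        sse[d] = float((r[pos : pos + k] ** 2).sum())
        pos += k

    stderr = _fraction_stderr(best.x, cov, J, n_ds, shared_centers, shared_width, order)
    return MixtureModel(
        centers=centers,
        widths=widths,
        fractions=fracs,
        labels=[p.label or f"dataset{d}" for d, p in enumerate(pdfs)],
        shared_centers=shared_centers,
        shared_width=shared_width,
        sse=sse,
        stderr=stderr,
    )


def _ls_covariance(res) -> np.ndarray | None:
    """Asymptotic parameter covariance of a least-squares fit."""
    m, k = res.jac.shape
    dof = m - k
    if dof <= 0:
        return None
    try:
        return np.linalg.pinv(res.jac.T @ res.jac) * 2.0 * res.cost / dof
    except np.linalg.LinAlgError:  # pragma: no cover
        return None


def _nll_covariance(nll, x, lower, upper, eps: float = 1e-5) -> np.ndarray | None:
    """Inverse observed information from a central finite-difference Hessian."""
    k = len(x)
    if ((x <= lower + 2 * eps) | (x >= upper - 2 * eps)).any():
        return None  # optimum on a bound: curvature ill-defined
    h = eps * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = nll(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (nll(x + ei) - 2 * f0 + nll(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll(x + ei + ej) - nll(x + ei - ej) - nll(x - ei + ej) + nll(x - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        return np.linalg.pinv(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None


def _fraction_stderr(x, cov, J, n_ds, shared_centers, shared_width, order) -> np.ndarray | None:
    """Asymptotic fraction uncertainties via the delta method on the softmax."""
    if cov is None:
        return None
    out = np.full((n_ds, J), np.nan)
    n_center = J if shared_centers else J * n_ds
    n_width = 1 if shared_width else J
    base = n_center + n_width
    for d in range(n_ds):
        idx = np.arange(base + d * (J - 1), base + (d + 1) * (J - 1))
        logits = x[idx]
        f = _softmax(logits)
        # Jacobian of softmax (with fixed last logit 0) wrt the free logits
        Jf = np.zeros((J, J - 1))
        for a in range(J):
            for b in range(J - 1):
                Jf[a, b] = f[a] * ((1.0 if a == b else 0.0) - f[b])
        sub = cov[np.ix_(idx, idx)]
        var = np.einsum("ab,bc,ac->a", Jf, sub, Jf)
        out[d] = np.sqrt(np.maximum(var, 0.0))[order]
    return out


def find_peak_D(pdf: HistogramPDF) -> PeakFit:
    """Peak diffusivity from a Gaussian fit to the top of the dominant mode.

    Only histogram bins with density strictly above half the global maximum,
    restricted to the contiguous run of such bins containing the maximum, are
    fit (a plain Gaussian on the D_log axis). At least 3 qualifying bins are
    required. D_pk = 10**center.
    """
    x, y = pdf.centers, pdf.density
    imax = int(np.argmax(y))
    half = 0.5 * y[imax]
    qual = y > half
    # contiguous run containing the global maximum
    a = imax
    while a > 0 and qual[a - 1]:
        a -= 1
    b = imax
    while b < len(y) - 1 and qual[b + 1]:
        b += 1
    sel = slice(a, b + 1)
    xs, ys = x[sel], y[sel]
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} bins above half maximum; need >= 3")

    def gauss(x, amp, c, s):
        return amp * np.exp(-((x - c) ** 2) / (2 * s**2))

    p0 = [y[imax], x[imax], max(pdf.bin_width, (xs[-1] - xs[0]) / 2.355)]
    popt, _ = optimize.curve_fit(gauss, xs, ys, p0=p0, maxfev=10_000)
    _amp, c, s = popt
    return PeakFit(D_pk=float(10.0**c), center=float(c), width=float(abs(s)), n_points=len(xs))


def population_shift(
    fractions_before: np.ndarray, fractions_after: np.ndarray
) -> dict[str, float | dict[int, float]]:
    """Population-1 loss and where it went, in percent of the pre-lesion f1.

    Both inputs are fraction vectors summing to 1 with population 1 first.
    Returns ``loss_pop1_pct`` = 100*(f1_before - f1_after)/f1_before and
    ``gain_pct`` = {k: 100*(fk_after - fk_before)/f1_before} for k >= 2
    (1-based population indices).
    """
    fb = np.asarray(fractions_before, dtype=float)
    fa = np.asarray(fractions_after, dtype=float)
    if fb.shape != fa.shape:
        raise ValueError("fraction vectors must have the same length")
    for name, f in (("before", fb), ("after", fa)):
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} fractions sum to {f.sum()!r}, not 1")
    if fb[0] == 0:
        raise ValueError("pre-lesion population-1 fraction is zero")
    loss = 100.0 * (fb[0] - fa[0]) / fb[0]
    gains = {k + 1: 100.0 * (fa[k] - fb[k]) / fb[0] for k in range(1, len(fb))}
    return {"loss_pop1_pct": float(loss), "gain_pct": gains}
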