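"""Gaussian peak fitting of identity distributions and burst-time calibration.

Each amplification burst leaves a roughly Gaussian peak in the
fragment-weighted identity distribution.  Peaks are separated at the
valleys of the smoothed curve, each is fitted with a Gaussian
A*exp(-(x-mu)^2 / (2 sigma^2)) by least squares, and the fitted width is
converted to an age with the clock

    K = 2.58 * sigma      (sigma as a per-site fraction)
    t = K / r             (r: substitutions per site per year)

with r = 7e-9 for cotton by default.  An alternative, non-canonical mode
derives K from the peak mean instead, K = (100 - mu)/100; it is useful for
validating the simulator, where mean divergence tracks age directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, signal
from scipy.ndimage import uniform_filter1d

from .dots import IdentityDistribution, build_distribution
from .hits import TEHit

__all__ = [
    "GaussianPeak",
    "BurstEstimate",
    "detect_peaks",
    "fit_gpdf",
    "burst_time",
    "profile_and_date",
    "K_SIGMA_FACTOR",
    "DEFAULT_RATE",
]

K_SIGMA_FACTOR = 2.58
DEFAULT_RATE = 7e-9
DEFAULT_MIN_ADJ_R2 = 0.95
DEFAULT_MIN_PROMINENCE = 0.05
DEFAULT_SMOOTH_WINDOW = 5
#: peaks with mu at or above this identity are flagged too recent to date
#: reliably (the youngest, still-amplifying peaks sit at 96-99% identity)
RECENT_IDENTITY_THRESHOLD = 96.0


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted peak: mean and width on the percent-identity axis."""

    mu: float
    sigma_pct: float
    amplitude: float
    adj_r2: float
    fit_window: tuple[float, float]
    rejected: bool = False

    def __post_init__(self) -> None:
        if self.sigma_pct <= 0:
            raise ValueError(f"sigma_pct must be positive, got {self.sigma_pct}")
        if self.adj_r2 > 1.0 + 1e-12:
            raise ValueError(f"adj_r2 {self.adj_r2} exceeds 1")


@dataclass(frozen=True)
class BurstEstimate:
    """A dated burst: substitution ratio K and age t = K/r in years."""

    peak: GaussianPeak
    K: float
    t: float
    r: float
    mode: str = "sigma"
    too_recent: bool = False

    @property
    def t_ma(self) -> float:
        """Age in millions of years."""
        return self.t / 1e6


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def detect_peaks(
    dist: IdentityDistribution,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[tuple[float, float]]:
    """Separate single peaks of an identity distribution into fit windows.

    The counts are smoothed with a moving average of ``smooth_window`` bins
    and local maxima with prominence >= ``min_prominence`` times the global
    maximum are kept.  Each peak's window extends to the flanking minima of
    the smoothed curve: the valley between two adjacent peaks splits their
    windows, and the outermost windows extend to the ends of the non-empty
    support.

    Returns windows as (lo, hi) in percent identity.  An all-zero
    distribution yields no windows.
    """
    counts = np.asarray(dist.counts, dtype=float)
    if not np.any(counts > 0):
        return []
    if np.count_nonzero(counts) < 3:
        raise ValueError("distribution needs >= 3 non-empty bins for peak detection")
    smooth = uniform_filter1d(counts, size=max(1, smooth_window), mode="nearest")
    gmax = smooth.max()
    peak_idx, _ = signal.find_peaks(smooth, prominence=min_prominence * gmax)
    if len(peak_idx) == 0:
        return []

    edges = np.asarray(dist.bin_edges, dtype=float)
    nz = np.flatnonzero(counts > 0)
    left_support, right_support = int(nz[0]), int(nz[-1])
    cuts = [float(edges[min(left_support, int(peak_idx[0]))])]
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        valley = a + int(np.argmin(smooth[a : b + 1]))
        cuts.append(float(edges[valley]))  # valley bin joins the right window
    cuts.append(float(edges[max(right_support, int(peak_idx[-1])) + 1]))
    return list(zip(cuts[:-1], cuts[1:]))


def fit_gpdf(
    dist: IdentityDistribution,
    window: tuple[float, float],
    min_adj_r2: float = DEFAULT_MIN_ADJ_R2,
    restarts: int = 5,
    restart_seed: int = 0,
) -> GaussianPeak:
    """Least-squares Gaussian fit over the bin midpoints inside a window.

    The window must hold at least 4 bins (one more than the 3 free
    parameters).  Fit quality is summarised by the adjusted R-squared
    1 - (1 - R^2)(n - 1)/(n - p - 1) with p = 3; a peak whose adjusted
    R-squared falls below ``min_adj_r2`` is returned flagged ``rejected``
    rather than silently dropped.

    Initialisation: mu at the window argmax, sigma at a quarter of the
    window width, amplitude at the max count; on failure up to ``restarts``
    jittered re-initialisations are tried with a fixed seed.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty fit window {window}")
    mids = dist.midpoints
    mask = (mids >= lo) & (mids <= hi)
    x = mids[mask]
    y = np.asarray(dist.counts, dtype=float)[mask]
    if x.size < 4:
        raise ValueError(
            f"window {window} holds {x.size} bins; need >= 4 for a 3-parameter fit"
        )

    a0 = float(y.max())
    mu0 = float(x[int(np.argmax(y))])
    sigma0 = (hi - lo) / 4.0
    rng = np.random.default_rng(restart_seed)
    last_err: Exception | None = None
    popt = None
    for attempt in range(restarts + 1):
        if attempt == 0:
            p0 = (a0, mu0, sigma0)
        else:
            p0 = (
                a0 * rng.uniform(0.5, 1.5),
                float(rng.uniform(lo, hi)),
                sigma0 * rng.uniform(0.25, 2.0),
            )
        try:
            popt, _ = optimize.curve_fit(
                _gaussian,
                x,
                y,
                p0=p0,
                bounds=([0.0, lo - (hi - lo), 1e-9], [np.inf, hi + (hi - lo), np.inf]),
                maxfev=20000,
            )
            break
        except (RuntimeError, optimize.OptimizeWarning) as exc:  # non-convergence
            last_err = exc
    if popt is None:
        raise RuntimeError(f"Gaussian fit failed in window {window}: {last_err}")

    amplitude, mu, sigma = (float(v) for v in popt)
    sigma = abs(sigma)
    if sigma < 1e-8:
        raise RuntimeError(f"degenerate fit (sigma -> 0) in window {window}")

    resid = y - _gaussian(x, amplitude, mu, sigma)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, p = x.size, 3
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else r2
    adj_r2 = min(adj_r2, 1.0)
    return GaussianPeak(
        mu=mu,
        sigma_pct=sigma,
        amplitude=amplitude,
        adj_r2=adj_r2,
        fit_window=(lo, hi),
        rejected=adj_r2 < min_adj_r2,
    )


def burst_time(
    peak: GaussianPeak,
    r: float = DEFAULT_RATE,
    mode: str = "sigma",
    recent_identity: float = RECENT_IDENTITY_THRESHOLD,
) -> BurstEstimate:
    """Convert a fitted peak to a dated burst.

    In the default ``"sigma"`` mode the average nucleotide substitution
    ratio is K = 2.58 * sigma (sigma converted from percentage points to a
    per-site fraction), and t = K/r years.  The alternative ``"mean"`` mode
    (non-canonical) takes K = (100 - mu)/100, the peak's mean divergence.

    Peaks whose mean identity is at or above ``recent_identity`` percent
    are still dated but flagged ``too_recent``: so close to 100% identity
    the width no longer resolves an age.
    """
    if r <= 0:
        raise ValueError(f"substitution rate r must be positive, got {r}")
    if mode == "sigma":
        K = K_SIGMA_FACTOR * (peak.sigma_pct / 100.0)
    elif mode == "mean":
        K = (100.0 - peak.mu) / 100.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BurstEstimate(
        peak=peak,
        K=K,
        t=K / r,
        r=r,
        mode=mode,
        too_recent=peak.mu >= recent_identity,
    )


def profile_and_date(
    hits: Sequence[TEHit],
    *,
    unit: int = 30,
    rounding: str = "floor",
    bin_width: float = 0.1,
    id_range: tuple[float, float] = (50.0, 100.0),
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_adj_r2: float = DEFAULT_MIN_ADJ_R2,
    r: float = DEFAULT_RATE,
    mode: str = "sigma",
    recent_identity: float = RECENT_IDENTITY_THRESHOLD,
) -> list[BurstEstimate]:
    """Full pipeline: hits -> dots -> distribution -> peaks -> dated bursts.

    Returns estimates ordered by peak mean identity descending, i.e. the
    youngest burst first.  Rejected fits are included, flagged.
    """
    hits = list(hits)
    if not hits:
        return []
    dist = build_distribution(
        hits, bin_width=bin_width, id_range=id_range, unit=unit, rounding=rounding
    )
    windows = detect_peaks(
        dist, min_prominence=min_prominence, smooth_window=smooth_window
    )
    estimates = []
    for window in windows:
        peak = fit_gpdf(dist, window, min_adj_r2=min_adj_r2)
        estimates.append(
            burst_time(peak, r=r, mode=mode, recent_identity=recent_identity)
        )
    estimates.sort(key=lambda e: -e.peak.mu)
    return estimates
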