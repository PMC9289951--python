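"""Diagnostics linking first-passage-time features to landscape funnels.

Each kinetic trap contributes one slow relaxation mode; on a logarithmic
time axis the trap escapes appear as separate peaks in the density of
y = ln t and as separate steps in the observation-time-restricted MFPT
<t>_obs as a function of ln t_obs.  The helpers here histogram sampled
ensembles on the log axis, count peaks in a density curve at a prominence
floor, and locate steps in an MFPT curve, matching the plateau heights to
the partial-mode sums that predict them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .kmc import FPTEnsemble
from .spectral import (
    SpectralFPT,
    NoFeasibleEventsError,
    log_time_density,
    partial_sum_mfpt,
    truncated_mfpt,
)

__all__ = [
    "PeakReport",
    "StepReport",
    "default_y_grid",
    "histogram_log",
    "detect_peaks",
    "detect_steps",
    "mfpt_vs_observation_time",
    "spectral_cdf",
    "cdf_sup_distance",
]

DEFAULT_GRID_POINTS = 600
DEFAULT_PROMINENCE_FRAC = 0.05
DEFAULT_STEP_DERIV_FRAC = 0.10


@dataclass
class PeakReport:
    """Peaks of a log-time density: (position y, height, prominence)."""

    positions: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray
    prominence_floor: float
    grid: np.ndarray

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass
class StepReport:
    """Steps of <t>_obs vs ln t_obs and the plateau values around them."""

    positions: np.ndarray        # ln t_obs at maximum slope of each rise
    plateaus_before: np.ndarray
    plateaus_after: np.ndarray
    predicted_plateaus: np.ndarray  # partial-mode sums, slowest mode added last
    grid: np.ndarray

    @property
    def count(self) -> int:
        return len(self.positions)


def default_y_grid(sp: SpectralFPT, points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Uniform grid in y = ln t spanning [ln(1e-3/nu_max), ln(1e3/nu_min)]."""
    lo = np.log(1e-3 / sp.nus.max())
    hi = np.log(1e3 / sp.nus.min())
    return np.linspace(lo, hi, points)


def histogram_log(
    ensemble: FPTEnsemble, which: str = "t", bins: int | np.ndarray = 80
):
    """Density histogram of ln t or ln s with uniform log-spaced bins.

    Censored samples are excluded (their count is available on the
    ensemble).  Returns ``(bin_edges, density)`` with the density normalized
    so that sum(density * bin_width) = 1.
    """
    if which not in ("t", "s"):
        raise ValueError("which must be 't' or 's'")
    vals = ensemble.t if which == "t" else ensemble.s.astype(float)
    if len(vals) == 0:
        raise ValueError("ensemble empty after censoring")
    logs = np.log(vals)
    if np.isscalar(bins) or np.ndim(bins) == 0:
        lo, hi = logs.min(), logs.max()
        if hi == lo:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    density, edges = np.histogram(logs, bins=edges, density=True)
    return edges, density


def detect_peaks(
    density: np.ndarray,
    grid: np.ndarray,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> PeakReport:
    """Local maxima with prominence at least ``prominence_frac`` of the
    global maximum.

    Boundary convention: a maximum at the very first or last grid point is
    not counted (a monotonically decreasing density has zero peaks; a
    single interior bump counts once).
    """
    density = np.asarray(density, dtype=float)
    grid = np.asarray(grid, dtype=float)
    steps = np.diff(grid)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("grid must be uniform")
    floor = prominence_frac * density.max()
    idx, props = find_peaks(density, prominence=floor)
    return PeakReport(
        positions=grid[idx],
        heights=density[idx],
        prominences=props["prominences"],
        prominence_floor=floor,
        grid=grid,
    )


def mfpt_vs_observation_time(
    sp: SpectralFPT, grid: np.ndarray | None = None, points: int = DEFAULT_GRID_POINTS
):
    """<t>_obs over a log-spaced observation-time grid.

    Grid points whose observation window admits no feasible events are
    reported as NaN rather than raising (the curve simply has no support
    there).  Returns ``(y_grid, mfpt_curve, z_curve)``.
    """
    if grid is None:
        grid = default_y_grid(sp, points)
    mfpt = np.full(len(grid), np.nan)
    z = np.zeros(len(grid))
    for i, y in enumerate(grid):
        try:
            mfpt[i], z[i] = truncated_mfpt(sp, float(np.exp(y)))
        except NoFeasibleEventsError:
            pass
    return grid, mfpt, z


def spectral_cdf(sp: SpectralFPT, t) -> np.ndarray:
    """Exact first-passage CDF F(t) = 1 - sum_l (A_l/nu_l) e^{-nu_l t}."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    F = 1.0 - np.exp(-np.outer(t_arr, sp.nus)) @ (sp.amps / sp.nus)
    return F if np.ndim(t) else float(F[0])


def cdf_sup_distance(sp: SpectralFPT, times: np.ndarray) -> float:
    """Kolmogorov-Smirnov sup-distance of sampled FPTs from the exact CDF.

    The statistic the cross-engine agreement checks report: the largest
    vertical gap between the empirical CDF of an ensemble and the spectral
    CDF, evaluated on both sides of each jump.
    """
    t = np.sort(np.asarray(times, dtype=float))
    n = len(t)
    if n == 0:
        raise ValueError("empty sample")
    F = spectral_cdf(sp, t)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return float(max(np.abs(F - hi).max(), np.abs(F - lo).max()))


def detect_steps(
    mfpt_curve: np.ndarray,
    grid: np.ndarray,
    spectral: SpectralFPT,
    deriv_frac: float = DEFAULT_STEP_DERIV_FRAC,
) -> StepReport:
    """Locate the rises of <t>_obs vs ln t_obs and predict their plateaus.

    A step is a contiguous region where d<t>_obs/d ln t_obs (on log-MFPT
    scale, so each rise registers regardless of absolute magnitude) exceeds
    ``deriv_frac`` of the maximum derivative.  Plateau values on either side
    of each rise are read off the curve and compared with the partial-mode
    sums: retaining the k fastest modes predicts the plateau before the
    (n_modes - k)-th slowest mode becomes feasible.
    """
    from scipy.signal import medfilt

    grid = np.asarray(grid, dtype=float)
    curve = np.asarray(mfpt_curve, dtype=float)
    ok = np.isfinite(curve) & (curve > 0)
    g, c = grid[ok], curve[ok]
    # slope of ln <t>_obs: scale-free measure of where the curve rises;
    # median-filtered to suppress single-point numerical spikes
    dlog = medfilt(np.gradient(np.log(c), g), 5)

    # a step is a local maximum of the slope, separated from its neighbors
    # by a valley (the plateau); prominence relative to the largest slope
    peak_idx, _ = find_peaks(dlog, prominence=max(deriv_frac * dlog.max(), 1e-12))

    # the fastest relaxation produces an initial ramp from zero whose slope
    # saturates rather than peaks, so it never registers as a slope maximum;
    # count it as the first step when the curve rises substantially before
    # the first interior peak's plateau.  Its position is the steepest point
    # of the ramp on the linear scale (for a single-exponential curve this
    # sits near -ln nu).
    first_valley = (
        int(np.argmin(dlog[: peak_idx[0]])) if len(peak_idx) else len(g) - 1
    )
    if first_valley > 1 and c[first_valley] > np.exp(1.0) * c[0]:
        seg = slice(0, first_valley + 1)
        ramp_pos = int(np.argmax(np.gradient(c[seg], g[seg])))
        peak_idx = np.concatenate(([ramp_pos], peak_idx)).astype(int)

    # plateau levels are read at the flattest point (slope minimum) between
    # consecutive steps; the level after step i is the level before step i+1
    valleys = []
    for i in range(len(peak_idx) + 1):
        lo = 0 if i == 0 else peak_idx[i - 1] + 1
        hi = len(g) if i == len(peak_idx) else peak_idx[i]
        if hi <= lo:
            valleys.append(min(lo, len(g) - 1))
        else:
            valleys.append(lo + int(np.argmin(dlog[lo:hi])))
    positions = [g[p] for p in peak_idx]
    before = [c[valleys[i]] for i in range(len(peak_idx))]
    after = [c[valleys[i + 1]] for i in range(len(peak_idx))]

    # plateau after the last step is the full MFPT (all modes feasible);
    # each earlier plateau drops one more of the slowest modes
    n_steps = len(positions)
    n_modes = spectral.n_modes
    preds = [
        partial_sum_mfpt(spectral, max(n_modes - (n_steps - 1 - i), 1))
        for i in range(n_steps)
    ]
    return StepReport(
        positions=np.array(positions),
        plateaus_before=np.array(before),
        plateaus_after=np.array(after),
        predicted_plateaus=np.array(preds),
        grid=grid,
    )
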