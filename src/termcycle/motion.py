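"""Windowed diffusion estimation and post-termination behavior calls.

Post-termination RNAP position traces are analyzed with the standard
single-trajectory toolkit: the time-averaged mean squared displacement
(MSD) is computed inside sliding 50-s windows, a straight line with
free intercept is fitted to the first ten lag points, and the effective
diffusion coefficient is taken as half the slope (1D convention; the
intercept absorbs static localization error).  A molecule is scored as
sliding when any window reaches D >= 2.2e4 bp^2/s, the saddle point
between the stuck (~0) and sliding (~3.5e4 bp^2/s) modes of the
windowed-D histogram.

Secondary initiation is scored from the intensity record after the
sense transcript is released: a sustained monotone intensity episode is
fitted to the (possibly time-mirrored) elongation decay, and the call
is antisense when the fitted exponential rate falls in
[0.002, 0.04] 1/s with promoter-ward motion, or a sense re-initiation
for the same rate band in the promoter-distal direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationFit, IntensityTrace, TerminationEvent, fit_elongation_decay

__all__ = [
    "DiffusionWindow",
    "BehaviorCall",
    "compute_msd",
    "estimate_D",
    "window_diffusion",
    "classify_sliding",
    "classify_secondary_initiation",
    "SLIDING_D_THRESHOLD",
    "SECONDARY_RATE_BAND",
]

#: bp^2/s; windows at or above this D score as sliding
SLIDING_D_THRESHOLD = 2.2e4

#: 1/s; fitted exponential rates in this closed band qualify as
#: secondary-initiation elongation
SECONDARY_RATE_BAND = (0.002, 0.04)


@dataclass
class DiffusionWindow:
    """MSD curve and linear-fit diffusion coefficient for one window."""

    t_start: float
    t_end: float
    lags: np.ndarray
    msd: np.ndarray
    D: float
    intercept: float
    n_frames: int


@dataclass
class BehaviorCall:
    """Post-termination behavior summary for one molecule."""

    slid: bool = False
    antisense: bool = False
    sense_reinit: bool = False
    rate: float = math.nan  # fitted secondary-initiation rate, 1/s
    episode: tuple[float, float] | None = None
    window_D: list[float] = field(default_factory=list)


def compute_msd(
    time: np.ndarray,
    z: np.ndarray,
    max_lag: float,
    dt: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD of a 1D trajectory at integer multiples of dt.

    Pairs spanning acquisition gaps are honored at their true time
    separation: frames are placed on a regular grid of spacing ``dt``
    (default: the smallest inter-frame interval) and only pairs whose
    grid separation matches each lag contribute.  Frames that do not
    sit on the grid (irregular sampling) are dropped from pairing.

    Parameters
    ----------
    time, z:
        Sample times (s) and positions (bp); NaN positions are ignored.
    max_lag:
        Largest lag in seconds; the segment must span >= 2*max_lag.

    Returns
    -------
    lags, msd : ndarray
        Lag times (s) and the averaged squared displacements (bp^2).
    """
    time = np.asarray(time, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(z) & np.isfinite(time)
    time, z = time[ok], z[ok]
    if time.size < 2:
        raise ValueError("need at least two finite frames")
    span = time[-1] - time[0]
    if span < 2.0 * max_lag:
        raise ValueError(
            f"segment spans {span:.1f}s; >= {2 * max_lag:.1f}s required for max_lag"
        )
    if dt is None:
        dt = float(np.min(np.diff(time)))
    idx = np.rint((time - time[0]) / dt).astype(np.int64)
    on_grid = np.abs((time - time[0]) - idx * dt) < dt * 0.25
    idx, z = idx[on_grid], z[on_grid]

    grid_len = idx[-1] + 1
    zz = np.full(grid_len, np.nan)
    zz[idx] = z
    n_lags = int(max_lag / dt)
    if n_lags < 1:
        raise ValueError("max_lag shorter than frame spacing")
    lags = np.arange(1, n_lags + 1) * dt
    msd = np.full(n_lags, np.nan)
    for k in range(1, n_lags + 1):
        d = zz[k:] - zz[:-k]
        d = d[np.isfinite(d)]
        if d.size:
            msd[k - 1] = np.mean(d * d)
    return lags, msd


def estimate_D(
    lags: np.ndarray, msd: np.ndarray, n_points: int = 10
) -> tuple[float, float]:
    """Diffusion coefficient from a straight-line fit to the MSD.

    Fits ``MSD = 2 D tau + c`` over the first ``n_points`` finite lag
    points with a free intercept ``c`` and returns (D, c).  D may come
    out negative on noisy or stuck segments; callers treat such windows
    as non-sliding.
    """
    lags = np.asarray(lags, dtype=float)
    msd = np.asarray(msd, dtype=float)
    ok = np.isfinite(msd)
    lags, msd = lags[ok], msd[ok]
    if lags.size < n_points:
        raise ValueError(f"need >= {n_points} finite MSD points, got {lags.size}")
    slope, intercept = np.polyfit(lags[:n_points], msd[:n_points], 1)
    return float(slope) / 2.0, float(intercept)


def window_diffusion(
    time: np.ndarray,
    z: np.ndarray,
    window: float = 50.0,
    stride: int = 1,
    n_fit_points: int = 10,
) -> list[DiffusionWindow]:
    """Per-window diffusion coefficients along a position trace.

    Windows of ``window`` seconds advance by ``stride`` frames
    (overlapping by default).  Within each window the MSD is evaluated
    at the first ``n_fit_points`` lags and D taken from the linear fit.
    Windows without enough finite frames are skipped.
    """
    time = np.asarray(time, dtype=float)
    z = np.asarray(z, dtype=float)
    if time.size < 2:
        raise ValueError("trace too short")
    dt = float(np.min(np.diff(time)))
    max_lag = n_fit_points * dt
    out: list[DiffusionWindow] = []
    i = 0
    while i < time.size:
        t0 = time[i]
        t1 = t0 + window
        if t1 > time[-1] + dt / 2:
            break
        sel = (time >= t0) & (time < t1)
        try:
            lags, msd = compute_msd(time[sel], z[sel], max_lag=max_lag, dt=dt)
            D, c = estimate_D(lags, msd, n_points=n_fit_points)
        except ValueError:
            i += stride
            continue
        out.append(
            DiffusionWindow(
                t_start=t0,
                t_end=t1,
                lags=lags,
                msd=msd,
                D=D,
                intercept=c,
                n_frames=int(np.count_nonzero(sel & np.isfinite(z))),
            )
        )
        i += stride
    return out


def histogram_modes(
    D_values: np.ndarray, n_components: int = 2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Mode locations of a (bi)modal windowed-D distribution.

    Single-window D estimates scatter widely (a 50-s window holds few
    independent displacements), so the raw histogram peak of the
    sliding population sits below its center.  Fitting a Gaussian
    mixture and reporting component means gives an unbiased location
    for each mode.  Returns (means, weights) sorted by mean.
    """
    from sklearn.mixture import GaussianMixture

    X = np.asarray(D_values, dtype=float).reshape(-1, 1)
    X = X[np.isfinite(X[:, 0])]
    gm = GaussianMixture(n_components, random_state=seed, n_init=3).fit(X)
    order = np.argsort(gm.means_.ravel())
    return gm.means_.ravel()[order], gm.weights_[order]


def classify_sliding(
    windows: list[DiffusionWindow], threshold: float = SLIDING_D_THRESHOLD
) -> bool:
    """Sliding is scored when any window reaches D >= threshold."""
    if not windows:
        raise ValueError("need at least one diffusion window")
    return bool(max(w.D for w in windows) >= threshold)


def _monotone_episodes(
    time: np.ndarray,
    intensity: np.ndarray,
    smooth_frames: int = 5,
    slack_frames: int = 2,
    trim_tol: float = 0.0,
) -> tuple[list[tuple[int, int, int]], np.ndarray]:
    """Maximal monotone runs (start, end, direction) of a smoothed record.

    Direction is +1 (rising) or -1 (falling).  ``slack_frames``
    consecutive counter-direction steps are tolerated before a run is
    closed, so frame noise does not shatter long episodes.  Each run is
    trimmed to the extremes of the smoothed record so that flat
    plateaus bordering a ramp are not swept into it.  Returns the runs
    and the smoothed record.
    """
    n = intensity.size
    if n < 3:
        return [], intensity
    w = min(smooth_frames, n)
    if w % 2 == 0:
        w -= 1
    kernel = np.ones(w) / w
    padded = np.pad(intensity, w // 2, mode="edge")
    sm = np.convolve(padded, kernel, mode="valid")
    steps = np.sign(np.diff(sm))
    episodes = []
    i = 0
    while i < steps.size:
        if steps[i] == 0:
            i += 1
            continue
        direction = int(steps[i])
        j = i
        bad = 0
        last_good = i
        while j < steps.size:
            if steps[j] == direction or steps[j] == 0:
                bad = 0
                if steps[j] == direction:
                    last_good = j
            else:
                bad += 1
                if bad > slack_frames:
                    break
            j += 1
        lo, hi = i, last_good + 1
        seg = sm[lo : hi + 1]
        mn, mx = float(seg.min()), float(seg.max())
        if direction > 0:
            # first arrival at the top, last departure from the bottom:
            # keeps the ramp, drops noise-level plateaus at either end
            at_top = np.nonzero(seg >= mx - trim_tol)[0]
            j1 = int(at_top[0]) if at_top.size else int(np.argmax(seg))
            at_bot = np.nonzero(seg[: j1 + 1] <= mn + trim_tol)[0]
            j0 = int(at_bot[-1]) if at_bot.size else int(np.argmin(seg[: j1 + 1]))
        else:
            at_bot = np.nonzero(seg <= mn + trim_tol)[0]
            j1 = int(at_bot[0]) if at_bot.size else int(np.argmin(seg))
            at_top = np.nonzero(seg[: j1 + 1] >= mx - trim_tol)[0]
            j0 = int(at_top[-1]) if at_top.size else int(np.argmax(seg[: j1 + 1]))
        if j1 > j0:
            episodes.append((lo + j0, lo + j1, direction))
        i = last_good + 1
    return episodes, sm


def classify_secondary_initiation(
    trace: IntensityTrace,
    fit: CalibrationFit,
    term: TerminationEvent,
    orientation: str = "up",
    rate_band: tuple[float, float] = SECONDARY_RATE_BAND,
    min_duration_frac: float = 0.25,
    min_amplitude_sd: float = 3.0,
    max_resid_ratio: float = 1.7,
) -> BehaviorCall:
    """Score antisense or sense re-initiation after termination.

    Candidate episodes are monotone stretches of the post-termination
    RNAP intensity lasting at least ``min_duration_frac`` of the sense
    elongation duration with amplitude >= ``min_amplitude_sd`` times
    the calibration residual SD (the reproducible surrogate for a
    "visible elongation profile").  The earliest qualifying episode is
    fitted to the elongation decay -- time-mirrored for promoter-ward
    motion -- and sets the call when its rate falls inside
    ``rate_band`` (closed interval) and the episode actually follows
    the exponential profile: its fit residual SD must stay below
    ``max_resid_ratio`` times the calibration residual SD, which
    separates true re-initiation ramps from diffusive sliding
    excursions that happen to trend monotonically.  Promoter-ward
    motion raises intensity on "up" templates and lowers it on "down"
    templates.

    Returns a no-call :class:`BehaviorCall` when there are no
    post-termination frames.
    """
    sel = trace.time > term.t_T
    if trace.rnap_present is not None:
        sel &= trace.rnap_present
    if term.rnap_departure_time is not None:
        sel &= trace.time < term.rnap_departure_time
    if not np.any(sel):
        return BehaviorCall()
    t = trace.time[sel]
    I = trace.I_rnap[sel]
    sense_duration = term.t_T - fit.window[0]
    min_duration = min_duration_frac * sense_duration
    min_amp = min_amplitude_sd * max(fit.resid_sd, 1e-12)
    promoterward_sign = +1 if orientation == "up" else -1

    episodes, _ = _monotone_episodes(t, I, trim_tol=fit.resid_sd)
    for i0, i1, direction in episodes:
        if t[i1] - t[i0] < min_duration:
            continue
        if abs(I[i1] - I[i0]) < min_amp:
            continue
        seg_t, seg_I = t[i0 : i1 + 1], I[i0 : i1 + 1]
        if seg_t.size < 10:
            continue
        if direction == promoterward_sign:
            # promoter-ward: mirror time so the rise becomes a decay
            sub = IntensityTrace(
                time=seg_t[-1] - seg_t[::-1],
                I_dna=np.zeros_like(seg_t),
                I_rnap=seg_I[::-1],
                I_probe=np.zeros_like(seg_t),
            )
        else:
            sub = IntensityTrace(
                time=seg_t - seg_t[0],
                I_dna=np.zeros_like(seg_t),
                I_rnap=seg_I,
                I_probe=np.zeros_like(seg_t),
            )
        try:
            epi_fit = fit_elongation_decay(sub, (0.0, float(sub.time[-1])))
        except ValueError:
            continue
        if not epi_fit.converged:
            continue
        # fit-quality gate: tolerate the calibration noise level, or a
        # small fraction of the episode amplitude when noise is tiny
        # (ramp ends are quantized to frames, leaving O(1-frame) misfit)
        resid_allow = max(max_resid_ratio * fit.resid_sd, 0.025 * abs(I[i1] - I[i0]))
        if epi_fit.resid_sd > resid_allow:
            continue
        rate = epi_fit.lam
        if rate_band[0] <= rate <= rate_band[1]:
            call = BehaviorCall(rate=rate, episode=(float(t[i0]), float(t[i1])))
            if direction == promoterward_sign:
                call.antisense = True
            else:
                call.sense_reinit = True
            return call
    return BehaviorCall()
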