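"""Intensity-decay calibration and intensity-to-position conversion.

In a TIRF geometry the evanescent excitation decays with distance from
the coverslip, so the fluorescence emitted by a labeled RNAP tethered on
a surface-anchored DNA reports its distance from the surface.  During
steady-state elongation at a constant rate the RNAP intensity record
follows a single exponential,

    I(t) = I_P * exp(-lambda * t) + I_mn,

where ``I_P`` is the intensity of the promoter-bound polymerase, ``I_mn``
the mean background level, and ``lambda`` the decay constant of that
particular molecule.  Combining the exponential with a constant
elongation rate z(t) = r_RNAP * t + z_P, and anchoring the curve at the
known promoter and terminator positions (z_P, z_T), gives a per-molecule
calibration that converts any post-termination intensity I into a
position along the DNA contour:

    r_RNAP = (z_T - z_P) / ( (1/lambda) * ln(I_P / (I_T - I_mn)) )
    z(I)   = (r_RNAP/lambda) * ln(I_P / (I - I_mn)) + z_P

``I_T`` is the intensity at the moment of transcript release.  For DNA
tethered by its downstream end ("down" orientation) the map is mirrored
about the transcription unit: elongation raises intensity, and position
is recovered by sign-flipping the calibrated axis.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityTrace",
    "TerminationEvent",
    "CalibrationFit",
    "PositionTrace",
    "fit_elongation_decay",
    "compute_elongation_rate",
    "intensity_to_position",
    "position_to_intensity",
]


@dataclass
class IntensityTrace:
    """Per-frame, three-channel fluorescence record at one DNA spot.

    Times are in seconds and strictly increasing; gaps (skipped frames)
    are allowed and recorded via :attr:`max_gap`.
    """

    time: np.ndarray
    I_dna: np.ndarray
    I_rnap: np.ndarray
    I_probe: np.ndarray
    rnap_present: np.ndarray | None = None
    probe_present: np.ndarray | None = None
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.I_dna = np.asarray(self.I_dna, dtype=float)
        self.I_rnap = np.asarray(self.I_rnap, dtype=float)
        self.I_probe = np.asarray(self.I_probe, dtype=float)
        n = self.time.size
        for name in ("I_dna", "I_rnap", "I_probe"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length != time length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        for name in ("rnap_present", "probe_present"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=bool)
                if v.size != n:
                    raise ValueError(f"{name} length != time length")
                setattr(self, name, v)

    def __len__(self) -> int:
        return self.time.size

    @property
    def max_gap(self) -> float:
        """Largest inter-frame interval in seconds (0 for <2 frames)."""
        if len(self) < 2:
            return 0.0
        return float(np.max(np.diff(self.time)))


@dataclass
class TerminationEvent:
    """Transcript-probe departure (termination) bookkeeping.

    ``rnap_departure_time`` is ``None`` when the RNAP spot outlived the
    recording (right-censored).
    """

    t_T: float
    I_T: float
    rnap_departure_time: float | None = None

    @property
    def rnap_censored(self) -> bool:
        return self.rnap_departure_time is None


@dataclass
class CalibrationFit:
    """Least-squares parameters of the elongation intensity decay."""

    I_P: float
    I_mn: float
    lam: float
    window: tuple[float, float]
    resid_sd: float
    converged: bool
    n_frames: int
    orientation: str = "up"

    def intensity_at(self, t_rel: float | np.ndarray) -> np.ndarray:
        """Model intensity at time ``t_rel`` past the window start."""
        return self.I_P * np.exp(-self.lam * np.asarray(t_rel, float)) + self.I_mn


@dataclass
class PositionTrace:
    """RNAP position along the DNA contour, in bp, per retained frame."""

    time: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    z_P: float
    z_T: float
    r_RNAP: float
    orientation: str = "up"
    template_length: float | None = None
    out_of_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.out_of_bounds is None:
            if self.template_length is not None:
                self.out_of_bounds = self.valid & (
                    (self.z < 0) | (self.z > self.template_length)
                )
            else:
                self.out_of_bounds = np.zeros_like(self.valid)


def _decay(t, I_P, lam, I_mn):
    return I_P * np.exp(-lam * t) + I_mn


def fit_elongation_decay(
    trace: IntensityTrace,
    window: tuple[float, float],
    orientation: str = "up",
    baseline: float | None = None,
) -> CalibrationFit:
    """Fit ``I(t) = I_P exp(-lambda t) + I_mn`` over an elongation window.

    The time origin is the window start.  For ``orientation="down"``
    (DNA tethered by its downstream end, intensity rising during
    elongation) the window is fitted in reversed time, which makes the
    recovered (I_P, I_mn, lambda) those of the mirrored map.

    Parameters
    ----------
    trace:
        The three-channel record; the RNAP channel is fitted.
    window:
        (t_start, t_end) in seconds, inclusive; must contain >= 10 frames.
    baseline:
        Optional externally measured background used only to seed the
        optimizer (e.g. the median pre-initiation level).

    Raises
    ------
    ValueError
        If fewer than 10 frames fall inside the window.
    """
    if orientation not in ("up", "down"):
        raise ValueError(f"unknown orientation {orientation!r}")
    t0, t1 = float(window[0]), float(window[1])
    sel = (trace.time >= t0) & (trace.time <= t1)
    if trace.rnap_present is not None:
        sel &= trace.rnap_present
    n = int(np.count_nonzero(sel))
    if n < 10:
        raise ValueError(f"elongation window holds {n} frames; >= 10 required")
    t = trace.time[sel]
    I = trace.I_rnap[sel]
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(I))):
        raise ValueError("non-finite values in elongation window")
    if orientation == "down":
        # mirrored map: a rising profile is a decay in reversed time
        t_rel = t1 - t[::-1]
        I = I[::-1]
    else:
        t_rel = t - t0

    # derivative-free starting point: baseline from the dimmest frames,
    # amplitude from the first five frames, rate from a log-linear slope
    I_mn0 = float(baseline) if baseline is not None else float(np.min(I)) * 0.9
    I_P0 = max(float(np.mean(I[:5])) - I_mn0, 1e-6)
    resid = np.clip(I - I_mn0, 1e-9, None)
    slope = np.polyfit(t_rel, np.log(resid), 1)[0]
    lam0 = max(-slope, 1e-5)

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _decay, t_rel, I, p0=[I_P0, lam0, I_mn0], maxfev=20000
            )
        I_P, lam, I_mn = (float(v) for v in popt)
        if not np.all(np.isfinite(popt)) or I_P <= 0 or lam <= 0:
            converged = False
    except RuntimeError:
        I_P, lam, I_mn = I_P0, lam0, I_mn0
        converged = False
    resid_sd = float(np.std(I - _decay(t_rel, I_P, lam, I_mn)))
    return CalibrationFit(
        I_P=I_P,
        I_mn=I_mn,
        lam=lam,
        window=(t0, t1),
        resid_sd=resid_sd,
        converged=converged,
        n_frames=n,
        orientation=orientation,
    )


def bootstrap_fit_ci(
    trace: IntensityTrace,
    window: tuple[float, float],
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
    orientation: str = "up",
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap CIs for the decay-fit parameters.

    Refits the model on the fitted curve plus resampled residuals and
    returns percentile intervals for I_P, I_mn and lambda.
    """
    fit = fit_elongation_decay(trace, window, orientation=orientation)
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    t0, t1 = fit.window
    sel = (trace.time >= t0) & (trace.time <= t1)
    t = trace.time[sel]
    I = trace.I_rnap[sel]
    t_rel = (t1 - t[::-1]) if orientation == "down" else (t - t0)
    I_obs = I[::-1] if orientation == "down" else I
    model = _decay(t_rel, fit.I_P, fit.lam, fit.I_mn)
    resid = I_obs - model
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {"I_P": [], "I_mn": [], "lam": []}
    for _ in range(n_boot):
        I_star = model + rng.choice(resid, resid.size, replace=True)
        boot_trace = IntensityTrace(
            time=t_rel,
            I_dna=np.zeros_like(t_rel),
            I_rnap=I_star,
            I_probe=np.zeros_like(t_rel),
        )
        bfit = fit_elongation_decay(boot_trace, (0.0, float(t_rel[-1])))
        if not bfit.converged:
            continue
        samples["I_P"].append(bfit.I_P)
        samples["I_mn"].append(bfit.I_mn)
        samples["lam"].append(bfit.lam)
    alpha = 100 * (1 - level) / 2
    return {
        k: tuple(np.percentile(v, [alpha, 100 - alpha])) for k, v in samples.items()
    }


def compute_elongation_rate(
    fit: CalibrationFit,
    term: TerminationEvent,
    z_P: float,
    z_T: float,
) -> float:
    """Elongation rate from the calibration and the termination intensity.

    r_RNAP = (z_T - z_P) / ((1/lambda) ln(I_P / (I_T - I_mn))).

    Returns ``math.inf`` (flagged unphysical via a logged warning) when
    the termination intensity is at or above the promoter-proximal level
    I_P + I_mn, where the logarithm vanishes or changes sign.

    Raises
    ------
    ValueError
        If the fit did not converge, z_T <= z_P, or I_T is at/below the
        background level I_mn (undefined logarithm).
    """
    if not fit.converged:
        raise ValueError("refusing to use a non-converged calibration fit")
    if z_T <= z_P:
        raise ValueError("z_T must exceed z_P")
    excess = term.I_T - fit.I_mn
    if excess <= 0:
        raise ValueError("termination intensity at/below background")
    log_term = math.log(fit.I_P / excess)
    if log_term <= 0:
        logger.warning(
            "termination intensity >= promoter-proximal level; "
            "elongation rate unphysical (infinite)"
        )
        return math.inf
    return (z_T - z_P) / (log_term / fit.lam)


def intensity_to_position(
    fit: CalibrationFit,
    r_RNAP: float,
    time: np.ndarray,
    intensity: np.ndarray,
    z_P: float,
    z_T: float | None = None,
    template_length: float | None = None,
) -> PositionTrace:
    """Convert an intensity segment to position along the DNA contour.

    z(I) = (r_RNAP/lambda) ln(I_P / (I - I_mn)) + z_P for the "up"
    orientation.  Frames with I <= I_mn are masked, never extrapolated;
    a warning is logged when more than half the frames are masked.  For
    the "down" orientation the axis is sign-flipped about (z_P, z_T),
    which requires ``z_T``.
    """
    time = np.asarray(time, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if fit.orientation == "down" and z_T is None:
        raise ValueError("down-orientation conversion requires z_T")
    valid = intensity > fit.I_mn
    z = np.full(intensity.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z[valid] = (r_RNAP / fit.lam) * np.log(
            fit.I_P / (intensity[valid] - fit.I_mn)
        ) + z_P
    if fit.orientation == "down":
        z[valid] = z_P + z_T - z[valid]
    frac_masked = 1.0 - np.count_nonzero(valid) / max(len(valid), 1)
    if frac_masked > 0.5:
        logger.warning("%.0f%% of frames at/below background; masked", 100 * frac_masked)
    return PositionTrace(
        time=time,
        z=z,
        valid=valid,
        z_P=z_P,
        z_T=z_T if z_T is not None else np.nan,
        r_RNAP=r_RNAP,
        orientation=fit.orientation,
        template_length=template_length,
    )


def position_to_intensity(
    fit: CalibrationFit,
    r_RNAP: float,
    z: np.ndarray,
    z_P: float,
    z_T: float | None = None,
) -> np.ndarray:
    """Inverse of :func:`intensity_to_position` (noiseless model map)."""
    z = np.asarray(z, dtype=float)
    if fit.orientation == "down":
        if z_T is None:
            raise ValueError("down-orientation map requires z_T")
        z = z_P + z_T - z
    return fit.I_P * np.exp(-(fit.lam / r_RNAP) * (z - z_P)) + fit.I_mn
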