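"""Beat-level processing of sampled right-heart pressure/flow signals.

Right-ventricular (RV) and pulmonary-arterial (PA) signals arrive as
uniformly sampled traces (clinical catheter recordings at 1 kHz, animal
recordings at 250 Hz).  This module segments the RV pressure signal into
beats, locates the ejection window of each beat from the smoothed first
derivative of RV pressure — ejection onset at the derivative maximum,
end-systole at the derivative trough — ensemble-averages consecutive
beats, and extracts the mean RV ejection pressure used by the energetic
model.

The derivative-based detection is invariant to a constant pressure
offset, which makes it robust to transducer zero drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import argrelextrema, savgol_filter

from .errors import InsufficientDataError, InvalidArgumentError, InvalidInputError

__all__ = [
    "PressureTrace",
    "BeatWindow",
    "segment_beats",
    "ensemble_average",
    "mean_ejection_pressure",
]

#: recognised channel labels
CHANNELS = ("RV_pressure", "PA_pressure", "PA_flow")

#: default width of the derivative smoothing window (seconds)
DEFAULT_SMOOTH_S = 0.015


@dataclass(frozen=True)
class PressureTrace:
    """A uniformly sampled pressure (mmHg) or flow (ml/min) signal.

    Parameters
    ----------
    samples:
        Signal values; pressures in mmHg, flows in ml/min.
    rate:
        Sampling rate in Hz (must be positive).
    channel:
        One of ``RV_pressure``, ``PA_pressure``, ``PA_flow``.
    t0:
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    channel: str = "RV_pressure"
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise InvalidInputError("trace needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("trace contains non-finite samples")
        if self.channel not in CHANNELS:
            raise InvalidArgumentError(
                f"channel must be one of {CHANNELS}, got {self.channel!r}"
            )

    @property
    def dt(self) -> float:
        """Sample spacing in seconds."""
        return 1.0 / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) * self.dt

    def value_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of the trace at time(s) ``t``."""
        return np.interp(t, self.times, self.samples)


@dataclass(frozen=True)
class BeatWindow:
    """Timing of one cardiac cycle.

    ``t_start`` is ejection onset, ``t_es`` end of RV ejection and
    ``t_ed`` the end of the cycle (next beat's onset).  The ejection
    period is ``T = t_es - t_start``.
    """

    t_start: float
    t_es: float
    t_ed: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_es < self.t_ed):
            raise InvalidArgumentError(
                f"require t_start < t_es < t_ed, got "
                f"({self.t_start}, {self.t_es}, {self.t_ed})"
            )

    @property
    def ejection_period(self) -> float:
        """Duration of ejection ``T`` in seconds."""
        return self.t_es - self.t_start

    @property
    def cycle_length(self) -> float:
        return self.t_ed - self.t_start


def _smoothed_derivative(trace: PressureTrace, smooth_s: float) -> np.ndarray:
    """First derivative of the trace, smoothed with an odd-length
    Savitzky-Golay window of roughly ``smooth_s`` seconds."""
    win = max(5, int(round(smooth_s * trace.rate)) | 1)  # odd, >= 5
    win = min(win, trace.samples.size - (trace.samples.size + 1) % 2)
    if win < 5:
        raise InsufficientDataError("trace too short to smooth")
    return savgol_filter(
        trace.samples, window_length=win, polyorder=3, deriv=1, delta=trace.dt
    )


def segment_beats(
    rv: PressureTrace,
    *,
    smooth_s: float = DEFAULT_SMOOTH_S,
    min_beats: int = 5,
) -> list[BeatWindow]:
    """Segment an RV pressure trace into beats and locate ejection windows.

    Ejection onset of each beat is placed at a local maximum of the
    smoothed first derivative of RV pressure (steepest upstroke);
    end-systole at the following local minimum (trough) of the
    derivative.  Cycle boundaries run onset-to-onset, so the last
    detected upstroke only closes the previous cycle.

    Parameters
    ----------
    rv:
        RV pressure trace covering at least ``min_beats`` full cycles.
    smooth_s:
        Width of the derivative smoothing window in seconds.
    min_beats:
        Minimum number of complete cycles required (default 5, the
        ensemble-averaging depth used downstream).

    Returns
    -------
    list of :class:`BeatWindow`, one per complete detected cycle.
    """
    if rv.channel != "RV_pressure":
        raise InvalidArgumentError("segment_beats expects an RV pressure trace")
    deriv = _smoothed_derivative(rv, smooth_s)

    # Candidate onsets: prominent local maxima of dP/dt.  A relative
    # threshold at half the global maximum rejects diastolic ripple.
    if np.ptp(rv.samples) <= 0 or deriv.max() <= 0:
        raise InsufficientDataError("no cycles detectable (flat signal)")
    thresh = 0.5 * deriv.max()
    maxima = argrelextrema(deriv, np.greater_equal, order=2)[0]
    maxima = maxima[deriv[maxima] >= thresh]
    # collapse plateaus / near-duplicates closer than 100 ms
    if maxima.size:
        keep = [maxima[0]]
        for i in maxima[1:]:
            if (i - keep[-1]) * rv.dt > 0.1:
                keep.append(i)
            elif deriv[i] > deriv[keep[-1]]:
                keep[-1] = i
        maxima = np.asarray(keep)

    windows: list[BeatWindow] = []
    times = rv.times
    for a, b in zip(maxima[:-1], maxima[1:]):
        seg = deriv[a:b]
        trough = a + int(np.argmin(seg))
        if trough <= a or trough >= b:
            continue
        windows.append(
            BeatWindow(t_start=times[a], t_es=times[trough], t_ed=times[b])
        )
    if len(windows) < min_beats:
        raise InsufficientDataError(
            f"detected {len(windows)} complete cycles, need >= {min_beats}"
        )
    return windows


def ensemble_average(
    trace: PressureTrace,
    windows: Sequence[BeatWindow],
    n_beats: int = 5,
    *,
    start: int = 0,
) -> PressureTrace:
    """Pointwise average of ``n_beats`` consecutive beats of a trace.

    Each beat (``t_start`` to ``t_ed``) is linearly resampled onto the
    time grid of the shortest of the selected beats, then averaged
    pointwise.  The returned trace starts at t0 = 0.

    Parameters
    ----------
    trace:
        Any channel sharing the time base of the segmented RV trace.
    windows:
        Beat windows from :func:`segment_beats`.
    n_beats:
        Number of beats to average (default 5).
    start:
        Index of the first beat to use (default 0, the first complete
        beat).
    """
    if n_beats < 1:
        raise InvalidArgumentError("n_beats must be >= 1")
    if start < 0 or start + n_beats > len(windows):
        raise InvalidArgumentError(
            f"requested beats [{start}, {start + n_beats}) but only "
            f"{len(windows)} windows available"
        )
    sel = list(windows[start : start + n_beats])
    t_min = min(w.cycle_length for w in sel)
    n = max(2, int(np.floor(t_min * trace.rate)) + 1)
    grid = np.linspace(0.0, t_min, n)
    beats = np.stack([trace.value_at(w.t_start + grid) for w in sel])
    return PressureTrace(
        samples=beats.mean(axis=0),
        rate=(n - 1) / t_min,
        channel=trace.channel,
        t0=0.0,
    )


def mean_ejection_pressure(rv: PressureTrace, window: BeatWindow) -> float:
    """Mean RV pressure over the ejection window ``[t_start, t_es]``.

    This is the mRV_EP entering the isovolumic-power terms of the
    energetic model.  Computed as the time-average (trapezoidal) of the
    interpolated pressure over the window, which for uniformly sampled
    data coincides with the arithmetic mean of the in-window samples up
    to end effects.
    """
    if not (rv.t0 <= window.t_start and window.t_es <= rv.t0 + rv.duration):
        raise InvalidArgumentError("window extends beyond trace extent")
    T = window.ejection_period
    if T <= 0:
        raise InvalidArgumentError("empty ejection window")
    n = max(2, int(np.ceil(T * rv.rate)) + 1)
    t = np.linspace(window.t_start, window.t_es, n)
    p = rv.value_at(t)
    return float(np.trapezoid(p, t) / T)
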