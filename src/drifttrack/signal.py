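"""Velocity estimation, breathing-peak detection, and baseline computation.

The baseline of a respiratory signal is defined as the median position of its
end-exhale peaks over a window: the end-exhale position is the most
reproducible point of the breathing cycle, so its peak median is a robust
reference level that ignores cycle-to-cycle amplitude variation.

On the abdominal AP surrogate, end-exhale corresponds to the *minima*
(the abdomen is most posterior at exhale, and AP is positive-anterior);
end-inhale to the maxima. For internal traces the phase of each peak can be
copied from the nearest external peak, falling back to extremum type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, peak_prominences

from .exceptions import EstimationError, ValidationError
from .trace_io import Trace

END_INHALE = "end_inhale"
END_EXHALE = "end_exhale"

#: Default smoothing window (samples): ~83 ms at the 60 Hz IR rate, enough to
#: suppress measurement noise without attenuating breathing-band motion.
DEFAULT_SMOOTH_WIN = 5
#: Minimum peak separation as a fraction of the estimated breathing period.
DEFAULT_MIN_SEP_FRAC = 0.4
#: Minimum peak prominence as a fraction of the median breathing amplitude.
DEFAULT_PROMINENCE_FRAC = 0.2


@dataclass
class PeakSet:
    """Detected respiratory extrema with end-inhale / end-exhale labels."""

    times: np.ndarray
    values: np.ndarray
    phases: np.ndarray  # per-peak, END_INHALE or END_EXHALE
    source_axis: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.phases = np.asarray(self.phases, dtype=object)
        if not (len(self.times) == len(self.values) == len(self.phases)):
            raise ValidationError("times, values, phases must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("peak times must be strictly increasing")

    @property
    def empty(self) -> bool:
        return len(self.times) == 0

    def select(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        """Times and values of the peaks labelled with ``phase``."""
        m = self.phases == phase
        return self.times[m], self.values[m]

    def count(self, phase: str) -> int:
        return int(np.sum(self.phases == phase))


def smooth(y: np.ndarray, smooth_win: int) -> np.ndarray:
    """Centred moving average with nearest-edge padding."""
    if smooth_win < 1 or smooth_win % 2 == 0:
        raise ValidationError("smooth_win must be odd and >= 1")
    if smooth_win == 1:
        return np.asarray(y, dtype=float)
    return uniform_filter1d(np.asarray(y, dtype=float), smooth_win, mode="nearest")


def estimate_velocity(trace: Trace, smooth_win: int = DEFAULT_SMOOTH_WIN) -> Trace:
    """Velocity (mm/s) of a trace: moving-average smoothing + finite differences.

    Central differences at interior points, one-sided at the endpoints, on the
    same time grid as the input. Exact for linear signals at interior points.
    """
    if len(trace.t) <= smooth_win:
        raise ValidationError(
            f"trace ({len(trace.t)} samples) shorter than smooth_win={smooth_win}"
        )
    ys = smooth(trace.y, smooth_win)
    v = np.gradient(ys, trace.t)
    return Trace(trace.t, v, trace.axis, trace.rate_hz)


def estimate_period(
    t: np.ndarray,
    y: np.ndarray,
    min_period_s: float = 1.5,
    max_period_s: float = 12.0,
) -> float:
    """Breathing period from the autocorrelation of the detrended signal.

    A linear trend (baseline drift) is removed first; the period is the lag of
    the highest autocorrelation peak between ``min_period_s`` and the smaller
    of ``max_period_s`` and half the record length.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    dt = float(np.median(np.diff(t)))
    span = t[-1] - t[0]
    hi_s = min(max_period_s, span / 2.0)
    lo = max(2, int(round(min_period_s / dt)))
    hi = int(round(hi_s / dt))
    if hi <= lo:
        raise EstimationError(
            f"record of {span:.1f}s too short to estimate a period >= {min_period_s}s"
        )
    y0 = y - np.polyval(np.polyfit(t, y, 1), t)
    ac = np.correlate(y0, y0, mode="full")[len(y0) - 1 :]
    k = int(np.argmax(ac[lo : hi + 1])) + lo
    # refine to the local maximum around the coarse argmax
    while 0 < k < len(ac) - 1 and ac[k + 1] > ac[k]:
        k += 1
    while 0 < k < len(ac) - 1 and ac[k - 1] > ac[k]:
        k -= 1
    return k * dt


def detect_peaks(
    trace: Trace,
    window: tuple[float, float] | None = None,
    *,
    min_sep_frac: float = DEFAULT_MIN_SEP_FRAC,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth_win: int = DEFAULT_SMOOTH_WIN,
    period_s: float | None = None,
    phase_reference: PeakSet | None = None,
) -> PeakSet:
    """Detect end-inhale / end-exhale peaks of a respiratory trace.

    Local maxima and minima of the moving-average-smoothed trace, subject to a
    minimum separation of ``min_sep_frac`` times the breathing period
    (estimated by autocorrelation unless ``period_s`` is given) and a
    prominence of at least ``prominence_frac`` times the peak-to-peak
    breathing amplitude (the 2.5-97.5 percentile spread of the smoothed
    window). Reported values are the raw (unsmoothed) positions at the
    detected sample.

    Phase labels: maxima are end-inhale and minima end-exhale (the AP
    surrogate convention, positive anterior). If ``phase_reference`` is given
    (e.g. external-marker peaks when labelling an internal trace), each peak
    instead inherits the phase of the nearest reference peak in time.

    Returns an empty PeakSet when nothing qualifies; callers decide whether
    that is an error.
    """
    tr = trace.slice(window) if window is not None else trace
    ys = smooth(tr.y, smooth_win)
    dt = float(np.median(np.diff(tr.t)))
    if period_s is None:
        period_s = estimate_period(tr.t, tr.y)
    distance = max(1, int(round(min_sep_frac * period_s / dt)))

    imax, _ = find_peaks(ys, distance=distance)
    imin, _ = find_peaks(-ys, distance=distance)
    if len(imax) == 0 and len(imin) == 0:
        return PeakSet(np.array([]), np.array([]), np.array([], dtype=object), tr.axis)

    # Peak-to-peak breathing amplitude, estimated from the percentile spread
    # of the smoothed window so that noise wiggles in the end-exhale dwell
    # (or on the flat inhale top) cannot drag the estimate down.
    amplitude = float(np.percentile(ys, 97.5) - np.percentile(ys, 2.5))
    threshold = prominence_frac * max(amplitude, 0.0)
    if threshold > 0:
        if len(imax):
            imax = imax[peak_prominences(ys, imax)[0] >= threshold]
        if len(imin):
            imin = imin[peak_prominences(-ys, imin)[0] >= threshold]

    idx = np.concatenate([imax, imin]).astype(int)
    kinds = np.concatenate(
        [np.full(len(imax), END_INHALE, object), np.full(len(imin), END_EXHALE, object)]
    )
    order = np.argsort(idx)
    idx, kinds = idx[order], kinds[order]
    times = tr.t[idx]
    values = tr.y[idx]

    if phase_reference is not None and not phase_reference.empty and len(times):
        ref_t = phase_reference.times
        nearest = np.abs(times[:, None] - ref_t[None, :]).argmin(axis=1)
        kinds = phase_reference.phases[nearest]

    return PeakSet(times, values, kinds, tr.axis)


def compute_baseline(peaks: PeakSet) -> float:
    """Baseline of a signal: the median of its end-exhale peak positions."""
    _, values = peaks.select(END_EXHALE)
    if len(values) == 0:
        raise EstimationError(f"no end-exhale peaks on axis {peaks.source_axis}")
    return float(np.median(values))
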