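"""The two-stage baseline-drift correction pipeline.

Stage 1 (external): the external baseline drift BDIR is, per marker, the
difference between the end-exhale peak-median baselines of the nth-session
training window and the first modeling window. The fitted model F1st is
translated along its abscissa: F'(x, v) = F1st(x - BDIR, v).

Stage 2 (internal): the residual internal drift is estimated from the
target's own end-inhale and end-exhale peaks in a short window just before
delivery: ER_in and ER_ex are the mean residuals at the two phases, and
BDdetect = (ER_in + ER_ex) / 2 is subtracted from the intercept. The fully
corrected model is

    Fcor(x, v) = F1st(x - BDIR, v) - BDdetect.

Sign convention: the peak residuals are measured as *prediction minus
detection*, so that subtracting BDdetect moves the predictions toward the
drifted detections — if the internal baseline drifted by +delta,
BDdetect = -delta and Fcor = F' + delta. (Measuring the residual the other
way round and still subtracting would double the error instead of
cancelling it.)

Peak phases sampled at the two extremes of the cycle keep the intercept
estimate insensitive to phase/hysteresis errors, and averaging the two
phases cancels residual amplitude mismatch to first order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import DriftRateWarning, EstimationError
from .model4d import Model4D, apply_bddetect, fit_model, predict, shift_model
from .signal import (
    DEFAULT_MIN_SEP_FRAC,
    DEFAULT_PROMINENCE_FRAC,
    DEFAULT_SMOOTH_WIN,
    END_EXHALE,
    END_INHALE,
    compute_baseline,
    detect_peaks,
    estimate_period,
)
from .trace_io import AXES, N_IR_MARKERS, Session, Trace, in_window

#: Smoothing window (samples) for peak detection on kV-rate internal traces:
#: ~0.56 s at 12.5 Hz, chosen to suppress cardiac-frequency jitter (~1.2 Hz)
#: without blunting the breathing extrema.
DEFAULT_INT_SMOOTH_WIN = 7


@dataclass
class PipelineConfig:
    """Tunable parameters of the correction pipeline."""

    smooth_win: int = DEFAULT_SMOOTH_WIN  # velocity/peak smoothing, IR rate
    int_smooth_win: int = DEFAULT_INT_SMOOTH_WIN  # peak smoothing, kV rate
    min_sep_frac: float = DEFAULT_MIN_SEP_FRAC
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC
    bdir_pooled: bool = False  # pool BDIR across markers (median) if True
    #: Warn when the residual trend in the intercept-training window exceeds
    #: this over 30 s — the baseline is still moving and the correction may
    #: not hold through delivery. Advisory only; nothing is auto-modified.
    drift_warn_mm_per_30s: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class DriftEstimate:
    """Estimated baseline drifts and the residuals they were derived from.

    Invariant: ``bddetect_mm[ax] == (er_in_mm[ax] + er_ex_mm[ax]) / 2``
    exactly, by construction.
    """

    bdir_mm: np.ndarray  # per marker, AP mm, positive anterior
    er_in_mm: dict[str, float]
    er_ex_mm: dict[str, float]
    bddetect_mm: dict[str, float]
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    peak_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bdir_mm": list(np.asarray(self.bdir_mm, dtype=float)),
            "er_in_mm": dict(sorted(self.er_in_mm.items())),
            "er_ex_mm": dict(sorted(self.er_ex_mm.items())),
            "bddetect_mm": dict(sorted(self.bddetect_mm.items())),
            "windows": {k: list(v) for k, v in sorted(self.windows.items())},
            "peak_counts": self.peak_counts,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def compute_bdir(
    session_first: Session,
    session_nth: Session,
    first_window: tuple[float, float] | None = None,
    bdir_window: tuple[float, float] | None = None,
    *,
    pooled: bool = False,
    smooth_win: int = DEFAULT_SMOOTH_WIN,
    min_sep_frac: float = DEFAULT_MIN_SEP_FRAC,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> np.ndarray:
    """External baseline drift per marker (mm, positive anterior).

    For each marker: the end-exhale peak-median baseline over the nth
    session's BDIR training window minus the same baseline over the first
    modeling window. With ``pooled=True`` the across-marker median replaces
    the per-marker values.
    """
    if first_window is None:
        first_window = session_first.windows["model_training"]
    if bdir_window is None:
        bdir_window = session_nth.windows["bdir_training"]
    out = np.empty(N_IR_MARKERS)
    for k in range(N_IR_MARKERS):
        baselines = []
        for sess, win, label in (
            (session_first, first_window, "first modeling window"),
            (session_nth, bdir_window, "BDIR training window"),
        ):
            peaks = detect_peaks(
                sess.ir[k], win,
                min_sep_frac=min_sep_frac, prominence_frac=prominence_frac,
                smooth_win=smooth_win,
            )
            if peaks.count(END_EXHALE) == 0:
                raise EstimationError(f"marker {k + 1}: no end-exhale peaks in the {label}")
            baselines.append(compute_baseline(peaks))
        out[k] = baselines[1] - baselines[0]
    if pooled:
        out[:] = np.median(out)
    return out


def compute_bddetect(
    session_nth: Session,
    model_shifted: Model4D,
    window: tuple[float, float] | None = None,
    *,
    int_smooth_win: int = DEFAULT_INT_SMOOTH_WIN,
    smooth_win: int = DEFAULT_SMOOTH_WIN,
    min_sep_frac: float = DEFAULT_MIN_SEP_FRAC,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> DriftEstimate:
    """Residual internal drift per axis from peak-time residuals.

    For each axis: detect the target's end-inhale and end-exhale peaks inside
    the training window (phases inherited from the nearest external-marker
    peak), evaluate the BDIR-shifted model at those timestamps, and average
    the mean prediction-minus-detection residual at the two phases; the
    result is *minus* the internal baseline drift and is subtracted from the
    model intercept by :func:`correct_model`. A phase with zero peaks raises
    :class:`EstimationError` — there is no silent single-phase fallback.
    """
    if window is None:
        window = session_nth.windows["bddetect_training"]

    mean_ir = Trace(
        session_nth.ir[0].t,
        np.mean([tr.y for tr in session_nth.ir], axis=0),
        "AP",
        session_nth.ir_rate_hz,
    )
    m = in_window(mean_ir.t, window)
    period = estimate_period(mean_ir.t[m], mean_ir.y[m])
    ext_peaks = detect_peaks(
        mean_ir, window,
        min_sep_frac=min_sep_frac, prominence_frac=prominence_frac,
        smooth_win=smooth_win, period_s=period,
    )

    er_in, er_ex, bdd, counts = {}, {}, {}, {}
    for ax in AXES:
        peaks = detect_peaks(
            session_nth.target[ax], window,
            min_sep_frac=min_sep_frac, prominence_frac=prominence_frac,
            smooth_win=int_smooth_win, period_s=period,
            phase_reference=ext_peaks if not ext_peaks.empty else None,
        )
        counts[ax] = {END_INHALE: peaks.count(END_INHALE), END_EXHALE: peaks.count(END_EXHALE)}
        ers = {}
        for phase in (END_INHALE, END_EXHALE):
            t_p, y_p = peaks.select(phase)
            if len(t_p) == 0:
                raise EstimationError(
                    f"axis {ax}: no {phase} peaks in the BDdetect training window {window}"
                )
            ers[phase] = float(np.mean(predict(model_shifted, session_nth, t_p, ax) - y_p))
        er_in[ax], er_ex[ax] = ers[END_INHALE], ers[END_EXHALE]
        bdd[ax] = (er_in[ax] + er_ex[ax]) / 2.0

    return DriftEstimate(
        bdir_mm=model_shifted.bdir_mm.copy(),
        er_in_mm=er_in, er_ex_mm=er_ex, bddetect_mm=bdd,
        windows={"bddetect_training": tuple(window)},
        peak_counts=counts,
    )


def correct_model(
    f1st: Model4D,
    bdir: float | np.ndarray,
    bddetect: float | dict[str, float],
) -> Model4D:
    """Fcor = (F1st shifted along x by bdir) minus the bddetect intercepts."""
    return apply_bddetect(shift_model(f1st, bdir), bddetect)


@dataclass
class PipelineResult:
    """Output of :func:`run_pipeline`: the two models and the drift estimate."""

    f1st: Model4D
    fprime: Model4D
    fcor: Model4D
    drift: DriftEstimate
    #: axis -> residual trend over 30 s (mm) for axes that tripped the
    #: drift-rate warning in the intercept-training window.
    drift_rate_flags: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    session_first: Session,
    session_nth: Session,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Fit F1st, estimate both drifts, and build the corrected model Fcor.

    Requires the standard window annotations: ``model_training`` on the first
    session; ``bdir_training``, ``bddetect_training`` and ``beam_delivery``
    on the nth. After correction, the linear trend of the corrected-model
    residuals over the intercept-training window is checked per axis; when it
    exceeds ``config.drift_warn_mm_per_30s`` (scaled to 30 s) a
    :class:`DriftRateWarning` is emitted and the axis recorded in
    ``drift_rate_flags`` — the baseline is still moving, and the correction
    is not expected to hold through delivery.
    """
    cfg = config or PipelineConfig()
    f1st = fit_model(session_first, session_first.windows["model_training"], cfg.smooth_win)
    bdir = compute_bdir(
        session_first, session_nth,
        pooled=cfg.bdir_pooled, smooth_win=cfg.smooth_win,
        min_sep_frac=cfg.min_sep_frac, prominence_frac=cfg.prominence_frac,
    )
    fprime = shift_model(f1st, bdir)
    drift = compute_bddetect(
        session_nth, fprime,
        int_smooth_win=cfg.int_smooth_win, smooth_win=cfg.smooth_win,
        min_sep_frac=cfg.min_sep_frac, prominence_frac=cfg.prominence_frac,
    )
    fcor = apply_bddetect(fprime, drift.bddetect_mm)

    window = session_nth.windows["bddetect_training"]
    t_kv = session_nth.kv_times(window)
    flags: dict[str, float] = {}
    for ax in AXES:
        resid = session_nth.target[ax].y[in_window(session_nth.target[ax].t, window)]
        resid = resid - predict(fcor, session_nth, t_kv, ax)
        slope = np.polyfit(t_kv, resid, 1)[0]
        trend30 = float(slope * 30.0)
        if abs(trend30) > cfg.drift_warn_mm_per_30s:
            flags[ax] = trend30
            warnings.warn(
                f"axis {ax}: residual trend {trend30:+.2f} mm / 30 s in the "
                "intercept-training window exceeds the drift-rate threshold; "
                "the baseline may still be moving and the correction may not "
                "hold during delivery",
                DriftRateWarning,
                stacklevel=2,
            )
    return PipelineResult(f1st=f1st, fprime=fprime, fcor=fcor, drift=drift,
                          drift_rate_flags=flags)
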