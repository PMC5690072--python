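"""Prediction-error series and summary statistics.

The prediction error is Ep(t) = Pdetect(t) - Pprediction(t), evaluated at the
kV timestamps of the evaluation window (no resampling). Per session and axis
the headline figure is the 95th percentile of |Ep|; across sessions the error
decomposes into an overall mean M (mean of session means), a systematic
component Sigma (SD of session means, ddof=1) and a random component sigma
(RMS of the per-session SDs, ddof=1).

Percentiles use the linear-interpolation convention between order statistics
(conventions differ by more than 0.1 mm at a few hundred samples, so the
choice is recorded in report metadata).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model4d import Model4D, predict
from .trace_io import AXES, Session, in_window

PERCENTILE_CONVENTION = "linear"


def prediction_error(
    session: Session,
    model: Model4D,
    window: tuple[float, float] | None = None,
    axis: str = "SI",
) -> np.ndarray:
    """Ep(t) = detected minus predicted target position at kV times in window."""
    if window is None:
        window = session.windows["beam_delivery"]
    t_kv = session.kv_times(window)
    if len(t_kv) == 0:
        raise ValidationError(f"window {window} contains no kV samples")
    detected = session.target[axis].y[in_window(session.target[axis].t, window)]
    return detected - predict(model, session, t_kv, axis)


def p95_abs(ep: np.ndarray) -> float:
    """95th percentile (linear interpolation) of |Ep|, in mm."""
    ep = np.asarray(ep, dtype=float)
    if ep.size == 0:
        raise ValidationError("empty error series")
    return float(np.percentile(np.abs(ep), 95.0, method="linear"))


class SessionReport:
    """Per-axis Ep series and summary statistics for one session and model."""

    def __init__(
        self,
        label: str,
        window: tuple[float, float],
        ep: dict[str, np.ndarray],
        meta: dict | None = None,
    ):
        self.label = label
        self.window = (float(window[0]), float(window[1]))
        self.ep = {ax: np.asarray(e, dtype=float) for ax, e in ep.items()}
        self.meta = dict(meta or {})
        self.meta.setdefault("percentile_convention", PERCENTILE_CONVENTION)

    def p95_abs(self, axis: str) -> float:
        return p95_abs(self.ep[axis])

    def mean(self, axis: str) -> float:
        return float(np.mean(self.ep[axis]))

    def sd(self, axis: str) -> float:
        return float(np.std(self.ep[axis], ddof=1))

    def summary(self) -> pd.DataFrame:
        rows = [
            {"axis": ax, "model": self.label, "n": len(self.ep[ax]),
             "p95_abs_mm": self.p95_abs(ax), "mean_mm": self.mean(ax),
             "sd_mm": self.sd(ax)}
            for ax in AXES if ax in self.ep
        ]
        return pd.DataFrame(rows)


def evaluate_session(
    session: Session,
    model: Model4D,
    window: tuple[float, float] | None = None,
    label: str = "model",
) -> SessionReport:
    """Ep series and summaries on all three axes over the evaluation window."""
    if window is None:
        window = session.windows["beam_delivery"]
    ep = {ax: prediction_error(session, model, window, ax) for ax in AXES}
    return SessionReport(label, window, ep, meta=dict(session.meta))


def pooled_stats(reports: list[SessionReport]) -> pd.DataFrame:
    """Cross-session (M, Sigma, sigma) per axis.

    M is the mean of the per-session mean errors; Sigma the SD (ddof=1) of
    those means (systematic, between-session); sigma the RMS of the
    per-session SDs (ddof=1; random, within-session). With fewer than two
    sessions Sigma and sigma are NaN and ``defined`` is False.
    """
    if not reports:
        raise ValidationError("no session reports")
    rows = []
    enough = len(reports) >= 2
    for ax in AXES:
        means = np.array([r.mean(ax) for r in reports])
        sds = np.array([r.sd(ax) for r in reports])
        rows.append({
            "axis": ax,
            "M_mm": float(np.mean(means)),
            "Sigma_mm": float(np.std(means, ddof=1)) if enough else np.nan,
            "sigma_mm": float(np.sqrt(np.mean(sds**2))) if enough else np.nan,
            "n_sessions": len(reports),
            "defined": enough,
        })
    return pd.DataFrame(rows)


def compare_models(
    reports_a: list[SessionReport],
    reports_b: list[SessionReport],
) -> pd.DataFrame:
    """Side-by-side per-axis comparison of two models on matched sessions.

    Reports the across-session median of the per-session 95th percentile of
    |Ep| and the pooled (M, Sigma, sigma) for each model. Sessions must be
    matched pairwise with identical evaluation windows.
    """
    if len(reports_a) != len(reports_b):
        raise ValidationError("report lists must have equal length")
    for ra, rb in zip(reports_a, reports_b):
        if ra.window != rb.window:
            raise ValidationError(
                f"mismatched evaluation windows: {ra.window} vs {rb.window}"
            )
    frames = []
    for reports in (reports_a, reports_b):
        label = reports[0].label
        pooled = pooled_stats(reports).set_index("axis")
        rows = []
        for ax in AXES:
            p95s = [r.p95_abs(ax) for r in reports]
            rows.append({
                "axis": ax, "model": label,
                "median_p95_abs_mm": float(np.median(p95s)),
                "max_p95_abs_mm": float(np.max(p95s)),
                "M_mm": pooled.loc[ax, "M_mm"],
                "Sigma_mm": pooled.loc[ax, "Sigma_mm"],
                "sigma_mm": pooled.loc[ax, "sigma_mm"],
            })
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def ep_histogram(
    ep: np.ndarray,
    bin_mm: float = 0.25,
    range_mm: float = 10.0,
) -> pd.DataFrame:
    """Histogram of an Ep series: counts per ``bin_mm`` bin over +/- ``range_mm``."""
    edges = np.arange(-range_mm, range_mm + bin_mm / 2, bin_mm)
    counts, _ = np.histogram(np.asarray(ep, dtype=float), bins=edges)
    return pd.DataFrame({
        "bin_left_mm": edges[:-1],
        "bin_right_mm": edges[1:],
        "count": counts,
    })
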