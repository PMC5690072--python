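"""The quadratic position-velocity correlation model ("4D model").

Each internal target axis j is predicted from each external marker k by

    F_kj(x, v) = a x^2 + b x + c + d v^2 + e v

where x is the marker's AP position (mm) and v its velocity (mm/s); the
velocity terms capture respiratory hysteresis (inhale and exhale paths
differ). The session-level prediction is the mean of the five per-marker
predictions. Coefficients are fitted per (marker, axis) by unweighted linear
least squares of the observed target positions on [x^2, x, 1, v^2, v], with
the marker position and velocity linearly interpolated to the kV (target)
timestamps inside the training window.

Baseline corrections are carried as metadata and applied at evaluation time:
a per-marker abscissa shift (the model is translated along x by the external
baseline drift) and a per-axis intercept offset subtracted from predictions.
Both can equivalently be folded into the coefficients
(b' = b - 2 a s, c' = c + a s^2 - b s - offset); see
:func:`expand_corrections`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import SingularFitError, ValidationError
from .signal import DEFAULT_SMOOTH_WIN, estimate_period, estimate_velocity
from .trace_io import AXES, N_IR_MARKERS, Session, in_window

COEF_NAMES = ("a", "b", "c", "d", "e")


@dataclass
class Model4D:
    """Per-(marker, axis) quadratic coefficients plus correction metadata.

    ``coeffs[(k, axis)]`` is the array (a, b, c, d, e) for marker k (1-based)
    and axis in {"LR", "AP", "SI"}. ``bdir_mm`` is the per-marker abscissa
    shift (external baseline drift, AP mm, positive anterior); ``bddetect_mm``
    the per-axis intercept offset (internal baseline drift, mm). A freshly
    fitted model has zero corrections.
    """

    coeffs: dict[tuple[int, str], np.ndarray]
    bdir_mm: np.ndarray = field(default_factory=lambda: np.zeros(N_IR_MARKERS))
    bddetect_mm: dict[str, float] = field(default_factory=dict)
    smooth_win: int = DEFAULT_SMOOTH_WIN
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = {k: np.asarray(v, dtype=float) for k, v in self.coeffs.items()}
        expected = {(k, ax) for k in range(1, N_IR_MARKERS + 1) for ax in AXES}
        if set(self.coeffs) != expected:
            raise ValidationError("coeffs must cover all 5 markers x 3 axes")
        for key, c in self.coeffs.items():
            if c.shape != (5,) or not np.all(np.isfinite(c)):
                raise ValidationError(f"coefficients for {key} must be 5 finite numbers")
        self.bdir_mm = np.asarray(self.bdir_mm, dtype=float)
        if self.bdir_mm.shape != (N_IR_MARKERS,) or not np.all(np.isfinite(self.bdir_mm)):
            raise ValidationError("bdir_mm must be 5 finite numbers")
        self.bddetect_mm = {ax: float(v) for ax, v in self.bddetect_mm.items()}

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "coeffs": {f"marker{k}": {ax: list(self.coeffs[(k, ax)]) for ax in AXES}
                       for k in range(1, N_IR_MARKERS + 1)},
            "corrections": {"bdir_mm": list(self.bdir_mm),
                            "bddetect_mm": dict(sorted(self.bddetect_mm.items()))},
            "smooth_win": self.smooth_win,
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Model4D":
        coeffs = {(k, ax): np.asarray(d["coeffs"][f"marker{k}"][ax], dtype=float)
                  for k in range(1, N_IR_MARKERS + 1) for ax in AXES}
        corr = d.get("corrections", {})
        return cls(
            coeffs=coeffs,
            bdir_mm=np.asarray(corr.get("bdir_mm", np.zeros(N_IR_MARKERS)), dtype=float),
            bddetect_mm=dict(corr.get("bddetect_mm", {})),
            smooth_win=int(d.get("smooth_win", DEFAULT_SMOOTH_WIN)),
            training_meta=d.get("training_meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Model4D":
        return cls.from_dict(json.loads(Path(path).read_text()))


def design_matrix(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Regressor matrix [x^2, x, 1, v^2, v] matching coefficients (a..e)."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.column_stack([x * x, x, np.ones_like(x), v * v, v])


def solve_quadratic_model(x: np.ndarray, v: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares (a, b, c, d, e) for y ~ a x^2 + b x + c + d v^2 + e v."""
    A = design_matrix(x, v)
    coef, _, rank, _ = np.linalg.lstsq(A, np.asarray(y, dtype=float), rcond=None)
    if rank < 5:
        raise SingularFitError(f"design matrix rank {rank} < 5 (degenerate regressors)")
    return coef


def _quad(c: np.ndarray, x: np.ndarray, v: np.ndarray) -> np.ndarray:
    a, b, cc, d, e = c
    return a * x * x + b * x + cc + d * v * v + e * v


def _marker_xv(session: Session, times: np.ndarray, smooth_win: int):
    """Per-marker position and velocity interpolated to ``times``."""
    out = []
    for tr in session.ir:
        vtr = estimate_velocity(tr, smooth_win)
        out.append((np.interp(times, tr.t, tr.y), np.interp(times, vtr.t, vtr.y)))
    return out


def fit_model(
    session: Session,
    window: tuple[float, float] | None = None,
    smooth_win: int = DEFAULT_SMOOTH_WIN,
) -> Model4D:
    """Fit the correlation model on a session's training window.

    Runs 15 independent 5-parameter least-squares fits (5 markers x 3 axes),
    each regressing the target positions at the kV timestamps inside the
    window on that marker's interpolated position and velocity. No
    regularization is applied; a rank-deficient design (e.g. a constant
    marker trace) raises :class:`SingularFitError` naming the marker/axis.
    Warns when the window covers fewer than two breathing cycles.
    """
    if window is None:
        window = session.windows["model_training"]
    kv_t = session.kv_times(window)
    if len(kv_t) < 5:
        raise ValidationError(
            f"training window {window} contains {len(kv_t)} kV samples; need >= 5"
        )
    try:
        mean_ir = np.mean([tr.y for tr in session.ir], axis=0)
        m = in_window(session.ir[0].t, window)
        period = estimate_period(session.ir[0].t[m], mean_ir[m])
        if (window[1] - window[0]) < 2 * period:
            warnings.warn(
                f"training window of {window[1] - window[0]:.1f}s covers fewer than "
                f"two breathing cycles (period ~{period:.1f}s)",
                stacklevel=2,
            )
    except Exception:
        pass  # period estimation is advisory only

    xv = _marker_xv(session, kv_t, smooth_win)
    targets = {ax: session.target[ax].y[in_window(session.target[ax].t, window)] for ax in AXES}
    coeffs: dict[tuple[int, str], np.ndarray] = {}
    for k, (x, v) in enumerate(xv, start=1):
        for ax in AXES:
            try:
                coeffs[(k, ax)] = solve_quadratic_model(x, v, targets[ax])
            except SingularFitError as exc:
                raise SingularFitError(f"marker {k}, axis {ax}: {exc}") from exc

    model = Model4D(coeffs=coeffs, smooth_win=smooth_win)
    rms = {}
    for ax in AXES:
        resid = targets[ax] - predict(model, session, kv_t, ax)
        rms[ax] = float(np.sqrt(np.mean(resid**2)))
    model.training_meta = {
        "window": [float(window[0]), float(window[1])],
        "n_samples": int(len(kv_t)),
        "residual_rms_mm": rms,
        "smooth_win": smooth_win,
    }
    return model


def predict(
    model: Model4D,
    session: Session,
    times: np.ndarray,
    axis: str,
) -> np.ndarray:
    """Predicted target position (mm) for one axis at the given times.

    The mean of the five per-marker predictions, each evaluated at the
    marker's interpolated (x - bdir_k, v), minus the axis intercept offset if
    set. ``times`` must lie within the session's recording span.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if axis not in AXES:
        raise ValidationError(f"unknown axis {axis!r}")
    lo, hi = session.span
    if len(times) and (times.min() < lo - 1e-9 or times.max() > hi + 1e-9):
        raise ValidationError(f"prediction times outside the recording span [{lo}, {hi})")
    xv = _marker_xv(session, times, model.smooth_win)
    total = np.zeros_like(times)
    for k, (x, v) in enumerate(xv, start=1):
        total += _quad(model.coeffs[(k, axis)], x - model.bdir_mm[k - 1], v)
    return total / N_IR_MARKERS - model.bddetect_mm.get(axis, 0.0)


def shift_model(model: Model4D, bdir: float | np.ndarray) -> Model4D:
    """Translate the model along the x-axis by the external baseline drift.

    The returned model evaluates each marker at ``x - bdir_k``; shifts
    accumulate with any existing correction. ``bdir`` may be a scalar
    (applied to every marker) or a length-5 array.
    """
    bdir = np.broadcast_to(np.asarray(bdir, dtype=float), (N_IR_MARKERS,))
    if not np.all(np.isfinite(bdir)):
        raise ValidationError("bdir must be finite")
    return Model4D(
        coeffs={k: c.copy() for k, c in model.coeffs.items()},
        bdir_mm=model.bdir_mm + bdir,
        bddetect_mm=dict(model.bddetect_mm),
        smooth_win=model.smooth_win,
        training_meta=dict(model.training_meta),
    )


def apply_bddetect(model: Model4D, bddetect: float | dict[str, float]) -> Model4D:
    """Subtract a per-axis constant from the model's predictions.

    ``bddetect`` may be a scalar (all axes) or a mapping axis -> mm; offsets
    accumulate with any existing correction.
    """
    if np.isscalar(bddetect):
        bddetect = {ax: float(bddetect) for ax in AXES}
    offsets = dict(model.bddetect_mm)
    for ax, val in bddetect.items():
        if ax not in AXES or not np.isfinite(val):
            raise ValidationError(f"invalid intercept offset {ax}={val}")
        offsets[ax] = offsets.get(ax, 0.0) + float(val)
    return Model4D(
        coeffs={k: c.copy() for k, c in model.coeffs.items()},
        bdir_mm=model.bdir_mm.copy(),
        bddetect_mm=offsets,
        smooth_win=model.smooth_win,
        training_meta=dict(model.training_meta),
    )


def expand_corrections(model: Model4D) -> Model4D:
    """Fold the stored corrections algebraically into the coefficients.

    Returns an equivalent model with zero corrections: for each marker with
    shift s, a' = a, b' = b - 2 a s, c' = c + a s^2 - b s (minus the axis
    intercept offset), d' = d, e' = e. Predictions agree with the original
    model to floating-point rounding.
    """
    coeffs = {}
    for (k, ax), c in model.coeffs.items():
        a, b, cc, d, e = c
        s = model.bdir_mm[k - 1]
        coeffs[(k, ax)] = np.array(
            [a, b - 2 * a * s, cc + a * s * s - b * s - model.bddetect_mm.get(ax, 0.0), d, e]
        )
    return Model4D(
        coeffs=coeffs,
        smooth_win=model.smooth_win,
        training_meta=dict(model.training_meta),
    )
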