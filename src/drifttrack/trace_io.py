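"""Session log I/O: uniformly sampled motion traces and paired recordings.

A *Session* bundles one synchronous recording of the five external infrared
(IR) markers on the abdominal wall (anterior-posterior axis, nominally 60 Hz)
with the internal fiducial-derived target position on three axes (LR/AP/SI,
kV-imaging rate, nominally 12.5 Hz), plus named analysis windows.

On disk a session is a single CSV with IR rows and kV rows interleaved by
time (target cells empty on IR-only rows) and a JSON sidecar holding window
annotations, sampling rates, and provenance metadata.

Conventions: units are millimetres and seconds throughout; AP positive is
anterior; SI positive is superior. Windows are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

AXES = ("LR", "AP", "SI")
N_IR_MARKERS = 5
WINDOW_NAMES = ("model_training", "bdir_training", "bddetect_training", "beam_delivery")

_CSV_COLUMNS = (
    ["time_s"]
    + [f"ir{k}_ap_mm" for k in range(1, N_IR_MARKERS + 1)]
    + ["target_lr_mm", "target_ap_mm", "target_si_mm"]
)

# Relative slack on the max-gap invariant (gaps up to twice the nominal
# interval are legal: the kV frame interval may double when motion slows).
_GAP_TOL = 1e-6


@dataclass
class Trace:
    """A uniformly sampled 1-D position time series for one signal on one axis.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing, max gap at most twice
        the nominal sampling interval.
    y : array of float
        Positions in millimetres, same length as ``t`` (at least 2 samples).
    axis : {"LR", "AP", "SI"}
    rate_hz : float
        Nominal sampling frequency.
    """

    t: np.ndarray
    y: np.ndarray
    axis: str
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.axis not in AXES:
            raise ValidationError(f"unknown axis {self.axis!r}; expected one of {AXES}")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValidationError("t and y must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise ValidationError("a Trace needs at least 2 samples")
        gaps = np.diff(self.t)
        if np.any(gaps <= 0):
            i = int(np.argmax(gaps <= 0))
            raise ValidationError(f"time not strictly increasing at sample {i + 1}")
        if gaps.max() > 2.0 / self.rate_hz * (1 + _GAP_TOL):
            raise ValidationError(
                f"max sample gap {gaps.max():.4f}s exceeds twice the nominal "
                f"interval {1.0 / self.rate_hz:.4f}s"
            )
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.y))):
            raise ValidationError("trace contains non-finite values")

    @property
    def span(self) -> tuple[float, float]:
        """Half-open [first sample, one nominal interval past the last sample)."""
        return float(self.t[0]), float(self.t[-1] + 1.0 / self.rate_hz)

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        t0, t1 = window
        return (self.t >= t0) & (self.t < t1)

    def slice(self, window: tuple[float, float]) -> "Trace":
        """Return the sub-trace inside the half-open ``window``."""
        m = self.window_mask(window)
        if m.sum() < 2:
            raise ValidationError(f"window {window} contains fewer than 2 samples")
        return Trace(self.t[m], self.y[m], self.axis, self.rate_hz)

    def allclose(self, other: "Trace", atol: float = 1e-9) -> bool:
        return (
            self.axis == other.axis
            and np.isclose(self.rate_hz, other.rate_hz)
            and self.t.shape == other.t.shape
            and np.allclose(self.t, other.t, atol=atol)
            and np.allclose(self.y, other.y, atol=atol)
        )


@dataclass
class Session:
    """A paired recording of 5 external IR traces and a 3-axis internal target.

    ``windows`` maps names (see :data:`WINDOW_NAMES`) to half-open ``(t0, t1)``
    intervals in the recording's absolute time; ``meta`` carries free-form
    provenance (seed, scenario, role).
    """

    ir: tuple[Trace, ...]
    target: dict[str, Trace]
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ir = tuple(self.ir)
        if len(self.ir) != N_IR_MARKERS:
            raise ValidationError(f"expected {N_IR_MARKERS} IR traces, got {len(self.ir)}")
        for k, tr in enumerate(self.ir, start=1):
            if tr.axis != "AP":
                raise ValidationError(f"IR trace {k} must be on the AP axis")
            if not np.array_equal(tr.t, self.ir[0].t):
                raise ValidationError(f"IR trace {k} does not share the common time grid")
        if set(self.target) != set(AXES):
            raise ValidationError(f"target traces must cover axes {AXES}")
        t_ref = self.target["LR"].t
        for ax in AXES:
            if self.target[ax].axis != ax:
                raise ValidationError(f"target trace for {ax} carries axis {self.target[ax].axis}")
            if not np.array_equal(self.target[ax].t, t_ref):
                raise ValidationError(f"target trace {ax} does not share the common time grid")
        lo, hi = self.span
        self.windows = {k: (float(a), float(b)) for k, (a, b) in self.windows.items()}
        for name, (t0, t1) in self.windows.items():
            if not t0 < t1:
                raise ValidationError(f"window {name!r} is empty or reversed: [{t0}, {t1})")
            if t0 < lo - _GAP_TOL or t1 > hi + _GAP_TOL:
                raise ValidationError(
                    f"window {name!r} [{t0}, {t1}) lies outside the recording span [{lo}, {hi})"
                )
        if "bddetect_training" in self.windows and "bdir_training" in self.windows:
            (a0, a1) = self.windows["bddetect_training"]
            (b0, b1) = self.windows["bdir_training"]
            if a0 < b0 - _GAP_TOL or a1 > b1 + _GAP_TOL:
                raise ValidationError("bddetect_training window must lie within bdir_training")

    @property
    def span(self) -> tuple[float, float]:
        return self.ir[0].span

    @property
    def ir_rate_hz(self) -> float:
        return self.ir[0].rate_hz

    @property
    def kv_rate_hz(self) -> float:
        return self.target["LR"].rate_hz

    def kv_times(self, window: tuple[float, float] | None = None) -> np.ndarray:
        """kV (target) sample times, optionally restricted to a window."""
        t = self.target["LR"].t
        if window is None:
            return t
        t0, t1 = window
        return t[(t >= t0) & (t < t1)]

    def allclose(self, other: "Session", atol: float = 1e-9) -> bool:
        return (
            all(a.allclose(b, atol) for a, b in zip(self.ir, other.ir))
            and all(self.target[ax].allclose(other.target[ax], atol) for ax in AXES)
            and self.windows == other.windows
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_session(session: Session, path: str | Path) -> None:
    """Write a Session as a CSV log plus a JSON sidecar.

    IR and kV rows are interleaved by time; target cells are empty on IR-only
    rows (and vice versa). Numbers are written with round-trip precision, so
    ``read_session(write_session(s))`` reproduces ``s`` exactly and a second
    write is byte-identical.
    """
    path = Path(path)
    ir_df = pd.DataFrame({"time_s": session.ir[0].t})
    for k, tr in enumerate(session.ir, start=1):
        ir_df[f"ir{k}_ap_mm"] = tr.y
    kv_df = pd.DataFrame({"time_s": session.target["LR"].t})
    for ax in AXES:
        kv_df[f"target_{ax.lower()}_mm"] = session.target[ax].y
    df = pd.merge(ir_df, kv_df, on="time_s", how="outer").sort_values("time_s")
    df = df[_CSV_COLUMNS]
    df.to_csv(path, index=False, na_rep="")
    sidecar = {
        "ir_rate_hz": session.ir_rate_hz,
        "kv_rate_hz": session.kv_rate_hz,
        "windows": {name: [t0, t1] for name, (t0, t1) in sorted(session.windows.items())},
        "meta": session.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_session(path: str | Path) -> Session:
    """Read a CSV log (plus JSON sidecar) written by :func:`write_session`.

    Raises :class:`ParseError` on a malformed header, non-monotone time
    column, or fewer than 2 target samples; the message names the offending
    row where applicable.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such log file: {path}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise ParseError(f"missing JSON sidecar: {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON sidecar {sidecar_path}: {exc}") from exc

    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != _CSV_COLUMNS:
        raise ParseError(
            f"malformed header in {path}: expected columns {_CSV_COLUMNS}, got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based row numbering
        raise ParseError(f"{path}: time not increasing at row {int(bad[0]) + 3}")

    ir_rate = float(sidecar.get("ir_rate_hz", 60.0))
    kv_rate = float(sidecar.get("kv_rate_hz", 12.5))

    ir_mask = df["ir1_ap_mm"].notna().to_numpy()
    ir_cols = [f"ir{k}_ap_mm" for k in range(1, N_IR_MARKERS + 1)]
    if df.loc[ir_mask, ir_cols].isna().to_numpy().any():
        raise ParseError(f"{path}: IR rows with partially empty marker cells")
    try:
        ir = tuple(
            Trace(t[ir_mask], df.loc[ir_mask, col].to_numpy(dtype=float), "AP", ir_rate)
            for col in ir_cols
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: invalid IR traces: {exc}") from exc

    target = {}
    for ax in AXES:
        col = f"target_{ax.lower()}_mm"
        m = df[col].notna().to_numpy()
        if m.sum() < 2:
            raise ParseError(f"{path}: fewer than 2 target samples in column {col}")
        try:
            target[ax] = Trace(t[m], df.loc[m, col].to_numpy(dtype=float), ax, kv_rate)
        except ValidationError as exc:
            raise ParseError(f"{path}: invalid target trace {ax}: {exc}") from exc

    windows = {name: (float(a), float(b)) for name, (a, b) in sidecar.get("windows", {}).items()}
    try:
        return Session(ir=ir, target=target, windows=windows, meta=sidecar.get("meta", {}))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def in_window(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask for times inside the half-open ``[t0, t1)`` window."""
    t0, t1 = window
    return (np.asarray(t) >= t0) & (np.asarray(t) < t1)
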