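"""Synthetic respiratory-motion sessions with known ground truth.

The generator emulates the statistical structure the correction method
assumes: quasi-periodic external abdominal motion observed by five IR markers
(AP axis, 60 Hz), an internal target (LR/AP/SI, kV rate 12.5 Hz) tied to the
external motion through a quadratic position-velocity relationship, plus the
disturbances that degrade that relationship over a treatment session:

* breathing waveform: the Lujan-type ``1 - cos^(2n)`` shape, which
  reproduces the long dwell at end-exhale that the baseline definition
  (median of end-exhale peaks) relies on;
* hysteresis: injected through the velocity terms (d, e) of the ground-truth
  coefficients, so the fitted model class is exactly realizable; an optional
  ``phase_lag_s`` produces genuine misspecification instead;
* baseline drift: independent linear drifts (mm/min, with optional start
  time) and/or step offsets on the external markers and on each internal
  axis. External drift moves only the *measured* marker positions — the
  internal target stays tied to the undrifted breathing motion, which is
  precisely the situation the abscissa-shift correction addresses;
* slow amplitude modulation, cardiac-frequency jitter on the internal
  traces, and white measurement noise on both.

The internal target is computed by applying the ground-truth coefficients to
the *noise-free* reference-marker position and its velocity — estimated with
the same smoothing/differencing used at fitting time and interpolated to the
kV timestamps the same way — so that with all disturbances at zero the fitted
model recovers the ground truth exactly.

All five markers share the breathing phase (they sit on the same abdominal
wall) but have distinct offsets and gains; per-marker ground-truth
coefficients are derived from the per-axis reference coefficients by the
exact affine substitution, and recorded in the ground-truth object.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .signal import estimate_velocity
from .trace_io import AXES, N_IR_MARKERS, Session, Trace

#: Per-marker resting AP offsets (mm) and breathing gains (relative).
MARKER_BASE_MM = (0.0, 1.0, 2.0, 3.0, 4.0)
MARKER_GAIN = (1.0, 0.90, 1.10, 0.95, 1.05)


def _as_axis_dict(value, name: str) -> dict[str, float]:
    if np.isscalar(value):
        return {ax: float(value) for ax in AXES}
    d = {ax: float(value.get(ax, 0.0)) for ax in AXES}
    if set(value) - set(AXES):
        raise ValidationError(f"{name}: unknown axes {set(value) - set(AXES)}")
    return d


@dataclass
class SimConfig:
    """Parameters of one simulated patient/session pair.

    Defaults describe a typical lung-tumor tracking session: 4 s breathing
    period (clinical range 2.8-6.7 s), 5 mm external excursion, internal
    peak-to-peak amplitudes of 2/3/15 mm on LR/AP/SI (clinical ranges
    0.2-5.6, 0.9-6.6 and 1.4-30.3 mm), 12 min between the first and the nth
    modeling procedure, 60 Hz external and 12.5 Hz kV sampling.
    """

    period_s: float = 4.0
    n_shape: int = 2  # cos-power exponent; breathing waveform is 1 - cos^(2n)
    ext_amp_mm: float = 5.0
    int_amp_mm: dict[str, float] = field(
        default_factory=lambda: {"LR": 2.0, "AP": 3.0, "SI": 15.0}
    )
    #: Per-axis ground-truth (a, b, c, d, e) with respect to the reference
    #: marker's position/velocity; None derives them from int_amp_mm.
    true_coeffs: dict[str, tuple] | None = None
    ext_drift_mm_per_min: float = 0.0
    int_drift_mm_per_min: float | dict[str, float] = 0.0
    ext_drift_start_s: float = 0.0
    int_drift_start_s: float = 0.0
    ext_step_mm: float = 0.0
    int_step_mm: float | dict[str, float] = 0.0
    step_time_s: float | None = None  # default: midway between the sessions
    amp_mod: float = 0.05  # fractional slow amplitude modulation
    amp_mod_period_s: float = 45.0
    cardiac_amp_mm: float = 0.3
    cardiac_hz: float = 1.17
    noise_ext_mm: float = 0.05
    noise_int_mm: float = 0.2
    phase_lag_s: float = 0.0  # internal response lag (model misspecification)
    duration_s: float = 40.0  # one modeling procedure
    ir_rate_hz: float = 60.0
    kv_rate_hz: float = 12.5
    elapsed_min: float = 12.0  # first modeling -> nth modeling
    pre_roll_s: float = 30.0  # IR-only lead-in before the nth modeling
    smooth_win: int = 5  # velocity estimator window, samples at ir_rate_hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_s <= 0 or self.ir_rate_hz <= 0 or self.kv_rate_hz <= 0:
            raise ValidationError("period and sampling rates must be positive")
        if self.duration_s < 2 * self.period_s:
            raise ValidationError("duration_s must cover at least two breathing cycles")
        if self.n_shape < 1:
            raise ValidationError("n_shape must be >= 1")
        self.int_amp_mm = _as_axis_dict(self.int_amp_mm, "int_amp_mm")
        for name, val in [("ext_amp_mm", self.ext_amp_mm), ("cardiac_amp_mm", self.cardiac_amp_mm),
                          ("noise_ext_mm", self.noise_ext_mm), ("noise_int_mm", self.noise_int_mm)]:
            if val < 0:
                raise ValidationError(f"{name} must be >= 0")
        for ax, amp in self.int_amp_mm.items():
            if amp < 0:
                raise ValidationError(f"int_amp_mm[{ax}] must be >= 0")

    def reference_coeffs(self) -> dict[str, np.ndarray]:
        """Ground-truth (a..e) per axis w.r.t. the reference marker (k=1).

        When not supplied explicitly, derived from the internal amplitudes:
        20% of the excursion comes from the quadratic term, the rest from the
        linear term, with velocity terms scaled to give a hysteresis loop
        width of about 5% of the internal amplitude.
        """
        if self.true_coeffs is not None:
            out = {ax: np.asarray(self.true_coeffs[ax], dtype=float) for ax in AXES}
            for ax, c in out.items():
                if c.shape != (5,):
                    raise ValidationError(f"true_coeffs[{ax}] must have 5 entries")
            return out
        E = self.ext_amp_mm * MARKER_GAIN[0]
        out = {}
        for ax in AXES:
            amp = self.int_amp_mm[ax]
            a = 0.2 * amp / E**2
            b = 0.8 * amp / E
            d = 0.0002 * amp
            e = 0.01 * amp
            out[ax] = np.array([a, b, 0.0, d, e])
        return out


@dataclass
class GroundTruth:
    """Everything injected by the simulator, for recovery checks.

    ``coeffs`` holds the exact per-(marker, axis) coefficient tuples realized
    by the generated data; ``ext_offset``/``int_offset`` evaluate the injected
    baseline offsets (drift + step) at arbitrary absolute times.
    """

    config: SimConfig
    coeffs: dict[tuple[int, str], np.ndarray]
    marker_base_mm: tuple[float, ...] = MARKER_BASE_MM
    marker_gain: tuple[float, ...] = MARKER_GAIN

    def ext_offset(self, t) -> np.ndarray:
        c = self.config
        t = np.asarray(t, dtype=float)
        step_t = _step_time(c)
        out = c.ext_drift_mm_per_min * np.maximum(0.0, t - c.ext_drift_start_s) / 60.0
        return out + c.ext_step_mm * (t >= step_t)

    def int_offset(self, axis: str, t) -> np.ndarray:
        c = self.config
        t = np.asarray(t, dtype=float)
        rate = _as_axis_dict(c.int_drift_mm_per_min, "int_drift_mm_per_min")[axis]
        step = _as_axis_dict(c.int_step_mm, "int_step_mm")[axis]
        out = rate * np.maximum(0.0, t - c.int_drift_start_s) / 60.0
        return out + step * (t >= _step_time(c))

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        return {
            "config": cfg,
            "coeffs": {f"marker{k}": {ax: list(self.coeffs[(k, ax)]) for ax in AXES}
                       for k in range(1, N_IR_MARKERS + 1)},
            "marker_base_mm": list(self.marker_base_mm),
            "marker_gain": list(self.marker_gain),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _step_time(config: SimConfig) -> float:
    if config.step_time_s is not None:
        return config.step_time_s
    # midway between the end of the first modeling and the nth pre-roll
    return 0.5 * (config.duration_s + config.elapsed_min * 60.0 - config.pre_roll_s)


def derive_marker_coeffs(config: SimConfig) -> dict[tuple[int, str], np.ndarray]:
    """Exact per-marker coefficients from the per-axis reference coefficients.

    With x_k = base_k + g_k * u and the reference x_1 = base_1 + g_1 * u, the
    substitution x_1 = alpha + beta x_k (beta = g_1/g_k,
    alpha = base_1 - beta base_k) carries (a, b, c, d, e) for marker 1 into
    the coefficients every other marker must have for the same internal
    response.
    """
    ref = config.reference_coeffs()
    out: dict[tuple[int, str], np.ndarray] = {}
    for k in range(1, N_IR_MARKERS + 1):
        beta = MARKER_GAIN[0] / MARKER_GAIN[k - 1]
        alpha = MARKER_BASE_MM[0] - beta * MARKER_BASE_MM[k - 1]
        for ax in AXES:
            a, b, c, d, e = ref[ax]
            out[(k, ax)] = np.array([
                a * beta**2,
                2 * a * alpha * beta + b * beta,
                a * alpha**2 + b * alpha + c,
                d * beta**2,
                e * beta,
            ])
    return out


def _breathing_u(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free, drift-free breathing excursion u(t) in mm (>= 0)."""
    shape = 1.0 - np.cos(np.pi * t / config.period_s) ** (2 * config.n_shape)
    amp = 1.0 + config.amp_mod * np.sin(2 * np.pi * t / config.amp_mod_period_s)
    return config.ext_amp_mm * amp * shape


def _simulate_one(
    config: SimConfig,
    truth: GroundTruth,
    t_start: float,
    ir_duration: float,
    kv_span: tuple[float, float],
    windows: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    meta: dict,
) -> Session:
    n_ir = int(round(ir_duration * config.ir_rate_hz))
    t_ir = t_start + np.arange(n_ir) / config.ir_rate_hz
    u = _breathing_u(config, t_ir)
    ext_off = truth.ext_offset(t_ir)

    ir = []
    for k in range(N_IR_MARKERS):
        x = MARKER_BASE_MM[k] + MARKER_GAIN[k] * u + ext_off
        x = x + rng.normal(0.0, config.noise_ext_mm, n_ir) if config.noise_ext_mm else x
        ir.append(Trace(t_ir, x, "AP", config.ir_rate_hz))

    # Clean reference-marker signal drives the internal target. Velocity is
    # computed with the same estimator/grid used at fitting time so the model
    # class is exactly realizable when disturbances are off.
    if config.phase_lag_s:
        u_ref = _breathing_u(config, t_ir - config.phase_lag_s)
    else:
        u_ref = u
    x_ref = MARKER_BASE_MM[0] + MARKER_GAIN[0] * u_ref
    ref_trace = Trace(t_ir, x_ref, "AP", config.ir_rate_hz)
    v_ref = estimate_velocity(ref_trace, config.smooth_win)

    n_kv = int(round((kv_span[1] - kv_span[0]) * config.kv_rate_hz))
    t_kv = kv_span[0] + np.arange(n_kv) / config.kv_rate_hz
    x_kv = np.interp(t_kv, t_ir, x_ref)
    v_kv = np.interp(t_kv, v_ref.t, v_ref.y)

    cardiac_phase = rng.uniform(0, 2 * np.pi)
    target = {}
    for ax in AXES:
        a, b, c, d, e = truth.coeffs[(1, ax)]
        y = a * x_kv**2 + b * x_kv + c + d * v_kv**2 + e * v_kv
        y = y + truth.int_offset(ax, t_kv)
        if config.cardiac_amp_mm:
            y = y + config.cardiac_amp_mm * np.sin(
                2 * np.pi * config.cardiac_hz * t_kv + cardiac_phase
            )
        if config.noise_int_mm:
            y = y + rng.normal(0.0, config.noise_int_mm, n_kv)
        target[ax] = Trace(t_kv, y, ax, config.kv_rate_hz)

    return Session(ir=tuple(ir), target=target, windows=windows, meta=meta)


def simulate_session(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Session, GroundTruth]:
    """Generate a single modeling session of ``config.duration_s`` seconds.

    The session spans absolute time [0, duration) with kV imaging throughout
    and a ``model_training`` window covering the whole recording. Returns the
    session and the ground-truth record. Bit-identical for a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = GroundTruth(config=config, coeffs=derive_marker_coeffs(config))
    meta = {"seed": config.seed, "role": "single", "scenario": "custom"}
    windows = {"model_training": (0.0, config.duration_s)}
    session = _simulate_one(
        config, truth, 0.0, config.duration_s, (0.0, config.duration_s), windows, rng, meta
    )
    return session, truth


def simulate_pair(config: SimConfig) -> tuple[Session, Session, GroundTruth]:
    """Generate the paired recordings the correction pipeline consumes.

    The *first* session covers absolute time [0, D) with kV imaging
    throughout and a ``model_training`` window. The *nth* session starts
    ``elapsed_min`` minutes later: its IR recording begins ``pre_roll_s``
    seconds before the nth modeling procedure (external monitoring continues
    between procedures; kV imaging does not), and it carries the standard
    window layout:

    * ``model_training``      [t0, t0 + D)
    * ``bdir_training``       [t0 - pre_roll, t0 + 10): 40 s by default
    * ``bddetect_training``   [t0, t0 + 10)
    * ``beam_delivery``       [t0 + 10, t0 + D): the tentative delivery period

    where t0 = elapsed_min * 60 and D = duration_s.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(config=config, coeffs=derive_marker_coeffs(config))
    D = config.duration_s
    first = _simulate_one(
        config, truth, 0.0, D, (0.0, D),
        {"model_training": (0.0, D)},
        rng,
        {"seed": config.seed, "role": "first"},
    )
    t0 = config.elapsed_min * 60.0
    windows = {
        "model_training": (t0, t0 + D),
        "bdir_training": (t0 - config.pre_roll_s, t0 + 10.0),
        "bddetect_training": (t0, t0 + 10.0),
        "beam_delivery": (t0 + 10.0, t0 + D),
    }
    nth = _simulate_one(
        config, truth, t0 - config.pre_roll_s, config.pre_roll_s + D, (t0, t0 + D),
        windows,
        rng,
        {"seed": config.seed, "role": "nth"},
    )
    return first, nth, truth


SCENARIOS = ("no_drift", "ext_drift_posterior", "int_drift_only", "both_drift",
             "patient5", "patient6_large_si")
_SCENARIO_SEED_OFFSET = {name: 1000 * i for i, name in enumerate(SCENARIOS)}


def scenario(name: str, seed: int = 0, **overrides) -> SimConfig:
    """A reproducible preset configuration for a named drift scenario.

    * ``no_drift``: stationary baselines on both signals (null case).
    * ``ext_drift_posterior``: external baseline drifts posteriorly (the
      dominant clinical direction) at -0.08 mm/min; internal stationary.
    * ``int_drift_only``: internal baseline drifts on all axes; external
      stationary.
    * ``both_drift``: both of the above combined.
    * ``patient5``: internal LR-dominant drift that *starts at the nth
      modeling procedure* and continues through delivery, with stronger
      cardiac jitter — the documented failure mode of a just-before-delivery
      intercept correction.
    * ``patient6_large_si``: 25 mm SI amplitude with posterior external
      drift — the large-amplitude case where an uncorrected model errs most.

    ``seed`` is combined with a fixed per-scenario offset so different
    scenarios never share a random stream.
    """
    if name not in SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    base = dict(seed=seed + _SCENARIO_SEED_OFFSET[name])
    if name == "no_drift":
        pass
    elif name == "ext_drift_posterior":
        base["ext_drift_mm_per_min"] = -0.08
    elif name == "int_drift_only":
        base["int_drift_mm_per_min"] = {"LR": 0.07, "AP": 0.08, "SI": 0.15}
    elif name == "both_drift":
        base["ext_drift_mm_per_min"] = -0.08
        base["int_drift_mm_per_min"] = {"LR": 0.07, "AP": 0.08, "SI": 0.15}
    elif name == "patient5":
        cfg = SimConfig()  # for the default elapsed time
        base["int_drift_mm_per_min"] = {"LR": 2.4, "AP": 0.3, "SI": 0.3}
        base["int_drift_start_s"] = cfg.elapsed_min * 60.0
        base["cardiac_amp_mm"] = 0.5
    elif name == "patient6_large_si":
        base["int_amp_mm"] = {"LR": 2.0, "AP": 3.0, "SI": 25.0}
        base["ext_drift_mm_per_min"] = -0.08
        base["int_drift_mm_per_min"] = {"LR": 0.05, "AP": 0.05, "SI": 0.3}
    cfg = SimConfig(**base)
    if overrides:
        cfg = replace(copy.deepcopy(cfg), **overrides)
    return cfg
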