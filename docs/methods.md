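# Methods

## Model

The correlation ("4D") model predicts the internal target position on each
axis (LR, AP, SI; mm) from the external surrogate position x (mm, AP,
positive anterior) and velocity v (mm/s) of each of the five IR markers:

    F_kj(x, v) = a x² + b x + c + d v² + e v,

fitted per (marker, axis) — 15 independent 5-parameter problems — by plain
unweighted linear least squares on the regressors [x², x, 1, v², v] at the
kV timestamps of the training window. The session-level prediction is the
mean over markers. Design choices behind this form:

* **Velocity terms model hysteresis**: inhale and exhale trace different
  paths in (x, target) space; a function of position alone cannot separate
  them, whereas v changes sign between the two limbs.
* **Per-marker fits, marker-mean prediction**: each marker sees the same
  breathing through a different local gain/offset; averaging five
  predictions suppresses single-marker noise without requiring a joint fit.
* **No regularization or centring**: the design is well conditioned for any
  non-degenerate breathing trace; a rank-deficient design (e.g. a constant
  marker) is reported as an error rather than silently ridge-stabilised.
* External signals are interpolated (linearly) to the kV timestamps, not
  the reverse: the target samples are the scarce, authoritative data.
* Velocity is a central finite difference of a moving-average-smoothed
  trace (default window 5 samples ≈ 83 ms at 60 Hz), one-sided at the
  endpoints; the same estimator and window are used at fit and predict
  time and recorded in the model metadata.

## Baselines and the two-stage correction

The baseline of a respiratory signal over a window is the **median of its
end-exhale peak positions** — end-exhale is the most reproducible phase of
the cycle, and the median ignores occasional deep or shallow breaths. On
the AP surrogate, end-exhale peaks are the minima (the abdomen is most
posterior at exhale).

* **BDIR** (per marker): baseline over the 40 s pre-delivery training
  window minus baseline over the first modeling window. Positive values
  mean the external baseline drifted anteriorly. The correction translates
  the model along its abscissa, F′(x, v) = F1st(x − BDIR, v), which is
  exact when the surrogate–target relationship itself is preserved and only
  the surrogate's reference level moved. BDIR is applied per marker
  (each marker has its own model); a pooled mode (across-marker median) is
  available as an option.
* **BDdetect** (per axis): with F′ in hand, the residual at the target's
  own end-inhale and end-exhale peak times over the final 10 s is averaged
  per phase (ER-in, ER-ex) and the two phases averaged:
  BDdetect = (ER-in + ER-ex)/2, subtracted from the intercept:
  Fcor = F′ − BDdetect. Sampling only the two phase extremes makes the
  estimate insensitive to phase/timing error, and averaging the phases
  cancels pure amplitude mismatch to first order (an amplitude error moves
  ER-in and ER-ex in opposite directions). Amplitude variation is
  deliberately *not* separated from baseline drift.

**Sign convention.** The peak residuals are measured as *prediction minus
detection*. With the residual in that direction, subtracting BDdetect from
the intercept moves predictions toward the drifted detections: an internal
baseline shift of +δ yields BDdetect = −δ and Fcor = F′ + δ. Measuring the
residual as detection minus prediction and still subtracting would double
the error instead of cancelling it — the two conventions are easy to mix
up, so the package fixes this one everywhere and the test suite pins it.
The evaluation error series keeps the opposite, conventional direction:
Ep = P_detect − P_predict.

Window layout (all configurable): the BDIR training window is 40 s ending
10 s into the nth modeling procedure; the BDdetect window is those first
10 s (long enough to cover at least one breathing cycle at clinical
periods); the last 30 s of the nth procedure serve as the tentative
beam-delivery window over which both models are evaluated.

**Drift-rate warning.** After correction, the linear trend of the corrected
model's residuals over the BDdetect window is checked per axis; a trend
exceeding 1 mm per 30 s (default) raises a warning that the baseline is
still moving and the correction may not hold through delivery. This mirrors
the known failure mode of any just-before-delivery correction — it is a
flag only, nothing is auto-adjusted.

## Peak detection

Peaks are local extrema of the moving-average-smoothed trace subject to
two filters: a minimum separation of 0.4 × the breathing period (estimated
from the autocorrelation of the linearly detrended window) and a minimum
topographic prominence of 0.2 × the breathing amplitude. The amplitude is
estimated as the 2.5–97.5 percentile spread of the smoothed window — a
median over candidate extrema is *not* robust here, because noise wiggles
in the long end-exhale dwell enter the candidate set and collapse the
estimate. Reported peak values are the raw (unsmoothed) positions at the
detected sample. Internal (kV-rate) traces use a wider smoothing window
(7 samples ≈ 0.56 s at 12.5 Hz) so cardiac-frequency jitter (~1.2 Hz,
sub-millimetre) cannot spawn false breathing peaks; internal peaks inherit
their phase label from the nearest external peak in time, falling back to
extremum type.

## Error metrics

Per session and axis: Ep at the kV timestamps of the evaluation window (no
resampling), its mean, SD (ddof = 1), and the 95th percentile of |Ep| using
the linear-interpolation percentile convention (conventions differ by more
than 0.1 mm at a few hundred samples; the choice is recorded in report
metadata). Across sessions: M = mean of session means, Σ = SD (ddof = 1) of
session means, σ = RMS of session SDs — the standard motion-management
decomposition; defining σ as the RMS rather than the mean of session SDs is
a documented choice.

## Synthetic data

The simulator generates exactly the structure the method assumes, with
every injected quantity recorded for recovery checks:

* **Waveform**: Lujan-type u(t) = A·(1 − cos^{2n}(πt/T)), default T = 4 s
  (clinical periods 2.8–6.7 s), n = 2, A = 5 mm external excursion. The
  cos^{2n} shape reproduces the long end-exhale dwell that the baseline
  definition relies on (and that trips naive peak detectors).
* **Markers**: five phase-locked copies with distinct offsets (0–4 mm) and
  gains (0.90–1.10); internal amplitudes default to 2/3/15 mm on LR/AP/SI
  (clinical ranges 0.2–5.6, 0.9–6.6, 1.4–30.3 mm).
* **Ground-truth coefficients** are specified per axis with respect to the
  reference marker and carried to the other markers by the exact affine
  substitution, so a *consistent* family of 15 tuples generates the data —
  the only construction under which per-marker fits can recover every tuple
  exactly. By default 20% of the internal excursion comes from the
  quadratic term and the velocity terms give a hysteresis loop of ~5% of
  the amplitude; the internal target is computed from the *noise-free*
  reference signal using the same velocity estimator and interpolation as
  the fitting path, so with all disturbances at zero the model class is
  exactly realizable (recovery to solver tolerance). An optional
  ``phase_lag_s`` produces genuine misspecification instead.
* **Disturbances**: linear baseline drifts in mm/min (optionally starting
  mid-session) and/or step offsets, independently on the external markers
  and each internal axis — external drift moves only the *measured*
  surrogate, leaving the target tied to the undrifted motion, which is the
  situation the abscissa shift corrects; 5% slow amplitude modulation
  (45 s period) entering both signals coherently; cardiac jitter
  (0.3 mm, 1.17 Hz) on the internal traces only; white measurement noise
  (0.05 mm external, 0.2 mm internal).
* **Timing**: 40 s modeling procedures 12 min apart (clinical median), a
  30 s external-only lead-in before the nth procedure, 60 Hz IR and a
  constant 12.5 Hz kV rate (the clinical 80→160 ms rate switching is not
  modelled).

Scenario presets fix the drift magnitudes: external drift −0.08 mm/min
(≈ −1 mm accumulated between modelings, mid-range of clinically reported
external drifts, posterior-dominant), internal drifts 0.07/0.08/0.15 mm/min
LR/AP/SI; a large-SI preset (25 mm amplitude); and an ongoing-drift preset
(2.4 mm/min LR starting at the nth procedure, stronger cardiac jitter) that
exercises the failure mode and the drift-rate warning.

What the simulator does **not** emulate: irregular breathing (apnea,
coughs, period changes), non-affine changes of the surrogate–target
relationship, imaging geometry and detection artefacts, and the kV rate
switching. Passing tests therefore demonstrate the correctness and internal
consistency of the algorithmic chain under the method's own assumptions —
not clinical performance, which can only come from real paired log files.

## Numerical choices and degenerate inputs

* Least squares via `numpy.linalg.lstsq`; rank < 5 raises an error naming
  the marker/axis. Coefficient-level agreement with an explicit
  normal-equations solve is tested to 1e-8.
* The abscissa shift can be evaluated by substitution or by expanding the
  coefficients (b′ = b − 2as, c′ = c + as² − bs); both paths agree to 1e-12
  and the equivalence is tested.
* Corrections accumulate (shifting twice composes) and commute with the
  intercept offset; re-estimating drifts from the corrected model on the
  same windows yields ≈ 0 (idempotence).
* Windows are half-open [t0, t1); traces must be strictly increasing in
  time with gaps at most twice the nominal interval (allowing the doubled
  kV interval); sessions require all five IR traces on one grid and all
  three target traces on another.
* Peak-set ties in the median baseline use the standard even-count
  midpoint. An analysis window with no detectable peaks in a required
  phase is an estimation error, never a silent fallback.
* File I/O is round-trip exact (`float_precision="round_trip"` on read,
  shortest-repr floats on write), so a second write is byte-identical —
  this underpins the determinism guarantee of the experiment driver.

## Problem sizes

The bundled experiments use 40 s sessions (≈ 2400 external samples per
marker, 500 kV samples), cohorts of 12 simulated patients, and Monte-Carlo
checks of 30–50 seeds; the full test suite and the acceptance script each
run in well under a minute on one core.

## Known limitations

* The correction is a constant (per axis) over the delivery window: drift
  continuing through delivery is flagged but not compensated.
* BDIR pooling across markers, the clinical peak-picking rule, and whether
  the clinical system centres x before fitting are not publicly specified;
  the defaults here are documented choices, configurable where reasonable.
* With exactly one peak per phase in the 10 s window the intercept estimate
  follows the formula but is high-variance; the peak counts are recorded in
  the drift estimate so callers can judge.
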