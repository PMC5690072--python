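# drifttrack

Baseline-drift correction for surrogate-based respiratory tumor tracking.

## The problem

Indirect dynamic tumor tracking steers the treatment beam from an *external*
respiratory surrogate — here, five infrared (IR) markers on the abdominal
wall, monitored on the anterior–posterior (AP) axis at ~60 Hz — because the
*internal* target (implanted fiducials near a lung tumor, seen on orthogonal
kV X-ray images at ~12.5 Hz) cannot be imaged continuously without dose. A
correlation model fitted at the start of treatment maps surrogate motion to
target position. Over the following minutes, however, the baselines of both
signals drift — the abdominal surface typically settles posteriorly, and the
target's resting position wanders independently — so a model fitted earlier
develops systematic prediction errors, largest on the superior–inferior (SI)
axis where breathing amplitude is biggest.

`drifttrack` implements the correlation model, a two-stage baseline
correction applied just before beam delivery, the associated prediction-error
metrics, and a synthetic respiratory-motion simulator with known ground
truth, so the whole chain is testable without clinical log files.

## The model and the correction

Per marker k and target axis, the "4D model" is quadratic in surrogate
position x (mm) and velocity v (mm/s):

    F(x, v) = a x² + b x + c + d v² + e v

with the velocity terms capturing hysteresis. The 15 coefficient tuples
(5 markers × 3 axes) are fitted by unweighted least squares at the kV
timestamps of the training window; the session prediction P_predict is the
mean of the five per-marker predictions.

The *baseline* of a respiratory signal is the median of its end-exhale peak
positions over a window (end-exhale is the most reproducible phase). Two
corrections update the initial model F1st just before delivery:

1. **BDIR** (external): the change in each marker's baseline between the
   first modeling window and a 40 s training window ending just before
   delivery. The model is translated along its abscissa:
   F′(x, v) = F1st(x − BDIR, v).
2. **BDdetect** (internal): the mean prediction-minus-detection residual of
   F′ at the target's own end-inhale and end-exhale peaks over the final
   10 s, averaged over the two phases, subtracted from the intercept:

       Fcor(x, v) = F1st(x − BDIR, v) − BDdetect.

Prediction error is Ep = P_detect − P_predict at the kV timestamps of the
30 s tentative beam-delivery window; the headline per-session figure is the
95th percentile of |Ep|, and errors pool across sessions into an overall
mean M, a systematic (between-session) component Σ and a random
(within-session) component σ.

## Worked example

```python
import numpy as np
import drifttrack as dt

cfg = dt.scenario("both_drift", seed=42)        # drifting synthetic patient
first, nth, truth = dt.simulate_pair(cfg)       # paired first/nth recordings
result = dt.run_pipeline(first, nth)            # F1st -> F' -> Fcor

print("BDIR per marker (mm):", np.round(result.drift.bdir_mm, 2))
print("BDdetect (mm):", {ax: round(v, 2) for ax, v in result.drift.bddetect_mm.items()})
win = nth.windows["beam_delivery"]
for label, model in [("F1st", result.f1st), ("Fcor", result.fcor)]:
    rep = dt.evaluate_session(nth, model, win, label)
    print(label, "p95 |Ep| (mm):", {ax: round(rep.p95_abs(ax), 2) for ax in dt.AXES})
```

prints

```
BDIR per marker (mm): [-0.91 -0.99 -0.92 -0.94 -0.92]
BDdetect (mm): {'LR': -0.87, 'AP': -1.11, 'SI': -1.76}
F1st p95 |Ep| (mm): {'LR': 1.76, 'AP': 2.06, 'SI': 5.38}
Fcor p95 |Ep| (mm): {'LR': 0.58, 'AP': 0.6, 'SI': 0.66}
```

The external baseline drifted ~−1 mm posteriorly (the injected value at
mid-delivery is −0.99 mm) and the internal baselines by ~+0.9/+1.0/+1.9 mm
on LR/AP/SI; BDdetect, measured as prediction minus detection, is their
negative. Uncorrected, the stale model errs by up to 5.4 mm (p95, SI);
after both corrections the errors drop to the noise floor (~0.6 mm,
dominated by cardiac jitter and kV detection noise).

The same pipeline is available from the shell:

```
drifttrack simulate --scenario both_drift --seed 42 --out demo
drifttrack correct --first demo_first.csv --nth demo_nth.csv --out demo_out/
drifttrack evaluate --session demo_nth.csv --model demo_out/fcor.json --out eval.csv
```

plus `validate`, `fit`, `peaks`, `report` and `experiment` subcommands
(`drifttrack --version` prints the algorithm-relevant defaults).

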