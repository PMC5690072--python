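import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drifttrack import (
    AXES,
    Model4D,
    SimConfig,
    SingularFitError,
    Trace,
    ValidationError,
    apply_bddetect,
    expand_corrections,
    fit_model,
    predict,
    shift_model,
    simulate_session,
)
from drifttrack.model4d import _quad, design_matrix, solve_quadratic_model

from conftest import noiseless_config
from oracles import normal_equations_fit


def _uniform_model(coeffs, **kwargs):
    return Model4D(coeffs={(k, ax): np.asarray(coeffs, float)
                           for k in range(1, 6) for ax in AXES}, **kwargs)


class TestSolver:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 5, 80)
        v = rng.normal(0, 3, 80)
        y = rng.normal(0, 2, 80)
        assert np.allclose(solve_quadratic_model(x, v, y),
                           normal_equations_fit(x, v, y), atol=1e-8)

    def test_constant_x_is_singular(self):
        with pytest.raises(SingularFitError):
            solve_quadratic_model(np.full(20, 2.0), np.zeros(20), np.ones(20))


class TestFit:
    def test_noiseless_recovery_of_all_tuples(self, clean_session):
        session, truth = clean_session
        model = fit_model(session)
        for key in model.coeffs:
            assert np.allclose(model.coeffs[key], truth.coeffs[key], atol=1e-6)

    def test_training_meta_residual_rms_self_consistent(self, noisy_pair):
        first, _, _ = noisy_pair
        model = fit_model(first)
        win = first.windows["model_training"]
        t_kv = first.kv_times(win)
        for ax in AXES:
            resid = first.target[ax].y - predict(model, first, t_kv, ax)
            rms = float(np.sqrt(np.mean(resid**2)))
            assert rms == pytest.approx(model.training_meta["residual_rms_mm"][ax], abs=1e-9)

    def test_constant_marker_trace_names_offender(self):
        session, _ = simulate_session(SimConfig(seed=1))
        ir = list(session.ir)
        ir[2] = Trace(ir[2].t, np.full_like(ir[2].y, 1.5), "AP", ir[2].rate_hz)
        from drifttrack import Session
        broken = Session(ir=tuple(ir), target=session.target, windows=session.windows)
        with pytest.raises(SingularFitError, match="marker 3"):
            fit_model(broken)

    def test_too_few_samples_rejected(self, noisy_pair):
        first, _, _ = noisy_pair
        with pytest.raises(ValidationError, match="kV samples"):
            fit_model(first, window=(0.0, 0.2))

    def test_noisy_coefficients_within_standard_errors(self):
        """With white target noise the estimates stay within 4 normal-theory
        standard errors of the injected truth."""
        for seed in (0, 1, 2):
            cfg = noiseless_config(noise_int_mm=0.1, seed=seed)
            session, truth = simulate_session(cfg)
            model = fit_model(session)
            t_kv = session.kv_times()
            ref = session.ir[0]
            from drifttrack import estimate_velocity
            vtr = estimate_velocity(ref, cfg.smooth_win)
            x = np.interp(t_kv, ref.t, ref.y)
            v = np.interp(t_kv, vtr.t, vtr.y)
            A = design_matrix(x, v)
            cov = 0.1**2 * np.linalg.inv(A.T @ A)
            se = np.sqrt(np.diag(cov))
            for ax in AXES:
                err = model.coeffs[(1, ax)] - truth.coeffs[(1, ax)]
                assert np.all(np.abs(err) < 4 * se)


class TestPredict:
    def test_identical_markers_equal_single_marker_evaluation(self):
        t = np.arange(0, 20, 1 / 60.0)
        y = 5 * (1 - np.cos(np.pi * t / 4.0) ** 4)
        ir = tuple(Trace(t, y, "AP", 60.0) for _ in range(5))
        t_kv = np.arange(0, 20, 0.08)
        from drifttrack import Session
        target = {ax: Trace(t_kv, np.zeros_like(t_kv), ax, 12.5) for ax in AXES}
        session = Session(ir=ir, target=target)
        model = _uniform_model([0.1, 0.5, 1.0, 0.01, 0.2])
        from drifttrack.model4d import _marker_xv
        (x, v), *_ = _marker_xv(session, t_kv, model.smooth_win)
        single = _quad(model.coeffs[(1, "SI")], x, v)
        assert np.allclose(predict(model, session, t_kv, "SI"), single, atol=1e-12)

    def test_intercept_arithmetic_with_offset(self, clean_session):
        session, _ = clean_session
        model = _uniform_model([0, 0, 2.0, 0, 0], bddetect_mm={"SI": 0.5})
        t = session.kv_times()[:10]
        assert np.allclose(predict(model, session, t, "SI"), 1.5, atol=1e-12)
        assert np.allclose(predict(model, session, t, "AP"), 2.0, atol=1e-12)

    def test_times_outside_span_rejected(self, clean_session):
        session, _ = clean_session
        model = _uniform_model([0, 0, 1.0, 0, 0])
        with pytest.raises(ValidationError, match="span"):
            predict(model, session, np.array([1e4]), "SI")

    def test_marker_permutation_invariance(self, noisy_pair):
        first, _, _ = noisy_pair
        model = fit_model(first)
        perm = [3, 0, 4, 1, 2]
        from drifttrack import Session
        permuted = Session(ir=tuple(first.ir[i] for i in perm),
                           target=first.target, windows=first.windows)
        permuted_model = Model4D(
            coeffs={(k, ax): model.coeffs[(perm[k - 1] + 1, ax)]
                    for k in range(1, 6) for ax in AXES},
            smooth_win=model.smooth_win,
        )
        t = first.kv_times()[:50]
        assert np.allclose(predict(model, first, t, "SI"),
                           predict(permuted_model, permuted, t, "SI"), atol=1e-12)


class TestShift:
    def test_zero_shift_is_identity(self, clean_session):
        session, _ = clean_session
        model = fit_model(session)
        shifted = shift_model(model, 0.0)
        t = session.kv_times()[:100]
        assert np.array_equal(predict(model, session, t, "SI"),
                              predict(shifted, session, t, "SI"))

    def test_hand_arithmetic_quadratic(self):
        # f(x) = x^2 shifted by 2: f'(3) = (3-2)^2 = 1
        model = _uniform_model([1.0, 0, 0, 0, 0])
        shifted = expand_corrections(shift_model(model, 2.0))
        a, b, c, d, e = shifted.coeffs[(1, "SI")]
        assert a * 9 + b * 3 + c == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-2, 2), min_size=5, max_size=5),
           st.floats(-5, 5), st.floats(-8, 8), st.floats(-6, 6))
    def test_substitution_equals_coefficient_expansion(self, coeffs, s, x, v):
        """F{(x - s), v} via substitution == the expanded polynomial."""
        c = np.asarray(coeffs)
        expanded = np.array([c[0], c[1] - 2 * c[0] * s,
                             c[2] + c[0] * s * s - c[1] * s, c[3], c[4]])
        assert _quad(c, x - s, v) == pytest.approx(_quad(expanded, x, v), abs=1e-12)

    def test_expand_corrections_matches_prediction_path(self, clean_session):
        session, _ = clean_session
        model = fit_model(session)
        rng = np.random.default_rng(5)
        corrected = apply_bddetect(shift_model(model, rng.normal(0, 2, 5)),
                                   {"LR": 0.3, "AP": -0.7, "SI": 1.9})
        flat = expand_corrections(corrected)
        t = session.kv_times()[:200]
        for ax in AXES:
            assert np.allclose(predict(corrected, session, t, ax),
                               predict(flat, session, t, ax), atol=1e-10)


class TestBddetectOffset:
    def test_single_axis_offset_lowers_only_that_axis(self, clean_session):
        session, _ = clean_session
        model = fit_model(session)
        off = apply_bddetect(model, {"SI": 1.5})
        t = session.kv_times()[:50]
        assert np.allclose(predict(off, session, t, "SI"),
                           predict(model, session, t, "SI") - 1.5, atol=1e-12)
        assert np.array_equal(predict(off, session, t, "LR"),
                              predict(model, session, t, "LR"))

    def test_offset_then_inverse_restores(self, clean_session):
        session, _ = clean_session
        model = fit_model(session)
        back = apply_bddetect(apply_bddetect(model, {"AP": 0.8}), {"AP": -0.8})
        t = session.kv_times()[:50]
        assert np.allclose(predict(back, session, t, "AP"),
                           predict(model, session, t, "AP"), atol=1e-12)

    def test_shift_and_offset_commute(self, clean_session):
        session, _ = clean_session
        model = fit_model(session)
        a = apply_bddetect(shift_model(model, 1.2), {"SI": 0.5})
        b = shift_model(apply_bddetect(model, {"SI": 0.5}), 1.2)
        t = session.kv_times()[:50]
        assert np.array_equal(predict(a, session, t, "SI"),
                              predict(b, session, t, "SI"))


class TestSerialization:
    def test_json_round_trip(self, tmp_path, noisy_pair):
        first, _, _ = noisy_pair
        model = apply_bddetect(shift_model(fit_model(first), 0.7), {"SI": -0.4})
        path = tmp_path / "model.json"
        model.save(path)
        back = Model4D.load(path)
        for key in model.coeffs:
            assert np.array_equal(model.coeffs[key], back.coeffs[key])
        assert np.array_equal(model.bdir_mm, back.bdir_mm)
        assert model.bddetect_mm == back.bddetect_mm
        assert model.training_meta == back.training_meta
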