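"""Unit and property tests for the switched trial-by-trial engine."""

import logging
import math
from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from doadapt import (EngineState, Mode, ModelParams, TrialSpec,
                     TrialValidationError, gain_L, gain_psi, run, step,
                     records_to_frame, write_trace)
from doadapt.protocols import Phase, Protocol


def learn_trial(r=90.0, d=15.0, alpha=1.0, r_aim=0.0, overrides=None):
    return TrialSpec(Mode.LEARN, r, d=d, alpha=alpha, r_aim=r_aim,
                     overrides=overrides)


def run_learn(n, params, d=15.0, alpha=1.0, x0=90.0, r=90.0):
    proto = Protocol("learn_only",
                     (Phase("learn", n, learn_trial(r, d, alpha)),))
    return run(proto, params, EngineState(x=x0))


# ---------------------------------------------------------------------------
# sensitivity functions

@pytest.mark.parametrize("e, psi0, b_w, expected", [
    (123.0, 0.7, 0.0, 0.7),            # saturation disabled
    (0.0, 0.9, 0.5, 0.9),              # zero-error identity
    (-15.0, 1.0, 0.001, 1.0 / 1.015),  # direct evaluation
])
def test_gain_psi(e, psi0, b_w, expected):
    p = ModelParams(psi0=psi0, b_w=b_w)
    assert gain_psi(e, p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("u_im, L0, b_f, expected", [
    (0.0, 1.1, 0.2, 1.1),              # zero-input identity
    (-77.0, 1.1, 0.0, 1.1),            # saturation disabled
    (-45.0, 1.1, 0.01, 1.1 / 1.45),    # direct evaluation
])
def test_gain_L(u_im, L0, b_f, expected):
    p = ModelParams(L0=L0, b_f=b_f)
    assert gain_L(u_im, p) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# single-step semantics

def test_veridical_baseline_is_a_fixed_point(linear_params):
    state = EngineState(x=90.0)
    new, rec = step(state, learn_trial(d=0.0), linear_params)
    assert rec.y == 90.0 and rec.e == 0.0
    assert rec.u == 90.0 and new.x == 90.0


def test_first_perturbed_trial_places_cursor_at_105(linear_params):
    _, rec = step(EngineState(x=90.0), learn_trial(d=15.0), linear_params)
    assert rec.y == pytest.approx(105.0, abs=1e-12)
    assert rec.e == pytest.approx(-15.0, abs=1e-12)


def test_two_step_learn_recursion(linear_params):
    """Hand-computed two-trial recursion through the cursor-trial updates."""
    state = EngineState(x=90.0)
    state, r1 = step(state, learn_trial(), linear_params)
    assert r1.u_s == pytest.approx(-3.75, abs=1e-12)
    assert r1.w_hat == pytest.approx(-4.5, abs=1e-12)
    assert r1.u_im == pytest.approx(-4.5, abs=1e-12)
    assert r1.u == pytest.approx(81.75, abs=1e-12)
    assert r1.w0 == pytest.approx(-5.625, abs=1e-12)
    assert r1.x_f == pytest.approx(-0.495, abs=1e-12)
    _, r2 = step(state, learn_trial(), linear_params)
    assert r2.w_hat == pytest.approx(-7.65, abs=1e-12)
    # cross-check against the closed form -d (1 - F^j)
    assert r2.w_hat == pytest.approx(-15.0 * (1 - 0.7 ** 2), abs=1e-12)


def test_ignore_trial_updates_observer_silently(linear_params):
    """On Ignore trials the feedforward command is expressed but the
    observer still learns from the error (efference copy u - u_f = x_f)."""
    state = EngineState(x=90.0)
    _, rec = step(state, TrialSpec(Mode.IGNORE, 90.0, d=15.0, alpha=1.0),
                  linear_params)
    assert rec.u == pytest.approx(90.0)  # u_f + x_f with x_f = 0
    assert rec.y == pytest.approx(105.0) and rec.e == pytest.approx(-15.0)
    assert rec.w0 == pytest.approx(0.7 * 0.3 * (-15.0), abs=1e-12)


def test_no_cursor_decay_and_holds(linear_params):
    state = EngineState(x=80.0, w0=-5.0, x_f=-10.0, r_f=-2.0, j=3)
    new, rec = step(state, TrialSpec(Mode.NO_CURSOR_HAND, 90.0),
                    linear_params)
    assert new.x_f == pytest.approx(-10.0 * 0.95, abs=1e-15)
    assert new.w0 == -5.0 and new.r_f == -2.0 and new.j == 3
    assert rec.y is None and rec.e is None
    assert rec.u == pytest.approx(90.0 - 2.0 - 10.0)  # u_f + x_f


def test_zero_clamp_identical_to_no_cursor_hand(linear_params):
    state = EngineState(x=80.0, w0=-5.0, x_f=-10.0, r_f=-2.0, j=3,
                        mem_e=-1.0, mem_us=-0.25, mem_uim=-0.5)
    s1, r1 = step(state, TrialSpec(Mode.NO_CURSOR_HAND, 90.0), linear_params)
    s2, r2 = step(state, TrialSpec(Mode.ZERO_CLAMP, 90.0), linear_params)
    assert s1 == s2
    assert replace(r1, mode=Mode.ZERO_CLAMP) == r2


def test_no_cursor_cursor_replays_remembered_signals(linear_params):
    state = EngineState(x=80.0, j=5, mem_us=-3.75, mem_uim=-4.5, r_f=-1.0)
    _, rec = step(state, TrialSpec(Mode.NO_CURSOR_CURSOR, 90.0),
                  linear_params)
    assert rec.u == pytest.approx(90.0 - 1.0 - 3.75 - 4.5)


def test_no_cursor_cursor_before_any_cursor_trial_warns(linear_params, caplog):
    with caplog.at_level(logging.WARNING, logger="doadapt.model_core"):
        _, rec = step(EngineState(), TrialSpec(Mode.NO_CURSOR_CURSOR, 90.0),
                      linear_params)
    assert "before any cursor trial" in caplog.text
    assert rec.u == pytest.approx(90.0)  # remembered signals default to 0


def test_r_aim_is_additive_and_enters_the_efference_copy(linear_params):
    _, plain = step(EngineState(x=90.0), learn_trial(), linear_params)
    _, aimed = step(EngineState(x=90.0), learn_trial(r_aim=7.5),
                    linear_params)
    assert aimed.u == pytest.approx(plain.u + 7.5)
    # w0 update uses G (u - u_f), which includes the re-aim offset
    assert aimed.w0 == pytest.approx(plain.w0 + 0.3 * 7.5)


def test_trial_overrides_replace_params_for_one_trial(linear_params):
    _, rec = step(EngineState(x=90.0), learn_trial(overrides={"K": 0.5}),
                  linear_params)
    assert rec.u_s == pytest.approx(0.5 * -15.0)


@pytest.mark.parametrize("trial", [
    TrialSpec(Mode.LEARN, 90.0, alpha=1.0),           # missing d
    TrialSpec(Mode.IGNORE, 90.0, d=15.0),             # missing alpha
    TrialSpec(Mode.LEARN, 90.0, d=15.0, alpha=1.2),   # alpha out of range
    TrialSpec(Mode.ZERO_CLAMP, 90.0, d=15.0),         # clamp carries no d
    TrialSpec(Mode.NO_CURSOR_HAND, 90.0, alpha=1.0),  # alpha without cursor
])
def test_invalid_trials_rejected(trial, linear_params):
    with pytest.raises(TrialValidationError):
        step(EngineState(), trial, linear_params)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ModelParams(F=1.0)
    with pytest.raises(ValueError):
        ModelParams(psi0=0.0)
    with pytest.raises(ValueError):
        ModelParams().merged({"nope": 1.0})


# ---------------------------------------------------------------------------
# protocol runs

def test_empty_protocol_gives_empty_trace(linear_params):
    assert run(SimpleNamespace(phases=[]), linear_params) == []


def test_j_staircase(linear_params):
    proto = Protocol("stair", (
        Phase("a", 2, learn_trial()),
        Phase("b", 3, TrialSpec(Mode.NO_CURSOR_HAND, 90.0)),
        Phase("c", 1, learn_trial()),
    ))
    recs = run(proto, linear_params)
    assert [r.j for r in recs] == [1, 2, 2, 2, 2, 3]
    assert [r.k for r in recs] == [1, 2, 3, 4, 5, 6]


def test_closed_form_observer_trace(linear_params):
    """With linear gains, alpha=1 and no learning transfer, the recorded
    observer output is exactly -d (1 - F^j)."""
    recs = run_learn(100, linear_params, d=15.0)
    for rec in recs:
        expected = -15.0 * (1.0 - 0.7 ** rec.j)
        assert abs(rec.w_hat - expected) < 1e-10
    assert recs[-1].w_hat == pytest.approx(-15.0, abs=1e-6)


@given(K=st.floats(0.05, 0.95), A_f=st.floats(0.0, 0.95),
       L0=st.floats(0.5, 2.0), L_f=st.floats(0.0, 0.01),
       d=st.floats(-45.0, 45.0))
def test_observer_cancellation_recursion(K, A_f, L0, L_f, d):
    """For any Learn-only run with alpha=1 and constant d, the observer
    obeys w_hat(j+1) = F w_hat(j) + G (-d - r_f(k)) regardless of K, A_f,
    L0 — the motor command cancels out of the update."""
    params = ModelParams(K=K, F=0.7, psi0=1.0, b_w=0.0, A_f=A_f, L0=L0,
                         b_f=0.0, L_f=L_f)
    recs = run_learn(60, params, d=d)
    G = params.G
    for prev, cur in zip(recs, recs[1:]):
        r_f_prev = prev.u_f - prev.r  # r_f active when u(k) was issued
        predicted = 0.7 * prev.w_hat + G * (-d - r_f_prev)
        assert abs(cur.w_hat - predicted) < 1e-10


def test_observer_is_agnostic_to_learn_vs_ignore(linear_params):
    """Matched trial sequences differing only in the Learn/Ignore
    instruction produce identical observer outputs."""
    p = linear_params
    learn_recs = run_learn(80, p, d=15.0)
    proto = Protocol("ignore_only", (
        Phase("ignore", 80, TrialSpec(Mode.IGNORE, 90.0, d=15.0, alpha=1.0)),))
    ignore_recs = run(proto, p, EngineState(x=90.0))
    for a, b in zip(learn_recs, ignore_recs):
        assert abs(a.w_hat - b.w_hat) < 1e-10


def test_no_cursor_block_conserves_observer_and_slow_state(linear_params):
    state = EngineState(x=75.0, w0=-12.345678901234, x_f=-6.0,
                        r_f=-0.5, j=10)
    w0_before, r_f_before = state.w0, state.r_f
    for i in range(1, 11):
        state, _ = step(state, TrialSpec(Mode.NO_CURSOR_HAND, 90.0),
                        linear_params)
        assert state.x_f == pytest.approx(-6.0 * 0.95 ** i, rel=1e-12)
    assert state.w0 == w0_before  # bit-identical with F_n = 1
    assert state.r_f == r_f_before


def test_bounded_signals_over_long_runs():
    """Stable parameters keep every signal bounded for bounded d."""
    params = ModelParams(K=0.25, F=0.7, psi0=1.0, b_w=0.001, A_f=0.9,
                         L0=1.1, b_f=0.01, L_f=0.0001)
    recs = run_learn(100_000, params, d=-45.0)
    arr = np.array([[r.x, r.w_hat, r.x_f, r.r_f, r.u] for r in recs])
    assert np.all(np.isfinite(arr))
    assert np.abs(arr).max() < 1e3


# ---------------------------------------------------------------------------
# trace output

def test_trace_frame_and_csv(tmp_path, linear_params):
    proto = Protocol("mix", (
        Phase("learn", 2, learn_trial()),
        Phase("nc", 1, TrialSpec(Mode.NO_CURSOR_HAND, 90.0)),
    ))
    recs = run(proto, linear_params, EngineState(x=90.0))
    frame = records_to_frame(recs)
    assert list(frame.columns) == [
        "k", "j", "mode", "r", "d", "alpha", "r_aim", "x", "y", "e", "u",
        "u_s", "u_im", "u_f", "w_hat", "w0", "x_f", "r_f"]
    assert frame["y"].isna().tolist() == [False, False, True]

    path = tmp_path / "trace.csv"
    write_trace(recs, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 4
    # no-cursor row has empty y and e cells, numbers carry 6 decimals
    cells = lines[3].split(",")
    y_idx, e_idx = 8, 9
    assert cells[y_idx] == "" and cells[e_idx] == ""
    assert lines[1].split(",")[y_idx] == "105.000000"
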