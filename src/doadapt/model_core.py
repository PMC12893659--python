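"""Switched discrete-time engine for the disturbance-observer (DO) model.

The DO model describes trial-by-trial visuomotor adaptation as a unity
feedback loop closed through the participant's visual error.  On each trial
the brain issues a motor command ``u(k)`` that becomes the hand angle on the
next trial (trivial plant ``x(k+1) = u(k)``).  Three controller modules
contribute to ``u``:

* an error feedback ``u_s = K e`` (single-trial learning),
* a disturbance observer — a recurrent internal model of constant
  perturbations — with state ``w0``, output ``w_hat`` and motor contribution
  ``u_im = psi(e) * w_hat``,
* a feedforward system with a fast state ``x_f`` (trained by ``u_im``) and a
  slow state ``r_f`` (learning transfer), producing ``u_f = r + r_f``.

Which module is *expressed* in ``u`` depends on the trial modality (a "phase
switch"): on Learn trials the observer drives the hand, on Ignore and
no-cursor trials the feedforward system does, while the observer keeps
updating silently whenever a cursor (hence an error) is available.

All angles are plain degrees with no wraparound.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Mode",
    "ModelParams",
    "TrialSpec",
    "EngineState",
    "TrialRecord",
    "TrialValidationError",
    "gain_psi",
    "gain_L",
    "step",
    "run",
    "records_to_frame",
    "write_trace",
    "TRACE_COLUMNS",
]


class TrialValidationError(ValueError):
    """A trial specification violates the engine's contract."""


class Mode(str, enum.Enum):
    """Trial modality.

    LEARN / IGNORE show a cursor (the observer sees an error); the three
    no-cursor modes differ only in which remembered or feedforward signals
    build the motor command.  ZERO_CLAMP is computed identically to
    NO_CURSOR_HAND: the model treats zero-error-clamp trials as driven by
    the feedforward system.
    """

    LEARN = "LEARN"
    IGNORE = "IGNORE"
    NO_CURSOR_HAND = "NO_CURSOR_HAND"
    NO_CURSOR_CURSOR = "NO_CURSOR_CURSOR"
    ZERO_CLAMP = "ZERO_CLAMP"

    @property
    def shows_cursor(self) -> bool:
        return self in (Mode.LEARN, Mode.IGNORE)


@dataclass(frozen=True)
class ModelParams:
    """Constants of the DO model (all dimensionless except the saturation
    strengths, which are per degree).

    K      error-feedback sensitivity (single-trial learning), in (0,1)
    F      observer learning rate, in (0,1); G = 1 - F is derived, never set
    psi0   asymptotic learning proportion, in (0,1]; psi0 = 1 means the
           internal model principle is satisfied and the error is driven to 0
    b_w    observer saturation strength (per degree), >= 0
    A_f    feedforward learning rate, in [0,1)
    A_fn   feedforward retention on no-cursor trials, in (0,1]
    L0     feedforward sensitivity to u_im, > 0
    b_f    feedforward saturation strength (per degree), >= 0
    L_f    learning-transfer rate (x_f -> r_f), >= 0, typically << 1
    F_n    observer retention on no-cursor trials, in (0,1]; default 1 (hold)

    Defaults are the nominal parameter set for visuomotor reaching.
    """

    K: float = 0.25
    F: float = 0.7
    psi0: float = 1.0
    b_w: float = 0.001
    A_f: float = 0.9
    A_fn: float = 0.95
    L0: float = 1.1
    b_f: float = 0.01
    L_f: float = 0.0001
    F_n: float = 1.0

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.K < 1.0, "K must be in (0,1)"),
            (0.0 < self.F < 1.0, "F must be in (0,1)"),
            (0.0 < self.psi0 <= 1.0, "psi0 must be in (0,1]"),
            (self.b_w >= 0.0, "b_w must be >= 0"),
            (0.0 <= self.A_f < 1.0, "A_f must be in [0,1)"),
            (0.0 < self.A_fn <= 1.0, "A_fn must be in (0,1]"),
            (self.L0 > 0.0, "L0 must be > 0"),
            (self.b_f >= 0.0, "b_f must be >= 0"),
            (self.L_f >= 0.0, "L_f must be >= 0"),
            (0.0 < self.F_n <= 1.0, "F_n must be in (0,1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid ModelParams: {msg}")

    @property
    def G(self) -> float:
        """Observer input gain, fixed at 1 - F by the internal model principle."""
        return 1.0 - self.F

    def merged(self, overrides: dict | None) -> "ModelParams":
        """Return a copy with ``overrides`` (field name -> value) applied."""
        if not overrides:
            return self
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown ModelParams override(s): {sorted(unknown)}")
        return replace(self, **overrides)


@dataclass(frozen=True)
class TrialSpec:
    """One trial of an experiment.

    ``d`` (perturbation) and ``alpha`` (hand angle-gain) are meaningful
    exactly when the cursor is shown; ``r_aim`` is an additive explicit
    re-aiming offset available in any mode; ``overrides`` replace
    ``ModelParams`` fields for this trial only.
    """

    mode: Mode
    r: float
    d: float | None = None
    alpha: float | None = None
    r_aim: float = 0.0
    overrides: dict | None = None

    def validate(self) -> None:
        if not isinstance(self.mode, Mode):
            raise TrialValidationError(f"unknown trial mode: {self.mode!r}")
        if self.mode.shows_cursor:
            if self.d is None:
                raise TrialValidationError(
                    f"{self.mode.value} trial requires a perturbation d")
            if self.alpha is None:
                raise TrialValidationError(
                    f"{self.mode.value} trial requires a hand angle-gain alpha")
            if not 0.0 <= self.alpha <= 1.0:
                raise TrialValidationError(
                    f"alpha must be in [0,1], got {self.alpha}")
        else:
            if self.d is not None:
                raise TrialValidationError(
                    f"{self.mode.value} trial must not carry a perturbation d")
            if self.alpha is not None:
                raise TrialValidationError(
                    f"{self.mode.value} trial must not carry alpha")
        if self.overrides:
            ModelParams().merged(self.overrides)  # raises on unknown fields


@dataclass
class EngineState:
    """Brain + plant state threaded across trials.

    ``x`` is the hand angle executed on the current trial, ``w0`` the
    observer state, ``x_f``/``r_f`` the feedforward fast/slow states and
    ``j`` the count of cursor trials so far.  ``mem_*`` remember the error,
    error-feedback and observer commands of the most recent cursor trial so
    that a cursor-to-target reach can be produced after a no-cursor trial.
    All default to zero (the model's stated initialization); users may
    supply values for mid-experiment starts.
    """

    x: float = 0.0
    w0: float = 0.0
    x_f: float = 0.0
    r_f: float = 0.0
    j: int = 0
    mem_e: float = 0.0
    mem_us: float = 0.0
    mem_uim: float = 0.0
    mem_what: float = 0.0  # held observer output, for tracing only


@dataclass(frozen=True)
class TrialRecord:
    """Full per-trial trace of the engine.

    ``x`` is the hand angle executed on this trial; ``u`` the motor command
    for the next trial; ``y``/``e`` are None on trials without a cursor;
    ``w0``, ``x_f``, ``r_f`` are the post-update states; ``w_hat`` is the
    observer output (held at its last cursor-trial value on no-cursor
    trials).
    """

    k: int
    j: int
    mode: Mode
    r: float
    d: float | None
    alpha: float | None
    r_aim: float
    x: float
    y: float | None
    e: float | None
    u: float
    u_s: float
    u_im: float
    u_f: float
    w_hat: float
    w0: float
    x_f: float
    r_f: float
    phase: str | None = None


def gain_psi(e: float, params: ModelParams) -> float:
    """Observer error-sensitivity psi(e) = psi0 / (1 + b_w |e|).

    Saturates the observer's expressed output for large errors; with
    b_w = 0 it is the constant psi0 (linear model).
    """
    return params.psi0 / (1.0 + params.b_w * abs(e))


def gain_L(u_im: float, params: ModelParams) -> float:
    """Feedforward sensitivity L(u_im) = L0 / (1 + b_f |u_im|).

    Shapes the plateau of the feedforward system under (graded) error-clamp
    conditions; with b_f = 0 it is the constant L0.
    """
    return params.L0 / (1.0 + params.b_f * abs(u_im))


def step(state: EngineState, trial: TrialSpec,
         params: ModelParams) -> tuple[EngineState, TrialRecord]:
    """Advance the DO model by one trial.

    Cursor trials (LEARN, IGNORE) increment j, place the cursor
    ``y = r + alpha (x - r) + d``, compute the visual error ``e = r - y``
    and update every module; the motor command expresses the observer
    (LEARN) or the feedforward state (IGNORE).  No-cursor trials produce no
    error: the observer state is retained (scaled by F_n), the feedforward
    fast state decays by A_fn and the command replays either the remembered
    cursor-trial signals (NO_CURSOR_CURSOR) or the feedforward state.

    Returns the post-trial state and a TrialRecord (k is filled in by
    :func:`run`; standalone calls get k = 0).
    """
    trial.validate()
    p = params.merged(trial.overrides)

    if trial.mode.shows_cursor:
        j = state.j + 1
        y = trial.r + trial.alpha * (state.x - trial.r) + trial.d
        e = trial.r - y
        u_s = p.K * e
        w_hat = state.w0 + p.G * e
        u_im = gain_psi(e, p) * w_hat
        u_f = trial.r + state.r_f
        if trial.mode is Mode.LEARN:
            u = u_f + u_s + u_im + trial.r_aim
        else:  # IGNORE: observer updates silently, feedforward is expressed
            u = u_f + state.x_f + trial.r_aim
        w0_next = p.F * state.w0 + p.F * p.G * e + p.G * (u - u_f)
        x_f_next = p.A_f * state.x_f + (1.0 - p.A_f) * gain_L(u_im, p) * u_im
        r_f_next = state.r_f + p.L_f * state.x_f
        new_state = EngineState(
            x=u, w0=w0_next, x_f=x_f_next, r_f=r_f_next, j=j,
            mem_e=e, mem_us=u_s, mem_uim=u_im, mem_what=w_hat)
        record = TrialRecord(
            k=0, j=j, mode=trial.mode, r=trial.r, d=trial.d,
            alpha=trial.alpha, r_aim=trial.r_aim, x=state.x, y=y, e=e,
            u=u, u_s=u_s, u_im=u_im, u_f=u_f, w_hat=w_hat,
            w0=w0_next, x_f=x_f_next, r_f=r_f_next)
        return new_state, record

    # no cursor: no error, observer quiescent, feedforward expressed
    u_f = trial.r + state.r_f
    if trial.mode is Mode.NO_CURSOR_CURSOR:
        if state.j == 0:
            logger.warning(
                "NO_CURSOR_CURSOR trial before any cursor trial: remembered "
                "signals are zero")
        u = u_f + state.mem_us + state.mem_uim + trial.r_aim
    else:  # NO_CURSOR_HAND and ZERO_CLAMP are computed identically
        u = u_f + state.x_f + trial.r_aim
    w0_next = p.F_n * state.w0
    x_f_next = p.A_fn * state.x_f
    r_f_next = state.r_f
    new_state = EngineState(
        x=u, w0=w0_next, x_f=x_f_next, r_f=r_f_next, j=state.j,
        mem_e=state.mem_e, mem_us=state.mem_us, mem_uim=state.mem_uim,
        mem_what=state.mem_what)
    record = TrialRecord(
        k=0, j=state.j, mode=trial.mode, r=trial.r, d=None, alpha=None,
        r_aim=trial.r_aim, x=state.x, y=None, e=None, u=u,
        u_s=state.mem_us, u_im=state.mem_uim, u_f=u_f,
        w_hat=state.mem_what, w0=w0_next, x_f=x_f_next, r_f=r_f_next)
    return new_state, record


def run(protocol, params: ModelParams,
        init: EngineState | None = None) -> list[TrialRecord]:
    """Simulate a full protocol, threading the engine state through every
    trial.  Phase-level parameter overrides are merged before trial-level
    ones.  Deterministic given its inputs.  Returns one record per trial
    (k = 1..N) annotated with the phase label.
    """
    state = init if init is not None else EngineState()
    records: list[TrialRecord] = []
    k = 0
    prev_mode: Mode | None = None
    for phase in protocol.phases:
        phase_params = params.merged(phase.overrides)
        for _ in range(phase.n_trials):
            k += 1
            trial = phase.template
            if prev_mode is not None and trial.mode is not prev_mode:
                logger.info("trial %d: mode switch %s -> %s (phase %r)",
                            k, prev_mode.value, trial.mode.value, phase.label)
            prev_mode = trial.mode
            try:
                state, rec = step(state, trial, phase_params)
            except TrialValidationError as err:
                raise TrialValidationError(
                    f"phase {phase.label!r}, trial {k}: {err}") from err
            records.append(replace(rec, k=k, phase=phase.label))
    return records


TRACE_COLUMNS = ["k", "j", "mode", "r", "d", "alpha", "r_aim", "x", "y", "e",
                 "u", "u_s", "u_im", "u_f", "w_hat", "w0", "x_f", "r_f"]


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tabulate records; y/e (and d/alpha) are NaN on no-cursor trials."""
    rows = []
    for rec in records:
        rows.append({
            "k": rec.k, "j": rec.j, "mode": rec.mode.value, "r": rec.r,
            "d": rec.d, "alpha": rec.alpha, "r_aim": rec.r_aim, "x": rec.x,
            "y": rec.y, "e": rec.e, "u": rec.u, "u_s": rec.u_s,
            "u_im": rec.u_im, "u_f": rec.u_f, "w_hat": rec.w_hat,
            "w0": rec.w0, "x_f": rec.x_f, "r_f": rec.r_f,
        })
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def write_trace(records: Sequence[TrialRecord], path) -> None:
    """Write the CSV trace (6 decimal places, empty cells where undefined)."""
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, float_format="%.6f")
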