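"""Reference model variants: the preliminary observer-only model, its
reduced two-state (error / estimate) form, the canonical two-rate model,
and the saccadic-amplitude variant.

The preliminary model is the DO model restricted to Learn trials with
alpha = 1 and no feedforward system.  Two coordinate transformations take
it to the reduced model, whose states are the visual error e (evolving in
the world) and the observer estimate w_hat (a brain state) — a variant of
the classic two-rate model with physically meaningful states.  The
saccadic variant adapts the same observer to intersaccadic-step paradigms,
where the error convention is e = r + d - x (the perturbation moves the
required amplitude, not the feedback).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model_core import ModelParams, TrialRecord, gain_psi

__all__ = [
    "ObserverState",
    "ReducedState",
    "TwoRateParams",
    "TwoRateState",
    "SACCADIC_PARAMS",
    "preliminary_step",
    "preliminary_run",
    "reduced_step",
    "reduced_run",
    "to_reduced",
    "initial_reduced_state",
    "two_rate_step",
    "saccadic_step",
    "saccadic_run",
]


@dataclass(frozen=True)
class ObserverState:
    """Plant + observer state for the preliminary and saccadic variants."""
    x: float = 0.0
    w0: float = 0.0


@dataclass(frozen=True)
class ReducedState:
    """Reduced closed-loop coordinates: fast state e, slow state w_hat."""
    e: float = 0.0
    w_hat: float = 0.0


@dataclass(frozen=True)
class VariantRecord:
    """Per-trial trace of a variant model."""
    x: float
    y: float | None
    e: float
    u_s: float
    w_hat: float
    u_im: float
    u: float
    w0: float  # post-update


def preliminary_step(state: ObserverState, r: float, d: float,
                     params: ModelParams) -> tuple[ObserverState, VariantRecord]:
    """One Learn trial of the observer-only model (alpha = 1, no feedforward).

    u = r + K e + psi0 w_hat with e = r - x - d; the observer state update
    uses the efference copy u - r.
    """
    p = params
    e = r - state.x - d
    u_s = p.K * e
    w_hat = state.w0 + p.G * e
    u_im = p.psi0 * w_hat
    u = r + u_s + u_im
    w0_next = p.F * state.w0 + p.F * p.G * e + p.G * (u - r)
    rec = VariantRecord(x=state.x, y=state.x + d, e=e, u_s=u_s, w_hat=w_hat,
                        u_im=u_im, u=u, w0=w0_next)
    return ObserverState(x=u, w0=w0_next), rec


def preliminary_run(n: int, r: float, d: float, params: ModelParams,
                    init: ObserverState | None = None) -> list[VariantRecord]:
    state = init if init is not None else ObserverState()
    out = []
    for _ in range(n):
        state, rec = preliminary_step(state, r, d, params)
        out.append(rec)
    return out


def reduced_step(state: ReducedState, d: float,
                 params: ModelParams) -> ReducedState:
    """Reduced closed-loop update for constant r, d:

    e' = -K e - psi0 w_hat - d,    w_hat' = F w_hat - G d.
    """
    p = params
    return ReducedState(
        e=-p.K * state.e - p.psi0 * state.w_hat - d,
        w_hat=p.F * state.w_hat - p.G * d,
    )


def reduced_run(n: int, d: float, params: ModelParams,
                init: ReducedState | None = None) -> list[ReducedState]:
    """Iterate :func:`reduced_step`; returns states *including* the initial
    one, so entry i is the reduced state on trial i+1."""
    state = init if init is not None else ReducedState()
    out = [state]
    for _ in range(n - 1):
        state = reduced_step(state, d, params)
        out.append(state)
    return out


def to_reduced(records: Sequence[VariantRecord | TrialRecord], r: float,
               d: float) -> list[ReducedState]:
    """Map a preliminary-model (or equivalent full-model) trace to reduced
    coordinates (e, w_hat).  Under constant r, d and alpha = 1 the mapped
    sequence equals the reduced_step iteration from matched initial
    conditions."""
    return [ReducedState(e=rec.e, w_hat=rec.w_hat) for rec in records]


def initial_reduced_state(x0: float, w0: float, r: float, d: float,
                          params: ModelParams) -> ReducedState:
    """Change of variables from (x, w0) to (e, w_hat) on the first trial."""
    e0 = r - x0 - d
    return ReducedState(e=e0, w_hat=w0 + params.G * e0)


@dataclass(frozen=True)
class TwoRateParams:
    """Free parameters of the canonical two-rate model.  A_s close to 1
    realizes the internal model (exosystem) of constant disturbances."""
    A_f: float = 0.8
    B_f: float = 0.2
    A_s: float = 0.99
    B_s: float = 0.01

    def __post_init__(self) -> None:
        if self.A_s > 1.0:
            raise ValueError("two-rate slow retention A_s must be <= 1")


@dataclass(frozen=True)
class TwoRateState:
    x_fast: float = 0.0
    x_slow: float = 0.0

    @property
    def output(self) -> float:
        return self.x_fast + self.x_slow


def two_rate_step(state: TwoRateState, e: float,
                  params: TwoRateParams) -> TwoRateState:
    """Canonical two-rate update: both states driven by the same error."""
    return TwoRateState(
        x_fast=params.A_f * state.x_fast + params.B_f * e,
        x_slow=params.A_s * state.x_slow + params.B_s * e,
    )


#: nominal parameters for the saccadic system (intersaccadic-step paradigm)
SACCADIC_PARAMS = ModelParams(K=0.22, F=0.9, psi0=0.95, b_w=0.0,
                              A_f=0.0, A_fn=1.0, L0=1.1, b_f=0.0,
                              L_f=0.0, F_n=1.0)


def saccadic_step(state: ObserverState, r: float, d: float,
                  params: ModelParams = SACCADIC_PARAMS,
                  ) -> tuple[ObserverState, VariantRecord]:
    """One trial of the saccadic-system variant.

    The perturbation shifts the *required* amplitude, so the error
    convention is e = r + d - x (the reach model uses e = r - y).  The
    feedforward term is the fixed nominal amplitude r; the observer's
    sensitivity psi uses the current-trial error.
    """
    p = params
    e = r + d - state.x
    w_hat = state.w0 + p.G * e
    u_s = p.K * e
    u_im = gain_psi(e, p) * w_hat
    u = r + u_s + u_im
    w0_next = p.F * state.w0 + p.F * p.G * e + p.G * (u_s + u_im)
    rec = VariantRecord(x=state.x, y=None, e=e, u_s=u_s, w_hat=w_hat,
                        u_im=u_im, u=u, w0=w0_next)
    return ObserverState(x=u, w0=w0_next), rec


def saccadic_run(schedule: Sequence[float], r: float,
                 params: ModelParams = SACCADIC_PARAMS,
                 init: ObserverState | None = None) -> list[VariantRecord]:
    """Simulate a saccadic perturbation schedule (one d per trial)."""
    state = init if init is not None else ObserverState()
    out = []
    for d in schedule:
        state, rec = saccadic_step(state, r, d, params)
        out.append(rec)
    return out
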