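"""Closed-form steady states, stability / internal-model diagnostics, and
behavioral summary statistics (bias correction, phase summaries).

The Learn-mode loop with the slow feedforward correction r_f frozen at 0
admits a closed-form fixed point.  With hand angle-gain alpha and constant
perturbation d the steady-state visual error is

    e_ss = -d (1 - psi0) / [(1 - psi0) + alpha (K + psi0)]

with the complete-learning limit e_ss = 0 when psi0 = 1, in which case the
hand deviation is x_ss - r = -d / alpha (the graded-error-clamp
prediction).  The internal model principle requires the observer eigenvalue
S = F + G psi0 to equal 1, which given G = 1 - F holds exactly when
psi0 = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import ModelParams, TrialRecord, gain_psi

__all__ = [
    "SteadyState",
    "StabilityReport",
    "ClampConditionError",
    "steady_state_learn",
    "closed_form_w_hat",
    "internal_model_check",
    "bias_correct",
    "phase_summary",
    "summarize_phases",
]


class ClampConditionError(ValueError):
    """alpha = 0 with psi0 = 1: the Learn loop has no finite fixed point
    (full error clamp with complete learning diverges linearly)."""


@dataclass(frozen=True)
class SteadyState:
    e_ss: float
    x_dev_ss: float  # x_ss - r
    w_hat_ss: float


@dataclass(frozen=True)
class StabilityReport:
    stable: bool
    S: float  # internal-model eigenvalue F + G * psi0
    im_satisfied: bool


def _linear_fixed_point(K: float, psi: float, alpha: float,
                        d: float) -> SteadyState:
    denom = (1.0 - psi) + alpha * (K + psi)
    if denom == 0.0:
        raise ClampConditionError(
            "no finite fixed point: alpha = 0 with psi0 = 1 (clamp condition)")
    e_ss = -d * (1.0 - psi) / denom
    if psi == 1.0:
        x_dev = 0.0 if alpha == 0.0 else -d / alpha
    else:
        x_dev = (K + psi) / (1.0 - psi) * e_ss
    return SteadyState(e_ss=e_ss, x_dev_ss=x_dev, w_hat_ss=e_ss + x_dev)


def steady_state_learn(params: ModelParams, r: float, d: float,
                       alpha: float, tol: float = 1e-10,
                       max_iter: int = 100_000) -> SteadyState:
    """Fixed point of the Learn-mode loop with r_f frozen at 0.

    In the linear regime (b_w = 0) the closed form above is returned.  With
    the observer saturation active (b_w > 0) the fixed point solves
    e = -d - alpha (K + psi(e)) / (1 - psi(e)) e with psi(e) =
    psi0 / (1 + b_w |e|); it is found by damped fixed-point iteration.
    The b_f saturation does not enter: x_f is not expressed on Learn trials
    and r_f is frozen.
    """
    if params.b_w == 0.0:
        return _linear_fixed_point(params.K, params.psi0, alpha, d)
    if alpha == 0.0 and params.psi0 == 1.0:
        raise ClampConditionError(
            "no finite fixed point: alpha = 0 with psi0 = 1 (clamp condition)")
    e = -d  # first-trial error from the baseline posture
    for _ in range(max_iter):
        psi = gain_psi(e, params)
        one_minus = 1.0 - psi
        if one_minus <= 0.0:
            raise ClampConditionError(
                "no finite fixed point: psi(e) reached 1 during iteration")
        target = -d / (1.0 + alpha * (params.K + psi) / one_minus)
        e_next = 0.5 * e + 0.5 * target
        if abs(e_next - e) < tol:
            e = e_next
            break
        e = e_next
    else:
        raise RuntimeError("saturated fixed-point iteration did not converge")
    psi = gain_psi(e, params)
    x_dev = (params.K + psi) / (1.0 - psi) * e
    return SteadyState(e_ss=e, x_dev_ss=x_dev, w_hat_ss=e + x_dev)


def closed_form_w_hat(j: int, d: float, F: float) -> float:
    """Observer output after j cursor trials in the linear Learn-only regime
    (alpha = 1, r_f = 0): w_hat(j) = -d (1 - F**j), telescoping the stable
    filter w_hat(j+1) = F w_hat(j) - G d."""
    return -d * (1.0 - F ** j)


def internal_model_check(params: ModelParams) -> StabilityReport:
    """Internal-model eigenvalue S = F + (1-F) psi0 and stability ranges.

    S = 1 (within 1e-12) means the observer embeds an exact internal model
    of constant perturbations, hence zero steady-state error; stability of
    the loop requires K and F in (0,1) (always true for valid ModelParams,
    reported for user-supplied edge cases)."""
    S = params.F + params.G * params.psi0
    stable = 0.0 < params.K < 1.0 and 0.0 < params.F < 1.0
    return StabilityReport(stable=stable, S=S,
                           im_satisfied=abs(S - 1.0) < 1e-12)


def bias_correct(deviations: Sequence[float], baseline_slice: slice,
                 window: int = 20) -> np.ndarray:
    """Subtract each participant's baseline bias — the mean reach deviation
    over the last ``window`` trials of the baseline phase — from every trial."""
    dev = np.asarray(deviations, dtype=float)
    baseline = dev[baseline_slice]
    if len(baseline) < window:
        raise ValueError(
            f"baseline has {len(baseline)} trials, fewer than window={window}")
    return dev - baseline[-window:].mean()


def phase_summary(records: Sequence[TrialRecord], label: str,
                  last_n: int = 10) -> float:
    """Mean reach deviation x - r over the final ``last_n`` trials of the
    named phase (aftereffect / asymptote readout)."""
    devs = [rec.x - rec.r for rec in records if rec.phase == label]
    if not devs:
        raise KeyError(f"no phase labelled {label!r} in the trace")
    if len(devs) < last_n:
        raise ValueError(
            f"phase {label!r} has {len(devs)} trials, fewer than last_n={last_n}")
    return float(np.mean(devs[-last_n:]))


def summarize_phases(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-phase mean and SD of the reach deviation, in trace order.

    Columns: phase (index), label, n, mean_dev, sd_dev.
    """
    rows = []
    seen: list[str] = []
    for rec in records:
        if rec.phase not in seen:
            seen.append(rec.phase)
    for i, label in enumerate(seen, start=1):
        devs = np.array([r.x - r.r for r in records if r.phase == label])
        rows.append({"phase": i, "label": label, "n": len(devs),
                     "mean_dev": devs.mean(),
                     "sd_dev": devs.std(ddof=1) if len(devs) > 1 else 0.0})
    return pd.DataFrame(rows, columns=["phase", "label", "n", "mean_dev",
                                       "sd_dev"])
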