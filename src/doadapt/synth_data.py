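"""Synthetic behavioral data: noisy participants, cohorts, aggregates and
parameter recovery.

The generator wraps the deterministic engine with the two ingredients real
reach data adds: per-trial motor execution noise (Gaussian, applied to the
hand angle *before* cursor placement, so it propagates into the cursor and
the visual error) and per-participant parameter jitter.  Cohort aggregates
follow the behavioral pipeline: per-participant baseline bias correction
(mean over the last 20 baseline trials) before averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import analysis
from .model_core import (EngineState, Mode, ModelParams, TrialRecord,
                         TrialValidationError, step, write_trace)
from .protocols import Protocol

__all__ = [
    "NoiseSpec",
    "CohortTrace",
    "simulate_participant",
    "simulate_cohort",
    "aggregate",
    "recover_observer_params",
    "export_cohort",
]

#: baseline window (trials) used for bias correction
BIAS_WINDOW = 20


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for synthetic participants.

    motor_sd      SD of per-trial hand-angle execution noise (degrees)
    param_jitter  optional per-participant multiplicative jitter: field name
                  -> (low, high) factor range, drawn once per participant
    seed          master random seed
    """

    motor_sd: float = 2.0
    param_jitter: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motor_sd < 0:
            raise ValueError("motor_sd must be >= 0")


@dataclass(frozen=True)
class CohortTrace:
    """Per-participant traces plus the bias-corrected aggregate."""

    participants: tuple  # tuple of per-participant TrialRecord lists
    corrected: np.ndarray  # (n_participants, n_trials) bias-corrected devs
    mean_dev: np.ndarray  # bias-corrected cohort mean
    se_dev: np.ndarray
    raw_mean_dev: np.ndarray  # uncorrected cohort mean (for model fitting)
    params: tuple  # per-participant ModelParams actually used

    @property
    def n(self) -> int:
        return len(self.participants)


def _jittered(params: ModelParams, jitter: dict | None,
              rng: np.random.Generator) -> ModelParams:
    if not jitter:
        return params
    updates = {}
    for name, (lo, hi) in jitter.items():
        updates[name] = getattr(params, name) * rng.uniform(lo, hi)
    return params.merged(updates)


def simulate_participant(protocol: Protocol, params: ModelParams,
                         noise: NoiseSpec,
                         init: EngineState | None = None) -> list[TrialRecord]:
    """Simulate one noisy participant.

    The hand angle executed on each trial is the previous motor command
    plus Gaussian motor noise; the noise is injected before cursor
    placement so it perturbs y, e and every downstream update.  With
    motor_sd = 0 this reproduces the deterministic engine exactly.
    Deterministic given the NoiseSpec seed.
    """
    rng = np.random.default_rng(noise.seed)
    state = init if init is not None else EngineState()
    records: list[TrialRecord] = []
    k = 0
    for phase in protocol.phases:
        phase_params = params.merged(phase.overrides)
        for _ in range(phase.n_trials):
            k += 1
            if noise.motor_sd > 0:
                state = replace(
                    state, x=state.x + rng.normal(0.0, noise.motor_sd))
            try:
                state, rec = step(state, phase.template, phase_params)
            except TrialValidationError as err:
                raise TrialValidationError(
                    f"phase {phase.label!r}, trial {k}: {err}") from err
            records.append(replace(rec, k=k, phase=phase.label))
    return records


def _baseline_slice(protocol: Protocol) -> slice:
    # bias correction uses the protocol's opening phase as the baseline
    return slice(0, protocol.phases[0].n_trials)


def simulate_cohort(protocol: Protocol, params: ModelParams, n: int,
                    noise: NoiseSpec) -> CohortTrace:
    """Simulate n participants with independent seeds (master seed + index)
    and per-participant parameter jitter, then aggregate after bias
    correction."""
    if n < 1:
        raise ValueError("n must be >= 1")
    participants = []
    used_params = []
    for i in range(n):
        pseed = noise.seed + i
        jitter_rng = np.random.default_rng(pseed)
        p_i = _jittered(params, noise.param_jitter, jitter_rng)
        trace = simulate_participant(
            protocol, p_i, replace(noise, seed=pseed))
        participants.append(trace)
        used_params.append(p_i)
    corrected, mean_dev, se_dev = aggregate(
        participants, baseline=_baseline_slice(protocol))
    raw = np.array([[rec.x - rec.r for rec in t] for t in participants])
    return CohortTrace(participants=tuple(participants), corrected=corrected,
                       mean_dev=mean_dev, se_dev=se_dev,
                       raw_mean_dev=raw.mean(axis=0),
                       params=tuple(used_params))


def aggregate(traces: Sequence[Sequence[TrialRecord]],
              baseline: slice) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-wise mean and standard error of bias-corrected reach
    deviations.  All traces must have the same length."""
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"trace length mismatch: {sorted(lengths)}")
    devs = np.array([[rec.x - rec.r for rec in trace] for trace in traces])
    corrected = np.array([
        analysis.bias_correct(row, baseline, window=BIAS_WINDOW)
        for row in devs])
    mean_dev = corrected.mean(axis=0)
    n = corrected.shape[0]
    if n > 1:
        se_dev = corrected.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se_dev = np.zeros_like(mean_dev)
    return corrected, mean_dev, se_dev


def predict_learn_devs(n_trials: int, d: float, K, F, psi0) -> np.ndarray:
    """Noiseless reach-deviation prediction for a Learn phase (alpha = 1,
    linear gains, feedforward transfer off), broadcast over parameter
    grids.  Entry t along the first axis is the deviation executed on trial
    t+1 of the phase, starting from the adapted-baseline posture x = r."""
    K, F, psi0 = np.broadcast_arrays(np.asarray(K, float),
                                     np.asarray(F, float),
                                     np.asarray(psi0, float))
    G = 1.0 - F
    dev = np.zeros(K.shape)
    w0 = np.zeros(K.shape)
    out = np.empty((n_trials,) + K.shape)
    for t in range(n_trials):
        out[t] = dev
        e = -dev - d
        u_s = K * e
        u_im = psi0 * (w0 + G * e)
        w0 = F * w0 + F * G * e + G * (u_s + u_im)
        dev = u_s + u_im
    return out


def recover_observer_params(mean_dev: np.ndarray, d: float,
                            K_grid: np.ndarray | None = None,
                            F_grid: np.ndarray | None = None,
                            psi0_grid: np.ndarray | None = None,
                            ) -> tuple[float, float, float]:
    """Grid-search least-squares recovery of (K, F, psi0) from a cohort
    mean reach-deviation series over an alpha = 1 Learn phase.

    ``mean_dev`` is the *uncorrected* cohort mean over the rotation phase
    only (its first entry is the still-unadapted trial; use
    ``CohortTrace.raw_mean_dev``, since baseline bias correction would
    inject a constant offset into the inferred error sequence).  Because
    each trial's motor command is a deterministic function of the errors
    the participant actually observed, the one-step-ahead prediction
    driven by the observed deviations has independent residuals (pure
    motor noise); the grids are scored by that conditional sum of squares.
    By linearity of the Learn loop the same holds for the cohort mean.  No
    iterative optimizer is involved.
    """
    if K_grid is None:
        K_grid = np.arange(0.05, 0.951, 0.01)
    if F_grid is None:
        F_grid = np.arange(0.05, 0.951, 0.01)
    if psi0_grid is None:
        psi0_grid = np.arange(0.80, 1.0001, 0.01)
    mean_dev = np.asarray(mean_dev, dtype=float)
    Kg = np.asarray(K_grid)[:, None, None]
    Fg = np.asarray(F_grid)[None, :, None]
    Pg = np.asarray(psi0_grid)[None, None, :]
    Kb, Fb, Pb = np.broadcast_arrays(Kg, Fg, Pg)
    G = 1.0 - Fb
    w0 = np.zeros(Kb.shape)
    sse = np.zeros(Kb.shape)
    for t in range(len(mean_dev) - 1):
        e = -mean_dev[t] - d  # error the cohort actually observed
        u_s = Kb * e
        u_im = Pb * (w0 + G * e)
        pred = u_s + u_im  # commanded deviation for the next trial
        sse += (mean_dev[t + 1] - pred) ** 2
        w0 = Fb * w0 + Fb * G * e + G * pred
    i, jj, m = np.unravel_index(np.argmin(sse), sse.shape)
    return (float(np.asarray(K_grid)[i]), float(np.asarray(F_grid)[jj]),
            float(min(np.asarray(psi0_grid)[m], 1.0)))


def export_cohort(cohort: CohortTrace, protocol: Protocol,
                  params: ModelParams, noise: NoiseSpec, out_dir) -> None:
    """Write one trace CSV per participant, an aggregate CSV
    (trial, mean_dev, se_dev) and a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, trace in enumerate(cohort.participants, start=1):
        write_trace(trace, out / f"participant_{i:03d}.csv")
    import pandas as pd
    agg = pd.DataFrame({
        "trial": np.arange(1, len(cohort.mean_dev) + 1),
        "mean_dev": cohort.mean_dev,
        "se_dev": cohort.se_dev,
    })
    agg.to_csv(out / "aggregate.csv", index=False, float_format="%.6f")
    manifest = {
        "protocol": protocol.name,
        "n_participants": cohort.n,
        "params": {k: getattr(params, k) for k in (
            "K", "F", "psi0", "b_w", "A_f", "A_fn", "L0", "b_f", "L_f",
            "F_n")},
        "noise": {"motor_sd": noise.motor_sd,
                  "param_jitter": noise.param_jitter,
                  "seed": noise.seed},
        "participant_seeds": [noise.seed + i for i in range(cohort.n)],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
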