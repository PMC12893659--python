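"""Experiment protocols: named builders, validation and serialization.

A :class:`Protocol` is an ordered list of :class:`Phase` blocks, each
repeating one :class:`~doadapt.model_core.TrialSpec` for ``n_trials`` and
optionally overriding model parameters for its duration.  Builders
reproduce the designs used to probe the DO model: graded-error-clamp
experiments (Ignore-N / Learn-N / Ignore-W / Learn-W), spontaneous and
evoked recovery, three savings paradigms, error clamp and
cursor/no-cursor alternation.

Targets are normalized to a single direction r = 90 degrees; the
multi-target randomization of the human experiments is not modeled.
Baseline and washout trials are Learn trials with veridical feedback
(d = 0, alpha = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import yaml

from .model_core import Mode, ModelParams, TrialSpec, TrialValidationError

__all__ = [
    "Phase",
    "Protocol",
    "ValidationIssue",
    "ValidationReport",
    "ProtocolError",
    "build_experiment",
    "available_protocols",
    "validate",
    "save",
    "load",
    "loads",
]

SCHEMA_VERSION = 1

#: single normalized target direction (degrees)
TARGET = 90.0


class ProtocolError(ValueError):
    """Raised on unknown builder names, bad options or malformed documents."""


@dataclass(frozen=True)
class Phase:
    label: str
    n_trials: int
    template: TrialSpec
    overrides: dict | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ProtocolError(f"phase {self.label!r}: n_trials must be >= 1")


@dataclass(frozen=True)
class Protocol:
    name: str
    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ProtocolError(f"protocol {self.name!r} has no phases")
        object.__setattr__(self, "phases", tuple(self.phases))

    @property
    def n_trials(self) -> int:
        return sum(p.n_trials for p in self.phases)


@dataclass(frozen=True)
class ValidationIssue:
    phase: str
    trial: int  # 1-based global trial index of the first offending trial
    message: str


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    issues: tuple[ValidationIssue, ...]


def validate(protocol: Protocol) -> ValidationReport:
    """Check every trial's invariants; report the first violation per phase."""
    issues = []
    k = 0
    for phase in protocol.phases:
        first = k + 1
        k += phase.n_trials
        try:
            phase.template.validate()
        except TrialValidationError as err:
            issues.append(ValidationIssue(phase.label, first, str(err)))
            continue
        if phase.overrides:
            try:
                ModelParams().merged(phase.overrides)
            except ValueError as err:
                issues.append(ValidationIssue(phase.label, first, str(err)))
    return ValidationReport(valid=not issues, issues=tuple(issues))


# ---------------------------------------------------------------------------
# phase helpers

def _learn(label: str, n: int, d: float, alpha: float = 1.0,
           r_aim: float = 0.0, overrides: dict | None = None) -> Phase:
    return Phase(label, n, TrialSpec(Mode.LEARN, TARGET, d=d, alpha=alpha,
                                     r_aim=r_aim), overrides)


def _ignore(label: str, n: int, d: float, alpha: float = 1.0,
            overrides: dict | None = None) -> Phase:
    return Phase(label, n, TrialSpec(Mode.IGNORE, TARGET, d=d, alpha=alpha),
                 overrides)


def _no_cursor(label: str, n: int) -> Phase:
    return Phase(label, n, TrialSpec(Mode.NO_CURSOR_HAND, TARGET))


def _baseline(n: int = 40) -> Phase:
    # veridical feedback, cursor-to-target instruction, alpha = 1
    return _learn("baseline", n, d=0.0, alpha=1.0)


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ProtocolError(f"alpha must be in [0,1], got {alpha}")


def _default_d15(alpha: float) -> float:
    # rotation sign convention of the graded-clamp study:
    # -15 deg for alpha in {1.0, 0.6}, +15 deg for alpha in {0.8, 0.4}
    return 15.0 if alpha in (0.8, 0.4) else -15.0


# ---------------------------------------------------------------------------
# builders

def exp1_ignore_n(alpha: float = 1.0, d: float | None = None) -> Protocol:
    """Ignore-N: 40 baseline + 100 Ignore (160 for alpha=0.4) + 40 no-cursor."""
    _check_alpha(alpha)
    if d is None:
        d = _default_d15(alpha)
    n_rot = 160 if alpha == 0.4 else 100
    return Protocol(f"exp1_ignore_n(alpha={alpha:g})", (
        _baseline(40),
        _ignore("rotation", n_rot, d=d, alpha=alpha),
        _no_cursor("no_cursor", 40),
    ))


def exp2_learn_n(alpha: float = 1.0, d: float | None = None) -> Protocol:
    """Learn-N: 40 baseline + 100 Learn + 40 no-cursor."""
    _check_alpha(alpha)
    if d is None:
        d = _default_d15(alpha)
    return Protocol(f"exp2_learn_n(alpha={alpha:g})", (
        _baseline(40),
        _learn("rotation", 100, d=d, alpha=alpha),
        _no_cursor("no_cursor", 40),
    ))


def exp3_ignore_w(alpha: float = 1.0, d: float = -25.0) -> Protocol:
    """Ignore-W: 40 baseline + 120 Ignore (+-25 deg) + 40 washout."""
    _check_alpha(alpha)
    return Protocol(f"exp3_ignore_w(alpha={alpha:g})", (
        _baseline(40),
        _ignore("rotation", 120, d=d, alpha=alpha),
        _learn("washout", 40, d=0.0, alpha=1.0),
    ))


def exp4_learn_w(alpha: float = 1.0, d: float = -25.0) -> Protocol:
    """Learn-W: 40 baseline + 120 Learn (+-25 deg) + 40 washout."""
    _check_alpha(alpha)
    return Protocol(f"exp4_learn_w(alpha={alpha:g})", (
        _baseline(40),
        _learn("rotation", 120, d=d, alpha=alpha),
        _learn("washout", 40, d=0.0, alpha=1.0),
    ))


def spontaneous_recovery(d: float = -45.0) -> Protocol:
    """80 Learn with d + 5 Learn with -d (unlearning) + 20 veridical washout."""
    return Protocol("spontaneous_recovery", (
        _learn("learn", 80, d=d),
        _learn("unlearn", 5, d=-d),
        _learn("washout", 20, d=0.0),
    ))


def evoked_recovery(d: float = -45.0) -> Protocol:
    """80 Learn + 4 counter + 3 no-cursor + 2 Learn + 20 no-cursor."""
    return Protocol("evoked_recovery", (
        _learn("learn", 80, d=d),
        _learn("unlearn", 4, d=-d),
        _no_cursor("probe", 3),
        _learn("relearn", 2, d=d),
        _no_cursor("no_cursor", 20),
    ))


def savings_counter(d: float = -45.0) -> Protocol:
    """Classical savings: 80 Learn + 5 counter-perturbation + 80 relearn."""
    return Protocol("savings_counter", (
        _learn("learn", 80, d=d),
        _learn("unlearn", 5, d=-d),
        _learn("relearn", 80, d=d),
    ))


def savings_reaim(d: float = -45.0, gamma: float = 0.5, n_learn: int = 80,
                  n_washout: int = 20) -> Protocol:
    """Savings via re-aiming: the relearn phase adds r_aim = -gamma * d."""
    if not 0.0 < gamma < 1.0:
        raise ProtocolError(f"gamma must be in (0,1), got {gamma}")
    return Protocol("savings_reaim", (
        _learn("learn", n_learn, d=d),
        _learn("washout", n_washout, d=0.0),
        _learn("relearn", n_learn, d=d, r_aim=-gamma * d),
    ))


def savings_error_sensitivity(d: float = -45.0, K: float = 0.5,
                              n_learn: int = 80,
                              n_washout: int = 20) -> Protocol:
    """Savings via raised error sensitivity: K is overridden during the
    washout and relearn phases."""
    return Protocol("savings_error_sensitivity", (
        _learn("learn", n_learn, d=d),
        _learn("washout", n_washout, d=0.0, overrides={"K": K}),
        _learn("relearn", n_learn, d=d, overrides={"K": K}),
    ))


def error_clamp(clamp: float = -45.0, n_clamp: int = 80,
                n_baseline: int = 40, n_nocursor: int = 40) -> Protocol:
    """Non-zero error clamp: Ignore trials with alpha = 0 and d = clamp."""
    return Protocol("error_clamp", (
        _baseline(n_baseline),
        _ignore("clamp", n_clamp, d=clamp, alpha=0.0),
        _no_cursor("no_cursor", n_nocursor),
    ))


def alternating_cursor_nocursor(d: float = 30.0, n: int = 60) -> Protocol:
    """n repetitions of [1 Learn trial with cursor, 1 no-cursor trial].

    The Learn trials genuinely show a cursor, so they use ordinary LEARN
    semantics; the interleaved trials are hand-to-target without a cursor.
    """
    if n < 1:
        raise ProtocolError(f"n must be >= 1, got {n}")
    phases = []
    for i in range(n):
        phases.append(_learn(f"cursor_{i + 1}", 1, d=d))
        phases.append(_no_cursor(f"no_cursor_{i + 1}", 1))
    return Protocol("alternating_cursor_nocursor", tuple(phases))


def learn_then_nocursor(d: float = -45.0, n_learn: int = 80,
                        n_nocursor: int = 40) -> Protocol:
    """Configurable aftereffect template: Learn phase then no-cursor probe."""
    return Protocol("learn_then_nocursor", (
        _learn("learn", n_learn, d=d),
        _no_cursor("no_cursor", n_nocursor),
    ))


_BUILDERS: dict[str, Callable[..., Protocol]] = {
    "exp1_ignore_n": exp1_ignore_n,
    "exp2_learn_n": exp2_learn_n,
    "exp3_ignore_w": exp3_ignore_w,
    "exp4_learn_w": exp4_learn_w,
    "spontaneous_recovery": spontaneous_recovery,
    "evoked_recovery": evoked_recovery,
    "savings_counter": savings_counter,
    "savings_reaim": savings_reaim,
    "savings_error_sensitivity": savings_error_sensitivity,
    "error_clamp": error_clamp,
    "alternating_cursor_nocursor": alternating_cursor_nocursor,
    "learn_then_nocursor": learn_then_nocursor,
}


def available_protocols() -> list[str]:
    return sorted(_BUILDERS)


def build_experiment(name: str, **options) -> Protocol:
    """Build a registered protocol by name with builder-specific options."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ProtocolError(
            f"unknown protocol {name!r}; available: "
            f"{', '.join(available_protocols())}") from None
    return builder(**options)


# ---------------------------------------------------------------------------
# serialization

def _phase_to_doc(phase: Phase) -> dict:
    t = phase.template
    doc = {
        "label": phase.label,
        "n_trials": phase.n_trials,
        "mode": t.mode.value,
        "r": t.r,
        "d": t.d,
        "alpha": t.alpha,
        "r_aim": t.r_aim,
        "overrides": dict(phase.overrides) if phase.overrides else None,
    }
    if t.overrides:
        doc["trial_overrides"] = dict(t.overrides)
    return doc


def save(protocol: Protocol, path=None) -> dict:
    """Serialize a protocol to its JSON document; optionally write to path."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": protocol.name,
        "phases": [_phase_to_doc(p) for p in protocol.phases],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")
    return doc


def _phase_from_doc(doc: dict, index: int) -> Phase:
    where = f"phases[{index}]"
    if not isinstance(doc, dict):
        raise ProtocolError(f"{where}: expected an object")
    for key in ("label", "n_trials", "mode", "r"):
        if key not in doc:
            raise ProtocolError(f"{where}: missing required field {key!r}")
    mode_label = doc["mode"]
    try:
        mode = Mode(mode_label)
    except ValueError:
        raise ProtocolError(
            f"{where}.mode: unknown mode label {mode_label!r}") from None
    template = TrialSpec(
        mode=mode,
        r=float(doc["r"]),
        d=None if doc.get("d") is None else float(doc["d"]),
        alpha=None if doc.get("alpha") is None else float(doc["alpha"]),
        r_aim=float(doc.get("r_aim") or 0.0),
        overrides=doc.get("trial_overrides") or None,
    )
    return Phase(label=str(doc["label"]), n_trials=int(doc["n_trials"]),
                 template=template, overrides=doc.get("overrides") or None)


def loads(doc: dict) -> Protocol:
    """Build a Protocol from a parsed document (round-trip of :func:`save`)."""
    if not isinstance(doc, dict):
        raise ProtocolError("protocol document must be an object")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ProtocolError(f"unsupported schema_version: {version!r}")
    if "name" not in doc:
        raise ProtocolError("missing required field 'name'")
    phases_doc = doc.get("phases")
    if not isinstance(phases_doc, list) or not phases_doc:
        raise ProtocolError("'phases' must be a non-empty list")
    phases = tuple(_phase_from_doc(p, i) for i, p in enumerate(phases_doc))
    return Protocol(name=str(doc["name"]), phases=phases)


def load(path) -> Protocol:
    """Load a protocol document from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return loads(doc)
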