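"""Calcifier-alkalinity dynamical system: states, parameters, forcing, feedback.

The model tracks ocean alkalinity ``A`` (mol eq m^-3) and the natural log
``P`` of the calcifier concentration ``C``.  Weathering supplies alkalinity
at rate ``I0`` modulated by a bounded positive feedback ``gamma * S(A)``;
calcifiers grow at rate ``k A`` and are buried at rate ``M``, removing
alkalinity through the ``k A C`` term:

    dA/dt = I0 (1 + gamma S(A)) - k A exp(P)
    dP/dt = k A - M

with the reaction rate periodically forced,
``k(t) = k0 (1 + alpha cos(2 pi t / T_force))``, emulating an astronomical
(obliquity-like) modulation of calcification.  The feedback shape is a
saturating sigmoid ``S(A) = (2/pi) arctan(pi (A - A0) / (2 z0))``, odd about
the midpoint ``A0`` with slope ``1/z0`` there and limits +-1.

This module also houses the closed-form local analysis of the unforced
(alpha = 0) system: equilibrium, Jacobian, Hopf threshold, and the period of
the linearized oscillation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "GammaSchedule",
    "SystemState",
    "TABLE_DEFAULTS",
    "sigmoid_feedback",
    "sigmoid_slope",
    "forcing_rate",
    "gamma_at",
    "rhs",
    "equilibrium",
    "jacobian",
    "hopf_threshold",
    "linear_internal_period",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, forcing, and feedback-shape parameters.

    Defaults are the published reference values: ``I0 = 4e-6`` mol eq m^-3
    yr^-1, ``k0 = 0.05`` (mol eq)^-1 m^3 yr^-1, ``M = 0.1`` yr^-1, forcing
    period 40 kyr, feedback midpoint ``A0 = 2.0`` and scale ``z0 = 0.1``
    mol eq m^-3.  ``extra_forcing`` optionally adds further cosine
    components ``(alpha_i, T_i, phase_i)`` on top of the primary one, for
    mixed obliquity/precession forcing experiments.
    """

    I0: float = 4e-6
    k0: float = 0.05
    M: float = 0.1
    alpha: float = 0.0
    T_force: float = 4e4
    A0: float = 2.0
    z0: float = 0.1
    extra_forcing: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        for name in ("I0", "k0", "M", "T_force", "A0", "z0"):
            v = getattr(self, name)
            if not (v > 0.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")
        total_alpha = abs(self.alpha) + sum(abs(a) for a, _, _ in self.extra_forcing)
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha!r}")
        if total_alpha >= 1.0:
            raise ValueError(
                "combined forcing amplitude must stay below 1 so the reaction "
                f"rate k(t) remains positive; got total {total_alpha}"
            )
        for a, T, _ in self.extra_forcing:
            if T <= 0:
                raise ValueError(f"forcing component period must be positive, got {T!r}")
            if a < 0:
                raise ValueError(f"forcing component amplitude must be >= 0, got {a!r}")

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {
            "I0": self.I0, "k0": self.k0, "M": self.M, "alpha": self.alpha,
            "T_force": self.T_force, "A0": self.A0, "z0": self.z0,
        }
        if self.extra_forcing:
            d["extra_forcing"] = [list(c) for c in self.extra_forcing]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        extra = tuple(tuple(c) for c in d.pop("extra_forcing", ()))
        return cls(extra_forcing=extra, **d)


#: The published reference parameter set (unforced).
TABLE_DEFAULTS = ModelParameters()


@dataclass(frozen=True)
class GammaSchedule:
    """Time course of the feedback strength gamma.

    ``constant``: gamma1 throughout.  ``step``: gamma1 before ``t_c``,
    gamma2 from ``t_c`` on.  ``ramp``: linear interpolation from gamma1 to
    gamma2 over [t_c, t_c + delta_t], clamped outside; a ramp with
    ``delta_t = 0`` is identical to a step.
    """

    kind: str = "constant"
    gamma1: float = 0.0
    gamma2: float | None = None
    t_c: float | None = None
    delta_t: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step", "ramp"):
            raise ValueError(f"kind must be constant|step|ramp, got {self.kind!r}")
        values = [self.gamma1]
        if self.kind != "constant":
            if self.gamma2 is None or self.t_c is None:
                raise ValueError(f"{self.kind} schedule requires gamma2 and t_c")
            values.append(self.gamma2)
        if self.kind == "ramp":
            if self.delta_t is None or self.delta_t < 0:
                raise ValueError("ramp schedule requires delta_t >= 0")
        for g in values:
            if not (0.0 <= g < 1.0):
                raise ValueError(
                    f"gamma must lie in [0, 1) to keep the alkalinity input positive, got {g!r}"
                )

    @classmethod
    def constant(cls, gamma: float) -> "GammaSchedule":
        return cls("constant", gamma)

    @classmethod
    def step(cls, gamma1: float, gamma2: float, t_c: float) -> "GammaSchedule":
        return cls("step", gamma1, gamma2, t_c)

    @classmethod
    def ramp(cls, gamma1: float, gamma2: float, t_c: float, delta_t: float) -> "GammaSchedule":
        return cls("ramp", gamma1, gamma2, t_c, delta_t)

    def breakpoints(self) -> tuple[float, ...]:
        """Times at which gamma(t) is non-smooth (integration restart points)."""
        if self.kind == "constant":
            return ()
        if self.kind == "step" or self.delta_t == 0:
            return (self.t_c,)
        return (self.t_c, self.t_c + self.delta_t)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "gamma1": self.gamma1}
        if self.kind != "constant":
            d["gamma2"] = self.gamma2
            d["t_c"] = self.t_c
        if self.kind == "ramp":
            d["delta_t"] = self.delta_t
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GammaSchedule":
        return cls(**d)


@dataclass(frozen=True)
class SystemState:
    """Phase-space point: alkalinity ``A`` and log-calcifiers ``P = ln C``."""

    A: float
    P: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A) and math.isfinite(self.P)):
            raise ValueError(f"state must be finite, got A={self.A!r}, P={self.P!r}")

    @property
    def C(self) -> float:
        """Calcifier concentration ``exp(P)`` (mol eq m^-3)."""
        return math.exp(self.P)

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.P], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "SystemState":
        return cls(float(y[0]), float(y[1]))


def sigmoid_feedback(A, A0: float = 2.0, z0: float = 0.1):
    """Bounded feedback shape S(A) = (2/pi) arctan(pi (A - A0) / (2 z0)).

    Odd about ``A0``, strictly increasing, bounded in (-1, 1), with slope
    ``1/z0`` at the midpoint.  Accepts scalars or arrays.
    """
    if not z0 > 0:
        raise ValueError(f"z0 must be positive, got {z0!r}")
    return (2.0 / np.pi) * np.arctan(np.pi * (np.asarray(A, float) - A0) / (2.0 * z0)) + 0.0


def sigmoid_slope(A, A0: float = 2.0, z0: float = 0.1):
    """dS/dA = (1/z0) / (1 + (pi (A - A0) / (2 z0))^2)."""
    if not z0 > 0:
        raise ValueError(f"z0 must be positive, got {z0!r}")
    u = np.pi * (np.asarray(A, float) - A0) / (2.0 * z0)
    return (1.0 / z0) / (1.0 + u * u)


def forcing_rate(t, params: ModelParameters):
    """Forced reaction rate k(t) = k0 (1 + alpha cos(2 pi t / T_force) + ...).

    The primary cosine has phase 0 at t = 0 (so ``k(0) = k0 (1 + alpha)``);
    extra components add ``alpha_i cos(2 pi t / T_i + phase_i)``.
    """
    t = np.asarray(t, float)
    mod = params.alpha * np.cos(2.0 * np.pi * t / params.T_force)
    for a, T, ph in params.extra_forcing:
        mod = mod + a * np.cos(2.0 * np.pi * t / T + ph)
    return params.k0 * (1.0 + mod)


def gamma_at(t, schedule: GammaSchedule):
    """Evaluate the feedback strength gamma at time(s) ``t``."""
    t = np.asarray(t, float)
    if schedule.kind == "constant":
        return np.broadcast_to(np.float64(schedule.gamma1), t.shape)[()] + 0.0
    if schedule.kind == "step" or schedule.delta_t == 0:
        return np.where(t < schedule.t_c, schedule.gamma1, schedule.gamma2) + 0.0
    frac = np.clip((t - schedule.t_c) / schedule.delta_t, 0.0, 1.0)
    return schedule.gamma1 + (schedule.gamma2 - schedule.gamma1) * frac


class BlowupError(RuntimeError):
    """The state left the representable range (exp(P) overflow or non-finite)."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


# exp(P) overflows double precision near P ~ 709; physical trajectories keep
# P far below 0, so crossing this bound is a diagnosable blow-up.
_P_OVERFLOW = 700.0


def rhs(t: float, state, params: ModelParameters, schedule: GammaSchedule | float):
    """Time derivatives (dA/dt, dP/dt) of the forced, feedback-extended system.

    ``schedule`` may be a :class:`GammaSchedule` or a plain gamma value.
    With gamma = 0 the equations reduce to the base model; evaluating in
    (A, C = e^P) coordinates recovers the original population form.
    """
    if isinstance(state, SystemState):
        A, P = state.A, state.P
    else:
        A, P = float(state[0]), float(state[1])
    if P > _P_OVERFLOW:
        raise BlowupError(f"exp(P) overflow at t={t}: P={P}", last_valid_time=t)
    g = schedule if isinstance(schedule, (int, float)) else float(gamma_at(t, schedule))
    k = float(forcing_rate(t, params))
    S = float(sigmoid_feedback(A, params.A0, params.z0))
    dA = params.I0 * (1.0 + g * S) - k * A * math.exp(P)
    dP = k * A - params.M
    return (dA, dP)


def equilibrium(params: ModelParameters, gamma: float = 0.0) -> SystemState:
    """Fixed point of the unforced system (alpha treated as 0).

    ``A* = M / k0`` (from dP/dt = 0) and ``C* = I0 (1 + gamma S(A*)) / M``.
    With the reference parameters ``A* = A0`` so ``S(A*) = 0`` and the
    equilibrium is independent of gamma.
    """
    A_star = params.M / params.k0
    S = float(sigmoid_feedback(A_star, params.A0, params.z0))
    C_star = params.I0 * (1.0 + gamma * S) / params.M
    if C_star <= 0.0:
        raise ValueError(
            f"no physical equilibrium: C* = {C_star} <= 0 (gamma too strong for this A*)"
        )
    return SystemState(A_star, math.log(C_star))


def jacobian(state: SystemState | Sequence[float], params: ModelParameters,
             gamma: float = 0.0) -> np.ndarray:
    """Jacobian of the autonomous (alpha = 0) vector field at ``state``.

    Rows are (dA/dt, dP/dt) derivatives with respect to (A, P):
    ``[[I0 gamma S'(A) - k0 e^P, -k0 A e^P], [k0, 0]]``.
    """
    if isinstance(state, SystemState):
        A, P = state.A, state.P
    else:
        A, P = float(state[0]), float(state[1])
    eP = math.exp(P)
    Sp = float(sigmoid_slope(A, params.A0, params.z0))
    return np.array([
        [params.I0 * gamma * Sp - params.k0 * eP, -params.k0 * A * eP],
        [params.k0, 0.0],
    ])


def _trace_at_equilibrium(params: ModelParameters, gamma: float) -> float:
    eq = equilibrium(params, gamma)
    J = jacobian(eq, params, gamma)
    return float(np.trace(J))


def hopf_threshold(params: ModelParameters) -> float:
    """Feedback strength at which the unforced equilibrium loses stability.

    The equilibrium Jacobian has positive determinant, so stability is set
    by the trace; the Hopf threshold is the gamma in [0, 1) where the trace
    crosses zero.  When ``A* = A0`` this reduces to the closed form
    ``gamma_H = k0 z0 / M`` (0.05 at the reference parameters); in general
    the crossing is located by root finding.
    """
    from scipy.optimize import brentq

    A_star = params.M / params.k0
    if math.isclose(A_star, params.A0, rel_tol=1e-12, abs_tol=1e-12):
        gamma_h = params.k0 * params.z0 / params.M
        if not (0.0 <= gamma_h < 1.0):
            raise ValueError(
                f"no Hopf crossing in [0, 1): closed form gives gamma_H = {gamma_h}"
            )
        return gamma_h
    f0 = _trace_at_equilibrium(params, 0.0)
    f1 = _trace_at_equilibrium(params, 1.0 - 1e-9)
    if f0 * f1 > 0:
        raise ValueError("no Hopf crossing in [0, 1) for these parameters")
    return float(brentq(lambda g: _trace_at_equilibrium(params, g), 0.0, 1.0 - 1e-9,
                        xtol=1e-14))


def linear_internal_period(params: ModelParameters, gamma: float = 0.0) -> float:
    """Period 2 pi / Im(lambda) of the linearized oscillation about equilibrium.

    Raises if the equilibrium eigenvalues are real (non-oscillatory).
    At the reference parameters with gamma = 0 this is ~14.05 kyr.
    """
    eq = equilibrium(params, gamma)
    lam = np.linalg.eigvals(jacobian(eq, params, gamma))
    im = float(np.max(np.abs(lam.imag)))
    if im == 0.0:
        raise ValueError("equilibrium eigenvalues are real: no linear oscillation period")
    return 2.0 * np.pi / im


def save_config(path, params: ModelParameters, schedule: GammaSchedule | None = None) -> None:
    """Write parameters (and optionally a gamma schedule) to a flat YAML file."""
    doc: dict = {"parameters": params.to_dict()}
    if schedule is not None:
        doc["schedule"] = schedule.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[ModelParameters, GammaSchedule | None]:
    """Read a YAML config written by :func:`save_config`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = ModelParameters.from_dict(doc["parameters"])
    schedule = GammaSchedule.from_dict(doc["schedule"]) if "schedule" in doc else None
    return params, schedule
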