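"""Time-dependent constraint bounds.

Each bounded constraint carries lower/upper bounds that interpolate from
loose initial values early in generation to strict final values at the end,
following a logistic (sigmoid) schedule

    s(t) = 1 / (1 + exp(-beta (t - t0))),

with ``t`` the normalized sampler progress in [0, 1] (0 = start of reverse
diffusion, 1 = final sample).  The interpolation used for the bounds is the
endpoint-normalized sigmoid s_hat(t) = (s(t) - s(0)) / (s(1) - s(0)), which
equals the raw sigmoid up to an affine rescaling but reaches the final
strict bounds *exactly* at t = 1: with finite beta the raw logistic never
attains 1, and the leftover tail would keep a finite slack window open at
the last step, breaking the holonomic (strict-equality) limit that bounded
constraints are meant to collapse to.

An ``None`` initial bound means "unbounded".  Rather than interpolating
from an infinite endpoint (which Eq.-style linear interpolation cannot do)
or substituting a large float, the effective bound recedes to infinity as
s_hat -> 0:

    lower(t) = lower_final - unbound_scale * (1 - s_hat) / s_hat,

and is reported as -inf while s_hat <= 1e-6 (symmetrically for upper).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constraints import ConstraintSet, _coords_of, wrap_degrees

__all__ = [
    "BoundSchedule",
    "ActiveConstraintView",
    "ScheduleState",
    "ScheduleInconsistencyError",
    "sigmoid",
    "bounds_at",
    "effective_bounds",
    "resolve_active",
    "zeta_step",
]

#: s_hat below this leaves an unbounded endpoint at +-inf.
UNBOUNDED_EPS = 1e-6


class ScheduleInconsistencyError(ValueError):
    """Interpolated bounds crossed (lower > upper)."""


@dataclass
class BoundSchedule:
    """Sigmoid interpolation of constraint bounds over sampler progress.

    Parameters
    ----------
    beta
        Steepness of the logistic transition (> 0).
    t0
        Transition midpoint in normalized progress [0, 1].
    lower_initial, upper_initial
        Bounds at t = 0; ``None`` = unbounded.
    lower_final, upper_final
        Strict bounds at t = 1.  May be left ``None`` when the schedule is
        attached to a constraint, in which case the constraint's own final
        bounds apply.
    unbound_scale
        Length scale (Angstrom or degrees) of the receding bound used while
        an unbounded endpoint tightens.
    """

    beta: float = 10.0
    t0: float = 0.5
    lower_initial: Optional[float] = None
    upper_initial: Optional[float] = None
    lower_final: Optional[float] = None
    upper_final: Optional[float] = None
    unbound_scale: float = 10.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.t0 <= 1.0:
            raise ValueError("t0 must lie in [0, 1]")
        for lo, up, tag in (
            (self.lower_initial, self.upper_initial, "initial"),
            (self.lower_final, self.upper_final, "final"),
        ):
            if lo is not None and up is not None and lo > up:
                raise ValueError(f"{tag} lower bound exceeds upper bound")


def sigmoid(t: float, schedule: BoundSchedule) -> float:
    """Raw logistic s(t); s(t0) = 0.5 exactly, strictly increasing."""
    return float(1.0 / (1.0 + np.exp(-schedule.beta * (t - schedule.t0))))


def _s_hat(t: float, schedule: BoundSchedule) -> float:
    s0 = sigmoid(0.0, schedule)
    s1 = sigmoid(1.0, schedule)
    s = (sigmoid(t, schedule) - s0) / (s1 - s0)
    return float(np.clip(s, 0.0, 1.0))


def _interp_bound(initial, final, s, scale, side):
    if final is None:
        return -np.inf if side == "lower" else np.inf
    if initial is None:
        if s <= UNBOUNDED_EPS:
            return -np.inf if side == "lower" else np.inf
        recede = scale * (1.0 - s) / s
        return final - recede if side == "lower" else final + recede
    return final + (initial - final) * (1.0 - s)


def bounds_at(t: float, schedule: BoundSchedule,
              lower_final: Optional[float] = None,
              upper_final: Optional[float] = None):
    """Effective (lower(t), upper(t)) under ``schedule``.

    ``lower_final``/``upper_final`` override the schedule's own endpoints
    (used when the schedule is shared between constraints with different
    targets).
    """
    lf = schedule.lower_final if lower_final is None else lower_final
    uf = schedule.upper_final if upper_final is None else upper_final
    s = _s_hat(t, schedule)
    lo = _interp_bound(schedule.lower_initial, lf, s, schedule.unbound_scale, "lower")
    up = _interp_bound(schedule.upper_initial, uf, s, schedule.unbound_scale, "upper")
    if lo > up:
        raise ScheduleInconsistencyError(
            f"interpolated bounds crossed at t={t:g}: lower {lo:g} > upper {up:g}"
        )
    return lo, up


def effective_bounds(constraint, t: float):
    """Bounds of one constraint at progress t (constant if unscheduled)."""
    sched = getattr(constraint, "schedule", None)
    if sched is None:
        return constraint.lower_final, constraint.upper_final
    return bounds_at(t, sched, constraint.lower_final, constraint.upper_final)


@dataclass
class ActiveConstraintView:
    """Active-set resolution of bounded constraints at one instant.

    A constraint whose current value lies strictly inside its bounds is
    inactive (the slack variable absorbs the deviation and the constraint
    drops out of the Jacobian); a violated bound becomes an active equality
    at that bound; coincident bounds are always active (holonomic limit).
    """

    active_indices: list
    effective_targets: np.ndarray  # per *active* constraint
    slack_values: np.ndarray       # per constraint, clipped deviation
    bounds: list                   # per constraint (lower, upper)


def resolve_active(cset: ConstraintSet, conf, t: float) -> ActiveConstraintView:
    coords = _coords_of(conf)
    active, targets, slacks, bounds = [], [], [], []
    for a, c in enumerate(cset):
        lo, up = effective_bounds(c, t)
        v = c.value(coords)
        if getattr(c, "angular", False):
            # compare on the shortest arc relative to the bound midpoint
            mid = 0.5 * (lo + up) if np.isfinite(lo) and np.isfinite(up) else c.target
            v = mid + wrap_degrees(v - mid)
        bounds.append((lo, up))
        slacks.append(float(np.clip(v - c.target, lo - c.target, up - c.target)))
        if lo == up:
            active.append(a)
            targets.append(lo)
        elif v > up:
            active.append(a)
            targets.append(up)
        elif v < lo:
            active.append(a)
            targets.append(lo)
    return ActiveConstraintView(active, np.asarray(targets), np.asarray(slacks), bounds)


@dataclass
class ScheduleState:
    """Deterministic component of the constrained sampler: the current
    progress variable and, through the closed-form schedules, the bound
    trajectory zeta(t)."""

    cset: ConstraintSet
    t: float = 0.0

    @property
    def bounds(self):
        return [effective_bounds(c, self.t) for c in self.cset]


def zeta_step(state: ScheduleState, dt: float) -> ScheduleState:
    """Advance the bound variables from t to t + dt.

    The sigmoid bound trajectory has a closed form, so the update evaluates
    it exactly at the new time; the result is independent of how [0, t] is
    partitioned into steps.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return ScheduleState(state.cset, min(state.t + dt, 1.0))
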