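"""Event-driven integration of (state, control) and the failure time.

A trajectory is integrated arc by arc.  Bang/constant arcs terminate
early when the volume crosses the failure boundary ``V = Vc`` from
below: if a sliding (PATH_FEEDBACK) arc is queued and the boundary
feedback is admissible at the contact point, the trajectory switches to
sliding; otherwise the crossing is the failure time ``t_c``.  A sliding
arc holds ``dV/dt = 0`` by applying the feedback ``u_p`` exactly and
ends when ``u_p`` saturates at ``M`` (the state then sits at the
tangency point, where any further arc immediately loses the boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .controls import BOUNDARY_TOL, ArcMode, ControlArc, PiecewiseControl, u_path
from .geometry import lie_V_along
from .model import constraint_psi, volume
from .params import DomainError, Params

__all__ = [
    "Trajectory",
    "Event",
    "integrate",
    "time_to_failure",
    "clock_form_time",
    "shoot_between",
    "HorizonExceededError",
    "IntegrationFailureError",
]

DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-10
EVENT_TOL = 1e-12
DEFAULT_HORIZON = 1e4


class HorizonExceededError(RuntimeError):
    """No failure event before the safety horizon."""


class IntegrationFailureError(RuntimeError):
    """The ODE solver failed or produced a non-finite state."""


@dataclass
class Event:
    time: float
    kind: str  # BOUNDARY_CONTACT | SLIDING_START | SLIDING_END | FAILURE


@dataclass
class Trajectory:
    """Integrated trajectory with applied doses and boundary metadata."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2)
    doses: np.ndarray
    events: list[Event] = field(default_factory=list)
    t_c: float | None = None

    def event_times(self, kind: str) -> list[float]:
        return [e.time for e in self.events if e.kind == kind]

    def to_frame(self):
        import pandas as pd

        v = self.states.sum(axis=1)
        return pd.DataFrame(
            {
                "t": self.times,
                "x1": self.states[:, 0],
                "x2": self.states[:, 1],
                "u": self.doses,
                "V": v,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def events_json(self) -> str:
        import json

        return json.dumps(
            [{"time": e.time, "kind": e.kind} for e in self.events]
            + ([] if self.t_c is None else [{"t_c": self.t_c}])
        )


class _Recorder:
    def __init__(self) -> None:
        self.t: list[float] = []
        self.x: list[np.ndarray] = []
        self.u: list[float] = []

    def extend(self, sol, tgrid, dose_of) -> None:
        ys = sol.sol(tgrid) if sol.sol is not None else sol.y
        for tk, yk in zip(tgrid, np.asarray(ys).T):
            self.t.append(float(tk))
            self.x.append(np.asarray(yk, dtype=float))
            self.u.append(dose_of(yk))


def _solve_arc(p, state, t0, t1, dose_fn, events, rtol, atol, dense_n):
    def f(t, y):
        # evaluate the fields on the clipped state so that integrator
        # underflow below zero cannot feed back as spurious growth
        x1 = y[0] if y[0] > 0.0 else 0.0
        x2 = y[1] if y[1] > 0.0 else 0.0
        k = 1.0 - (x1 + x2)
        u = dose_fn(y)
        return (
            k * x1 - p.eps * x1 - (p.alpha + p.d) * u * x1,
            p.pr * k * x2 + p.eps * x1 + p.alpha * u * x1,
        )

    sol = solve_ivp(
        f,
        (t0, t1),
        state,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=events,
        dense_output=dense_n is not None,
        max_step=max(min((t1 - t0) / 10.0, 10.0), 1e-6),
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationFailureError(sol.message)
    return sol


def integrate(
    p: Params,
    ctrl: PiecewiseControl,
    t_max: float,
    *,
    x0=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    dense_n: int | None = None,
) -> Trajectory:
    """Integrate the controlled system until failure or ``t_max``.

    ``dense_n`` requests at least that many stored points per arc
    (needed for clock-form integrals); by default the solver's own
    accepted steps are stored.
    """
    state = np.array(p.x0 if x0 is None else x0, dtype=float)
    if volume(state) > p.Vc + BOUNDARY_TOL or state.min() < -BOUNDARY_TOL:
        raise DomainError(f"initial state {tuple(state)} outside the treatment region")
    rec = _Recorder()
    events: list[Event] = []
    t = 0.0
    t_c: float | None = None
    arcs = list(ctrl.arcs)
    i = 0
    while i < len(arcs) and t_c is None and t < t_max - EVENT_TOL:
        arc = arcs[i]
        if arc.mode is ArcMode.PATH_FEEDBACK:
            t, state, done = _run_sliding(p, state, t, t_max, rec, events, rtol, atol, dense_n)
            if done:
                break
            i += 1
            continue
        # constant-dose arc (ZERO / MAX / CONST / SINGULAR feedback)
        if arc.mode is ArcMode.SINGULAR:
            dose_fn = lambda y, _a=arc: _a.dose(y, p)
            u_start = dose_fn(state)
        else:
            u_const = arc.dose(state, p)
            dose_fn = lambda y, _u=u_const: _u
            u_start = u_const
        # starting at (or beyond) the boundary with non-decreasing volume
        # means the constraint is lost immediately
        if constraint_psi(state, p) >= -BOUNDARY_TOL and lie_V_along(state, p, u_start) >= -1e-12:
            rec.t.append(t), rec.x.append(state.copy()), rec.u.append(u_start)
            events.append(Event(t, "FAILURE"))
            t_c = t
            break
        t_end = min(t_max, t + arc.duration) if arc.duration is not None else t_max

        def psi_up(tt, y):
            return y[0] + y[1] - p.Vc

        psi_up.terminal = True
        psi_up.direction = 1.0
        sol = _solve_arc(p, state, t, t_end, dose_fn, [psi_up], rtol, atol, dense_n)
        tgrid = (
            np.linspace(t, sol.t[-1], max(dense_n, 2)) if dense_n is not None else sol.t
        )
        rec.extend(sol, tgrid, dose_fn)
        t = float(sol.t[-1])
        state = np.asarray(sol.y[:, -1], dtype=float)
        if sol.status == 1:  # boundary crossing
            events.append(Event(t, "BOUNDARY_CONTACT"))
            slide_later = any(a.mode is ArcMode.PATH_FEEDBACK for a in arcs[i + 1 :])
            if slide_later and state[0] > 0.0 and u_path(state, p) <= p.M * (1 + 1e-12):
                # jump to the sliding arc, truncating intervening arcs
                i = next(
                    j for j in range(i + 1, len(arcs)) if arcs[j].mode is ArcMode.PATH_FEEDBACK
                )
                continue
            events.append(Event(t, "FAILURE"))
            t_c = t
            break
        i += 1
    traj = Trajectory(
        times=np.asarray(rec.t),
        states=np.asarray(rec.x).reshape(-1, 2),
        doses=np.asarray(rec.u),
        events=events,
        t_c=t_c,
    )
    return traj


def _run_sliding(p, state, t, t_max, rec, events, rtol, atol, dense_n):
    """Boundary-seek (dose 0) if off N, then slide with u_p until it
    saturates at M.  Returns (t, state, failed)."""
    if constraint_psi(state, p) < -BOUNDARY_TOL:
        # drift to the boundary with no dose
        def psi_up(tt, y):
            return y[0] + y[1] - p.Vc

        psi_up.terminal = True
        psi_up.direction = 1.0
        sol = _solve_arc(p, state, t, t_max, lambda y: 0.0, [psi_up], rtol, atol, dense_n)
        tgrid = np.linspace(t, sol.t[-1], max(dense_n, 2)) if dense_n is not None else sol.t
        rec.extend(sol, tgrid, lambda y: 0.0)
        t = float(sol.t[-1])
        state = np.asarray(sol.y[:, -1], dtype=float)
        if sol.status != 1:
            return t, state, True  # horizon reached while seeking
        events.append(Event(t, "BOUNDARY_CONTACT"))
    if state[0] <= 0.0 or u_path(state, p) > p.M * (1 + 1e-12):
        return t, state, False  # infeasible contact: zero-duration slide
    events.append(Event(t, "SLIDING_START"))

    def safe_up(y):
        # guard against wild solver trial states; the accepted solution
        # keeps x1 well away from zero (sliding ends at the tangency point)
        x1 = max(float(y[0]), 1e-12)
        x2 = float(y[1])
        return (1.0 - x1 - x2) * (x1 + p.pr * x2) / (p.d * x1)

    def saturates(tt, y):
        return safe_up(y) - p.M

    saturates.terminal = True
    saturates.direction = 1.0
    dose_fn = safe_up
    sol = _solve_arc(p, state, t, t_max, dose_fn, [saturates], rtol, atol, dense_n)
    tgrid = np.linspace(t, sol.t[-1], max(dense_n, 2)) if dense_n is not None else sol.t
    rec.extend(sol, tgrid, lambda y: min(u_path(y, p), p.M))
    t = float(sol.t[-1])
    state = np.asarray(sol.y[:, -1], dtype=float)
    events.append(Event(t, "SLIDING_END"))
    return t, state, sol.status != 1 and t >= t_max - EVENT_TOL


def time_to_failure(
    p: Params,
    ctrl: PiecewiseControl,
    *,
    horizon: float = DEFAULT_HORIZON,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> float:
    """Failure time ``t_c`` of a control (raises if none before the horizon)."""
    traj = integrate(p, ctrl, horizon, rtol=rtol, atol=atol)
    if traj.t_c is None:
        raise HorizonExceededError(f"no failure before t = {horizon}")
    return traj.t_c


def clock_form_time(traj: Trajectory, p: Params) -> float:
    """Elapsed time recovered from the clock one-form.

    ``omega = (g2 dx1 - g1 dx2) / det(f, g)`` satisfies ``omega(f) = 1``,
    ``omega(g) = 0``, so its line integral along any admissible
    trajectory equals the elapsed time.  Midpoint rule on the stored
    polyline; requires ``x1 > 0`` throughout.
    """
    x = traj.states
    if np.any(x[:, 0] <= 1e-12):
        raise DomainError("clock form singular: x1 -> 0 along the path")
    mid = 0.5 * (x[:-1] + x[1:])
    dx = np.diff(x, axis=0)
    x1, x2 = mid[:, 0], mid[:, 1]
    k = 1.0 - x1 - x2
    f1 = k * x1 - p.eps * x1
    f2 = p.pr * k * x2 + p.eps * x1
    g1 = -(p.alpha + p.d) * x1
    g2 = p.alpha * x1
    det = f1 * g2 - f2 * g1
    omega = (g2 * dx[:, 0] - g1 * dx[:, 1]) / det
    return float(np.sum(omega))


def _arc_to_line(p, q, u, line, direction, rtol, atol):
    """Integrate a constant-dose arc from q until it crosses the singular
    line (residual crossing with the given direction); returns (T, hit)."""

    def cross(t, y):
        return line.a * y[0] + line.b * y[1] - line.c

    cross.terminal = True
    cross.direction = direction
    sol = _solve_arc(p, np.asarray(q, float), 0.0, 1e3, lambda y: u, [cross], rtol, atol, None)
    if sol.status != 1:
        raise RuntimeError("arc never returned to the singular line")
    return float(sol.t[-1]), np.asarray(sol.y[:, -1], dtype=float)


def shoot_between(q1, q2, p: Params, word: str = "XY", *, rtol=1e-11, atol=1e-12):
    """Two-arc connection between nearby points of the singular segment.

    Finds by 1-D bisection the first-arc duration such that the ``word``
    trajectory (``"XY"`` or ``"YX"``) from ``q1`` returns to the singular
    line at ``q2``; returns the arc times ``(t_first, t_second)``.
    """
    from scipy.optimize import brentq

    from .geometry import line_coefficients

    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    if np.allclose(q1, q2, atol=1e-14):
        return (0.0, 0.0)
    if word not in ("XY", "YX"):
        raise ValueError("word must be 'XY' or 'YX'")
    line = line_coefficients(p)
    u1, u2 = (0.0, p.M) if word == "XY" else (p.M, 0.0)
    # XY excursions live on the gamma<0 side (residual > 0), YX on gamma>0:
    # the second arc crosses back with the matching direction
    direction = -1.0 if word == "XY" else 1.0

    def miss(tau: float) -> float:
        if tau <= 0.0:
            return float(q1[0] - q2[0])

        def f(t, y):
            x1, x2 = y
            k = 1.0 - (x1 + x2)
            return (
                k * x1 - p.eps * x1 - (p.alpha + p.d) * u1 * x1,
                p.pr * k * x2 + p.eps * x1 + p.alpha * u1 * x1,
            )

        sol = solve_ivp(f, (0.0, tau), q1, method="LSODA", rtol=rtol, atol=atol)
        mid = np.asarray(sol.y[:, -1], dtype=float)
        _, hit = _arc_to_line(p, mid, u2, line, direction, rtol, atol)
        return float(hit[0] - q2[0])

    # bracket the root in the first-arc duration
    hi = 1e-4
    m0 = miss(0.0)
    while miss(hi) * m0 > 0.0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("shooting failed: no bracketing first-arc duration")
    tau = brentq(miss, 0.0, hi, xtol=1e-12)

    def f1(t, y):
        x1, x2 = y
        k = 1.0 - (x1 + x2)
        return (
            k * x1 - p.eps * x1 - (p.alpha + p.d) * u1 * x1,
            p.pr * k * x2 + p.eps * x1 + p.alpha * u1 * x1,
        )

    sol = solve_ivp(f1, (0.0, tau), q1, method="LSODA", rtol=rtol, atol=atol)
    mid = np.asarray(sol.y[:, -1], dtype=float)
    t2, hit = _arc_to_line(p, mid, u2, line, direction, rtol, atol)
    if abs(hit[0] - q2[0]) > 1e-6:
        raise RuntimeError(f"shooting miss {abs(hit[0] - q2[0]):.2e} too large")
    return (float(tau), float(t2))
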