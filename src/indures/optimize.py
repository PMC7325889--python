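"""Maximization of the failure time over the structured control family.

The proven optimal structure is a word ``(YX)^n u_p Y`` (bang prefix,
boundary sliding, terminal max dose); the bang-bang words without a
sliding arc (``Y``, ``YX``, ``XY``, ``YXY``) are searched as well, since
the sliding arc may be infeasible at contact.  Within each word the free
parameters are the bang arc durations; the final approach arc before
sliding is event-determined (it ends at boundary contact), so it
contributes no free parameter.  Search is a deterministic coarse grid
followed by coordinate-wise golden-section refinement — no randomness
anywhere, so results are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .controls import ArcMode, ControlArc, PiecewiseControl, constant_control
from .params import Params
from .simulate import HorizonExceededError, Trajectory, integrate, time_to_failure

__all__ = ["OptimizationResult", "optimize", "evaluate_regularized", "sweep", "structure_word"]

SEARCH_RTOL = 1e-9
# absolute tolerance well below the smallest population scale that still
# matters (deep max-dose arcs drive x1 to ~1e-10 before regrowth)
SEARCH_ATOL = 1e-13
HORIZON = 3000.0
REFINE_XATOL = 1e-4


def _tc(p: Params, ctrl: PiecewiseControl, rtol=SEARCH_RTOL, atol=SEARCH_ATOL) -> float:
    try:
        return time_to_failure(p, ctrl, horizon=HORIZON, rtol=rtol, atol=atol)
    except HorizonExceededError:
        return HORIZON


def _sliding_control(p: Params, durations) -> PiecewiseControl:
    """(YX)^n u_p Y with Y/X arc durations; the last X approach arc is
    supplied by the sliding arc's boundary-seeking phase."""
    arcs: list[ControlArc] = []
    for i, dur in enumerate(durations):
        if dur > 0.0:
            arcs.append(ControlArc(ArcMode.MAX if i % 2 == 0 else ArcMode.ZERO, duration=dur))
    arcs.append(ControlArc(ArcMode.PATH_FEEDBACK))
    arcs.append(ControlArc(ArcMode.MAX))
    return PiecewiseControl(tuple(arcs))


def _bang_control(durations, modes) -> PiecewiseControl:
    arcs = [
        ControlArc(m, duration=dur) for m, dur in zip(modes[:-1], durations) if dur > 0.0
    ]
    arcs.append(ControlArc(modes[-1]))
    return PiecewiseControl(tuple(arcs))


def structure_word(traj: Trajectory, p: Params, dose_tol: float = 1e-9) -> str:
    """Read the realized arc word (e.g. ``"YXupY"``) off a trajectory."""
    sliding = list(
        zip(traj.event_times("SLIDING_START"), traj.event_times("SLIDING_END"))
    )
    labels = []
    for t, u in zip(traj.times, traj.doses):
        if any(a - 1e-12 <= t < b for a, b in sliding):
            lab = "up"
        elif u <= dose_tol:
            lab = "X"
        elif abs(u - p.M) <= 1e-9 * max(1.0, p.M):
            lab = "Y"
        else:
            lab = "c"
        if not labels or labels[-1] != lab:
            labels.append(lab)
    # zero-length sliding windows still count as boundary contact only
    return "".join(labels)


@dataclass
class OptimizationResult:
    """Best structured control found for one parameter set."""

    best_control: PiecewiseControl
    t_c: float
    structure_label: str
    trajectory: Trajectory
    candidates: dict[str, float] = field(default_factory=dict)
    switch_durations: tuple[float, ...] = ()


def _refine(fun, x0, bounds, spans, sweeps: int = 2):
    """Coordinate-wise bounded scalar ascent of ``fun`` (maximization).

    Each coordinate is refined on a window of one grid spacing around the
    incumbent, where the coarse grid guarantees rough unimodality."""
    x = list(x0)
    best = fun(x)
    for _ in range(sweeps):
        for k in range(len(x)):
            lo, hi = bounds[k]
            span = spans[k]
            a = max(lo, x[k] - span)
            b = min(hi, x[k] + span)
            if b - a < REFINE_XATOL:
                continue

            def neg(v):
                trial = list(x)
                trial[k] = v
                return -fun(trial)

            res = minimize_scalar(
                neg, bounds=(a, b), method="bounded", options={"xatol": REFINE_XATOL}
            )
            if -res.fun > best:
                best = -res.fun
                x[k] = float(res.x)
    return x, best


def optimize(
    p: Params,
    n_max: int = 2,
    *,
    grid_1d: int = 24,
    grid_2d: int = 16,
    grid_3d: int = 8,
) -> OptimizationResult:
    """Maximize ``t_c`` over the structured family with ``n <= n_max``
    interior YX switch pairs (plus the bang-bang words)."""
    cands: dict[str, tuple[float, tuple[float, ...], object]] = {}

    def consider(label, value, durations, builder):
        if label not in cands or value > cands[label][0]:
            cands[label] = (value, tuple(durations), builder)

    # constant corner controls
    consider("Y", _tc(p, constant_control(p.M)), (), lambda d: constant_control(p.M))
    consider("X", _tc(p, constant_control(0.0)), (), lambda d: constant_control(0.0))
    # sliding family, n = 0: drift to the boundary, slide, terminal Y
    consider("slide0", _tc(p, _sliding_control(p, ())), (), lambda d: _sliding_control(p, ()))

    t_y = cands["Y"][0]
    t_x = cands["X"][0]
    b_y = min(max(1.5 * t_y, 10.0), HORIZON)  # Y-arc duration bound
    b_x = min(max(1.5 * t_x, 10.0), HORIZON)  # X-arc duration bound

    if n_max >= 1:
        # sliding family, n = 1: free first Y duration
        fun1 = lambda d: _tc(p, _sliding_control(p, (d[0],)))
        grid = np.linspace(0.0, b_y, grid_1d)
        step = grid[1] - grid[0]
        vals = [fun1((t,)) for t in grid]
        k = int(np.argmax(vals))
        x, v = _refine(fun1, [grid[k]], [(0.0, b_y)], [step])
        consider("slide1", v, x, lambda d: _sliding_control(p, (d[0],)))

        # bang words YX. and XY.
        fun_yx = lambda d: _tc(p, _bang_control((d[0],), (ArcMode.MAX, ArcMode.ZERO)))
        grid = np.linspace(0.0, b_y, grid_2d)
        step = grid[1] - grid[0]
        vals = [fun_yx((t,)) for t in grid]
        k = int(np.argmax(vals))
        x, v = _refine(fun_yx, [grid[k]], [(0.0, b_y)], [step])
        consider("YX", v, x, lambda d: _bang_control((d[0],), (ArcMode.MAX, ArcMode.ZERO)))

        fun_xy = lambda d: _tc(p, _bang_control((d[0],), (ArcMode.ZERO, ArcMode.MAX)))
        grid = np.linspace(0.0, b_x, grid_2d)
        step = grid[1] - grid[0]
        vals = [fun_xy((t,)) for t in grid]
        k = int(np.argmax(vals))
        x, v = _refine(fun_xy, [grid[k]], [(0.0, b_x)], [step])
        consider("XY", v, x, lambda d: _bang_control((d[0],), (ArcMode.ZERO, ArcMode.MAX)))

        # bang word YXY (the candidate bang-bang junction)
        fun_yxy = lambda d: _tc(
            p, _bang_control((d[0], d[1]), (ArcMode.MAX, ArcMode.ZERO, ArcMode.MAX))
        )
        g1 = np.linspace(0.0, b_y, grid_2d)
        g2 = np.linspace(0.0, b_x, grid_2d)
        best_v, best_x = -np.inf, (0.0, 0.0)
        for t1 in g1:
            for t2 in g2:
                v = fun_yxy((t1, t2))
                if v > best_v:
                    best_v, best_x = v, (t1, t2)
        x, v = _refine(fun_yxy, list(best_x), [(0.0, b_y), (0.0, b_x)],
                       [g1[1] - g1[0], g2[1] - g2[0]])
        consider(
            "YXY",
            v,
            x,
            lambda d: _bang_control((d[0], d[1]), (ArcMode.MAX, ArcMode.ZERO, ArcMode.MAX)),
        )

    if n_max >= 2:
        # sliding family, n = 2: Y, X, Y durations free (second X arc is
        # the event-determined approach)
        fun2 = lambda d: _tc(p, _sliding_control(p, (d[0], d[1], d[2])))
        g1 = np.linspace(0.0, b_y, grid_3d)
        g2 = np.linspace(0.0, b_x, grid_3d)
        best_v, best_x = -np.inf, (0.0, 0.0, 0.0)
        for t1 in g1:
            for t2 in g2:
                for t3 in g1:
                    v = fun2((t1, t2, t3))
                    if v > best_v:
                        best_v, best_x = v, (t1, t2, t3)
        x, v = _refine(fun2, list(best_x), [(0.0, b_y), (0.0, b_x), (0.0, b_y)],
                       [g1[1] - g1[0], g2[1] - g2[0], g1[1] - g1[0]])
        consider("slide2", v, x, lambda d: _sliding_control(p, tuple(d)))

    best_label = max(cands, key=lambda k: cands[k][0])
    _, durations, builder = cands[best_label]
    best_ctrl = builder(durations)
    traj = integrate(p, best_ctrl, HORIZON)
    if traj.t_c is None:
        raise HorizonExceededError("re-simulation of the best control did not fail")
    return OptimizationResult(
        best_control=best_ctrl,
        t_c=traj.t_c,
        structure_label=structure_word(traj, p),
        trajectory=traj,
        candidates={k: v[0] for k, v in cands.items()},
        switch_durations=durations,
    )


def evaluate_regularized(p: Params, ctrl: PiecewiseControl, eta: float) -> float:
    """Regularized objective ``J_eta = -int_0^tc [1 - (1-eta)^2 u^2] dt``.

    Reduces to ``-t_c`` at ``eta = 1``; used as a numerical-accuracy
    probe, not as an alternative optimization target.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    traj = integrate(p, ctrl, HORIZON, dense_n=2000)
    if traj.t_c is None:
        raise HorizonExceededError("control does not fail before the horizon")
    w = 1.0 - (1.0 - eta) ** 2 * traj.doses**2
    return -float(np.trapezoid(w, traj.times))


def sweep(p_base: Params, d_values, alpha_values, n_max: int = 2, **opt_kw):
    """Run the optimizer over a (d, alpha) grid; returns a DataFrame with
    one row per cell (failed cells are recorded, not fatal)."""
    import pandas as pd

    rows = []
    for d in d_values:
        for al in alpha_values:
            p = p_base.replace(d=float(d), alpha=float(al))
            try:
                res = optimize(p, n_max=n_max, **opt_kw)
                rows.append(
                    {
                        "d": d,
                        "alpha": al,
                        "t_c": res.t_c,
                        "structure": res.structure_label,
                        "switch_durations": ";".join(f"{x:.6g}" for x in res.switch_durations),
                        "error": "",
                    }
                )
            except Exception as exc:  # per-cell failure marker
                rows.append(
                    {"d": d, "alpha": al, "t_c": np.nan, "structure": "",
                     "switch_durations": "", "error": str(exc)}
                )
    return pd.DataFrame(rows)
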