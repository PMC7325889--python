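"""Adjoint / extremal-lift machinery for Maximum Principle checks.

The Hamiltonian is ``H = -lambda0 + <lam, f> + u <lam, g>`` with
switching function ``Phi = <lam, g>``; along a normalized extremal lift
(``lambda0 = 1``) ``H`` vanishes identically and ``Phi`` obeys
``dPhi/dt = gamma + (beta - u gamma) Phi``.  The lift is used as a
*verifier* of computed controls (sign of ``Phi`` vs the applied bang
value, residual of the switching ODE), not as a shooting solver: the
optimal structure is already pinned down analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .controls import ArcMode, PiecewiseControl
from .geometry import _jac_f, _jac_g, beta, gamma, lie_gamma_along, singular_segment
from .model import control_field, drift_field
from .params import DomainError, Params

__all__ = [
    "AdjointLift",
    "hamiltonian",
    "switching_value",
    "adjoint_rhs",
    "initial_covector",
    "integrate_lift",
    "LiftedTrajectory",
    "legendre_clebsch_value",
]


@dataclass(frozen=True)
class AdjointLift:
    """Multipliers of an extremal lift: abnormal flag and covector."""

    lambda0: float
    lam: np.ndarray

    def __post_init__(self) -> None:
        if self.lambda0 == 0.0 and np.allclose(self.lam, 0.0):
            raise ValueError("(lambda0, lam) must be nonzero")


def hamiltonian(lift: AdjointLift, s, u: float, p: Params) -> float:
    """``H = -lambda0 + <lam, f> + u <lam, g>``."""
    return float(
        -lift.lambda0
        + lift.lam @ drift_field(s, p)
        + u * (lift.lam @ control_field(s, p))
    )


def switching_value(lift: AdjointLift, s, p: Params) -> float:
    """Switching function ``Phi = <lam, g>``."""
    return float(lift.lam @ control_field(s, p))


def adjoint_rhs(lift: AdjointLift, s, u: float, p: Params) -> np.ndarray:
    """Adjoint equation right-hand side ``-(D(f + u g))^T lam``."""
    J = _jac_f(s, p) + u * _jac_g(p)
    return -J.T @ lift.lam


def initial_covector(p: Params, s0, u0: float, phi0: float) -> np.ndarray:
    """Covector with ``H = 0`` (``lambda0 = 1``) and ``Phi(0) = phi0``.

    Solves ``<lam, f> = 1 - u0 phi0`` and ``<lam, g> = phi0``; unique
    wherever ``f`` and ``g`` are independent (``x1 > 0``).
    """
    A = np.vstack([drift_field(s0, p), control_field(s0, p)])
    if abs(np.linalg.det(A)) < 1e-300:
        raise DomainError("f and g dependent at s0 (x1 = 0): no normalized lift")
    return np.linalg.solve(A, np.array([1.0 - u0 * phi0, phi0]))


@dataclass
class LiftedTrajectory:
    times: np.ndarray
    states: np.ndarray
    lams: np.ndarray
    doses: np.ndarray

    def phi(self, p: Params) -> np.ndarray:
        g = np.column_stack(
            [-(p.alpha + p.d) * self.states[:, 0], p.alpha * self.states[:, 0]]
        )
        return np.einsum("ij,ij->i", self.lams, g)

    def hamiltonian(self, p: Params) -> np.ndarray:
        x1, x2 = self.states[:, 0], self.states[:, 1]
        k = 1.0 - x1 - x2
        f = np.column_stack([k * x1 - p.eps * x1, p.pr * k * x2 + p.eps * x1])
        lf = np.einsum("ij,ij->i", self.lams, f)
        return -1.0 + lf + self.doses * self.phi(p)

    def switching_ode_residual(self, p: Params) -> np.ndarray:
        """Residual of ``dPhi/dt = gamma + (beta - u gamma) Phi``, with the
        left side computed independently as ``<lam, [f, g]>``."""
        from .geometry import lie_bracket_fg

        phi = self.phi(p)
        res = np.empty_like(phi)
        for i, (s, lam, u) in enumerate(zip(self.states, self.lams, self.doses)):
            lhs = float(lam @ lie_bracket_fg(s, p))
            rhs = gamma(s, p) + (beta(s, p) - u * gamma(s, p)) * phi[i]
            res[i] = lhs - rhs
        return res


def integrate_lift(
    p: Params,
    ctrl: PiecewiseControl,
    lam0_init,
    *,
    n_per_arc: int = 400,
    rtol: float = 1e-11,
    atol: float = 1e-12,
) -> LiftedTrajectory:
    """Co-integrate state and adjoint along a bang/constant control.

    Arcs must have finite durations and constant doses (PMP verification
    is restricted to interior sub-arcs; sliding arcs are excluded).
    """
    for a in ctrl.arcs[:-1]:
        if a.mode in (ArcMode.PATH_FEEDBACK, ArcMode.SINGULAR) or a.duration is None:
            raise ValueError("lift integration supports finite constant-dose arcs only")
    y = np.concatenate([np.array(p.x0), np.asarray(lam0_init, dtype=float)])
    t = 0.0
    T, X, L, U = [t], [y[:2].copy()], [y[2:].copy()], []

    for arc in ctrl.arcs:
        if arc.duration is None:
            break
        u = arc.dose(y[:2], p)
        if not U:
            U.append(u)

        def f(tt, yy, _u=u):
            x1, x2, l1, l2 = yy
            k = 1.0 - x1 - x2
            dx1 = k * x1 - p.eps * x1 - (p.alpha + p.d) * _u * x1
            dx2 = p.pr * k * x2 + p.eps * x1 + p.alpha * _u * x1
            J11 = 1.0 - 2.0 * x1 - x2 - p.eps - (p.alpha + p.d) * _u
            J12 = -x1
            J21 = p.eps - p.pr * x2 + p.alpha * _u
            J22 = p.pr * (1.0 - x1 - 2.0 * x2)
            dl1 = -(J11 * l1 + J21 * l2)
            dl2 = -(J12 * l1 + J22 * l2)
            return (dx1, dx2, dl1, dl2)

        teval = np.linspace(t, t + arc.duration, n_per_arc)[1:]
        sol = solve_ivp(
            f, (t, t + arc.duration), y, method="LSODA", rtol=rtol, atol=atol, t_eval=teval
        )
        for tk, yk in zip(sol.t, sol.y.T):
            T.append(float(tk))
            X.append(yk[:2].copy())
            L.append(yk[2:].copy())
            U.append(u)
        t = float(sol.t[-1])
        y = np.asarray(sol.y[:, -1], dtype=float)
    U = U[: len(T)] if len(U) >= len(T) else U + [U[-1]] * (len(T) - len(U))
    return LiftedTrajectory(
        times=np.asarray(T),
        states=np.asarray(X),
        lams=np.asarray(L),
        doses=np.asarray(U, dtype=float),
    )


def legendre_clebsch_value(s, p: Params, tol: float = 1e-6) -> float:
    """``<lam, [g,[f,g]]> = L_g gamma = (L_Y gamma - L_X gamma)/M`` on the
    singular segment; a positive value certifies that the generalized
    Legendre-Clebsch (Kelley) condition is violated there, i.e. singular
    dwell is sub-optimal."""
    seg = singular_segment(p)
    if seg is None:
        raise DomainError("no admissible singular segment for these parameters")
    x1 = float(s[0])
    if not (seg[0] - tol <= x1 <= seg[1] + tol):
        raise DomainError(f"x1 = {x1} off the singular segment {seg}")
    return (lie_gamma_along(s, p, p.M) - lie_gamma_along(s, p, 0.0)) / p.M
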