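"""Phase-plane geometry of the control problem.

For the control-affine system ``dx/dt = f + u g`` the Lie bracket
decomposes on the basis ``(f, g)`` as ``[f, g] = gamma f + beta g``
(possible wherever ``det(f, g) != 0``, i.e. ``x1 > 0``).  The zero set of
``gamma`` is the line ``L: a x1 + b x2 = c``; singular arcs can only live
on ``L``, and the admissible singular segment ``Lbar`` is the portion of
``L`` where the max-dose field ``Y = f + M g`` has positive Lie
derivative of ``gamma`` (the zero-dose field ``X = f`` always has
``L_X gamma < 0`` there).  The failure boundary ``N: x1 + x2 = Vc``
carries the tangency point ``x*`` where ``Y`` is tangent to ``N``; the
boundary (sliding) feedback is feasible exactly for ``x1 >= x1*``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import control_field, drift_field, in_omega, kappa, volume
from .params import DomainError, Params

__all__ = [
    "SingularLine",
    "TangencyPoint",
    "line_coefficients",
    "det_A",
    "gamma",
    "beta",
    "lie_bracket_fg",
    "tangency_point",
    "lie_V_along",
    "line_interior",
    "lie_gamma_along",
    "lie_gamma_grad",
    "singular_segment",
    "max_dose_kills_sensitive",
    "geometry_report",
]


@dataclass(frozen=True)
class SingularLine:
    """Coefficients of the candidate singular line ``a x1 + b x2 = c``."""

    a: float
    b: float
    c: float

    def residual(self, s) -> float:
        """Signed residual ``a x1 + b x2 - c`` (gamma > 0 iff this < 0)."""
        return self.a * float(s[0]) + self.b * float(s[1]) - self.c

    def x2_of_x1(self, x1: float) -> float:
        """Height of the line at ``x1`` (requires ``b != 0``)."""
        return (self.c - self.a * x1) / self.b


@dataclass(frozen=True)
class TangencyPoint:
    """Point on ``N`` where the max-dose field is tangent to ``N``."""

    x1s: float
    x2s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x1s, self.x2s])


def line_coefficients(p: Params) -> SingularLine:
    """Coefficients of the singular line.

    ``a = alpha((1-pr) + d/(alpha+d))``, ``b = alpha(1-pr) + d pr``,
    ``c = alpha(1-pr) + eps d``; all positive for 0 < pr < 1, alpha, d > 0.
    """
    al, d, pr, eps = p.alpha, p.d, p.pr, p.eps
    if al + d == 0.0:
        raise ValueError("alpha + d = 0: line coefficients degenerate")
    a = al * ((1.0 - pr) + d / (al + d))
    b = al * (1.0 - pr) + d * pr
    c = al * (1.0 - pr) + eps * d
    return SingularLine(a, b, c)


def det_A(s, p: Params) -> float:
    """Determinant of the frame matrix ``A = (f | g)``.

    Equals ``alpha x1^2 kappa + pr (alpha+d) x2 x1 kappa + eps d x1^2``;
    in ``Omega`` it vanishes iff ``x1 = 0``, so ``f`` and ``g`` are
    linearly independent wherever the sensitive population persists.
    """
    x1, x2 = float(s[0]), float(s[1])
    k = 1.0 - (x1 + x2)
    return (
        p.alpha * x1 * x1 * k
        + p.pr * (p.alpha + p.d) * x2 * x1 * k
        + p.eps * p.d * x1 * x1
    )


def gamma(s, p: Params) -> float:
    """Coefficient of ``f`` in ``[f, g] = gamma f + beta g``.

    ``gamma = -(alpha+d) x1^2 (a x1 + b x2 - c) / det_A``; requires
    ``x1 > 0`` so that the frame ``(f, g)`` is invertible.
    """
    x1 = float(s[0])
    if x1 <= 0.0:
        raise DomainError("gamma undefined at x1 <= 0 (det A = 0)")
    line = line_coefficients(p)
    return -(p.alpha + p.d) * x1 * x1 * line.residual(s) / det_A(s, p)


def beta(s, p: Params) -> float:
    """Coefficient of ``g`` in ``[f, g] = gamma f + beta g``.

    Positive throughout ``0 < x1 + x2 < Vc`` under ``Vc < 1 - eps``.
    """
    x1, x2 = float(s[0]), float(s[1])
    if x1 <= 0.0:
        raise DomainError("beta undefined at x1 <= 0 (det A = 0)")
    k = 1.0 - (x1 + x2)
    al, d, pr, eps = p.alpha, p.d, p.pr, p.eps
    num = al * (1.0 - pr) * k * (k - eps) + eps * d * (x1 + pr * x2 + k - eps)
    return x1 * x1 * num / det_A(s, p)


def _jac_f(s, p: Params) -> np.ndarray:
    x1, x2 = float(s[0]), float(s[1])
    return np.array(
        [
            [1.0 - 2.0 * x1 - x2 - p.eps, -x1],
            [p.eps - p.pr * x2, p.pr * (1.0 - x1 - 2.0 * x2)],
        ]
    )


def _jac_g(p: Params) -> np.ndarray:
    return np.array([[-(p.alpha + p.d), 0.0], [p.alpha, 0.0]])


def lie_bracket_fg(s, p: Params) -> np.ndarray:
    """Exact Jacobian-based Lie bracket ``[f, g] = Dg f - Df g``."""
    if not in_omega(s):
        raise DomainError(f"state {tuple(s)} outside Omega")
    f = drift_field(s, p)
    g = control_field(s, p)
    return _jac_g(p) @ f - _jac_f(s, p) @ g


def tangency_point(p: Params) -> TangencyPoint:
    """Tangency point ``x*`` of the max-dose field on ``N``.

    ``x1* = pr (1-Vc) Vc / (d M - (1-Vc)(1-pr))``, ``x2* = Vc - x1*``.
    Exists only when ``M > (1-Vc)(1-pr)/d`` (drug strong enough to shrink
    the tumor somewhere on the boundary).
    """
    thresh = (1.0 - p.Vc) * (1.0 - p.pr) / p.d
    if p.M <= thresh:
        raise ValueError(
            f"no tangency point: need M > (1-Vc)(1-pr)/d = {thresh}, got M = {p.M}"
        )
    x1s = p.pr * (1.0 - p.Vc) * p.Vc / (p.d * p.M - (1.0 - p.Vc) * (1.0 - p.pr))
    return TangencyPoint(x1s, p.Vc - x1s)


def lie_V_along(s, p: Params, u: float) -> float:
    """Lie derivative of the volume ``V = x1 + x2`` along ``f + u g``.

    Equals ``kappa (x1 + pr x2) - d u x1``; on ``N`` with ``u = M`` its
    sign flips from positive to negative across the tangency point.
    """
    x1, x2 = float(s[0]), float(s[1])
    return kappa(s) * (x1 + p.pr * x2) - p.d * u * x1


def line_interior(p: Params) -> bool:
    """Whether the singular line lies interior to the treatment region.

    True iff ``c/a <= Vc`` and ``c/b <= Vc``.  With ``alpha = 0`` the
    line is horizontal (``a = 0``) and, for ``eps > 0``, never interior.
    """
    if p.alpha == 0.0:
        return False
    line = line_coefficients(p)
    return line.c / line.a <= p.Vc and line.c / line.b <= p.Vc


# --- gradient of gamma: symbolic closed form, lowered once to numpy -----

_GAMMA_GRAD_FN = None


def _gamma_grad_fn():
    global _GAMMA_GRAD_FN
    if _GAMMA_GRAD_FN is None:
        import sympy as sp

        x1, x2, pr, eps, al, d = sp.symbols("x1 x2 pr eps alpha d", real=True)
        k = 1 - x1 - x2
        detA = al * x1**2 * k + pr * (al + d) * x2 * x1 * k + eps * d * x1**2
        a = al * ((1 - pr) + d / (al + d))
        b = al * (1 - pr) + d * pr
        c = al * (1 - pr) + eps * d
        gam = -(al + d) * x1**2 * (a * x1 + b * x2 - c) / detA
        grad = [sp.simplify(sp.diff(gam, v)) for v in (x1, x2)]
        _GAMMA_GRAD_FN = sp.lambdify((x1, x2, pr, eps, al, d), grad, "numpy")
    return _GAMMA_GRAD_FN


def lie_gamma_grad(s, p: Params) -> np.ndarray:
    """Exact gradient of ``gamma`` (symbolically derived, cached)."""
    x1 = float(s[0])
    if x1 <= 0.0:
        raise DomainError("grad gamma undefined at x1 <= 0")
    fn = _gamma_grad_fn()
    return np.array(fn(x1, float(s[1]), p.pr, p.eps, p.alpha, p.d), dtype=float)


def lie_gamma_along(s, p: Params, u: float) -> float:
    """Directional derivative of ``gamma`` along ``f + u g``."""
    grad = lie_gamma_grad(s, p)
    vel = drift_field(s, p) + u * control_field(s, p)
    return float(grad @ vel)


@functools.lru_cache(maxsize=256)
def singular_segment(p: Params, xtol: float = 1e-10):
    """Admissible singular segment ``Lbar`` as an ``x1`` interval on ``L``.

    Returns ``(s_bar, c/a)`` where ``s_bar`` solves ``L_Y gamma = 0``
    along the line (found by bracketed root-finding), or ``None`` when no
    admissible segment exists (``alpha = 0``, line not interior, or the
    max-dose Lie derivative non-positive at ``(c/a, 0)``).
    """
    if p.alpha == 0.0 or not line_interior(p):
        return None
    line = line_coefficients(p)
    x1_hi = line.c / line.a

    def lyg(x1: float) -> float:
        return lie_gamma_along((x1, line.x2_of_x1(x1)), p, p.M)

    if lyg(x1_hi) <= 0.0:
        return None
    # L_Y gamma < 0 as x1 -> 0+ on L (Y points out of gamma > 0 there);
    # walk down from c/a for a sign change to bracket the root.
    x1_lo = x1_hi
    for _ in range(200):
        x1_lo *= 0.5
        if lyg(x1_lo) < 0.0:
            break
    else:
        return (0.0, x1_hi)
    s_bar = brentq(lyg, x1_lo, 2.0 * x1_lo, xtol=xtol)
    return (s_bar, x1_hi)


def max_dose_kills_sensitive(p: Params) -> bool:
    """Whether ``u = M`` guarantees a shrinking sensitive population.

    True iff ``M > (1 - eps)/(alpha + d)``.
    """
    return p.M > (1.0 - p.eps) / (p.alpha + p.d)


def geometry_report(p: Params) -> dict:
    """Flat record of the geometric diagnostics for a parameter set."""
    line = line_coefficients(p)
    rec: dict = {
        "a": line.a,
        "b": line.b,
        "c": line.c,
        "line_interior": line_interior(p),
        "max_dose_kills_sensitive": max_dose_kills_sensitive(p),
        "tangency_exists": p.M > (1.0 - p.Vc) * (1.0 - p.pr) / p.d,
    }
    if rec["tangency_exists"]:
        ts = tangency_point(p)
        rec["x1_star"] = ts.x1s
        rec["x2_star"] = ts.x2s
    seg = singular_segment(p) if p.alpha > 0.0 else None
    rec["singular_segment_exists"] = seg is not None
    if seg is not None:
        rec["s_bar"], rec["s_max"] = seg
    return rec
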