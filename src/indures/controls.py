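"""Control laws and the piecewise-control language.

The optimal synthesis uses only five arc kinds: the bang arcs ``X``
(``u = 0``) and ``Y`` (``u = M``), constant intermediate doses, the
boundary feedback ``u_p`` that slides the state along the failure line
``V = Vc``, and the singular feedback ``u_s`` defined on the singular
segment (proved sub-optimal, kept for diagnostics).  The provably
optimal structure is a word ``(YX)^n u_p Y``: a bang prefix, then
sliding until the feedback saturates at the tangency point, then a
terminal max-dose arc.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field

from .geometry import lie_gamma_along, line_coefficients, singular_segment
from .model import constraint_psi, kappa
from .params import DomainError, Params

__all__ = [
    "ArcMode",
    "ControlArc",
    "PiecewiseControl",
    "u_path",
    "u_path_feasible",
    "u_singular",
    "structured_control",
    "pure_bang_control",
    "constant_control",
]

#: tolerance on |psi| for "state is on the boundary N"
BOUNDARY_TOL = 1e-8


class ArcMode(enum.Enum):
    ZERO = "X"
    MAX = "Y"
    CONST = "const"
    PATH_FEEDBACK = "up"
    SINGULAR = "us"


@dataclass(frozen=True)
class ControlArc:
    """One arc of a piecewise control.

    ``duration`` is a finite time length, or ``None`` for
    condition-terminated arcs (a PATH_FEEDBACK arc ends when the
    feedback saturates at ``M``; a trailing bang arc ends at failure).
    """

    mode: ArcMode
    duration: float | None = None
    value: float | None = None  # CONST only

    def __post_init__(self) -> None:
        if self.duration is not None and (
            not math.isfinite(self.duration) or self.duration < 0.0
        ):
            raise ValueError(f"arc duration must be finite and >= 0, got {self.duration}")
        if self.mode is ArcMode.CONST and self.value is None:
            raise ValueError("CONST arc requires a dose value")

    def dose(self, s, p: Params) -> float:
        """Dose applied at state ``s`` (never clamped; arcs are switched
        before the feedback laws would leave ``[0, M]``)."""
        if self.mode is ArcMode.ZERO:
            return 0.0
        if self.mode is ArcMode.MAX:
            return p.M
        if self.mode is ArcMode.CONST:
            if not 0.0 <= self.value <= p.M:
                raise ValueError(f"constant dose {self.value} outside [0, {p.M}]")
            return self.value
        if self.mode is ArcMode.PATH_FEEDBACK:
            return u_path(s, p)
        return u_singular(s, p)


@dataclass(frozen=True)
class PiecewiseControl:
    """Ordered concatenation of control arcs (read left to right)."""

    arcs: tuple[ControlArc, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n_fb = sum(1 for a in self.arcs if a.mode is ArcMode.PATH_FEEDBACK)
        if n_fb > 1:
            raise ValueError("at most one PATH_FEEDBACK arc is allowed")

    @property
    def word(self) -> str:
        return "".join(a.mode.value for a in self.arcs)

    def to_json(self) -> str:
        items = []
        for a in self.arcs:
            rec: dict = {"mode": a.mode.name}
            if a.value is not None:
                rec["value"] = a.value
            if a.duration is not None:
                rec["duration"] = a.duration
            else:
                rec["until"] = (
                    "FEEDBACK_SATURATES" if a.mode is ArcMode.PATH_FEEDBACK else "FAILURE"
                )
            items.append(rec)
        return json.dumps(items)

    @classmethod
    def from_json(cls, text: str) -> "PiecewiseControl":
        arcs = []
        for rec in json.loads(text):
            arcs.append(
                ControlArc(
                    mode=ArcMode[rec["mode"]],
                    duration=rec.get("duration"),
                    value=rec.get("value"),
                )
            )
        return cls(tuple(arcs))


def u_path(s, p: Params) -> float:
    """Boundary (sliding) feedback holding ``dV/dt = 0``.

    ``u_p = (1/d) (1 - (x1+x2)) (x1 + pr x2) / x1``.  The value is not
    clamped: on ``N`` it exceeds ``M`` precisely for ``x1 < x1*``.
    """
    x1, x2 = float(s[0]), float(s[1])
    if x1 <= 0.0:
        raise DomainError("boundary feedback undefined at x1 <= 0")
    return kappa(s) * (x1 + p.pr * x2) / (p.d * x1)


def u_path_feasible(s, p: Params, tol: float = 1e-6) -> bool:
    """Whether the sliding feedback is admissible at a point of ``N``.

    The control set is closed, so ``u_p = M`` (the tangency point) counts
    as feasible.
    """
    if abs(constraint_psi(s, p)) > tol:
        raise DomainError(f"state {tuple(s)} not on the boundary N")
    return 0.0 <= u_path(s, p) <= p.M * (1.0 + 1e-12)


def u_singular(s, p: Params, tol: float = 1e-6) -> float:
    """Singular feedback on the segment ``Lbar`` of the line ``a x1 + b x2 = c``.

    Derived from tangency to the line (``a dx1/dt + b dx2/dt = 0``)::

        u_s = (a (kappa - eps) x1 + b eps x1 + b pr kappa x2)
              / (2 alpha d (1 - pr) x1)

    and equal to ``M L_X gamma / (L_X gamma - L_Y gamma)``; strictly in
    ``(0, M)`` on the interior of ``Lbar`` and exactly ``M`` at the lower
    endpoint ``s_bar``.
    """
    x1, x2 = float(s[0]), float(s[1])
    line = line_coefficients(p)
    if abs(line.residual(s)) > tol * max(1.0, line.c):
        raise DomainError(f"state {tuple(s)} not on the singular line")
    seg = singular_segment(p)
    if seg is None or not (seg[0] - tol <= x1 <= seg[1] + tol):
        raise DomainError(f"state {tuple(s)} off the singular segment")
    denom = 2.0 * p.alpha * p.d * (1.0 - p.pr) * x1
    if denom == 0.0:
        raise ZeroDivisionError("degenerate singular feedback (alpha d (1-pr) x1 = 0)")
    k = 1.0 - (x1 + x2)
    num = line.a * (k - p.eps) * x1 + line.b * p.eps * x1 + line.b * p.pr * k * x2
    return num / denom


def u_singular_lie(s, p: Params) -> float:
    """Independent form of the singular feedback via Lie derivatives."""
    lx = lie_gamma_along(s, p, 0.0)
    ly = lie_gamma_along(s, p, p.M)
    if lx == ly:
        raise ZeroDivisionError("L_X gamma = L_Y gamma: singular dose degenerate")
    return p.M * lx / (lx - ly)


def structured_control(n: int, t_switches, p: Params) -> PiecewiseControl:
    """Build the ``(YX)^n u_p Y`` word from absolute switch times.

    ``t_switches`` are the ``2n`` non-decreasing bang switch times; the
    prefix alternates ``Y`` then ``X`` starting at ``t = 0``.  After the
    prefix a PATH_FEEDBACK arc runs until the feedback saturates (the
    simulator extends the final ``X`` arc to boundary contact, where the
    sliding arc activates), followed by a terminal max-dose arc until
    failure.  Zero-duration arcs are dropped, so the family contains the
    degenerate words ``Y``, ``u_p Y``, ``Y X u_p Y``, etc.
    """
    t_switches = [float(t) for t in t_switches]
    if len(t_switches) != 2 * n:
        raise ValueError(f"expected {2 * n} switch times, got {len(t_switches)}")
    if any(b < a for a, b in zip(t_switches, t_switches[1:])):
        raise ValueError("switch times must be non-decreasing")
    arcs: list[ControlArc] = []
    prev = 0.0
    for i, t in enumerate(t_switches):
        dur = t - prev
        mode = ArcMode.MAX if i % 2 == 0 else ArcMode.ZERO
        if dur > 0.0:
            arcs.append(ControlArc(mode, duration=dur))
        prev = t
    arcs.append(ControlArc(ArcMode.PATH_FEEDBACK))
    arcs.append(ControlArc(ArcMode.MAX))
    return PiecewiseControl(tuple(arcs))


def pure_bang_control(t_switches, first: ArcMode = ArcMode.MAX) -> PiecewiseControl:
    """Bang-bang word with no sliding arc: alternating arcs from ``first``
    at the given absolute switch times, then the final bang mode held
    until failure."""
    t_switches = [float(t) for t in t_switches]
    if any(b < a for a, b in zip(t_switches, t_switches[1:])):
        raise ValueError("switch times must be non-decreasing")
    other = ArcMode.ZERO if first is ArcMode.MAX else ArcMode.MAX
    arcs: list[ControlArc] = []
    prev = 0.0
    mode = first
    for t in t_switches:
        if t - prev > 0.0:
            arcs.append(ControlArc(mode, duration=t - prev))
        prev = t
        mode = other if mode is first else first
    arcs.append(ControlArc(mode))
    return PiecewiseControl(tuple(arcs))


def constant_control(u: float) -> PiecewiseControl:
    """Constant dose held until failure."""
    if u == 0.0:
        return PiecewiseControl((ControlArc(ArcMode.ZERO),))
    return PiecewiseControl((ControlArc(ArcMode.CONST, value=u),))
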