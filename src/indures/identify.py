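"""Structural identifiability via iterated Lie derivatives of the volume.

With the tumor volume ``y = h(x) = x1 + x2`` as the only output, an
entirely sensitive initial state ``x0 = (x10, 0)`` and dosing as the
input, five elementary observables (iterated Lie derivatives of ``h``
along the drift ``f`` and control field ``g``, evaluated at ``x0``)
determine the parameter vector ``(x10, d, alpha, eps, pr)`` exactly and
uniquely.  Closed forms at ``x0``::

    h           = x10
    L_g h       = -d x10
    L_g^2 h     = d (alpha + d) x10
    L_f L_g h   = -d x10 (1 - x10 - eps)
    L_g L_f h   = x10 [-(alpha+d)(1 - 2 x10) + alpha pr (1 - x10) - alpha x10]

and the recovery inverts them in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import Params

__all__ = ["Observables", "RecoveredParams", "lie_observables", "recover"]


@dataclass(frozen=True)
class Observables:
    """Elementary observables of the volume output at ``x0 = (x10, 0)``."""

    h0: float
    Lg_h: float
    Lg2_h: float
    LfLg_h: float
    LgLf_h: float


@dataclass(frozen=True)
class RecoveredParams:
    x10: float
    d: float
    alpha: float
    eps: float
    pr: float


def lie_observables(p: Params) -> Observables:
    """Evaluate the closed-form observables for a parameter set.

    Requires an entirely sensitive initial population (``x20 = 0``); the
    closed forms are derived under that initial condition.
    """
    if p.x20 != 0.0:
        raise ValueError("observables derived for x20 = 0 only")
    x10, d, al, eps, pr = p.x10, p.d, p.alpha, p.eps, p.pr
    return Observables(
        h0=x10,
        Lg_h=-d * x10,
        Lg2_h=d * (al + d) * x10,
        LfLg_h=-d * x10 * (1.0 - x10 - eps),
        LgLf_h=x10 * (-(al + d) * (1.0 - 2.0 * x10) + al * pr * (1.0 - x10) - al * x10),
    )


def recover(obs: Observables) -> RecoveredParams:
    """Exactly invert the observables to ``(x10, d, alpha, eps, pr)``.

    ``x10 = h0``; ``d = -L_g h / x10``; ``alpha = L_g^2 h/(d x10) - d``;
    ``eps = L_f L_g h/(d x10) + 1 - x10``; ``pr`` solved from the
    ``L_g L_f h`` closed form.  Raises if the observables are mutually
    inconsistent (non-positive recovered ``d``); with ``alpha = 0`` the
    relative resistant growth rate drops out of every observable, so
    ``pr`` is flagged non-recoverable.
    """
    x10 = obs.h0
    if not 0.0 < x10 < 1.0:
        raise ValueError(f"h0 = {x10} outside (0, 1)")
    d = -obs.Lg_h / x10
    if d <= 0.0:
        raise ValueError(f"inconsistent observables: recovered d = {d} <= 0")
    alpha = obs.Lg2_h / (d * x10) - d
    eps = obs.LfLg_h / (d * x10) + 1.0 - x10
    if alpha == 0.0:
        raise ValueError("alpha = 0: pr is not recoverable from this observable set")
    pr = (obs.LgLf_h / x10 + (alpha + d) * (1.0 - 2.0 * x10) + alpha * x10) / (
        alpha * (1.0 - x10)
    )
    return RecoveredParams(x10=x10, d=d, alpha=alpha, eps=eps, pr=pr)
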