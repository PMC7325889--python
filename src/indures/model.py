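"""Vector fields and region predicates of the resistance model.

The controlled dynamics are affine in the dose ``u``::

    dx/dt = f(x) + u(t) g(x)

with drift (no drug) and control fields

    f(x) = ( (1 - (x1+x2)) x1 - eps*x1,
             pr (1 - (x1+x2)) x2 + eps*x1 )
    g(x) = ( -(alpha + d) x1,  alpha x1 )

on the simplex ``Omega = {x1, x2 >= 0, x1 + x2 <= 1}``.  With ``eps > 0``
every trajectory tends to the fully resistant equilibrium ``(0, 1)``
regardless of the control, so treatment can only delay failure.
"""

from __future__ import annotations

import numpy as np

from .params import DOMAIN_TOL, ControlBoundsError, DomainError, Params

__all__ = [
    "drift_field",
    "control_field",
    "rhs",
    "volume",
    "kappa",
    "in_omega",
    "in_omega_c",
    "constraint_psi",
    "clip_state",
]

StateLike = "tuple[float, float] | np.ndarray"


def _unpack(s) -> tuple[float, float]:
    x1, x2 = float(s[0]), float(s[1])
    return x1, x2


def volume(s) -> float:
    """Total tumor volume ``V = x1 + x2``."""
    x1, x2 = _unpack(s)
    return x1 + x2


def kappa(s) -> float:
    """Free carrying capacity ``1 - (x1 + x2)``."""
    return 1.0 - volume(s)


def in_omega(s, tol: float = DOMAIN_TOL) -> bool:
    """Membership in the simplex ``Omega`` within absolute tolerance."""
    x1, x2 = _unpack(s)
    return x1 >= -tol and x2 >= -tol and x1 + x2 <= 1.0 + tol


def in_omega_c(s, p: Params, tol: float = DOMAIN_TOL) -> bool:
    """Membership in the treatment region ``{x >= 0, x1 + x2 <= Vc}``.

    The failure boundary ``N`` (where ``x1 + x2 = Vc``) counts as inside.
    """
    x1, x2 = _unpack(s)
    return x1 >= -tol and x2 >= -tol and x1 + x2 <= p.Vc + tol


def constraint_psi(s, p: Params) -> float:
    """Path-constraint function ``psi = x1 + x2 - Vc``.

    Negative in the interior of the treatment region, zero on the
    failure boundary ``N``.
    """
    return volume(s) - p.Vc


def drift_field(s, p: Params) -> np.ndarray:
    """Uncontrolled field ``f``; requires the state to lie in ``Omega``."""
    if not in_omega(s):
        raise DomainError(f"state {tuple(s)} outside Omega")
    x1, x2 = _unpack(s)
    k = 1.0 - (x1 + x2)
    return np.array([k * x1 - p.eps * x1, p.pr * k * x2 + p.eps * x1])


def control_field(s, p: Params) -> np.ndarray:
    """Per-unit-dose field ``g = (-(alpha+d) x1, alpha x1)``."""
    if not in_omega(s):
        raise DomainError(f"state {tuple(s)} outside Omega")
    x1, _ = _unpack(s)
    return np.array([-(p.alpha + p.d) * x1, p.alpha * x1])


def rhs(s, u: float, p: Params) -> np.ndarray:
    """Controlled field ``f + u g`` for an admissible dose ``u in [0, M]``."""
    if not -DOMAIN_TOL <= u <= p.M + DOMAIN_TOL:
        raise ControlBoundsError(f"dose {u} outside [0, {p.M}]")
    return drift_field(s, p) + u * control_field(s, p)


def clip_state(s: np.ndarray, floor: float = -1e-12) -> np.ndarray:
    """Clamp slightly negative components (integrator underflow) to zero."""
    out = np.asarray(s, dtype=float).copy()
    mask = (out < 0.0) & (out >= floor)
    out[mask] = 0.0
    return out
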