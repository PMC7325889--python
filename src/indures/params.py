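"""Model parameters and the phase-space domain.

The tumor is described by two competing subpopulations sharing a joint
carrying capacity (scaled to 1): a drug-sensitive fraction ``x1`` and a
fully resistant fraction ``x2``.  The drug kills sensitive cells
(log-kill, rate ``d*u*x1``) and induces transitions to resistance at rate
``alpha*u*x1`` on top of the spontaneous rate ``eps*x1``.  Treatment is
judged failed once the total volume ``V = x1 + x2`` exceeds the critical
volume ``Vc``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

__all__ = ["Params", "TABLE1", "PRESETS", "DomainError", "ControlBoundsError"]

#: absolute tolerance for domain-membership tests; absorbs integrator drift
DOMAIN_TOL = 1e-9


class DomainError(ValueError):
    """State outside the admissible region (or off a required manifold)."""


class ControlBoundsError(ValueError):
    """Dose outside the admissible control set [0, M]."""


@dataclass(frozen=True)
class Params:
    """Model and problem constants, plus the initial state.

    Parameters
    ----------
    pr : float
        Relative growth rate of resistant cells, ``0 <= pr < 1``
        (resistant cells divide no faster than sensitive ones).
    eps : float
        Spontaneous (drug-independent) sensitive-to-resistant transition
        rate, per unit time.
    alpha : float
        Drug-induced transition rate, per unit dose-time.
    d : float
        Drug cytotoxicity (log-kill coefficient), per unit dose-time.
        Must be positive: the boundary feedback and the identifiability
        recovery both divide by ``d``.
    M : float
        Maximum tolerated dose.
    Vc : float
        Critical tumor volume (fraction of carrying capacity) defining
        treatment failure; requires ``0 < Vc < 1 - eps``.
    x10, x20 : float
        Initial sensitive/resistant fractions, inside the constrained
        region ``x1 + x2 <= Vc`` with ``x10 > 0``.
    """

    pr: float = 0.2
    eps: float = 1e-6
    alpha: float = 1e-2
    d: float = 1.0
    M: float = 5.0
    Vc: float = 0.9
    x10: float = 1e-2
    x20: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pr < 1.0:
            raise ValueError(f"pr must satisfy 0 <= pr < 1, got {self.pr}")
        if self.eps < 0.0 or self.alpha < 0.0:
            raise ValueError("eps and alpha must be non-negative")
        if self.d <= 0.0:
            raise ValueError(
                "d must be positive: the boundary feedback and parameter "
                "recovery divide by the cytotoxicity"
            )
        if self.M <= 0.0:
            raise ValueError(f"M must be positive, got {self.M}")
        if not 0.0 < self.Vc < 1.0 - self.eps:
            raise ValueError(
                f"Vc must lie in (0, 1 - eps) = (0, {1.0 - self.eps}), got {self.Vc}"
            )
        if self.x10 <= 0.0:
            raise ValueError("x10 must be positive (x1 = 0 is control-invariant)")
        if self.x20 < -DOMAIN_TOL:
            raise ValueError("x20 must be non-negative")
        if self.x10 + self.x20 > self.Vc + DOMAIN_TOL:
            raise ValueError(
                f"initial volume {self.x10 + self.x20} exceeds the critical volume {self.Vc}"
            )

    @property
    def x0(self) -> tuple[float, float]:
        """Initial state ``(x10, x20)``."""
        return (self.x10, self.x20)

    def replace(self, **changes) -> "Params":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- flat key/value (JSON or YAML) serialization ---------------------

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "Params":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "Params":
        """Load from a flat JSON or YAML config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


#: Baseline parameter set used throughout the numerical experiments.
TABLE1 = Params(pr=0.2, eps=1e-6, alpha=1e-2, d=1.0, M=5.0, Vc=0.9, x10=1e-2, x20=0.0)

PRESETS: dict[str, Params] = {"table1": TABLE1}
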