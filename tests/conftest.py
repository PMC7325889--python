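import numpy as np
import pytest

from indures import TABLE1, Params


@pytest.fixture(scope="session")
def table1() -> Params:
    return TABLE1


@pytest.fixture(scope="session")
def fig9_params() -> Params:
    """Weakly cytotoxic, weakly inducing drug: boundary-sliding optimum."""
    return TABLE1.replace(d=0.05, alpha=0.005)


@pytest.fixture(scope="session")
def interior_grid():
    """Grid of states strictly inside the treatment region (x1 > 0)."""
    pts = []
    for x1 in np.linspace(0.02, 0.85, 12):
        for x2 in np.linspace(0.0, 0.85, 12):
            if x1 + x2 < 0.88:
                pts.append((x1, x2))
    return pts
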