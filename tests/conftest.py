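import numpy as np
import pytest

from fibsinet.fibsi import Trace
from fibsinet.synthetic import (
    CalciumNetworkParams,
    EpscParams,
    generate_calcium_network,
    generate_epsc_recording,
)


@pytest.fixture(scope="session")
def calcium_field():
    """A small imaging field with default study conditions (active cells only)."""
    params = CalciumNetworkParams(n_cells=10, frac_silent=0.0, seed=11)
    traces, truth = generate_calcium_network(params)
    return params, traces, truth


@pytest.fixture(scope="session")
def epsc_recording():
    """One default 180 s, 2 kHz sEPSC recording with planted clusters."""
    params = EpscParams(seed=7)
    trace, truth = generate_epsc_recording(params)
    return params, trace, truth


@pytest.fixture()
def flat_trace():
    t = np.arange(0.0, 50.0)
    return Trace("flat", t, np.full_like(t, 3.0))


def rdp_recursive_oracle(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Naive recursive Ramer-Douglas-Peucker used as an independent oracle."""
    points = np.asarray(points, dtype=float)

    def perp(p, a, b):
        d = b - a
        n = np.hypot(*d)
        if n == 0:
            return np.hypot(*(p - a))
        return abs(d[0] * (a[1] - p[1]) - (a[0] - p[0]) * d[1]) / n

    def rec(i0, i1):
        if i1 - i0 < 2:
            return [i0, i1]
        dmax, imax = -1.0, None
        for i in range(i0 + 1, i1):
            d = perp(points[i], points[i0], points[i1])
            if d > dmax:
                dmax, imax = d, i
        if dmax > epsilon:
            left = rec(i0, imax)
            right = rec(imax, i1)
            return left[:-1] + right
        return [i0, i1]

    return np.array(rec(0, len(points) - 1))
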