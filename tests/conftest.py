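import numpy as np
import pytest
from hypothesis import settings

from boutscape import ModelParams, RenewalParams, compute_potential

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def renewal():
    return RenewalParams()


@pytest.fixture(scope="session")
def landscape(params):
    return compute_potential(params)


def grid_scan_fixed_points(params, n_E=2000, n_bisect=60):
    """Independent brute-force oracle for the model's fixed points.

    For each E on a dense grid, find the inhibitory steady state by plain
    bisection of I - s(w_EI E - w_II I) (hand-rolled, no library root
    finder), then locate sign changes of dE/dt along the resulting curve.
    Returns a list of (E_root, stable) pairs estimated to grid accuracy.
    """
    E = np.linspace(0.0, 1.0, n_E)

    def s(x):
        return 1.0 / (1.0 + np.exp(-params.a * (x - params.theta)))

    lo, hi = np.zeros(n_E), np.ones(n_E)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        g = mid - s(params.w_EI * E - params.w_II * mid)
        hi = np.where(g > 0, mid, hi)
        lo = np.where(g > 0, lo, mid)
    I_hat = 0.5 * (lo + hi)
    f = (-E + s(params.w_EE * E - params.w_IE * I_hat + params.current)) / params.tau_E
    roots = []
    sign = np.sign(f)
    for i in np.nonzero(np.diff(sign) != 0)[0]:
        # linear interpolation of the crossing
        e_root = E[i] - f[i] * (E[i + 1] - E[i]) / (f[i + 1] - f[i])
        roots.append((float(e_root), bool(f[i] > 0)))
    return roots
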