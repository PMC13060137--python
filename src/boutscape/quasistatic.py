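"""Quasi-static 1-D reduction and potential-energy landscape.

Because tau_I << tau_E, the inhibitory population relaxes quickly to its
E-conditional steady state I_hat(E), the unique root of I = s(w_EI E - w_II I).
Substituting I_hat into the excitatory equation gives a one-dimensional flow
whose negative antiderivative is a potential V(E). When the flow has three
roots the landscape is a double well: the lower stable root is the feeding
state, the upper one the non-feeding state, and the middle unstable root
E_th is the threshold between them. The barrier V(E_th) - V(E_feeding)
(with V zeroed at E_th, simply -V(E_feeding)) is the energy a perturbation
must supply to end a feeding bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .model_core import ModelParams, gain, gain_deriv

__all__ = [
    "LandscapeProfile",
    "Root1D",
    "solve_I_steady",
    "effective_drift",
    "find_roots_1d",
    "classify_landscape",
    "compute_potential",
]


@dataclass(frozen=True)
class Root1D:
    """A root of the 1-D effective drift, labeled by its role in the landscape."""

    E: float
    stable: bool
    label: str  # "feeding", "threshold", "non-feeding", or "only"


@dataclass(frozen=True)
class LandscapeProfile:
    """Quasi-static landscape evaluated on a uniform E grid."""

    E_grid: np.ndarray
    I_hat: np.ndarray
    eff_drift: np.ndarray
    V: np.ndarray
    fixed_points: tuple[Root1D, ...]
    bistable: bool
    barrier: float  # NaN when not bistable
    params: ModelParams = field(repr=False)

    @property
    def E_feeding(self) -> float:
        """Location of the feeding (low-E) attractor."""
        return self._by_label("feeding" if self.bistable else "only")

    @property
    def E_threshold(self) -> float:
        if not self.bistable:
            raise ValueError("threshold undefined: landscape is not bistable")
        return self._by_label("threshold")

    @property
    def E_nonfeeding(self) -> float:
        if not self.bistable:
            raise ValueError("non-feeding attractor undefined: landscape is not bistable")
        return self._by_label("non-feeding")

    def _by_label(self, label: str) -> float:
        for r in self.fixed_points:
            if r.label == label:
                return r.E
        raise ValueError(f"no fixed point labeled {label!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "E": self.E_grid, "I_hat": self.I_hat,
            "eff_drift": self.eff_drift, "V": self.V,
        })

    def summary(self) -> dict:
        return {
            "bistable": self.bistable,
            "barrier": self.barrier,
            "current": self.params.current,
            "fixed_points": [
                {"E": r.E, "stable": r.stable, "label": r.label}
                for r in self.fixed_points
            ],
        }

    def write(self, path) -> None:
        """Export the profile as tabular text with a commented summary block."""
        with open(path, "w") as fh:
            for line in _summary_lines(self):
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)


def _summary_lines(prof: LandscapeProfile) -> list[str]:
    lines = [
        f"current = {prof.params.current}",
        f"bistable = {prof.bistable}",
        f"barrier = {prof.barrier}",
    ]
    for r in prof.fixed_points:
        lines.append(f"fixed_point E={r.E:.10g} stable={r.stable} label={r.label}")
    return lines


def solve_I_steady(E: float, params: ModelParams) -> float:
    """Steady-state inhibitory activity I_hat(E): root of I = s(w_EI E - w_II I).

    g(I) = I - s(w_EI E - w_II I) is strictly increasing for w_II > 0, so the
    root is unique; it is bracketed in [0, 1] because s maps into (0, 1).
    """
    if not np.isfinite(E):
        raise ValueError(f"E must be finite, got {E}")

    def g(I: float) -> float:
        return I - gain(params.w_EI * E - params.w_II * I, params.a, params.theta)

    lo, hi = 0.0, 1.0
    if not (g(lo) < 0 < g(hi)):  # cannot occur for w_II > 0; guard anyway
        raise RuntimeError(
            f"failed to bracket I_hat at E={E}: g(0)={g(lo):.3g}, g(1)={g(hi):.3g}"
        )
    root = optimize.brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
    # one Newton polish to push the residual to machine precision
    gp = 1.0 + params.w_II * gain_deriv(
        params.w_EI * E - params.w_II * root, params.a, params.theta)
    root -= g(root) / gp
    return float(min(max(root, 0.0), 1.0))


def effective_drift(E, params: ModelParams):
    """1-D flow dE/dt = (-E + s(w_EE E - w_IE I_hat(E) + current)) / tau_E.

    ``E`` may be a scalar or array.
    """
    E_arr = np.atleast_1d(np.asarray(E, dtype=float))
    I_hat = np.array([solve_I_steady(e, params) for e in E_arr])
    out = (-E_arr + gain(params.w_EE * E_arr - params.w_IE * I_hat + params.current,
                         params.a, params.theta)) / params.tau_E
    return float(out[0]) if np.isscalar(E) or np.ndim(E) == 0 else out


def find_roots_1d(params: ModelParams, *, grid_size: int = 4096) -> list[Root1D]:
    """Roots of the effective drift on [0, 1], labeled by 1-D stability.

    Sign-change bracketing on a uniform grid followed by Brent polishing.
    The flow is positive at E=0 and negative at E=1 (s maps into (0,1)), so
    the root count is odd; more than three roots means the model is outside
    its intended regime and raises ``ValueError``.
    """
    if grid_size < 256:
        raise ValueError(f"grid_size must be >= 256 to isolate roots, got {grid_size}")
    E_grid = np.linspace(0.0, 1.0, grid_size)
    f = effective_drift(E_grid, params)
    sign = np.sign(f)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    roots: list[Root1D] = []
    for i in idx:
        r = optimize.brentq(lambda e: effective_drift(e, params),
                            E_grid[i], E_grid[i + 1], xtol=1e-14)
        stable = f[i] > 0  # flow decreasing through the root
        roots.append(Root1D(float(r), bool(stable), ""))
    if len(roots) > 3:
        raise ValueError(
            f"effective drift has {len(roots)} roots; model outside intended regime"
        )
    if len(roots) == 3:
        labels = ["feeding", "threshold", "non-feeding"]
        roots = [Root1D(r.E, r.stable, lab) for r, lab in zip(roots, labels)]
    elif len(roots) == 1:
        roots = [Root1D(roots[0].E, roots[0].stable, "only")]
    return roots


def classify_landscape(params: ModelParams, *, grid_size: int = 4096) -> list[Root1D]:
    """Fixed points of the 1-D reduction with feeding/threshold/non-feeding labels."""
    return find_roots_1d(params, grid_size=grid_size)


def compute_potential(params: ModelParams, grid_size: int = 4096) -> LandscapeProfile:
    """Potential landscape V(E) = -int dE/dt dE on a uniform grid.

    Trapezoidal accumulation of the negative effective drift, shifted so
    V(E_th) = 0 when the landscape is bistable (V at the global minimum when
    it is not, with ``bistable=False`` and a NaN barrier). The barrier is
    V(E_th) - V(E_feeding) = -V(E_feeding) under the zeroing convention.
    """
    if grid_size < 256:
        raise ValueError(f"grid_size must be >= 256, got {grid_size}")
    E_grid = np.linspace(0.0, 1.0, grid_size)
    I_hat = np.array([solve_I_steady(e, params) for e in E_grid])
    f = (-E_grid + gain(params.w_EE * E_grid - params.w_IE * I_hat + params.current,
                        params.a, params.theta)) / params.tau_E
    roots = find_roots_1d(params, grid_size=grid_size)
    V = -integrate.cumulative_trapezoid(f, E_grid, initial=0.0)

    bistable = len(roots) == 3
    if bistable:
        E_th = roots[1].E
        V = V - np.interp(E_th, E_grid, V)
        E_feed = roots[0].E
        barrier = float(-np.interp(E_feed, E_grid, V))
    else:
        V = V - V.min()
        barrier = float("nan")
    return LandscapeProfile(
        E_grid=E_grid, I_hat=I_hat, eff_drift=f, V=V,
        fixed_points=tuple(roots), bistable=bistable, barrier=barrier,
        params=params,
    )
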