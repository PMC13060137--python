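"""Deterministic core of the excitatory/inhibitory population model.

A single Wilson-Cowan pair: an excitatory population E and an inhibitory
population I coupled through a logistic gain. With the default coupling the
noiseless system is bistable -- a low-E attractor (the feeding state) and a
high-E attractor (the non-feeding state) separated by a saddle. A tonic
``current`` term entering the E gain argument emulates optogenetic-style
tonic drive (negative for inhibition, positive for activation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

__all__ = [
    "ModelParams",
    "PopulationState",
    "FixedPoint",
    "gain",
    "gain_deriv",
    "drift",
    "jacobian",
    "find_fixed_points_2d",
]


@dataclass(frozen=True)
class ModelParams:
    """Constants of the E/I population model.

    Time constants are in seconds; synaptic weights, gain parameters, the
    tonic current and the diffusion amplitude are dimensionless. ``dt`` is
    the Euler-Maruyama integration step in seconds.
    """

    tau_E: float = 2.0
    tau_I: float = 0.4
    w_EE: float = 15.0
    w_EI: float = 10.0
    w_IE: float = 10.0
    w_II: float = 15.0
    a: float = 1.0
    theta: float = 8.0
    current: float = 0.0
    noise_sd: float = 0.1055
    dt: float = 0.02

    def __post_init__(self) -> None:
        if not self.tau_E > 0:
            raise ValueError(f"tau_E must be positive, got {self.tau_E}")
        if not self.tau_I > 0:
            raise ValueError(f"tau_I must be positive, got {self.tau_I}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.dt < self.tau_I:
            raise ValueError(
                f"dt={self.dt} must resolve the fast variable (dt < tau_I={self.tau_I})"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if not self.a > 0:
            raise ValueError(f"gain slope a must be positive, got {self.a}")
        for name in ("tau_E", "tau_I", "w_EE", "w_EI", "w_IE", "w_II", "a",
                     "theta", "current", "noise_sd", "dt"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PopulationState:
    """Instantaneous activity of the two populations (dimensionless fractions)."""

    E: float
    I: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.E) and np.isfinite(self.I)):
            raise ValueError(f"state must be finite, got E={self.E}, I={self.I}")


@dataclass(frozen=True)
class FixedPoint:
    """A root of the drift field with its local linearization."""

    E: float
    I: float
    stability: str  # "stable", "unstable" or "saddle"
    eigenvalues: tuple[complex, complex]


def gain(x, a: float = 1.0, theta: float = 8.0):
    """Logistic gain s(x) = 1 / (1 + exp(-a (x - theta))).

    Strictly increasing from 0 to 1 with s(theta) = 1/2. Accepts scalars or
    arrays; ``a`` must be positive.
    """
    if not a > 0:
        raise ValueError(f"gain slope a must be positive, got {a}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("gain input must be finite")
    out = expit(a * (x - theta))
    return float(out) if out.ndim == 0 else out


def gain_deriv(x, a: float = 1.0, theta: float = 8.0):
    """Derivative of the logistic gain: a * s(x) * (1 - s(x))."""
    s = gain(x, a, theta)
    return a * s * (1.0 - s)


def _as_EI(state) -> tuple:
    if isinstance(state, PopulationState):
        return state.E, state.I
    E, I = state
    return E, I


def drift(state, params: ModelParams):
    """Deterministic vector field (dE/dt, dI/dt).

    dE/dt = (-E + s(w_EE E - w_IE I + current)) / tau_E
    dI/dt = (-I + s(w_EI E - w_II I)) / tau_I

    The tonic current enters only the excitatory gain argument. ``state`` may
    be a :class:`PopulationState` or an (E, I) pair of scalars/arrays.
    """
    E, I = _as_EI(state)
    sE = gain(params.w_EE * E - params.w_IE * I + params.current,
              params.a, params.theta)
    sI = gain(params.w_EI * E - params.w_II * I, params.a, params.theta)
    return (-E + sE) / params.tau_E, (-I + sI) / params.tau_I


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Jacobian matrix of the drift field at ``state``."""
    E, I = _as_EI(state)
    gE = gain_deriv(params.w_EE * E - params.w_IE * I + params.current,
                    params.a, params.theta)
    gI = gain_deriv(params.w_EI * E - params.w_II * I, params.a, params.theta)
    return np.array([
        [(-1.0 + params.w_EE * gE) / params.tau_E, -params.w_IE * gE / params.tau_E],
        [params.w_EI * gI / params.tau_I, (-1.0 - params.w_II * gI) / params.tau_I],
    ])


def _classify_eigs(eigs: np.ndarray) -> str:
    re = np.real(eigs)
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def find_fixed_points_2d(
    params: ModelParams,
    *,
    tol: float = 1e-10,
    dedup_radius: float = 1e-6,
    grid_size: int = 4096,
) -> list[FixedPoint]:
    """All fixed points of the 2-D drift field in [0, 1]^2.

    The roots of the 1-D quasi-static reduction (which shares all steady
    states with the full system) seed a damped-Newton polish of the 2-D
    field; polished roots are deduplicated and labeled by the eigenvalues of
    the local Jacobian. Raises ``RuntimeError`` when a seed fails to polish.
    """
    from . import quasistatic  # deferred: quasistatic imports gain from here

    seeds = [(r.E, quasistatic.solve_I_steady(r.E, params))
             for r in quasistatic.find_roots_1d(params, grid_size=grid_size)]
    points: list[FixedPoint] = []
    for E0, I0 in seeds:
        sol = optimize.root(
            lambda v: np.array(drift((v[0], v[1]), params)),
            x0=np.array([E0, I0]),
            jac=lambda v: jacobian((v[0], v[1]), params),
            method="hybr",
            tol=1e-14,
        )
        resid = float(np.hypot(*drift((sol.x[0], sol.x[1]), params)))
        if not sol.success or resid > tol:
            raise RuntimeError(
                f"fixed-point polishing failed from seed (E={E0:.6g}, I={I0:.6g}): "
                f"residual {resid:.3g}"
            )
        E, I = float(sol.x[0]), float(sol.x[1])
        if any(np.hypot(E - p.E, I - p.I) <= dedup_radius for p in points):
            continue
        eigs = np.linalg.eigvals(jacobian((E, I), params))
        points.append(FixedPoint(E, I, _classify_eigs(eigs),
                                 (complex(eigs[0]), complex(eigs[1]))))
    points.sort(key=lambda p: p.E)
    return points
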