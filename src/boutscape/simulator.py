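"""Stochastic simulation: Euler-Maruyama integration with renewal pulses.

Additive Gaussian noise (diffusion amplitude ``noise_sd`` in
dX = f(X) dt + sigma dW, applied to both populations) drives the model
around its attractors. While the system occupies the feeding (low-E) state,
interruption inputs arrive as a renewal process with lognormal intervals;
each event kicks the excitatory population by a Gaussian pulse E <- E + Delta.
Small kicks produce transient excursions that resettle (intra-bout
interruptions); kicks that clear the threshold commit the system to the
non-feeding attractor (bout terminations).

Tonic-current presets emulate the optogenetic conditions (eOPN3 inhibition:
current -0.7; ChR2 activation: +0.85) and a visual-threat condition that
multiplies the interruption rate without touching the current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ModelParams
from .quasistatic import LandscapeProfile, compute_potential, solve_I_steady

__all__ = [
    "RenewalParams",
    "StateTrajectory",
    "ConditionSpec",
    "sample_renewal_intervals",
    "sample_pulse_amplitudes",
    "simulate",
    "run_condition",
    "label_states",
    "bouts_from_trajectory",
    "events_from_trajectory",
    "trajectory_to_annotations",
]


@dataclass(frozen=True)
class RenewalParams:
    """Lognormal interval law and Gaussian pulse-amplitude law of interruptions.

    Intervals are exp(N(log_mean, log_sd^2)) / rate_scale seconds; pulse
    amplitudes are N(pulse_mean, pulse_sd^2), applied without truncation.
    rate_scale > 1 compresses intervals, emulating a raised interruption
    rate (visual threat) with the interval shape otherwise unchanged.
    """

    log_mean: float = 2.22
    log_sd: float = 0.99
    pulse_mean: float = 0.56
    pulse_sd: float = 0.11
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.log_sd > 0:
            raise ValueError(f"log_sd must be positive, got {self.log_sd}")
        if self.pulse_sd < 0:
            raise ValueError(f"pulse_sd must be non-negative, got {self.pulse_sd}")
        if not self.rate_scale > 0:
            raise ValueError(f"rate_scale must be positive, got {self.rate_scale}")

    def replace(self, **changes) -> "RenewalParams":
        import dataclasses
        return dataclasses.replace(self, **changes)


@dataclass
class StateTrajectory:
    """A simulated session: uniform time grid, state series, pulse log, labels."""

    t: np.ndarray
    E: np.ndarray
    I: np.ndarray
    pulses: list[tuple[float, float]]  # (time, amplitude)
    state_label: np.ndarray  # bool, True = feeding
    seed: object
    params: ModelParams
    renewal: RenewalParams | None
    commit_time: float = 4.0
    E_threshold: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "E": self.E, "I": self.I,
            "label": np.where(self.state_label, "feeding", "non-feeding"),
        })


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition to simulate: current, interruption rate, sessions."""

    name: str
    current: float = 0.0
    rate_scale: float = 1.0
    n_sessions: int = 20
    session_length: float = 600.0
    seed: int = 0
    reentry_rate: float | None = 0.05  # 1/s; mean non-feeding dwell 20 s

    _PRESETS = {
        "baseline": {"current": 0.0, "rate_scale": 1.0},
        "ctrl": {"current": 0.0, "rate_scale": 1.0},
        "eOPN3": {"current": -0.7, "rate_scale": 1.0},
        "ChR2": {"current": 0.85, "rate_scale": 1.0},
        "looming": {"current": 0.0, "rate_scale": 2.0},
    }

    @classmethod
    def preset(cls, name: str, **overrides) -> "ConditionSpec":
        if name not in cls._PRESETS:
            raise KeyError(
                f"unknown preset {name!r}; choose from {sorted(cls._PRESETS)}")
        kw = dict(cls._PRESETS[name])
        kw.update(overrides)
        return cls(name=name, **kw)


def sample_renewal_intervals(rp: RenewalParams, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. renewal intervals, seconds: exp(N(log_mean, log_sd^2))/rate_scale."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(rp.log_mean, rp.log_sd, n)) / rp.rate_scale


def sample_pulse_amplitudes(rp: RenewalParams, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. pulse amplitudes Delta ~ N(pulse_mean, pulse_sd^2), untruncated."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.normal(rp.pulse_mean, rp.pulse_sd, n)


def simulate(
    params: ModelParams,
    rp: RenewalParams | None,
    duration: float,
    seed,
    init=None,
    *,
    commit_time: float = 4.0,
    reentry_rate: float | None = None,
    landscape: LandscapeProfile | None = None,
    forced_pulses: list[tuple[float, float]] | None = None,
) -> StateTrajectory:
    """Euler-Maruyama simulation of one session.

    Per step: X += f(X) dt + noise_sd sqrt(dt) xi, with independent standard
    normals for E and I. The renewal clock accrues time only at sub-threshold
    samples of an ongoing bout (the first interval is drawn at each feeding
    entry); when it expires, E jumps by a sampled Delta and the jump is
    logged. Pass ``rp=None`` to disable renewal pulses; ``forced_pulses``
    injects (time, amplitude) jumps explicitly (for controlled experiments).

    Labels use a hysteresis rule: a bout ends at the first threshold crossing
    whose supra-threshold excursion lasts at least ``commit_time``; shorter
    excursions stay inside the bout. ``reentry_rate``, if set, forces the
    state back to the feeding attractor after an exponentially distributed
    non-feeding dwell (an orchestration extension; noise-driven re-entry is
    always allowed).

    The landscape must be bistable and ``duration >= 10 tau_E``.
    """
    if landscape is None:
        landscape = compute_potential(params)
    if not landscape.bistable:
        raise ValueError("simulation requires a bistable landscape")
    if duration < 10.0 * params.tau_E:
        raise ValueError(
            f"duration {duration} s too short; need >= 10 tau_E = {10 * params.tau_E} s")

    dt = params.dt
    n = int(round(duration / dt))
    E_th = landscape.E_threshold
    commit_steps = max(1, int(round(commit_time / dt)))

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, 2)) * (params.noise_sd * math.sqrt(dt))

    if init is None:
        E0 = landscape.E_feeding
        init = (E0, solve_I_steady(E0, params))
    E_arr = np.empty(n + 1)
    I_arr = np.empty(n + 1)
    label = np.ones(n + 1, dtype=bool)
    E, I = float(init[0]), float(init[1])
    E_arr[0], I_arr[0] = E, I

    feeding = E < E_th
    label[0] = feeding

    forced = sorted(forced_pulses or [])
    forced_i = 0

    def next_interval() -> float:
        if rp is None:
            return math.inf
        return math.exp(rng.normal(rp.log_mean, rp.log_sd)) / rp.rate_scale

    def draw_pulse() -> float:
        return rng.normal(rp.pulse_mean, rp.pulse_sd)

    clock = next_interval() if feeding else math.inf
    nonfeed_dwell = math.inf
    above_idx: int | None = None  # step index of the unresolved upward crossing
    pulses: list[tuple[float, float]] = []

    # cache params in locals for the inner loop
    tau_E, tau_I = params.tau_E, params.tau_I
    w_EE, w_EI, w_IE, w_II = params.w_EE, params.w_EI, params.w_IE, params.w_II
    a, theta, cur = params.a, params.theta, params.current
    exp = math.exp

    for i in range(n):
        t_now = i * dt
        # forced pulses fire at the first grid point at/after their nominal time
        while forced_i < len(forced) and forced[forced_i][0] <= t_now + 0.5 * dt:
            E += forced[forced_i][1]
            pulses.append((t_now, forced[forced_i][1]))
            forced_i += 1

        if feeding and E < E_th and clock is not math.inf:
            clock -= dt
            if clock <= 0.0:
                delta = draw_pulse()
                E += delta
                pulses.append((t_now, delta))
                clock = next_interval()

        xE = a * (w_EE * E - w_IE * I + cur - theta)
        xI = a * (w_EI * E - w_II * I - theta)
        sE = 1.0 / (1.0 + exp(-xE)) if xE > -500 else 0.0
        sI = 1.0 / (1.0 + exp(-xI)) if xI > -500 else 0.0
        E += (-E + sE) / tau_E * dt + noise[i, 0]
        I += (-I + sI) / tau_I * dt + noise[i, 1]
        # E may legitimately reach ~E_th + Delta right after a pulse, so its
        # guard is wider than I's
        if not (-0.5 <= E <= 2.0 and -0.5 <= I <= 1.5):
            raise RuntimeError(
                f"state left its plausible range at t={t_now:.2f} s "
                f"(E={E:.3g}, I={I:.3g}); noise amplitude is likely mis-set")
        j = i + 1
        E_arr[j], I_arr[j] = E, I

        if feeding:
            label[j] = True
            if E >= E_th:
                if above_idx is None:
                    above_idx = j
                elif j - above_idx + 1 >= commit_steps:
                    # excursion outlasted the commit window: the bout ended
                    # retroactively at the crossing
                    label[above_idx:j + 1] = False
                    feeding = False
                    above_idx = None
                    clock = math.inf
                    if reentry_rate is not None:
                        nonfeed_dwell = rng.exponential(1.0 / reentry_rate)
            else:
                above_idx = None
        else:
            label[j] = False
            if reentry_rate is not None:
                nonfeed_dwell -= dt
                if nonfeed_dwell <= 0.0:
                    E = landscape.E_feeding
                    I = solve_I_steady(E, params)
                    E_arr[j], I_arr[j] = E, I
                    label[j] = True
                    feeding = True
                    clock = next_interval()
                    nonfeed_dwell = math.inf
                    continue
            if E < E_th:
                feeding = True
                label[j] = True
                clock = next_interval()

    t = np.arange(n + 1) * dt
    return StateTrajectory(
        t=t, E=E_arr, I=I_arr, pulses=pulses, state_label=label,
        seed=seed, params=params, renewal=rp, commit_time=commit_time,
        E_threshold=E_th,
    )


def label_states(
    traj: StateTrajectory,
    landscape: LandscapeProfile,
    commit_time: float = 4.0,
) -> np.ndarray:
    """Feeding/non-feeding labels for an arbitrary E series.

    Hysteresis rule: within a bout, E excursions above the threshold shorter
    than ``commit_time`` stay labeled feeding (model interruptions); once an
    excursion persists for ``commit_time``, the bout is deemed to have ended
    at the upward crossing. A bout starts at the first sample back below the
    threshold.
    """
    if not landscape.bistable:
        raise ValueError("labeling requires a bistable landscape")
    E = np.asarray(traj.E, dtype=float)
    dt = float(traj.t[1] - traj.t[0])
    E_th = landscape.E_threshold
    commit_steps = max(1, int(round(commit_time / dt)))

    label = np.empty(len(E), dtype=bool)
    feeding = E[0] < E_th
    label[0] = feeding
    above_idx: int | None = None
    for j in range(1, len(E)):
        if feeding:
            label[j] = True
            if E[j] >= E_th:
                if above_idx is None:
                    above_idx = j
                elif j - above_idx + 1 >= commit_steps:
                    label[above_idx:j + 1] = False
                    feeding = False
                    above_idx = None
            else:
                above_idx = None
        else:
            label[j] = E[j] < E_th
            feeding = label[j]
    return label


def run_condition(
    spec: ConditionSpec,
    params: ModelParams | None = None,
    rp: RenewalParams | None = None,
) -> list[StateTrajectory]:
    """Simulate ``spec.n_sessions`` independent seeded sessions for one condition.

    The spec's current and rate_scale are applied on top of the provided (or
    default) parameters; session seeds are spawned from ``spec.seed`` so the
    whole condition is reproducible from one integer.
    """
    base = params if params is not None else ModelParams()
    base = base.replace(current=spec.current)
    rnw = (rp if rp is not None else RenewalParams()).replace(
        rate_scale=spec.rate_scale)
    landscape = compute_potential(base)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_sessions)
    return [
        simulate(base, rnw, spec.session_length, child,
                 reentry_rate=spec.reentry_rate, landscape=landscape)
        for child in children
    ]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean array."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def bouts_from_trajectory(
    traj: StateTrajectory,
    *,
    subject: str = "model",
    condition: str = "model",
    drop_censored: bool = True,
) -> pd.DataFrame:
    """Feeding bouts (contiguous feeding-labeled runs) as a table.

    Runs still open at the session end are right-censored and dropped by
    default. Columns: subject, condition, start, end, duration, n_interruptions.
    """
    dt = float(traj.t[1] - traj.t[0])
    rows = []
    pulse_times = np.array([p[0] for p in traj.pulses])
    for lo, hi in _runs(traj.state_label):
        if drop_censored and hi >= len(traj.state_label):
            continue
        start, end = traj.t[lo], traj.t[min(hi, len(traj.t) - 1)]
        in_bout = (pulse_times >= start) & (pulse_times < end) if pulse_times.size else np.array([], bool)
        n_pulses = int(in_bout.sum())
        # the final pulse of a run that triggered its end is the termination,
        # not an interruption
        n_interruptions = max(0, n_pulses - 1) if _ended_by_pulse(traj, lo, hi) else n_pulses
        rows.append({
            "subject": subject, "condition": condition,
            "start": start, "end": end, "duration": end - start,
            "n_interruptions": n_interruptions,
        })
    return pd.DataFrame(rows, columns=[
        "subject", "condition", "start", "end", "duration", "n_interruptions"])


def _ended_by_pulse(traj: StateTrajectory, lo: int, hi: int,
                    window: float = 1.0) -> bool:
    if hi >= len(traj.state_label):
        return False
    end_t = traj.t[hi]
    return any(end_t - window <= pt < end_t for pt, _ in traj.pulses)


def events_from_trajectory(
    traj: StateTrajectory,
    *,
    subject: str = "model",
    condition: str = "model",
    outcome_window: float = 1.0,
) -> pd.DataFrame:
    """Classify each logged pulse as interruption or termination.

    A pulse terminates its bout when the feeding run containing it ends
    within ``outcome_window`` seconds of the pulse (the kick cleared the
    threshold and never resettled); otherwise it is an intra-bout
    interruption. ``preceding_interval`` is measured on the feeding clock
    -- sub-threshold bout time since the previous event (or since bout
    start for the first event) -- matching the clock that drives the
    renewal process, so fitted intervals recover the generating law.
    Columns: subject, condition, time, kind, amplitude, preceding_interval.
    """
    dt = float(traj.t[1] - traj.t[0])
    sub_thresh = traj.state_label & (traj.E < traj.E_threshold)
    feed_clock = np.concatenate(([0.0], np.cumsum(sub_thresh[:-1] * dt)))
    runs = _runs(traj.state_label)
    rows = []
    for lo, hi in runs:
        start = traj.t[lo]
        end = traj.t[min(hi, len(traj.t) - 1)]
        in_run = [(pt, amp) for pt, amp in traj.pulses if start <= pt < end]
        prev_clock = feed_clock[lo]
        for k, (pt, amp) in enumerate(in_run):
            terminal = (k == len(in_run) - 1
                        and hi < len(traj.state_label)
                        and end - pt <= outcome_window)
            idx = int(round(pt / dt))
            rows.append({
                "subject": subject, "condition": condition, "time": pt,
                "kind": "termination" if terminal else "interruption",
                "amplitude": amp,
                "preceding_interval": feed_clock[idx] - prev_clock,
            })
            prev_clock = feed_clock[idx]
    return pd.DataFrame(rows, columns=[
        "subject", "condition", "time", "kind", "amplitude",
        "preceding_interval"])


def trajectory_to_annotations(
    traj: StateTrajectory,
    *,
    subject: str = "model",
    condition: str = "model",
    min_dwell: float = 0.2,
) -> pd.DataFrame:
    """Re-express a trajectory as a behavior-style annotation table.

    Feeding intervals are the sub-threshold stretches of each bout; the
    supra-threshold excursions between them become the short gaps that the
    behavioral segmentation reads as intra-bout interruptions. Sub-``min_dwell``
    feeding slivers (grid-scale threshold re-crossings) are absorbed into the
    surrounding gap. Includes a ``food_intro`` column at time 0.
    """
    feed_sample = traj.state_label & (traj.E < traj.E_threshold)
    rows = []
    for lo, hi in _runs(feed_sample):
        start = traj.t[lo]
        stop = traj.t[min(hi, len(traj.t) - 1)]
        if stop - start < min_dwell:
            continue
        rows.append({
            "subject": subject, "condition": condition, "label": "feeding",
            "start": start, "stop": stop, "food_intro": 0.0,
        })
    return pd.DataFrame(rows, columns=[
        "subject", "condition", "label", "start", "stop", "food_intro"])
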