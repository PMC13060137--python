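"""Synthetic fasted-refeeding sessions for end-to-end pipeline testing.

Generates behavior annotation tables and photometry-like traces with the
statistical structure the analytics assume: lognormal-interval intra-bout
interruptions, bout-locked drops in a z-scored activity trace, brief
transients at interruptions, a sustained return to baseline at termination,
and a locomotion channel anticorrelated with feeding. Two generation paths
are provided -- a parametric one (bouts and gaps drawn directly from their
laws, so the analytics can be validated independently of the dynamical
model) and a simulator-driven one (sessions relabeled from the bistable
model).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bout_analytics import segment_bouts
from .model_core import ModelParams
from .photometry import PhotometryRecording
from .simulator import RenewalParams, simulate, trajectory_to_annotations

__all__ = ["SynthSessionSpec", "make_annotations", "make_photometry", "make_cohort"]


@dataclass(frozen=True)
class SynthSessionSpec:
    """Generative knobs for one synthetic cohort condition.

    Defaults emulate a 30 min fasted-refeeding session in a small cohort:
    bout durations of a few tens of seconds, inter-bout pauses of tens of
    seconds, lognormal interruption intervals, activity low during bouts with
    brief transients at interruptions, and locomotion suppressed in-bout.
    """

    n_subjects: int = 8
    session_length: float = 1800.0
    condition: str = "ctrl"
    source: str = "parametric"  # or "simulator"
    # parametric bout laws
    bout_log_mean: float = 3.4  # log seconds; median bout ~30 s
    bout_log_sd: float = 0.8
    interbout_rate: float = 1 / 36.0  # 1/s; mean pause 4 + 36 s
    renewal: RenewalParams = RenewalParams()
    gap_range: tuple[float, float] = (0.5, 2.0)  # interruption gap length, s
    food_intro: float = 10.0
    # photometry kernel
    dip_amp: float = 1.5  # z units, bout-locked drop
    transient_amp: float = 1.2  # z units, bump at interruptions
    transient_width: float = 0.5  # s, Gaussian SD
    kernel_tau: float = 1.5  # s, exponential onset/offset (rise at termination)
    noise_sd: float = 0.3  # z units
    fs: float = 20.0  # Hz
    # locomotion
    speed_out: float = 6.0  # cm/s between bouts
    speed_in: float = 1.0  # cm/s during bouts
    speed_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 5.0:
            raise ValueError(f"sampling rate must be >= 5 Hz, got {self.fs}")
        if self.source not in ("parametric", "simulator"):
            raise ValueError(f"unknown source {self.source!r}")
        for name in ("dip_amp", "transient_amp", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def replace(self, **changes) -> "SynthSessionSpec":
        return dataclasses.replace(self, **changes)


def _subject_rng(spec: SynthSessionSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(subject_index)]))


def _parametric_subject(spec: SynthSessionSpec, subject: str,
                        rng: np.random.Generator) -> list[dict]:
    """Feeding intervals for one subject drawn from the parametric laws.

    Interruption events within a bout follow the renewal law in real time
    (successive event times are one renewal interval apart); each event
    opens a gap shorter than 4 s, clamped so some feeding remains between
    events. The bout's last feeding interval ends at the bout's scheduled
    termination, and the following pause is at least 4 s.
    """
    rows = []
    t = spec.food_intro + rng.exponential(1.0 / spec.interbout_rate)
    lo, hi = spec.gap_range
    while t < spec.session_length:
        dur = float(np.exp(rng.normal(spec.bout_log_mean, spec.bout_log_sd)))
        dur = min(dur, spec.session_length - t)
        if dur < 1.0:
            break
        feed_start = t
        elapsed = float(np.exp(rng.normal(spec.renewal.log_mean,
                                          spec.renewal.log_sd))
                        / spec.renewal.rate_scale)
        while elapsed < dur:
            event = t + elapsed
            gap = min(rng.uniform(lo, hi), 3.9)
            nxt = float(np.exp(rng.normal(spec.renewal.log_mean,
                                          spec.renewal.log_sd))
                        / spec.renewal.rate_scale)
            gap = min(gap, 0.5 * nxt)  # keep feeding between events
            rows.append({"start": feed_start, "stop": event})
            feed_start = event + gap
            elapsed += nxt
        if t + dur > feed_start:
            rows.append({"start": feed_start, "stop": t + dur})
        t = t + dur + 4.0 + rng.exponential(1.0 / spec.interbout_rate)
    out = []
    for r in rows:
        out.append({"subject": subject, "condition": spec.condition,
                    "label": "feeding", "start": r["start"], "stop": r["stop"],
                    "food_intro": spec.food_intro})
    return out


def make_annotations(spec: SynthSessionSpec) -> pd.DataFrame:
    """Annotation table for a full cohort (all subjects, one condition).

    Parametric path: bouts, pauses and intra-bout gaps drawn from the spec's
    laws. Simulator path: each subject is one stochastic model session,
    relabeled into feeding intervals. Deterministic given ``spec.seed``.
    """
    frames = []
    for s in range(spec.n_subjects):
        subject = f"m{s + 1:02d}"
        rng = _subject_rng(spec, s)
        if spec.source == "parametric":
            frames.extend(_parametric_subject(spec, subject, rng))
        else:
            traj = simulate(
                ModelParams(), spec.renewal, spec.session_length,
                np.random.SeedSequence([int(spec.seed), int(s)]),
                reentry_rate=spec.interbout_rate)
            ann = trajectory_to_annotations(
                traj, subject=subject, condition=spec.condition)
            ann["food_intro"] = spec.food_intro
            ann[["start", "stop"]] += spec.food_intro
            frames.extend(ann.to_dict("records"))
    return pd.DataFrame(frames, columns=[
        "subject", "condition", "label", "start", "stop", "food_intro"])


def make_photometry(
    ann: pd.DataFrame,
    spec: SynthSessionSpec,
    subject: str | None = None,
) -> PhotometryRecording:
    """Photometry-like channels for one subject's annotations.

    The latent z trace relaxes (time constant ``kernel_tau``) toward
    ``-dip_amp`` inside bouts and toward 0 outside -- so initiation is a
    drop and termination a sustained rise -- with Gaussian bumps of
    ``transient_amp`` at each intra-bout interruption and white noise on
    top. The raw signal embeds the latent trace together with a shared
    slow artifact that also drives the reference channel, so the standard
    preprocessing must undo it. Speed relaxes toward ``speed_in`` inside
    bouts and ``speed_out`` outside.
    """
    if subject is None:
        subjects = ann["subject"].unique()
        if len(subjects) != 1:
            raise ValueError("pass subject= when the table holds several subjects")
        subject = subjects[0]
    sub = ann[ann["subject"] == subject]
    if not len(sub):
        raise ValueError(f"no annotations for subject {subject!r}")
    subject_index = int(str(subject).lstrip("m")) - 1 if str(subject).startswith("m") else 0
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 10_000 + subject_index]))

    dt = 1.0 / spec.fs
    n = int(round(spec.session_length / dt))
    t = np.arange(n) * dt

    bouts, events = segment_bouts(sub)
    in_bout = np.zeros(n, dtype=bool)
    for _, b in bouts.iterrows():
        in_bout[(t >= b["start"]) & (t < b["end"])] = True

    target = np.where(in_bout, -spec.dip_amp, 0.0)
    latent = np.empty(n)
    latent[0] = target[0]
    alpha = dt / spec.kernel_tau
    for i in range(1, n):
        latent[i] = latent[i - 1] + (target[i] - latent[i - 1]) * alpha
    intr = events.loc[events["kind"] == "interruption", "time"].to_numpy(float)
    for e in intr:
        mask = np.abs(t - e) < 4 * spec.transient_width
        latent[mask] += spec.transient_amp * np.exp(
            -0.5 * ((t[mask] - e) / spec.transient_width) ** 2)
    latent = latent + rng.normal(0.0, spec.noise_sd, n)

    artifact = (0.5 * np.sin(2 * np.pi * t / 120.0)
                + 0.3 * np.cos(2 * np.pi * t / 311.0) + 0.1)
    signal = 2.0 + 0.8 * latent + 1.3 * artifact
    reference = 1.0 + artifact + rng.normal(0.0, 0.01, n)

    speed_target = np.where(in_bout, spec.speed_in, spec.speed_out)
    speed = np.empty(n)
    speed[0] = speed_target[0]
    for i in range(1, n):
        speed[i] = speed[i - 1] + (speed_target[i] - speed[i - 1]) * alpha
    speed = np.clip(speed + rng.normal(0.0, spec.speed_noise_sd, n), 0.0, None)

    return PhotometryRecording.from_channels(
        t, signal, reference, speed,
        subject=str(subject), condition=spec.condition)


def make_cohort(
    spec: SynthSessionSpec,
    conditions: dict[str, dict],
    out_dir,
) -> Path:
    """Write a cohort folder: per condition/subject annotation + photometry files.

    ``conditions`` maps a condition label to spec-field overrides applied on
    top of ``spec`` (empty dict = as-is). Layout::

        out_dir/manifest.json
        out_dir/<condition>/annotations.csv
        out_dir/<condition>/<subject>_photometry.csv

    Refuses to write into an existing non-empty directory. Byte-identical
    for identical specs and seed.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"output directory {out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)

    manifest = {"seed": spec.seed, "conditions": {}}
    for k, (label, overrides) in enumerate(sorted(conditions.items())):
        cond_spec = spec.replace(condition=label, seed=spec.seed + 1000 * k,
                                 **overrides)
        cond_dir = out / label
        cond_dir.mkdir()
        ann = make_annotations(cond_spec)
        ann.to_csv(cond_dir / "annotations.csv", index=False, float_format="%.6f")
        for subject in ann["subject"].unique():
            rec = make_photometry(ann, cond_spec, subject=subject)
            pd.DataFrame({
                "t": rec.t, "signal": rec.signal, "reference": rec.reference,
                "speed": rec.speed,
            }).to_csv(cond_dir / f"{subject}_photometry.csv", index=False,
                      float_format="%.6f")
        manifest["conditions"][label] = {
            "seed": cond_spec.seed,
            "overrides": {k2: (list(v) if isinstance(v, tuple) else v)
                          for k2, v in overrides.items()},
            "n_subjects": cond_spec.n_subjects,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
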