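"""Photometry-style trace quantification.

Reference-corrected z-scoring, peri-event alignment, baseline-subtracted
AUC responses, and the feeding-vs-speed regression with unique-variance
partitioning. Works on any uniformly sampled bulk-activity trace with an
optional isosbestic reference channel; nothing here is specific to a
particular sensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhotometryRecording",
    "PeriEventMatrix",
    "preprocess",
    "align_events",
    "group_peri_event_mean",
    "auc_response",
    "regress_signal",
]


@dataclass
class PhotometryRecording:
    """A uniformly sampled session trace with its derived z-score.

    ``z`` is the session z-score of the reference-corrected signal; ``speed``
    is an optional locomotion channel on the same grid (cm/s).
    """

    t: np.ndarray
    signal: np.ndarray
    reference: np.ndarray | None
    z: np.ndarray
    speed: np.ndarray | None = None
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("signal", "z"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != t length {n}")
        for name in ("reference", "speed"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != t length {n}")
        steps = np.diff(self.t)
        if len(steps) and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    @classmethod
    def from_channels(cls, t, signal, reference=None, speed=None, **kw):
        t = np.asarray(t, float)
        signal = np.asarray(signal, float)
        reference = None if reference is None else np.asarray(reference, float)
        z = preprocess(signal, reference)
        speed = None if speed is None else np.asarray(speed, float)
        return cls(t=t, signal=signal, reference=reference, z=z, speed=speed, **kw)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw):
        """Build from a tabular export with columns t, signal[, reference][, speed] or t, z."""
        if "z" in df.columns and "signal" not in df.columns:
            z = df["z"].to_numpy(float)
            return cls(t=df["t"].to_numpy(float), signal=z, reference=None, z=z,
                       speed=df["speed"].to_numpy(float) if "speed" in df else None,
                       **kw)
        return cls.from_channels(
            df["t"], df["signal"],
            df["reference"] if "reference" in df.columns else None,
            df["speed"] if "speed" in df.columns else None, **kw)


@dataclass
class PeriEventMatrix:
    """Event x lag matrix of z values aligned to a behavioral event."""

    lags: np.ndarray  # seconds, 0 at event onset
    matrix: np.ndarray  # (n_events, n_lags)
    alignment: str = ""
    n_dropped: int = 0

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.matrix.shape[0]
        return self.matrix.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else \
            np.zeros(self.matrix.shape[1])


def preprocess(signal, reference=None) -> np.ndarray:
    """Reference-corrected session z-score.

    The reference channel is regressed onto the signal (slope + intercept,
    least squares) and the fit subtracted, removing shared motion/bleaching
    artifacts up to an affine gain; the corrected trace is then z-scored
    over the session. Without a reference, the signal is z-scored directly.
    A constant corrected trace (SD 0) maps to all zeros.
    """
    signal = np.asarray(signal, float)
    if reference is not None:
        reference = np.asarray(reference, float)
        if len(reference) != len(signal):
            raise ValueError("signal and reference must be the same length")
        if np.std(reference) > 0:
            slope, intercept = np.polyfit(reference, signal, 1)
            corrected = signal - (slope * reference + intercept)
        else:
            corrected = signal - reference
    else:
        corrected = signal
    sd = corrected.std()
    # degenerate after correction (e.g. signal == reference up to gain):
    # do not amplify numerical residue into a fake z trace
    if sd <= 1e-9 * max(signal.std(), np.abs(signal).max(), 1e-30):
        return np.zeros_like(corrected)
    return (corrected - corrected.mean()) / sd


def align_events(
    rec: PhotometryRecording,
    event_times,
    window: tuple[float, float] = (10.0, 20.0),
    alignment: str = "",
) -> PeriEventMatrix:
    """Extract peri-event z snippets on a common lag grid.

    ``window = (pre, post)`` in seconds; lag 0 is event onset. Events whose
    window is not fully contained in the recording are dropped (counted in
    ``n_dropped``); overlapping windows of nearby events are all kept.
    """
    pre, post = window
    dt = 1.0 / rec.fs
    lag_idx = np.arange(-int(round(pre / dt)), int(round(post / dt)) + 1)
    lags = lag_idx * dt
    rows, dropped = [], 0
    t0 = float(rec.t[0])
    for ev in np.atleast_1d(np.asarray(event_times, float)):
        center = int(round((ev - t0) / dt))
        idx = center + lag_idx
        if idx[0] < 0 or idx[-1] >= len(rec.z):
            dropped += 1
            continue
        rows.append(rec.z[idx])
    if not rows:
        raise ValueError("no event with a complete peri-event window")
    return PeriEventMatrix(lags=lags, matrix=np.vstack(rows),
                           alignment=alignment, n_dropped=dropped)


def group_peri_event_mean(
    mats: list[PeriEventMatrix],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-level average: per-subject peri-event means, then the grand mean.

    Returns (lags, grand_mean, sem_across_subjects). All matrices must share
    one lag grid.
    """
    if not mats:
        raise ValueError("no peri-event matrices")
    lags = mats[0].lags
    for m in mats[1:]:
        if len(m.lags) != len(lags) or not np.allclose(m.lags, lags):
            raise ValueError("peri-event matrices have mismatched lag grids")
    per_subject = np.vstack([m.mean for m in mats])
    grand = per_subject.mean(axis=0)
    n = per_subject.shape[0]
    sem = per_subject.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else \
        np.zeros_like(grand)
    return lags, grand, sem


def auc_response(
    rec: PhotometryRecording,
    event_start: float,
    event_duration: float,
    *,
    baseline_window: float = 10.0,
    max_window: float = 20.0,
) -> float:
    """Baseline-subtracted mean response around one event.

    AUC = mean z over [start, start + min(max_window, duration)] minus the
    mean z over the ``baseline_window`` seconds before the event. Requires
    the full baseline window of pre-event data.
    """
    if event_duration <= 0:
        raise ValueError(f"event_duration must be positive, got {event_duration}")
    t0 = float(rec.t[0])
    if event_start - baseline_window < t0 - 1e-9:
        raise ValueError(
            f"insufficient pre-event data: need {baseline_window} s before "
            f"t={event_start}")
    post = min(max_window, event_duration)
    pre_mask = (rec.t >= event_start - baseline_window) & (rec.t < event_start)
    post_mask = (rec.t >= event_start) & (rec.t < event_start + post)
    if not pre_mask.any() or not post_mask.any():
        raise ValueError("empty baseline or response window")
    return float(rec.z[post_mask].mean() - rec.z[pre_mask].mean())


def regress_signal(
    z,
    feeding,
    speed=None,
    *,
    collinearity_tol: float = 0.999,
):
    """OLS of the z trace on a feeding indicator and (optionally) speed.

    Returns a dict with ``coef`` (per-predictor slopes), ``abs_coef``,
    ``r2_total``, and ``unique_r2`` -- the semi-partial R^2 of each
    predictor, i.e. the drop in total R^2 when that predictor is removed.
    Near-collinear predictors (|r| > ``collinearity_tol``) trigger a warning
    and the shared variance is reported under ``shared_r2``.
    """
    import warnings

    z = np.asarray(z, float)
    feeding = np.asarray(feeding, float)
    predictors = {"feeding": feeding}
    if speed is not None:
        predictors["speed"] = np.asarray(speed, float)

    names = list(predictors)
    X = np.column_stack([predictors[k] for k in names])

    def r2_of(cols: list[int]) -> float:
        A = np.column_stack([np.ones(len(z))] + [X[:, c] for c in cols])
        beta, *_ = np.linalg.lstsq(A, z, rcond=None)
        resid = z - A @ beta
        tss = ((z - z.mean()) ** 2).sum()
        return 1.0 - resid @ resid / tss if tss > 0 else 0.0

    A = np.column_stack([np.ones(len(z)), X])
    beta, *_ = np.linalg.lstsq(A, z, rcond=None)
    r2_total = r2_of(list(range(len(names))))

    unique = {}
    for i, name in enumerate(names):
        others = [j for j in range(len(names)) if j != i]
        unique[name] = r2_total - (r2_of(others) if others else 0.0)

    out = {
        "coef": dict(zip(names, beta[1:])),
        "abs_coef": {k: abs(v) for k, v in zip(names, beta[1:])},
        "r2_total": r2_total,
        "unique_r2": unique,
    }
    if len(names) == 2:
        sds = X.std(axis=0)
        r = (np.corrcoef(X[:, 0], X[:, 1])[0, 1]
             if np.all(sds > 0) else 1.0)
        if abs(r) > collinearity_tol:
            warnings.warn(
                f"predictors nearly collinear (|r|={abs(r):.4f}); unique R^2 "
                "is not interpretable")
        out["shared_r2"] = r2_total - sum(unique.values())
    return out
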