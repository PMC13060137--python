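"""Feeding-microstructure analytics: bouts, events, tests, renewal fits.

Input is an annotation table (one row per manually scored feeding interval,
with subject and condition); output is the standard bout battery: merged
bouts under the 4 s interruption rule, interruption/termination event
streams, duration distributions and their permutation Kolmogorov-Smirnov
comparisons, lognormal renewal fits, and a Bernoulli GLM on event outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ANNOTATION_COLUMNS",
    "BoutStats",
    "validate_annotations",
    "segment_bouts",
    "bout_statistics",
    "permutation_ks",
    "fit_lognormal",
    "termination_glm",
]

ANNOTATION_COLUMNS = ("subject", "condition", "label", "start", "stop")

#: gap length (s) separating an intra-bout interruption from a termination
DEFAULT_GAP_THRESHOLD = 4.0


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, stop > start, and non-overlap within sessions."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    bad = ann[ann["stop"] <= ann["start"]]
    if len(bad):
        raise ValueError(f"{len(bad)} annotation rows have stop <= start")
    feeding = ann[ann["label"] == "feeding"]
    for (subj, cond), grp in feeding.groupby(["subject", "condition"], sort=False):
        g = grp.sort_values("start")
        overlap = g["start"].to_numpy()[1:] < g["stop"].to_numpy()[:-1]
        if overlap.any():
            offenders = g.iloc[np.flatnonzero(overlap) + 1][["start", "stop"]]
            raise ValueError(
                f"overlapping feeding intervals for subject={subj!r}, "
                f"condition={cond!r}:\n{offenders.to_string()}")
    return ann


def segment_bouts(
    ann: pd.DataFrame,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge feeding intervals into bouts and emit the event stream.

    Within each subject x condition session, consecutive feeding intervals
    separated by a gap shorter than ``gap_threshold`` (default 4 s) belong to
    one bout; each such internal gap is an intra-bout interruption event at
    the gap's start, and each bout's end is a termination event. Returns
    ``(bout_table, event_table)``:

    - bouts: subject, condition, start, end, duration, n_interruptions
    - events: subject, condition, time, kind, preceding_interval (time since
      the previous event in the bout, or since bout start for the first)
    """
    validate_annotations(ann)
    feeding = ann[ann["label"] == "feeding"]
    bout_rows, event_rows = [], []
    for (subj, cond), grp in feeding.groupby(["subject", "condition"], sort=False):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy(float)
        stops = g["stop"].to_numpy(float)
        if len(starts) == 0:
            continue
        bout_start = starts[0]
        prev_stop = stops[0]
        prev_event = bout_start
        n_intr = 0
        for s, e in zip(starts[1:], stops[1:]):
            gap = s - prev_stop
            if gap < gap_threshold:
                event_rows.append({
                    "subject": subj, "condition": cond, "time": prev_stop,
                    "kind": "interruption",
                    "preceding_interval": prev_stop - prev_event,
                })
                prev_event = prev_stop
                n_intr += 1
            else:
                event_rows.append({
                    "subject": subj, "condition": cond, "time": prev_stop,
                    "kind": "termination",
                    "preceding_interval": prev_stop - prev_event,
                })
                bout_rows.append({
                    "subject": subj, "condition": cond, "start": bout_start,
                    "end": prev_stop, "duration": prev_stop - bout_start,
                    "n_interruptions": n_intr,
                })
                bout_start = s
                prev_event = bout_start
                n_intr = 0
            prev_stop = e
        event_rows.append({
            "subject": subj, "condition": cond, "time": prev_stop,
            "kind": "termination", "preceding_interval": prev_stop - prev_event,
        })
        bout_rows.append({
            "subject": subj, "condition": cond, "start": bout_start,
            "end": prev_stop, "duration": prev_stop - bout_start,
            "n_interruptions": n_intr,
        })
    bouts = pd.DataFrame(bout_rows, columns=[
        "subject", "condition", "start", "end", "duration", "n_interruptions"])
    events = pd.DataFrame(event_rows, columns=[
        "subject", "condition", "time", "kind", "preceding_interval"])
    return bouts, events


@dataclass(frozen=True)
class BoutStats:
    """Per-condition summary of feeding microstructure."""

    condition: str
    n_bouts: int
    mean_duration: float
    durations: np.ndarray  # pooled, sorted (the ECDF support)
    ecdf: np.ndarray  # nondecreasing from 1/n to 1
    per_subject_mean: pd.Series
    mean_interbout_interval: float
    latency_to_first: float  # NaN when no food_intro column supplied
    event_freq_per_min: float  # events per minute of time-in-bout
    termination_proportion: float
    lognormal_fit: tuple[float, float]  # (log_mean, log_sd) of event intervals

    def summary(self) -> dict:
        return {
            "condition": self.condition,
            "n_bouts": self.n_bouts,
            "mean_duration_s": self.mean_duration,
            "mean_interbout_interval_s": self.mean_interbout_interval,
            "latency_to_first_s": self.latency_to_first,
            "event_freq_per_min": self.event_freq_per_min,
            "termination_proportion": self.termination_proportion,
            "log_mean": self.lognormal_fit[0],
            "log_sd": self.lognormal_fit[1],
        }


def bout_statistics(
    bouts: pd.DataFrame,
    events: pd.DataFrame | None = None,
    *,
    ann: pd.DataFrame | None = None,
) -> dict[str, BoutStats]:
    """Summaries per condition from a bout table (and optionally its events).

    Durations are pooled across subjects for the ECDF (mirroring pooled
    distribution plots) and also averaged per subject. Event frequency is
    events per minute of time-in-bout; termination proportion counts
    terminations among all interruption+termination events. The lognormal
    fit is on event ``preceding_interval`` values (excluding zero-length
    first-event intervals). Latency to first bout needs ``ann`` with a
    ``food_intro`` column.
    """
    if len(bouts) == 0:
        raise ValueError("empty bout table")
    out: dict[str, BoutStats] = {}
    for cond, grp in bouts.groupby("condition", sort=False):
        durations = np.sort(grp["duration"].to_numpy(float))
        ecdf = np.arange(1, len(durations) + 1) / len(durations)
        per_subject = grp.groupby("subject")["duration"].mean()
        ibis = []
        for _, sg in grp.groupby("subject"):
            sg = sg.sort_values("start")
            ibis.extend((sg["start"].to_numpy()[1:] - sg["end"].to_numpy()[:-1]).tolist())
        latency = float("nan")
        if ann is not None and "food_intro" in ann.columns:
            lat = []
            sub = ann[ann["condition"] == cond]
            for subj, sg in grp.groupby("subject"):
                intro = sub[sub["subject"] == subj]["food_intro"]
                if len(intro):
                    lat.append(sg["start"].min() - float(intro.iloc[0]))
            latency = float(np.mean(lat)) if lat else float("nan")

        freq = term_prop = float("nan")
        logfit = (float("nan"), float("nan"))
        if events is not None:
            ev = events[events["condition"] == cond]
            total_bout_min = grp["duration"].sum() / 60.0
            if len(ev) and total_bout_min > 0:
                freq = len(ev) / total_bout_min
                n_term = int((ev["kind"] == "termination").sum())
                term_prop = n_term / len(ev)
                iv = ev["preceding_interval"].to_numpy(float)
                iv = iv[iv > 0]
                if len(iv) >= 2:
                    logfit = fit_lognormal(iv)
        out[str(cond)] = BoutStats(
            condition=str(cond), n_bouts=len(grp),
            mean_duration=float(durations.mean()),
            durations=durations, ecdf=ecdf, per_subject_mean=per_subject,
            mean_interbout_interval=float(np.mean(ibis)) if ibis else float("nan"),
            latency_to_first=latency,
            event_freq_per_min=freq, termination_proportion=term_prop,
            lognormal_fit=logfit,
        )
    return out


def _ks_stats(pooled_sorted_labels: np.ndarray, n_a: int, n_b: int,
              distinct: np.ndarray) -> tuple:
    """(D_two_sided, D_a_less, D_a_greater) from labels in pooled sort order.

    ``pooled_sorted_labels`` is a boolean matrix (..., n) marking membership
    of sample A along the pooled sorted values; ``distinct`` marks the last
    position of each tie group (ECDF gaps are only defined between distinct
    values). D_a_less = max(F_a - F_b) is large when A's values sit below
    B's; D_a_greater = max(F_b - F_a).
    """
    is_a = pooled_sorted_labels.astype(np.float64)
    F_a = np.cumsum(is_a, axis=-1) / n_a
    F_b = np.cumsum(1.0 - is_a, axis=-1) / n_b
    diff = (F_a - F_b)[..., distinct]
    d_less = diff.max(axis=-1)
    d_greater = (-diff).max(axis=-1)
    return np.abs(diff).max(axis=-1), d_less, d_greater


def permutation_ks(
    sample_a,
    sample_b,
    n_perm: int = 9999,
    seed=0,
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Permutation Kolmogorov-Smirnov test between two duration samples.

    ``alternative``:

    - ``"two_sided"``: D = sup |F_a - F_b|
    - ``"less"``: D = sup (F_a - F_b), sensitive to A shifted toward
      smaller values (its ECDF above B's)
    - ``"greater"``: D = sup (F_b - F_a), sensitive to A shifted larger

    p = (1 + #{permuted D >= observed}) / (n_perm + 1) under seeded label
    shuffles of the pooled sample.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    if n_perm < 999:
        raise ValueError(f"n_perm must be >= 999, got {n_perm}")
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")

    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    distinct = np.append(np.diff(pooled[order]) != 0, True)
    labels = np.zeros(len(pooled), dtype=bool)
    labels[: len(a)] = True
    obs = _ks_stats(labels[order][None, :], len(a), len(b), distinct)
    key = {"two_sided": 0, "less": 1, "greater": 2}[alternative]
    d_obs = float(obs[key][0])

    rng = np.random.default_rng(seed)
    perm = rng.permuted(
        np.broadcast_to(labels, (n_perm, len(pooled))).copy(), axis=1)
    d_perm = _ks_stats(perm[:, order], len(a), len(b), distinct)[key]
    p = (1.0 + np.count_nonzero(d_perm >= d_obs - 1e-12)) / (n_perm + 1.0)
    return d_obs, float(p)


def fit_lognormal(intervals) -> tuple[float, float]:
    """Maximum-likelihood lognormal fit: mean and population SD of log intervals."""
    iv = np.asarray(intervals, float)
    if len(iv) < 2:
        raise ValueError("need at least 2 intervals")
    if np.any(iv <= 0):
        raise ValueError("intervals must be strictly positive")
    logs = np.log(iv)
    return float(logs.mean()), float(logs.std(ddof=0))


def termination_glm(
    events: pd.DataFrame,
    *,
    baseline: str | None = None,
    condition_values: dict | None = None,
):
    """Bernoulli GLM of event outcome (termination vs interruption) on condition.

    Per-subject fixed intercepts approximate the subject random effect.
    When every subject appears in a single condition (a between-subject
    design), subject intercepts are collinear with the condition term and
    are dropped -- the model reduces to a pooled logistic regression. With
    two conditions the condition enters as an indicator (``baseline`` names
    the reference level; default: first level in table order). With
    ``condition_values`` given (condition label -> numeric covariate, e.g.
    injected current), the condition enters as a single linear covariate and
    the returned coefficient is its slope.

    Returns ``(coef, se, p)``; under complete separation the coefficient is
    reported as ``+/-inf`` with ``p = nan`` and a warning.
    """
    import warnings

    import statsmodels.api as sm

    if events["condition"].nunique() < 2:
        raise ValueError("need >= 2 conditions")
    y = (events["kind"] == "termination").astype(float).to_numpy()

    if condition_values is not None:
        x_cond = events["condition"].map(condition_values).to_numpy(float)[:, None]
    else:
        levels = list(pd.unique(events["condition"]))
        if len(levels) != 2:
            raise ValueError(
                "categorical contrast needs exactly 2 conditions; "
                "pass condition_values for a numeric coding")
        ref = baseline if baseline is not None else levels[0]
        other = [l for l in levels if l != ref][0]
        x_cond = (events["condition"] == other).astype(float).to_numpy()[:, None]

    nested = (events.groupby("subject")["condition"].nunique() == 1).all()
    if nested:
        X = np.column_stack([np.ones(len(events)), x_cond])
    else:
        subjects = pd.get_dummies(events["subject"], drop_first=True, dtype=float)
        X = np.column_stack([np.ones(len(events)), x_cond] +
                            ([subjects.to_numpy()] if subjects.shape[1] else []))

    # complete separation check on the condition margin
    margins = events.groupby("condition")["kind"].apply(
        lambda k: (k == "termination").mean())
    if ((margins == 0) | (margins == 1)).any() and margins.nunique() > 1:
        warnings.warn("complete separation by condition; log-odds unbounded")
        sign = 1.0 if margins.iloc[-1] > margins.iloc[0] else -1.0
        return sign * np.inf, np.inf, float("nan")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
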