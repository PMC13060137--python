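# Methods

## Model

The circuit gating feeding-bout termination is modeled as a stochastic
Wilson–Cowan pair: an excitatory population E and an inhibitory population I
with logistic gain `s(x) = 1/(1 + exp(-a(x - theta)))`,

    tau_E dE = [-E + s(w_EE E - w_IE I + current)] dt + sigma dW_E
    tau_I dI = [-I + s(w_EI E - w_II I)] dt           + sigma dW_I

Reference parameters: `tau_E = 2 s`, `tau_I = 0.4 s`, `w_EE = w_II = 15`,
`w_IE = w_EI = 10`, `a = 1`, `theta = 8`, diffusion amplitude
`sigma = 0.1055`, Euler–Maruyama step `dt = 0.02 s`. The E/I pair is an
abstraction of the gating circuit's population dynamics, not a claim about
its literal wiring. At the reference parameters the deterministic system is
bistable: a feeding attractor at `E ≈ 3.4e-4` and a non-feeding attractor at
`E ≈ 0.991` separated by a saddle whose quasi-static threshold sits at
`E_th ≈ 0.595`.

**Noise convention.** "Euler–Maruyama with additive noise" is read as the
SDE convention: the per-step increment is `sigma sqrt(dt) xi` with
independent standard normals for E and I, sigma not divided by the time
constants. The convention is self-verifying: drift-corrected increments
rescaled by `1/sqrt(dt)` must have SD sigma, which the suite and the
acceptance script check.

**Quasi-static reduction.** Since `tau_I << tau_E`, I is eliminated by
solving `dI/dt = 0` for `I_hat(E)` (unique root because
`I - s(w_EI E - w_II I)` is strictly increasing in I for `w_II > 0`;
bracketed Brent iteration plus one Newton polish, residual < 1e-10). The
resulting 1-D flow is integrated trapezoidally on a uniform 4096-point grid
over [0, 1] to give the potential `V(E)`, zeroed at `E_th` when bistable
(zeroed at the global minimum, with `bistable = False` and a NaN barrier,
when a current sweep has destroyed bistability — downstream state labeling
then refuses to run). The barrier is `V(E_th) - V(E_feeding) =
-V(E_feeding)`. Roots are located by sign-change bracketing on the grid and
polished to 1e-14; the 2-D fixed-point finder seeds a damped-Newton polish
from the 1-D roots and labels stability by the Jacobian's eigenvalues
(deduplication radius 1e-6).

The two wells are asymmetric: at the reference parameters the feeding well
is ~3x deeper (barrier 0.054 against 0.019 for the non-feeding well). At
`sigma = 0.1055` the feeding state is strongly metastable over bout
timescales while noise alone re-enters feeding from the non-feeding well on
~100 s timescales.

## Interruptions and terminations

Intra-bout interruptions are a renewal process with lognormal intervals
`log(interval/s) ~ N(2.22, 0.99^2)`; each event is an instantaneous kick
`E <- E + Delta`, `Delta ~ N(0.56, 0.11^2)`, applied untruncated (negative
draws, ~2e-7 of the mass, are applied as-is). The renewal clock accrues
time only at sub-threshold samples of an ongoing bout and restarts at each
feeding entry: pulses are meaningful only within bouts, and a pulse never
fires during the supra-threshold excursion caused by the previous one.
Event tables therefore report inter-event intervals on this feeding clock,
which makes interval refits recover the generating law exactly.

**State labeling (hysteresis).** A sample belongs to a bout while E is
below `E_th`; an excursion above `E_th` ends the bout, retroactively at the
upward crossing, only if it persists for at least `commit_time = 4 s` —
mirroring the behavioral rule that a gap shorter than 4 s is an
interruption, not a termination. The same rule, applied post hoc, exactly
reproduces the labels the simulator assigns online.

**Condition presets.** Tonic current emulates optogenetic manipulations
(`eOPN3`: -0.7; `ChR2`: +0.85; values enter only the excitatory gain
argument) and `looming` scales the renewal rate by 2 at zero current.
Session orchestration (`run_condition`) enables a forced re-entry extension:
after an exponentially distributed non-feeding dwell (rate 0.05 /s, mean
20 s, a realistic inter-bout pause), the state is reset to the feeding
attractor. Plain `simulate()` keeps this off; purely noise-driven re-entry
is too slow to produce multi-bout sessions at the reference noise. A guard
aborts if the state leaves a plausible range (E in [-0.5, 2.0] — a pulse
fired just below threshold legitimately reaches `E_th + Delta` — and I in
[-0.5, 1.5]), which catches mis-set noise amplitudes.

**A second-order rate effect.** Doubling the interruption rate slightly
raises the per-event termination probability (~+0.05 absolute): with
halved intervals, more pulses launch during the ~3 s relaxation after a
previous interruption, where E is still elevated and a given kick is more
likely to clear the threshold. The rate manipulation therefore leaves the
termination proportion *essentially* unchanged — its shift is several times
smaller than the shift produced by any threshold (current) manipulation —
but the difference is detectable at high power. The acceptance check for
the rate condition accordingly compares magnitudes (rate-induced shift
smaller than the smallest current-induced shift) rather than requiring a
non-significant difference test, whose verdict would depend on the sample
size chosen.

## Behavioral analytics

`segment_bouts` applies the 4 s rule (threshold exposed as a parameter)
per subject and condition; each internal gap emits an interruption event at
the gap start and each bout end emits a termination. Summaries report
pooled duration ECDFs (matching pooled distribution displays) alongside
per-subject means, events per minute of time-in-bout, the termination
proportion among all events, and a lognormal ML fit (mean and population SD
of log intervals) of inter-event intervals.

`permutation_ks` computes the two-sample KS statistic (sup of the ECDF gap,
signed for one-tailed alternatives, evaluated only at distinct-value
boundaries so ties are handled exactly; the statistic matches the classical
two-sample D) with the +1-corrected permutation p-value
`(1 + #{D_perm >= D_obs})/(n_perm + 1)`, exact at finite permutation counts.
Its null calibration is verified by simulation (type-I error within
[0.03, 0.07] at alpha = 0.05).

`termination_glm` fits a Bernoulli GLM of event outcome on condition —
a fixed-per-subject-intercept approximation of a mixed-effects model.
When subjects are nested within conditions (between-subject designs) the
subject dummies are collinear with the condition term, so the model reduces
to pooled logistic regression; complete separation is flagged and reported
as an unbounded coefficient rather than a spurious finite estimate.
Conditions may be coded categorically (two levels) or numerically (e.g. by
injected current), in which case the reported coefficient is the slope in
log-odds per unit current.

## Photometry analytics

Preprocessing regresses the reference channel onto the signal (slope and
intercept) and subtracts the fit before session z-scoring — robust to gain
differences between channels, unlike plain subtraction; without a reference
only z-scoring is applied. A corrected trace with negligible variance
(perfect artifact) maps to zeros instead of amplifying numerical residue.
Note that least-squares correction removes the component of the biological
signal that projects onto the reference; it is unbiased only insofar as
reference and signal-of-interest are uncorrelated.

Event alignment extracts fixed windows on the lag grid (incomplete windows
dropped and counted; overlapping windows kept) and averages per subject
before averaging across subjects. The event response (AUC) is the mean z
over `[start, start + min(20 s, duration)]` minus the mean over the 10 s
pre-event baseline, and is invariant to constant offsets.

`regress_signal` fits OLS of the z trace on a raw feeding indicator and
optional speed; "variance explained" per predictor is the semi-partial
(unique) R^2 — the drop in total R^2 when that predictor is removed — with
shared variance reported separately and a warning under near-collinearity.
Predictors are used unconvolved; an optional low-pass of the indicator at
the sensor timescale is deliberately left out of the default path.

## Synthetic sessions

The generator produces fasted-refeeding-like cohorts two ways. The
*parametric* path draws bout durations (lognormal, default log-mean 3.4,
log-SD 0.8: median ~30 s), inter-bout pauses (4 s plus an exponential of
mean 36 s), and intra-bout interruptions from the renewal law, with gap
lengths 0.5–2 s; successive event times are one renewal interval apart, so
interval refits are unbiased except for the censoring of the interval that
would straddle the bout end (negligible when bouts are much longer than
intervals; with the heavy-tailed default interval law the refit log-mean is
biased low by ~0.1–0.2, which is why recovery tests run in the long-bout
regime). The *simulator* path relabels stochastic model sessions. Defaults
(8 subjects, 30 min sessions) mirror small-cohort in-vivo designs.

Photometry-like traces relax with a 1.5 s time constant toward -1.5 z
during bouts and 0 outside (so initiation is a drop and termination a
sustained rise), add 1.2 z Gaussian transients (SD 0.5 s) at interruptions
and white noise (SD 0.3 z), and embed the latent trace in a raw channel
that shares a slow multiplicative-free artifact with the reference channel,
so the standard preprocessing is actually exercised. Speed relaxes toward
1 cm/s in-bout and 6 cm/s out-of-bout, anticorrelated with feeding. Every
knob is chosen so that each pipeline statistic moves monotonically with the
knob that generates it; what passing tests show is that the analytics
invert this generative family, not that real recordings satisfy its
assumptions (no bleaching, stationary noise, ideal annotations).

## Problem sizes and statistics in the acceptance battery

Parameter-recovery checks use 10^5 draws (3-standard-error bands) and a
1000 s pulse-free simulation for the diffusion amplitude. Directional model
experiments use 20 sessions of 900 s per condition; bout-duration shifts
are tested with one-sided permutation tests on per-session mean durations
(pooled one-tailed KS is less powerful here because long bouts are
right-censored by session ends), event-frequency flatness with two-sided
permutation tests at the same size, and the current's effect on termination
odds with the numeric-coded Bernoulli GLM. The rate-condition proportion
check is the magnitude comparison described above.

## Known limitations

- The model is a two-population abstraction; nothing constrains it to the
  anatomy or firing statistics of the real circuit.
- Bout re-initiation is not part of the modeled mechanism; the forced
  re-entry used for session orchestration is an explicit extension.
- The mixed-effects GLM is approximated by fixed intercepts (or pooled
  regression under nesting); with few subjects and strong heterogeneity the
  standard errors are optimistic.
- The synthetic photometry family has no bleaching, no hemodynamic
  confound, and white noise only; the linear reference correction is a
  stand-in for a full preprocessing pipeline.
- Escape-rate theory (Kramers/mean first passage) is deliberately out of
  scope; all energy-threshold arguments are geometric.
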