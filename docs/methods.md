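# Methods

`ictaloop` reimplements, as a tested pipeline, the analysis machinery of a
closed-loop optogenetic seizure-control experiment in the pilocarpine
model: a synthetic single-channel ECoG generator with known ground truth, a
20-feature random-forest network-state classifier with a mixed-state
confidence rule, an online threshold detector with stimulation scheduling,
and the paired / reshuffled seizure-duration analysis with per-animal
statistics.  No raw in vivo data are used anywhere; every number the
package reports is computed at run time from seeded synthetic sessions.

## The synthetic ECoG generator

### Network states and waveforms

Recordings are sampled at 512 Hz (microvolts) and emulate four regimes of
pilocarpine-induced focal cortical activity:

* **baseline** — 1/f (pink) noise, SD 10 uV;
* **State 1, interictal bursting** — brief 100–150 ms bursts of 2–3
  biphasic spikes (100–160 uV) at ~0.4 bursts/s;
* **State 2, discrete seizures** — each discharge opens with a large
  negative *sentinel spike* (raised-cosine lobe, −400 uV, 60 ms, with a
  +20% overshoot) followed by a ~10 Hz train of smaller negative spikes
  (110–180 uV) riding on a 40–90 Hz oscillation (±25 uV);
* **State 3, continuous epileptiform activity** — uninterrupted ~3 Hz
  large spiking with slow and gamma components and no sentinels.

The waveform model is phenomenological: only the segment statistics that
the downstream detector, feature extractor and duration analysis consume
are calibrated.  The amplitude tiers are chosen so that three thresholds
separate cleanly (worst case over the ±15% per-animal gain jitter): the
pink-noise tail stays above −50 uV, seizure-body spikes reach −68 to −210
uV, and only sentinels cross −240 uV.  Consequently a −60 uV threshold
tracks the full extent of a discharge (offline segmentation) while a
−240 uV threshold fires exactly once per discharge (online detection).

### Seizure durations

Within an animal, log durations follow a stationary AR(1) chain with
marginal lognormal law: mean per protocol from the condition table
(below), sigma = 0.5, lag-1 correlation rho = 0.95.  The slow drift this
produces is what makes the *immediately preceding* discharge a meaningful
control: with independent draws the mean of paired ratios would carry a
Jensen bias of e^{sigma^2} ≈ 1.28, and no paired design could recover a
34.5% effect to within a few percent.  With rho = 0.95 the consecutive-pair
bias is e^{sigma^2(1-rho)} ≈ 1.013, inside every printed uncertainty.
Each animal additionally receives a lognormal offset of its mean duration
(sd 0.1 on the log scale) and a gain jitter on waveform amplitudes.

Two sampling consequences are intentional and documented rather than
"fixed": (i) pooling all events of a fixed-length session is length-biased
(sessions whose drift runs short pack in more events), so the empirical
pooled mean sits a few percent below the configured marginal mean — ratio
statistics are immune; (ii) per-animal session means wobble with an
effective sample size of roughly n(1−rho)/(1+rho), which dominates the
group s.e.m. of *absolute* duration estimates (the continuous-stimulation
analysis) but not of normalized ones.

### Stimulation effects (condition table)

Each condition profile maps a delay class {0, 0.5, 2, >2 s, continuous} to
a multiplicative effect on the duration of the ongoing discharge, applied
at generation time to trials the scheduler triggers:

| profile        | 0 s   | 0.5 s | 2 s | >2 s  | continuous |
|----------------|-------|-------|-----|-------|------------|
| PV_ChR2        | 0.655 | 0.80  | 1.0 | 1.351 | 0.627      |
| PV_Arch        | 1.0   | 1.0   | 1.0 | 0.709 | 1.0        |
| SOM_ChR2       | 0.782 | 0.782 | 0.782 | 0.9592 | 1.0     |
| PV_ChR2_KCC2   | 0.724 | 0.846 | 1.0 | 0.994 | 0.627      |
| PV_ChR2_GFP    | 0.741 | 1.0   | 1.0 | 1.508 | 1.0        |
| NO_OPSIN       | 1.0   | 1.0   | 1.0 | 1.0   | 1.0        |

Control (unstimulated) mean durations per protocol are 3.31 / 3.66 / 4.32 /
5.52 s for the 0 / 0.5 / 2 / >2 s delay classes and 2.84 s for the
continuous protocol.  The 0.5-s PV_ChR2 value (0.80) is a qualitative
setting (weaker suppression than at 0 s) and is configurable.  Multipliers
for a given animal are jittered lognormally (sd 0.05) unless the nominal
effect is exactly 1.  The multiplier encodes the *measured* total-duration
effect; in particular a delayed suppression (Arch) may yield a realized
duration shorter than the delay — no clamp is applied, because the
published effect size already embeds any physical constraint.

For stimulated trials in the 2 s and >2 s classes the counterfactual
duration is drawn truncated below at the realized delay (the triggering
seizure must outlast the light onset); ">2 s" delays are uniform on
[2.5, 4.8] s (mean ≈ 3.65 s).  The analysis-side control-substitution rule
(below) mirrors this truncation, which keeps the multiplier identifiable
by the paired estimator.

Event spacing: gaps are 0.6 s plus an exponential whose mean makes the
long-run event rate equal `seizure_rate` (default 0.2 events/s) where the
durations permit; with long-duration protocols the rate is
duration-limited.

### Seeding

Everything derives from integer seeds through
`numpy.random.SeedSequence`; per-animal streams use
`SeedSequence(master, spawn_key=(animal_index,))`.  Equal seeds give
bit-identical recordings, logs and reports.

## Closed loop

Online detection is a causal negative threshold crossing.  The session
default threshold is 0.6 x sentinel amplitude (−240 uV), emulating the
per-experiment manual adjustment of the in vivo system.  An automatic
alternative, `auto_threshold` (median − k·MAD, k = 6), is provided and
tested; note that over a quiet prefix k = 6 amounts to ~4 Gaussian sigma,
where noise tails alone fire every minute or two, so the manual-style
threshold is the default.  The refractory period defaults to 1.0 s: at the
sentinel-only threshold a refractory only needs to span one sentinel, and
anything approaching the ~5 s inter-onset spacing would mask genuine
onsets (recall would fall to ~0.8).

The scheduler accepts a detection only ≥ 20 s after the previous accepted
trial (room for clean 10-s pre- and post-stimulation epochs), alternates
control / light-triggered trials starting with a control, samples the
delay class per configured weights, and delivers 10-s light pulses.
Sessions begin with a 30-s stimulation-free warm-up.  In
`run_closed_loop_session` the experiment is simulated event by event —
later event timing depends on realized stimulated durations — using the
*same* scheduler implementation exposed as `schedule_stimulations`;
detection times are the analytic sentinel-crossing times, which the
sample-domain detector reproduces on the rendered waveform to within a
few milliseconds (asserted in tests).

## Features and classifier

Recordings are min-max scaled to [0, 1] once per recording (constant
recordings map to 0) and cut into consecutive non-overlapping 10-s epochs;
the final partial epoch is discarded.  Per epoch, 20 features in fixed
order: mean, std, Fisher excess kurtosis, adjusted Fisher–Pearson skew,
sum of absolute first differences, number of peaks, number of valleys,
mean valley level, mean peak level, mean peak minus mean valley, Morlet
wavelet power at 1, 5, 10, 15, 20, 30, 60, 90 Hz, number of baseline
points, and mean index difference between consecutive baseline points.

Conventions the source experiments left open, declared here and isolated
behind single functions: peak/valley = topographic prominence ≥ 0.05
(scaled units); baseline points = samples within ±0.02 of the epoch
median, with the index-difference defaulting to the epoch length when
fewer than two qualify; peak–valley range = difference of means (robust to
unequal counts); wavelet power = scale x mean squared CWT coefficient of a
Morlet wavelet, one scale per centre frequency, after removing the epoch
mean (the scale weighting is a 1/f normalization under which white-noise
powers decay with frequency; mean removal prevents DC step artifacts at
epoch edges).

The classifier is a scikit-learn random forest (200 trees, unlimited
depth, fixed seed) over four classes (baseline, States 1–3).  An epoch is
accepted only if the top class probability is at least **twice** the
runner-up ("strictly less than twice ⇒ mixed"; equality counts as
confident).  Closed-loop trials are gated on the 10 s immediately before
the trigger classifying confidently as State 2.  Evaluation is always
split by animal; the 3-D LDA projection (eigen solver with light
shrinkage, so duplicated feature columns are harmless) reproduces the
state-separation visualization.

## Paired seizure-duration analysis

Offline events are segmented from the scaled trace at the scaled
equivalent of −60 uV: an event starts at a downward crossing and ends when
no suprathreshold deflection occurs for 0.3 s; events shorter than 0.5 s
are discarded (this removes State-1 bursts by construction).  The offset
criterion is a declared convention — the source experiments never define
one — and is isolated behind configuration.  Measured durations
underestimate truth by ≲ 0.1 s (last body spike to true offset), which
cancels in ratios.

Each triggered trial is linked to the event containing its detection and
compared to the immediately preceding non-stimulated event; for delayed
trials whose immediate control is shorter than the realized delay, the
nearest preceding discharge exceeding the delay substitutes.  Normalized
duration = 100 x stimulated / control.  Trials are averaged within animal
first; group statistics (mean ± s.e.m., two-tailed paired t on per-animal
mean stimulated vs control durations, df = n_animals − 1) weight animals
equally.  Pairing and the reshuffle never cross animals.

The pseudo-stimulation (reshuffle) null ignores stimulation entirely:
events longer than 2.5 s are randomly assigned (p = 0.5) to the
pseudo-stimulated group, compared to the immediately preceding event, or —
if that is shorter than 3 s — to the closest *preceding* qualifying (≥ 3 s)
event.  The search runs backwards only, mirroring the directionality of
the experimental pairing.  The null experiment generates its no-effect
streams with the delayed-protocol duration calibration (mean 5.52 s),
because the randomized group in the source design re-analyzes exactly
those recordings; with much shorter seizures the 2.5/3-s cuts select
longer controls and depress the null several percent below 100.

The continuous-stimulation analysis assigns events to 10-s pre / during /
post windows by onset; the triggering discharge (onset within 50 ms before
light onset, i.e. the detection latency) counts as "during".  Per-animal
window means feed a one-way repeated-measures ANOVA (statsmodels AnovaRM)
with Bonferroni-corrected paired-t post hocs (p x 3, capped at 1).
Degenerate inputs are resolved by convention: identical paired vectors
give t = 0, p = 1; a zero-variance nonzero difference is flagged as NaN;
windows with no within-animal variation give F = 0 and post-hoc p = 1.

## Problem sizes and what passing shows

The acceptance script simulates one ~30-min session per animal at the
published cohort sizes (8/5/5/7/8/13/6 animals for the seven recovery
targets) and trains the classifier on ~730 labeled epochs from 7 animals,
evaluating on ~210 epochs from 3 unseen animals; the test suite uses
10–15-min sessions.  Both finish in a few minutes on one CPU.

The generator emulates the statistics the analysis consumes — state
occupancy, event timing, duration law and drift, sentinel/body amplitudes,
per-condition duration effects.  It does **not** emulate electrode
artifacts, line noise, behavioral contamination, gradual waveform
evolution within a discharge, post-stimulation rebound (the "post" window
mean equals the pre mean here, whereas rebound above baseline has been
reported in vivo), or any chloride/biophysical mechanism.  Passing tests
therefore demonstrate that the *pipeline* implements the stated detection,
gating, pairing, resampling and aggregation rules faithfully enough to
recover known effects under realistic signal statistics — not that the
classifier or detector would reach the same scores on real ECoG.

## Known limitations

* Single channel only; no artifact rejection or line-noise filtering.
* The online path is threshold detection only; no streaming classifier.
* Delay classes 0/0.5/2 s are exact constants; real hardware jitter is not
  modeled beyond detection latency.
* The per-condition multipliers are constants per (condition, delay
  class); dose–response inside a class is not modeled.
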