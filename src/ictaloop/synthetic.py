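"""Seeded synthetic ECoG generator for the pilocarpine model.

Emulates the four network states seen in pilocarpine-induced focal cortical
activity — quiescent baseline, brief interictal bursts (State 1), discrete
electrographic seizures with a large negative sentinel spike and a
high-frequency body (State 2), and continuous epileptiform activity
(State 3) — together with per-condition photostimulation effects on seizure
duration.  The waveform model is deliberately phenomenological (pink noise
plus stereotyped spike templates): only the segment statistics matter to the
downstream detector, classifier and paired analysis.

Durations of consecutive seizures within an animal follow an AR(1) chain on
the log scale (slow within-experiment drift); the marginal distribution is
lognormal with the configured mean and dispersion.  This correlation is what
makes the immediately preceding discharge a meaningful control in the paired
analysis.

Determinism: every public entry point takes an integer seed; equal seeds
give bit-identical output.  Per-animal sub-seeds are derived from a master
seed via ``numpy.random.SeedSequence(master, spawn_key=(animal_index,))``.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional

import numpy as np
from scipy import stats

from .profiles import get_profile
from .types import (
    ConditionProfile,
    EcogRecording,
    GroundTruth,
    SeizureEvent,
    SeizureWaveformParams,
    StateLabel,
)

__all__ = [
    "generate_recording",
    "generate_seizure_waveform",
    "apply_stimulation_effect",
    "draw_control_duration",
    "animal_seed_sequence",
    "DEFAULT_SAMPLING_RATE",
]

DEFAULT_SAMPLING_RATE = 512.0

#: Shortest gap between consecutive seizures (s); keeps events separable by
#: the offline segmentation gap rule (0.3 s).
GAP_FLOOR = 0.6

#: Seizure body spikes start this long after the sentinel onset.
BODY_START = 0.15


def animal_seed_sequence(master_seed: int, animal_index: int) -> np.random.SeedSequence:
    """Reproducible per-animal seed stream: SeedSequence(master, spawn_key=(i,))."""
    return np.random.SeedSequence(int(master_seed), spawn_key=(int(animal_index),))


# ---------------------------------------------------------------------------
# noise and templates
# ---------------------------------------------------------------------------


def pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise of length ``n`` normalized to standard deviation ``sd``."""
    if n <= 0:
        return np.zeros(0)
    if n == 1:
        return rng.normal(0.0, sd, size=1)
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid division by zero; DC handled below
    spec /= np.sqrt(f)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def sentinel_template(
    sampling_rate: float,
    amplitude: float,
    width: float = 0.06,
    overshoot_frac: float = 0.2,
) -> np.ndarray:
    """Sentinel spike: raised-cosine negative lobe then a positive overshoot."""
    n_neg = max(2, int(round(width * sampling_rate)))
    t = np.arange(n_neg) / max(n_neg - 1, 1)
    neg = 0.5 * amplitude * (1.0 - np.cos(2.0 * np.pi * t))
    n_pos = max(2, int(round(0.08 * sampling_rate)))
    tp = np.arange(n_pos) / max(n_pos - 1, 1)
    pos = overshoot_frac * abs(amplitude) * np.sin(np.pi * tp)
    return np.concatenate([neg, pos])


def sentinel_crossing_time(
    amplitude: float, threshold: float, width: float = 0.06
) -> Optional[float]:
    """Time from sentinel onset to the first downward crossing of ``threshold``.

    Analytic inverse of the raised-cosine lobe; returns None if the sentinel
    never reaches the threshold.  Both arguments are negative microvolts.
    """
    if threshold >= 0 or amplitude >= 0 or amplitude > threshold:
        return None
    c = 1.0 - 2.0 * threshold / amplitude
    c = min(1.0, max(-1.0, c))
    return width * math.acos(c) / (2.0 * math.pi)


def _spike_template(sampling_rate: float, amplitude: float) -> np.ndarray:
    """Biphasic interictal/ictal spike: sharp negative trough, small rebound."""
    n1 = max(3, int(round(0.016 * sampling_rate)))
    n2 = max(3, int(round(0.024 * sampling_rate)))
    neg = -abs(amplitude) * np.hanning(n1)
    pos = 0.3 * abs(amplitude) * np.hanning(n2)
    return np.concatenate([neg, pos])


def _add_at(buf: np.ndarray, idx: int, wave: np.ndarray) -> None:
    """Add ``wave`` into ``buf`` starting at ``idx`` with boundary clipping."""
    if idx >= len(buf):
        return
    lo = max(idx, 0)
    hi = min(idx + len(wave), len(buf))
    if hi <= lo:
        return
    buf[lo:hi] += wave[lo - idx : hi - idx]


# ---------------------------------------------------------------------------
# seizure waveform
# ---------------------------------------------------------------------------


def generate_seizure_waveform(
    duration: float,
    params: Optional[SeizureWaveformParams] = None,
    seed: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> np.ndarray:
    """Clean (noise-free) waveform of one ictal discharge.

    The discharge opens with the sentinel spike — the most negative point of
    the whole event — followed from ``BODY_START`` onward by a ~10 Hz train
    of smaller negative spikes riding on a high-frequency oscillation inside
    ``params.hf_band``.  If ``duration`` does not exceed the sentinel width
    the event is sentinel-only.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    params = params or SeizureWaveformParams()
    params.validate_for_rate(sampling_rate)
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    n = max(1, int(round(duration * sampling_rate)))
    buf = np.zeros(n)
    sent = sentinel_template(
        sampling_rate,
        params.sentinel_amplitude,
        params.sentinel_width,
        params.sentinel_overshoot_frac,
    )
    _add_at(buf, 0, sent[:n])
    body_end = duration - 0.03
    if body_end > BODY_START:
        step = 1.0 / params.body_spike_rate
        times = np.arange(BODY_START, body_end, step)
        times = times + rng.uniform(-0.015, 0.015, size=len(times))
        if len(times) == 0 or body_end - times[-1] > 0.6 * step:
            times = np.append(times, body_end - 1e-3)
        times = np.clip(times, BODY_START, max(BODY_START, body_end - 1e-3))
        lo, hi = params.body_spike_amp_range
        for t in times:
            amp = rng.uniform(lo, hi)
            _add_at(buf, int(round(t * sampling_rate)), _spike_template(sampling_rate, amp))
        # continuous high-frequency component across the body
        i0 = int(round(BODY_START * sampling_rate))
        i1 = min(n, int(round(body_end * sampling_rate)))
        if i1 > i0 + 4:
            f0 = rng.uniform(*params.hf_band)
            tt = np.arange(i1 - i0) / sampling_rate
            env = np.hanning(2 * (i1 - i0))[: i1 - i0] * 0 + 1.0
            # taper the first/last 10% so the oscillation dies at event edges
            k = max(1, (i1 - i0) // 10)
            ramp = np.ones(i1 - i0)
            ramp[:k] = np.linspace(0, 1, k)
            ramp[-k:] = np.linspace(1, 0, k)
            phase = rng.uniform(0, 2 * np.pi)
            buf[i0:i1] += params.hf_amplitude * ramp * env * np.sin(
                2 * np.pi * f0 * tt + phase
            )
    return buf


def _burst_waveform(
    params: SeizureWaveformParams, rng: np.random.Generator, sampling_rate: float
) -> tuple:
    """One State-1 interictal burst; returns (waveform, length_s)."""
    length = rng.uniform(*params.burst_len_range)
    n = int(round(length * sampling_rate))
    buf = np.zeros(n)
    n_spikes = rng.integers(2, 4)
    for t in np.linspace(0.0, max(length - 0.03, 0.0), n_spikes):
        amp = rng.uniform(*params.burst_amp_range)
        _add_at(buf, int(round(t * sampling_rate)), _spike_template(sampling_rate, amp))
    return buf, length


def _s3_content(
    n: int, params: SeizureWaveformParams, rng: np.random.Generator, sampling_rate: float
) -> np.ndarray:
    """Continuous epileptiform activity: rhythmic ~3 Hz spiking, no sentinels."""
    buf = np.zeros(n)
    t = 0.1
    dur = n / sampling_rate
    while t < dur - 0.05:
        amp = rng.uniform(100.0, 150.0)
        _add_at(buf, int(round(t * sampling_rate)), _spike_template(sampling_rate, amp))
        t += rng.uniform(0.25, 0.42)
    tt = np.arange(n) / sampling_rate
    buf += 40.0 * np.sin(2 * np.pi * 1.5 * tt + rng.uniform(0, 2 * np.pi))
    buf += 15.0 * np.sin(2 * np.pi * rng.uniform(20, 40) * tt)
    return buf


# ---------------------------------------------------------------------------
# duration chain and plain effect operations
# ---------------------------------------------------------------------------


class DurationChain:
    """AR(1) chain on log seizure duration for one animal.

    Marginal: lognormal with mean ``mean_duration`` and sigma
    ``dispersion``; lag-1 autocorrelation ``rho``.
    """

    def __init__(self, mean_duration: float, dispersion: float, rho: float):
        if mean_duration <= 0:
            raise ValueError("mean_duration must be positive")
        self.sigma = float(dispersion)
        self.rho = float(rho)
        self.mu = math.log(mean_duration) - 0.5 * self.sigma**2
        self.innov_sd = self.sigma * math.sqrt(max(1.0 - self.rho**2, 0.0))
        self.a: Optional[float] = None

    def next(self, rng: np.random.Generator) -> float:
        if self.a is None:
            self.a = rng.normal(0.0, self.sigma)
        else:
            self.a = self.rho * self.a + rng.normal(0.0, self.innov_sd)
        return math.exp(self.mu + self.a)

    def next_truncated(self, min_duration: float, rng: np.random.Generator) -> float:
        """Advance the chain with the draw truncated below at ``min_duration``.

        Used for stimulated trials in delayed classes: the counterfactual
        seizure must outlast the programmed delay (otherwise the light would
        have arrived after the discharge had already ended).
        """
        a_min = math.log(min_duration) - self.mu
        if self.a is None:
            m, s = 0.0, self.sigma
        else:
            m, s = self.rho * self.a, max(self.innov_sd, 1e-9)
        lo = (a_min - m) / s
        if lo > 7.0:  # far tail: avoid truncnorm numerical trouble
            self.a = a_min + 0.02
        else:
            self.a = float(
                stats.truncnorm.rvs(lo, np.inf, loc=m, scale=s, random_state=rng)
            )
        return math.exp(self.mu + self.a)


def apply_stimulation_effect(
    control_duration: float, delay_class: str, profile: ConditionProfile
) -> float:
    """Deterministic duration effect: control duration times the class multiplier."""
    if control_duration <= 0:
        raise ValueError("control_duration must be positive")
    return control_duration * profile.multiplier(delay_class)


def draw_control_duration(
    delay_class: str,
    profile: ConditionProfile,
    seed_or_rng,
    size: Optional[int] = None,
    realized_delay: Optional[float] = None,
) -> np.ndarray | float:
    """Marginal control-duration draw(s) for a delay protocol.

    Lognormal with the profile's configured mean for the class; for delay
    classes "2" and ">2" the draw is truncated below at the realized delay
    (defaults to the class's nominal delay).
    """
    rng = (
        np.random.default_rng(seed_or_rng)
        if isinstance(seed_or_rng, (int, np.integer))
        else seed_or_rng
    )
    mean = profile.control_mean(delay_class)
    sigma = profile.duration_dispersion
    mu = math.log(mean) - 0.5 * sigma**2
    n = 1 if size is None else int(size)
    if delay_class in ("2", ">2"):
        if realized_delay is None:
            realized_delay = 2.0 if delay_class == "2" else float(
                np.mean(profile.delayed_delay_range)
            )
        lo = (math.log(realized_delay) - mu) / sigma
        x = np.exp(mu + sigma * stats.truncnorm.rvs(lo, np.inf, size=n, random_state=rng))
    else:
        x = np.exp(rng.normal(mu, sigma, size=n))
    return float(x[0]) if size is None else x


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

_CYCLE = (
    (StateLabel.BASELINE, 40.0),
    (StateLabel.S1_INTERICTAL, 40.0),
    (StateLabel.S2_ICTAL, 120.0),
    (StateLabel.S3_CONTINUOUS, 40.0),
)


def _plan_state_intervals(duration: float, layout: str, rng: np.random.Generator):
    if layout == "s2_only":
        return [(0.0, duration, StateLabel.S2_ICTAL)]
    if layout != "cycle":
        raise ValueError(f"unknown layout {layout!r}")
    iv = []
    t = 0.0
    i = 0
    while t < duration:
        label, base = _CYCLE[i % len(_CYCLE)]
        block = base * rng.uniform(0.8, 1.2)
        end = min(t + block, duration)
        iv.append((t, end, label))
        t = end
        i += 1
    return iv


def _plan_s2_events(
    t0: float,
    t1: float,
    profile: ConditionProfile,
    chain: DurationChain,
    rng: np.random.Generator,
    animal_id: str,
    mean_duration: float,
):
    """Sequential event plan for one State-2 interval (no stimulation)."""
    gap_mean = max(1.0 / profile.seizure_rate - mean_duration, 1.0)
    events = []
    t = t0 + GAP_FLOOR + rng.exponential(max(gap_mean - GAP_FLOOR, 0.1))
    while True:
        dur = max(chain.next(rng), 0.05)
        if t + dur > t1 - 0.5:
            break
        events.append(
            SeizureEvent(
                onset=t,
                offset=t + dur,
                animal_id=animal_id,
                control_duration=dur,
            )
        )
        t = t + dur + GAP_FLOOR + rng.exponential(max(gap_mean - GAP_FLOOR, 0.1))
    return events


def render_waveform(
    duration: float,
    truth: GroundTruth,
    params: SeizureWaveformParams,
    rng: np.random.Generator,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    amp_jitter: float = 1.0,
    burst_rate: float = 0.4,
    collect_bursts: bool = False,
) -> np.ndarray:
    """Render a full recording from its ground-truth plan.

    ``amp_jitter`` scales all deterministic content (per-animal electrode
    variability); noise is drawn fresh from ``rng``.
    """
    n = max(1, int(round(duration * sampling_rate)))
    buf = pink_noise(n, params.baseline_noise_sd, rng)
    for s, e, label in truth.state_intervals:
        i0, i1 = int(round(s * sampling_rate)), int(round(e * sampling_rate))
        if label is StateLabel.S1_INTERICTAL:
            t = s + rng.exponential(1.0 / burst_rate)
            while t < e - params.burst_len_range[1]:
                wave, blen = _burst_waveform(params, rng, sampling_rate)
                _add_at(buf, int(round(t * sampling_rate)), amp_jitter * wave)
                if collect_bursts:
                    truth.burst_intervals.append((t, t + blen))
                t += blen + rng.exponential(1.0 / burst_rate)
        elif label is StateLabel.S3_CONTINUOUS:
            buf[i0:i1] += amp_jitter * _s3_content(
                max(i1 - i0, 0), params, rng, sampling_rate
            )
    for ev in truth.seizure_events:
        # the closed-loop planner pre-assigns sentinel amplitudes so that the
        # logged detection times match the rendered waveform exactly
        if np.isfinite(ev.peak_negative_amplitude):
            sent_amp = ev.peak_negative_amplitude / amp_jitter
        else:
            sent_amp = params.sentinel_amplitude * rng.uniform(0.95, 1.1)
            ev.peak_negative_amplitude = amp_jitter * sent_amp
        p = replace(params, sentinel_amplitude=sent_amp)
        wave = generate_seizure_waveform(
            ev.duration, p, seed=rng, sampling_rate=sampling_rate
        )
        _add_at(buf, int(round(ev.onset * sampling_rate)), amp_jitter * wave)
    return buf


def generate_recording(
    profile: ConditionProfile | str,
    duration: float,
    seed: int,
    layout: str = "cycle",
    params: Optional[SeizureWaveformParams] = None,
    animal_id: str = "animal-00",
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> EcogRecording:
    """Generate an unstimulated recording with complete ground truth.

    ``layout="cycle"`` alternates baseline/S1/S2/S3 blocks (for classifier
    training material); ``layout="s2_only"`` yields one long State-2
    interval.  Discrete seizures are placed only inside State-2 intervals at
    ~``profile.seizure_rate`` events per second.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(profile, str):
        profile = get_profile(profile)
    params = params or SeizureWaveformParams()
    ss = np.random.SeedSequence(int(seed))
    plan_rng, wave_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    intervals = _plan_state_intervals(duration, layout, plan_rng)
    mean_dur = profile.control_mean("0")
    chain = DurationChain(mean_dur, profile.duration_dispersion, profile.duration_autocorr)
    events = []
    for s, e, label in intervals:
        if label is StateLabel.S2_ICTAL:
            events.extend(
                _plan_s2_events(s, e, profile, chain, plan_rng, animal_id, mean_dur)
            )
    truth = GroundTruth(state_intervals=intervals, seizure_events=events)
    samples = render_waveform(
        duration, truth, params, wave_rng, sampling_rate, collect_bursts=True
    )
    return EcogRecording(
        samples=samples,
        sampling_rate=sampling_rate,
        animal_id=animal_id,
        annotations=truth,
    )
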