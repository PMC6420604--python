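"""Closed-loop path: online threshold detection and stimulation scheduling.

Mirrors the FPGA system used in vivo: seizure onsets are detected by a
negative-going voltage threshold crossing of the sentinel spike, light
pulses are scheduled with randomized delays, are only triggered on
alternate accepted trials (so every stimulated discharge has a preceding
unstimulated one as its control), and accepted trials are separated by at
least 20 s so that clean 10-s pre- and post-stimulation epochs exist.

:func:`run_closed_loop_session` simulates a whole experiment event by
event: because stimulation changes the duration of the ongoing discharge
(and therefore the timing of everything after it), the session is built
sequentially with the *same* scheduler implementation that
:func:`schedule_stimulations` exposes for offline detection streams.
Detection times are the exact analytic threshold-crossing times of each
event's sentinel; the sample-domain detector reproduces them to within a
few milliseconds on the rendered waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import median_abs_deviation

from .profiles import get_profile
from .synthetic import (
    DEFAULT_SAMPLING_RATE,
    GAP_FLOOR,
    DurationChain,
    render_waveform,
    sentinel_crossing_time,
)
from .types import (
    ConditionProfile,
    EcogRecording,
    GroundTruth,
    SeizureEvent,
    SeizureWaveformParams,
    StateLabel,
    StimulationEvent,
)

__all__ = [
    "DetectorConfig",
    "SchedulerPolicy",
    "detect_onsets",
    "auto_threshold",
    "schedule_stimulations",
    "plan_closed_loop_session",
    "run_closed_loop_session",
]

_FIXED_DELAYS = {"0": 0.0, "0.5": 0.5, "2": 2.0, "continuous": 0.0}


@dataclass
class DetectorConfig:
    """Online detector: negative-going threshold crossing with a refractory."""

    threshold: float
    refractory: float = 1.0
    direction: str = "negative"

    def __post_init__(self) -> None:
        if self.refractory < 0:
            raise ValueError("refractory must be nonnegative")
        if self.direction != "negative":
            raise ValueError("only negative-going detection is supported")


@dataclass
class SchedulerPolicy:
    """Stimulation scheduling rules.

    ``min_interval`` (>= 20 s) guarantees room for the 10-s pre- and
    post-stimulation epochs; with ``alternate`` the first accepted trial is
    a control and triggers alternate thereafter.  ``delay_classes`` are
    sampled with ``delay_weights`` for each triggered trial; the ">2" class
    draws its delay uniformly from ``delayed_range``.
    """

    min_interval: float = 20.0
    alternate: bool = True
    delay_classes: tuple = ("0", "0.5", "2", ">2")
    delay_weights: Optional[tuple] = None
    rng_seed: int = 0
    warmup: float = 0.0
    light_duration: float = 10.0
    delayed_range: tuple = (2.5, 4.8)

    def weights(self) -> np.ndarray:
        if self.delay_weights is None:
            w = np.ones(len(self.delay_classes))
        else:
            w = np.asarray(self.delay_weights, dtype=float)
            if len(w) != len(self.delay_classes):
                raise ValueError("delay_weights must match delay_classes")
        return w / w.sum()


class _SchedulerState:
    """Stateful trial acceptance shared by the online and offline paths."""

    def __init__(
        self,
        policy: SchedulerPolicy,
        rng: np.random.Generator,
        condition: str,
        animal_id: str = "animal-00",
    ):
        self.policy = policy
        self.rng = rng
        self.condition = condition
        self.animal_id = animal_id
        self.last_accepted: Optional[float] = None
        self.next_is_control = policy.alternate

    def _draw_delay(self) -> tuple:
        cls = str(self.rng.choice(self.policy.delay_classes, p=self.policy.weights()))
        if cls == ">2":
            delay = float(self.rng.uniform(*self.policy.delayed_range))
        else:
            delay = _FIXED_DELAYS[cls]
        return cls, delay

    def step(self, detection_time: float) -> Optional[StimulationEvent]:
        if detection_time < self.policy.warmup:
            return None
        if (
            self.last_accepted is not None
            and detection_time - self.last_accepted < self.policy.min_interval
        ):
            return None
        self.last_accepted = detection_time
        if self.next_is_control:
            self.next_is_control = False
            return StimulationEvent(
                detection_time=detection_time,
                delay=0.0,
                delay_class=None,
                light_on=None,
                triggered=False,
                condition=self.condition,
                light_duration=self.policy.light_duration,
                animal_id=self.animal_id,
            )
        if self.policy.alternate:
            self.next_is_control = True
        cls, delay = self._draw_delay()
        return StimulationEvent(
            detection_time=detection_time,
            delay=delay,
            delay_class=cls,
            light_on=detection_time + delay,
            triggered=True,
            condition=self.condition,
            light_duration=self.policy.light_duration,
            animal_id=self.animal_id,
        )


def schedule_stimulations(
    detections,
    policy: SchedulerPolicy,
    condition: str = "NO_OPSIN",
    rng: Optional[np.random.Generator] = None,
    animal_id: str = "animal-00",
) -> list:
    """Apply the scheduling rules to a sorted stream of detection times."""
    detections = list(detections)
    if any(b < a for a, b in zip(detections, detections[1:])):
        raise ValueError("detections must be sorted ascending")
    rng = rng if rng is not None else np.random.default_rng(policy.rng_seed)
    state = _SchedulerState(policy, rng, condition, animal_id)
    out = []
    for d in detections:
        ev = state.step(d)
        if ev is not None:
            out.append(ev)
    return out


def detect_onsets(recording: EcogRecording, config: DetectorConfig) -> list:
    """Causal negative-threshold-crossing detection with a refractory period.

    A detection is emitted at the first sample strictly below the threshold
    following a sample at or above it; crossings within ``refractory``
    seconds of the previous detection are ignored.
    """
    x = recording.samples
    fs = recording.sampling_rate
    below = x < config.threshold
    cross = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if len(below) and below[0]:
        cross = np.concatenate([[0], cross])
    out = []
    last = -math.inf
    ref = config.refractory * fs
    for i in cross:
        if i - last >= ref:
            out.append(i / fs)
            last = i
    return out


def auto_threshold(
    recording_prefix: EcogRecording, k: float = 6.0, min_prefix: float = 30.0
) -> float:
    """Robust threshold from a recording prefix: median - k * MAD.

    Requires at least ``min_prefix`` seconds of signal.  For a constant
    prefix (MAD = 0) the threshold equals the constant, so a strictly
    downward crossing can never occur.
    """
    if recording_prefix.duration < min_prefix:
        raise ValueError(
            f"prefix of {recording_prefix.duration:.1f} s is shorter than the "
            f"required {min_prefix:.0f} s"
        )
    x = recording_prefix.samples
    return float(np.median(x) - k * median_abs_deviation(x))


# ---------------------------------------------------------------------------
# full closed-loop session
# ---------------------------------------------------------------------------


@dataclass
class SessionPlan:
    """Event-level plan of a closed-loop session (pre-rendering)."""

    truth: GroundTruth
    stims: list
    detector_threshold: float
    amp_jitter: float
    duration: float
    animal_id: str
    profile: ConditionProfile
    params: SeizureWaveformParams
    waveform_seed: np.random.SeedSequence = field(repr=False, default=None)


def plan_closed_loop_session(
    profile: ConditionProfile | str,
    policy: SchedulerPolicy,
    duration: float,
    seed,
    params: Optional[SeizureWaveformParams] = None,
    animal_id: str = "animal-00",
    detector_threshold: Optional[float] = None,
) -> SessionPlan:
    """Simulate the closed loop event by event without rendering samples.

    The returned ground truth records, for every discharge, its realized
    duration and its counterfactual (unstimulated) duration; for triggered
    trials the two differ by the condition's delay-class multiplier (with a
    small lognormal per-animal effect jitter).  Stimulated trials in the
    "2" and ">2" delay classes draw their counterfactual truncated below at
    the realized delay.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(profile, str):
        profile = get_profile(profile)
    params = params or SeizureWaveformParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    s_plan, s_sched, s_animal, s_wave = ss.spawn(4)
    rng = np.random.default_rng(s_plan)
    rng_an = np.random.default_rng(s_animal)

    amp_jitter = float(rng_an.uniform(0.9, 1.15))
    logmean_off = float(rng_an.normal(0.0, profile.animal_logmean_sd))
    effect_jit = float(rng_an.normal(0.0, profile.animal_effect_sd))
    if detector_threshold is None:
        # emulates the per-experiment manual threshold adjustment
        detector_threshold = 0.6 * params.sentinel_amplitude

    w = policy.weights()
    mean_ctrl = float(
        sum(wi * profile.control_mean(c) for wi, c in zip(w, policy.delay_classes))
    )
    chain = DurationChain(
        mean_ctrl * math.exp(logmean_off),
        profile.duration_dispersion,
        profile.duration_autocorr,
    )
    gap_mean = max(1.0 / profile.seizure_rate - mean_ctrl, 1.0)
    sched = _SchedulerState(policy, np.random.default_rng(s_sched), profile.name, animal_id)
    continuous = "continuous" in policy.delay_classes

    def _mult(cls: str) -> float:
        m = profile.multiplier(cls)
        return m if m == 1.0 else m * math.exp(effect_jit)

    events: list = []
    stims: list = []
    light_end = -math.inf
    light_stim: Optional[StimulationEvent] = None
    t = GAP_FLOOR + rng.exponential(max(gap_mean - GAP_FLOOR, 0.1))
    while True:
        onset = t
        sent_amp = params.sentinel_amplitude * amp_jitter * rng.uniform(0.95, 1.1)
        latency = sentinel_crossing_time(
            sent_amp, detector_threshold, params.sentinel_width
        )
        decision = sched.step(onset + latency) if latency is not None else None

        stimulated = False
        linked = decision
        if decision is not None and decision.triggered:
            cls = decision.delay_class
            if cls in ("2", ">2"):
                cf = chain.next_truncated(max(decision.delay, 0.05), rng)
            else:
                cf = chain.next(rng)
            dur = max(cf * _mult(cls), 0.05)
            stimulated = True
            if continuous:
                light_end = decision.light_on + decision.light_duration
                light_stim = decision
        elif continuous and onset < light_end:
            cf = chain.next(rng)
            dur = max(cf * _mult("continuous"), 0.05)
            stimulated = True
            linked = light_stim
        else:
            cf = chain.next(rng)
            dur = cf

        if onset + dur > duration - 1.0:
            break
        events.append(
            SeizureEvent(
                onset=onset,
                offset=onset + dur,
                animal_id=animal_id,
                peak_negative_amplitude=sent_amp,
                stimulated=stimulated,
                control_duration=cf,
                linked_stim=linked,
            )
        )
        if decision is not None:
            stims.append(decision)
        t = onset + dur + GAP_FLOOR + rng.exponential(max(gap_mean - GAP_FLOOR, 0.1))

    truth = GroundTruth(
        state_intervals=[(0.0, duration, StateLabel.S2_ICTAL)],
        seizure_events=events,
        stim_events=stims,
    )
    return SessionPlan(
        truth=truth,
        stims=stims,
        detector_threshold=detector_threshold,
        amp_jitter=amp_jitter,
        duration=duration,
        animal_id=animal_id,
        profile=profile,
        params=params,
        waveform_seed=s_wave,
    )


def render_session(plan: SessionPlan, sampling_rate: float = DEFAULT_SAMPLING_RATE) -> EcogRecording:
    """Render a planned session into an :class:`EcogRecording`."""
    rng = np.random.default_rng(plan.waveform_seed)
    samples = render_waveform(
        plan.duration,
        plan.truth,
        plan.params,
        rng,
        sampling_rate=sampling_rate,
        amp_jitter=plan.amp_jitter,
    )
    return EcogRecording(
        samples=samples,
        sampling_rate=sampling_rate,
        animal_id=plan.animal_id,
        annotations=plan.truth,
    )


def run_closed_loop_session(
    profile: ConditionProfile | str,
    policy: SchedulerPolicy,
    duration: float,
    seed,
    params: Optional[SeizureWaveformParams] = None,
    animal_id: str = "animal-00",
    detector_threshold: Optional[float] = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> tuple:
    """Simulate one full closed-loop experiment.

    Returns ``(recording, stim_events)``.  The recording's ground truth
    marks, for every stimulated trial, both the counterfactual control
    duration and the realized (stimulated) duration.
    """
    plan = plan_closed_loop_session(
        profile,
        policy,
        duration,
        seed,
        params=params,
        animal_id=animal_id,
        detector_threshold=detector_threshold,
    )
    recording = render_session(plan, sampling_rate=sampling_rate)
    return recording, plan.stims
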