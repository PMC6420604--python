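"""Core domain types for single-channel ECoG seizure analytics.

All times are seconds, all voltages microvolts unless a recording has been
min-max scaled (in which case ``scale_info`` records the original range so
thresholds can be mapped between the two unit systems).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "StateLabel",
    "DELAY_CLASSES",
    "EcogRecording",
    "GroundTruth",
    "SeizureEvent",
    "StimulationEvent",
    "TrialPair",
    "ConditionProfile",
    "SeizureWaveformParams",
]


class StateLabel(str, Enum):
    """Network states of pilocarpine-induced cortical activity.

    BASELINE is quiescence; S1 is brief (100-150 ms) interictal bursting;
    S2 is discrete electrographic seizures; S3 is continuous epileptiform
    activity.  MIXED is a classifier *output* only (low-confidence epochs)
    and never appears as a generator ground-truth label.
    """

    BASELINE = "baseline"
    S1_INTERICTAL = "s1_interictal"
    S2_ICTAL = "s2_ictal"
    S3_CONTINUOUS = "s3_continuous"
    MIXED = "mixed"


#: Photostimulation delay classes: fixed delays of 0, 0.5 and 2 s, a
#: randomized ">2" class (drawn uniformly, see ConditionProfile), and
#: "continuous" for the immediate 10-s-pulse protocol.
DELAY_CLASSES = ("0", "0.5", "2", ">2", "continuous")


@dataclass
class SeizureEvent:
    """One ictal discharge.

    ``control_duration`` is the generator's counterfactual (the duration the
    event would have had without photostimulation); for measured events it
    is ``None``.
    """

    onset: float
    offset: float
    animal_id: str = "animal-00"
    peak_negative_amplitude: float = float("nan")
    stimulated: bool = False
    control_duration: Optional[float] = None
    linked_stim: Optional["StimulationEvent"] = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(
                f"event offset ({self.offset}) must exceed onset ({self.onset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class StimulationEvent:
    """One accepted closed-loop trial (control or light-triggered)."""

    detection_time: float
    delay: float
    delay_class: Optional[str]
    light_on: Optional[float]
    triggered: bool
    condition: str = "NO_OPSIN"
    light_duration: float = 10.0
    animal_id: str = "animal-00"

    def __post_init__(self) -> None:
        if self.triggered:
            if self.light_on is None:
                raise ValueError("triggered stimulation requires light_on")
            if abs(self.light_on - (self.detection_time + self.delay)) > 1e-9:
                raise ValueError("light_on must equal detection_time + delay")
            if self.delay_class not in DELAY_CLASSES:
                raise ValueError(f"unknown delay class {self.delay_class!r}")


@dataclass
class GroundTruth:
    """Generator-side truth for one recording."""

    state_intervals: list  # of (start_s, end_s, StateLabel)
    seizure_events: list = field(default_factory=list)  # of SeizureEvent
    stim_events: list = field(default_factory=list)  # of StimulationEvent
    burst_intervals: list = field(default_factory=list)  # of (start_s, end_s)

    def __post_init__(self) -> None:
        iv = sorted(self.state_intervals, key=lambda t: t[0])
        for (s0, e0, _), (s1, _, _) in zip(iv, iv[1:]):
            if s1 < e0 - 1e-9:
                raise ValueError("state intervals overlap")
        self.state_intervals = iv
        for lab in (t[2] for t in iv):
            if lab is StateLabel.MIXED:
                raise ValueError("MIXED is never a ground-truth label")


@dataclass
class EcogRecording:
    """Single-channel voltage trace.

    ``samples`` are microvolts for raw recordings; after :func:`minmax_scale`
    they lie in [0, 1] and ``scale_info = (orig_min, orig_max)``.
    """

    samples: np.ndarray
    sampling_rate: float = 512.0
    animal_id: str = "animal-00"
    annotations: Optional[GroundTruth] = None
    scale_info: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("recording must be single-channel (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def is_scaled(self) -> bool:
        return self.scale_info is not None

    def to_scaled_units(self, value_uv: float) -> float:
        """Map a raw microvolt value into this recording's scaled units."""
        if self.scale_info is None:
            raise ValueError("recording carries no scale_info; scale it first")
        mn, mx = self.scale_info
        if mx == mn:
            return 0.0
        return (value_uv - mn) / (mx - mn)


@dataclass
class TrialPair:
    """A stimulated event and its (possibly substituted) control."""

    stimulated: SeizureEvent
    control: SeizureEvent
    delay_class: Optional[str]
    condition: str

    def __post_init__(self) -> None:
        if not self.control.onset < self.stimulated.onset:
            raise ValueError("control must precede the stimulated event")

    @property
    def normalized_duration(self) -> float:
        """Stimulated duration as percent of the control duration."""
        if self.control.duration <= 0:
            raise ValueError("control duration must be positive")
        return 100.0 * self.stimulated.duration / self.control.duration

    @property
    def animal_id(self) -> str:
        return self.stimulated.animal_id


@dataclass
class ConditionProfile:
    """Experimental condition: opsin/promoter combination and its effects.

    ``duration_multiplier_by_delay`` maps each delay class to the
    multiplicative effect of light on seizure duration (1.0 = no effect);
    ``control_duration_mean_by_delay`` gives the mean unstimulated seizure
    duration (s) under each delay protocol.  ``duration_dispersion`` is the
    marginal lognormal sigma of durations and ``duration_autocorr`` the
    lag-1 autocorrelation of the per-animal log-duration chain (seizure
    durations drift slowly over an experiment, which is what makes the
    previous event a meaningful control).
    """

    name: str
    duration_multiplier_by_delay: dict
    control_duration_mean_by_delay: dict
    seizure_rate: float = 0.2  # events per second of State-2 activity
    duration_dispersion: float = 0.5
    duration_autocorr: float = 0.95
    animal_effect_sd: float = 0.05
    animal_logmean_sd: float = 0.10
    delayed_delay_range: tuple = (2.5, 4.8)

    def __post_init__(self) -> None:
        for c, m in self.duration_multiplier_by_delay.items():
            if c not in DELAY_CLASSES:
                raise ValueError(f"unknown delay class {c!r}")
            if m <= 0:
                raise ValueError("duration multipliers must be positive")
        if self.name == "NO_OPSIN" and any(
            m != 1.0 for m in self.duration_multiplier_by_delay.values()
        ):
            raise ValueError("NO_OPSIN must have all multipliers equal to 1")

    def multiplier(self, delay_class: str) -> float:
        try:
            return self.duration_multiplier_by_delay[delay_class]
        except KeyError:
            raise KeyError(
                f"profile {self.name} defines no multiplier for delay class "
                f"{delay_class!r}"
            ) from None

    def control_mean(self, delay_class: str) -> float:
        try:
            return self.control_duration_mean_by_delay[delay_class]
        except KeyError:
            raise KeyError(
                f"profile {self.name} defines no control duration mean for "
                f"delay class {delay_class!r}"
            ) from None


@dataclass
class SeizureWaveformParams:
    """Phenomenological waveform parameters (microvolts / Hz / seconds)."""

    sentinel_amplitude: float = -400.0
    sentinel_width: float = 0.06
    sentinel_overshoot_frac: float = 0.2
    body_spike_rate: float = 10.0
    body_spike_amp_range: tuple = (110.0, 180.0)
    hf_band: tuple = (40.0, 90.0)
    hf_amplitude: float = 25.0
    burst_len_range: tuple = (0.100, 0.150)
    burst_amp_range: tuple = (100.0, 160.0)
    baseline_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.sentinel_amplitude >= 0:
            raise ValueError("sentinel_amplitude must be negative")
        lo, hi = self.hf_band
        if not (0 < lo < hi):
            raise ValueError("hf_band must satisfy 0 < low < high")

    def validate_for_rate(self, sampling_rate: float) -> None:
        if self.hf_band[1] >= sampling_rate / 2:
            raise ValueError("hf_band must lie below the Nyquist frequency")
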