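"""Epoch segmentation and the 20-feature vector.

Recordings are min-max scaled to [0, 1] once per recording, cut into
consecutive non-overlapping 10-s epochs, and summarized by 20 features:
moments (mean, std, Fisher excess kurtosis, adjusted Fisher-Pearson skew),
total variation (sum of absolute first differences), extrema counts and
levels (peaks/valleys by topographic prominence), average Morlet wavelet
power at 1, 5, 10, 15, 20, 30, 60 and 90 Hz, and two quiescence measures
(number of baseline points within a small band of the epoch median, and the
mean index difference between consecutive baseline points).

Wavelet power convention: one Morlet scale per listed centre frequency;
the feature is the scale-weighted mean squared coefficient magnitude
(``scale * mean|coef|^2``), a 1/f weighting under which white-noise powers
decay with frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import pywt
from scipy.signal import find_peaks
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .types import EcogRecording, StateLabel

__all__ = [
    "EPOCH_SECONDS",
    "FEATURE_NAMES",
    "WAVELET_FREQS_HZ",
    "Epoch",
    "minmax_scale",
    "segment_epochs",
    "detect_extrema",
    "wavelet_powers",
    "baseline_points",
    "extract_features",
    "feature_matrix",
]

EPOCH_SECONDS = 10.0

WAVELET_FREQS_HZ = (1, 5, 10, 15, 20, 30, 60, 90)

FEATURE_NAMES = (
    "mean",
    "std",
    "kurtosis",
    "skew",
    "sum_abs_diff",
    "n_peaks",
    "n_valleys",
    "mean_valley",
    "mean_peak",
    "mean_peak_valley_range",
    *(f"wpow_{f}" for f in WAVELET_FREQS_HZ),
    "n_baseline_points",
    "baseline_idx_mean_diff",
)

#: Default peak/valley topographic prominence, in scaled units.
DEFAULT_PROMINENCE = 0.05

#: Default half-width of the baseline band around the epoch median (scaled).
DEFAULT_BASELINE_BAND = 0.02

_WAVELET = "morl"


@dataclass
class Epoch:
    """A 10-s slice of a scaled recording."""

    samples: np.ndarray
    start: float
    sampling_rate: float
    label: Optional[StateLabel] = None
    animal_id: str = "animal-00"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def minmax_scale(recording: EcogRecording) -> EcogRecording:
    """Scale a whole recording to [0, 1] (idempotent; constant maps to 0)."""
    x = recording.samples
    if len(x) < 2:
        raise ValueError("need at least two samples to scale")
    mn, mx = float(x.min()), float(x.max())
    if mx == mn:
        scaled = np.zeros_like(x)
    else:
        scaled = (x - mn) / (mx - mn)
    info = recording.scale_info if recording.is_scaled else (mn, mx)
    return EcogRecording(
        samples=scaled,
        sampling_rate=recording.sampling_rate,
        animal_id=recording.animal_id,
        annotations=recording.annotations,
        scale_info=info,
    )


def _label_for(start: float, end: float, recording: EcogRecording):
    if recording.annotations is None:
        return None
    for s, e, lab in recording.annotations.state_intervals:
        if start >= s - 1e-9 and end <= e + 1e-9:
            return lab
    return None  # straddles a state boundary


def segment_epochs(recording: EcogRecording) -> list:
    """Cut a scaled recording into floor(duration/10) consecutive epochs.

    Each epoch is labeled with the ground-truth state if it lies entirely
    inside one state interval, else ``None``.  The final partial epoch is
    discarded.
    """
    n_epoch = int(round(EPOCH_SECONDS * recording.sampling_rate))
    n = len(recording.samples) // n_epoch
    out = []
    for i in range(n):
        start = i * EPOCH_SECONDS
        out.append(
            Epoch(
                samples=recording.samples[i * n_epoch : (i + 1) * n_epoch],
                start=start,
                sampling_rate=recording.sampling_rate,
                label=_label_for(start, start + EPOCH_SECONDS, recording),
                animal_id=recording.animal_id,
            )
        )
    return out


def epoch_at(recording: EcogRecording, start: float) -> Epoch:
    """The 10-s epoch beginning at ``start`` seconds (for pre-trigger gating)."""
    fs = recording.sampling_rate
    i0 = int(round(start * fs))
    i1 = i0 + int(round(EPOCH_SECONDS * fs))
    if i0 < 0 or i1 > len(recording.samples):
        raise ValueError("requested epoch extends outside the recording")
    return Epoch(
        samples=recording.samples[i0:i1],
        start=start,
        sampling_rate=fs,
        label=_label_for(start, start + EPOCH_SECONDS, recording),
        animal_id=recording.animal_id,
    )


def detect_extrema(samples: np.ndarray, prominence: float = DEFAULT_PROMINENCE):
    """Peak and valley indices by topographic prominence (valleys on -x)."""
    if prominence < 0:
        raise ValueError("prominence must be nonnegative")
    x = np.asarray(samples, dtype=float)
    peaks, _ = find_peaks(x, prominence=prominence)
    valleys, _ = find_peaks(-x, prominence=prominence)
    return peaks, valleys


def wavelet_powers(
    samples: np.ndarray, sampling_rate: float, freqs=WAVELET_FREQS_HZ
) -> np.ndarray:
    """Scale-weighted mean squared Morlet coefficients at the given frequencies.

    The epoch mean is removed first: the wavelet measures oscillatory power,
    and a DC offset would otherwise leak step artifacts in from the epoch
    edges of the finite convolution.
    """
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    scales = pywt.frequency2scale(_WAVELET, np.asarray(freqs, float) / sampling_rate)
    coef, _ = pywt.cwt(x, scales, _WAVELET, method="fft")
    return scales * (np.abs(coef) ** 2).mean(axis=1)


def baseline_points(samples: np.ndarray, band: float = DEFAULT_BASELINE_BAND):
    """Quiescence measures of an epoch.

    Baseline points are samples within ``band`` of the epoch median; the
    second value is the mean first-difference of their (sorted) indices.
    With fewer than two baseline points the difference defaults to the
    epoch length.
    """
    if band <= 0:
        raise ValueError("band must be positive")
    x = np.asarray(samples, dtype=float)
    idx = np.flatnonzero(np.abs(x - np.median(x)) <= band)
    if len(idx) < 2:
        return len(idx), float(len(x))
    return len(idx), float(np.diff(idx).mean())


def extract_features(
    epoch: Epoch,
    prominence: float = DEFAULT_PROMINENCE,
    baseline_band: float = DEFAULT_BASELINE_BAND,
) -> np.ndarray:
    """The ordered 20-feature vector of one epoch (see FEATURE_NAMES)."""
    x = epoch.samples
    mean = float(x.mean())
    std = float(x.std())
    if std <= 1e-12 * max(1.0, abs(mean)):
        std, kurt, skw = 0.0, 0.0, 0.0
    else:
        kurt = float(_kurtosis(x, fisher=True, bias=False))
        skw = float(_skew(x, bias=False))
    sad = float(np.abs(np.diff(x)).sum())
    peaks, valleys = detect_extrema(x, prominence)
    mean_peak = float(x[peaks].mean()) if len(peaks) else mean
    mean_valley = float(x[valleys].mean()) if len(valleys) else mean
    wpow = wavelet_powers(x, epoch.sampling_rate)
    nbp, bmd = baseline_points(x, baseline_band)
    fv = np.array(
        [
            mean,
            std,
            kurt,
            skw,
            sad,
            float(len(peaks)),
            float(len(valleys)),
            mean_valley,
            mean_peak,
            mean_peak - mean_valley,
            *wpow,
            float(nbp),
            bmd,
        ]
    )
    assert len(fv) == len(FEATURE_NAMES)
    if not np.all(np.isfinite(fv)):
        raise ValueError("non-finite feature value")
    return fv


def feature_matrix(
    epochs,
    prominence: float = DEFAULT_PROMINENCE,
    baseline_band: float = DEFAULT_BASELINE_BAND,
) -> pd.DataFrame:
    """Feature DataFrame (one row per epoch) with animal/start/label columns."""
    rows = [extract_features(ep, prominence, baseline_band) for ep in epochs]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "animal_id", [ep.animal_id for ep in epochs])
    df.insert(1, "epoch_start_s", [ep.start for ep in epochs])
    df["label"] = [ep.label.value if ep.label is not None else "" for ep in epochs]
    return df
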