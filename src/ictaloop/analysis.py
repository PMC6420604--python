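"""Offline seizure-duration analysis.

Implements the paired stimulated-vs-control comparison used to quantify
closed-loop photostimulation effects: events are segmented from the scaled
trace by threshold crossings, each triggered trial is linked to the
discharge that caused detection and compared to the immediately preceding
non-stimulated discharge (for delayed trials whose control is shorter than
the delay itself, the nearest preceding discharge exceeding the delay is
substituted), durations are expressed as percent of control, averaged
within animal first, and tested across animals.  A randomized
pseudo-stimulation (reshuffle) procedure provides the no-effect null.

The model/results pair :class:`StimulationEffectModel` /
:class:`StimulationEffectResults` packages the full paired pipeline;
:class:`WindowAnalysis` packages the pre/during/post 10-s-window analysis
of the continuous-stimulation protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import EcogRecording, SeizureEvent, StimulationEvent, TrialPair

__all__ = [
    "segment_events",
    "pair_trials",
    "normalized_duration",
    "reshuffle_null",
    "per_animal_aggregate",
    "paired_t",
    "rm_anova_bonferroni",
    "window_analysis",
    "StimulationEffectModel",
    "StimulationEffectResults",
    "WindowAnalysis",
    "WindowResults",
]

#: Offline event criteria (seconds): an event ends when no suprathreshold
#: deflection occurs for MIN_GAP; events shorter than MIN_DURATION are
#: discarded (after gap merging).
DEFAULT_MIN_GAP = 0.3
DEFAULT_MIN_DURATION = 0.5

#: Reshuffle rules: events longer than ELIGIBLE_MIN may be pseudo-stimulated;
#: a control must be at least QUALIFY_MIN long.
RESHUFFLE_ELIGIBLE_MIN = 2.5
RESHUFFLE_QUALIFY_MIN = 3.0


def segment_events(
    recording: EcogRecording,
    threshold: float,
    min_gap: float = DEFAULT_MIN_GAP,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> list:
    """Segment ictal discharges from a (scaled) recording.

    An event starts at a downward threshold crossing and ends when no
    suprathreshold deflection occurs for ``min_gap`` seconds; events
    shorter than ``min_duration`` are discarded.  ``threshold`` must be in
    the recording's units (use ``recording.to_scaled_units`` to map a
    microvolt threshold onto a scaled recording).
    """
    x = recording.samples
    fs = recording.sampling_rate
    idx = np.flatnonzero(x < threshold)
    if len(idx) == 0:
        return []
    gap_samples = min_gap * fs
    breaks = np.flatnonzero(np.diff(idx) > gap_samples)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    events = []
    for s, e in zip(starts, ends):
        onset = idx[s] / fs
        offset = (idx[e] + 1) / fs
        if offset - onset < min_duration:
            continue
        events.append(
            SeizureEvent(
                onset=onset,
                offset=offset,
                animal_id=recording.animal_id,
                peak_negative_amplitude=float(x[idx[s] : idx[e] + 1].min()),
            )
        )
    return events


def normalized_duration(pair: TrialPair) -> float:
    """Stimulated duration as percent of its control (100 = no change)."""
    return pair.normalized_duration


def _link_events(events, stims):
    """Map each triggered stimulation to the event containing its detection."""
    onsets = np.array([ev.onset for ev in events])
    links = {}
    for k, stim in enumerate(stims):
        if not stim.triggered:
            continue
        i = int(np.searchsorted(onsets, stim.detection_time, side="right")) - 1
        if i >= 0 and events[i].onset <= stim.detection_time <= events[i].offset:
            links[k] = i
    return links


def _split_by_animal(events, stims):
    """Group events and stims per animal; time axes are per-animal."""
    animals = sorted(
        {ev.animal_id for ev in events} | {s.animal_id for s in stims}
    )
    for a in animals:
        yield (
            [ev for ev in events if ev.animal_id == a],
            [s for s in stims if s.animal_id == a],
        )


def pair_trials(
    events,
    stims,
    gate: Optional[Callable[[StimulationEvent], bool]] = None,
    dropped: Optional[list] = None,
) -> list:
    """Pair each triggered trial with its control discharge.

    The control is the immediately preceding non-stimulated event; for
    trials in the "2" and ">2" delay classes whose immediate control is
    shorter than the realized delay, the nearest preceding discharge
    exceeding the delay is substituted.  Trials failing ``gate`` (e.g. the
    pre-trigger epoch is not confidently State 2) or lacking a qualifying
    control are dropped; reasons are appended to ``dropped`` if given.

    Streams of several animals may be passed together; pairing never
    crosses animals.
    """
    groups = list(_split_by_animal(events, stims))
    if len(groups) > 1:
        pairs = []
        for evs, sts in groups:
            pairs.extend(pair_trials(evs, sts, gate=gate, dropped=dropped))
        return pairs
    events = sorted(events, key=lambda ev: ev.onset)
    links = _link_events(events, stims)
    stim_event_idx = set(links.values())

    def _drop(stim, reason):
        if dropped is not None:
            dropped.append((stim, reason))

    pairs = []
    for k, stim in enumerate(stims):
        if not stim.triggered:
            continue
        if k not in links:
            _drop(stim, "no event at detection time")
            continue
        if gate is not None and not gate(stim):
            _drop(stim, "pre-stimulation epoch not confident State 2")
            continue
        i = links[k]
        control = None
        for j in range(i - 1, -1, -1):
            if j in stim_event_idx:
                continue
            control = events[j]
            break
        if control is None:
            _drop(stim, "no prior event")
            continue
        if stim.delay_class in ("2", ">2") and control.duration <= stim.delay:
            control = None
            for j in range(i - 1, -1, -1):
                if j in stim_event_idx:
                    continue
                if events[j].duration > stim.delay:
                    control = events[j]
                    break
            if control is None:
                _drop(stim, "no control exceeding the delay")
                continue
        stim_ev = events[i]
        if stim_ev.linked_stim is None:
            stim_ev.linked_stim = stim
        pairs.append(
            TrialPair(
                stimulated=stim_ev,
                control=control,
                delay_class=stim.delay_class,
                condition=stim.condition,
            )
        )
    return pairs


def reshuffle_null(
    events,
    seed,
    eligible_min: float = RESHUFFLE_ELIGIBLE_MIN,
    qualify_min: float = RESHUFFLE_QUALIFY_MIN,
    p_select: float = 0.5,
    condition: str = "NO_OPSIN",
) -> list:
    """Randomized pseudo-stimulation pairs, ignoring any stimulation log.

    Events longer than ``eligible_min`` are randomly assigned to the
    pseudo-stimulated group; the comparison uses the immediately preceding
    discharge, and if that is shorter than ``qualify_min`` the closest
    qualifying (>= ``qualify_min``) preceding event is used instead.
    Pseudo-trials with no qualifying control are dropped.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    animals = sorted({ev.animal_id for ev in events})
    if len(animals) > 1:
        pairs = []
        for a in animals:
            pairs.extend(
                reshuffle_null(
                    [ev for ev in events if ev.animal_id == a],
                    rng,
                    eligible_min,
                    qualify_min,
                    p_select,
                    condition,
                )
            )
        return pairs
    events = sorted(events, key=lambda ev: ev.onset)
    pairs = []
    for i in range(1, len(events)):
        ev = events[i]
        if ev.duration <= eligible_min:
            continue
        if rng.random() >= p_select:
            continue
        control = events[i - 1]
        if control.duration < qualify_min:
            control = None
            for j in range(i - 2, -1, -1):
                if events[j].duration >= qualify_min:
                    control = events[j]
                    break
        if control is None:
            continue
        pairs.append(
            TrialPair(
                stimulated=ev,
                control=control,
                delay_class="pseudo",
                condition=condition,
            )
        )
    return pairs


def per_animal_aggregate(pairs) -> dict:
    """Mean normalized duration per animal (trials averaged within animal)."""
    acc: dict = {}
    for p in pairs:
        acc.setdefault(p.animal_id, []).append(p.normalized_duration)
    return {a: float(np.mean(v)) for a, v in acc.items()}


def paired_t(group_a, group_b):
    """Two-tailed paired t-test over per-animal values; df = n - 1.

    Returns ``(t, p, df)``; with zero-variance differences the statistic is
    degenerate and returned as ``(nan, nan, df)`` (flagged to the caller).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired groups must have equal length")
    if len(a) < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):  # identical vectors: no effect, by convention
            return (0.0, 1.0, len(a) - 1)
        return (float("nan"), float("nan"), len(a) - 1)  # degenerate: flagged
    t, p = sps.ttest_rel(a, b)
    return (float(t), float(p), len(a) - 1)


def rm_anova_bonferroni(values: pd.DataFrame):
    """One-way repeated-measures ANOVA across windows with Bonferroni post hoc.

    ``values``: one row per animal, one column per window (complete cases
    required).  Returns ``(F, (df1, df2), posthoc)`` where ``posthoc`` maps
    window pairs to Bonferroni-corrected paired-t p-values (capped at 1).
    """
    from statsmodels.stats.anova import AnovaRM

    if values.isna().any().any():
        raise ValueError("repeated-measures ANOVA requires complete cases")
    if len(values) < 2:
        raise ValueError("need at least two animals")
    cols0 = list(values.columns)
    if np.allclose(values.sub(values.mean(axis=1), axis=0), 0.0):
        # no within-animal variation across windows: no effect, by convention
        df = (len(cols0) - 1, (len(cols0) - 1) * (len(values) - 1))
        posthoc = {
            (cols0[i], cols0[j]): 1.0
            for i in range(len(cols0))
            for j in range(i + 1, len(cols0))
        }
        return 0.0, df, posthoc
    long = values.reset_index(names="animal").melt(
        id_vars="animal", var_name="window", value_name="value"
    )
    res = AnovaRM(long, depvar="value", subject="animal", within=["window"]).fit()
    row = res.anova_table.iloc[0]
    F = float(row["F Value"])
    df = (int(row["Num DF"]), int(row["Den DF"]))
    cols = list(values.columns)
    n_comp = len(cols) * (len(cols) - 1) // 2
    posthoc = {}
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            t, p, _ = paired_t(values[cols[i]], values[cols[j]])
            p_adj = 1.0 if math.isnan(p) else min(1.0, p * n_comp)
            posthoc[(cols[i], cols[j])] = p_adj
    return F, df, posthoc


# ---------------------------------------------------------------------------
# paired stimulation analysis (model / results)
# ---------------------------------------------------------------------------


@dataclass
class StimulationEffectResults:
    """Fitted paired analysis: per-animal means, group statistics, test."""

    pairs: list
    per_animal_normalized: dict
    group_mean: float
    group_sem: float
    t_statistic: float
    p_value: float
    df: int
    n_animals: int
    n_trials: int
    condition: str
    delay_classes: tuple
    dropped: list = field(default_factory=list)

    @property
    def percent_change(self) -> float:
        """Group mean normalized duration minus 100 (negative = suppression)."""
        return self.group_mean - 100.0

    def pairs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "animal_id": p.animal_id,
                "stim_onset_s": p.stimulated.onset,
                "stim_duration_s": p.stimulated.duration,
                "control_onset_s": p.control.onset,
                "control_duration_s": p.control.duration,
                "normalized_pct": p.normalized_duration,
                "delay_class": p.delay_class,
                "condition": p.condition,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Paired stimulation analysis",
            "===========================",
            f"condition:        {self.condition}",
            f"delay classes:    {', '.join(map(str, self.delay_classes))}",
            f"animals:          {self.n_animals}",
            f"trials:           {self.n_trials} (dropped {len(self.dropped)})",
            f"normalized duration: {self.group_mean:.1f} +/- {self.group_sem:.1f} % of control",
            f"paired t (stim vs control durations, per animal): "
            f"t({self.df}) = {self.t_statistic:.3f}, p = {self.p_value:.4g}",
            "",
            "per-animal mean normalized duration (%):",
        ]
        for a in sorted(self.per_animal_normalized):
            lines.append(f"  {a}: {self.per_animal_normalized[a]:.1f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of control vs stimulated durations with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = [p.control.duration for p in self.pairs]
        s = [p.stimulated.duration for p in self.pairs]
        ax.scatter(c, s, s=12, alpha=0.6)
        lim = max(max(c, default=1.0), max(s, default=1.0)) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("control duration (s)")
        ax.set_ylabel("stimulated duration (s)")
        ax.set_title(f"{self.condition}: {self.group_mean:.0f}% of control")
        return ax


class StimulationEffectModel:
    """Paired stimulated-vs-control seizure-duration model.

    Built from measured events and the stimulation log of one or more
    animals; ``fit`` runs pairing, per-animal aggregation and the paired
    t-test (per-animal mean stimulated vs control durations).
    """

    def __init__(
        self,
        events,
        stims,
        condition: str = "",
        gate: Optional[Callable[[StimulationEvent], bool]] = None,
    ):
        self.events = list(events)
        self.stims = list(stims)
        self.condition = condition or (stims[0].condition if stims else "")
        self.gate = gate

    @classmethod
    def from_sessions(cls, sessions, threshold_uv: float = -60.0, gate_factory=None, **kw):
        """Build from (scaled-or-raw recording, stims) session tuples.

        Each recording is min-max scaled, events are segmented at the
        scaled equivalent of ``threshold_uv``, and an optional per-session
        gate is created by ``gate_factory(scaled_recording)``.
        """
        from .features import minmax_scale

        events, stims = [], []
        gates = []
        for recording, session_stims in sessions:
            scaled = recording if recording.is_scaled else minmax_scale(recording)
            thr = scaled.to_scaled_units(threshold_uv)
            evs = segment_events(scaled, thr, kw.get("min_gap", DEFAULT_MIN_GAP),
                                 kw.get("min_duration", DEFAULT_MIN_DURATION))
            events.extend(evs)
            stims.extend(session_stims)
            if gate_factory is not None:
                g = gate_factory(scaled)
                gates.append((set(id(s) for s in session_stims), g))
        gate = None
        if gates:
            def gate(stim):
                for ids, g in gates:
                    if id(stim) in ids:
                        return g(stim)
                return True
        return cls(events, stims, gate=gate,
                   condition=kw.get("condition", ""))

    def fit(self) -> StimulationEffectResults:
        dropped: list = []
        pairs = pair_trials(self.events, self.stims, gate=self.gate, dropped=dropped)
        if not pairs:
            raise ValueError("no valid trial pairs")
        per_animal = per_animal_aggregate(pairs)
        vals = np.array(list(per_animal.values()))
        group_mean = float(vals.mean())
        group_sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        # paired t on per-animal mean stimulated vs control durations
        stim_means, ctrl_means = {}, {}
        for p in pairs:
            stim_means.setdefault(p.animal_id, []).append(p.stimulated.duration)
            ctrl_means.setdefault(p.animal_id, []).append(p.control.duration)
        animals = sorted(stim_means)
        if len(animals) >= 2:
            t, pval, df = paired_t(
                [np.mean(stim_means[a]) for a in animals],
                [np.mean(ctrl_means[a]) for a in animals],
            )
        else:
            t, pval, df = float("nan"), float("nan"), 0
        classes = tuple(sorted({p.delay_class for p in pairs}, key=str))
        return StimulationEffectResults(
            pairs=pairs,
            per_animal_normalized=per_animal,
            group_mean=group_mean,
            group_sem=group_sem,
            t_statistic=t,
            p_value=pval,
            df=df,
            n_animals=len(per_animal),
            n_trials=len(pairs),
            condition=self.condition,
            delay_classes=classes,
            dropped=dropped,
        )


# ---------------------------------------------------------------------------
# pre / during / post window analysis
# ---------------------------------------------------------------------------

WINDOWS = ("pre", "during", "post")

#: Events whose onset precedes light onset by less than this are the
#: triggering discharge itself and belong to the "during" window.
TRIGGER_TOLERANCE = 0.05


def window_analysis(events, stims, light_duration: float = 10.0) -> pd.DataFrame:
    """Assign events to 10-s pre/during/post windows around each light pulse.

    An event belongs to a window if its onset falls inside it; the
    triggering discharge (onset within ``TRIGGER_TOLERANCE`` s before light
    onset) counts as "during".  Returns a long DataFrame with one row per
    (trial, window, event).  Multi-animal inputs are grouped per animal.
    """
    groups = list(_split_by_animal(events, stims))
    if len(groups) > 1:
        frames = [window_analysis(evs, sts, light_duration) for evs, sts in groups]
        return pd.concat(frames, ignore_index=True)
    events = sorted(events, key=lambda ev: ev.onset)
    onsets = np.array([ev.onset for ev in events])
    rows = []
    for stim in stims:
        if not stim.triggered or stim.light_on is None:
            continue
        t0 = stim.light_on
        spans = {
            "pre": (t0 - 10.0, t0 - TRIGGER_TOLERANCE),
            "during": (t0 - TRIGGER_TOLERANCE, t0 + light_duration),
            "post": (t0 + light_duration, t0 + light_duration + 10.0),
        }
        for w, (a, b) in spans.items():
            lo = int(np.searchsorted(onsets, a, side="left"))
            hi = int(np.searchsorted(onsets, b, side="left"))
            for ev in events[lo:hi]:
                rows.append(
                    {
                        "animal_id": ev.animal_id,
                        "window": w,
                        "light_on_s": t0,
                        "onset_s": ev.onset,
                        "duration_s": ev.duration,
                    }
                )
    return pd.DataFrame(rows, columns=["animal_id", "window", "light_on_s", "onset_s", "duration_s"])


@dataclass
class WindowResults:
    """Group-level pre/during/post duration statistics."""

    table: pd.DataFrame  # per-animal mean duration and counts per window
    group_mean: pd.Series
    group_sem: pd.Series
    anova_F: float
    anova_df: tuple
    posthoc: dict
    n_animals: int

    def summary(self) -> str:
        lines = [
            "Stimulation window analysis (10-s windows)",
            "==========================================",
            f"animals: {self.n_animals}",
        ]
        for w in WINDOWS:
            lines.append(
                f"  {w:7s} mean duration {self.group_mean[w]:.2f} +/- "
                f"{self.group_sem[w]:.2f} s"
            )
        lines.append(
            f"RM-ANOVA: F({self.anova_df[0]}, {self.anova_df[1]}) = "
            f"{self.anova_F:.2f}"
        )
        for (a, b), p in self.posthoc.items():
            lines.append(f"  {a} vs {b}: Bonferroni p = {p:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        means = [self.group_mean[w] for w in WINDOWS]
        sems = [self.group_sem[w] for w in WINDOWS]
        ax.bar(WINDOWS, means, yerr=sems, capsize=4)
        ax.set_ylabel("mean discharge duration (s)")
        return ax


class WindowAnalysis:
    """Pre/during/post analysis of the continuous-stimulation protocol."""

    def __init__(self, events, stims, light_duration: float = 10.0):
        self.events = list(events)
        self.stims = list(stims)
        self.light_duration = light_duration

    def fit(self) -> WindowResults:
        long = window_analysis(self.events, self.stims, self.light_duration)
        if long.empty:
            raise ValueError("no events fall inside any stimulation window")
        per_animal = (
            long.groupby(["animal_id", "window"])["duration_s"]
            .agg(["mean", "count"])
            .unstack("window")
        )
        means = per_animal["mean"].reindex(columns=list(WINDOWS))
        complete = means.dropna()
        group_mean = means.mean(axis=0)
        group_sem = means.sem(axis=0)
        if len(complete) >= 2:
            F, df, posthoc = rm_anova_bonferroni(complete)
        else:
            F, df, posthoc = float("nan"), (0, 0), {}
        return WindowResults(
            table=per_animal,
            group_mean=group_mean,
            group_sem=group_sem,
            anova_F=F,
            anova_df=df,
            posthoc=posthoc,
            n_animals=means.shape[0],
        )
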