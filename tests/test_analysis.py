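"""Paired analysis: event segmentation accuracy, the pairing and
control-substitution rules (against a brute-force oracle), the reshuffle
null, per-animal aggregation, and the statistical tests against
hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from ictaloop.analysis import (
    StimulationEffectModel,
    WindowAnalysis,
    pair_trials,
    paired_t,
    per_animal_aggregate,
    reshuffle_null,
    rm_anova_bonferroni,
    segment_events,
    window_analysis,
)
from ictaloop.closed_loop import SchedulerPolicy, plan_closed_loop_session
from ictaloop.features import minmax_scale
from ictaloop.types import EcogRecording, SeizureEvent, StimulationEvent, TrialPair

FS = 512.0


def _events(durations, gap=10.0, animal="a"):
    """Consecutive events with the given durations, separated by ``gap``."""
    out, t = [], 0.0
    for d in durations:
        out.append(SeizureEvent(onset=t, offset=t + d, animal_id=animal))
        t += d + gap
    return out


def _stim_on(event, delay=0.0, delay_class="0", condition="PV_ChR2"):
    det = event.onset + 0.01
    return StimulationEvent(
        detection_time=det,
        delay=delay,
        delay_class=delay_class,
        light_on=det + delay,
        triggered=True,
        condition=condition,
        animal_id=event.animal_id,
    )


class TestSegmentEvents:
    def test_gap_rule_merges_close_deflections(self):
        x = np.zeros(int(5 * FS))
        x[512:1024] = -100.0
        x[1024 + int(0.1 * FS) : 1024 + int(0.1 * FS) + 512] = -100.0
        rec = EcogRecording(samples=x)
        evs = segment_events(rec, threshold=-60.0, min_gap=0.3, min_duration=0.5)
        assert len(evs) == 1

    def test_short_burst_like_deflections_filtered(self):
        x = np.zeros(int(5 * FS))
        for t in (1.0, 2.0, 3.0):
            i = int(t * FS)
            x[i : i + int(0.15 * FS)] = -100.0  # State-1-like 150 ms bursts
        evs = segment_events(EcogRecording(samples=x), -60.0, 0.3, 0.5)
        assert evs == []

    def test_durations_match_ground_truth_on_synthetic_session(self, pv0_session):
        recording, _ = pv0_session
        scaled = minmax_scale(recording)
        evs = segment_events(scaled, scaled.to_scaled_units(-60.0))
        truth = recording.annotations.seizure_events
        assert len(evs) == len(truth)
        errors = [abs(m.duration - t.duration) for m, t in zip(evs, truth)]
        assert np.mean(np.array(errors) <= 0.2) >= 0.95


class TestPairing:
    def test_direct_rule(self):
        evs = _events([3.0, 4.0, 2.6])
        stim = _stim_on(evs[2])
        pairs = pair_trials(evs, [stim])
        assert len(pairs) == 1
        assert pairs[0].control.duration == pytest.approx(4.0)
        assert pairs[0].normalized_duration == pytest.approx(65.0)

    def test_control_substitution_for_delayed_trials(self):
        evs = _events([5.0, 2.0, 6.0])
        stim = _stim_on(evs[2], delay=3.5, delay_class=">2")
        pairs = pair_trials(evs, [stim])
        assert pairs[0].control.duration == pytest.approx(5.0)  # 2.0 < 3.5 skipped

    def test_no_prior_event_dropped(self):
        evs = _events([4.0])
        dropped = []
        pairs = pair_trials(evs, [_stim_on(evs[0])], dropped=dropped)
        assert pairs == []
        assert dropped and "no prior" in dropped[0][1]

    def test_gate_rejection_drops_trial(self):
        evs = _events([3.0, 4.0])
        pairs = pair_trials(evs, [_stim_on(evs[1])], gate=lambda s: False)
        assert pairs == []

    def test_pairing_never_crosses_animals(self):
        evs_a = _events([4.0, 2.0], animal="a")
        evs_b = _events([8.0, 3.0], animal="b")
        stim = _stim_on(evs_b[1])
        pairs = pair_trials(evs_a + evs_b, [stim])
        assert len(pairs) == 1
        assert pairs[0].control.duration == pytest.approx(8.0)

    def test_matches_brute_force_oracle_on_random_streams(self, rng):
        # literal re-implementation of the stated rules with explicit loops
        def oracle(events, stims):
            events = sorted(events, key=lambda e: e.onset)
            stim_idx = set()
            for s in stims:
                for i, ev in enumerate(events):
                    if s.triggered and ev.onset <= s.detection_time <= ev.offset:
                        stim_idx.add(i)
            out = []
            for s in stims:
                if not s.triggered:
                    continue
                hit = [
                    i
                    for i, ev in enumerate(events)
                    if ev.onset <= s.detection_time <= ev.offset
                ]
                if not hit:
                    continue
                i = hit[0]
                preceding = [j for j in range(i) if j not in stim_idx]
                if not preceding:
                    continue
                control = events[preceding[-1]]
                if s.delay_class in ("2", ">2") and control.duration <= s.delay:
                    candidates = [
                        j for j in preceding if events[j].duration > s.delay
                    ]
                    if not candidates:
                        continue
                    control = events[candidates[-1]]
                out.append((i, control.onset))
            return out

        for trial in range(30):
            n = int(rng.integers(3, 20))
            durations = rng.lognormal(1.0, 0.5, size=n)
            evs = _events(list(durations), gap=float(rng.uniform(5, 25)))
            stims = []
            for i in rng.choice(n, size=min(n, 4), replace=False):
                cls = str(rng.choice(["0", "0.5", "2", ">2"]))
                delay = {"0": 0.0, "0.5": 0.5, "2": 2.0}.get(cls) or float(
                    rng.uniform(2.5, 4.8)
                )
                stims.append(_stim_on(evs[int(i)], delay=delay, delay_class=cls))
            stims.sort(key=lambda s: s.detection_time)
            got = [
                (evs.index(p.stimulated), p.control.onset)
                for p in pair_trials(evs, stims)
            ]
            assert got == oracle(evs, stims), f"stream {trial}"


class TestNormalizedDuration:
    @pytest.mark.parametrize(
        "stim_dur,control_dur,expected",
        [(2.0, 2.0, 100.0), (5.404, 4.0, 135.1), (1.31, 4.0, 32.75)],
    )
    def test_arithmetic(self, stim_dur, control_dur, expected):
        evs = _events([control_dur, stim_dur])
        pair = TrialPair(
            stimulated=evs[1], control=evs[0], delay_class="0", condition="PV_ChR2"
        )
        assert pair.normalized_duration == pytest.approx(expected)

    def test_control_must_precede(self):
        evs = _events([3.0, 3.0])
        with pytest.raises(ValueError, match="precede"):
            TrialPair(stimulated=evs[0], control=evs[1], delay_class="0", condition="x")


class TestReshuffle:
    def test_identical_durations_give_100_percent(self):
        evs = _events([4.0] * 12)
        pairs = reshuffle_null(evs, seed=0, p_select=1.0)
        assert pairs
        assert all(p.normalized_duration == pytest.approx(100.0) for p in pairs)

    def test_qualifying_control_rule(self):
        evs = _events([2.0, 3.5, 4.0])
        pairs = reshuffle_null(evs, seed=0, p_select=1.0)
        chosen = {p.stimulated.onset: p.control.duration for p in pairs}
        assert chosen[evs[2].onset] == pytest.approx(3.5)  # 2.0 s < 3 s skipped

    def test_short_events_never_pseudo_stimulated(self):
        evs = _events([4.0, 2.4, 4.0, 2.0])
        pairs = reshuffle_null(evs, seed=1, p_select=1.0)
        assert all(p.stimulated.duration > 2.5 for p in pairs)

    def test_ignores_stimulation_information(self):
        # the null never reads a stimulation log: its signature admits none,
        # and results depend only on the event stream and seed
        evs = _events([4.0, 3.2, 5.0, 2.8, 4.4, 3.9])
        a = reshuffle_null(evs, seed=3)
        b = reshuffle_null(list(evs), seed=3)
        assert [(p.stimulated.onset, p.control.onset) for p in a] == [
            (p.stimulated.onset, p.control.onset) for p in b
        ]

    def test_no_effect_streams_recover_100_percent(self):
        policy = SchedulerPolicy(delay_classes=("0",), warmup=30.0)
        per_animal = []
        for a in range(4):
            plan = plan_closed_loop_session(
                "NO_OPSIN", policy, 900.0, np.random.SeedSequence(31, spawn_key=(a,))
            )
            pairs = reshuffle_null(plan.truth.seizure_events, seed=a)
            per_animal.append(np.mean([p.normalized_duration for p in pairs]))
        assert np.mean(per_animal) == pytest.approx(100.0, abs=8.0)


class TestAggregation:
    def test_per_animal_mean(self):
        evs = _events([1.0, 0.9, 1.0, 1.1], animal="m1")
        pairs = [
            TrialPair(evs[1], evs[0], "0", "x"),
            TrialPair(evs[3], evs[2], "0", "x"),
        ]
        out = per_animal_aggregate(pairs)
        assert out == {"m1": pytest.approx(100.0)}

    def test_equal_animal_weighting_under_trial_duplication(self):
        evs_a = _events([2.0, 1.0], animal="a")
        evs_b = _events([2.0, 3.0], animal="b")
        pairs = [TrialPair(evs_a[1], evs_a[0], "0", "x"), TrialPair(evs_b[1], evs_b[0], "0", "x")]
        base = np.mean(list(per_animal_aggregate(pairs).values()))
        duplicated = pairs + [pairs[0]] * 5  # animal "a" trials duplicated
        dup = np.mean(list(per_animal_aggregate(duplicated).values()))
        assert dup == pytest.approx(base)


class TestPairedT:
    def test_identical_vectors(self):
        t, p, df = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, df) == (0.0, 1.0, 2)

    def test_constant_nonzero_difference_is_flagged(self):
        t, p, df = paired_t([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert np.isnan(t) and np.isnan(p)
        assert df == 4

    def test_matches_textbook_formula(self):
        a = np.array([5.1, 6.2, 4.9, 7.3, 5.8])
        b = np.array([4.0, 5.5, 5.2, 6.1, 5.0])
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, p, df = paired_t(a, b)
        assert t == pytest.approx(expected_t)
        assert df == 4
        assert 0 < p < 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestRmAnova:
    def test_identical_windows_give_zero_F_and_unit_posthoc(self):
        df = pd.DataFrame({"pre": [3, 4, 5], "during": [3, 4, 5], "post": [3, 4, 5]})
        F, dof, posthoc = rm_anova_bonferroni(df)
        assert F == 0.0
        assert all(p == 1.0 for p in posthoc.values())

    def test_df_2_12_with_seven_animals(self, rng):
        df = pd.DataFrame(
            {
                "pre": rng.normal(3.0, 0.3, 7),
                "during": rng.normal(2.0, 0.3, 7),
                "post": rng.normal(3.1, 0.3, 7),
            }
        )
        _, dof, _ = rm_anova_bonferroni(df)
        assert dof == (2, 12)

    def test_matches_hand_computed_sums_of_squares(self, rng):
        values = pd.DataFrame(
            {
                "pre": [3.2, 2.9, 3.6, 3.1],
                "during": [2.0, 1.7, 2.4, 2.2],
                "post": [3.4, 3.0, 3.3, 3.2],
            }
        )
        x = values.to_numpy()
        n, k = x.shape
        grand = x.mean()
        ss_windows = n * ((x.mean(axis=0) - grand) ** 2).sum()
        ss_subjects = k * ((x.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((x - grand) ** 2).sum()
        ss_error = ss_total - ss_windows - ss_subjects
        expected_F = (ss_windows / (k - 1)) / (ss_error / ((k - 1) * (n - 1)))
        F, dof, _ = rm_anova_bonferroni(values)
        assert F == pytest.approx(expected_F)
        assert dof == (k - 1, (k - 1) * (n - 1))

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"pre": [1.0, np.nan], "during": [1.0, 2.0], "post": [1.0, 2.0]})
        with pytest.raises(ValueError, match="complete"):
            rm_anova_bonferroni(df)


class TestWindowAnalysis:
    def test_no_events_in_windows(self):
        stim = StimulationEvent(
            detection_time=100.0, delay=0.0, delay_class="continuous",
            light_on=100.0, triggered=True,
        )
        long = window_analysis([], [stim])
        assert long.empty

    def test_trigger_event_counts_as_during(self):
        trigger = SeizureEvent(onset=99.99, offset=101.5, animal_id="a")
        stim = StimulationEvent(
            detection_time=100.0, delay=0.0, delay_class="continuous",
            light_on=100.0, triggered=True, animal_id="a",
        )
        long = window_analysis([trigger], [stim])
        assert list(long["window"]) == ["during"]

    def test_null_condition_windows_indistinguishable(self):
        policy = SchedulerPolicy(
            delay_classes=("continuous",), alternate=False, warmup=30.0
        )
        events, stims = [], []
        for a in range(6):
            plan = plan_closed_loop_session(
                "NO_OPSIN", policy, 900.0,
                np.random.SeedSequence(41, spawn_key=(a,)), animal_id=f"m{a}",
            )
            events += plan.truth.seizure_events
            stims += plan.stims
        res = WindowAnalysis(events, stims).fit()
        assert res.group_mean["during"] == pytest.approx(res.group_mean["pre"], rel=0.25)
        assert res.group_mean["post"] == pytest.approx(res.group_mean["pre"], rel=0.25)

    def test_continuous_suppression_ratio(self):
        policy = SchedulerPolicy(
            delay_classes=("continuous",), alternate=False, warmup=30.0
        )
        events, stims = [], []
        for a in range(8):
            plan = plan_closed_loop_session(
                "PV_ChR2", policy, 900.0,
                np.random.SeedSequence(42, spawn_key=(a,)), animal_id=f"m{a}",
            )
            events += plan.truth.seizure_events
            stims += plan.stims
        res = WindowAnalysis(events, stims).fit()
        ratio = res.group_mean["during"] / res.group_mean["pre"]
        assert ratio == pytest.approx(1.78 / 2.84, abs=0.08)


class TestStimulationEffectModel:
    def test_summary_reports_group_statistics(self):
        evs = _events([4.0, 2.6, 4.2, 2.8], animal="m1")
        stims = [_stim_on(evs[1]), _stim_on(evs[3])]
        res = StimulationEffectModel(evs, stims, condition="PV_ChR2").fit()
        assert res.n_trials == 2
        assert res.n_animals == 1
        assert "PV_ChR2" in res.summary()
        assert res.group_mean == pytest.approx(
            np.mean([100 * 2.6 / 4.0, 100 * 2.8 / 4.2])
        )

    def test_no_valid_pairs_rejected(self):
        evs = _events([4.0])
        with pytest.raises(ValueError, match="no valid"):
            StimulationEffectModel(evs, [_stim_on(evs[0])]).fit()

    def test_plot_renders(self):
        import matplotlib

        matplotlib.use("Agg")
        evs = _events([4.0, 2.6, 4.2, 2.8], animal="m1")
        stims = [_stim_on(evs[1]), _stim_on(evs[3])]
        ax = StimulationEffectModel(evs, stims).fit().plot()
        assert ax.get_xlabel() == "control duration (s)"
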