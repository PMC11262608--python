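import numpy as np
import pandas as pd
import pytest

from vgskit import (
    GazeEvent,
    SimulationParams,
    StimulusProtocol,
    Trial,
    TrialValidityParams,
    aggregate_subject,
    analyze_session,
    blink_rate,
    build_schedule,
    compute_saccade_metrics,
    degrees_to_pixels,
    segment_trials,
    select_first_saccade,
    simulate_session,
    simulate_trial,
    validate_trial,
)

from conftest import center_path, make_recording

VPARAMS = TrialValidityParams()
CX, CY = 960.0, 540.0


def _stim(amplitude=10.0, task="horizontal", index=0, t0=0.0):
    return {
        "trial_index": index,
        "task": task,
        "amplitude_deg": amplitude,
        "eccentricity_class": "near" if abs(amplitude) <= 10 else "far",
        "central_onset_ms": t0,
        "central_offset_ms": t0 + 1500.0,
        "target_onset_ms": t0 + 1700.0,
        "target_offset_ms": t0 + 3200.0,
        "target_x_px": CX + degrees_to_pixels(abs(amplitude)) * np.sign(amplitude),
        "target_y_px": CY,
    }


def _saccade(t_start, t_end, x0=CX, y0=CY, amp_deg=9.0):
    return GazeEvent(
        "saccade", t_start, t_end, x0, y0, x0 + degrees_to_pixels(amp_deg), y0
    )


class TestBuildSchedule:
    def test_horizontal_counts_and_timing(self):
        sched = build_schedule(StimulusProtocol.horizontal(), seed=1)
        assert len(sched) == 40
        counts = sched["amplitude_deg"].value_counts()
        assert all(counts[a] == 10 for a in (-18.0, -10.0, 10.0, 18.0))
        assert (np.diff(sched["target_onset_ms"]) == 3200.0).all()
        assert set(sched["eccentricity_class"]) == {"near", "far"}

    def test_vertical_protocol_covers_40_presentations(self):
        sched = build_schedule(StimulusProtocol.vertical(), seed=1)
        assert len(sched) == 40
        assert set(sched["amplitude_deg"]) == {-8.0, 8.0}
        up = sched[sched["amplitude_deg"] == -8.0]
        assert (up["eccentricity_class"] == "up").all()
        assert (up["target_y_px"] < CY).all()  # screen-y decreases upward

    def test_seed_determinism(self):
        a = build_schedule(StimulusProtocol.horizontal(), seed=7)
        b = build_schedule(StimulusProtocol.horizontal(), seed=7)
        c = build_schedule(StimulusProtocol.horizontal(), seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not a["amplitude_deg"].equals(c["amplitude_deg"])


class TestSegmentTrials:
    def test_count_conservation_and_truncation_error(self):
        sched = build_schedule(StimulusProtocol.horizontal(), seed=0)
        n = 40 * 800
        t, x, y = center_path(n)
        rec = make_recording(t, x, y)
        trials = segment_trials(rec, sched, [])
        assert len(trials) == 40
        short = make_recording(*center_path(n // 2))
        with pytest.raises(ValueError, match="trial"):
            segment_trials(short, sched, [])

    def test_empty_event_stream_yields_no_saccade_verdicts(self):
        sched = build_schedule(StimulusProtocol.horizontal(), seed=0)
        rec = make_recording(*center_path(40 * 800))
        trials = segment_trials(rec, sched, [])
        for tr in trials:
            validate_trial(tr, VPARAMS)
            assert tr.verdict == "invalid"
            assert tr.invalid_reason == "no_saccade"


class TestValidateTrial:
    def test_blink_inside_pre_offset_window(self):
        # blink ends 30 ms before the central dot disappears
        tr = Trial(_stim(), [GazeEvent("blink", 1350.0, 1470.0)])
        validate_trial(tr, VPARAMS)
        assert (tr.verdict, tr.invalid_reason) == ("invalid", "pre_offset_blink")

    def test_saccade_inside_pre_offset_window(self):
        tr = Trial(_stim(), [_saccade(1450.0, 1490.0)])
        validate_trial(tr, VPARAMS)
        assert tr.invalid_reason == "pre_offset_saccade"

    def test_anticipatory_latency(self):
        tr = Trial(_stim(), [_saccade(1780.0, 1830.0)])  # +80 ms after onset
        validate_trial(tr, VPARAMS)
        assert tr.invalid_reason == "anticipatory"

    def test_off_center_start_at_dot_offset(self):
        n = 900
        t = np.arange(n) * 4.0
        x = np.full(n, CX + 150.0)
        cyc = pd.DataFrame(
            {"t": t, "x": x, "y": np.full(n, CY), "source": ["both"] * n}
        )
        tr = Trial(_stim(), [_saccade(1950.0, 2000.0)])
        validate_trial(tr, VPARAMS, cyclopean=cyc)
        assert tr.invalid_reason == "off_center_start"

    def test_valid_trial_carries_metrics_iff_valid(self):
        n = 900
        t = np.arange(n) * 4.0
        cyc = pd.DataFrame(
            {
                "t": t,
                "x": np.full(n, CX),
                "y": np.full(n, CY),
                "source": ["both"] * n,
            }
        )
        vel = np.zeros(n)
        tr = Trial(_stim(), [_saccade(1950.0, 2000.0)])
        validate_trial(tr, VPARAMS, cyclopean=cyc, velocity=vel)
        assert tr.verdict == "valid" and tr.metrics is not None
        assert tr.metrics.latency_ms == pytest.approx(250.0)

    def test_verdict_partition_on_simulated_session(self):
        rec, sched, _ = simulate_session(
            StimulusProtocol.horizontal(), SimulationParams(seed=9)
        )
        res = analyze_session(rec, sched)
        for tr in res.trials:
            if tr.verdict == "valid":
                assert tr.invalid_reason is None and tr.metrics is not None
            else:
                assert tr.invalid_reason is not None and tr.metrics is None


class TestSelectFirstSaccade:
    def test_earliest_center_origin_saccade_wins(self):
        tr = Trial(_stim(), [_saccade(1850.0, 1900.0), _saccade(2100.0, 2150.0)])
        sel = select_first_saccade(tr, VPARAMS)
        assert sel.t_start == 1850.0

    def test_off_center_origin_excluded(self):
        tr = Trial(_stim(), [_saccade(1850.0, 1900.0, x0=CX + 300.0)])
        assert select_first_saccade(tr, VPARAMS) is None

    def test_no_saccade_in_target_window(self):
        tr = Trial(_stim(), [_saccade(500.0, 550.0)])
        assert select_first_saccade(tr, VPARAMS) is None


class TestSaccadeMetrics:
    def test_gain_is_amplitude_over_target(self):
        n = 900
        t = np.arange(n) * 4.0
        cyc = pd.DataFrame(
            {"t": t, "x": np.full(n, CX), "y": np.full(n, CY), "source": ["both"] * n}
        )
        vel = np.zeros(n)
        sacc = _saccade(1950.0, 2000.0, amp_deg=9.0)
        m = compute_saccade_metrics(sacc, cyc, vel, _stim(10.0))
        assert m.gain == pytest.approx(0.90, abs=1e-6)
        assert m.duration_ms == pytest.approx(50.0)

    def test_mean_velocity_is_about_half_peak(self):
        # raised-cosine profile: time-mean velocity = Vp/2
        sched = build_schedule(StimulusProtocol.horizontal(), seed=0)
        p0 = SimulationParams(
            seed=2, noise_sd_deg=0.0, blink_rate_per_min=0.0,
            data_loss_rate=0.0, p_anticipatory=0.0,
        )
        rec, gt = simulate_trial(sched.iloc[0].to_dict(), p0)
        one = StimulusProtocol(
            task="horizontal",
            amplitudes_deg=(sched.iloc[0]["amplitude_deg"],),
            reps_per_amplitude=1,
        )
        res = analyze_session(rec, build_schedule(one, seed=0))
        m = res.trials[0].metrics
        assert m.mean_velocity_deg_s == pytest.approx(
            m.peak_velocity_deg_s / 2.0, rel=0.05
        )


class TestBlinkRate:
    def test_counts_per_minute(self):
        blinks = [GazeEvent("blink", 1000.0 * i, 1000.0 * i + 120.0) for i in range(12)]
        assert blink_rate(blinks, 4 * 60000.0) == pytest.approx(3.0)
        assert blink_rate([], 60000.0) == 0.0

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            blink_rate([], 0.0)


def _made_trials(n_valid, n_invalid, task="horizontal"):
    trials = []
    idx = 0
    for _ in range(n_valid):
        tr = Trial(_stim(index=idx, t0=idx * 3200.0), [])
        tr.verdict = "valid"
        tr.metrics = compute_saccade_metrics(
            _saccade(idx * 3200 + 1950.0, idx * 3200 + 2000.0),
            pd.DataFrame(
                {
                    "t": [idx * 3200 + 1950.0, idx * 3200 + 1996.0],
                    "x": [CX, CX],
                    "y": [CY, CY],
                    "source": ["both", "both"],
                }
            ),
            np.array([200.0, 300.0]),
            _stim(index=idx, t0=idx * 3200.0),
        )
        trials.append(tr)
        idx += 1
    for _ in range(n_invalid):
        tr = Trial(_stim(index=idx, t0=idx * 3200.0), [])
        tr.verdict = "invalid"
        tr.invalid_reason = "no_saccade"
        trials.append(tr)
        idx += 1
    return trials


class TestAggregateSubject:
    def test_minimum_valid_trials_is_inclusive(self):
        five = aggregate_subject(_made_trials(5, 35), {"horizontal": 10.0})
        six = aggregate_subject(_made_trials(6, 34), {"horizontal": 10.0})
        assert five.included["horizontal"] is False
        assert six.included["horizontal"] is True

    def test_percent_valid(self):
        s = aggregate_subject(_made_trials(30, 10), {"horizontal": 10.0})
        assert s.percent_valid["horizontal"] == pytest.approx(75.0)

    def test_percent_valid_invariant_to_trial_order(self):
        trials = _made_trials(12, 28)
        rng = np.random.default_rng(0)
        shuffled = [trials[i] for i in rng.permutation(len(trials))]
        a = aggregate_subject(trials, {"horizontal": 10.0})
        b = aggregate_subject(shuffled, {"horizontal": 10.0})
        assert a.percent_valid == b.percent_valid

    def test_sd_uses_sample_denominator(self):
        trials = _made_trials(6, 0)
        # perturb latencies to a known spread
        for i, tr in enumerate(trials):
            object.__setattr__(tr.metrics, "latency_ms", 200.0 + 10.0 * i)
        s = aggregate_subject(trials, {"horizontal": 10.0})
        row = s.by_class.iloc[0]
        lat = np.array([200.0 + 10.0 * i for i in range(6)])
        assert row["latency_ms_sd"] == pytest.approx(np.std(lat, ddof=1))
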