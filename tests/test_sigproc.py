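import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfatigue import sigproc
from emgfatigue.sigproc import (
    ISOKINETIC,
    MUSCLES,
    CrankSignal,
    EMGTrace,
    Revolution,
    bandpass_filter,
    composite_fr_emg,
    instantaneous_power,
    isokinetic_result,
    revolution_peak_emg,
    rms_envelope,
    segment_revolutions,
    select_isokinetic_revolutions,
    visit_maxima,
)
from emgfatigue.synth import SimConfig, generate_crank_signal

RATE = 2000.0


def _sine(freq, amplitude=1.0, duration=2.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return amplitude * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# bandpass_filter
# ---------------------------------------------------------------------------


class TestBandpassFilter:
    def test_dc_killed(self, make_trace):
        out = bandpass_filter(make_trace(np.full(4000, 3.0)))
        assert np.max(np.abs(out.samples)) < 0.01 * 3.0

    def test_midband_passes(self, make_trace):
        out = bandpass_filter(make_trace(_sine(100.0)))
        mid = out.samples[1000:-1000]
        assert np.max(np.abs(mid)) >= 0.99

    def test_subband_attenuated(self, make_trace):
        out = bandpass_filter(make_trace(_sine(2.0, duration=6.0)))
        mid = out.samples[3000:-3000]
        assert np.max(np.abs(mid)) <= 0.05

    def test_already_filtered_rejected(self, make_trace):
        tr = make_trace(_sine(100.0), filtered=True)
        with pytest.raises(ValueError, match="already filtered"):
            bandpass_filter(tr)

    def test_high_edge_clipped_with_warning(self, make_trace, caplog):
        tr = make_trace(_sine(100.0, rate=800.0), rate=800.0)
        with caplog.at_level("WARNING"):
            out = bandpass_filter(tr, low=10.0, high=500.0)
        assert "clipping" in caplog.text
        assert out.filtered

    def test_marks_filtered(self, make_trace):
        assert bandpass_filter(make_trace(_sine(100.0))).filtered


# ---------------------------------------------------------------------------
# rms_envelope
# ---------------------------------------------------------------------------


class TestRmsEnvelope:
    def test_constant(self):
        env = rms_envelope(np.full(1000, -2.5), 200)
        assert np.allclose(env, 2.5)

    def test_alternating(self):
        x = np.tile([3.0, -3.0], 500)
        assert np.allclose(rms_envelope(x, 200), 3.0)

    def test_ramp_brute_force(self):
        x = np.arange(1.0, 401.0)
        env = rms_envelope(x, 200)
        expected = np.sqrt(np.mean(np.arange(201.0, 401.0) ** 2))
        assert env[-1] == pytest.approx(expected, rel=1e-12)

    def test_partial_window_warmup(self):
        x = np.arange(1.0, 401.0)
        env = rms_envelope(x, 200)
        assert env[0] == pytest.approx(1.0)
        assert env[2] == pytest.approx(np.sqrt(np.mean([1.0, 4.0, 9.0])))

    def test_length_preserved_and_trace_form(self, make_trace):
        tr = make_trace(_sine(150.0))
        env = rms_envelope(tr, 200)
        assert isinstance(env, EMGTrace)
        assert len(env) == len(tr)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rms_envelope(np.array([]), 200)

    def test_window_longer_than_trace_errors(self):
        with pytest.raises(ValueError):
            rms_envelope(np.ones(10), 200)

    @given(
        st.lists(st.floats(-10, 10), min_size=5, max_size=200),
        st.integers(min_value=1, max_value=5),
    )
    def test_envelope_bounded_by_max_abs(self, values, window):
        x = np.asarray(values)
        env = rms_envelope(x, window)
        assert np.all(env <= np.max(np.abs(x)) + 1e-12)

    def test_filter_then_rms_sinusoid_closed_form(self, make_trace):
        # mid-band sinusoid of amplitude a -> envelope ~ a / sqrt(2)
        a = 0.8
        tr = bandpass_filter(make_trace(_sine(150.0, amplitude=a, duration=3.0)))
        env = rms_envelope(tr, 200)
        mid = env.samples[2000:-2000]
        assert np.allclose(mid, a / np.sqrt(2), rtol=0.01)


# ---------------------------------------------------------------------------
# crank segmentation and power
# ---------------------------------------------------------------------------


class TestSegmentRevolutions:
    def test_seven_revolutions_at_70rpm(self, default_config):
        crank = generate_crank_signal(100.0, 70.0, default_config, duration=6.0)
        revs = segment_revolutions(crank)
        assert len(revs) == 7
        assert all(abs(r.mean_cadence - 70.0) < 0.01 for r in revs)

    def test_five_revolutions_at_60rpm(self, default_config):
        crank = generate_crank_signal(100.0, 60.0, default_config, duration=5.0)
        assert len(segment_revolutions(crank)) == 5

    def test_cadence_step_doubles_duration(self, default_config):
        from emgfatigue.synth import PiecewiseConstant

        crank = generate_crank_signal(
            100.0,
            PiecewiseConstant([0.0, 6.0], [70.0, 35.0]),
            default_config,
            duration=12.0,
        )
        revs = segment_revolutions(crank)
        early = [r for r in revs if r.end_time <= 6.0]
        late = [r for r in revs if r.start_time >= 6.0]
        d_early = np.mean([r.end_time - r.start_time for r in early])
        d_late = np.mean([r.end_time - r.start_time for r in late])
        assert d_late == pytest.approx(2 * d_early, rel=1e-6)

    def test_less_than_one_revolution_empty(self, default_config):
        crank = generate_crank_signal(100.0, 70.0, default_config, duration=0.5)
        assert segment_revolutions(crank) == []


class TestInstantaneousPower:
    def test_zero_torque(self):
        assert np.all(instantaneous_power(np.zeros(5), np.full(5, 7.33)) == 0)

    def test_closed_form_product(self):
        p = instantaneous_power(np.array([50.0]), np.array([7.3304]))
        assert p[0] == pytest.approx(366.52)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            instantaneous_power(np.ones(3), np.ones(4))

    def test_revolution_mean_matches_profile(self, default_config):
        crank = generate_crank_signal(200.0, 70.0, default_config, duration=6.0)
        for rev in segment_revolutions(crank):
            assert rev.left_power == pytest.approx(200.0, abs=0.1)


class TestRevolutionPeakEmg:
    def _rev(self, start=0.0, end=1.0):
        return Revolution(
            index=0,
            start_time=start,
            end_time=end,
            mean_cadence=60.0,
            left_power=100.0,
            isokinetic=True,
        )

    def test_constant_envelope(self, make_trace):
        env = make_trace(np.full(2000, 0.7))
        assert revolution_peak_emg(env, self._rev()) == pytest.approx(0.7)

    def test_triangular_burst(self, make_trace):
        x = np.zeros(2000)
        x[800:1200] = np.concatenate([np.linspace(0, 5, 200), np.linspace(5, 0, 200)])
        assert revolution_peak_emg(make_trace(x), self._rev()) == pytest.approx(5.0)

    def test_two_bursts_brute_force(self, make_trace):
        rng = np.random.default_rng(0)
        x = np.zeros(2000)
        x[200:400] = 2.0 + rng.normal(0, 0.01, 200)
        x[1400:1600] = 3.0 + rng.normal(0, 0.01, 200)
        env = make_trace(x)
        rev = self._rev()
        t = env.times
        brute = np.max(x[(t >= rev.start_time) & (t < rev.end_time)])
        assert revolution_peak_emg(env, rev) == pytest.approx(brute)

    def test_no_samples_errors(self, make_trace):
        env = make_trace(np.ones(100))
        with pytest.raises(ValueError, match="no samples"):
            revolution_peak_emg(env, self._rev(start=10.0, end=11.0))


def _revolution(i, cadence, power, iso=True):
    return Revolution(
        index=i,
        start_time=float(i),
        end_time=float(i) + 60.0 / cadence,
        mean_cadence=cadence,
        left_power=power,
        isokinetic=iso,
    )


def _brute_force_selection(revs, target=70.0, tol=0.05):
    """Exhaustive scan over every 3-revolution window (independent oracle)."""
    best = None
    best_power = -np.inf
    for i in range(len(revs) - 2):
        window = revs[i : i + 3]
        if all(
            r.isokinetic and abs(r.mean_cadence - target) / target <= tol
            for r in window
        ):
            p = sum(r.left_power for r in window) / 3.0
            if p > best_power:
                best_power = p
                best = (i, i + 1, i + 2)
    return best


class TestSelectIsokineticRevolutions:
    def test_spec_window_example(self):
        revs = [_revolution(i, c, 100.0) for i, c in enumerate([62, 69, 70, 71, 70])]
        assert select_isokinetic_revolutions(revs) == (1, 2, 3)

    def test_tie_breaks_to_earliest(self):
        revs = [_revolution(i, 70.0, 100.0) for i in range(6)]
        assert select_isokinetic_revolutions(revs) == (0, 1, 2)

    def test_highest_power_run_wins(self):
        powers = [100, 100, 100, 250, 250, 250]
        revs = [_revolution(i, 70.0, p) for i, p in enumerate(powers)]
        assert select_isokinetic_revolutions(revs) == (3, 4, 5)

    def test_all_off_target_errors_with_near_miss(self):
        revs = [_revolution(i, 60.0, 100.0) for i in range(5)]
        with pytest.raises(ValueError, match="near-miss"):
            select_isokinetic_revolutions(revs, target_rpm=70.0)

    def test_too_few_isokinetic(self):
        revs = [_revolution(i, 70.0, 100.0, iso=(i == 0)) for i in range(5)]
        with pytest.raises(ValueError, match="at least 3"):
            select_isokinetic_revolutions(revs)

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_matches_exhaustive_oracle(self, data):
        n = data.draw(st.integers(min_value=3, max_value=20))
        cadences = data.draw(
            st.lists(st.floats(55.0, 85.0), min_size=n, max_size=n)
        )
        powers = data.draw(
            st.lists(st.floats(10.0, 400.0), min_size=n, max_size=n)
        )
        revs = [
            _revolution(i, c, p) for i, (c, p) in enumerate(zip(cadences, powers))
        ]
        oracle = _brute_force_selection(revs)
        if oracle is None:
            with pytest.raises(ValueError):
                select_isokinetic_revolutions(revs)
        else:
            assert select_isokinetic_revolutions(revs) == oracle


class TestCompositeFrEmg:
    MAXES = dict(zip(MUSCLES, [0.9, 0.5, 0.8, 0.4]))

    def test_at_maxima_gives_one(self):
        assert composite_fr_emg(self.MAXES, self.MAXES) == pytest.approx(1.0)

    def test_mean_of_fractions(self):
        fracs = dict(zip(MUSCLES, [0.8, 0.6, 1.0, 0.6]))
        peaks = {m: fracs[m] * self.MAXES[m] for m in MUSCLES}
        assert composite_fr_emg(peaks, self.MAXES) == pytest.approx(0.75)

    def test_zero_visit_max_errors(self):
        bad = dict(self.MAXES, vastus_lateralis=0.0)
        with pytest.raises(ValueError, match="positive"):
            composite_fr_emg(self.MAXES, bad)

    @given(st.permutations(list(MUSCLES)))
    def test_muscle_order_irrelevant(self, order):
        peaks = dict(zip(order, [0.3, 0.2, 0.5, 0.1]))
        base = composite_fr_emg(peaks, self.MAXES)
        again = composite_fr_emg(dict(reversed(list(peaks.items()))), self.MAXES)
        assert base == pytest.approx(again)


# ---------------------------------------------------------------------------
# isokinetic_result
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def maximal_bout():
    from emgfatigue.synth import SimConfig, generate_baseline_session, noise_free

    cfg = noise_free(SimConfig(seed=1, max_power_sd=0.0))  # truth max exactly 342 W
    emg, crank, truth = generate_baseline_session(cfg, 1)
    return emg, crank, truth


class TestIsokineticResult:
    def test_maximal_bout_342_chainring_684(self, maximal_bout):
        emg, crank, truth = maximal_bout
        revs = [sigproc.revolution_features(c, t) for t, c in zip(emg, crank)]
        maxima = visit_maxima(revs)
        k = 3  # first 100%-effort bout
        res = isokinetic_result(crank[k], emg[k], maxima)
        assert res.p_iso_single_leg == pytest.approx(342.0, abs=0.01)
        assert res.p_iso_chainring == pytest.approx(684.0, abs=0.02)
        assert res.fr_emg == pytest.approx(1.0, abs=1e-6)

    def test_chainring_is_exactly_twice_single_leg(self, maximal_bout):
        emg, crank, _ = maximal_bout
        revs = [sigproc.revolution_features(c, t) for t, c in zip(emg, crank)]
        maxima = visit_maxima(revs)
        for k in range(len(crank)):
            res = isokinetic_result(crank[k], emg[k], maxima)
            assert res.p_iso_chainring == 2.0 * res.p_iso_single_leg

    def test_near_zero_effort_bout(self, default_config):
        from emgfatigue.synth import generate_emg_trace

        crank = generate_crank_signal(1e-9, 70.0, default_config, duration=6.0)
        traces = [
            generate_emg_trace(
                np.full(7, 1e-6), default_config, seed=[5, mi], muscle=m
            )
            for mi, m in enumerate(MUSCLES)
        ]
        maxima = dict(zip(MUSCLES, [0.9, 0.5, 0.8, 0.4]))
        res = isokinetic_result(crank, traces, maxima)
        assert abs(res.p_iso_single_leg) < 1e-6

    def test_doubling_torque_doubles_p_iso_not_fr(self, maximal_bout):
        emg, crank, _ = maximal_bout
        revs = [sigproc.revolution_features(c, t) for t, c in zip(emg, crank)]
        maxima = visit_maxima(revs)
        k = 3
        base = isokinetic_result(crank[k], emg[k], maxima)
        doubled = CrankSignal(
            time=crank[k].time,
            angle=crank[k].angle,
            torque_left=2 * crank[k].torque_left,
            torque_right=2 * crank[k].torque_right,
            angular_velocity=crank[k].angular_velocity,
            mode=crank[k].mode,
        )
        res = isokinetic_result(doubled, emg[k], maxima)
        assert res.p_iso_single_leg == pytest.approx(2 * base.p_iso_single_leg)
        assert res.fr_emg == pytest.approx(base.fr_emg)

    def test_pipeline_matches_bruteforce_window_scan(self, maximal_bout):
        # segment -> select -> mean equals an exhaustive scan oracle
        emg, crank, _ = maximal_bout
        revs = [sigproc.revolution_features(c, t) for t, c in zip(emg, crank)]
        maxima = visit_maxima(revs)
        for k in range(len(crank)):
            oracle_idx = _brute_force_selection(revs[k])
            oracle_p = np.mean([revs[k][i].left_power for i in oracle_idx])
            res = sigproc.isokinetic_result_from_revolutions(revs[k], maxima)
            assert res.revolutions_used == oracle_idx
            assert res.p_iso_single_leg == pytest.approx(oracle_p)
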