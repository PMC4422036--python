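"""Generator contracts: determinism, protocol arithmetic, injected
structure recoverable by independent oracles."""

import numpy as np
import pytest

from thetagamma.synthetic import (BandProfile, EvokedShapeConfig, StepCurve,
                                  StimulationProtocol, SyntheticConfig,
                                  default_config, default_evoked_config,
                                  generate_cohort, generate_evoked_series,
                                  generate_lfp, inject_stimulus_artifacts)


class TestStimulationProtocol:
    def test_hfs_span_matches_schedule_arithmetic(self):
        p = StimulationProtocol()
        assert p.hfs_span == pytest.approx(10 * (14 / 200) + 9 * 10)
        assert round(p.hfs_span, 1) == 90.7

    def test_pulse_times_reproducible_from_arithmetic(self):
        p = StimulationProtocol(trains=3, pulses_per_train=4,
                                intra_train_rate=100.0, inter_train_gap=2.0)
        times = p.hfs_pulse_times(onset=10.0)
        assert len(times) == 12
        # second train starts gap after the first train's last pulse
        assert times[4] == pytest.approx(10.0 + 3 / 100 + 2.0)

    def test_test_pulse_count_is_floor_of_duration_times_rate(self):
        p = StimulationProtocol()
        assert len(p.test_pulse_times(400.0)) == 10

    @pytest.mark.parametrize("bad", [
        dict(trains=1, pulses_per_train=0),
        dict(intra_train_rate=0.0),
        dict(inter_train_gap=-1.0),
        dict(test_pulse_rate=0.0),
    ])
    def test_invalid_protocols_rejected(self, bad):
        with pytest.raises(ValueError):
            StimulationProtocol(**bad)


class TestStepCurve:
    def test_zero_order_hold_lookup(self):
        c = StepCurve((0.0, 10.0, 20.0), (100.0, 50.0, 80.0))
        assert np.array_equal(c.at(np.array([-5.0, 0.0, 9.9, 10.0, 25.0])),
                              [100.0, 100.0, 100.0, 50.0, 80.0])

    def test_nonpositive_gains_rejected(self):
        with pytest.raises(ValueError):
            BandProfile("theta", 8.0, 1.0,
                        gain=StepCurve((0.0,), (0.0,)))


class TestGenerateLfp:
    def test_zero_amplitudes_zero_noise_gives_flat_trace(self):
        cfg = SyntheticConfig(bands=(
            BandProfile("theta", 8.0, 0.0), BandProfile("gamma", 60.0, 0.0)),
            noise_sd=0.0)
        sess = generate_lfp(cfg, 10.0)
        assert np.all(sess.signal == 0.0)

    def test_sub_nyquist_rate_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SyntheticConfig(rate=100.0,
                            bands=(BandProfile("gamma", 60.0, 1.0),))

    def test_fixed_seed_bit_identical(self):
        cfg = default_config("control", seed=9)
        a = generate_lfp(cfg, 20.0)
        b = generate_lfp(cfg, 20.0)
        assert np.array_equal(a.signal, b.signal)

    def test_gamma_envelope_tracks_theta_oracle(self):
        """With m=0.8 the known analytic gamma envelope must correlate
        strongly (negatively: envelope peaks at theta phase 0 = theta
        maxima) with the theta waveform itself -- and the generated gamma
        component's magnitude must match the stored envelope."""
        cfg = SyntheticConfig(bands=(
            BandProfile("theta", 8.0, 1.0), BandProfile("gamma", 60.0, 0.5)),
            m=0.8, noise_sd=0.0)
        sess = generate_lfp(cfg, 16.0)
        env = sess.components["gamma_envelope"]
        theta = sess.components["theta"]
        r = np.corrcoef(env, theta)[0, 1]
        assert abs(r) > 0.8
        # envelope really bounds the gamma component
        assert np.all(np.abs(sess.components["gamma"]) <= env + 1e-9)

    def test_control_theta_gain_injected_at_half_power_early_hfs(self):
        cfg = default_config("control", hfs_onset=100.0, seed=2)
        theta = cfg.band("theta")
        early = theta.gain.at(np.arange(100.0, 150.0, 10.0))
        assert np.all(early == 50.0)
        assert theta.gain.at(50.0) == 100.0


class TestArtifacts:
    def test_hfs_first_to_last_pulse_span(self):
        cfg = default_config("control", seed=0)
        sess = generate_lfp(cfg, 610.0)
        sess = inject_stimulus_artifacts(sess, StimulationProtocol(), 100.0)
        hfs = sess.events.loc[sess.events["kind"] == "hfs_pulse", "time_s"]
        assert hfs.max() - hfs.min() == pytest.approx(90.7)
        assert len(hfs) == 150

    def test_zero_trains_leaves_no_hfs_events(self):
        cfg = default_config("control", seed=0)
        sess = generate_lfp(cfg, 60.0)
        out = inject_stimulus_artifacts(
            sess, StimulationProtocol(trains=0), 30.0)
        assert not (out.events["kind"] == "hfs_pulse").any()

    def test_events_beyond_trace_truncated_with_warning(self):
        cfg = default_config("control", seed=0)
        sess = generate_lfp(cfg, 120.0)
        with pytest.warns(UserWarning, match="truncated"):
            out = inject_stimulus_artifacts(sess, StimulationProtocol(),
                                            100.0)
        assert out.events["time_s"].max() < 120.0

    def test_artifact_added_to_trace_at_event_times(self):
        cfg = default_config("control", seed=0)
        sess = generate_lfp(cfg, 120.0)
        out = inject_stimulus_artifacts(sess, StimulationProtocol(trains=0),
                                        10.0, amplitude=1000.0)
        t0 = out.events["time_s"].iloc[0]
        i = int(round(t0 * out.rate))
        seg = out.signal[i:i + 5] - sess.signal[i:i + 5]
        assert np.max(np.abs(seg)) > 500.0


class TestEvokedSeries:
    def test_noise_free_unit_factors_give_identical_sweeps(self):
        shape = EvokedShapeConfig(potentiation=(1.0, 1.0), noise_sd=0.0)
        sweeps = generate_evoked_series(shape, [0.0, 5.0])
        ref = sweeps[0].values_mv
        assert all(np.array_equal(s.values_mv, ref) for s in sweeps)

    def test_factor_two_doubles_measured_slope(self):
        from thetagamma.evoked import fepsp_slope
        shape = EvokedShapeConfig(potentiation=(1.0, 2.0), noise_sd=0.0)
        sweeps = generate_evoked_series(shape, [0.0, 5.0])
        s1 = fepsp_slope(sweeps[0])
        s2 = fepsp_slope(sweeps[-1])
        assert s2 == pytest.approx(2.0 * s1)

    def test_empty_schedule_empty_output(self):
        shape = EvokedShapeConfig(potentiation=())
        assert generate_evoked_series(shape, []) == []

    def test_condition_profiles_order_potentiation(self):
        _, times, phases = default_evoked_config("control")
        fc, _, _ = default_evoked_config("control")
        fa, _, _ = default_evoked_config("abeta")
        late = [i for i, p in enumerate(phases) if p == "24h"]
        assert np.mean(np.asarray(fc.potentiation)[late]) > \
            np.mean(np.asarray(fa.potentiation)[late])


class TestCohort:
    def test_cohort_sizes_and_labels(self):
        subs = generate_cohort(2, 1, master_seed=1)
        assert [s.condition for s in subs] == ["control", "control", "abeta"]

    def test_control_only_cohort(self):
        subs = generate_cohort(1, 0, master_seed=1)
        assert len(subs) == 1 and subs[0].condition == "control"

    def test_same_master_seed_is_byte_identical(self):
        a = generate_cohort(1, 1, master_seed=3)
        b = generate_cohort(1, 1, master_seed=3)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.session.signal, sb.session.signal)
            assert sa.session.events.equals(sb.session.events)
            assert all(np.array_equal(x.values_mv, y.values_mv)
                       for x, y in zip(sa.sweeps, sb.sweeps))

    def test_subjects_differ_between_seeds_and_within_cohort(self):
        a, b = generate_cohort(2, 0, master_seed=5)
        assert not np.array_equal(a.session.signal, b.session.signal)
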