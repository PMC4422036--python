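"""ESC phase-amplitude coupling: analytic constructions with known
envelopes, exact surrogate oracle, and qualitative comodulogram structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetagamma.pac import (CENTERS, esc, esc_surrogates, lowband_signal,
                            pac_matrix, surrogate_null, theta_gamma_pool,
                            wavelet_envelope, PACMatrix)

RATE = 500.0
N = 2048
T = np.arange(N) / RATE


def am_signal(m=0.8, f_theta=8.0, f_gamma=58.0, noise=0.1, seed=0,
              invert=False):
    rng = np.random.default_rng(seed)
    mod = 1.0 - m * np.cos(2 * np.pi * f_theta * T) if invert \
        else 1.0 + m * np.cos(2 * np.pi * f_theta * T)
    return (np.cos(2 * np.pi * f_theta * T)
            + mod * np.cos(2 * np.pi * f_gamma * T)
            + noise * rng.standard_normal(N))


class TestWaveletEnvelope:
    def test_on_center_tone_envelope_constant(self):
        env = wavelet_envelope(np.cos(2 * np.pi * 43.0 * T), 43.0)
        core = env[N // 8: -N // 8]
        assert np.std(core) / np.mean(core) < 0.05
        assert np.mean(core) == pytest.approx(1.0, rel=0.05)

    def test_am_tone_envelope_matches_modulator(self):
        x = (1 + 0.8 * np.cos(2 * np.pi * 8 * T)) * np.cos(2 * np.pi * 60 * T)
        env = wavelet_envelope(x, 58.0)
        mod = 1 + 0.8 * np.cos(2 * np.pi * 8 * T)
        assert np.corrcoef(env, mod)[0, 1] > 0.9

    def test_off_center_tone_suppressed(self):
        on = wavelet_envelope(np.cos(2 * np.pi * 58.0 * T), 58.0)
        off = wavelet_envelope(np.cos(2 * np.pi * 88.0 * T), 58.0)
        assert np.mean(off) < 0.10 * np.mean(on)

    def test_center_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            wavelet_envelope(np.zeros(N), 250.0)

    def test_block_size_invariance(self):
        x = am_signal()
        a = wavelet_envelope(x, 58.0, block_size=200)
        b = wavelet_envelope(x, 58.0, block_size=None)
        c = wavelet_envelope(x, 58.0, block_size=731)
        assert np.allclose(a, b, atol=1e-10)
        assert np.allclose(a, c, atol=1e-10)


class TestEsc:
    def test_affine_envelope_gives_unit_correlation(self):
        low = lowband_signal(am_signal(noise=0.0), 8.0)
        env = 3.0 + 2.0 * low
        assert esc(low, env) == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(-50, 50), b=st.floats(0.1, 50),
           c=st.floats(-50, 50), d=st.floats(0.1, 50))
    def test_invariant_to_affine_rescaling(self, a, b, c, d):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(256)
        y = rng.standard_normal(256)
        r0 = esc(x, y)
        assert esc(a + b * x, c + d * y) == pytest.approx(r0, abs=1e-9)

    def test_zero_variance_returns_missing(self):
        assert np.isnan(esc(np.ones(100), np.random.default_rng(0)
                            .standard_normal(100)))

    def test_strong_modulation_high_esc_and_sign_flip(self):
        low = lowband_signal(am_signal(), 8.0)
        env = wavelet_envelope(am_signal(), 58.0)
        r = esc(low, env)
        assert r > 0.8
        inv = am_signal(invert=True)
        r_inv = esc(lowband_signal(inv, 8.0), wavelet_envelope(inv, 58.0))
        assert r_inv == pytest.approx(-r, abs=0.05)


class TestPacMatrix:
    def test_twenty_center_frequency_bins(self):
        assert len(CENTERS) == 20
        assert CENTERS[0] == 3.0 and CENTERS[-1] == 98.0
        assert np.all(np.diff(CENTERS) == 5.0)

    def test_cells_with_flow_geq_fhigh_missing(self):
        mat = pac_matrix(am_signal())
        for i, fl in enumerate(mat.low_centers):
            for j, fh in enumerate(mat.high_centers):
                if fl >= fh:
                    assert np.isnan(mat.values[i, j])

    def test_injected_pair_maximum_in_theta_row_near_carrier(self):
        """A single injected AM pair concentrates the comodulogram maximum
        at the theta signal row, within one bin of the gamma carrier (the
        wavelet's proportional bandwidth makes the two bins adjacent to
        the carrier nearly equivalent)."""
        mat = pac_matrix(am_signal(noise=0.05))
        i, j = np.unravel_index(np.nanargmax(mat.values), mat.values.shape)
        assert mat.low_centers[i] == 8.0
        assert abs(mat.high_centers[j] - 58.0) <= 5.0
        assert mat.values[list(CENTERS).index(8.0),
                          list(CENTERS).index(58.0)] > 0.8

    def test_white_noise_cells_mostly_inside_surrogate_bound(self, rng):
        x = rng.standard_normal(N)
        mat = pac_matrix(x)
        null = surrogate_null(x, rng=1)
        z = (mat.values - null.mean) / null.sd
        valid = np.isfinite(z)
        frac_in = np.mean(np.abs(z[valid]) <= 1.96)
        assert frac_in >= 0.90

    def test_upper_left_dominance_on_one_over_f_noise(self):
        """On 1/f-like noise the ESC magnitude concentrates at low signal
        frequencies against high envelope frequencies (top-left of the
        comodulogram), because those cells have the fewest effective
        degrees of freedom."""
        rng = np.random.default_rng(3)
        acc = np.zeros((20, 20))
        reps = 8
        for _ in range(reps):
            spec = (np.fft.rfftfreq(N, 1 / RATE) + 1e-9) ** -0.5
            spec[0] = 0.0
            phases = np.exp(2j * np.pi * rng.random(len(spec)))
            x = np.fft.irfft(spec * phases * N, N)
            acc += np.abs(np.nan_to_num(pac_matrix(x).values))
        mean_abs = acc / reps
        upper_left = np.nanmean(mean_abs[:3, -5:])
        tri = mean_abs[np.triu_indices(20, 1)]
        assert upper_left > 2.0 * np.mean(tri)


class TestSurrogates:
    def test_segment_shuffle_matches_direct_recomputation(self):
        """Oracle: the vectorized surrogate ESC must equal a literal
        rebuild-the-shuffled-envelope-and-correlate computation."""
        rng = np.random.default_rng(5)
        low = rng.standard_normal(430)
        env = np.abs(rng.standard_normal(430))
        n_windows = 40
        seg = len(low) // n_windows
        m = seg * n_windows
        vals = esc_surrogates(low, env, n_windows=n_windows,
                              n_surrogates=10, rng=7)
        perm_rng = np.random.default_rng(7)
        for k in range(10):
            perm = perm_rng.permutation(n_windows)
            shuffled = np.concatenate(
                [env[p * seg:(p + 1) * seg] for p in perm])
            direct = np.corrcoef(low[:m], shuffled)[0, 1]
            assert vals[k] == pytest.approx(direct, abs=1e-12)

    def test_am_true_esc_exceeds_null_by_3sd(self):
        x = am_signal()
        low = lowband_signal(x, 8.0)
        env = wavelet_envelope(x, 58.0)
        surr = esc_surrogates(low, env, rng=3)
        assert esc(low, env) > surr.mean() + 3.0 * surr.std()

    def test_m_zero_within_null_interval(self):
        x = am_signal(m=0.0, seed=12)
        low = lowband_signal(x, 8.0)
        env = wavelet_envelope(x, 58.0)
        surr = esc_surrogates(low, env, rng=3)
        assert abs(esc(low, env) - surr.mean()) < 1.96 * surr.std()

    def test_fixed_seed_identical_null(self):
        x = am_signal()
        a = surrogate_null(x, rng=9)
        b = surrogate_null(x, rng=9)
        assert np.array_equal(a.mean, b.mean, equal_nan=True)
        assert np.array_equal(a.sd, b.sd, equal_nan=True)

    def test_short_epoch_reduces_window_count_with_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="reduced"):
            vals = esc_surrogates(rng.standard_normal(150),
                                  np.abs(rng.standard_normal(150)),
                                  n_windows=200, n_surrogates=5, rng=0)
        assert len(vals) == 5


class TestThetaGammaPool:
    @staticmethod
    def matrix(scale=1.0):
        vals = np.full((20, 20), np.nan)
        for i, fl in enumerate(CENTERS):
            for j, fh in enumerate(CENTERS):
                if fl < fh:
                    vals[i, j] = 0.2 * scale
        return PACMatrix(CENTERS.copy(), CENTERS.copy(), vals)

    def test_identical_matrices_flat_100pct(self):
        mats = {w: self.matrix() for w in
                ("baseline", "hfs", "post1", "post2", "post3")}
        pooled, _ = theta_gamma_pool(mats)
        assert np.allclose(pooled["rel_pct"], 100.0)

    def test_injected_gain_during_hfs_reports_150pct(self):
        mats = {"baseline": self.matrix(), "hfs": self.matrix(scale=1.5)}
        pooled, per_center = theta_gamma_pool(mats)
        hfs = pooled.set_index("window").loc["hfs", "rel_pct"]
        assert hfs == pytest.approx(150.0)
        assert np.allclose(
            per_center[per_center["window"] == "hfs"]["rel_pct"], 150.0)

    def test_missing_baseline_gives_missing_relative(self):
        pooled, _ = theta_gamma_pool({"hfs": self.matrix()})
        assert pooled["rel_pct"].isna().all()

    def test_pooled_score_is_mean_of_included_cells(self):
        mats = {"baseline": self.matrix()}
        pooled, _ = theta_gamma_pool(mats)
        assert pooled["pooled_esc"].iloc[0] == pytest.approx(0.2)
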