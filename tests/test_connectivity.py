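import numpy as np
import pytest

import menet as m
from menet.connectivity import band_frequencies, edge_trim_samples
from menet.errors import ParameterError

ALPHA, BETA, GAMMA = m.DEFAULT_BANDS
FS = 256.0


def _epoch(data, fs=FS):
    ids = tuple(f"c{k}" for k in range(data.shape[0]))
    return m.EEGEpoch(data=np.asarray(data, float), fs=fs, channel_ids=ids)


def _tone(freq, dur=2.0, fs=FS, phase=0.0):
    t = np.arange(int(fs * dur)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


class TestWaveletPhase:
    def test_phase_ramp_slope(self):
        """A pure tone analysed at its own frequency has an unwrapped phase
        advancing by 2*pi*f per second (checked mid-epoch, 1% tolerance)."""
        ep = _epoch(_tone(10.0)[None, :])
        pt = m.wavelet_phase(ep, [10.0])
        ph = np.unwrap(pt.phases[0, 0])
        mid = slice(128, 384)
        t = np.arange(ep.n_samples) / FS
        slope = np.polyfit(t[mid], ph[mid], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_lagged_copies_show_expected_phase_difference(self):
        lag = 4  # samples
        x = _tone(10.0)
        ep = _epoch(np.stack([x, np.roll(x, lag)]))
        pt = m.wavelet_phase(ep, [10.0])
        mid = slice(128, 384)
        dphi = np.angle(np.exp(1j * (pt.phases[0, 0] - pt.phases[1, 0])[mid])).mean()
        assert dphi == pytest.approx(2 * np.pi * 10.0 * lag / FS, rel=0.02)

    def test_zero_signal_phases_finite_and_zero(self):
        ep = _epoch(np.zeros((2, 512)))
        pt = m.wavelet_phase(ep, [10.0, 20.0])
        assert np.all(np.isfinite(pt.phases))
        assert np.allclose(pt.phases, 0.0)

    def test_frequency_at_nyquist_rejected(self):
        ep = _epoch(np.zeros((1, 512)))
        with pytest.raises(ParameterError):
            m.wavelet_phase(ep, [FS / 2])


class TestPlvPair:
    def test_identical_series(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert m.plv_pair(ph, ph) == pytest.approx(1.0)

    def test_constant_offset(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert m.plv_pair(ph, ph + np.pi / 3) == pytest.approx(1.0)

    def test_cancelling_differences(self):
        ph_i = np.zeros(100)
        ph_j = np.tile([0.0, np.pi], 50)
        assert m.plv_pair(ph_i, ph_j) == pytest.approx(0.0, abs=1e-12)

    def test_independent_phase_null_mean(self, rng):
        """E[PLV] for independent uniform phases is ~sqrt(pi)/(2*sqrt(n))."""
        n = 1000
        vals = [m.plv_pair(rng.uniform(-np.pi, np.pi, n),
                           rng.uniform(-np.pi, np.pi, n)) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(np.sqrt(np.pi) / (2 * np.sqrt(n)), abs=0.005)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            m.plv_pair(np.zeros(10), np.zeros(11))


class TestBandPlv:
    def test_identical_channels_fully_locked(self):
        ep = _epoch(np.tile(_tone(10.0, dur=1.0), (4, 1)))
        plv = m.band_plv(ep, ALPHA).values
        off = plv[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0, atol=1e-9)

    def test_independent_noise_null_modest_in_gamma(self, rng):
        """Gamma-band PLV of independent noise stays low; slower bands have a
        higher small-sample floor because a 7-cycle wavelet leaves fewer
        independent phase samples in a 1-s block."""
        ep = _epoch(rng.standard_normal((8, 256)), fs=256.0)
        plv = m.band_plv(ep, GAMMA).values
        off = plv[~np.eye(8, dtype=bool)]
        assert off.mean() <= 0.25

    def test_symmetric_unit_diagonal_bounded(self, rng):
        ep = _epoch(rng.standard_normal((6, 256)))
        plv = m.band_plv(ep, BETA).values
        assert np.array_equal(plv, plv.T)
        assert np.allclose(np.diag(plv), 1.0)
        assert plv.min() >= 0.0 and plv.max() <= 1.0

    def test_common_phase_offset_invariance(self, rng):
        """PLV depends only on the phase difference: exact at the phase level,
        and at the estimator level up to wavelet block-edge effects."""
        ph_i = rng.uniform(-np.pi, np.pi, 300)
        ph_j = rng.uniform(-np.pi, np.pi, 300)
        assert m.plv_pair(ph_i, ph_j) == pytest.approx(
            m.plv_pair(ph_i + 0.8, ph_j + 0.8), abs=1e-12)
        x = _tone(10.0, dur=1.0)
        y = _tone(10.0, dur=1.0, phase=0.9)
        a = m.band_plv(_epoch(np.stack([x, y])), ALPHA).values[0, 1]
        xs = _tone(10.0, dur=1.0, phase=0.4)
        ys = _tone(10.0, dur=1.0, phase=1.3)
        b = m.band_plv(_epoch(np.stack([xs, ys])), ALPHA).values[0, 1]
        assert a == pytest.approx(b, abs=1e-4)

    def test_matches_naive_per_pair_loop(self, rng):
        """Dual route: the vectorised matrix equals an explicit plv_pair loop
        over the same edge-trimmed phase tensor."""
        ep = _epoch(rng.standard_normal((4, 256)))
        freqs = band_frequencies(ALPHA)
        pt = m.wavelet_phase(ep, freqs)
        trim = edge_trim_samples(freqs.min(), FS)
        sl = slice(trim, ep.n_samples - trim)
        expected = np.eye(4)
        for i in range(4):
            for j in range(i + 1, 4):
                vals = [m.plv_pair(pt.phases[i, k, sl], pt.phases[j, k, sl])
                        for k in range(len(freqs))]
                expected[i, j] = expected[j, i] = np.mean(vals)
        got = m.band_plv(ep, ALPHA).values
        assert np.allclose(got, expected, atol=1e-10)

    def test_batch_equals_single(self, rng):
        eps = [_epoch(rng.standard_normal((4, 256))) for _ in range(3)]
        batch = m.band_plv_batch(eps, BETA)
        for ep, got in zip(eps, batch):
            assert np.allclose(got.values, m.band_plv(ep, BETA).values, atol=1e-12)

    def test_band_outside_nyquist_rejected(self):
        ep = _epoch(np.zeros((2, 256)), fs=64.0)
        with pytest.raises(ParameterError):
            m.band_plv(ep, GAMMA)


class TestCouplingResponse:
    def test_plv_increases_with_von_mises_concentration(self):
        """On synthetic pairs whose phase difference is von Mises jitter, the
        trial-mean PLV is strictly increasing in the concentration."""
        means = []
        for kappa in (0.0, 1.0, 4.0, 16.0):
            trials = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                base = rng.uniform(-np.pi, np.pi, 400)
                jit_i = rng.vonmises(0.0, kappa, 400) if kappa > 0 else rng.uniform(-np.pi, np.pi, 400)
                jit_j = rng.vonmises(0.0, kappa, 400) if kappa > 0 else rng.uniform(-np.pi, np.pi, 400)
                trials.append(m.plv_pair(base + jit_i, base + jit_j))
            means.append(np.mean(trials))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestWindowedPlv:
    def test_four_windows_per_block(self, rng):
        block = _epoch(rng.standard_normal((4, 256)))
        conns = m.windowed_band_plv(block, BETA)
        assert len(conns) == 4

    def test_windows_are_valid_matrices(self, rng):
        block = _epoch(rng.standard_normal((4, 256)))
        for conn in m.windowed_band_plv(block, BETA):
            v = conn.values
            assert np.array_equal(v, v.T)
            assert v.min() >= 0.0 and v.max() <= 1.0
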