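import numpy as np
import pytest

from rhythmcode import (
    InvalidInputError,
    InvalidSpecError,
    SignalSegment,
    SmoothingSpec,
    TimeFrequencyPlane,
    analytic_signal,
    blocked_rspwvd,
    compute_rspwvd,
    compute_spwvd,
    compute_wvd,
    reassignment_coordinates,
)

from conftest import chirp_segment, tone_segment

FS = 128.0


def brute_force_wvd(z):
    """Independent double-loop evaluation of the discrete distribution."""
    n = z.size
    out = np.zeros((n, n), dtype=complex)
    for ti in range(n):
        mmax = min(ti, n - 1 - ti)
        m = np.arange(-mmax, mmax + 1)
        prod = z[ti + m] * np.conj(z[ti - m])
        for k in range(n):
            out[k, ti] = np.sum(prod * np.exp(-2j * np.pi * k * m / n))
    return out


class TestSignalSegment:
    def test_rejects_nonfinite(self):
        with pytest.raises(InvalidInputError):
            SignalSegment(np.array([0.0, np.nan] + [0.0] * 100), FS)

    def test_rejects_nonpositive_fs(self):
        with pytest.raises(InvalidInputError):
            SignalSegment(np.zeros(100), 0.0)

    def test_rejects_sub_timestamp_segments(self):
        with pytest.raises(InvalidInputError):
            SignalSegment(np.zeros(10), FS)  # < 0.2 s at 128 Hz

    def test_tail(self):
        seg = tone_segment(10.0, duration=4.0)
        assert seg.tail(2.0).samples.size == 256
        np.testing.assert_array_equal(seg.tail(2.0).samples, seg.samples[-256:])


class TestSmoothingSpec:
    def test_even_length_rejected(self):
        with pytest.raises(InvalidSpecError):
            SmoothingSpec(g=np.ones(4), h=np.ones(3))

    def test_asymmetric_rejected(self):
        with pytest.raises(InvalidSpecError):
            SmoothingSpec(g=np.array([0.1, 0.5, 0.9]), h=np.ones(1))

    def test_normalisation(self):
        spec = SmoothingSpec(g=np.ones(5), h=np.array([1.0, 2.0, 1.0]))
        assert spec.g.sum() == pytest.approx(1.0)
        assert spec.h.max() == pytest.approx(1.0)

    def test_derived_kernels_match_windows(self):
        spec = SmoothingSpec.default(256)
        assert spec.tau_g.size == spec.g.size
        assert spec.d_h.size == spec.h.size
        half = (spec.g.size - 1) // 2
        np.testing.assert_allclose(
            spec.tau_g, np.arange(-half, half + 1) * spec.g
        )


class TestAnalyticSignal:
    def test_zero_signal(self):
        z = analytic_signal(SignalSegment(np.zeros(64), FS))
        np.testing.assert_array_equal(z, np.zeros(64, complex))

    def test_constant_removed(self):
        z = analytic_signal(SignalSegment(np.full(64, 3.7), FS))
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_real_part_is_mean_removed_input(self, rng):
        x = rng.normal(size=256)
        z = analytic_signal(SignalSegment(x, FS))
        np.testing.assert_allclose(z.real, x - x.mean(), atol=1e-10)

    def test_against_direct_dft_oracle(self):
        seg = tone_segment(10.0)
        x = seg.samples - seg.samples.mean()
        n = x.size
        spec = np.fft.fft(x)
        gain = np.zeros(n)
        gain[0] = 1.0
        gain[1 : n // 2] = 2.0
        gain[n // 2] = 1.0
        oracle = np.fft.ifft(spec * gain)
        z = analytic_signal(seg)
        np.testing.assert_allclose(z, oracle, atol=1e-10)
        # modulus ~ 1 away from edges for a unit tone
        assert np.all(np.abs(np.abs(z[20:-20]) - 1.0) < 0.05)

    def test_one_sided_spectrum(self, rng):
        z = analytic_signal(SignalSegment(rng.normal(size=128), FS))
        spec = np.fft.fft(z)
        assert np.abs(spec[65:]).max() < 1e-9 * np.abs(spec).max()


class TestWVD:
    def test_zero_signal(self):
        plane = compute_wvd(SignalSegment(np.zeros(64), FS))
        np.testing.assert_array_equal(plane.values, 0.0)

    def test_too_short(self):
        with pytest.raises(InvalidInputError):
            compute_wvd(SignalSegment(np.zeros(3), 10.0))

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=48)
        seg = SignalSegment(x, FS)
        plane = compute_wvd(seg)
        oracle = brute_force_wvd(analytic_signal(seg))
        scale = np.abs(oracle.real).max()
        assert np.abs(oracle.real - plane.values).max() <= 1e-9 * scale
        assert np.abs(oracle.imag).max() <= 1e-9 * scale

    def test_tone_energy_argmax_from_oracle_crop(self):
        seg = tone_segment(10.0, duration=0.5)  # 64-sample crop
        plane = compute_wvd(seg)
        oracle = brute_force_wvd(analytic_signal(seg)).real
        np.testing.assert_allclose(plane.values, oracle, atol=1e-9 * np.abs(oracle).max())
        k = int(np.argmax(plane.values.sum(axis=1)))
        assert abs(plane.freqs[k] - 10.0) <= plane.freqs[1] - plane.freqs[0]

    def test_grids(self, tone_10hz):
        plane = compute_wvd(tone_10hz)
        assert plane.freqs[0] == 0.0
        assert plane.freqs[-1] < FS / 2
        np.testing.assert_allclose(np.diff(plane.times), 1 / FS)

    def test_cross_term_energy_between_two_tones(self):
        t = np.arange(256) / FS

        def energy_12_14(x):
            plane = compute_wvd(SignalSegment(x, FS))
            band = (plane.freqs >= 12.0) & (plane.freqs <= 14.0)
            return np.abs(plane.values[band]).sum()

        tone6 = np.cos(2 * np.pi * 6 * t)
        tone20 = np.cos(2 * np.pi * 20 * t)
        both = energy_12_14(tone6 + tone20)
        assert both > energy_12_14(tone6)
        assert both > energy_12_14(tone20)


class TestSPWVD:
    def test_unit_windows_equal_wvd(self, rng):
        seg = SignalSegment(rng.normal(size=96), FS)
        w = compute_wvd(seg).values
        s = compute_spwvd(seg, SmoothingSpec.unit()).values
        assert np.abs(w - s).max() <= 1e-9 * np.abs(w).max()

    def test_zero_signal(self):
        plane = compute_spwvd(SignalSegment(np.zeros(64), FS), SmoothingSpec.default(64))
        np.testing.assert_array_equal(plane.values, 0.0)

    def test_smoothing_reduces_cross_terms(self):
        t = np.arange(256) / FS
        x = np.cos(2 * np.pi * 6 * t) + np.cos(2 * np.pi * 20 * t)
        seg = SignalSegment(x, FS)
        spec = SmoothingSpec.default(256)
        wvd = compute_wvd(seg)
        spw = compute_spwvd(seg, spec)
        band = (wvd.freqs >= 12.0) & (wvd.freqs <= 14.0)
        assert np.abs(spw.values[band]).sum() < np.abs(wvd.values[band]).sum()

    def test_window_longer_than_segment_rejected(self):
        seg = SignalSegment(np.zeros(64), FS)
        with pytest.raises(InvalidSpecError):
            compute_spwvd(seg, SmoothingSpec(g=np.ones(65), h=np.ones(1)))


class TestReassignment:
    def test_zero_signal_identity_coordinates(self):
        seg = SignalSegment(np.zeros(64), FS)
        spec = SmoothingSpec.default(64)
        t_hat, f_hat = reassignment_coordinates(seg, spec)
        n = 64
        np.testing.assert_allclose(t_hat, np.broadcast_to(np.arange(n) / FS, (n, n)))
        np.testing.assert_allclose(
            f_hat, np.broadcast_to((np.arange(n) * FS / (2 * n))[:, None], (n, n))
        )

    def test_tone_frequency_coordinates(self, tone_10hz):
        spec = SmoothingSpec.default(256)
        plane = compute_spwvd(tone_10hz, spec)
        _, f_hat = reassignment_coordinates(tone_10hz, spec)
        df = plane.freqs[1] - plane.freqs[0]
        energy = np.abs(plane.values)
        top = energy >= np.quantile(energy, 0.999)
        assert np.all(np.abs(f_hat[top] - 10.0) <= df + 1e-9)

    def test_chirp_reassignment_tightens_localization(self, chirp):
        spec = SmoothingSpec.default(256)
        plane = compute_spwvd(chirp, spec)
        t_hat, f_hat = reassignment_coordinates(chirp, spec)
        f_inst = lambda t: 5.0 + 10.0 * t  # 5 -> 25 Hz over 2 s
        energy = np.abs(plane.values)
        top = energy >= np.quantile(energy, 0.9)
        tt, ff = np.meshgrid(plane.times, plane.freqs)
        err_re = np.abs(f_hat - f_inst(t_hat))[top].mean()
        err_un = np.abs(ff - f_inst(tt))[top].mean()
        assert err_re < err_un


class TestRSPWVD:
    def test_zero_signal(self):
        plane = compute_rspwvd(SignalSegment(np.zeros(64), FS), SmoothingSpec.default(64))
        np.testing.assert_array_equal(plane.values, 0.0)

    @pytest.mark.parametrize("make", [
        lambda: tone_segment(10.0),
        lambda: chirp_segment(),
        lambda: SignalSegment(np.random.default_rng(3).normal(size=256), FS),
    ])
    def test_energy_conservation(self, make):
        seg = make()
        spec = SmoothingSpec.default(seg.samples.size)
        spw = compute_spwvd(seg, spec)
        rsp = compute_rspwvd(seg, spec)
        assert rsp.total_energy == pytest.approx(spw.total_energy, rel=1e-6)

    def test_tone_localization(self):
        for f0 in (3.0, 10.0, 27.0, 45.0):
            seg = tone_segment(f0)
            plane = compute_rspwvd(seg, SmoothingSpec.default(256))
            k = int(np.argmax(plane.values.sum(axis=1)))
            df = plane.freqs[1] - plane.freqs[0]
            assert abs(plane.freqs[k] - f0) <= df + 1e-9

    def test_chirp_concentration_increases(self, chirp):
        spec = SmoothingSpec.default(256)

        def concentration(values):  # independent Renyi-type functional
            v = np.clip(np.asarray(values, dtype=float), 0.0, None)
            v = v / v.sum()
            return float((v**2).sum())

        spw = compute_spwvd(chirp, spec)
        rsp = compute_rspwvd(chirp, spec)
        assert concentration(rsp.values) > concentration(spw.values)

    def test_time_shift_covariance(self):
        # a localized packet delayed by k samples moves the reassigned
        # ridge by k time bins (cross-correlation peak at lag k)
        fs, n, k = FS, 256, 16
        t = np.arange(n) / fs
        packet = np.cos(2 * np.pi * 15 * t) * np.exp(-((t - 0.6) ** 2) / 0.02)
        delayed = np.concatenate([np.zeros(k), packet[:-k]])
        spec = SmoothingSpec.default(n)
        e0 = np.clip(compute_rspwvd(SignalSegment(packet, fs), spec).values, 0, None).sum(axis=0)
        e1 = np.clip(compute_rspwvd(SignalSegment(delayed, fs), spec).values, 0, None).sum(axis=0)
        xc = np.correlate(e1 - e1.mean(), e0 - e0.mean(), mode="full")
        lag = int(np.argmax(xc)) - (n - 1)
        assert abs(lag - k) <= 1


class TestBlockedRSPWVD:
    def test_matches_single_block(self, tone_10hz):
        spec = SmoothingSpec.default(256)
        whole = compute_rspwvd(tone_10hz, spec)
        blocked = blocked_rspwvd(tone_10hz, spec=spec, block_s=2.0)
        np.testing.assert_allclose(blocked.values, whole.values)

    def test_concatenates_blocks(self):
        seg = tone_segment(10.0, duration=4.0)
        plane = blocked_rspwvd(seg, block_s=2.0)
        assert plane.values.shape == (256, 512)
        assert plane.times.size == 512

    def test_misaligned_block_rejected(self, tone_10hz):
        with pytest.raises(InvalidSpecError):
            blocked_rspwvd(tone_10hz, block_s=0.5001)

    def test_energy_conservation_across_blocks(self):
        # reassignment within each block conserves that block's SPWVD energy
        from rhythmcode.timefreq import _spwvd_blocks, analytic_signal as asig

        seg = SignalSegment(np.random.default_rng(9).normal(size=512), FS)
        spec = SmoothingSpec.default(256)
        z = asig(seg).reshape(2, 256)
        tf1, _, _ = _spwvd_blocks(z, spec)
        blocked = blocked_rspwvd(seg, spec=spec, block_s=2.0)
        assert blocked.total_energy == pytest.approx(float(tf1.real.sum()), rel=1e-6)


class TestPlaneValidation:
    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            TimeFrequencyPlane(np.zeros((3, 4)), np.arange(3), np.arange(5))

    def test_non_monotone_grid(self):
        with pytest.raises(InvalidInputError):
            TimeFrequencyPlane(np.zeros((3, 3)), np.array([0.0, 2.0, 1.0]), np.arange(3))
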