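import numpy as np
import pytest
from hypothesis import given, strategies as st

import ewtdoppler as ed
from ewtdoppler.errors import ConfigurationError, DomainError
from ewtdoppler.ewt import admissible_kappa

from conftest import rel_l2


def make_partition(*interior):
    return ed.SpectrumPartition(np.array([0.0, *interior, np.pi]))


class TestMeyerBeta:
    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.5)])
    def test_reference_points(self, x, expected):
        assert ed.meyer_beta(x) == expected

    def test_symmetry_on_dense_grid(self):
        """beta(x) + beta(1-x) = 1 on 10^4 points, exact to 1e-12."""
        x = np.linspace(0, 1, 10_000)
        assert np.max(np.abs(ed.meyer_beta(x) + ed.meyer_beta(1 - x) - 1)) < 1e-12

    def test_monotone(self):
        x = np.linspace(0, 1, 2001)
        assert np.all(np.diff(ed.meyer_beta(x)) >= 0)

    @given(st.floats(0.0, 1.0))
    def test_range(self, x):
        assert 0.0 <= ed.meyer_beta(x) <= 1.0

    @pytest.mark.parametrize("x", [-0.01, 1.01])
    def test_no_clamping_outside_domain(self, x):
        with pytest.raises(DomainError):
            ed.meyer_beta(x)


class TestDetectBoundaries:
    @staticmethod
    def bump_spectrum(n, centers, width=6.0, height=1.0):
        k = np.arange(n)
        spec = np.zeros(n)
        for c in np.atleast_1d(centers):
            spec += height * np.exp(-0.5 * ((k - c) / width) ** 2)
        return spec

    def test_two_tone_midpoint(self):
        n = 512
        spec = self.bump_spectrum(n, [round(0.3 * (n - 1)), round(0.7 * (n - 1))])
        part = ed.detect_boundaries(spec, 2)
        assert part.n_segments == 2
        assert part.boundaries[1] == pytest.approx(0.5 * np.pi, abs=0.02)

    def test_single_tone_trivial_partition(self):
        spec = self.bump_spectrum(256, [100])
        part = ed.detect_boundaries(spec, 1)
        assert part.n_segments == 1
        assert np.allclose(part.boundaries, [0.0, np.pi])

    def test_flat_spectrum_reduces_with_warning(self):
        with pytest.warns(UserWarning, match="local maxima"):
            part = ed.detect_boundaries(np.ones(128), 2)
        assert part.n_segments == 1

    def test_dc_anchor_adds_clutter_band(self):
        n = 512
        c = 200
        spec = self.bump_spectrum(n, [c])
        part = ed.detect_boundaries(spec, 2, anchor_dc=True)
        # first band ends halfway up to the peak, isolating the near-DC floor
        assert part.n_segments == 2
        assert part.boundaries[1] == pytest.approx(np.pi * c / 2 / (n - 1), rel=0.1)

    def test_rejects_negative_spectrum(self):
        with pytest.raises(DomainError):
            ed.detect_boundaries(-np.ones(64), 2)


class TestFilterBank:
    @pytest.mark.parametrize(
        "interior",
        [(), (1.0,), (0.6, 1.4, 2.2), (0.3, 0.9, 1.5, 2.1, 2.7)],
    )
    def test_partition_of_unity(self, interior):
        bank = ed.build_filter_bank(make_partition(*interior), fft_length=1024)
        assert bank.partition_of_unity_error() < 1e-10

    def test_single_segment_is_identity(self):
        bank = ed.build_filter_bank(make_partition(), fft_length=256)
        assert bank.n_bands == 1
        assert np.allclose(bank.scaling_response, 1.0)

    def test_transition_midpoint_value(self):
        # scaling response at the boundary itself is cos(pi/2 * beta(1/2))
        part = make_partition(np.pi / 4)
        bank = ed.build_filter_bank(part, fft_length=1024)
        k = 128  # bin at omega = pi/4
        assert bank.scaling_response[k] == pytest.approx(np.cos(np.pi / 4), abs=1e-12)

    def test_inadmissible_kappa_rejected(self):
        part = make_partition(1.0, 1.2)
        bound = admissible_kappa(part)
        with pytest.raises(ConfigurationError, match="bound"):
            ed.build_filter_bank(part, kappa=1.1 * bound, fft_length=256)

    def test_auto_kappa_is_half_bound(self):
        part = make_partition(0.8, 2.0)
        bank = ed.build_filter_bank(part, fft_length=256)
        assert bank.kappa == pytest.approx(0.5 * admissible_kappa(part))

    def test_responses_symmetric_around_nyquist(self):
        bank = ed.build_filter_bank(make_partition(1.0), fft_length=512)
        for resp in bank.responses:
            assert np.allclose(resp[1:], resp[1:][::-1])


class TestDecomposeReconstruct:
    fs = 1000.0

    def two_tone_signal(self, n=1024):
        t = np.arange(n) / self.fs
        return np.cos(2 * np.pi * 2 * t), np.cos(2 * np.pi * 50 * t), t

    def test_two_tone_band_assignment(self):
        """Each band-limited mode matches its own tone (r > 0.99)."""
        lo, hi, _ = self.two_tone_signal()
        x = lo + hi
        boundary = 2 * np.pi * 26.0 / self.fs  # between 2 and 50 Hz
        bank = ed.build_filter_bank(make_partition(boundary), fft_length=len(x))
        dec = ed.decompose(x, bank)
        assert np.corrcoef(dec.approximation, lo)[0, 1] > 0.99
        assert np.corrcoef(dec.details[0], hi)[0, 1] > 0.99

    def test_zero_signal_zero_modes(self):
        bank = ed.build_filter_bank(make_partition(1.0), fft_length=256)
        dec = ed.decompose(np.zeros(256), bank)
        for mode in dec.modes:
            assert np.allclose(mode, 0.0)

    def test_energy_conservation_white_noise(self):
        """Tight frame: band energies sum to input energy (rel 1e-8)."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2048)
        bank = ed.build_filter_bank(make_partition(0.5, 1.5, 2.5),
                                    fft_length=len(x))
        dec = ed.decompose(x, bank)
        e_bands = sum(float(np.sum(m**2)) for m in dec.modes)
        assert e_bands == pytest.approx(float(np.sum(x**2)), rel=1e-8)

    @pytest.mark.parametrize("kind", ["random", "tones", "chirp"])
    def test_round_trip(self, kind):
        n = 2048
        t = np.arange(n) / self.fs
        rng = np.random.default_rng(42)
        if kind == "random":
            x = rng.standard_normal(n)
        elif kind == "tones":
            x = np.cos(2 * np.pi * 7 * t) + 0.5 * np.cos(2 * np.pi * 120 * t)
        else:
            from scipy.signal import chirp

            x = chirp(t, f0=5.0, f1=80.0, t1=t[-1], method="linear")
        bank = ed.build_filter_bank(make_partition(0.4, 1.1, 2.0), fft_length=n)
        back = ed.reconstruct(ed.decompose(x, bank), bank)
        assert rel_l2(back, x) < 1e-8

    def test_zero_decomposition_zero_signal(self):
        bank = ed.build_filter_bank(make_partition(1.0), fft_length=128)
        dec = ed.EWTDecomposition(np.zeros(128), [np.zeros(128)], 128)
        assert np.allclose(ed.reconstruct(dec, bank), 0.0)

    def test_bank_mismatch_rejected(self):
        bank = ed.build_filter_bank(make_partition(1.0), fft_length=256)
        other = ed.build_filter_bank(make_partition(0.7, 1.9), fft_length=256)
        dec = ed.decompose(np.ones(256), bank)
        with pytest.raises(DomainError):
            ed.reconstruct(dec, other)

    def test_nan_input_rejected(self):
        bank = ed.build_filter_bank(make_partition(1.0), fft_length=128)
        bad = np.zeros(128)
        bad[5] = np.nan
        with pytest.raises(DomainError):
            ed.decompose(bad, bank)

    def test_two_tone_mode_separation(self):
        """Tones >= 4 transition widths apart leak < 1% energy across bands."""
        n = 1024
        ka, kb = 150, 360  # exact FFT bins
        t = np.arange(n)
        tone_a = np.cos(2 * np.pi * ka * t / n)
        tone_b = np.cos(2 * np.pi * kb * t / n)
        boundary = np.pi * (ka + kb) / n
        bank = ed.build_filter_bank(make_partition(boundary), fft_length=n)
        dec = ed.decompose(tone_a + tone_b, bank)
        e_a = float(np.sum(tone_a**2))
        leak_a = float(np.sum((dec.details[0] - tone_b) ** 2))
        leak_b = float(np.sum((dec.approximation - tone_a) ** 2))
        assert leak_a < 0.01 * e_a
        assert leak_b < 0.01 * e_a


class TestInstantaneousFrequency:
    fs = 1000.0

    def test_pure_tone(self):
        t = np.arange(1024) / self.fs
        inst = ed.instantaneous_frequency(np.cos(2 * np.pi * 50 * t), self.fs)
        assert inst.median() == pytest.approx(50.0, abs=0.1)

    def test_linear_chirp_tracks_ramp(self):
        from scipy.signal import chirp

        n = 4096
        t = np.arange(n) / self.fs
        f0, f1 = 20.0, 180.0
        x = chirp(t, f0=f0, f1=f1, t1=t[-1], method="linear")
        inst = ed.instantaneous_frequency(x, self.fs)
        programmed = f0 + (f1 - f0) * t / t[-1]
        dev = np.abs(inst.hz - programmed)[inst.reliable]
        assert np.median(dev) < 0.01 * (f1 - f0)

    def test_amplitude_invariance(self):
        t = np.arange(512) / self.fs
        x = np.cos(2 * np.pi * 80 * t)
        a = ed.instantaneous_frequency(x, self.fs)
        b = ed.instantaneous_frequency(7.3 * x, self.fs)
        assert np.allclose(a.hz, b.hz)

    def test_constant_mode_degenerate(self):
        inst = ed.instantaneous_frequency(np.full(64, 2.5), self.fs)
        assert inst.degenerate
        assert np.all(inst.hz == 0.0)

    def test_edge_samples_flagged(self):
        t = np.arange(200) / self.fs
        inst = ed.instantaneous_frequency(np.cos(2 * np.pi * 30 * t), self.fs)
        assert not inst.reliable[0] and not inst.reliable[-1]
        assert inst.reliable[100]

    def test_too_short_rejected(self):
        with pytest.raises(DomainError):
            ed.instantaneous_frequency(np.ones(8), self.fs)
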