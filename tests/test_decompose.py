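"""Decomposition engines: analytic signal, AFD, HVD, VMD, diagnostics."""

import numpy as np
import pytest

from rppgkit.decompose import (AFDConfig, HVDConfig, VMDConfig, ENGINES,
                               afd_decompose, analytic_signal,
                               component_center_frequency, hvd_decompose,
                               vmd_decompose)
from rppgkit.rates import prepare_signal
from rppgkit.synthio import generate_tone_mixture

FPS = 23.0


def _dominant_freq(x, fps=FPS):
    freqs = np.fft.rfftfreq(len(x), d=1 / fps)
    return freqs[int(np.argmax(np.abs(np.fft.rfft(x)) ** 2))]


class TestAnalyticSignal:
    def test_cosine_has_unit_envelope(self):
        t = np.arange(int(FPS * 30)) / FPS
        psi = analytic_signal(np.cos(2 * np.pi * 1.2 * t), FPS)
        core = psi.envelope[50:-50]
        assert np.allclose(core, 1.0, atol=1e-2)

    def test_hilbert_of_sine_is_minus_cosine(self):
        t = np.arange(int(FPS * 30)) / FPS
        psi = analytic_signal(np.sin(2 * np.pi * 1.0 * t), FPS)
        h = np.imag(psi.values)
        assert np.allclose(h[50:-50], -np.cos(2 * np.pi * 1.0 * t)[50:-50],
                           atol=1e-2)

    def test_real_part_is_the_input_exactly(self, rng):
        s = rng.normal(size=256)
        psi = analytic_signal(s, FPS)
        assert np.allclose(np.real(psi.values), s, atol=1e-12)

    def test_spectrum_is_one_sided(self, rng):
        s = rng.normal(size=256)
        s -= s.mean()
        spec = np.fft.fft(analytic_signal(s, FPS).values)
        neg = np.sum(np.abs(spec[129:]) ** 2)
        assert neg / np.sum(np.abs(spec) ** 2) <= 1e-6

    def test_instantaneous_frequency_of_tone(self):
        t = np.arange(int(FPS * 30)) / FPS
        psi = analytic_signal(np.cos(2 * np.pi * 1.2 * t), FPS)
        assert np.median(psi.instantaneous_frequency()) == pytest.approx(1.2,
                                                                         rel=1e-3)


class TestAFD:
    def test_grid_dictionary_element_reproduced_at_level_one(self):
        # a signal that *is* a dictionary element leaves no remainder
        n = 512
        z = np.exp(2j * np.pi * np.arange(n) / n)
        a = 0.5 * np.exp(2j * np.pi * 16 / 64)  # on the default grid
        e_a = np.sqrt(1 - abs(a) ** 2) / (1 - np.conj(a) * z)
        s = np.real(e_a)
        modes = afd_decompose(s, AFDConfig(max_levels=1), fps=FPS)
        assert modes.extras["remainder_energy_ratio"] < 1e-10

    def test_energy_conservation_on_random_signals(self, rng):
        for _ in range(5):
            s = rng.normal(size=512)
            modes = afd_decompose(s, AFDConfig(max_levels=30), fps=FPS)
            psi_e = modes.extras["analytic_energy"]
            comp_e = sum(np.sum(np.abs(c) ** 2)
                         for c in modes.extras["complex_components"])
            rem_e = np.sum(np.abs(modes.extras["complex_remainder"]) ** 2)
            assert abs(psi_e - comp_e - rem_e) / psi_e < 1e-6

    def test_remainder_energy_monotone_over_levels(self, rng):
        s = rng.normal(size=512)
        modes = afd_decompose(s, AFDConfig(max_levels=40), fps=FPS)
        trace = modes.extras["remainder_energy_trace"]
        assert all(b <= a + 1e-9 * trace[0] for a, b in zip(trace, trace[1:]))

    def test_two_tone_mixture_splits_into_tone_components(self):
        s = generate_tone_mixture([0.25, 1.2], [1.0, 1.0], FPS, 60.0, seed=1)
        modes = afd_decompose(s, fps=FPS)
        top2 = np.argsort(modes.energies)[::-1][:2]
        doms = sorted(_dominant_freq(modes.components[i]) for i in top2)
        bin_hz = FPS / len(s)
        assert abs(doms[0] - 0.25) <= bin_hz
        assert abs(doms[1] - 1.2) <= bin_hz

    def test_reconstruction_identity(self, rng):
        s = rng.normal(size=256)
        modes = afd_decompose(s, AFDConfig(max_levels=20), fps=FPS)
        assert np.allclose(modes.reconstruction(), s, atol=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="magnitudes"):
            AFDConfig(magnitudes=()).validate()


class TestHVD:
    def test_single_tone_is_one_mono_component(self):
        s = generate_tone_mixture([1.2], [1.0], FPS, 60.0, seed=5)
        modes = hvd_decompose(s, HVDConfig(n_components=1), fps=FPS)
        assert np.sum(modes.remainder ** 2) / np.sum(s ** 2) < 1e-3

    def test_largest_amplitude_extracted_first(self):
        s = generate_tone_mixture([0.3, 1.5], [3.0, 1.0], FPS, 60.0, seed=4)
        modes = hvd_decompose(s, HVDConfig(n_components=2), fps=FPS)
        assert modes.center_freqs[0] == pytest.approx(0.3, rel=0.02)
        assert modes.center_freqs[1] == pytest.approx(1.5, rel=0.02)

    def test_reconstruction_is_exact_bookkeeping(self, rng):
        s = rng.normal(size=512)
        modes = hvd_decompose(s, HVDConfig(n_components=2), fps=FPS)
        err = np.linalg.norm(modes.reconstruction() - s) / np.linalg.norm(s)
        assert err < 1e-9

    def test_three_tone_extraction_quality(self):
        s = generate_tone_mixture([0.25, 1.2, 2.5], [3.0, 2.0, 1.0], FPS,
                                  60.0, seed=2)
        modes = hvd_decompose(s, HVDConfig(n_components=3), fps=FPS)
        assert np.sum(modes.remainder ** 2) / np.sum(s ** 2) < 0.01

    def test_zero_signal_reports_envelope_collapse(self):
        modes = hvd_decompose(np.zeros(256), HVDConfig(n_components=1), fps=FPS)
        assert modes.extras["status"] == "envelope_collapse"
        assert not modes.converged


class TestVMD:
    def test_two_tone_center_frequencies(self):
        s = generate_tone_mixture([0.25, 1.2], [1.0, 1.0], FPS, 60.0, seed=1)
        modes = vmd_decompose(s, VMDConfig(n_modes=2), fps=FPS)
        assert modes.center_freqs[0] == pytest.approx(0.25, rel=0.02)
        assert modes.center_freqs[1] == pytest.approx(1.2, rel=0.02)

    def test_single_mode_on_single_tone(self):
        s = generate_tone_mixture([1.2], [1.0], FPS, 30.0, seed=3)
        modes = vmd_decompose(s, VMDConfig(n_modes=1), fps=FPS)
        bin_hz = FPS / len(s)
        assert abs(modes.center_freqs[0] - 1.2) <= bin_hz
        corr = np.corrcoef(modes.components[0], s)[0, 1]
        assert corr > 0.99

    def test_reconstruction_energy(self):
        s = generate_tone_mixture([0.25, 1.2], [1.0, 1.0], FPS, 60.0, seed=1)
        modes = vmd_decompose(s, VMDConfig(n_modes=2), fps=FPS)
        resid = np.sum((s - sum(modes.components)) ** 2) / np.sum(s ** 2)
        assert resid < 0.05

    def test_bandwidth_penalty_narrows_modes(self):
        """Higher alpha_bw concentrates each mode around its center."""
        s = generate_tone_mixture([0.25, 1.2], [1.0, 1.0], FPS, 60.0, seed=1)
        fracs = []
        for alpha in (200.0, 2000.0, 20000.0):
            modes = vmd_decompose(s, VMDConfig(n_modes=2, alpha_bw=alpha),
                                  fps=FPS)
            out = 0.0
            tot = 0.0
            for comp, fc in zip(modes.components, modes.center_freqs):
                spec = np.abs(np.fft.rfft(comp)) ** 2
                freqs = np.fft.rfftfreq(len(comp), d=1 / FPS)
                sel = np.abs(freqs - fc) <= 0.1
                out += spec[~sel].sum()
                tot += spec.sum()
            fracs.append(out / tot)
        assert fracs[0] > fracs[1] > fracs[2]

    def test_auto_mode_count_on_two_tones(self):
        s = generate_tone_mixture([0.25, 1.2], [1.0, 1.0], FPS, 60.0, seed=6)
        modes = vmd_decompose(s, VMDConfig(n_modes=None), fps=FPS)
        assert modes.extras["K"] >= 2
        recovered = sorted(modes.center_freqs)
        assert any(abs(f - 0.25) / 0.25 < 0.05 for f in recovered)
        assert any(abs(f - 1.2) / 1.2 < 0.05 for f in recovered)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="32"):
            vmd_decompose(np.zeros(16), VMDConfig(n_modes=1), fps=FPS)


class TestCenterFrequency:
    def test_pure_tone(self):
        s = generate_tone_mixture([1.2], [1.0], FPS, 60.0, seed=0)
        bin_hz = FPS / len(s)
        assert abs(component_center_frequency(s, FPS) - 1.2) <= bin_hz

    def test_white_noise_centroid_near_quarter_rate(self, rng):
        s = rng.normal(size=8192)
        assert component_center_frequency(s, FPS) == pytest.approx(FPS / 4,
                                                                   rel=0.1)

    def test_equal_tones_average(self):
        s = generate_tone_mixture([0.5, 1.5], [1.0, 1.0], FPS, 120.0, seed=0)
        bin_hz = FPS / len(s)
        assert abs(component_center_frequency(s, FPS) - 1.0) <= 2 * bin_hz

    def test_zero_component_rejected(self):
        with pytest.raises(ValueError, match="zero component"):
            component_center_frequency(np.zeros(64), FPS)


@pytest.mark.parametrize("engine", ["mafd", "ehvd", "ivmd"])
def test_each_engine_isolates_cardiac_and_respiratory_modes(
        engine, standard_trace):
    """Every engine yields a mode at the pulse and one at the breath rate."""
    trace, truth = standard_trace
    x = prepare_signal(trace)
    modes = ENGINES[engine](x, trace.fps_nominal)
    hr_hz, rr_hz = truth.hr_bpm / 60, truth.rr_bpm / 60
    assert any(abs(f - hr_hz) / hr_hz <= 0.05 for f in modes.center_freqs)
    assert any(abs(f - rr_hz) / rr_hz <= 0.10 for f in modes.center_freqs)


@pytest.mark.parametrize("engine", ["mafd", "ehvd", "ivmd"])
def test_component_order_does_not_change_reconstruction(engine, rng):
    s = generate_tone_mixture([0.25, 1.2], [1.0, 1.0], FPS, 30.0,
                              noise_sd=0.1, seed=8)
    modes = ENGINES[engine](s, FPS)
    total = modes.remainder + np.sum(modes.components, axis=0)
    perm = rng.permutation(len(modes.components))
    permuted = modes.remainder + np.sum([modes.components[i] for i in perm],
                                        axis=0)
    assert np.allclose(total, permuted, atol=1e-12)
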