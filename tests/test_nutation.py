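"""Distributions, selection weights, nutation signals and spectrum processing."""

import numpy as np
import pytest

from b1select import (
    MasModulation,
    RfDistribution,
    SelectivePulseSpec,
    make_rf_distribution,
    process_spectrum,
    selection_weights,
    simulate_nutation,
)


class TestDistributions:
    def test_delta_concentrates_on_nearest_grid_point(self):
        dist = make_rf_distribution("delta", 100.2e3, grid=np.arange(10e3, 150e3 + 1, 1e3))
        assert np.count_nonzero(dist.weights) == 1
        assert dist.grid[np.argmax(dist.weights)] == 100e3
        assert dist.weights.sum() == pytest.approx(1.0)

    def test_parametric_mode_placed_at_request(self):
        grid = np.arange(60e3, 150e3 + 1, 500.0)
        dist = make_rf_distribution("parametric", 109e3, width_hz=8e3, skew=-4.0, grid=grid)
        assert dist.grid[np.argmax(dist.weights)] == pytest.approx(109e3, abs=500.0)
        assert dist.weights.sum() == pytest.approx(1.0, abs=1e-12)
        # negative skew: more weight below the mode than above
        below = dist.weights[grid < 109e3 - 8e3].sum()
        above = dist.weights[grid > 109e3 + 8e3].sum()
        assert below > above

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            make_rf_distribution("delta", 100e3, grid=np.array([]))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_rf_distribution("uniformish", 100e3)

    def test_weight_invariants_enforced(self):
        g = np.array([1e3, 2e3])
        with pytest.raises(ValueError):
            RfDistribution("histogram", g, np.array([0.5, 0.6]), 1e3)
        with pytest.raises(ValueError):
            RfDistribution("histogram", g, np.array([1.5, -0.5]), 1e3)


@pytest.fixture(scope="module")
def band_setup():
    from b1select import iburp2_envelope

    spec = SelectivePulseSpec(
        nu_sl=100e3, nu_mod=100e3, tau_p=1e-3, dt=1e-6, envelope=iburp2_envelope()
    )
    grid = np.arange(80e3, 120e3 + 1, 1e3)
    dist = make_rf_distribution("parametric", 100e3, width_hz=5e3, grid=grid)
    return spec, dist


class TestSelectionWeights:

    def test_plain_weights_are_unity(self, band_setup):
        spec, dist = band_setup
        assert np.all(selection_weights(spec, dist, "plain") == 1.0)

    def test_selected_weight_at_band_center(self, band_setup):
        spec, dist = band_setup
        w = selection_weights(spec, dist, "selected")
        assert w[dist.grid == 100e3][0] <= -0.98

    def test_difference_weight_two_in_band_zero_outside(self, band_setup):
        spec, dist = band_setup
        w = selection_weights(spec, dist, "difference")
        assert w[dist.grid == 100e3][0] == pytest.approx(2.0, abs=0.04)
        far = (dist.grid < 88e3) | (dist.grid > 112e3)
        assert np.abs(w[far]).max() < 0.11

    def test_linearity_plain_equals_selected_plus_difference(self, band_setup):
        spec, dist = band_setup
        sel = selection_weights(spec, dist, "selected")
        diff = selection_weights(spec, dist, "difference")
        assert np.allclose(sel + diff, 1.0, atol=1e-12)

    def test_unknown_mode_rejected(self, band_setup):
        spec, dist = band_setup
        with pytest.raises(ValueError):
            selection_weights(spec, dist, "subtracted")


class TestNutationSpectra:
    def test_delta_distribution_peaks_at_its_frequency(self):
        dist = make_rf_distribution("delta", 100e3, grid=np.arange(10e3, 150e3 + 1, 1e3))
        res = simulate_nutation(dist, np.ones(dist.grid.size), t1_points=512, dwell=3.5e-6)
        bin_hz = res.freq_hz[1] - res.freq_hz[0]
        assert res.freq_hz[np.argmax(res.spectrum)] == pytest.approx(100e3, abs=bin_hz)

    def test_parametric_distribution_peaks_at_mode(self):
        dist = make_rf_distribution(
            "parametric", 109e3, width_hz=8e3, skew=-4.0, grid=np.arange(60e3, 150e3 + 1, 500.0)
        )
        res = simulate_nutation(dist, np.ones(dist.grid.size))
        assert res.freq_hz[np.argmax(res.spectrum)] == pytest.approx(109e3, abs=1e3)

    def test_mas_modulation_produces_rotor_sidebands(self):
        grid = np.arange(10e3, 150e3 + 1, 1e3)
        dist = make_rf_distribution("delta", 100e3, grid=grid).with_modulation(
            MasModulation(rotor_freq_hz=30e3, amp_mod_depth=0.1, fraction_modulated=1.0)
        )
        res = simulate_nutation(dist, np.ones(grid.size), t1_points=512, dwell=3.5e-6)
        mag = np.abs(res.spectrum)

        def peak_near(f0):
            sel = np.abs(res.freq_hz - f0) < 2e3
            return mag[sel].max()

        floor = np.median(mag)
        assert peak_near(70e3) > 10 * floor
        assert peak_near(130e3) > 10 * floor
        assert peak_near(100e3) > peak_near(70e3)

    def test_spectrum_supported_only_on_distribution(self):
        """Without modulation, intensity far from the distribution is window leakage."""
        dist = make_rf_distribution(
            "parametric", 100e3, width_hz=3e3, grid=np.arange(80e3, 120e3 + 1, 500.0)
        )
        res = simulate_nutation(dist, np.ones(dist.grid.size))
        mag = np.abs(res.spectrum)
        far = (res.freq_hz > 10e3) & (res.freq_hz < 60e3)
        assert mag[far].max() < 0.01 * mag.max()

    def test_acquisition_mode_linearity_spectrum_level(self):
        from b1select import iburp2_envelope

        spec = SelectivePulseSpec(
            nu_sl=100e3, nu_mod=100e3, tau_p=1e-3, dt=1e-6, envelope=iburp2_envelope()
        )
        grid = np.arange(85e3, 115e3 + 1, 1e3)
        dist = make_rf_distribution("parametric", 102e3, width_hz=4e3, grid=grid)
        runs = {
            mode: simulate_nutation(dist, selection_weights(spec, dist, mode), t1_points=128)
            for mode in ("plain", "selected", "difference")
        }
        assert np.allclose(
            runs["plain"].spectrum,
            runs["selected"].spectrum + runs["difference"].spectrum,
            atol=1e-9,
        )

    def test_difference_integral_counts_band_mass_twice(self):
        from b1select import iburp2_envelope

        spec = SelectivePulseSpec(
            nu_sl=100e3, nu_mod=100e3, tau_p=1e-3, dt=1e-6, envelope=iburp2_envelope()
        )
        # narrow distribution fully inside the inversion band
        grid = np.arange(96e3, 104e3 + 1, 250.0)
        dist = make_rf_distribution("parametric", 100e3, width_hz=800.0, grid=grid)
        w = selection_weights(spec, dist, "difference")
        ratio = float(np.sum(dist.weights * w))  # signal integral ratio vs plain (=1)
        assert 1.8 <= ratio <= 2.0

    def test_too_few_points_rejected(self):
        dist = make_rf_distribution("delta", 100e3)
        with pytest.raises(ValueError):
            simulate_nutation(dist, np.ones(dist.grid.size), t1_points=1)


class TestProcessing:
    def test_constant_signal_transforms_to_zero_frequency(self):
        freq, spec = process_spectrum(np.ones(64), 3.5e-6, apodization="none")
        assert np.argmax(np.abs(spec)) == 0

    def test_cosine_signal_peaks_at_its_frequency(self):
        dwell = 3.5e-6
        t = np.arange(256) * dwell
        freq, spec = process_spectrum(np.cos(2 * np.pi * 100e3 * t), dwell)
        bin_hz = freq[1] - freq[0]
        assert freq[np.argmax(spec)] == pytest.approx(100e3, abs=bin_hz)

    def test_parseval_identity_one_sided(self):
        """Energy of the windowed, padded signal equals one-sided spectrum energy."""
        from b1select.nutation import cosine_squared_window

        rng = np.random.default_rng(7)
        sig = rng.normal(size=200)
        n = 4096
        freq, spec = process_spectrum(sig, 1e-6, zero_fill_to=n, return_complex=True)
        windowed = sig * cosine_squared_window(sig.size)
        windowed[0] *= 0.5  # first-point scaling applied by process_spectrum
        time_energy = np.sum(windowed**2)
        freq_energy = (
            np.abs(spec[0]) ** 2 + 2 * np.sum(np.abs(spec[1:-1]) ** 2) + np.abs(spec[-1]) ** 2
        ) / n
        assert freq_energy == pytest.approx(time_energy, rel=1e-9)

    def test_zero_fill_shorter_than_signal_rejected(self):
        with pytest.raises(ValueError):
            process_spectrum(np.ones(64), 1e-6, zero_fill_to=32)

    def test_unknown_apodization_rejected(self):
        with pytest.raises(ValueError):
            process_spectrum(np.ones(64), 1e-6, apodization="gauss")
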