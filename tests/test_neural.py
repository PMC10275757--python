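"""Unit tests of the spike-train and ECoG response metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonosim.neural import (
    EcogRecording,
    SL_LL_THRESHOLD,
    activated_density,
    centre_displacement,
    ecog_activation_map,
    evoked_potential,
    fano_factor,
    response_centre,
    response_dominance_index,
    response_duration,
    response_latency,
    spatial_dispersion,
    spike_density_function,
)


def _burst_trains(rng, n_trials, latency, duration, peak, baseline=2.0):
    """Baseline + rectangular response starting at `latency` after t=0."""
    trains = []
    for _ in range(n_trials):
        base = rng.uniform(-0.2, 0.2, rng.poisson(baseline * 0.4))
        resp = rng.uniform(latency, latency + duration, rng.poisson(peak * duration))
        trains.append(np.sort(np.concatenate([base, resp])))
    return trains


class TestSDF:
    def test_single_spike_is_unit_mass_kernel_at_spike(self):
        t, sdf = spike_density_function(
            [np.array([0.05])], t_start=0.0, t_stop=0.1, dt=1e-3
        )
        assert t[np.argmax(sdf)] == pytest.approx(0.05, abs=1e-3)
        assert np.trapezoid(sdf, t) == pytest.approx(1.0, rel=1e-3)

    def test_poisson_rate_recovery(self, rng):
        rate, t_stop = 40.0, 20.0
        spikes = np.sort(rng.uniform(0, t_stop, rng.poisson(rate * t_stop)))
        t, sdf = spike_density_function([spikes], t_start=0, t_stop=t_stop)
        # interior average (clear of edge truncation)
        inner = (t > 0.5) & (t < t_stop - 0.5)
        assert sdf[inner].mean() == pytest.approx(rate, rel=0.05)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=10e-3))
    def test_mass_conserved_across_kernel_widths(self, sigma):
        spikes = np.array([0.02, 0.05, 0.051, 0.09])
        t, sdf = spike_density_function(
            [spikes], t_start=-0.1, t_stop=0.2, kernel_sigma=sigma
        )
        assert np.trapezoid(sdf, t) == pytest.approx(len(spikes), rel=1e-2)

    def test_empty_train_gives_zero_trace(self):
        t, sdf = spike_density_function([np.array([])], t_start=0, t_stop=0.1)
        assert np.all(sdf == 0)


class TestLatency:
    def test_recovers_short_latency_within_kernel_width(self, rng):
        trains = _burst_trains(rng, n_trials=50, latency=0.012, duration=0.05, peak=60)
        t, sdf = spike_density_function(trains, t_start=-0.2, t_stop=0.2)
        lat = response_latency(t, sdf, 0.0, window=0.1)
        assert lat == pytest.approx(0.012, abs=3e-3)  # one kernel sigma

    def test_long_latency_classified_ll_at_threshold(self, rng):
        trains = _burst_trains(rng, n_trials=50, latency=0.050, duration=0.05, peak=60)
        t, sdf = spike_density_function(trains, t_start=-0.2, t_stop=0.2)
        lat = response_latency(t, sdf, 0.0, window=0.15)
        assert lat > SL_LL_THRESHOLD
        assert lat == pytest.approx(0.050, abs=3e-3)

    def test_time_shift_equivariance(self, rng):
        trains = _burst_trains(rng, n_trials=50, latency=0.02, duration=0.05, peak=60)
        shift = 0.123
        shifted = [tr + shift for tr in trains]
        t1, s1 = spike_density_function(trains, t_start=-0.2, t_stop=0.2)
        t2, s2 = spike_density_function(
            shifted, t_start=-0.2 + shift, t_stop=0.2 + shift
        )
        l1 = response_latency(t1, s1, 0.0, window=0.1)
        l2 = response_latency(t2, s2, shift, window=0.1)
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_flat_trace_returns_nan(self):
        t = np.linspace(-0.1, 0.1, 201)
        assert np.isnan(response_latency(t, np.ones_like(t), 0.0))


class TestDuration:
    def test_gaussian_sdf_closed_form(self):
        # A Gaussian falls to A/e at sqrt(2)*sigma: duration = 2 sqrt(2) sigma
        sigma = 0.02
        t = np.linspace(-0.2, 0.2, 4001)
        sdf = 50 * np.exp(-(t**2) / (2 * sigma**2))
        d, censored = response_duration(t, sdf)
        assert not censored
        assert d == pytest.approx(2 * np.sqrt(2) * sigma, rel=1e-3)

    def test_scale_invariance(self):
        t = np.linspace(-0.2, 0.2, 2001)
        sdf = np.exp(-(t**2) / (2 * 0.03**2))
        d1, _ = response_duration(t, sdf)
        d2, _ = response_duration(t, 7.3 * sdf)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_rectangular_response_width_recovered(self, rng):
        length = 0.08
        trains = _burst_trains(
            rng, n_trials=80, latency=0.0, duration=length, peak=100, baseline=0.5
        )
        t, sdf = spike_density_function(
            trains, t_start=-0.2, t_stop=0.3, kernel_sigma=2e-3
        )
        d, censored = response_duration(t, sdf)
        assert not censored
        assert d == pytest.approx(length, rel=0.10)

    def test_right_censoring_flagged(self):
        t = np.linspace(0, 0.1, 101)
        sdf = np.linspace(1.0, 2.0, 101)  # still rising at window end
        d, censored = response_duration(t, sdf)
        assert censored


class TestFano:
    def test_poisson_counts_near_unity(self, rng):
        counts = rng.poisson(12.0, size=500)
        assert fano_factor(counts) == pytest.approx(1.0, abs=0.15)

    def test_deterministic_counts_zero(self):
        assert fano_factor([5, 5, 5, 5]) == 0.0

    def test_hand_computed_value(self):
        # counts {2,4,6,8}: unbiased variance 20/3, mean 5 -> 4/3
        assert fano_factor([2, 4, 6, 8]) == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_zero_mean_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(fano_factor([0, 0, 0]))


class TestSpatialMetrics:
    def test_coincident_cells_zero_dispersion(self):
        pos = np.zeros((5, 2))
        assert spatial_dispersion(pos, [1, 2, 3, 4, 5]) == 0.0

    def test_two_equal_weight_cells_distance_apart(self):
        pos = np.array([[0.0, 0.0], [0.0, 1.5e-3]])
        assert spatial_dispersion(pos, [3.0, 3.0]) == pytest.approx(1.5e-3)

    def test_dispersion_grows_with_footprint(self, rng):
        disp = []
        for sigma in (0.2e-3, 0.8e-3, 2e-3):
            pos = rng.normal(0.0, sigma, size=(200, 2))
            disp.append(spatial_dispersion(pos))
        assert disp[0] < disp[1] < disp[2]

    def test_centre_of_symmetric_footprint(self, rng):
        centre = np.array([0.3e-3, -0.2e-3])
        pos = centre + rng.normal(0, 0.2e-3, size=(400, 2))
        w = np.exp(-np.sum((pos - centre) ** 2, axis=1) / (2 * (0.2e-3) ** 2))
        got = response_centre(pos, w)
        assert np.linalg.norm(got - centre) < 0.05e-3

    def test_single_unit_centre_is_its_position(self):
        got = response_centre(np.array([[1e-3, 2e-3]]), [5.0])
        np.testing.assert_allclose(got, [1e-3, 2e-3])

    def test_centre_displacement_basics(self):
        assert centre_displacement([0, 0], [0, 0]) == 0.0
        assert centre_displacement([0, 0], [0, 0.4e-3]) == pytest.approx(0.4e-3)

    def test_activated_density_area_selection(self):
        # high frequency uses the focal-spot area, 0.5 MHz the array area
        assert activated_density(10, 15e6, 1e-6, 9e-6) == pytest.approx(1e7)
        assert activated_density(10, 0.5e6, 1e-6, 9e-6) == pytest.approx(10 / 9e-6)
        assert activated_density(0, 15e6, 1e-6, 9e-6) == 0.0

    def test_focal_disc_area_from_fwhm(self):
        # density over the pi (FWHM/2)^2 disc of the 15 MHz focal spot
        fwhm = 0.276e-3
        area = np.pi * (fwhm / 2) ** 2
        assert activated_density(6, 15e6, area, 9e-6) == pytest.approx(6 / area)


class TestDominanceIndex:
    @pytest.mark.parametrize(
        "on,off,expected",
        [(30.0, 0.0, 1.0), (10.0, 10.0, 0.0), (30.0, 10.0, 0.5), (0.0, 5.0, -1.0)],
    )
    def test_values(self, on, off, expected):
        assert response_dominance_index(on, off) == pytest.approx(expected)

    def test_no_response_is_nan(self):
        assert np.isnan(response_dominance_index(0.0, 0.0))


def _ecog_with_template(rng, amps, fs=1000.0, n_trials=40, noise=2e-6):
    n_ch = len(amps)
    coords = np.array([[i * 3e-4, j * 3e-4] for j in range(2) for i in range(3)])
    onsets = 1.0 + np.arange(n_trials) * 0.8
    n_samp = int((onsets[-1] + 0.8) * fs)
    data = rng.normal(0, noise, size=(n_ch, n_samp))
    t_rel = np.arange(int(0.1 * fs)) / fs
    template = -np.exp(-((t_rel - 0.03) ** 2) / (2 * 0.008**2))
    for onset in onsets:
        i0 = int(onset * fs)
        data[:, i0 : i0 + t_rel.size] += np.asarray(amps)[:, None] * template
    positions = pd.DataFrame(
        {"channel": np.arange(n_ch), "x": coords[:, 0], "y": coords[:, 1]}
    )
    return EcogRecording(data=data, fs=fs, positions=positions, trial_onsets=onsets)


class TestEvokedPotential:
    def test_recovers_template_amplitude(self, rng):
        amps = np.array([30e-6, 15e-6, 5e-6, 0.0, 0.0, 0.0])
        rec = _ecog_with_template(rng, amps)
        ev = evoked_potential(rec)
        np.testing.assert_allclose(ev.n1_amplitude[:3], amps[:3], rtol=0.12)

    def test_noise_only_channels_below_threshold(self, rng):
        rec = _ecog_with_template(rng, np.zeros(6), noise=3e-6)
        ev = evoked_potential(rec)
        # N1 of pure noise stays below the 2 s.d. activation threshold
        assert np.all(ev.n1_amplitude < 2 * ev.noise_sd)

    def test_averaging_identical_trials_preserves_amplitude(self):
        rng = np.random.default_rng(3)
        amps = np.full(6, 20e-6)
        rec_few = _ecog_with_template(rng, amps, n_trials=10, noise=0.0)
        rec_many = _ecog_with_template(rng, amps, n_trials=80, noise=0.0)
        a1 = evoked_potential(rec_few).n1_amplitude
        a2 = evoked_potential(rec_many).n1_amplitude
        np.testing.assert_allclose(a1, a2, rtol=1e-9)


class TestActivationMap:
    def _grid_coords(self, n=5, pitch=3e-4):
        return np.array(
            [[i * pitch, j * pitch] for j in range(n) for i in range(n)], dtype=float
        )

    def test_uniform_amplitude_activates_full_hull(self):
        coords = self._grid_coords()
        amap = ecog_activation_map(np.full(25, 3.0), coords, noise_sd=1.0)
        hull_area = (4 * 3e-4) ** 2
        assert amap.activated_area == pytest.approx(hull_area, rel=0.05)

    def test_all_zero_map_has_no_area_and_no_centre(self):
        coords = self._grid_coords()
        amap = ecog_activation_map(np.zeros(25), coords, noise_sd=1.0)
        assert amap.activated_area == 0.0
        assert amap.centre is None

    def test_area_monotone_in_footprint_amplitude(self):
        coords = self._grid_coords()
        d2 = np.sum((coords - coords.mean(axis=0)) ** 2, axis=1)
        shape = np.exp(-d2 / (2 * (3e-4) ** 2))
        areas = [
            ecog_activation_map(a * shape, coords, noise_sd=1.0).activated_area
            for a in (3.0, 6.0, 12.0)
        ]
        assert areas[0] < areas[1] < areas[2]

    def test_centre_tracks_footprint_peak(self):
        coords = self._grid_coords()
        peak = np.array([2 * 3e-4, 2 * 3e-4])
        d2 = np.sum((coords - peak) ** 2, axis=1)
        amap = ecog_activation_map(10 * np.exp(-d2 / (2 * (3e-4) ** 2)), coords, 1.0)
        assert np.linalg.norm(amap.centre - peak) < 1.5e-4  # half a pitch

    def test_collinear_layout_rejected(self):
        coords = np.array([[0.0, 0.0], [1e-3, 0.0], [2e-3, 0.0]])
        with pytest.raises(ValueError, match="need >= 3|degenerate"):
            ecog_activation_map(np.ones(3), coords, 1.0)
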