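"""Time-domain transform, arrival-time estimation, inversion and mapping."""

import math

import numpy as np
import pytest

from tmscan import (
    FreqSweep,
    GridSpec,
    TransformParams,
    estimate_arrival_time,
    estimate_path_permittivity,
    homogeneous_phantom,
    inverse_czt,
    map_paths_to_image,
    reconstruct_phantom,
    to_time_domain,
)
from tmscan.forward import PathPair, PathSpectrum, reference_spectra, simulate_scan_spectra
from tmscan.grid import C_MM_PER_NS
from tmscan.recon import PathPermittivity, TimeSignal, reconstruct_scan


def _pure_delay_spectrum(sweep, tau_ns):
    f = sweep.frequencies_ghz
    window = np.hanning(sweep.n_points + 2)[1:-1]
    return PathSpectrum(None, sweep, window * np.exp(-2j * np.pi * f * tau_ns))


class TestInverseCzt:
    def test_degenerate_matches_inverse_dft(self, rng):
        """On a uniform full-band grid the zoom transform is K * ifft."""
        K = 128
        df = 0.0625
        spec = rng.standard_normal(K) + 1j * rng.standard_normal(K)
        got = inverse_czt(spec, 0.0, df, 0.0, 1.0 / (K * df), K)
        want = K * np.fft.ifft(spec)
        assert np.max(np.abs(got - want)) / np.max(np.abs(want)) < 1e-9

    def test_batched_rows_match_single(self, rng):
        spec = rng.standard_normal((4, 64)) + 1j * rng.standard_normal((4, 64))
        batch = inverse_czt(spec, 0.1, 0.05, 0.0, 0.01, 100)
        for i in range(4):
            single = inverse_czt(spec[i], 0.1, 0.05, 0.0, 0.01, 100)
            assert np.allclose(batch[i], single, atol=1e-12)


class TestToTimeDomain:
    def test_zero_spectrum_gives_zero_signal(self, sweep):
        spec = PathSpectrum(None, sweep, np.zeros(sweep.n_points, dtype=complex))
        sig = to_time_domain(spec)
        assert np.all(sig.amplitude == 0)

    def test_pure_delay_peaks_at_tau(self, sweep):
        params = TransformParams(0.0, 3.0, 1024)
        sig = to_time_domain(_pure_delay_spectrum(sweep, 0.5), params)
        step = sig.times_ns[1] - sig.times_ns[0]
        assert abs(sig.times_ns[np.argmax(sig.amplitude)] - 0.5) <= step

    def test_delay_outside_window_flagged(self, sweep):
        params = TransformParams(0.0, 0.3, 64)
        sig = to_time_domain(_pure_delay_spectrum(sweep, 0.5), params)
        assert sig.peak_at_edge


class TestArrivalTime:
    def test_on_grid_pulse(self, sweep):
        sig = to_time_domain(_pure_delay_spectrum(sweep, 0.5), TransformParams(0.0, 3.0, 1024))
        assert estimate_arrival_time(sig) == pytest.approx(0.5, abs=1e-3)

    def test_between_sample_pulse_beats_grid_resolution(self, sweep):
        """Parabolic refinement versus a brute-force 100x oversampled argmax."""
        params = TransformParams(0.0, 3.0, 256)
        tau = 0.5012345  # off-grid for the coarse window
        spec = _pure_delay_spectrum(sweep, tau)
        sig = to_time_domain(spec, params)
        coarse_step = sig.times_ns[1] - sig.times_ns[0]
        fine = to_time_domain(spec, TransformParams(0.0, 3.0, 25600))
        t_oracle = fine.times_ns[np.argmax(fine.amplitude)]
        refined = estimate_arrival_time(sig)
        assert abs(refined - t_oracle) < coarse_step / 2
        discrete = sig.times_ns[np.argmax(sig.amplitude)]
        assert abs(refined - tau) <= abs(discrete - tau) + 1e-12

    def test_global_maximum_rule(self):
        t = np.linspace(0, 3, 301)
        amp = np.exp(-((t - 1.0) ** 2) / 0.01) + 0.5 * np.exp(-((t - 2.0) ** 2) / 0.01)
        sig = TimeSignal(t, amp)
        assert estimate_arrival_time(sig) == pytest.approx(1.0, abs=0.01)

    def test_zero_signal_raises(self):
        sig = TimeSignal(np.linspace(0, 1, 16), np.zeros(16))
        with pytest.raises(ValueError, match="no peak"):
            estimate_arrival_time(sig)


class TestPermittivityInversion:
    def test_zero_delay_is_air(self):
        eps, clamped = estimate_path_permittivity(0.0, 0.0, 50.0)
        assert eps == 1.0 and not clamped

    @pytest.mark.parametrize(
        "d,tau_factor,expected",
        [(50.0, 2.0, 9.0), (60.0, 1.0, 4.0)],
    )
    def test_slab_inversion(self, d, tau_factor, expected):
        """dt = d (sqrt(eps)-1)/c inverts back to eps for an aligned pair."""
        dt = d * tau_factor / C_MM_PER_NS
        eps, clamped = estimate_path_permittivity(dt, 0.0, d)
        assert eps == pytest.approx(expected, rel=1e-12)
        assert not clamped

    def test_negative_delay_clamped(self):
        eps, clamped = estimate_path_permittivity(-0.01, 0.0, 50.0)
        assert eps == 1.0 and clamped

    def test_oblique_inversion_consistent(self):
        offset, d, true_eps = 20.0, 50.0, 9.0
        length = math.hypot(d, offset)
        dt = length * (math.sqrt(true_eps) - 1) / C_MM_PER_NS
        eps, _ = estimate_path_permittivity(dt, offset, d)
        assert eps == pytest.approx(true_eps, rel=1e-12)


class TestFootprintMapping:
    GRID = GridSpec(40.0, 40.0, 2.0)

    def _est(self, x, y, eps):
        pair = PathPair(0, 0, (x, y), (x, y))
        return PathPermittivity(pair, 0.1, eps)

    def test_single_estimate_paints_disk(self):
        img = map_paths_to_image([self._est(20.0, 20.0, 9.0)], self.GRID, 6.0)
        covered = img.coverage > 0
        assert covered.any()
        assert np.all(img.epsilon_map[covered] == 9.0)
        assert np.all(img.epsilon_map[~covered] == 1.0)
        assert np.all(img.coverage[covered] == 1)

    def test_overlap_takes_mean(self):
        img = map_paths_to_image(
            [self._est(18.0, 20.0, 4.0), self._est(22.0, 20.0, 16.0)], self.GRID, 6.0
        )
        both = img.coverage == 2
        assert both.any()
        assert np.allclose(img.epsilon_map[both], 10.0)

    def test_disk_coverage_matches_bruteforce(self):
        center, radius = (21.0, 17.0), 6.0
        img = map_paths_to_image([self._est(*center, 9.0)], self.GRID, radius)
        x, y = self.GRID.pixel_centers()
        for iy in range(self.GRID.ny):
            for ix in range(self.GRID.nx):
                inside = (x[ix] - center[0]) ** 2 + (y[iy] - center[1]) ** 2 <= radius**2
                assert bool(img.coverage[iy, ix]) == inside

    def test_footprint_outside_grid_skipped(self):
        img = map_paths_to_image(
            [self._est(20.0, 20.0, 9.0), self._est(500.0, 500.0, 16.0)], self.GRID, 6.0
        )
        assert np.all(img.epsilon_map[img.coverage > 0] == 9.0)

    def test_empty_estimates_rejected(self):
        with pytest.raises(ValueError):
            map_paths_to_image([], self.GRID)


class TestReconstructScan:
    def test_homogeneous_roundtrip(self, small_grid, sweep, small_paths):
        ph = homogeneous_phantom(small_grid, 9.0, 50.0)
        img = reconstruct_phantom(ph, small_paths, sweep)
        vals = img.epsilon_map[img.coverage > 0]
        assert np.max(np.abs(vals - 9.0)) / 9.0 < 0.02

    def test_air_phantom_reconstructs_to_one(self, small_grid, sweep, small_paths):
        ph = homogeneous_phantom(small_grid, 1.0, 60.0)
        img = reconstruct_phantom(ph, small_paths, sweep)
        assert np.allclose(img.epsilon_map, 1.0, atol=0.01)

    def test_inclusion_raises_local_mean(self, small_grid, sweep, small_paths):
        ph = homogeneous_phantom(small_grid, 4.0, 50.0)
        ph.epsilon_map[8:12, 10:20] = 16.0  # x in [20,40], y in [16,24]
        img = reconstruct_phantom(ph, small_paths, sweep)
        inc = np.zeros(small_grid.shape, dtype=bool)
        inc[8:12, 10:20] = True
        covered = img.coverage > 0
        assert img.epsilon_map[inc & covered].mean() > img.epsilon_map[~inc & covered].mean()

    def test_order_independent(self, small_grid, sweep, small_paths, rng):
        ph = homogeneous_phantom(small_grid, 4.0, 50.0)
        ph.epsilon_map[5:10, 5:10] = 9.0
        spectra = simulate_scan_spectra(ph, small_paths, sweep)
        offs = np.array([p.offset_mm for p in small_paths])
        refs = reference_spectra(50.0, offs, sweep)
        img1 = reconstruct_scan(spectra, refs, small_paths, 50.0, sweep, small_grid)
        perm = rng.permutation(len(small_paths))
        pairs2 = [small_paths[i] for i in perm]
        img2 = reconstruct_scan(spectra[perm], refs[perm], pairs2, 50.0, sweep, small_grid)
        assert np.allclose(img1.epsilon_map, img2.epsilon_map, atol=1e-12)

    def test_pointwise_monotonicity(self, small_grid, sweep, small_paths):
        lo = homogeneous_phantom(small_grid, 4.0, 50.0)
        hi = homogeneous_phantom(small_grid, 4.0, 50.0)
        hi.epsilon_map[6:14, 8:22] = 6.0
        img_lo = reconstruct_phantom(lo, small_paths, sweep)
        img_hi = reconstruct_phantom(hi, small_paths, sweep)
        covered = img_lo.coverage > 0
        assert np.all(img_hi.epsilon_map[covered] >= img_lo.epsilon_map[covered] - 1e-9)

    def test_missing_reference_rejected(self, small_grid, sweep, small_paths):
        ph = homogeneous_phantom(small_grid, 4.0, 50.0)
        spectra = simulate_scan_spectra(ph, small_paths, sweep)
        with pytest.raises(ValueError, match="reference"):
            reconstruct_scan(spectra, None, small_paths, 50.0, sweep, small_grid)

    def test_noise_perturbation_bounded(self, small_grid, sweep):
        """100 seeded noisy paths at 30 dB move a uniform eps=9 slab < 5%."""
        ph = homogeneous_phantom(small_grid, 9.0, 50.0)
        from tmscan import build_array, enumerate_paths

        pairs = enumerate_paths(build_array(small_grid, 50.0))[:100]
        img = reconstruct_phantom(ph, pairs, sweep, snr_db=30.0, seed=21)
        vals = img.epsilon_map[img.coverage > 0]
        assert np.max(np.abs(vals - 9.0)) / 9.0 < 0.05
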