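import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import tdraman as td
import tdraman.raman as rr
from tdraman.units import au_to_cm1, cm1_to_au, ev_to_au, fs_to_au


def const_amplitude_trajectory(model, amp=0.01, n=4096, dt=4.0):
    """Hand-built trajectory: single excited state with constant modulus."""
    times = np.arange(n) * dt
    c = np.zeros((n, model.n_states), dtype=complex)
    ej = model.energies[model.excited_indices[0]]
    c[:, model.excited_indices[0]] = amp * np.exp(-1j * ej * times)
    c[:, 0] = np.sqrt(1 - amp**2)
    grid = td.PropagationGrid(dt, (n - 1), 1)
    return td.CoefficientTrajectory(times, c, grid), ej


class TestSecondOrderMap:
    def test_zero_field_gives_zero_scattering(self, demo):
        grid = td.PropagationGrid(1.0, 4000, 8)
        pulse = td.GaussianPulse(0.0, 500.0, 0.0, demo.zero_zero_energy)
        traj = td.propagate_first_order(demo, pulse, grid)
        b, _ = rr.second_order_map(traj, demo, [2000.0],
                                   omega_window=(0.05, 0.11))
        assert np.all(b == 0.0)

    def test_observation_time_outside_run_rejected(self, demo):
        grid = td.PropagationGrid(1.0, 800, 8)
        pulse = td.GaussianPulse(0.0, 500.0, 0.0, demo.zero_zero_energy)
        traj = td.propagate_first_order(demo, pulse, grid)
        with pytest.raises(ValueError, match="observation time"):
            rr.second_order_map(traj, demo, [5000.0], omega_window=(0.05, 0.11))

    def test_constant_amplitude_gives_sinc_line(self, demo):
        traj, ej = const_amplitude_trajectory(demo)
        window = (ej - 0.02, ej + 0.005)
        t_total = traj.times[-1]
        def fwhm_interp(om, mag):
            half = mag.max() / 2
            above = np.flatnonzero(mag > half)
            i0, i1 = above[0], above[-1]
            left = np.interp(half, [mag[i0 - 1], mag[i0]], [om[i0 - 1], om[i0]])
            right = np.interp(half, [mag[i1 + 1], mag[i1]], [om[i1 + 1], om[i1]])
            return right - left

        results = {}
        for t_obs in (t_total / 2, t_total):
            b, om = rr.second_order_map(traj, demo, [t_obs], window, pad=16)
            mag = np.abs(b[0, 1, 0])  # scattered x, final state |g,1_738>
            center = om[np.argmax(mag)]
            results[t_obs] = (center, fwhm_interp(om, mag))
        grid_step = 2 * np.pi / (16 * len(traj.times) * 4.0)
        for t_obs, (center, fwhm) in results.items():
            # energy conservation: line at E_J - E_N
            assert abs(center - (ej - demo.energies[1])) <= 2 * grid_step
            # finite-window Fourier transform of e^{i w t}: FWHM = 7.582/T
            assert fwhm == pytest.approx(7.5819 / t_obs, rel=0.05)
        assert results[t_total][1] == pytest.approx(results[t_total / 2][1] / 2,
                                                    rel=0.1)


class TestOrientationalAverage:
    def test_isotropic_tensor_has_no_anisotropy(self):
        b = (0.3 + 0.4j) * np.eye(3)
        assert td.combine_tensor(b) == pytest.approx(abs(0.3 + 0.4j) ** 2, rel=1e-12)
        assert td.combine_tensor(np.zeros((3, 3))) == 0.0

    def test_depolarization_ratio_of_traceless_symmetric_tensor(self):
        t = np.array([[1.0, 0.2, 0.0], [0.2, -0.5, 0.1], [0.0, 0.1, -0.5]])
        ratio = (td.combine_tensor(t, rr.PERPENDICULAR_DEPOLARIZED)
                 / td.combine_tensor(t, rr.PARALLEL_POLARIZED))
        assert ratio == pytest.approx(0.75, rel=1e-12)

    def test_matches_monte_carlo_rotation_average(self):
        rng = np.random.default_rng(11)
        t = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        rot = Rotation.random(20_000, rng=rng).as_matrix()
        lab = np.einsum("ria,ab,rjb->rij", rot, t, rot)
        mc = np.mean(np.abs(lab[:, 0, 0]) ** 2 + np.abs(lab[:, 1, 0]) ** 2)
        assert td.combine_tensor(t) == pytest.approx(mc, rel=0.02)

    @given(st.integers(0, 2**31 - 1))
    def test_combined_intensity_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        for setup in (rr.PERPENDICULAR_UNPOLARIZED, rr.PARALLEL_POLARIZED,
                      rr.PERPENDICULAR_DEPOLARIZED):
            assert td.combine_tensor(t, setup) >= -1e-12

    def test_missing_components_rejected(self, demo):
        bad = rr.SecondOrderTensorMap(
            b=np.zeros((3, 2, 1, 1, 4), dtype=complex), omega=np.arange(4.0),
            t_obs=np.array([1.0]), final_states=np.array([0]),
            final_energies=np.array([0.0]))
        with pytest.raises(ValueError):
            rr.combine_setup(bad)


@pytest.fixture(scope="module")
def small_series(demo):
    pulse = td.GaussianPulse(1e-6, fs_to_au(24.0), fs_to_au(96.0),
                             demo.zero_zero_energy - ev_to_au(0.24))
    grid = td.PropagationGrid.from_fs(0.024, 288.0, 8)
    t_obs = [fs_to_au(f) for f in (96.0, 192.0, 240.0, 288.0)]
    return td.time_resolved_spectrum(demo, pulse, grid, t_obs), pulse


class TestCrossSection:
    def test_zero_fluence_rejected(self, demo):
        pulse = td.GaussianPulse(0.0, 100.0, 0.0, 0.08)
        tmap = rr.SecondOrderTensorMap(
            b=np.zeros((3, 3, 1, 1, 4), dtype=complex), omega=np.arange(1.0, 5.0),
            t_obs=np.array([1.0]), final_states=np.array([0]),
            final_energies=np.array([0.0]))
        with pytest.raises(ValueError, match="fluence"):
            rr.cross_section(tmap, pulse)

    def test_nonnegative_and_summed_over_states(self, small_series):
        series, _ = small_series
        assert np.all(series.per_state >= 0.0)
        np.testing.assert_allclose(series.total,
                                   series.per_state.sum(axis=0), rtol=1e-12)

    def test_stokes_lines_at_mode_frequencies(self, small_series, demo):
        # a sigma = 24 fs pulse has ~150 cm^-1 bandwidth and its finite-band
        # response pulls lines toward the carrier by ~1/(sigma^2 Delta); the
        # tight position check lives in the quasi-CW acceptance test
        series, _ = small_series
        shift = series.raman_shift_cm1
        tot = series.total[-1]
        for target in (738.0, 1400.0):
            mask = np.abs(shift - target) < 300.0
            peak = shift[mask][np.argmax(tot[mask])]
            assert abs(peak - target) < 80.0

    def test_raman_plateau_after_pulse(self, small_series):
        series, _ = small_series
        band = td.peak_integral(series, (538.0, 938.0))
        # nonresonant: no more signal accumulates once the pulse is over
        assert abs(band[-1] / band[-2] - 1.0) < 0.01


class TestKHDOracle:
    def test_far_detuning_quadratic_falloff(self, two_level_model):
        w00 = two_level_model.zero_zero_energy
        intensities = []
        for delta in (0.02, 0.04):
            res = td.khd_cross_section(two_level_model, w00 - delta)
            # remove the w_I w_S^3 kinematic factor to isolate |alpha|^2
            intensities.append(res.cross_sections[0]
                               / ((w00 - delta) * res.omega_s[0] ** 3))
        assert intensities[0] / intensities[1] == pytest.approx(4.0, rel=1e-10)

    def test_real_polarizability_off_resonance_without_damping(self, demo):
        res = td.khd_cross_section(demo, demo.zero_zero_energy - ev_to_au(0.3))
        assert np.max(np.abs(res.alpha.imag)) == 0.0

    def test_pole_requires_damping(self, demo):
        with pytest.raises(ValueError, match="pole"):
            td.khd_cross_section(demo, demo.zero_zero_energy)
        res = td.khd_cross_section(demo, demo.zero_zero_energy,
                                   damping=cm1_to_au(10.0))
        assert np.all(np.isfinite(res.cross_sections))


class TestSpectrumPostprocessing:
    def make_series(self, values):
        omega = np.linspace(0.07, 0.09, 201)
        return rr.SpectrumSeries(
            omega=omega, t_obs=np.array([1.0]), per_state=values[None, None, :],
            final_states=np.array([0]), final_energies=np.array([0.0]),
            omega_i=0.088)

    def test_zero_spectrum_integrates_to_zero(self):
        series = self.make_series(np.zeros(201))
        assert td.peak_integral(series, (100.0, 600.0))[0] == 0.0

    def test_band_additivity(self):
        rng = np.random.default_rng(3)
        series = self.make_series(rng.random(201))
        # split at an exact grid node so the two trapezoids tile the union
        shifts = series.raman_shift_cm1
        lo, split, hi = shifts[180], shifts[100], shifts[20]
        a = td.peak_integral(series, (lo, split))
        b = td.peak_integral(series, (split, hi))
        union = td.peak_integral(series, (lo, hi))
        assert a + b == pytest.approx(union, rel=1e-9)

    def test_empty_band_rejected(self):
        series = self.make_series(np.ones(201))
        with pytest.raises(ValueError):
            td.peak_integral(series, (600.0, 100.0))

    def test_average_single_input_is_identity(self):
        series = self.make_series(np.ones(201))
        mean, se = td.average_spectra([series])
        np.testing.assert_array_equal(mean.per_state, series.per_state)
        np.testing.assert_array_equal(se, 0.0)

    def test_average_identical_inputs_zero_error(self):
        series = self.make_series(np.full(201, 2.5))
        mean, se = td.average_spectra([series, series, series])
        np.testing.assert_array_equal(mean.per_state, series.per_state)
        np.testing.assert_array_equal(se, 0.0)

    def test_average_grid_mismatch_rejected(self):
        a = self.make_series(np.ones(201))
        b = self.make_series(np.ones(201))
        b.omega = b.omega + 1e-3
        with pytest.raises(ValueError):
            td.average_spectra([a, b])
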