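"""Generalized 2D correlation: maps, invariants, sign rules, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tristepir as t
from tristepir import twod_correlation as td
from tristepir.errors import DegenerateDataError, ParameterError, RangeError
from tristepir.synthetic_data import Band, band_profile


GRID = np.arange(1000.0, 1200.0, 1.0)
TEMPS = np.linspace(20.0, 120.0, 11)


def _series(profiles_and_bands, offset=0.3, m=11, grid=GRID):
    """Series whose j-th spectrum is offset + sum_i profile_i[j] * band_i."""
    temps = np.linspace(20.0, 120.0, m)
    Y = np.full((m, grid.size), float(offset))
    for profile, band in profiles_and_bands:
        Y += np.outer(np.asarray(profile, float), band_profile(band, grid))
    spectra = tuple(
        t.Spectrum(grid, Y[j], "absorbance", temperature_C=temps[j])
        for j in range(m))
    return t.PerturbationSeries(spectra, temps)


def _brute_force_maps(M):
    """Naive double-loop synchronous/asynchronous maps (the oracle)."""
    m, n = M.shape
    N = td.hilbert_noda_matrix(m)
    phi = np.empty((n, n))
    psi = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            phi[i, j] = np.dot(M[:, i], M[:, j]) / (m - 1)
            psi[i, j] = np.dot(M[:, i], N @ M[:, j]) / (m - 1)
    return phi, psi


class TestDynamicSpectra:
    def test_identical_spectra_give_zero(self):
        ser = _series([(np.ones(11), Band(1100, 20, 0.5))])
        d = td.dynamic_spectra(ser)
        np.testing.assert_allclose(d.matrix, 0.0, atol=1e-14)

    def test_column_means_are_zero(self, templates):
        ser = t.generate_perturbation_series(templates["flower"], seed=3,
                                             grid=GRID)
        d = td.dynamic_spectra(ser)
        np.testing.assert_allclose(d.matrix.mean(axis=0), 0.0, atol=1e-12)

    def test_hand_computed_three_point_series(self):
        ser = _series([(np.array([1.0, 2.0, 3.0]), Band(1100, 20, 1.0))], m=3)
        d = td.dynamic_spectra(ser)
        center = np.argmin(np.abs(d.grid - 1100))
        np.testing.assert_allclose(d.matrix[:, center], [-1.0, 0.0, 1.0],
                                   atol=1e-12)

    def test_window_restriction(self):
        ser = _series([(np.arange(11.0), Band(1100, 20, 0.1))])
        d = td.dynamic_spectra(ser, window=(1150, 1050))
        assert d.grid[0] == 1050.0 and d.grid[-1] == 1150.0

    def test_window_outside_grid_rejected(self):
        ser = _series([(np.arange(11.0), Band(1100, 20, 0.1))])
        with pytest.raises(RangeError):
            td.dynamic_spectra(ser, window=(900, 1100))


class TestHilbertNoda:
    def test_m2_matrix(self):
        N = td.hilbert_noda_matrix(2)
        np.testing.assert_allclose(
            N, [[0.0, 1.0 / np.pi], [-1.0 / np.pi, 0.0]])

    def test_m3_entry(self):
        N = td.hilbert_noda_matrix(3)
        assert N[0, 2] == pytest.approx(0.15915494309189535)  # 1/(2*pi)

    @pytest.mark.parametrize("m", [2, 5, 11])
    def test_antisymmetric_zero_diagonal(self, m):
        N = td.hilbert_noda_matrix(m)
        np.testing.assert_allclose(N + N.T, 0.0, atol=1e-15)
        np.testing.assert_allclose(np.diag(N), 0.0)

    def test_too_small_rejected(self):
        with pytest.raises(ParameterError):
            td.hilbert_noda_matrix(1)


class TestMaps:
    def test_oracle_equivalence_11x60(self):
        rng = np.random.default_rng(12)
        ser = _series([
            (rng.normal(size=11), Band(1020, 15, 0.5)),
            (rng.normal(size=11), Band(1050, 15, 0.4)),
        ], grid=np.arange(1000.0, 1060.0, 1.0))
        d = td.dynamic_spectra(ser)
        phi = td.synchronous_map(d)
        psi = td.asynchronous_map(d)
        phi_bf, psi_bf = _brute_force_maps(d.matrix)
        assert np.max(np.abs(phi - phi_bf)) < 1e-12
        assert np.max(np.abs(psi - psi_bf)) < 1e-12

    def test_structural_invariants(self, templates):
        ser = t.generate_perturbation_series(templates["seed"], seed=9,
                                             grid=GRID)
        maps = td.TwoDMaps.compute(td.dynamic_spectra(ser))
        maps.validate(tol=1e-10)
        assert np.min(np.diag(maps.phi)) >= 0.0

    def test_single_band_auto_peak(self):
        profile = np.linspace(1.0, 0.6, 11)
        ser = _series([(profile, Band(1100, 20, 0.8))])
        maps = td.TwoDMaps.compute(td.dynamic_spectra(ser))
        peaks = td.extract_auto_peaks(maps)
        assert len(peaks) == 1
        assert abs(peaks.positions[0] - 1100.0) <= 2.0

    def test_proportional_dynamics_null(self):
        # every band follows one shared profile: no asynchronous signal
        profile = 1.0 + 0.3 * np.sin(np.linspace(0, 2, 11))
        ser = _series([
            (profile, Band(1040, 20, 0.5)),
            (profile, Band(1120, 20, 0.9)),
            (profile, Band(1170, 15, 0.3)),
        ])
        d = td.dynamic_spectra(ser)
        phi = td.synchronous_map(d)
        psi = td.asynchronous_map(d)
        assert np.max(np.abs(psi)) < 1e-10 * np.max(np.abs(phi))

    def test_quadrature_pair_dominates_asynchronous_map(self):
        theta = np.linspace(0, 2 * np.pi, 11, endpoint=False)
        ser = _series([
            (np.sin(theta), Band(1050, 20, 1.0)),
            (np.cos(theta), Band(1150, 20, 1.0)),
        ])
        d = td.dynamic_spectra(ser)
        psi = td.asynchronous_map(d)
        off = np.abs(psi.copy())
        np.fill_diagonal(off, 0.0)
        i, j = np.unravel_index(np.argmax(off), off.shape)
        assert {round(d.grid[i]), round(d.grid[j])} == {1050, 1150}

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        ser = _series([(rng.normal(size=11), Band(1100, 20, 0.5))])
        d = td.dynamic_spectra(ser)
        scaled = td.DynamicSpectra(3.0 * d.matrix, d.grid, d.temperatures_C)
        np.testing.assert_allclose(td.synchronous_map(scaled),
                                   9.0 * td.synchronous_map(d), atol=1e-12)
        np.testing.assert_allclose(td.asynchronous_map(scaled),
                                   9.0 * td.asynchronous_map(d), atol=1e-12)

    def test_window_then_map_equals_map_then_submatrix(self):
        rng = np.random.default_rng(4)
        ser = _series([
            (rng.normal(size=11), Band(1040, 15, 0.5)),
            (rng.normal(size=11), Band(1150, 15, 0.5)),
        ])
        d_full = td.dynamic_spectra(ser)
        phi_full = td.synchronous_map(d_full)
        d_win = td.dynamic_spectra(ser, window=(1100, 1199))
        phi_win = td.synchronous_map(d_win)
        mask = (d_full.grid >= 1100) & (d_full.grid <= 1199)
        np.testing.assert_allclose(phi_win, phi_full[np.ix_(mask, mask)],
                                   atol=1e-12)

    def test_two_bands_variance_ratio(self):
        rng = np.random.default_rng(8)
        p1 = rng.normal(size=11)
        p1 -= p1.mean()
        p2 = rng.normal(size=11)
        p2 -= p2.mean()
        p2 *= np.linalg.norm(p1) / (np.sqrt(2.0) * np.linalg.norm(p2))
        ser = _series([(p1, Band(1040, 14, 1.0)), (p2, Band(1150, 14, 1.0))])
        maps = td.TwoDMaps.compute(td.dynamic_spectra(ser))
        peaks = td.extract_auto_peaks(maps)
        assert len(peaks) == 2
        # intensity variance ratio 2:1 propagates to the auto-peak heights
        assert peaks.intensities[0] / peaks.intensities[1] == pytest.approx(
            2.0, rel=0.05)

    def test_flat_series_has_no_auto_peaks(self):
        ser = _series([(np.ones(11), Band(1100, 20, 0.5))])
        maps = td.TwoDMaps.compute(td.dynamic_spectra(ser))
        assert len(td.extract_auto_peaks(maps)) == 0

    def test_short_series_rejected(self):
        with pytest.raises((DegenerateDataError, Exception)):
            _series([(np.ones(2), Band(1100, 20, 0.5))], m=2)


class TestCrossPeakCalls:
    def _maps(self, prof1, prof2):
        ser = _series([(prof1, Band(1050, 20, 1.0)),
                       (prof2, Band(1150, 20, 1.0))])
        return td.TwoDMaps.compute(td.dynamic_spectra(ser))

    def test_in_phase_same_direction(self):
        profile = np.linspace(0.0, 1.0, 11)
        call = td.classify_cross_peak(self._maps(profile, profile),
                                      1050.0, 1150.0)
        assert call.coordination == "same_direction"
        assert call.sequence == "indeterminate"

    def test_anti_phase_opposite_direction(self):
        profile = np.linspace(0.0, 1.0, 11)
        call = td.classify_cross_peak(self._maps(profile, -profile),
                                      1050.0, 1150.0)
        assert call.coordination == "opposite_direction"

    def test_lead_lag_sequence_hint(self):
        theta = np.linspace(0, 1.5 * np.pi, 11)
        leading = np.sin(theta + np.pi / 4)
        lagging = np.sin(theta)
        call = td.classify_cross_peak(self._maps(leading, lagging),
                                      1050.0, 1150.0)
        assert call.coordination == "same_direction"
        assert call.sequence == "nu1 before nu2"
        swapped = td.classify_cross_peak(self._maps(lagging, leading),
                                         1050.0, 1150.0)
        assert swapped.sequence == "nu1 after nu2"

    def test_uncoordinated_below_floor(self):
        rng = np.random.default_rng(10)
        strong = rng.normal(size=11)
        call = td.classify_cross_peak(
            self._maps(strong, np.zeros(11)), 1050.0, 1150.0)
        assert call.coordination == "uncoordinated"

    def test_off_grid_wavenumber_rejected(self):
        maps = self._maps(np.arange(11.0), np.arange(11.0))
        with pytest.raises(RangeError):
            td.classify_cross_peak(maps, 1050.5, 1150.0)

    def test_same_wavenumber_rejected(self):
        maps = self._maps(np.arange(11.0), np.arange(11.0))
        with pytest.raises(ParameterError):
            td.classify_cross_peak(maps, 1050.0, 1050.0)


@settings(deadline=None, max_examples=15)
@given(st.integers(0, 2 ** 31 - 1))
def test_random_series_invariants(seed):
    """Phi symmetric with nonnegative diagonal, Psi antisymmetric, zero diag."""
    rng = np.random.default_rng(seed)
    grid = np.arange(1000.0, 1040.0, 1.0)
    M = rng.normal(size=(7, grid.size))
    d = td.DynamicSpectra(M - M.mean(axis=0), grid, np.arange(7.0))
    maps = td.TwoDMaps(td.synchronous_map(d), td.asynchronous_map(d), grid)
    maps.validate(tol=1e-10)
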