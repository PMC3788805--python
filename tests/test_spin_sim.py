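"""Density-matrix STEAM simulation: analytic anchors and invariants."""

import numpy as np
import pytest

from mrst2.registry import available_moieties, build_spin_system
from mrst2.spin_sim import (AcquisitionScheme, MacromoleculeModel, SpinSystem,
                            build_basis_set, fid_to_spectrum, simulate_steam_fid)
from mrst2.spin_sim import _evolve, _hamiltonian, _spin_ops, one_pulse_fid


def ax_steam_amplitude(j_hz, delta_ppm, te_ms, tm_ms, f0_mhz=169.0):
    """Product-operator closed form for the weak-coupling AX stimulated echo.

    Echo-top in-phase amplitude per two protons:
    cos^2(pi J TE/2) - (1/2) sin^2(pi J TE/2) cos(delta TM) (1 - cos(delta TE/2)),
    with delta the shift difference in rad/s.  Derived independently by
    product-operator algebra with the same coherence-pathway selection
    (+1 during the first TE/2, populations/ZQ during TM, -1 afterwards).
    """
    th = np.pi * j_hz * te_ms * 1e-3 / 2
    delta = 2 * np.pi * delta_ppm * f0_mhz
    return (np.cos(th) ** 2
            - 0.5 * np.sin(th) ** 2 * np.cos(delta * tm_ms * 1e-3)
            * (1 - np.cos(delta * te_ms * 1e-3 / 2)))


class TestRegistry:
    def test_naa_methyl_is_a_weighted_singlet_at_2_01_ppm(self):
        sys = build_spin_system("naa_ch3")
        assert sys.n_spins == 1
        assert sys.shifts[0] == pytest.approx(2.01, abs=0.01)
        assert sys.proton_count_scale == 3
        assert sys.j_matrix.shape == (1, 1) and sys.j_matrix[0, 0] == 0

    def test_creatine_methyl_sits_at_3_03_ppm(self):
        assert build_spin_system("cr_ch3").shifts[0] == pytest.approx(3.03, abs=0.01)

    @pytest.mark.parametrize("key", available_moieties())
    def test_every_registry_entry_validates_and_is_symmetric(self, key):
        sys = build_spin_system(key)
        assert np.array_equal(sys.j_matrix, sys.j_matrix.T)
        assert all(0 <= s <= 10 for s in sys.shifts)

    def test_unknown_moiety_lists_available_keys(self):
        with pytest.raises(KeyError, match="naa_ch3"):
            build_spin_system("nonexistent")


class TestSpinSystemValidation:
    def test_asymmetric_j_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SpinSystem("bad", (1.0, 2.0), np.array([[0.0, 7.0], [3.0, 0.0]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            SpinSystem("bad", (1.0, 2.0), np.zeros((3, 3)))

    def test_spin_count_cap(self, scheme):
        big = SpinSystem("big", tuple(np.linspace(1, 4, 8)), np.zeros((8, 8)))
        with pytest.raises(ValueError, match="cap"):
            simulate_steam_fid(big, scheme, 20.0)


class TestSteamAmplitude:
    @pytest.mark.parametrize("te", [10.0, 40.0, 180.0])
    @pytest.mark.parametrize("tm", [42.0, 10.0, 150.0])
    def test_uncoupled_spin_keeps_exactly_half_the_one_pulse_signal(self, scheme, te, tm):
        sys = SpinSystem("s", (2.008,), np.zeros((1, 1)), proton_count_scale=3.0)
        steam = simulate_steam_fid(sys, scheme, te, tm=tm)
        pulse = one_pulse_fid(sys, scheme)
        assert abs(steam[0]) / abs(pulse[0]) == pytest.approx(0.5, rel=1e-12)

    def test_echo_amplitude_scales_with_proton_weight(self, scheme):
        one = simulate_steam_fid(SpinSystem("a", (2.0,), np.zeros((1, 1))), scheme, 30.0)
        three = simulate_steam_fid(
            SpinSystem("a", (2.0,), np.zeros((1, 1)), proton_count_scale=3.0), scheme, 30.0)
        np.testing.assert_allclose(three, 3 * one, rtol=1e-12)

    @pytest.mark.parametrize("j", [3.5, 7.0, 12.0])
    @pytest.mark.parametrize("dppm", [1.0, 0.4])
    @pytest.mark.parametrize("te", [11.0, 40.0, 80.0, 181.0])
    def test_ax_doublet_matches_product_operator_closed_form(self, j, dppm, te):
        tm = 42.0
        scheme = AcquisitionScheme(tm=tm)
        ax = SpinSystem("ax", (2.0, 2.0 + dppm), np.array([[0.0, j], [j, 0.0]]))
        fid = simulate_steam_fid(ax, scheme, te, weak_coupling=True)
        assert fid[0].real == pytest.approx(ax_steam_amplitude(j, dppm, te, tm), abs=1e-8)
        assert abs(fid[0].imag) < 1e-10

    def test_ax_in_phase_signal_is_modulated_as_cos_pi_j_te(self):
        # shift difference chosen so the zero-quantum factor cos(delta*TM)
        # vanishes: amplitude = (1 + cos(pi J TE))/2 exactly
        j, tm = 7.0, 42.0
        dppm = 7.5 / (2 * 169.0 * tm * 1e-3)
        scheme = AcquisitionScheme(tm=tm)
        ax = SpinSystem("ax", (2.0, 2.0 + dppm), np.array([[0.0, j], [j, 0.0]]))
        for te in (10.0, 30.0, 60.0, 120.0, 180.0):
            fid0 = simulate_steam_fid(ax, scheme, te, weak_coupling=True)[0].real
            assert 2 * fid0 - 1 == pytest.approx(np.cos(np.pi * j * te * 1e-3), abs=1e-8)

    def test_naa_methyl_peak_lands_at_its_chemical_shift(self, scheme):
        fid = simulate_steam_fid(build_spin_system("naa_ch3"), scheme, 10.0)
        spec = fid_to_spectrum(fid, scheme, linewidth=12.0)
        peak_ppm = spec.ppm[np.argmax(spec.values.real)]
        assert peak_ppm == pytest.approx(2.008, abs=0.005)


class TestPropagation:
    def test_unitary_evolution_preserves_hermiticity_and_trace(self, rng, scheme):
        sys = build_spin_system("naa_asp")
        ops = _spin_ops(sys.n_spins)
        h = _hamiltonian(sys, scheme, ops)
        evals, vec = np.linalg.eigh(h)
        dim = 2 ** sys.n_spins
        a = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
        rho = a + a.conj().T
        rho = rho / np.trace(rho).real  # unit trace, Hermitian
        for t in (1e-3, 5e-3, 0.042):
            rho = _evolve(rho, evals, vec, t)
            assert np.trace(rho) == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(rho, rho.conj().T, atol=1e-12)


class TestSpectrum:
    def test_zero_linewidth_gives_delta_like_peak(self, scheme):
        # on-grid resonance: the undamped FID transforms to a single bin
        ppm = scheme.carrier_ppm - 280 * (scheme.sw / scheme.n_points) / scheme.f0
        sys = SpinSystem("s", (ppm,), np.zeros((1, 1)))
        spec = fid_to_spectrum(simulate_steam_fid(sys, scheme, 20.0), scheme, linewidth=0.0)
        i = np.argmax(np.abs(spec.values))
        assert spec.ppm[i] == pytest.approx(ppm, abs=0.01)
        # nearly all energy in a few bins around the peak
        total = np.sum(np.abs(spec.values) ** 2)
        local = np.sum(np.abs(spec.values[i - 3:i + 4]) ** 2)
        assert local / total > 0.95

    def test_spectrum_is_linear_in_the_fid(self, scheme):
        fid = simulate_steam_fid(SpinSystem("s", (2.0,), np.zeros((1, 1))), scheme, 10.0)
        a = fid_to_spectrum(fid, scheme, 12.0).values
        b = fid_to_spectrum(2 * fid, scheme, 12.0).values
        np.testing.assert_allclose(b, 2 * a, rtol=1e-12)

    def test_singlet_fwhm_matches_requested_linewidth(self, scheme):
        # resonance placed exactly on an FFT bin; FWHM read off the grid
        ppm = scheme.carrier_ppm - 500 * (scheme.sw / scheme.n_points) / scheme.f0
        sys = SpinSystem("s", (ppm,), np.zeros((1, 1)))
        spec = fid_to_spectrum(simulate_steam_fid(sys, scheme, 10.0), scheme, linewidth=12.0)
        r = spec.values.real
        above = spec.hz[r > r.max() / 2]
        bin_hz = scheme.sw / scheme.n_points
        assert above.max() - above.min() == pytest.approx(12.0, abs=bin_hz)

    def test_total_integral_proportional_to_first_fid_point(self, scheme):
        fid = simulate_steam_fid(SpinSystem("s", (2.0,), np.zeros((1, 1))), scheme, 10.0)
        spec = fid_to_spectrum(fid, scheme, linewidth=0.0)
        assert np.sum(spec.values) == pytest.approx(scheme.n_points * fid[0], rel=1e-9)


class TestBasisSet:
    def test_entry_count_and_te_coverage(self, basis, scheme):
        assert len(basis.entries) == 11
        for per_te in basis.entries.values():
            assert set(per_te) == set(scheme.te_list)

    def test_mm_component_absent_only_at_180_ms(self, basis, scheme):
        assert 180.0 not in basis.mm
        assert set(basis.mm) == set(scheme.te_list) - {180.0}

    def test_duplicate_moiety_names_rejected(self, scheme):
        sys = build_spin_system("naa_ch3")
        with pytest.raises(ValueError, match="duplicate"):
            build_basis_set([sys, sys], scheme)

    def test_regenerated_basis_is_bit_identical(self, scheme):
        small_scheme = AcquisitionScheme(te_list=(10, 30), n_points=1024)
        moieties = [build_spin_system("naa_ch3"), build_spin_system("cr_ch3")]
        b1 = build_basis_set(moieties, small_scheme, linewidth=12.0)
        b2 = build_basis_set(moieties, small_scheme, linewidth=12.0)
        for name in b1.entries:
            for te in small_scheme.te_list:
                assert np.array_equal(b1.entries[name][te].values,
                                      b2.entries[name][te].values)

    def test_mm_model_decays_with_its_own_fast_t2(self, scheme):
        mm = MacromoleculeModel()
        s10 = mm.spectrum(scheme, 10.0).values.real
        s80 = mm.spectrum(scheme, 80.0).values.real
        ratio = s80.max() / s10.max()
        assert ratio == pytest.approx(np.exp(-70.0 / mm.t2_mm), rel=1e-9)
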