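"""RRHO thermochemistry against closed forms and textbook values."""

import math

import numpy as np
import pytest

from solvmode import constants as const
from solvmode.modes import HessianData
from solvmode.structure import AtomicStructure, principal_moments
from solvmode.thermo import (ActivationResult, SpeciesThermo,
                             ThermoConditions, activation, eyring_rate,
                             rotational, species_thermo, translational,
                             vibrational)

COND = ThermoConditions()
R = const.GAS_CONSTANT_R


class TestTranslational:
    def test_internal_energy_is_three_halves_RT(self):
        U, _ = translational(123.4, COND)
        assert U == pytest.approx(1.5 * R * 298.15 / 1000.0)
        assert U == pytest.approx(3.718, abs=1e-3)

    def test_sackur_tetrode_water_vapor(self):
        # textbook: S_tra(H2O, 298.15 K, 1 atm) ~ 144.80 J/(mol K)
        _, S = translational(18.0153, COND)
        assert S == pytest.approx(144.80, abs=0.01)

    def test_mass_scaling_law(self):
        _, s1 = translational(10.0, COND)
        _, s8 = translational(80.0, COND)
        assert s8 - s1 == pytest.approx(1.5 * R * math.log(8.0), rel=1e-12)


class TestRotational:
    def test_single_atom_has_no_rotation(self):
        assert rotational([0.0, 0.0, 0.0], COND) == (0.0, 0.0)

    def test_water_entropy(self, water):
        moments = principal_moments(water)
        _, s1 = rotational(moments, COND)
        _, s2 = rotational(moments, ThermoConditions(sigma=2))
        # textbook sigma=2 value ~ 43.9; sigma=1 adds R ln 2
        assert s2 == pytest.approx(43.9, abs=0.5)
        assert s1 - s2 == pytest.approx(R * math.log(2.0), rel=1e-12)

    def test_moment_scaling_law(self):
        m = [1.0, 2.0, 3.0]
        _, s1 = rotational(m, COND)
        _, s2 = rotational([2 * x for x in m], COND)
        assert s2 - s1 == pytest.approx(1.5 * R * math.log(2.0), rel=1e-12)

    def test_linear_rotor(self):
        # diatomic: one vanishing moment, two equal ones
        U, S = rotational([0.0, 5.0, 5.0], COND)
        assert U == pytest.approx(R * 298.15 / 1000.0)
        I = 5.0 * const.AMU_KG * 1e-20
        q = 8 * math.pi ** 2 * const.BOLTZMANN_KB * 298.15 * I / const.PLANCK_H ** 2
        assert S == pytest.approx(R * (1 + math.log(q)), rel=1e-12)

    def test_negative_moment_rejected(self):
        with pytest.raises(ValueError):
            rotational([-1.0, 1.0, 1.0], COND)


class TestVibrational:
    def test_low_mode_entropy(self):
        _, S = vibrational([100.0], COND)
        assert S == pytest.approx(14.45, abs=0.01)

    def test_high_frequency_limit(self):
        U, S = vibrational([40000.0], COND)
        zpe = const.AVOGADRO_NA * const.PLANCK_H * const.SPEED_OF_LIGHT_CM \
            * 40000.0 / 2.0 / 1000.0
        assert S == pytest.approx(0.0, abs=1e-9)
        assert U == pytest.approx(zpe, rel=1e-12)

    def test_empty_mode_list(self):
        assert vibrational([], COND) == (0.0, 0.0)

    def test_nonpositive_frequency_names_mode(self):
        with pytest.raises(ValueError, match="mode index 1"):
            vibrational([100.0, -5.0], COND)

    def test_entropy_decreases_with_frequency(self):
        entropies = [vibrational([nu], COND)[1]
                     for nu in (50, 200, 800, 3200)]
        assert entropies == sorted(entropies, reverse=True)

    def test_internal_energy_increases_with_temperature(self):
        energies = [vibrational([300.0], ThermoConditions(T=t))[0]
                    for t in (100, 300, 600, 1200)]
        assert energies == sorted(energies)


def _diatomic_hessian(k, d, symbols=("H", "Cl")):
    st = AtomicStructure(symbols, np.array([[0.0, 0, 0], [d, 0, 0]]))
    u = np.array([1.0, 0, 0])
    block = k * np.outer(u, u)
    h = np.zeros((6, 6))
    h[:3, :3] += block
    h[3:, 3:] += block
    h[:3, 3:] -= block
    h[3:, :3] -= block
    return st, HessianData(h, (0, 1), units="hartree/angstrom^2")


class TestSpeciesThermo:
    def test_single_atom_gibbs(self):
        st = AtomicStructure(("Ar",), np.zeros((1, 3)))
        hess = HessianData(np.zeros((3, 3)), (0,),
                           units="hartree/angstrom^2")
        sp = species_thermo(st, 10.0, hess, COND)
        _, s_tra = translational(st.masses[0], COND)
        expected = 10.0 + 2.5 * R * COND.T / 1000.0 - COND.T * s_tra / 1000.0
        assert sp.G == pytest.approx(expected, rel=1e-12)

    def test_diatomic_matches_closed_form(self):
        k = 0.8
        st, hess = _diatomic_hessian(k, 1.3)
        sp = species_thermo(st, 0.0, hess, COND)
        mu = st.masses[0] * st.masses[1] / st.masses.sum()
        omega = math.sqrt(k * const.HARTREE_J / (1e-20 * const.AMU_KG) / mu)
        nu_ref = omega / (2 * math.pi * const.SPEED_OF_LIGHT_CM)
        assert len(sp.frequencies) == 1
        assert sp.frequencies[0] == pytest.approx(nu_ref, abs=0.1)

    def test_gibbs_identity(self):
        st, hess = _diatomic_hessian(1.0, 1.1)
        sp = species_thermo(st, 50.0, hess, COND)
        assert sp.G == pytest.approx(sp.H - COND.T * sp.S / 1000.0, abs=1e-9)
        zpe = const.AVOGADRO_NA * const.PLANCK_H * const.SPEED_OF_LIGHT_CM \
            * sum(sp.frequencies) / 2000.0
        assert sp.U_vib >= zpe

    def test_ts_imaginary_mode_excluded(self):
        st, hess = _diatomic_hessian(-0.02, 1.8)
        sp = species_thermo(st, 0.0, hess, COND, is_ts=True)
        assert sp.imaginary_count == 1
        assert sp.frequencies == ()

    def test_minimum_with_imaginary_mode_rejected(self):
        st, hess = _diatomic_hessian(-0.02, 1.8)
        with pytest.raises(ValueError, match="imaginary"):
            species_thermo(st, 0.0, hess, COND)

    def test_higher_order_saddle_rejected(self, water):
        h = -0.1 * np.eye(9)
        hess = HessianData(h, (0, 1, 2), units="hartree/angstrom^2")
        with pytest.raises(ValueError, match="saddle"):
            species_thermo(water, 0.0, hess, COND, is_ts=True)


class TestActivation:
    def _pair(self):
        st_r, h_r = _diatomic_hessian(1.0, 1.3)
        st_t, h_t = _diatomic_hessian(-0.05, 1.9)
        r = species_thermo(st_r, 0.0, h_r, COND)
        t = species_thermo(st_t.with_coordinates(st_t.coordinates), 40.0,
                           h_t, COND, is_ts=True)
        return r, t

    def test_identity_gives_zero_barriers(self):
        st, hess = _diatomic_hessian(1.0, 1.3)
        sp = species_thermo(st, 5.0, hess, COND)
        act = activation(sp, sp)
        assert act.dG == act.dH == act.dS == 0.0

    def test_enthalpy_sum_rule(self):
        r, t = self._pair()
        act = activation(r, t)
        assert act.dH == pytest.approx(act.dE_el + act.dU_vib, rel=1e-12)
        assert act.dS == pytest.approx(act.dS_rot + act.dS_vib, rel=1e-12)

    def test_cancellation_matches_bruteforce_gibbs_difference(self):
        # same composition: translational terms cancel exactly, so the
        # shortcut dG must equal the full G(TS) - G(R)
        r, t = self._pair()
        act = activation(r, t)
        assert act.dG == pytest.approx(t.G - r.G, abs=1e-9)

    def test_condition_mismatch_rejected(self):
        st, hess = _diatomic_hessian(1.0, 1.3)
        a = species_thermo(st, 0.0, hess, COND)
        b = species_thermo(st, 0.0, hess, ThermoConditions(T=350.0))
        with pytest.raises(ValueError, match="conditions"):
            activation(a, b)


class TestEyring:
    def test_prefactor(self):
        kbt_h = const.BOLTZMANN_KB * 298.15 / const.PLANCK_H
        assert eyring_rate(0.0, 298.15) == pytest.approx(kbt_h, rel=1e-6)
        assert eyring_rate(0.0, 298.15) == pytest.approx(6.212e12, rel=1e-3)

    def test_experimental_scale_barrier(self):
        assert eyring_rate(67.1, 298.15) == pytest.approx(10.9, abs=0.05)

    def test_monotone_decreasing_in_barrier(self):
        rates = [eyring_rate(g, 298.15) for g in (0.0, 20.0, 60.0, 120.0)]
        assert rates == sorted(rates, reverse=True)
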