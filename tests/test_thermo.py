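"""Multiwell thermodynamics: partition factors, normal modes, breakdown."""

import math

import numpy as np
import pytest
from scipy import constants as sc

import minimadock as md
from minimadock.constants import CONSTANTS
from minimadock.structures import AtomRecord, Conformation, FlexibleLigand
from minimadock.thermo import (
    SaddlePointError,
    SpeciesThermo,
    WellDescriptor,
    binding_breakdown,
    dG_from_Ki,
    multiwell_free_energy,
    normal_mode_frequencies,
    principal_moments,
    rotational_partition,
    translational_partition,
    vibrational_partition,
)

T = 310.0


def mode(x_ratio):
    """Angular frequency with hbar*omega/kT equal to x_ratio at 310 K."""
    return x_ratio * CONSTANTS.k_J * T / CONSTANTS.hbar


class TestVibrationalPartition:
    def test_single_mode_at_unit_ratio(self):
        well = WellDescriptor(0.0, [mode(1.0)], 1)
        assert vibrational_partition(well, T) == pytest.approx(
            math.exp(-0.5) / (1 - math.exp(-1)), rel=1e-12
        )

    def test_classical_limit_is_kT_over_hbar_omega(self):
        well = WellDescriptor(0.0, [mode(1e-4)], 1)
        assert vibrational_partition(well, T) == pytest.approx(1e4, rel=1e-4)

    def test_per_mode_bounded_by_classical_value(self):
        for x in (0.01, 0.1, 1.0, 5.0):
            well = WellDescriptor(0.0, [mode(x)], 1)
            assert vibrational_partition(well, T) <= 1.0 / x + 1e-12

    def test_empty_mode_list_gives_unity(self):
        well = WellDescriptor(0.0, [], 1, species="free-ligand")
        assert vibrational_partition(well, T) == 1.0

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            WellDescriptor(0.0, [-1.0], 1)


class TestTranslationalPartition:
    def test_density_inverse_dependence(self):
        z1 = translational_partition(SpeciesThermo(100.0, temperature=T))
        z2 = translational_partition(
            SpeciesThermo(100.0, temperature=T, density=2 * CONSTANTS.standard_density)
        )
        assert z1 / z2 == pytest.approx(2.0, rel=1e-12)

    def test_mass_scaling_three_halves(self):
        z1 = translational_partition(SpeciesThermo(100.0, temperature=T))
        z8 = translational_partition(SpeciesThermo(800.0, temperature=T))
        assert z8 / z1 == pytest.approx(8**1.5, rel=1e-12)

    def test_against_direct_constant_substitution(self):
        """Independent evaluation of e*(2 pi M k T)^(3/2)/(h^3 rho) from
        scipy.constants, M = 100 amu, T = 310 K, rho = 1 mol/L."""
        M = 100 * sc.atomic_mass
        rho = 1000 * sc.Avogadro
        expected = math.e * (2 * math.pi * M * sc.k * T) ** 1.5 / (sc.h**3 * rho)
        got = translational_partition(SpeciesThermo(100.0, temperature=T))
        assert got == pytest.approx(expected, rel=1e-7)


class TestRotationalPartition:
    def _triangle(self):
        # equilateral, side 1 Å, unit masses: moments (0.5, 0.5, 1.0) amu Å^2
        c = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, math.sqrt(3) / 2, 0.0]]
        )
        return Conformation(c), np.ones(3)

    def test_equilateral_triangle_moments_closed_form(self):
        conf, masses = self._triangle()
        assert principal_moments(conf, masses) == pytest.approx((0.5, 0.5, 1.0))

    def test_rotation_invariance(self, rng):
        conf, masses = self._triangle()
        th = 0.7
        R = np.array(
            [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1]]
        )
        z1 = rotational_partition(conf, masses, T)
        z2 = rotational_partition(Conformation(conf.coords @ R.T), masses, T)
        assert z1 == pytest.approx(z2, rel=1e-9)

    def test_mass_doubling_scales_three_halves(self):
        conf, masses = self._triangle()
        z1 = rotational_partition(conf, masses, T)
        z2 = rotational_partition(conf, 2 * masses, T)
        assert z2 / z1 == pytest.approx(2**1.5, rel=1e-9)

    def test_collinear_geometry_rejected(self):
        line = Conformation([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            rotational_partition(line, np.ones(3), T)


class TestMultiwell:
    def _well(self, E0):
        return WellDescriptor(E0, [mode(1.0)], 1)

    def _sp(self):
        return SpeciesThermo(100.0, moments=(10.0, 10.0, 10.0), temperature=T)

    def test_single_well_closed_form(self):
        w = self._well(-5.0)
        sp = self._sp()
        zv = vibrational_partition(w, T)
        zt = translational_partition(sp)
        zr = rotational_partition(
            Conformation(np.eye(3)), np.ones(3), T
        )  # not used; direct moments below
        from minimadock.thermo import log_rotational_partition

        g = multiwell_free_energy([w], sp)
        expected = -5.0 - CONSTANTS.kT(T) * (
            math.log(zv) + math.log(zt) + log_rotational_partition(sp)
        )
        assert g == pytest.approx(expected, rel=1e-10)

    def test_two_identical_wells_lower_G_by_kT_ln2(self):
        sp = self._sp()
        g1 = multiwell_free_energy([self._well(-5.0)], sp)
        g2 = multiwell_free_energy([self._well(-5.0), self._well(-5.0)], sp)
        assert g1 - g2 == pytest.approx(CONSTANTS.kT(T) * math.log(2), rel=1e-10)

    def test_adding_a_well_only_lowers_G(self):
        sp = self._sp()
        g1 = multiwell_free_energy([self._well(-5.0)], sp)
        g2 = multiwell_free_energy([self._well(-5.0), self._well(20.0)], sp)
        assert g2 <= g1

    def test_well_order_irrelevant(self):
        sp = self._sp()
        wells = [self._well(-5.0), self._well(-4.0), self._well(0.0)]
        assert multiwell_free_energy(wells, sp) == pytest.approx(
            multiwell_free_energy(wells[::-1], sp), rel=1e-12
        )

    def test_empty_well_list_rejected(self):
        with pytest.raises(ValueError):
            multiwell_free_energy([], self._sp())


class _Iso:
    """External isotropic harmonic well k|x|^2 acting on every atom."""

    name = "iso"

    def __init__(self, k=50.0):
        self.k = k

    def evaluate(self, receptor, ligand, conf):
        return float(self.k * np.sum(conf.coords**2)), 2 * self.k * conf.coords


class _Saddle:
    name = "saddle"

    def evaluate(self, receptor, ligand, conf):
        x = conf.coords
        e = float(50.0 * (x[0, 0] ** 2 + x[0, 1] ** 2) - 50.0 * x[0, 2] ** 2)
        g = np.array([[100.0 * x[0, 0], 100.0 * x[0, 1], -100.0 * x[0, 2]]])
        return e, g


class TestNormalModes:
    def test_diatomic_frequency_closed_form(self):
        """Two equal masses on a harmonic bond: one mode at sqrt(K/mu)
        after the five rigid modes are removed."""
        atoms = [AtomRecord("C", [0.0, 0, 0]), AtomRecord("C", [1.54, 0, 0])]
        lig = FlexibleLigand(atoms=atoms, bonds=[(0, 1, 1, False)])
        from minimadock.energy import ToyForceField

        well = normal_mode_frequencies(
            ToyForceField(), None, lig, lig.reference_conformation(), "free-ligand"
        )
        K = 2 * 300.0  # curvature of E = bond_k (r - r0)^2
        mu = 12.011 / 2
        expected = math.sqrt(K / mu * CONSTANTS.hessian_to_si)
        assert len(well.frequencies) == 1
        assert well.frequencies[0] == pytest.approx(expected, rel=1e-3)

    def test_single_atom_in_isotropic_well_has_three_equal_modes(self):
        lig = FlexibleLigand(atoms=[AtomRecord("C", np.zeros(3))], bonds=[])
        well = normal_mode_frequencies(
            _Iso(50.0), None, lig, Conformation([[0.0, 0, 0]]), "complex"
        )
        expected = math.sqrt(2 * 50.0 / 12.011 * CONSTANTS.hessian_to_si)
        assert len(well.frequencies) == 3
        assert np.allclose(well.frequencies, expected, rtol=1e-6)

    def test_free_single_atom_keeps_no_modes(self):
        lig = FlexibleLigand(atoms=[AtomRecord("C", np.zeros(3))], bonds=[])

        class Flat:
            name = "flat"

            def evaluate(self, receptor, ligand, conf):
                return 0.0, np.zeros_like(conf.coords)

        well = normal_mode_frequencies(
            Flat(), None, lig, Conformation([[0.0, 0, 0]]), "free-ligand"
        )
        assert len(well.frequencies) == 0

    def test_saddle_point_is_rejected(self):
        lig = FlexibleLigand(atoms=[AtomRecord("C", np.zeros(3))], bonds=[])
        with pytest.raises(SaddlePointError):
            normal_mode_frequencies(
                _Saddle(), None, lig, Conformation([[0.0, 0, 0]]), "complex"
            )


class TestBindingBreakdown:
    def _species(self):
        sp_c = SpeciesThermo(5000.0, (1e4, 1.2e4, 1.5e4), T)
        sp_l = SpeciesThermo(100.0, (50.0, 60.0, 80.0), T)
        sp_p = SpeciesThermo(4900.0, (9e3, 1.1e4, 1.4e4), T)
        return sp_c, sp_l, sp_p

    def _wells(self, energies, n=3):
        return [WellDescriptor(e, [mode(1.0)] * 3, n) for e in energies]

    def test_single_wells_make_dG_all_zero(self):
        sp_c, sp_l, sp_p = self._species()
        bb = binding_breakdown(self._wells([-60.0]), self._wells([-5.0]), -10.0,
                               sp_c, sp_l, sp_p)
        assert bb.dG_all == pytest.approx(0.0, abs=1e-10)
        assert bb.dE == pytest.approx(-60.0 - (-10.0) - (-5.0))

    def test_identity_holds_exactly(self):
        sp_c, sp_l, sp_p = self._species()
        bb = binding_breakdown(
            self._wells([-60.0, -59.0, -58.0]), self._wells([-5.0, -4.0]), -10.0,
            sp_c, sp_l, sp_p,
        )
        assert bb.dG_bind == pytest.approx(
            bb.dE + bb.dG_v + bb.dG_t + bb.dG_r + bb.dG_all, abs=1e-12
        )

    def test_two_complex_wells_split_by_kT_ln2_closed_form(self):
        """Wells at E0 and E0 + kT ln 2 sum to 1.5x the single-well weight,
        so dG_all = -kT ln(3/2)."""
        sp_c, sp_l, sp_p = self._species()
        kT = CONSTANTS.kT(T)
        bb = binding_breakdown(
            self._wells([-60.0, -60.0 + kT * math.log(2)]),
            self._wells([-5.0]), -10.0, sp_c, sp_l, sp_p,
        )
        assert bb.dG_all == pytest.approx(-kT * math.log(1.5), rel=1e-9)

    def test_inconsistent_temperatures_rejected(self):
        sp_c, sp_l, sp_p = self._species()
        sp_l.temperature = 300.0
        with pytest.raises(ValueError, match="temperature"):
            binding_breakdown(self._wells([-60.0]), self._wells([-5.0]), -10.0,
                              sp_c, sp_l, sp_p)


class TestDGFromKi:
    def test_unit_Ki_is_zero(self):
        assert dG_from_Ki(1.0, T) == 0.0

    def test_nanomolar_at_310K(self):
        # independent: k = 1.9872e-3 kcal/(mol K)
        assert dG_from_Ki(1e-9, 310.0) == pytest.approx(
            1.9872e-3 * 310.0 * math.log(1e-9), rel=1e-4
        )

    def test_monotone_in_Ki(self):
        assert dG_from_Ki(1e-9) < dG_from_Ki(1e-6) < dG_from_Ki(1e-3)

    def test_nonpositive_Ki_rejected(self):
        with pytest.raises(ValueError):
            dG_from_Ki(0.0)
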