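"""Soft-core alchemical Hamiltonians: endpoints, singularities, derivatives."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from densassign import (
    AlchemicalHamiltonian,
    SiteModel,
    SoftCoreParams,
    Species,
    alchemical_dhdl,
    alchemical_potential,
    softcore_distance,
)
from densassign.toy_model import SitePotential
from densassign._kernels import _force as kernel_force


@pytest.fixture(scope="module")
def mixed_site():
    return SiteModel(
        centers=[
            ((0.0, 0.33, 0.0), -0.1, 4.0, 0.30),
            ((0.2, -0.1, 0.1), 0.125, 0.4, 0.28),
        ],
        dielectric=4.0,
    )


ION = Species("ion", -1.0, 0.8, 0.30, mass=19.0)
WAT = Species("wat", 0.0, 4.0, 0.28)


class TestSoftCoreDistance:
    def test_identity_when_coupled(self):
        assert softcore_distance(0.5, 0.0, SoftCoreParams()) == pytest.approx(0.5, rel=1e-14)

    def test_hand_value_at_contact(self):
        # (0.5 * 0.3^6 * 0.5)^(1/6) at r = 0
        d = softcore_distance(0.0, 0.5, SoftCoreParams(alpha=0.5, sigma_sc=0.3, power=1))
        assert d == pytest.approx(0.238110158, rel=1e-8)

    @given(
        r=st.floats(0.0, 1.0),
        w1=st.floats(0.0, 1.0),
        w2=st.floats(0.0, 1.0),
        power=st.sampled_from([1, 2]),
    )
    def test_monotone_in_off_weight(self, r, w1, w2, power):
        sc = SoftCoreParams(alpha=0.5, sigma_sc=0.3, power=power)
        lo, hi = sorted([w1, w2])
        assert softcore_distance(r, lo, sc) <= softcore_distance(r, hi, sc) + 1e-15

    def test_power_validation(self):
        with pytest.raises(ValueError):
            SoftCoreParams(power=3)


class TestEndpointIdentity:
    @pytest.mark.parametrize("lam,ref_species", [(0.0, ION), (1.0, WAT)])
    def test_relative_endpoints(self, mixed_site, lam, ref_species):
        alch = AlchemicalHamiltonian(
            site=mixed_site, species_a=ION, species_b=WAT, mode="relative", lam=lam
        )
        ref = SitePotential(mixed_site, ref_species)
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.uniform(-0.7, 0.7, 3)
            assert abs(alchemical_potential(alch, x) - ref.energy(x)) < 1e-10

    def test_decouple_endpoints(self, mixed_site):
        # full Coulomb+LJ at lam=0; LJ only at lam=1 of the Coulomb leg
        alch = AlchemicalHamiltonian(site=mixed_site, species_a=ION, mode="decouple_coulomb")
        uncharged = Species("ion0", 0.0, ION.lj_epsilon, ION.lj_sigma)
        full = SitePotential(mixed_site, ION)
        lj_only = SitePotential(mixed_site, uncharged)
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.uniform(-0.7, 0.7, 3)
            assert alch.at_lambda(0.0).energy(x) == pytest.approx(full.energy(x), abs=1e-10)
            assert alch.at_lambda(1.0).energy(x) == pytest.approx(lj_only.energy(x), abs=1e-10)


class TestSingularityRemoval:
    @pytest.mark.parametrize("mode", ["relative", "decouple_lj"])
    @pytest.mark.parametrize("lam", [0.05, 0.25, 0.5, 0.75, 0.95])
    def test_finite_on_a_center(self, mixed_site, mode, lam):
        alch = AlchemicalHamiltonian(
            site=mixed_site, species_a=ION, species_b=None, mode=mode, lam=lam
        )
        x_on_center = np.array([0.0, 0.33, 0.0])
        assert math.isfinite(alchemical_potential(alch, x_on_center))
        assert math.isfinite(alchemical_dhdl(alch, x_on_center))
        assert np.all(np.isfinite(alch.force(x_on_center)))


class TestAnalyticDerivatives:
    def test_identical_states_no_softcore_is_flat(self, mixed_site):
        alch = AlchemicalHamiltonian(
            site=mixed_site, species_a=ION, species_b=ION,
            softcore=SoftCoreParams(alpha=0.0), mode="relative",
        )
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.uniform(-0.7, 0.7, 3)
            lam = rng.uniform(0.0, 1.0)
            assert alchemical_dhdl(alch.at_lambda(lam), x) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("species_b", [WAT, None])
    def test_finite_difference_agreement(self, mixed_site, species_b):
        # central FD with dlam = 1e-6 over 100 random (x, lambda) draws
        alch = AlchemicalHamiltonian(
            site=mixed_site, species_a=ION, species_b=species_b, mode="relative"
        )
        rng = np.random.default_rng(4)
        dl = 1e-6
        for _ in range(100):
            x = rng.uniform(-0.7, 0.7, 3)
            lam = rng.uniform(0.01, 0.99)
            fd = (
                alch.at_lambda(lam + dl).energy(x) - alch.at_lambda(lam - dl).energy(x)
            ) / (2 * dl)
            an = alchemical_dhdl(alch.at_lambda(lam), x)
            assert an == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_restraint_on_is_linear_coupling(self, mixed_site):
        k = 200.0
        x0 = np.array([0.05, -0.1, 0.02])
        alch = AlchemicalHamiltonian(
            site=mixed_site, species_a=WAT, mode="restraint_on",
            restraint_k=k, restraint_center=x0,
        )
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.uniform(-0.7, 0.7, 3)
            lam = rng.uniform(0.0, 1.0)
            expected = 0.5 * k * np.sum((x - x0) ** 2)
            assert alchemical_dhdl(alch.at_lambda(lam), x) == pytest.approx(expected, rel=1e-12)

    def test_ghost_lj_hand_value_at_contact(self):
        # (1-0.5)*4*0.5*(16-4) = 12 kJ/mol at r=0, eps_ij=0.5, sig_ij=0.3
        site = SiteModel(centers=[((0.0, 0.0, 0.0), 0.0, 0.5, 0.3)])
        sp = Species("lj", 0.0, 0.5, 0.3)
        alch = AlchemicalHamiltonian(
            site=site, species_a=sp, species_b=None, mode="relative", lam=0.5,
            softcore=SoftCoreParams(alpha=0.5, sigma_sc=0.3, power=1),
        )
        assert alchemical_potential(alch, np.zeros(3)) == pytest.approx(12.0, rel=1e-9)

    def test_force_matches_energy_gradient(self, mixed_site):
        rng = np.random.default_rng(6)
        for mode, spb, k in [
            ("relative", WAT, 0.0),
            ("decouple_coulomb", None, 200.0),
            ("decouple_lj", None, 200.0),
            ("restraint_on", None, 200.0),
        ]:
            alch = AlchemicalHamiltonian(
                site=mixed_site, species_a=ION, species_b=spb, mode=mode,
                restraint_k=k, lam=0.37,
            )
            for _ in range(20):
                x = rng.uniform(-0.7, 0.7, 3)
                f = alch.force(x)
                for c in range(3):
                    dx = np.zeros(3)
                    dx[c] = 1e-6
                    fd = -(alch.energy(x + dx) - alch.energy(x - dx)) / 2e-6
                    assert f[c] == pytest.approx(fd, rel=1e-4, abs=1e-3)


class TestKernelConsistency:
    """The compiled force used by the integrator must agree with the
    reference numpy implementation for every coupling mode."""

    @pytest.mark.parametrize("mode,spb,k", [
        ("relative", WAT, 0.0),
        ("relative", None, 0.0),
        ("decouple_coulomb", None, 200.0),
        ("decouple_lj", None, 200.0),
        ("restraint_on", None, 200.0),
    ])
    def test_kernel_force_matches_numpy(self, mixed_site, mode, spb, k):
        alch = AlchemicalHamiltonian(
            site=mixed_site, species_a=ION, species_b=spb, mode=mode,
            restraint_k=k, lam=0.42,
        )
        args = alch.kernel_args()
        rng = np.random.default_rng(7)
        for _ in range(30):
            x = rng.uniform(-0.7, 0.7, 3)
            f = np.zeros(3)
            kernel_force(
                x, f,
                np.ascontiguousarray(args[0], dtype=float),
                *[np.asarray(a, dtype=float) for a in args[1:7]],
                float(args[7]), float(args[8]), float(args[9]), int(args[10]),
                float(args[11]), np.asarray(args[12], dtype=float),
                float(args[13]), np.asarray(args[14], dtype=float),
            )
            assert np.allclose(f, alch.force(x), rtol=1e-10, atol=1e-10)

    def test_site_potential_kernel(self, mixed_site):
        pot = SitePotential(mixed_site, ION)
        args = pot.kernel_args()
        rng = np.random.default_rng(8)
        for _ in range(30):
            x = rng.uniform(-0.7, 0.7, 3)
            f = np.zeros(3)
            kernel_force(
                x, f,
                np.ascontiguousarray(args[0], dtype=float),
                *[np.asarray(a, dtype=float) for a in args[1:7]],
                float(args[7]), float(args[8]), float(args[9]), int(args[10]),
                float(args[11]), np.asarray(args[12], dtype=float),
                float(args[13]), np.asarray(args[14], dtype=float),
            )
            assert np.allclose(f, pot.force(x), rtol=1e-10, atol=1e-10)


class TestModeValidation:
    def test_unknown_mode(self, mixed_site):
        with pytest.raises(ValueError):
            AlchemicalHamiltonian(site=mixed_site, species_a=ION, mode="morph")

    def test_lambda_bounds(self, mixed_site):
        with pytest.raises(ValueError):
            AlchemicalHamiltonian(site=mixed_site, species_a=ION, lam=1.5)
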