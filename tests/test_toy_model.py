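"""Toy-model physics: potential terms, Langevin sampling, synthetic survival."""

import math

import numpy as np
import pytest
from scipy import stats

from densassign import (
    KB,
    SimulationParams,
    SiteModel,
    Species,
    generate_survival_synthetic,
    potential_energy,
    sample_dhdl,
    simulate_langevin,
    tau_ml,
    window_mean,
)
from densassign.alchemy import HarmonicSwitchHamiltonian
from densassign.toy_model import SingularConfigurationError, SitePotential

from conftest import make_params


def single_center_site(q=0.0, eps=0.0, sig=0.3, dielectric=1.0, **kw):
    return SiteModel(centers=[((0.0, 0.0, 0.0), q, eps, sig)], dielectric=dielectric, **kw)


class TestPotentialEnergy:
    def test_inert_species_feels_nothing(self):
        site = single_center_site(q=1.0, eps=1.0)
        ghost = Species("ghost", charge=0.0, lj_epsilon=0.0, lj_sigma=0.3)
        for x in ([0.1, 0.0, 0.0], [0.3, 0.2, -0.5], [0.0, 0.0, 0.7]):
            assert potential_energy(site, ghost, np.array(x)) == pytest.approx(0.0, abs=1e-14)

    def test_lj_zero_crossing_at_sigma(self):
        # combined eps_ij = 0.5, sig_ij = 0.3: LJ vanishes exactly at r = sigma
        site = single_center_site(eps=0.5, sig=0.3)
        sp = Species("lj", charge=0.0, lj_epsilon=0.5, lj_sigma=0.3)
        assert potential_energy(site, sp, np.array([0.3, 0.0, 0.0])) == pytest.approx(0.0, abs=1e-12)

    def test_coulomb_hand_value(self):
        # q_i q_j = -1 e^2, r = 0.2 nm, dielectric 1: -138.935458/0.2
        site = single_center_site(q=1.0)
        anion = Species("an", charge=-1.0, lj_epsilon=0.0, lj_sigma=0.3)
        e = potential_energy(site, anion, np.array([0.2, 0.0, 0.0]))
        assert e == pytest.approx(-694.67729, rel=1e-9)

    def test_cage_term(self):
        site = SiteModel(centers=[], cage_k=200.0)
        sp = Species("w", 0.0, 0.0, 0.3)
        assert potential_energy(site, sp, np.array([0.1, 0.0, 0.0])) == pytest.approx(1.0)

    def test_singular_configuration(self):
        site = single_center_site(q=1.0, eps=0.5)
        sp = Species("an", charge=-1.0, lj_epsilon=0.5, lj_sigma=0.3)
        with pytest.raises(SingularConfigurationError):
            potential_energy(site, sp, np.zeros(3))

    def test_force_matches_gradient(self, f85_site, fluoride):
        pot = SitePotential(f85_site, fluoride)
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.uniform(-0.6, 0.6, 3)
            f = pot.force(x)
            for k in range(3):
                dx = np.zeros(3)
                dx[k] = 1e-6
                fd = -(pot.energy(x + dx) - pot.energy(x - dx)) / 2e-6
                assert f[k] == pytest.approx(fd, rel=1e-4, abs=1e-4)


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(lj_epsilon=-1.0),
            dict(lj_sigma=0.0),
            dict(mass=0.0),
        ],
    )
    def test_species_invariants(self, kw):
        base = dict(name="x", charge=0.0, lj_epsilon=1.0, lj_sigma=0.3)
        base.update(kw)
        with pytest.raises(ValueError):
            Species(**base)

    def test_escape_radius_inside_box(self):
        with pytest.raises(ValueError):
            SiteModel(centers=[], escape_radius=1.2, box_halfwidth=1.0)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(dt=0.0),
            dict(temperature=0.0),
            dict(n_steps=100, burn_in_steps=100),
        ],
    )
    def test_simulation_params_invariants(self, kw):
        with pytest.raises(ValueError):
            make_params(**kw)


class TestLangevin:
    def test_seed_determinism(self, f85_site, water):
        p = make_params(n_steps=4000, seed=42)
        t1 = simulate_langevin(f85_site, water, p)
        t2 = simulate_langevin(f85_site, water, p)
        assert np.array_equal(t1.positions, t2.positions)
        t3 = simulate_langevin(f85_site, water, make_params(n_steps=4000, seed=43))
        assert not np.array_equal(t1.positions, t3.positions)

    def test_equipartition_in_harmonic_cage(self):
        # each coordinate's variance must match kB T / K within 3 block SEs
        K = 200.0
        site = SiteModel(centers=[], cage_k=K, box_halfwidth=2.0, escape_radius=1.0)
        sp = Species("w", 0.0, 0.0, 0.3)
        p = make_params(n_steps=400000, burn_in_steps=0, dt=0.004, friction=3.0, seed=7)
        traj = simulate_langevin(site, sp, p)
        X = traj.positions[2000:]
        expected = KB * 300.0 / K
        for k in range(3):
            dev2 = (X[:, k] - X[:, k].mean()) ** 2
            blocks = dev2[: 10 * (len(dev2) // 10)].reshape(10, -1).mean(axis=1)
            se = blocks.std(ddof=1) / math.sqrt(10)
            assert abs(dev2.mean() - expected) < 3.0 * se

    def test_free_diffusion_coefficient(self):
        # zero force: long-time MSD slope is 2 kB T/(m gamma) per dimension
        site = SiteModel(centers=[], box_halfwidth=50.0, escape_radius=10.0)
        sp = Species("w", 0.0, 0.0, 0.3)
        gamma = 5.0
        p = make_params(n_steps=200000, burn_in_steps=0, friction=gamma, seed=11, sample_stride=50)
        traj = simulate_langevin(site, sp, p)
        lag = 100  # frames = 10 ps
        disp = traj.positions[lag:] - traj.positions[:-lag]
        msd = np.einsum("ij,ij->i", disp, disp).mean() / 3.0  # per dimension
        D_est = msd / (2.0 * lag * traj.frame_dt)
        D_exp = KB * 300.0 / (sp.mass * gamma)
        assert D_est == pytest.approx(D_exp, rel=0.2)

    def test_reflecting_walls_confine(self, water):
        site = SiteModel(centers=[], box_halfwidth=0.3, escape_radius=0.2)
        p = make_params(n_steps=20000, burn_in_steps=0, seed=5)
        traj = simulate_langevin(site, water, p)
        assert np.all(np.abs(traj.positions) <= 0.3 + 1e-12)

    def test_boltzmann_sampling_double_well(self):
        # chi-square GOF of the sampled |x|-histogram against exp(-U/kBT)/Z
        # on near-independent subsamples of a long run (quartic double well
        # along x, harmonic in y/z, handled by the pure-Python fallback).
        # Folding onto |x| uses the potential's symmetry to remove the one
        # slow antisymmetric mode (inter-well hopping), whose relaxation
        # would otherwise miscalibrate the chi-square statistic.
        a, b, Ky = 195.0, 0.4, 100.0
        half = 0.8

        class DoubleWell:
            def energy(self, x):
                return a * (x[0] ** 2 - b**2) ** 2 + 0.5 * Ky * (x[1] ** 2 + x[2] ** 2)

            def force(self, x):
                return np.array(
                    [
                        -4.0 * a * x[0] * (x[0] ** 2 - b**2),
                        -Ky * x[1],
                        -Ky * x[2],
                    ]
                )

        site = SiteModel(centers=[], box_halfwidth=half, escape_radius=0.5)
        sp = Species("w", 0.0, 0.0, 0.3)
        p = make_params(
            n_steps=150000, burn_in_steps=0, dt=0.004, friction=3.0, seed=19,
            sample_stride=100,
        )
        traj = simulate_langevin(site, sp, p, hamiltonian_override=DoubleWell())
        xs = np.abs(traj.positions[50:, 0])
        kt = KB * 300.0
        edges = np.linspace(0.0, half, 11)
        grid = np.linspace(0.0, half, 4001)
        dens = np.exp(-a * (grid**2 - b**2) ** 2 / kt)
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0)])
        cdf /= cdf[-1]
        probs = np.diff(np.interp(edges, grid, cdf))
        counts, _ = np.histogram(xs, bins=edges)
        res = stats.chisquare(counts, probs * len(xs))
        assert res.pvalue > 0.01


class TestSurvivalSynthetic:
    def test_no_censoring_limit(self):
        data = generate_survival_synthetic(true_tau=0.05, M=500, T_s=40.0, seed=1)
        assert data.m == data.M == 500
        tau, bound = tau_ml(data)
        assert not bound
        assert tau == pytest.approx(0.05, rel=3.0 / math.sqrt(500))

    def test_full_censoring_limit(self):
        data = generate_survival_synthetic(true_tau=1e7, M=100, T_s=40.0, seed=2)
        assert data.m == 0
        tau, bound = tau_ml(data)
        assert bound and tau == pytest.approx(4000.0)

    def test_censored_fraction(self):
        # survival probability exp(-T_s/tau) = exp(-0.8)
        M, tau, T_s = 2000, 50.0, 40.0
        data = generate_survival_synthetic(true_tau=tau, M=M, T_s=T_s, seed=3)
        p = math.exp(-T_s / tau)
        frac = (M - data.m) / M
        assert abs(frac - p) < 3.0 * math.sqrt(p * (1 - p) / M)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_survival_synthetic(0.0, 10, 1.0, 0)
        with pytest.raises(ValueError):
            generate_survival_synthetic(1.0, 0, 1.0, 0)


class TestSampleDhdl:
    def test_lambda_independent_hamiltonian(self, water):
        site = SiteModel(centers=[], box_halfwidth=1.0, escape_radius=0.5)
        ham = HarmonicSwitchHamiltonian(site=site, species_a=water, k0=100.0, k1=100.0)
        series = sample_dhdl(ham, 0.3, make_params(n_steps=5000, seed=1))
        assert np.all(series.values == 0.0)

    def test_harmonic_switch_window_mean(self, water):
        # <dH/dl> = (K1-K0)/2 * 3 kB T / K(lambda) for the linear switch
        site = SiteModel(centers=[], box_halfwidth=1.0, escape_radius=0.5)
        ham = HarmonicSwitchHamiltonian(site=site, species_a=water, k0=100.0, k1=400.0)
        lam = 0.5
        p = make_params(n_steps=100000, burn_in_steps=2000, friction=3.0, seed=21)
        series = sample_dhdl(ham, lam, p)
        mean, sem = window_mean(series)
        expected = 0.5 * 300.0 * 3.0 * KB * 300.0 / 250.0
        assert abs(mean - expected) < 3.0 * sem

    def test_two_seeds_statistically_compatible(self, water):
        site = SiteModel(centers=[], box_halfwidth=1.0, escape_radius=0.5)
        ham = HarmonicSwitchHamiltonian(site=site, species_a=water, k0=100.0, k1=400.0)
        stats_ = []
        for seed in (31, 32):
            p = make_params(n_steps=60000, burn_in_steps=2000, friction=3.0, seed=seed)
            stats_.append(window_mean(sample_dhdl(ham, 0.5, p)))
        (m1, s1), (m2, s2) = stats_
        assert abs(m1 - m2) < 3.0 * math.hypot(s1, s2)

    def test_lambda_out_of_range(self, water):
        site = SiteModel(centers=[], box_halfwidth=1.0, escape_radius=0.5)
        ham = HarmonicSwitchHamiltonian(site=site, species_a=water, k0=0.0, k1=1.0)
        with pytest.raises(ValueError):
            sample_dhdl(ham, 1.5, make_params())
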