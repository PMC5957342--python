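"""Synthetic binding-site model and single-particle Langevin dynamics.

This module is the package's data generator.  It replaces atomistic MD of a
membrane channel with a deliberately minimal physical model: one tagged
particle (an "ion" or a "water") moving in a rigid arrangement of
interaction centers (a coordination shell), with Lennard-Jones plus
dielectric-screened Coulomb interactions, an optional harmonic cage, and a
reflecting confinement box standing in for bulk solvent.  Because every
potential here has a known closed form, equilibrium observables (variances,
free-energy differences between harmonic states, escape statistics of an
exponential process) can be checked against exact results — which is the
whole point of the toy.

Dynamics are integrated with the BAOAB splitting of underdamped Langevin
dynamics, which has very small configurational sampling bias at moderate
time steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KB, F_COULOMB

__all__ = [
    "Species",
    "SiteModel",
    "SimulationParams",
    "Trajectory",
    "SitePotential",
    "SingularConfigurationError",
    "potential_energy",
    "simulate_langevin",
    "generate_survival_synthetic",
    "sample_dhdl",
]


class SingularConfigurationError(ValueError):
    """A particle sits exactly on an interaction center of a non-soft-core
    potential, where LJ/Coulomb energies diverge."""


@dataclass(frozen=True)
class Species:
    """A mobile particle type: charge and Lennard-Jones parameters.

    Parameters
    ----------
    name : str
    charge : float
        In elementary charges.
    lj_epsilon : float
        LJ well depth, kJ/mol (>= 0).
    lj_sigma : float
        LJ radius, nm (> 0).
    mass : float
        Particle mass, g/mol.  Needed for the dynamics; 18 (water-like)
        by default.
    """

    name: str
    charge: float
    lj_epsilon: float
    lj_sigma: float
    mass: float = 18.0

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be >= 0")
        if self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be > 0")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")


@dataclass
class SiteModel:
    """A rigid environment for the tagged particle.

    ``centers`` is a sequence of ``(position, charge, lj_epsilon,
    lj_sigma)`` tuples (position is a length-3 array-like in nm).  The
    environment may additionally confine the particle with a harmonic cage
    of stiffness ``cage_k`` about ``site_center`` and always confines it to
    the cube ``|x_i| <= box_halfwidth`` with reflecting walls.  An empty
    ``centers`` list is a featureless box — the toy's "bulk" end state.
    """

    centers: Sequence[tuple] = field(default_factory=list)
    dielectric: float = 1.0
    cage_k: float = 0.0
    site_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    escape_radius: float = 0.6
    box_halfwidth: float = 1.0

    # derived arrays (filled in __post_init__)
    positions: np.ndarray = field(init=False, repr=False)
    charges: np.ndarray = field(init=False, repr=False)
    epsilons: np.ndarray = field(init=False, repr=False)
    sigmas: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.site_center = np.asarray(self.site_center, dtype=float)
        n = len(self.centers)
        self.positions = np.zeros((n, 3))
        self.charges = np.zeros(n)
        self.epsilons = np.zeros(n)
        self.sigmas = np.full(n, 0.3)
        for i, (pos, q, eps, sig) in enumerate(self.centers):
            self.positions[i] = np.asarray(pos, dtype=float)
            self.charges[i] = q
            self.epsilons[i] = eps
            self.sigmas[i] = sig
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("center positions must be finite")
        if np.any(self.epsilons < 0) or np.any(self.sigmas <= 0):
            raise ValueError("center LJ parameters invalid")
        if self.dielectric < 1:
            raise ValueError("dielectric must be >= 1")
        if self.cage_k < 0:
            raise ValueError("cage_k must be >= 0")
        if self.escape_radius <= 0:
            raise ValueError("escape_radius must be > 0")
        if not self.escape_radius < self.box_halfwidth:
            raise ValueError("escape_radius must be < box_halfwidth")


@dataclass(frozen=True)
class SimulationParams:
    """Langevin run settings.

    ``dt`` in ps, ``friction`` in ps^-1, ``temperature`` in K.
    ``burn_in_steps`` are simulated but flagged as equilibration by
    downstream consumers; ``sample_stride`` controls how often frames (and
    dH/dlambda values) are recorded.
    """

    temperature: float = 300.0
    friction: float = 1.0
    dt: float = 0.002
    n_steps: int = 10000
    burn_in_steps: int = 1000
    seed: int = 0
    sample_stride: int = 10

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if not self.n_steps > self.burn_in_steps >= 0:
            raise ValueError("need n_steps > burn_in_steps >= 0")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


@dataclass
class Trajectory:
    """Recorded path of the tagged particle.

    ``times`` in ps (strictly increasing, uniform stride), ``positions``
    with shape (n_frames, 3) in nm.
    """

    times: np.ndarray
    positions: np.ndarray
    species: Species
    site: SiteModel

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0) or not np.allclose(dts, dts[0]):
                raise ValueError("times must increase with uniform stride")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def frame_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


class SitePotential:
    """Plain (fully coupled) interaction of a species with a site.

    U(x) = sum_j [ 4 eps_ij (sig_ij^12/r^12 - sig_ij^6/r^6) + f q_i q_j /
    (dielectric r) ] + cage_k |x - site_center|^2 / 2, with
    Lorentz-Berthelot combination rules (arithmetic sigma, geometric
    epsilon).
    """

    def __init__(self, site: SiteModel, species: Species):
        self.site = site
        self.species = species
        self.eps_ij = np.sqrt(site.epsilons * species.lj_epsilon)
        self.sig_ij = 0.5 * (site.sigmas + species.lj_sigma)
        self.sig6 = self.sig_ij**6
        self.qq = F_COULOMB * site.charges * species.charge / site.dielectric

    def _distances(self, X: np.ndarray) -> np.ndarray:
        d = X[:, None, :] - self.site.positions[None, :, :]
        return np.sqrt(np.einsum("ijk,ijk->ij", d, d))

    def energies(self, X: np.ndarray) -> np.ndarray:
        """Potential energy for each frame in ``X`` (shape (N, 3))."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        dx = X - self.site.site_center
        cage = 0.5 * self.site.cage_k * np.einsum("ij,ij->i", dx, dx)
        if len(self.site.positions) == 0:
            return cage
        r = self._distances(X)
        active = (self.eps_ij > 0) | (self.qq != 0)
        if np.any((r == 0) & active[None, :]):
            raise SingularConfigurationError(
                "particle exactly on an interaction center (r = 0)"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_r6 = np.where(r > 0, self.sig6 / np.maximum(r, 1e-300) ** 6, 0.0)
            lj = 4.0 * self.eps_ij * (inv_r6**2 - inv_r6)
            coul = np.where(r > 0, self.qq / np.maximum(r, 1e-300), 0.0)
        return (lj + coul).sum(axis=1) + cage

    def energy(self, x: np.ndarray) -> float:
        return float(self.energies(np.asarray(x, dtype=float)[None, :])[0])

    def kernel_args(self) -> tuple:
        """Parameter pack for the compiled integrator (mode 0)."""
        n = len(self.site.positions)
        zeros = np.zeros(n)
        return (
            self.site.positions, self.eps_ij, self.sig6, self.qq,
            zeros, zeros, zeros,
            0.0, 0.0, 0.0, 0,
            self.site.cage_k, self.site.site_center,
            0.0, np.zeros(3),
        )

    def force(self, x: np.ndarray) -> np.ndarray:
        """-dU/dx at a single configuration."""
        x = np.asarray(x, dtype=float)
        f = -self.site.cage_k * (x - self.site.site_center)
        if len(self.site.positions) == 0:
            return f
        d = x[None, :] - self.site.positions
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        active = (self.eps_ij > 0) | (self.qq != 0)
        if np.any((r == 0) & active):
            raise SingularConfigurationError(
                "particle exactly on an interaction center (r = 0)"
            )
        r_safe = np.maximum(r, 1e-300)
        inv_r6 = self.sig6 / r_safe**6
        # dU/dr for LJ + Coulomb
        du_dr = 4.0 * self.eps_ij * (-12.0 * inv_r6**2 + 6.0 * inv_r6) / r_safe
        du_dr -= self.qq / r_safe**2
        with np.errstate(invalid="ignore"):
            f -= np.einsum("i,ij->j", np.where(r > 0, du_dr / r_safe, 0.0), d)
        return f


def potential_energy(site: SiteModel, species: Species, x: np.ndarray) -> float:
    """Pairwise LJ + screened Coulomb + optional harmonic cage, kJ/mol."""
    return SitePotential(site, species).energy(x)


def _reflect(x: np.ndarray, v: np.ndarray, half: float) -> None:
    """Reflect position/velocity at the walls of [-half, half]^3 in place."""
    over = x > half
    if over.any():
        x[over] = 2.0 * half - x[over]
        v[over] = -v[over]
    under = x < -half
    if under.any():
        x[under] = -2.0 * half - x[under]
        v[under] = -v[under]


def simulate_langevin(
    site: SiteModel,
    species: Species,
    params: SimulationParams,
    hamiltonian_override=None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate underdamped Langevin dynamics with the BAOAB splitting.

    ``hamiltonian_override`` may supply any object with a ``force(x)``
    method (e.g. an alchemical Hamiltonian frozen at fixed lambda); by
    default the plain :class:`SitePotential` of ``(site, species)`` is
    used.  Positions are reflected at ``site.box_halfwidth``.  The run is
    reproducible bit-for-bit given ``params.seed``.
    """
    ham = hamiltonian_override if hamiltonian_override is not None else SitePotential(site, species)
    rng = np.random.default_rng(params.seed)
    m = species.mass
    dt = params.dt
    kt = KB * params.temperature
    c1 = math.exp(-params.friction * dt)
    c2 = math.sqrt(kt / m * (1.0 - c1 * c1))
    half = site.box_halfwidth

    x = np.array(site.site_center if x0 is None else x0, dtype=float)
    v = rng.normal(0.0, math.sqrt(kt / m), size=3)
    noise = rng.normal(size=(params.n_steps, 3))

    n_rec = params.n_steps // params.sample_stride
    rec_pos = np.empty((n_rec, 3))
    rec_times = np.empty(n_rec)

    if hasattr(ham, "kernel_args"):
        from ._kernels import baoab_run

        (centers, epsA, sig6A, qqA, epsB, sig6B, qqB,
         padA, padB, lam, mode, cage_k, site_center, rest_k, rest_c) = ham.kernel_args()
        status = baoab_run(
            x, v, noise, dt, float(m), c1, c2, float(half),
            params.sample_stride,
            np.ascontiguousarray(centers, dtype=float),
            np.asarray(epsA, dtype=float), np.asarray(sig6A, dtype=float),
            np.asarray(qqA, dtype=float), np.asarray(epsB, dtype=float),
            np.asarray(sig6B, dtype=float), np.asarray(qqB, dtype=float),
            float(padA), float(padB), float(lam), int(mode),
            float(cage_k), np.asarray(site_center, dtype=float),
            float(rest_k), np.asarray(rest_c, dtype=float),
            rec_pos, rec_times,
        )
        if status != 0:
            where = "the initial configuration" if status < 0 else f"step {status}"
            raise FloatingPointError(
                f"diverging force at {where} (particle inside a singular core?)"
            )
        return Trajectory(times=rec_times, positions=rec_pos, species=species, site=site)

    f = ham.force(x)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("diverging force at the initial configuration")
    half_dt = 0.5 * dt
    stride = params.sample_stride
    k = 0
    for step in range(1, params.n_steps + 1):
        v += half_dt / m * f          # B
        x += half_dt * v              # A
        _reflect(x, v, half)
        v *= c1                        # O
        v += c2 * noise[step - 1]
        x += half_dt * v              # A
        _reflect(x, v, half)
        f = ham.force(x)              # B
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                f"diverging force at step {step} (particle inside a singular core?)"
            )
        v += half_dt / m * f
        if step % stride == 0:
            rec_pos[k] = x
            rec_times[k] = step * dt
            k += 1
    return Trajectory(times=rec_times, positions=rec_pos, species=species, site=site)


def generate_survival_synthetic(true_tau: float, M: int, T_s: float, seed: int):
    """Draw ``M`` exponential escape times with fixed-duration censoring.

    Times <= ``T_s`` are retained as events, the rest are censored at
    ``T_s``.  Returns a :class:`densassign.survival.SurvivalData`.
    """
    from .survival import SurvivalData

    if true_tau <= 0:
        raise ValueError("true_tau must be > 0")
    if M < 1:
        raise ValueError("M must be >= 1")
    if T_s <= 0:
        raise ValueError("T_s must be > 0")
    rng = np.random.default_rng(seed)
    t = rng.exponential(true_tau, size=M)
    escaped = t <= T_s
    return SurvivalData(
        escape_times=t[escaped],
        censor_times=np.full(int((~escaped).sum()), float(T_s)),
    )


def sample_dhdl(
    alch,
    lam: float,
    params: SimulationParams,
    site: SiteModel | None = None,
    species: Species | None = None,
):
    """Simulate under H(lambda=lam) and record dH/dlambda at sampled frames.

    ``alch`` must provide ``at_lambda(lam)`` returning a Hamiltonian with
    ``force(x)`` and a vectorized ``dhdl(X)``.  ``site``/``species``
    default to the ones attached to the Hamiltonian.  Returns a
    :class:`densassign.ti.DerivativeSeries` tagged with ``lam`` and the
    sampling interval; its ``burn_in`` is ``params.burn_in_steps * dt`` ps.
    """
    from .ti import DerivativeSeries

    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    ham = alch.at_lambda(lam)
    site = site if site is not None else ham.site
    species = species if species is not None else ham.species_a
    traj = simulate_langevin(site, species, params, hamiltonian_override=ham)
    values = ham.dhdl(traj.positions)
    return DerivativeSeries(
        lam=lam,
        dt=params.dt * params.sample_stride,
        values=np.asarray(values, dtype=float),
        burn_in=params.burn_in_steps * params.dt,
    )
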