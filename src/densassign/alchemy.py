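"""Lambda-coupled Hamiltonians with soft-core LJ and Coulomb interactions.

The alchemical coordinate lambda interpolates between two physical end
states (lambda = 0: state A, lambda = 1: state B).  To keep energies and
lambda-derivatives finite while a particle appears or vanishes, interatomic
distances entering the vanishing terms are soft-cored:

    d(r, w) = (alpha sigma_sc^6 w^p + r^6)^(1/6)

where w is the "off-ness" of the state (w = lambda for state A, 1 - lambda
for state B).  With alpha = 0.5, sigma_sc = 0.3 nm and p = 1 — the
parameterization this package defaults to — d(r=0) stays > 0.23 nm for any
intermediate lambda, removing the r -> 0 singularities of both the LJ and
the Coulomb terms.

Four coupling modes cover the legs of the thermodynamic cycles:

``relative``
    V = (1-lam) V_A(d_A) + lam V_B(d_B): species A morphs into species B
    (a ghost ``species_b=None`` makes this a full decoupling in one leg).
``decouple_coulomb``
    Charges of species A are scaled off over the soft-cored distance while
    LJ stays at full, unsoftened strength (charges leave before cores).
``decouple_lj``
    LJ of species A is scaled off over the soft-cored distance; charges
    are taken as already off.
``restraint_on``
    Full interactions plus a lambda-scaled harmonic position restraint
    K_x |x - x0|^2 / 2, so dH/dlambda is the restraint energy itself.

All derivatives dH/dlambda are analytic; a finite-difference cross-check
is part of the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .constants import F_COULOMB
from .toy_model import SiteModel, Species

__all__ = [
    "SoftCoreParams",
    "AlchemicalHamiltonian",
    "HarmonicSwitchHamiltonian",
    "softcore_distance",
    "alchemical_potential",
    "alchemical_dhdl",
    "MODES",
]

MODES = ("relative", "decouple_coulomb", "decouple_lj", "restraint_on")


@dataclass(frozen=True)
class SoftCoreParams:
    """Soft-core shape parameters (alpha dimensionless, sigma_sc in nm,
    integer power p in {1, 2})."""

    alpha: float = 0.5
    sigma_sc: float = 0.3
    power: int = 1

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma_sc <= 0:
            raise ValueError("sigma_sc must be > 0")
        if self.power not in (1, 2):
            raise ValueError("soft-core power must be 1 or 2")


def softcore_distance(r, lam_off, sc: SoftCoreParams):
    """Soft-cored distance (alpha sigma_sc^6 lam_off^p + r^6)^(1/6).

    Equals ``r`` exactly when ``lam_off`` is 0 (fully coupled state).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    pad = sc.alpha * sc.sigma_sc**6 * float(lam_off) ** sc.power
    out = (pad + r**6) ** (1.0 / 6.0)
    return out if out.ndim else float(out)


def _pair_terms(d, eps, sig6, qq):
    """LJ + Coulomb energy and d/d(distance) for pair arrays.

    ``d`` has shape (N, n_centers); eps/sig6/qq have shape (n_centers,).
    Returns (u, du_dd) with shape (N, n_centers).  Centers with eps = 0
    and qq = 0 (ghost pairs) contribute exactly zero even at d = 0; a
    genuinely interacting pair at d = 0 yields the physical infinity.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        inv6 = np.where(eps > 0, sig6 / d**6, 0.0)
        coul = np.where(qq != 0, qq / d, 0.0)
        u = 4.0 * eps * (inv6**2 - inv6) + coul
        du = (4.0 * eps * (-12.0 * inv6**2 + 6.0 * inv6) - coul) / d
        du = np.where((eps > 0) | (qq != 0), du, 0.0)
    return u, du


class _PairTable:
    """Combined LJ/Coulomb parameters of one species against the site."""

    def __init__(self, site: SiteModel, species: Species | None):
        if species is None or len(site.positions) == 0:
            self.ghost = True
            n = len(site.positions)
            self.eps = np.zeros(n)
            self.sig6 = np.zeros(n)
            self.qq = np.zeros(n)
        else:
            self.ghost = False
            self.eps = np.sqrt(site.epsilons * species.lj_epsilon)
            self.sig6 = (0.5 * (site.sigmas + species.lj_sigma)) ** 6
            self.qq = F_COULOMB * site.charges * species.charge / site.dielectric


@dataclass
class AlchemicalHamiltonian:
    """The lambda-coupled potential of one tagged particle in a site.

    ``species_b=None`` denotes the non-interacting ghost end state (used
    by the decoupling modes, and allowed in ``relative`` mode for a
    single-leg annihilation).  ``restraint_k`` > 0 adds a harmonic
    position restraint about ``restraint_center``: at full strength in the
    decouple modes (the restraint is on throughout those legs) and scaled
    by lambda in ``restraint_on`` mode.  The site's cage and the
    confinement box are environment terms and are never scaled.
    """

    site: SiteModel
    species_a: Species
    species_b: Species | None = None
    softcore: SoftCoreParams = field(default_factory=SoftCoreParams)
    mode: str = "relative"
    lam: float = 0.0
    restraint_k: float = 0.0
    restraint_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.restraint_k < 0:
            raise ValueError("restraint_k must be >= 0")
        self.restraint_center = np.asarray(self.restraint_center, dtype=float)
        self._pa = _PairTable(self.site, self.species_a)
        self._pb = _PairTable(self.site, self.species_b)

    def at_lambda(self, lam: float) -> "AlchemicalHamiltonian":
        """A copy of this Hamiltonian frozen at a different lambda."""
        return dataclasses.replace(self, lam=lam)

    def kernel_args(self) -> tuple:
        """Parameter pack for the compiled integrator (modes 1-4)."""
        mode = 1 + MODES.index(self.mode)  # relative -> 1 ... restraint_on -> 4
        sc = self.softcore
        padA = sc.alpha * sc.sigma_sc**6 * self.lam**sc.power
        padB = sc.alpha * sc.sigma_sc**6 * (1.0 - self.lam) ** sc.power
        rest_k = self.restraint_k * (self.lam if self.mode == "restraint_on" else 1.0)
        return (
            self.site.positions,
            self._pa.eps, self._pa.sig6, self._pa.qq,
            self._pb.eps, self._pb.sig6, self._pb.qq,
            padA, padB, self.lam, mode,
            self.site.cage_k, self.site.site_center,
            rest_k, self.restraint_center,
        )

    # -- internals ---------------------------------------------------------

    def _distances(self, X: np.ndarray) -> np.ndarray:
        d = X[:, None, :] - self.site.positions[None, :, :]
        return np.sqrt(np.einsum("ijk,ijk->ij", d, d))

    def _sc(self, r: np.ndarray, w: float):
        """Soft-core distance and its partial derivatives.

        Returns (d, dd_dw_core, dd_dr) where dd_dw_core is
        d d/d(w^p) * p w^(p-1), i.e. the full d d/d w.
        """
        sc = self.softcore
        pad = sc.alpha * sc.sigma_sc**6 * w**sc.power
        d6 = pad + r**6
        d = d6 ** (1.0 / 6.0)
        d5 = d**5
        dd_dw = sc.alpha * sc.sigma_sc**6 * sc.power * w ** (sc.power - 1) / (6.0 * d5)
        dd_dr = r**5 / d5
        return d, dd_dw, dd_dr

    def _env_energy(self, X: np.ndarray) -> np.ndarray:
        dx = X - self.site.site_center
        e = 0.5 * self.site.cage_k * np.einsum("ij,ij->i", dx, dx)
        if self.restraint_k > 0 and self.mode != "restraint_on":
            dr = X - self.restraint_center
            e += 0.5 * self.restraint_k * np.einsum("ij,ij->i", dr, dr)
        return e

    def _restraint_energy(self, X: np.ndarray) -> np.ndarray:
        dr = X - self.restraint_center
        return 0.5 * self.restraint_k * np.einsum("ij,ij->i", dr, dr)

    def _eval(self, X: np.ndarray, want: str):
        """Shared evaluation core.

        ``want`` in {"energy", "dhdl"}; returns an (N,) array.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lam = self.lam
        n = len(self.site.positions)
        out = np.zeros(len(X))
        if self.mode == "restraint_on":
            if want == "dhdl":
                return self._restraint_energy(X)
            if n:
                r = self._distances(X)
                u, _ = _pair_terms(
                    np.maximum(r, 1e-300), self._pa.eps, self._pa.sig6, self._pa.qq
                )
                out += u.sum(axis=1)
            return out + self._env_energy(X) + lam * self._restraint_energy(X)

        if n == 0:
            return out if want == "dhdl" else out + self._env_energy(X)
        r = self._distances(X)

        if self.mode == "relative":
            dA, dAw, _ = self._sc(r, lam)
            dB, dBw, _ = self._sc(r, 1.0 - lam)
            uA, duA = _pair_terms(dA, self._pa.eps, self._pa.sig6, self._pa.qq)
            uB, duB = _pair_terms(dB, self._pb.eps, self._pb.sig6, self._pb.qq)
            if want == "energy":
                out = ((1.0 - lam) * uA + lam * uB).sum(axis=1)
                return out + self._env_energy(X)
            d_dl = (
                -uA
                + (1.0 - lam) * duA * dAw
                + uB
                - lam * duB * dBw
            )
            return d_dl.sum(axis=1)

        if self.mode == "decouple_coulomb":
            dA, dAw, _ = self._sc(r, lam)
            with np.errstate(divide="ignore", invalid="ignore"):
                uC = np.where(self._pa.qq != 0, self._pa.qq / dA, 0.0)
                duC = np.where(self._pa.qq != 0, -self._pa.qq / dA**2, 0.0)
            if want == "energy":
                lj, _ = _pair_terms(
                    r, self._pa.eps, self._pa.sig6, np.zeros_like(self._pa.qq)
                )
                return lj.sum(axis=1) + ((1.0 - lam) * uC).sum(axis=1) + self._env_energy(X)
            return (-uC + (1.0 - lam) * duC * dAw).sum(axis=1)

        # decouple_lj: charges already off
        dA, dAw, _ = self._sc(r, lam)
        uL, duL = _pair_terms(
            dA, self._pa.eps, self._pa.sig6, np.zeros_like(self._pa.qq)
        )
        if want == "energy":
            return ((1.0 - lam) * uL).sum(axis=1) + self._env_energy(X)
        return (-uL + (1.0 - lam) * duL * dAw).sum(axis=1)

    # -- public surface ----------------------------------------------------

    def energies(self, X: np.ndarray) -> np.ndarray:
        """V(lambda) for each frame in ``X`` (shape (N, 3)), kJ/mol."""
        return self._eval(X, "energy")

    def energy(self, x: np.ndarray) -> float:
        return float(self._eval(np.asarray(x, dtype=float)[None, :], "energy")[0])

    def dhdl(self, X: np.ndarray) -> np.ndarray:
        """Analytic dV/dlambda for each frame in ``X``, kJ/mol."""
        return self._eval(X, "dhdl")

    def dhdl_single(self, x: np.ndarray) -> float:
        return float(self.dhdl(np.asarray(x, dtype=float)[None, :])[0])

    def force(self, x: np.ndarray) -> np.ndarray:
        """-dV/dx at a single configuration."""
        x = np.asarray(x, dtype=float)
        lam = self.lam
        f = -self.site.cage_k * (x - self.site.site_center)
        if self.restraint_k > 0:
            scale = lam if self.mode == "restraint_on" else 1.0
            f -= scale * self.restraint_k * (x - self.restraint_center)
        n = len(self.site.positions)
        if n == 0:
            return f
        d = x[None, :] - self.site.positions
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        r_safe = np.maximum(r, 1e-300)

        if self.mode == "restraint_on":
            _, du = _pair_terms(
                r_safe[None, :], self._pa.eps, self._pa.sig6, self._pa.qq
            )
            du_dr = du[0]
        elif self.mode == "relative":
            dA, _, dAr = self._sc(r, lam)
            dB, _, dBr = self._sc(r, 1.0 - lam)
            _, duA = _pair_terms(dA[None, :], self._pa.eps, self._pa.sig6, self._pa.qq)
            _, duB = _pair_terms(dB[None, :], self._pb.eps, self._pb.sig6, self._pb.qq)
            du_dr = (1.0 - lam) * duA[0] * dAr + lam * duB[0] * dBr
        elif self.mode == "decouple_coulomb":
            dA, _, dAr = self._sc(r, lam)
            inv6 = self._pa.sig6 / r_safe**6
            du_lj = 4.0 * self._pa.eps * (-12.0 * inv6**2 + 6.0 * inv6) / r_safe
            du_dr = du_lj + (1.0 - lam) * (-self._pa.qq / dA**2) * dAr
        else:  # decouple_lj
            dA, _, dAr = self._sc(r, lam)
            inv6 = self._pa.sig6 / dA**6
            duL = 4.0 * self._pa.eps * (-12.0 * inv6**2 + 6.0 * inv6) / dA
            du_dr = (1.0 - lam) * duL * dAr
        with np.errstate(invalid="ignore"):
            f -= np.einsum("i,ij->j", np.where(r > 0, du_dr / r_safe, 0.0), d)
        return f


def alchemical_potential(alch: AlchemicalHamiltonian, x: np.ndarray) -> float:
    """V(lambda) at configuration ``x``, kJ/mol."""
    return alch.energy(x)


def alchemical_dhdl(alch: AlchemicalHamiltonian, x: np.ndarray) -> float:
    """Analytic dV/dlambda at configuration ``x``, kJ/mol.

    Finite for every ``x`` (including r = 0) whenever 0 < lambda < 1 and
    the diverging terms are soft-cored.
    """
    return alch.dhdl_single(x)


@dataclass
class HarmonicSwitchHamiltonian:
    """Linear interpolation between two isotropic harmonic wells.

    V(lambda) = (1-lam)(c0 + k0 |x-x0|^2/2) + lam (c1 + k1 |x-x0|^2/2),
    so dV/dlambda = (c1 - c0) + (k1 - k0)|x-x0|^2/2.  This is the package's
    main analytic oracle: the exact free-energy difference of switching a
    3-D harmonic well from k0 to k1 at temperature T is
    (3/2) kB T ln(k1/k0) (plus c1 - c0), and switching a restraint onto a
    free particle (k0 = 0) in a box of volume V_box gives
    kB T ln(V_box / V_eff) up to wall-truncation corrections.

    ``site``/``species_a`` mirror the attributes of
    :class:`AlchemicalHamiltonian` so :func:`~densassign.toy_model.sample_dhdl`
    can drive either interchangeably.
    """

    site: SiteModel
    species_a: Species
    k0: float = 0.0
    k1: float = 0.0
    c0: float = 0.0
    c1: float = 0.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.k0 < 0 or self.k1 < 0:
            raise ValueError("force constants must be >= 0")
        self.center = np.asarray(self.center, dtype=float)

    def at_lambda(self, lam: float) -> "HarmonicSwitchHamiltonian":
        return dataclasses.replace(self, lam=lam)

    def kernel_args(self) -> tuple:
        """Parameter pack for the compiled integrator (mode 5)."""
        empty = np.zeros(0)
        return (
            np.zeros((0, 3)), empty, empty, empty, empty, empty, empty,
            0.0, 0.0, self.lam, 5,
            0.0, np.zeros(3),
            self._k(), self.center,
        )

    def _k(self) -> float:
        return (1.0 - self.lam) * self.k0 + self.lam * self.k1

    def energies(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        dx = X - self.center
        r2 = np.einsum("ij,ij->i", dx, dx)
        off = (1.0 - self.lam) * self.c0 + self.lam * self.c1
        return off + 0.5 * self._k() * r2

    def energy(self, x: np.ndarray) -> float:
        return float(self.energies(np.asarray(x, dtype=float)[None, :])[0])

    def force(self, x: np.ndarray) -> np.ndarray:
        return -self._k() * (np.asarray(x, dtype=float) - self.center)

    def dhdl(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        dx = X - self.center
        r2 = np.einsum("ij,ij->i", dx, dx)
        return (self.c1 - self.c0) + 0.5 * (self.k1 - self.k0) * r2

    def dhdl_single(self, x: np.ndarray) -> float:
        return float(self.dhdl(np.asarray(x, dtype=float)[None, :])[0])
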