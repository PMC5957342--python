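"""Assembly of relative and absolute binding free energies from leg results.

Relative cycle
--------------
Alchemically transforming an ion into a water at the binding site (dG3)
and a water into an ion in bulk (dG2, or equivalently the reverse leg of
the same transformation run in bulk) closes a thermodynamic cycle whose
physical content is the binding free-energy difference

    ddG_bind = dG3 - dG2,

negative when water binds more favourably than the ion.

Absolute cycle
--------------
The absolute binding free energy of a species is obtained by decoupling it
once at the site and once in bulk:

    dG_bind = dG2 - dG1

where dG1 (site path) = restrain (simulated) + Coulomb off + LJ off +
translation of the non-interacting particle (identically zero), and dG2
(bulk path) = the bulk decoupling legs plus the analytic standard-state
restraint term.  Restraining a non-interacting particle with a harmonic
potential of force constant K_x confines it to the effective volume

    V_eff = (2 pi kB T / K_x)^(3/2),

and the free energy of confining an ideal particle from the standard
volume V0 into V_eff is kB T ln(V0 / V_eff) — with K_x = 200 kJ/mol/nm^2,
T = 300 K and V0 = 0.02992 nm^3 (the molecular volume of water) this is
the well-known 0.774 kJ/mol correction.  The module stores the magnitude
and applies it on the bulk path, which keeps the assembled dG_bind
self-consistent: for a purely harmonic site of stiffness K_cage and depth
E0 the assembly reduces to the closed form
dG_bind = -E0 + kB T ln(V0 / V_eff(K_cage)), independent of K_x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KB, V_STANDARD_WATER

__all__ = [
    "LegResult",
    "RestraintSpec",
    "RelativeCycle",
    "AbsoluteCycle",
    "relative_ddg",
    "restraint_free_energy",
    "assemble_absolute",
    "restraint_confinement_free_energy",
    "occupancy_ratio",
    "REQUIRED_SITE_LEGS",
]

#: Leg names assemble_absolute requires on the site path.
REQUIRED_SITE_LEGS = ("posre_on", "coulomb_off", "lj_off")


@dataclass(frozen=True)
class LegResult:
    """One simulated leg of a thermodynamic cycle."""

    name: str
    delta_g: float
    stderr: float = 0.0

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic position restraint and standard-state bookkeeping.

    ``k_x`` in kJ mol^-1 nm^-2, ``temperature`` in K, ``v_standard`` in
    nm^3 (default: molecular volume of water, tying the absolute free
    energy to a water-replacement interpretation).
    """

    k_x: float = 200.0
    temperature: float = 300.0
    v_standard: float = V_STANDARD_WATER

    def __post_init__(self) -> None:
        if self.k_x <= 0 or self.temperature <= 0 or self.v_standard <= 0:
            raise ValueError("k_x, temperature and v_standard must be > 0")

    @property
    def v_eff(self) -> float:
        """Effective volume (2 pi kB T / K_x)^(3/2), nm^3."""
        return (2.0 * math.pi * KB * self.temperature / self.k_x) ** 1.5


@dataclass(frozen=True)
class RelativeCycle:
    """The two simulated legs of a relative (A <-> B) cycle.

    ``leg_g3``: transformation at the binding site; ``leg_g2``: the same
    transformation in bulk solvent.
    """

    leg_g3: LegResult
    leg_g2: LegResult


@dataclass
class AbsoluteCycle:
    """Leg bookkeeping for one absolute decoupling cycle.

    ``legs_site`` must contain the sub-steps named ``posre_on``,
    ``coulomb_off`` and ``lj_off``; the translation of the decoupled
    particle into bulk is identically zero and hard-coded.  ``legs_bulk``
    holds the bulk decoupling legs (the analytic standard-state restraint
    term is added by :func:`assemble_absolute`, never listed as a leg).
    """

    legs_site: Sequence[LegResult] = field(default_factory=list)
    legs_bulk: Sequence[LegResult] = field(default_factory=list)


def relative_ddg(cycle: RelativeCycle) -> tuple[float, float]:
    """ddG_bind = dG3 - dG2; negative favours water binding.

    The uncertainty is the root-sum-square of the leg errors.
    """
    if cycle.leg_g3 is None or cycle.leg_g2 is None:
        missing = "leg_g3" if cycle.leg_g3 is None else "leg_g2"
        raise ValueError(f"relative cycle is missing {missing}")
    ddg = cycle.leg_g3.delta_g - cycle.leg_g2.delta_g
    err = math.hypot(cycle.leg_g3.stderr, cycle.leg_g2.stderr)
    return ddg, err


def restraint_free_energy(spec: RestraintSpec) -> float:
    """|kB T ln(V0 / V_eff)|: the analytic standard-state restraint term.

    The magnitude is returned (matching how the correction is usually
    quoted); :func:`assemble_absolute` applies the signed form
    :func:`restraint_confinement_free_energy` at its place in the cycle.
    """
    return abs(restraint_confinement_free_energy(spec))


def restraint_confinement_free_energy(spec: RestraintSpec) -> float:
    """Signed free energy +kB T ln(V0/V_eff) of confining an ideal
    particle from the standard volume into the restraint's effective
    volume (negative if the restraint is softer than the standard
    volume is small)."""
    kt = KB * spec.temperature
    return kt * math.log(spec.v_standard / spec.v_eff)


def assemble_absolute(
    cycle: AbsoluteCycle, spec: RestraintSpec
) -> tuple[float, float]:
    """dG_bind = dG2 - dG1 with the analytic restraint term on the bulk path.

    dG1 = sum of the site legs (+ the identically-zero translation step);
    dG2 = sum of the bulk legs + |kB T ln(V0/V_eff)| (zero stderr).
    Errors are propagated in quadrature across all simulated legs.
    """
    names = {leg.name for leg in cycle.legs_site}
    missing = [n for n in REQUIRED_SITE_LEGS if n not in names]
    if missing:
        raise ValueError(f"absolute cycle site path is missing legs: {missing}")
    dg1 = sum(leg.delta_g for leg in cycle.legs_site)  # + 0 (translation)
    dg2 = sum(leg.delta_g for leg in cycle.legs_bulk) + restraint_confinement_free_energy(spec)
    var = sum(leg.stderr**2 for leg in cycle.legs_site)
    var += sum(leg.stderr**2 for leg in cycle.legs_bulk)
    return dg2 - dg1, math.sqrt(var)


def occupancy_ratio(ddg: float, c_wat: float, c_ion: float, T: float) -> float:
    """P_bind^wat / P_bind^ion = (c_wat/c_ion) exp(-ddG/kBT).

    Concentrations in any common unit (only the ratio enters).  Overflow
    returns +inf.
    """
    if c_wat <= 0 or c_ion <= 0:
        raise ValueError("concentrations must be > 0")
    if T <= 0:
        raise ValueError("temperature must be > 0")
    with np.errstate(over="ignore"):
        ratio = (c_wat / c_ion) * np.exp(-ddg / (KB * T))
    return float(ratio)
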