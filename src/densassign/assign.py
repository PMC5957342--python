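"""Three-criterion decision logic for ambiguous water/ion densities.

A candidate site is adjudicated from three independent lines of evidence:

1. the relative binding free energy ddG between the two candidate species
   (robust only when it deviates strongly from zero — ion force-field
   uncertainty contaminates small differences);
2. the absolute binding free energy of water, which must be negative or
   near zero for a water assignment to be plausible at all;
3. comparative residence lifetimes in free simulations, with censored
   estimates treated conservatively (a lower bound only ever supports the
   species it bounds).

The criteria are combined conjunctively: a verdict is issued only when at
least one criterion speaks and none opposes it; any disagreement is
surfaced as "inconclusive" rather than averaged away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "WATER_FAVORED",
    "ION_FAVORED",
    "INCONCLUSIVE",
    "PLAUSIBLE",
    "IMPLAUSIBLE",
    "Thresholds",
    "SiteAssessment",
    "Verdict",
    "criterion_relative",
    "criterion_absolute",
    "criterion_stability",
    "verdict",
]

WATER_FAVORED = "water_favored"
ION_FAVORED = "ion_favored"
INCONCLUSIVE = "inconclusive"
PLAUSIBLE = "plausible"
IMPLAUSIBLE = "implausible"


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds (all > 0, configurable, declared — not fitted).

    ``ddg_robust``: |ddG| below this is not considered decisive (kJ/mol).
    The default 20 sits conservatively between the force-field bias scale
    (~40 kJ/mol for ion-aromatic interactions) and the hundreds of kJ/mol
    where conclusions are unambiguous.
    ``dg_plausible``: water binding counts as plausible when dG_bind does
    not exceed this (kJ/mol) — "negative or at least close to zero".
    ``tau_ratio``: lifetime ratio (default one order of magnitude) needed
    for the stability criterion to favour a species.
    """

    ddg_robust: float = 20.0
    dg_plausible: float = 5.0
    tau_ratio: float = 10.0

    def __post_init__(self) -> None:
        if min(self.ddg_robust, self.dg_plausible, self.tau_ratio) <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class SiteAssessment:
    """Collected evidence for one candidate site.

    ``ddg``/``dg_bind_water`` are (value, stderr) pairs in kJ/mol;
    ``tau_water``/``tau_ion`` are (lifetime_ns, is_lower_bound) pairs.
    Any line of evidence may be None (not computed).
    """

    ddg: tuple[float, float] | None = None
    dg_bind_water: tuple[float, float] | None = None
    tau_water: tuple[float, bool] | None = None
    tau_ion: tuple[float, bool] | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)


@dataclass
class Verdict:
    call: str
    evidence: dict
    rationale: str


def criterion_relative(ddg: float, stderr: float, ddg_robust: float) -> str:
    """Label from the relative binding free energy.

    Water is favoured when ddG is both strongly negative (beyond the
    robustness threshold) and statistically resolved (|ddG| > 2 sigma);
    symmetrically for the ion.  Anything near zero is inconclusive.
    """
    if stderr < 0:
        raise ValueError("stderr must be >= 0")
    if ddg < -ddg_robust and abs(ddg) > 2.0 * stderr:
        return WATER_FAVORED
    if ddg > ddg_robust and abs(ddg) > 2.0 * stderr:
        return ION_FAVORED
    return INCONCLUSIVE


def criterion_absolute(dg_bind: float, stderr: float, dg_plausible: float) -> str:
    """Is water binding plausible per se?  dG_bind must be <= +tolerance."""
    if stderr < 0:
        raise ValueError("stderr must be >= 0")
    return PLAUSIBLE if dg_bind <= dg_plausible else IMPLAUSIBLE


def criterion_stability(
    tau_water: tuple[float, bool],
    tau_ion: tuple[float, bool],
    ratio_threshold: float = 10.0,
) -> str:
    """Label from comparative residence lifetimes.

    A species is favoured when its lifetime (or lower bound) exceeds the
    other's point estimate by at least ``ratio_threshold``.  Bounds are
    compared conservatively: a lower bound supports only the species it
    bounds, so two censored lifetimes are always inconclusive.
    """
    tw, w_bound = tau_water
    ti, i_bound = tau_ion
    if tw <= 0 or ti <= 0:
        raise ValueError("lifetimes must be > 0")
    if w_bound and i_bound:
        return INCONCLUSIVE
    if not i_bound and tw >= ratio_threshold * ti:
        return WATER_FAVORED
    if not w_bound and ti >= ratio_threshold * tw:
        return ION_FAVORED
    return INCONCLUSIVE


def verdict(assessment: SiteAssessment) -> Verdict:
    """Combine the criteria conjunctively into a single call.

    water_favored / ion_favored require agreement of every criterion that
    speaks; the absolute criterion acts as a veto on water (an implausible
    water dG_bind blocks a water call but does not by itself identify the
    ion).  All-inconclusive, or any opposition, yields inconclusive.
    """
    th = assessment.thresholds
    evidence: dict = {}
    votes = []

    if assessment.ddg is not None:
        val, err = assessment.ddg
        label = criterion_relative(val, err, th.ddg_robust)
        evidence["relative"] = {"label": label, "ddg_kj_mol": val, "stderr_kj_mol": err}
        votes.append(label)
    abs_label = None
    if assessment.dg_bind_water is not None:
        val, err = assessment.dg_bind_water
        abs_label = criterion_absolute(val, err, th.dg_plausible)
        evidence["absolute_water"] = {
            "label": abs_label,
            "dg_bind_kj_mol": val,
            "stderr_kj_mol": err,
        }
    if assessment.tau_water is not None and assessment.tau_ion is not None:
        label = criterion_stability(
            assessment.tau_water, assessment.tau_ion, th.tau_ratio
        )
        evidence["stability"] = {
            "label": label,
            "tau_water_ns": assessment.tau_water[0],
            "tau_water_is_bound": assessment.tau_water[1],
            "tau_ion_ns": assessment.tau_ion[0],
            "tau_ion_is_bound": assessment.tau_ion[1],
        }
        votes.append(label)

    if not evidence:
        raise ValueError("no criterion is evaluable")

    decisive = [v for v in votes if v != INCONCLUSIVE]
    if not decisive:
        call = INCONCLUSIVE
        why = "no criterion is decisive"
    elif WATER_FAVORED in decisive and ION_FAVORED in decisive:
        call = INCONCLUSIVE
        why = "criteria oppose each other"
    elif decisive[0] == WATER_FAVORED:
        if abs_label == IMPLAUSIBLE:
            call = INCONCLUSIVE
            why = "water favoured relatively but absolute water binding is implausible"
        else:
            call = WATER_FAVORED
            why = "all decisive criteria favour water and none opposes"
    else:
        call = ION_FAVORED
        why = "all decisive criteria favour the ion and none opposes"
    return Verdict(call=call, evidence=evidence, rationale=why)
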