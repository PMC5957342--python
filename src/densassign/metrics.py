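"""Trajectory-derived stability observables.

Escape detection (feeding the censored lifetime estimator), projections of
the particle path onto an axis (the membrane-normal traces one inspects by
eye), and root-mean-square fluctuations about the mean position (the
standard proxy for how localized — hence how crystallographically
resolvable — a bound solvent molecule is).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .toy_model import SiteModel, Trajectory

__all__ = [
    "EscapeEvent",
    "RmsfResult",
    "detect_escape",
    "rmsf",
    "axis_trace",
    "events_to_survival",
]


@dataclass(frozen=True)
class EscapeEvent:
    """Outcome of watching one molecule: escape at ``time`` (ns) or
    censoring at trajectory end."""

    molecule_id: str
    escaped: bool
    time: float

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be > 0")


@dataclass(frozen=True)
class RmsfResult:
    rmsf: float
    n_frames: int
    reference: str = "mean-position"

    def __post_init__(self) -> None:
        if self.rmsf < 0:
            raise ValueError("rmsf must be >= 0")


def detect_escape(
    traj: Trajectory,
    site: SiteModel | None = None,
    persistence: float = 5.0,
    molecule_id: str = "mol",
) -> EscapeEvent:
    """First sustained exit of the particle from the site's escape sphere.

    The escape time is the first frame at which |x - site_center| >
    escape_radius holds continuously for at least ``persistence`` ps —
    brief rattling excursions across the boundary do not count.  If no
    such exit occurs the molecule is censored at the trajectory end.
    Times are reported in ns.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    site = site if site is not None else traj.site
    d = traj.positions - site.site_center
    outside = np.einsum("ij,ij->i", d, d) > site.escape_radius**2
    frame_dt = traj.frame_dt or traj.times[0]
    need = max(1, math.ceil(persistence / frame_dt)) if persistence > 0 else 1

    run = 0
    for i, out in enumerate(outside):
        run = run + 1 if out else 0
        if run >= need:
            start = i - run + 1
            return EscapeEvent(
                molecule_id=molecule_id,
                escaped=True,
                time=float(traj.times[start]) / 1000.0,
            )
    return EscapeEvent(
        molecule_id=molecule_id, escaped=False, time=float(traj.times[-1]) / 1000.0
    )


def rmsf(traj: Trajectory, equilibration: float = 0.0) -> RmsfResult:
    """sqrt(< |x - <x>|^2 >) over frames with t >= ``equilibration`` ps.

    The reference is the retained-frame mean position, not the initial
    frame, so a particle vibrating in a well reports its thermal cloud
    size (sqrt(3 kB T / K) for an isotropic harmonic well of stiffness K).
    """
    keep = traj.times >= equilibration
    X = traj.positions[keep]
    if len(X) < 2:
        raise ValueError("need at least 2 frames after equilibration removal")
    d = X - X.mean(axis=0)
    return RmsfResult(
        rmsf=float(np.sqrt(np.einsum("ij,ij->i", d, d).mean())),
        n_frames=len(X),
    )


def axis_trace(traj: Trajectory, axis) -> tuple[np.ndarray, np.ndarray]:
    """Projections of the particle positions onto a (normalized) axis."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    return traj.times.copy(), traj.positions @ (axis / norm)


def events_to_survival(events: Sequence[EscapeEvent]):
    """Pool escape/censoring events into a SurvivalData record."""
    from .survival import SurvivalData

    if not events:
        raise ValueError("no events")
    return SurvivalData(
        escape_times=np.array([e.time for e in events if e.escaped]),
        censor_times=np.array([e.time for e in events if not e.escaped]),
    )
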