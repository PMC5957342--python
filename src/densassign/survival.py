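"""Censored maximum-likelihood lifetime estimation for site residence.

Residence times at a binding site are modelled as exponential with mean
tau.  Monitoring M molecules for finite spans censors the molecules that
never leave; the maximum-likelihood estimate of tau under fixed-duration
(type-I) censoring is the classic

    tau_ml = m^-1 [ (M - m) T_s + sum_i t_i ]

— total time at risk divided by the number of escape events — which
generalizes transparently to per-molecule observation spans.  When no
event is observed (m = 0) the likelihood is monotone in tau and only a
lower bound can be reported: the total observation time, flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurvivalData", "tau_ml", "tau_confidence"]


@dataclass
class SurvivalData:
    """Escape/censoring record of M monitored molecules.

    ``escape_times`` (length m) are the observed residence times of the
    molecules that left; ``censor_times`` (length M - m) are the
    observation spans of the molecules that never left.  All times in ns.
    """

    escape_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    censor_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.escape_times = np.atleast_1d(np.asarray(self.escape_times, dtype=float))
        self.censor_times = np.atleast_1d(np.asarray(self.censor_times, dtype=float))
        if self.M < 1:
            raise ValueError("need at least one monitored molecule")
        if np.any(self.escape_times <= 0) or np.any(self.censor_times <= 0):
            raise ValueError("times must be > 0")

    @classmethod
    def from_pooled(cls, M: int, T_s: float, escape_times) -> "SurvivalData":
        """Common-span constructor: M molecules each observed for T_s ns."""
        escape_times = np.atleast_1d(np.asarray(escape_times, dtype=float))
        m = len(escape_times)
        if m > M:
            raise ValueError("more escape events than molecules")
        if np.any(escape_times > T_s):
            raise ValueError("escape times must not exceed the observation span")
        return cls(
            escape_times=escape_times,
            censor_times=np.full(M - m, float(T_s)),
        )

    @property
    def M(self) -> int:
        return len(self.escape_times) + len(self.censor_times)

    @property
    def m(self) -> int:
        return len(self.escape_times)

    @property
    def time_at_risk(self) -> float:
        """Total observed time, ns: sum of event times and censored spans."""
        return float(self.escape_times.sum() + self.censor_times.sum())


def tau_ml(data: SurvivalData) -> tuple[float, bool]:
    """Censored-exponential MLE of the residence time, ns.

    Returns ``(tau, is_lower_bound)``.  With at least one event the
    estimate is time-at-risk / events and the flag is False; with no
    events the total observation time is returned flagged as a lower
    bound (the data only support "tau is at least this much").
    """
    if data.m == 0:
        return data.time_at_risk, True
    return data.time_at_risk / data.m, False


def tau_confidence(
    data: SurvivalData,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile interval for the residence time.

    Escape experiments are resampled from Exponential(tau_ml) under the
    same censoring layout (each molecule keeps its observation span; the
    spans of molecules that escaped are taken as the longest observed span,
    the only information the data carry about them).  Fully censored data
    return (lower bound, +inf).  The interval is widened, if necessary, to
    contain the point estimate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    tau, is_bound = tau_ml(data)
    if is_bound:
        return tau, float("inf")
    span_pool = np.concatenate([data.censor_times, data.escape_times])
    default_span = float(span_pool.max())
    spans = np.concatenate(
        [np.full(data.m, default_span), data.censor_times]
    )
    rng = np.random.default_rng(seed)
    draws = rng.exponential(tau, size=(n_boot, data.M))
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        t = draws[b]
        escaped = t <= spans
        m = int(escaped.sum())
        at_risk = float(t[escaped].sum() + spans[~escaped].sum())
        estimates[b] = at_risk if m == 0 else at_risk / m
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return min(float(lo), tau), max(float(hi), tau)
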