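"""Closed-form lineage timing for exponentially growing multi-lineage tissues.

With ``l`` lineages dividing synchronously every ``r`` hours, the population
after ``n`` generations is ``P = l * 2**n``.  Solving for time gives

    t = log2(P / l) * r

which relates the ~900 follicle cells of a Stage-6 egg chamber, the number of
founding stem-cell lineages, and the 9.6 h follicle-cell cycle: two founders
need ~85 h (compatible with the ~100 h transit from the germarium border to
Stage 6), whereas sixteen founders would need only ~56 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TimingQuery", "time_to_population", "population_after"]


class TimingDomainError(ValueError):
    """Inputs outside the model's domain (P < l, nonpositive rate, ...)."""


@dataclass(frozen=True)
class TimingQuery:
    """A resolved timing computation: population P, lineages l, rate r (h per
    division), elapsed time t (h) and generation count n = t / r."""

    P: float
    l: int
    r: float
    t: float

    @property
    def n_generations(self) -> float:
        return self.t / self.r

    @property
    def t_rounded(self) -> int:
        return round(self.t)


def time_to_population(P: float, l: int, r: float) -> TimingQuery:
    """Hours for ``l`` lineages dividing every ``r`` h to reach ``P`` cells.

    Returns a :class:`TimingQuery` whose ``t`` is the exact value
    ``log2(P/l) * r`` and whose ``t_rounded`` is the nearest integer hour.
    """
    if r <= 0:
        raise TimingDomainError(f"division time r must be positive, got {r}")
    if l < 1:
        raise TimingDomainError(f"lineage count l must be >= 1, got {l}")
    if P < l:
        raise TimingDomainError(f"target population P={P} below lineage count l={l}")
    t = math.log2(P / l) * r
    return TimingQuery(P=P, l=l, r=r, t=t)


def population_after(t: float, l: int, r: float) -> float:
    """Continuous population size ``l * 2**(t/r)`` after ``t`` hours.

    Inverse of :func:`time_to_population`.
    """
    if r <= 0:
        raise TimingDomainError(f"division time r must be positive, got {r}")
    if l < 1:
        raise TimingDomainError(f"lineage count l must be >= 1, got {l}")
    if t < 0:
        raise TimingDomainError(f"time must be non-negative, got {t}")
    return l * 2.0 ** (t / r)
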