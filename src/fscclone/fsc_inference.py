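"""Inference of active follicle-stem-cell number from clone-size fractions.

Under neutral growth with ``l`` equipotent active FSCs, a single labeled FSC
lineage is expected to produce ``1/l`` of the follicle-cell population, so the
mean labeled fraction across mosaic ovarioles identifies ``l`` through its
reciprocal: a mean clone size of ~50% implies two active FSCs.  Uncertainty is
quantified by a percentile bootstrap over ovarioles, and the population-level
spread of clone sizes translates (via mean +/- 2 SD) into an implied range of
FSC numbers — e.g. the published 50.1 +/- 14.1% clone size is compatible with
roughly one to four active FSCs.

Also provided: inversion of the labeling complement rule
``1 - (1 - p)**l = fraction_with_clones`` to recover the per-FSC induction
probability, and Welch tests for cross-condition clone-size comparisons.

For a statsmodels-style workflow, :class:`CloneSizeModel` wraps these
estimators into a fit/results object with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FscEstimate",
    "estimate_fsc_number",
    "implied_fsc_range",
    "estimate_induction_probability",
    "compare_clone_sizes",
    "CloneSizeModel",
    "CloneSizeResults",
]

#: Floor for (mean - 2 SD) when it is non-positive; caps the upper bound of
#: the implied FSC range at 1/_EPS_FRACTION.
_EPS_FRACTION = 1e-3


@dataclass(frozen=True)
class FscEstimate:
    """Inferred number of active FSCs from mosaic clone-size fractions."""

    mean_fraction: float
    sd_fraction: float
    l_hat: float
    l_rounded: int
    ci: tuple[float, float]
    implied_range: tuple[float, float]
    n: int
    n_boot: int


def estimate_fsc_number(
    fractions: Sequence[float],
    n_boot: int = 10_000,
    seed: "int | np.random.Generator | None" = None,
    ci_level: float = 0.95,
) -> FscEstimate:
    """Reciprocal-mean estimate of active FSC number.

    ``l_hat = 1 / mean(fractions)`` with a seeded percentile bootstrap CI
    over ovarioles.  Fractions must come from mosaic ovarioles with
    persistent clones (values in (0, 1]).
    """
    x = np.asarray(list(fractions), dtype=float)
    if x.size == 0:
        raise ValueError("fractions must be non-empty")
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("all fractions must lie in (0, 1]")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    l_hat = max(1.0, 1.0 / mean)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot = 1.0 / x[idx].mean(axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    lo = min(float(lo), l_hat)
    hi = max(float(hi), l_hat)
    return FscEstimate(
        mean_fraction=mean,
        sd_fraction=sd,
        l_hat=l_hat,
        l_rounded=max(1, round(l_hat)),
        ci=(lo, hi),
        implied_range=implied_fsc_range(mean, sd),
        n=int(x.size),
        n_boot=int(n_boot),
    )


def implied_fsc_range(mean_fraction: float, sd_fraction: float) -> tuple[float, float]:
    """FSC-number range implied by clone sizes within mean +/- 2 SD.

    ``low = 1/(mean + 2 sd)`` (clamped to >= 1) and
    ``high = 1/max(mean - 2 sd, eps)`` with ``eps = 1e-3``.  Returned
    unrounded; e.g. (0.501, 0.141) -> (1.28, 4.57), the published
    "approximately one to four FSCs".
    """
    if mean_fraction <= 0:
        raise ValueError("mean_fraction must be positive")
    if sd_fraction < 0:
        raise ValueError("sd_fraction must be non-negative")
    hi_frac = min(mean_fraction + 2.0 * sd_fraction, 1.0)
    lo_frac = max(mean_fraction - 2.0 * sd_fraction, _EPS_FRACTION)
    low = max(1.0, 1.0 / hi_frac)
    high = 1.0 / lo_frac
    return (low, high)


def estimate_induction_probability(frac_with_clones: float, l: int) -> float:
    """Per-FSC labeling probability from the fraction of ovarioles with
    at least one labeled FSC: solves ``1 - (1 - p)**l = frac``.
    """
    if not 0.0 <= frac_with_clones < 1.0:
        raise ValueError("frac_with_clones must be in [0, 1)")
    if l < 1:
        raise ValueError("l must be >= 1")
    return 1.0 - (1.0 - frac_with_clones) ** (1.0 / l)


def compare_clone_sizes(
    groups: Mapping[str, Sequence[float]],
) -> "dict[tuple[str, str], dict[str, float]]":
    """Pairwise Welch two-sample tests of clone-size fractions.

    Returns, per condition pair, the raw Welch p-value, the Bonferroni-
    adjusted p-value, and the t statistic.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for name, vals in groups.items():
        a = np.asarray(list(vals), dtype=float)
        if a.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 observations")
        arrays[name] = a
    pairs = list(combinations(sorted(arrays), 2))
    m = len(pairs)
    out = {}
    for a, b in pairs:
        t, p = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
        out[(a, b)] = {
            "t": float(t),
            "p_raw": float(p),
            "p_bonferroni": float(min(1.0, p * m)),
            "n_a": int(arrays[a].size),
            "n_b": int(arrays[b].size),
        }
    return out


# --------------------------------------------------------------------------
# statsmodels-style wrapper


class CloneSizeModel:
    """Clone-size model for mosaic ovarioles under neutral multi-lineage growth.

    Parameters
    ----------
    fractions : sequence of float
        Per-ovariole labeled fractions in (0, 1], mosaic ovarioles only.

    Examples
    --------
    >>> res = CloneSizeModel([0.5, 0.45, 0.55]).fit(seed=0)
    >>> res.l_rounded
    2
    """

    def __init__(self, fractions: Sequence[float]):
        self.fractions = np.asarray(list(fractions), dtype=float)
        if self.fractions.size == 0:
            raise ValueError("fractions must be non-empty")

    @classmethod
    def from_records(cls, records) -> "CloneSizeModel":
        """Build from simulator records, keeping mosaic ovarioles with
        persistent clones only (non-mosaic ovarioles are excluded, matching
        the measurement protocol)."""
        from .clone_stats import LabelingClass, classify_labeling, persistent_clone_fraction

        fracs = []
        for r in records:
            if classify_labeling(r) != LabelingClass.MOSAIC:
                continue
            f = persistent_clone_fraction(r)
            if f is not None and 0.0 < f < 1.0:
                fracs.append(f)
        return cls(fracs)

    def fit(
        self, n_boot: int = 10_000, seed: "int | None" = None, ci_level: float = 0.95
    ) -> "CloneSizeResults":
        est = estimate_fsc_number(
            self.fractions, n_boot=n_boot, seed=seed, ci_level=ci_level
        )
        return CloneSizeResults(self, est, ci_level)


class CloneSizeResults:
    """Fit results: point estimate, bootstrap CI and implied range."""

    def __init__(self, model: CloneSizeModel, estimate: FscEstimate, ci_level: float):
        self.model = model
        self.estimate = estimate
        self.ci_level = ci_level

    @property
    def mean_fraction(self) -> float:
        return self.estimate.mean_fraction

    @property
    def l_hat(self) -> float:
        return self.estimate.l_hat

    @property
    def l_rounded(self) -> int:
        return self.estimate.l_rounded

    @property
    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci

    def summary(self) -> str:
        e = self.estimate
        pct = 100.0 * e.mean_fraction
        sd = 100.0 * e.sd_fraction
        lines = [
            "Clone-size model of active FSC number",
            "=" * 54,
            f"Mosaic ovarioles (n)        {e.n:>10d}",
            f"Mean clone size             {pct:>9.1f}% +/- {sd:.1f}%",
            f"Active FSCs (l_hat)         {e.l_hat:>10.2f}",
            f"Active FSCs (rounded)       {e.l_rounded:>10d}",
            f"{int(self.ci_level*100)}% bootstrap CI          "
            f"[{e.ci[0]:.2f}, {e.ci[1]:.2f}]  ({e.n_boot} resamples)",
            f"Implied range (mean+/-2SD)  "
            f"[{e.implied_range[0]:.2f}, {e.implied_range[1]:.2f}]",
            "=" * 54,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<CloneSizeResults l_hat={self.l_hat:.3f} "
            f"ci=({self.conf_int[0]:.3f}, {self.conf_int[1]:.3f}) "
            f"n={self.estimate.n}>"
        )
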