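"""Combinatorics of Flp/FRT mitotic-recombination marking systems.

Heat-shock-driven flippase induces mitotic recombination between FRT sites on
homologous chromosome arms, heritably changing which marker alleles a daughter
cell carries.  This module enumerates the possible daughter genotypes for the
three marking schemes used in follicle stem cell (FSC) clonal analysis, maps
genotypes to expressed marker combinations (phenotypes), and predicts phenotype
frequencies.

Supported schemes
-----------------
``LGR``
    Dual-FRT system on chromosome II: one homolog carries constitutive GFP
    distal to FRT40A (2L) and constitutive RFP distal to the 2R site; the other
    homolog carries constitutive LacZ distal to FRT40A and nothing distal on
    2R.  All cells initially express all three markers; recombination can
    produce six marker combinations.  The 2R FRT site appears in the literature
    both as FRT42B and FRT42D; the arm topology, not the site name, determines
    the outcomes, so a single 2R site is modelled.
``GFPNEG_FRT19A``
    Standard negatively marked system: all cells start GFP+; recombination at
    FRT19A can produce GFP-null homozygous daughters, so clones are marked by
    the *absence* of GFP.
``MARCM_FRT19A``
    MARCM: a repressor (tubGal80) sits distal to FRT19A; cells start GFP-
    and only daughters that lose both repressor copies express GFP.

The canonical frequency model is the *equal-genotype* assumption: every
per-arm allele pair (hom1/hom1, hom1/hom2, hom2/hom2) is equally likely and
arms are independent.  For the LGR system this yields nine genotypes at 1/9
each and six phenotypes at 1:1:1:2:2:2.  :func:`chromatid_oracle` provides an
independent chromatid-level audit of that assumption under explicit exchange
and segregation rules.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np

__all__ = [
    "NULL_ALLELE",
    "ArmSpec",
    "MarkingSystem",
    "Genotype",
    "Phenotype",
    "PhenotypeDistribution",
    "SegregationAssumptions",
    "get_system",
    "enumerate_genotypes",
    "genotype_to_phenotype",
    "phenotype_distribution",
    "is_canonical_phenotype",
    "chromatid_oracle",
]

#: Name of the empty (marker-less) allele on a homolog arm.
NULL_ALLELE = "none"

#: Marker alleles that act as repressors rather than reporters (MARCM).
REPRESSOR_ALLELES = frozenset({"tubGal80"})


class ConfigurationError(ValueError):
    """Unknown marking system or malformed system definition."""


class ValidationError(ValueError):
    """Genotype/system mismatch or invalid operation input."""


@dataclass(frozen=True)
class ArmSpec:
    """One chromosome arm of a marking system.

    ``allele_hom1``/``allele_hom2`` are the marker alleles distal to the FRT
    site on each homolog ("none" for an empty arm).
    """

    arm_id: str
    frt_site: str
    allele_hom1: str
    allele_hom2: str

    def __post_init__(self) -> None:
        if self.allele_hom1 == self.allele_hom2 and self.allele_hom1 != NULL_ALLELE:
            raise ConfigurationError(
                f"arm {self.arm_id}: homolog alleles must differ (got "
                f"{self.allele_hom1!r} twice)"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_hom1, self.allele_hom2)


@dataclass(frozen=True)
class MarkingSystem:
    """A clonal marking scheme: named arms plus a labeling rule.

    ``labeling`` is ``"dominant"`` (a marker is expressed iff at least one
    copy is present) or ``"repressor_loss"`` (MARCM: the reporter is expressed
    iff zero repressor copies remain).
    """

    name: str
    arms: tuple[ArmSpec, ...]
    labeling: Literal["dominant", "repressor_loss"] = "dominant"
    #: Reporter switched on by repressor loss (MARCM only).
    reporter: str = "GFP"
    #: True if clones are scored by marker *absence* (negative marking).
    negative_marking: bool = False

    def __post_init__(self) -> None:
        if not self.arms:
            raise ConfigurationError(f"system {self.name}: needs at least one arm")
        ids = [a.arm_id for a in self.arms]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"system {self.name}: duplicate arm ids {ids}")

    @property
    def markers(self) -> frozenset[str]:
        """All reporter markers the system can express."""
        if self.labeling == "repressor_loss":
            return frozenset({self.reporter})
        out = {
            a
            for arm in self.arms
            for a in arm.alleles
            if a != NULL_ALLELE and a not in REPRESSOR_ALLELES
        }
        return frozenset(out)


@dataclass(frozen=True)
class Genotype:
    """Per-arm unordered allele pairs of one daughter cell.

    ``pairs`` maps arm_id -> sorted 2-tuple of allele names.
    """

    pairs: tuple[tuple[str, tuple[str, str]], ...]

    @classmethod
    def from_mapping(cls, m: Mapping[str, Iterable[str]]) -> "Genotype":
        items = []
        for arm_id in sorted(m):
            pair = tuple(sorted(m[arm_id]))
            if len(pair) != 2:
                raise ValidationError(f"arm {arm_id}: allele pair must have 2 elements")
            items.append((arm_id, pair))
        return cls(tuple(items))

    def pair(self, arm_id: str) -> tuple[str, str]:
        for aid, p in self.pairs:
            if aid == arm_id:
                return p
        raise ValidationError(f"genotype has no arm {arm_id!r}")

    def allele_count(self, allele: str) -> int:
        return sum(p.count(allele) for _, p in self.pairs)

    def __str__(self) -> str:  # e.g. "2L:GFP/LacZ;2R:RFP/none"
        return ";".join(f"{aid}:{p[0]}/{p[1]}" for aid, p in self.pairs)


@dataclass(frozen=True)
class Phenotype:
    """The set of markers a cell expresses (binary presence/absence)."""

    expressed: frozenset[str]

    @classmethod
    def of(cls, *markers: str) -> "Phenotype":
        return cls(frozenset(markers))

    def __contains__(self, marker: str) -> bool:
        return marker in self.expressed

    def label(self, system: "MarkingSystem | None" = None) -> str:
        """Human-readable label, e.g. ``LacZ+GFP-RFP+``.

        With a system, every system marker is shown with +/-; without, only
        expressed markers are listed (or ``(none)``).
        """
        if system is not None:
            order = _marker_order(system)
            return "".join(f"{m}{'+' if m in self.expressed else '-'}" for m in order)
        if not self.expressed:
            return "(none)"
        return "+".join(sorted(self.expressed))

    def __str__(self) -> str:
        return self.label()


def _marker_order(system: MarkingSystem) -> list[str]:
    canonical = ["LacZ", "GFP", "RFP"]
    ms = system.markers
    ordered = [m for m in canonical if m in ms]
    ordered += sorted(ms - set(ordered))
    return ordered


@dataclass
class PhenotypeDistribution:
    """Mapping phenotype -> probability; non-negative, sums to one."""

    probs: dict[Phenotype, float]

    def __post_init__(self) -> None:
        total = math.fsum(self.probs.values())
        if any(p < 0 for p in self.probs.values()):
            raise ValidationError("negative phenotype probability")
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"phenotype probabilities sum to {total}, not 1")

    def __getitem__(self, p: Phenotype) -> float:
        return self.probs.get(p, 0.0)

    def __len__(self) -> int:
        return len(self.probs)

    def __iter__(self):
        return iter(self.probs.items())

    def support(self) -> set[Phenotype]:
        return {p for p, q in self.probs.items() if q > 0}

    def total_variation(self, other: "PhenotypeDistribution") -> float:
        keys = set(self.probs) | set(other.probs)
        return 0.5 * math.fsum(abs(self[k] - other[k]) for k in keys)

    def to_table(self, system: MarkingSystem | None = None) -> "list[tuple[str, float]]":
        rows = [(p.label(system), q) for p, q in self.probs.items()]
        return sorted(rows)


# --- built-in system definitions -------------------------------------------

_SYSTEMS: dict[str, MarkingSystem] = {
    "LGR": MarkingSystem(
        name="LGR",
        arms=(
            ArmSpec("2L", "FRT40A", "GFP", "LacZ"),
            ArmSpec("2R", "FRT42B", "RFP", NULL_ALLELE),
        ),
    ),
    "GFPNEG_FRT19A": MarkingSystem(
        name="GFPNEG_FRT19A",
        arms=(ArmSpec("X", "FRT19A", "GFP", NULL_ALLELE),),
        negative_marking=True,
    ),
    "MARCM_FRT19A": MarkingSystem(
        name="MARCM_FRT19A",
        arms=(ArmSpec("X", "FRT19A", "tubGal80", NULL_ALLELE),),
        labeling="repressor_loss",
    ),
}


def get_system(name: "str | MarkingSystem") -> MarkingSystem:
    """Resolve a system by name (or pass a MarkingSystem through)."""
    if isinstance(name, MarkingSystem):
        return name
    try:
        return _SYSTEMS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown marking system {name!r}; expected one of {sorted(_SYSTEMS)}"
        ) from None


# --- operations -------------------------------------------------------------


def enumerate_genotypes(system: "str | MarkingSystem") -> list[tuple[Genotype, float]]:
    """All daughter genotypes under the equal-genotype model, with probabilities.

    Each arm independently yields one of three unordered allele pairs
    (hom1/hom1, hom1/hom2, hom2/hom2) with equal probability; an arm whose two
    homolog alleles are identical (both null) yields a single pair.  The LGR
    system thus yields nine genotypes at 1/9 each.
    """
    system = get_system(system)
    per_arm: list[list[tuple[str, str]]] = []
    for arm in system.arms:
        a, b = arm.alleles
        if a == b:
            pairs = [tuple(sorted((a, b)))]
        else:
            pairs = [
                tuple(sorted((a, a))),
                tuple(sorted((a, b))),
                tuple(sorted((b, b))),
            ]
        per_arm.append(pairs)
    n_combo = 1
    for pairs in per_arm:
        n_combo *= len(pairs)
    out = []
    for combo in itertools.product(*per_arm):
        g = Genotype.from_mapping(
            {arm.arm_id: pair for arm, pair in zip(system.arms, combo)}
        )
        out.append((g, 1.0 / n_combo))
    return out


def genotype_to_phenotype(system: "str | MarkingSystem", g: Genotype) -> Phenotype:
    """Expressed marker set of a genotype.

    Dominant systems express a marker iff at least one copy is present.
    Repressor-loss systems (MARCM) express the reporter iff the repressor
    count is zero.
    """
    system = get_system(system)
    arm_ids = {a.arm_id for a in system.arms}
    g_ids = {aid for aid, _ in g.pairs}
    if arm_ids != g_ids:
        raise ValidationError(
            f"genotype arms {sorted(g_ids)} do not match system arms {sorted(arm_ids)}"
        )
    for arm in system.arms:
        pair = g.pair(arm.arm_id)
        valid = set(arm.alleles)
        if not set(pair) <= valid:
            raise ValidationError(
                f"arm {arm.arm_id}: alleles {pair} not in {sorted(valid)}"
            )
    if system.labeling == "repressor_loss":
        n_rep = sum(g.allele_count(a) for a in REPRESSOR_ALLELES)
        return Phenotype.of(system.reporter) if n_rep == 0 else Phenotype.of()
    expressed = {
        a
        for _, pair in g.pairs
        for a in pair
        if a != NULL_ALLELE and a not in REPRESSOR_ALLELES
    }
    return Phenotype(frozenset(expressed))


def phenotype_distribution(system: "str | MarkingSystem") -> PhenotypeDistribution:
    """Predicted phenotype frequencies under the equal-genotype model.

    For LGR this is the six-way 1:1:1:2:2:2 distribution over
    LacZ : GFP : LacZ+GFP : LacZ+RFP : GFP+RFP : LacZ+GFP+RFP.
    """
    system = get_system(system)
    acc: dict[Phenotype, float] = {}
    for g, prob in enumerate_genotypes(system):
        ph = genotype_to_phenotype(system, g)
        acc[ph] = acc.get(ph, 0.0) + prob
    return PhenotypeDistribution(acc)


def is_canonical_phenotype(
    system: "str | MarkingSystem", p: Phenotype
) -> tuple[bool, str]:
    """Whether a phenotype is reachable by FRT recombination in this system.

    Returns ``(flag, reason)``.  For LGR, any phenotype lacking both 2L
    markers (LacZ and GFP) is unreachable — every daughter retains at least
    one 2L-distal allele — so triple-negative and RFP-only clones indicate a
    non-canonical event (e.g. heritable transgene silencing).
    """
    system = get_system(system)
    reachable = phenotype_distribution(system).support()
    if p in reachable:
        return True, "reachable by FRT recombination"
    if system.name == "LGR" and not ({"LacZ", "GFP"} & set(p.expressed)):
        return False, "2L markers both absent"
    return False, "phenotype unreachable by FRT recombination in this system"


# --- chromatid-level oracle --------------------------------------------------


@dataclass(frozen=True)
class SegregationAssumptions:
    """Explicit mechanistic assumptions for the chromatid-level oracle.

    exchange_prob
        Per-site probability that a G2 exchange occurs (uniform random
        non-sister chromatid pairing when it does).
    independent_sites
        Whether exchanges at the two FRT sites occur independently.  When
        False, either both sites exchange or neither does (perfectly coupled).
    segregation
        ``"random"``  — each daughter draws one chromatid per homolog uniformly;
        ``"x_only"``  — recombinant chromatids always segregate to opposite
        daughters (yields homozygous daughters);
        ``"z_only"``  — recombinant chromatids co-segregate (daughters stay
        heterozygous);
        ``"uniform_genotype"`` — bypass chromatid mechanics and draw per-arm
        allele pairs uniformly (the equal-genotype assumption, by construction).
    """

    exchange_prob: float = 1.0
    independent_sites: bool = True
    segregation: Literal["random", "x_only", "z_only", "uniform_genotype"] = "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.exchange_prob <= 1.0:
            raise ValidationError("exchange_prob must be in [0, 1]")


def _arm_pair_outcomes(
    arm: ArmSpec, assumptions: SegregationAssumptions, exchanged: bool
) -> list[tuple[tuple[str, str], float]]:
    """Daughter allele-pair distribution for one arm, given exchange status.

    Chromatid bookkeeping: hom1 sisters both carry allele a, hom2 sisters both
    carry b.  An exchange swaps the site-distal segment between one chromatid
    of each homolog (pairing choice is irrelevant by symmetry when sisters are
    identical).  A daughter receives one chromatid per homolog.
    """
    a, b = arm.alleles
    het = tuple(sorted((a, b)))
    if not exchanged or a == b:
        return [(het, 1.0)]
    aa = tuple(sorted((a, a)))
    bb = tuple(sorted((b, b)))
    seg = assumptions.segregation
    if seg == "random":
        # hom1 pool {b, a}, hom2 pool {a, b}; uniform draw from each.
        return [(aa, 0.25), (bb, 0.25), (het, 0.5)]
    if seg == "x_only":
        # Recombinants to opposite poles: daughters are aa and bb.
        return [(aa, 0.5), (bb, 0.5)]
    if seg == "z_only":
        return [(het, 1.0)]
    raise ValidationError(f"unhandled segregation mode {seg!r}")


def chromatid_oracle(
    system: "str | MarkingSystem",
    assumptions: SegregationAssumptions | None = None,
    mode: Literal["exhaustive", "monte_carlo"] = "exhaustive",
    n: int = 100_000,
    seed: "int | np.random.Generator | None" = None,
) -> PhenotypeDistribution:
    """Daughter phenotype distribution from explicit G2 chromatid mechanics.

    An independent audit of :func:`phenotype_distribution`: instead of
    assuming equal genotype frequencies, it enumerates (or samples) exchange
    configurations and sister-chromatid segregations.  Under
    ``segregation="uniform_genotype"`` it reproduces the equal-genotype model
    exactly; under mechanistic modes the distribution generally differs
    (e.g. heterozygous arms are twice as likely under random segregation).
    """
    system = get_system(system)
    assumptions = assumptions or SegregationAssumptions()
    if mode == "monte_carlo" and n <= 0:
        raise ValidationError("n must be positive in monte_carlo mode")

    if assumptions.segregation == "uniform_genotype":
        base = phenotype_distribution(system)
        if mode == "exhaustive":
            return base
        rng = np.random.default_rng(seed)
        phenos = list(base.probs)
        probs = np.array([base.probs[p] for p in phenos])
        counts = rng.multinomial(n, probs)
        return PhenotypeDistribution(
            {p: c / n for p, c in zip(phenos, counts) if c > 0}
        )

    arms = system.arms
    p_ex = assumptions.exchange_prob
    if assumptions.independent_sites or len(arms) == 1:
        ex_patterns = [
            (pattern, math.prod(p_ex if e else 1 - p_ex for e in pattern))
            for pattern in itertools.product([False, True], repeat=len(arms))
        ]
    else:
        ex_patterns = [
            (tuple([False] * len(arms)), 1 - p_ex),
            (tuple([True] * len(arms)), p_ex),
        ]

    acc: dict[Phenotype, float] = {}
    for pattern, w in ex_patterns:
        if w == 0:
            continue
        per_arm = [
            _arm_pair_outcomes(arm, assumptions, ex)
            for arm, ex in zip(arms, pattern)
        ]
        for combo in itertools.product(*per_arm):
            prob = w * math.prod(q for _, q in combo)
            g = Genotype.from_mapping(
                {arm.arm_id: pair for arm, (pair, _) in zip(arms, combo)}
            )
            ph = genotype_to_phenotype(system, g)
            acc[ph] = acc.get(ph, 0.0) + prob
    exact = PhenotypeDistribution(acc)
    if mode == "exhaustive":
        return exact
    rng = np.random.default_rng(seed)
    phenos = list(exact.probs)
    probs = np.array([exact.probs[p] for p in phenos])
    counts = rng.multinomial(n, probs / probs.sum())
    return PhenotypeDistribution({p: c / n for p, c in zip(phenos, counts) if c > 0})


def recombinant_phenotype_distribution(
    system: "str | MarkingSystem",
) -> PhenotypeDistribution:
    """Phenotype distribution of *detectable* recombinant daughters.

    Conditions the equal-genotype model on recombination having occurred,
    i.e. excludes the fully heterozygous (unrecombined) genotype, and for
    labeling schemes that mark only one daughter class keeps the detectable
    outcomes:

    - LGR: all non-heterozygous genotypes (any phenotype, including the
      triple-positive combinations that arise from single-site events).
    - GFP-negative marking: the GFP-null homozygote (the GFP+ sister is
      indistinguishable from background).
    - MARCM: the repressor-free homozygote (GFP+ clone).
    """
    system = get_system(system)
    ancestral = {arm.arm_id: tuple(sorted(arm.alleles)) for arm in system.arms}
    acc: dict[Phenotype, float] = {}
    for g, prob in enumerate_genotypes(system):
        if all(pair == ancestral[aid] for aid, pair in g.pairs):
            continue  # unrecombined ancestral genotype
        ph = genotype_to_phenotype(system, g)
        if system.negative_marking and ph.expressed:
            continue  # only the marker-null daughter is scored as a clone
        if system.labeling == "repressor_loss" and not ph.expressed:
            continue  # only the reporter-positive daughter is visible
        acc[ph] = acc.get(ph, 0.0) + prob
    total = math.fsum(acc.values())
    if total == 0:
        raise ValidationError(f"system {system.name}: no detectable recombinant class")
    return PhenotypeDistribution({p: q / total for p, q in acc.items()})
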