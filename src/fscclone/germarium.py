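"""Stochastic simulator of ovariole clonal labeling.

An ovariole is modelled as ``n_fsc`` follicle stem cell (FSC) lineages at the
germarium's Region 2a/2b border, a small pool of transit (prefollicle) cells,
and a chain of budded follicles.  Heat shocks label FSCs and transit cells
with a marker phenotype drawn from the marking system's recombinant
distribution; follicles are founded at a fixed budding interval with one
founder cell per active FSC and grow to ~900 cells by Stage 6; labeled FSC
lineages form contiguous border-touching patches while labeled transit cells
form transient patches that leave the scored region after the oogenesis
transit time (~8–9 days).  Optional processes produce the rarer clone
patterns seen in real time courses: spontaneous (background) recombination,
heritable marker silencing (the LGR failure mode), FSC loss-and-replacement
(border-truncated clones), and quiescence of labeled prefollicle cells
(small-germarium and discontinuous patterns).

The scored region follows the experimental convention: the germarium from the
Region 2a/2b border through the first 2–3 budded follicles.

Follicle growth uses either a Polya-urn model (exchangeable reinforcement:
founder-lineage fractions are Dirichlet(1,...,1)-distributed, giving the broad
clone-size spread seen in mosaic ovarioles) or a deterministic equal split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from . import timing
from .marker_models import (
    MarkingSystem,
    Phenotype,
    get_system,
    recombinant_phenotype_distribution,
)

__all__ = [
    "SimConfig",
    "ClonePatch",
    "OvarioleRecord",
    "AnteriorAnnotation",
    "sample_follicle_composition",
    "simulate_ovariole",
    "simulate_cohort",
]

GrowthModel = Literal["polya", "deterministic"]

#: Hours a newly labeled transit cell remains inside the germarium before it
#: is incorporated into a budding follicle.
GERMARIUM_RESIDENCE_H = 36.0


class SimParameterError(ValueError):
    """Invalid simulator configuration or call parameters."""


@dataclass
class SimConfig:
    """All simulator parameters.

    The defaults encode the study conditions of standard FSC clonal analysis:
    two active FSCs, a 9.6 h follicle-cell cycle, ~900 cells per Stage-6
    follicle, ~100 h border-to-Stage-6 transit, an 8.5-day clearance of
    transient clones from the scored region, the 4 x 1 h heat-shock regimen
    over two days, and the GFP-negative FRT19A marking system.

    Parameters without a published value (documented as modelling choices):

    budding_interval_h
        Hours between follicle foundings; default 12 h (a placeholder between
        the ~8 h and ~16 h implied by different transit estimates).
    transit_pool_size
        Effective number of heat-shock-labelable transit cells resident in
        the scored germarium region (default 6).
    igs_induction_prob
        Per-heat-shock probability that an inner germarial sheath cell is
        labeled, producing the non-border anterior-cell classes (default 0.05).
    induction_prob
        Per-FSC labeling probability *per heat shock*; the default 0.05 gives
        roughly one third of ovarioles an FSC clone under the default
        4 x 1 h regimen with two FSCs.
    force_n_labeled_fsc
        When set, exactly this many FSCs are labeled at the first heat shock
        and stochastic FSC induction is skipped (transit-cell labeling still
        follows induction_prob).  Used for controlled experiments.
    """

    n_fsc: int = 2
    cycle_h: float = 9.6
    follicle_cells_stage6: int = 900
    transit_h: float = 100.0
    ovariole_clearance_d: float = 8.5
    budding_interval_h: float = 12.0
    induction_prob: float = 0.05
    background_rate: float = 1e-4
    silencing_rate: float = 0.0
    replacement_rate: float = 0.0
    quiescence_rate: float = 0.0
    heat_shock_times_h: tuple[float, ...] = (0.0, 8.0, 24.0, 32.0)
    sample_dphs: tuple[float, ...] = (5, 7, 9, 12, 14, 20, 25)
    marking_system: "str | MarkingSystem" = "GFPNEG_FRT19A"
    growth_model: GrowthModel = "polya"
    seed: Optional[int] = None
    # modelling-choice extras (see class docstring)
    transit_pool_size: int = 6
    igs_induction_prob: float = 0.05
    n_scored_follicles: int = 3
    germarium_cells: int = 60
    force_n_labeled_fsc: Optional[int] = None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_fsc < 1:
            raise SimParameterError("n_fsc must be >= 1")
        for name in (
            "induction_prob",
            "background_rate",
            "silencing_rate",
            "replacement_rate",
            "quiescence_rate",
            "igs_induction_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("cycle_h", "transit_h", "budding_interval_h"):
            if getattr(self, name) <= 0:
                raise SimParameterError(f"{name} must be positive")
        if not 0 < self.ovariole_clearance_d:
            raise SimParameterError("ovariole_clearance_d must be positive")
        dphs = tuple(self.sample_dphs)
        if list(dphs) != sorted(dphs):
            raise SimParameterError("sample_dphs must be sorted ascending")
        self.sample_dphs = dphs
        self.heat_shock_times_h = tuple(self.heat_shock_times_h)
        if self.growth_model not in ("polya", "deterministic"):
            raise SimParameterError(f"unknown growth model {self.growth_model!r}")
        if self.force_n_labeled_fsc is not None and not (
            0 <= self.force_n_labeled_fsc <= self.n_fsc
        ):
            raise SimParameterError("force_n_labeled_fsc must be in [0, n_fsc]")

    @property
    def system(self) -> MarkingSystem:
        return get_system(self.marking_system)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ClonePatch:
    """One contiguous same-phenotype patch of labeled cells."""

    phenotype: Phenotype
    touches_border: bool
    n_follicles_spanned: int
    fraction_of_follicle: list[float]
    cell_count: int
    in_germarium_only: bool = False
    contiguous_with: Optional[int] = None
    patch_id: int = 0

    def __post_init__(self) -> None:
        if self.cell_count < 1:
            raise SimParameterError("patch cell_count must be >= 1")
        if any(not 0.0 <= f <= 1.0 for f in self.fraction_of_follicle):
            raise SimParameterError("per-follicle fractions must lie in [0, 1]")


@dataclass(frozen=True)
class AnteriorAnnotation:
    """Status of the anterior-most labeled cell relative to the FasIII
    expression boundary (the Region 2a/2b border)."""

    fasiii_positive: bool
    at_boundary: bool
    contiguous_with_clone: bool


@dataclass
class OvarioleRecord:
    """Per-ovariole clone inventory at one sampling time."""

    dphs: float
    patches: list[ClonePatch]
    total_cells_scored: int
    labeled_cells: dict[Phenotype, int]
    anterior_cell_position: Literal["border", "adjacent", "anterior", "none"] = "none"
    anterior_annotation: Optional[AnteriorAnnotation] = None
    background_phenotype: Optional[Phenotype] = None
    follicle_cells_scored: int = 0
    ovariole_id: int = 0
    condition: str = ""

    @property
    def background_cells(self) -> int:
        return self.total_cells_scored - sum(self.labeled_cells.values())


# --------------------------------------------------------------------------


def sample_follicle_composition(
    founder_labels: Sequence,
    final_cells: int,
    growth_model: GrowthModel = "polya",
    rng: "np.random.Generator | None" = None,
) -> dict:
    """Final per-lineage cell counts of one follicle.

    polya
        Exchangeable reinforcement: each added cell joins a lineage with
        probability proportional to its current size.  Sampled exactly via
        the de Finetti representation — fractions are Dirichlet(1,...,1) and
        counts are 1 + Multinomial(final_cells - k, fractions).
    deterministic
        Equal split with largest-remainder rounding.
    """
    founders = list(founder_labels)
    k = len(founders)
    if k == 0:
        raise SimParameterError("at least one founder is required")
    if final_cells < k:
        raise SimParameterError("final_cells must be >= number of founders")
    counts: dict = {f: 0 for f in founders}  # aggregates duplicate labels
    if growth_model == "deterministic":
        base, rem = divmod(final_cells, k)
        per_slot = [base + (1 if i < rem else 0) for i in range(k)]
    elif growth_model == "polya":
        if rng is None:
            rng = np.random.default_rng()
        fracs = rng.dirichlet(np.ones(k))
        extra = rng.multinomial(final_cells - k, fracs)
        per_slot = [1 + int(e) for e in extra]
    else:
        raise SimParameterError(f"unknown growth model {growth_model!r}")
    for f, c in zip(founders, per_slot):
        counts[f] = counts[f] + c
    return counts


# --------------------------------------------------------------------------
# internal simulation state


class _Lineage:
    __slots__ = ("uid", "label", "label_time", "silenced")

    def __init__(self, uid: int):
        self.uid = uid
        self.label: Optional[Phenotype] = None  # recombinant phenotype
        self.label_time: float = np.inf
        self.silenced: set[str] = set()

    @property
    def marked(self) -> bool:
        return self.label is not None or bool(self.silenced)


def _background_phenotype(system: MarkingSystem) -> Phenotype:
    """Phenotype of unrecombined, unsilenced tissue."""
    if system.labeling == "repressor_loss":
        return Phenotype.of()
    return Phenotype(system.markers)


def _effective_phenotype(system: MarkingSystem, lin: _Lineage) -> Phenotype:
    base = lin.label.expressed if lin.label is not None else _background_phenotype(system).expressed
    return Phenotype(frozenset(base - lin.silenced))


def _draw_recombinant(dist, rng: np.random.Generator) -> Phenotype:
    phenos = list(dist.probs)
    probs = np.array([dist.probs[p] for p in phenos])
    idx = rng.choice(len(phenos), p=probs / probs.sum())
    return phenos[idx]


@dataclass
class _Transient:
    phenotype: Phenotype
    t_induced: float
    fraction: float
    exit_time: float


@dataclass
class _Quiescent:
    phenotype: Phenotype
    t_start: float
    detach_time: float
    exit_time: float
    germ_fraction: float
    follicle_fraction: float


@dataclass
class _Truncated:
    phenotype: Phenotype
    label_time: float
    t_replaced: float


def simulate_ovariole(
    config: SimConfig, rng: "np.random.Generator | None" = None
) -> list[OvarioleRecord]:
    """Simulate one ovariole and return a record per entry of sample_dphs.

    Time is continuous in hours with t = 0 at the first heat shock (or at the
    start of observation when no heat shock is given); sampling times are
    ``last_heat_shock + dphs * 24``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    system = config.system
    rec_dist = recombinant_phenotype_distribution(system)
    silencing_on = config.silencing_rate > 0 and system.name == "LGR"

    last_hs = max(config.heat_shock_times_h) if config.heat_shock_times_h else 0.0
    sample_times = [last_hs + d * 24.0 for d in config.sample_dphs]
    t_max = max(sample_times) if sample_times else 0.0
    clearance_h = config.ovariole_clearance_d * 24.0

    lineages = [_Lineage(i) for i in range(config.n_fsc)]
    slots: list[_Lineage] = list(lineages)
    transients: list[_Transient] = []
    quiescents: list[_Quiescent] = []
    truncated: list[_Truncated] = []
    igs_labeled = False
    igs_adjacent = False
    # follicles: (found_time, {lineage_uid: fraction}, {uid: label_time at founding})
    follicles: list[tuple[float, dict[int, float]]] = []

    def new_transient(t: float) -> None:
        ph = _draw_recombinant(rec_dist, rng)
        transients.append(
            _Transient(
                phenotype=ph,
                t_induced=t,
                fraction=float(rng.uniform(0.05, 0.5)),
                exit_time=t + clearance_h,
            )
        )

    # ---- build chronological event list --------------------------------
    events: list[tuple[float, int, str]] = []
    for hs in config.heat_shock_times_h:
        events.append((hs, 0, "heat_shock"))
    k = 0
    while k * config.budding_interval_h <= t_max:
        events.append((k * config.budding_interval_h, 1, "bud"))
        k += 1
    k = 1
    while k * config.cycle_h <= t_max:
        events.append((k * config.cycle_h, 2, "division"))
        k += 1
    k = 1
    while k * 24.0 <= t_max:
        events.append((k * 24.0, 3, "day"))
        k += 1
    for st in sample_times:
        events.append((st, 4, "sample"))
    events.sort(key=lambda e: (e[0], e[1]))

    forced_done = config.force_n_labeled_fsc is None
    records: list[OvarioleRecord] = []
    sample_idx = 0

    for t, _prio, kind in events:
        if kind == "heat_shock":
            if not forced_done:
                order = rng.permutation(config.n_fsc)
                for i in order[: config.force_n_labeled_fsc]:
                    lin = lineages[i]
                    lin.label = _draw_recombinant(rec_dist, rng)
                    lin.label_time = t
                forced_done = True
            elif config.force_n_labeled_fsc is None:
                for lin in dict.fromkeys(slots):
                    if lin.label is None and rng.random() < config.induction_prob:
                        lin.label = _draw_recombinant(rec_dist, rng)
                        lin.label_time = t
            for _ in range(config.transit_pool_size):
                if rng.random() < config.induction_prob:
                    new_transient(t)
            if not igs_labeled and rng.random() < config.igs_induction_prob:
                igs_labeled = True
                igs_adjacent = bool(rng.random() < 0.5)
        elif kind == "bud":
            comp = sample_follicle_composition(
                [lin.uid for lin in slots],
                config.follicle_cells_stage6,
                config.growth_model,
                rng,
            )
            total = float(config.follicle_cells_stage6)
            follicles.append((t, {uid: c / total for uid, c in comp.items()}))
        elif kind == "division":
            # one synchronous division round of FSCs and transit cells
            if config.background_rate > 0:
                for lin in dict.fromkeys(slots):
                    if lin.label is None and rng.random() < config.background_rate:
                        lin.label = _draw_recombinant(rec_dist, rng)
                        lin.label_time = t
                for _ in range(config.transit_pool_size):
                    if rng.random() < config.background_rate:
                        new_transient(t)
            if silencing_on:
                for lin in dict.fromkeys(slots):
                    if rng.random() < config.silencing_rate:
                        expressed = _effective_phenotype(system, lin).expressed
                        if expressed:
                            lin.silenced.add(str(rng.choice(sorted(expressed))))
                            if lin.label_time == np.inf:
                                lin.label_time = t
        elif kind == "day":
            if config.replacement_rate > 0 and config.n_fsc >= 2:
                if rng.random() < config.replacement_rate:
                    lose = int(rng.integers(config.n_fsc))
                    loser = slots[lose]
                    others = [i for i in range(config.n_fsc) if i != lose]
                    winner = slots[int(rng.choice(others))]
                    slots[lose] = winner
                    if loser not in slots and loser.marked and loser.label_time <= t:
                        truncated.append(
                            _Truncated(
                                phenotype=_effective_phenotype(system, loser),
                                label_time=loser.label_time,
                                t_replaced=t,
                            )
                        )
            if config.quiescence_rate > 0:
                for lin in [l for l in dict.fromkeys(slots) if l.marked and l.label_time <= t]:
                    if rng.random() < config.quiescence_rate:
                        detach = t + float(rng.uniform(24.0, 72.0))
                        quiescents.append(
                            _Quiescent(
                                phenotype=_effective_phenotype(system, lin),
                                t_start=t,
                                detach_time=detach,
                                exit_time=detach + clearance_h,
                                germ_fraction=float(rng.uniform(0.02, 0.10)),
                                follicle_fraction=float(rng.uniform(0.05, 0.30)),
                            )
                        )
        elif kind == "sample":
            records.append(
                _snapshot(
                    config,
                    system,
                    t,
                    config.sample_dphs[sample_idx],
                    slots,
                    follicles,
                    transients,
                    quiescents,
                    truncated,
                    igs_labeled,
                    igs_adjacent,
                )
            )
            sample_idx += 1

    return records


def _window(
    config: SimConfig, follicles, t: float
) -> list[tuple[float, dict[int, float], int]]:
    """Scored follicles at time t: the youngest budded ones, with current size."""
    budded = [(ft, fr) for ft, fr in follicles if ft <= t]
    budded.sort(key=lambda x: x[0])
    win = budded[-config.n_scored_follicles :]
    out = []
    for ft, fr in win:
        size = timing.population_after(t - ft, config.n_fsc, config.cycle_h)
        out.append((ft, fr, int(round(min(size, config.follicle_cells_stage6)))))
    return out


def _snapshot(
    config: SimConfig,
    system: MarkingSystem,
    t: float,
    dphs: float,
    slots: list[_Lineage],
    follicles,
    transients,
    quiescents,
    truncated,
    igs_labeled: bool,
    igs_adjacent: bool,
) -> OvarioleRecord:
    window = _window(config, follicles, t)
    follicle_cells = sum(size for _, _, size in window)
    total = config.germarium_cells + follicle_cells
    remaining = [size for _, _, size in window]  # unassigned cells per follicle
    germ_remaining = config.germarium_cells
    patches: list[ClonePatch] = []
    pid = 0

    def add_patch(**kw) -> ClonePatch:
        nonlocal pid
        p = ClonePatch(patch_id=pid, **kw)
        patches.append(p)
        pid += 1
        return p

    # persistent (border-touching) marked lineages
    n_slots = len(slots)
    border_patch_by_pheno: dict[Phenotype, int] = {}
    for lin in sorted(set(slots), key=lambda l: l.uid):
        if not (lin.marked and lin.label_time <= t):
            continue
        pheno = _effective_phenotype(system, lin)
        share = slots.count(lin) / n_slots
        germ_cells = int(round(share * config.germarium_cells))
        germ_cells = min(germ_cells, germ_remaining)
        germ_remaining -= germ_cells
        fracs: list[float] = []
        cells = germ_cells
        for j, (ft, fr, size) in enumerate(window):
            if ft < lin.label_time:
                continue  # follicle founded before this lineage was marked
            f = fr.get(lin.uid, 0.0)
            if f <= 0:
                continue
            c = min(int(round(f * size)), remaining[j])
            remaining[j] -= c
            fracs.append(f)
            cells += c
        if cells < 1:
            continue
        patch = add_patch(
            phenotype=pheno,
            touches_border=True,
            n_follicles_spanned=len(fracs),
            fraction_of_follicle=fracs,
            cell_count=cells,
            in_germarium_only=len(fracs) == 0,
        )
        border_patch_by_pheno.setdefault(pheno, patch.patch_id)

    # border-truncated (replacement) patches
    for tr in truncated:
        if tr.t_replaced > t:
            continue
        fracs = []
        cells = 0
        for j, (ft, fr, size) in enumerate(window):
            if not (tr.label_time <= ft <= tr.t_replaced):
                continue
            # fraction of a past composition is unknown per-uid here; the
            # replaced lineage held one slot, so use the neutral expectation
            f = 1.0 / n_slots
            c = min(int(round(f * size)), remaining[j])
            remaining[j] -= c
            fracs.append(f)
            cells += c
        if cells >= 1 and fracs:
            add_patch(
                phenotype=tr.phenotype,
                touches_border=False,
                n_follicles_spanned=len(fracs),
                fraction_of_follicle=fracs,
                cell_count=cells,
            )

    # transient clones
    for tc in transients:
        if not (tc.t_induced <= t < tc.exit_time):
            continue
        in_germ = (t - tc.t_induced) < GERMARIUM_RESIDENCE_H
        if in_germ:
            cells = min(max(1, int(round(0.1 * config.germarium_cells))), germ_remaining)
            if cells < 1:
                continue
            germ_remaining -= cells
            add_patch(
                phenotype=tc.phenotype,
                touches_border=False,
                n_follicles_spanned=0,
                fraction_of_follicle=[],
                cell_count=cells,
                in_germarium_only=True,
            )
        else:
            if not window:
                continue
            j = len(window) // 2  # middle follicle of the scored window
            size = window[j][2]
            c = min(int(round(tc.fraction * size)), remaining[j])
            if c < 1:
                continue
            remaining[j] -= c
            add_patch(
                phenotype=tc.phenotype,
                touches_border=False,
                n_follicles_spanned=1,
                fraction_of_follicle=[c / size],
                cell_count=c,
            )

    # quiescent / detached patches
    for q in quiescents:
        if not (q.t_start <= t < q.exit_time):
            continue
        if t < q.detach_time:  # still a small patch in the germarium
            cells = min(
                max(1, int(round(q.germ_fraction * config.germarium_cells))),
                germ_remaining,
            )
            if cells < 1:
                continue
            germ_remaining -= cells
            add_patch(
                phenotype=q.phenotype,
                touches_border=False,
                n_follicles_spanned=0,
                fraction_of_follicle=[],
                cell_count=cells,
                in_germarium_only=True,
            )
        else:  # detached: disjoint downstream patch (discontinuous pattern)
            if not window:
                continue
            j = len(window) - 1
            size = window[j][2]
            c = min(max(1, int(round(q.follicle_fraction * size))), remaining[j])
            if c < 1:
                continue
            remaining[j] -= c
            add_patch(
                phenotype=q.phenotype,
                touches_border=False,
                n_follicles_spanned=1,
                fraction_of_follicle=[c / size],
                cell_count=c,
                contiguous_with=None,
            )

    labeled: dict[Phenotype, int] = {}
    for p in patches:
        labeled[p.phenotype] = labeled.get(p.phenotype, 0) + p.cell_count

    has_fsc_clone = any(p.touches_border and not p.in_germarium_only for p in patches)
    if has_fsc_clone:
        if igs_labeled:
            ann = AnteriorAnnotation(
                fasiii_positive=False,
                at_boundary=igs_adjacent,
                contiguous_with_clone=igs_adjacent,
            )
            pos = "adjacent" if igs_adjacent else "anterior"
        else:
            ann = AnteriorAnnotation(
                fasiii_positive=True, at_boundary=True, contiguous_with_clone=True
            )
            pos = "border"
    else:
        ann = None
        pos = "none"

    return OvarioleRecord(
        dphs=dphs,
        patches=patches,
        total_cells_scored=total,
        labeled_cells=labeled,
        anterior_cell_position=pos,
        anterior_annotation=ann,
        background_phenotype=_background_phenotype(system),
        follicle_cells_scored=follicle_cells,
        condition=config.condition,
    )


def simulate_cohort(
    config: SimConfig, n_ovarioles: int, seed: "int | None" = None
) -> list[list[OvarioleRecord]]:
    """Independent replicate ovarioles with reproducible seed substreams.

    One master seed spawns a child stream per ovariole via
    ``numpy.random.SeedSequence``; identical (config, n, seed) triples produce
    identical cohorts.
    """
    if n_ovarioles < 1:
        raise SimParameterError("n_ovarioles must be >= 1")
    if seed is None:
        seed = config.seed
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_ovarioles)
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        records = simulate_ovariole(config, rng)
        for r in records:
            r.ovariole_id = i
        cohort.append(records)
    return cohort
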