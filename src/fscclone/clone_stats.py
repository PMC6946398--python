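"""Classification and tabulation of ovariole clone inventories.

Implements the five-category clone-pattern scheme used to score GFP-negative
FSC clones:

fsc_persistent
    A contiguous labeled patch extending from the Region 2a/2b border over one
    or more budded follicles — the signature of a labeled follicle stem cell.
transient
    A patch covering half of a follicle or less, not touching the border:
    the descendants of a labeled non-stem prefollicle cell.
replacement
    A large patch spanning multiple follicles but not reaching the border —
    the expected pattern after a labeled FSC was lost and replaced.
small_germarium
    Labeled cells confined to the germarium.
discontinuous
    A border-touching patch coexisting with a disjoint same-phenotype patch
    downstream.

Also provides per-ovariole labeling classes (none/mosaic/full), unique-lineage
diversity counts, frequency tables with chi-square goodness of fit against a
predicted phenotype distribution, and the anterior-most-labeled-cell classes
relative to the FasIII expression boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .germarium import ClonePatch, OvarioleRecord
from .marker_models import Phenotype, PhenotypeDistribution

__all__ = [
    "CloneCategory",
    "LabelingClass",
    "FrequencyTable",
    "classify_clone_pattern",
    "classify_labeling",
    "count_unique_lineages",
    "persistent_clone_fraction",
    "tabulate",
    "goodness_of_fit",
    "anterior_cell_class",
    "diversity_timecourse",
]


class CloneCategory(str, Enum):
    FSC_PERSISTENT = "fsc_persistent"
    TRANSIENT = "transient"
    REPLACEMENT = "replacement"
    SMALL_GERMARIUM = "small_germarium"
    DISCONTINUOUS = "discontinuous"


class LabelingClass(str, Enum):
    NONE = "none"
    MOSAIC = "mosaic"
    FULL = "full"


class NoCloneError(ValueError):
    """Raised when a record has no recombinant patch to classify."""


class AnnotationError(ValueError):
    """Missing anterior-cell annotation."""


@dataclass
class FrequencyTable:
    """Counts and percentages per label, optionally per group."""

    table: pd.DataFrame  # columns: [group?], label, count, percent
    n: int

    def percents(self, group=None) -> dict:
        df = self.table
        if group is not None:
            df = df[df["group"] == group]
        return dict(zip(df["label"], df["percent"]))

    def counts(self, group=None) -> dict:
        df = self.table
        if group is not None:
            df = df[df["group"] == group]
        return dict(zip(df["label"], df["count"]))


def _is_recombinant(record: OvarioleRecord, patch: ClonePatch) -> bool:
    # Any patch in the inventory is a clone; the simulator only emits patches
    # for marked lineages/cells.  Kept as a hook for annotated real data.
    return True


def classify_clone_pattern(
    record: OvarioleRecord,
) -> dict[Phenotype, CloneCategory]:
    """Classify each recombinant phenotype of a record into one category.

    Precedence (first match wins), applied to all patches of one phenotype:

    1. discontinuous — a border-touching patch coexists with a disjoint
       same-phenotype patch downstream (outside the germarium);
    2. fsc_persistent — a contiguous border-touching patch spanning at least
       one budded follicle;
    3. replacement — a patch spanning two or more follicles without border
       contact;
    4. small_germarium — all patches confined to the germarium (this includes
       a border-touching patch that has not yet contributed to a follicle);
    5. transient — a patch covering at most half of one follicle without
       border contact (also the fallback for larger single-follicle
       non-border patches).
    """
    groups: dict[Phenotype, list[ClonePatch]] = {}
    for p in record.patches:
        if _is_recombinant(record, p):
            groups.setdefault(p.phenotype, []).append(p)
    if not groups:
        raise NoCloneError("record contains no recombinant patch")
    out: dict[Phenotype, CloneCategory] = {}
    for pheno, patches in groups.items():
        border = [p for p in patches if p.touches_border]
        downstream_disjoint = [
            p
            for p in patches
            if not p.touches_border and not p.in_germarium_only
        ]
        if border and downstream_disjoint:
            out[pheno] = CloneCategory.DISCONTINUOUS
            continue
        if any(
            p.touches_border and not p.in_germarium_only and p.n_follicles_spanned >= 1
            for p in patches
        ):
            out[pheno] = CloneCategory.FSC_PERSISTENT
            continue
        if any(
            not p.touches_border and p.n_follicles_spanned >= 2 for p in patches
        ):
            out[pheno] = CloneCategory.REPLACEMENT
            continue
        if all(p.in_germarium_only for p in patches):
            out[pheno] = CloneCategory.SMALL_GERMARIUM
            continue
        out[pheno] = CloneCategory.TRANSIENT
    return out


def classify_labeling(record: OvarioleRecord) -> LabelingClass:
    """Per-ovariole labeling class: none / mosaic / full.

    ``none`` when no phenotype classifies as fsc_persistent; ``full`` when a
    single phenotype's persistent patches cover the entire follicle-cell
    population of every scored follicle; ``mosaic`` otherwise.
    """
    try:
        cats = classify_clone_pattern(record)
    except NoCloneError:
        return LabelingClass.NONE
    persistent = [p for p, c in cats.items() if c == CloneCategory.FSC_PERSISTENT]
    if not persistent:
        return LabelingClass.NONE
    for pheno in persistent:
        patches = [
            p
            for p in record.patches
            if p.phenotype == pheno and p.touches_border and p.n_follicles_spanned >= 1
        ]
        fracs = [f for p in patches for f in p.fraction_of_follicle]
        if fracs and all(f >= 1.0 - 1e-9 for f in fracs):
            return LabelingClass.FULL
    return LabelingClass.MOSAIC


def count_unique_lineages(record: OvarioleRecord) -> int:
    """Number of distinct marker phenotypes observed in the scored region.

    Counts phenotype classes, not patches: the unrecombined (background)
    class is included when background cells are present, and a recombinant
    patch sharing the background phenotype merges with it.
    """
    if record.total_cells_scored == 0:
        return 0
    phenos = {p.phenotype for p in record.patches}
    if record.background_cells > 0 and record.background_phenotype is not None:
        phenos.add(record.background_phenotype)
    return len(phenos)


def persistent_clone_fraction(record: OvarioleRecord) -> Optional[float]:
    """Labeled-cell fraction of the budded-follicle population for the
    dominant persistent clone, or None if the record has no such clone.

    Computed as the mean per-follicle labeled fraction of the largest
    border-touching patch — the quantity measured as "clone size" in mosaic
    ovarioles.
    """
    candidates = [
        p
        for p in record.patches
        if p.touches_border and p.n_follicles_spanned >= 1
    ]
    if not candidates:
        return None
    best = max(candidates, key=lambda p: p.cell_count)
    return float(np.mean(best.fraction_of_follicle))


def anterior_cell_class(record: OvarioleRecord) -> str:
    """Position class of the anterior-most labeled cell.

    ``border`` — FasIII-positive at the expression boundary (the cell is a
    follicle cell, consistent with an FSC at the boundary); ``adjacent`` —
    FasIII-negative but contiguous with the clone at the boundary;
    ``anterior`` — FasIII-negative and disjoint from the clone.
    """
    ann = record.anterior_annotation
    if ann is None:
        raise AnnotationError("record has no anterior-cell annotation")
    if ann.fasiii_positive and ann.at_boundary:
        return "border"
    if ann.contiguous_with_clone:
        return "adjacent"
    return "anterior"


# --------------------------------------------------------------------------


def _flatten(cohort) -> list[OvarioleRecord]:
    if not cohort:
        return []
    if isinstance(cohort[0], OvarioleRecord):
        return list(cohort)
    return [r for ov in cohort for r in ov]


def _record_labels(record: OvarioleRecord, key: str) -> list[str]:
    if key == "phenotype":
        return [p.phenotype.label() for p in record.patches]
    if key == "category":
        try:
            cats = classify_clone_pattern(record)
        except NoCloneError:
            return []
        return [c.value for c in cats.values()]
    if key == "diversity":
        return [str(count_unique_lineages(record))]
    if key == "labeling":
        return [classify_labeling(record).value]
    raise ValueError(f"unknown tabulation key {key!r}")


def tabulate(
    cohort,
    key: str = "category",
    group_by: Optional[str] = None,
) -> FrequencyTable:
    """Frequency table of a per-record statistic over a cohort.

    key: ``phenotype`` (patch phenotypes), ``category`` (clone-pattern
    classes), ``diversity`` (unique-lineage counts) or ``labeling``
    (none/mosaic/full).  group_by: ``dphs`` or ``condition`` for grouped
    tables.  Rows are ordered lexicographically by (group, label).
    """
    records = _flatten(cohort)
    if not records:
        raise ValueError("empty cohort")
    rows = []
    for r in records:
        group = getattr(r, group_by) if group_by else None
        for label in _record_labels(r, key):
            rows.append((group, label))
    if not rows:
        raise ValueError(f"no observations for key {key!r}")
    df = pd.DataFrame(rows, columns=["group", "label"])
    counts = (
        df.groupby(["group", "label"], dropna=False).size().reset_index(name="count")
    )
    totals = counts.groupby("group", dropna=False)["count"].transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    counts = counts.sort_values(["group", "label"], kind="mergesort").reset_index(
        drop=True
    )
    if group_by is None:
        counts = counts.drop(columns=["group"])
    return FrequencyTable(table=counts, n=len(rows))


def goodness_of_fit(
    observed: "FrequencyTable | Mapping[str, int]",
    expected: "PhenotypeDistribution | Mapping[str, float]",
) -> tuple[float, int, float]:
    """Pearson chi-square of observed label counts against expected
    proportions.  Returns (statistic, df, p).
    """
    if isinstance(observed, FrequencyTable):
        obs = observed.counts()
    else:
        obs = dict(observed)
    if isinstance(expected, PhenotypeDistribution):
        exp = {p.label(): q for p, q in expected}
    else:
        exp = dict(expected)
    missing = [k for k in obs if k not in exp]
    if missing:
        raise ValueError(f"expected distribution lacks observed labels: {missing}")
    zero = [k for k, v in exp.items() if v == 0 and obs.get(k, 0) > 0]
    if zero:
        raise ValueError(f"expected probability 0 with observed counts: {zero}")
    labels = sorted(exp)
    n = sum(obs.values())
    if n < 1:
        raise ValueError("total observed count must be >= 1")
    f_obs = np.array([obs.get(k, 0) for k in labels], dtype=float)
    probs = np.array([exp[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    f_exp = n * probs
    stat, p = stats.chisquare(f_obs, f_exp)
    return float(stat), len(labels) - 1, float(p)


def diversity_timecourse(cohort) -> pd.Series:
    """Mean unique-lineage count per ovariole, indexed by dphs."""
    records = _flatten(cohort)
    if not records:
        raise ValueError("empty cohort")
    df = pd.DataFrame(
        {
            "dphs": [r.dphs for r in records],
            "k": [count_unique_lineages(r) for r in records],
        }
    )
    return df.groupby("dphs")["k"].mean()
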