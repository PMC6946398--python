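"""Clone-pattern classification, frequency tables, goodness of fit."""

import numpy as np
import pytest

from conftest import GFP_NEG, GFP_POS, make_category_record, make_record
from fscclone import clone_stats as cs
from fscclone.clone_stats import CloneCategory, LabelingClass
from fscclone.germarium import AnteriorAnnotation, ClonePatch
from fscclone.marker_models import Phenotype, phenotype_distribution


class TestClassifyClonePattern:
    @pytest.mark.parametrize("category", list(CloneCategory))
    def test_canonical_patterns_round_trip(self, category):
        rec = make_category_record(category)
        cats = cs.classify_clone_pattern(rec)
        assert list(cats.values()) == [category]

    def test_border_spanning_patch_is_persistent(self):
        rec = make_record([ClonePatch(GFP_NEG, True, 3, [0.4, 0.5, 0.6], 1300)])
        assert cs.classify_clone_pattern(rec)[GFP_NEG] == CloneCategory.FSC_PERSISTENT

    def test_small_nonborder_patch_is_transient(self):
        rec = make_record([ClonePatch(GFP_NEG, False, 1, [0.4], 360)])
        assert cs.classify_clone_pattern(rec)[GFP_NEG] == CloneCategory.TRANSIENT

    def test_border_plus_disjoint_downstream_is_discontinuous(self):
        rec = make_record(
            [
                ClonePatch(GFP_NEG, True, 1, [0.3], 280, patch_id=0),
                ClonePatch(GFP_NEG, False, 1, [0.6], 540, patch_id=1),
            ]
        )
        assert cs.classify_clone_pattern(rec)[GFP_NEG] == CloneCategory.DISCONTINUOUS

    def test_distinct_phenotypes_classified_independently(self):
        a, b = Phenotype.of("LacZ"), Phenotype.of("GFP")
        rec = make_record(
            [
                ClonePatch(a, True, 2, [0.5, 0.5], 900, patch_id=0),
                ClonePatch(b, False, 1, [0.3], 270, patch_id=1),
            ]
        )
        cats = cs.classify_clone_pattern(rec)
        assert cats[a] == CloneCategory.FSC_PERSISTENT
        assert cats[b] == CloneCategory.TRANSIENT

    def test_record_without_clones_signals_no_clone(self):
        with pytest.raises(cs.NoCloneError):
            cs.classify_clone_pattern(make_record([]))


class TestLabeling:
    def test_no_patches_is_none(self):
        assert cs.classify_labeling(make_record([])) == LabelingClass.NONE

    def test_transient_only_is_none(self):
        rec = make_category_record(CloneCategory.TRANSIENT)
        assert cs.classify_labeling(rec) == LabelingClass.NONE

    def test_half_coverage_is_mosaic(self):
        rec = make_category_record(CloneCategory.FSC_PERSISTENT)
        assert cs.classify_labeling(rec) == LabelingClass.MOSAIC

    def test_full_coverage_is_full(self):
        rec = make_record([ClonePatch(GFP_NEG, True, 3, [1.0, 1.0, 1.0], 2700)])
        assert cs.classify_labeling(rec) == LabelingClass.FULL


class TestUniqueLineages:
    def test_background_only_counts_one(self):
        assert cs.count_unique_lineages(make_record([])) == 1

    def test_background_plus_recombinant_counts_two(self):
        rec = make_record([ClonePatch(GFP_NEG, True, 2, [0.5, 0.5], 900)])
        assert cs.count_unique_lineages(rec) == 2

    def test_empty_record_counts_zero(self):
        rec = make_record([], total=0)
        assert cs.count_unique_lineages(rec) == 0

    def test_patch_matching_background_merges_with_it(self):
        rec = make_record([ClonePatch(GFP_POS, True, 2, [0.5, 0.5], 900)])
        assert cs.count_unique_lineages(rec) == 1


class TestTabulate:
    def test_identical_records_single_row_100_percent(self):
        recs = [make_category_record(CloneCategory.TRANSIENT) for _ in range(10)]
        tab = cs.tabulate(recs, key="category")
        assert len(tab.table) == 1
        assert tab.table["percent"].iloc[0] == pytest.approx(100.0)

    def test_grouped_percents_sum_to_100(self):
        recs = []
        for dphs in (5.0, 14.0):
            for cat in (CloneCategory.TRANSIENT, CloneCategory.FSC_PERSISTENT):
                r = make_category_record(cat)
                r.dphs = dphs
                recs.append(r)
        tab = cs.tabulate(recs, key="category", group_by="dphs")
        sums = tab.table.groupby("group")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_multinomial_category_proportions_recovered(self):
        """Cohorts generated at the observed five-pattern frequencies are
        recovered by classification within 1.5 percentage points."""
        target = {
            CloneCategory.FSC_PERSISTENT: 61.5,
            CloneCategory.TRANSIENT: 20.6,
            CloneCategory.REPLACEMENT: 3.6,
            CloneCategory.SMALL_GERMARIUM: 8.3,
            CloneCategory.DISCONTINUOUS: 6.0,
        }
        rng = np.random.default_rng(2024)
        cats = list(target)
        probs = np.array([target[c] for c in cats]) / 100.0
        n = 10_000
        draws = rng.choice(len(cats), size=n, p=probs)
        recs = [make_category_record(cats[i]) for i in draws]
        tab = cs.tabulate(recs, key="category")
        got = tab.percents()
        for cat, pct in target.items():
            assert got[cat.value] == pytest.approx(pct, abs=1.5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cs.tabulate([], key="category")


class TestGoodnessOfFit:
    EXPECTED = {
        "B": 1 / 9,
        "G": 1 / 9,
        "BG": 1 / 9,
        "BR": 2 / 9,
        "GR": 2 / 9,
        "LGR": 2 / 9,
    }

    def test_exactly_proportional_counts_give_zero_statistic(self):
        obs = {"B": 10, "G": 10, "BG": 10, "BR": 20, "GR": 20, "LGR": 20}
        stat, df, p = cs.goodness_of_fit(obs, self.EXPECTED)
        assert stat == pytest.approx(0.0)
        assert df == 5
        assert p == pytest.approx(1.0)

    def test_concentrated_counts_match_hand_computed_statistic(self):
        # all 90 observations in the first class: chi2 = 80^2/10 + 10 + 10
        # + 3 * 20 = 720
        obs = {"B": 90, "G": 0, "BG": 0, "BR": 0, "GR": 0, "LGR": 0}
        stat, df, _ = cs.goodness_of_fit(obs, self.EXPECTED)
        assert stat == pytest.approx(720.0)
        assert df == 5

    def test_accepts_phenotype_distribution(self):
        dist = phenotype_distribution("GFPNEG_FRT19A")
        obs = {"GFP": 60, "(none)": 30}
        stat, df, p = cs.goodness_of_fit(obs, dist)
        assert stat == pytest.approx(0.0)
        assert df == 1

    def test_zero_expected_with_observed_count_rejected(self):
        with pytest.raises(ValueError):
            cs.goodness_of_fit({"A": 5, "B": 5}, {"A": 1.0, "B": 0.0})

    def test_unknown_observed_label_rejected(self):
        with pytest.raises(ValueError):
            cs.goodness_of_fit({"X": 5}, {"A": 1.0})


class TestAnteriorCellClass:
    def _rec(self, fasiii, boundary, contiguous):
        return make_record(
            [ClonePatch(GFP_NEG, True, 2, [0.5, 0.5], 900)],
            ann=AnteriorAnnotation(fasiii, boundary, contiguous),
        )

    def test_fasiii_positive_at_boundary_is_border(self):
        assert cs.anterior_cell_class(self._rec(True, True, True)) == "border"

    def test_fasiii_negative_contiguous_is_adjacent(self):
        assert cs.anterior_cell_class(self._rec(False, True, True)) == "adjacent"

    def test_fasiii_negative_disjoint_is_anterior(self):
        assert cs.anterior_cell_class(self._rec(False, False, False)) == "anterior"

    def test_missing_annotation_rejected(self):
        rec = make_record([ClonePatch(GFP_NEG, True, 2, [0.5, 0.5], 900)])
        with pytest.raises(cs.AnnotationError):
            cs.anterior_cell_class(rec)


def test_diversity_proportions_recovered_from_constructed_cohort():
    """Diversity counts (1, 2, 3 unique lineages) generated at known
    proportions are recovered within binomial 3-SE bounds."""
    rng = np.random.default_rng(11)
    target = {1: 0.40, 2: 0.45, 3: 0.15}
    n = 5000
    phenos = [Phenotype.of("LacZ"), Phenotype.of("RFP")]  # distinct from background
    recs = []
    for d in rng.choice(list(target), size=n, p=list(target.values())):
        patches = [
            ClonePatch(phenos[i], True, 2, [0.3, 0.3], 500, patch_id=i)
            for i in range(int(d) - 1)
        ]
        recs.append(make_record(patches))
    tab = cs.tabulate(recs, key="diversity")
    got = tab.percents()
    for d, frac in target.items():
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(got[str(d)] / 100.0 - frac) <= 3 * se
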