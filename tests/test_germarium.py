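"""Ovariole simulator: growth model, induction arithmetic, invariants."""

import numpy as np
import pytest

from fscclone import clone_stats as cs
from fscclone.germarium import (
    SimConfig,
    SimParameterError,
    sample_follicle_composition,
    simulate_cohort,
    simulate_ovariole,
)


class TestFollicleComposition:
    def test_deterministic_split_is_equal(self):
        counts = sample_follicle_composition(["A", "B"], 900, "deterministic")
        assert counts == {"A": 450, "B": 450}

    def test_single_founder_takes_all(self):
        rng = np.random.default_rng(0)
        for model in ("polya", "deterministic"):
            assert sample_follicle_composition(["A"], 900, model, rng) == {"A": 900}

    def test_counts_sum_and_positivity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = sample_follicle_composition(list("ABCD"), 900, "polya", rng)
            assert sum(c.values()) == 900
            assert all(v >= 1 for v in c.values())

    def test_empty_founder_list_raises(self):
        with pytest.raises(SimParameterError):
            sample_follicle_composition([], 900, "polya")

    def test_polya_two_founders_mean_half_with_spread(self):
        """Polya-urn reinforcement: founder shares are uniform on (0,1) in the
        two-founder limit — mean 1/2, SD near sqrt(1/12)."""
        rng = np.random.default_rng(2)
        n = 10_000
        fracs = np.empty(n)
        for i in range(n):
            c = sample_follicle_composition(["A", "B"], 900, "polya", rng)
            fracs[i] = c["A"] / 900
        se = fracs.std(ddof=1) / np.sqrt(n)
        assert abs(fracs.mean() - 0.5) <= 3 * se
        assert 0.24 < fracs.std(ddof=1) < 0.34  # ~sqrt(1/12) = 0.289
        assert (fracs > 0.9).any() and (fracs < 0.1).any()


class TestSimulateOvariole:
    def test_no_label_sources_gives_no_patches(self):
        cfg = SimConfig(
            induction_prob=0.0,
            background_rate=0.0,
            silencing_rate=0.0,
            igs_induction_prob=0.0,
            sample_dphs=(5, 14, 25),
        )
        recs = simulate_ovariole(cfg, np.random.default_rng(0))
        assert len(recs) == 3
        assert all(not r.patches for r in recs)
        assert all(r.anterior_cell_position == "none" for r in recs)

    def test_forced_single_label_deterministic_growth_gives_half_fractions(self):
        cfg = SimConfig(
            force_n_labeled_fsc=1,
            induction_prob=0.0,
            background_rate=0.0,
            igs_induction_prob=0.0,
            growth_model="deterministic",
            heat_shock_times_h=(0.0,),
            sample_dphs=(7,),
        )
        for seed in range(5):
            (rec,) = simulate_ovariole(cfg, np.random.default_rng(seed))
            border = [p for p in rec.patches if p.touches_border]
            assert len(border) == 1
            assert border[0].fraction_of_follicle == [0.5, 0.5, 0.5]
            assert cs.persistent_clone_fraction(rec) == pytest.approx(0.5)

    def test_induction_complement_rule(self):
        """P(>=1 labeled FSC) = 1 - (1-p)^l for a single heat shock."""
        p, l, n = 0.187, 2, 10_000
        cfg = SimConfig(
            induction_prob=p,
            background_rate=0.0,
            igs_induction_prob=0.0,
            heat_shock_times_h=(0.0,),
            sample_dphs=(7,),
        )
        cohort = simulate_cohort(cfg, n, seed=123)
        got = sum(
            1
            for ov in cohort
            for r in ov
            if any(q.touches_border and not q.in_germarium_only for q in r.patches)
        )
        expected = 1 - (1 - p) ** l
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(got / n - expected) <= 3 * se

    @pytest.mark.parametrize("l", [1, 2, 4, 16])
    def test_single_labeled_lineage_expected_fraction_is_reciprocal(self, l):
        n = 500
        cfg = SimConfig(
            n_fsc=l,
            force_n_labeled_fsc=1,
            induction_prob=0.0,
            background_rate=0.0,
            igs_induction_prob=0.0,
            heat_shock_times_h=(0.0,),
            sample_dphs=(7,),
        )
        cohort = simulate_cohort(cfg, n, seed=42 + l)
        fracs = np.array(
            [
                f
                for ov in cohort
                for r in ov
                if (f := cs.persistent_clone_fraction(r)) is not None
            ]
        )
        assert len(fracs) == n
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 1.0 / l) <= 3 * max(se, 1e-4)

    def test_cell_count_conservation_under_all_processes(self):
        cfg = SimConfig(
            marking_system="LGR",
            induction_prob=0.187,
            background_rate=1e-3,
            silencing_rate=5e-3,
            replacement_rate=0.05,
            quiescence_rate=0.05,
            sample_dphs=(5, 9, 14, 25),
        )
        cohort = simulate_cohort(cfg, 50, seed=7)
        for ov in cohort:
            for r in ov:
                patch_sum = sum(p.cell_count for p in r.patches)
                assert patch_sum == sum(r.labeled_cells.values())
                assert patch_sum <= r.total_cells_scored
                for p in r.patches:
                    assert all(0.0 <= f <= 1.0 for f in p.fraction_of_follicle)

    def test_transients_cleared_after_clearance_time(self):
        cfg = SimConfig(
            induction_prob=0.8,  # many transient clones early
            background_rate=0.0,
            quiescence_rate=0.0,
            replacement_rate=0.0,
            igs_induction_prob=0.0,
            force_n_labeled_fsc=0,  # no FSC clones: isolate transients
            heat_shock_times_h=(0.0,),
            ovariole_clearance_d=8.5,
            sample_dphs=(5, 14),
        )
        cohort = simulate_cohort(cfg, 100, seed=3)
        early = [r for ov in cohort for r in ov if r.dphs == 5]
        late = [r for ov in cohort for r in ov if r.dphs == 14]
        assert any(r.patches for r in early)  # transients present before clearance
        assert all(
            not [p for p in r.patches if not p.touches_border] for r in late
        )

    def test_diversity_bounded_by_phenotype_classes(self):
        cfg = SimConfig(
            marking_system="LGR",
            induction_prob=0.9,
            background_rate=0.0,
            silencing_rate=0.0,
            sample_dphs=(5,),
        )
        cohort = simulate_cohort(cfg, 100, seed=9)
        for ov in cohort:
            for r in ov:
                assert cs.count_unique_lineages(r) <= 6


class TestCohort:
    def test_identical_seed_gives_identical_cohort(self, tmp_path):
        from fscclone.io import write_cohort_tsv

        cfg = SimConfig(induction_prob=0.187, sample_dphs=(5, 14))
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cohort_tsv(simulate_cohort(cfg, 30, seed=5), a)
        write_cohort_tsv(simulate_cohort(cfg, 30, seed=5), b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        cfg = SimConfig(induction_prob=0.187, sample_dphs=(5,))
        c1 = simulate_cohort(cfg, 30, seed=5)
        c2 = simulate_cohort(cfg, 30, seed=6)
        n1 = sum(len(r.patches) for ov in c1 for r in ov)
        n2 = sum(len(r.patches) for ov in c2 for r in ov)
        assert (n1, n2) != (0, 0)
        assert n1 != n2 or any(
            r1.patches and r2.patches and r1.patches[0].fraction_of_follicle
            != r2.patches[0].fraction_of_follicle
            for ov1, ov2 in zip(c1, c2)
            for r1, r2 in zip(ov1, ov2)
        )

    def test_zero_ovarioles_rejected(self):
        with pytest.raises(SimParameterError):
            simulate_cohort(SimConfig(), 0, seed=1)

    def test_mean_diversity_non_increasing_from_5_to_25_dphs(self):
        cfg = SimConfig(
            marking_system="LGR",
            induction_prob=0.187,
            sample_dphs=(5, 25),
        )
        cohort = simulate_cohort(cfg, 300, seed=17)
        tc = cs.diversity_timecourse(cohort)
        assert tc.loc[25] <= tc.loc[5]


def test_invalid_configs_rejected():
    with pytest.raises(SimParameterError):
        SimConfig(n_fsc=0)
    with pytest.raises(SimParameterError):
        SimConfig(induction_prob=1.5)
    with pytest.raises(SimParameterError):
        SimConfig(sample_dphs=(9, 5))
    with pytest.raises(SimParameterError):
        SimConfig(cycle_h=0.0)
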