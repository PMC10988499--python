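"""Group statistics: ANOVA, BH-FDR, volcano tables, compound matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capdomain import (
    CompoundRecord,
    FeatureRecord,
    MetaboliteMatrix,
    ValidationError,
    bh_fdr,
    match_compound,
    one_way_anova,
    volcano_table,
)
from capdomain.synth import EffectSpec, generate_metabolome


def brute_force_f(groups):
    """Direct between/within sum-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    df_b, df_w = len(groups) - 1, allv.size - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = [np.array([1.0, 2.0, 3.0])] * 3
        res = one_way_anova(g)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        from scipy import stats

        a = np.array([4.1, 5.2, 6.3, 5.8])
        b = np.array([7.4, 8.1, 6.9, 7.7, 8.5])
        res = one_way_anova([a, b])
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t**2, rel=1e-12)
        assert res.p == pytest.approx(p_t, rel=1e-12)

    def test_f_matches_brute_force_decomposition(self, rng):
        groups = [rng.normal(i, 1.0, size=6) for i in range(4)]
        res = one_way_anova(groups)
        assert res.F == pytest.approx(brute_force_f(groups), rel=1e-10)
        assert res.df == (3, 20)

    def test_tukey_pairs_complete_and_bounded(self, rng):
        groups = [rng.normal(i, 1.0, size=5) for i in range(3)]
        res = one_way_anova(groups, labels=["CT", "10Hz", "40Hz"])
        assert len(res.tukey) == 3
        for diff, p in res.tukey.values():
            assert 0.0 <= p <= 1.0

    def test_degenerate_zero_variance_is_error(self):
        with pytest.raises(ValidationError):
            one_way_anova([np.array([1.0, 1.0]), np.array([1.0, 1.0])])
        with pytest.raises(ValidationError):
            one_way_anova([np.array([1.0, 1.0]), np.array([2.0, 2.0])])

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([np.array([1.0]), np.array([2.0, 3.0])])


class TestBHFDR:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ps=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30)
    )
    def test_adjusted_never_below_raw_and_capped(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_permutation_equivariance(self, rng):
        ps = rng.uniform(size=20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_fdr(ps)[perm], bh_fdr(ps[perm]))

    def test_matches_hand_step_up_on_random_input(self, rng):
        ps = rng.uniform(size=15)
        order = np.argsort(ps)
        m = ps.size
        adj_sorted = np.minimum.accumulate(
            (ps[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(ps), expected)


class TestVolcano:
    def make_matrix(self, a, b, compounds=None):
        a, b = np.asarray(a, float), np.asarray(b, float)
        compounds = compounds or [f"c{j}" for j in range(a.shape[1])]
        return MetaboliteMatrix(
            intensities=np.vstack([a, b]),
            sample_groups=["A"] * a.shape[0] + ["B"] * b.shape[0],
            compound_ids=compounds,
        )

    def test_doubling_with_zero_variance(self):
        m = self.make_matrix([[10.0], [10.0]], [[20.0], [20.0]])
        (row,) = volcano_table(m, "A", "B")
        assert row.log2_fold_change == pytest.approx(1.0)
        assert 0 < row.raw_p <= np.finfo(float).tiny

    def test_identical_groups_give_zero_log2fc(self):
        m = self.make_matrix([[5.0, 7.0], [6.0, 8.0]], [[5.0, 7.0], [6.0, 8.0]])
        rows = volcano_table(m, "A", "B")
        for r in rows:
            assert r.log2_fold_change == pytest.approx(0.0)

    def test_zero_group_mean_flagged_not_dropped(self):
        m = self.make_matrix([[0.0], [0.0]], [[1.0], [2.0]])
        (row,) = volcano_table(m, "A", "B")
        assert row.flagged and np.isnan(row.log2_fold_change)

    def test_fdr_never_below_raw(self, rng):
        mat = rng.lognormal(10, 0.5, size=(10, 40))
        m = MetaboliteMatrix(mat, ["A"] * 5 + ["B"] * 5,
                             [f"c{j}" for j in range(40)])
        for r in volcano_table(m, "A", "B"):
            assert r.fdr_adjusted_p >= r.raw_p - 1e-15

    def test_planted_two_fold_compound_detected(self):
        effects = EffectSpec(metabolite_folds={"10Hz": {"kynurenic acid": 2.0}})
        hits = 0
        for seed in range(20):
            m = generate_metabolome(
                n_per_group=5, compounds=["kynurenic acid"]
                + [f"c{j}" for j in range(49)],
                effects=effects, sigma_log=0.1, seed=seed,
                groups=("CT", "10Hz"),
            )
            rows = volcano_table(m, "CT", "10Hz")
            best = min(rows, key=lambda r: r.raw_p)
            hits += best.compound_id == "kynurenic acid"
        assert hits >= 19  # planted effect ranks first almost always

    def test_null_calibration_small(self, rng):
        """Under the global null ~5% of raw p-values fall below 0.05."""
        effects = EffectSpec(metabolite_folds={})
        fracs = []
        for seed in range(10):
            m = generate_metabolome(
                n_per_group=5, compounds=[f"c{j}" for j in range(200)],
                effects=effects, sigma_log=0.2, seed=seed,
                groups=("CT", "10Hz"),
            )
            rows = volcano_table(m, "CT", "10Hz")
            fracs.append(np.mean([r.raw_p < 0.05 for r in rows]))
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.015)


class TestCompoundMatching:
    REC = CompoundRecord("glutamate", 147.05316, 312.0, isotope_match=100.0)

    def feature(self, dppm=0.0, drt=0.0, iso=95.0):
        mass = self.REC.theoretical_mass * (1 + dppm * 1e-6)
        return FeatureRecord("f1", mass, self.REC.retention_time + drt, iso)

    def test_within_all_tolerances_accepted(self):
        assert match_compound(self.feature(4.9, 29.0, 91.0), self.REC)

    def test_mass_just_over_tolerance_rejected(self):
        assert not match_compound(self.feature(5.1, 0.0, 99.0), self.REC)

    def test_rt_just_over_tolerance_rejected(self):
        assert not match_compound(self.feature(0.0, 31.0, 99.0), self.REC)

    def test_isotope_at_boundary_rejected(self):
        assert not match_compound(self.feature(0.0, 0.0, 90.0), self.REC)

    def test_exact_match_accepted(self):
        assert match_compound(self.feature(0.0, 0.0, 100.0), self.REC)
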