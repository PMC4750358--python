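import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpmeta as sm
from snpmeta.effects import EffectEstimate
from snpmeta.pooling import (
    cochran_q,
    dl_tau2,
    fixed_effect_pool,
    galbraith,
    i_squared,
    leave_one_out,
    random_effects_pool,
    subgroup_analysis,
)

from conftest import brute_force_pool

estimate_lists = st.lists(
    st.tuples(
        st.floats(min_value=-2.0, max_value=2.0),
        st.floats(min_value=0.05, max_value=1.0),
    ),
    min_size=2,
    max_size=4,
)


def to_estimates(pairs):
    return [EffectEstimate(y, se, f"s{i}") for i, (y, se) in enumerate(pairs)]


class TestFixedEffect:
    def test_single_estimate_is_identity(self):
        est = EffectEstimate(0.3, 0.1, "only")
        res = fixed_effect_pool([est])
        assert res.y == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1)
        assert res.q == 0.0 and res.df == 0

    def test_two_identical_closed_form(self):
        est = EffectEstimate(0.5, 0.2)
        res = fixed_effect_pool([est, est])
        assert res.y == pytest.approx(0.5)
        assert res.se == pytest.approx(0.2 / math.sqrt(2))

    def test_empty_input(self):
        with pytest.raises(ValueError):
            fixed_effect_pool([])

    @given(pairs=estimate_lists)
    @settings(max_examples=200)
    def test_matches_brute_force(self, pairs):
        oracle = brute_force_pool(pairs)
        res = fixed_effect_pool(to_estimates(pairs))
        assert res.y == pytest.approx(oracle["y_fixed"], rel=1e-10)
        assert res.se == pytest.approx(oracle["se_fixed"], rel=1e-10)


class TestCochranQ:
    def test_identical_estimates_zero(self):
        ests = [EffectEstimate(0.4, 0.3)] * 3
        q, df, p = cochran_q(ests)
        assert q == pytest.approx(0.0)
        assert df == 2 and p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        ests = to_estimates([(0.1, 0.2), (0.5, 0.3), (-0.2, 0.15)])
        q1, _, _ = cochran_q(ests)
        q2, _, _ = cochran_q(ests[::-1])
        assert q1 == pytest.approx(q2)

    def test_requires_two(self):
        with pytest.raises(ValueError):
            cochran_q([EffectEstimate(0.1, 0.1)])

    def test_rs2472304_q_below_df(self, records_by_snp):
        units = sm.build_analysis_units(records_by_snp["rs2472304"], model="recessive")
        ests = [u.effect for u in units]
        q, df, _ = cochran_q(ests)
        assert q < df
        assert i_squared(q, df) == 0.0


class TestISquared:
    @pytest.mark.parametrize(
        "q,df,expected", [(0, 1, 0.0), (4, 2, 50.0), (1, 5, 0.0), (10, 10, 0.0)]
    )
    def test_closed_form(self, q, df, expected):
        assert i_squared(q, df) == pytest.approx(expected)

    def test_rs35694136_high_heterogeneity(self, records_by_snp):
        units = sm.build_analysis_units(records_by_snp["rs35694136"], model="dominant")
        res = random_effects_pool([u.effect for u in units])
        # published value 89.0; recomputed from the 2-dp table rows: 88.9
        assert round(res.i2) == 89


class TestDlTau2:
    def test_zero_when_q_below_df(self):
        ests = to_estimates([(0.1, 0.5), (0.11, 0.5), (0.09, 0.5)])
        assert dl_tau2(ests) == 0.0

    def test_identical_estimates(self):
        assert dl_tau2([EffectEstimate(0.2, 0.3)] * 4) == 0.0

    def test_bladder_subset_hand_value(self, records_by_snp):
        bladder = [r for r in records_by_snp["rs762551"] if r.tumour_site == "bladder"]
        ests = [sm.effect_from_record(r) for r in bladder]
        # hand-summation oracle on the CI-derived (y, se) pairs
        oracle = brute_force_pool([(e.y, e.se) for e in ests])
        assert dl_tau2(ests) == pytest.approx(oracle["tau2"], rel=1e-12)
        assert dl_tau2(ests) == pytest.approx(0.0143, abs=5e-4)

    @given(pairs=estimate_lists)
    @settings(max_examples=200)
    def test_matches_brute_force(self, pairs):
        oracle = brute_force_pool(pairs)
        assert dl_tau2(to_estimates(pairs)) == pytest.approx(oracle["tau2"], abs=1e-12)


class TestRandomEffects:
    def test_reduces_to_fixed_when_homogeneous(self):
        ests = to_estimates([(0.2, 0.3), (0.2, 0.4), (0.2, 0.25)])
        fixed = fixed_effect_pool(ests)
        random = random_effects_pool(ests)
        assert random.tau2 == 0.0
        assert random.y == pytest.approx(fixed.y)
        assert random.se == pytest.approx(fixed.se)

    def test_homogeneous_limit_properties(self):
        ests = [EffectEstimate(0.7, 0.2, f"s{i}") for i in range(5)]
        res = random_effects_pool(ests)
        assert res.y == pytest.approx(0.7)
        assert res.se == pytest.approx(0.2 / math.sqrt(5))
        assert res.q == pytest.approx(0.0)
        assert res.i2 == 0.0 and res.tau2 == 0.0

    def test_k1_degenerate(self):
        res = random_effects_pool([EffectEstimate(0.1, 0.2, "solo")])
        assert res.degenerate
        assert res.y == pytest.approx(0.1)

    @given(pairs=estimate_lists)
    @settings(max_examples=200)
    def test_matches_brute_force(self, pairs):
        oracle = brute_force_pool(pairs)
        res = random_effects_pool(to_estimates(pairs))
        assert res.y == pytest.approx(oracle["y_random"], rel=1e-9, abs=1e-12)
        assert res.se == pytest.approx(oracle["se_random"], rel=1e-9)
        assert res.q == pytest.approx(oracle["q"], abs=1e-9)

    @given(pairs=estimate_lists, se_new=st.floats(min_value=0.05, max_value=1.0))
    @settings(max_examples=100)
    def test_monotone_precision(self, pairs, se_new):
        # appending a unit at the current (fixed) pooled value leaves Q
        # unchanged and cannot inflate tau2, so the pooled log-OR interval
        # never widens (the OR-scale width can still shift with the pooled
        # point because exp is convex, hence the log-scale comparison)
        ests = to_estimates(pairs)
        before = random_effects_pool(ests)
        anchor = fixed_effect_pool(ests).y
        after = random_effects_pool(ests + [EffectEstimate(anchor, se_new, "new")])
        assert after.se <= before.se + 1e-12
        assert after.tau2 <= before.tau2 + 1e-12


class TestSubgroups:
    def test_mixed_rs2470890(self, records_by_snp):
        by = subgroup_analysis(records_by_snp["rs2470890"], "ethnicity")
        res = by["Mixed"]
        assert res.k == 2
        assert round(res.odds_ratio, 2) == 1.44
        assert res.i2 == 0.0
        members = set(res.labels)
        assert any("Aldrich" in m for m in members)
        assert any("Anderson" in m for m in members)

    def test_large_rs2472304(self, records_by_snp):
        by = subgroup_analysis(records_by_snp["rs2472304"], "sample_size")
        assert round(by["large"].odds_ratio, 2) == 0.79

    def test_single_level_equals_overall(self, records_by_snp):
        recs = records_by_snp["rs2069526"]  # all Caucasian
        by = subgroup_analysis(recs, "ethnicity")
        assert set(by) == {"Caucasian"}
        units = sm.build_analysis_units(recs, model="dominant")
        overall = random_effects_pool([u.effect for u in units])
        assert by["Caucasian"].y == pytest.approx(overall.y)

    def test_unknown_factor(self, records_by_snp):
        with pytest.raises(ValueError, match="unknown factor"):
            subgroup_analysis(records_by_snp["rs2472304"], "phase_of_moon")

    def test_tumour_site_keeps_shared_controls_separate(self, records_by_snp):
        by = subgroup_analysis(records_by_snp["rs762551"], "tumour_site")
        # the three shared-control rows are different sites, so no merging
        assert sum(res.k for res in by.values()) == 64
        assert by["bladder"].k == 5

    def test_degenerate_stratum_flagged(self, records_by_snp):
        by = subgroup_analysis(records_by_snp["rs762551"], "tumour_site")
        assert by["prostate"].k == 1 and by["prostate"].degenerate


class TestLeaveOneOut:
    def test_requires_three(self):
        with pytest.raises(ValueError):
            leave_one_out(to_estimates([(0.1, 0.2), (0.2, 0.2)]))

    def test_symmetric_input_gives_identical_iterations(self):
        ests = [EffectEstimate(0.3, 0.25, f"s{i}") for i in range(5)]
        results = leave_one_out(ests)
        ys = {round(res.y, 12) for _, res in results}
        assert len(results) == 5 and len(ys) == 1

    def test_restoring_omitted_unit_recovers_full_pool(self, records_by_snp):
        units = sm.build_analysis_units(records_by_snp["rs2470890"], model="recessive")
        ests = [u.effect for u in units]
        full = random_effects_pool(ests)
        for label, _ in leave_one_out(ests):
            rest = [e for e in ests if e.label != label]
            restored = random_effects_pool(
                rest + [e for e in ests if e.label == label]
            )
            assert restored.y == pytest.approx(full.y)
            assert restored.tau2 == pytest.approx(full.tau2)

    def test_tau2_reestimated_per_iteration(self, records_by_snp):
        units = sm.build_analysis_units(records_by_snp["rs2470890"], model="recessive")
        results = leave_one_out([u.effect for u in units])
        tau2s = {round(res.tau2, 10) for _, res in results}
        assert len(tau2s) > 1


class TestGalbraith:
    def test_requires_three(self):
        with pytest.raises(ValueError):
            galbraith(to_estimates([(0.1, 0.2), (0.2, 0.2)]))

    def test_homogeneous_set_no_outliers(self):
        points = galbraith([EffectEstimate(0.4, 0.1 + 0.05 * i) for i in range(5)])
        assert not any(p.outlier for p in points)

    def test_planted_outlier_flagged_alone(self):
        cluster = [EffectEstimate(0.0, 0.1, f"c{i}") for i in range(6)]
        planted = EffectEstimate(0.5, 0.1, "planted")  # 5 SEs off the cluster
        points = galbraith(cluster + [planted])
        flagged = [p.label for p in points if p.outlier]
        assert flagged == ["planted"]

    def test_outlier_flag_definition(self):
        for p in galbraith(to_estimates([(0.0, 0.1), (0.1, 0.2), (1.5, 0.3)])):
            assert p.outlier == (abs(p.residual) > 2)

    def test_rs2069514_main_contributor(self, records_by_snp):
        units = sm.build_analysis_units(records_by_snp["rs2069514"], model="dominant")
        flagged = [p.label for p in galbraith([u.effect for u in units]) if p.outlier]
        assert any(label.startswith("B'chir") for label in flagged)
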