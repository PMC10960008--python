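"""Statistical pipeline: composites, ROC/AUC, ANOVA, t-tests, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import misinfosim as m
from misinfosim.analysis import participant_summaries


def make_trials(actions_true, actions_false):
    """Build a one-participant trial table from explicit action lists."""
    rows = []
    for veracity, actions in ((True, actions_true), (False, actions_false)):
        for i, a in enumerate(actions):
            rows.append(
                {
                    "participant_id": "p1",
                    "badge": False,
                    "norm": False,
                    "trial_index": len(rows) + 1,
                    "claim_id": f"{'t' if veracity else 'f'}{i}",
                    "veracity": veracity,
                    "action": a,
                }
            )
    return pd.DataFrame(rows)


def concordance_auc(true_ratings, false_ratings):
    """Independent oracle: pairwise concordance with ties counted half."""
    conc = sum(
        1.0 if t > f else (0.5 if t == f else 0.0)
        for t in true_ratings
        for f in false_ratings
    )
    return conc / (len(true_ratings) * len(false_ratings))


class TestCompositeEngagement:
    @pytest.mark.parametrize(
        "action,expected",
        [("share", 80), ("flag", -40), ("skip", 0), ("like", 40)],
    )
    def test_uniform_action_scores(self, action, expected):
        trials = make_trials(["skip"] * 40, [action] * 40)
        assert m.composite_engagement(trials, False) == expected

    def test_mixed_arithmetic(self):
        actions = ["flag"] * 10 + ["like"] * 5 + ["share"] * 5 + ["skip"] * 20
        trials = make_trials(actions, ["skip"] * 40)
        assert m.composite_engagement(trials, True) == -10 + 5 + 10

    def test_counts_sum_and_identity(self):
        actions = ["flag"] * 7 + ["like"] * 13 + ["share"] * 4 + ["skip"] * 16
        trials = make_trials(["skip"] * 40, actions)
        counts = m.engagement_type_counts(trials, False)
        assert sum(counts.values()) == 40
        assert m.composite_engagement(trials, False) == (
            -counts["flag"] + counts["like"] + 2 * counts["share"]
        )

    def test_missing_class_raises(self):
        trials = make_trials(["skip"] * 3, [])
        with pytest.raises(ValueError):
            m.composite_engagement(trials, False)

    @given(st.lists(st.sampled_from(["flag", "skip", "like", "share"]), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounds_property(self, actions):
        trials = make_trials(actions, ["skip"])
        score = m.composite_engagement(trials, True)
        assert -len(actions) <= score <= 2 * len(actions)


class TestROC:
    def test_perfect_discrimination(self):
        assert m.roc_curve([10] * 40, [0] * 40).auc == pytest.approx(1.0)

    def test_chance_when_distributions_identical(self):
        assert m.roc_curve([5] * 40, [5] * 40).auc == pytest.approx(0.5)

    def test_small_worked_example(self):
        # concordance oracle: (concordant + 0.5 ties) / 9 = 7.5 / 9
        curve = m.roc_curve([10, 8, 5], [7, 5, 2])
        assert curve.auc == pytest.approx(7.5 / 9)

    def test_ten_cutoffs_and_monotone_rates(self):
        curve = m.roc_curve([9, 4, 6, 2], [1, 3, 8, 0])
        assert curve.cutoffs == tuple(range(10, 0, -1))
        assert len(curve.hit_rates) == 10
        hr, fa = curve.hit_rates, curve.false_alarm_rates
        assert all(b >= a for a, b in zip(hr, hr[1:]))
        assert all(b >= a for a, b in zip(fa, fa[1:]))
        pts = curve.points
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_out_of_range_rating_raises(self):
        with pytest.raises(ValueError):
            m.roc_curve([11, 5], [3, 2])
        with pytest.raises(ValueError):
            m.roc_curve([5], [-1])

    def test_trapezoid_diagonal_and_step(self):
        assert m.auc_trapezoid([(0, 0), (1, 1)]) == pytest.approx(0.5)
        assert m.auc_trapezoid([(0, 0), (0, 1), (1, 1)]) == pytest.approx(1.0)

    def test_missing_anchor_raises(self):
        with pytest.raises(ValueError):
            m.auc_trapezoid([(0.2, 0.4), (1, 1)])

    def test_equals_concordance_oracle_on_random_instances(self):
        g = np.random.default_rng(123)
        for _ in range(200):
            t = g.integers(0, 11, size=40)
            f = g.integers(0, 11, size=40)
            assert m.roc_curve(t, f).auc == pytest.approx(
                concordance_auc(t, f), abs=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_auc_range_and_complement(self, seed):
        g = np.random.default_rng(seed)
        t = g.integers(0, 11, size=12)
        f = g.integers(0, 11, size=9)
        a = m.roc_curve(t, f).auc
        b = m.roc_curve(f, t).auc
        assert 0.0 <= a <= 1.0
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestAnova:
    def test_balanced_worked_example(self):
        # direct sums-of-squares oracle on 8 points
        dv = [1, 3, 2, 4, 5, 7, 6, 8]
        badge = [False, False, False, False, True, True, True, True]
        norm = [False, False, True, True, False, False, True, True]
        table = m.anova_2x2(dv, badge, norm)
        assert table["badge"].F == pytest.approx(16.0)
        assert (table["badge"].df1, table["badge"].df2) == (1, 4)
        assert table["badge"].partial_eta2 == pytest.approx(0.8)
        assert table["interaction"].F == pytest.approx(0.0, abs=1e-12)

    def test_constant_dv_convention(self):
        dv = [2.0] * 8
        badge = [False] * 4 + [True] * 4
        norm = [False, False, True, True] * 2
        table = m.anova_2x2(dv, badge, norm)
        for eff in ("badge", "norm", "interaction"):
            assert table[eff].F == 0.0
            assert table[eff].p == 1.0

    def test_missing_cell_raises(self):
        with pytest.raises(ValueError):
            m.anova_2x2([1, 2, 3, 4], [False, False, True, True], [False] * 4)

    def test_matches_reference_implementation(self):
        # independent cross-check against pingouin on unbalanced random data
        pingouin = pytest.importorskip("pingouin")
        g = np.random.default_rng(5)
        n = 90
        badge = g.integers(2, size=n).astype(bool)
        norm = g.integers(2, size=n).astype(bool)
        dv = g.normal(size=n) + 0.8 * badge + 0.3 * badge * norm
        df = pd.DataFrame({"dv": dv, "badge": badge, "norm": norm})
        ref = pingouin.anova(
            data=df, dv="dv", between=["badge", "norm"], ss_type=3, effsize="np2"
        ).set_index("Source")
        ours = m.anova_2x2(dv, badge, norm)
        p_col = "p-unc" if "p-unc" in ref.columns else "p_unc"
        for eff, key in (("badge", "badge"), ("norm", "norm"), ("interaction", "badge * norm")):
            assert ours[eff].F == pytest.approx(float(ref.loc[key, "F"]), rel=1e-6)
            assert ours[eff].p == pytest.approx(float(ref.loc[key, p_col]), abs=1e-9)
            assert ours[eff].partial_eta2 == pytest.approx(float(ref.loc[key, "np2"]), rel=1e-6)

    def test_eta2_ci_brackets_point_estimate(self):
        g = np.random.default_rng(8)
        dv = g.normal(size=80) + np.repeat([0, 1], 40)
        badge = np.repeat([False, True], 40)
        norm = np.tile([False, True], 40)
        res = m.anova_2x2(dv, badge, norm)["badge"]
        lo, hi = res.eta2_ci
        assert 0.0 <= lo <= res.partial_eta2 <= hi <= 1.0


class TestTTest:
    def test_identical_groups(self):
        res = m.t_test_pooled([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.cohens_d == 0.0

    def test_worked_example(self):
        res = m.t_test_pooled([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        assert res.cohens_d == pytest.approx(-1.0)

    def test_df_convention(self, rng):
        res = m.t_test_pooled(rng.normal(size=104), rng.normal(size=104))
        assert res.df == 206

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            m.t_test_pooled([2, 2, 2], [2, 2, 2])

    def test_matches_scipy(self, rng):
        from scipy import stats

        x, y = rng.normal(size=30), rng.normal(0.5, 1.2, size=25)
        res = m.t_test_pooled(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_d_ci_brackets_estimate(self, rng):
        x, y = rng.normal(1, 1, size=50), rng.normal(0, 1, size=50)
        res = m.t_test_pooled(x, y)
        lo, hi = res.d_ci
        assert lo < res.cohens_d < hi


class TestPower:
    def test_study_anchor(self):
        assert m.power_n_per_group(m.PowerSpec(effect_f=0.20)) == 100

    def test_medium_effect(self):
        # d = 0.5 (f = 0.25) needs 64 per group
        assert m.power_n_per_group(m.PowerSpec(effect_f=0.25)) == 64

    def test_monotone_in_effect_size(self):
        assert m.power_n_per_group(m.PowerSpec(effect_f=0.4)) < m.power_n_per_group(
            m.PowerSpec(effect_f=0.2)
        )

    def test_matches_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        for f in (0.15, 0.2, 0.3):
            ref = smp.TTestIndPower().solve_power(
                effect_size=2 * f, alpha=0.05, power=0.8, alternative="two-sided"
            )
            assert m.power_n_per_group(m.PowerSpec(effect_f=f)) == int(np.ceil(ref))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            m.PowerSpec(effect_f=0.0)
        with pytest.raises(ValueError):
            m.PowerSpec(effect_f=0.2, alpha=1.5)


class TestSummariesAndReport:
    def test_vectorized_summaries_match_scalar_path(self, small_run):
        summ = participant_summaries(small_run.trials, small_run.beliefs)
        assert len(summ) == 32
        for pid in summ["participant_id"].iloc[[0, 13, 31]]:
            sub = small_run.trials[small_run.trials["participant_id"] == pid]
            b = small_run.beliefs[small_run.beliefs["participant_id"] == pid]
            row = summ[summ["participant_id"] == pid].iloc[0]
            assert m.composite_engagement(sub, True) == row["composite_true"]
            assert m.composite_engagement(sub, False) == row["composite_false"]
            counts = m.engagement_type_counts(sub, False)
            for action, cnt in counts.items():
                assert row[f"n_{action}_false"] == cnt
            tr = b.loc[b["veracity"], "rating"].to_numpy()
            fr = b.loc[~b["veracity"].astype(bool), "rating"].to_numpy()
            assert row["auc"] == pytest.approx(m.roc_curve(tr, fr).auc, abs=1e-12)
            assert row["belief_true"] == pytest.approx(tr.mean())

    def test_full_report_structure(self, small_run):
        import json

        rep = m.full_report(small_run.trials, small_run.beliefs, compute_ci=False)
        assert rep["n_participants"] == 32
        assert set(rep["cells"]) == {
            "nobadge_nonorm", "nobadge_norm", "badge_nonorm", "badge_norm"
        }
        for dv in m.analysis.ANOVA_DVS:
            assert set(rep["anova"][dv]) == {"badge", "norm", "interaction"}
        assert "credibility_t_test" in rep
        json.dumps(rep)  # must be serializable

    def test_perfect_discriminator_cohort(self, posts):
        # deterministic raters: huge gain, no noise => AUC 1 in every cell
        rows_t, rows_b = [], []
        agent = m.AgentParams(d=40.0, sigma=1e-6, g=10.0, w_src=0.0, delta_norm=0.0)
        for i, cond in enumerate(m.CONDITIONS):
            g = np.random.default_rng(100 + i)
            for j in range(2):
                t, b, _ = m.run_participant(
                    agent, cond, posts, m.DynamicsParams(), g, f"{cond.label}_{j}"
                )
                rows_t.extend(t)
                rows_b.extend(b)
        summ = participant_summaries(pd.DataFrame(rows_t), pd.DataFrame(rows_b))
        assert np.allclose(summ["auc"], 1.0)
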