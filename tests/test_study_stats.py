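"""Study statistics: omnibus routing, Wilcoxon/Holm, best condition."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitpose import (
    CohortSpec,
    analyze_cohort,
    holm_adjust,
    select_best_condition,
    simulate_cohort_outcomes,
    wilcoxon_holm_posthoc,
)
from gaitpose.errors import DegenerateDataError, IncompleteParticipantError
from gaitpose.simulate import CONDITIONS, OUTCOME_COLUMNS
from gaitpose.study_stats import (
    friedman_test,
    mean_difference_table,
    outcome_matrix,
    render_report,
    repeated_measures_anova,
    route_omnibus,
    wilcoxon_signed_rank,
)


def wide(rows, columns):
    df = pd.DataFrame(rows, columns=list(columns), dtype=float)
    df.index = pd.RangeIndex(1, len(df) + 1, name="participant")
    return df


class TestRepeatedAnova:
    def test_matches_sums_of_squares_oracle(self):
        mat = wide([[1, 2, 3], [2, 2.5, 4], [0.5, 1, 2], [3, 3.5, 5]], "abc")
        F, p, (df1, df2) = repeated_measures_anova(mat)
        arr = mat.to_numpy()
        n, k = arr.shape
        grand = arr.mean()
        ss_cond = n * ((arr.mean(0) - grand) ** 2).sum()
        ss_subj = k * ((arr.mean(1) - grand) ** 2).sum()
        ss_err = ((arr - grand) ** 2).sum() - ss_cond - ss_subj
        f_oracle = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        assert F == pytest.approx(f_oracle, abs=1e-9)
        assert (df1, df2) == (k - 1, (n - 1) * (k - 1))

    def test_invariant_to_per_participant_constant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(8, 4))
        mat = wide(base, "abcd")
        shifted = wide(base + rng.normal(size=(8, 1)) * 5.0, "abcd")
        F1, _, _ = repeated_measures_anova(mat)
        F2, _, _ = repeated_measures_anova(shifted)
        assert F1 == pytest.approx(F2, rel=1e-9)

    def test_all_constant_matrix_rejected(self):
        mat = wide([[1, 1, 1]] * 6, "abc")
        with pytest.raises(DegenerateDataError):
            repeated_measures_anova(mat)


class TestFriedman:
    def test_matches_rank_closed_form_on_latin_square(self):
        mat = wide([[1, 2, 3], [2, 3, 1], [3, 1, 2]], "abc")
        chi2, p, _ = friedman_test(mat)
        ranks = np.array([[1, 2, 3], [2, 3, 1], [3, 1, 2]])
        R = ranks.sum(axis=0)
        n, k = 3, 3
        oracle = 12.0 / (n * k * (k + 1)) * (R**2).sum() - 3 * n * (k + 1)
        assert chi2 == pytest.approx(oracle, abs=1e-9)


class TestRouting:
    def test_normal_data_routes_to_anova(self):
        rng = np.random.default_rng(3)
        mat = wide(rng.normal(size=(20, 3)) + [0.0, 0.2, 0.4], "abc")
        res = route_omnibus(mat)
        assert res.test == "repeated_anova"

    def test_heavy_tailed_data_routes_to_friedman(self):
        rng = np.random.default_rng(4)
        arr = rng.standard_cauchy(size=(20, 3)) ** 3
        res = route_omnibus(wide(arr, "abc"))
        assert res.test == "friedman"

    def test_override_forces_the_named_test(self):
        rng = np.random.default_rng(5)
        mat = wide(rng.normal(size=(12, 3)), "abc")
        assert route_omnibus(mat, override="friedman").test == "friedman"
        assert route_omnibus(mat, override="anova").test == "repeated_anova"


class TestWilcoxon:
    def test_exact_p_matches_sign_enumeration(self):
        x = np.array([5.0, 7.0, 9.0, 11.0, 13.0])
        y = np.array([4.0, 5.0, 6.0, 7.0, 8.0])  # differences 1..5
        res = wilcoxon_signed_rank(x, y)
        # enumeration over all 2^5 sign patterns
        ranks = np.arange(1, 6)
        w_obs = ranks.sum()
        stats = []
        for signs in itertools.product([1, -1], repeat=5):
            wp = sum(r for r, s in zip(ranks, signs) if s > 0)
            stats.append(min(wp, 15 - wp))
        obs = min(w_obs, 15 - w_obs)
        p_oracle = np.mean([s <= obs for s in stats])
        assert res["p"] == pytest.approx(p_oracle)
        assert res["p"] == pytest.approx(1 / 16)

    @given(st.lists(st.integers(-50, 50), min_size=6, max_size=10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exact_p_matches_enumeration_on_random_untied_data(self, diffs):
        d = np.array(diffs, dtype=float)
        d = d[d != 0]
        if len(d) < 3 or len(np.unique(np.abs(d))) != len(d):
            return  # zeros dropped; ties route to the normal approximation
        res = wilcoxon_signed_rank(d, np.zeros_like(d))
        n = len(d)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        tot = n * (n + 1) / 2
        obs = min(w_obs, tot - w_obs)
        count = 0
        for signs in itertools.product([1, -1], repeat=n):
            wp = sum(r for r, s in zip(ranks, signs) if s > 0)
            count += min(wp, tot - wp) <= obs
        assert res["p"] == pytest.approx(count / 2**n)

    def test_antisymmetric_differences_give_zero_effect(self):
        res = wilcoxon_signed_rank(np.array([-2.0, -1.0, 1.0, 2.0]),
                                   np.zeros(4))
        assert res["z"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_all_zero_differences_flagged_degenerate(self):
        res = wilcoxon_signed_rank(np.ones(8), np.ones(8))
        assert res["degenerate"]
        assert res["p"] == 1.0


class TestHolm:
    def test_step_down_example(self):
        adj = holm_adjust(np.array([0.001, 0.02, 0.04]))
        assert adj == pytest.approx([0.003, 0.04, 0.04])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=15))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dominates_raw_p_and_is_rank_monotone(self, ps):
        ps = np.array(ps)
        adj = holm_adjust(ps)
        assert (adj >= ps - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_step_down_definition(self, ps):
        ps = np.array(ps)
        m = len(ps)
        order = np.argsort(ps)
        stepped = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            stepped[idx] = min(1.0, running)
        assert holm_adjust(ps) == pytest.approx(stepped)


class TestBestCondition:
    def cohort(self, speeds_by_participant):
        rows = []
        for pid, speeds in speeds_by_participant.items():
            for cond, v in zip(CONDITIONS, speeds):
                row = {"participant": pid, "condition": cond, "gait_speed": v}
                for out in OUTCOME_COLUMNS[1:]:
                    row[out] = 1.0
                rows.append(row)
        return pd.DataFrame(rows)

    def test_argmax_selection(self):
        df = self.cohort({1: [0.50, 0.55, 0.61, 0.58, 0.54]})
        _, best, counts = select_best_condition(df)
        assert best[1] == "spring2"
        assert counts["spring2"] == 1

    def test_exact_tie_breaks_toward_no_afo(self):
        df = self.cohort({1: [0.60, 0.60, 0.50, 0.40, 0.30]})
        _, best, _ = select_best_condition(df)
        assert best[1] == "no_afo"
        assert best.attrs["ties"] == [1]

    def test_best_rows_duplicate_the_winner(self):
        df = self.cohort({1: [0.50, 0.55, 0.61, 0.58, 0.54]})
        with_best, _, _ = select_best_condition(df)
        b = with_best[with_best["condition"] == "best"]
        assert len(b) == 1
        assert b["gait_speed"].iloc[0] == pytest.approx(0.61)

    def test_missing_condition_rejected(self):
        df = self.cohort({1: [0.5, 0.6, 0.7, 0.8, 0.9]})
        df = df[df["condition"] != "spring3"]
        with pytest.raises(IncompleteParticipantError):
            select_best_condition(df)


class TestMeanDifferences:
    def test_two_participant_example(self):
        df = pd.DataFrame([
            {"participant": p, "condition": c, **{o: 1.0 for o in OUTCOME_COLUMNS}}
            for p in (1, 2) for c in CONDITIONS
        ])
        speeds = {
            1: {"no_afo": 0.50, "spring1": 0.60, "spring2": 0.45,
                "spring3": 0.40, "spring4": 0.42},
            2: {"no_afo": 0.48, "spring1": 0.60, "spring2": 0.44,
                "spring3": 0.41, "spring4": 0.43},
        }
        for p, m in speeds.items():
            for c, v in m.items():
                df.loc[(df.participant == p) & (df.condition == c), "gait_speed"] = v
        with_best, _, _ = select_best_condition(df)
        md = mean_difference_table(with_best)
        row = md[(md.outcome == "gait_speed") & (md.condition == "no_afo")]
        # best - no-AFO differences are 0.10 and 0.12
        assert row["mean_difference"].iloc[0] == pytest.approx(0.11)

    def test_best_vs_own_source_condition_is_zero(self):
        df = pd.DataFrame([
            {"participant": p, "condition": c, **{o: 1.0 for o in OUTCOME_COLUMNS}}
            for p in (1, 2, 3) for c in CONDITIONS
        ])
        df.loc[df.condition == "spring2", "gait_speed"] = 2.0
        with_best, _, _ = select_best_condition(df)
        md = mean_difference_table(with_best)
        row = md[(md.outcome == "gait_speed") & (md.condition == "spring2")]
        assert row["mean_difference"].iloc[0] == 0.0


class TestCohortAnalysis:
    def test_full_report_structure_and_posthoc_count(self):
        df = simulate_cohort_outcomes(CohortSpec(n_participants=16, seed=9))
        rep = analyze_cohort(df)
        assert set(rep.omnibus) == set(OUTCOME_COLUMNS)
        for outcome in OUTCOME_COLUMNS:
            assert len(rep.pairwise[outcome]) == 15  # all pairs of 6 levels
            pw = rep.pairwise[outcome]
            assert (pw["p_holm"] >= pw["p_raw"] - 1e-12).all()
            assert pw["band"].isin(["small", "medium", "large"]).all()
        text = render_report(rep, table=df)
        assert "winner counts" in text
        assert "not independent" in rep.caveat

    def test_effect_sizes_banded_correctly(self):
        df = simulate_cohort_outcomes(CohortSpec(n_participants=16, seed=9))
        rep = analyze_cohort(df, outcomes=("gait_speed",))
        pw = rep.pairwise["gait_speed"]
        for _, row in pw.iterrows():
            r = row["effect_size_r"]
            want = "large" if r > 0.5 else ("medium" if r >= 0.3 else "small")
            assert row["band"] == want
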