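import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from patchforage import StrategySpec, make_policy, run_session
from patchforage.analysis import (
    classify_cohort,
    exclusion_filter,
    gut_precision,
    pearson_chi2,
    recovery_harness,
    session_metrics,
    strategy_contingency,
    switch_performance_summary,
)
from patchforage.synthetic_data import CohortConfig, generate_cohort
from patchforage.task_env import SessionLog

from conftest import make_log


class TestSessionMetrics:
    def test_unfinished_final_river_excluded(self, toy_log):
        m = session_metrics(toy_log)
        # rivers 1 and 2 are included (1 + 2 nuggets); river 3's nugget is not
        assert m.performance == 3
        assert m.n_patches == 2
        assert m.mean_resident_time == 4.0
        # giving-up runs at the two leaves: 1 and 2 failures
        assert m.mean_giving_up_time == 1.5
        # 8 pans + 2 travels = 18 time units on included rivers
        assert m.efficiency == pytest.approx(3 / 18)

    def test_empty_session_is_all_zero(self):
        m = session_metrics(SessionLog(events=[]))
        assert (m.performance, m.efficiency, m.n_patches) == (0.0, 0.0, 0)

    def test_deterministic_ft_resident_time(self, env, rng):
        log = run_session(make_policy(StrategySpec("FT", 12.0)), env, rng)
        assert session_metrics(log).mean_resident_time == 12.0


class TestExclusion:
    def test_half_optimal_rule_is_strict_below(self):
        ref = 58.96
        perfs = {"a": 46.88, "b": 29.0, "c": 0.5 * ref, "d": 0.5 * ref - 1e-9}
        kept = exclusion_filter(perfs, ref)
        assert kept == {"a", "c"}

    def test_positive_reference_required(self):
        with pytest.raises(ValueError):
            exclusion_filter({"a": 1.0}, 0.0)


class TestContingencyAndChi2:
    def test_counts_tabulated_by_session(self):
        pre = {1: "GUT", 2: "GUT", 3: "FT", 4: "FN"}
        post = {1: "FT", 2: "GUT", 3: "FT", 4: "FN"}
        table = strategy_contingency(pre, post)
        assert list(table.loc["pre"]) == [2, 1, 1]
        assert list(table.loc["post"]) == [1, 2, 1]

    def test_mismatched_participants_rejected(self):
        with pytest.raises(ValueError):
            strategy_contingency({1: "GUT"}, {2: "GUT"})
        with pytest.raises(ValueError):
            strategy_contingency({1: "MVT"}, {1: "GUT"})

    def test_proportional_rows_give_zero(self):
        stat, df = pearson_chi2([[10, 20, 30], [1, 2, 3]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_zero_margin_column_dropped_from_df(self):
        stat, df = pearson_chi2([[5, 0, 3], [2, 0, 1]])
        assert df == 1

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [0, 0]])

    @given(
        counts=st.lists(st.integers(0, 60), min_size=6, max_size=6).filter(
            lambda c: sum(c[:3]) > 0 and sum(c[3:]) > 0 and all(c[i] + c[i + 3] > 0 for i in range(3))
        )
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_agrees_with_scipy_on_random_tables(self, counts):
        table = np.array(counts, dtype=float).reshape(2, 3)
        stat, df = pearson_chi2(table)
        ref = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-9)
        assert df == ref.dof


class TestGutPrecision:
    def test_absolute_deviation_from_optimum(self):
        log = make_log([([0, 1, 0, 0, 0, 0], True)])  # giving-up run of 4
        assert gut_precision(log, 4.0) == 0.0
        assert gut_precision(log, 6.0) == 2.0

    def test_requires_a_completed_river(self):
        with pytest.raises(ValueError):
            gut_precision(make_log([([0, 1], False)]), 4.0)


class TestSwitchSummary:
    def test_group_means_match_streaming_recount(self):
        rows = []
        perf = {}
        rng = np.random.default_rng(0)
        for i in range(12):
            pid = f"p{i}"
            pre_s = "GUT"
            post_s = "FT" if i % 2 else "GUT"
            for s in ("pre", "post"):
                perf[(pid, s)] = float(rng.normal(47, 5))
                rows.append(
                    {
                        "participant_id": pid,
                        "condition": "FT",
                        "session": s,
                        "best": pre_s if s == "pre" else post_s,
                        "performance": perf[(pid, s)],
                        "efficiency": perf[(pid, s)] / 250,
                    }
                )
        df = pd.DataFrame(rows)
        labels = df[["participant_id", "condition", "session", "best"]]
        metrics = df[["participant_id", "condition", "session", "performance", "efficiency"]]
        summary = switch_performance_summary(labels, metrics)
        assert summary["n"].sum() == 12
        switchers = summary[summary.post_strategy == "FT"].iloc[0]
        manual = np.mean(
            [perf[(f"p{i}", "post")] for i in range(12) if i % 2]
        )
        assert switchers["performance_post_mean"] == pytest.approx(manual)
        assert switchers["n"] == 6


class TestRecoveryHarness:
    def test_row_sums_and_low_noise_diagonal(self):
        confusion, errors = recovery_harness(
            noise_grid=(0.05,), n_agents=6, seed=3
        )
        counts = confusion[["GUT", "FT", "FN"]].to_numpy()
        assert (counts.sum(axis=1) == 6).all()
        # near-deterministic agents are classified near-perfectly
        assert np.trace(counts) >= 16
        assert (errors["abs_error"] < 1.0).mean() >= 0.8

    def test_empty_grids_rejected(self):
        with pytest.raises(ValueError):
            recovery_harness(noise_grid=(), n_agents=3)


class TestPipelineDirection:
    def test_switching_cohort_produces_larger_chi2(self):
        """With feedback-driven switching the pre/post strategy table
        shifts; without it the chi-square stays near zero."""
        stats = {}
        for sp in (0.5, 0.0):
            cfg = CohortConfig(
                n_participants=16,
                condition="FT",
                strategy_mixture={"GUT": 1.0, "FT": 0.0, "FN": 0.0},
                switch_probability=sp,
                seed=42,
            )
            cohort = generate_cohort(cfg, sessions=("pre", "post"))
            labels = classify_cohort(cohort)
            pre = labels[labels.session == "pre"].set_index("participant_id")["best"].to_dict()
            post = labels[labels.session == "post"].set_index("participant_id")["best"].to_dict()
            stat, _ = pearson_chi2(strategy_contingency(pre, post).values)
            stats[sp] = stat
        assert stats[0.5] > stats[0.0]
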