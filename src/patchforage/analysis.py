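"""Behavioral analysis stages: per-session metrics, exclusion, strategy
contingency tables with Pearson chi-square, giving-up-time precision,
switch/performance summaries, and the model/parameter recovery harness.

Performance is the total gold acquired in a session *excluding the last
river if the session ended without leaving it* — a river counts only
once the forager committed to departing it. Efficiency divides that
gold by the time actually spent on the included rivers (pans plus
travel). Participants scoring below half the optimal (MVT) session
performance pre-feedback are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fitting, synthetic_data
from .strategies import FITTABLE_STRATEGIES, OPTIMAL_THRESHOLDS, StrategySpec
from .task_env import ACTION_LEAVE, ACTION_PAN, EnvConfig, SessionLog

#: MVT optimal session performance in the study environment; the
#: strategy-free reference for the low-performance exclusion rule.
#: Recompute via optimal_perf.table1_report.
MVT_OPTIMAL_PERFORMANCE = 58.96


@dataclass(frozen=True)
class SessionMetrics:
    performance: float  # gold over included (left) rivers
    efficiency: float  # gold per time unit over included rivers
    mean_resident_time: float  # pans per included river
    mean_giving_up_time: float  # consecutive failures at each leave
    n_patches: int  # included rivers


def session_metrics(log: SessionLog) -> SessionMetrics:
    """Behavioral summary of one session over its *included* rivers.

    A river is included iff it ends with a leave action; a final river
    the session ended inside contributes nothing. With zero included
    rivers all metrics are zero.
    """
    gold = 0
    pans = 0
    time_units = 0
    guts = []
    prev_end = 0
    for river in log.rivers():
        if river[-1].action != ACTION_LEAVE:
            continue
        fails = 0
        for e in river:
            if e.action == ACTION_PAN:
                pans += 1
                if e.outcome == 1:
                    gold += 1
                    fails = 0
                else:
                    fails += 1
        guts.append(fails)
        # time consumed on this river = clock advance since previous river
        start = prev_end
        time_units += river[-1].global_time_after - start
        prev_end = river[-1].global_time_after
    n = len(guts)
    if n == 0:
        return SessionMetrics(0.0, 0.0, 0.0, 0.0, 0)
    return SessionMetrics(
        performance=float(gold),
        efficiency=float(gold / time_units) if time_units else 0.0,
        mean_resident_time=pans / n,
        mean_giving_up_time=float(np.mean(guts)),
        n_patches=n,
    )


def exclusion_filter(
    performance_by_participant: dict, optimal_reference: float = MVT_OPTIMAL_PERFORMANCE
) -> set:
    """Participants kept by the low-performance rule.

    Excluded iff pre-feedback performance is strictly lower than half
    the optimal reference; the boundary case is kept.
    """
    if optimal_reference <= 0:
        raise ValueError("optimal_reference must be > 0")
    cut = 0.5 * optimal_reference
    return {pid for pid, perf in performance_by_participant.items() if perf >= cut}


def strategy_contingency(pre_labels: dict, post_labels: dict) -> pd.DataFrame:
    """2x3 session-by-strategy count table for one feedback condition."""
    if set(pre_labels) != set(post_labels):
        raise ValueError("pre and post label sets must cover the same participants")
    table = pd.DataFrame(
        0, index=["pre", "post"], columns=list(FITTABLE_STRATEGIES), dtype=int
    )
    for labels, row in ((pre_labels, "pre"), (post_labels, "post")):
        for label in labels.values():
            if label not in FITTABLE_STRATEGIES:
                raise ValueError(f"unknown strategy label {label!r}")
            table.loc[row, label] += 1
    return table


def pearson_chi2(table) -> tuple[float, int]:
    """Pearson chi-square statistic and df for a count table.

    Expected counts come from the row/column margins; columns (and
    rows) with zero margin are dropped before computing df. No
    continuity correction.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    obs = obs[obs.sum(axis=1) > 0, :]
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.size == 0:
        raise ValueError("table has no positive margins")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df


def gut_precision(log: SessionLog, optimal_g: float = 4.0) -> float:
    """Absolute deviation of the session's mean giving-up time from the
    optimal giving-up time (behavioral, not the fitted threshold)."""
    m = session_metrics(log)
    if m.n_patches == 0:
        raise ValueError("log has no completed (left) rivers")
    return abs(m.mean_giving_up_time - optimal_g)


def classify_cohort(
    cohort: list, sessions: tuple[str, ...] = ("pre", "post")
) -> pd.DataFrame:
    """Strategy classification of every participant-session in a cohort."""
    rows = []
    for p in cohort:
        for s in sessions:
            res = fitting.classify(p.sessions[s])
            row = {
                "participant_id": p.participant_id,
                "condition": p.condition,
                "session": s,
                "best": res.best,
            }
            for name in FITTABLE_STRATEGIES:
                row[f"aic_{name}"] = res.fits[name].aic
                row[f"w_{name}"] = res.aic_weights[name]
                row[f"threshold_{name}"] = res.fits[name].threshold_hat
                row[f"noise_{name}"] = res.fits[name].noise_hat
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_metrics(
    cohort: list, sessions: tuple[str, ...] = ("pre", "post")
) -> pd.DataFrame:
    rows = []
    for p in cohort:
        for s in sessions:
            m = session_metrics(p.sessions[s])
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "condition": p.condition,
                    "session": s,
                    "performance": m.performance,
                    "efficiency": m.efficiency,
                    "mean_resident_time": m.mean_resident_time,
                    "mean_giving_up_time": m.mean_giving_up_time,
                    "n_patches": m.n_patches,
                }
            )
    return pd.DataFrame(rows)


def switch_performance_summary(
    classifications: pd.DataFrame, metrics: pd.DataFrame
) -> pd.DataFrame:
    """Performance/efficiency by (pre-strategy, post-strategy, condition).

    Expects the outputs of :func:`classify_cohort` and
    :func:`cohort_metrics` covering the pre and post sessions; returns
    one row per group with n and the mean and SD of performance and
    efficiency in each session.
    """
    wide = None
    for name, df, cols in (
        ("label", classifications, ["best"]),
        ("metric", metrics, ["performance", "efficiency"]),
    ):
        piv = df.pivot(index=["participant_id", "condition"], columns="session", values=cols)
        piv.columns = [f"{c}_{s}" for c, s in piv.columns]
        wide = piv if wide is None else wide.join(piv)
    wide = wide.reset_index()
    grouped = wide.groupby(["best_pre", "best_post", "condition"])
    rows = []
    for (pre_s, post_s, cond), g in grouped:
        row = {
            "pre_strategy": pre_s,
            "post_strategy": post_s,
            "condition": cond,
            "n": len(g),
        }
        for col in ("performance_pre", "performance_post", "efficiency_pre", "efficiency_post"):
            row[f"{col}_mean"] = float(g[col].mean())
            row[f"{col}_sd"] = float(g[col].std(ddof=1)) if len(g) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_harness(
    thresholds: dict[str, float] | None = None,
    noise_grid: tuple[float, ...] = (0.25,),
    n_agents: int = 50,
    seed: int = 0,
    env: EnvConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model- and parameter-recovery check for the classifier.

    Simulates ``n_agents`` single sessions per (true strategy, noise
    level), classifies each, and tabulates the classification confusion
    matrix plus threshold-recovery errors. Returns
    ``(confusion, errors)``: confusion has one row per (noise, true
    strategy) with counts of assigned labels; errors one row per agent
    with the absolute threshold error of the true strategy's fit.
    """
    thresholds = (
        {k: OPTIMAL_THRESHOLDS[k] for k in FITTABLE_STRATEGIES}
        if thresholds is None
        else thresholds
    )
    if not thresholds or not noise_grid:
        raise ValueError("thresholds and noise_grid must be non-empty")
    env = EnvConfig(balanced_sampling=True) if env is None else env
    rng = np.random.default_rng(seed)
    conf_rows, err_rows = [], []
    for tau in noise_grid:
        counts = {
            true: {label: 0 for label in FITTABLE_STRATEGIES} for true in thresholds
        }
        for true, theta in thresholds.items():
            spec = StrategySpec(true, float(theta), float(tau))
            for i in range(n_agents):
                log = synthetic_data.simulate_session(
                    spec, env, rng, {"participant_id": f"{true}_{i}", "session": "pre"}
                )
                res = fitting.classify(log)
                counts[true][res.best] += 1
                err_rows.append(
                    {
                        "noise": tau,
                        "true_strategy": true,
                        "true_threshold": float(theta),
                        "threshold_hat": res.fits[true].threshold_hat,
                        "abs_error": abs(res.fits[true].threshold_hat - theta),
                        "classified": res.best,
                    }
                )
        for true in thresholds:
            conf_rows.append({"noise": tau, "true_strategy": true, **counts[true]})
    return pd.DataFrame(conf_rows), pd.DataFrame(err_rows)
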