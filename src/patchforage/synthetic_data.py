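"""Synthetic participant cohorts for the three-session feedback pipeline.

Generates cohorts with the statistical structure the behavioral
analysis assumes: each participant forages three 250-unit sessions
(pre-feedback, feedback, post-feedback), initially following a noisy
threshold strategy drawn from a mixture over GUT/FT/FN. In the feedback
session every leave earns an instructor label (*too_early*, *on_time*,
*too_late*) by comparing the leave-point decision variable with the
instructor strategy's optimal threshold. After feedback, an agent
either adopts the instructor's strategy (probability
``switch_probability``, threshold near that strategy's optimum) or
keeps its own strategy with its threshold pulled toward the optimum
(``precision_gain``). The switch/precision rule is a generative
convenience for exercising the pipeline end to end — the study it
emulates *measures* these effects rather than modelling them.

Default cohort parameters mirror the study's analyzable sample: ~40
participants per condition, roughly 77% GUT / 21% FT / 2% FN
pre-feedback strategy use, and a 50% switch rate under FT feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fitting
from .strategies import (
    FITTABLE_STRATEGIES,
    OPTIMAL_THRESHOLDS,
    StrategySpec,
    make_policy,
)
from .task_env import (
    ACTION_LEAVE,
    EVENT_COLUMNS,
    EnvConfig,
    SessionLog,
    run_session,
)

SESSION_ORDER = ("pre", "feedback", "post")

TRUTH_COLUMNS = ("participant_id", "condition", "session", "strategy", "threshold", "noise")


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic feedback-condition cohort."""

    n_participants: int = 40
    condition: str = "FT"  # instructor strategy
    strategy_mixture: dict = field(
        default_factory=lambda: {"GUT": 0.77, "FT": 0.21, "FN": 0.02}
    )
    threshold_mean: dict = field(
        default_factory=lambda: {"GUT": 4.0, "FT": 12.0, "FN": 3.0}
    )
    threshold_sd: dict = field(
        default_factory=lambda: {"GUT": 1.0, "FT": 2.5, "FN": 0.75}
    )
    noise_mean: float = 0.25
    noise_sd: float = 0.10
    switch_probability: float = 0.5
    precision_gain: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("FT", "GUT"):
            raise ValueError("condition must be 'FT' or 'GUT'")
        probs = [self.strategy_mixture.get(s, 0.0) for s in FITTABLE_STRATEGIES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("strategy_mixture must be a distribution over GUT/FT/FN")
        for p in (self.switch_probability,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("switch_probability must be in [0, 1]")
        if any(sd < 0 for sd in self.threshold_sd.values()) or self.noise_sd < 0:
            raise ValueError("spreads must be >= 0")


@dataclass
class Participant:
    participant_id: str
    condition: str
    sessions: dict[str, SessionLog]
    truth: dict[str, StrategySpec]


def generate_feedback(
    leave_point: dict,
    instructor: str,
    optima: dict[str, float] | None = None,
) -> str:
    """Instructor label for one leave, from the leave-point variables.

    An FT instructor compares the resident time (``ft_x``) with the
    optimal resident time; a GUT instructor compares the run of
    failures (``gut_x``) with the optimal giving-up time. Below the
    optimum is *too_early*, exact equality *on_time*, above *too_late*.
    """
    optima = dict(OPTIMAL_THRESHOLDS) if optima is None else optima
    if instructor == "FT":
        x = leave_point["ft_x"]
    elif instructor == "GUT":
        x = leave_point["gut_x"]
    else:
        raise ValueError(f"unknown instructor {instructor!r}")
    opt = optima[instructor]
    if x < opt:
        return "too_early"
    if x > opt:
        return "too_late"
    return "on_time"


def simulate_session(
    spec: StrategySpec,
    env: EnvConfig,
    rng: np.random.Generator,
    metadata: dict | None = None,
) -> SessionLog:
    """One session under a noisy threshold agent."""
    return run_session(make_policy(spec), env, rng, metadata)


def _label_feedback_session(log: SessionLog, instructor: str) -> SessionLog:
    pts = fitting.decision_points(log)
    labeled = []
    k = 0
    for e in log.events:
        if e.action == ACTION_LEAVE:
            label = generate_feedback(
                {"ft_x": pts.ft[k], "gut_x": pts.gut[k]}, instructor
            )
            e = replace(e, feedback_label=label)
        labeled.append(e)
        k += 1
    return SessionLog(events=labeled, metadata=dict(log.metadata))


def _draw_spec(cfg: CohortConfig, name: str, rng: np.random.Generator) -> StrategySpec:
    theta = rng.normal(cfg.threshold_mean[name], cfg.threshold_sd[name])
    tau = rng.normal(cfg.noise_mean, cfg.noise_sd)
    return StrategySpec(name, max(theta, 0.5), max(tau, 0.05))


def _post_feedback_spec(
    cfg: CohortConfig, pre: StrategySpec, rng: np.random.Generator
) -> StrategySpec:
    optima = OPTIMAL_THRESHOLDS
    if rng.random() < cfg.switch_probability:
        name = cfg.condition
        theta = rng.normal(optima[name], 0.5)
        return StrategySpec(name, max(theta, 0.5), pre.noise)
    opt = optima[pre.name]
    theta = opt + cfg.precision_gain * (pre.threshold - opt)
    return StrategySpec(pre.name, max(theta, 0.5), pre.noise)


def generate_participant(
    cfg: CohortConfig,
    pid: str,
    rng: np.random.Generator,
    env: EnvConfig | None = None,
    sessions: tuple[str, ...] = SESSION_ORDER,
) -> Participant:
    """Three linked session logs (and their generating specs) for one agent."""
    env = EnvConfig(balanced_sampling=True) if env is None else env
    probs = [cfg.strategy_mixture.get(s, 0.0) for s in FITTABLE_STRATEGIES]
    pre_name = str(rng.choice(FITTABLE_STRATEGIES, p=probs))
    pre_spec = _draw_spec(cfg, pre_name, rng)
    post_spec = _post_feedback_spec(cfg, pre_spec, rng)
    specs = {"pre": pre_spec, "feedback": pre_spec, "post": post_spec}
    logs: dict[str, SessionLog] = {}
    for session in sessions:
        meta = {
            "participant_id": pid,
            "condition": cfg.condition,
            "session": session,
            "budget": env.session_budget,
        }
        log = simulate_session(specs[session], env, rng, meta)
        if session == "feedback":
            log = _label_feedback_session(log, cfg.condition)
        logs[session] = log
    return Participant(
        participant_id=pid,
        condition=cfg.condition,
        sessions=logs,
        truth={s: specs[s] for s in sessions},
    )


def generate_cohort(
    cfg: CohortConfig,
    env: EnvConfig | None = None,
    sessions: tuple[str, ...] = SESSION_ORDER,
) -> list[Participant]:
    """A full cohort, deterministically from ``cfg.seed``."""
    root = np.random.SeedSequence(cfg.seed)
    out = []
    for i, child in enumerate(root.spawn(cfg.n_participants)):
        rng = np.random.default_rng(child)
        out.append(generate_participant(cfg, f"p{i + 1:03d}", rng, env, sessions))
    return out


def cohort_frame(cohort: list[Participant]) -> pd.DataFrame:
    """All event records of a cohort as one tidy DataFrame."""
    frames = [
        log.to_frame()
        for p in cohort
        for log in (p.sessions[s] for s in SESSION_ORDER if s in p.sessions)
    ]
    return pd.concat(frames, ignore_index=True)


def truth_frame(cohort: list[Participant]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": p.participant_id,
            "condition": p.condition,
            "session": s,
            "strategy": spec.name,
            "threshold": spec.threshold,
            "noise": spec.noise,
        }
        for p in cohort
        for s, spec in p.truth.items()
    ]
    return pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))


def write_cohort(
    cohort: list[Participant], path, truth_path=None
) -> None:
    """Event log CSV (and optional ground-truth sidecar CSV)."""
    cohort_frame(cohort).to_csv(path, index=False)
    if truth_path is not None:
        truth_frame(cohort).to_csv(truth_path, index=False)


def read_cohort(path) -> list[Participant]:
    """Rebuild a cohort (without ground truth) from an event-log CSV.

    Tolerates files lacking the latent ``river_quality`` or the
    ``feedback_label`` column, as real data would.
    """
    df = pd.read_csv(path)
    required = [c for c in EVENT_COLUMNS if c not in ("river_quality", "feedback_label")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    for c in ("river_quality", "feedback_label"):
        if c not in df.columns:
            df[c] = pd.NA
    _validate_cohort_frame(df)
    out = []
    for pid, pdf in df.groupby("participant_id", sort=False):
        condition = str(pdf["condition"].iloc[0])
        sessions = {}
        for session, sdf in pdf.groupby("session", sort=False):
            sessions[str(session)] = SessionLog.from_frame(
                sdf, metadata={"participant_id": str(pid), "condition": condition,
                               "session": str(session)},
            )
        out.append(
            Participant(
                participant_id=str(pid),
                condition=condition,
                sessions=sessions,
                truth={},
            )
        )
    return out


def _validate_cohort_frame(df: pd.DataFrame) -> None:
    bad_action = ~df["action"].isin(["pan", "leave"])
    if bad_action.any():
        rows = df.index[bad_action].tolist()[:5]
        raise ValueError(f"invalid action values at rows {rows}")
    leave = df["action"] == "leave"
    bad_outcome = (leave & df["outcome"].notna()) | (~leave & ~df["outcome"].isin([0, 1]))
    if bad_outcome.any():
        rows = df.index[bad_outcome].tolist()[:5]
        raise ValueError(f"outcome inconsistent with action at rows {rows}")
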