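"""Discrete-time simulator of the gold-panning patch-leaving task.

A session is a fixed budget of time units. The forager sits at a river
(a patch) holding a latent number of gold nuggets and repeatedly chooses
between two actions: *pan* (1 time unit; finds a nugget with probability
``find_rate_per_nugget * remaining``) or *leave* (travel to a fresh river,
5 time units). Each found nugget depletes the river, so the instantaneous
reward rate falls as the patch is exploited — the classic patch-leaving
trade-off. Every action is logged as an :class:`EventRecord`; the ordered
log of one participant-session is a :class:`SessionLog`, the interchange
object for the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

ACTION_PAN = "pan"
ACTION_LEAVE = "leave"
SESSION_NAMES = ("pre", "feedback", "post")
FEEDBACK_LABELS = ("too_early", "on_time", "too_late")

#: CSV column order for serialized event logs.
EVENT_COLUMNS = (
    "participant_id",
    "condition",
    "session",
    "river_index",
    "step_in_river",
    "global_time_after",
    "action",
    "outcome",
    "river_quality",
    "feedback_label",
)


class InvalidPolicyError(ValueError):
    """A decision policy returned something other than 'pan' or 'leave'."""


class LogValidationError(ValueError):
    """An event log violates the SessionLog invariants."""


@dataclass(frozen=True)
class EnvConfig:
    """Constants of the gold-panning environment.

    Defaults are the task as run in the study: per-nugget find probability
    0.05, river qualities 5/8/11 nuggets drawn with equal probability,
    panning costs 1 time unit, travelling 5, and a session budget of 250
    time units.
    """

    find_rate_per_nugget: float = 0.05
    qualities: tuple[int, ...] = (5, 8, 11)
    quality_probs: tuple[float, ...] | None = None
    travel_cost: int = 5
    pan_cost: int = 1
    session_budget: int = 250
    balanced_sampling: bool = False

    def __post_init__(self) -> None:
        if not self.qualities:
            raise ValueError("qualities must be non-empty")
        if any(q <= 0 or q != int(q) for q in self.qualities):
            raise ValueError("qualities must be positive integers")
        if not 0 < self.find_rate_per_nugget * max(self.qualities) <= 1:
            raise ValueError(
                "find_rate_per_nugget * max(quality) must lie in (0, 1]"
            )
        if self.quality_probs is None:
            n = len(self.qualities)
            object.__setattr__(self, "quality_probs", tuple([1.0 / n] * n))
        if len(self.quality_probs) != len(self.qualities):
            raise ValueError("quality_probs must match qualities")
        if any(p < 0 for p in self.quality_probs) or not math.isclose(
            sum(self.quality_probs), 1.0, abs_tol=1e-9
        ):
            raise ValueError("quality_probs must be non-negative and sum to 1")
        for name in ("travel_cost", "pan_cost", "session_budget"):
            v = getattr(self, name)
            if v != int(v) or v <= 0:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class PatchState:
    """Latent and observed state of one river during foraging.

    ``remaining`` is latent (only the simulator and the omniscient MVT
    benchmark read it); ``pans_made``, ``gold_collected`` and
    ``consecutive_failures`` are observable and are the decision variables
    of the fixed-time, fixed-number and giving-up-time strategies.
    """

    quality: int
    remaining: int
    pans_made: int = 0
    gold_collected: int = 0
    consecutive_failures: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.remaining <= self.quality:
            raise ValueError("remaining must lie in [0, quality]")
        if self.gold_collected != self.quality - self.remaining:
            raise ValueError("gold_collected must equal quality - remaining")
        if self.consecutive_failures > self.pans_made:
            raise ValueError("consecutive_failures cannot exceed pans_made")


@dataclass(frozen=True)
class EventRecord:
    """One logged action (a pan or a leave) within a session."""

    participant_id: str
    condition: str
    session: str
    river_index: int
    step_in_river: int
    global_time_after: int
    action: str
    outcome: int | None  # 1 gold / 0 no gold; None on leave rows
    river_quality: int | None = None  # latent ground truth; absent for real data
    feedback_label: str | None = None


@dataclass
class SessionLog:
    """Ordered event records for one participant-session."""

    events: list[EventRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def total_time(self) -> int:
        return self.events[-1].global_time_after if self.events else 0

    @property
    def total_gold(self) -> int:
        return sum(e.outcome or 0 for e in self.events if e.action == ACTION_PAN)

    def validate(self) -> None:
        """Raise LogValidationError on any invariant violation."""
        last_t = 0
        for i, e in enumerate(self.events):
            if e.action not in (ACTION_PAN, ACTION_LEAVE):
                raise LogValidationError(f"row {i}: unknown action {e.action!r}")
            if e.global_time_after <= last_t:
                raise LogValidationError(
                    f"row {i}: global_time_after not strictly increasing"
                )
            if (e.outcome is None) != (e.action == ACTION_LEAVE):
                raise LogValidationError(
                    f"row {i}: outcome must be NA exactly on leave rows"
                )
            if e.feedback_label is not None and (
                e.session != "feedback" or e.action != ACTION_LEAVE
            ):
                raise LogValidationError(
                    f"row {i}: feedback_label only allowed on feedback-session leaves"
                )
            last_t = e.global_time_after
        budget = self.metadata.get("budget")
        if budget is not None and last_t > budget:
            raise LogValidationError("session exceeds its time budget")

    def rivers(self) -> list[list[EventRecord]]:
        """Events grouped by river, in encounter order."""
        out: dict[int, list[EventRecord]] = {}
        for e in self.events:
            out.setdefault(e.river_index, []).append(e)
        return [out[k] for k in sorted(out)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(e, c) for c in EVENT_COLUMNS} for e in self.events
        ]
        df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "SessionLog":
        events = [_record_from_row(row) for row in df.itertuples(index=False)]
        return cls(events=events, metadata=dict(metadata or {}))


def _na(value) -> bool:
    if value is None:
        return True
    if isinstance(value, str):
        return value in ("", "NA")
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def _record_from_row(row) -> EventRecord:
    d = row._asdict() if hasattr(row, "_asdict") else dict(row)
    quality = d.get("river_quality")
    outcome = d.get("outcome")
    label = d.get("feedback_label")
    return EventRecord(
        participant_id=str(d["participant_id"]),
        condition=str(d["condition"]),
        session=str(d["session"]),
        river_index=int(d["river_index"]),
        step_in_river=int(d["step_in_river"]),
        global_time_after=int(d["global_time_after"]),
        action=str(d["action"]),
        outcome=None if _na(outcome) else int(outcome),
        river_quality=None if _na(quality) else int(quality),
        feedback_label=None if _na(label) else str(label),
    )


class PatchSampler:
    """Draws fresh rivers; optionally balances quality presence.

    With ``env.balanced_sampling`` the qualities are drawn from shuffled
    blocks containing each quality exactly once, so any run of
    ``3k`` consecutive rivers contains each quality ``k`` times. Otherwise
    each river's quality is an independent draw from ``quality_probs``.
    """

    def __init__(self, env: EnvConfig, rng: np.random.Generator) -> None:
        self.env = env
        self.rng = rng
        self._block: list[int] = []

    def sample(self) -> PatchState:
        env = self.env
        if env.balanced_sampling:
            if not self._block:
                block = list(env.qualities)
                self.rng.shuffle(block)
                self._block = block
            q = self._block.pop()
        else:
            q = int(
                self.rng.choice(np.asarray(env.qualities), p=np.asarray(env.quality_probs))
            )
        return PatchState(quality=q, remaining=q)


def sample_patch(env: EnvConfig, rng: np.random.Generator) -> PatchState:
    """One fresh patch from the equal-probability quality marginal."""
    q = int(rng.choice(np.asarray(env.qualities), p=np.asarray(env.quality_probs)))
    return PatchState(quality=q, remaining=q)


def pan(
    patch: PatchState, env: EnvConfig, rng: np.random.Generator
) -> tuple[int, PatchState]:
    """One panning attempt; mutates and returns the patch.

    Success probability is ``find_rate_per_nugget * remaining``; a success
    removes one nugget and resets the consecutive-failure counter.
    """
    p = env.find_rate_per_nugget * patch.remaining
    outcome = int(rng.random() < p)
    patch.pans_made += 1
    if outcome:
        patch.remaining -= 1
        patch.gold_collected += 1
        patch.consecutive_failures = 0
    else:
        patch.consecutive_failures += 1
    return outcome, patch


Policy = Callable[[PatchState, EnvConfig, np.random.Generator], str]


def run_session(
    policy: Policy,
    env: EnvConfig,
    rng: np.random.Generator,
    metadata: Mapping | None = None,
) -> SessionLog:
    """Simulate one full session under a decision policy.

    The policy is queried before every action with the current patch
    state. Panning costs ``pan_cost``; leaving costs ``travel_cost``
    except that a leave chosen with fewer units remaining consumes only
    the remainder and ends the session. If the budget hits zero right
    after a pan, the session ends inside the river — the behavioral
    performance measure later excludes such an unfinished final river.
    """
    meta = dict(metadata or {})
    pid = str(meta.get("participant_id", "sim"))
    condition = str(meta.get("condition", "none"))
    session = str(meta.get("session", "pre"))
    budget = int(meta.get("budget", env.session_budget))
    meta.setdefault("budget", budget)
    meta.setdefault("condition", condition)

    sampler = PatchSampler(env, rng)
    log = SessionLog(metadata=meta)
    t = 0
    river_index = 1
    patch = sampler.sample()
    while t < budget:
        action = policy(patch, env, rng)
        if action == ACTION_PAN:
            outcome, patch = pan(patch, env, rng)
            t += env.pan_cost
            log.events.append(
                EventRecord(
                    participant_id=pid,
                    condition=condition,
                    session=session,
                    river_index=river_index,
                    step_in_river=patch.pans_made,
                    global_time_after=t,
                    action=ACTION_PAN,
                    outcome=outcome,
                    river_quality=patch.quality,
                )
            )
        elif action == ACTION_LEAVE:
            cost = min(env.travel_cost, budget - t)  # truncated final travel
            t += cost
            log.events.append(
                EventRecord(
                    participant_id=pid,
                    condition=condition,
                    session=session,
                    river_index=river_index,
                    step_in_river=patch.pans_made + 1,
                    global_time_after=t,
                    action=ACTION_LEAVE,
                    outcome=None,
                    river_quality=patch.quality,
                )
            )
            if t < budget:
                river_index += 1
                patch = sampler.sample()
        else:
            raise InvalidPolicyError(
                f"policy must return 'pan' or 'leave', got {action!r}"
            )
    return log
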