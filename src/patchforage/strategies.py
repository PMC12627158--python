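"""The four patch-leaving policies: MVT, GUT, FT and FN.

Each strategy watches one decision variable and leaves the river once a
threshold is reached:

* **GUT** (giving-up time): consecutive unrewarded pans since the last
  nugget (or since entering the river).
* **FT** (fixed time): pans made in this river (resident time).
* **FN** (fixed number): nuggets collected in this river.
* **MVT** (marginal value theorem): the instantaneous reward rate
  ``find_rate_per_nugget * remaining``; leaves when it drops *below* the
  threshold. MVT reads the latent nugget count and is an omniscient
  benchmark, not a fittable model.

With decision noise ``tau > 0`` the hard threshold softens into a
logistic choice rule: P(leave) = logistic((x - theta) / tau) for
GUT/FT/FN and logistic((theta - x) / tau) for MVT (whose variable falls
rather than rises as the patch is exploited). At ``tau = 0`` a tie
``x == theta`` resolves to leave for GUT/FT/FN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .task_env import ACTION_LEAVE, ACTION_PAN, EnvConfig, PatchState, Policy

STRATEGY_NAMES = ("MVT", "GUT", "FT", "FN")
#: the candidate set for maximum-likelihood classification (MVT excluded).
FITTABLE_STRATEGIES = ("GUT", "FT", "FN")

#: optimal thresholds in the study environment (grid-search results,
#: reproducible via patchforage.optimal_perf.table1_report).
OPTIMAL_THRESHOLDS = {"GUT": 4.0, "FT": 12.0, "FN": 3.0, "MVT": 0.236}


@dataclass(frozen=True)
class StrategySpec:
    """A named strategy with threshold and decision-noise parameters."""

    name: str
    threshold: float
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def decision_variable(name: str, patch: PatchState, env: EnvConfig) -> float:
    """The quantity the named strategy compares against its threshold."""
    if name == "GUT":
        return float(patch.consecutive_failures)
    if name == "FT":
        return float(patch.pans_made)
    if name == "FN":
        return float(patch.gold_collected)
    if name == "MVT":
        return env.find_rate_per_nugget * patch.remaining
    raise ValueError(f"unknown strategy {name!r}")


def leave_probability(spec: StrategySpec, x: float) -> float:
    """P(leave) given the current decision variable value."""
    sign = -1.0 if spec.name == "MVT" else 1.0
    if spec.noise == 0.0:
        if spec.name == "MVT":
            return float(x < spec.threshold)
        return float(x >= spec.threshold)  # tie resolves to leave
    return float(expit(sign * (x - spec.threshold) / spec.noise))


def decide(
    spec: StrategySpec,
    patch: PatchState,
    env: EnvConfig,
    rng: np.random.Generator,
) -> str:
    x = decision_variable(spec.name, patch, env)
    p = leave_probability(spec, x)
    if p == 1.0 or (0.0 < p and rng.random() < p):
        return ACTION_LEAVE
    return ACTION_PAN


def make_policy(spec: StrategySpec) -> Policy:
    """Wrap a StrategySpec as a run_session-compatible policy callback."""

    def policy(patch: PatchState, env: EnvConfig, rng: np.random.Generator) -> str:
        return decide(spec, patch, env, rng)

    return policy
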