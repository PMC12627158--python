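"""Maximum-likelihood strategy fitting and AIC classification.

Each candidate strategy (GUT, FT, FN — the omniscient MVT benchmark is
not a candidate) is a two-parameter choice model of the stay/leave
decisions in one session: at every decision point the probability of
leaving is logistic in the strategy's decision variable minus its
threshold, ``P(leave) = expit((x - theta) / tau)``, with ``tau`` the
decision temperature. Decision variables are reconstructed from the
*observed* pans and outcomes only; the latent river quality is never
used. Each model is fitted by minimizing the negative log-likelihood
(coarse grid, then local refinement), compared by AIC with k = 2, and
the minimum-AIC model is the session's classified strategy. Akaike
weights ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` quantify the relative
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .strategies import FITTABLE_STRATEGIES
from .task_env import ACTION_LEAVE, ACTION_PAN, LogValidationError, SessionLog

#: per-decision probabilities are floored here before taking logs.
PROB_FLOOR = 1e-10
#: free parameters per model (threshold, noise) for AIC.
N_PARAMS = 2
_MIN_TAU = 1e-3


class DecisionPoints(NamedTuple):
    """Per-decision strategy variables reconstructed from a session log."""

    gut: np.ndarray  # consecutive failures before the action
    ft: np.ndarray  # pans already made in the river
    fn: np.ndarray  # gold already collected in the river
    is_leave: np.ndarray  # True where the action taken was 'leave'

    @property
    def n(self) -> int:
        return len(self.is_leave)

    def variable(self, name: str) -> np.ndarray:
        if name not in FITTABLE_STRATEGIES:
            raise ValueError(f"{name!r} is not a fittable strategy")
        return getattr(self, name.lower())


@dataclass(frozen=True)
class FitResult:
    strategy: str
    threshold_hat: float
    noise_hat: float
    log_likelihood: float
    aic: float
    n_decisions: int


@dataclass(frozen=True)
class ClassificationResult:
    fits: dict[str, FitResult]
    best: str
    aic_weights: dict[str, float]


def decision_points(log: SessionLog) -> DecisionPoints:
    """One tuple of decision variables per action row in the log.

    Variables are computed from the observed event stream: consecutive
    failures, pans made and gold collected within the current river,
    all as of *before* the action. A final river that the session ended
    inside contributes its pan decisions; there is no terminal leave to
    score.
    """
    gut, ft, fn, leave = [], [], [], []
    river = None
    pans = gold = fails = 0
    last_t = 0
    for i, e in enumerate(log.events):
        if e.global_time_after <= last_t:
            raise LogValidationError(f"row {i}: time not strictly increasing")
        last_t = e.global_time_after
        if e.river_index != river:
            river = e.river_index
            pans = gold = fails = 0
        if e.action == ACTION_PAN:
            if e.outcome not in (0, 1):
                raise LogValidationError(f"row {i}: pan row needs outcome 0/1")
            gut.append(fails)
            ft.append(pans)
            fn.append(gold)
            leave.append(False)
            pans += 1
            if e.outcome == 1:
                gold += 1
                fails = 0
            else:
                fails += 1
        elif e.action == ACTION_LEAVE:
            if e.outcome is not None:
                raise LogValidationError(f"row {i}: leave row must have NA outcome")
            gut.append(fails)
            ft.append(pans)
            fn.append(gold)
            leave.append(True)
        else:
            raise LogValidationError(f"row {i}: unknown action {e.action!r}")
    return DecisionPoints(
        gut=np.asarray(gut, dtype=float),
        ft=np.asarray(ft, dtype=float),
        fn=np.asarray(fn, dtype=float),
        is_leave=np.asarray(leave, dtype=bool),
    )


def _nll_array(x, is_leave, thetas, taus):
    """NLL broadcast over a (theta, tau) grid; shapes (T,) and (K,)."""
    z = (x[:, None, None] - thetas[None, :, None]) / taus[None, None, :]
    p_leave = expit(z)
    p = np.where(is_leave[:, None, None], p_leave, 1.0 - p_leave)
    return -np.log(np.maximum(p, PROB_FLOOR)).sum(axis=0)


def neg_log_likelihood(
    name: str, threshold: float, noise: float, points: DecisionPoints
) -> float:
    """-sum log P(action) under the logistic leave rule."""
    if not (np.isfinite(threshold) and np.isfinite(noise)) or noise <= 0:
        raise ValueError("threshold must be finite and noise > 0")
    x = points.variable(name)
    out = _nll_array(x, points.is_leave, np.array([threshold]), np.array([noise]))
    return float(out[0, 0])


def fit_strategy(log: SessionLog | DecisionPoints, name: str) -> FitResult:
    """MLE of (threshold, noise) for one strategy on one session.

    A coarse grid (thresholds at half-integer steps over the observed
    range of the decision variable, noise log-spaced) is refined by a
    Nelder-Mead search from the best grid point. Deterministic given
    the log: no random restarts.
    """
    points = log if isinstance(log, DecisionPoints) else decision_points(log)
    if points.n < 1:
        raise ValueError("log contains no decision points")
    x = points.variable(name)
    lo, hi = float(np.floor(x.min())) - 0.5, float(x.max()) + 0.5
    thetas = np.arange(lo, hi + 0.25, 0.5)
    taus = np.geomspace(1e-2, 5.0, 12)
    grid = _nll_array(x, points.is_leave, thetas, taus)
    i, j = np.unravel_index(np.argmin(grid), grid.shape)

    def objective(params):
        theta, log_tau = params
        return _nll_array(
            x, points.is_leave, np.array([theta]), np.array([np.exp(log_tau)])
        )[0, 0]

    start = np.array([thetas[i], np.log(taus[j])])
    res = minimize(
        objective,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 250},
    )
    best = res.x if res.fun <= grid[i, j] else start
    nll = float(min(res.fun, grid[i, j]))
    theta_hat = float(best[0])
    tau_hat = float(max(np.exp(best[1]), _MIN_TAU))
    ll = -nll
    return FitResult(
        strategy=name,
        threshold_hat=theta_hat,
        noise_hat=tau_hat,
        log_likelihood=ll,
        aic=2 * N_PARAMS - 2 * ll,
        n_decisions=points.n,
    )


def aic_weights(aics: dict[str, float]) -> dict[str, float]:
    """Akaike weights: relative evidence per candidate model."""
    m = min(aics.values())
    w = {k: float(np.exp(-(v - m) / 2.0)) for k, v in aics.items()}
    s = sum(w.values())
    return {k: v / s for k, v in w.items()}


def classify(log: SessionLog | DecisionPoints) -> ClassificationResult:
    """Fit all candidate strategies and pick the minimum-AIC one.

    Exact AIC ties break toward GUT, then FT (candidate order) — a
    conservative choice that biases against detecting switches away
    from GUT.
    """
    points = log if isinstance(log, DecisionPoints) else decision_points(log)
    fits = {name: fit_strategy(points, name) for name in FITTABLE_STRATEGIES}
    best = min(FITTABLE_STRATEGIES, key=lambda n: (fits[n].aic, FITTABLE_STRATEGIES.index(n)))
    weights = aic_weights({n: f.aic for n, f in fits.items()})
    return ClassificationResult(fits=fits, best=best, aic_weights=weights)
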