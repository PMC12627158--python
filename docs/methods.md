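# Methods

## Task environment

The simulated task is a discrete-time patch-leaving problem. A session
is a budget of 250 integer time units. The forager occupies a river
with a latent initial nugget count N₀ ∈ {5, 8, 11} (equal probability;
with `balanced_sampling` qualities are drawn from shuffled triples so
every block of three rivers contains each quality once). Each *pan*
costs 1 unit and succeeds with probability `0.05 × N_remain`; a success
removes one nugget. Each *leave* costs 5 units of travel and delivers a
fresh river. The session ends when the budget is exhausted; a leave
chosen with fewer than 5 units left consumes only the remainder, and a
budget that hits zero after a pan ends the session inside the river.
That truncation rule is an assumption (the behavioral performance
measure needs a well-defined "unfinished final river"), not something
the task's original description fixes.

Every action is logged as one CSV row (participant, session, river
index, step, cumulative time, action, outcome, latent quality if
known, feedback label if any). The reader tolerates files without the
latent-quality column, as real data would be.

## Strategies

All four policies are thresholds on a scalar decision variable:
giving-up time (GUT) on the run of consecutive unrewarded pans,
fixed-time (FT) on pans made, fixed-number (FN) on nuggets collected,
and the Marginal Value Theorem benchmark (MVT) on the latent
instantaneous rate `0.05 × N_remain`. MVT reads hidden state, so it is
a normative benchmark only and is excluded from the fitted candidate
set. With decision temperature τ > 0 the rules become logistic:
`P(leave) = σ((x − θ)/τ)`, reversed for MVT whose variable falls rather
than rises. At τ = 0 a tie `x = θ` resolves to leave. The GUT counter
starts at 0 on river entry and resets on every success.

### Leave-timing conventions

Behavioral agents evaluate the rule before each pan and leave the
moment it fires ("check-then-pan"). For a deterministic GUT agent this
means the run of failures equals g exactly at every leave — the
property the feedback rules and the giving-up-time analyses rely on.

The *reference optima*, however, are computed under a convention in
which the outcome-triggered rules (GUT and MVT — the two whose
variable is only revealed by pan outcomes) complete **one further pan**
after the criterion fires. This is deliberate: it is the accounting
under which the reference performance table is internally consistent —
GUT4 scores 51.75 with mean resident times 8.0/10.8/14.4 and g = 4 is
the optimum, MVT scores 59.0 at an achieved rate of 0.236 with resident
times 5.0/13.7/19.7, and optimal FT beats optimal GUT by exactly 4.5%.
Under the plain rule the GUT optimum would sit at g = 5 (51.32 vs
51.10 by exact dynamic programming) and both GUT and MVT resident
times would be one pan shorter. FT and FN, whose variables are known
before the pan, are identical under both conventions.
`optimal_perf` defaults to the final-pan convention for GUT/MVT
(`final_pan=None`); everything behavioral uses the plain rule.

## Optimal performance

`long_run_rate` uses steady-state accounting: simulate complete patch
cycles (resident pans + one travel), total gold over total time, no
session boundary; session performance is rate × 250. Episodic
accounting (literal 250-unit sessions, total gold) differs by a real
boundary term — the unfinished final river contributes gold but never
pays its travel — worth about +3% for FT at a 250-unit budget and
vanishing as the budget grows; the equivalence test therefore runs at
a 2500-unit budget. A deterministic FN policy whose threshold exceeds
a river's initial count would pan an empty river forever; its long-run
rate is defined as 0 (finite gold over unbounded time), which keeps
FN grids above the minimum quality well-posed.

### Grid search

Deterministic threshold policies are *stopping times* of a policy-free
pan trajectory: the sequence of pan outcomes does not depend on when
the policy would stop. `evaluate_threshold_grids` therefore simulates
one set of trajectories and reads off, for every strategy and every
threshold, the stopped resident time and the gold at stopping — all
grid points (and all strategies, when searched together) see identical
randomness. Gold is credited by its conditional expectation given the
trajectory (`0.05 × N_remain` per pan) for FT and GUT, and by its
exact stopped value for FN (= n) and MVT (= N₀ − stop level); both are
unbiased for the long-run rate, and the expected-value crediting is
what makes the FT argmax resolvable: T = 12 and T = 13 differ by only
0.002 gold/session (exactly 54.0753 vs 54.0731), far below naive
Monte-Carlo noise at feasible sizes. Searches default to 4 × 10⁶ patch
cycles, at which the T = 12 vs 13 comparison is a >3σ decision; plain
rate estimates default to 2 × 10⁵ cycles (sampling error ≈ 0.1%).
Ties in the argmax go to the smallest threshold. The MVT "parameter"
is reported as the achieved long-run rate, since every rate threshold
between two adjacent discrete rates `0.05k` induces identical
behavior.

## Fitting and classification

Decision variables are reconstructed from the observed event stream
only (never from latent quality). Every action row is a decision
point; an unfinished final river contributes its pan decisions but has
no terminal leave to score. The likelihood treats decisions as
independent logistic choices, `P(leave) = σ((x_t − θ)/τ)`, with
probabilities floored at 1e-10 before the log. Each of GUT/FT/FN has
two free parameters, so AIC = 4 − 2·logL. Fitting minimizes the NLL on
a coarse grid (θ at half-integer steps over the observed variable
range, τ log-spaced on [0.01, 5]) refined by Nelder-Mead from the best
grid point; the optimizer is deterministic (no random restarts), so
classification is exactly reproducible. AIC ties break toward GUT,
then FT — conservative in the sense that it biases *against* detecting
switches away from GUT, so any detected switching is not a tie-break
artifact. Note that for a noiseless agent the likelihood is flat over
θ ∈ (g − 1, g], so the fitted threshold of a hard-threshold agent is
identified only up to that interval; with τ ≈ 0.25 the threshold is
point-identified and recovered to well within half a unit (median).

## Synthetic cohorts

`synthetic_data` generates the three-session structure the behavioral
analyses assume. Defaults mirror the experimental scale: ~40
participants per condition; pre-feedback strategy mixture 77% GUT /
21% FT / 2% FN (the typical preponderance of giving-up-time users);
thresholds drawn per strategy from normals centered on the optima
(GUT 4 ± 1, FT 12 ± 2.5, FN 3 ± 0.75, clipped at 0.5); decision
temperature τ ~ N(0.25, 0.10) clipped at 0.05, a noise level at which
strategies remain identifiable but behavior is visibly stochastic.
Feedback labels are a deterministic function of the leave point: an FT
instructor compares resident time with 12, a GUT instructor compares
the failure run with 4; below → *too_early*, exact equality →
*on_time*, above → *too_late*. Exact equality is the only
parameter-free reading of "right on time"; whether a real instructor
would use a tolerance band is unknown.

The post-feedback adaptation rule is openly a generative convenience,
not a cognitive model: with probability `switch_probability` (default
0.5, matching the observed ~20/40 switch rate under FT feedback) the
agent adopts the instructor's strategy with a threshold near its
optimum (N(optimum, 0.5)); otherwise it keeps its strategy with its
threshold deviation from the optimum shrunk by `precision_gain`
(default 0.5). The study these cohorts emulate *measures* feedback
effects; it does not model them. Synthetic cohorts therefore validate
the pipeline's machinery (metrics, classification, contingency tables,
recovery), not any claim about human learning; passing tests say the
analyses detect structure that is present and stay silent when it is
absent, nothing more. Real data also contain within-session strategy
mixing, sequential dependencies, and attention lapses that the
logistic-threshold agents do not emulate.

## Behavioral analyses

*Performance* is the gold acquired in a session excluding the final
river if the session ended without leaving it; a river counts only
once departed. *Efficiency* divides that gold by the time actually
spent on included rivers (pans + travel; the two candidate
denominators, included-river time vs full budget, agree to the
reported precision and the included-river reading keeps the metric
self-contained). *Giving-up-time precision* is the absolute deviation
of the session's mean behavioral failure run at leaving from the
optimal g = 4 — behavioral, not the fitted threshold, because the
summary tables it feeds are behavioral. The low-performance exclusion
keeps participants whose pre-feedback performance is at least half the
MVT optimal performance (58.96, the only strategy-free optimum); the
boundary case is kept, "lower than" being strict. The pre/post
strategy contingency table is 2 × 3 (sessions × GUT/FT/FN); Pearson's
chi-square uses margin-derived expected counts, no continuity
correction (the uncorrected statistic reproduces the worked examples
7.351 and 1.26 exactly), with zero-margin rows/columns dropped before
df = (r−1)(c−1).

`recovery_harness` closes the loop: simulate agents of known strategy
and threshold, classify them, tabulate confusion and threshold error.
At τ = 0.25 and the optimal thresholds, 50 agents per strategy are
classified ≥ 80% correctly per strategy with median |θ̂ − θ| ≤ 0.5; at
τ = 0.01 recovery is ≥ 95%.

## Problem sizes and tolerances

Reference-table reproduction uses 4 × 10⁶ shared patch cycles (the
argmax-resolution argument above); rate-level checks use 1–3 × 10⁵
cycles against exact values from the depletion law
`E[N_remain after t pans] = N₀ · 0.95ᵗ`; recovery uses 50 agents per
cell; the pipeline direction check uses 100 paired replications of
24-participant two-session cohorts, a size at which a 50% switch rate
moves the contingency chi-square far above its no-switch distribution.
Stochastic assertions are stated at 3 standard errors or at the
tolerances quoted above.

## Known limitations

- The final-pan convention for GUT/MVT reference optima is an inference
  from internal consistency of the reference quantities, not an
  independently documented rule; `final_pan=False` gives the plain
  reading everywhere.
- One strategy is fitted per session; within-session mixtures or
  switches are outside the model family (Akaike weights flag, but do
  not model, mixing).
- The likelihood assumes decision-level independence given the state;
  perseveration or history effects beyond the decision variables are
  not represented.
- Bayesian group-level analyses on participant data are out of scope;
  the package stops at per-session classification and frequentist
  contingency tests.
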