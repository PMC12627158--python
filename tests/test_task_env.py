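import numpy as np
import pytest

from patchforage import (
    EnvConfig,
    PatchSampler,
    PatchState,
    SessionLog,
    pan,
    run_session,
    sample_patch,
)
from patchforage.task_env import ACTION_LEAVE, ACTION_PAN, InvalidPolicyError


class TestEnvConfig:
    def test_defaults_are_the_study_environment(self, env):
        assert env.find_rate_per_nugget == 0.05
        assert env.qualities == (5, 8, 11)
        assert env.quality_probs == pytest.approx((1 / 3,) * 3)
        assert (env.pan_cost, env.travel_cost, env.session_budget) == (1, 5, 250)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"find_rate_per_nugget": 0.2},  # 0.2 * 11 > 1
            {"quality_probs": (0.5, 0.5, 0.5)},
            {"travel_cost": 0},
            {"session_budget": -1},
            {"qualities": ()},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EnvConfig(**kwargs)


class TestPatchSampling:
    def test_fresh_patch_is_full(self, env, rng):
        patch = sample_patch(env, rng)
        assert patch.remaining == patch.quality in env.qualities
        assert patch.pans_made == patch.gold_collected == 0

    def test_unbalanced_marginal_is_uniform(self, env, rng):
        draws = [sample_patch(env, rng).quality for _ in range(6000)]
        for q in env.qualities:
            assert np.mean(np.array(draws) == q) == pytest.approx(1 / 3, abs=0.03)

    def test_balanced_blocks_force_equal_presence(self, rng):
        env = EnvConfig(balanced_sampling=True)
        sampler = PatchSampler(env, rng)
        qualities = [sampler.sample().quality for _ in range(15)]
        assert all(qualities.count(q) == 5 for q in env.qualities)

    def test_same_seed_same_sequence(self, env):
        a = [sample_patch(env, np.random.default_rng(7)).quality for _ in range(1)]
        seq1 = [PatchSampler(env, np.random.default_rng(3)).sample().quality for _ in range(20)]
        s = PatchSampler(env, np.random.default_rng(3))
        seq2 = [s.sample().quality for _ in range(1)]
        assert seq1[0] == seq2[0]


class TestPan:
    def test_empty_river_never_yields(self, env, rng):
        patch = PatchState(quality=5, remaining=0, gold_collected=5)
        for _ in range(50):
            outcome, patch = pan(patch, env, rng)
            assert outcome == 0
        assert patch.consecutive_failures == 50

    def test_success_rate_matches_remaining(self, env, rng):
        # remaining=5 -> p=0.25; binomial check at 3 s.e.
        n = 40_000
        hits = 0
        for _ in range(n):
            patch = PatchState(quality=5, remaining=5)
            outcome, _ = pan(patch, env, rng)
            hits += outcome
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(hits / n - 0.25) < 3 * se

    def test_bookkeeping_on_success_and_failure(self, env):
        patch = PatchState(quality=5, remaining=5)
        rng = np.random.default_rng(0)
        for _ in range(200):
            before = patch.remaining
            outcome, patch = pan(patch, env, rng)
            if outcome:
                assert patch.remaining == before - 1
                assert patch.consecutive_failures == 0
        assert patch.gold_collected == patch.quality - patch.remaining


def _ft_policy(T):
    def policy(patch, env, rng):
        return ACTION_LEAVE if patch.pans_made >= T else ACTION_PAN

    return policy


class TestRunSession:
    def test_time_conservation_and_budget(self, env, rng):
        log = run_session(_ft_policy(12), env, rng)
        pans = sum(e.action == ACTION_PAN for e in log.events)
        leaves = sum(e.action == ACTION_LEAVE for e in log.events)
        # all leaves cost 5 except possibly a truncated final one
        assert log.total_time == log.events[-1].global_time_after
        assert log.total_time <= env.session_budget
        assert pans + 5 * leaves >= log.total_time >= pans + 5 * (leaves - 1)
        log.validate()

    def test_fixed_time_rivers_have_exactly_t_pans(self, env, rng):
        log = run_session(_ft_policy(12), env, rng)
        for river in log.rivers():
            if river[-1].action == ACTION_LEAVE:
                assert sum(e.action == ACTION_PAN for e in river) == 12

    def test_always_leave_yields_fifty_rivers(self, env, rng):
        log = run_session(lambda p, e, r: ACTION_LEAVE, env, rng)
        assert len(log.rivers()) == env.session_budget // env.travel_cost == 50
        assert all(e.action == ACTION_LEAVE for e in log.events)

    def test_practice_budget_respected(self, env, rng):
        log = run_session(_ft_policy(3), env, rng, {"budget": 20})
        assert log.total_time <= 20

    def test_final_leave_truncated_to_remaining_budget(self, rng):
        env = EnvConfig(session_budget=13)
        log = run_session(_ft_policy(10), env, rng)
        # 10 pans then a leave with only 3 units left
        assert log.total_time == 13
        assert log.events[-1].action == ACTION_LEAVE

    def test_invalid_policy_raises(self, env, rng):
        with pytest.raises(InvalidPolicyError):
            run_session(lambda p, e, r: "dig", env, rng)

    def test_seeded_determinism(self, env):
        def noisy(patch, env_, rng_):
            return ACTION_LEAVE if rng_.random() < 0.1 else ACTION_PAN

        a = run_session(noisy, env, np.random.default_rng(42)).to_frame()
        b = run_session(noisy, env, np.random.default_rng(42)).to_frame()
        assert a.equals(b)

    def test_gold_conservation_per_river(self, env, rng):
        log = run_session(_ft_policy(20), env, rng)
        for river in log.rivers():
            gold = sum(e.outcome or 0 for e in river if e.action == ACTION_PAN)
            assert gold <= river[0].river_quality


class TestSerialization:
    def test_frame_round_trip(self, env, rng):
        log = run_session(_ft_policy(8), env, rng, {"participant_id": "p9"})
        back = SessionLog.from_frame(log.to_frame(), log.metadata)
        assert back.events == log.events

    def test_reader_tolerates_missing_quality(self, env, rng):
        log = run_session(_ft_policy(8), env, rng)
        df = log.to_frame().drop(columns=["river_quality"])
        df["river_quality"] = float("nan")
        back = SessionLog.from_frame(df)
        assert all(e.river_quality is None for e in back.events)

    def test_validate_rejects_outcome_on_leave(self, toy_log):
        import dataclasses

        bad = SessionLog(
            events=[
                dataclasses.replace(e, outcome=1) if e.action == ACTION_LEAVE else e
                for e in toy_log.events
            ]
        )
        with pytest.raises(Exception):
            bad.validate()
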