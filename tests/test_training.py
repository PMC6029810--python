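"""Target generation, curriculum, schedule, A3C losses and gradients."""

import numpy as np
import pytest

from rnaforge.environment import DesignState, action_mask, env_step
from rnaforge.fold import parse_dot_bracket
from rnaforge.network import (
    NetworkParams,
    forward_pass,
    masked_softmax,
    sample_action,
)
from rnaforge.training import (
    EpisodeTrace,
    TargetSet,
    TrainingConfig,
    compute_a3c_losses,
    curriculum_split,
    discounted_returns,
    evaluate_policy,
    generate_targets,
    holdout_easy,
    learning_rate,
    network_policy,
    policy_gradients,
    train,
    uniform_policy,
    validate,
)


def tiny_config(**kw) -> TrainingConfig:
    base = dict(
        total_steps=200,
        phase1_steps=100,
        lr0=1e-3,
        lr_interval=100,
        validation_interval=100,
        n_validation=0,
        target_length=8,
        n_target_sequences=50,
        n_step=5,
        n_workers=1,
        step_cap=20,
        validation_step_cap=20,
        channels=4,
        n_blocks=1,
        engine="nussinov",
        seed=11,
    )
    base.update(kw)
    return TrainingConfig(**base)


class TestGenerateTargets:
    def test_too_short_to_pair_gives_single_structure(self, nussinov, rng):
        ts = generate_targets(30, 3, nussinov, rng)
        assert len(ts.entries) == 1
        assert ts.entries[0][0].to_dot_bracket() == "..."

    def test_counts_conserve_sample_size(self, nussinov, rng):
        ts = generate_targets(200, 10, nussinov, rng)
        assert sum(c for _, c in ts.entries) == 200

    def test_save_load_round_trip(self, nussinov, rng, tmp_path):
        ts = generate_targets(100, 10, nussinov, rng)
        path = tmp_path / "targets.csv"
        ts.save(path)
        loaded = TargetSet.load(path)
        assert [(p.to_dot_bracket(), c) for p, c in loaded.entries] == [
            (p.to_dot_bracket(), c) for p, c in ts.entries
        ]

    def test_histogram_fields(self, nussinov, rng):
        ts = generate_targets(300, 12, nussinov, rng)
        h = ts.occurrence_histogram()
        assert h["unique"] == len(ts.entries)
        assert h["singletons"] + h["doubletons"] + h["three_or_more"] == h["unique"]


def toy_target_set():
    structures = ["((((....))))", "(((......)))", "((.......)).", "............"]
    counts = [5, 2, 1, 1]
    return TargetSet(
        [(parse_dot_bracket(s), c) for s, c in zip(structures, counts)]
    )


class TestCurriculumSplit:
    def test_bucketing_by_occurrence(self, rng):
        split = curriculum_split(toy_target_set(), 1, rng)
        assert [p.to_dot_bracket() for p in split.phase1] == ["((((....))))"]
        assert len(split.validation) == 1
        singles = {"((.......)).", "............"}
        assert split.validation[0].to_dot_bracket() in singles
        assert len(split.phase2) == 3

    def test_validation_disjoint_from_phase2(self, rng):
        split = curriculum_split(toy_target_set(), 2, rng)
        assert not set(split.validation) & set(split.phase2)

    def test_same_seed_same_split(self):
        a = curriculum_split(toy_target_set(), 1, np.random.default_rng(5))
        b = curriculum_split(toy_target_set(), 1, np.random.default_rng(5))
        assert a.validation == b.validation

    def test_too_few_singletons_rejected(self, rng):
        with pytest.raises(ValueError, match="singleton"):
            curriculum_split(toy_target_set(), 3, rng)


class TestHoldoutEasy:
    def test_takes_most_common_nontrivial(self):
        ts = toy_target_set()
        remaining, held = holdout_easy(ts, 2)
        assert [p.to_dot_bracket() for p in held] == [
            "((((....))))",
            "(((......)))",
        ]  # all-dots excluded as trivial
        assert len(remaining.entries) == 2

    def test_held_out_removed_from_set(self):
        remaining, held = holdout_easy(toy_target_set(), 1)
        assert held[0] not in {p for p, _ in remaining.entries}


class TestLearningRate:
    @pytest.mark.parametrize(
        "step, expected",
        [(0, 1e-5), (99_999, 1e-5), (100_000, 8e-6), (250_000, 6.4e-6)],
    )
    def test_published_schedule(self, step, expected):
        cfg = TrainingConfig()
        assert learning_rate(step, cfg) == pytest.approx(expected, rel=1e-12)

    def test_closed_form_and_monotone(self, rng):
        cfg = TrainingConfig()
        steps = np.sort(rng.integers(0, 2_000_000, size=50))
        values = [learning_rate(int(s), cfg) for s in steps]
        for s, v in zip(steps, values):
            assert v == pytest.approx(cfg.lr0 * cfg.lr_decay ** (s // cfg.lr_interval))
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestA3CLosses:
    def test_zero_advantage_zero_policy_loss(self):
        trace = EpisodeTrace(
            log_probs=[-1.0, -2.0],
            values=[0.9, 1.0],  # equal to the returns below
            rewards=[0.0, 1.0],
            entropies=[0.5, 0.5],
            bootstrap_value=0.0,
        )
        pol, val, ent = compute_a3c_losses(trace, gamma=0.9, beta=0.01)
        assert pol == pytest.approx(0.0) and val == pytest.approx(0.0)
        assert ent == pytest.approx(1.0)

    def test_undiscounted_returns(self):
        assert discounted_returns([0, 0, 1], 0.0, 1.0).tolist() == [1, 1, 1]

    def test_uniform_policy_entropy_is_log_3n(self, nussinov):
        n = 7
        probs = np.full((n, 4), 1.0 / (3 * n))
        seq = "AAAAAAA"
        state = DesignState(
            target=parse_dot_bracket("." * n),
            sequence=seq,
            current_fold=nussinov.fold(seq).structure,
        )
        probs[~action_mask(state)] = 0.0
        flat = probs.reshape(-1)
        ent = -(flat[flat > 0] * np.log(flat[flat > 0])).sum()
        assert ent == pytest.approx(np.log(3 * n))

    def test_mismatched_trace_rejected(self):
        with pytest.raises(ValueError):
            EpisodeTrace(log_probs=[0.0], values=[], rewards=[0.0], entropies=[0.0])


class GradientCheckHarness:
    """Frozen-advantage A3C objective for finite-difference comparison.

    The policy-gradient term treats the advantage as a constant, so the
    oracle objective freezes the advantages at their base-parameter values
    while letting the value-loss and entropy terms vary with the
    parameters.
    """

    def __init__(self, nussinov, cfg, n=6, seed=21):
        self.engine = nussinov
        self.cfg = cfg
        self.target = parse_dot_bracket("(....)")
        rng = np.random.default_rng(seed)
        self.params = NetworkParams.initialize(
            rng, channels=cfg.channels, n_blocks=cfg.n_blocks, n_train=n
        )
        from rnaforge.environment import reset

        state = reset(self.target, rng, self.engine)
        self.steps = []
        for _ in range(3):
            cache = forward_pass(
                self.params, state.sequence, state.target, state.current_fold,
                want_value=True,
            )
            probs = masked_softmax(cache["logits"], action_mask(state))
            action = sample_action(probs, rng)
            nxt, reward, _ = env_step(state, action, self.engine, step_cap=50)
            self.steps.append(
                {
                    "sequence": state.sequence,
                    "fold": state.current_fold,
                    "action_index": action.position * 4 + "ACGU".index(action.new_base),
                    "reward": reward,
                }
            )
            state = nxt
        boot = forward_pass(
            self.params, state.sequence, state.target, state.current_fold,
            want_value=True,
        )
        self.bootstrap = boot["value"]
        self.returns = discounted_returns(
            [s["reward"] for s in self.steps], self.bootstrap, cfg.gamma
        )
        self.frozen_adv = [
            r - self._forward(self.params, s)[0]["value"]
            for s, r in zip(self.steps, self.returns)
        ]

    def _forward(self, params, s):
        cache = forward_pass(
            params, s["sequence"], self.target, s["fold"], want_value=True
        )
        state = DesignState(
            target=self.target, sequence=s["sequence"], current_fold=s["fold"]
        )
        probs = masked_softmax(cache["logits"], action_mask(state))
        return cache, probs

    def objective(self, params):
        cfg = self.cfg
        pol = val = ent = 0.0
        for s, ret, adv in zip(self.steps, self.returns, self.frozen_adv):
            cache, probs = self._forward(params, s)
            flat = probs.reshape(-1)
            pos = flat > 0
            logp = np.zeros_like(flat)
            logp[pos] = np.log(flat[pos])
            pol += -logp[s["action_index"]] * adv
            val += (ret - cache["value"]) ** 2
            ent += -(flat[pos] * logp[pos]).sum()
        return pol + cfg.value_loss_weight * val - cfg.entropy_coef * ent

    def analytic_gradients(self):
        segment = []
        for s in self.steps:
            cache, probs = self._forward(self.params, s)
            segment.append(
                {
                    "cache": cache,
                    "probs": probs,
                    "action_index": s["action_index"],
                    "reward": s["reward"],
                    "value": cache["value"],
                }
            )
        grads, _ = policy_gradients(self.params, segment, self.bootstrap, self.cfg)
        return grads

    def max_relative_error(self, coords_per_array=4, eps=1e-6):
        grads = self.analytic_gradients()
        pick = np.random.default_rng(0)
        worst = 0.0
        for key, arr in self.params.arrays.items():
            flat = arr.reshape(-1) if arr.shape else arr.reshape(1)
            g = grads[key].reshape(-1) if grads[key].shape else grads[key].reshape(1)
            idxs = pick.choice(flat.size, min(coords_per_array, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                fp = self.objective(self.params)
                flat[i] = orig - eps
                fm = self.objective(self.params)
                flat[i] = orig
                num = (fp - fm) / (2 * eps)
                denom = max(abs(num) + abs(g[i]), 1e-6)
                worst = max(worst, abs(num - g[i]) / denom)
        return worst


def test_analytic_gradients_match_finite_differences(nussinov):
    """Backprop through the miniature network agrees with central differences."""
    cfg = tiny_config(channels=4, n_blocks=1, gamma=0.9)
    harness = GradientCheckHarness(nussinov, cfg)
    assert harness.max_relative_error() < 1e-3


class TestTrainDriver:
    def test_zero_steps_returns_initial_network(self, nussinov, rng):
        ts = generate_targets(100, 8, nussinov, rng)
        cfg = tiny_config(total_steps=0, phase1_steps=0)
        params, log = train(cfg, ts, nussinov)
        assert params.channels == cfg.channels
        assert log.empty

    def test_short_run_progresses_and_logs(self, nussinov, rng):
        ts = generate_targets(150, 8, nussinov, rng)
        cfg = tiny_config(total_steps=200, phase1_steps=100, validation_interval=100)
        params, log = train(cfg, ts, nussinov)
        assert not log.empty
        assert (log["lr"] > 0).all()
        assert log.attrs["episode_targets"]  # draw audit present

    def test_phase1_draws_only_easy_structures(self, nussinov, rng):
        ts = generate_targets(150, 8, nussinov, rng)
        easy = {p.to_dot_bracket() for p, c in ts.entries if c >= 3}
        cfg = tiny_config(total_steps=200, phase1_steps=200)
        _, log = train(cfg, ts, nussinov)
        for step, phase, struct in log.attrs["episode_targets"]:
            if step < cfg.phase1_steps:
                assert phase == 1 and struct in easy

    def test_two_worker_run_completes(self, nussinov, rng):
        ts = generate_targets(150, 8, nussinov, rng)
        cfg = tiny_config(total_steps=200, n_workers=2)
        params, log = train(cfg, ts, nussinov)
        assert params is not None


class TestValidation:
    def test_empty_validation_set_scores_zero(self, nussinov, rng):
        params = NetworkParams.initialize(rng, channels=4, n_blocks=1)
        assert validate(params, [], 10, nussinov, rng) == 0

    def test_score_bounded_by_cap(self, nussinov, rng):
        params = NetworkParams.initialize(rng, channels=4, n_blocks=1)
        structures = [parse_dot_bracket(s) for s in ["((((....))))", "(((....))).."]]
        score = validate(params, structures, 15, nussinov, rng)
        assert 0 <= score <= len(structures) * 15

    def test_evaluate_policy_reports_per_structure_steps(self, nussinov, rng):
        structures = [parse_dot_bracket("....")] * 3
        steps = evaluate_policy(uniform_policy, structures, 10, nussinov, rng)
        assert steps == [0, 0, 0]  # length-4 chains cannot pair, so reset solves them

    def test_network_policy_solves_trivial_target(self, nussinov, rng):
        params = NetworkParams.initialize(rng, channels=4, n_blocks=1)
        target = parse_dot_bracket("...")
        steps = evaluate_policy(network_policy(params), [target], 10, nussinov, rng)
        assert steps == [0]


class TestTrainingConfig:
    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = tiny_config()
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert TrainingConfig.from_yaml(path) == cfg

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("warp_speed: 9\n")
        with pytest.raises(ValueError, match="unknown config"):
            TrainingConfig.from_yaml(path)

    @pytest.mark.parametrize(
        "bad",
        [dict(lr_decay=1.5), dict(phase1_steps=10, total_steps=5), dict(n_step=0)],
    )
    def test_invalid_values_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            TrainingConfig(**bad)
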