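"""Composite loss, gradients, and the two optimization regimes."""

import numpy as np
import pytest

from curladapt import engine
from curladapt.controller import Trajectory, init_params, rollout
from curladapt.effector import ArmConfig, CurlField, forward_kinematics
from curladapt.engine import EpisodeBatch
from curladapt.protocol import CentreOutTask, PhaseSpec, centre_out_batch
from curladapt.training import (
    Adam,
    EpisodeSpec,
    LossWeights,
    compute_loss,
    desired_position,
    growing_up,
    sample_random_reach_batch,
    sgd_step,
    train_phase,
)


def _manual_traj(P, F, H, xstar, dt=0.01):
    """Assemble a minimal trajectory carrying given loss inputs."""
    T = F.shape[0]
    z2, z6 = np.zeros((T + 1, 1, 2)), np.zeros((T + 1, 1, 6))
    return Trajectory(
        joint_angles=z2, joint_velocities=z2, activations=z6,
        hidden=H, endpoint=P, muscle_lengths=z6, muscle_velocities=z6,
        stimulation=np.zeros((T, 1, 6)), muscle_forces=F,
        observations=np.zeros((T, 1, 17)), desired=xstar,
        go_step=np.array([0]), target=xstar[-1], start_position=P[0],
        field_gain=0.0, dt=dt)


class TestDesiredPosition:
    def test_catch_trial_goal_stays_at_start(self, arm_cfg):
        ep = EpisodeSpec(start_theta=arm_cfg.theta_ref, target=np.array([0.0, 0.3]),
                         go_step=None)
        start = forward_kinematics(np.asarray(arm_cfg.theta_ref), arm_cfg)
        for t in (0, 50, 99):
            assert desired_position(ep, t, arm_cfg) == pytest.approx(start)

    def test_boundary_step(self, arm_cfg):
        tgt = np.array([0.0, 0.3])
        ep = EpisodeSpec(start_theta=arm_cfg.theta_ref, target=tgt, go_step=20)
        start = forward_kinematics(np.asarray(arm_cfg.theta_ref), arm_cfg)
        assert desired_position(ep, 19, arm_cfg) == pytest.approx(start)
        assert desired_position(ep, 20, arm_cfg) == pytest.approx(tgt)


class TestComputeLoss:
    def test_perfect_tracking_zero_loss(self):
        T = 20
        xstar = np.tile([0.1, 0.2], (T, 1, 1))
        P = np.tile([0.1, 0.2], (T + 1, 1, 1))
        total, bd = compute_loss(_manual_traj(P, np.zeros((T, 1, 6)),
                                              np.zeros((T + 1, 1, 4)), xstar))
        assert total == 0.0
        assert all(v == 0.0 for v in bd.values())

    def test_position_term_substitution(self):
        """A constant 1 cm offset in x costs exactly 1e3 * 0.01 = 10."""
        T = 20
        xstar = np.tile([0.1, 0.2], (T, 1, 1))
        P = np.tile([0.11, 0.2], (T + 1, 1, 1))
        total, bd = compute_loss(_manual_traj(P, np.zeros((T, 1, 6)),
                                              np.zeros((T + 1, 1, 4)), xstar))
        assert total == pytest.approx(10.0)
        assert bd["position"] == pytest.approx(10.0)

    def test_hidden_term_substitution(self):
        """Constant h with h.h = 1.28 and no derivative costs 1.28e-5."""
        T = 20
        h = np.sqrt(1.28 / 4.0)
        H = np.full((T + 1, 1, 4), h)
        xstar = np.tile([0.0, 0.0], (T, 1, 1))
        P = np.zeros((T + 1, 1, 2))
        total, bd = compute_loss(_manual_traj(P, np.zeros((T, 1, 6)), H, xstar))
        assert total == pytest.approx(1.28e-5)
        assert bd["hidden"] == pytest.approx(1.28e-5)

    def test_breakdown_nonnegative_and_sums(self, toy_params, arm_cfg):
        ep = EpisodeSpec(start_theta=arm_cfg.theta_ref,
                         target=np.array([-0.05, 0.35]), go_step=15,
                         duration=0.5)
        traj = rollout(toy_params, ep, arm_cfg, CurlField(8.0))
        total, bd = compute_loss(traj)
        assert all(v >= 0.0 for v in bd.values())
        assert total == pytest.approx(sum(bd.values()))

    def test_invariant_to_episode_order(self, toy_params, arm_cfg):
        rng = np.random.default_rng(0)
        eps = sample_random_reach_batch(rng, 6, arm_cfg, n_steps=30)
        cache = engine.simulate(toy_params.weights, eps, arm_cfg)
        t1, _ = engine.loss_terms(cache, eps, arm_cfg, LossWeights())
        perm = np.random.default_rng(1).permutation(6)
        eps2 = EpisodeBatch(eps.start_theta[perm], eps.target[perm],
                            eps.go_step[perm], eps.n_steps)
        cache2 = engine.simulate(toy_params.weights, eps2, arm_cfg)
        t2, _ = engine.loss_terms(cache2, eps2, arm_cfg, LossWeights())
        assert t1 == pytest.approx(t2, rel=1e-12)


class TestGradients:
    def test_manual_bptt_matches_autograd_oracle(self, toy_params, arm_cfg):
        """Hand-derived adjoint vs automatic differentiation of the same
        forward pass, through the full plant + GRU + delays + loss."""
        anp = pytest.importorskip("autograd.numpy")
        from autograd import grad as agrad

        w = LossWeights()
        eps = sample_random_reach_batch(np.random.default_rng(1), 3, arm_cfg, n_steps=15)
        _, _, grads, _ = engine.loss_and_grad(toy_params.weights, eps, arm_cfg, w, b=8.0)

        def loss_fn(p):
            c = engine.simulate(p, eps, arm_cfg, b=8.0, xp=anp)
            t, _ = engine.loss_terms(c, eps, arm_cfg, w, xp=anp)
            return t

        oracle = agrad(loss_fn)({k: anp.array(v) for k, v in toy_params.weights.items()})
        for k in grads:
            a = np.asarray(oracle[k])
            denom = max(np.abs(a).max(), 1e-12)
            assert np.abs(a - grads[k]).max() / denom < 1e-8, k

    def test_manual_bptt_matches_finite_differences(self, arm_cfg):
        """Independent second route: central finite differences on a tiny net."""
        p = init_params(4, 0)
        rng = np.random.default_rng(2)
        for k in p.weights:
            p.weights[k] = p.weights[k] + 0.1 * rng.standard_normal(p.weights[k].shape)
        w = LossWeights()
        eps = sample_random_reach_batch(np.random.default_rng(3), 2, arm_cfg, n_steps=10)
        _, _, grads, _ = engine.loss_and_grad(p.weights, eps, arm_cfg, w, b=8.0)

        def f(weights):
            c = engine.simulate(weights, eps, arm_cfg, b=8.0)
            t, _ = engine.loss_terms(c, eps, arm_cfg, w)
            return float(t)

        h = 1e-5
        rngi = np.random.default_rng(4)
        for k in ("Wh", "Wi", "Wout", "h0", "bh"):
            arr = p.weights[k]
            idx = tuple(rngi.integers(0, s) for s in arr.shape)
            wp = {kk: vv.copy() for kk, vv in p.weights.items()}
            wp[k][idx] += h
            wm = {kk: vv.copy() for kk, vv in p.weights.items()}
            wm[k][idx] -= h
            fd = (f(wp) - f(wm)) / (2 * h)
            assert grads[k][idx] == pytest.approx(fd, rel=1e-3, abs=1e-8), k

    def test_sgd_step_is_minus_lr_times_gradient(self, arm_cfg):
        p = init_params(4, 1)
        eps = sample_random_reach_batch(np.random.default_rng(5), 2, arm_cfg, n_steps=10)
        _, _, grads, _ = engine.loss_and_grad(p.weights, eps, arm_cfg, LossWeights())
        before = {k: v.copy() for k, v in p.weights.items()}
        lr = 1e-3
        sgd_step(p.weights, grads, lr)
        for k in engine.PLASTIC_KEYS:
            assert np.allclose(p.weights[k], before[k] - lr * grads[k])
        for k in set(engine.PARAM_KEYS) - set(engine.PLASTIC_KEYS):
            assert np.array_equal(p.weights[k], before[k])


class TestGrowingUp:
    def test_deterministic(self, arm_cfg):
        p = init_params(6, 0)
        a, la = growing_up(p, arm_cfg, seed=0, n_batches=5, batch_size=4, n_steps=20)
        b, lb = growing_up(p, arm_cfg, seed=0, n_batches=5, batch_size=4, n_steps=20)
        assert np.array_equal(la, lb)
        for k in a.weights:
            assert np.array_equal(a.weights[k], b.weights[k])

    def test_loss_decreases_at_reduced_scale(self, arm_cfg):
        p = init_params(16, 2)
        _, log = growing_up(p, arm_cfg, seed=2, n_batches=250, batch_size=8, n_steps=100)
        assert np.mean(log[-25:]) < 0.6 * log[0]

    def test_catch_fraction(self, arm_cfg):
        rng = np.random.default_rng(0)
        n_catch, n_tot = 0, 0
        for _ in range(100):
            eps = sample_random_reach_batch(rng, 32, arm_cfg)
            n_catch += int(eps.catch.sum())
            n_tot += 32
        assert abs(n_catch / n_tot - 0.5) < 0.03  # ~3 binomial sd

    def test_go_times_in_window(self, arm_cfg):
        eps = sample_random_reach_batch(np.random.default_rng(1), 200, arm_cfg)
        go = eps.go_step[~eps.catch]
        assert go.min() >= 10 and go.max() <= 30


class TestTrainPhase:
    def _sampler(self, arm_cfg, seed=0):
        task = CentreOutTask()
        rng = np.random.default_rng(seed)
        return lambda i: centre_out_batch(task, 8, 0.5, rng, arm_cfg, n_steps=30)

    def test_frozen_groups_bit_identical(self, arm_cfg):
        p = init_params(6, 3)
        phase = PhaseSpec("FF1", 8.0, 4, 8)
        p2, log = train_phase(p, phase, arm_cfg, self._sampler(arm_cfg), lr=5e-3)
        for k in set(engine.PARAM_KEYS) - set(engine.PLASTIC_KEYS):
            assert np.array_equal(p2.weights[k], p.weights[k]), k
        assert any(not np.array_equal(p2.weights[k], p.weights[k])
                   for k in engine.PLASTIC_KEYS)
        assert log.shape == (4,)

    def test_zero_learning_rate_keeps_parameters(self, arm_cfg):
        p = init_params(6, 3)
        phase = PhaseSpec("NF1", 0.0, 3, 8)
        p2, log = train_phase(p, phase, arm_cfg, self._sampler(arm_cfg), lr=0.0)
        for k in engine.PARAM_KEYS:
            assert np.array_equal(p2.weights[k], p.weights[k])
        assert log.shape == (3,) and np.all(np.isfinite(log))

    def test_freeze_violation_raises(self, arm_cfg):
        p = init_params(6, 3)
        phase = PhaseSpec("NF1", 0.0, 2, 8)
        bad_frozen = {"Wout": p.weights["Wout"] + 1.0}
        with pytest.raises(RuntimeError, match="freeze violation"):
            train_phase(p, phase, arm_cfg, self._sampler(arm_cfg), frozen=bad_frozen)


class TestAdam:
    def test_single_step_matches_closed_form(self):
        w = {"a": np.array([1.0, 2.0])}
        g = {"a": np.array([0.5, -1.0])}
        opt = Adam(("a",), lr=0.1)
        opt.step(w, g)
        # first Adam step moves by -lr * sign(g) up to eps
        assert w["a"] == pytest.approx([1.0 - 0.1, 2.0 + 0.1], rel=1e-6)
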