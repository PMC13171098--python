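"""Composite loss and the two optimization regimes.

Growing up: Adam (lr 3e-3) on 20,000 batches of 32 random point-to-point
reaches, 50% catch trials, go cue uniform on [100, 300] ms.  Experimental
phases: plain batch-local stochastic gradient descent (lr 5e-3) on centre-out
batches, with the input map, output map, their biases and the initial hidden
state frozen — only the recurrent weights and recurrent gate biases change.

Batch counts and sizes are configurable; the defaults here are the full-scale
values, and the desk-scale preset in :func:`curladapt.fixtures.tiny_config`
reduces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import behavior, engine
from .controller import ControllerParams, Trajectory
from .effector import ArmConfig, forward_kinematics
from .engine import PLASTIC_KEYS, EpisodeBatch

__all__ = [
    "LossWeights", "EpisodeSpec", "desired_position", "compute_loss",
    "Adam", "sgd_step", "sample_random_reach_batch", "growing_up", "train_phase",
]


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the composite loss; defaults are the trained values."""

    position: float = 1e3
    jerk: float = 1e5
    muscle: float = 1e-1
    hidden: float = 1e-5
    muscle_deriv: float = 3e-3
    hidden_deriv: float = 1e2


@dataclass
class EpisodeSpec:
    """One reaching episode: start posture, target, go timing, catch flag."""

    start_theta: np.ndarray          # (2,) joint angles, rad
    target: np.ndarray               # (2,) endpoint target, m
    go_step: Optional[int] = None    # None for a catch trial
    duration: float = 1.0            # s
    dt: float = 0.01

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def catch(self) -> bool:
        return self.go_step is None or self.go_step >= self.n_steps

    def to_batch(self) -> EpisodeBatch:
        go = self.n_steps + 1 if self.go_step is None else int(self.go_step)
        return EpisodeBatch(
            start_theta=np.asarray(self.start_theta, dtype=float)[None],
            target=np.asarray(self.target, dtype=float)[None],
            go_step=np.array([go]),
            n_steps=self.n_steps,
        )


def desired_position(episode: EpisodeSpec, t: int, cfg: ArmConfig) -> np.ndarray:
    """Goal at step t: the start endpoint before the go step, target after.

    On catch trials the goal stays at the start for the whole episode.
    """
    start = forward_kinematics(np.asarray(episode.start_theta, dtype=float), cfg)
    if episode.catch or t < episode.go_step:
        return start
    return np.asarray(episode.target, dtype=float)


def compute_loss(traj: Trajectory, weights: LossWeights = LossWeights()):
    """Composite loss of a trajectory with its per-term breakdown.

    Returns ``(total, breakdown)``; both are scalars for a single-episode
    batch, otherwise they keep the trajectory's leading dims.  Raises if any
    term is non-finite, naming the first offending term.
    """
    total, breakdown = engine.loss_arrays(
        traj.endpoint, traj.muscle_forces, traj.hidden, traj.desired, weights,
    )
    for name, val in breakdown.items():
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"non-finite loss term: {name}")
    if np.ndim(total) == 0 or total.size == 1:
        return float(np.squeeze(total)), {k: float(np.squeeze(v)) for k, v in breakdown.items()}
    return total, breakdown


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction, operating on parameter dicts."""

    def __init__(self, keys, lr=3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.keys = tuple(keys)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v = {}, {}
        self.t = 0

    def step(self, weights: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k in self.keys:
            g = grads[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            weights[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sgd_step(weights: dict, grads: dict, lr: float, keys=PLASTIC_KEYS) -> None:
    """Momentum-free gradient descent on the given parameter groups only."""
    for k in keys:
        weights[k] -= lr * grads[k]


# ---------------------------------------------------------------------------
# episode sampling
# ---------------------------------------------------------------------------

def sample_random_reach_batch(rng: np.random.Generator, batch_size: int,
                              cfg: ArmConfig, n_steps: int = 100,
                              catch_fraction: float = 0.5,
                              go_range=(10, 30), margin: float = 0.15) -> EpisodeBatch:
    """Random point-to-point reaches, start/target uniform in joint space.

    Postures are drawn inside the joint limits (with a safety margin), which
    makes every sample reachable by construction.  Half the episodes are
    catch trials; on the rest the go step is uniform on ``go_range``
    (100-300 ms at the default step).
    """
    lims = np.asarray(cfg.joint_limits)
    lo, hi = lims[:, 0] + margin, lims[:, 1] - margin
    th_start = rng.uniform(lo, hi, size=(batch_size, 2))
    th_tgt = rng.uniform(lo, hi, size=(batch_size, 2))
    catch = rng.random(batch_size) < catch_fraction
    go = rng.integers(go_range[0], go_range[1] + 1, size=batch_size)
    go = np.where(catch, n_steps + 1, go)
    return EpisodeBatch(start_theta=th_start,
                        target=forward_kinematics(th_tgt, cfg),
                        go_step=go, n_steps=n_steps)


def _stack_batches(batches) -> EpisodeBatch:
    return EpisodeBatch(
        start_theta=np.stack([b.start_theta for b in batches]),
        target=np.stack([b.target for b in batches]),
        go_step=np.stack([b.go_step for b in batches]),
        n_steps=batches[0].n_steps,
    )


# ---------------------------------------------------------------------------
# optimization regimes
# ---------------------------------------------------------------------------

def growing_up(params: ControllerParams, cfg: ArmConfig,
               seed, n_batches: int = 20000, batch_size: int = 32,
               lr: float = 3e-3, weights: LossWeights = LossWeights(),
               n_steps: int = 100,
               progress: Optional[Callable[[int, np.ndarray], None]] = None):
    """Adam training on random reaches; returns (params, per-batch loss log).

    ``seed`` is an int for unbatched parameters or a sequence of ints matching
    the leading ensemble axis (one independent episode stream per seed).
    Divergence (non-finite loss) aborts with the batch index.
    """
    params = params.copy()
    lead = params.lead_shape
    if lead:
        seeds = list(seed)
        if len(seeds) != lead[0]:
            raise ValueError("need one seed per ensemble member")
        rngs = [np.random.default_rng([s, 11]) for s in seeds]
    else:
        rngs = [np.random.default_rng([int(seed), 11])]
    opt = Adam(engine.PARAM_KEYS, lr=lr)
    log = np.empty((n_batches,) + lead)
    for i in range(n_batches):
        batches = [sample_random_reach_batch(r, batch_size, cfg, n_steps=n_steps)
                   for r in rngs]
        eps = batches[0] if not lead else _stack_batches(batches)
        total, _, grads, _ = engine.loss_and_grad(params.weights, eps, cfg, weights)
        if not np.all(np.isfinite(total)):
            raise FloatingPointError(f"growing-up loss diverged at batch {i}")
        opt.step(params.weights, grads)
        log[i] = total
        if progress is not None:
            progress(i, total)
    return params, log


def train_phase(params: ControllerParams, phase, cfg: ArmConfig,
                batch_sampler: Callable[[int], EpisodeBatch],
                frozen: Optional[dict] = None,
                lr: float = 5e-3, weights: LossWeights = LossWeights()):
    """One experimental phase: batch-local SGD on the recurrent cell only.

    ``phase`` provides the field gain ``b`` and batch count ``n_batches``;
    ``batch_sampler(i)`` yields the i-th episode batch.  Only the parameter
    groups in :data:`curladapt.engine.PLASTIC_KEYS` are updated; if a frozen
    snapshot is supplied it is re-verified afterwards and any drift is a hard
    failure.  Returns ``(params, deviation_log)`` where the log holds, per
    batch, the mean clockwise-signed lateral deviation of the batch's
    non-catch reaches measured *before* that batch's update (entry 0 is the
    phase's batch-0 performance).
    """
    params = params.copy()
    check = frozen if frozen is not None else params.frozen_values()
    n_batches = int(phase.n_batches)
    b = float(phase.b)
    lead = params.lead_shape
    log = np.empty((n_batches,) + lead)
    for i in range(n_batches):
        eps = batch_sampler(i)
        total, _, grads, cache = engine.loss_and_grad(params.weights, eps, cfg, weights, b=b)
        if not np.all(np.isfinite(total)):
            raise FloatingPointError(f"phase {getattr(phase, 'name', '?')} diverged at batch {i}")
        log[i] = _batch_deviation(cache, eps, cfg)
        sgd_step(params.weights, grads, lr)
    for k, v in check.items():
        if not np.array_equal(params.weights[k], v):
            raise RuntimeError(f"freeze violation: parameter {k} changed during phase")
    return params, log


def _batch_deviation(cache: dict, eps: EpisodeBatch, cfg: ArmConfig) -> np.ndarray:
    """Mean CW-signed lateral deviation over the non-catch episodes."""
    dev = behavior.lateral_deviation_paths(
        cache["P"], eps.start_position(cfg), eps.target, eps.go_step)
    keep = ~eps.catch
    return np.sum(np.where(keep, dev, 0.0), axis=-1) / np.maximum(keep.sum(axis=-1), 1)
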