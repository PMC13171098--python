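"""GRU policy mapping delayed observations to muscle stimulation commands.

The controller is a single layer of fully connected gated recurrent units.
Its 17-dimensional observation is ``[target_x, target_y, go, endpoint_x,
endpoint_y, len_1..6, vel_1..6]``: the target coordinates are undelayed task
input, the go cue and endpoint feedback pass through a 7-step (70 ms) visual
queue, and the normalized muscle lengths/velocities through a 2-step (20 ms)
proprioceptive queue.  Output is ``sigmoid(W_out h + b_out)``, six stimulation
commands strictly inside (0, 1).

The GRU follows the convention in which the reset gate scales the candidate's
recurrent pre-activation, n = tanh(W_in x + b_in + r * (W_hn h + b_hn)), with
separate input-side and recurrent-side gate biases and the three gates fused
into single weight blocks (order: update, reset, candidate).  After the
growing-up phase only the recurrent weights and recurrent gate biases remain
plastic (see :data:`curladapt.engine.PLASTIC_KEYS`).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import engine
from .effector import ArmConfig, ArmState, CurlField
from .engine import (
    PARAM_KEYS,
    PLASTIC_KEYS,
    PROPRIO_DELAY_STEPS,
    VISUAL_DELAY_STEPS,
    EpisodeBatch,
    Hook,
)

OBS_DIM = 17
N_MUSCLES = 6


@dataclass
class ControllerParams:
    """All trainable quantities of the policy.

    Arrays may carry a leading ensemble axis (one slice per seed); the public
    constructors produce unbatched parameters and :func:`stack_params` builds
    an ensemble.
    """

    weights: dict  # name -> ndarray, keys = engine.PARAM_KEYS

    @property
    def n_units(self) -> int:
        return self.weights["h0"].shape[-1]

    @property
    def lead_shape(self):
        return self.weights["h0"].shape[:-1]

    def copy(self) -> "ControllerParams":
        return ControllerParams({k: v.copy() for k, v in self.weights.items()})

    def __getitem__(self, i) -> "ControllerParams":
        return ControllerParams({k: v[i] for k, v in self.weights.items()})

    def frozen_values(self) -> dict:
        """Snapshot of the parameter groups frozen after growing up."""
        return {k: self.weights[k].copy() for k in PARAM_KEYS if k not in PLASTIC_KEYS}

    def save(self, path) -> None:
        np.savez(path, **self.weights,
                 _plastic=np.array(",".join(PLASTIC_KEYS)),
                 _shapes=np.array(str({k: v.shape for k, v in self.weights.items()})))

    @classmethod
    def load(cls, path) -> "ControllerParams":
        with np.load(path, allow_pickle=False) as z:
            return cls({k: z[k] for k in PARAM_KEYS})


def stack_params(params_list) -> ControllerParams:
    """Stack single-network parameters into an ensemble along a new axis 0."""
    return ControllerParams({
        k: np.stack([p.weights[k] for p in params_list])
        for k in PARAM_KEYS
    })


def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def _orthogonal(rng, n):
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def init_params(n_units: int, seed: int) -> ControllerParams:
    """Freshly initialized policy parameters, deterministic given the seed.

    Input maps are Glorot-initialized, recurrent maps orthogonal, all gate
    biases zero, the output bias -5.0 (so initial stimulation is near zero),
    and the learnable initial hidden state zero.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    rng = np.random.default_rng(seed)
    w = {
        "Wi": np.concatenate([_glorot(rng, OBS_DIM, n_units) for _ in range(3)], axis=1),
        "Wh": np.concatenate([_orthogonal(rng, n_units) for _ in range(3)], axis=1),
        "bi": np.zeros(3 * n_units),
        "bh": np.zeros(3 * n_units),
        "Wout": _glorot(rng, n_units, N_MUSCLES),
        "bout": np.full(N_MUSCLES, -5.0),
        "h0": np.zeros(n_units),
    }
    return ControllerParams(w)


# ---------------------------------------------------------------------------
# single-step public API
# ---------------------------------------------------------------------------

class DelayBuffer:
    """Fixed-depth visual and proprioceptive queues.

    Before a queue fills it yields the pre-trial value it was primed with.
    """

    def __init__(self, initial_visual, initial_proprio,
                 visual_depth: int = VISUAL_DELAY_STEPS,
                 proprio_depth: int = PROPRIO_DELAY_STEPS):
        self.visual = deque([np.asarray(initial_visual, dtype=float)] * (visual_depth + 1),
                            maxlen=visual_depth + 1)
        self.proprio = deque([np.asarray(initial_proprio, dtype=float)] * (proprio_depth + 1),
                             maxlen=proprio_depth + 1)

    def push(self, visual, proprio) -> None:
        self.visual.append(np.asarray(visual, dtype=float))
        self.proprio.append(np.asarray(proprio, dtype=float))

    def delayed_visual(self) -> np.ndarray:
        return self.visual[0]

    def delayed_proprio(self) -> np.ndarray:
        return self.proprio[0]


def assemble_input(target, go_raw, buffers: DelayBuffer, state: ArmState, t: int) -> np.ndarray:
    """Build the 17-entry observation for step t from the delay queues.

    ``go_raw`` is the *raw* go schedule (indexable by step); the cue the
    network sees is the 7-step delayed value bundled in the visual queue
    (entry 0 of the delayed visual sample).
    """
    vis = buffers.delayed_visual()       # [go, px, py] at t - 7
    prop = buffers.delayed_proprio()     # [ln(6), vn(6)] at t - 2
    return np.concatenate([np.asarray(target, dtype=float), vis, prop])


def forward_step(params: ControllerParams, h: np.ndarray, obs: np.ndarray):
    """One GRU update and output readout: (h', stimulation).

    Gate blocks are ordered (update z, reset r, candidate n) inside the fused
    weight matrices; the reset gate scales the candidate's recurrent
    pre-activation.
    """
    w = params.weights
    n = params.n_units
    gi = obs @ w["Wi"] + w["bi"]
    gh = h @ w["Wh"] + w["bh"]
    z = engine._sig(gi[..., :n] + gh[..., :n])
    r = engine._sig(gi[..., n:2 * n] + gh[..., n:2 * n])
    nc = np.tanh(gi[..., 2 * n:] + r * gh[..., 2 * n:])
    h1 = (1.0 - z) * nc + z * h
    if not np.all(np.isfinite(h1)):
        raise FloatingPointError("non-finite hidden state after GRU step")
    u = engine._sig(h1 @ w["Wout"] + w["bout"])
    return h1, u


# ---------------------------------------------------------------------------
# trajectories and rollouts
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Per-step time series of one (batch of) closed-loop episode(s).

    Time axis first.  State sequences (``joint_angles``, ``hidden``,
    ``endpoint`` ...) have ``n_steps + 1`` samples including the initial
    state; commands/forces/observations have ``n_steps`` samples.
    """

    joint_angles: np.ndarray     # (T+1, ..., 2)
    joint_velocities: np.ndarray
    activations: np.ndarray      # (T+1, ..., 6)
    hidden: np.ndarray           # (T+1, ..., n)
    endpoint: np.ndarray         # (T+1, ..., 2)
    muscle_lengths: np.ndarray   # (T+1, ..., 6)
    muscle_velocities: np.ndarray
    stimulation: np.ndarray      # (T, ..., 6)
    muscle_forces: np.ndarray    # (T, ..., 6)
    observations: np.ndarray     # (T, ..., 17)
    desired: np.ndarray          # (T, ..., 2) goal from step 1..T
    go_step: np.ndarray
    target: np.ndarray
    start_position: np.ndarray
    field_gain: float
    dt: float

    @property
    def n_steps(self) -> int:
        return self.stimulation.shape[0]

    @classmethod
    def from_cache(cls, cache: dict, eps: EpisodeBatch, cfg: ArmConfig,
                   b: float) -> "Trajectory":
        return cls(
            joint_angles=cache["TH"], joint_velocities=cache["OM"],
            activations=cache["A"], hidden=cache["H"], endpoint=cache["P"],
            muscle_lengths=cache["LN"], muscle_velocities=cache["VN"],
            stimulation=cache["U"], muscle_forces=cache["F"],
            observations=cache["OBS"],
            desired=engine.desired_positions(eps, cfg),
            go_step=np.asarray(eps.go_step), target=np.asarray(eps.target),
            start_position=eps.start_position(cfg), field_gain=b, dt=cfg.dt,
        )


def rollout(params: ControllerParams, episode, cfg: ArmConfig,
            fld: CurlField = CurlField(0.0), hook: Optional[Hook] = None) -> Trajectory:
    """Closed-loop simulation of one episode batch.

    ``episode`` is an :class:`curladapt.engine.EpisodeBatch` or anything with
    a ``to_batch()`` method (e.g. :class:`curladapt.training.EpisodeSpec`).
    The optional hook edits the hidden state at exactly one declared step
    before the controller reads it.
    """
    eps = episode if isinstance(episode, EpisodeBatch) else episode.to_batch()
    cache = engine.simulate(params.weights, eps, cfg, b=fld.b, hook=hook)
    return Trajectory.from_cache(cache, eps, cfg, fld.b)
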