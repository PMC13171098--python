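"""Causal probe: inject the uniform shift into preparatory activity.

At the preparatory sample time (340 ms before the go cue) the hidden state is
displaced by m * us for magnitudes m in {-2, -1, 0, 1, 2}, for exactly one
simulation step, separately for each movement direction, on the network as it
stands at FF2 batch 0 (adapted, washed out, not yet re-trained).  Negative
magnitudes deplete the residual learning trace and should raise the lateral
deviation back toward naive (FF1 batch-0) levels; positive magnitudes deepen
the trace and should reduce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior
from .controller import ControllerParams, Trajectory, rollout
from .effector import ArmConfig, CurlField
from .engine import Hook
from .neural_analysis import UniformShift

__all__ = ["PerturbationSpec", "perturbed_rollout", "perturbation_experiment",
           "PREP_OFFSET_STEPS"]

#: preparatory sample time relative to the go cue, in steps (340 ms at 10 ms)
PREP_OFFSET_STEPS = 34

DEFAULT_MAGNITUDES = (-2.0, -1.0, 0.0, 1.0, 2.0)


@dataclass
class PerturbationSpec:
    """Direction, magnitude and timing of a one-step hidden-state injection."""

    direction: np.ndarray        # (n,) unit-space vector (the uniform shift)
    magnitude: float
    step: int                    # application step (go - 340 ms)
    duration_steps: int = 1      # fixed; the injection lasts one step

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        if self.duration_steps != 1:
            raise ValueError("the injection duration is fixed at one step")


def perturbed_rollout(params: ControllerParams, episode, cfg: ArmConfig,
                      fld: CurlField, spec: PerturbationSpec) -> Trajectory:
    """Rollout with h <- h + m*us at the declared step, before the GRU reads h.

    With magnitude 0 the trajectory is bit-identical to the unperturbed one.
    """
    eps = episode if not hasattr(episode, "to_batch") else episode.to_batch()
    if spec.step < 0 or spec.step >= eps.n_steps:
        raise ValueError(f"application step {spec.step} outside the episode")
    delta = spec.magnitude * spec.direction
    hook = Hook(step=spec.step, edit=lambda h: h + delta)
    return rollout(params, eps, cfg, fld, hook=hook)


def perturbation_experiment(params: ControllerParams, us: UniformShift,
                            task, cfg: ArmConfig,
                            magnitudes: Sequence[float] = DEFAULT_MAGNITUDES,
                            b: float = 8.0,
                            go_step: int = None, n_steps: int = None) -> pd.DataFrame:
    """Dose-response of lateral deviation to uniform-shift injections.

    ``params`` is the FF2 batch-0 checkpoint (post-washout, pre-retraining)
    and ``us`` that network's own NF1->FF1 uniform shift.  One evaluation
    rollout per (magnitude, target) in the trained field.  Returns a tidy
    table with columns magnitude, target, deviation_cw, deviation_field
    (metres; the field-direction sign is the paper-style positive-adaptation
    convention).
    """
    if us is None or params is None:
        raise ValueError("need both a checkpoint and a uniform shift")
    from .protocol import EvalSpec  # default timing

    ev = EvalSpec()
    go = ev.go_step if go_step is None else go_step
    T = ev.n_steps if n_steps is None else n_steps
    step = go - PREP_OFFSET_STEPS
    if step < 0:
        raise ValueError("go cue too early for a 340 ms preparatory injection")
    from .protocol import CentreOutTask

    task = task or CentreOutTask()
    eps = task.evaluation_batch(go_step=go, n_steps=T)
    rows = []
    for m in magnitudes:
        spec = PerturbationSpec(direction=us.us, magnitude=float(m), step=step)
        traj = perturbed_rollout(params, eps, cfg, CurlField(b), spec)
        dev = behavior.lateral_deviation_paths(
            traj.endpoint, traj.start_position, traj.target, traj.go_step)
        for k in range(dev.shape[-1]):
            rows.append(dict(magnitude=float(m), target=k,
                             deviation_cw=float(dev[k]),
                             deviation_field=float(behavior.field_direction(dev[k], b))))
    return pd.DataFrame(rows)
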