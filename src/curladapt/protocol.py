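"""Experiment orchestration: growing up, NF1 -> FF1 -> NF2 -> FF2, controls.

The protocol mirrors a classical force-field savings design: a long baseline
block of centre-out reaching in the null field (NF1), adaptation to a
velocity-dependent curl field (FF1), washout back in the null field (NF2),
and re-exposure to the same field (FF2).  The opposite-field control runs
FF1 with the negated gain and FF2 with the trained gain, so any FF2 advantage
specific to prior *same-field* learning disappears.  At no point does any
observation entry encode the field's presence — context-freeness is
structural (the observation vector is built from target, go cue and delayed
feedback only; no code path reads the gain).

Seeds are vectorized: the whole ensemble (one network per seed) trains in a
single pass, so every logged number is reproducible bit-for-bit from the
config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import yaml

from . import behavior, engine, training
from .controller import ControllerParams, Trajectory, init_params, rollout, stack_params
from .effector import ArmConfig, CurlField, endpoint_force_arrays, forward_kinematics
from .engine import EpisodeBatch
from .neural_analysis import ForceMatrix, PrepActivityMatrix
from .perturbation import PREP_OFFSET_STEPS

__all__ = [
    "PhaseSpec", "CentreOutTask", "EvalSpec", "ExperimentConfig",
    "ExperimentRecord", "centre_out_batch", "run_experiment",
    "run_full_study", "evaluation_rollouts",
]

PHASE_ORDER = ("NF1", "FF1", "NF2", "FF2")

#: endpoint-force sample time after the go cue, steps (90 ms at 10 ms)
FORCE_OFFSET_STEPS = 9


@dataclass(frozen=True)
class PhaseSpec:
    """One experimental phase: name, field gain and training extent."""

    name: str
    b: float
    n_batches: int
    batch_size: int = 32

    def __post_init__(self):
        if self.name.startswith("NF") and self.b != 0.0:
            raise ValueError("null-field phases must have b = 0")


@dataclass(frozen=True)
class CentreOutTask:
    """Eight equidistant targets on a 0.1 m circle around the start endpoint.

    The start posture is shoulder 60 deg, elbow 90 deg; target 0 lies along
    +x of the workspace frame and targets are numbered counter-clockwise.
    """

    start_theta: tuple = (np.pi / 3.0, np.pi / 2.0)
    n_targets: int = 8
    radius: float = 0.10

    def start_position(self, cfg: ArmConfig) -> np.ndarray:
        return forward_kinematics(np.asarray(self.start_theta), cfg)

    def target_positions(self, cfg: ArmConfig) -> np.ndarray:
        ang = 2.0 * np.pi * np.arange(self.n_targets) / self.n_targets
        return self.start_position(cfg) + self.radius * np.stack(
            [np.cos(ang), np.sin(ang)], axis=1)

    def evaluation_batch(self, go_step: int, n_steps: int,
                         cfg: Optional[ArmConfig] = None) -> EpisodeBatch:
        """One non-catch episode per target with a fixed late go cue."""
        cfg = cfg or ArmConfig()
        tgts = self.target_positions(cfg)
        k = self.n_targets
        return EpisodeBatch(
            start_theta=np.tile(np.asarray(self.start_theta), (k, 1)),
            target=tgts, go_step=np.full(k, go_step), n_steps=n_steps)


@dataclass(frozen=True)
class EvalSpec:
    """Timing of analysis rollouts.

    Training episodes (1 s, go before 300 ms) cannot host a sample 340 ms
    before the go cue, so analysis uses dedicated longer episodes: 1.5 s with
    the go cue at 0.5 s, leaving the preparatory sample at step 16 with the
    hidden state settled.
    """

    n_steps: int = 150
    go_step: int = 50

    def __post_init__(self):
        if self.go_step - PREP_OFFSET_STEPS < 0:
            raise ValueError("go cue earlier than the 340 ms preparatory sample")


def centre_out_batch(task: CentreOutTask, size: int, catch_fraction: float,
                     rng: np.random.Generator, cfg: ArmConfig,
                     n_steps: int = 100, go_range=(10, 30)) -> EpisodeBatch:
    """A training batch with size/8 repetitions of each of the 8 targets.

    Order is shuffled; each episode is independently a catch trial with the
    given probability, and non-catch go steps are uniform on go_range.
    """
    if size % task.n_targets:
        raise ValueError("batch size must be divisible by the number of targets")
    reps = size // task.n_targets
    tgts = np.tile(task.target_positions(cfg), (reps, 1))
    order = rng.permutation(size)
    tgts = tgts[order]
    catch = rng.random(size) < catch_fraction
    go = rng.integers(go_range[0], go_range[1] + 1, size=size)
    go = np.where(catch, n_steps + 1, go)
    return EpisodeBatch(
        start_theta=np.tile(np.asarray(task.start_theta), (size, 1)),
        target=tgts, go_step=go, n_steps=n_steps)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end-to-end.

    Defaults are the full-scale protocol (128 units, 20,000 growing-up
    batches of 32, NF phases 10,000 batches, FF phases 3,200, field gain
    8 N s/m); :func:`curladapt.fixtures.tiny_config` supplies the desk-scale
    preset used by the tests and the analysis scripts.
    """

    n_units: int = 128
    seeds: Sequence[int] = tuple(range(40))
    gu_batches: int = 20000
    gu_batch_size: int = 32
    phase_batches: Dict[str, int] = field(default_factory=lambda: {
        "NF1": 10000, "FF1": 3200, "NF2": 10000, "FF2": 3200})
    phase_batch_size: int = 32
    field_gain: float = 8.0
    condition: str = "main"            # "main" or "control" (opposite FF1)
    lr_gu: float = 3e-3
    lr_phase: float = 5e-3
    catch_fraction: float = 0.5
    episode_steps: int = 100
    go_range: tuple = (10, 30)
    arm: ArmConfig = field(default_factory=ArmConfig)
    loss: training.LossWeights = field(default_factory=training.LossWeights)
    task: CentreOutTask = field(default_factory=CentreOutTask)
    eval: EvalSpec = field(default_factory=EvalSpec)

    def phases(self, condition: Optional[str] = None):
        cond = condition or self.condition
        ff1 = -self.field_gain if cond == "control" else self.field_gain
        gains = {"NF1": 0.0, "FF1": ff1, "NF2": 0.0, "FF2": self.field_gain}
        return [PhaseSpec(nm, gains[nm], self.phase_batches[nm], self.phase_batch_size)
                for nm in PHASE_ORDER]

    # -- structured-file round trip ------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["seeds"] = list(map(int, d["seeds"]))
        for key in ("arm", "loss", "task", "eval"):
            d[key] = {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in d[key].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        def _tuplify(dd):
            return {k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                        if isinstance(v, list) else v) for k, v in dd.items()}
        d["arm"] = ArmConfig(**_tuplify(d["arm"]))
        d["loss"] = training.LossWeights(**d["loss"])
        d["task"] = CentreOutTask(**_tuplify(d["task"]))
        d["eval"] = EvalSpec(**d["eval"])
        d["seeds"] = tuple(d["seeds"])
        for k in ("phase_batches",):
            d[k] = dict(d[k])
        d["go_range"] = tuple(d["go_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class ExperimentRecord:
    """Everything logged while running one condition across the seed ensemble.

    ``checkpoints`` holds the parameter ensemble after growing up and after
    each phase; ``curves`` the per-batch CW-signed lateral deviation per seed;
    ``eval`` the end-of-phase evaluation rollouts (hidden activity at full
    resolution).  ``curves_field`` converts to the field-direction sign.
    """

    config: ExperimentConfig
    condition: str
    checkpoints: Dict[str, ControllerParams]
    curves: Dict[str, np.ndarray]            # phase -> (n_batches, S)
    eval: Dict[str, Trajectory]              # phase -> batched trajectory (S, 8)
    gu_loss: Optional[np.ndarray] = None     # (gu_batches, S)

    @property
    def n_seeds(self) -> int:
        return len(self.config.seeds)

    def phase_gain(self, name: str) -> float:
        return next(p.b for p in self.config.phases(self.condition) if p.name == name)

    def curves_field(self, name: str) -> np.ndarray:
        """Learning curve in the field's push direction, shape (n_batches, S).

        FF phases use their own gain (so the control's opposite field also
        yields positive decaying curves); NF phases use the trained gain, so
        the NF2 after-effect shows up negative (opposite the trained push).
        """
        b = self.phase_gain(name)
        if b == 0.0:
            b = self.config.field_gain
        return behavior.field_direction(self.curves[name], b)

    # -- neural-analysis inputs ----------------------------------------
    def prep_matrices(self, seed_idx: int) -> Dict[str, PrepActivityMatrix]:
        """Per-phase preparatory activity (8 targets x units) for one seed,
        sampled 340 ms before the go cue of the evaluation rollouts."""
        s_prep = self.config.eval.go_step - PREP_OFFSET_STEPS
        return {ph: PrepActivityMatrix(self.eval[ph].hidden[s_prep, seed_idx], phase=ph)
                for ph in PHASE_ORDER}

    def force_matrix(self, seed_idx: int, phase: str = "NF1") -> ForceMatrix:
        """Muscle-generated endpoint force (8 x 2) 90 ms after the go cue."""
        t_f = self.config.eval.go_step + FORCE_OFFSET_STEPS
        traj = self.eval[phase]
        F = endpoint_force_arrays(traj.joint_angles[t_f, seed_idx],
                                  traj.muscle_forces[t_f, seed_idx],
                                  self.config.arm)
        return ForceMatrix(F, phase=phase)

    def batch0_deviation(self, phase: str) -> np.ndarray:
        """Per-seed mean deviation of the phase's first batch (field sign)."""
        return self.curves_field(phase)[0]

    def save(self, prefix) -> None:
        """Persist curves/checkpoints/eval activity as array archives plus a
        YAML manifest of shapes next to them."""
        arrays = {}
        for ph, c in self.curves.items():
            arrays[f"curve_{ph}"] = c
        for nm, p in self.checkpoints.items():
            for k, v in p.weights.items():
                arrays[f"ckpt_{nm}_{k}"] = v
        for ph, tr in self.eval.items():
            arrays[f"eval_{ph}_hidden"] = tr.hidden
            arrays[f"eval_{ph}_endpoint"] = tr.endpoint
        if self.gu_loss is not None:
            arrays["gu_loss"] = self.gu_loss
        np.savez_compressed(f"{prefix}_record.npz", **arrays)
        self.config.to_yaml(f"{prefix}_config.yaml")
        with open(f"{prefix}_manifest.yaml", "w") as fh:
            yaml.safe_dump({k: list(v.shape) for k, v in arrays.items()}, fh)


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------

def evaluation_rollouts(params: ControllerParams, task: CentreOutTask,
                        fld: CurlField, cfg: ArmConfig,
                        ev: EvalSpec = EvalSpec()) -> Trajectory:
    """Noise-free non-catch rollouts, one per target, with a fixed late go cue.

    For an ensemble the episode batch is broadcast across the leading axis.
    Preparatory activity (at go - 340 ms) is well-defined and settled; two
    calls with the same checkpoint return identical trajectories.
    """
    eps = task.evaluation_batch(ev.go_step, ev.n_steps, cfg)
    lead = params.lead_shape
    if lead:
        S = lead[0]
        eps = EpisodeBatch(
            start_theta=np.broadcast_to(eps.start_theta, (S,) + eps.start_theta.shape).copy(),
            target=np.broadcast_to(eps.target, (S,) + eps.target.shape).copy(),
            go_step=np.broadcast_to(eps.go_step, (S,) + eps.go_step.shape).copy(),
            n_steps=eps.n_steps)
    return rollout(params, eps, cfg, fld)


def _phase_sampler(config: ExperimentConfig, phase: PhaseSpec, lead: bool):
    """Deterministic per-batch episode stream for one phase."""
    pidx = PHASE_ORDER.index(phase.name)
    if lead:
        rngs = [np.random.default_rng([int(s), 23, pidx]) for s in config.seeds]
        def sampler(i):
            return training._stack_batches([
                centre_out_batch(config.task, phase.batch_size, config.catch_fraction,
                                 r, config.arm, config.episode_steps, config.go_range)
                for r in rngs])
    else:
        rng = np.random.default_rng([int(config.seeds[0]), 23, pidx])
        def sampler(i):
            return centre_out_batch(config.task, phase.batch_size, config.catch_fraction,
                                    rng, config.arm, config.episode_steps, config.go_range)
    return sampler


def grow_ensemble(config: ExperimentConfig):
    """Initialize and grow up the seed ensemble; returns (params, loss log)."""
    ens = stack_params([init_params(config.n_units, s) for s in config.seeds])
    return training.growing_up(
        ens, config.arm, seed=list(config.seeds), n_batches=config.gu_batches,
        batch_size=config.gu_batch_size, lr=config.lr_gu, weights=config.loss,
        n_steps=config.episode_steps)


def _run_phases(params: ControllerParams, config: ExperimentConfig,
                condition: str, gu_loss=None,
                skip: Dict[str, tuple] = None) -> ExperimentRecord:
    """Run the four phases from a post-growing-up ensemble.

    ``skip`` maps phase names to precomputed (params, curve, eval) triples so
    the shared NF1 block of the opposite-field control is not recomputed.
    """
    frozen = params.frozen_values()
    checkpoints = {"grown": params.copy()}
    curves, evals = {}, {}
    for phase in config.phases(condition):
        if skip and phase.name in skip:
            params, curve, ev_traj = skip[phase.name]
            params = params.copy()
        else:
            sampler = _phase_sampler(config, phase, bool(params.lead_shape))
            params, curve = training.train_phase(
                params, phase, config.arm, sampler, frozen=frozen,
                lr=config.lr_phase, weights=config.loss)
            ev_traj = evaluation_rollouts(params, config.task, CurlField(phase.b),
                                          config.arm, config.eval)
        checkpoints[phase.name] = params.copy()
        curves[phase.name] = curve
        evals[phase.name] = ev_traj
    return ExperimentRecord(config=config, condition=condition,
                            checkpoints=checkpoints, curves=curves,
                            eval=evals, gu_loss=gu_loss)


def run_experiment(config: ExperimentConfig) -> ExperimentRecord:
    """Grow up the ensemble, then run NF1/FF1/NF2/FF2 for one condition."""
    params, gu_log = grow_ensemble(config)
    return _run_phases(params, config, config.condition, gu_loss=gu_log)


def run_full_study(config: ExperimentConfig):
    """Main + opposite-field control, sharing growing up and NF1.

    NF1 contains no field, so both conditions are identical through its end;
    the branch point is the start of FF1.  Returns {"main": record,
    "control": record}.
    """
    params, gu_log = grow_ensemble(config)
    main = _run_phases(params, config, "main", gu_loss=gu_log)
    shared = {"NF1": (main.checkpoints["NF1"], main.curves["NF1"], main.eval["NF1"])}
    control = _run_phases(params, config, "control", gu_loss=gu_log, skip=shared)
    return {"main": main, "control": control}
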