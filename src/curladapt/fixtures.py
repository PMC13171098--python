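"""Synthetic-data generators with known ground truth.

These give every analysis stage an oracle without a training run: planted
preparatory-activity matrices whose force-predictive plane, uniform shift and
washout fraction are known by construction; arc paths with known signed
lateral deviation; exponential learning curves with known (alpha, r); and the
desk-scale experiment preset.  All generators are deterministic given their
(truth, seed) arguments and emit the same containers the real pipeline uses,
so analysis code cannot tell them from trained-network data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import LearningCurve
from .neural_analysis import ForceMatrix, PrepActivityMatrix

__all__ = [
    "PlantedActivityTruth", "synth_prep_activity", "synth_trajectory",
    "synth_learning_curve", "tiny_config",
]

PHASES = ("NF1", "FF1", "NF2", "FF2")


@dataclass
class PlantedActivityTruth:
    """Ground truth for planted preparatory activity.

    ``M`` (2 x units) maps early forces into unit space, ``c`` is the
    intercept, ``s`` the planted uniform shift (kept orthogonal to the force
    readout plane by construction), ``w`` the residual washout fraction in
    [0, 1] (0 = full washout), ``sigma`` the noise scale relative to the
    signal norm.
    """

    M: np.ndarray
    c: np.ndarray
    s: np.ndarray
    w: float = 0.3
    sigma: float = 0.0
    seed: int = 0

    @classmethod
    def random(cls, n_units: int, w: float = 0.3, sigma: float = 0.0,
               seed: int = 0, shift_scale: float = 1.0) -> "PlantedActivityTruth":
        if n_units < 4:
            raise ValueError("need at least 4 units")
        rng = np.random.default_rng([seed, 101])
        M = rng.standard_normal((2, n_units))
        c = rng.standard_normal(n_units)
        s = rng.standard_normal(n_units)
        # orthogonalize the planted shift against the readout rows AND the
        # intercept: the fitted force-predictive plane lives inside
        # span{M rows, c}, so this keeps the shift exactly outside it
        q, _ = np.linalg.qr(np.column_stack([M.T, c]))
        s = s - q @ (q.T @ s)
        s *= shift_scale / np.linalg.norm(s)
        return cls(M=M, c=c, s=s, w=w, sigma=sigma, seed=seed)


def synth_prep_activity(truth: PlantedActivityTruth, n_targets: int = 8,
                        force_scale: float = 3.0):
    """Planted phase activity matrices + the NF1 force matrix.

    Construction: F rows are force_scale * (cos, sin) of the 8 target angles;
    H_NF1 = [F 1][M; c] + noise; H_FF1 adds the planted shift to every row;
    H_NF2 retains fraction ``w`` of it; H_FF2 equals H_FF1.  Noise is i.i.d.
    Gaussian with sd sigma * ||signal|| / sqrt(size).
    """
    rng = np.random.default_rng([truth.seed, 202])
    ang = 2.0 * np.pi * np.arange(n_targets) / n_targets
    F = force_scale * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    X = np.column_stack([F, np.ones(n_targets)])
    base = X @ np.vstack([truth.M, truth.c])
    sd = truth.sigma * np.linalg.norm(base) / np.sqrt(base.size)
    ones = np.ones((n_targets, 1))
    mats = {
        "NF1": base,
        "FF1": base + ones * truth.s,
        "NF2": base + truth.w * (ones * truth.s),
        "FF2": base + ones * truth.s,
    }
    out = {ph: PrepActivityMatrix(H + sd * rng.standard_normal(H.shape), phase=ph)
           for ph, H in mats.items()}
    return out, ForceMatrix(F), truth


def synth_trajectory(start, target, offset: float, n_samples: int = 60) -> np.ndarray:
    """Smooth arc from start to target whose peak signed lateral excursion
    (clockwise positive) equals ``offset``.

    Returns a (n_samples, 2) path; the perpendicular bump is a half-sine, so
    the maximum |perpendicular distance| is exactly |offset| at the midpoint.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    u = target - start
    L = np.linalg.norm(u)
    if L == 0:
        raise ValueError("degenerate chord")
    u_hat = u / L
    # clockwise unit normal in the y-up frame
    n_cw = np.array([u_hat[1], -u_hat[0]])
    ts = np.linspace(0.0, 1.0, n_samples)
    along = start + ts[:, None] * u
    bump = offset * np.sin(np.pi * ts)[:, None] * n_cw
    return along + bump


def synth_learning_curve(alpha: float, r: float, sigma: float,
                         n_batches: int, seed: int = 0,
                         phase: str = "") -> LearningCurve:
    """y_n = alpha * exp(-r n / 1000) + N(0, sigma), n = 0..n_batches-1."""
    if n_batches < 10:
        raise ValueError("need at least 10 batches")
    rng = np.random.default_rng([seed, 303])
    x = np.arange(n_batches)
    y = alpha * np.exp(-r * x / 1000.0) + sigma * rng.standard_normal(n_batches)
    return LearningCurve(deviation=y, phase=phase, batch=x)


def tiny_config():
    """Desk-scale experiment preset (see docs/methods.md for the rationale).

    Reduces the unit count, batch counts and batch sizes so the full
    four-phase protocol plus the opposite-field control runs on one CPU in
    minutes; every hyperparameter not explicitly reduced (time step, episode
    length, delays, loss weights, learning rates, field gain, catch fraction,
    go-cue window, target layout) keeps its full-scale value.
    """
    from .protocol import ExperimentConfig  # local import to avoid a cycle

    return ExperimentConfig(
        n_units=48,
        seeds=(0, 1, 2, 3, 4),
        gu_batches=2600,
        gu_batch_size=16,
        phase_batches={"NF1": 400, "FF1": 320, "NF2": 800, "FF2": 320},
        phase_batch_size=16,
    )
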