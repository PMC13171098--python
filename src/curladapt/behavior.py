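"""Behavioral metrics: lateral deviation, learning-rate fits, savings.

Sign convention.  ``lateral_deviation`` is the maximum perpendicular distance
of the endpoint path from the straight start-to-target segment, over the
samples after the go cue, signed positive when the excursion is *clockwise*
of the segment in the y-up workspace frame (negative z-component of
``cross(target - start, point - start)``).  The trained curl field (gain
b = +8 with the verbatim rotation matrix) deflects reaches counter-clockwise
in this frame, so the protocol layer reports learning curves in the *field's*
direction, ``d_field = -sign(b) * d_cw``, which makes adaptation curves
positive and decaying as in the usual presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "LearningCurve", "ExpFit", "lateral_deviation", "lateral_deviation_paths",
    "field_direction", "smooth_curve", "fit_learning_curve",
    "classify_savings", "savings_rate", "paired_t",
]


@dataclass
class LearningCurve:
    """Per-batch mean signed lateral deviation (metres) for one phase."""

    deviation: np.ndarray
    phase: str = ""
    batch: np.ndarray = None

    def __post_init__(self):
        self.deviation = np.asarray(self.deviation, dtype=float)
        if self.batch is None:
            self.batch = np.arange(self.deviation.size)


@dataclass
class ExpFit:
    """Exponential decay fit y = alpha * exp(-r * x / 1000).

    ``alpha`` is in metres; ``r`` is the decay rate per 1000 batches (the
    learning rate).  ``converged`` is False when the optimizer failed and the
    values are the diagnostic best-so-far.
    """

    alpha: float
    r: float
    residual: float
    converged: bool = True


def lateral_deviation(traj_or_path, start, target, go_step=None) -> float:
    """Signed maximum lateral deviation of one reach, metres.

    Accepts a ``Trajectory`` (single episode) or a bare ``(T, 2)`` path.
    Samples before the go cue are excluded.  Positive means clockwise of the
    start->target segment.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.allclose(start, target):
        raise ValueError("start and target coincide; deviation undefined")
    if hasattr(traj_or_path, "endpoint"):
        path = np.asarray(traj_or_path.endpoint, dtype=float)
        path = path.reshape(path.shape[0], -1, 2)[:, 0, :]
        if go_step is None:
            go_step = int(np.ravel(traj_or_path.go_step)[0])
    else:
        path = np.asarray(traj_or_path, dtype=float)
        if go_step is None:
            go_step = 0
    u = target - start
    rel = path - start
    crossz = u[0] * rel[:, 1] - u[1] * rel[:, 0]
    d_cw = -crossz / np.linalg.norm(u)
    s = np.arange(path.shape[0])
    d_cw = np.where(s >= go_step, d_cw, 0.0)
    return float(d_cw[np.argmax(np.abs(d_cw))])


def lateral_deviation_paths(P, start, target, go_step) -> np.ndarray:
    """Vectorized CW-signed max deviation for batched paths.

    ``P`` has shape (T+1, ..., 2); start/target broadcast against the batch
    dims; go_step is an integer array.  Pre-go samples are masked out.
    """
    u = target - start
    rel = P - start
    crossz = u[..., 0] * rel[..., 1] - u[..., 1] * rel[..., 0]
    d_cw = -crossz / np.linalg.norm(u, axis=-1)
    s = np.arange(P.shape[0]).reshape((-1,) + (1,) * go_step.ndim)
    d_cw = np.where(s >= go_step, d_cw, 0.0)
    idx = np.argmax(np.abs(d_cw), axis=0)
    return np.take_along_axis(d_cw, idx[None], axis=0)[0]


def field_direction(dev_cw, b) -> np.ndarray:
    """Deviation measured positive in the curl field's push direction."""
    sgn = -np.sign(b) if b != 0 else 1.0
    return sgn * np.asarray(dev_cw)


def smooth_curve(y, kernel: int = 5) -> np.ndarray:
    """Centred moving average (edge-shortened windows keep the length)."""
    return pd.Series(np.asarray(y, dtype=float)).rolling(
        kernel, center=True, min_periods=1).mean().to_numpy()


def fit_learning_curve(curve: LearningCurve, kernel: int = 5) -> ExpFit:
    """Fit y = alpha*exp(-r x/1000) to the 5-batch-smoothed deviation series.

    ``r`` is left unbounded: a negative rate encodes a worsening curve (the
    opposite-field control needs this).  Non-convergence returns a flagged
    fit rather than raising.
    """
    y = np.asarray(curve.deviation, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 batches to fit a learning curve")
    ys = smooth_curve(y, kernel)
    x = np.asarray(curve.batch, dtype=float)

    def model(x, alpha, r):
        return alpha * np.exp(-r * x / 1000.0)

    a0 = ys[0] if ys[0] != 0 else (np.mean(ys) or 1e-6)
    try:
        popt, _ = optimize.curve_fit(model, x, ys, p0=(a0, 1.0), maxfev=20000)
        alpha, r = float(popt[0]), float(popt[1])
        resid = float(np.linalg.norm(ys - model(x, *popt)))
        return ExpFit(alpha, r, resid, converged=True)
    except RuntimeError:
        return ExpFit(float(a0), 0.0, float(np.linalg.norm(ys - a0)), converged=False)


def classify_savings(fit1: ExpFit, fit2: ExpFit,
                     dev1_b0: float, dev2_b0: float):
    """Savings flags from the FF1/FF2 pair of one network.

    rate_savings: relearning is faster (r2 > r1).  deviation_savings: initial
    error on re-exposure is smaller (dev2_b0 < dev1_b0, field-direction
    deviations).  Strict inequalities; ties count as no savings.
    """
    return bool(fit2.r > fit1.r), bool(dev2_b0 < dev1_b0)


def savings_rate(flags: Sequence[bool]):
    """Percentage of networks with savings and its Wilson 95% CI (percent)."""
    flags = list(flags)
    if not flags:
        raise ValueError("empty flag list")
    k = int(np.sum(flags))
    n = len(flags)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return 100.0 * k / n, (100.0 * lo, 100.0 * hi)


def paired_t(sample_a, sample_b):
    """Paired two-tailed t test; returns (t, df, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0) and np.allclose(d, d[0]):
        if np.allclose(d, 0.0):
            return 0.0, a.size - 1, 1.0
        raise ValueError("zero variance of differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), a.size - 1, float(res.pvalue)
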