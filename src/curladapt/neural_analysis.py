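"""Geometry of preparatory activity: force-predictive subspace and uniform shift.

Preparatory hidden activity is sampled 340 ms before the go cue (after it has
settled); early-execution endpoint force is sampled 90 ms after the go cue
(around peak acceleration).  Targeted dimensionality reduction (TDR) regresses
the 8 x n preparatory matrix onto the 8 x 2 force matrix (plus an intercept),
H = [F 1] W, and takes the orthonormalized first two columns of pinv(W) as the
force-predictive plane.  The uniform shift is the target-averaged displacement
of preparatory activity from the null-field baseline (NF1) to the adapted
state (FF1), orthogonalized against that plane — the component of learning
common to all reach directions and invisible to the force readout.  Its
post-washout residual is the candidate memory trace behind savings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "PrepActivityMatrix", "ForceMatrix", "TDRSubspace", "UniformShift",
    "fit_tdr", "project_onto_tdr", "compute_uniform_shift",
    "project_and_normalize", "pca_project",
]


@dataclass
class PrepActivityMatrix:
    """Condition x unit preparatory activity for one phase (targets x units)."""

    H: np.ndarray
    phase: str = ""

    def __post_init__(self):
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))


@dataclass
class ForceMatrix:
    """Early-execution endpoint forces, one row per target (targets x 2)."""

    F: np.ndarray
    phase: str = "NF1"

    def __post_init__(self):
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))


@dataclass
class TDRSubspace:
    """Force-predictive plane in unit space.

    ``basis`` is the (units x 2) orthonormal plane; ``W`` the raw (3 x units)
    regression map and ``W_pinv`` its (units x 3) pseudo-inverse.
    """

    basis: np.ndarray
    W: np.ndarray
    W_pinv: np.ndarray

    def project_out(self, v: np.ndarray) -> np.ndarray:
        """Remove the in-plane component of a unit-space vector."""
        return v - self.basis @ (self.basis.T @ v)


@dataclass
class UniformShift:
    """Learning-trace direction in unit space, orthogonal to the TDR plane."""

    us: np.ndarray
    raw: np.ndarray          # before orthogonalization
    anchor_nf1: float = 0.0  # raw projection anchors used for normalization
    anchor_ff1: float = 1.0


def _gram_schmidt_2(cols: np.ndarray) -> np.ndarray:
    """Orthonormalize two columns in order: normalize the first, then
    orthogonalize-and-normalize the second against it."""
    q1 = cols[:, 0] / np.linalg.norm(cols[:, 0])
    v2 = cols[:, 1] - q1 * (q1 @ cols[:, 1])
    q2 = v2 / np.linalg.norm(v2)
    return np.stack([q1, q2], axis=1)


def fit_tdr(H_nf1: PrepActivityMatrix, F_nf1: ForceMatrix) -> TDRSubspace:
    """Fit the force-predictive subspace on null-field baseline data.

    Solves H = [F 1] W by least squares (W is 3 x units), takes the first two
    columns of pinv(W) — ignoring the intercept column — and Gram-Schmidt
    orthonormalizes them in column order.
    """
    H = H_nf1.H
    F = F_nf1.F
    n_t, n_units = H.shape
    if n_units < 3:
        raise ValueError("need at least 3 units for TDR")
    if F.shape != (n_t, 2):
        raise ValueError("force matrix must be targets x 2")
    X = np.column_stack([F, np.ones(n_t)])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError("regressor matrix [F 1] is rank deficient")
    W, *_ = np.linalg.lstsq(X, H, rcond=None)
    W_pinv = np.linalg.pinv(W, rcond=1e-12)
    basis = _gram_schmidt_2(W_pinv[:, :2])
    return TDRSubspace(basis=basis, W=W, W_pinv=W_pinv)


def project_onto_tdr(H: PrepActivityMatrix, tdr: TDRSubspace,
                     global_mean: np.ndarray) -> np.ndarray:
    """Mean-centred coordinates of preparatory states in the TDR plane.

    ``global_mean`` is the grand mean over all phases x targets entering the
    comparison.  Returns (targets x 2); plotting these for the 8 centre-out
    targets renders the preparatory ring.
    """
    return (H.H - global_mean) @ tdr.basis


def compute_uniform_shift(H_ff1: PrepActivityMatrix, H_nf1: PrepActivityMatrix,
                          tdr: TDRSubspace) -> UniformShift:
    """Target-averaged NF1->FF1 displacement, orthogonalized to the TDR plane."""
    raw = H_ff1.H.mean(axis=0) - H_nf1.H.mean(axis=0)
    us = tdr.project_out(raw)
    return UniformShift(us=us, raw=raw)


def project_and_normalize(H_by_phase, us: UniformShift,
                          global_mean: np.ndarray, tol: float = 1e-12):
    """Normalized uniform-shift projection of each phase's mean activity.

    Projects each phase's target-mean preparatory state (minus the global
    mean) onto the shift direction, then rescales affinely so NF1 maps to 0
    and FF1 to 1; washout and re-adaptation phases land on that scale.
    ``H_by_phase`` is an ordered mapping or sequence (NF1, FF1, NF2, FF2).
    """
    if np.linalg.norm(us.us) < tol:
        raise ValueError("uniform shift is numerically zero; normalization undefined")
    mats = list(H_by_phase.values()) if hasattr(H_by_phase, "values") else list(H_by_phase)
    names = (list(H_by_phase.keys()) if hasattr(H_by_phase, "keys")
             else [m.phase or str(i) for i, m in enumerate(mats)])
    proj = {nm: float((m.H.mean(axis=0) - global_mean) @ us.us)
            for nm, m in zip(names, mats)}
    p_nf1, p_ff1 = proj[names[0]], proj[names[1]]
    if abs(p_ff1 - p_nf1) < tol:
        raise ValueError("degenerate normalization anchors (NF1 == FF1 projection)")
    us.anchor_nf1, us.anchor_ff1 = p_nf1, p_ff1
    return {nm: (v - p_nf1) / (p_ff1 - p_nf1) for nm, v in proj.items()}


def global_mean(mats) -> np.ndarray:
    """Grand mean over all phases x targets of the given activity matrices."""
    return np.concatenate([m.H for m in mats], axis=0).mean(axis=0)


def pca_project(hidden: np.ndarray, k: int = 3):
    """Top-k principal-component trajectories of pooled condition x time activity.

    ``hidden`` is (conditions, steps, units) or (samples, units).  PCA is fit
    on the pooled mean-centred samples; returns (scores, explained_variance_ratio)
    with scores shaped like the input but with ``k`` trailing features.
    Visualization support only.
    """
    arr = np.asarray(hidden, dtype=float)
    flat = arr.reshape(-1, arr.shape[-1])
    if arr.shape[-1] < k:
        raise ValueError("need at least k units")
    pca = PCA(n_components=k)
    scores = pca.fit_transform(flat)
    return scores.reshape(arr.shape[:-1] + (k,)), pca.explained_variance_ratio_
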