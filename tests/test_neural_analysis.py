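"""TDR subspace, uniform shift, normalized projections, PCA utility."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from curladapt.fixtures import PHASES, PlantedActivityTruth, synth_prep_activity
from curladapt.neural_analysis import (
    ForceMatrix,
    PrepActivityMatrix,
    compute_uniform_shift,
    fit_tdr,
    global_mean,
    pca_project,
    project_and_normalize,
    project_onto_tdr,
)


@pytest.fixture()
def planted():
    truth = PlantedActivityTruth.random(n_units=24, w=0.3, sigma=0.0, seed=5)
    mats, F, _ = synth_prep_activity(truth)
    return truth, mats, F


class TestFitTDR:
    def test_columns_orthonormal(self, planted):
        _, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        assert np.allclose(tdr.basis.T @ tdr.basis, np.eye(2), atol=1e-10)

    def test_planted_subspace_recovery(self, planted):
        """Noiseless planted data: the fitted plane matches an exact symbolic
        computation of the same pipeline (sympy pseudo-inverse oracle)."""
        sympy = pytest.importorskip("sympy")
        truth = PlantedActivityTruth.random(n_units=6, w=0.0, sigma=0.0, seed=2)
        mats, F, _ = synth_prep_activity(truth)
        tdr = fit_tdr(mats["NF1"], F)
        # independent route: exact rational least squares + pinv + Gram-Schmidt
        Hs = sympy.Matrix(np.round(mats["NF1"].H, 12))
        Xs = sympy.Matrix(np.column_stack([F.F, np.ones(8)]))
        Ws = (Xs.T * Xs).inv() * Xs.T * Hs
        Wp = Ws.pinv()
        c1 = Wp[:, 0]
        c2 = Wp[:, 1]
        q1 = c1 / c1.norm()
        v2 = c2 - q1 * (q1.T * c2)[0]
        q2 = v2 / v2.norm()
        oracle = np.array(q1.row_join(q2)).astype(float)
        angles = subspace_angles(tdr.basis, oracle)
        assert np.max(angles) < 1e-6

    def test_row_permutation_invariance(self, planted):
        _, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        perm = np.random.default_rng(0).permutation(8)
        tdr_p = fit_tdr(PrepActivityMatrix(mats["NF1"].H[perm]), ForceMatrix(F.F[perm]))
        assert np.allclose(tdr.basis, tdr_p.basis, atol=1e-10)

    def test_rank_deficient_forces_rejected(self):
        H = np.random.default_rng(1).standard_normal((8, 10))
        F = ForceMatrix(np.zeros((8, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            fit_tdr(PrepActivityMatrix(H), F)


class TestProjection:
    def test_global_mean_rows_project_to_zero(self, planted):
        _, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        gm = global_mean(mats.values())
        coords = project_onto_tdr(PrepActivityMatrix(np.tile(gm, (8, 1))), tdr, gm)
        assert np.allclose(coords, 0.0, atol=1e-10)

    def test_ring_angular_order(self, planted):
        """Projected NF1 points are angularly ordered like the 8 targets."""
        _, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        gm = global_mean([mats["NF1"]])
        xy = project_onto_tdr(mats["NF1"], tdr, gm)
        ang = np.unwrap(np.arctan2(xy[:, 1], xy[:, 0]))
        diffs = np.diff(ang)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_ring_rotation_follows_force_rotation(self):
        """Rotating the planted force tuning by theta rotates the ring read
        out through the raw pseudo-inverse columns by exactly theta (the
        adapted preparatory ring counter-rotates with the adapted forces)."""
        truth = PlantedActivityTruth.random(n_units=24, w=0.0, sigma=0.0, seed=3)
        mats, F, _ = synth_prep_activity(truth)
        theta = -np.pi / 8
        c, s = np.cos(theta), np.sin(theta)
        Rm = np.array([[c, -s], [s, c]])
        F_rot = F.F @ Rm.T
        H_rot = np.column_stack([F_rot, np.ones(8)]) @ np.vstack([truth.M, truth.c])
        tdr = fit_tdr(mats["NF1"], F)
        # H W+ reproduces [F 1] exactly on noiseless planted data, so the
        # force-plane readout of the rotated activity is the rotated ring
        xy0 = mats["NF1"].H @ tdr.W_pinv[:, :2]
        xy1 = H_rot @ tdr.W_pinv[:, :2]
        assert np.allclose(xy0, F.F, atol=1e-8)
        assert np.allclose(xy1, F.F @ Rm.T, atol=1e-8)
        a0 = np.arctan2(xy0[:, 1], xy0[:, 0])
        a1 = np.arctan2(xy1[:, 1], xy1[:, 0])
        dd = np.angle(np.exp(1j * (a1 - a0)))
        assert np.allclose(dd, theta, atol=1e-8)


class TestUniformShift:
    def test_identical_phases_zero_shift(self, planted):
        _, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        us = compute_uniform_shift(mats["NF1"], mats["NF1"], tdr)
        assert np.allclose(us.us, 0.0)

    def test_orthogonal_to_tdr(self, planted):
        _, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        us = compute_uniform_shift(mats["FF1"], mats["NF1"], tdr)
        assert np.allclose(tdr.basis.T @ us.us, 0.0, atol=1e-10)

    def test_planted_shift_recovery(self, planted):
        truth, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        us = compute_uniform_shift(mats["FF1"], mats["NF1"], tdr)
        cos = us.us @ truth.s / (np.linalg.norm(us.us) * np.linalg.norm(truth.s))
        assert cos > 0.999


class TestNormalizedProjection:
    def test_anchors_exact(self, planted):
        _, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        us = compute_uniform_shift(mats["FF1"], mats["NF1"], tdr)
        proj = project_and_normalize(mats, us, global_mean(mats.values()))
        assert proj["NF1"] == pytest.approx(0.0, abs=1e-10)
        assert proj["FF1"] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("w", [0.0, 0.3, 0.5, 1.0])
    def test_washout_fraction_recovered(self, w):
        truth = PlantedActivityTruth.random(n_units=24, w=w, sigma=0.0, seed=7)
        mats, F, _ = synth_prep_activity(truth)
        tdr = fit_tdr(mats["NF1"], F)
        us = compute_uniform_shift(mats["FF1"], mats["NF1"], tdr)
        proj = project_and_normalize(mats, us, global_mean(mats.values()))
        assert proj["NF2"] == pytest.approx(w, abs=1e-8)
        assert proj["FF2"] == pytest.approx(1.0, abs=1e-8)

    def test_full_planted_pipeline_under_noise(self):
        """Normalized projections (0, 1, w, 1) within 0.02 at 5% noise."""
        errs = []
        for seed in range(20):
            truth = PlantedActivityTruth.random(n_units=48, w=0.4, sigma=0.05,
                                                seed=seed, shift_scale=3.0)
            mats, F, _ = synth_prep_activity(truth)
            tdr = fit_tdr(mats["NF1"], F)
            us = compute_uniform_shift(mats["FF1"], mats["NF1"], tdr)
            proj = project_and_normalize(mats, us, global_mean(mats.values()))
            errs.append(abs(proj["NF2"] - 0.4))
        assert np.median(errs) < 0.02

    def test_translation_invariance(self, planted):
        """Adding a constant vector to every row leaves the normalized
        projections unchanged once the global mean is recomputed."""
        _, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        us = compute_uniform_shift(mats["FF1"], mats["NF1"], tdr)
        p0 = project_and_normalize(mats, us, global_mean(mats.values()))
        shift = 3.7 * np.ones(mats["NF1"].H.shape[1])
        mats2 = {ph: PrepActivityMatrix(m.H + shift, phase=ph) for ph, m in mats.items()}
        p1 = project_and_normalize(mats2, us, global_mean(mats2.values()))
        for ph in PHASES:
            assert p1[ph] == pytest.approx(p0[ph], abs=1e-8)

    def test_zero_shift_rejected(self, planted):
        _, mats, F = planted
        tdr = fit_tdr(mats["NF1"], F)
        us = compute_uniform_shift(mats["NF1"], mats["NF1"], tdr)
        with pytest.raises(ValueError):
            project_and_normalize(mats, us, global_mean(mats.values()))


class TestPCA:
    def test_planted_low_rank_variance(self):
        rng = np.random.default_rng(0)
        latent = rng.standard_normal((8, 50, 3))
        mix = rng.standard_normal((3, 30))
        data = latent @ mix
        scores, evr = pca_project(data, k=3)
        assert scores.shape == (8, 50, 3)
        assert evr.sum() > 0.999

    def test_variances_non_increasing(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((200, 12)) * np.linspace(3, 0.1, 12)
        _, evr = pca_project(data, k=5)
        assert np.all(np.diff(evr) <= 1e-12)
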