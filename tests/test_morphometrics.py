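"""GPA and shape PCA against brute-force oracles and algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbmshape.curve_io import ScanMeta
from pbmshape.errors import InputError
from pbmshape.landmarks import STRATEGIES, LandmarkConfig
from pbmshape.morphometrics import gpa, orient_pc1, pc1_scores, shape_pca

ANGLES = (0, 30, 60, 90, 120, 150)


def make_config(points, subject="S1", eye="OD", angle=0, strategy="user-16"):
    meta = ScanMeta(subject, eye, angle, 6.0, 3.9, 1024)
    return LandmarkConfig(points=np.asarray(points, dtype=float),
                          strategy=STRATEGIES[strategy], meta=meta)


def pbm_like(rng=None, bump=0.0, noise=0.0, subject="S1", eye="OD", angle=0):
    """A 16-point configuration shaped like a flanking-curve pair."""
    rng = rng or np.random.default_rng(0)
    xl = 2300.0 - 180.0 * np.arange(8)
    xr = 3800.0 + 180.0 * np.arange(8)
    yl = -0.02 * (2300.0 - xl) + bump * np.exp(-np.arange(8) / 2.0)
    yr = -0.02 * (xr - 3800.0) + bump * np.exp(-np.arange(8) / 2.0)
    pts = np.vstack([np.column_stack([xl, yl]), np.column_stack([xr, yr])])
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return make_config(pts, subject=subject, eye=eye, angle=angle)


def rotate(points, theta_deg, scale=1.0, shift=(0.0, 0.0)):
    t = np.deg2rad(theta_deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return scale * points @ R.T + np.asarray(shift)


def normalized(points):
    p = points - points.mean(axis=0)
    return p / np.linalg.norm(p)


class TestGpa:
    def test_identical_configurations_give_zero_residual(self):
        cfg = pbm_like(noise=0.0)
        aligned = gpa([cfg] * 5)
        consensus = aligned.aligned.mean(axis=0)
        assert np.allclose(aligned.aligned - consensus, 0.0, atol=1e-10)
        assert np.allclose(np.linalg.norm(consensus), 1.0, atol=1e-8)

    def test_similarity_transformed_copy_aligns_exactly(self):
        base = pbm_like(noise=0.0)
        moved = make_config(rotate(base.points, 90.0, scale=3.0, shift=(500.0, -200.0)))
        aligned = gpa([base, moved])
        assert np.allclose(aligned.aligned[0], aligned.aligned[1], atol=1e-8)

    def test_unit_centroid_size_and_zero_centroid(self):
        rng = np.random.default_rng(3)
        cfgs = [pbm_like(rng, noise=20.0, subject=f"S{i}") for i in range(6)]
        aligned = gpa(cfgs)
        for X in aligned.aligned:
            assert np.allclose(X.mean(axis=0), 0.0, atol=1e-8)
            assert np.isclose(np.linalg.norm(X), 1.0, atol=1e-8)

    def test_similarity_invariance_of_aligned_coordinates(self):
        """Random per-configuration similarity transforms leave aligned coords unchanged."""
        rng = np.random.default_rng(8)
        cfgs = [pbm_like(rng, noise=15.0, subject=f"S{i}") for i in range(6)]
        ref = gpa(cfgs).aligned
        moved = []
        for c in cfgs:
            theta = rng.uniform(0, 360)
            scale = rng.uniform(0.2, 5.0)
            shift = rng.uniform(-1e4, 1e4, 2)
            moved.append(make_config(rotate(c.points, theta, scale, shift)))
        out = gpa(moved).aligned
        assert np.max(np.abs(out - ref)) < 1e-6

    def test_two_config_rotation_matches_grid_search_oracle(self):
        """Full Procrustes distance equals a 0.001-degree brute-force minimum."""
        rng = np.random.default_rng(5)
        a = normalized(pbm_like(rng, noise=30.0).points)
        b = normalized(pbm_like(rng, noise=30.0).points)
        # brute force over rotation angle: cost = 2 - 2*(c1 cos t + c2 sin t)
        thetas = np.deg2rad(np.arange(0.0, 360.0, 0.001))
        c1 = np.sum(a * b)
        c2 = np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
        costs = 2.0 - 2.0 * (c1 * np.cos(thetas) + c2 * np.sin(thetas))
        brute_min = costs.min()
        aligned = gpa([make_config(a), make_config(b)]).aligned
        gpa_dist = np.sum((aligned[0] - aligned[1]) ** 2)
        assert gpa_dist == pytest.approx(brute_min, abs=1e-6)

    def test_consensus_matches_alternating_optimization_oracle(self):
        """Independent naive GPA (closed-form per-config angle) agrees to 1e-6."""
        rng = np.random.default_rng(9)
        cfgs = [pbm_like(rng, noise=25.0, subject=f"S{i}") for i in range(6)]
        X = np.stack([normalized(c.points) for c in cfgs])
        consensus = X[0].copy()
        for _ in range(2000):
            for i in range(len(X)):
                c1 = np.sum(X[i] * consensus)
                c2 = np.sum(X[i][:, 0] * consensus[:, 1] - X[i][:, 1] * consensus[:, 0])
                t = np.arctan2(c2, c1)
                R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
                X[i] = X[i] @ R.T
            new = X.mean(axis=0)
            new /= np.linalg.norm(new)
            if np.sqrt(np.mean((new - consensus) ** 2)) < 1e-14:
                consensus = new
                break
            consensus = new
        ours = gpa(cfgs).aligned.mean(axis=0)
        # compare up to the global rotation freedom of the oracle
        c1 = np.sum(consensus * ours)
        c2 = np.sum(consensus[:, 0] * ours[:, 1] - consensus[:, 1] * ours[:, 0])
        t = np.arctan2(c2, c1)
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        oracle_rotated = consensus @ R.T
        norm_ours = ours / np.linalg.norm(ours)
        assert np.max(np.abs(oracle_rotated - norm_ours)) < 1e-6

    def test_degenerate_configuration_rejected(self):
        flat = make_config(np.zeros((16, 2)))
        with pytest.raises(InputError, match="centroid size"):
            gpa([flat, pbm_like()])

    def test_fewer_than_two_configs_rejected(self):
        with pytest.raises(InputError):
            gpa([pbm_like()])


class TestShapePca:
    def test_rank_one_variation_explained_by_pc1(self):
        """Aligned shapes varying along one displacement vector are pure PC1."""
        import pandas as pd

        from pbmshape.morphometrics import AlignedSet

        base = pbm_like(noise=0.0).points
        base = base - base.mean(axis=0)
        base = base / np.linalg.norm(base)
        direction = np.zeros((16, 2))
        direction[[0, 8], 1] = 1.0
        direction /= np.linalg.norm(direction)
        ts = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        X = np.stack([base + 0.01 * t * direction for t in ts])
        keys = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(5)],
            "eye": ["OD"] * 5, "angle_deg": [0] * 5,
            "strategy": ["user-16"] * 5,
            "scan_id": [f"S{i}_OD_000" for i in range(5)],
        })
        aligned = AlignedSet(aligned=X, centroid_sizes=np.ones(5), keys=keys,
                             iterations=1, final_change=0.0, converged=True)
        space = shape_pca(aligned)
        assert space.variance_explained()[0] == pytest.approx(1.0, abs=1e-8)

    def test_pc1_score_variance_equals_first_eigenvalue(self):
        rng = np.random.default_rng(12)
        cfgs = [pbm_like(rng, noise=20.0, subject=f"S{i}") for i in range(8)]
        space = shape_pca(gpa(cfgs))
        assert np.var(space.scores[:, 0], ddof=1) == pytest.approx(space.eigenvalues[0])

    def test_eigenvalue_sum_equals_residual_variance(self):
        rng = np.random.default_rng(13)
        cfgs = [pbm_like(rng, noise=25.0, subject=f"S{i}") for i in range(7)]
        aligned = gpa(cfgs)
        space = shape_pca(aligned)
        resid = aligned.aligned - aligned.aligned.mean(axis=0)
        total = np.sum(resid**2) / (len(cfgs) - 1)
        assert space.eigenvalues.sum() == pytest.approx(total, abs=1e-8)
        gram = space.components @ space.components.T
        assert np.allclose(gram, np.eye(len(space.components)), atol=1e-8)
        assert np.allclose(space.scores.mean(axis=0), 0.0, atol=1e-8)
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)

    def test_scores_match_explicit_covariance_oracle(self):
        """Brute-force eigen-decomposition of the residual covariance, 5 configs."""
        rng = np.random.default_rng(14)
        cfgs = [pbm_like(rng, noise=30.0, subject=f"S{i}") for i in range(5)]
        aligned = gpa(cfgs)
        space = shape_pca(aligned)
        X = aligned.aligned.reshape(5, -1)
        resid = X - X.mean(axis=0)
        cov = sum(np.outer(r, r) for r in resid) / 4.0
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        m = len(space.eigenvalues)
        assert np.allclose(space.eigenvalues, w[:m], atol=1e-10)
        for j in range(2):  # leading components carry all the signal here
            oracle_scores = resid @ v[:, j]
            match_direct = np.allclose(space.scores[:, j], oracle_scores, atol=1e-8)
            match_flipped = np.allclose(space.scores[:, j], -oracle_scores, atol=1e-8)
            assert match_direct or match_flipped


class TestOrientPc1:
    def test_negative_inner_loadings_are_flipped(self):
        rng = np.random.default_rng(15)
        cfgs = [pbm_like(rng, bump=b, noise=5.0, subject=f"S{i}")
                for i, b in enumerate((0, 10, 20, 30, 40, 50))]
        space = shape_pca(gpa(cfgs))
        k = space.consensus.shape[0]
        flipped = space
        flipped.components[0] *= -1
        flipped.scores[:, 0] *= -1
        a = orient_pc1(space)
        inner_y = a.components[0].reshape(k, 2)[[0, k // 2], 1].mean()
        assert inner_y > 0

    def test_orientation_idempotent(self):
        rng = np.random.default_rng(16)
        cfgs = [pbm_like(rng, bump=b, noise=5.0, subject=f"S{i}")
                for i, b in enumerate((0, 15, 30, 45, 60))]
        once = orient_pc1(shape_pca(gpa(cfgs)))
        twice = orient_pc1(once)
        assert np.array_equal(once.components, twice.components)
        assert np.array_equal(once.scores, twice.scores)

    def test_oriented_scores_track_bump_size(self):
        rng = np.random.default_rng(17)
        bumps = np.linspace(0, 60, 12)
        cfgs = [pbm_like(rng, bump=b, noise=2.0, subject=f"S{i}")
                for i, b in enumerate(bumps)]
        space = orient_pc1(shape_pca(gpa(cfgs)))
        r = np.corrcoef(space.scores[:, 0], bumps)[0, 1]
        assert r > 0.95


class TestPc1Scores:
    def _cohort_configs(self):
        rng = np.random.default_rng(18)
        cfgs = []
        for s in range(4):
            for eye in ("OD", "OS"):
                for angle in ANGLES:
                    cfgs.append(
                        pbm_like(rng, bump=rng.uniform(0, 40), noise=5.0,
                                 subject=f"S{s}", eye=eye, angle=angle)
                    )
        return cfgs

    def test_per_angle_tables_partition_all_table(self):
        cfgs = self._cohort_configs()
        _, table_all = pc1_scores(cfgs, grouping="all")
        _, table_angle = pc1_scores(cfgs, grouping="per_angle")
        key = ["subject_id", "eye", "angle_deg"]
        all_keys = set(map(tuple, table_all[key].itertuples(index=False)))
        angle_keys = set(map(tuple, table_angle[key].itertuples(index=False)))
        assert all_keys == angle_keys
        assert len(table_angle) == len(table_all)

    def test_single_angle_cohort_matches_all_grouping_up_to_sign(self):
        cfgs = [c for c in self._cohort_configs() if c.meta.angle_deg == 90]
        _, t_all = pc1_scores(cfgs, grouping="all")
        _, t_angle = pc1_scores(cfgs, grouping="per_angle")
        merged = t_all.merge(t_angle, on=["subject_id", "eye", "angle_deg"],
                             suffixes=("_all", "_angle"))
        same = np.allclose(merged["score_all"], merged["score_angle"], atol=1e-10)
        flip = np.allclose(merged["score_all"], -merged["score_angle"], atol=1e-10)
        assert same or flip

    def test_sparse_angle_skipped_with_remaining_groups(self):
        cfgs = [c for c in self._cohort_configs() if not
                (c.meta.angle_deg == 150 and not (c.meta.subject_id == "S0" and c.meta.eye == "OD"))]
        spaces, table = pc1_scores(cfgs, grouping="per_angle")
        assert "angle_150" not in spaces
        assert set(table["angle_deg"]) == {0, 30, 60, 90, 120}
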