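"""Generalized Procrustes analysis and shape PCA for semi-landmark configurations.

Shape is what remains of a landmark configuration after removing translation,
scale and rotation (full Procrustes: centroid at the origin, unit centroid
size, rotations only — reflections are disallowed).  The consensus shape is
the per-landmark mean of the aligned configurations; principal components are
the eigenvectors of the covariance of aligned residuals about the consensus,
and a configuration's PC score ("magnitude") is the projection of its
residual onto a component.  Here PC1 indexes vitreous-ward deflection of the
pBM margins, and its sign is fixed so that positive scores mean deflection
toward the vitreous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .landmarks import LandmarkConfig

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 100


@dataclass
class AlignedSet:
    """Procrustes-superimposed configurations plus convergence diagnostics."""

    aligned: np.ndarray  # (n, k, 2), centroid 0, unit centroid size
    centroid_sizes: np.ndarray  # (n,), pre-scaling sizes
    keys: pd.DataFrame  # subject_id, eye, angle_deg, strategy, scan_id
    iterations: int
    final_change: float
    converged: bool


@dataclass
class ShapeSpace:
    """Consensus shape, shape-change components and per-scan scores."""

    consensus: np.ndarray  # (k, 2)
    components: np.ndarray  # (m, 2k), orthonormal rows, descending eigenvalue
    eigenvalues: np.ndarray  # (m,), variances along components
    scores: np.ndarray  # (n, m)
    keys: pd.DataFrame
    grouping: str = "all"  # "all" or "angle_<deg>"
    pc1_oriented: bool = False
    orientation_flagged: bool = False
    diagnostics: dict = field(default_factory=dict)

    def variance_explained(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues * 0.0

    def scores_table(self, components: tuple[int, ...] = (1,)) -> pd.DataFrame:
        """Tidy table of scores, 1-based component numbering."""
        frames = []
        for c in components:
            df = self.keys.copy()
            df["grouping"] = self.grouping
            df["component"] = c
            df["score"] = self.scores[:, c - 1]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _optimal_rotation(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rotation R (reflections disallowed) minimizing ||X R - ref||_F."""
    M = X.T @ ref
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation putting the consensus into a canonical orientation.

    The consensus' major principal axis is rotated onto the x-axis
    (reflection-free), and of the two such rotations the one keeping the
    second half of the landmark ordering (the right side of the pBM opening)
    at larger x is chosen.  This anchors the aligned frame to the data rather
    than to the arbitrary orientation of the first input configuration, so
    superimposition output is invariant to similarity transforms of the
    inputs and the aligned y-axis keeps its vitreous-positive meaning.
    """
    _, _, Vt = np.linalg.svd(consensus, full_matrices=False)
    R = Vt.T
    if np.linalg.det(R) < 0:
        R = R.copy()
        R[:, 1] *= -1.0
    rot = consensus @ R
    k = rot.shape[0]
    if rot[k // 2:, 0].mean() < rot[: k // 2, 0].mean():
        R = -R
    return R


def _keys_frame(configs: list[LandmarkConfig]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [c.meta.subject_id for c in configs],
            "eye": [c.meta.eye for c in configs],
            "angle_deg": [c.meta.angle_deg for c in configs],
            "strategy": [c.strategy.name for c in configs],
            "scan_id": [c.meta.scan_id for c in configs],
        }
    )


def gpa(
    configs: list[LandmarkConfig],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> AlignedSet:
    """Generalized Procrustes superimposition of equal-count configurations.

    Translates centroids to the origin, scales to unit centroid size, then
    iteratively rotates every configuration to the running consensus (optimal
    rotation via SVD of the cross-covariance) until the consensus
    root-mean-square change drops below ``tol`` or ``max_iter`` is reached.
    Non-convergence is recorded in the diagnostics, not raised.
    """
    if len(configs) < 2:
        raise InputError(f"gpa requires >= 2 configurations, got {len(configs)}")
    k = configs[0].points.shape[0]
    if any(c.points.shape[0] != k for c in configs):
        raise InputError("all configurations must have the same landmark count")
    X = np.stack([c.points for c in configs]).astype(float)  # (n, k, 2)
    X -= X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((X**2).sum(axis=(1, 2)))
    if np.any(sizes < 1e-12):
        bad = int(np.argmin(sizes))
        raise InputError(f"degenerate configuration {bad}: zero centroid size")
    X /= sizes[:, None, None]

    consensus = X[0].copy()
    consensus /= np.linalg.norm(consensus)
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new_consensus = X.mean(axis=0)
        norm = np.linalg.norm(new_consensus)
        if norm < 1e-12:
            raise InputError("degenerate consensus: configurations cancel out")
        new_consensus /= norm
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            break
    converged = change < tol
    if not converged:
        logger.warning("GPA did not converge: final change %.3e after %d iterations", change, it)
    R = _canonical_rotation(consensus)
    X = X @ R
    return AlignedSet(
        aligned=X,
        centroid_sizes=sizes,
        keys=_keys_frame(configs),
        iterations=it,
        final_change=change,
        converged=converged,
    )


def shape_pca(aligned: AlignedSet, grouping: str = "all") -> ShapeSpace:
    """PCA of Procrustes residuals about the consensus shape.

    Components are eigenvectors of the residual covariance (flattened to
    2k coordinates); eigenvalues use the n-1 denominator and their sum equals
    the total residual variance.  Scores are projections of residuals onto
    components, so each component's scores have zero mean.
    """
    X = aligned.aligned
    n, k, _ = X.shape
    if n < 2:
        raise InputError("shape_pca requires >= 2 configurations")
    consensus = X.mean(axis=0)
    resid = (X - consensus).reshape(n, 2 * k)
    U, S, Vt = np.linalg.svd(resid, full_matrices=False)
    m = min(n - 1, 2 * k)
    components = Vt[:m]
    eigenvalues = (S[:m] ** 2) / (n - 1)
    scores = U[:, :m] * S[:m]
    return ShapeSpace(
        consensus=consensus,
        components=components,
        eigenvalues=eigenvalues,
        scores=scores,
        keys=aligned.keys.copy(),
        grouping=grouping,
        diagnostics={
            "iterations": aligned.iterations,
            "final_change": aligned.final_change,
            "converged": aligned.converged,
        },
    )


def orient_pc1(space: ShapeSpace) -> ShapeSpace:
    """Fix PC1's sign so positive scores mean vitreous-ward margin deflection.

    The two innermost semi-landmarks (one per side) carry the deflection
    signal; PC1 is flipped when their mean y-loading is negative.  A loading
    of exactly zero leaves the sign unchanged and sets
    ``orientation_flagged``.  Idempotent.
    """
    if space.components.shape[0] < 1:
        raise InputError("shape space has no components")
    k = space.consensus.shape[0]
    inner = (0, k // 2)
    loadings = space.components[0].reshape(k, 2)
    mean_inner_y = float(loadings[list(inner), 1].mean())
    components = space.components.copy()
    scores = space.scores.copy()
    flagged = False
    if mean_inner_y < 0:
        components[0] = -components[0]
        scores[:, 0] = -scores[:, 0]
    elif mean_inner_y == 0:
        flagged = True
        logger.warning("PC1 inner-landmark y-loading is exactly zero; orientation unchanged")
    return ShapeSpace(
        consensus=space.consensus,
        components=components,
        eigenvalues=space.eigenvalues.copy(),
        scores=scores,
        keys=space.keys.copy(),
        grouping=space.grouping,
        pc1_oriented=True,
        orientation_flagged=flagged,
        diagnostics=dict(space.diagnostics),
    )


def pc1_scores(
    configs: list[LandmarkConfig],
    grouping: str = "all",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
):
    """PC1 magnitudes for one strategy's configurations.

    ``grouping="all"`` builds one shape space over every configuration
    (PC1_all); ``"per_angle"`` builds one per scan angle (PC1_0 ... PC1_150),
    skipping angles with fewer than two configurations.  Returns
    ``(spaces, table)`` where ``spaces`` maps grouping label to an oriented
    :class:`ShapeSpace` and ``table`` is the tidy concatenated score table.
    """
    if grouping not in ("all", "per_angle"):
        raise InputError(f"grouping must be all|per_angle, got {grouping!r}")
    spaces: dict[str, ShapeSpace] = {}
    if grouping == "all":
        space = orient_pc1(shape_pca(gpa(configs, tol, max_iter), grouping="all"))
        spaces["all"] = space
    else:
        angles = sorted({c.meta.angle_deg for c in configs})
        for ang in angles:
            sub = [c for c in configs if c.meta.angle_deg == ang]
            if len(sub) < 2:
                logger.warning("angle %d skipped: only %d configuration(s)", ang, len(sub))
                continue
            label = f"angle_{ang}"
            spaces[label] = orient_pc1(shape_pca(gpa(sub, tol, max_iter), grouping=label))
    if not spaces:
        raise InputError("no groupings with >= 2 configurations")
    table = pd.concat([s.scores_table() for s in spaces.values()], ignore_index=True)
    return spaces, table
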