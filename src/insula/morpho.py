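"""Landmark-based geometric morphometrics.

Centroid size, generalized full Procrustes superimposition (translation,
unit-centroid-size scaling, and optimal rotation onto an iterated mean
shape), shape PCA on the covariance of the aligned coordinates, and
group mean-shape difference vectors for wireframe plots.

Rotations are proper (determinant +1): reflections are disallowed, so
mirrored specimens (e.g. right hemimandibles) must be flipped explicitly
on input. Analyses operate in Procrustes coordinates; orthogonal
tangent-space projection is available behind a flag but off by default,
as shape variation at this scale is small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LandmarkSet",
    "ProcrustesResult",
    "ShapePCA",
    "centroid_size",
    "gpa",
    "shape_pca",
    "group_shape_difference",
    "centroid_size_report",
    "procrustes_distance",
]


@dataclass
class LandmarkSet:
    """Specimens x landmarks x 2 coordinates with group labels."""

    coords: np.ndarray  # (n, k, 2)
    ids: list
    groups: list
    side: list | None = None
    replicate: list | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 + 1 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n, k, 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite landmark coordinates")
        n = self.coords.shape[0]
        if len(self.ids) != n or len(self.groups) != n:
            raise ValueError("ids/groups length does not match specimens")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "LandmarkSet":
        """Build from the long TSV layout (specimen_id, group,
        landmark_index, x, y)."""
        coords, ids, groups = [], [], []
        for (sid, grp), sub in df.groupby(["specimen_id", "group"], sort=True):
            sub = sub.sort_values("landmark_index")
            coords.append(sub[["x", "y"]].to_numpy(dtype=float))
            ids.append(sid)
            groups.append(grp)
        return cls(np.stack(coords), ids, groups)


@dataclass
class ProcrustesResult:
    aligned: np.ndarray  # (n, k, 2), unit centroid size
    mean_shape: np.ndarray  # (k, 2), centered, unit centroid size
    centroid_sizes: np.ndarray  # original sizes per specimen
    iterations: int
    converged: bool
    ids: list = field(default_factory=list)
    groups: list = field(default_factory=list)


@dataclass
class ShapePCA:
    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # (2k, n_components), columns are components
    scores: np.ndarray  # (n, n_components)
    variance_fractions: np.ndarray
    mean_vector: np.ndarray  # (2k,)


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared landmark distances to the centroid."""
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _normalize(config: np.ndarray) -> np.ndarray:
    centered = config - config.mean(axis=0)
    return centered / centroid_size(config)


def _optimal_rotation(target: np.ndarray, config: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||target - config @ R|| (det +1)."""
    u, _s, vt = np.linalg.svd(config.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, d])
    return u @ correction @ vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (after
    centering, unit scaling and optimal proper rotation)."""
    a, b = _normalize(a), _normalize(b)
    rot = _optimal_rotation(a, b)
    return float(np.linalg.norm(a - b @ rot))


def gpa(
    landmarks: LandmarkSet, tol: float = 1e-10, max_iter: int = 1000
) -> ProcrustesResult:
    """Generalized full Procrustes superimposition.

    Centers every configuration, scales to unit centroid size, rotates
    each onto the current mean shape by the optimal proper rotation,
    re-estimates the mean (re-centered, re-scaled to unit size), and
    iterates until the Procrustes distance between successive means is
    below ``tol``. Exceeding ``max_iter`` returns the current state with
    ``converged=False`` and a warning.
    """
    if landmarks.n_specimens < 2:
        raise ValueError("GPA requires at least 2 specimens")
    sizes = np.array([centroid_size(c) for c in landmarks.coords])
    aligned = np.stack([_normalize(c) for c in landmarks.coords])
    mean = aligned[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(aligned.shape[0]):
            aligned[i] = aligned[i] @ _optimal_rotation(mean, aligned[i])
        new_mean = _normalize(aligned.mean(axis=0))
        shift = procrustes_distance(mean, new_mean)
        mean = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations")
    # final superimposition onto the converged mean
    for i in range(aligned.shape[0]):
        aligned[i] = aligned[i] @ _optimal_rotation(mean, aligned[i])
    return ProcrustesResult(
        aligned=aligned,
        mean_shape=mean,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        ids=list(landmarks.ids),
        groups=list(landmarks.groups),
    )


def shape_pca(
    result: ProcrustesResult,
    n_components: int | None = None,
    tangent_projection: bool = False,
) -> ShapePCA:
    """PCA of the covariance matrix of the aligned coordinates.

    Specimens become rows of a (n, 2k) matrix; the eigendecomposition of
    its covariance gives the shape components. Component signs are fixed
    by making the largest-magnitude loading positive. With
    ``tangent_projection=True`` the aligned shapes are first projected
    orthogonally onto the tangent space at the mean shape.
    """
    n, k, _ = result.aligned.shape
    if n < 3:
        raise ValueError("shape PCA requires at least 3 specimens")
    X = result.aligned.reshape(n, 2 * k)
    if tangent_projection:
        m = result.mean_shape.reshape(-1)
        m = m / np.linalg.norm(m)
        X = X - np.outer(X @ m - 1.0, m)
    mean_vec = X.mean(axis=0)
    Xc = X - mean_vec
    cov = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    if n_components is None:
        n_components = min(n - 1, 2 * k)
    eigvals = eigvals[:n_components]
    eigvecs = eigvecs[:, :n_components]
    for j in range(eigvecs.shape[1]):
        if eigvecs[np.argmax(np.abs(eigvecs[:, j])), j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = Xc @ eigvecs
    total = float(np.trace(cov))
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return ShapePCA(
        eigenvalues=eigvals,
        loadings=eigvecs,
        scores=scores,
        variance_fractions=fractions,
        mean_vector=mean_vec,
    )


def group_shape_difference(
    result: ProcrustesResult,
    group_a: str,
    group_b: str,
    pca: ShapePCA | None = None,
    components: list | None = None,
) -> pd.DataFrame:
    """Per-landmark displacement from group_a's mean shape to group_b's.

    Optionally projects the difference onto selected PCA components
    (indices into ``pca``). Returns a wireframe-ready table with the
    group-a mean coordinates and the displacement vector per landmark.
    """
    groups = np.asarray(result.groups)
    for g in (group_a, group_b):
        if not (groups == g).any():
            raise ValueError(f"group {g!r} is empty or absent")
    mean_a = result.aligned[groups == group_a].mean(axis=0)
    mean_b = result.aligned[groups == group_b].mean(axis=0)
    diff = (mean_b - mean_a).reshape(-1)
    if components is not None:
        if pca is None:
            raise ValueError("components given without a ShapePCA")
        basis = pca.loadings[:, components]
        diff = basis @ (basis.T @ diff)
    diff = diff.reshape(mean_a.shape)
    k = mean_a.shape[0]
    return pd.DataFrame(
        {
            "landmark": np.arange(1, k + 1),
            "x": mean_a[:, 0],
            "y": mean_a[:, 1],
            "dx": diff[:, 0],
            "dy": diff[:, 1],
        }
    )


def centroid_size_report(
    landmarks: LandmarkSet, correction: str = "holm"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-plot summaries of centroid size per group plus pairwise tests.

    Summaries are median, quartiles, whisker bounds (1.5 IQR) and
    outlier count. Pairwise comparisons use the two-sided Mann-Whitney U
    test with multiple-testing correction; groups of fewer than 2
    specimens are excluded from the tests with a warning.
    """
    sizes = np.array([centroid_size(c) for c in landmarks.coords])
    groups = np.asarray(landmarks.groups)
    uniq = sorted(set(landmarks.groups))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    testable = []
    for g in uniq:
        vals = sizes[groups == g]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = int(((vals < lo) | (vals > hi)).sum())
        rows.append((g, len(vals), med, q1, q3, lo, hi, outliers))
        if len(vals) >= 2:
            testable.append(g)
        else:
            warnings.warn(f"group {g!r} has < 2 specimens; excluded from tests")
    summary = pd.DataFrame(
        rows,
        columns=[
            "group", "n", "median", "q1", "q3",
            "whisker_low", "whisker_high", "n_outliers",
        ],
    )
    pairs, pvals, stats_u = [], [], []
    for i, a in enumerate(testable):
        for b in testable[i + 1:]:
            u, p = stats.mannwhitneyu(
                sizes[groups == a], sizes[groups == b], alternative="two-sided"
            )
            pairs.append((a, b))
            pvals.append(p)
            stats_u.append(u)
    tests = pd.DataFrame(pairs, columns=["group_a", "group_b"])
    if pairs:
        tests["U"] = stats_u
        tests["p"] = pvals
        tests["p_adj"] = multipletests(pvals, method=correction)[1]
    else:
        tests["U"] = []
        tests["p"] = []
        tests["p_adj"] = []
    return summary, tests
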