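"""Procrustes superimposition of landmark configurations.

Generalized Procrustes analysis (GPA) removes translation, scale and rotation
from a set of configurations, producing dimensionless shape coordinates on the
unit-size pre-shape sphere and a consensus (mean) shape.  New specimens (e.g.
fossils) are aligned to a previously fitted consensus with ordinary Procrustes
analysis (:func:`opa_to_consensus`) so the reference shape space stays fixed.

Scaling to unit centroid size is included by default, matching the standard
geomorph-style workflow; set ``scale=False`` in :func:`gpa` to superimpose
raw-size configurations.  Reflections are never applied: rotations are
restricted to the proper orthogonal group, as specimens are photographed in a
consistent orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateShapeError, StructureError
from .landmark_io import LandmarkConfiguration, ShapeDataset

logger = logging.getLogger(__name__)


@dataclass
class ProcrustesResult:
    """Aligned shape coordinates plus the consensus from a GPA fit."""

    aligned: np.ndarray          # (n, p, 2), dimensionless
    centroid_sizes: np.ndarray   # (n,), in source units
    consensus: np.ndarray        # (p, 2), coordinate-wise mean of aligned
    specimen_ids: list[str]
    n_iter: int
    delta: float
    converged: bool = True

    @property
    def n_specimens(self) -> int:
        return len(self.aligned)

    @property
    def n_points(self) -> int:
        return self.aligned.shape[1]


def _as_points(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.points
    return np.asarray(config, dtype=float)


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of points to their centroid."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def center_and_scale(config) -> tuple[np.ndarray, float]:
    """Translate to the origin and scale to unit centroid size.

    Returns ``(centered_points, centroid_size)``.
    """
    pts = _as_points(config)
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size < 1e-12:
        raise DegenerateShapeError("all landmarks coincide; centroid size is zero")
    return centered / size, size


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation ``R`` minimizing ``||source @ R - target||_F``.

    Solved via SVD of the cross-covariance with determinant correction;
    reflections are never returned.  With a rank-deficient cross-covariance
    the optimum is ambiguous: some minimizer is returned with a warning.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise StructureError(
            f"point-count mismatch: {source.shape} vs {target.shape}"
        )
    H = source.T @ target
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:
        d = 1.0
    R = U @ np.diag([1.0, d]) @ Vt
    if s[-1] <= 1e-12 * max(s[0], 1e-300):
        warnings.warn(
            "rank-deficient cross-covariance: optimal rotation is ambiguous",
            RuntimeWarning,
            stacklevel=2,
        )
    return R


def _rotate_all_to(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimally rotate each configuration in ``X`` (n, p, 2) onto ``target``.

    Uses the closed-form 2-D solution (identical to the SVD route): the
    optimal angle maximizes ``t1*cos + t2*sin`` with
    ``t1 = sum(x.x' + y.y')`` and ``t2 = sum(x.y' - y.x')``.
    """
    t1 = np.einsum("npk,pk->n", X, target)
    t2 = X[:, :, 0] @ target[:, 1] - X[:, :, 1] @ target[:, 0]
    norm = np.hypot(t1, t2)
    norm = np.where(norm < 1e-300, 1.0, norm)
    c, s = t1 / norm, t2 / norm
    # row-vector rotation: (x, y) -> (x c - y s, x s + y c)
    out = np.empty_like(X)
    out[:, :, 0] = X[:, :, 0] * c[:, None] - X[:, :, 1] * s[:, None]
    out[:, :, 1] = X[:, :, 0] * s[:, None] + X[:, :, 1] * c[:, None]
    return out


def _standardization_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation aligning the consensus's principal axis with the x-axis.

    The 180-degree ambiguity is resolved by making the x-skewness of the
    consensus non-negative, so results are insensitive to input order.
    """
    pts = consensus - consensus.mean(axis=0)
    cov = pts.T @ pts
    eigvals, eigvecs = np.linalg.eigh(cov)
    major = eigvecs[:, -1]
    phi = np.arctan2(major[1], major[0])
    c, s = np.cos(-phi), np.sin(-phi)
    R = np.array([[c, s], [-s, c]])
    rotated = pts @ R
    skew = float((rotated[:, 0] ** 3).sum())
    if skew < -1e-12 or (abs(skew) <= 1e-12 and rotated[np.argmax(np.abs(rotated[:, 0])), 0] < 0):
        R = R @ np.array([[-1.0, 0.0], [0.0, -1.0]])
    return R


def gpa(
    dataset: ShapeDataset | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    scale: bool = True,
) -> ProcrustesResult:
    """Generalized Procrustes analysis of a homogeneous dataset.

    Iterates rotate-to-consensus / recompute-consensus until the consensus
    moves less than ``tol`` (Frobenius norm) or ``max_iter`` is reached.  The
    final configuration set is rotated so the consensus's principal axis lies
    along x, making the result insensitive to specimen order.
    """
    if isinstance(dataset, ShapeDataset):
        ids = dataset.specimen_ids
        X_raw = dataset.points_array()
    else:
        X_raw = np.asarray(dataset, dtype=float)
        ids = [f"spec_{i}" for i in range(len(X_raw))]
    if X_raw.ndim != 3 or X_raw.shape[2] != 2:
        raise StructureError(f"expected (n, p, 2) array, got {X_raw.shape}")
    n = len(X_raw)
    if n < 2:
        raise DegenerateShapeError("GPA needs at least 2 specimens")

    X = np.empty_like(X_raw)
    sizes = np.empty(n)
    for i in range(n):
        centered, size = center_and_scale(X_raw[i])
        sizes[i] = size
        X[i] = centered if scale else centered * size

    consensus = X[0].copy()
    consensus_unit = consensus / np.linalg.norm(consensus)
    n_iter = 0
    delta = np.inf
    converged = False
    for n_iter in range(1, max_iter + 1):
        X = _rotate_all_to(X, consensus_unit)
        mean = X.mean(axis=0)
        new_unit = mean / np.linalg.norm(mean)
        delta = float(np.linalg.norm(new_unit - consensus_unit))
        consensus_unit = new_unit
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations (delta=%.3e)", max_iter, delta)

    # final pass so every specimen is rotated to the final consensus, then
    # standardize the global orientation
    X = _rotate_all_to(X, consensus_unit)
    R = _standardization_rotation(X.mean(axis=0))
    X = X @ R
    consensus = X.mean(axis=0)
    return ProcrustesResult(
        aligned=X,
        centroid_sizes=sizes,
        consensus=consensus,
        specimen_ids=ids,
        n_iter=n_iter,
        delta=delta,
        converged=converged,
    )


def opa_to_consensus(config, consensus: np.ndarray, scale: bool = True) -> np.ndarray:
    """Ordinary Procrustes alignment of one configuration onto a consensus.

    Centers, scales to unit centroid size (if ``scale``) and rotates to best
    fit; reference specimens aligned this way reproduce their GPA coordinates.
    """
    pts = _as_points(config)
    consensus = np.asarray(consensus, dtype=float)
    if pts.shape != consensus.shape:
        raise StructureError(
            f"point-count mismatch: {pts.shape} vs consensus {consensus.shape}"
        )
    centered, size = center_and_scale(pts)
    if not scale:
        centered = centered * size
    R = optimal_rotation(centered, consensus)
    return centered @ R


def align_dataset(dataset: ShapeDataset, consensus: np.ndarray, scale: bool = True) -> np.ndarray:
    """OPA-align every configuration of a dataset to a consensus; (n, p, 2)."""
    return np.stack([opa_to_consensus(c, consensus, scale=scale) for c in dataset])


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (rotations only,
    no reflection); both inputs are centered and scaled to unit size first."""
    A, _ = center_and_scale(np.asarray(a, dtype=float))
    B, _ = center_and_scale(np.asarray(b, dtype=float))
    s = np.linalg.svd(B.T @ A, compute_uv=False)
    d = np.sign(np.linalg.det(B.T @ A))
    if d == 0:
        d = 1.0
    gain = s[0] + d * s[1]
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * gain)))
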