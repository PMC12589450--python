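"""Reference morphospaces: PCA fit on the modern assemblage, CVA on guilds.

The principal-component morphospace is fit once, on the aligned modern
reference specimens only; fossils are *projected* into it (never refit), so
the axes stay stable as new material is added.  Canonical variate analysis is
then fit on a reduced number of PC dimensions (13 by default) to maximize
between-guild relative to pooled within-guild variance, and fossils are
projected into the canonical space the same way.

Score tables are plain :class:`pandas.DataFrame` objects with axis columns
``PC1..``/``CV1..`` plus ``specimen_id`` and any carried metadata; the space
tag is stored in ``DataFrame.attrs["space_tag"]``.

Axis sign convention: the largest-magnitude loading of every axis is made
positive, so orientations are reproducible across runs and platforms.
Covariances use the n-1 denominator throughout.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DegenerateDataError, StructureError
from .landmark_io import LandmarkConfiguration
from .superimposition import ProcrustesResult

_AXIS_RE = re.compile(r"^(PC|CV)(\d+)$")


def score_columns(table: pd.DataFrame) -> list[str]:
    """Axis columns of a score table (PC1.., CV1..), in numeric order."""
    cols = [c for c in table.columns if _AXIS_RE.match(c)]
    return sorted(cols, key=lambda c: (c[:2], int(c[2:])))


def score_matrix(table: pd.DataFrame) -> np.ndarray:
    return table[score_columns(table)].to_numpy(dtype=float)


def make_score_table(
    specimen_ids,
    scores: np.ndarray,
    space_tag: str,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble a score table from ids, a score matrix and optional metadata."""
    cols = [f"{space_tag}{i + 1}" for i in range(scores.shape[1])]
    table = pd.DataFrame(scores, columns=cols)
    table.insert(0, "specimen_id", list(specimen_ids))
    if meta is not None:
        meta = meta.drop(columns=[c for c in meta.columns if c in table.columns])
        table = pd.concat([table.reset_index(drop=True), meta.reset_index(drop=True)], axis=1)
    table.attrs["space_tag"] = space_tag
    return table


@dataclass
class ReferenceMorphospace:
    """Consensus + orthonormal eigenbasis fit on the modern reference."""

    consensus: np.ndarray          # (p, 2)
    eigenvectors: np.ndarray       # (2p, m), columns orthonormal
    eigenvalues: np.ndarray        # (m,), non-increasing, >= 0
    variance_fractions: np.ndarray  # sums to 1
    n_components: int

    @property
    def n_points(self) -> int:
        return len(self.consensus)

    def to_json(self, path: str | Path, loadings_path: str | Path | None = None) -> None:
        payload = {
            "consensus": self.consensus.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "n_components": self.n_components,
        }
        Path(path).write_text(json.dumps(payload, indent=1))
        if loadings_path is not None:
            cols = [f"PC{i + 1}" for i in range(self.eigenvectors.shape[1])]
            pd.DataFrame(self.eigenvectors, columns=cols).to_csv(
                loadings_path, index=False, float_format="%.12g"
            )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-|loading| entry of each column positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        idx = np.argmax(np.abs(out[:, j]))
        if out[idx, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_reference_pca(
    aligned_reference: ProcrustesResult | np.ndarray,
    consensus: np.ndarray | None = None,
) -> ReferenceMorphospace:
    """Eigendecompose the covariance of flattened aligned reference shapes.

    Centering uses the consensus (the coordinate-wise mean of the aligned
    reference), so reference scores have exactly zero column means.
    """
    if isinstance(aligned_reference, ProcrustesResult):
        X = aligned_reference.aligned
        consensus = aligned_reference.consensus
    else:
        X = np.asarray(aligned_reference, dtype=float)
        if consensus is None:
            consensus = X.mean(axis=0)
    n = len(X)
    if n < 2:
        raise DegenerateDataError("reference PCA needs at least 2 specimens")
    flat = X.reshape(n, -1)
    center = np.asarray(consensus, dtype=float).reshape(-1)
    centered = flat - center
    cov = centered.T @ centered / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return ReferenceMorphospace(
        consensus=np.asarray(consensus, dtype=float).reshape(-1, 2),
        eigenvectors=eigvecs,
        eigenvalues=eigvals,
        variance_fractions=fractions,
        n_components=len(eigvals),
    )


def project(
    specimens: np.ndarray,
    space: ReferenceMorphospace,
    k: int | None = None,
    specimen_ids=None,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Project aligned specimens into a reference morphospace.

    ``scores = (coordinates - consensus) . eigenvectors``, first ``k`` axes.
    Specimens must already be aligned to the same consensus
    (:func:`paleomorph.superimposition.opa_to_consensus`).
    """
    X = np.asarray(specimens, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    k = space.n_components if k is None else k
    if k > space.n_components:
        raise ValueError(f"k={k} exceeds available axes ({space.n_components})")
    flat = X.reshape(len(X), -1)
    scores = (flat - space.consensus.reshape(-1)) @ space.eigenvectors[:, :k]
    if single:
        return scores[0]
    if specimen_ids is None:
        specimen_ids = [f"spec_{i}" for i in range(len(X))]
    return make_score_table(specimen_ids, scores, "PC", meta=meta)


def shape_along_axis(
    space: ReferenceMorphospace, axis: int, score: float
) -> LandmarkConfiguration:
    """Model shape at a given score along one principal axis (0-based index).

    Returns ``consensus + score * eigenvector`` reshaped to landmarks; a score
    of 0 returns the consensus itself.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if not 0 <= axis < space.n_components:
        raise ValueError(f"axis {axis} outside 0..{space.n_components - 1}")
    flat = space.consensus.reshape(-1) + score * space.eigenvectors[:, axis]
    return LandmarkConfiguration(
        specimen_id=f"PC{axis + 1}_score_{score:+g}",
        points=flat.reshape(-1, 2),
        n_fixed=len(space.consensus),
    )


# ---------------------------------------------------------------------------
# canonical variate analysis


@dataclass
class CVAModel:
    """Canonical axes over PC scores, maximizing between/within guild variance.

    Canonical scores are scaled so the pooled within-group covariance is the
    identity; ``canonical_eigenvalues`` are the between/within variance ratios.
    """

    n_pcs_used: int
    grand_mean: np.ndarray           # (n_pcs_used,)
    canonical_axes: np.ndarray       # (n_pcs_used, n_axes)
    canonical_eigenvalues: np.ndarray
    group_means: pd.DataFrame = field(default=None)  # index: group, cols CV1..

    @property
    def n_axes(self) -> int:
        return self.canonical_axes.shape[1]


def fit_cva(reference_scores: pd.DataFrame | np.ndarray, groups) -> CVAModel:
    """Fit canonical variate analysis on reference PC scores.

    Solves the generalized eigenproblem of the between-group covariance
    against the pooled within-group covariance.  A singular within-group
    covariance is handled by pseudo-inverse whitening, with a warning.
    """
    X = score_matrix(reference_scores) if isinstance(reference_scores, pd.DataFrame) else np.asarray(reference_scores, dtype=float)
    groups = np.asarray(groups)
    if len(groups) != len(X):
        raise StructureError("groups length must match score rows")
    labels, inverse = np.unique(groups, return_inverse=True)
    g = len(labels)
    n, p = X.shape
    if g < 2:
        raise DegenerateDataError("CVA needs at least 2 groups")
    counts = np.bincount(inverse)
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise DegenerateDataError(f"every group needs >= 2 members; too small: {small}")
    grand = X.mean(axis=0)
    means = np.stack([X[inverse == i].mean(axis=0) for i in range(g)])
    B = (counts[:, None] * (means - grand)).T @ (means - grand) / (g - 1)
    W = np.zeros((p, p))
    for i in range(g):
        resid = X[inverse == i] - means[i]
        W += resid.T @ resid
    W /= n - g

    n_axes = min(g - 1, p)
    w_eigvals = np.linalg.eigvalsh(W)
    if w_eigvals[0] <= 1e-10 * max(w_eigvals[-1], 1e-300):
        warnings.warn(
            "singular within-group covariance; using pseudo-inverse whitening",
            RuntimeWarning,
            stacklevel=2,
        )
        vals, vecs = np.linalg.eigh(W)
        keep = vals > 1e-10 * vals.max()
        T = vecs[:, keep] / np.sqrt(vals[keep])  # whitening transform
        Bw = T.T @ B @ T
        bw_vals, bw_vecs = np.linalg.eigh(Bw)
        order = np.argsort(bw_vals)[::-1][:n_axes]
        eigvals = np.clip(bw_vals[order], 0.0, None)
        axes = T @ bw_vecs[:, order]
    else:
        vals, vecs = scipy.linalg.eigh(B, W)
        order = np.argsort(vals)[::-1][:n_axes]
        eigvals = np.clip(vals[order], 0.0, None)
        axes = vecs[:, order]  # eigh(B, W) normalizes v' W v = 1
    axes = _fix_signs(axes)
    model = CVAModel(
        n_pcs_used=p,
        grand_mean=grand,
        canonical_axes=axes,
        canonical_eigenvalues=eigvals,
    )
    cv_means = (means - grand) @ axes
    model.group_means = pd.DataFrame(
        cv_means, index=pd.Index(labels, name="group"),
        columns=[f"CV{i + 1}" for i in range(axes.shape[1])],
    )
    return model


def cva_project(
    specimens: pd.DataFrame | np.ndarray,
    model: CVAModel,
    specimen_ids=None,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Project PC-score rows into canonical space; reference specimens
    reproduce their training scores exactly."""
    if isinstance(specimens, pd.DataFrame):
        X = score_matrix(specimens)
        if specimen_ids is None and "specimen_id" in specimens.columns:
            specimen_ids = specimens["specimen_id"].tolist()
        if meta is None:
            extra = [
                c for c in specimens.columns
                if c != "specimen_id" and not _AXIS_RE.match(c)
            ]
            if extra:
                meta = specimens[extra]
    else:
        X = np.asarray(specimens, dtype=float)
    if X.shape[1] != model.n_pcs_used:
        raise StructureError(
            f"axis mismatch: scores have {X.shape[1]} axes, model expects "
            f"{model.n_pcs_used}"
        )
    scores = (X - model.grand_mean) @ model.canonical_axes
    if specimen_ids is None:
        specimen_ids = [f"spec_{i}" for i in range(len(X))]
    return make_score_table(specimen_ids, scores, "CV", meta=meta)
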