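"""Time binning, guild-divergence vectors and morphospace recovery.

Fossils are assigned to sequential time windows (ages in ka BP, larger =
older).  Two standard schemes are provided: the coarse three-bin scheme
(wetland 16.5-14.2, shallow-lake 14.2-13.5, deep-lake 13.5-0 ka) and the fine
1-ka scheme over the first three millennia (early-wetland 16.5-15.5, wetland
15.5-14.5, shallow-lake 14.5-13.5, deep-lake 13.5-0 ka).  A shared bin edge is
assigned to the *younger* bin (membership: younger < age <= older; the
youngest bin is additionally closed at its younger edge).

Divergence vectors run from the ancestral centroid — the centroid of the
earliest (early-wetland) fossil assemblage, computed in the same ordination
space as the guild centroids — to each modern trophic-guild centroid.  A
guild counts as *recovered* in a bin when its centroid lies inside or on the
convex hull of that bin's fossil scores (first two axes by default).  Because
hulls are sensitive to sample size, an alternative criterion (centroid within
the alpha-quantile Mahalanobis ellipse of the bin's scores) is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import chi2

from .errors import DegenerateDataError, StructureError
from .landmark_io import ShapeDataset
from .ordination import score_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeBin:
    name: str
    older_ka: float
    younger_ka: float

    def __post_init__(self):
        if not self.older_ka > self.younger_ka >= 0:
            raise ValueError(f"bin {self.name!r}: need older > younger >= 0")


@dataclass
class TimeBinning:
    bins: list[TimeBin]
    scheme: str = "custom"

    def __post_init__(self):
        if not self.bins:
            raise ValueError("need at least one bin")
        for a, b in zip(self.bins, self.bins[1:]):
            if b.older_ka > a.younger_ka:
                raise ValueError(
                    f"bins {a.name!r} and {b.name!r} overlap; edges must "
                    "decrease through the sequence"
                )

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bins]

    def assign(self, age_ka: float) -> str | None:
        """Bin name for one age; a shared edge goes to the younger bin."""
        if age_ka is None or not np.isfinite(age_ka):
            return None
        for i, b in enumerate(self.bins):
            lower_closed = i == len(self.bins) - 1
            if (b.younger_ka < age_ka <= b.older_ka) or (
                lower_closed and age_ka == b.younger_ka
            ):
                return b.name
        return None

    @classmethod
    def coarse(cls) -> "TimeBinning":
        return cls(
            [
                TimeBin("wetland", 16.5, 14.2),
                TimeBin("shallow-lake", 14.2, 13.5),
                TimeBin("deep-lake", 13.5, 0.0),
            ],
            scheme="coarse",
        )

    @classmethod
    def fine(cls) -> "TimeBinning":
        return cls(
            [
                TimeBin("early-wetland", 16.5, 15.5),
                TimeBin("wetland", 15.5, 14.5),
                TimeBin("shallow-lake", 14.5, 13.5),
                TimeBin("deep-lake", 13.5, 0.0),
            ],
            scheme="fine",
        )


def assign_time_bins(data, binning: TimeBinning) -> pd.DataFrame:
    """Label rows with their time bin.

    ``data`` may be a :class:`ShapeDataset` (ages read from metadata) or a
    DataFrame with an ``age_ka`` column.  Returns a copy with a ``time_bin``
    column; rows outside every bin (or without an age) get NA and are counted
    in a warning.
    """
    if isinstance(data, ShapeDataset):
        table = data.meta_frame()
    else:
        table = data.copy()
    if "age_ka" not in table.columns:
        raise StructureError("no age_ka column/metadata present")
    table["time_bin"] = [
        binning.assign(a) if pd.notna(a) else None for a in table["age_ka"]
    ]
    n_unbinned = int(table["time_bin"].isna().sum())
    if n_unbinned:
        logger.warning("%d rows fall outside all bins (unbinned)", n_unbinned)
    return table


def late_holocene_slice(data, start_ka: float = 4.5):
    """Rows with ``age_ka <= start_ka`` — the late-Holocene deep-water bin."""
    table = data.meta_frame() if isinstance(data, ShapeDataset) else data
    if "age_ka" not in table.columns:
        raise StructureError("no age_ka column/metadata present")
    ages = pd.to_numeric(table["age_ka"], errors="coerce")
    return table[(ages >= 0) & (ages <= start_ka)]


def group_centroid(scores) -> np.ndarray:
    """Arithmetic mean per axis of a (possibly tabular) score subset."""
    if isinstance(scores, pd.DataFrame):
        X = score_matrix(scores)
    else:
        X = np.asarray(scores, dtype=float)
    if len(X) == 0:
        raise DegenerateDataError("cannot take the centroid of an empty subset")
    return X.mean(axis=0)


@dataclass
class GuildDivergence:
    """Vectors from the ancestral centroid to each modern guild centroid."""

    bin_name: str
    ancestral_centroid: np.ndarray
    table: pd.DataFrame = field(default=None)
    # table columns: guild, d<axis>..., length, recovered


def divergence_vectors(ancestral: np.ndarray, guild_centroids) -> pd.DataFrame:
    """Per-guild vector ``centroid - ancestral`` and its Euclidean length.

    ``guild_centroids`` is a mapping guild -> point or a DataFrame indexed by
    guild with axis columns.  All vectors share the ancestral origin.
    """
    ancestral = np.asarray(ancestral, dtype=float)
    if isinstance(guild_centroids, pd.DataFrame):
        items = [(idx, row.to_numpy(dtype=float)) for idx, row in guild_centroids.iterrows()]
    else:
        items = [(k, np.asarray(v, dtype=float)) for k, v in guild_centroids.items()]
    rows = []
    for guild, centroid in items:
        if centroid.shape != ancestral.shape:
            raise StructureError(
                f"guild {guild!r}: dimension mismatch {centroid.shape} vs "
                f"{ancestral.shape}"
            )
        vec = centroid - ancestral
        row = {"guild": guild}
        for j, v in enumerate(vec):
            row[f"d{j + 1}"] = float(v)
        row["length"] = float(np.linalg.norm(vec))
        rows.append(row)
    return pd.DataFrame(rows)


def points_in_hull(points: np.ndarray, queries: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Boundary-inclusive convex-hull membership via the hull's facet equations."""
    points = np.asarray(points, dtype=float)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    hull = ConvexHull(points)
    scale = max(1.0, np.abs(points).max())
    A, b = hull.equations[:, :-1], hull.equations[:, -1]
    return np.all(queries @ A.T + b <= tol * scale, axis=1)


def guild_recovery(
    bin_scores,
    guild_centroids,
    dims: int = 2,
    criterion: str = "hull",
    alpha: float = 0.95,
) -> pd.DataFrame:
    """Flag which modern guild centroids a fossil assemblage has recovered.

    ``criterion='hull'`` (default): centroid inside or on the convex hull of
    the bin's fossil scores on the first ``dims`` axes.  ``'mahalanobis'``:
    centroid within the ``alpha``-quantile Mahalanobis ellipse of the bin's
    scores — less sensitive to sample size than the hull.  Degenerate bins
    return all-False flags with ``degenerate=True``.
    """
    if isinstance(bin_scores, pd.DataFrame):
        X = score_matrix(bin_scores)[:, :dims]
    else:
        X = np.asarray(bin_scores, dtype=float)[:, :dims]
    if isinstance(guild_centroids, pd.DataFrame):
        guilds = list(guild_centroids.index)
        C = guild_centroids.to_numpy(dtype=float)[:, :dims]
    else:
        guilds = list(guild_centroids.keys())
        C = np.asarray([np.asarray(v, dtype=float)[:dims] for v in guild_centroids.values()])
    degenerate = False
    if len(X) < dims + 1:
        degenerate = True
    if criterion == "hull":
        if not degenerate:
            try:
                flags = points_in_hull(X, C)
            except QhullError:
                degenerate = True
        if degenerate:
            logger.warning("degenerate fossil hull; no guilds recovered")
            flags = np.zeros(len(C), dtype=bool)
    elif criterion == "mahalanobis":
        if len(X) < dims + 2:
            degenerate = True
            flags = np.zeros(len(C), dtype=bool)
        else:
            mean = X.mean(axis=0)
            cov = np.cov(X, rowvar=False)
            try:
                inv = np.linalg.inv(cov)
            except np.linalg.LinAlgError:
                logger.warning("singular score covariance; no guilds recovered")
                flags = np.zeros(len(C), dtype=bool)
                degenerate = True
            else:
                d2 = np.einsum("ij,jk,ik->i", C - mean, inv, C - mean)
                flags = d2 <= chi2.ppf(alpha, dims)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return pd.DataFrame({"guild": guilds, "recovered": flags,
                         "degenerate": degenerate})


def first_recovery(
    scores_by_bin: dict,
    guild_centroids,
    dims: int = 2,
    criterion: str = "hull",
) -> pd.DataFrame:
    """First bin (in the given temporal order) in which each guild is recovered.

    ``scores_by_bin`` maps bin name -> score subset, ordered oldest to
    youngest.  Returns guild, first_bin (name or NA) and first_bin_index.
    """
    names = list(scores_by_bin.keys())
    recovered_at: dict = {}
    for i, name in enumerate(names):
        flags = guild_recovery(
            scores_by_bin[name], guild_centroids, dims=dims, criterion=criterion
        )
        for _, row in flags.iterrows():
            if row["recovered"] and row["guild"] not in recovered_at:
                recovered_at[row["guild"]] = (name, i)
    if isinstance(guild_centroids, pd.DataFrame):
        guilds = list(guild_centroids.index)
    else:
        guilds = list(guild_centroids.keys())
    rows = []
    for g in guilds:
        name, idx = recovered_at.get(g, (pd.NA, pd.NA))
        rows.append({"guild": g, "first_bin": name, "first_bin_index": idx})
    return pd.DataFrame(rows)
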