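"""Disparity, permutation tests and morphospace-occupation measures.

Disparity is the sum of per-axis sample variances of ordination scores
(computed on PC1-PC4 by default).  Sampling variability is handled by
bootstrapping each group with replacement at its own size; pairs of groups are
then compared with Welch t-tests on the bootstrap distributions, sequentially
corrected with the Holm-Bonferroni procedure — mirroring the
disparity-through-time workflow of the dispRity package.

PERMANOVA uses the distance-algebra identity (within-group sums of squared
inter-point Euclidean distances divided by group sizes), equivalent to
centered-coordinate ANOVA, with significance from unrestricted label
permutations and the +1 correction so the minimum attainable p at
``n_perm=999`` is 0.001.

All stochastic operations are reproducible under a fixed seed and independent
of row order given the seed (rows are put into a canonical order before
resampling).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError
from .ordination import score_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sum of variances & bootstrap


def _scores_array(scores, axes: int | None = None) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        X = score_matrix(scores)
        if X.size == 0:  # plain frame without PC/CV columns
            X = scores.select_dtypes("number").to_numpy(dtype=float)
    else:
        X = np.asarray(scores, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if axes is not None:
        if axes > X.shape[1]:
            raise ValueError(f"axes={axes} exceeds table width {X.shape[1]}")
        X = X[:, :axes]
    return X


def sum_of_variances(scores, axes: int = 4) -> float:
    """Disparity: sum over the first ``axes`` columns of the sample variance."""
    X = _scores_array(scores, axes)
    if len(X) < 2:
        raise DegenerateDataError("variance undefined for a single specimen")
    return float(X.var(axis=0, ddof=1).sum())


@dataclass
class DisparityResult:
    """Per-group disparity with bootstrap distributions and pairwise tests."""

    group_order: list
    point_estimates: dict
    bootstrap_draws: dict           # group -> (n_boot,) array
    group_sizes: dict
    n_boot: int
    seed: int | None
    axes: int
    excluded: list = field(default_factory=list)
    pairwise: pd.DataFrame | None = None  # group_a, group_b, t, p_raw, p_holm


def _canonical_order(X: np.ndarray, ids=None) -> np.ndarray:
    """Row order independent of input order: by specimen id, else by value."""
    if ids is not None:
        return np.argsort(np.asarray(ids, dtype=object).astype(str), kind="stable")
    return np.lexsort(X.T[::-1])


def bootstrap_disparity(
    scores,
    groups,
    axes: int = 4,
    n_boot: int = 500,
    seed: int | None = None,
    group_order=None,
) -> DisparityResult:
    """Bootstrap the sum-of-variances statistic within each group.

    Each group is resampled with replacement at its original size ``n_boot``
    times.  Groups of size 1 are excluded with a warning.  The draw streams
    are derived from ``seed`` per group (in sorted-label order), so results do
    not depend on row order.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    ids = None
    if isinstance(scores, pd.DataFrame) and "specimen_id" in scores.columns:
        ids = scores["specimen_id"].to_numpy()
    X = _scores_array(scores, axes)
    groups = np.asarray(groups)
    if len(groups) != len(X):
        raise ValueError("groups length must match score rows")
    labels = list(group_order) if group_order is not None else list(pd.unique(groups))
    sorted_labels = sorted(str(l) for l in labels)
    estimates, draws, sizes, excluded = {}, {}, {}, []
    for label in labels:
        mask = groups == label
        Xg = X[mask]
        idg = ids[mask] if ids is not None else None
        if len(Xg) < 2:
            logger.warning("group %r has < 2 members; excluded from disparity", label)
            excluded.append(label)
            continue
        order = _canonical_order(Xg, idg)
        Xg = Xg[order]
        rng = np.random.default_rng(
            np.random.SeedSequence([0 if seed is None else seed,
                                    sorted_labels.index(str(label))])
        )
        idx = rng.integers(0, len(Xg), size=(n_boot, len(Xg)))
        boot = Xg[idx]  # (n_boot, n_g, axes)
        draws[label] = boot.var(axis=1, ddof=1).sum(axis=1)
        estimates[label] = float(Xg.var(axis=0, ddof=1).sum())
        sizes[label] = int(len(Xg))
    return DisparityResult(
        group_order=[l for l in labels if l not in excluded],
        point_estimates=estimates,
        bootstrap_draws=draws,
        group_sizes=sizes,
        n_boot=n_boot,
        seed=seed,
        axes=axes,
        excluded=excluded,
    )


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def sequential_disparity_ttests(
    result: DisparityResult,
    order=None,
    mode: str = "adjacent",
) -> DisparityResult:
    """Welch t-tests between bootstrap disparity distributions.

    ``mode='adjacent'`` compares consecutive groups in ``order`` (bins in
    time); ``mode='all-pairs'`` compares every pair.  P-values are
    Holm-corrected across the comparison family.  Pairs whose distributions
    are both degenerate (zero variance) get p = 1 by convention and a flag.
    """
    order = list(order) if order is not None else list(result.group_order)
    missing = [g for g in order if g not in result.bootstrap_draws]
    if missing:
        raise DegenerateDataError(f"groups without distributions: {missing}")
    if len(order) < 2:
        raise DegenerateDataError("need at least 2 groups to compare")
    if mode == "adjacent":
        pairs = list(zip(order[:-1], order[1:]))
    elif mode == "all-pairs":
        pairs = list(itertools.combinations(order, 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for a, b in pairs:
        da, db = result.bootstrap_draws[a], result.bootstrap_draws[b]
        degenerate = da.std() == 0 and db.std() == 0
        if degenerate:
            t, p = (np.nan, 1.0) if np.isclose(da.mean(), db.mean()) else (np.inf, 0.0)
            if p == 1.0:
                logger.warning("degenerate distributions for pair (%r, %r); p=1", a, b)
        else:
            t, p = ttest_ind(da, db, equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "estimate_a": result.point_estimates[a],
                "estimate_b": result.point_estimates[b],
                "t": float(t),
                "p_raw": float(p),
                "degenerate": bool(degenerate),
            }
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_bonferroni(table["p_raw"].to_numpy())
    result.pairwise = table
    return result


def classify_tempo(result: DisparityResult, order=None, alpha: float = 0.05,
                   attained_fraction: float = 0.45) -> str:
    """Classify a fossil disparity trajectory as early-burst or constant-rate.

    Combines the sequential (adjacent) Holm-corrected test pattern on the
    ordered fossil time bins with the shape of the disparity curve.  With no
    significant change anywhere the trajectory is ``flat``.  Otherwise the
    deciding signature is how much of the final fossil disparity was already
    attained before the last bin: under an early burst most variety
    accumulates early (``D[-2]/D[-1]`` large), under constant-rate
    diversification most guilds are still arriving in the last bin
    (``D[-2]/D[-1]`` small).  The trajectory is ``constant-rate`` when the
    final adjacent comparison is a significant increase and the penultimate
    bin holds less than ``attained_fraction`` of the final disparity;
    otherwise it is ``early-burst``.
    """
    order = list(order) if order is not None else list(result.group_order)
    if result.pairwise is None or list(result.pairwise["group_a"]) != order[:-1]:
        result = sequential_disparity_ttests(result, order=order, mode="adjacent")
    table = result.pairwise
    D = [result.point_estimates[g] for g in order]
    if not (table["p_holm"] < alpha).any():
        return "flat"
    last = table.iloc[-1]
    late_rise = D[-1] - D[-2]
    attained = D[-2] / D[-1] if D[-1] > 0 else 1.0
    if last["p_holm"] < alpha and late_rise > 0 and attained < attained_fraction:
        return "constant-rate"
    return "early-burst"


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    seed: int | None
    method: str = "permutation"          # or "exact"
    pairwise: pd.DataFrame | None = None


def _permanova_stats(D2: np.ndarray, inverse: np.ndarray, counts: np.ndarray):
    n = len(inverse)
    g = len(counts)
    sst = D2.sum() / (2 * n)
    ssw = 0.0
    for i in range(g):
        mask = inverse == i
        ssw += D2[np.ix_(mask, mask)].sum() / (2 * counts[i])
    ssb = sst - ssw
    if ssw <= 1e-300:
        F = np.inf if ssb > 1e-300 else 0.0
    else:
        F = (ssb / (g - 1)) / (ssw / (n - g))
    R2 = ssb / sst if sst > 0 else 0.0
    return float(F), float(R2), sst


def _perm_F(D2: np.ndarray, perms: np.ndarray, g: int, counts: np.ndarray,
            sst: float) -> np.ndarray:
    """Pseudo-F for many label permutations, vectorized per group.

    ``perms`` is (n_perm, n) of group indices 0..g-1.
    """
    n = perms.shape[1]
    ssw = np.zeros(len(perms))
    for i in range(g):
        Z = (perms == i).astype(float)          # (n_perm, n)
        ssw += np.einsum("kn,kn->k", Z @ D2, Z) / (2 * counts[i])
    ssb = sst - ssw
    dfw = np.maximum(ssw, 1e-300)
    F = (ssb / (g - 1)) / (dfw / (n - g))
    F[ssw <= 1e-300] = np.where(ssb[ssw <= 1e-300] > 1e-300, np.inf, 0.0)
    return F


def permanova(
    scores,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """Permutational MANOVA on Euclidean distances between score rows.

    ``p = (count of permuted F >= observed + 1) / (n_perm + 1)``; with
    ``exact=True`` all distinct label assignments are enumerated instead and
    p is the exact fraction (the observed assignment included).
    """
    X = _scores_array(scores)
    groups = np.asarray(groups)
    if len(groups) != len(X):
        raise ValueError("groups length must match score rows")
    labels, inverse = np.unique(groups, return_inverse=True)
    counts = np.bincount(inverse)
    g = len(labels)
    n = len(X)
    if g < 2:
        raise DegenerateDataError("PERMANOVA needs >= 2 groups")
    if counts.min() < 1 or n < 4:
        raise DegenerateDataError("PERMANOVA needs non-empty groups and n >= 4")
    D2 = squareform(pdist(X)) ** 2
    F_obs, R2, sst = _permanova_stats(D2, inverse, counts)

    if exact:
        from sympy.utilities.iterables import multiset_permutations

        perms = np.array(list(multiset_permutations(inverse.tolist())))
        Fp = _perm_F(D2, perms, g, counts, sst)
        p = float(np.mean(Fp >= F_obs - 1e-12))
        return PermanovaResult(F_obs, R2, p, len(perms), seed, method="exact")

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perms = inverse[order]
    Fp = _perm_F(D2, perms, g, counts, sst)
    count = int(np.sum(Fp >= F_obs - 1e-12))
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(F_obs, R2, float(p), n_perm, seed)


def pairwise_permanova(
    scores,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    correction: str = "holm",
) -> pd.DataFrame:
    """PERMANOVA on every group pair; raw p always reported, Holm optional."""
    X = _scores_array(scores)
    groups = np.asarray(groups)
    labels = sorted(map(str, pd.unique(groups)))
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(labels, 2)):
        mask = (groups.astype(str) == a) | (groups.astype(str) == b)
        child = np.random.SeedSequence([0 if seed is None else seed, i])
        res = permanova(
            X[mask], groups[mask], n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        rows.append(
            {"group_a": a, "group_b": b, "pseudo_F": res.pseudo_F,
             "R2": res.R2, "p_raw": res.p}
        )
    table = pd.DataFrame(rows)
    if correction == "holm":
        table["p_adjusted"] = holm_bonferroni(table["p_raw"].to_numpy())
    elif correction == "none":
        table["p_adjusted"] = table["p_raw"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return table


# ---------------------------------------------------------------------------
# morphospace occupation


@dataclass
class HullMeasure:
    dims: int
    measure: float              # area (2 axes) or hypervolume (> 2 axes)
    vertices: np.ndarray        # hull vertex coordinates, ordered for 2-D
    degenerate: bool = False


def hull_measure(scores, dims: int = 2) -> HullMeasure:
    """Convex-hull occupation of the first ``dims`` score axes.

    Degenerate point sets (too few points, collinear/coplanar) return a
    measure of 0 with the ``degenerate`` flag set.
    """
    X = _scores_array(scores, dims)
    if len(X) < dims + 1:
        return HullMeasure(dims, 0.0, np.empty((0, dims)), degenerate=True)
    try:
        hull = ConvexHull(X)
    except QhullError:
        return HullMeasure(dims, 0.0, np.empty((0, dims)), degenerate=True)
    # ConvexHull.volume is the area in 2-D and the hypervolume above
    return HullMeasure(dims, float(hull.volume), X[hull.vertices])
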