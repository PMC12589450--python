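"""Reading, writing and preprocessing of 2-D landmark configurations.

The on-disk format is the TPS dialect written by tpsDig2: each record starts
with an ``LM=<n>`` line followed by ``n`` whitespace-separated ``x y`` lines;
digitized curves may follow as a ``CURVES=<c>`` line with one ``POINTS=<k>``
block per curve; trailing ``ID=``, ``IMAGE=`` and ``SCALE=`` lines attach the
specimen identifier, the source image and a units-per-pixel factor.  Both the
structured form (``LM=7`` plus one ``CURVES`` block) and the flattened form
(``LM=45``, no curves) are accepted.

TPS coordinates are image-based (origin at the top-left of the photograph with
y increasing downwards), so ``read_tps`` negates the y axis by default
(``y_flip=True``).  This changes the sign of shape axes only, never distances.
Digitized curves are resampled to evenly spaced semilandmarks once at ingest
(:func:`resample_curve`) and treated as fixed landmarks thereafter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCurveError,
    StructureError,
    TPSParseError,
)

logger = logging.getLogger(__name__)

#: metadata columns recognised in specimen tables
META_COLUMNS = ("guild", "assemblage", "age_ka", "site", "tooth_row")


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmarks plus metadata.

    ``points`` holds the fixed landmarks first, then the (resampled) curve
    points, in file order.  ``curves`` lists half-open index ranges
    ``(start, stop)`` into ``points`` for each digitized curve.
    """

    specimen_id: str
    points: np.ndarray
    n_fixed: int
    curves: list[tuple[int, int]] = field(default_factory=list)
    scale: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise StructureError(
                f"{self.specimen_id}: points must be (n, 2), got {self.points.shape}"
            )
        if len(self.points) < 3:
            raise StructureError(f"{self.specimen_id}: need >= 3 points")
        if not 0 <= self.n_fixed <= len(self.points):
            raise StructureError(f"{self.specimen_id}: bad n_fixed={self.n_fixed}")
        covered = self.n_fixed
        for start, stop in self.curves:
            if start != covered or stop <= start or stop > len(self.points):
                raise StructureError(
                    f"{self.specimen_id}: curve range ({start}, {stop}) must be "
                    "disjoint and follow the fixed landmarks"
                )
            covered = stop
        age = self.meta.get("age_ka")
        if age is not None and not (float(age) >= 0):
            raise StructureError(f"{self.specimen_id}: age_ka must be >= 0, got {age}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def curve_points(self, index: int) -> np.ndarray:
        start, stop = self.curves[index]
        return self.points[start:stop]

    def structure(self) -> tuple:
        """Hashable structural signature used for homogeneity checks."""
        return (self.n_fixed, tuple(stop - start for start, stop in self.curves),
                self.n_points)


@dataclass
class ShapeDataset:
    """An ordered, structurally homogeneous collection of configurations."""

    configurations: list[LandmarkConfiguration]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StructureError(f"duplicate specimen ids: {dupes}")
        if self.configurations:
            ref = self.configurations[0].structure()
            offenders = [
                c.specimen_id for c in self.configurations if c.structure() != ref
            ]
            if offenders:
                raise StructureError(
                    f"inconsistent landmark structure (expected {ref}): {offenders}"
                )

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    def __getitem__(self, i: int) -> LandmarkConfiguration:
        return self.configurations[i]

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def points_array(self) -> np.ndarray:
        """Stack all configurations into an ``(n, p, 2)`` array."""
        return np.stack([c.points for c in self.configurations])

    def meta_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.configurations:
            row = {"specimen_id": c.specimen_id}
            row.update(c.meta)
            rows.append(row)
        return pd.DataFrame(rows)

    def subset(self, ids: Iterable[str]) -> "ShapeDataset":
        wanted = set(ids)
        return ShapeDataset(
            [c for c in self.configurations if c.specimen_id in wanted],
            provenance=dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# TPS parsing / writing


def _parse_key(line: str) -> tuple[str, str] | None:
    if "=" in line:
        key, _, value = line.partition("=")
        key = key.strip().upper()
        if key in {"LM", "CURVES", "POINTS", "ID", "IMAGE", "SCALE"}:
            return key, value.strip()
    return None


def _read_coords(lines: list[str], pos: int, count: int, record: str) -> tuple[np.ndarray, int]:
    coords = []
    while len(coords) < count and pos < len(lines):
        line = lines[pos].strip()
        if not line:
            pos += 1
            continue
        if _parse_key(line) is not None:
            break
        parts = line.split()
        if len(parts) != 2:
            raise TPSParseError(f"record {record!r}: bad coordinate line {line!r}")
        try:
            coords.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise TPSParseError(f"record {record!r}: bad coordinate line {line!r}") from exc
        pos += 1
    if len(coords) != count:
        raise TPSParseError(
            f"record {record!r}: declared {count} points but found {len(coords)}"
        )
    return np.asarray(coords, dtype=float), pos


def read_tps(path: str | Path, y_flip: bool = True) -> ShapeDataset:
    """Read a tpsDig2-style TPS file into a :class:`ShapeDataset`.

    ``SCALE=`` factors are applied to the coordinates; with ``y_flip`` (the
    default) y coordinates are negated so shapes follow the mathematical
    convention rather than the image one.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    pos = 0
    record_index = 0
    while pos < len(lines):
        line = lines[pos].strip()
        if not line:
            pos += 1
            continue
        parsed = _parse_key(line)
        if parsed is None or parsed[0] != "LM":
            raise TPSParseError(f"unexpected line outside a record: {line!r}")
        record_index += 1
        record = f"#{record_index}"
        try:
            n_fixed = int(parsed[1])
        except ValueError as exc:
            raise TPSParseError(f"record {record}: bad LM= count {parsed[1]!r}") from exc
        pos += 1
        fixed, pos = _read_coords(lines, pos, n_fixed, record)
        curve_blocks: list[np.ndarray] = []
        specimen_id = None
        image = None
        scale = None
        while pos < len(lines):
            line = lines[pos].strip()
            if not line:
                pos += 1
                continue
            parsed = _parse_key(line)
            if parsed is None:
                raise TPSParseError(f"record {record}: unexpected line {line!r}")
            key, value = parsed
            if key == "LM":
                break
            pos += 1
            if key == "CURVES":
                n_curves = int(value)
                for _ in range(n_curves):
                    while pos < len(lines) and not lines[pos].strip():
                        pos += 1
                    cparsed = _parse_key(lines[pos].strip()) if pos < len(lines) else None
                    if cparsed is None or cparsed[0] != "POINTS":
                        raise TPSParseError(
                            f"record {record}: expected POINTS= after CURVES="
                        )
                    n_pts = int(cparsed[1])
                    pos += 1
                    pts, pos = _read_coords(lines, pos, n_pts, record)
                    curve_blocks.append(pts)
            elif key == "ID":
                specimen_id = value
            elif key == "IMAGE":
                image = value
            elif key == "SCALE":
                scale = float(value)
        if specimen_id is None:
            specimen_id = Path(image).stem if image else f"record_{record_index}"
        points = np.vstack([fixed] + curve_blocks) if curve_blocks else fixed
        if scale is not None:
            points = points * scale
        if y_flip:
            points = points * np.array([1.0, -1.0])
        curves = []
        start = n_fixed
        for block in curve_blocks:
            curves.append((start, start + len(block)))
            start += len(block)
        meta = {} if image is None else {"image": image}
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                points=points,
                n_fixed=n_fixed,
                curves=curves,
                scale=scale,
                meta=meta,
            )
        )
    if not configs:
        logger.warning("TPS file %s contains no records", path)
    return ShapeDataset(
        configs,
        provenance={"source": str(path), "y_flip": y_flip},
    )


def write_tps(
    dataset: ShapeDataset,
    path: str | Path,
    structured: bool = True,
    y_flip: bool = False,
    precision: int = 6,
) -> None:
    """Write a dataset as a TPS file re-readable by :func:`read_tps`.

    In structured mode (default) each record is emitted as ``LM=<n_fixed>``
    plus ``CURVES=``/``POINTS=`` blocks; otherwise all points are flattened
    into a single ``LM=`` block.  Set ``y_flip`` to negate y on output,
    mirroring the read-time convention.
    """
    path = Path(path)
    fmt = f"{{:.{precision}f}} {{:.{precision}f}}"
    sign = np.array([1.0, -1.0]) if y_flip else np.array([1.0, 1.0])
    out: list[str] = []
    for config in dataset:
        pts = config.points * sign
        if structured and config.curves:
            out.append(f"LM={config.n_fixed}")
            for x, y in pts[: config.n_fixed]:
                out.append(fmt.format(x, y))
            out.append(f"CURVES={len(config.curves)}")
            for start, stop in config.curves:
                out.append(f"POINTS={stop - start}")
                for x, y in pts[start:stop]:
                    out.append(fmt.format(x, y))
        else:
            out.append(f"LM={config.n_points}")
            for x, y in pts:
                out.append(fmt.format(x, y))
        out.append(f"ID={config.specimen_id}")
    path.write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# curve resampling


def resample_curve(curve_points: np.ndarray, n_out: int) -> np.ndarray:
    """Resample a piecewise-linear curve at equal arc-length spacing.

    Returns ``n_out`` points on the input polyline; the first and last input
    points are preserved exactly.
    """
    pts = np.asarray(curve_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("curve must be an (n >= 2, 2) array")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0.0:
        raise DegenerateCurveError("curve has zero arc length (all points identical)")
    targets = np.linspace(0.0, total, n_out)
    x = np.interp(targets, arc, pts[:, 0])
    y = np.interp(targets, arc, pts[:, 1])
    out = np.column_stack([x, y])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def resample_curves(dataset: ShapeDataset, n_out: int | Sequence[int]) -> ShapeDataset:
    """Resample every digitized curve of every specimen to ``n_out`` points."""
    configs = []
    for config in dataset:
        counts = (
            [n_out] * len(config.curves) if isinstance(n_out, int) else list(n_out)
        )
        if len(counts) != len(config.curves):
            raise StructureError(
                f"{config.specimen_id}: {len(counts)} counts for "
                f"{len(config.curves)} curves"
            )
        blocks = [config.points[: config.n_fixed]]
        curves = []
        start = config.n_fixed
        for i, k in enumerate(counts):
            blocks.append(resample_curve(config.curve_points(i), k))
            curves.append((start, start + k))
            start += k
        configs.append(
            replace(config, points=np.vstack(blocks), curves=curves)
        )
    provenance = dict(dataset.provenance)
    provenance["resampled_to"] = n_out
    return ShapeDataset(configs, provenance=provenance)


# ---------------------------------------------------------------------------
# metadata


def attach_metadata(
    dataset: ShapeDataset, table: pd.DataFrame | str | Path
) -> ShapeDataset:
    """Merge a specimen metadata table (keyed by ``specimen_id``) into a dataset.

    Specimens missing from the table keep their existing metadata and are
    reported via a warning; the merge is independent of table row order.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    if "specimen_id" not in table.columns:
        raise ValueError("metadata table must have a 'specimen_id' column")
    if table.empty:
        logger.warning("metadata table is empty; dataset unchanged")
        return ShapeDataset(
            [replace(c, meta=dict(c.meta)) for c in dataset],
            provenance=dict(dataset.provenance),
        )
    if table["specimen_id"].duplicated().any():
        dupes = sorted(table.loc[table["specimen_id"].duplicated(), "specimen_id"])
        raise ValueError(f"duplicate specimen_id keys in metadata table: {dupes}")
    if "age_ka" in table.columns:
        for row_idx, value in table["age_ka"].items():
            if pd.isna(value):
                continue
            try:
                age = float(value)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"metadata row {row_idx} (specimen "
                    f"{table.at[row_idx, 'specimen_id']!r}): invalid age_ka {value!r}"
                ) from exc
            if age < 0:
                raise ValueError(
                    f"metadata row {row_idx} (specimen "
                    f"{table.at[row_idx, 'specimen_id']!r}): age_ka must be >= 0"
                )
    indexed = table.set_index("specimen_id")
    configs = []
    missing = []
    for config in dataset:
        meta = dict(config.meta)
        if config.specimen_id in indexed.index:
            row = indexed.loc[config.specimen_id]
            for col, value in row.items():
                if pd.isna(value):
                    continue
                meta[col] = float(value) if col == "age_ka" else value
        else:
            missing.append(config.specimen_id)
        configs.append(replace(config, meta=meta))
    if missing:
        logger.warning(
            "%d specimens missing from metadata table: %s",
            len(missing),
            missing[:10],
        )
    return ShapeDataset(configs, provenance=dict(dataset.provenance))
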