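"""Cell-to-region assignment, point editing, tallies, 3D lifting, and atlas comparison.

Once cells are in the atlas-canvas frame, each one is pushed through the
virtual section's per-pixel coordinate map to the 3D voxel it represents
and resolved to a named structure.  Points falling on label-0 voxels or
outside the volume are assigned the reserved outside-brain record — a
first-class category that participates in every tally, so the per-brain
total always equals the number of ingested cells.

Counts are reported at the annotation's leaf label (flat region lists);
hierarchy roll-ups are available via ``rollup_to_parent``.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .atlas_model import (
    OUT_OF_VOLUME,
    OUTSIDE_BRAIN,
    AtlasBundle,
    SlicePlane,
    StructureNode,
    extract_slice,
    lookup_region,
)
from .ingest import PointSet

__all__ = [
    "SliceRecord",
    "RegionCountTable",
    "AtlasComparison",
    "assign_regions",
    "edit_points",
    "tally_regions",
    "to_ccf3d",
    "compare_atlases",
    "AddPoint",
    "MovePoint",
    "DeletePoint",
    "PolygonDelete",
    "PolygonTranslate",
]


@dataclass
class SliceRecord:
    """One registered slice: atlas-frame cell points with per-point structure assignments."""

    slice_id: str
    slice_plane: SlicePlane
    atlas_variant: str
    points: PointSet
    assignments: list[StructureNode]
    canvas_shape: tuple[int, int]
    transform_path: str = ""
    edit_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.assignments) != len(self.points):
            raise ValueError("assignments length must equal number of points")

    def to_frame(self) -> pd.DataFrame:
        """Per-cell region list: one row per counted cell."""
        return pd.DataFrame(
            {
                "slice_id": self.slice_id,
                "x": self.points.x,
                "y": self.points.y,
                "structure_id": [a.id for a in self.assignments],
                "acronym": [a.acronym for a in self.assignments],
                "name": [a.name for a in self.assignments],
            }
        )


@dataclass
class RegionCountTable:
    """Structure-keyed cell counts for one slice or one whole brain."""

    rows: pd.DataFrame  # columns: structure_id, acronym, name, count
    scope: str  # "per_slice" | "per_brain"
    atlas_variant: str

    def __post_init__(self) -> None:
        required = ["structure_id", "acronym", "name", "count"]
        if list(self.rows.columns) != required:
            self.rows = self.rows[required]
        if len(self.rows) and (self.rows["count"] < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        """Total cells including the outside-brain row."""
        return int(self.rows["count"].sum())

    @property
    def counts(self) -> dict[int, int]:
        return dict(zip(self.rows["structure_id"].astype(int), self.rows["count"].astype(int)))

    @property
    def n_structures(self) -> int:
        """Number of named brain structures with nonzero counts (outside excluded)."""
        inside = self.rows[self.rows["structure_id"] != OUTSIDE_BRAIN.id]
        return int((inside["count"] > 0).sum())

    def names(self, include_outside: bool = False) -> set[str]:
        rows = self.rows if include_outside else self.rows[self.rows["structure_id"] != 0]
        return set(rows.loc[rows["count"] > 0, "name"])

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(values + 0.5).astype(np.int64)


def assign_regions(
    point_set: PointSet,
    bundle: AtlasBundle,
    slice_plane: SlicePlane,
    canvas_shape: tuple[int, int] | None = None,
    slice_id: str = "",
    transform_path: str = "",
) -> SliceRecord:
    """Assign every atlas-frame cell point to a brain structure.

    Each point's pixel (half-up rounded; sub-pixel boundaries are below
    atlas resolution) is mapped through the virtual section's coordinate
    map to its 3D voxel, then resolved via the structure tree.  Points off
    the canvas or on voxels outside the brain are assigned
    :data:`~histoslice_quant.atlas_model.OUTSIDE_BRAIN`.

    Sagittal quantification with the Chon (modified Franklin–Paxinos)
    variant is rejected: those labels are defined for coronal use.
    """
    if point_set.frame != "atlas":
        raise ValueError(f"point_set must be in the atlas frame, got {point_set.frame!r}")
    if bundle.variant == "chon" and slice_plane.plane == "sagittal":
        raise ValueError(
            "sagittal cell count quantification with the chon atlas variant is not supported"
        )
    _, coordinate_map = extract_slice(bundle, slice_plane, canvas_shape)
    rows_n, cols_n = coordinate_map.shape[:2]
    cols = _round_half_up(point_set.x)
    rows = _round_half_up(point_set.y)
    assignments: list[StructureNode] = []
    for r, c in zip(rows, cols):
        if not (0 <= r < rows_n and 0 <= c < cols_n):
            assignments.append(OUTSIDE_BRAIN)
            continue
        voxel = coordinate_map[r, c]
        if voxel[0] == OUT_OF_VOLUME:
            assignments.append(OUTSIDE_BRAIN)
        else:
            assignments.append(lookup_region(bundle, voxel))
    return SliceRecord(
        slice_id=slice_id,
        slice_plane=slice_plane,
        atlas_variant=bundle.variant,
        points=point_set,
        assignments=assignments,
        canvas_shape=(rows_n, cols_n),
        transform_path=transform_path,
    )


# ---------------------------------------------------------------------------
# point edits


@dataclass(frozen=True)
class AddPoint:
    x: float
    y: float


@dataclass(frozen=True)
class MovePoint:
    index: int
    x: float
    y: float


@dataclass(frozen=True)
class DeletePoint:
    index: int


@dataclass(frozen=True)
class PolygonDelete:
    """Delete every point inside (or on the boundary of) the polygon."""

    vertices: tuple


@dataclass(frozen=True)
class PolygonTranslate:
    """Translate every point inside (or on the boundary of) the polygon by (dx, dy)."""

    vertices: tuple
    dx: float
    dy: float


def _polygon_mask(vertices, points: np.ndarray) -> np.ndarray:
    poly = Polygon(vertices)
    if not poly.is_valid:
        raise ValueError("self-intersecting or otherwise invalid selection polygon")
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    # intersects includes the boundary, matching an even-odd rule on a simple polygon
    return shapely.intersects_xy(poly, points[:, 0], points[:, 1])


def edit_points(
    target: PointSet | SliceRecord,
    edits: list,
    bundle: AtlasBundle | None = None,
):
    """Apply add / move / delete / polygon-group edits in order.

    Accepts a :class:`~histoslice_quant.ingest.PointSet` or a
    :class:`SliceRecord`; for a record, region assignments are recomputed
    (requires ``bundle``) and an edit log entry is appended per operation
    for provenance.  Indices are 0-based into the current point order.
    """
    record = target if isinstance(target, SliceRecord) else None
    point_set = record.points if record is not None else target
    pts = point_set.points.copy()
    log: list[dict] = []
    for edit in edits:
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        if isinstance(edit, AddPoint):
            pts = np.vstack([pts, [[edit.x, edit.y]]])
            log.append({"op": "add", "x": edit.x, "y": edit.y, "time": stamp})
        elif isinstance(edit, MovePoint):
            if not (0 <= edit.index < len(pts)):
                raise IndexError(f"move index {edit.index} out of range for {len(pts)} points")
            pts[edit.index] = (edit.x, edit.y)
            log.append(
                {"op": "move", "index": edit.index, "x": edit.x, "y": edit.y, "time": stamp}
            )
        elif isinstance(edit, DeletePoint):
            if not (0 <= edit.index < len(pts)):
                raise IndexError(f"delete index {edit.index} out of range for {len(pts)} points")
            pts = np.delete(pts, edit.index, axis=0)
            log.append({"op": "delete", "index": edit.index, "time": stamp})
        elif isinstance(edit, PolygonDelete):
            mask = _polygon_mask(edit.vertices, pts)
            pts = pts[~mask]
            log.append(
                {"op": "polygon_delete", "n_deleted": int(mask.sum()), "time": stamp}
            )
        elif isinstance(edit, PolygonTranslate):
            mask = _polygon_mask(edit.vertices, pts)
            pts[mask] += (edit.dx, edit.dy)
            log.append(
                {
                    "op": "polygon_translate",
                    "n_moved": int(mask.sum()),
                    "dx": edit.dx,
                    "dy": edit.dy,
                    "time": stamp,
                }
            )
        else:
            raise TypeError(f"unknown edit operation: {edit!r}")
    new_points = point_set.with_points(pts)
    # group edits may change the count; drop per-point labels rather than misalign
    if new_points.labels is not None and len(new_points.labels) != len(pts):
        new_points = PointSet(
            points=pts, frame=point_set.frame, source_image=point_set.source_image
        )
    if record is None:
        return new_points
    if bundle is None:
        raise ValueError("editing a SliceRecord requires the atlas bundle for re-assignment")
    new_record = assign_regions(
        new_points,
        bundle,
        record.slice_plane,
        canvas_shape=record.canvas_shape,
        slice_id=record.slice_id,
        transform_path=record.transform_path,
    )
    new_record.edit_log = record.edit_log + log
    return new_record


# ---------------------------------------------------------------------------
# tallies and 3D lifting


def _tally_one(record: SliceRecord) -> pd.DataFrame:
    rows: dict[int, list] = {}
    for node in record.assignments:
        if node.id in rows:
            rows[node.id][3] += 1
        else:
            rows[node.id] = [node.id, node.acronym, node.name, 1]
    df = pd.DataFrame(
        rows.values(), columns=["structure_id", "acronym", "name", "count"]
    )
    return df.sort_values("structure_id").reset_index(drop=True)


def tally_regions(records: list[SliceRecord], scope: str = "per_brain"):
    """Tally cell counts by structure.

    ``scope='per_slice'`` returns one :class:`RegionCountTable` per record;
    ``scope='per_brain'`` returns a single table with element-wise summed
    counts.  All records must share an atlas variant; totals (including the
    outside-brain row) are conserved.
    """
    if scope not in ("per_slice", "per_brain"):
        raise ValueError("scope must be 'per_slice' or 'per_brain'")
    variants = {r.atlas_variant for r in records}
    if len(variants) > 1:
        raise ValueError(f"records mix atlas variants: {sorted(variants)}")
    variant = variants.pop() if variants else "allen"
    if scope == "per_slice":
        return [
            RegionCountTable(rows=_tally_one(r), scope="per_slice", atlas_variant=variant)
            for r in records
        ]
    if not records:
        empty = pd.DataFrame(columns=["structure_id", "acronym", "name", "count"])
        return RegionCountTable(rows=empty, scope="per_brain", atlas_variant=variant)
    combined = pd.concat([_tally_one(r) for r in records], ignore_index=True)
    agg = (
        combined.groupby(["structure_id", "acronym", "name"], as_index=False)["count"]
        .sum()
        .sort_values("structure_id")
        .reset_index(drop=True)
    )
    return RegionCountTable(rows=agg, scope="per_brain", atlas_variant=variant)


def to_ccf3d(slice_record: SliceRecord, bundle: AtlasBundle) -> pd.DataFrame:
    """Lift a slice's cells to 3D atlas coordinates in microns (AP, DV, ML).

    Every point's pixel is mapped through the section's coordinate map and
    multiplied by the voxel size.  Outside-brain points are exported with
    ``outside=True``; points whose pixel sampled outside the volume have
    NaN coordinates.
    """
    _, coordinate_map = extract_slice(
        bundle, slice_record.slice_plane, slice_record.canvas_shape
    )
    rows_n, cols_n = coordinate_map.shape[:2]
    n = len(slice_record.points)
    um = np.full((n, 3), np.nan)
    voxels = np.full((n, 3), OUT_OF_VOLUME, dtype=np.int64)
    cols = _round_half_up(slice_record.points.x)
    rows = _round_half_up(slice_record.points.y)
    for i, (r, c) in enumerate(zip(rows, cols)):
        if 0 <= r < rows_n and 0 <= c < cols_n:
            voxel = coordinate_map[r, c]
            if voxel[0] != OUT_OF_VOLUME:
                voxels[i] = voxel
                um[i] = voxel * bundle.voxel_size_um
    return pd.DataFrame(
        {
            "AP_um": um[:, 0],
            "DV_um": um[:, 1],
            "ML_um": um[:, 2],
            "voxel_ap": voxels[:, 0],
            "voxel_dv": voxels[:, 1],
            "voxel_ml": voxels[:, 2],
            "structure_id": [a.id for a in slice_record.assignments],
            "acronym": [a.acronym for a in slice_record.assignments],
            "outside": [a.id == OUTSIDE_BRAIN.id for a in slice_record.assignments],
            "slice_id": slice_record.slice_id,
        }
    )


# ---------------------------------------------------------------------------
# atlas comparison


@dataclass(frozen=True)
class AtlasComparison:
    """Paired comparison of the same cells quantified under two ontologies."""

    n_slices: int
    pearson_r_totals: float
    pearson_p_totals: float
    t_structures: float
    t_dof: int
    t_p: float
    mean_structures_a: float
    sd_structures_a: float
    mean_structures_b: float
    sd_structures_b: float
    name_overlap: int
    names_a: int
    names_b: int


def compare_atlases(
    tables_a: list[RegionCountTable],
    tables_b: list[RegionCountTable],
) -> AtlasComparison:
    """Compare per-slice quantifications under two atlas ontologies.

    Computes the Pearson correlation of paired per-slice cell totals, a
    paired t statistic on the number of structures per slice, per-atlas
    means/SDs of structures per slice, and the nomenclature overlap by
    exact structure-name matching across all slices.  Requires >= 3 paired
    slices.
    """
    if len(tables_a) != len(tables_b):
        raise ValueError(
            f"paired slice counts differ: {len(tables_a)} vs {len(tables_b)}"
        )
    n = len(tables_a)
    if n < 3:
        raise ValueError(f"at least 3 paired slices required, got {n}")
    totals_a = np.array([t.total for t in tables_a], dtype=float)
    totals_b = np.array([t.total for t in tables_b], dtype=float)
    if np.std(totals_a) == 0 or np.std(totals_b) == 0:
        r, p_r = (1.0, 0.0) if np.array_equal(totals_a, totals_b) else (np.nan, np.nan)
    else:
        r, p_r = stats.pearsonr(totals_a, totals_b)

    ns_a = np.array([t.n_structures for t in tables_a], dtype=float)
    ns_b = np.array([t.n_structures for t in tables_b], dtype=float)
    diff = ns_a - ns_b
    sd_diff = diff.std(ddof=1)
    if sd_diff == 0:
        t_stat = 0.0 if diff.mean() == 0 else float(np.sign(diff.mean()) * np.inf)
        t_p = 1.0 if diff.mean() == 0 else 0.0
    else:
        t_stat, t_p = stats.ttest_rel(ns_a, ns_b)

    names_a = set().union(*(t.names() for t in tables_a))
    names_b = set().union(*(t.names() for t in tables_b))
    return AtlasComparison(
        n_slices=n,
        pearson_r_totals=float(r),
        pearson_p_totals=float(p_r),
        t_structures=float(t_stat),
        t_dof=n - 1,
        t_p=float(t_p),
        mean_structures_a=float(ns_a.mean()),
        sd_structures_a=float(ns_a.std(ddof=1)),
        mean_structures_b=float(ns_b.mean()),
        sd_structures_b=float(ns_b.std(ddof=1)),
        name_overlap=len(names_a & names_b),
        names_a=len(names_a),
        names_b=len(names_b),
    )


def rollup_to_parent(table: RegionCountTable, bundle: AtlasBundle) -> RegionCountTable:
    """Roll leaf counts up one level of the structure tree (optional view)."""
    rows = []
    for _, row in table.rows.iterrows():
        node = bundle.structure_tree.get(int(row["structure_id"]))
        if node is None or node.parent_id is None or node.parent_id not in bundle.structure_tree:
            rows.append(row)
            continue
        parent = bundle.structure_tree[node.parent_id]
        rows.append(
            pd.Series(
                {
                    "structure_id": parent.id,
                    "acronym": parent.acronym,
                    "name": parent.name,
                    "count": row["count"],
                }
            )
        )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["structure_id", "acronym", "name"], as_index=False)["count"]
        .sum()
        .sort_values("structure_id")
        .reset_index(drop=True)
    )
    return RegionCountTable(rows=agg, scope=table.scope, atlas_variant=table.atlas_variant)
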