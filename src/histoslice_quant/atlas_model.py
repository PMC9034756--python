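"""Annotation volumes, structure trees, and oblique virtual sectioning.

The 3D mouse brain atlas is represented as an integer annotation volume in
which every voxel carries a brain-structure label, plus a structure tree
naming those labels.  Internally the volume axis order is fixed as
AP x DV x ML (anterior-posterior, dorsal-ventral, medial-lateral); loaders
reorder any declared input axis order to this convention.  On the Allen CCF
10-um 2017 grid the full volume is 1320 x 800 x 1140 voxels.

Stereotaxic positions are expressed in mm relative to bregma.  The sign
table used throughout (configurable via ``AtlasBundle.bregma_voxel``):

==========  ===========  ==============================================
plane       normal axis  fractional index at position p (mm)
==========  ===========  ==============================================
coronal     AP (axis 0)  bregma_AP - p * 1000 / voxel_size_um
sagittal    ML (axis 2)  bregma_ML + p * 1000 / voxel_size_um
transverse  DV (axis 1)  bregma_DV - p * 1000 / voxel_size_um
==========  ===========  ==============================================

so anterior, the animal's right, and dorsal are positive, matching the
usual mouse stereotaxic convention (e.g. an injection at DV -4.3 is 4.3 mm
below bregma).  The default bregma voxel (AP 540, DV 0, ML 570) follows
the SHARP-Track convention for the 10-um CCF grid.

Tilt sign convention for oblique sections: positive ``ml_tilt_deg`` moves
the sampled plane anterior on the animal's right (increasing column),
positive ``dv_tilt_deg`` moves it anterior dorsally (decreasing row index
direction is 'up' on screen; the formula below is the single source of
truth).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "StructureNode",
    "AtlasBundle",
    "SlicePlane",
    "OUTSIDE_BRAIN",
    "DEFAULT_BREGMA_VOXEL",
    "load_atlas",
    "load_structure_tree",
    "mm_to_index",
    "index_to_mm",
    "extract_slice",
    "lookup_region",
    "default_canvas_shape",
    "OUT_OF_VOLUME",
]

PLANES = ("coronal", "sagittal", "transverse")
VARIANTS = ("allen", "chon")

#: default bregma voxel (AP, DV, ML) on the 10-um CCF grid
DEFAULT_BREGMA_VOXEL = (540, 0, 570)

#: coordinate-map sentinel for pixels sampled outside the volume
OUT_OF_VOLUME = -1

#: fixed coronal canvas (DV rows x ML cols) at 10 um/px
CORONAL_CANVAS = (800, 1140)

# (normal axis, row axis, col axis) of the volume for each plane
_PLANE_AXES = {
    "coronal": (0, 1, 2),   # rows = DV, cols = ML
    "sagittal": (2, 1, 0),  # rows = DV, cols = AP
    "transverse": (1, 0, 2),  # rows = AP, cols = ML
}

# sign s in: index = bregma[normal] + s * mm * 1000 / voxel_size
_PLANE_SIGN = {"coronal": -1.0, "sagittal": +1.0, "transverse": -1.0}


@dataclass(frozen=True)
class StructureNode:
    """One named brain structure: annotation label, acronym, full name, parent."""

    id: int
    acronym: str
    name: str
    parent_id: int | None = None


#: reserved record for points outside the brain (label 0 or out of volume);
#: participates in tallies like any structure.
OUTSIDE_BRAIN = StructureNode(id=0, acronym="outside", name="outside brain", parent_id=None)


@dataclass(frozen=True)
class SlicePlane:
    """A virtual sectioning plane: viewing plane, bregma-relative position, tilts.

    ``position_mm`` is signed mm from bregma (positive = anterior for
    coronal).  Tilts are in degrees and must satisfy ``|tilt| < 45``.
    """

    plane: str
    position_mm: float
    dv_tilt_deg: float = 0.0
    ml_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")
        if not (abs(self.dv_tilt_deg) < 45 and abs(self.ml_tilt_deg) < 45):
            raise ValueError("tilt angles must satisfy |tilt| < 45 degrees")

    def to_dict(self) -> dict:
        return {
            "plane": self.plane,
            "position_mm": self.position_mm,
            "dv_tilt_deg": self.dv_tilt_deg,
            "ml_tilt_deg": self.ml_tilt_deg,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SlicePlane":
        return cls(
            plane=d["plane"],
            position_mm=float(d["position_mm"]),
            dv_tilt_deg=float(d.get("dv_tilt_deg", 0.0)),
            ml_tilt_deg=float(d.get("ml_tilt_deg", 0.0)),
        )


@dataclass
class AtlasBundle:
    """One atlas variant: annotation volume + structure tree + grid metadata.

    ``annotation`` is an integer label array in AP x DV x ML axis order;
    ``structure_tree`` maps label id -> :class:`StructureNode`.  ``template``
    is an optional grayscale reference volume of identical shape.
    """

    variant: str
    annotation: np.ndarray
    structure_tree: dict[int, StructureNode]
    voxel_size_um: float = 10.0
    bregma_voxel: tuple[int, int, int] = DEFAULT_BREGMA_VOXEL
    template: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.annotation.ndim != 3:
            raise ValueError(f"annotation must be 3D, got ndim={self.annotation.ndim}")
        if not np.issubdtype(self.annotation.dtype, np.integer):
            raise ValueError(f"annotation labels must be integers, got {self.annotation.dtype}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.template is not None and self.template.shape != self.annotation.shape:
            raise ValueError(
                f"template shape {self.template.shape} != annotation shape {self.annotation.shape}"
            )
        ap, dv, ml = self.bregma_voxel
        n_ap, _, n_ml = self.annotation.shape
        if not (0 <= ap < n_ap and 0 <= ml < n_ml):
            raise ValueError(
                f"bregma voxel AP/ML components {(ap, ml)} outside volume bounds "
                f"{(n_ap, n_ml)}"
            )
        missing = sorted(
            int(lab)
            for lab in np.unique(self.annotation)
            if lab != 0 and int(lab) not in self.structure_tree
        )
        if missing:
            raise ValueError(f"annotation labels missing from structure tree: {missing}")
        _check_tree(self.structure_tree)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.annotation.shape)  # type: ignore[return-value]


def _check_tree(tree: Mapping[int, StructureNode]) -> None:
    """Validate parent chains terminate at a root without cycles."""
    for node in tree.values():
        seen = set()
        cur: StructureNode | None = node
        while cur is not None and cur.parent_id is not None:
            if cur.id in seen:
                raise ValueError(f"cycle in structure tree at id {cur.id}")
            seen.add(cur.id)
            parent = tree.get(cur.parent_id)
            if parent is None:
                # dangling parent reference: tolerated as an implicit root
                break
            cur = parent


def load_structure_tree(path: str | Path) -> dict[int, StructureNode]:
    """Read a structure tree from CSV (id, acronym, name, parent_id) or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure tree file not found: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        required = {"id", "acronym", "name", "parent_id"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"structure tree CSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        records = df.to_dict("records")
    tree: dict[int, StructureNode] = {}
    for rec in records:
        sid = int(rec["id"])
        if sid in tree:
            raise ValueError(f"duplicate structure id {sid} in tree file")
        parent = rec.get("parent_id")
        if parent is None or (isinstance(parent, float) and math.isnan(parent)):
            parent_id = None
        else:
            parent_id = int(parent)
        tree[sid] = StructureNode(
            id=sid, acronym=str(rec["acronym"]), name=str(rec["name"]), parent_id=parent_id
        )
    return tree


def _load_volume(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix == ".npy":
        return np.load(path)
    if suffix == ".nrrd":
        import SimpleITK as sitk

        return sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    raise ValueError(f"unsupported volume format {suffix!r} (expected .npy or .nrrd)")


def load_atlas(
    annotation_path: str | Path,
    tree_path: str | Path,
    variant: str = "allen",
    voxel_size_um: float = 10.0,
    *,
    axis_order: str = "ap,dv,ml",
    bregma_voxel: tuple[int, int, int] | None = None,
    template_path: str | Path | None = None,
) -> AtlasBundle:
    """Load and validate an annotation volume plus structure tree.

    ``axis_order`` declares the axis order of the file on disk; the volume is
    transposed to the internal AP x DV x ML order.  Labels present in the
    volume but absent from the tree raise, naming the offending labels.
    """
    annotation_path = Path(annotation_path)
    if not annotation_path.exists():
        raise FileNotFoundError(f"annotation volume not found: {annotation_path}")
    annotation = _load_volume(annotation_path)
    if annotation.ndim != 3:
        raise ValueError(f"annotation must be a 3D array, got ndim={annotation.ndim}")
    order = [a.strip().lower() for a in axis_order.split(",")]
    if sorted(order) != ["ap", "dv", "ml"]:
        raise ValueError(f"axis_order must be a permutation of ap,dv,ml, got {axis_order!r}")
    perm = [order.index(a) for a in ("ap", "dv", "ml")]
    annotation = np.ascontiguousarray(np.transpose(annotation, perm))
    template = None
    if template_path is not None:
        template = np.ascontiguousarray(np.transpose(_load_volume(Path(template_path)), perm))
    tree = load_structure_tree(tree_path)
    if bregma_voxel is None:
        n_ap, n_dv, n_ml = annotation.shape
        if (n_ap, n_dv, n_ml) == (1320, 800, 1140):
            bregma_voxel = DEFAULT_BREGMA_VOXEL
        else:
            # volumes on other grids default to a centered AP/ML bregma at DV 0
            bregma_voxel = (n_ap // 2, 0, n_ml // 2)
    return AtlasBundle(
        variant=variant,
        annotation=annotation,
        structure_tree=tree,
        voxel_size_um=float(voxel_size_um),
        bregma_voxel=tuple(int(v) for v in bregma_voxel),  # type: ignore[arg-type]
        template=template,
    )


def mm_to_index(bundle: AtlasBundle, position_mm: float, plane: str) -> float:
    """Convert a bregma-relative position (mm) to a fractional voxel index.

    Raises if the index falls outside ``[0, axis length)`` for the plane's
    normal axis.  Inverse of :func:`index_to_mm`.
    """
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}, got {plane!r}")
    normal_axis = _PLANE_AXES[plane][0]
    origin = bundle.bregma_voxel[{0: 0, 1: 1, 2: 2}[normal_axis]]
    index = origin + _PLANE_SIGN[plane] * position_mm * 1000.0 / bundle.voxel_size_um
    n = bundle.annotation.shape[normal_axis]
    if not (0 <= index < n):
        raise ValueError(
            f"position {position_mm} mm maps to index {index:g}, outside [0, {n}) "
            f"on the {plane} normal axis"
        )
    return index


def index_to_mm(bundle: AtlasBundle, index: float, plane: str) -> float:
    """Convert a voxel index along a plane's normal axis back to mm from bregma."""
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}, got {plane!r}")
    normal_axis = _PLANE_AXES[plane][0]
    origin = bundle.bregma_voxel[normal_axis]
    return (index - origin) * bundle.voxel_size_um / (1000.0 * _PLANE_SIGN[plane])


def default_canvas_shape(bundle: AtlasBundle, plane: str) -> tuple[int, int]:
    """Canvas (rows, cols) for a plane: fixed 800x1140 for coronal at 10 um,
    the corresponding volume face otherwise."""
    _, row_axis, col_axis = _PLANE_AXES[plane]
    face = (bundle.annotation.shape[row_axis], bundle.annotation.shape[col_axis])
    if plane == "coronal" and abs(bundle.voxel_size_um - 10.0) < 1e-9:
        return CORONAL_CANVAS
    return face


def extract_slice(
    bundle: AtlasBundle,
    slice_plane: SlicePlane,
    canvas_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract an oblique virtual section of the annotation volume.

    Returns ``(label_image, coordinate_map)`` where ``label_image`` has shape
    ``canvas_shape`` and ``coordinate_map`` has shape ``canvas_shape + (3,)``
    giving, for every pixel, the AP/DV/ML voxel it was sampled from
    (``OUT_OF_VOLUME`` sentinel where the sample fell outside the volume;
    those pixels take label 0).

    The normal-axis coordinate at pixel (r, c) is::

        base + tan(ml_tilt) * (c - c_center) + tan(dv_tilt) * (r - r_center)

    with ``base = mm_to_index(bundle, position_mm, plane)`` and the canvas
    center at ``((rows - 1) / 2, (cols - 1) / 2)``.  Labels are sampled
    nearest-neighbor (half-up rounding of the normal coordinate): labels are
    categorical, so interpolation would fabricate ids.  Deterministic.
    """
    plane = slice_plane.plane
    normal_axis, row_axis, col_axis = _PLANE_AXES[plane]
    base = mm_to_index(bundle, slice_plane.position_mm, plane)
    if canvas_shape is None:
        canvas_shape = default_canvas_shape(bundle, plane)
    rows, cols = canvas_shape

    r = np.arange(rows, dtype=np.float64)
    c = np.arange(cols, dtype=np.float64)
    rc, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    normal = (
        base
        + math.tan(math.radians(slice_plane.ml_tilt_deg)) * (c[None, :] - cc)
        + math.tan(math.radians(slice_plane.dv_tilt_deg)) * (r[:, None] - rc)
    )
    normal_idx = np.floor(normal + 0.5).astype(np.int64)  # half-up nearest voxel

    shape = bundle.annotation.shape
    row_idx = np.broadcast_to(np.arange(rows, dtype=np.int64)[:, None], (rows, cols))
    col_idx = np.broadcast_to(np.arange(cols, dtype=np.int64)[None, :], (rows, cols))
    valid = (
        (normal_idx >= 0)
        & (normal_idx < shape[normal_axis])
        & (row_idx < shape[row_axis])
        & (col_idx < shape[col_axis])
    )

    coords = [None, None, None]
    coords[normal_axis] = normal_idx
    coords[row_axis] = row_idx
    coords[col_axis] = col_idx

    labels = np.zeros((rows, cols), dtype=bundle.annotation.dtype)
    labels[valid] = bundle.annotation[
        coords[0][valid], coords[1][valid], coords[2][valid]
    ]
    coordinate_map = np.full((rows, cols, 3), OUT_OF_VOLUME, dtype=np.int64)
    for axis in range(3):
        coordinate_map[..., axis][valid] = coords[axis][valid]
    return labels, coordinate_map


def lookup_region(bundle: AtlasBundle, voxel_coordinate) -> StructureNode:
    """Resolve an AP/DV/ML voxel coordinate to its structure.

    Total function: out-of-volume coordinates (including the
    ``OUT_OF_VOLUME`` sentinel) and label-0 voxels return the reserved
    :data:`OUTSIDE_BRAIN` record.
    """
    ap, dv, ml = (int(v) for v in voxel_coordinate)
    shape = bundle.annotation.shape
    if not (0 <= ap < shape[0] and 0 <= dv < shape[1] and 0 <= ml < shape[2]):
        return OUTSIDE_BRAIN
    label = int(bundle.annotation[ap, dv, ml])
    if label == 0:
        return OUTSIDE_BRAIN
    return bundle.structure_tree[label]
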