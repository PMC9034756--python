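"""Synthetic atlases, slices, cells, and landmarks with known ground truth.

Everything the pipeline consumes can be generated here at run time: a toy
labeled volume with a structure tree, a virtual section rendered back to
acquisition resolution with Gaussian cell blobs, the matching FIJI-dialect
coordinate file, and exact landmark pairs.  Because the generator knows
the true transform, true cell placements, and true region memberships, any
pipeline result can be checked against ground truth exactly.

All randomness flows through one ``numpy.random.Generator`` seeded per
call: the same seed reproduces every array, file, and truth byte-for-byte.
The default fixture pixel size is 0.5 um/px, matching common confocal
acquisition for this kind of material.  The rendering is deliberately
minimal (blobs + noise, no PSF or channel bleed-through): it exercises the
geometry, which is what the pipeline transforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .atlas_model import (
    AtlasBundle,
    SlicePlane,
    StructureNode,
    extract_slice,
    lookup_region,
)
from .ingest import CanvasRecord, PointSet
from .quantify import RegionCountTable, SliceRecord, tally_regions
from .registration import LandmarkSet, PlanarTransform

__all__ = [
    "FixtureTruth",
    "make_toy_atlas",
    "make_synthetic_slice",
    "perturb_landmarks",
    "make_true_transform",
    "TOY_ROOT_ID",
]

#: structure id used for the toy tree's root node (never a voxel label)
TOY_ROOT_ID = 1000


@dataclass
class FixtureTruth:
    """Ground truth for one synthetic slice: everything needed to verify the pipeline."""

    bundle: AtlasBundle
    slice_plane: SlicePlane
    true_transform: PlanarTransform
    canvas_shape: tuple[int, int]
    canvas_record: CanvasRecord
    cell_points_raw: PointSet
    cell_points_atlas: np.ndarray  # (n, 2) true atlas-frame positions
    true_assignments: list[StructureNode]
    true_counts: RegionCountTable
    landmarks: LandmarkSet
    seed: int
    raw_image: np.ndarray
    image_path: Path | None = None
    points_path: Path | None = None


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def make_toy_atlas(
    seed: int = 0,
    shape: tuple[int, int, int] = (60, 50, 70),
    n_regions: int = 4,
    variant: str = "allen",
    voxel_size_um: float = 10.0,
) -> AtlasBundle:
    """Generate a toy annotation volume of nested ellipsoidal regions.

    Region 1 is the outer brain ellipsoid (deterministic given ``shape``,
    independent of seed and variant, so allen/chon counterparts share the
    same brain mask); regions 2..n are successively smaller ellipsoids
    nested inside it, with seed-dependent centers and radii.  The structure
    tree has a root node plus one child per region.  Chon-variant trees use
    a different nomenclature (with region 2's name shared across variants,
    mimicking partial nomenclature overlap between ontologies).
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 20 for s in shape):
        raise ValueError(f"shape must be at least (20, 20, 20), got {shape}")
    if not (1 <= n_regions <= 20):
        raise ValueError(f"n_regions must be in [1, 20], got {n_regions}")
    rng = np.random.default_rng(seed)
    center = np.array(shape) / 2.0
    outer_radii = np.array(shape) * 0.45
    if n_regions > 1 and min(outer_radii) * (0.65 ** (n_regions - 1)) < 2.5:
        raise ValueError(f"shape {shape} too small to nest {n_regions} regions")

    annotation = np.zeros(shape, dtype=np.int32)
    annotation[_ellipsoid_mask(shape, center, outer_radii)] = 1
    radii = outer_radii.astype(float)
    cur_center = center.copy()
    # chon variant perturbs inner borders so the two ontologies disagree on borders
    variant_jitter = 0.0 if variant == "allen" else 1.5
    for rid in range(2, n_regions + 1):
        radii = radii * rng.uniform(0.55, 0.65, size=3)
        offset = rng.uniform(-0.12, 0.12, size=3) * radii
        if variant != "allen":
            offset = offset + rng.uniform(-variant_jitter, variant_jitter, size=3)
        cur_center = cur_center + offset
        annotation[_ellipsoid_mask(shape, cur_center, np.maximum(radii, 2.0))] = rid

    tree = {TOY_ROOT_ID: StructureNode(TOY_ROOT_ID, "root", "toy brain root", None)}
    for rid in range(1, n_regions + 1):
        if variant == "allen":
            acronym, name = f"R{rid}", f"toy region {rid}"
        else:
            # one shared name across ontologies for overlap statistics
            if rid == 2:
                acronym, name = "cR2", "toy region 2"
            else:
                acronym, name = f"cR{rid}", f"chon toy area {rid}"
        parent = TOY_ROOT_ID if rid == 1 else rid - 1
        tree[rid] = StructureNode(rid, acronym, name, parent)

    return AtlasBundle(
        variant=variant,
        annotation=annotation,
        structure_tree=tree,
        voxel_size_um=voxel_size_um,
        bregma_voxel=(shape[0] // 2, 0, shape[2] // 2),
    )


def make_true_transform(
    seed: int = 0,
    canvas_shape: tuple[int, int] = (50, 70),
    family: str = "projective",
    magnitude: float = 1.0,
) -> PlanarTransform:
    """A near-identity ground-truth transform (padded -> atlas frame).

    Small rotation, anisotropic scale, translation, and (for projective) a
    mild perspective term, scaled by ``magnitude``; invertible and gentle
    enough that brain content stays on the canvas.
    """
    rng = np.random.default_rng(seed)
    rows, cols = canvas_shape
    angle = np.radians(rng.uniform(-3, 3) * magnitude)
    sx, sy = 1 + rng.uniform(-0.04, 0.04, 2) * magnitude
    tx, ty = rng.uniform(-2.5, 2.5, 2) * magnitude
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    ca, sa = np.cos(angle), np.sin(angle)
    linear = np.array(
        [
            [sx * ca, -sy * sa, cx + tx - (sx * ca * cx - sy * sa * cy)],
            [sx * sa, sy * ca, cy + ty - (sx * sa * cx + sy * ca * cy)],
            [0.0, 0.0, 1.0],
        ]
    )
    if family == "projective":
        linear[2, :2] = rng.uniform(-1e-4, 1e-4, 2) * magnitude
        fam = "projective"
    elif family == "affine":
        fam = "affine"
    else:
        raise ValueError("true transform family must be 'affine' or 'projective'")
    return PlanarTransform(
        family=fam,
        params={"matrix": linear.tolist()},
        fit_residuals=np.zeros(0),
    )


def _boundary_landmarks(
    mask: np.ndarray, true_transform: PlanarTransform, n: int = 12
) -> LandmarkSet:
    """Exact landmark pairs at distinctive points of the brain-mask outline.

    Atlas-side points are the outermost mask pixels along ``n`` evenly
    spaced rays from the mask centroid; slice-side partners are their exact
    preimages under the true transform.
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("empty mask: cannot place landmarks")
    cy, cx = rows.mean(), cols.mean()
    angles = np.arctan2(rows - cy, cols - cx)
    radii = np.hypot(rows - cy, cols - cx)
    atlas_pts = []
    for k in range(n):
        target = -np.pi + (2 * np.pi) * (k + 0.5) / n
        sector = np.abs(np.angle(np.exp(1j * (angles - target)))) < (np.pi / n)
        if not np.any(sector):
            continue
        i = np.flatnonzero(sector)[np.argmax(radii[sector])]
        atlas_pts.append((cols[i], rows[i]))
    atlas_pts = np.unique(np.asarray(atlas_pts, dtype=np.float64), axis=0)
    if len(atlas_pts) < 10:
        raise ValueError(f"could only place {len(atlas_pts)} distinct landmarks (need >= 10)")
    slice_pts = true_transform.inverse_points(atlas_pts)
    return LandmarkSet(slice_points=slice_pts, atlas_points=atlas_pts)


def _render_blobs(
    shape: tuple[int, int], points: np.ndarray, rng: np.random.Generator, sigma: float
) -> np.ndarray:
    """16-bit image of Gaussian cell blobs over low background noise."""
    img = rng.normal(400.0, 60.0, size=shape)
    half = int(np.ceil(4 * sigma))
    win = np.arange(-half, half + 1)
    gy, gx = np.meshgrid(win, win, indexing="ij")
    for x, y in points:
        r0, c0 = int(round(y)), int(round(x))
        blob = 30000.0 * np.exp(
            -(((gy + r0 - y) ** 2) + ((gx + c0 - x) ** 2)) / (2 * sigma**2)
        )
        r_lo, r_hi = max(r0 - half, 0), min(r0 + half + 1, shape[0])
        c_lo, c_hi = max(c0 - half, 0), min(c0 + half + 1, shape[1])
        img[r_lo:r_hi, c_lo:c_hi] += blob[
            r_lo - (r0 - half) : blob.shape[0] - ((r0 + half + 1) - r_hi),
            c_lo - (c0 - half) : blob.shape[1] - ((c0 + half + 1) - c_hi),
        ]
    return np.clip(img, 0, 65535).astype(np.uint16)


def make_synthetic_slice(
    bundle: AtlasBundle,
    slice_plane: SlicePlane,
    true_transform: PlanarTransform | None = None,
    cells_per_region: dict[int, int] | None = None,
    pixel_size_um: float = 0.5,
    seed: int = 0,
    canvas_shape: tuple[int, int] | None = None,
    out_dir: str | Path | None = None,
    border_margin_vox: float = 3.0,
    slice_id: str = "synthetic_slice",
) -> FixtureTruth:
    """Render a synthetic slice with known cells, landmarks, and counts.

    Cells are sampled on the extracted atlas section at least
    ``border_margin_vox`` voxels inside their region's in-plane border,
    carried through the inverse of the true transform and the inverse
    canvas geometry into a raw image frame at ``pixel_size_um``, and
    rendered as Gaussian blobs.  If ``out_dir`` is given, the raw TIFF and
    a FIJI-dialect X,Y CSV are written there (byte-identical per seed).
    At least 10 exact landmark pairs are placed on the brain-mask outline.
    """
    rng = np.random.default_rng(seed)
    labels, _ = extract_slice(bundle, slice_plane, canvas_shape)
    canvas = labels.shape
    if true_transform is None:
        true_transform = make_true_transform(seed, canvas)
    if cells_per_region is None:
        present = [int(v) for v in np.unique(labels) if v > 0]
        cells_per_region = {rid: 20 for rid in present}

    atlas_pts = []
    for rid, count in sorted(cells_per_region.items()):
        region = labels == rid
        if not region.any():
            raise ValueError(f"region {rid} absent from this section")
        # distance to the nearest differently-labeled pixel, in-plane
        dist = ndimage.distance_transform_edt(region)
        safe_r, safe_c = np.nonzero(dist > border_margin_vox)
        if len(safe_r) < count:
            raise ValueError(
                f"region {rid} too small for {count} cells at margin {border_margin_vox}"
            )
        pick = rng.choice(len(safe_r), size=count, replace=False)
        jitter = rng.uniform(-0.25, 0.25, size=(count, 2))
        atlas_pts.append(
            np.column_stack([safe_c[pick] + jitter[:, 0], safe_r[pick] + jitter[:, 1]])
        )
    atlas_pts = (
        np.vstack(atlas_pts) if atlas_pts else np.empty((0, 2), dtype=np.float64)
    )

    scale = bundle.voxel_size_um / pixel_size_um
    record = CanvasRecord(
        scale_factor=scale,
        pad_offset=(0, 0),
        canvas_shape=canvas,
        downsampled_shape=canvas,
    )
    padded_pts = true_transform.inverse_points(atlas_pts)
    raw_pts = record.padded_to_raw(padded_pts)
    raw_shape = (int(canvas[0] * scale), int(canvas[1] * scale))
    if len(raw_pts) and (
        raw_pts.min() < 0
        or raw_pts[:, 0].max() >= raw_shape[1]
        or raw_pts[:, 1].max() >= raw_shape[0]
    ):
        raise ValueError("true transform pushes cells outside the raw image frame")

    raw_image = _render_blobs(raw_shape, raw_pts, rng, sigma=1.5 * scale / 10.0 + 2.0)
    landmarks = _boundary_landmarks(labels > 0, true_transform)

    # ground-truth assignments straight from the annotation at the sampled pixels
    truth_points = PointSet(points=atlas_pts, frame="atlas", source_image=slice_id)
    pix_c = np.floor(atlas_pts[:, 0] + 0.5).astype(int) if len(atlas_pts) else []
    pix_r = np.floor(atlas_pts[:, 1] + 0.5).astype(int) if len(atlas_pts) else []
    _, coord_map = extract_slice(bundle, slice_plane, canvas)
    assignments = [
        lookup_region(bundle, coord_map[r, c]) for r, c in zip(pix_r, pix_c)
    ]
    truth_record = SliceRecord(
        slice_id=slice_id,
        slice_plane=slice_plane,
        atlas_variant=bundle.variant,
        points=truth_points,
        assignments=assignments,
        canvas_shape=canvas,
    )
    true_counts = tally_regions([truth_record], scope="per_brain")

    image_path = points_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        image_path = out_dir / f"{slice_id}.tif"
        tifffile.imwrite(image_path, raw_image)
        points_path = out_dir / f"{slice_id}.csv"
        pd.DataFrame(
            {
                " ": np.arange(1, len(raw_pts) + 1),
                "X": raw_pts[:, 0],
                "Y": raw_pts[:, 1],
            }
        ).to_csv(points_path, index=False)

    return FixtureTruth(
        bundle=bundle,
        slice_plane=slice_plane,
        true_transform=true_transform,
        canvas_shape=canvas,
        canvas_record=record,
        cell_points_raw=PointSet(points=raw_pts, frame="raw", source_image=slice_id),
        cell_points_atlas=atlas_pts,
        true_assignments=assignments,
        true_counts=true_counts,
        landmarks=landmarks,
        seed=seed,
        raw_image=raw_image,
        image_path=image_path,
        points_path=points_path,
    )


def perturb_landmarks(
    landmark_set: LandmarkSet, sigma_px: float, seed: int = 0
) -> LandmarkSet:
    """Add isotropic Gaussian noise to the slice-side landmark points only.

    Emulates imprecise clicking on the slice; atlas-side points stay exact.
    Seed-deterministic; ``sigma_px = 0`` returns the landmarks unchanged.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    if sigma_px == 0:
        return LandmarkSet(
            slice_points=landmark_set.slice_points.copy(),
            atlas_points=landmark_set.atlas_points.copy(),
        )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_px, size=landmark_set.slice_points.shape)
    return LandmarkSet(
        slice_points=landmark_set.slice_points + noise,
        atlas_points=landmark_set.atlas_points.copy(),
    )
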