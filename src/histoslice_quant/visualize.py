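"""Qualitative outputs: composite overlay images and the 3D brain point cloud.

Rendering is a pure view: nothing here mutates records, and every plot
writes a CSV companion with exactly the plotted values so figures can be
regenerated or re-styled downstream.  All output is static (TIFF/PNG),
suitable for headless runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile
from skimage import measure
from skimage.draw import disk

from .atlas_model import AtlasBundle
from .quantify import SliceRecord

__all__ = ["OverlaySpec", "border_map", "composite_overlay", "plot_brain_cloud"]


@dataclass(frozen=True)
class OverlaySpec:
    """Layer selection and styling for the image-cells-borders composite."""

    show_image: bool = True
    show_points: bool = True
    show_borders: bool = True
    marker_radius_px: int = 2
    channel_colors: tuple = ((0.0, 1.0, 0.0), (0.0, 0.3, 1.0), (1.0, 0.0, 0.0))
    point_color: tuple = (1.0, 1.0, 0.0)
    border_color: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not (self.show_image or self.show_points or self.show_borders):
            raise ValueError("at least one overlay layer must be enabled")


def border_map(label_image: np.ndarray) -> np.ndarray:
    """True where a pixel's label differs from any 4-neighbor (1-px borders)."""
    if not np.issubdtype(label_image.dtype, np.integer):
        raise ValueError(f"label image must be integer, got {label_image.dtype}")
    edges = np.zeros(label_image.shape, dtype=bool)
    edges[:-1, :] |= label_image[:-1, :] != label_image[1:, :]
    edges[1:, :] |= label_image[1:, :] != label_image[:-1, :]
    edges[:, :-1] |= label_image[:, :-1] != label_image[:, 1:]
    edges[:, 1:] |= label_image[:, 1:] != label_image[:, :-1]
    return edges


def _normalized_channels(image: np.ndarray) -> np.ndarray:
    channels = image[None] if image.ndim == 2 else image
    out = np.empty(channels.shape, dtype=np.float64)
    for i, ch in enumerate(channels):
        ch = ch.astype(np.float64)
        hi = ch.max()
        out[i] = ch / hi if hi > 0 else ch
    return out


def composite_overlay(
    warped_image: np.ndarray | None,
    slice_record: SliceRecord | None,
    label_image: np.ndarray,
    spec: OverlaySpec = OverlaySpec(),
    out_path: str | Path | None = None,
) -> np.ndarray:
    """Blend the warped slice, cell markers, and atlas borders into one RGB image.

    All enabled layers must share the atlas canvas shape.  The blend is
    deterministic (additive image channels, then borders, then markers on
    top), so re-rendering identical inputs is bit-identical.  Returns the
    uint8 RGB array; optionally writes it as TIFF.
    """
    shape = label_image.shape
    rgb = np.zeros(shape + (3,), dtype=np.float64)

    if spec.show_image and warped_image is not None:
        if warped_image.shape[-2:] != shape:
            raise ValueError(
                f"warped image shape {warped_image.shape[-2:]} != canvas {shape}"
            )
        for i, ch in enumerate(_normalized_channels(warped_image)):
            color = spec.channel_colors[i % len(spec.channel_colors)]
            rgb += ch[..., None] * np.asarray(color)

    if spec.show_borders:
        edges = border_map(label_image)
        rgb[edges] = np.asarray(spec.border_color)

    if spec.show_points and slice_record is not None:
        if slice_record.canvas_shape != shape:
            raise ValueError(
                f"record canvas {slice_record.canvas_shape} != label canvas {shape}"
            )
        for x, y in slice_record.points.points:
            rr, cc = disk((y, x), spec.marker_radius_px + 0.5, shape=shape)
            rgb[rr, cc] = np.asarray(spec.point_color)

    out = np.clip(rgb * 255.0, 0, 255).astype(np.uint8)
    if out_path is not None:
        tifffile.imwrite(Path(out_path), out)
    return out


def plot_brain_cloud(
    point_clouds: list[pd.DataFrame] | pd.DataFrame,
    bundle: AtlasBundle,
    out_path: str | Path,
    max_wire_vertices: int = 4000,
) -> tuple[Path, Path]:
    """Write a static 3D scatter of cells inside a brain-outline wireframe.

    ``point_clouds`` are per-slice tables from
    :func:`~histoslice_quant.quantify.to_ccf3d` (micron AP/DV/ML columns);
    the outline is the marching-cubes surface of the annotation's nonzero
    mask, subsampled to at most ``max_wire_vertices`` vertices for drawing.
    Writes the PNG figure and a CSV companion holding exactly the plotted
    points; returns both paths.
    """
    if isinstance(point_clouds, pd.DataFrame):
        point_clouds = [point_clouds]
    cloud = (
        pd.concat(point_clouds, ignore_index=True)
        if point_clouds
        else pd.DataFrame(columns=["AP_um", "DV_um", "ML_um"])
    )
    out_path = Path(out_path)
    csv_path = out_path.with_suffix(".csv")
    cloud.to_csv(csv_path, index=False)

    mask = bundle.annotation > 0
    fig = plt.figure(figsize=(8, 6))
    ax = fig.add_subplot(projection="3d")
    if mask.any():
        verts, faces, _, _ = measure.marching_cubes(mask.astype(np.float64), level=0.5)
        verts_um = verts * bundle.voxel_size_um
        step = max(1, len(verts_um) // max_wire_vertices)
        sub = verts_um[::step]
        ax.scatter(sub[:, 0], sub[:, 2], sub[:, 1], s=0.3, c="gray", alpha=0.25)
    plotted = cloud.dropna(subset=["AP_um", "DV_um", "ML_um"]) if len(cloud) else cloud
    if len(plotted):
        ax.scatter(
            plotted["AP_um"], plotted["ML_um"], plotted["DV_um"], s=4, c="crimson"
        )
    ax.set_xlabel("AP (um)")
    ax.set_ylabel("ML (um)")
    ax.set_zlabel("DV (um)")
    ax.invert_zaxis()  # dorsal up
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path, csv_path
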