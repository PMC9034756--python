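"""Reading slice images and cell coordinates; downsampling and padding to the atlas canvas.

Histology images arrive at acquisition resolution (e.g. 0.5 um/px) and must
be brought to the atlas grid (10 um/px) and padded onto the fixed atlas
canvas (800 x 1140 for coronal) before landmark registration.  Counted-cell
coordinates are carried as float (x, y) pixel positions and transformed with
the exact same geometry as the image, which preserves multiplicity when two
cells fall in one atlas pixel (a binary cell mask cannot); a mask export is
still provided for parity with mask-based workflows.

Coordinate conventions: origin at the image top-left, x = column, y = row,
as produced by FIJI's multi-point "measure" export on an uncalibrated image.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import downscale_local_mean, resize

__all__ = [
    "RawSlice",
    "PointSet",
    "CanvasRecord",
    "ContrastSpec",
    "read_slice_image",
    "read_points",
    "preprocess",
    "points_to_mask",
    "FRAMES",
]

FRAMES = ("raw", "downsampled", "padded", "atlas", "ccf3d")
DIALECTS = ("fiji_csv", "photoshop_txt", "plain_xy_csv")


@dataclass
class RawSlice:
    """A slice image as acquired: integer array, channel-first if multichannel.

    The image must already be in the correct anatomic orientation (dorsal up
    for coronal sections); only shape and dtype are validated here.
    """

    image: np.ndarray  # (H, W) or (C, H, W), integer dtype
    pixel_size_um: float
    channel_names: list[str] = field(default_factory=lambda: ["ch0"])
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.image.ndim not in (2, 3):
            raise ValueError(f"image must be 2D or 2D-multichannel, got ndim={self.image.ndim}")
        if not np.issubdtype(self.image.dtype, np.integer):
            raise ValueError(f"image dtype must be integer (8/16-bit), got {self.image.dtype}")
        n_ch = 1 if self.image.ndim == 2 else self.image.shape[0]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"channel count {n_ch} != number of channel names {len(self.channel_names)}"
            )

    @property
    def n_channels(self) -> int:
        return 1 if self.image.ndim == 2 else self.image.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.image.shape[-2:]


@dataclass
class PointSet:
    """Ordered cell coordinates with a coordinate-frame tag.

    ``points`` is an (n, 2) float array of (x = column, y = row) positions.
    Duplicate coordinates are legitimate (two cells in one pixel) and are
    kept and counted separately.  ``frame`` tracks which geometry the
    coordinates live in; transitions happen only through the documented
    operations (preprocess, warp, lift to 3D).
    """

    points: np.ndarray
    frame: str = "raw"
    labels: list | None = None
    source_image: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}, got {self.frame!r}")
        if self.labels is not None and len(self.labels) != len(pts):
            raise ValueError("labels length must match number of points")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def with_points(self, points: np.ndarray, frame: str | None = None) -> "PointSet":
        return PointSet(
            points=points,
            frame=frame if frame is not None else self.frame,
            labels=None if self.labels is None else list(self.labels),
            source_image=self.source_image,
        )


@dataclass(frozen=True)
class CanvasRecord:
    """Downsample-and-pad geometry, recorded for exact invertibility.

    ``scale_factor`` is raw pixels per atlas pixel (e.g. 20 for 0.5 um/px
    raw on a 10 um atlas grid); ``pad_offset`` is the (row, col) of the
    downsampled image's origin on the canvas.
    """

    scale_factor: float
    pad_offset: tuple[int, int]
    canvas_shape: tuple[int, int]
    downsampled_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if min(self.pad_offset) < 0:
            raise ValueError("pad offsets must be non-negative")
        if (
            self.pad_offset[0] + self.downsampled_shape[0] > self.canvas_shape[0]
            or self.pad_offset[1] + self.downsampled_shape[1] > self.canvas_shape[1]
        ):
            raise ValueError("downsampled image does not fit inside the canvas")

    def raw_to_padded(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        f = 1.0 / self.scale_factor
        return np.column_stack(
            [pts[:, 0] * f + self.pad_offset[1], pts[:, 1] * f + self.pad_offset[0]]
        )

    def padded_to_raw(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        return np.column_stack(
            [
                (pts[:, 0] - self.pad_offset[1]) * self.scale_factor,
                (pts[:, 1] - self.pad_offset[0]) * self.scale_factor,
            ]
        )

    def to_dict(self) -> dict:
        return {
            "scale_factor": self.scale_factor,
            "pad_offset": list(self.pad_offset),
            "canvas_shape": list(self.canvas_shape),
            "downsampled_shape": list(self.downsampled_shape),
        }

    @classmethod
    def from_dict(cls, d) -> "CanvasRecord":
        return cls(
            scale_factor=float(d["scale_factor"]),
            pad_offset=tuple(int(v) for v in d["pad_offset"]),
            canvas_shape=tuple(int(v) for v in d["canvas_shape"]),
            downsampled_shape=tuple(int(v) for v in d["downsampled_shape"]),
        )


@dataclass(frozen=True)
class ContrastSpec:
    """Per-channel linear contrast stretch.

    ``mode='quantile'`` interprets (low, high) as intensity quantiles in
    [0, 1]; ``mode='absolute'`` as raw intensity bounds.  Values below/above
    the bounds saturate; in between, intensities rescale linearly to the
    full dtype range.  ``per_channel`` overrides (low, high) by channel name.
    """

    low: float = 0.0
    high: float = 1.0
    mode: str = "quantile"
    per_channel: dict | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("quantile", "absolute"):
            raise ValueError("mode must be 'quantile' or 'absolute'")
        if self.low >= self.high:
            raise ValueError("low bound must be below high bound")

    def bounds_for(self, channel_name: str, channel: np.ndarray) -> tuple[float, float]:
        low, high = self.low, self.high
        if self.per_channel and channel_name in self.per_channel:
            low, high = self.per_channel[channel_name]
        if self.mode == "quantile":
            lo = float(np.quantile(channel, low))
            hi = float(np.quantile(channel, high))
        else:
            lo, hi = float(low), float(high)
        if hi <= lo:
            hi = lo + 1.0
        return lo, hi


def read_slice_image(
    path: str | Path,
    pixel_size_um: float,
    channel_names: Sequence[str] | None = None,
) -> RawSlice:
    """Read a TIFF slice image with declared pixel size and channel names.

    Multipage / multichannel TIFFs map pages (or the short leading axis) to
    the named channels in order.  Non-TIFF paths are rejected: TIFF is the
    required acquisition format.
    """
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError(
            f"slice images must be .tif or .tiff files, got {path.suffix!r} ({path.name})"
        )
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    image = tifffile.imread(path)
    if image.ndim == 3 and image.shape[-1] <= 4 and image.shape[0] > 4:
        image = np.moveaxis(image, -1, 0)  # H,W,C -> C,H,W
    n_ch = 1 if image.ndim == 2 else image.shape[0]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    return RawSlice(
        image=image,
        pixel_size_um=pixel_size_um,
        channel_names=list(channel_names),
        source_path=str(path),
    )


def _read_table_xy(text: str, col_x: str, col_y: str) -> np.ndarray:
    df = pd.read_csv(io.StringIO(text))
    cols = {c.strip(): c for c in df.columns}
    if col_x not in cols or col_y not in cols:
        raise ValueError(
            f"coordinate file must have {col_x!r} and {col_y!r} columns, got {list(df.columns)}"
        )
    xy = df[[cols[col_x], cols[col_y]]].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-numeric or non-finite coordinates in file")
    return xy


def read_points(
    path: str | Path,
    dialect: str = "fiji_csv",
    *,
    calibrated_pixel_size_um: float | None = None,
) -> PointSet:
    """Read counted-cell coordinates in one of the supported dialects.

    - ``fiji_csv``: FIJI "measure" export; matched on header names X and Y
      only (other measure columns are ignored).
    - ``photoshop_txt``: count-tool export, whitespace- or tab-delimited
      x/y pairs; header lines without two leading numbers are skipped
      (the .txt-to-.csv conversion is done internally).
    - ``plain_xy_csv``: two-column CSV with x, y headers (case-insensitive).

    Order and multiplicity are preserved; an empty file yields an empty
    PointSet.  ``calibrated_pixel_size_um`` divides calibrated (um)
    coordinates back to pixel units.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinate file not found: {path}")
    text = path.read_text()
    if not text.strip():
        xy = np.empty((0, 2), dtype=np.float64)
    elif dialect == "fiji_csv":
        xy = _read_table_xy(text, "X", "Y")
    elif dialect == "plain_xy_csv":
        # normalize headers case-insensitively to X/Y
        first, rest = text.split("\n", 1) if "\n" in text else (text, "")
        header = ",".join(
            "X" if h.strip().lower() == "x" else "Y" if h.strip().lower() == "y" else h.strip()
            for h in first.split(",")
        )
        xy = _read_table_xy(header + "\n" + rest, "X", "Y")
    else:  # photoshop_txt
        rows = []
        for line in text.splitlines():
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                continue
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                continue  # header / annotation line
        xy = np.asarray(rows, dtype=np.float64).reshape(-1, 2)
    if calibrated_pixel_size_um is not None:
        xy = xy / calibrated_pixel_size_um
    return PointSet(points=xy, frame="raw", source_image=path.stem)


def _apply_contrast(image: np.ndarray, names: Sequence[str], spec: ContrastSpec) -> np.ndarray:
    """Linear contrast stretch per channel to the full dtype range; shape preserved."""
    info = np.iinfo(image.dtype)
    out = np.empty_like(image)
    channels = image[None] if image.ndim == 2 else image
    dest = out[None] if image.ndim == 2 else out
    for i, name in enumerate(names):
        lo, hi = spec.bounds_for(name, channels[i])
        stretched = (channels[i].astype(np.float64) - lo) / (hi - lo)
        np.clip(stretched, 0.0, 1.0, out=stretched)
        dest[i] = np.floor(stretched * info.max + 0.5).astype(image.dtype)
    return out


def _downsample_channel(channel: np.ndarray, f: float, out_shape: tuple[int, int]) -> np.ndarray:
    """Area-average downsampling by factor f (<= 1)."""
    inv = 1.0 / f
    if abs(inv - round(inv)) < 1e-9 and all(
        s % int(round(inv)) == 0 for s in channel.shape
    ):
        return downscale_local_mean(channel.astype(np.float64), int(round(inv)))
    return resize(
        channel.astype(np.float64),
        out_shape,
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )


def preprocess(
    raw_slice: RawSlice,
    point_set: PointSet,
    atlas_voxel_um: float = 10.0,
    canvas_shape: tuple[int, int] = (800, 1140),
    contrast_spec: ContrastSpec | None = None,
) -> tuple[np.ndarray, PointSet, CanvasRecord]:
    """Contrast-adjust, downsample to atlas resolution, and pad to the canvas.

    The image is rescaled by ``f = pixel_size_um / atlas_voxel_um`` with
    area-average resampling, then centered on the canvas with symmetric
    padding (zeros).  Every point (x, y) maps to ``(x * f + pad_col,
    y * f + pad_row)`` — the identical geometry, applied analytically.
    Returns the padded image, the point set in the ``padded`` frame, and a
    :class:`CanvasRecord` that inverts the mapping exactly.
    """
    if point_set.frame != "raw":
        raise ValueError(f"point_set must be in the raw frame, got {point_set.frame!r}")
    if point_set.source_image and raw_slice.source_path:
        if Path(raw_slice.source_path).stem != point_set.source_image:
            raise ValueError(
                "point file does not match image: "
                f"{point_set.source_image!r} vs {Path(raw_slice.source_path).stem!r}"
            )
    if raw_slice.pixel_size_um > atlas_voxel_um:
        raise ValueError(
            f"raw pixel size ({raw_slice.pixel_size_um} um) must not exceed the atlas "
            f"voxel size ({atlas_voxel_um} um)"
        )
    f = raw_slice.pixel_size_um / atlas_voxel_um
    image = raw_slice.image
    if contrast_spec is not None:
        image = _apply_contrast(image, raw_slice.channel_names, contrast_spec)

    h_raw, w_raw = raw_slice.frame_shape
    out_shape = (int(round(h_raw * f)), int(round(w_raw * f)))
    if out_shape[0] > canvas_shape[0] or out_shape[1] > canvas_shape[1]:
        raise ValueError(
            f"downsampled image {out_shape} larger than canvas {canvas_shape}; "
            "check pixel size or canvas"
        )
    pad_row = (canvas_shape[0] - out_shape[0]) // 2
    pad_col = (canvas_shape[1] - out_shape[1]) // 2
    record = CanvasRecord(
        scale_factor=1.0 / f,
        pad_offset=(pad_row, pad_col),
        canvas_shape=tuple(canvas_shape),
        downsampled_shape=out_shape,
    )

    channels = image[None] if image.ndim == 2 else image
    n_ch = channels.shape[0]
    padded = np.zeros((n_ch,) + tuple(canvas_shape), dtype=image.dtype)
    for i in range(n_ch):
        if f == 1.0:
            small = channels[i].astype(np.float64)
        else:
            small = _downsample_channel(channels[i], f, out_shape)
        padded[
            i, pad_row : pad_row + out_shape[0], pad_col : pad_col + out_shape[1]
        ] = np.floor(small + 0.5).astype(image.dtype)
    if image.ndim == 2:
        padded = padded[0]

    padded_points = point_set.with_points(record.raw_to_padded(point_set.points), frame="padded")
    return padded, padded_points, record


def points_to_mask(point_set: PointSet, shape: tuple[int, int]) -> np.ndarray:
    """Render points as a binary matrix of the given (rows, cols) shape.

    Provided for parity with mask-based cell representations; the
    quantification path does not use it (two cells in one pixel collapse to
    a single True).  Rounding is half-up on both axes.
    """
    mask = np.zeros(shape, dtype=bool)
    if len(point_set) == 0:
        return mask
    cols = np.floor(point_set.x + 0.5).astype(np.int64)
    rows = np.floor(point_set.y + 0.5).astype(np.int64)
    bad = (rows < 0) | (rows >= shape[0]) | (cols < 0) | (cols >= shape[1])
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"point {i} at ({point_set.x[i]}, {point_set.y[i]}) falls outside shape {shape}"
        )
    mask[rows, cols] = True
    return mask
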