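"""Landmark-based 2D registration of padded slice images onto the atlas canvas.

Registration is driven entirely by numbered landmark pairs the user
identifies between the slice and the atlas section (a file contract
replacing interactive clicking): a planar transform is least-squares
fitted from the pairs, then applied identically to the image (inverse-map
resampling) and to the cell coordinates (forward mapping).  Because the
same transform handles both, the warped cells stay glued to the warped
tissue — and a saved transform can be re-applied to further channels
counted on the same slice without re-registering.

Supported families: ``affine`` (6 parameters, >= 3 pairs), ``projective``
(homography, 8 parameters, >= 4 pairs; the default), and
``thin_plate_spline`` (landmark-interpolating, regularization 0, >= 4
pairs).  Strict mode additionally enforces the recommended minimum of 10
landmark pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import (
    AffineTransform,
    ProjectiveTransform,
    ThinPlateSplineTransform,
    warp,
)

from .atlas_model import SlicePlane
from .ingest import PointSet

__all__ = [
    "LandmarkSet",
    "PlanarTransform",
    "fit_transform",
    "warp_image",
    "warp_points",
    "save_transform",
    "load_transform",
    "apply_saved",
    "read_landmarks",
    "write_landmarks",
    "STRICT_MIN_LANDMARKS",
    "FAMILY_MIN_LANDMARKS",
]

FAMILIES = ("affine", "projective", "thin_plate_spline")
FAMILY_MIN_LANDMARKS = {"affine": 3, "projective": 4, "thin_plate_spline": 4}

#: enforced default minimum of matched landmark pairs (strict mode); the
#: workflow recommendation is to click at least 10 matching points.
STRICT_MIN_LANDMARKS = 10

SCHEMA_VERSION = 1


@dataclass
class LandmarkSet:
    """Numbered landmark pairs: (x, y) in the padded slice frame and the atlas frame."""

    slice_points: np.ndarray  # (n, 2) float, padded frame
    atlas_points: np.ndarray  # (n, 2) float, atlas-canvas frame

    def __post_init__(self) -> None:
        self.slice_points = np.asarray(self.slice_points, dtype=np.float64).reshape(-1, 2)
        self.atlas_points = np.asarray(self.atlas_points, dtype=np.float64).reshape(-1, 2)
        if len(self.slice_points) != len(self.atlas_points):
            raise ValueError("slice and atlas landmark counts differ")
        if self.slice_points.size and not (
            np.all(np.isfinite(self.slice_points)) and np.all(np.isfinite(self.atlas_points))
        ):
            raise ValueError("landmark coordinates must be finite")
        uniq = np.unique(self.slice_points, axis=0)
        if len(uniq) != len(self.slice_points):
            raise ValueError("duplicated slice-side landmark points")

    def __len__(self) -> int:
        return len(self.slice_points)

    @property
    def indices(self) -> np.ndarray:
        """1-based landmark numbers, matching the on-screen numbering."""
        return np.arange(1, len(self) + 1)


@dataclass
class PlanarTransform:
    """A fitted 2D geometric transform from the padded frame to the atlas frame.

    ``params`` holds the family-specific parameter block: a 3x3 matrix for
    affine/projective; the landmark pairs themselves for thin-plate spline
    (the spline is re-fitted deterministically from them, so serialization
    reproduces the mapping bit-exactly).
    """

    family: str
    params: dict
    fit_residuals: np.ndarray  # per-landmark distances, atlas px
    slice_plane: SlicePlane | None = None
    source_frame: str = "padded"
    target_frame: str = "atlas"
    _forward: object = field(default=None, repr=False)
    _inverse: object = field(default=None, repr=False)

    def _build(self) -> None:
        if self._forward is not None:
            return
        if self.family in ("affine", "projective"):
            matrix = np.asarray(self.params["matrix"], dtype=np.float64)
            cls = AffineTransform if self.family == "affine" else ProjectiveTransform
            self._forward = cls(matrix=matrix)
            self._inverse = cls(matrix=np.linalg.inv(matrix))
        else:
            src = np.asarray(self.params["slice_points"], dtype=np.float64)
            dst = np.asarray(self.params["atlas_points"], dtype=np.float64)
            fwd = _estimate(ThinPlateSplineTransform, src, dst)
            inv = _estimate(ThinPlateSplineTransform, dst, src)
            if fwd is None or inv is None:
                raise ValueError("degenerate landmark configuration for thin-plate spline")
            self._forward = fwd
            self._inverse = inv

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Forward-map (n, 2) (x, y) coordinates from padded to atlas frame."""
        self._build()
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        if len(pts) == 0:
            return pts.copy()
        return np.asarray(self._forward(pts), dtype=np.float64)

    def inverse_points(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 2) atlas-frame coordinates back to the padded frame."""
        self._build()
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        if len(pts) == 0:
            return pts.copy()
        return np.asarray(self._inverse(pts), dtype=np.float64)

    @property
    def max_residual(self) -> float:
        return float(np.max(self.fit_residuals)) if len(self.fit_residuals) else 0.0


def _estimate(cls, src: np.ndarray, dst: np.ndarray):
    """Estimate an skimage transform; None on failure (API-version tolerant)."""
    if hasattr(cls, "from_estimate"):
        tform = cls.from_estimate(src, dst)
        return tform if tform else None
    tform = cls()
    return tform if tform.estimate(src, dst) else None


def _fit_matrix_family(family: str, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    cls = AffineTransform if family == "affine" else ProjectiveTransform
    tform = _estimate(cls, src, dst)
    matrix = None if tform is None else np.asarray(tform.params, dtype=np.float64)
    if matrix is None or not np.all(np.isfinite(matrix)):
        raise ValueError(
            f"degenerate landmark configuration: could not fit a {family} transform "
            "(collinear or coincident points?)"
        )
    return matrix


def fit_transform(
    landmarks: LandmarkSet,
    family: str = "projective",
    slice_plane: SlicePlane | None = None,
    strict: bool = True,
) -> PlanarTransform:
    """Least-squares fit of a planar transform mapping slice landmarks to atlas landmarks.

    In strict mode (the default) at least :data:`STRICT_MIN_LANDMARKS`
    pairs are required, operationalizing the recommendation to click at
    least 10 matched points; pass ``strict=False`` to override.  The
    thin-plate spline interpolates the landmarks exactly (zero residuals,
    regularization 0).  Per-landmark fit residuals (atlas px) are reported
    on the returned transform.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    n = len(landmarks)
    n_min = FAMILY_MIN_LANDMARKS[family]
    if n < n_min:
        raise ValueError(
            f"under-determined: {family} requires at least {n_min} landmark pairs, got {n}"
        )
    if strict and n < STRICT_MIN_LANDMARKS:
        raise ValueError(
            f"strict mode: got {n} landmark pairs, but at least {STRICT_MIN_LANDMARKS} "
            "matched landmarks are recommended for reliable registration "
            "(pass strict=False to override)"
        )
    src, dst = landmarks.slice_points, landmarks.atlas_points
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate landmark configuration: slice points are collinear")

    if family in ("affine", "projective"):
        matrix = _fit_matrix_family(family, src, dst)
        params = {"matrix": matrix.tolist()}
    else:
        params = {"slice_points": src.tolist(), "atlas_points": dst.tolist()}

    transform = PlanarTransform(
        family=family,
        params=params,
        fit_residuals=np.empty(0),
        slice_plane=slice_plane,
    )
    fitted = transform.transform_points(src)
    transform.fit_residuals = np.linalg.norm(fitted - dst, axis=1)
    return transform


def warp_image(
    image: np.ndarray,
    transform: PlanarTransform,
    output_shape: tuple[int, int],
) -> np.ndarray:
    """Warp a padded-frame image onto the atlas canvas by inverse mapping.

    Intensities are resampled bilinearly; pixels that map outside the
    source image (or through a non-invertible homography point) are 0.
    Output shape is the atlas canvas (rows, cols); multichannel images are
    warped channel-by-channel.
    """
    transform._build()
    inverse = transform._inverse

    def _warp_one(channel: np.ndarray) -> np.ndarray:
        out = warp(
            channel.astype(np.float64),
            inverse,
            output_shape=output_shape,
            order=1,
            cval=0.0,
            preserve_range=True,
        )
        out[~np.isfinite(out)] = 0.0
        if np.issubdtype(channel.dtype, np.integer):
            info = np.iinfo(channel.dtype)
            return np.clip(np.floor(out + 0.5), info.min, info.max).astype(channel.dtype)
        return out.astype(channel.dtype)

    if image.ndim == 2:
        return _warp_one(image)
    return np.stack([_warp_one(ch) for ch in image])


def warp_points(point_set: PointSet, transform: PlanarTransform) -> PointSet:
    """Map a padded-frame point set into the atlas frame through the same transform.

    Count and order are conserved; points may land outside the brain and
    are kept (they are tallied as outside-brain downstream).
    """
    if point_set.frame != "padded":
        raise ValueError(f"point_set must be in the padded frame, got {point_set.frame!r}")
    return point_set.with_points(transform.transform_points(point_set.points), frame="atlas")


def save_transform(transform: PlanarTransform, path: str | Path) -> None:
    """Serialize a fitted transform to a JSON geometric-transformation file."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "family": transform.family,
        "params": transform.params,
        "fit_residuals": np.asarray(transform.fit_residuals, dtype=float).tolist(),
        "slice_plane": None if transform.slice_plane is None else transform.slice_plane.to_dict(),
        "source_frame": transform.source_frame,
        "target_frame": transform.target_frame,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_transform(path: str | Path) -> PlanarTransform:
    """Load a transform saved by :func:`save_transform`; bit-exact mapping."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupted transform file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ValueError(f"corrupted transform file {path}: missing schema_version")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"transform file schema version {doc['schema_version']} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )
    if doc.get("family") not in FAMILIES:
        raise ValueError(f"corrupted transform file {path}: bad family {doc.get('family')!r}")
    return PlanarTransform(
        family=doc["family"],
        params=doc["params"],
        fit_residuals=np.asarray(doc["fit_residuals"], dtype=np.float64),
        slice_plane=None
        if doc.get("slice_plane") is None
        else SlicePlane.from_dict(doc["slice_plane"]),
        source_frame=doc.get("source_frame", "padded"),
        target_frame=doc.get("target_frame", "atlas"),
    )


def apply_saved(path: str | Path, point_set: PointSet) -> PointSet:
    """Warp a point set with a previously saved transform.

    This is how additional channels counted on the same slice reuse one
    registration instead of repeating it.
    """
    return warp_points(point_set, load_transform(path))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark CSV with columns idx, slice_x, slice_y, atlas_x, atlas_y."""
    df = pd.read_csv(path)
    required = {"idx", "slice_x", "slice_y", "atlas_x", "atlas_y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"landmark CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    df = df.sort_values("idx")
    return LandmarkSet(
        slice_points=df[["slice_x", "slice_y"]].to_numpy(dtype=np.float64),
        atlas_points=df[["atlas_x", "atlas_y"]].to_numpy(dtype=np.float64),
    )


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "idx": landmarks.indices,
            "slice_x": landmarks.slice_points[:, 0],
            "slice_y": landmarks.slice_points[:, 1],
            "atlas_x": landmarks.atlas_points[:, 0],
            "atlas_y": landmarks.atlas_points[:, 1],
        }
    ).to_csv(path, index=False)
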