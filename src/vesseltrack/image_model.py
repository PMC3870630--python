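"""Core raster types, image I/O, FOV masking and tree rasterization.

A fundus photograph is held as a float grey-level raster on a 0-255 scale,
optionally restricted to a circular field of view (FOV).  The tracker's
output is a :class:`VesselTree` - ordered edge-point pairs per segment with
topology links - which :func:`rasterize_tree` converts back into a binary
segmentation mask by filling, for every pair of consecutive steps, the
quadrilateral spanned by the two edge-point pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import measure

from .errors import DegenerateFOVError, ImageFormatError

__all__ = [
    "FundusImage",
    "PixelMask",
    "TrackStep",
    "Segment",
    "VesselTree",
    "load_image",
    "save_image",
    "compute_fov_mask",
    "rasterize_tree",
]


@dataclass
class FundusImage:
    """Grayscale fundus raster (float, 0-255) with an optional FOV mask."""

    pixels: np.ndarray
    fov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ImageFormatError("pixel raster must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ImageFormatError("grey levels must be finite")
        if self.fov is not None:
            self.fov = np.asarray(self.fov).astype(bool)
            if self.fov.shape != self.pixels.shape:
                raise ImageFormatError("FOV mask shape must match the image")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def contains(self, point: np.ndarray) -> bool:
        """True if the (row, col) point rounds to an in-image pixel."""
        r, c = int(round(float(point[0]))), int(round(float(point[1])))
        return 0 <= r < self.height and 0 <= c < self.width

    def grey_at(self, point: np.ndarray) -> float:
        """Grey level of the pixel nearest to a sub-pixel (row, col) point."""
        r = int(round(float(point[0])))
        c = int(round(float(point[1])))
        r = min(max(r, 0), self.height - 1)
        c = min(max(c, 0), self.width - 1)
        return float(self.pixels[r, c])


@dataclass
class PixelMask:
    """Binary per-pixel annotation with the shape of the image it describes."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ImageFormatError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class TrackStep:
    """One tracker iteration: center, direction, diameter and edge pair."""

    k: int
    center: np.ndarray
    direction_angle: float
    diameter: float
    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)


@dataclass
class Segment:
    """An ordered run of tracked steps with topology and provenance."""

    steps: list[TrackStep] = field(default_factory=list)
    seed_id: int = -1
    segment_id: int = -1
    parent_id: int | None = None
    stop_reasons: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class VesselTree:
    """All tracked segments of an image, with parent/child links."""

    segments: list[Segment] = field(default_factory=list)

    def add(self, segment: Segment) -> int:
        segment.segment_id = len(self.segments)
        self.segments.append(segment)
        return segment.segment_id

    def widths(self) -> np.ndarray:
        """Per-step diameters over the whole tree."""
        vals = [s.diameter for seg in self.segments for s in seg.steps]
        return np.asarray(vals, dtype=float)

    def to_dict(self) -> dict:
        return {
            "segments": [
                {
                    "segment_id": seg.segment_id,
                    "seed_id": seg.seed_id,
                    "parent_id": seg.parent_id,
                    "stop_reasons": list(seg.stop_reasons),
                    "steps": [
                        {
                            "k": s.k,
                            "center": [float(s.center[0]), float(s.center[1])],
                            "direction_angle": float(s.direction_angle),
                            "diameter": float(s.diameter),
                            "U": [float(s.U[0]), float(s.U[1])],
                            "V": [float(s.V[0]), float(s.V[1])],
                        }
                        for s in seg.steps
                    ],
                }
                for seg in self.segments
            ]
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "VesselTree":
        tree = cls()
        for sd in d["segments"]:
            seg = Segment(
                steps=[
                    TrackStep(
                        k=st["k"],
                        center=np.array(st["center"]),
                        direction_angle=st["direction_angle"],
                        diameter=st["diameter"],
                        U=np.array(st["U"]),
                        V=np.array(st["V"]),
                    )
                    for st in sd["steps"]
                ],
                seed_id=sd["seed_id"],
                segment_id=sd["segment_id"],
                parent_id=sd["parent_id"],
                stop_reasons=list(sd["stop_reasons"]),
            )
            tree.segments.append(seg)
        return tree

    @classmethod
    def from_json(cls, path: str | Path) -> "VesselTree":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_image(path: str | Path, channel_policy: str = "green") -> FundusImage:
    """Load a PNG/TIFF/PPM/JPEG raster as a float grey image on 0-255.

    RGB(A) input is reduced according to ``channel_policy``: one of
    ``green`` (the standard high-contrast channel for retinal photographs,
    the default), ``red``, ``blue`` or ``luminance`` (Rec. 601 weights).
    16-bit input is rescaled linearly onto 0-255.
    """
    try:
        arr = iio.imread(Path(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by format
        raise ImageFormatError(f"cannot decode image {path!r}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ImageFormatError(f"unsupported channel count {arr.shape[2]}")
        rgb = arr[:, :, :3].astype(float)
        if channel_policy == "green":
            plane = rgb[:, :, 1]
        elif channel_policy == "red":
            plane = rgb[:, :, 0]
        elif channel_policy == "blue":
            plane = rgb[:, :, 2]
        elif channel_policy == "luminance":
            plane = rgb @ np.array([0.299, 0.587, 0.114])
        else:
            raise ImageFormatError(f"unknown channel policy {channel_policy!r}")
    elif arr.ndim == 2:
        plane = arr.astype(float)
    else:
        raise ImageFormatError(f"unsupported raster dimensionality {arr.ndim}")

    if arr.dtype == np.uint16:
        plane = plane * (255.0 / 65535.0)
    elif arr.dtype not in (np.uint8, np.float32, np.float64):
        if np.issubdtype(arr.dtype, np.integer):
            info = np.iinfo(arr.dtype)
            plane = plane * (255.0 / info.max)
        else:
            raise ImageFormatError(f"unsupported bit depth {arr.dtype}")
    return FundusImage(plane)


def save_image(image: FundusImage | PixelMask | np.ndarray, path: str | Path) -> None:
    """Write a grey image (rounded to uint8) or a mask (0/255 PNG)."""
    if isinstance(image, PixelMask):
        arr = image.data.astype(np.uint8) * 255
    elif isinstance(image, FundusImage):
        arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    else:
        arr = np.asarray(image)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8) * 255
        else:
            arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def load_mask(path: str | Path) -> PixelMask:
    """Read a binary PNG mask (any nonzero pixel counts as foreground)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return PixelMask(arr > 0)


def compute_fov_mask(image: FundusImage, threshold: float) -> PixelMask:
    """Field-of-view mask: largest bright connected region, holes filled."""
    bright = image.pixels > threshold
    if not bright.any():
        raise DegenerateFOVError(f"no pixels above grey level {threshold}")
    labels = measure.label(bright, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(np.argmax(counts))
    mask = ndimage.binary_fill_holes(labels == biggest)
    return PixelMask(mask)


def _quad_fill(mask: np.ndarray, corners: list[np.ndarray]) -> None:
    rows = np.clip([c[0] for c in corners], 0, mask.shape[0] - 1)
    cols = np.clip([c[1] for c in corners], 0, mask.shape[1] - 1)
    rr, cc = skdraw.polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True


def rasterize_segment(segment: Segment, shape: tuple[int, int]) -> PixelMask:
    """Fill the quadrilateral between every pair of consecutive steps."""
    mask = np.zeros(shape, dtype=bool)
    for prev, cur in zip(segment.steps[:-1], segment.steps[1:]):
        _quad_fill(mask, [prev.U, cur.U, cur.V, prev.V])
    return PixelMask(mask)


def rasterize_tree(tree: VesselTree, shape: tuple[int, int]) -> PixelMask:
    """Union of all per-segment quadrilateral fills; empty trees allowed."""
    mask = np.zeros(shape, dtype=bool)
    for seg in tree.segments:
        for prev, cur in zip(seg.steps[:-1], seg.steps[1:]):
            _quad_fill(mask, [prev.U, cur.U, cur.V, prev.V])
    return PixelMask(mask)
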