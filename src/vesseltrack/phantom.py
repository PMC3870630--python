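"""Synthetic fundus phantoms with exact ground truth.

A phantom is a constant background holding dark vessels whose cross-section
is an inverted Gaussian dip: at distance l from the centerline the grey level
is  (I_c - I_b) exp(-l^2 / (2 sigma^2)) + I_b  for |l| <= w/2 and I_b
outside, with sigma set to half the vessel radius (w/4).  Independent
zero-mean Gaussian noise is added, with different standard deviations inside
(sigma_v) and outside (sigma_b) the vessel.  The generator emits the noisy
image together with the exact membership mask, centerline samples (position,
width, direction) and junction coordinates, so segmentation, width and
structure results can be scored without any manual annotation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import unit_vector
from .errors import SpecError
from .image_model import FundusImage, PixelMask

__all__ = [
    "VesselSpec",
    "PhantomSpec",
    "PhantomTruth",
    "render_vessel_profile",
    "generate_phantom",
    "add_noise",
    "straight_spec",
    "y_junction_spec",
    "crossing_spec",
    "parallel_spec",
    "benchmark_tree_spec",
]

#: centerline sampling step (px) for distance queries
_SAMPLE_STEP = 0.25


@dataclass
class VesselSpec:
    """One vessel: polyline/quadratic centerline, width, center grey level.

    ``points`` is a list of (row, col) vertices.  With ``quadratic=True`` and
    exactly three points they are Bezier control points; otherwise the
    centerline is the polyline through them.  ``width`` is either a scalar or
    a (start, end) pair varied linearly along arc length.
    """

    points: list[tuple[float, float]]
    width: float | tuple[float, float] = 6.0
    level: float = 100.0
    quadratic: bool = False

    def width_pair(self) -> tuple[float, float]:
        if isinstance(self.width, (tuple, list)):
            w0, w1 = float(self.width[0]), float(self.width[1])
        else:
            w0 = w1 = float(self.width)
        if min(w0, w1) < 1:
            raise SpecError("vessel width must be >= 1 px")
        return w0, w1


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (512, 512)
    background: float = 160.0
    vessels: list[VesselSpec] = field(default_factory=list)
    sigma_v: float = 5.0
    sigma_b: float = 5.0
    seed: int = 0
    junctions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in self.vessels:
            if v.level >= self.background:
                raise SpecError("vessels must be darker than the background")
            v.width_pair()
        if self.sigma_v < 0 or self.sigma_b < 0:
            raise SpecError("noise standard deviations must be >= 0")


@dataclass
class PhantomTruth:
    mask: PixelMask
    centerline: np.ndarray  # (M, 2) sample positions
    widths: np.ndarray  # (M,) local full widths
    angles: np.ndarray  # (M,) local direction angles (radians)
    vessel_ids: np.ndarray  # (M,) index into spec.vessels
    junctions: list[tuple[float, float]] = field(default_factory=list)

    def export_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "col", "width", "angle_deg", "vessel_id"])
            for p, w, a, vid in zip(self.centerline, self.widths, self.angles, self.vessel_ids):
                writer.writerow(
                    [f"{p[0]:.3f}", f"{p[1]:.3f}", f"{w:.3f}", f"{np.rad2deg(a):.2f}", int(vid)]
                )


def render_vessel_profile(
    l: float | np.ndarray, w: float, I_c: float, I_b: float
) -> float | np.ndarray:
    """Cross-section grey level at distance ``l`` from the centerline.

    Gaussian dip with sigma = w/4 inside the vessel (|l| <= w/2), exact
    background level outside.
    """
    if w < 1:
        raise SpecError("vessel width must be >= 1 px")
    l = np.asarray(l, dtype=float)
    sigma = w / 4.0
    value = (I_c - I_b) * np.exp(-(l**2) / (2.0 * sigma**2)) + I_b
    out = np.where(np.abs(l) <= w / 2.0, value, I_b)
    return float(out) if out.ndim == 0 else out


def _sample_centerline(vessel: VesselSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense (positions, widths, angles) samples along one centerline."""
    pts = np.asarray(vessel.points, dtype=float)
    if vessel.quadratic:
        if len(pts) != 3:
            raise SpecError("quadratic centerline needs exactly 3 control points")
        t = np.linspace(0.0, 1.0, 400)[:, None]
        curve = (1 - t) ** 2 * pts[0] + 2 * t * (1 - t) * pts[1] + t**2 * pts[2]
        pts = curve
    if len(pts) < 2:
        raise SpecError("centerline needs at least 2 points")
    seglens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seglens.sum())
    if total == 0:
        raise SpecError("degenerate centerline of zero length")
    n = max(int(np.ceil(total / _SAMPLE_STEP)) + 1, 2)
    cum = np.concatenate([[0.0], np.cumsum(seglens)])
    s = np.linspace(0.0, total, n)
    rows = np.interp(s, cum, pts[:, 0])
    cols = np.interp(s, cum, pts[:, 1])
    positions = np.column_stack([rows, cols])
    d = np.gradient(positions, axis=0)
    angles = np.arctan2(d[:, 0], d[:, 1])
    w0, w1 = vessel.width_pair()
    widths = w0 + (w1 - w0) * (s / total)
    return positions, widths, angles


def generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[FundusImage, PhantomTruth]:
    """Render the noise-free phantom, add noise, and emit ground truth.

    Per pixel, the grey level is the darkest prediction over all vessels
    (overlaps at crossings keep the darker value).  The truth mask marks
    pixels within half the local width of any centerline.
    """
    h, w = spec.shape
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    clean = np.full((h, w), spec.background, dtype=float)
    mask = np.zeros((h, w), dtype=bool)

    grid = np.column_stack(
        [g.ravel() for g in np.mgrid[0:h, 0:w].astype(float)]
    )

    all_pos, all_w, all_a, all_id = [], [], [], []
    for vid, vessel in enumerate(spec.vessels):
        positions, widths, angles = _sample_centerline(vessel)
        all_pos.append(positions)
        all_w.append(widths)
        all_a.append(angles)
        all_id.append(np.full(len(widths), vid))
        tree = cKDTree(positions)
        dist, idx = tree.query(grid, workers=-1)
        local_w = widths[idx]
        inside = dist <= local_w / 2.0
        sigma = local_w / 4.0
        value = (vessel.level - spec.background) * np.exp(
            -(dist**2) / (2.0 * sigma**2)
        ) + spec.background
        value = np.where(inside, value, spec.background).reshape(h, w)
        clean = np.minimum(clean, value)
        mask |= inside.reshape(h, w)

    truth = PhantomTruth(
        mask=PixelMask(mask),
        centerline=np.concatenate(all_pos) if all_pos else np.empty((0, 2)),
        widths=np.concatenate(all_w) if all_w else np.empty(0),
        angles=np.concatenate(all_a) if all_a else np.empty(0),
        vessel_ids=np.concatenate(all_id) if all_id else np.empty(0, dtype=int),
        junctions=list(spec.junctions),
    )
    noisy = add_noise(FundusImage(clean), truth.mask, spec.sigma_v, spec.sigma_b, rng)
    return noisy, truth


def add_noise(
    image: FundusImage,
    truth: PixelMask,
    sigma_v: float,
    sigma_b: float,
    rng: np.random.Generator,
) -> FundusImage:
    """Independent zero-mean Gaussian noise per region, clipped to [0, 255]."""
    if truth.shape != image.shape:
        raise SpecError("truth mask must match the image shape")
    vessel_noise = rng.normal(0.0, sigma_v, image.shape) if sigma_v > 0 else 0.0
    bg_noise = rng.normal(0.0, sigma_b, image.shape) if sigma_b > 0 else 0.0
    noisy = image.pixels + np.where(truth.data, vessel_noise, bg_noise)
    return FundusImage(np.clip(noisy, 0.0, 255.0), fov=image.fov)


# --------------------------------------------------------------------------
# layout factories (defaults follow the benchmark conditions: background 160,
# vessel level 100 i.e. contrast 60, noise sigma 5)


def _line_through(
    shape: tuple[int, int], center: tuple[float, float], angle_deg: float, half_len: float
) -> list[tuple[float, float]]:
    d = unit_vector(np.deg2rad(angle_deg))
    c = np.asarray(center, dtype=float)
    return [tuple(c - half_len * d), tuple(c + half_len * d)]


def straight_spec(
    width: float = 6.0,
    angle_deg: float = 20.0,
    shape: tuple[int, int] = (160, 160),
    background: float = 160.0,
    level: float = 100.0,
    sigma_v: float = 5.0,
    sigma_b: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    """A single straight vessel through the canvas center."""
    h, w = shape
    half = 0.48 * min(h, w)
    return PhantomSpec(
        shape=shape,
        background=background,
        vessels=[
            VesselSpec(_line_through(shape, (h / 2 + 0.3, w / 2 + 0.2), angle_deg, half), width, level)
        ],
        sigma_v=sigma_v,
        sigma_b=sigma_b,
        seed=seed,
    )


def y_junction_spec(
    trunk_width: float = 8.0,
    branch_widths: tuple[float, float] = (6.0, 5.0),
    shape: tuple[int, int] = (200, 200),
    sigma: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    """A trunk entering from the bottom that splits into two branches."""
    h, w = shape
    junction = (h * 0.5, w * 0.5)
    trunk = VesselSpec([(h - 8.0, w * 0.5 - 4.0), junction], trunk_width)
    b1 = VesselSpec([junction, (10.0, w * 0.18)], branch_widths[0])
    b2 = VesselSpec([junction, (10.0, w * 0.85)], branch_widths[1])
    return PhantomSpec(
        shape=shape,
        vessels=[trunk, b1, b2],
        sigma_v=sigma,
        sigma_b=sigma,
        seed=seed,
        junctions=[junction],
    )


def crossing_spec(
    widths: tuple[float, float] = (8.0, 6.0),
    shape: tuple[int, int] = (200, 200),
    sigma: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    """Two straight vessels crossing near the canvas center."""
    h, w = shape
    center = (h * 0.5, w * 0.5)
    v1 = VesselSpec(_line_through(shape, center, 75.0, 0.46 * min(h, w)), widths[0])
    v2 = VesselSpec(_line_through(shape, center, 5.0, 0.46 * min(h, w)), widths[1])
    return PhantomSpec(
        shape=shape,
        vessels=[v1, v2],
        sigma_v=sigma,
        sigma_b=sigma,
        seed=seed,
        junctions=[center],
    )


def parallel_spec(
    width: float = 6.0,
    separation: float = 40.0,
    shape: tuple[int, int] = (160, 160),
    sigma: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    """Two parallel straight vessels (no contact)."""
    h, w = shape
    off = separation / 2.0
    v1 = VesselSpec(_line_through(shape, (h / 2 - off, w / 2), 10.0, 0.46 * min(h, w)), width)
    v2 = VesselSpec(_line_through(shape, (h / 2 + off, w / 2), 10.0, 0.46 * min(h, w)), width)
    return PhantomSpec(shape=shape, vessels=[v1, v2], sigma_v=sigma, sigma_b=sigma, seed=seed)


def benchmark_tree_spec(seed: int = 0, sigma: float = 5.0) -> PhantomSpec:
    """Default 512x512 benchmark: a 4-vessel tree spanning widths 3-12.

    A wide trunk rises from the bottom edge to a junction, splits into two
    branches (widths 8 and 5), and a thin width-3 vessel crosses the trunk -
    one instance of every tracked structure on a single canvas.
    """
    junction = (210.0, 262.0)
    trunk = VesselSpec([(500.0, 242.5), junction], 12.0)
    branch_a = VesselSpec([junction, (30.0, 95.5)], 8.0)
    branch_b = VesselSpec([junction, (40.0, 430.5)], 5.0)
    crosser = VesselSpec([(390.0, 20.5), (340.0, 495.5)], 3.0)
    return PhantomSpec(
        shape=(512, 512),
        vessels=[trunk, branch_a, branch_b, crosser],
        sigma_v=sigma,
        sigma_b=sigma,
        seed=seed,
        junctions=[junction],
    )
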