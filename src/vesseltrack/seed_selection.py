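"""Automatic seed detection on grid lines with matched-filter validation.

Two steps: (1) every strict local minimum of the grey profile along a sparse
set of horizontal and vertical grid lines becomes a candidate (vessels are
dark, so their cross-sections dip); (2) each candidate is scored by a bank of
12 oriented Gaussian matched filters on the inverted image, and kept only if
the best response exceeds a local adaptive threshold mu + alpha * sigma
computed over a large neighborhood of the same inverted raster.  The winning
filter orientation doubles as the initial vessel direction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import SpecError
from .image_model import FundusImage

__all__ = [
    "GridSpec",
    "SeedCandidate",
    "MatchedFilterBank",
    "SeedThresholdParams",
    "SeedPoint",
    "detect_grid_minima",
    "build_filter_bank",
    "local_adaptive_threshold",
    "validate_seeds",
    "detect_seeds",
    "export_seeds_csv",
]


@dataclass
class GridSpec:
    """Spacing (px) between consecutive horizontal/vertical grid lines."""

    spacing: int = 30

    def __post_init__(self) -> None:
        if self.spacing < 2:
            raise SpecError("grid spacing must be >= 2")


@dataclass
class SeedCandidate:
    position: np.ndarray  # (row, col), integer-valued
    line_kind: str  # "horizontal" | "vertical"
    profile_value: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class MatchedFilterBank:
    """12 zero-mean oriented kernels with a Gaussian cross profile.

    Orientations run 0, 15, ..., 165 degrees; the kernel at angle t is the
    continuous Gaussian band (length ``kernel_length`` along the vessel,
    cross spread ``profile_sigma``) evaluated in rotated coordinates on the
    pixel grid, then demeaned over its footprint.
    """

    kernels: list[np.ndarray]
    orientations: np.ndarray  # radians
    profile_sigma: float
    kernel_length: float


@dataclass
class SeedThresholdParams:
    alpha: float = 1.2
    window: int = 61

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise SpecError("alpha must be positive")
        if self.window < 1 or self.window % 2 == 0:
            raise SpecError("window must be odd")


@dataclass
class SeedPoint:
    position: np.ndarray
    direction_angle: float  # radians; best filter orientation (mod pi)
    response: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


def _plateau_minima(profile: np.ndarray) -> list[int]:
    """Indices of strict local minima; plateaus report their center index."""
    n = len(profile)
    out: list[int] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and profile[j + 1] == profile[i]:
            j += 1
        # plateau profile[i..j]; strict minimum needs both flanks higher
        if j < n - 1 and profile[i - 1] > profile[i] and profile[j + 1] > profile[i]:
            out.append((i + j) // 2)
        i = j + 1
    return out


def detect_grid_minima(image: FundusImage, grid: GridSpec) -> list[SeedCandidate]:
    """Candidate seeds: local grey minima along every grid line, inside FOV."""
    h, w = image.shape
    candidates: list[SeedCandidate] = []
    for row in range(grid.spacing, h, grid.spacing):
        for col in _plateau_minima(image.pixels[row, :]):
            candidates.append(
                SeedCandidate(np.array([row, col]), "horizontal", float(image.pixels[row, col]))
            )
    for col in range(grid.spacing, w, grid.spacing):
        for row in _plateau_minima(image.pixels[:, col]):
            candidates.append(
                SeedCandidate(np.array([row, col]), "vertical", float(image.pixels[row, col]))
            )
    if image.fov is not None:
        candidates = [
            c for c in candidates if image.fov[int(c.position[0]), int(c.position[1])]
        ]
    return _merge_close(candidates, radius=3.0)


def _merge_close(candidates: list[SeedCandidate], radius: float) -> list[SeedCandidate]:
    """Collapse candidates closer than ``radius`` px to the deepest minimum.

    Greedy in order of increasing grey value: a candidate survives only if no
    already-kept candidate lies strictly within ``radius``. Neighbor lookups go
    through a k-d tree so dense candidate sets stay near-linear.
    """
    if not candidates:
        return []
    ordered = sorted(candidates, key=lambda c: c.profile_value)
    positions = np.array([c.position for c in ordered], dtype=float)
    pairs = cKDTree(positions).query_pairs(radius, output_type="ndarray")
    if len(pairs):
        dist = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
        pairs = pairs[dist < radius]
    neighbors: list[list[int]] = [[] for _ in ordered]
    for a, b in pairs:
        neighbors[a].append(b)
        neighbors[b].append(a)
    kept_flag = np.zeros(len(ordered), dtype=bool)
    kept: list[SeedCandidate] = []
    for i, cand in enumerate(ordered):
        if any(kept_flag[j] for j in neighbors[i]):
            continue
        kept_flag[i] = True
        kept.append(cand)
    kept.sort(key=lambda c: (c.position[0], c.position[1]))
    return kept


def build_filter_bank(profile_sigma: float = 2.0, kernel_length: float = 9.0) -> MatchedFilterBank:
    """12 oriented zero-mean Gaussian matched filters, 15 degrees apart."""
    if profile_sigma <= 0:
        raise SpecError("profile_sigma must be positive")
    if kernel_length < 3:
        raise SpecError("kernel_length must be >= 3")
    half_len = kernel_length / 2.0
    half_cross = float(np.ceil(3.0 * profile_sigma))
    radius = int(np.ceil(np.hypot(half_len, half_cross)))
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1].astype(float)
    orientations = np.deg2rad(np.arange(12) * 15.0)
    kernels = []
    for theta in orientations:
        # coordinates in the frame where the vessel runs along +col
        along = cc * np.cos(theta) + rr * np.sin(theta)
        across = -cc * np.sin(theta) + rr * np.cos(theta)
        band = (np.abs(along) <= half_len) & (np.abs(across) <= half_cross)
        kern = np.zeros_like(rr)
        kern[band] = np.exp(-(across[band] ** 2) / (2.0 * profile_sigma**2))
        kern[band] -= kern[band].mean()
        kernels.append(kern)
    return MatchedFilterBank(kernels, orientations, profile_sigma, kernel_length)


def local_adaptive_threshold(
    image: FundusImage, point: np.ndarray, params: SeedThresholdParams
) -> float:
    """mu + alpha * sigma over the window x window neighborhood (clipped)."""
    r, c = int(round(float(point[0]))), int(round(float(point[1])))
    half = params.window // 2
    patch = image.pixels[
        max(r - half, 0) : r + half + 1, max(c - half, 0) : c + half + 1
    ]
    return float(patch.mean() + params.alpha * patch.std())


def _response_at(inverted: np.ndarray, kernel: np.ndarray, r: int, c: int) -> float:
    """Correlation of a kernel with the inverted image, clipped at borders.

    A border-clipped kernel no longer sums to zero over its band, which would
    leak the local grey level into the response; the clipped band is therefore
    demeaned again before correlating.
    """
    kh = kernel.shape[0] // 2
    r0, r1 = max(r - kh, 0), min(r + kh + 1, inverted.shape[0])
    c0, c1 = max(c - kh, 0), min(c + kh + 1, inverted.shape[1])
    kr0, kc0 = r0 - (r - kh), c0 - (c - kh)
    patch = inverted[r0:r1, c0:c1]
    kpatch = kernel[kr0 : kr0 + patch.shape[0], kc0 : kc0 + patch.shape[1]]
    if kpatch.shape != kernel.shape:
        band = kpatch != 0.0
        if not band.any():
            return 0.0
        kpatch = np.where(band, kpatch - kpatch[band].mean(), 0.0)
    return float(np.sum(patch * kpatch))


def validate_seeds(
    image: FundusImage,
    candidates: list[SeedCandidate],
    bank: MatchedFilterBank,
    params: SeedThresholdParams,
) -> list[SeedPoint]:
    """Keep candidates whose best matched-filter response beats Eq-style
    local threshold; both computed on the inverted image (vessel dips become
    peaks there, so "highest response" is well defined)."""
    inverted_img = FundusImage(255.0 - image.pixels)
    seeds: list[SeedPoint] = []
    for cand in candidates:
        r, c = int(cand.position[0]), int(cand.position[1])
        responses = [_response_at(inverted_img.pixels, k, r, c) for k in bank.kernels]
        best = int(np.argmax(responses))
        threshold = local_adaptive_threshold(inverted_img, cand.position, params)
        if responses[best] > threshold:
            seeds.append(
                SeedPoint(cand.position.copy(), float(bank.orientations[best]), responses[best])
            )
    return seeds


def detect_seeds(
    image: FundusImage,
    grid: GridSpec | None = None,
    bank: MatchedFilterBank | None = None,
    params: SeedThresholdParams | None = None,
) -> list[SeedPoint]:
    """Grid-minima detection followed by matched-filter validation."""
    grid = grid or GridSpec()
    bank = bank or build_filter_bank()
    params = params or SeedThresholdParams()
    return validate_seeds(image, detect_grid_minima(image, grid), bank, params)


def export_seeds_csv(seeds: list[SeedPoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "angle_deg", "response"])
        for s in seeds:
            writer.writerow(
                [
                    f"{s.position[0]:.1f}",
                    f"{s.position[1]:.1f}",
                    f"{np.rad2deg(s.direction_angle):.1f}",
                    f"{s.response:.4f}",
                ]
            )
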