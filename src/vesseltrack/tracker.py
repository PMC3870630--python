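"""Iterative vessel tracking: windows, branch prediction, state updates.

From every validated seed the tracker walks along the vessel in both
directions.  Each iteration extrapolates the center ``s`` px ahead, lays a
search window across the vessel (a perpendicular line segment, or a forward
semicircle when the edge directions diverge and a branch is predicted),
samples the intensity profile, and asks the Bayesian layer for the MAP
configuration.  Normal configurations update the edge pair; bifurcations and
crossings spawn branch tracks which are processed biggest-diameter-first.
Tracking stops when the diameter collapses below one pixel, the local
contrast fades, an already-detected vessel is met, the window leaves the
image, no feasible configuration remains, or a safety iteration cap hits.
"""

from __future__ import annotations

import csv
import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import perpendicular, unit_vector, vector_angle, wrap_angle
from .bayes_config import (
    GibbsParams,
    LocalStatistics,
    PruningParams,
    estimate_local_statistics,
    fit_edge_lines,
    map_configuration,
    sample_profile,
)
from .config import RunConfig
from .errors import (
    NoConfigurationError,
    StatisticsUnavailableError,
    UndefinedDirectionError,
    VesselTrackError,
    WindowDegenerateError,
)
from .gradient_direction import GradientField, sobel_gradient, vessel_direction_at
from .image_model import FundusImage, PixelMask, Segment, TrackStep, VesselTree, _quad_fill
from .seed_selection import SeedPoint, detect_seeds

__all__ = [
    "TrackerState",
    "SearchWindow",
    "StopReason",
    "BranchQueue",
    "initial_window",
    "extrapolate_center",
    "linear_window",
    "semicircle_window",
    "predict_branch",
    "check_stop",
    "track_from_seed",
    "track_all",
    "export_steps_csv",
]

#: iterations at the start of a track during which the collision test is
#: suppressed (a branch or the reverse direction begins on its parent's mask)
GRACE_ITERATIONS = 3

#: hard cap on segments grown from one seed (guards against branch cascades)
MAX_SEGMENTS_PER_SEED = 64


class StopReason:
    DIAMETER_COLLAPSE = "diameter_collapse"
    LOW_CONTRAST = "low_contrast"
    COLLISION = "collision"
    OUT_OF_IMAGE = "out_of_image"
    NO_CONFIGURATION = "no_configuration"
    MAX_ITERATIONS = "max_iterations"
    BRANCHED = "branched"


@dataclass
class TrackerState:
    """Per-iteration bundle of local vessel parameters."""

    k: int
    center: np.ndarray
    direction: np.ndarray  # unit vector
    diameter: float
    U: np.ndarray
    V: np.ndarray
    history: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)

    def as_step(self) -> TrackStep:
        return TrackStep(
            k=self.k,
            center=self.center.copy(),
            direction_angle=vector_angle(self.direction),
            diameter=self.diameter,
            U=self.U.copy(),
            V=self.V.copy(),
        )


@dataclass
class SearchWindow:
    kind: str  # "linear" | "semicircle"
    center: np.ndarray
    axis_direction: np.ndarray
    candidates: np.ndarray  # (N, 2), ~1 px spacing
    extent: float


@dataclass(order=True)
class _QueuedBranch:
    priority: float
    order: int
    U: np.ndarray = field(compare=False)
    V: np.ndarray = field(compare=False)
    origin: np.ndarray = field(compare=False)
    parent_id: int = field(compare=False, default=-1)


class BranchQueue:
    """Pending branch tracks, biggest initial diameter first."""

    def __init__(self) -> None:
        self._heap: list[_QueuedBranch] = []
        self._count = 0

    def push(self, U: np.ndarray, V: np.ndarray, origin: np.ndarray, parent_id: int) -> None:
        d = float(np.linalg.norm(np.asarray(U, float) - np.asarray(V, float)))
        item = _QueuedBranch(-d, self._count, np.asarray(U, float), np.asarray(V, float), np.asarray(origin, float), parent_id)
        self._count += 1
        heapq.heappush(self._heap, item)

    def pop(self) -> _QueuedBranch:
        return heapq.heappop(self._heap)

    def __len__(self) -> int:
        return len(self._heap)


def _line_candidates(
    center: np.ndarray, axis_direction: np.ndarray, length: float, spacing: float = 1.0
) -> np.ndarray:
    half = int(round(length / (2.0 * spacing)))
    perp = perpendicular(axis_direction)
    offsets = (np.arange(-half, half + 1, dtype=float) * spacing)[:, None]
    return center[None, :] + offsets * perp[None, :]


def initial_window(seed: SeedPoint, L0: float, spacing: float = 1.0) -> SearchWindow:
    """Linear window of length L0 centered on the seed, across the vessel."""
    axis = unit_vector(seed.direction_angle)
    cands = _line_candidates(seed.position, axis, L0, spacing)
    return SearchWindow("linear", seed.position.copy(), axis, cands, L0)


def extrapolate_center(
    state: TrackerState, s: float, field_: GradientField, neighborhood: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Step ``s`` px ahead and re-estimate the direction there.

    Falls back to the previous direction when the local gradient vanishes.
    Raises :class:`VesselTrackError` when the point leaves the image.
    """
    O_s = state.center + s * state.direction
    h, w = field_.shape
    if not (0 <= round(O_s[0]) < h and 0 <= round(O_s[1]) < w):
        raise VesselTrackError(StopReason.OUT_OF_IMAGE)
    try:
        est = vessel_direction_at(field_, O_s, state.direction, neighborhood)
        direction = est.unit
    except UndefinedDirectionError:
        direction = state.direction.copy()
    return O_s, direction


def linear_window(
    center: np.ndarray,
    direction: np.ndarray,
    prev_diameter: float,
    min_length: float = 4.0,
    spacing: float = 1.0,
) -> SearchWindow:
    """Window perpendicular to the direction, twice the previous diameter."""
    length = max(2.0 * prev_diameter, min_length)
    cands = _line_candidates(center, direction, length, spacing)
    return SearchWindow("linear", np.asarray(center, float), np.asarray(direction, float), cands, length)


def semicircle_window(
    state: TrackerState, radius_factor: float = 1.5, spacing: float = 1.0
) -> SearchWindow:
    """Forward arc spanning +-90 degrees around the current direction."""
    radius = radius_factor * state.diameter
    n = max(int(round(np.pi * radius / spacing)) + 1, 5)
    base = vector_angle(state.direction)
    angles = base + np.linspace(-np.pi / 2.0, np.pi / 2.0, n)
    cands = state.center[None, :] + radius * np.column_stack([np.sin(angles), np.cos(angles)])
    return SearchWindow("semicircle", state.center.copy(), state.direction.copy(), cands, radius)


def predict_branch(
    field_: GradientField,
    state: TrackerState,
    t_angle_deg: float = 5.0,
    neighborhood: int = 5,
) -> bool:
    """True when the directions of the two vessel edges diverge by >= T_angle.

    A single vessel has parallel edges; diverging edge directions announce a
    bifurcation or crossing ahead.  Each edge's direction is estimated at the
    point half-way between the centre and the edge point: for the profile's
    shape that is where the edge's gradient magnitude peaks, so the
    squared-magnitude-weighted direction estimate has the best signal-to-noise
    ratio there.  Undefined edge gradients count as parallel (linear window
    assumed).
    """
    pu = state.center + 0.5 * (state.U - state.center)
    pv = state.center + 0.5 * (state.V - state.center)
    try:
        eu = vessel_direction_at(field_, pu, state.direction, neighborhood)
        ev = vessel_direction_at(field_, pv, state.direction, neighborhood)
    except UndefinedDirectionError:
        return False
    delta = abs(wrap_angle(eu.vessel_angle - ev.vessel_angle))
    if delta > np.pi / 2.0:
        delta = np.pi - delta
    return bool(np.rad2deg(delta) >= t_angle_deg)


def check_stop(
    state: TrackerState,
    stats,
    visited: np.ndarray,
    image: FundusImage,
    config: RunConfig,
    check_collision: bool = True,
) -> str | None:
    """End-condition test on the freshly updated state, or None to continue."""
    if state.diameter < 1.0:
        return StopReason.DIAMETER_COLLAPSE
    if stats is not None and abs(stats.I_c - stats.I_b) < config.kappa_contrast * stats.sigma_b:
        return StopReason.LOW_CONTRAST
    if not image.contains(state.center):
        return StopReason.OUT_OF_IMAGE
    if check_collision and _collides(visited, state.center):
        return StopReason.COLLISION
    if state.k >= config.max_iterations:
        return StopReason.MAX_ITERATIONS
    return None


def _collides(visited: np.ndarray, point: np.ndarray) -> bool:
    """Collision test with a 1-px dilation around the query point."""
    r, c = int(round(float(point[0]))), int(round(float(point[1])))
    h, w = visited.shape
    patch = visited[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
    return bool(patch.any())


def _mark_quad(visited: np.ndarray, prev: TrackerState, cur: TrackerState) -> None:
    _quad_fill(visited, [prev.U, cur.U, cur.V, prev.V])


def _initial_state_from_seed(
    image: FundusImage, seed: SeedPoint, config: RunConfig
) -> TrackerState | None:
    """Edge pair on the initial window around the seed, or None to reject."""
    window = initial_window(seed, config.L0, config.candidate_spacing)
    try:
        profile = sample_profile(image, window)
    except WindowDegenerateError:
        return None
    n = profile.count
    center_idx = int(np.argmin(np.linalg.norm(profile.positions - seed.position, axis=1)))
    # bootstrap statistics: the window tails approximate the background
    tail = max(n // 4, 1)
    tails = np.concatenate([profile.values[:tail], profile.values[-tail:]])
    sigma_b = max(float(tails.std()), config.sigma_floor)
    stats = LocalStatistics(
        I_c=image.grey_at(seed.position),
        I_b=float(tails.mean()),
        sigma_v=sigma_b,
        sigma_b=sigma_b,
    )
    try:
        cfg = map_configuration(
            profile, stats, None, "linear", require_cover=center_idx,
            gibbs=GibbsParams(config.gibbs_z, config.gibbs_lambda),
        )
    except (NoConfigurationError, WindowDegenerateError):
        return None
    m1, m2 = cfg.indices
    U, V = profile.positions[m1], profile.positions[m2]
    center = 0.5 * (U + V)
    return TrackerState(
        k=0,
        center=center,
        direction=unit_vector(seed.direction_angle),
        diameter=float(np.linalg.norm(U - V)),
        U=U,
        V=V,
        history=[(U.copy(), V.copy())],
    )


def _track_direction(
    image: FundusImage,
    field_: GradientField,
    start: TrackerState,
    config: RunConfig,
    visited: np.ndarray,
    queue: BranchQueue,
    parent_id: int,
) -> tuple[list[TrackStep], str]:
    """Run the iteration loop in one direction from a starting state."""
    state = start
    steps = [state.as_step()]
    gibbs = GibbsParams(config.gibbs_z, config.gibbs_lambda)
    while True:
        k = state.k + 1
        try:
            stats = estimate_local_statistics(
                image, state.center, state.U, state.V, state.diameter,
                margin=config.region_margin, sigma_floor=config.sigma_floor,
            ).floored(config.sigma_floor)
        except StatisticsUnavailableError:
            return steps, StopReason.OUT_OF_IMAGE
        if abs(stats.I_c - stats.I_b) < config.kappa_contrast * stats.sigma_b:
            return steps, StopReason.LOW_CONTRAST

        branch = predict_branch(field_, state, config.t_angle_deg, config.neighborhood)
        try:
            if branch:
                window = semicircle_window(
                    state, config.semicircle_radius_factor, config.candidate_spacing
                )
                profile = sample_profile(image, window)
                constraints = PruningParams(
                    d_prev=state.diameter,
                    min_gap=config.min_gap,
                    max_chord_factor=config.max_chord_factor,
                    axis_point=state.center,
                    axis_dir=state.direction,
                    axis_tol=state.diameter,
                )
                cfg = map_configuration(profile, stats, None, "semicircle", constraints, gibbs)
            else:
                O_s, D_s = extrapolate_center(state, config.s, field_, config.neighborhood)
                window = linear_window(
                    O_s, D_s, state.diameter, config.min_window_length,
                    config.candidate_spacing,
                )
                profile = sample_profile(image, window)
                lines = fit_edge_lines(state.history, state.direction, k)
                cfg = map_configuration(profile, stats, lines, "linear", None, gibbs)
        except (WindowDegenerateError, NoConfigurationError):
            return steps, StopReason.NO_CONFIGURATION
        except VesselTrackError as exc:
            if str(exc) == StopReason.OUT_OF_IMAGE:
                return steps, StopReason.OUT_OF_IMAGE
            raise

        if cfg.kind == "bifurcation":
            p1, p2, p3, p4 = cfg.indices
            queue.push(profile.positions[p1], profile.positions[p2], state.center, parent_id)
            queue.push(profile.positions[p3], profile.positions[p4], state.center, parent_id)
            return steps, StopReason.BRANCHED
        if cfg.kind == "crossing":
            p1, p2, p3, p4, p5, p6 = cfg.indices
            queue.push(profile.positions[p1], profile.positions[p2], state.center, parent_id)
            queue.push(profile.positions[p5], profile.positions[p6], state.center, parent_id)
            m1, m2 = p3, p4
        else:
            m1, m2 = cfg.indices

        U, V = profile.positions[m1], profile.positions[m2]
        center = 0.5 * (U + V)
        try:
            direction = vessel_direction_at(field_, center, state.direction, config.neighborhood).unit
        except (UndefinedDirectionError, IndexError):
            direction = state.direction.copy()
        new_state = TrackerState(
            k=k,
            center=center,
            direction=direction,
            diameter=float(np.linalg.norm(U - V)),
            U=U,
            V=V,
            history=(state.history + [(U.copy(), V.copy())])[-4:],
        )
        # contrast was already tested at the top of the iteration
        reason = check_stop(
            new_state, None, visited, image, config,
            check_collision=(k > GRACE_ITERATIONS),
        )
        if reason is not None:
            return steps, reason
        _mark_quad(visited, state, new_state)
        steps.append(new_state.as_step())
        state = new_state


def track_from_seed(
    image: FundusImage,
    seed: SeedPoint,
    config: RunConfig,
    visited: np.ndarray,
    field_: GradientField | None = None,
    seed_id: int = -1,
) -> list[Segment]:
    """Track in both directions from one seed and drain the branch queue."""
    if field_ is None:
        field_ = sobel_gradient(image, config.gradient_sigma)
    start = _initial_state_from_seed(image, seed, config)
    if start is None:
        return []

    queue = BranchQueue()
    segments: list[Segment] = []

    forward, r_fwd = _track_direction(image, field_, start, config, visited, queue, 0)
    back_start = TrackerState(
        k=0,
        center=start.center.copy(),
        direction=-start.direction,
        diameter=start.diameter,
        U=start.V.copy(),
        V=start.U.copy(),
        history=[(start.V.copy(), start.U.copy())],
    )
    backward, r_bwd = _track_direction(image, field_, back_start, config, visited, queue, 0)

    merged = list(reversed(backward[1:])) + forward
    root = Segment(steps=merged, seed_id=seed_id, stop_reasons=[r_bwd, r_fwd])
    segments.append(root)

    while len(queue) and len(segments) < MAX_SEGMENTS_PER_SEED:
        item = queue.pop()
        Ob = 0.5 * (item.U + item.V)
        d0 = float(np.linalg.norm(item.U - item.V))
        if d0 < 1.0 or not image.contains(Ob):
            continue
        ref = Ob - item.origin
        nrm = np.linalg.norm(ref)
        if nrm == 0:
            continue
        ref = ref / nrm
        try:
            direction = vessel_direction_at(field_, Ob, ref, config.neighborhood).unit
        except (UndefinedDirectionError, IndexError):
            direction = ref
        bstate = TrackerState(
            k=0, center=Ob, direction=direction, diameter=d0,
            U=item.U.copy(), V=item.V.copy(),
            history=[(item.U.copy(), item.V.copy())],
        )
        bsteps, breason = _track_direction(image, field_, bstate, config, visited, queue, len(segments))
        seg = Segment(steps=bsteps, seed_id=seed_id, parent_id=item.parent_id, stop_reasons=[breason])
        segments.append(seg)

    return [s for s in segments if len(s.steps) >= 2 or s is segments[0]]


def track_all(
    image: FundusImage,
    config: RunConfig | None = None,
    seeds: list[SeedPoint] | None = None,
) -> tuple[VesselTree, list[SeedPoint]]:
    """Detect seeds and track the whole image into a vessel tree.

    Seeds are processed in row-major order; a seed falling on an already
    detected vessel is skipped (the collision end condition applied up
    front), so each vessel is traced once.
    """
    config = config or RunConfig()
    if seeds is None:
        from .seed_selection import GridSpec, SeedThresholdParams, build_filter_bank

        seeds = detect_seeds(
            image,
            GridSpec(config.grid_spacing),
            build_filter_bank(config.profile_sigma, config.kernel_length),
            SeedThresholdParams(config.alpha, config.seed_window),
        )
    seeds = sorted(seeds, key=lambda s: (s.position[0], s.position[1]))
    field_ = sobel_gradient(image, config.gradient_sigma)
    visited = np.zeros(image.shape, dtype=bool)
    tree = VesselTree()
    for sid, seed in enumerate(seeds):
        r, c = int(seed.position[0]), int(seed.position[1])
        if visited[r, c]:
            continue
        for seg in track_from_seed(image, seed, config, visited, field_, seed_id=sid):
            if len(seg.steps) >= 2:
                tree.add(seg)
    return tree, seeds


def export_steps_csv(tree: VesselTree, path: str | Path) -> None:
    """One row per tracked step: segment, k, center, edges, diameter, angle."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["segment_id", "k", "o_row", "o_col", "u_row", "u_col", "v_row", "v_col", "diameter", "angle_deg"]
        )
        for seg in tree.segments:
            for s in seg.steps:
                writer.writerow(
                    [
                        seg.segment_id,
                        s.k,
                        f"{s.center[0]:.4f}",
                        f"{s.center[1]:.4f}",
                        f"{s.U[0]:.4f}",
                        f"{s.U[1]:.4f}",
                        f"{s.V[0]:.4f}",
                        f"{s.V[1]:.4f}",
                        f"{s.diameter:.4f}",
                        f"{np.rad2deg(s.direction_angle):.3f}",
                    ]
                )
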