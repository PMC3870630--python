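"""Configuration models and MAP edge-point selection.

At each tracking step the candidate points of the search window are
partitioned by a *configuration* into vessel intervals and background:

* normal        - indices (m1, m2): one vessel spanning [m1, m2];
* bifurcation   - (p1..p4): two vessel intervals [p1,p2], [p3,p4];
* crossing      - (p1..p6): three vessel intervals, the middle one being the
  continuation of the tracked vessel, the outer two the other vessel.

Inside a vessel interval the true grey level follows an inverted Gaussian
dip centered on the chord midpoint, with spread set to half the hypothesized
radius (sigma_chi = |chord| / 4), on a constant background I_b; observed
levels are the truth plus Gaussian noise (sigma_v inside vessels, sigma_b
outside).  The likelihood of a configuration is the product of the per-point
normal densities; normal configurations on a linear window additionally
carry a Gibbs prior exp(-lambda (t1^2 + t2^2)) / Z penalizing edge points
far from the extrapolated edge lines.  The best configuration maximizes the
log-posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import point_line_distance, total_least_squares_line
from .errors import (
    InvalidConfigurationError,
    NoConfigurationError,
    StatisticsUnavailableError,
    WindowDegenerateError,
)
from .image_model import FundusImage

__all__ = [
    "IntensityProfile",
    "Configuration",
    "LocalStatistics",
    "EdgeLineModel",
    "GibbsParams",
    "PruningParams",
    "sample_profile",
    "estimate_local_statistics",
    "model_profile",
    "log_likelihood",
    "fit_edge_lines",
    "log_prior",
    "map_configuration",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

KIND_RANK = {"normal": 0, "bifurcation": 1, "crossing": 2}
_KIND_SIZES = {"normal": 2, "bifurcation": 4, "crossing": 6}


@dataclass
class IntensityProfile:
    """Sub-pixel candidate positions with their sampled grey levels."""

    positions: np.ndarray  # (N, 2) (row, col)
    values: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values):
            raise WindowDegenerateError("positions and values must align")

    @property
    def count(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Configuration:
    """A structural hypothesis: 2, 4 or 6 strictly increasing indices."""

    kind: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KIND_SIZES:
            raise InvalidConfigurationError(f"unknown kind {self.kind!r}")
        if len(self.indices) != _KIND_SIZES[self.kind]:
            raise InvalidConfigurationError(
                f"{self.kind} needs {_KIND_SIZES[self.kind]} indices, got {len(self.indices)}"
            )
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise InvalidConfigurationError("indices must be strictly increasing")

    @property
    def intervals(self) -> tuple[tuple[int, int], ...]:
        idx = self.indices
        return tuple((idx[i], idx[i + 1]) for i in range(0, len(idx), 2))


@dataclass
class LocalStatistics:
    """Grey-level and noise statistics from the three moving regions."""

    I_c: float
    I_b: float
    sigma_v: float
    sigma_b: float

    def floored(self, floor: float) -> "LocalStatistics":
        return LocalStatistics(
            self.I_c, self.I_b, max(self.sigma_v, floor), max(self.sigma_b, floor)
        )


@dataclass
class EdgeLineModel:
    """The two extrapolated vessel edge lines (point + unit direction)."""

    e1_point: np.ndarray
    e1_dir: np.ndarray
    e2_point: np.ndarray
    e2_dir: np.ndarray


@dataclass
class GibbsParams:
    Z: float = 1.0
    lam: float = 0.01


@dataclass
class PruningParams:
    """Feasibility constraints bounding the semicircle configuration search.

    Vessel intervals must have chord length in [min_chord, max_chord_factor
    * d_prev]; consecutive intervals must be separated by at least min_gap
    background candidates; a crossing's middle interval midpoint must lie
    within axis_tol of the window's axis of symmetry.
    """

    d_prev: float
    min_chord: float = 1.0
    max_chord_factor: float = 1.5
    min_gap: int = 2
    axis_point: np.ndarray | None = None
    axis_dir: np.ndarray | None = None
    axis_tol: float | None = None


def sample_profile(image: FundusImage, window) -> IntensityProfile:
    """Grey level of the nearest pixel at each in-image candidate position.

    ``window`` is anything with a ``candidates`` (N, 2) attribute, or the
    array itself.  Out-of-bounds candidates are trimmed from both ends.
    """
    candidates = getattr(window, "candidates", window)
    candidates = np.asarray(candidates, dtype=float)
    rc = np.rint(candidates).astype(int)
    inside = (
        (rc[:, 0] >= 0)
        & (rc[:, 0] < image.height)
        & (rc[:, 1] >= 0)
        & (rc[:, 1] < image.width)
    )
    # trimming from both ends covers linear windows; arcs may additionally
    # leave and re-enter the frame, so drop every out-of-bounds candidate
    if inside.sum() < 3:
        raise WindowDegenerateError("fewer than 3 candidates inside the image")
    rc = rc[inside]
    return IntensityProfile(candidates[inside], image.pixels[rc[:, 0], rc[:, 1]])


def _region_pixels(image: FundusImage, center: np.ndarray, side: int) -> np.ndarray:
    r = int(round(float(center[0])))
    c = int(round(float(center[1])))
    half = side // 2
    r_lo = max(r - half, 0)
    r_hi = max(min(r + side - half, image.height), r_lo)
    c_lo = max(c - half, 0)
    c_hi = max(min(c + side - half, image.width), c_lo)
    return image.pixels[r_lo:r_hi, c_lo:c_hi].ravel()


def _strip_pixels(
    image: FundusImage, center: np.ndarray, along: np.ndarray, half_len: float, half_wid: float
) -> np.ndarray:
    """Pixels whose centers lie in an oriented rectangle around ``center``."""
    r0, c0 = float(center[0]), float(center[1])
    reach = int(np.ceil(half_len + 1))
    r_lo = min(max(int(r0) - reach, 0), image.height)
    r_hi = max(min(int(r0) + reach + 1, image.height), r_lo)
    c_lo = min(max(int(c0) - reach, 0), image.width)
    c_hi = max(min(int(c0) + reach + 1, image.width), c_lo)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    dr, dc = rr - r0, cc - c0
    a = dr * along[0] + dc * along[1]
    x = dr * along[1] - dc * along[0]
    m = (np.abs(a) <= half_len) & (np.abs(x) <= half_wid)
    return image.pixels[rr[m], cc[m]]


def estimate_local_statistics(
    image: FundusImage,
    center: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    diameter: float,
    margin: float = 2.0,
    sigma_floor: float = 0.5,
) -> LocalStatistics:
    """Statistics of the three moving regions around the previous step.

    The vessel region is a narrow strip along the local vessel axis
    (perpendicular to the edge chord U-V), so its grey levels sample the
    near-constant profile top rather than the dip's flanks; its standard
    deviation therefore estimates the vessel noise, not profile curvature.
    Two square background regions sit beyond each edge point, offset away
    from the vessel by ``diameter/2 + margin``.  All sizes adapt to the
    local diameter.  Background location and scale use the median and the
    scaled median absolute deviation: near junctions the squares can straddle
    a neighbouring vessel, and moment estimators would absorb those dark
    pixels into an inflated sigma_b that masks real vessel intervals.
    """
    center = np.asarray(center, dtype=float)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    side = max(3, int(round(diameter)))
    chord = V - U
    nrm = np.linalg.norm(chord)
    if nrm > 0:
        along = np.array([chord[1], -chord[0]]) / nrm  # vessel axis
        inside = _strip_pixels(
            image, center, along, side / 2.0, max(0.5, diameter / 8.0)
        )
    else:
        inside = _region_pixels(image, center, side)

    outs = []
    for edge in (U, V):
        n = edge - center
        norm = np.linalg.norm(n)
        if norm == 0:
            continue
        n = n / norm
        out_center = edge + n * (diameter / 2.0 + margin)
        outs.append(_region_pixels(image, out_center, side))
    background = np.concatenate(outs) if outs else np.array([])
    if inside.size == 0 or background.size == 0:
        raise StatisticsUnavailableError("moving regions fall outside the image")
    # the strip mean estimates the centreline grey far more stably than the
    # single pixel under the centre point, whose noise would perturb the
    # model's dip amplitude by a full noise standard deviation
    med = float(np.median(background))
    mad = float(np.median(np.abs(background - med)))
    return LocalStatistics(
        I_c=float(inside.mean()) if nrm > 0 else image.grey_at(center),
        I_b=med,
        sigma_v=float(inside.std()),
        sigma_b=1.4826 * mad,
    ).floored(sigma_floor)


def _interval_model(
    profile: IntensityProfile, a: int, b: int, stats: LocalStatistics
) -> np.ndarray:
    """True grey levels for candidates a..b under a single vessel interval.

    The dip is centered on the chord midpoint with spread sigma_chi equal to
    half the hypothesized radius, i.e. |chord| / 4.
    """
    pos = profile.positions
    chord = pos[b] - pos[a]
    clen = float(np.linalg.norm(chord))
    if clen == 0:
        raise InvalidConfigurationError("zero-length vessel interval")
    u = chord / clen
    mid = 0.5 * (pos[a] + pos[b])
    l = (pos[a : b + 1] - mid) @ u  # signed distance along the chord
    sigma_chi = clen / 4.0
    return (stats.I_c - stats.I_b) * np.exp(-(l**2) / (2.0 * sigma_chi**2)) + stats.I_b


def model_profile(
    config: Configuration, profile: IntensityProfile, stats: LocalStatistics
) -> np.ndarray:
    """True intensity profile under a configuration hypothesis.

    Background candidates take I_b; vessel intervals take the Gaussian dip.
    Overlapping interval predictions resolve to the pointwise darker value.
    """
    if config.indices[-1] >= profile.count:
        raise InvalidConfigurationError("configuration index outside profile")
    x = np.full(profile.count, stats.I_b)
    for a, b in config.intervals:
        x[a : b + 1] = np.minimum(x[a : b + 1], _interval_model(profile, a, b, stats))
    return x


def log_likelihood(
    profile: IntensityProfile, config: Configuration, stats: LocalStatistics
) -> float:
    """Sum of per-point normal log-densities under the configuration."""
    x = model_profile(config, profile, stats)
    sigma = np.full(profile.count, stats.sigma_b)
    for a, b in config.intervals:
        sigma[a : b + 1] = stats.sigma_v
    z = (profile.values - x) / sigma
    return float(np.sum(-_LOG_SQRT_2PI - np.log(sigma) - 0.5 * z**2))


def fit_edge_lines(
    history: list[tuple[np.ndarray, np.ndarray]],
    direction: np.ndarray,
    k: int,
) -> EdgeLineModel:
    """Extrapolated edge lines from recent edge pairs.

    Early in a track (k < 5) the lines run through the latest edge points
    along the current direction; once four pairs are available they become
    total-least-squares lines through the last four U and V points.
    """
    if not history:
        raise InvalidConfigurationError("edge-line fit needs at least one edge pair")
    if k >= 5 and len(history) >= 4:
        us = np.array([p[0] for p in history[-4:]])
        vs = np.array([p[1] for p in history[-4:]])
        p1, d1 = total_least_squares_line(us)
        p2, d2 = total_least_squares_line(vs)
        return EdgeLineModel(p1, d1, p2, d2)
    U, V = history[-1]
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return EdgeLineModel(np.asarray(U, float), d, np.asarray(V, float), d.copy())


def log_prior(
    config: Configuration,
    profile: IntensityProfile,
    lines: EdgeLineModel | None,
    params: GibbsParams,
) -> float:
    """Gibbs log-prior -log Z - lambda (t1^2 + t2^2) for normal configs.

    Bifurcation and crossing configurations (and any configuration when no
    edge-line model applies) carry no prior information and return 0.
    """
    if config.kind != "normal" or lines is None:
        return 0.0
    m1, m2 = config.indices
    t1 = point_line_distance(profile.positions[m1], lines.e1_point, lines.e1_dir)
    t2 = point_line_distance(profile.positions[m2], lines.e2_point, lines.e2_dir)
    return float(-np.log(params.Z) - params.lam * (t1**2 + t2**2))


def _chord_length(profile: IntensityProfile, a: int, b: int) -> float:
    return float(np.linalg.norm(profile.positions[b] - profile.positions[a]))


def _normal_priors(
    profile: IntensityProfile,
    A: np.ndarray,
    B: np.ndarray,
    lines: EdgeLineModel,
    params: GibbsParams,
) -> np.ndarray:
    """Gibbs log-prior of every normal configuration (A[i], B[i]), batched."""
    pos = profile.positions
    r1 = pos[A] - lines.e1_point[None, :]
    t1 = np.abs(r1[:, 0] * lines.e1_dir[1] - r1[:, 1] * lines.e1_dir[0])
    r2 = pos[B] - lines.e2_point[None, :]
    t2 = np.abs(r2[:, 0] * lines.e2_dir[1] - r2[:, 1] * lines.e2_dir[0])
    return -np.log(params.Z) - params.lam * (t1**2 + t2**2)


def _pair_gains(
    profile: IntensityProfile,
    stats: LocalStatistics,
    constraints: PruningParams | None,
    bg_lp: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Likelihood gain over background for every feasible interval, batched.

    Returns index arrays ``A``, ``B`` (lexicographic pair order) and the
    matching gains.  One broadcast evaluates the dip model of all pairs at
    once, which keeps sub-pixel candidate spacing affordable.
    """
    pos = profile.positions
    vals = profile.values
    A, B = np.triu_indices(profile.count, k=1)
    clen = np.linalg.norm(pos[B] - pos[A], axis=1)
    keep = clen > 0.0
    if constraints is not None:
        hi = constraints.max_chord_factor * constraints.d_prev
        keep &= (clen >= constraints.min_chord) & (clen <= hi)
    A, B, clen = A[keep], B[keep], clen[keep]
    if A.size == 0:
        return A, B, np.empty(0)
    mid = 0.5 * (pos[A] + pos[B])
    u = (pos[B] - pos[A]) / clen[:, None]
    # signed distance of every candidate from each pair's chord midpoint
    l = (pos[None, :, 0] - mid[:, 0, None]) * u[:, 0, None] + (
        pos[None, :, 1] - mid[:, 1, None]
    ) * u[:, 1, None]
    sigma_chi = clen / 4.0
    x = (stats.I_c - stats.I_b) * np.exp(
        -(l**2) / (2.0 * sigma_chi[:, None] ** 2)
    ) + stats.I_b
    lv = (
        -_LOG_SQRT_2PI
        - np.log(stats.sigma_v)
        - 0.5 * ((vals[None, :] - x) / stats.sigma_v) ** 2
    )
    idx = np.arange(profile.count)
    inside = (idx[None, :] >= A[:, None]) & (idx[None, :] <= B[:, None])
    gains = np.where(inside, lv - bg_lp[None, :], 0.0).sum(axis=1)
    return A, B, gains


def _axis_ok(
    profile: IntensityProfile, a: int, b: int, constraints: PruningParams
) -> bool:
    if constraints.axis_point is None or constraints.axis_dir is None:
        return True
    mid = 0.5 * (profile.positions[a] + profile.positions[b])
    tol = constraints.axis_tol if constraints.axis_tol is not None else constraints.d_prev
    return point_line_distance(mid, constraints.axis_point, constraints.axis_dir) <= tol


def map_configuration(
    profile: IntensityProfile,
    stats: LocalStatistics,
    lines: EdgeLineModel | None,
    window_kind: str,
    constraints: PruningParams | None = None,
    gibbs: GibbsParams | None = None,
    require_cover: int | None = None,
) -> Configuration:
    """MAP configuration on a search window.

    Linear windows score every normal configuration by log-likelihood plus
    the Gibbs log-prior; semicircle windows score normal, bifurcation and
    crossing configurations by log-likelihood alone (the edge-line prior has
    no meaning for branch hypotheses).  Ties break toward the structurally
    simplest kind, then the lexicographically smallest index tuple.
    ``require_cover`` restricts normal intervals to those spanning a given
    candidate index (used for window initialization around a seed).
    """
    if profile.count < 3:
        raise WindowDegenerateError("profile needs at least 3 candidates")
    if window_kind not in ("linear", "semicircle"):
        raise InvalidConfigurationError(f"unknown window kind {window_kind!r}")
    gibbs = gibbs or GibbsParams()

    # per-candidate background log-density and per-interval likelihood gains
    bg_lp = (
        -_LOG_SQRT_2PI
        - np.log(stats.sigma_b)
        - 0.5 * ((profile.values - stats.I_b) / stats.sigma_b) ** 2
    )
    total_bg = float(np.sum(bg_lp))
    A, B, gains = _pair_gains(profile, stats, constraints, bg_lp)

    best_score = -np.inf
    best: Configuration | None = None

    def consider(kind: str, indices: tuple[int, ...], score: float) -> None:
        nonlocal best_score, best
        if score > best_score:
            best_score = score
            best = Configuration(kind, indices)

    # normal configurations (scored first: ties prefer simpler structure;
    # pair order is lexicographic, so argmax keeps the smallest index tuple)
    if A.size:
        scores = total_bg + gains
        if window_kind == "linear" and lines is not None:
            scores = scores + _normal_priors(profile, A, B, lines, gibbs)
        ok = np.ones(A.size, dtype=bool)
        if require_cover is not None:
            ok = (A <= require_cover) & (require_cover <= B)
        if ok.any():
            masked = np.where(ok, scores, -np.inf)
            i = int(np.argmax(masked))
            consider("normal", (int(A[i]), int(B[i])), float(masked[i]))

    if window_kind == "semicircle" and A.size:
        min_gap = constraints.min_gap if constraints is not None else 0
        # Dominance pruning: a branch hypothesis containing an interval whose
        # likelihood gain over background is <= 0 scores no better than the
        # simpler hypothesis without it, which also wins the kind-rank tie;
        # it can therefore never be the MAP and only positive-gain intervals
        # need considering for bifurcations and crossings.  Over those, the
        # best partner interval left (right) of a given candidate index is a
        # prefix (suffix) maximum, so the exact optimum over all ordered
        # non-overlapping pairs and triples costs O(pairs), not O(pairs^3).
        pos_idx = np.nonzero(gains > 0.0)[0]
        Ap, Bp, Gp = A[pos_idx], B[pos_idx], gains[pos_idx]
        n = profile.count
        pad = min_gap + 2
        NONE = (-np.inf, -1)

        def better(c1: tuple, c2: tuple) -> tuple:
            # higher gain wins; ties keep the lexicographically first interval
            if c2[0] > c1[0] or (c2[0] == c1[0] and 0 <= c2[1] < c1[1]):
                return c2
            return c1

        # best positive interval with start >= s / with end <= e
        suffix = [NONE] * (n + pad)
        for i in range(Ap.size - 1, -1, -1):
            suffix[Ap[i]] = better(suffix[Ap[i]], (float(Gp[i]), i))
        for s_ in range(n - 1, -1, -1):
            suffix[s_] = better(suffix[s_ + 1], suffix[s_])
        prefix = [NONE] * (n + pad)
        for i in range(Ap.size):
            prefix[Bp[i]] = better(prefix[Bp[i]], (float(Gp[i]), i))
        for e_ in range(1, n):
            prefix[e_] = better(prefix[e_], prefix[e_ - 1])

        for i in range(Ap.size):
            g_r, j = suffix[Bp[i] + 1 + min_gap]
            if j >= 0:
                consider(
                    "bifurcation",
                    (int(Ap[i]), int(Bp[i]), int(Ap[j]), int(Bp[j])),
                    total_bg + float(Gp[i]) + g_r,
                )
        for m in range(Ap.size):
            e_ = Ap[m] - 1 - min_gap
            if e_ < 0:
                continue
            g_l, i = prefix[e_]
            g_r, j = suffix[Bp[m] + 1 + min_gap]
            if i < 0 or j < 0:
                continue
            if constraints is not None and not _axis_ok(
                profile, int(Ap[m]), int(Bp[m]), constraints
            ):
                continue
            consider(
                "crossing",
                (
                    int(Ap[i]), int(Bp[i]),
                    int(Ap[m]), int(Bp[m]),
                    int(Ap[j]), int(Bp[j]),
                ),
                total_bg + g_l + float(Gp[m]) + g_r,
            )

    if best is None:
        raise NoConfigurationError("no feasible configuration on this window")
    return best
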