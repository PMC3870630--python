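"""Shared planar geometry helpers.

Conventions used throughout the package:

* points are ``(row, col)`` float arrays, 0-based, pixel centers at integer
  coordinates;
* angles are in radians, measured counterclockwise from the +col axis, so the
  unit vector of angle ``t`` is ``(sin t, cos t)`` in (row, col) order.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def unit_vector(angle: float) -> np.ndarray:
    """(row, col) unit vector for an angle measured from the +col axis."""
    return np.array([np.sin(angle), np.cos(angle)])


def vector_angle(v: np.ndarray) -> float:
    """Angle of a (row, col) vector, inverse of :func:`unit_vector`."""
    return float(np.arctan2(v[0], v[1]))


def perpendicular(v: np.ndarray) -> np.ndarray:
    """Rotate a (row, col) vector by +90 degrees (angle + pi/2)."""
    return np.array([v[1], -v[0]])


def wrap_angle(a: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    w = (a + np.pi) % TWO_PI - np.pi
    if w == -np.pi:
        w = np.pi
    return float(w)


def angle_difference_mod_pi(a: float, b: float) -> float:
    """Absolute difference between two axial angles, folded into [0, pi/2].

    Directions along a line are defined mod pi; the distance between two of
    them is at most a quarter turn.
    """
    d = abs(wrap_angle(a - b)) % np.pi
    if d > np.pi / 2:
        d = np.pi - d
    return float(d)


def point_line_distance(p: np.ndarray, line_point: np.ndarray, line_dir: np.ndarray) -> float:
    """Perpendicular distance from ``p`` to the line (point, unit direction)."""
    r = np.asarray(p, dtype=float) - np.asarray(line_point, dtype=float)
    return float(abs(r[0] * line_dir[1] - r[1] * line_dir[0]))


def total_least_squares_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit a line minimizing perpendicular distances (principal axis).

    Returns ``(point_on_line, unit_direction)``; the point is the centroid.
    Degenerate (coincident) point sets fall back to the +col axis direction.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    direction = v[:, int(np.argmax(w))]
    if np.max(w) <= 0:
        direction = np.array([0.0, 1.0])
    n = np.linalg.norm(direction)
    return centroid, direction / n
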