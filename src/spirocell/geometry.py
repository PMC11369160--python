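"""Geometric primitives for rod-shaped (possibly bent) cells.

All coordinates are in micrometres, with the image-array convention:
origin at the top-left corner, x increasing to the right, y increasing
downward.  A cell is modelled as a tube: an open centerline polyline from
pole to pole, swept by a disc of radius ``half_width`` (so the poles are
hemispherical caps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon


@dataclass
class CellGeometry:
    """Outline + centerline description of a single cell.

    Attributes
    ----------
    outline : (N, 2) array
        Closed simple polygon (first vertex not repeated), µm.
    centerline : (M, 2) array
        Open polyline ordered pole to pole, µm.
    half_width : float
        Nominal tube half-width (radius of the swept disc), µm.
    half_width_profile : (M,) array or None
        Per-vertex distance from centerline to outline along normals, µm.
    """

    outline: np.ndarray
    centerline: np.ndarray
    half_width: float
    half_width_profile: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.outline.ndim != 2 or self.outline.shape[1] != 2:
            raise ValueError("outline must be an (N, 2) array")
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2:
            raise ValueError("centerline must be an (M, 2) array")

    @property
    def length(self) -> float:
        """Centerline arc length (µm)."""
        return polyline_length(self.centerline)

    def outline_polygon(self) -> Polygon:
        return Polygon(self.outline)


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    seg = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at ``n`` equally spaced arc-length positions."""
    s = cumulative_arclength(points)
    if s[-1] == 0:
        raise ValueError("degenerate polyline of zero length")
    t = np.linspace(0.0, s[-1], n)
    x = np.interp(t, s, points[:, 0])
    y = np.interp(t, s, points[:, 1])
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Centerline constructors
# ---------------------------------------------------------------------------

def straight_centerline(length: float, n: int = 200, origin=(0.0, 0.0)) -> np.ndarray:
    t = np.linspace(0.0, length, n)
    x0, y0 = origin
    return np.column_stack([x0 + t, np.full(n, y0)])


def arc_centerline(radius: float, length: float, n: int = 200) -> np.ndarray:
    """Circular arc of given radius and arc length, convex side up (−y).

    The arc is centred horizontally and sags so that its convex (outer)
    boundary faces negative y.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    theta = length / radius
    if theta >= 2 * np.pi:
        raise ValueError("arc length exceeds full circle")
    ang = np.linspace(-theta / 2, theta / 2, n)
    x = radius * np.sin(ang)
    y = radius * np.cos(ang)  # centre at origin; apex at (0, radius)
    # shift so the apex sits at y = 0 and the arc opens downward in +y
    return np.column_stack([x, radius - y])


def sinusoid_centerline(amplitude: float, wavelength: float, length: float,
                        n: int = 400) -> np.ndarray:
    """Sinusoidal centerline y = a·sin(2πx/λ), truncated at horizontal extent
    ``length`` (cefalexin-like helical filaments projected to 2-D)."""
    x = np.linspace(0.0, length, n)
    y = amplitude * np.sin(2 * np.pi * x / wavelength)
    return np.column_stack([x, y])


def helix_projection_centerline(amplitude: float, pitch: float, length: float,
                                n: int = 400) -> np.ndarray:
    """2-D projection of a helix of radius ``amplitude`` and pitch ``pitch``
    viewed side-on; identical functional form to a sinusoid in projection."""
    return sinusoid_centerline(amplitude, pitch, length, n)


def tube_outline(centerline: np.ndarray, half_width: float,
                 resolution: int = 32) -> np.ndarray:
    """Outline polygon of the tube swept by a disc of radius ``half_width``
    along the centerline (round pole caps)."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    line = LineString(np.asarray(centerline, dtype=float))
    poly = line.buffer(half_width, quad_segs=resolution)
    coords = np.asarray(poly.exterior.coords)[:-1]
    return coords


def make_cell(centerline: np.ndarray, half_width: float) -> CellGeometry:
    outline = tube_outline(centerline, half_width)
    return CellGeometry(outline=outline, centerline=np.asarray(centerline, float),
                        half_width=half_width,
                        half_width_profile=np.full(len(centerline), half_width))


# ---------------------------------------------------------------------------
# Distance fields and curvature
# ---------------------------------------------------------------------------

def polyline_distance_field(points: np.ndarray, polyline: np.ndarray,
                            chunk: int = 65536):
    """For each query point: distance to the polyline, side sign, arc position.

    Returns ``(dist, side, s, seg_idx)`` where ``side`` is the sign of the
    cross product of the local tangent with the offset vector (+1 on the
    left of the travel direction, −1 on the right, in the y-down frame),
    and ``s`` is the arc-length coordinate of the nearest point.
    """
    pts = np.asarray(points, dtype=float)
    pl = np.asarray(polyline, dtype=float)
    a = pl[:-1]
    b = pl[1:]
    ab = b - a
    ab_len2 = np.einsum("ij,ij->i", ab, ab)
    ab_len2 = np.where(ab_len2 == 0, 1e-300, ab_len2)
    s0 = cumulative_arclength(pl)[:-1]
    seg_len = np.sqrt(ab_len2)

    n = len(pts)
    dist = np.empty(n)
    side = np.empty(n)
    s_out = np.empty(n)
    idx_out = np.empty(n, dtype=int)
    for start in range(0, n, chunk):
        p = pts[start:start + chunk]  # (m, 2)
        ap = p[:, None, :] - a[None, :, :]  # (m, nseg, 2)
        t = np.clip(np.einsum("mkj,kj->mk", ap, ab) / ab_len2, 0.0, 1.0)
        proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d2 = np.einsum("mkj,mkj->mk", p[:, None, :] - proj, p[:, None, :] - proj)
        k = np.argmin(d2, axis=1)
        m_idx = np.arange(len(p))
        dist[start:start + chunk] = np.sqrt(d2[m_idx, k])
        off = p - proj[m_idx, k]
        cross = ab[k, 0] * off[:, 1] - ab[k, 1] * off[:, 0]
        side[start:start + chunk] = np.sign(cross)
        s_out[start:start + chunk] = s0[k] + t[m_idx, k] * seg_len[k]
        idx_out[start:start + chunk] = k
    return dist, side, s_out, idx_out


def signed_curvature(polyline: np.ndarray) -> np.ndarray:
    """Signed curvature at each vertex by finite differences (µm⁻¹).

    Positive curvature bends toward the left of the travel direction
    (cross product convention matching :func:`polyline_distance_field`).
    """
    p = np.asarray(polyline, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 vertices for curvature")
    s = cumulative_arclength(p)
    dx = np.gradient(p[:, 0], s)
    dy = np.gradient(p[:, 1], s)
    ddx = np.gradient(dx, s)
    ddy = np.gradient(dy, s)
    denom = (dx ** 2 + dy ** 2) ** 1.5
    denom = np.where(denom == 0, np.inf, denom)
    return (dx * ddy - dy * ddx) / denom


def fit_circle_curvature(points: np.ndarray) -> float:
    """Unsigned curvature 1/R of the least-squares circle through ``points``
    (Kåsa algebraic fit); returns 0 for collinear input."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0] - p[:, 0].mean(), p[:, 1] - p[:, 1].mean()
    A = np.column_stack([2 * x, 2 * y, np.ones(len(p))])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx ** 2 + cy ** 2
    if r2 <= 0 or not np.isfinite(r2):
        return 0.0
    r = np.sqrt(r2)
    if r > 1e6:
        return 0.0
    return float(1.0 / r)
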