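"""Cell-shape and fluorescence-asymmetry quantification.

Covers segmentation, centerline extraction, sinuosity, inner/outer curve
partitioning, outer-versus-inner intensity ratios, demographs, kymographs,
two-channel area overlap, and superplot replicate statistics.

Sinuosity is defined as centerline arc length divided by the Euclidean
pole-to-pole distance (dimensionless, 1 for a straight cell).  The outer
curve is the boundary on the convex side of the centerline, determined by
the sign of the integrated signed curvature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, stats
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString, Polygon
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .geometry import (
    CellGeometry,
    cumulative_arclength,
    polyline_distance_field,
    polyline_length,
    resample_polyline,
    signed_curvature,
)
from .io import ImageStack

log = logging.getLogger(__name__)


class NotCurvedError(ValueError):
    """The cell's net curvature is below the partitioning threshold."""


@dataclass
class CurveHalves:
    """Outer (convex-side) and inner (concave-side) boundary polylines,
    pole caps excluded, plus the convex-side sign used to label them."""

    outer: np.ndarray
    inner: np.ndarray
    outer_sign: float


@dataclass
class RatioResult:
    """Per-cell outer/inner intensity ratio with replicate bookkeeping."""

    per_cell_ratio: np.ndarray
    replicate_id: np.ndarray | None = None

    @property
    def replicate_means(self) -> pd.Series:
        if self.replicate_id is None:
            raise ValueError("no replicate ids attached")
        return pd.Series(self.per_cell_ratio).groupby(
            pd.Series(self.replicate_id)).mean()

    @property
    def grand_mean(self) -> float:
        if self.replicate_id is None:
            return float(np.mean(self.per_cell_ratio))
        return float(self.replicate_means.mean())


@dataclass
class Demograph:
    """Row-per-cell matrix of concatenated outer+inner intensity profiles,
    rows sorted by combined profile length, each min-max normalized."""

    matrix: np.ndarray
    combined_lengths: np.ndarray
    bins_per_um: float


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_cells(image: ImageStack, frame: int = 0,
                  min_area: float = 0.5) -> list[np.ndarray]:
    """Threshold (Otsu) → connected components → sub-pixel contour
    polygons, in µm.  Components smaller than ``min_area`` (µm²) are
    dropped; an empty image yields an empty list.
    """
    img = np.asarray(image.frame(frame), dtype=float)
    px = image.pixel_size
    if img.max() == img.min():
        log.info("segment_cells: blank image, no components")
        return []
    thr = threshold_otsu(img)
    mask = img > thr
    labels = measure.label(mask)
    polygons = []
    for region in measure.regionprops(labels):
        if region.area * px * px < min_area:
            continue
        comp = labels == region.label
        contours = measure.find_contours(comp.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # (row, col) = (y, x)
        poly = np.column_stack([contour[:, 1], contour[:, 0]]) + 0.5
        polygons.append(poly * px)
    if not polygons:
        log.info("segment_cells: no component above min_area")
    return polygons


# ---------------------------------------------------------------------------
# Centerline
# ---------------------------------------------------------------------------

def extract_centerline(outline: np.ndarray, pixel_size: float = 0.05,
                       smoothing: float | None = None,
                       n_points: int = 100) -> np.ndarray:
    """Medial-axis centerline of a cell outline, ordered pole to pole.

    The outline is rasterized, skeletonized, and pruned to the longest
    skeleton path; the path is smoothed with a spline and extended along
    its end tangents to the outline (poles).  Raises on degenerate shapes
    with no elongated axis (e.g. a disc) or on branched skeletons with no
    dominant path.
    """
    poly = Polygon(np.asarray(outline, float))
    if not poly.is_valid:
        poly = poly.buffer(0)
    minx, miny, maxx, maxy = poly.bounds
    pad = 2 * pixel_size
    nx = int(np.ceil((maxx - minx + 2 * pad) / pixel_size))
    ny = int(np.ceil((maxy - miny + 2 * pad) / pixel_size))
    xs = minx - pad + (np.arange(nx) + 0.5) * pixel_size
    ys = miny - pad + (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    import shapely

    mask = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(ny, nx)
    skel = skeletonize(mask)
    pix = np.argwhere(skel)
    if len(pix) < 3:
        raise ValueError("no elongated axis: skeleton degenerate")

    g = nx_graph_from_pixels(pix)
    path = longest_path(g)
    if len(path) < 3:
        raise ValueError("no elongated axis: skeleton path too short")
    if len(pix) > 1.5 * len(path) and len(pix) - len(path) > 10:
        raise ValueError("branched skeleton with no dominant path")

    pts = np.array([(xs[c], ys[r]) for r, c in path])
    # estimate local half width to judge elongation
    width = np.sqrt(poly.area / max(polyline_length(pts), 1e-9))
    if polyline_length(pts) < 1.0 * width:
        raise ValueError("no elongated axis: shape not elongated")

    pts = _smooth_spline(pts, smoothing, pixel_size, n_points)
    pts = _extend_to_poles(pts, poly)
    return resample_polyline(pts, n_points)


def nx_graph_from_pixels(pix: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    pixset = {tuple(p) for p in pix}
    for r, c in pixset:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in pixset:
                    g.add_edge((r, c), nb, weight=np.hypot(dr, dc))
    return g


def longest_path(g: nx.Graph) -> list:
    """Approximate longest weighted path: double Dijkstra sweep from an
    arbitrary node (exact on trees, which pruned skeletons are)."""
    start = next(iter(g.nodes))
    far1 = _farthest(g, start)
    far2, path = _farthest(g, far1, return_path=True)
    return path


def _farthest(g, src, return_path=False):
    dist, paths = nx.single_source_dijkstra(g, src)
    far = max(dist, key=dist.get)
    if return_path:
        return far, paths[far]
    return far


def _smooth_spline(pts: np.ndarray, smoothing, pixel_size, n_points):
    if len(pts) < 8:
        return pts
    s_arc = cumulative_arclength(pts)
    if smoothing is None:
        # average ~half-pixel deviation tolerated
        smoothing = len(pts) * (0.5 * pixel_size) ** 2
    try:
        tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]],
                                     u=s_arc, s=smoothing, k=3)
        u = np.linspace(s_arc[0], s_arc[-1], max(n_points, len(pts)))
        x, y = interpolate.splev(u, tck)
        return np.column_stack([x, y])
    except Exception:
        return pts


def _extend_to_poles(pts: np.ndarray, poly: Polygon) -> np.ndarray:
    """Extend the skeleton path along its end tangents until it meets the
    outline, so the centerline spans pole to pole."""
    out = [pts]
    for end, sl in ((0, slice(0, 8)), (-1, slice(-8, None))):
        seg = pts[sl]
        tangent = seg[0] - seg[-1] if end == 0 else seg[-1] - seg[0]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent = tangent / norm
        p0 = pts[0] if end == 0 else pts[-1]
        far = p0 + tangent * 4.0 * np.sqrt(poly.area)
        ray = LineString([p0, far])
        inter = ray.intersection(poly.exterior)
        if inter.is_empty:
            continue
        if inter.geom_type == "Point":
            hit = np.array(inter.coords[0])
        else:
            pieces = getattr(inter, "geoms", [inter])
            hit = min((np.asarray(pt.coords).reshape(-1, 2)[0]
                       for pt in pieces),
                      key=lambda q: np.linalg.norm(q - p0))
        if end == 0:
            out.insert(0, hit[None, :])
        else:
            out.append(hit[None, :])
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Sinuosity
# ---------------------------------------------------------------------------

def sinuosity(centerline: np.ndarray) -> float:
    """Arc length / pole-to-pole Euclidean distance (≥ 1)."""
    c = np.asarray(centerline, dtype=float)
    if len(c) < 2:
        raise ValueError("centerline needs at least 2 vertices")
    chord = float(np.linalg.norm(c[-1] - c[0]))
    if chord == 0:
        raise ValueError("sinuosity undefined: coincident endpoints")
    return polyline_length(c) / chord


# ---------------------------------------------------------------------------
# Inner/outer partition
# ---------------------------------------------------------------------------

def partition_inner_outer(geometry: CellGeometry,
                          curvature_threshold: float = 0.02) -> CurveHalves:
    """Split the outline (minus pole caps) into outer (convex-side) and
    inner (concave-side) boundaries.

    The convex side is taken from the sign of the integrated signed
    curvature of the centerline; a cell whose mean |signed curvature| is
    below ``curvature_threshold`` (µm⁻¹) is flagged as not clearly curved.
    """
    c = geometry.centerline
    kappa = signed_curvature(c)
    mean_k = float(np.mean(kappa))
    if abs(mean_k) < curvature_threshold:
        raise NotCurvedError(
            f"mean signed curvature {mean_k:.4f}/µm below threshold "
            f"{curvature_threshold}/µm")
    outer_sign = -np.sign(mean_k)

    s_total = polyline_length(c)
    dist, side, s, _ = polyline_distance_field(geometry.outline, c)
    # pole caps: outline points whose nearest centerline point is an endpoint
    cap_margin = min(1.5 * geometry.half_width, 0.25 * s_total)
    body = (s > cap_margin) & (s < s_total - cap_margin)

    outer_mask = body & (side == outer_sign)
    inner_mask = body & (side == -outer_sign)
    outer = _ordered_boundary(geometry.outline, outer_mask, s)
    inner = _ordered_boundary(geometry.outline, inner_mask, s)
    if len(outer) < 2 or len(inner) < 2:
        raise ValueError("partition failed: a boundary half is empty")
    return CurveHalves(outer=outer, inner=inner, outer_sign=outer_sign)


def _ordered_boundary(outline: np.ndarray, mask: np.ndarray,
                      s: np.ndarray) -> np.ndarray:
    """Extract the masked vertices in the outline's own cyclic order
    (each half is one contiguous run on the ring), oriented pole to pole.

    Sorting by projected centerline position would zigzag among
    nearly-coincident vertices; the ring order preserves the true
    boundary geometry.
    """
    idx = np.flatnonzero(mask)
    n = len(outline)
    # rotate the ring so the masked run is contiguous (not wrapping)
    gaps = np.flatnonzero(np.diff(idx) > 1)
    if len(gaps):
        start = idx[gaps[0] + 1]
        order = [(i - start) % n for i in idx]
        idx = idx[np.argsort(order)]
    pts = outline[idx]
    if s[idx][0] > s[idx][-1]:  # orient in the centerline's direction
        pts = pts[::-1]
    return pts


# ---------------------------------------------------------------------------
# Outer/inner intensity ratio
# ---------------------------------------------------------------------------

def _sample_image(img: np.ndarray, pts_um: np.ndarray, pixel_size: float):
    cols = pts_um[:, 0] / pixel_size - 0.5
    rows = pts_um[:, 1] / pixel_size - 0.5
    return map_coordinates(np.asarray(img, float), [rows, cols], order=1,
                           mode="nearest")


def curve_ratio(fluor: ImageStack, geometry: CellGeometry,
                halves: CurveHalves, frame: int = 0,
                background: float | None = None,
                n_scans: int = 60, statistic: str = "mean") -> float:
    """Outer/inner integrated-intensity ratio from centerline line scans.

    At ``n_scans`` positions along the centerline body, intensity is
    sampled from the centerline to the outline along the normal on each
    side, integrated per unit scan length (so the geometrically longer
    outer half does not inflate the ratio on uniform signal), and
    background-subtracted.  The ratio is statistic(outer)/statistic(inner).
    Cells whose inner integral is non-positive after background
    subtraction are rejected with ``ValueError``.
    """
    img = fluor.frame(frame)
    px = fluor.pixel_size
    c = resample_polyline(geometry.centerline, n_scans + 8)[4:-4]
    tang = np.gradient(c, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])  # side > 0 direction

    if background is None:
        background = estimate_background(img, [geometry.outline], px)

    n_samples = max(int(np.ceil(geometry.half_width / px)) * 2, 6)
    sides = {}
    for label, sign in (("outer", halves.outer_sign),
                        ("inner", -halves.outer_sign)):
        vals = []
        for p, nvec in zip(c, normal):
            scan = p[None, :] + sign * nvec[None, :] * np.linspace(
                0.0, geometry.half_width, n_samples)[:, None]
            profile = _sample_image(img, scan, px) - background
            vals.append(np.mean(profile))  # per-unit-length integral
        sides[label] = np.asarray(vals)
    stat = np.mean if statistic == "mean" else np.median
    inner_val = float(stat(sides["inner"]))
    outer_val = float(stat(sides["outer"]))
    if inner_val <= 0:
        raise ValueError("inner integral non-positive after background "
                         "subtraction; cell excluded")
    return outer_val / inner_val


def estimate_background(img: np.ndarray, outlines, pixel_size: float) -> float:
    """Median intensity outside all cell outlines."""
    import shapely

    img = np.asarray(img, dtype=float)
    ny, nx = img.shape
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    inside = np.zeros(img.shape, dtype=bool)
    for o in outlines:
        poly = Polygon(np.asarray(o, float)).buffer(2 * pixel_size)
        inside |= shapely.contains_xy(poly, gx.ravel(),
                                      gy.ravel()).reshape(img.shape)
    outside = img[~inside]
    return float(np.median(outside)) if outside.size else 0.0


# ---------------------------------------------------------------------------
# Demograph / kymograph
# ---------------------------------------------------------------------------

def demograph(cells: list, bins_per_um: float = 10.0) -> Demograph:
    """Stack per-cell concatenated outer+inner boundary profiles.

    ``cells`` is a list of (geometry, halves, fluor ImageStack) tuples.
    Each cell's outer then inner boundary is sampled at ``bins_per_um``
    samples per µm, concatenated, and min-max normalized; rows are sorted
    by combined profile length and right-padded with NaN.
    """
    if not cells:
        raise ValueError("need at least one cell")
    profiles = []
    for geometry, halves, fluor in cells:
        img = fluor.frame(0)
        px = fluor.pixel_size
        parts = []
        for boundary in (halves.outer, halves.inner):
            L = polyline_length(boundary)
            n = max(int(round(L * bins_per_um)), 2)
            pts = resample_polyline(boundary, n)
            parts.append(_sample_image(img, pts, px))
        prof = np.concatenate(parts)
        lo, hi = prof.min(), prof.max()
        span = hi - lo
        if span > 1e-9 * max(abs(hi), 1.0):
            prof = (prof - lo) / span
        else:  # uniform signal: no contrast to normalize
            prof = np.zeros_like(prof)
        profiles.append(prof)
    lengths = np.array([len(p) for p in profiles], dtype=float) / bins_per_um
    order = np.argsort(lengths, kind="stable")
    width = max(len(p) for p in profiles)
    mat = np.full((len(profiles), width), np.nan)
    for row, idx in enumerate(order):
        mat[row, : len(profiles[idx])] = profiles[idx]
    return Demograph(matrix=mat, combined_lengths=lengths[order],
                     bins_per_um=bins_per_um)


def kymograph(stack: ImageStack, path: np.ndarray,
              samples_per_um: float = 20.0) -> np.ndarray:
    """Position × time intensity matrix sampled along a fixed path.

    Each column is one frame (bilinear interpolation along the path).
    Raises if the path leaves the image.
    """
    if stack.n_frames < 2:
        raise ValueError("kymograph needs a time-lapse with >= 2 frames")
    px = stack.pixel_size
    L = polyline_length(np.asarray(path, float))
    n = max(int(round(L * samples_per_um)), 2)
    pts = resample_polyline(np.asarray(path, float), n)
    ny, nx = stack.data.shape[1:]
    if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > nx * px or pts[:, 1].max() > ny * px):
        raise ValueError("sampling path exits the image")
    cols = []
    for t in range(stack.n_frames):
        cols.append(_sample_image(stack.frame(t), pts, px))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Overlap and statistics
# ---------------------------------------------------------------------------

def area_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> dict:
    """Percent area overlap 100·|A∩B|/|A| (A = first-named channel), with
    the symmetric Jaccard index also reported."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    na = a.sum()
    if na == 0:
        raise ValueError("first mask is empty; overlap undefined")
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return {"overlap_pct": 100.0 * inter / na,
            "jaccard_pct": 100.0 * inter / union if union else 0.0}


def superplot_stats(values_a, replicates_a, values_b, replicates_b,
                    pooled: bool = False) -> dict:
    """Superplot comparison of two conditions.

    The Welch t-test runs on replicate means (biological replicates as the
    unit of inference); set ``pooled=True`` to test pooled single cells
    instead.  Each replicate must contain at least 2 cells.
    """
    def _rep_means(vals, reps):
        s = pd.Series(np.asarray(vals, float))
        g = s.groupby(pd.Series(np.asarray(reps)))
        if (g.size() < 2).any():
            raise ValueError("every replicate needs at least 2 cells")
        return g.mean()

    ma = _rep_means(values_a, replicates_a)
    mb = _rep_means(values_b, replicates_b)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("need at least 2 replicates per condition")
    xa, xb = (np.asarray(values_a, float), np.asarray(values_b, float)) \
        if pooled else (ma.to_numpy(), mb.to_numpy())
    if np.var(xa) == 0 and np.var(xb) == 0:
        t = 0.0 if np.mean(xa) == np.mean(xb) else np.inf
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
    return {
        "replicate_means_a": ma.to_numpy(),
        "replicate_means_b": mb.to_numpy(),
        "grand_mean_a": float(ma.mean()),
        "grand_mean_b": float(mb.mean()),
        "t": float(t),
        "p": float(p),
        "pooled": pooled,
    }
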