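"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (morphometrics, FRAP fitting,
single-particle tracking, SMLM density mapping, growth mechanics) is
exercised on output of this module, so each generator returns both the
observable data and the exact truth it was built from.

Determinism contract: identical (spec, seed) gives bit-identical output.
All generator outputs are in µm and seconds; pixels appear only when an
image is rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon

from .geometry import (
    CellGeometry,
    arc_centerline,
    cumulative_arclength,
    helix_projection_centerline,
    make_cell,
    polyline_distance_field,
    signed_curvature,
    sinusoid_centerline,
    straight_centerline,
)
from .io import ImageStack

#: package-default cell dimensions for the emulated organism; the source
#: study does not report them numerically, so these are package choices.
DEFAULT_HALF_WIDTH_UM = 0.4
DEFAULT_CURVATURE_RADIUS_UM = 5.7


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SynthCellSpec:
    """Parameters of one rendered curved/filamentous cell.

    The fluorescent "ribbon" is a band hugging the convex (outer-curve)
    boundary: pixels on the outer side whose distance d from the centerline
    satisfies r − 2·ribbon_band_halfwidth ≤ d ≤ r are boosted β-fold.
    """

    half_width: float = DEFAULT_HALF_WIDTH_UM
    centerline_kind: str = "arc"  # straight | arc | sinusoid | helixProjection
    curvature_radius: float = DEFAULT_CURVATURE_RADIUS_UM
    amplitude: float = 0.8
    wavelength: float = 4.0
    length: float = 5.0
    ribbon_boost: float = 1.0
    ribbon_band_halfwidth: float = 0.1
    background: float = 100.0
    peak_intensity: float = 2000.0
    psf_sigma: float = 0.1
    pixel_size: float = 0.05
    poisson_gain: float = 1.0
    gaussian_sd: float = 5.0
    margin: float = 0.6
    canvas_shape: tuple | None = None  # (ny, nx) pixels; autosized if None

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.ribbon_boost < 1:
            raise ValueError("ribbon_boost must be >= 1")
        if self.centerline_kind == "arc" and self.curvature_radius <= self.half_width:
            raise ValueError("curvature_radius must exceed half_width")
        valid = {"straight", "arc", "sinusoid", "helixProjection"}
        if self.centerline_kind not in valid:
            raise ValueError(f"centerline_kind must be one of {sorted(valid)}")

    def build_centerline(self) -> np.ndarray:
        n = max(64, int(self.length / self.pixel_size))
        if self.centerline_kind == "straight":
            return straight_centerline(self.length, n)
        if self.centerline_kind == "arc":
            return arc_centerline(self.curvature_radius, self.length, n)
        if self.centerline_kind == "sinusoid":
            return sinusoid_centerline(self.amplitude, self.wavelength,
                                       self.length, n)
        return helix_projection_centerline(self.amplitude, self.wavelength,
                                           self.length, n)


@dataclass
class ParticleMixtureSpec:
    """Mixture of membrane-particle populations imaged by sparse tracking.

    ``populations`` is a list of (fraction, D) pairs with fractions summing
    to 1 and D in µm²/s.  Track lengths are geometric(p) truncated to
    [min_frames, max_frames]; default acquisition uses the study's 20-ms
    frame interval.
    """

    populations: list
    frame_interval: float = 0.02
    n_tracks: int = 1000
    length_p: float = 0.12
    min_frames: int = 5
    max_frames: int = 60
    localization_sd: float = 0.02
    activation_rate: float = 2.0  # track starts per frame
    confinement: np.ndarray | None = None  # polygon vertices, µm

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("populations must be non-empty")
        fr = np.array([f for f, _ in self.populations], dtype=float)
        ds = np.array([d for _, d in self.populations], dtype=float)
        if np.any(ds < 0):
            raise ValueError("diffusion coefficients must be >= 0")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.min_frames < 2:
            raise ValueError("min_frames must be >= 2")


@dataclass
class FrapTruth:
    """Ground truth for one photobleaching-recovery experiment.

    Rates are per minute; ``frame_interval`` is seconds; ``duration`` is
    minutes of post-bleach acquisition.  ``noise_sd`` is relative
    (multiplicative Gaussian).
    """

    mobile_fraction: float = 0.5
    rate_constant: float = 0.3
    bleach_depth: float = 0.8
    acquisition_bleaching_rate: float = 0.02
    frame_interval: float = 10.0
    duration: float = 15.0
    noise_sd: float = 0.02
    n_prebleach: int = 10
    roi_prebleach: float = 1000.0
    cell_prebleach: float = 10000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be >= 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")

    def normalized_recovery(self, t_min: np.ndarray) -> np.ndarray:
        """Analytic normalized ROI trace at post-bleach times (minutes).

        The acquisition-bleaching factor cancels in the double
        normalization, leaving the immobile floor plus the mobile
        exponential recovery.
        """
        t = np.asarray(t_min, dtype=float)
        floor = 1.0 - self.bleach_depth
        rec = self.mobile_fraction * self.bleach_depth * (
            1.0 - np.exp(-self.rate_constant * t))
        return floor + rec


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def render_fields(spec: SynthCellSpec):
    """Noiseless pre-PSF intensity field and the masks that define it.

    Returns a dict with the float image, interior mask, outer/inner band
    masks, the pixel size and the ground-truth geometry.  Used both by
    :func:`render_cell_image` and as the band-mask oracle in tests.
    """
    centerline = spec.build_centerline()
    geom = make_cell(centerline, spec.half_width)

    r = spec.half_width
    lo = geom.outline.min(axis=0)
    hi = geom.outline.max(axis=0)
    if spec.canvas_shape is None:
        # autosize: shift the cell so its bounding box sits at `margin`
        centerline = centerline - lo + spec.margin
        geom = make_cell(centerline, spec.half_width)
        extent = hi - lo + 2 * spec.margin
        nx = int(np.ceil(extent[0] / spec.pixel_size))
        ny = int(np.ceil(extent[1] / spec.pixel_size))
    else:
        ny, nx = spec.canvas_shape
        if hi[0] > nx * spec.pixel_size or hi[1] > ny * spec.pixel_size \
                or lo[0] < 0 or lo[1] < 0:
            raise ValueError(
                "cell exceeds the requested canvas; enlarge canvas_shape "
                "(silent cropping is not performed)")

    xs = (np.arange(nx) + 0.5) * spec.pixel_size
    ys = (np.arange(ny) + 0.5) * spec.pixel_size
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    dist, side, _, _ = polyline_distance_field(pts, centerline)
    dist = dist.reshape(ny, nx)
    side = side.reshape(ny, nx)

    interior = dist <= r
    kappa = signed_curvature(centerline)
    mean_k = float(np.mean(kappa))
    # the convex (outer) side is opposite the sign of the curvature vector
    outer_sign = -np.sign(mean_k) if mean_k != 0 else 0.0
    band_lo = r - 2.0 * spec.ribbon_band_halfwidth
    in_band_radius = (dist >= band_lo) & (dist <= r)
    outer_band = interior & in_band_radius & (side == outer_sign)
    inner_band = interior & in_band_radius & (side == -outer_sign)
    if outer_sign == 0.0:  # straight cell: split bands by side label only
        outer_band = interior & in_band_radius & (side > 0)
        inner_band = interior & in_band_radius & (side < 0)

    img = np.full((ny, nx), float(spec.background))
    img[interior] += spec.peak_intensity
    img[outer_band] += (spec.ribbon_boost - 1.0) * spec.peak_intensity
    return {
        "noiseless": img,
        "interior": interior,
        "outer_band": outer_band,
        "inner_band": inner_band,
        "geometry": geom,
        "pixel_size": spec.pixel_size,
    }


def render_cell_image(spec: SynthCellSpec, seed: int):
    """Render one 16-bit fluorescence snapshot of a synthetic cell.

    PSF blur (Gaussian, ``psf_sigma``) is applied to the noiseless field,
    then Poisson shot noise (scaled by ``poisson_gain`` photons per count)
    and additive Gaussian read noise.  Returns the image stack and the
    ground-truth :class:`CellGeometry` in µm canvas coordinates.
    """
    fields = render_fields(spec)
    rng = np.random.default_rng(seed)
    blurred = gaussian_filter(fields["noiseless"],
                              spec.psf_sigma / spec.pixel_size)
    g = max(spec.poisson_gain, 1e-12)
    noisy = rng.poisson(np.clip(blurred, 0, None) * g) / g
    noisy = noisy + rng.normal(0.0, spec.gaussian_sd, size=noisy.shape)
    img = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)
    stack = ImageStack(data=img[None, ...], pixel_size=spec.pixel_size)
    return stack, fields["geometry"]


# ---------------------------------------------------------------------------
# Particle tracks
# ---------------------------------------------------------------------------

def simulate_tracks(spec: ParticleMixtureSpec, seed: int) -> pd.DataFrame:
    """Brownian-mixture trajectories observed with localization error.

    Per-axis step variance is 2·D·Δt; each observation gets independent
    N(0, σ_loc²) noise per axis.  Returns a TrackMate-like table with
    columns frame, track_id, x_um, y_um, intensity plus the ground-truth
    ``population`` index per track.
    """
    rng = np.random.default_rng(seed)
    fracs = np.array([f for f, _ in spec.populations])
    ds = np.array([d for _, d in spec.populations])
    n = spec.n_tracks
    pop = rng.choice(len(fracs), size=n, p=fracs)

    # truncated geometric lengths: rejection-free via inverse CDF on the
    # admissible support
    k = np.arange(spec.min_frames, spec.max_frames + 1)
    pmf = spec.length_p * (1 - spec.length_p) ** (k - spec.min_frames)
    pmf /= pmf.sum()
    lengths = rng.choice(k, size=n, p=pmf)

    n_frames = max(1, int(np.ceil(n / spec.activation_rate)))
    starts = rng.integers(0, n_frames, size=n)

    if spec.confinement is not None:
        out = _simulate_confined(spec, rng, pop, lengths, starts, ds)
    else:
        # vectorized: pad all tracks to the maximum length and mask
        lmax = int(lengths.max())
        sd_step = np.sqrt(2.0 * ds[pop] * spec.frame_interval)
        steps = rng.normal(0.0, 1.0, size=(n, lmax, 2)) \
            * sd_step[:, None, None]
        steps[:, 0, :] = rng.normal(0.0, 1.0, size=(n, 2))  # start positions
        xy = np.cumsum(steps, axis=1)
        obs = xy + rng.normal(0.0, spec.localization_sd, size=xy.shape)
        valid = np.arange(lmax)[None, :] < lengths[:, None]
        tid_grid = np.broadcast_to(np.arange(n)[:, None], (n, lmax))
        frame_grid = starts[:, None] + np.arange(lmax)[None, :]
        out = pd.DataFrame({
            "frame": frame_grid[valid],
            "track_id": tid_grid[valid],
            "x_um": obs[:, :, 0][valid],
            "y_um": obs[:, :, 1][valid],
            "intensity": 1000.0,
            "population": pop[tid_grid[valid]],
        })
    return out.sort_values(["frame", "track_id"], ignore_index=True)


def _simulate_confined(spec, rng, pop, lengths, starts, ds) -> pd.DataFrame:
    """Per-track loop with step rejection at the confinement boundary."""
    confinement = Polygon(np.asarray(spec.confinement, float))
    minx, miny, maxx, maxy = confinement.bounds
    rows = []
    for tid in range(spec.n_tracks):
        L = int(lengths[tid])
        sd_step = np.sqrt(2.0 * ds[pop[tid]] * spec.frame_interval)
        while True:
            x0 = rng.uniform(minx, maxx)
            y0 = rng.uniform(miny, maxy)
            if confinement.contains(Point(x0, y0)):
                break
        xy = np.empty((L, 2))
        xy[0] = (x0, y0)
        for i in range(1, L):
            for _ in range(20):  # reject steps that leave the region
                cand = xy[i - 1] + rng.normal(0.0, sd_step, size=2)
                if sd_step == 0 or confinement.contains(Point(*cand)):
                    xy[i] = cand
                    break
            else:
                xy[i] = xy[i - 1]
        obs = xy + rng.normal(0.0, spec.localization_sd, size=xy.shape)
        rows.append(pd.DataFrame({
            "frame": starts[tid] + np.arange(L),
            "track_id": tid,
            "x_um": obs[:, 0],
            "y_um": obs[:, 1],
            "intensity": np.full(L, 1000.0),
            "population": pop[tid],
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# FRAP series
# ---------------------------------------------------------------------------

def simulate_frap_series(truth: FrapTruth, seed: int) -> pd.DataFrame:
    """Photobleaching-recovery time series for one region of interest.

    Emits ``n_prebleach`` frames before the bleach event, then frames at
    ``frame_interval`` for ``duration`` minutes.  The whole-cell trace
    decays with the acquisition-bleaching rate; the ROI trace is the
    immobile floor plus the mobile exponential recovery, multiplied by the
    same decay, plus relative Gaussian noise.  Columns: t_min (0 at first
    post-bleach frame), roi, cell, prebleach flag.
    """
    rng = np.random.default_rng(seed)
    dt_min = truth.frame_interval / 60.0
    t_pre = -dt_min * np.arange(truth.n_prebleach, 0, -1)
    n_post = int(np.floor(truth.duration / dt_min)) + 1
    t_post = dt_min * np.arange(n_post)
    t = np.concatenate([t_pre, t_post])
    pre = t < 0

    t_abs = t - t_pre[0]  # acquisition time since first frame
    decay = np.exp(-truth.acquisition_bleaching_rate * t_abs)

    roi_norm = np.where(pre, 1.0, truth.normalized_recovery(np.clip(t, 0, None)))
    roi = truth.roi_prebleach * roi_norm * decay
    # whole-cell trace follows only the acquisition decay; the small step
    # loss from the bleach pulse itself is not modelled (see methods note)
    cell = truth.cell_prebleach * decay
    if truth.noise_sd > 0:
        roi = roi * (1.0 + rng.normal(0.0, truth.noise_sd, size=roi.shape))
        cell = cell * (1.0 + rng.normal(0.0, truth.noise_sd * 0.3,
                                        size=cell.shape))
    return pd.DataFrame({"t_min": t, "roi": roi, "cell": cell,
                         "prebleach": pre})


# ---------------------------------------------------------------------------
# SMLM localizations
# ---------------------------------------------------------------------------

def ribbon_path(half_width: float = DEFAULT_HALF_WIDTH_UM,
                curvature_radius: float = DEFAULT_CURVATURE_RADIUS_UM,
                length: float = 5.0, n: int = 512,
                inset: float = 0.05) -> np.ndarray:
    """Polyline along the outer-curve membrane band of an arc cell.

    The band is offset ``inset`` µm inside the membrane so that jittered
    localizations remain within the cell outline.
    """
    centerline = arc_centerline(curvature_radius, length, n)
    kappa = signed_curvature(centerline)
    outer_sign = -np.sign(float(np.mean(kappa)))
    # normals: rotate tangent by ±90°; offset toward the convex side
    t = np.gradient(centerline, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    normal = np.column_stack([-t[:, 1], t[:, 0]])  # left of travel (y down)
    return centerline + outer_sign * (half_width - inset) * normal


def simulate_localizations(n_molecules: int,
                           path: np.ndarray | None = None,
                           clustering_sd: float = 0.01,
                           precision_sd: float = 0.015,
                           blinks: int = 1,
                           placement: str = "even",
                           seed: int = 0) -> pd.DataFrame:
    """Single-molecule localization list along a ribbon path.

    Molecules are placed along ``path`` (default: outer-curve band of the
    default arc cell) either at even arc-length spacing or uniformly at
    random, with lateral Gaussian jitter ``clustering_sd``.  Each molecule
    emits ``blinks`` localizations, each offset by Gaussian precision
    noise.  Returns the localization table with a ``molecule`` truth
    column.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    if path is None:
        path = ribbon_path()
    s = cumulative_arclength(path)
    total = s[-1]
    if placement == "even":
        pos_s = (np.arange(n_molecules) + 0.5) * total / n_molecules
    elif placement == "uniform":
        pos_s = rng.uniform(0.0, total, size=n_molecules)
    else:
        raise ValueError("placement must be 'even' or 'uniform'")
    x = np.interp(pos_s, s, path[:, 0])
    y = np.interp(pos_s, s, path[:, 1])
    mol = np.column_stack([x, y])
    if clustering_sd > 0:
        mol = mol + rng.normal(0.0, clustering_sd, size=mol.shape)

    idx = np.repeat(np.arange(n_molecules), blinks)
    obs = mol[idx]
    if precision_sd > 0:
        obs = obs + rng.normal(0.0, precision_sd, size=obs.shape)
    return pd.DataFrame({
        "frame": np.arange(len(obs)),
        "x_um": obs[:, 0],
        "y_um": obs[:, 1],
        "precision_um": np.full(len(obs), precision_sd),
        "molecule": idx,
    })
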