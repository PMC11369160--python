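"""Single-particle tracking: spot detection, linking, MSD/SQD diffusion
analysis with model selection, ROI filtering, and SMLM density operators.

Diffusion-state inference follows the squared-displacement (SQD) approach:
the empirical cumulative distribution of single-frame squared displacements
x is fitted to a mixture of exponential components,

    P(x) = 1 − Σ_i f_i · exp(−x / (4·D_i·Δt + 4·σ_loc²)),

one component per diffusive state, with fractions f_i summing to 1.  More
complex models (up to three states) are accepted only if an
extra-sum-of-squares F-test gives p < 0.05 AND the Bayesian information
criterion drops by more than 5%.  Apparent coefficients can be constrained
to be shared across experimental conditions, with only the fractions free
per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares, linear_sum_assignment
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from skimage.feature import blob_log

MAX_STATES = 3


# ---------------------------------------------------------------------------
# Configuration / containers
# ---------------------------------------------------------------------------

@dataclass
class LinkConfig:
    """Frame-to-frame linking parameters (defaults follow the two-step
    nearest-neighbour LAP scheme: 300 nm link, 1-frame gaps closed within
    500 nm, tracks shorter than 5 frames discarded)."""

    max_link_dist: float = 0.3
    gap_frames: int = 1
    gap_close_dist: float = 0.5
    min_track_len: int = 5

    def __post_init__(self) -> None:
        if min(self.max_link_dist, self.gap_close_dist) <= 0 \
                or self.min_track_len <= 0 or self.gap_frames < 0:
            raise ValueError("link parameters must be positive")
        if self.gap_close_dist < self.max_link_dist:
            raise ValueError("gap_close_dist must be >= max_link_dist")


@dataclass
class TrackSet:
    """Linked trajectories.  ``spots`` has columns frame, track_id, x_um,
    y_um (frames strictly increasing within a track); ``frame_interval``
    in seconds; optional per-track ROI labels."""

    spots: pd.DataFrame
    frame_interval: float
    roi_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tid, fr, _ = self._arrays()
        same = tid[1:] == tid[:-1]
        if np.any(same & (np.diff(fr) <= 0)):
            raise ValueError("frames must be strictly increasing per track")

    def _arrays(self):
        """(track_id, frame, xy) sorted by track then frame (cached)."""
        cached = getattr(self, "_sorted", None)
        if cached is None:
            df = self.spots.sort_values(["track_id", "frame"], kind="stable")
            cached = (df["track_id"].to_numpy(), df["frame"].to_numpy(),
                      df[["x_um", "y_um"]].to_numpy())
            object.__setattr__(self, "_sorted", cached)
        return cached

    @property
    def track_ids(self) -> np.ndarray:
        return self.spots["track_id"].unique()

    def tracks(self):
        for tid, df in self.spots.groupby("track_id"):
            yield tid, df

    def displacements(self, lag: int = 1) -> np.ndarray:
        """Single-lag squared displacements pooled over tracks (µm²),
        taken between observations exactly ``lag`` frames apart."""
        tid, fr, xy = self._arrays()
        if len(tid) <= lag:
            return np.empty(0)
        same = tid[lag:] == tid[:-lag]
        d_fr = fr[lag:] - fr[:-lag]
        d = xy[lag:] - xy[:-lag]
        sq = np.einsum("ij,ij->i", d, d)
        return sq[same & (d_fr == lag)]


@dataclass
class SQDModel:
    """Mixture-of-exponentials fit to the squared-displacement CDF.

    ``rss``/``bic`` describe the quantile-grid CDF residuals; ``pearson_x2``
    is a goodness-of-fit chi-square over ``n_bins`` equal-count bins of the
    displacement sample, whose residuals are near-independent and therefore
    carry the calibrated F-test in :func:`model_select`.
    """

    n_states: int
    fractions: np.ndarray
    diffusion: np.ndarray  # µm²/s, sorted descending
    sigma_loc: float
    rss: float
    n_points: int
    n_params: int
    bic: float
    pearson_x2: float = np.nan
    n_bins: int = 0
    n_data: int = 0
    shared_d: bool = False
    condition: str | None = None


@dataclass
class MsdCurve:
    lags: np.ndarray          # seconds
    msd: np.ndarray           # µm²
    sd: np.ndarray
    slope: float              # µm²/s; apparent D = slope / 4
    intercept: float          # µm²

    @property
    def apparent_d(self) -> float:
        return self.slope / 4.0


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_spots(frame: np.ndarray, pixel_size: float,
                 diameter: float = 0.5, snr_threshold: float = 5.0
                 ) -> pd.DataFrame:
    """Laplacian-of-Gaussian spot detection with sub-pixel refinement.

    ``diameter`` is the expected spot diameter in µm; detections whose
    signal-to-noise ratio (peak above background, over the robust
    background sd) falls below ``snr_threshold`` are dropped.  Returns
    columns x_um, y_um, intensity, snr.
    """
    from scipy.ndimage import median_filter

    img = np.asarray(frame, dtype=float)
    img = median_filter(img, size=3)
    sigma_px = (diameter / 2.0) / np.sqrt(2.0) / pixel_size

    bg = np.median(img)
    mad = np.median(np.abs(img - bg))
    noise_sd = 1.4826 * mad if mad > 0 else max(img.std(), 1e-12)

    blobs = blob_log(img, min_sigma=max(sigma_px * 0.8, 0.5),
                     max_sigma=sigma_px * 1.5, num_sigma=3, overlap=0.3,
                     threshold=0.5 * snr_threshold * noise_sd / 10.0)
    rows = []
    half = max(int(round(sigma_px * 2)), 2)
    ny, nx = img.shape
    for by, bx, _ in blobs:
        iy, ix = int(round(by)), int(round(bx))
        y0, y1 = max(iy - half, 0), min(iy + half + 1, ny)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, nx)
        patch = img[y0:y1, x0:x1] - bg
        peak = img[iy, ix] - bg  # centre value, not patch max: rejects
        snr = peak / noise_sd    # flank blobs of a brighter neighbour
        if snr < snr_threshold:
            continue
        w = np.clip(patch, 0, None)
        if w.sum() == 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cy = float((w * yy).sum() / w.sum())
        cx = float((w * xx).sum() / w.sum())
        rows.append({"x_um": (cx + 0.5) * pixel_size,
                     "y_um": (cy + 0.5) * pixel_size,
                     "intensity": float(peak), "snr": float(snr)})
    out = pd.DataFrame(rows, columns=["x_um", "y_um", "intensity", "snr"])
    return _suppress_duplicates(out, min_dist=0.7 * diameter)


def _suppress_duplicates(spots: pd.DataFrame, min_dist: float) -> pd.DataFrame:
    """Keep only the brightest of any detections closer than ``min_dist``
    (multi-scale LoG can fire more than once per spot)."""
    if len(spots) < 2:
        return spots
    spots = spots.sort_values("intensity", ascending=False)
    pts = spots[["x_um", "y_um"]].to_numpy()
    keep = []
    kept_pts = np.empty((0, 2))
    for i, p in enumerate(pts):
        if len(kept_pts) == 0 or np.min(
                np.hypot(*(kept_pts - p).T)) >= min_dist:
            keep.append(i)
            kept_pts = np.vstack([kept_pts, p])
    return spots.iloc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def link_tracks(spots: pd.DataFrame, cfg: LinkConfig,
                frame_interval: float = 0.02) -> TrackSet:
    """Two-step linking: per-frame optimal assignment within
    ``max_link_dist``, then gap closing of track ends to later track starts
    across ≤ ``gap_frames`` missing frames within ``gap_close_dist``;
    finally tracks shorter than ``min_track_len`` observations are removed.

    Every retained spot belongs to exactly one track and no spot is used
    twice.
    """
    df = spots.sort_values("frame").reset_index(drop=True)
    frames = df["frame"].to_numpy()
    xy = df[["x_um", "y_um"]].to_numpy()
    track_of = np.full(len(df), -1, dtype=int)
    next_track = 0

    unique_frames = np.unique(frames)
    prev_idx = np.array([], dtype=int)
    prev_frame = None
    for f in unique_frames:
        cur_idx = np.flatnonzero(frames == f)
        if prev_frame is not None and f == prev_frame + 1 and len(prev_idx):
            cost = np.linalg.norm(xy[prev_idx][:, None, :]
                                  - xy[cur_idx][None, :, :], axis=2)
            big = 1e6
            cost = np.where(cost <= cfg.max_link_dist, cost, big)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] < big:
                    track_of[cur_idx[j]] = track_of[prev_idx[i]]
        for i in cur_idx:
            if track_of[i] < 0:
                track_of[i] = next_track
                next_track += 1
        prev_idx = cur_idx
        prev_frame = f

    # gap closing: match segment ends to segment starts
    merged = _close_gaps(df, xy, frames, track_of, cfg)

    df = df.assign(track_id=merged)
    keep = df.groupby("track_id")["frame"].transform("size") >= cfg.min_track_len
    df = df[keep].reset_index(drop=True)
    # renumber compactly
    df["track_id"] = pd.factorize(df["track_id"])[0]
    return TrackSet(spots=df, frame_interval=frame_interval)


def _close_gaps(df, xy, frames, track_of, cfg: LinkConfig) -> np.ndarray:
    track_of = track_of.copy()
    changed = True
    while changed:
        changed = False
        ends, starts = {}, {}
        for tid in np.unique(track_of):
            idx = np.flatnonzero(track_of == tid)
            ends[tid] = idx[np.argmax(frames[idx])]
            starts[tid] = idx[np.argmin(frames[idx])]
        candidates = []
        for ta, ia in ends.items():
            for tb, ib in starts.items():
                if ta == tb:
                    continue
                gap = frames[ib] - frames[ia]
                if 2 <= gap <= cfg.gap_frames + 1:
                    d = np.linalg.norm(xy[ia] - xy[ib])
                    if d <= cfg.gap_close_dist:
                        candidates.append((d, ta, tb))
        used_a, used_b = set(), set()
        for d, ta, tb in sorted(candidates):
            if ta in used_a or tb in used_b or ta in used_b or tb in used_a:
                continue
            track_of[track_of == tb] = ta
            used_a.add(ta)
            used_b.add(tb)
            changed = True
    return track_of


# ---------------------------------------------------------------------------
# ROI filtering
# ---------------------------------------------------------------------------

def filter_by_roi(tracks: TrackSet, rois: dict) -> TrackSet:
    """Assign each track to the ROI containing the majority of its
    observations; tracks outside all ROIs (background) are dropped.

    ``rois`` maps label → polygon vertex array.  Overlapping ROIs are an
    error.
    """
    polys = {name: Polygon(np.asarray(p, float)) for name, p in rois.items()}
    names = list(polys)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = polys[a].intersection(polys[b])
            if inter.area > 1e-12:
                raise ValueError(f"ROIs {a!r} and {b!r} overlap")

    keep_rows = []
    labels = {}
    for tid, df in tracks.tracks():
        pts = [Point(x, y) for x, y in df[["x_um", "y_um"]].to_numpy()]
        counts = {name: sum(poly.covers(p) for p in pts)
                  for name, poly in polys.items()}
        best = max(counts, key=counts.get)
        if counts[best] * 2 > len(pts):  # strict majority inside an ROI
            labels[tid] = best
            keep_rows.append(df)
    spots = (pd.concat(keep_rows, ignore_index=True) if keep_rows
             else tracks.spots.iloc[0:0])
    return TrackSet(spots=spots, frame_interval=tracks.frame_interval,
                    roi_labels=labels)


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def msd(tracks: TrackSet, lags_s: np.ndarray | None = None) -> MsdCurve:
    """Ensemble/time-averaged MSD at the given lags with a linear fit
    MSD = 4·D·τ + b.  The last observation of every track is excluded to
    avoid track-ending artifacts.
    """
    dt = tracks.frame_interval
    if lags_s is None:
        # first four multiples of the frame time (24..96 ms for a 24-ms
        # frame-to-frame cycle)
        lags_s = dt * np.arange(1, 5)
    lags_s = np.asarray(lags_s, dtype=float)
    lag_frames = np.unique(np.maximum(1, np.round(lags_s / dt).astype(int)))

    tid, fr, xy = tracks._arrays()
    # drop the last observation of every track
    last = np.r_[tid[1:] != tid[:-1], True]
    tid, fr, xy = tid[~last], fr[~last], xy[~last]
    means, sds, taus = [], [], []
    for k in lag_frames:
        if len(tid) <= k:
            continue
        same = tid[k:] == tid[:-k]
        d_fr = fr[k:] - fr[:-k]
        d = xy[k:] - xy[:-k]
        sq = np.einsum("ij,ij->i", d, d)
        vals = sq[same & (d_fr == k)]
        if len(vals) == 0:
            continue
        taus.append(k * dt)
        means.append(vals.mean())
        sds.append(vals.std(ddof=1) if len(vals) > 1 else 0.0)
    if len(taus) < 2:
        raise ValueError("fewer than two usable lags; tracks too short")
    taus = np.array(taus)
    means = np.array(means)
    slope, intercept = np.polyfit(taus, means, 1)
    return MsdCurve(lags=taus, msd=means, sd=np.array(sds),
                    slope=float(slope), intercept=float(intercept))


# ---------------------------------------------------------------------------
# SQD mixture fitting
# ---------------------------------------------------------------------------

def _ecdf_grid(sq: np.ndarray, n_grid: int = 200):
    """Quantile-grid evaluation points of the empirical CDF."""
    sq = np.sort(sq)
    n = len(sq)
    q = (np.arange(1, n_grid + 1) - 0.5) / n_grid
    x = np.quantile(sq, q)
    ecdf = np.searchsorted(sq, x, side="right") / n
    return x, ecdf


def _mixture_cdf(x, scales, fracs):
    x = np.asarray(x)[..., None]
    return 1.0 - np.sum(fracs * np.exp(-x / scales), axis=-1)


def _softmax(z):
    z = np.concatenate([z, [0.0]])
    e = np.exp(z - z.max())
    return e / e.sum()


def sqd_fit(tracks, n_states: int, frame_interval: float | None = None,
            sigma_loc: float = 0.0, conditions: dict | None = None,
            n_grid: int = 200, n_starts: int = 4):
    """Fit the squared-displacement CDF with ``n_states`` exponential
    components.

    Parameters
    ----------
    tracks : TrackSet or array of squared displacements
        When ``conditions`` is given, ignored; pass data per condition.
    sigma_loc : known localization sd (µm).  The fitted per-state scale is
        4·D·Δt + 4·σ_loc², so D is reported after subtracting the
        localization term; σ is an input, not a free parameter, because a
        single-lag CDF only identifies the combined scales.
    conditions : optional dict name → TrackSet (or displacement array).
        D (and σ) are shared across conditions; only the fractions are
        free per condition.  Returns a dict name → SQDModel.
    """
    if n_states < 1 or n_states > MAX_STATES:
        raise ValueError(f"n_states must be in 1..{MAX_STATES}")

    if conditions is not None:
        datasets = {name: _get_sq(ts) for name, ts in conditions.items()}
        dt = frame_interval or next(
            ts.frame_interval for ts in conditions.values()
            if isinstance(ts, TrackSet))
        return _sqd_fit_shared(datasets, n_states, dt, sigma_loc,
                               n_grid, n_starts)

    sq = _get_sq(tracks)
    dt = frame_interval or tracks.frame_interval
    if len(sq) < 200:
        raise ValueError("need at least 200 single-frame displacements")
    x, ecdf = _ecdf_grid(sq, n_grid)
    scale0 = max(np.mean(sq), 1e-12)
    off = 4.0 * sigma_loc ** 2

    def make_resid(k):
        def resid(p):
            scales = np.exp(p[:k])
            fr = _softmax(p[k:]) if k > 1 else np.array([1.0])
            return _mixture_cdf(x, scales, fr) - ecdf
        return resid

    starts = []
    if n_states == 1:
        starts.append(np.array([np.log(scale0)]))
    else:
        s_em, f_em = _em_scales(sq, n_states)
        f_em = np.clip(f_em, 1e-6, None)
        logits = np.log(f_em[:-1]) - np.log(f_em[-1])
        starts.append(np.concatenate([np.log(s_em), logits]))
        for spread in np.linspace(0.5, 2.5, n_starts):
            logs = np.log(scale0) + spread * np.linspace(1, -1, n_states)
            starts.append(np.concatenate([logs, np.zeros(n_states - 1)]))
    best = None
    for p0 in starts:
        sol = least_squares(make_resid(n_states), p0, method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    scales = np.exp(best.x[:n_states])
    fracs = _softmax(best.x[n_states:]) if n_states > 1 else np.array([1.0])
    order = np.argsort(scales)[::-1]
    scales, fracs = scales[order], fracs[order]
    d = np.clip(scales - off, 0.0, None) / (4.0 * dt)
    rss = float(2.0 * best.cost)
    n_par = 2 * n_states - 1
    bic = _bic(rss, n_grid, n_par)
    x2, n_bins = _pearson_x2(sq, scales, fracs)
    return SQDModel(n_states=n_states, fractions=fracs, diffusion=d,
                    sigma_loc=sigma_loc, rss=rss, n_points=n_grid,
                    n_params=n_par, bic=bic, pearson_x2=x2, n_bins=n_bins,
                    n_data=len(sq))


def _pearson_x2(sq: np.ndarray, scales: np.ndarray, fracs: np.ndarray,
                n_bins: int = 64):
    """Goodness-of-fit chi-square over equal-count bins of the sample.

    Equal-count binning via sample quantiles gives observed counts n/B per
    bin against the model's bin probabilities; the resulting standardized
    residuals are near-independent, unlike CDF residuals on a quantile
    grid.
    """
    n = len(sq)
    n_bins = min(n_bins, max(n // 20, 4))
    edges = np.quantile(sq, np.linspace(0.0, 1.0, n_bins + 1))
    edges[0], edges[-1] = 0.0, np.inf
    cdf_edges = _mixture_cdf(edges[:-1], scales, fracs)
    cdf_edges = np.append(cdf_edges, 1.0)
    p = np.diff(cdf_edges)
    p = np.clip(p, 1e-12, None)
    observed = np.full(n_bins, n / n_bins)
    x2 = float(np.sum((observed - n * p) ** 2 / (n * p)))
    return x2, n_bins


def _get_sq(obj) -> np.ndarray:
    if isinstance(obj, TrackSet):
        return obj.displacements(lag=1)
    return np.asarray(obj, dtype=float)


def _em_scales(sq: np.ndarray, k: int, iters: int = 120,
               max_points: int = 8000) -> tuple:
    """Expectation-maximization for a k-component exponential mixture;
    used only to initialize the CDF least-squares fit near its global
    optimum (the LS fit on the quantile grid remains the estimator)."""
    if len(sq) > max_points:  # deterministic thinning for the init only
        sq = np.sort(sq)[:: len(sq) // max_points + 1]
    s = np.mean(sq) * np.geomspace(2.0, 0.3, k)
    f = np.full(k, 1.0 / k)
    x = sq[:, None]
    for _ in range(iters):
        dens = np.clip(f / s * np.exp(-x / s), 1e-300, None)
        resp = dens / dens.sum(axis=1, keepdims=True)
        f = resp.mean(axis=0)
        s = (resp * x).sum(axis=0) / np.maximum(resp.sum(axis=0), 1e-12)
        s = np.clip(s, 1e-12, None)
    return s, f


def _bic(rss, n, k) -> float:
    return n * np.log(max(rss, 1e-300) / n) + k * np.log(n)


def _sqd_fit_shared(datasets: dict, n_states: int, dt: float,
                    sigma_loc: float, n_grid: int, n_starts: int) -> dict:
    """Global fit: one set of state scales (hence D_i), per-condition
    fractions."""
    names = list(datasets)
    grids = {}
    for name in names:
        sq = datasets[name]
        if len(sq) < 200:
            raise ValueError(f"condition {name!r}: need >= 200 displacements")
        grids[name] = _ecdf_grid(sq, n_grid)
    scale0 = max(np.mean(np.concatenate(list(datasets.values()))), 1e-12)
    off = 4.0 * sigma_loc ** 2
    k = n_states
    nf = k - 1

    def unpack(p):
        scales = np.exp(p[:k])
        fr = {}
        for i, name in enumerate(names):
            z = p[k + i * nf: k + (i + 1) * nf]
            fr[name] = _softmax(z) if nf else np.array([1.0])
        return scales, fr

    def resid(p):
        scales, fr = unpack(p)
        out = []
        for name in names:
            x, ecdf = grids[name]
            out.append(_mixture_cdf(x, scales, fr[name]) - ecdf)
        return np.concatenate(out)

    starts = []
    if k == 1:
        starts.append(np.concatenate([[np.log(scale0)],
                                      np.zeros(len(names) * nf)]))
    else:
        s_em, _ = _em_scales(np.concatenate(list(datasets.values())), k)
        starts.append(np.concatenate([np.log(s_em),
                                      np.zeros(len(names) * nf)]))
        for spread in np.linspace(0.5, 2.5, n_starts):
            logs = np.log(scale0) + spread * np.linspace(1, -1, k)
            starts.append(np.concatenate([logs, np.zeros(len(names) * nf)]))
    best = None
    for p0 in starts:
        sol = least_squares(resid, p0, method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    scales, fr = unpack(best.x)
    order = np.argsort(scales)[::-1]
    d = np.clip(scales[order] - off, 0.0, None) / (4.0 * dt)
    n_total = n_grid * len(names)
    n_par = k + len(names) * nf
    rss = float(2.0 * best.cost)
    out = {}
    for name in names:
        out[name] = SQDModel(
            n_states=k, fractions=fr[name][order], diffusion=d,
            sigma_loc=sigma_loc, rss=rss, n_points=n_total, n_params=n_par,
            bic=_bic(rss, n_total, n_par), shared_d=True, condition=name)
    return out


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def model_select(fits: dict, alpha: float = 0.05,
                 bic_drop: float = 0.05):
    """Choose the number of diffusive states among nested SQD fits.

    ``fits`` maps K → SQDModel fitted on the same data.  K+1 replaces K
    only when an extra-sum-of-squares F-test has p < ``alpha`` AND the
    BIC decreases by more than ``bic_drop`` (relative to |BIC_K|).

    Both statistics are computed on the equal-count-bin chi-square
    residuals (``pearson_x2``), which are near-independent; CDF residuals
    on a quantile grid have an effective dimension of only a few, which
    makes a nominal F-test on them wildly anticonservative.  BIC here is
    the binned-deviance form X² + k·ln(n_data).
    Returns (chosen K, report DataFrame).
    """
    ks = sorted(fits)
    n0 = fits[ks[0]].n_data
    if any(fits[k].n_data != n0 for k in ks):
        raise ValueError("fits are not nested on identical data")
    rows = []
    chosen = ks[0]
    for k_prev, k_next in zip(ks, ks[1:]):
        a, b = fits[k_prev], fits[k_next]
        df_extra = b.n_params - a.n_params
        df_resid = b.n_bins - 1 - b.n_params
        if a.pearson_x2 <= b.pearson_x2:
            fstat, p = 0.0, 1.0
        elif b.pearson_x2 <= 0:
            fstat, p = np.inf, 0.0
        else:
            fstat = ((a.pearson_x2 - b.pearson_x2) / df_extra) \
                / (b.pearson_x2 / df_resid)
            p = float(stats.f.sf(fstat, df_extra, df_resid))
        bic_a = a.pearson_x2 + a.n_params * np.log(a.n_data)
        bic_b = b.pearson_x2 + b.n_params * np.log(b.n_data)
        rel_drop = (bic_a - bic_b) / abs(bic_a) if bic_a != 0 else np.inf
        accept = (p < alpha) and (rel_drop > bic_drop)
        rows.append({"k_from": k_prev, "k_to": k_next, "F": fstat, "p": p,
                     "bic_from": bic_a, "bic_to": bic_b,
                     "rel_bic_drop": rel_drop, "accepted": accept})
        if accept and chosen == k_prev:
            chosen = k_next
        elif not accept:
            break
    return chosen, pd.DataFrame(rows)


def mobility_bubble_summary(models: dict) -> pd.DataFrame:
    """Tidy (condition, state, fraction, D) table for bubble plots."""
    rows = []
    for cond, m in models.items():
        for i, (f, d) in enumerate(zip(m.fractions, m.diffusion)):
            rows.append({"condition": cond, "state": i,
                         "fraction": float(f), "D_um2_s": float(d)})
    return pd.DataFrame(rows)


def plot_bubbles(summary: pd.DataFrame, ax=None):
    """Bubble plot: x = condition, y = D, area ∝ fraction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    conds = list(dict.fromkeys(summary["condition"]))
    for i, cond in enumerate(conds):
        sub = summary[summary["condition"] == cond]
        ax.scatter(np.full(len(sub), i), sub["D_um2_s"],
                   s=2000 * sub["fraction"], alpha=0.6)
    ax.set_xticks(range(len(conds)), conds)
    ax.set_ylabel("apparent D (µm²/s)")
    return ax


# ---------------------------------------------------------------------------
# SMLM operators
# ---------------------------------------------------------------------------

def nn_distance(locs: pd.DataFrame, raster_pixel: float | None = None):
    """Exact nearest-neighbour distance per localization.

    Returns the per-point distances; when ``raster_pixel`` is given, also a
    (heat-map, origin) raster of the per-pixel mean NN distance.
    """
    pts = locs[["x_um", "y_um"]].to_numpy()
    if len(pts) < 2:
        raise ValueError("need at least 2 localizations")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    nn = d[:, 1]
    if raster_pixel is None:
        return nn
    return nn, _rasterize(pts, nn, raster_pixel)


def local_density(locs: pd.DataFrame, radius: float) -> np.ndarray:
    """Number of neighbours within ``radius`` of each point (self excluded)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = locs[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius, return_length=True)
    return np.asarray(counts) - 1


def _rasterize(pts, values, pixel):
    lo = pts.min(axis=0)
    ij = np.floor((pts - lo) / pixel).astype(int)
    nx, ny = ij.max(axis=0) + 1
    acc = np.zeros((ny, nx))
    cnt = np.zeros((ny, nx))
    np.add.at(acc, (ij[:, 1], ij[:, 0]), values)
    np.add.at(cnt, (ij[:, 1], ij[:, 0]), 1)
    with np.errstate(invalid="ignore"):
        heat = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return heat, lo


def events_per_cell(locs: pd.DataFrame, outline: np.ndarray) -> int:
    """Count localization events inside a cell outline polygon."""
    poly = Polygon(np.asarray(outline, float))
    pts = locs[["x_um", "y_um"]].to_numpy()
    return int(sum(poly.covers(Point(x, y)) for x, y in pts))
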