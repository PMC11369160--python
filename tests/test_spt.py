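"""Tracking, diffusion-state inference and SMLM operators."""

import numpy as np
import pandas as pd
import pytest

from spirocell.spt import (
    LinkConfig,
    TrackSet,
    detect_spots,
    events_per_cell,
    filter_by_roi,
    link_tracks,
    local_density,
    mobility_bubble_summary,
    model_select,
    msd,
    nn_distance,
    sqd_fit,
)
from spirocell.synthgen import (
    ParticleMixtureSpec,
    simulate_localizations,
    simulate_tracks,
)


def _spot_frame(positions, amp=2000.0, shape=(40, 40), bg=100.0, seed=0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    sig = 0.25 / np.sqrt(2) / 0.1  # diameter 0.5 µm at 0.1 µm/px
    img = np.full(shape, bg)
    for (cx, cy) in positions:
        img = img + amp * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)
                                   / (2 * sig ** 2)))
    return np.random.default_rng(seed).poisson(img).astype(float)


class TestDetectSpots:
    def test_single_spot_subpixel_accuracy(self):
        img = _spot_frame([(20.3, 14.7)])
        spots = detect_spots(img, pixel_size=0.1)
        assert len(spots) == 1
        assert abs(spots.x_um[0] / 0.1 - 0.5 - 20.3) < 0.5
        assert abs(spots.y_um[0] / 0.1 - 0.5 - 14.7) < 0.5

    def test_blank_noise_false_positive_rate(self):
        """At SNR threshold 5, ≥99% of pure-noise frames yield zero
        detections."""
        clean = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame = rng.poisson(100, (64, 64)).astype(float)
            clean += len(detect_spots(frame, pixel_size=0.1)) == 0
        assert clean >= 99

    def test_resolvable_pair(self):
        img = _spot_frame([(12.0, 20.0), (19.5, 20.0)], seed=3)
        assert len(detect_spots(img, pixel_size=0.1)) == 2


def _spots_df(rows):
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "intensity"])


class TestLinkTracks:
    """Hand-enumerated scenarios under the 300 nm / 1-gap / 500 nm /
    ≥5-frame rules."""

    CFG = LinkConfig()

    def test_within_link_distance_joins(self):
        rows = [(f, 0.2 * f, 0.0, 1.0) for f in range(6)]
        ts = link_tracks(_spots_df(rows), self.CFG)
        assert len(ts.track_ids) == 1
        assert len(ts.spots) == 6

    def test_beyond_link_distance_splits(self):
        # 0.4 µm jumps every frame: no links, all singleton tracks die
        rows = [(f, 0.4 * f, 0.0, 1.0) for f in range(6)]
        ts = link_tracks(_spots_df(rows), self.CFG)
        assert len(ts.spots) == 0

    def test_one_frame_gap_bridged_within_500nm(self):
        rows = [(f, 0.2 * f, 0.0, 1.0) for f in [0, 1, 2, 4, 5, 6]]
        ts = link_tracks(_spots_df(rows), self.CFG)
        assert len(ts.track_ids) == 1
        assert len(ts.spots) == 6

    def test_two_frame_gap_not_bridged(self):
        rows = [(f, 0.1 * f, 0.0, 1.0) for f in [0, 1, 2, 5, 6, 7]]
        ts = link_tracks(_spots_df(rows), self.CFG)
        assert len(ts.spots) == 0  # two fragments of 3 < min length

    def test_minimum_track_length_enforced(self):
        rows = [(f, 0.1 * f, 0.0, 1.0) for f in range(4)]
        assert len(link_tracks(_spots_df(rows), self.CFG).spots) == 0
        rows = [(f, 0.1 * f, 0.0, 1.0) for f in range(5)]
        assert len(link_tracks(_spots_df(rows), self.CFG).spots) == 5

    def test_crossing_particles_optimal_assignment(self):
        rows = []
        for f in range(6):
            rows.append((f, 0.1 * f, 0.0, 1.0))
            rows.append((f, 0.1 * f, 0.3, 1.0))
        ts = link_tracks(_spots_df(rows), self.CFG)
        assert len(ts.track_ids) == 2
        for _, tr in ts.tracks():
            assert tr["y_um"].nunique() == 1  # no swaps between lanes

    def test_spot_conservation(self, two_state_tracks):
        """Every retained spot belongs to exactly one track."""
        _, df = two_state_tracks
        sub = df[df["frame"] < 40].drop(columns=["track_id"])
        ts = link_tracks(sub, LinkConfig(max_link_dist=0.12))
        n_obs = len(ts.spots)
        assert ts.spots.groupby(["frame", "x_um", "y_um"]).size().max() == 1
        assert ts.spots["track_id"].value_counts().min() >= self.CFG.min_track_len
        assert n_obs <= len(sub)


class TestFilterByRoi:
    def _tracks(self):
        rows = []
        for f in range(5):
            rows.append({"frame": f, "track_id": 0, "x_um": 0.1 * f,
                         "y_um": 0.5, "intensity": 1.0})
            rows.append({"frame": f, "track_id": 1, "x_um": 10 + 0.1 * f,
                         "y_um": 0.5, "intensity": 1.0})
        return TrackSet(spots=pd.DataFrame(rows), frame_interval=0.02)

    ROI = {"cell": np.array([[-1, -1], [2, -1], [2, 2], [-1, 2]], float)}

    def test_outside_track_dropped(self):
        out = filter_by_roi(self._tracks(), self.ROI)
        assert list(out.track_ids) == [0]
        assert out.roi_labels == {0: "cell"}

    def test_majority_rule(self):
        rows = [{"frame": f, "track_id": 0, "x_um": x, "y_um": 0.5,
                 "intensity": 1.0}
                for f, x in enumerate([0.5, 0.6, 0.7, 0.8, 5.0])]
        ts = TrackSet(spots=pd.DataFrame(rows), frame_interval=0.02)
        out = filter_by_roi(ts, self.ROI)
        assert out.roi_labels == {0: "cell"}

    def test_vertex_order_invariance(self):
        roi_rev = {"cell": self.ROI["cell"][::-1]}
        a = filter_by_roi(self._tracks(), self.ROI)
        b = filter_by_roi(self._tracks(), roi_rev)
        assert a.roi_labels == b.roi_labels

    def test_overlapping_rois_rejected(self):
        rois = {"a": self.ROI["cell"], "b": self.ROI["cell"] + 0.5}
        with pytest.raises(ValueError, match="overlap"):
            filter_by_roi(self._tracks(), rois)


class TestMsd:
    def test_immobile_noiseless_is_zero(self):
        spec = ParticleMixtureSpec(populations=[(1.0, 0.0)], n_tracks=50,
                                   localization_sd=0.0)
        ts = TrackSet(spots=simulate_tracks(spec, seed=1),
                      frame_interval=0.02)
        curve = msd(ts)
        assert np.allclose(curve.msd, 0.0)

    def test_single_population_slope(self):
        """Fitted slope/4 within 5% of D for 10⁴ noise-free tracks."""
        d_true = 0.05
        spec = ParticleMixtureSpec(populations=[(1.0, d_true)],
                                   n_tracks=10_000, localization_sd=0.0)
        ts = TrackSet(spots=simulate_tracks(spec, seed=2),
                      frame_interval=0.02)
        curve = msd(ts)
        assert curve.apparent_d == pytest.approx(d_true, rel=0.05)

    def test_immobile_with_noise_intercept(self):
        """Localization error alone gives a flat MSD ≈ 4σ²."""
        sig = 0.03
        spec = ParticleMixtureSpec(populations=[(1.0, 0.0)],
                                   n_tracks=4000, localization_sd=sig)
        ts = TrackSet(spots=simulate_tracks(spec, seed=3),
                      frame_interval=0.02)
        curve = msd(ts)
        assert curve.intercept == pytest.approx(4 * sig ** 2, rel=0.10)
        assert abs(curve.slope) * 0.096 < 0.2 * 4 * sig ** 2

    def test_lag_exceeding_tracks_rejected(self):
        spec = ParticleMixtureSpec(populations=[(1.0, 0.05)], n_tracks=20,
                                   min_frames=5, max_frames=6)
        ts = TrackSet(spots=simulate_tracks(spec, seed=4),
                      frame_interval=0.02)
        with pytest.raises(ValueError):
            msd(ts, lags_s=np.array([0.4, 0.8]))


class TestSqdFit:
    def test_single_population_closed_form(self):
        """Noise-free single state: the CDF is 1 − e^(−x/4DΔt) and the
        fitted D lands within 5% of truth."""
        d_true = 0.04
        spec = ParticleMixtureSpec(populations=[(1.0, d_true)],
                                   n_tracks=2000, localization_sd=0.0)
        ts = TrackSet(spots=simulate_tracks(spec, seed=5),
                      frame_interval=0.02)
        m = sqd_fit(ts, 1)
        assert m.diffusion[0] == pytest.approx(d_true, rel=0.05)
        assert m.fractions[0] == 1.0

    def test_well_separated_two_state_recovery(self):
        """D ratio > 3 at n = 2000 tracks: fractions within 0.05 and D
        within 10% of generator truth."""
        spec = ParticleMixtureSpec(populations=[(0.5, 0.08), (0.5, 0.02)],
                                   n_tracks=2000, localization_sd=0.02)
        ts = TrackSet(spots=simulate_tracks(spec, seed=6),
                      frame_interval=0.02)
        m = sqd_fit(ts, 2, sigma_loc=0.02)
        assert m.diffusion[0] == pytest.approx(0.08, rel=0.10)
        assert m.diffusion[1] == pytest.approx(0.02, rel=0.10)
        assert m.fractions[0] == pytest.approx(0.5, abs=0.05)

    def test_shared_d_across_conditions(self):
        """Global fit: D identical across conditions by construction,
        per-condition fractions recovered."""
        a = simulate_tracks(ParticleMixtureSpec(
            populations=[(0.7, 0.06), (0.3, 0.015)], n_tracks=3000), seed=7)
        b = simulate_tracks(ParticleMixtureSpec(
            populations=[(0.3, 0.06), (0.7, 0.015)], n_tracks=3000), seed=8)
        out = sqd_fit(None, 2, frame_interval=0.02, sigma_loc=0.02,
                      conditions={
                          "wt": TrackSet(spots=a, frame_interval=0.02),
                          "mut": TrackSet(spots=b, frame_interval=0.02)})
        assert np.array_equal(out["wt"].diffusion, out["mut"].diffusion)
        assert out["wt"].fractions[0] == pytest.approx(0.7, abs=0.05)
        assert out["mut"].fractions[0] == pytest.approx(0.3, abs=0.05)

    def test_mixture_cdf_is_valid(self, two_state_tracks):
        from spirocell.spt import _mixture_cdf

        _, df = two_state_tracks
        ts = TrackSet(spots=df, frame_interval=0.02)
        m = sqd_fit(ts, 2, sigma_loc=0.02)
        scales = 4 * m.diffusion * 0.02 + 4 * m.sigma_loc ** 2
        x = np.linspace(0, 1.0, 2000)
        cdf = _mixture_cdf(x, scales, m.fractions)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert cdf[-1] > 0.999
        assert m.fractions.sum() == pytest.approx(1.0)

    def test_too_many_states_rejected(self, two_state_tracks):
        _, df = two_state_tracks
        ts = TrackSet(spots=df, frame_interval=0.02)
        with pytest.raises(ValueError):
            sqd_fit(ts, 4)


class TestModelSelect:
    def _fits(self, pops, seed):
        spec = ParticleMixtureSpec(populations=pops, n_tracks=2000,
                                   localization_sd=0.02)
        ts = TrackSet(spots=simulate_tracks(spec, seed=seed),
                      frame_interval=0.02)
        return {k: sqd_fit(ts, k, sigma_loc=0.02) for k in (1, 2, 3)}

    def test_single_state_truth_keeps_one(self):
        fits = self._fits([(1.0, 0.05)], seed=21)
        k, report = model_select(fits)
        assert k == 1
        assert not report["accepted"].iloc[0]

    def test_two_state_truth_accepts_two(self):
        fits = self._fits([(0.5, 0.08), (0.5, 0.02)], seed=22)
        k, _ = model_select(fits)
        assert k == 2

    def test_identical_fit_quality_keeps_simpler(self, two_state_tracks):
        _, df = two_state_tracks
        ts = TrackSet(spots=df, frame_interval=0.02)
        a = sqd_fit(ts, 2, sigma_loc=0.02)
        import dataclasses

        b = dataclasses.replace(a, n_states=3, n_params=a.n_params + 2)
        k, report = model_select({2: a, 3: b})
        assert k == 2
        assert report["F"].iloc[0] == 0.0

    def test_mismatched_data_rejected(self):
        f1 = self._fits([(1.0, 0.05)], seed=23)[1]
        f2 = self._fits([(1.0, 0.05), ], seed=24)[2]
        import dataclasses

        f2 = dataclasses.replace(f2, n_data=f1.n_data + 1)
        with pytest.raises(ValueError):
            model_select({1: f1, 2: f2})


class TestBubbleSummary:
    def test_round_trip_from_fits(self, two_state_tracks):
        _, df = two_state_tracks
        ts = TrackSet(spots=df, frame_interval=0.02)
        m = sqd_fit(ts, 2, sigma_loc=0.02)
        table = mobility_bubble_summary({"wt": m})
        assert table["fraction"].sum() == pytest.approx(1.0)
        assert list(table["condition"].unique()) == ["wt"]
        assert table["D_um2_s"].iloc[0] > table["D_um2_s"].iloc[1]


class TestSmlmOperators:
    def test_grid_nn_distance(self):
        g = np.arange(10) * 0.03
        pts = np.array([(x, y) for x in g for y in g])
        locs = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
        nn = nn_distance(locs)
        assert np.allclose(nn, 0.03)

    def test_nn_matches_brute_force(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 2, size=(500, 2))
        locs = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
        nn = nn_distance(locs)
        brute = np.array([np.min(np.hypot(*(np.delete(pts, i, 0)
                                            - pts[i]).T))
                          for i in range(len(pts))])
        assert np.array_equal(nn, brute) or np.allclose(nn, brute, atol=0)

    def test_density_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 2, size=(500, 2))
        locs = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
        counts = local_density(locs, radius=0.15)
        brute = np.array([np.sum(np.hypot(*(np.delete(pts, i, 0)
                                            - pts[i]).T) <= 0.15)
                          for i in range(len(pts))])
        assert np.array_equal(counts, brute)

    def test_poisson_field_mean_density(self):
        """Uniform Poisson field: mean neighbour count ≈ λπr²."""
        rng = np.random.default_rng(3)
        lam, area_side, r = 500.0, 4.0, 0.2
        n = rng.poisson(lam * area_side ** 2)
        pts = rng.uniform(0, area_side, size=(n, 2))
        locs = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
        inner = (pts.min(axis=1) > r) & (pts.max(axis=1) < area_side - r)
        counts = local_density(locs, radius=r)[inner]
        expect = lam * np.pi * r ** 2
        assert counts.mean() == pytest.approx(expect, rel=0.05)

    def test_dense_ribbon_packing(self):
        """15-nm molecular spacing puts the majority of neighbour
        distances below 20 nm."""
        from spirocell.geometry import polyline_length
        from spirocell.synthgen import ribbon_path

        path = ribbon_path()
        n = int(np.ceil(polyline_length(path) / 0.015))
        locs = simulate_localizations(n, clustering_sd=0.004,
                                      precision_sd=0.0, seed=4)
        nn = nn_distance(locs)
        assert (nn < 0.02).mean() > 0.5

    def test_events_count_conservation(self):
        """Single-blink simulation of a 15,000-copy cell returns exactly
        the planted molecule count inside the outline."""
        from spirocell.geometry import arc_centerline, make_cell

        geom = make_cell(arc_centerline(5.7, 5.0, 400), 0.4)
        locs = simulate_localizations(15_000, clustering_sd=0.004,
                                      precision_sd=0.005, seed=5)
        assert events_per_cell(locs, geom.outline) == 15_000

    def test_no_points_inside(self):
        locs = pd.DataFrame({"x_um": [10.0], "y_um": [10.0], "frame": [0],
                             "precision_um": [0.01]})
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert events_per_cell(locs, square) == 0
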