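"""Ratiometric E*/RF computation, channel inference, ALEX filtering."""

import numpy as np
import pandas as pd
import pytest

from swifi.detect import DetectionConfig, detect_movie
from swifi.link import LinkConfig, iterate_linking
from swifi.ratiometric import (
    per_track_estar,
    ChannelRegistration,
    alex_filter,
    build_ed_histogram,
    estar,
    fit_two_gaussians,
    infer_intensity_at,
    make_fret_records,
    pair_dual_channel_tracks,
)
from swifi.simulate import (
    CameraModel,
    PhotophysicsModel,
    SimulationConfig,
    simulate_movie,
)


class TestEstar:
    def test_equal_channels_give_half(self):
        assert estar(100.0, 100.0) == pytest.approx(0.5)

    def test_no_donor_signal_gives_one(self):
        assert estar(50.0, 0.0) == pytest.approx(1.0)

    def test_high_fret_standard_arithmetic(self):
        assert estar(880.0, 120.0) == pytest.approx(0.88)

    def test_zero_total_is_nan(self):
        assert np.isnan(estar(0.0, 0.0))
        assert np.isnan(estar(50.0, -50.0))

    def test_noise_can_push_outside_unit_interval(self):
        assert estar(120.0, -20.0) == pytest.approx(1.2)
        assert estar(-10.0, 110.0) == pytest.approx(-0.1)


class TestInference:
    def test_intensity_in_empty_region_is_near_zero(self):
        rng = np.random.default_rng(0)
        img = np.full((40, 40), 100.0) + rng.normal(0, 1.5, (40, 40))
        net = infer_intensity_at(img, (10, 10, 14, 14), ring=2)
        assert abs(net) < 40.0

    def test_box_outside_image_returns_none(self):
        img = np.zeros((20, 20))
        assert infer_intensity_at(img, (30, 30, 34, 34)) is None

    def test_recovers_known_spot_intensity(self):
        img = np.full((30, 30), 10.0)
        img[12:17, 12:17] += 40.0
        net = infer_intensity_at(img, (12, 12, 16, 16), ring=2)
        assert net == pytest.approx(25 * 40.0, rel=0.01)


def fret_movie(e_value, seed=5, n_frames=150, inactive=0.0, rate=200.0,
               switch=None):
    cfg = SimulationConfig(
        n_emitters_mean=8, fov_px=(64, 64), d_um2_s=(1.0,),
        frame_time_ms=30.0, n_frames=n_frames, seed=seed,
    )
    photo = PhotophysicsModel(
        photon_rate_per_ms=rate,
        e_states=tuple(e_value) if isinstance(e_value, (tuple, list))
        else (e_value,),
        switch_rates_per_s=tuple(switch) if switch else
        tuple(0.0 for _ in np.atleast_1d(e_value)),
        acceptor_inactive_fraction=inactive,
    )
    return simulate_movie(cfg, photophysics=photo)


def records_from_movie(movie, det=None, channel="donor"):
    det = det or DetectionConfig(smooth_sigma=1.0, min_snr=6.0)
    locs = detect_movie(movie, det)
    ch = locs[locs.channel == channel].reset_index(drop=True)
    res = iterate_linking(ch, 8.0,
                          LinkConfig(mad=8.0, max_gap=1, mode="greedy"))
    return make_fret_records(res.tracks, locs, movie)


class TestFretRecords:
    def test_donor_only_species_has_near_zero_estar(self):
        movie, _ = fret_movie(0.0)
        rec = records_from_movie(movie)
        assert len(rec) > 50
        assert np.median(rec.e_star) == pytest.approx(0.0, abs=0.06)

    def test_intermediate_fret_recovered(self):
        movie, _ = fret_movie(0.45)
        rec = records_from_movie(movie)
        assert len(rec) > 50
        assert rec.e_star.mean() == pytest.approx(0.45, abs=0.05)
        assert rec.e_star.std() <= 0.15

    def test_high_fret_recovered_tracking_either_channel(self):
        movie, _ = fret_movie(0.88)
        rec = records_from_movie(movie, channel="acceptor")
        assert len(rec) > 50
        assert rec.e_star.mean() == pytest.approx(0.88, abs=0.05)

    def test_inactive_acceptor_fraction_recovered(self):
        """Two-population decomposition finds the dark-acceptor share."""
        movie, _ = fret_movie(0.88, inactive=0.66, n_frames=260, seed=8)
        rec = records_from_movie(movie)
        fit = fit_two_gaussians(rec.e_star.to_numpy(), (0.02, 0.88))
        frac_dark = fit.areas[0] / sum(fit.areas)
        assert frac_dark == pytest.approx(0.66, abs=0.08)

    def test_acceptor_only_tracking_biases_estar_upward(self):
        """Red-channel tracking loses low-E* frames of an intermediate
        species, pushing the mean apparent efficiency up."""
        movie, _ = fret_movie(0.45, seed=12, rate=60.0)
        dual = records_from_movie(movie, channel="donor")
        red = records_from_movie(movie, channel="acceptor")
        assert red.e_star.mean() > dual.e_star.mean()


class TestPairing:
    def _tracks(self, pts, channel):
        df = pd.DataFrame(pts, columns=["track_id", "frame", "x_px", "y_px"])
        df["channel"] = channel
        return df

    def test_identical_trajectories_pair_fully(self):
        pts = [(0, f, 10.0 + f, 5.0) for f in range(5)]
        g = self._tracks(pts, "donor")
        r = self._tracks(pts, "acceptor")
        out = pair_dual_channel_tracks(g, r, ChannelRegistration())
        assert len(out) == 1
        assert out.iloc[0].n_overlap == 5

    def test_disjoint_tracks_do_not_pair(self):
        g = self._tracks([(0, f, 5.0, 5.0) for f in range(4)], "donor")
        r = self._tracks([(0, f, 50.0, 50.0) for f in range(4)], "acceptor")
        out = pair_dual_channel_tracks(g, r, ChannelRegistration())
        assert len(out) == 0

    def test_ambiguity_resolved_by_distance_then_overlap(self):
        g = self._tracks([(0, f, 10.0, 10.0) for f in range(6)], "donor")
        r = pd.concat([
            self._tracks([(0, f, 10.4, 10.0) for f in range(3)], "acceptor"),
            self._tracks([(1, f, 10.1, 10.0) for f in range(6)], "acceptor"),
        ])
        out = pair_dual_channel_tracks(g, r, ChannelRegistration(tolerance=2))
        assert len(out) == 1 and out.iloc[0].red_track_id == 1

    def test_registration_offset_is_applied(self):
        g = self._tracks([(0, f, 10.0, 10.0) for f in range(4)], "donor")
        r = self._tracks([(0, f, 13.0, 10.0) for f in range(4)], "acceptor")
        assert len(pair_dual_channel_tracks(
            g, r, ChannelRegistration(offset=(3.0, 0.0)))) == 1
        assert len(pair_dual_channel_tracks(
            g, r, ChannelRegistration(offset=(0.0, 0.0)))) == 0


class TestAlexFilter:
    def _track(self, frames):
        return pd.DataFrame({
            "track_id": 0, "frame": frames,
            "x_px": np.zeros(len(frames)), "y_px": np.zeros(len(frames)),
        })

    def test_three_localizations_rejected(self):
        labels = np.array(["D", "A"] * 10)
        out = alex_filter(self._track([0, 1, 2]), labels)
        assert not out.accepted

    def test_four_frame_dada_accepted(self):
        labels = np.array(["D", "A"] * 10)
        out = alex_filter(self._track([0, 1, 2, 3]), labels)
        assert out.accepted
        assert list(out.fret_frames) == [0, 2]

    def test_adad_start_also_accepted(self):
        labels = np.array(["D", "A"] * 10)
        out = alex_filter(self._track([1, 2, 3, 4]), labels)
        assert out.accepted
        assert list(out.fret_frames) == [2, 4]

    def test_five_localizations_rejected_as_odd(self):
        labels = np.array(["D", "A"] * 10)
        out = alex_filter(self._track([0, 1, 2, 3, 4]), labels)
        assert not out.accepted and out.reason == "odd count"

    def test_gapped_track_rejected(self):
        labels = np.array(["D", "A"] * 10)
        out = alex_filter(self._track([0, 1, 3, 4]), labels)
        assert not out.accepted

    def test_alex_reduces_donor_only_fraction(self):
        """ALEX acceptance removes dark-acceptor molecules."""
        cfg = SimulationConfig(
            n_emitters_mean=10, fov_px=(64, 64), d_um2_s=(0.8,),
            frame_time_ms=30.0, n_frames=200, seed=31,
        )
        photo = PhotophysicsModel(
            photon_rate_per_ms=200.0, e_states=(0.6,),
            acceptor_inactive_fraction=0.5,
        )
        movie, truth = simulate_movie(cfg, photophysics=photo,
                                      excitation="alex")
        locs = detect_movie(movie, DetectionConfig(smooth_sigma=1.0,
                                                   min_snr=6.0))
        from swifi.ratiometric import alex_localizations
        stream = alex_localizations(locs)
        res = iterate_linking(stream, 8.0,
                              LinkConfig(mad=8.0, max_gap=2, mode="greedy"))
        rec = make_fret_records(res.tracks, locs, movie)
        rec_d = rec[rec.excitation == "D"]
        unfiltered_dark = (rec_d.e_star < 0.3).mean()
        accepted = []
        for tid, g in res.tracks.groupby("track_id"):
            out = alex_filter(g, movie.excitation)
            if out.accepted:
                accepted.extend(
                    rec_d[(rec_d.track_id == tid)
                          & rec_d.frame.isin(out.fret_frames)].e_star
                )
        accepted = np.asarray(accepted)
        if len(accepted) < 10:
            pytest.skip("too few accepted ALEX tracks at this density")
        assert (accepted < 0.3).mean() < unfiltered_dark


class TestEDHistogram:
    def test_two_species_form_two_clusters(self):
        rng = np.random.default_rng(0)
        n = 400
        table = pd.DataFrame({
            "e_star": np.concatenate([rng.normal(0.9, 0.03, n),
                                      rng.normal(0.1, 0.03, n)]),
            "d_star": np.concatenate([rng.gamma(3, 2 / 3, n),
                                      rng.gamma(3, 20 / 3, n)]),
        })
        h = build_ed_histogram(table)
        assert h.counts.sum() == 2 * n == h.n_tracks
        # locate the two occupied modes
        ei, di = np.unravel_index(np.argmax(h.counts), h.counts.shape)
        e_mode = 0.5 * (h.e_edges[ei] + h.e_edges[ei + 1])
        assert e_mode < 0.3 or e_mode > 0.7
        low = h.counts[h.e_edges[:-1] < 0.5].sum()
        high = h.counts[h.e_edges[:-1] >= 0.5].sum()
        assert low == pytest.approx(n, abs=5)
        assert high == pytest.approx(n, abs=5)

    def test_single_species_is_unimodal_in_e(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "e_star": rng.normal(0.5, 0.05, 500),
            "d_star": rng.gamma(3, 5 / 3, 500),
        })
        h = build_ed_histogram(table)
        marg = h.e_marginal
        peak = marg.argmax()
        assert marg[peak] > 0
        assert abs(0.5 * (h.e_edges[peak] + h.e_edges[peak + 1]) - 0.5) < 0.1

    def test_empty_input_gives_zero_histogram(self):
        h = build_ed_histogram(pd.DataFrame({"e_star": [], "d_star": []}))
        assert h.counts.sum() == 0

    def test_tracks_missing_a_quantity_are_counted(self):
        table = pd.DataFrame({
            "e_star": [0.5, np.nan, 0.4],
            "d_star": [2.0, 3.0, np.nan],
        })
        h = build_ed_histogram(table)
        assert h.n_tracks == 1 and h.n_excluded == 2


class TestTwoGaussians:
    def test_recovers_known_mixture_ratio(self):
        rng = np.random.default_rng(3)
        lo = rng.normal(0.18, 0.07, 3700)
        hi = rng.normal(0.75, 0.09, 1000)
        fit = fit_two_gaussians(np.concatenate([lo, hi]), (0.18, 0.75))
        assert fit.area_ratio_low_high == pytest.approx(3.7, rel=0.1)
        assert fit.means[0] == pytest.approx(0.18, abs=0.02)
        assert fit.means[1] == pytest.approx(0.75, abs=0.02)

    def test_requires_enough_values(self):
        with pytest.raises(ValueError):
            fit_two_gaussians(np.zeros(10), (0.2, 0.8))


class TestPerTrackEstar:
    def _records(self):
        return pd.DataFrame({
            "track_id": [0, 0, 0, 1, 1],
            "frame": [0, 2, 4, 0, 2],
            "i_green": [100.0, 100.0, 300.0, 50.0, 50.0],
            "i_red": [100.0, 300.0, 100.0, 0.0, 50.0],
            "e_star": [0.5, 0.75, 0.25, 0.0, 0.5],
            "excitation": ["D"] * 5,
        })

    def test_unweighted_mean(self):
        out = per_track_estar(self._records())
        assert out.set_index("track_id").loc[0, "e_star"] == pytest.approx(0.5)
        assert out.set_index("track_id").loc[1, "e_star"] == pytest.approx(0.25)

    def test_intensity_weighted_mean(self):
        out = per_track_estar(self._records(), intensity_weighted=True)
        # track 0: weights 200, 400, 400 -> (0.5*200+0.75*400+0.25*400)/1000
        assert out.set_index("track_id").loc[0, "e_star"] == pytest.approx(0.5)
        # track 1: weights 50, 100 -> (0 + 0.5*100)/150
        assert out.set_index("track_id").loc[1, "e_star"] == pytest.approx(1/3)

    def test_clipping_is_optional(self):
        rec = self._records()
        rec.loc[0, "e_star"] = -0.2
        raw = per_track_estar(rec)
        clipped = per_track_estar(rec, clip=True)
        assert raw.e_star.iloc[0] < clipped.e_star.iloc[0]


def test_subtract_first_centroid_variant():
    """Background-subtracted weights remove the pedestal pull."""
    from swifi.detect import DetectionConfig, segment_frame
    img = np.full((21, 21), 50.0)
    img[10, 9] += 30.0
    img[10, 10] += 40.0
    raw = segment_frame(img, DetectionConfig(sensitivity=1.0))[0]
    sub = segment_frame(
        img, DetectionConfig(sensitivity=1.0, subtract_before_weighting=True)
    )[0]
    assert raw.area == sub.area == 2
    # signal-only weights (30, 40): x = (9*30 + 10*40)/70
    assert sub.centroid[0] == pytest.approx((9 * 30 + 10 * 40) / 70.0)
    # the 50-count pedestal drags the raw centroid toward the mask centre
    assert sub.centroid[0] > raw.centroid[0]


def test_per_axis_max_mad_option():
    from swifi.link import estimate_mad
    rng = np.random.default_rng(0)
    rows = []
    for t in range(100):
        x = np.cumsum(rng.normal(0, 1.0, 20))
        y = np.cumsum(rng.normal(0, 3.0, 20))
        rows.extend((t, f, x[f], y[f]) for f in range(20))
    tracks = pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px"])
    pooled = estimate_mad(tracks)
    axis_max = estimate_mad(tracks, per_axis_max=True)
    assert axis_max > pooled
    assert axis_max == pytest.approx(3 * 3.0, rel=0.05)
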