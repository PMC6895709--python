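"""Ratiometric (FRET / red-fraction) analysis along tracks.

The apparent FRET efficiency of a localization is the acceptor-channel
share of the total emitted intensity,

    E* = I_red / (I_red + I_green),

computed from background-subtracted net intensities.  The same ratio
serves as the "red fraction" for spectral classification of particles
such as nanodiamond NV centres.  When a molecule is detected in only
one channel, the registered position in the other channel is used to
measure the missing intensity directly from the image (the detected
blob's bounding box transferred through the channel registration).
Tracks found independently in the two channels can be paired into one
molecule record, ALEX tracks are filtered by the even->=4 alternation
rule, and per-track mean E* pairs with per-track D* in bivariate
histograms that separate species by structure and mobility at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Blob, local_background
from .movie import Movie

__all__ = [
    "ChannelRegistration",
    "alex_localizations",
    "estar",
    "infer_intensity_at",
    "make_fret_records",
    "pair_dual_channel_tracks",
    "alex_filter",
    "AlexTrack",
    "build_ed_histogram",
    "EDHistogram",
    "fit_two_gaussians",
    "TwoGaussianFit",
]


@dataclass
class ChannelRegistration:
    """Mapping between donor- and acceptor-channel pixel coordinates.

    The offset (dx, dy) maps donor coordinates to acceptor coordinates;
    ``tolerance`` is the pairing radius for deciding that localizations
    in the two channels belong to the same molecule.
    """

    offset: tuple[float, float] = (0.0, 0.0)
    tolerance: float = 2.0

    def donor_to_acceptor(self, x, y):
        return x + self.offset[0], y + self.offset[1]

    def acceptor_to_donor(self, x, y):
        return x - self.offset[0], y - self.offset[1]

    def map(self, x, y, from_channel: str):
        if from_channel == "donor":
            return self.donor_to_acceptor(x, y)
        if from_channel == "acceptor":
            return self.acceptor_to_donor(x, y)
        raise ValueError(f"unknown channel {from_channel!r}")


def estar(i_red, i_green):
    """Apparent FRET efficiency / red fraction.

    E* = I_red / (I_red + I_green).  Returns NaN where the denominator
    is zero (undefined records; callers count and exclude them).  Values
    outside [0, 1] are legitimate consequences of background-subtracted
    noise and are not clipped.
    """
    i_red = np.asarray(i_red, dtype=float)
    i_green = np.asarray(i_green, dtype=float)
    total = i_red + i_green
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total != 0, i_red / total, np.nan)
    return out if out.ndim else float(out)


def alex_localizations(
    locs: pd.DataFrame,
    registration: ChannelRegistration | None = None,
) -> pd.DataFrame:
    """One localization stream for tracking under alternating excitation.

    Under ALEX a molecule is seen in the donor channel on donor-
    excitation frames and in the acceptor channel on acceptor-excitation
    frames, so neither channel alone yields consecutive-frame steps.
    This combines the two: donor-channel spots from "D" frames plus
    acceptor-channel spots from "A" frames, with the acceptor-channel
    coordinates mapped into the donor pixel frame through the
    registration.  The original ``channel`` labels are kept so intensity
    bookkeeping downstream still knows where each spot was measured.
    """
    registration = registration or ChannelRegistration()
    d = locs[(locs.channel == "donor") & (locs.excitation == "D")]
    a = locs[(locs.channel == "acceptor") & (locs.excitation == "A")].copy()
    if len(a):
        ax, ay = registration.acceptor_to_donor(
            a["x_px"].to_numpy(float), a["y_px"].to_numpy(float)
        )
        a["x_px"], a["y_px"] = ax, ay
    return pd.concat([d, a], ignore_index=True).sort_values(
        "frame", kind="stable"
    ).reset_index(drop=True)


def infer_intensity_at(
    image: np.ndarray,
    bbox: tuple[int, int, int, int],
    ring: int = 2,
) -> float | None:
    """Background-subtracted intensity in a transferred bounding box.

    ``bbox`` is (min_row, min_col, max_row, max_col), inclusive, already
    mapped into this channel's pixel frame.  Returns None when the box
    falls outside the image.
    """
    r0, c0, r1, c1 = (int(round(v)) for v in bbox)
    ny, nx = image.shape
    if r1 < 0 or c1 < 0 or r0 >= ny or c0 >= nx:
        return None
    r0c, r1c = max(r0, 0), min(r1, ny - 1)
    c0c, c1c = max(c0, 0), min(c1, nx - 1)
    area = (r1c - r0c + 1) * (c1c - c0c + 1)
    probe = Blob(
        frame=-1, channel="", coords=np.empty((0, 2), int),
        bbox=(r0c, c0c, r1c, c1c), area=area, raw_sum=0.0,
    )
    bg = local_background(image, probe, ring=ring)
    raw = float(image[r0c:r1c + 1, c0c:c1c + 1].sum())
    return raw - area * bg


def make_fret_records(
    tracks: pd.DataFrame,
    locs: pd.DataFrame,
    movie: Movie,
    registration: ChannelRegistration | None = None,
    ring: int = 2,
) -> pd.DataFrame:
    """Per-frame (I_green, I_red, E*) records for a set of tracks.

    ``tracks`` is a linked localization table (one channel of origin per
    row, from either channel); ``locs`` is the full localization table
    of both channels.  For each track point, the intensity in the other
    channel is taken from the nearest same-frame localization within
    the registration tolerance; when none exists it is inferred from
    the other channel's image at the registered position.  Rows whose
    mapped box leaves the image, or whose total intensity is zero, are
    dropped and counted in the ``dropped_*`` attrs of the result.
    """
    registration = registration or ChannelRegistration(
        offset=movie.layout.channel_offset
    )
    other_of = {"donor": "acceptor", "acceptor": "donor"}
    stacks = {ch: movie.channel(ch) for ch in ("donor", "acceptor")}

    loc_index: dict[tuple[int, str], np.ndarray] = {
        (int(f), str(ch)): idx
        for (f, ch), idx in locs.groupby(["frame", "channel"]).indices.items()
    }
    lx = locs["x_px"].to_numpy(float)
    ly = locs["y_px"].to_numpy(float)
    li = locs["intensity"].to_numpy(float)

    rows = []
    dropped_outside = 0
    dropped_zero = 0
    for r in tracks.itertuples():
        ch = r.channel
        other = other_of[ch]
        mx, my = registration.map(r.x_px, r.y_px, from_channel=ch)
        # nearest other-channel localization within tolerance
        cand = loc_index.get((int(r.frame), other))
        partner = None
        if cand is not None and len(cand):
            d = np.hypot(lx[cand] - mx, ly[cand] - my)
            k = int(np.argmin(d))
            if d[k] <= registration.tolerance:
                partner = cand[k]
        inferred = False
        if partner is not None:
            i_other = li[partner]
        else:
            dx = mx - r.x_px
            dy = my - r.y_px
            bbox = (
                r.min_row + dy, r.min_col + dx,
                r.max_row + dy, r.max_col + dx,
            )
            i_other = infer_intensity_at(
                stacks[other][int(r.frame)].astype(float), bbox, ring=ring
            )
            inferred = True
            if i_other is None:
                dropped_outside += 1
                continue
        i_self = float(r.intensity)
        i_green = i_self if ch == "donor" else i_other
        i_red = i_other if ch == "donor" else i_self
        e = estar(i_red, i_green)
        if np.isnan(e):
            dropped_zero += 1
            continue
        rows.append((
            r.track_id, int(r.frame), i_green, i_red, e,
            str(r.excitation), inferred,
        ))
    out = pd.DataFrame(
        rows,
        columns=[
            "track_id", "frame", "i_green", "i_red", "e_star",
            "excitation", "inferred",
        ],
    )
    out.attrs["dropped_outside"] = dropped_outside
    out.attrs["dropped_zero_total"] = dropped_zero
    return out


def dual_channel_records(
    tracks_green: pd.DataFrame,
    tracks_red: pd.DataFrame,
    locs: pd.DataFrame,
    movie: Movie,
    registration: ChannelRegistration | None = None,
    ring: int = 2,
) -> pd.DataFrame:
    """E* records from tracks of either channel, without double counting.

    Molecules are tracked independently in the two channels (a molecule
    whose current FRET state darkens one channel stays trackable in the
    other).  Tracks that coincide through the registration are paired
    into one molecule; for a pair, the green track's frames are used and
    the red track contributes only frames the green track misses.
    Unpaired tracks contribute all their frames.  ``track_id`` in the
    result is re-keyed as ``g<id>``/``r<id>`` molecule labels, with
    paired red tracks mapped onto their green mate's label.
    """
    registration = registration or ChannelRegistration(
        offset=movie.layout.channel_offset
    )
    rec_g = make_fret_records(tracks_green, locs, movie, registration, ring)
    rec_r = make_fret_records(tracks_red, locs, movie, registration, ring)
    pairs = pair_dual_channel_tracks(tracks_green, tracks_red, registration)
    red_mate = dict(zip(pairs["red_track_id"], pairs["green_track_id"]))

    rec_g = rec_g.copy()
    rec_g["molecule"] = "g" + rec_g["track_id"].astype(str)
    keep_rows = []
    green_frames = {
        tid: set(g["frame"]) for tid, g in rec_g.groupby("track_id")
    }
    for r in rec_r.itertuples(index=False):
        mate = red_mate.get(r.track_id)
        if mate is not None and r.frame in green_frames.get(mate, set()):
            continue  # frame already covered by the green mate
        keep_rows.append(r._asdict() | {
            "molecule": f"g{mate}" if mate is not None else f"r{r.track_id}"
        })
    rec_r2 = pd.DataFrame(keep_rows, columns=list(rec_r.columns) + ["molecule"])
    out = pd.concat([rec_g, rec_r2], ignore_index=True)
    return out.sort_values(["molecule", "frame"], kind="stable").reset_index(
        drop=True
    )


def per_track_estar(
    records: pd.DataFrame,
    intensity_weighted: bool = False,
    clip: bool = False,
    donor_excitation_only: bool = True,
    group_col: str = "track_id",
) -> pd.DataFrame:
    """Per-track mean ratiometric value from per-frame records.

    The default is the unweighted mean of per-frame E* over
    donor-excitation frames; ``intensity_weighted`` weights each frame
    by its total intensity instead.  ``clip`` restricts values to
    [0, 1] (a display convention; the unclipped default is unbiased for
    histogramming).
    """
    work = records
    if donor_excitation_only and "excitation" in records:
        work = records[records["excitation"] == "D"]
    rows = []
    for tid, g in work.groupby(group_col):
        e = g["e_star"].to_numpy(float)
        if clip:
            e = np.clip(e, 0.0, 1.0)
        if intensity_weighted:
            w = np.clip(
                g["i_green"].to_numpy(float) + g["i_red"].to_numpy(float),
                0.0, None,
            )
            mean = float((w * e).sum() / w.sum()) if w.sum() > 0 \
                else float(np.mean(e))
        else:
            mean = float(np.mean(e))
        rows.append((tid, len(g), mean))
    return pd.DataFrame(rows, columns=[group_col, "n_frames", "e_star"])


def pair_dual_channel_tracks(
    tracks_green: pd.DataFrame,
    tracks_red: pd.DataFrame,
    registration: ChannelRegistration,
    tolerance: float | None = None,
) -> pd.DataFrame:
    """Pair tracks found independently in the two channels.

    Two tracks are candidate mates when they overlap in time and their
    registered positions coincide (mean distance over the overlapping
    frames <= tolerance).  Many-to-many ambiguities resolve by smallest
    mean distance, ties by longer overlap.  Returns a table with one
    row per pairing (green track id, red track id, overlap, distance);
    unpaired tracks simply do not appear.
    """
    tol = registration.tolerance if tolerance is None else tolerance
    cands = []
    red_by_id = {
        tid: g.set_index("frame") for tid, g in tracks_red.groupby("track_id")
    }
    for gid, g in tracks_green.groupby("track_id"):
        gf = g.set_index("frame")
        gx, gy = registration.donor_to_acceptor(
            gf["x_px"].to_numpy(float), gf["y_px"].to_numpy(float)
        )
        gframes = gf.index.to_numpy()
        for rid, rf in red_by_id.items():
            common = np.intersect1d(gframes, rf.index.to_numpy())
            if len(common) == 0:
                continue
            sel = np.isin(gframes, common)
            d = np.hypot(
                gx[sel] - rf.loc[common, "x_px"].to_numpy(float),
                gy[sel] - rf.loc[common, "y_px"].to_numpy(float),
            ).mean()
            if d <= tol:
                cands.append((gid, rid, len(common), float(d)))
    cands.sort(key=lambda c: (c[3], -c[2]))
    used_g, used_r, rows = set(), set(), []
    for gid, rid, n, d in cands:
        if gid in used_g or rid in used_r:
            continue
        used_g.add(gid)
        used_r.add(rid)
        rows.append((gid, rid, n, d))
    return pd.DataFrame(
        rows, columns=["green_track_id", "red_track_id", "n_overlap",
                       "mean_distance"]
    )


@dataclass
class AlexTrack:
    """ALEX acceptance decision for one track."""

    track_id: int
    accepted: bool
    n_localizations: int
    fret_frames: np.ndarray      # donor-excitation frames usable for E*
    reason: str = ""


def alex_filter(
    track: pd.DataFrame, excitation: np.ndarray
) -> AlexTrack:
    """Accept a track for ALEX FRET analysis.

    Accepted tracks have an even number >= 4 of localizations in
    strictly consecutive frames, so the excitation labels alternate as
    DADA... or ADAD...  E* is later computed only from the
    donor-excitation frames of accepted tracks; the acceptor-excitation
    frames certify that the acceptor is active.
    """
    g = track.sort_values("frame")
    f = g["frame"].to_numpy(int)
    tid = int(g["track_id"].iloc[0]) if "track_id" in g else -1
    n = len(f)
    labels = np.asarray(excitation)
    if n < 4:
        return AlexTrack(tid, False, n, np.empty(0, int), "fewer than 4")
    if n % 2:
        return AlexTrack(tid, False, n, np.empty(0, int), "odd count")
    if np.any(np.diff(f) != 1):
        return AlexTrack(tid, False, n, np.empty(0, int), "gapped track")
    lab = labels[f]
    if np.any(lab[:-1] == lab[1:]):
        return AlexTrack(tid, False, n, np.empty(0, int),
                         "excitation does not alternate")
    fret_frames = f[lab == "D"]
    return AlexTrack(tid, True, n, fret_frames)


@dataclass
class EDHistogram:
    """2D histogram of per-track ratiometric value vs diffusion."""

    counts: np.ndarray
    e_edges: np.ndarray
    d_edges: np.ndarray
    e_marginal: np.ndarray
    d_marginal: np.ndarray
    n_tracks: int
    n_excluded: int


def build_ed_histogram(
    table: pd.DataFrame,
    e_col: str = "e_star",
    d_col: str = "d_star",
    e_range: tuple[float, float] = (-0.1, 1.1),
    e_bins: int = 50,
    d_range: tuple[float, float] | None = None,
    d_bins: int = 50,
) -> EDHistogram:
    """Bin per-track (mean E*, D*) pairs on an E x log-D grid.

    Tracks missing either quantity are excluded and counted.  The D
    axis is log-spaced over ``d_range`` (default: data range padded by
    one decade tenth).
    """
    e = table[e_col].to_numpy(float) if len(table) else np.empty(0)
    d = table[d_col].to_numpy(float) if len(table) else np.empty(0)
    ok = np.isfinite(e) & np.isfinite(d) & (d > 0)
    n_excluded = int(len(e) - ok.sum())
    e, d = e[ok], d[ok]
    e_edges = np.linspace(*e_range, e_bins + 1)
    if d_range is None:
        if len(d):
            lo, hi = np.log10(d.min()), np.log10(d.max())
            pad = 0.1 * max(hi - lo, 1.0)
            d_range = (10 ** (lo - pad), 10 ** (hi + pad))
        else:
            d_range = (1e-2, 1e3)
    d_edges = np.logspace(np.log10(d_range[0]), np.log10(d_range[1]),
                          d_bins + 1)
    counts, _, _ = np.histogram2d(e, d, bins=[e_edges, d_edges])
    return EDHistogram(
        counts=counts, e_edges=e_edges, d_edges=d_edges,
        e_marginal=counts.sum(axis=1), d_marginal=counts.sum(axis=0),
        n_tracks=int(ok.sum()), n_excluded=n_excluded,
    )


@dataclass
class TwoGaussianFit:
    """Two-Gaussian decomposition of an E* histogram."""

    means: tuple[float, float]         # (low, high)
    sigmas: tuple[float, float]
    areas: tuple[float, float]
    area_ratio_low_high: float
    success: bool
    redchi: float

    def summary(self) -> str:
        return (
            f"two-Gaussian E* decomposition: "
            f"low {self.means[0]:.3f} (sd {self.sigmas[0]:.3f}, "
            f"area {self.areas[0]:.3g}); "
            f"high {self.means[1]:.3f} (sd {self.sigmas[1]:.3f}, "
            f"area {self.areas[1]:.3g}); "
            f"low/high = {self.area_ratio_low_high:.3g}"
        )


def fit_two_gaussians(
    values: np.ndarray,
    init_means: tuple[float, float],
    bins: int = 60,
    hist_range: tuple[float, float] = (-0.2, 1.2),
    init_sigma: float = 0.08,
    max_sigma: float = 0.5,
) -> TwoGaussianFit:
    """Decompose a ratiometric histogram into two Gaussian populations.

    Fits the binned counts with a sum of two Gaussians (nonlinear least
    squares) and reports the area ratio of the lower-mean to the
    higher-mean component, which estimates the population (occupancy)
    ratio of the two states.
    """
    from lmfit.models import GaussianModel

    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 50:
        raise ValueError("need at least 50 values for a stable decomposition")
    counts, edges = np.histogram(values, bins=bins, range=hist_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bw = edges[1] - edges[0]

    m1, m2 = sorted(init_means)
    g1, g2 = GaussianModel(prefix="g1_"), GaussianModel(prefix="g2_")
    model = g1 + g2
    params = model.make_params()
    span = (m2 - m1) / 2.0
    for pfx, mu in (("g1_", m1), ("g2_", m2)):
        sel = np.abs(centers - mu) < max(2 * init_sigma, bw)
        amp = max(counts[sel].sum() * bw, bw)
        params[f"{pfx}center"].set(value=mu, min=mu - span, max=mu + span)
        params[f"{pfx}sigma"].set(value=init_sigma, min=bw / 4, max=max_sigma)
        params[f"{pfx}amplitude"].set(value=float(amp), min=0)
    out = model.fit(counts, params, x=centers)

    comps = []
    for pfx in ("g1_", "g2_"):
        comps.append((
            float(out.params[f"{pfx}center"].value),
            float(out.params[f"{pfx}sigma"].value),
            float(out.params[f"{pfx}amplitude"].value),  # area (lmfit norm)
        ))
    comps.sort(key=lambda c: c[0])
    (mu_lo, sd_lo, a_lo), (mu_hi, sd_hi, a_hi) = comps
    ratio = a_lo / a_hi if a_hi > 0 else np.inf
    return TwoGaussianFit(
        means=(mu_lo, mu_hi), sigmas=(sd_lo, sd_hi), areas=(a_lo, a_hi),
        area_ratio_low_high=float(ratio), success=bool(out.success),
        redchi=float(out.redchi),
    )
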