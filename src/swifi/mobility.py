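"""Diffusion statistics: MSD curves, ensemble fits, radii, mixtures.

Per-track apparent diffusion coefficients follow directly from the
first-lag mean-square displacement, <dr^2> = 4 D dt for 2D steps.  The
ensemble estimate averages per-track per-axis MSD curves

    p(n) = 1/(N-n+1) * sum_k (X_{k+n} - X_k)^2

over tracks and fits a straight line whose slope gives D; the intercept
absorbs localization error and motion blur,

    P(n) = 2 D n dt + sigma^2 - (4/6) D dt

(a ``standard`` offset convention with a 2 sigma^2 localization term,
the per-axis camera-integration result, is available as an option; the
blur term -(2/3) D dt is common to both).  Diffusion coefficients convert to hydrodynamic radii
through the Stokes-Einstein relation D = kB T / (6 pi eta Rh), with the
solvent viscosity of water/glycerol mixtures from an empirical
correlation.  Populations of per-track coefficients are modelled by the
single-species density

    f_D(x) = 1/2 (3/D)^3 x^2 exp(-3x/D)

(a gamma density with shape 3 and scale D/3) and by a two-species
mixture of the same form, fitted by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

__all__ = [
    "per_track_msd",
    "per_track_D",
    "per_track_table",
    "ensemble_msd",
    "EnsembleMsd",
    "glycerol_viscosity",
    "stokes_einstein_radius",
    "stokes_einstein_d",
    "pdf_single",
    "pdf_two",
    "sample_single",
    "sample_two",
    "fit_single",
    "fit_two",
    "DistributionFit",
]

KB = 1.380649e-23  # J/K
GLYCEROL_DENSITY = 1.261  # g/mL at 20 C
WATER_DENSITY = 0.997     # g/mL at 20 C


# ---------------------------------------------------------------------------
# MSD estimators
# ---------------------------------------------------------------------------

def per_track_msd(
    frames: np.ndarray, values: np.ndarray, max_lag: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping-window MSD of one coordinate axis of one track.

    Returns (lags, msd); lag n uses every pair of positions exactly n
    frames apart, so gapped tracks contribute what they can and a lag
    with no pairs is omitted.  For a contiguous track this is exactly
    the 1/(N-n+1) overlapping average.
    """
    frames = np.asarray(frames, dtype=int)
    values = np.asarray(values, dtype=float)
    if len(frames) != len(values):
        raise ValueError("frames and values must align")
    order = np.argsort(frames)
    frames, values = frames[order], values[order]
    n_max = int(frames.max() - frames.min()) if len(frames) else 0
    if max_lag is not None:
        n_max = min(n_max, max_lag)
    lags, msd = [], []
    ptr = {int(f): v for f, v in zip(frames, values)}
    for n in range(1, n_max + 1):
        # pairs (i, j) with frame difference exactly n
        sq = [
            (ptr[f + n] - ptr[f]) ** 2 for f in frames if f + n in ptr
        ]
        if sq:
            lags.append(n)
            msd.append(float(np.mean(sq)))
    return np.asarray(lags), np.asarray(msd)


def per_track_D(
    track: pd.DataFrame, frame_time_s: float, pixel_size_um: float
) -> float:
    """Apparent D of one track from <dr^2> = 4 D dt (consecutive steps).

    Only consecutive-frame steps enter; returns NaN when a gapped track
    has none.
    """
    g = track.sort_values("frame")
    f = g["frame"].to_numpy(int)
    x = g["x_px"].to_numpy(float) * pixel_size_um
    y = g["y_px"].to_numpy(float) * pixel_size_um
    sel = np.nonzero(np.diff(f) == 1)[0]
    if len(sel) == 0:
        return float("nan")
    dr2 = (x[sel + 1] - x[sel]) ** 2 + (y[sel + 1] - y[sel]) ** 2
    return float(dr2.mean() / (4.0 * frame_time_s))


def per_track_table(
    tracks: pd.DataFrame, frame_time_s: float, pixel_size_um: float
) -> pd.DataFrame:
    """Per-track summary: number of steps and apparent D (um^2/s)."""
    rows = []
    for tid, g in tracks.groupby("track_id"):
        d = per_track_D(g, frame_time_s, pixel_size_um)
        rows.append((tid, len(g) - 1, d))
    return pd.DataFrame(rows, columns=["track_id", "n_steps", "d_star"])


@dataclass
class EnsembleMsd:
    """Ensemble MSD curves and the linear-fit diffusion estimate."""

    lags: np.ndarray
    p_x: np.ndarray            # um^2
    p_y: np.ndarray
    m_x: np.ndarray            # contributing track count per lag
    m_y: np.ndarray
    frame_time_s: float
    fit_lags: tuple[int, ...]
    slope_x: float             # um^2 / frame
    slope_y: float
    intercept_x: float
    intercept_y: float
    d_x: float                 # um^2/s
    d_y: float
    d: float
    sigma_um: float            # localization accuracy from the intercept
    drift_flag: bool
    offset_model: str

    def summary(self) -> str:
        lines = [
            "Ensemble MSD fit",
            f"  lags used        : {list(self.fit_lags)}",
            f"  D (x, y)         : {self.d_x:.4g}, {self.d_y:.4g} um^2/s",
            f"  D (mean)         : {self.d:.4g} um^2/s",
            f"  sigma (loc.)     : {self.sigma_um * 1000:.1f} nm"
            f" [{self.offset_model} offset model]",
            f"  drift flag       : {self.drift_flag}",
        ]
        return "\n".join(lines)


def ensemble_msd(
    tracks: pd.DataFrame,
    frame_time_s: float,
    pixel_size_um: float,
    fit_lags: tuple[int, ...] = (1, 2, 3, 4),
    offset_model: str = "printed",
    drift_fraction: float = 0.25,
    auto_lags: bool = False,
    max_lag: int | None = None,
) -> EnsembleMsd:
    """Ensemble MSD per axis and the linear-fit diffusion coefficient.

    P(n) is the unweighted mean of the per-track p(n) over every track
    for which that lag exists.  A straight line is fitted over
    ``fit_lags`` (at least three points); D = slope / (2 dt) per axis
    and the reported D is the mean of the axes.  ``drift_flag`` is set
    when the axis slopes disagree by more than ``drift_fraction`` of
    their mean.  With ``auto_lags`` the contiguous >= 3-lag window with
    the best pooled linear-fit R^2 is chosen instead.

    ``offset_model`` controls how the intercept is converted into a
    localization-accuracy estimate: "printed" uses
    intercept = sigma^2 - (4/6) D dt, "standard" uses
    intercept = 2 sigma^2 - (4/3) D dt.
    """
    if offset_model not in ("printed", "standard"):
        raise ValueError("offset_model must be 'printed' or 'standard'")
    if len(fit_lags) < 3:
        raise ValueError("at least three lag points are required")
    need = max(fit_lags) if max_lag is None else max(max(fit_lags), max_lag)

    curves: dict[str, dict[int, list[float]]] = {
        "x": {}, "y": {},
    }
    for _, g in tracks.groupby("track_id"):
        f = g["frame"].to_numpy(int)
        for axis, col in (("x", "x_px"), ("y", "y_px")):
            lags, msd = per_track_msd(
                f, g[col].to_numpy(float) * pixel_size_um, max_lag=need
            )
            for n, v in zip(lags, msd):
                curves[axis].setdefault(int(n), []).append(v)

    all_lags = sorted(set(curves["x"]) | set(curves["y"]))
    if not all_lags:
        raise ValueError("no usable MSD lags in the track set")
    lag_arr = np.asarray(all_lags)
    p = {a: np.array([np.mean(curves[a].get(n, [np.nan])) for n in all_lags])
         for a in ("x", "y")}
    m = {a: np.array([len(curves[a].get(n, [])) for n in all_lags])
         for a in ("x", "y")}

    def _window_ok(ls: tuple[int, ...]) -> bool:
        return all(
            n in curves["x"] and n in curves["y"] for n in ls
        )

    if auto_lags:
        best, best_r2 = None, -np.inf
        usable = [n for n in all_lags if m["x"][all_lags.index(n)] > 0]
        for w in range(3, len(usable) + 1):
            for s in range(0, len(usable) - w + 1):
                ls = tuple(usable[s:s + w])
                if ls != tuple(range(ls[0], ls[-1] + 1)):
                    continue
                r2 = _pooled_r2(ls, curves)
                if r2 > best_r2:
                    best, best_r2 = ls, r2
        if best is not None:
            fit_lags = best
    if not _window_ok(tuple(fit_lags)):
        raise ValueError(
            f"fit lags {fit_lags} not all present in the ensemble curves"
        )

    sel = np.isin(lag_arr, np.asarray(fit_lags))
    fits = {}
    for a in ("x", "y"):
        slope, intercept = np.polyfit(lag_arr[sel], p[a][sel], 1)
        fits[a] = (float(slope), float(intercept))
    dt = frame_time_s
    d_x = fits["x"][0] / (2.0 * dt)
    d_y = fits["y"][0] / (2.0 * dt)
    d_mean = 0.5 * (d_x + d_y)
    mean_slope = 0.5 * (fits["x"][0] + fits["y"][0])
    drift = (
        abs(fits["x"][0] - fits["y"][0]) > drift_fraction * abs(mean_slope)
        if mean_slope != 0 else False
    )
    intercept = 0.5 * (fits["x"][1] + fits["y"][1])
    # full-frame motion blur shifts the per-axis intercept by -(2/3) D dt
    # (equivalently -(1/3) * 2 D dt); the two models differ only in the
    # coefficient of the localization-error term (sigma^2 vs 2 sigma^2)
    blur = (2.0 / 3.0) * d_mean * dt
    if offset_model == "printed":
        sig2 = intercept + blur
    else:
        sig2 = (intercept + blur) / 2.0
    sigma = float(np.sqrt(sig2)) if sig2 > 0 else 0.0

    return EnsembleMsd(
        lags=lag_arr, p_x=p["x"], p_y=p["y"], m_x=m["x"], m_y=m["y"],
        frame_time_s=dt, fit_lags=tuple(int(n) for n in fit_lags),
        slope_x=fits["x"][0], slope_y=fits["y"][0],
        intercept_x=fits["x"][1], intercept_y=fits["y"][1],
        d_x=d_x, d_y=d_y, d=d_mean, sigma_um=sigma,
        drift_flag=bool(drift), offset_model=offset_model,
    )


def _pooled_r2(lags: tuple[int, ...], curves) -> float:
    xs, ys = [], []
    for a in ("x", "y"):
        for n in lags:
            if n in curves[a]:
                xs.append(n)
                ys.append(np.mean(curves[a][n]))
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if len(xs) < 3:
        return -np.inf
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    if ss_tot == 0:
        return -np.inf
    return 1.0 - (resid ** 2).sum() / ss_tot


# ---------------------------------------------------------------------------
# Viscosity and Stokes-Einstein
# ---------------------------------------------------------------------------

def volume_to_mass_fraction(fraction_vv: float) -> float:
    """Glycerol v/v fraction to mass fraction (20 C densities)."""
    g = fraction_vv * GLYCEROL_DENSITY
    return g / (g + (1.0 - fraction_vv) * WATER_DENSITY)


def glycerol_viscosity(fraction_vv: float, temperature_c: float) -> float:
    """Viscosity (Pa s) of a water/glycerol mixture.

    Uses the exponential mixing rule of the Cheng correlation: the
    mixture viscosity is mu_w^alpha * mu_g^(1-alpha) with a
    concentration- and temperature-dependent weighting alpha, and
    temperature-dependent pure-component viscosities.  Valid for
    0-100 C and the full composition range.
    """
    if not 0.0 <= fraction_vv <= 1.0:
        raise ValueError("glycerol fraction must be in [0, 1]")
    if not 0.0 <= temperature_c <= 100.0:
        raise ValueError("temperature must be within 0-100 C")
    t = temperature_c
    cm = volume_to_mass_fraction(fraction_vv)
    mu_w = 1.790 * np.exp((-1230.0 - t) * t / (36100.0 + 360.0 * t))   # cP
    mu_g = 12100.0 * np.exp((-1233.0 + t) * t / (9900.0 + 70.0 * t))   # cP
    a = 0.705 - 0.0017 * t
    b = (4.9 + 0.036 * t) * a ** 2.5
    alpha = 1.0 - cm + a * b * cm * (1.0 - cm) / (a * cm + b * (1.0 - cm))
    mu = mu_w ** alpha * mu_g ** (1.0 - alpha)
    return float(mu * 1e-3)  # Pa s


def stokes_einstein_radius(
    d_um2_s: float, temperature_k: float, eta_pa_s: float
) -> float:
    """Hydrodynamic radius (nm) from D (um^2/s) via Stokes-Einstein."""
    if d_um2_s <= 0 or temperature_k <= 0 or eta_pa_s <= 0:
        raise ValueError("all Stokes-Einstein arguments must be positive")
    d = d_um2_s * 1e-12  # m^2/s
    rh_m = KB * temperature_k / (6.0 * np.pi * eta_pa_s * d)
    return float(rh_m * 1e9)


def stokes_einstein_d(
    rh_nm: float, temperature_k: float, eta_pa_s: float
) -> float:
    """Diffusion coefficient (um^2/s) of a sphere of radius rh (nm)."""
    if rh_nm <= 0 or temperature_k <= 0 or eta_pa_s <= 0:
        raise ValueError("all Stokes-Einstein arguments must be positive")
    d_m = KB * temperature_k / (6.0 * np.pi * eta_pa_s * rh_nm * 1e-9)
    return float(d_m * 1e12)


# ---------------------------------------------------------------------------
# Diffusion-coefficient distributions
# ---------------------------------------------------------------------------

def pdf_single(x, d: float):
    """Single-species density f_D(x) = 1/2 (3/D)^3 x^2 exp(-3x/D)."""
    if d <= 0:
        raise ValueError("D must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0, 0.5 * (3.0 / d) ** 3 * x ** 2 * np.exp(-3.0 * x / d), 0.0
    )
    return out if out.ndim else float(out)


def pdf_two(x, a: float, d1: float, d2: float):
    """Two-species mixture of the single-species form (weight a on D1)."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("mixture weight a must be in [0, 1]")
    return a * pdf_single(x, d1) + (1.0 - a) * pdf_single(x, d2)


def sample_single(n: int, d: float, rng: np.random.Generator) -> np.ndarray:
    """Draw apparent-D samples from the single-species density."""
    return rng.gamma(shape=3.0, scale=d / 3.0, size=n)


def sample_two(
    n: int, a: float, d1: float, d2: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw from the two-species mixture (weight a on species D1)."""
    comp = rng.random(n) < a
    out = np.empty(n)
    out[comp] = rng.gamma(3.0, d1 / 3.0, size=int(comp.sum()))
    out[~comp] = rng.gamma(3.0, d2 / 3.0, size=int((~comp).sum()))
    return out


@dataclass
class DistributionFit:
    """Maximum-likelihood fit of a diffusion-coefficient distribution."""

    model: str                      # "single" or "two_species"
    params: dict
    log_likelihood: float
    n_samples: int
    n_excluded: int
    conf_int: dict = field(default_factory=dict)
    success: bool = True
    message: str = ""

    def summary(self) -> str:
        lines = [f"{self.model} diffusion-distribution fit "
                 f"(n={self.n_samples}, excluded={self.n_excluded})"]
        for k, v in self.params.items():
            ci = self.conf_int.get(k)
            tail = f"  CI95 [{ci[0]:.4g}, {ci[1]:.4g}]" if ci else ""
            lines.append(f"  {k:10s}= {v:.4g}{tail}")
        lines.append(f"  log L     = {self.log_likelihood:.4g}")
        return "\n".join(lines)


def _clean_samples(samples) -> tuple[np.ndarray, int]:
    s = np.asarray(samples, dtype=float)
    good = s[np.isfinite(s) & (s > 0)]
    return good, int(len(s) - len(good))


def fit_single(samples, min_samples: int = 50) -> DistributionFit:
    """MLE of the single-species density on per-track D samples.

    With the gamma shape fixed at 3 the scale MLE is the sample mean
    divided by 3, so D-hat is simply the sample mean; the CI comes from
    the exact variance D^2/(3n) of that estimator.
    """
    s, excluded = _clean_samples(samples)
    if len(s) < min_samples:
        raise ValueError(
            f"need at least {min_samples} positive samples, got {len(s)}"
        )
    d_hat = float(s.mean())
    ll = float(np.log(pdf_single(s, d_hat)).sum())
    se = d_hat / np.sqrt(3.0 * len(s))
    return DistributionFit(
        model="single",
        params={"D": d_hat},
        log_likelihood=ll,
        n_samples=len(s),
        n_excluded=excluded,
        conf_int={"D": (d_hat - 1.96 * se, d_hat + 1.96 * se)},
    )


def fit_two(
    samples,
    d2_fixed: float,
    min_samples: int = 50,
    profile_ci: bool = True,
) -> DistributionFit:
    """MLE of the two-species mixture with D2 held fixed.

    Optimizes (a, D1) by L-BFGS-B from several starts; the confidence
    interval for the bound fraction a comes from the profile likelihood
    (chi-square cutoff at 3.84).
    """
    if d2_fixed <= 0:
        raise ValueError("fixed D2 must be positive")
    s, excluded = _clean_samples(samples)
    if len(s) < min_samples:
        raise ValueError(
            f"need at least {min_samples} positive samples, got {len(s)}"
        )

    def nll(theta):
        a, d1 = theta
        dens = pdf_two(s, a, d1, d2_fixed)
        if np.any(dens <= 0):
            return 1e12
        return -np.log(dens).sum()

    bounds = [(1e-6, 1.0 - 1e-6), (1e-3 * d2_fixed, 1e3 * d2_fixed)]
    q = np.quantile(s, [0.25, 0.5])
    starts = [
        (0.5, q[0]), (0.3, q[0]), (0.7, q[1]), (0.5, 0.4 * d2_fixed),
    ]
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    a_hat, d1_hat = map(float, best.x)
    ll = -float(best.fun)
    flat = not best.success and abs(best.fun) > 1e11

    ci = {}
    if profile_ci and not flat:
        def prof(a):
            r = minimize(
                lambda d1: nll((a, d1[0])), [d1_hat], method="L-BFGS-B",
                bounds=[bounds[1]],
            )
            return -r.fun

        target = ll - 1.92  # chi2(1)/2 at 95%
        lo, hi = 1e-6, 1.0 - 1e-6

        def g(a):
            return prof(a) - target

        try:
            a_lo = brentq(g, lo, a_hat) if g(lo) < 0 else lo
        except ValueError:
            a_lo = lo
        try:
            a_hi = brentq(g, a_hat, hi) if g(hi) < 0 else hi
        except ValueError:
            a_hi = hi
        ci["a"] = (float(a_lo), float(a_hi))

    return DistributionFit(
        model="two_species",
        params={"a": a_hat, "D1": d1_hat, "D2": float(d2_fixed)},
        log_likelihood=ll,
        n_samples=len(s),
        n_excluded=excluded,
        conf_int=ci,
        success=not flat,
        message="" if not flat else "flat likelihood; fit unreliable",
    )
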