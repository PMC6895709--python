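"""Closed-form auxiliary models: FCS autocorrelation and anisotropy.

The fluorescence-correlation function for free 3D diffusion through an
elongated Gaussian observation volume, with a non-negligible triplet
population, is

    G(tau) = (1/n) (1 + tau/tau_d)^-1 (1 + tau/(SP^2 tau_d))^-1/2
             * (1 + T exp(-tau/tau_t) / (1 - T))

where n is the effective number of molecules in the volume, tau_d the
diffusion time, SP the axial elongation of the volume, T the triplet
fraction and tau_t the triplet lifetime.  The relative bound fraction
from steady-state anisotropy interpolates linearly between the free-
and fully-bound anchors:  RBF = (AN_c - AN_free) / (AN_bound - AN_free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FcsParams", "fcs_g", "fit_fcs", "FcsFit", "relative_bound_fraction"]


@dataclass
class FcsParams:
    """Parameters of the triplet-corrected 3D diffusion correlation."""

    n: float
    tau_diff: float      # s
    sp: float            # axial elongation ratio of the volume
    triplet: float = 0.0   # triplet fraction, in [0, 1)
    tau_trip: float = 1e-6  # s

    def __post_init__(self) -> None:
        if self.n <= 0 or self.tau_diff <= 0 or self.sp <= 0:
            raise ValueError("n, tau_diff and sp must be positive")
        if not 0 <= self.triplet < 1:
            raise ValueError("triplet fraction must be in [0, 1)")
        if self.tau_trip <= 0:
            raise ValueError("tau_trip must be positive")


def fcs_g(tau, params: FcsParams):
    """Evaluate the correlation model at lag(s) tau (seconds)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lags must be non-negative")
    diff = (1.0 + tau / params.tau_diff) ** -1
    axial = (1.0 + tau / (params.sp ** 2 * params.tau_diff)) ** -0.5
    trip = 1.0 + params.triplet * np.exp(-tau / params.tau_trip) / (
        1.0 - params.triplet
    )
    out = diff * axial * trip / params.n
    return out if out.ndim else float(out)


@dataclass
class FcsFit:
    """Result of a nonlinear FCS fit."""

    params: FcsParams
    stderr: dict
    redchi: float
    success: bool
    message: str = ""

    def summary(self) -> str:
        p = self.params
        se = {k: (f" +/- {v:.3g}" if v is not None else "")
              for k, v in self.stderr.items()}
        return "\n".join([
            "FCS fit" + ("" if self.success else " (NOT converged)"),
            f"  n        = {p.n:.4g}{se.get('n', '')}",
            f"  tau_diff = {p.tau_diff:.4g} s{se.get('tau_diff', '')}",
            f"  SP       = {p.sp:.4g}{se.get('sp', '')}",
            f"  T        = {p.triplet:.4g}{se.get('triplet', '')}",
            f"  tau_trip = {p.tau_trip:.4g} s{se.get('tau_trip', '')}",
            f"  red. chi2= {self.redchi:.4g}",
        ])


def fit_fcs(
    tau: np.ndarray,
    g: np.ndarray,
    initial: FcsParams,
    weights: np.ndarray | None = None,
    fix: tuple[str, ...] = (),
) -> FcsFit:
    """Weighted least-squares fit of the correlation model.

    Any subset of {"n", "tau_diff", "sp", "triplet", "tau_trip"} can be
    frozen at its initial value via ``fix``.  Weights default to
    uniform.  Non-convergence is reported, not raised.
    """
    from lmfit import Model

    tau = np.asarray(tau, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(tau) < 10:
        raise ValueError("need at least 10 lag points")

    def _model(x, n, tau_diff, sp, triplet, tau_trip):
        return fcs_g(x, FcsParams(n, tau_diff, sp, triplet, tau_trip))

    model = Model(_model, independent_vars=["x"])
    params = model.make_params(
        n=initial.n, tau_diff=initial.tau_diff, sp=initial.sp,
        triplet=initial.triplet, tau_trip=initial.tau_trip,
    )
    params["n"].set(min=1e-12)
    params["tau_diff"].set(min=1e-12)
    params["sp"].set(min=1e-6)
    params["triplet"].set(min=0.0, max=1.0 - 1e-9)
    params["tau_trip"].set(min=1e-12)
    for name in fix:
        params[name].set(vary=False)
    out = model.fit(g, params, x=tau, weights=weights)
    fitted = FcsParams(
        n=float(out.params["n"].value),
        tau_diff=float(out.params["tau_diff"].value),
        sp=float(out.params["sp"].value),
        triplet=float(out.params["triplet"].value),
        tau_trip=float(out.params["tau_trip"].value),
    )
    stderr = {k: (float(out.params[k].stderr)
                  if out.params[k].stderr is not None else None)
              for k in out.params}
    return FcsFit(
        params=fitted, stderr=stderr, redchi=float(out.redchi),
        success=bool(out.success),
        message="" if out.success else out.message,
    )


def relative_bound_fraction(
    an_c: float, an_free: float, an_bound: float
) -> float:
    """Fraction bound from anisotropy anchors.

    RBF = (AN_c - AN_free) / (AN_bound - AN_free); the free-species and
    fully-bound anisotropies anchor 0 and 1.
    """
    if an_bound == an_free:
        raise ValueError("anchors coincide; bound fraction undefined")
    return float((an_c - an_free) / (an_bound - an_free))
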