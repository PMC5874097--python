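"""Extended Kety (extended Tofts) two-compartment model: forward and fitting.

Tissue concentration is modelled as

    Ct(t) = vp * Cp(t - t0) + Ktrans * [Cp(. - t0) (x) exp(-(Ktrans/ve) t)](t)

with Cp the plasma input (AIF), Ktrans the volume transfer constant between
plasma and the extravascular extracellular space (EES), ve the fractional EES
volume, vp the fractional plasma volume and t0 the bolus-arrival delay of the
tissue relative to the AIF.

Unit conventions: rate constants (Ktrans, kep = Ktrans/ve) are per minute;
time grids and t0 are seconds.  The convolution is evaluated by an exact
trapezoidal recursion on the uniform acquisition grid; the delay is applied by
linear interpolation of Cp, so sub-frame t0 is meaningful.

Per-voxel parameters are estimated by bounded nonlinear least squares
(scipy TRF).  Fits are voxel-independent and deterministic given the data and
the initial point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .aif import AIF

__all__ = [
    "KetyParams",
    "KetyFit",
    "FitBounds",
    "ParameterMaps",
    "kety_forward",
    "fit_voxel",
    "fit_map",
]

log = logging.getLogger(__name__)

#: Sentinel for ve when Ktrans fitted to ~0 leaves the EES fraction
#: unidentifiable (no tracer ever enters the EES).
VE_UNIDENTIFIABLE = np.nan
#: Fitted Ktrans below this (1/min) is treated as zero for identifiability.
KTRANS_ZERO_TOL = 1e-6


@dataclass(frozen=True)
class KetyParams:
    """Parameter tuple of the extended Kety model.

    ktrans: 1/min, >= 0; ve, vp: dimensionless fractions in [0, 1];
    t0: bolus-arrival delay in seconds, >= 0.
    """

    ktrans: float
    ve: float
    vp: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("ktrans must be >= 0")
        if not (np.isnan(self.ve) or 0.0 <= self.ve <= 1.0):
            raise ValueError("ve must be in [0, 1]")
        if not 0.0 <= self.vp <= 1.0:
            raise ValueError("vp must be in [0, 1]")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.ktrans, self.ve, self.vp, self.t0], dtype=float)


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for the voxel fit; defaults bracket liver-tumor values widely."""

    ktrans: tuple[float, float] = (0.0, 10.0)     # 1/min
    ve: tuple[float, float] = (1e-6, 1.0)
    vp: tuple[float, float] = (0.0, 1.0)
    t0: tuple[float, float] = (0.0, 30.0)         # seconds

    def lower(self) -> np.ndarray:
        return np.array([self.ktrans[0], self.ve[0], self.vp[0], self.t0[0]])

    def upper(self) -> np.ndarray:
        return np.array([self.ktrans[1], self.ve[1], self.vp[1], self.t0[1]])


DEFAULT_INIT = KetyParams(ktrans=0.1, ve=0.2, vp=0.02, t0=0.0)


@dataclass
class KetyFit:
    params: KetyParams
    rss: float               # mM^2
    n_iter: int
    converged: bool
    ve_identifiable: bool = True

    def __post_init__(self) -> None:
        if self.rss < -0.0:
            raise ValueError("rss must be >= 0")


@dataclass
class ParameterMaps:
    """Voxel-wise parametric maps over an ROI; non-ROI voxels carry NaN."""

    ktrans_map: np.ndarray
    ve_map: np.ndarray
    vp_map: np.ndarray
    t0_map: np.ndarray
    rss_map: np.ndarray
    converged_mask: np.ndarray
    roi_mask: np.ndarray

    def convergence_rate(self) -> float:
        n = int(self.roi_mask.sum())
        return float(self.converged_mask[self.roi_mask].mean()) if n else float("nan")


def _delayed_cp(cp: np.ndarray, t: np.ndarray, t0: float) -> np.ndarray:
    """Cp(t - t0) by linear interpolation, zero before the record starts."""
    if t0 == 0.0:
        return cp
    return np.interp(t - t0, t, cp, left=0.0)


def _exp_conv(cpd: np.ndarray, dt_s: float, kep_per_min: float) -> np.ndarray:
    """Trapezoidal convolution of cpd with exp(-kep tau) on a uniform grid.

    Exact trapezoid via the recursion
    I_i = E * I_{i-1} + dt/2 * (E * cpd_{i-1} + cpd_i),  E = exp(-kep dt),
    with I_0 = 0, returning the integral in mM*min (dt converted from
    seconds).  Evaluated as an order-1 IIR filter; the free response of the
    filter's implicit I_0 = dt/2 * cpd_0 is subtracted to restore I_0 = 0.
    """
    dt_min = dt_s / 60.0
    e = np.exp(-kep_per_min * dt_min)
    out = lfilter([0.5 * dt_min, 0.5 * dt_min * e], [1.0, -e], cpd)
    if cpd[0] != 0.0:
        out -= (0.5 * dt_min * cpd[0]) * e ** np.arange(cpd.size)
    else:
        out[0] = 0.0
    return out


def _forward(theta: np.ndarray, cp: np.ndarray, t: np.ndarray, dt_s: float) -> np.ndarray:
    ktrans, ve, vp, t0 = theta
    cpd = _delayed_cp(cp, t, t0)
    ct = vp * cpd
    if ktrans > 0.0:
        ct = ct + ktrans * _exp_conv(cpd, dt_s, ktrans / ve)
    return ct


def kety_forward(params: KetyParams, aif: AIF) -> np.ndarray:
    """Tissue concentration curve Ct(t) in mM on the AIF's time grid.

    Degenerate cases follow the model: ktrans=0 gives the pure plasma term
    vp*Cp(t-t0); ktrans>0 with ve=0 is rejected (the efflux rate Ktrans/ve
    is undefined).
    """
    t = aif.time_grid
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0]):
        raise ValueError("AIF time grid must be uniform")
    if params.ktrans > 0.0 and not params.ve > 0.0:
        raise ValueError("ve must be > 0 when ktrans > 0 (rate Ktrans/ve undefined)")
    theta = params.as_array()
    if params.ktrans == 0.0:
        theta[1] = 1.0  # ve unused; avoid NaN sentinel entering arithmetic
    return _forward(theta, aif.cp_of_t, t, float(dt[0]))


def fit_voxel(
    ct: np.ndarray,
    aif: AIF,
    init: KetyParams = DEFAULT_INIT,
    bounds: FitBounds = FitBounds(),
) -> KetyFit:
    """Bounded least-squares fit of (Ktrans, ve, vp, t0) to one voxel curve.

    Returns the minimizer of ||ct - kety_forward(theta)||^2 within ``bounds``.
    An identically-zero curve is an exact fit at ktrans=vp=0 (not an error);
    non-finite input yields a non-converged fit flagged invalid.
    """
    ct = np.asarray(ct, dtype=float)
    t = aif.time_grid
    if ct.shape != t.shape:
        raise ValueError("ct and AIF must share the time grid")
    if not np.all(np.isfinite(ct)):
        return KetyFit(
            params=KetyParams(0.0, VE_UNIDENTIFIABLE, 0.0, 0.0),
            rss=float("nan"), n_iter=0, converged=False, ve_identifiable=False,
        )
    if np.all(ct == 0.0):
        return KetyFit(
            params=KetyParams(0.0, VE_UNIDENTIFIABLE, 0.0, 0.0),
            rss=0.0, n_iter=0, converged=True, ve_identifiable=False,
        )
    dt = float(t[1] - t[0])
    cp = aif.cp_of_t

    def resid(theta: np.ndarray) -> np.ndarray:
        return _forward(theta, cp, t, dt) - ct

    x0 = np.clip(init.as_array(), bounds.lower(), bounds.upper())
    sol = least_squares(
        resid, x0, bounds=(bounds.lower(), bounds.upper()),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
    )
    k, ve, vp, t0 = sol.x
    ve_ident = k > KTRANS_ZERO_TOL
    if not ve_ident:
        k, ve = 0.0, VE_UNIDENTIFIABLE
    return KetyFit(
        params=KetyParams(float(k), float(ve), float(vp), float(t0)),
        rss=float(2.0 * sol.cost),
        n_iter=int(sol.nfev),
        converged=bool(sol.success),
        ve_identifiable=bool(ve_ident),
    )


def fit_map(
    conc,
    aif: AIF,
    roi_mask: np.ndarray,
    init: KetyParams = DEFAULT_INIT,
    bounds: FitBounds = FitBounds(),
) -> ParameterMaps:
    """Voxel-by-voxel fit over an ROI mask; voxels are fitted independently.

    ``conc`` is a :class:`~dcequant.concentration.ConcentrationSeries` (or any
    object with ``c_of_t`` shaped (..., n_frames) and matching time grid).
    Non-ROI voxels carry NaN sentinels.  The convergence rate is logged.
    """
    c4d = np.asarray(conc.c_of_t, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != c4d.shape[:-1]:
        raise ValueError("roi_mask must match the spatial shape of the series")
    shape = roi_mask.shape
    maps = {name: np.full(shape, np.nan) for name in ("ktrans", "ve", "vp", "t0", "rss")}
    conv = np.zeros(shape, dtype=bool)
    idx = np.argwhere(roi_mask)
    if idx.size == 0:
        log.warning("fit_map called with an empty ROI mask")
    for vox in idx:
        key = tuple(vox)
        fit = fit_voxel(c4d[key], aif, init=init, bounds=bounds)
        maps["ktrans"][key] = fit.params.ktrans
        maps["ve"][key] = fit.params.ve
        maps["vp"][key] = fit.params.vp
        maps["t0"][key] = fit.params.t0
        maps["rss"][key] = fit.rss
        conv[key] = fit.converged
    out = ParameterMaps(
        ktrans_map=maps["ktrans"], ve_map=maps["ve"], vp_map=maps["vp"],
        t0_map=maps["t0"], rss_map=maps["rss"], converged_mask=conv, roi_mask=roi_mask,
    )
    if idx.size:
        log.info("fit_map: %d voxels, convergence rate %.3f", len(idx), out.convergence_rate())
    return out
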