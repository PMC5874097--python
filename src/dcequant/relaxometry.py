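"""Variable-flip-angle T1 estimation and SPGR signal inversion.

The precontrast longitudinal relaxation time T10 is estimated per voxel from
spoiled gradient-echo (SPGR) images acquired at several flip angles, using the
standard linearisation of the SPGR signal equation

    S = S0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),   E1 = exp(-TR / T1),

in which S/sin(a) is linear in S/tan(a) with slope E1.  During the dynamic
acquisition the same equation, evaluated at the single dynamic flip angle, is
inverted for E1 to recover T1(t) from the signal time course.

All functions broadcast over numpy arrays; times are seconds except TR, which
is milliseconds (the scanner convention used throughout the package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "T1MapSet",
    "spgr_signal",
    "fit_vfa",
    "fit_vfa_maps",
    "t1_from_signal",
]

#: T1 assigned (and flagged) when the SPGR inversion is driven out of domain
#: by signal >= the saturation value S0*sin(a): enhancement this strong means
#: T1 -> 0, so a small floor is the physically sensible clamp.
T1_FLOOR_S = 1e-3
#: T1 ceiling for signals at 0+ (T1 -> infinity side of the inversion).
T1_CEILING_S = 20.0


@dataclass(frozen=True)
class T1MapSet:
    """Per-voxel S0 / T10 estimates from a variable-flip-angle fit.

    ``fit_mask`` is True where the linearised fit produced a physical result
    (slope strictly inside (0, 1) and positive S0); elsewhere the maps carry
    NaN sentinels and must not be used downstream.
    """

    t10_map: np.ndarray  # seconds
    s0_map: np.ndarray   # signal units
    fit_mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        ok = self.fit_mask
        if np.any(~(self.t10_map[ok] > 0)) or np.any(~(self.s0_map[ok] > 0)):
            raise ValueError("t10_map and s0_map must be positive wherever fit_mask is set")


def spgr_signal(s0, t1, alpha_deg, tr_ms):
    """Spoiled gradient-echo steady-state signal.

    Parameters
    ----------
    s0 : array_like
        Equilibrium signal (proton density x gain), arbitrary units.
    t1 : array_like
        Longitudinal relaxation time, seconds.  Must be > 0.
    alpha_deg : array_like
        Flip angle in degrees, in (0, 90].
    tr_ms : float
        Repetition time in milliseconds.

    Returns
    -------
    ndarray or scalar
        Signal in the units of ``s0``.
    """
    s0 = np.asarray(s0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    e1 = np.exp(-(tr_ms / 1000.0) / t1)
    sig = s0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    return sig if sig.ndim else float(sig)


def fit_vfa(signals, angles_deg, tr_ms):
    """Fit (S0, T10) from signals at multiple flip angles (one voxel).

    Linearised VFA regression: y = S/sin(a) against x = S/tan(a); the slope is
    E1 = exp(-TR/T10) and the intercept S0*(1-E1).

    Returns ``(s0, t10, ok)``.  ``ok`` is False (and the estimates NaN) when
    the slope falls outside (0, 1), the intercept is non-positive, or the
    signals are degenerate (e.g. all zero); NaNs never propagate silently.
    """
    s = np.asarray(signals, dtype=float)
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if s.shape != a.shape or s.size < 2 or np.unique(a).size < 2:
        raise ValueError("need signals at >=2 distinct flip angles")
    if not np.all(np.isfinite(s)) or np.allclose(s, 0.0):
        return np.nan, np.nan, False
    y = s / np.sin(a)
    x = s / np.tan(a)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0.0:
        return np.nan, np.nan, False
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    if not (0.0 < slope < 1.0) or intercept <= 0.0:
        return np.nan, np.nan, False
    t10 = -(tr_ms / 1000.0) / np.log(slope)
    s0 = intercept / (1.0 - slope)
    return float(s0), float(t10), True


def fit_vfa_maps(volumes, angles_deg, tr_ms) -> T1MapSet:
    """Voxel-wise VFA fit over a stack of per-angle volumes.

    ``volumes`` is a sequence of equally shaped arrays, one per flip angle.
    Vectorised ordinary least squares of S/sin(a) on S/tan(a) per voxel.
    """
    vols = np.stack([np.asarray(v, dtype=float) for v in volumes], axis=-1)
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if vols.shape[-1] != a.size:
        raise ValueError("one volume required per flip angle")
    y = vols / np.sin(a)
    x = vols / np.tan(a)
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=-1)
    sxy = np.sum((x - xm) * (y - ym), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym[..., 0] - slope * xm[..., 0]
        ok = (
            np.isfinite(slope)
            & (slope > 0.0)
            & (slope < 1.0)
            & (intercept > 0.0)
            & ~np.all(vols == 0.0, axis=-1)
        )
        t10 = np.where(ok, -(tr_ms / 1000.0) / np.log(np.where(ok, slope, 0.5)), np.nan)
        s0 = np.where(ok, intercept / (1.0 - np.where(ok, slope, 0.5)), np.nan)
    return T1MapSet(t10_map=t10, s0_map=s0, fit_mask=ok)


def t1_from_signal(signal, s0, alpha_deg, tr_ms):
    """Invert the SPGR equation for T1 given the equilibrium signal S0.

    Solves S = S0 sin(a) (1-E1)/(1-E1 cos(a)) for E1 and returns
    T1 = -TR/ln(E1) in seconds.  Out-of-domain inputs are clamped and
    flagged rather than raised, so one bad voxel cannot abort a map:

    * signal >= S0*sin(a) (saturation) -> T1 clamped to ``T1_FLOOR_S``;
    * signal <= 0 -> T1 clamped to ``T1_CEILING_S``;

    Returns ``(t1, valid)`` where ``valid`` is False for clamped entries.
    Broadcasts over arrays.
    """
    sig = np.asarray(signal, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("s0 must be positive")
    a = np.deg2rad(float(alpha_deg))
    smax = s0 * np.sin(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (smax - sig) / (smax - sig * np.cos(a))
    low = sig <= 0.0
    high = sig >= smax
    valid = ~(low | high) & np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0)
    e1 = np.where(valid, e1, 0.5)
    t1 = -(tr_ms / 1000.0) / np.log(e1)
    t1 = np.where(valid, t1, np.where(high & ~low, T1_FLOOR_S, T1_CEILING_S))
    if t1.ndim == 0:
        return float(t1), bool(valid)
    return t1, valid
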