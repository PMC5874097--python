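"""Signal-derived T1 to contrast-agent concentration, and blood/plasma units.

Gadolinium shortens T1 in proportion to its local concentration:
C(t) = (1/T1(t) - 1/T10) / r1, with r1 the longitudinal relaxivity
(4.39 s^-1 mM^-1 for Gd-DOTA in blood at 3 T, applied to tissue as well).
Whole-blood concentration is converted to plasma via the hematocrit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConcentrationSeries", "concentration_from_t1", "blood_to_plasma"]

#: Gd-DOTA longitudinal relaxivity used throughout, s^-1 mM^-1.
R1_DEFAULT = 4.39
#: Rabbit hematocrit.
HCT_DEFAULT = 0.45


@dataclass
class ConcentrationSeries:
    """Contrast-agent concentration over time, mM, with its time grid.

    ``c_of_t`` has the time axis last (..., n_frames).  Baseline frames are
    precontrast; for noise-free input their concentration is exactly zero.
    Negative values arising from noise are retained (clipping would bias the
    baseline); ``n_negative()`` reports their count.
    """

    c_of_t: np.ndarray
    time_grid: np.ndarray  # seconds
    baseline_frames: int = 0
    valid_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.c_of_t = np.asarray(self.c_of_t, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.c_of_t.shape[-1] != self.time_grid.size:
            raise ValueError("time axis of c_of_t must match time_grid length")
        dt = np.diff(self.time_grid)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("time_grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    def n_negative(self) -> int:
        return int(np.sum(self.c_of_t < 0))


def concentration_from_t1(t1_t, t10, r1=R1_DEFAULT):
    """Concentration from post- and precontrast T1 (both seconds), in mM.

    C = (1/T1(t) - 1/T10) / r1.  Linear in the relaxation-rate difference;
    slightly negative values under noise pass through unclipped.

    Returns ``(c, valid)``; entries with non-positive T1 on either side are
    flagged invalid and set to NaN.  Broadcasts over arrays.
    """
    t1_t = np.asarray(t1_t, dtype=float)
    t10 = np.asarray(t10, dtype=float)
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    valid = (t1_t > 0) & (t10 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (1.0 / t1_t - 1.0 / t10) / r1
    c = np.where(valid, c, np.nan)
    if c.ndim == 0:
        return float(c), bool(valid)
    return c, valid


def blood_to_plasma(cb, hct=HCT_DEFAULT, convention="divide"):
    """Convert whole-blood concentration (mM) to plasma concentration.

    The contrast agent stays in plasma, so a blood-pool measurement
    underestimates the plasma concentration by the plasma volume fraction:
    Cp = Cb / (1 - Hct).  ``convention="multiply"`` computes Cb*(1-Hct)
    instead, for compatibility with sources that state the relation in that
    direction; correlation-type results downstream are invariant to the
    choice because it rescales the AIF (hence Ktrans and vp) by a common
    factor.
    """
    cb = np.asarray(cb, dtype=float)
    if not 0.0 <= hct < 1.0:
        raise ValueError("hct must be in [0, 1)")
    if convention == "divide":
        out = cb / (1.0 - hct)
    elif convention == "multiply":
        out = cb * (1.0 - hct)
    else:
        raise ValueError("convention must be 'divide' or 'multiply'")
    return out if out.ndim else float(out)
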