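"""Arterial input function: curve-shape scoring, voxel selection, extraction.

The AIF is measured from blood-pool voxels (near the heart in this pipeline's
intended acquisitions) rather than taken from a population model, so that
per-subject variation in cardiac output and vascular state is reflected in
the fitted parameters.  Visual selection — a high, narrow first-pass peak
with fast wash-in and wash-out — is made operational here as a composite
score

    score = peak height / (time-to-peak * FWHM),

ranked over candidate voxels; an explicit voxel list bypasses the scoring for
the operator-driven mode.  The averaged whole-blood curve is converted to
plasma with the hematocrit correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .concentration import HCT_DEFAULT, blood_to_plasma

__all__ = ["AIF", "AIFCandidate", "curve_metrics", "score_aif_candidates", "extract_aif"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AIF:
    """Plasma concentration-time curve Cp(t), mM, with provenance."""

    cp_of_t: np.ndarray
    time_grid: np.ndarray  # seconds
    source_voxels: tuple = ()
    peak_mM: float = float("nan")
    time_to_peak_s: float = float("nan")
    fwhm_s: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "cp_of_t", np.asarray(self.cp_of_t, dtype=float))
        object.__setattr__(self, "time_grid", np.asarray(self.time_grid, dtype=float))
        if self.cp_of_t.shape != self.time_grid.shape:
            raise ValueError("cp_of_t and time_grid must have equal length")
        if not np.all(np.isfinite(self.cp_of_t)):
            raise ValueError("cp_of_t must be finite")


@dataclass(frozen=True)
class AIFCandidate:
    voxel: tuple            # (i, j, k)
    linear_index: int
    peak_mM: float
    time_to_peak_s: float
    fwhm_s: float
    score: float


def curve_metrics(c: np.ndarray, t: np.ndarray) -> tuple[float, float, float]:
    """(peak height, time-to-peak, FWHM) of a concentration-time curve.

    FWHM is found by linear interpolation of the half-maximum crossings on
    either side of the peak; if the curve never falls back to half maximum
    the right edge is taken at the last frame (the width is then a lower
    bound, which only penalises the candidate's score).
    """
    c = np.asarray(c, dtype=float)
    ip = int(np.argmax(c))
    peak = float(c[ip])
    ttp = float(t[ip] - t[0])
    if peak <= 0:
        return peak, ttp, float("nan")
    half = 0.5 * peak
    # left crossing: last index before the peak where c < half
    left = t[0]
    below = np.where(c[: ip + 1] < half)[0]
    if below.size:
        i = below[-1]
        frac = (half - c[i]) / (c[i + 1] - c[i])
        left = t[i] + frac * (t[i + 1] - t[i])
    right = t[-1]
    below = np.where(c[ip:] < half)[0]
    if below.size:
        i = ip + below[0]
        frac = (c[i - 1] - half) / (c[i - 1] - c[i])
        right = t[i - 1] + frac * (t[i] - t[i - 1])
    return peak, ttp, float(right - left)


def score_aif_candidates(conc, search_mask: np.ndarray) -> list[AIFCandidate]:
    """Rank voxels in ``search_mask`` by the composite bolus-shape score.

    Higher, narrower, earlier peaks rank first; ties are broken by the lower
    linear voxel index so the ordering is fully deterministic.  Voxels whose
    curves never enhance (peak <= 0) are excluded; an empty result triggers a
    warning rather than an error.
    """
    mask = np.asarray(search_mask, dtype=bool)
    if not mask.any():
        raise ValueError("search_mask is empty")
    c4d = np.asarray(conc.c_of_t, dtype=float)
    t = np.asarray(conc.time_grid, dtype=float)
    out: list[AIFCandidate] = []
    for vox in np.argwhere(mask):
        key = tuple(int(v) for v in vox)
        curve = c4d[key]
        peak, ttp, fwhm = curve_metrics(curve, t)
        if not peak > 0:
            continue
        denom = max(ttp, t[1] - t[0]) * fwhm  # ttp floored at one frame
        score = peak / denom if denom > 0 else 0.0
        lin = int(np.ravel_multi_index(key, mask.shape))
        out.append(AIFCandidate(key, lin, peak, ttp, fwhm, float(score)))
    if not out:
        warnings.warn("no enhancing voxel in the AIF search mask", stacklevel=2)
        return []
    out.sort(key=lambda cand: (-cand.score, cand.linear_index))
    return out


def extract_aif(conc, voxels, hct: float = HCT_DEFAULT, convention: str = "divide") -> AIF:
    """Average the whole-blood curves of ``voxels`` and convert to plasma.

    Duplicate voxels are collapsed (order-preserving), so a voxel listed
    twice carries no extra weight.  Quality metrics are recomputed on the
    plasma curve.
    """
    c4d = np.asarray(conc.c_of_t, dtype=float)
    t = np.asarray(conc.time_grid, dtype=float)
    seen: dict[tuple, None] = {}
    for v in voxels:
        key = tuple(int(x) for x in v)
        if len(key) != c4d.ndim - 1:
            raise ValueError(f"voxel {key} has wrong dimensionality")
        if any(i < 0 or i >= s for i, s in zip(key, c4d.shape[:-1])):
            raise ValueError(f"voxel {key} outside the volume")
        seen.setdefault(key, None)
    if not seen:
        raise ValueError("need at least one voxel")
    unique = tuple(seen)
    cb = np.mean([c4d[k] for k in unique], axis=0)
    cp = blood_to_plasma(cb, hct=hct, convention=convention)
    peak, ttp, fwhm = curve_metrics(cp, t)
    return AIF(
        cp_of_t=cp, time_grid=t, source_voxels=unique,
        peak_mM=peak, time_to_peak_s=ttp, fwhm_s=fwhm,
    )
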