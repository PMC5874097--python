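"""Tumor-subregion extraction: ROI resampling, window averaging, summaries.

Histology-derived subregion labels (CNA / PNA / VTA) live on a
high-resolution grid; they are resampled to the dynamic-image grid by
majority vote of source voxels per target voxel.  A representative
pharmacokinetic value per region is the mean over a 3x3 in-plane voxel
neighborhood (slices are ~3x thicker than the in-plane spacing, so the
9-voxel window stays within one slice), placed deterministically at the
region voxel whose window mean is the region's median among fully-interior
windows.  One summary row per (tumor, region) joins the window means with
the region's microvessel density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REGION_CODES",
    "SubregionLabels",
    "resample_roi",
    "neighborhood_mean",
    "pick_region_center",
    "summarize_tumor",
]

log = logging.getLogger(__name__)

REGION_CODES = {"CNA": 1, "PNA": 2, "VTA": 3}
CODE_REGIONS = {v: k for k, v in REGION_CODES.items()}


@dataclass(frozen=True)
class SubregionLabels:
    """Integer label volume with codes {0: background, 1: CNA, 2: PNA, 3: VTA}."""

    volume: np.ndarray
    provenance: str = "resampled-to-dce"

    def __post_init__(self) -> None:
        vol = np.asarray(self.volume)
        if not np.isin(vol, [0, 1, 2, 3]).all():
            raise ValueError("subregion labels restricted to codes {0, 1, 2, 3}")
        object.__setattr__(self, "volume", vol.astype(np.int16))

    def regions_present(self) -> list[str]:
        return [CODE_REGIONS[c] for c in (1, 2, 3) if np.any(self.volume == c)]


def resample_roi(
    highres_mask: np.ndarray,
    source_affine: np.ndarray,
    target_shape: tuple[int, ...],
    target_affine: np.ndarray,
) -> np.ndarray:
    """Resample an integer label volume onto a coarser grid by majority vote.

    Every source voxel casts its label (background included) into the target
    voxel containing its center, via the two voxel-to-world affines; each
    target voxel takes the most frequent label in its footprint, ties going
    to the lower label code.  Target voxels receiving no votes are
    background.  Grids whose physical extents do not overlap are rejected.
    """
    src = np.asarray(highres_mask)
    source_affine = np.asarray(source_affine, dtype=float)
    target_affine = np.asarray(target_affine, dtype=float)
    ndim = src.ndim
    idx = np.indices(src.shape).reshape(ndim, -1)
    ones = np.ones((1, idx.shape[1]))
    world = source_affine @ np.vstack([idx, ones])
    tgt = np.linalg.inv(target_affine) @ world
    tgt_idx = np.rint(tgt[:ndim]).astype(int)
    inside = np.all((tgt_idx >= 0) & (tgt_idx < np.array(target_shape)[:, None]), axis=0)
    if not inside.any():
        raise ValueError("source and target grids have no overlapping physical extent")
    labels = src.reshape(-1)[inside]
    flat = np.ravel_multi_index(tuple(tgt_idx[:, inside]), target_shape)
    n_labels = int(src.max()) + 1
    votes = np.zeros((int(np.prod(target_shape)), n_labels), dtype=np.int64)
    np.add.at(votes, (flat, labels.astype(int)), 1)
    out = np.where(votes.any(axis=1), np.argmax(votes, axis=1), 0)  # argmax -> lowest code on ties
    return out.reshape(target_shape).astype(src.dtype)


def neighborhood_mean(volume: np.ndarray, center: tuple[int, int, int]) -> float:
    """Mean over the 3x3 in-plane window (9 voxels, same slice) at ``center``.

    The window must lie fully inside the volume; edge centers are rejected.
    """
    vol = np.asarray(volume, dtype=float)
    i, j, k = center
    if not (1 <= i <= vol.shape[0] - 2 and 1 <= j <= vol.shape[1] - 2):
        raise ValueError(f"3x3 window at {center} crosses the volume edge")
    if not 0 <= k < vol.shape[2]:
        raise ValueError(f"slice index {k} outside the volume")
    return float(vol[i - 1 : i + 2, j - 1 : j + 2, k].mean())


def _window_interior_mask(region_mask: np.ndarray) -> np.ndarray:
    """Voxels whose 3x3 in-plane window lies entirely inside the region."""
    m = region_mask
    ok = np.zeros_like(m, dtype=bool)
    ok[1:-1, 1:-1, :] = True
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            shifted = np.zeros_like(m)
            src = m[
                max(0, -di) : m.shape[0] - max(0, di),
                max(0, -dj) : m.shape[1] - max(0, dj),
                :,
            ]
            shifted[
                max(0, di) : m.shape[0] - max(0, -di),
                max(0, dj) : m.shape[1] - max(0, -dj),
                :,
            ] = src
            ok &= shifted
    return ok & m


def pick_region_center(
    label_volume: np.ndarray, region: str | int, ktrans_map: np.ndarray
) -> tuple[tuple[int, int, int], bool]:
    """Deterministic window placement for a region's representative value.

    Among voxels whose 3x3 in-plane window lies fully inside the region, the
    one whose window-mean Ktrans is the region's median (lower median for an
    even count) is selected; ties go to the lowest linear voxel index.  When
    no fully-interior window exists the region centroid is returned with
    ``interior=False``.

    Returns ``((i, j, k), interior)``.
    """
    code = REGION_CODES[region] if isinstance(region, str) else int(region)
    lab = np.asarray(label_volume)
    mask = lab == code
    if not mask.any():
        raise ValueError(f"region {region!r} not present in the label volume")
    eligible = _window_interior_mask(mask)
    if not eligible.any():
        centroid = tuple(int(round(c)) for c in np.argwhere(mask).mean(axis=0))
        log.warning("region %s has no interior 3x3 window; falling back to centroid", region)
        return centroid, False
    vox = np.argwhere(eligible)
    means = np.array([neighborhood_mean(ktrans_map, tuple(v)) for v in vox])
    order = np.argsort(means, kind="stable")
    median_val = means[order[(len(means) - 1) // 2]]
    at_median = np.where(means == median_val)[0]
    lin = np.ravel_multi_index(vox[at_median].T, lab.shape)
    chosen = vox[at_median[np.argmin(lin)]]
    return tuple(int(c) for c in chosen), True


def summarize_tumor(
    maps,
    labels: SubregionLabels | np.ndarray,
    mvd_table: pd.DataFrame | None = None,
    tumor_id: int = 1,
) -> pd.DataFrame:
    """One summary row per subregion present: window-mean parameters + MVD.

    ``maps`` is a :class:`~dcequant.kety.ParameterMaps`; the window is placed
    on the Ktrans map and the same 9 voxels average ve and vp.  MVD values
    are joined by (tumor_id, region); a present region with no MVD row gets
    a NaN sentinel and a warning.
    """
    lab = labels.volume if isinstance(labels, SubregionLabels) else np.asarray(labels)
    if lab.shape != maps.ktrans_map.shape:
        raise ValueError("label volume and parameter maps must share a grid")
    rows = []
    for region, code in REGION_CODES.items():
        if not np.any(lab == code):
            continue
        center, interior = pick_region_center(lab, region, maps.ktrans_map)
        vals = {}
        for name, vol in (("ktrans", maps.ktrans_map), ("ve", maps.ve_map), ("vp", maps.vp_map)):
            try:
                vals[name] = neighborhood_mean(vol, center)
            except ValueError:
                vals[name] = float(np.nanmean(vol[lab == code]))
        mvd = np.nan
        if mvd_table is not None:
            hit = mvd_table[
                (mvd_table.tumor_id == tumor_id) & (mvd_table.region == region)
            ]
            if len(hit):
                mvd = float(hit.mvd.iloc[0])
            else:
                warnings.warn(
                    f"no MVD value for tumor {tumor_id} region {region}", stacklevel=2
                )
        rows.append({
            "tumor_id": tumor_id, "region": region, **vals, "mvd": mvd,
            "center_i": center[0], "center_j": center[1], "center_k": center[2],
            "window_interior": interior,
        })
    return pd.DataFrame(rows)
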