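"""Digital DCE-MRI phantom: ground truth, bolus model, image rendering, MVD.

The phantom emulates the study design the analysis targets: a multi-slice
coronal liver acquisition over ablated hypervascular tumors, each tumor
containing a completely necrotic core (CNA), a partially necrotic transition
ring (PNA) and a viable rim (VTA) with distinct perfusion.  One tumor is
placed per slice as concentric discs inside a liver disc, plus a small
blood-pool region from which the arterial input is read.

Ground-truth Ktrans per (tumor, region) is drawn around region anchors that
match the bundled per-tumor summary table (CNA ~0.04, PNA ~0.29,
VTA ~1.00 /min), with a shared log-normal tumor-level vascularity factor (so
PNA and VTA co-vary across tumors, as real tumors do) and voxel-level
scatter.  Microvessel density is linked linearly to the regional Ktrans with
additive field-count noise, near-zero in necrosis.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aif import AIF
from .kety import KetyParams, kety_forward
from .relaxometry import spgr_signal

__all__ = [
    "LABELS",
    "REGIONS",
    "AcquisitionParams",
    "PhantomConfig",
    "PhantomTruth",
    "MVDLink",
    "BolusShape",
    "DynamicSeries",
    "make_ground_truth",
    "simulate_blood_curve",
    "render_vfa_images",
    "render_dynamic_series",
    "sample_mvd",
]

#: Label codes. Subregion codes 1-3 follow the histology convention used by
#: the subregions module; liver and blood are phantom-only context labels.
LABELS = {"background": 0, "CNA": 1, "PNA": 2, "VTA": 3, "liver": 4, "blood": 5}
REGIONS = ("CNA", "PNA", "VTA")


@dataclass(frozen=True)
class AcquisitionParams:
    """Dynamic + variable-flip-angle acquisition protocol.

    Defaults follow a 3 T coronal T1-weighted TFE liver protocol:
    TE/TR = 4.5/2.3 ms, 160x160 matrix, 2 mm slices, one dynamic every
    2.4 s, 120 dynamics of which the first 2 are precontrast baseline,
    precontrast flip angles 2/5/10/12 deg with the dynamics at 12 deg;
    Gd-DOTA relaxivity 4.39 s^-1 mM^-1 and rabbit hematocrit 0.45.
    """

    tr_ms: float = 2.3
    te_ms: float = 4.5
    flip_angles_deg: tuple[float, ...] = (2.0, 5.0, 10.0, 12.0)
    dynamic_flip_deg: float = 12.0
    dt_s: float = 2.4
    n_dynamics: int = 120
    n_baseline: int = 2
    r1: float = 4.39   # s^-1 mM^-1
    hct: float = 0.45

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if not self.n_baseline < self.n_dynamics:
            raise ValueError("n_baseline must be smaller than n_dynamics")
        for a in (*self.flip_angles_deg, self.dynamic_flip_deg):
            if not 0.0 < a <= 90.0:
                raise ValueError("flip angles must lie in (0, 90] degrees")
        if not 0.0 <= self.hct < 1.0:
            raise ValueError("hct must be in [0, 1)")

    @property
    def time_grid(self) -> np.ndarray:
        """Frame times in seconds, starting at 0."""
        return np.arange(self.n_dynamics) * self.dt_s


@dataclass(frozen=True)
class MVDLink:
    """Linear link from regional Ktrans to microvessel density.

    MVD field counts (vessels per x200 field) for perfused regions are drawn
    around slope * Ktrans + intercept; completely necrotic regions carry
    near-zero counts around ``cna_rate``.  Defaults put PNA near 6 and VTA
    near 17 vessels/field at the phantom's Ktrans anchors.
    """

    slope: float = 15.0      # vessels per (1/min)
    intercept: float = 2.0   # vessels
    noise_sd: float = 1.5    # vessels, per field
    cna_rate: float = 1.0    # vessels

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class BolusShape:
    """Synthetic first-pass bolus: gamma-variate plus biexponential washout.

    A smooth stand-in for a measured arterial curve with the canonical
    features — zero before arrival, a single narrow peak shortly after
    arrival, fast wash-out with a slow recirculation/clearance tail.
    """

    arrival_s: float = 6.0      # bolus arrival after acquisition start
    peak_delay_s: float = 9.6   # gamma-variate mode, relative to arrival
    sharpness: float = 3.0      # gamma-variate shape exponent
    washout_fracs: tuple[float, float] = (0.2, 0.1)
    washout_rates: tuple[float, float] = (0.02, 0.002)  # 1/s
    washin_tau_s: float = 3.0


@dataclass
class PhantomTruth:
    """Voxel-wise ground truth plus the per-(tumor, region) parameter table."""

    ktrans_map: np.ndarray   # 1/min
    ve_map: np.ndarray       # fraction
    vp_map: np.ndarray       # fraction
    t0_map: np.ndarray       # seconds
    t10_map: np.ndarray      # seconds
    s0_map: np.ndarray       # signal units
    label_map: np.ndarray    # int codes, see LABELS
    voxel_spacing: tuple[float, float, float]  # mm
    region_means: pd.DataFrame  # tumor_id, region, ktrans, ve, vp

    def __post_init__(self) -> None:
        if np.any(self.ktrans_map < 0):
            raise ValueError("ktrans_map must be nonnegative")
        if np.any(self.ktrans_map[self.label_map == LABELS["background"]] != 0):
            raise ValueError("ktrans must be zero in background")
        s = self.ve_map + self.vp_map
        if np.any(self.ve_map < 0) or np.any(self.vp_map < 0) or np.any(s > 1):
            raise ValueError("need 0 <= ve, vp and ve + vp <= 1 everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_map.shape

    def tumor_mask(self) -> np.ndarray:
        return np.isin(self.label_map, [LABELS[r] for r in REGIONS])

    def blood_mask(self) -> np.ndarray:
        return self.label_map == LABELS["blood"]

    def subregion_labels(self) -> np.ndarray:
        """Label volume restricted to the {0: bg, 1: CNA, 2: PNA, 3: VTA} codes."""
        lab = self.label_map.copy()
        lab[~self.tumor_mask()] = 0
        return lab


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and statistical structure of the digital phantom."""

    nx: int = 160
    ny: int = 160
    n_tumors: int = 8                      # one lesion per slice
    voxel_spacing: tuple[float, float, float] = (0.75, 0.75, 2.0)  # mm
    tumor_radii_vox: tuple[float, float, float] = (5.0, 10.0, 15.0)  # CNA, PNA, VTA outer
    liver_radius_frac: float = 0.42        # of min(nx, ny)
    blood_radius_vox: float = 2.5
    # Region anchors (median tumor): Ktrans 1/min, ve, vp — bracketing the
    # bundled summary-table column means.
    region_ktrans: dict = field(default_factory=lambda: {"CNA": 0.04, "PNA": 0.29, "VTA": 1.00})
    region_ve: dict = field(default_factory=lambda: {"CNA": 0.23, "PNA": 0.13, "VTA": 0.14})
    region_vp: dict = field(default_factory=lambda: {"CNA": 0.015, "PNA": 0.034, "VTA": 0.033})
    # Voxel-level scatter inside a region (SD = 0 gives piecewise-constant maps):
    ktrans_voxel_cv: float = 0.10          # log-normal sigma
    ve_voxel_sd: float = 0.01
    vp_voxel_sd: float = 0.003
    # Tumor-level variability across the cohort:
    tumor_sigma_log: float = 0.8           # shared vascularity factor, log-normal
    region_jitter_log: float = 0.25        # per-region log-normal jitter
    ve_tumor_sd: float = 0.04
    vp_tumor_sd: float = 0.01
    # Tissue and context:
    liver_ktrans: float = 0.15
    liver_ve: float = 0.25
    liver_vp: float = 0.04
    t0_s: float = 3.0                      # tissue bolus delay vs the AIF
    t10_s: dict = field(default_factory=lambda: {
        "background": 1.0, "CNA": 1.3, "PNA": 1.2, "VTA": 1.1, "liver": 0.8, "blood": 1.6,
    })
    s0: float = 1000.0
    aif_peak_mM: float = 5.0               # whole-blood first-pass peak
    bolus: BolusShape = BolusShape()

    def __post_init__(self) -> None:
        for r in REGIONS:
            budget = (self.region_ve[r] + 4 * (self.ve_tumor_sd + self.ve_voxel_sd)
                      + self.region_vp[r] + 4 * (self.vp_tumor_sd + self.vp_voxel_sd))
            if budget > 1.0:
                raise ValueError(f"ve + vp for region {r} can exceed 1 under the configured SDs")
        if not np.all(np.diff(self.tumor_radii_vox) > 0):
            raise ValueError("tumor radii must be strictly increasing (CNA < PNA < VTA)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.n_tumors)


@dataclass
class DynamicSeries:
    """4D dynamic signal-intensity series with acquisition metadata."""

    data: np.ndarray                 # (nx, ny, nz, n_dynamics), signal units
    acq: AcquisitionParams
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic series must be 4D")
        if self.data.shape[-1] != self.acq.n_dynamics:
            raise ValueError(
                f"series has {self.data.shape[-1]} frames but acquisition "
                f"declares {self.acq.n_dynamics}"
            )

    @property
    def time_grid(self) -> np.ndarray:
        return self.acq.time_grid


def draw_tumor_table(config: PhantomConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-(tumor, region) parameter means for the cohort.

    A shared log-normal vascularity factor scales all three regions of a
    tumor; per-region jitter is applied on top and the CNA < PNA < VTA
    ordering is restored by sorting where the jitter would break it.
    """
    rows = []
    for t in range(1, config.n_tumors + 1):
        f = float(np.exp(config.tumor_sigma_log * rng.standard_normal()))
        ks = np.array([
            config.region_ktrans[r] * f
            * np.exp(config.region_jitter_log * rng.standard_normal())
            for r in REGIONS
        ])
        ks = np.sort(np.clip(ks, 0.0, 6.0))  # enforce CNA < PNA < VTA, keep within fit bounds
        for r, k in zip(REGIONS, ks):
            ve = float(np.clip(rng.normal(config.region_ve[r], config.ve_tumor_sd), 0.01, 0.9))
            vp = float(np.clip(rng.normal(config.region_vp[r], config.vp_tumor_sd), 0.001, 0.3))
            rows.append({"tumor_id": t, "region": r, "ktrans": float(k), "ve": ve, "vp": vp})
    return pd.DataFrame(rows)


def _disc(nx: int, ny: int, cx: float, cy: float, r: float) -> np.ndarray:
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2


def make_ground_truth(config: PhantomConfig = PhantomConfig(), seed: int = 0) -> PhantomTruth:
    """Build the voxel-wise ground-truth phantom (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    table = draw_tumor_table(config, rng)
    nx, ny, nz = config.shape
    label = np.zeros((nx, ny, nz), dtype=np.int16)
    ktrans = np.zeros((nx, ny, nz))
    ve = np.zeros((nx, ny, nz))
    vp = np.zeros((nx, ny, nz))
    t0 = np.zeros((nx, ny, nz))
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r_cna, r_pna, r_vta = config.tumor_radii_vox
    liver_r = config.liver_radius_frac * min(nx, ny)
    # blood pool in a corner, clear of the liver disc
    bx = by = max(3.0, config.blood_radius_vox + 1.0)
    blood = _disc(nx, ny, bx, by, config.blood_radius_vox)

    for k in range(nz):
        liver = _disc(nx, ny, cx, cy, liver_r)
        sl_label = np.zeros((nx, ny), dtype=np.int16)
        sl_label[liver] = LABELS["liver"]
        vta = _disc(nx, ny, cx, cy, r_vta)
        pna = _disc(nx, ny, cx, cy, r_pna)
        cna = _disc(nx, ny, cx, cy, r_cna)
        sl_label[vta] = LABELS["VTA"]
        sl_label[pna] = LABELS["PNA"]
        sl_label[cna] = LABELS["CNA"]
        sl_label[blood] = LABELS["blood"]
        label[:, :, k] = sl_label

        sl_k = np.zeros((nx, ny))
        sl_ve = np.zeros((nx, ny))
        sl_vp = np.zeros((nx, ny))
        liver_only = liver & (sl_label == LABELS["liver"])
        sl_k[liver_only] = config.liver_ktrans
        sl_ve[liver_only] = config.liver_ve
        sl_vp[liver_only] = config.liver_vp
        trow = table[table.tumor_id == k + 1].set_index("region")
        for r in REGIONS:
            m = sl_label == LABELS[r]
            n = int(m.sum())
            if n == 0:
                continue
            kv = trow.loc[r, "ktrans"] * np.exp(
                config.ktrans_voxel_cv * rng.standard_normal(n)
            )
            vev = np.clip(rng.normal(trow.loc[r, "ve"], config.ve_voxel_sd, n), 1e-3, 0.95)
            vpv = np.clip(rng.normal(trow.loc[r, "vp"], config.vp_voxel_sd, n), 1e-4, 0.5)
            sl_k[m], sl_ve[m], sl_vp[m] = kv, vev, vpv
        ktrans[:, :, k] = sl_k
        ve[:, :, k] = sl_ve
        vp[:, :, k] = sl_vp
        t0[:, :, k] = np.where((sl_label > 0) & (sl_label != LABELS["blood"]), config.t0_s, 0.0)

    # blood compartment: pure plasma signal handled by the renderer
    ve[label == LABELS["blood"]] = 0.0
    vp[label == LABELS["blood"]] = 1.0
    ktrans[label == LABELS["blood"]] = 0.0

    t10 = np.full((nx, ny, nz), config.t10_s["background"])
    for name, code in LABELS.items():
        t10[label == code] = config.t10_s[name]
    s0 = np.full((nx, ny, nz), config.s0)

    # replace the region table's anchors by the realised voxel means so the
    # MVD link and downstream oracles refer to the actual painted maps
    realised = []
    for t in range(1, nz + 1):
        for r in REGIONS:
            m = (label[:, :, t - 1] == LABELS[r])
            row = {"tumor_id": t, "region": r}
            row["ktrans"] = float(ktrans[:, :, t - 1][m].mean()) if m.any() else np.nan
            row["ve"] = float(ve[:, :, t - 1][m].mean()) if m.any() else np.nan
            row["vp"] = float(vp[:, :, t - 1][m].mean()) if m.any() else np.nan
            realised.append(row)
    return PhantomTruth(
        ktrans_map=ktrans, ve_map=ve, vp_map=vp, t0_map=t0, t10_map=t10,
        s0_map=s0, label_map=label, voxel_spacing=config.voxel_spacing,
        region_means=pd.DataFrame(realised),
    )


def simulate_blood_curve(
    peak: float, time_grid: np.ndarray, shape: BolusShape = BolusShape()
) -> np.ndarray:
    """Whole-blood concentration curve Cb(t), mM, on a uniform time grid.

    Gamma-variate first pass plus a slowly rising biexponential washout
    tail; zero before arrival, normalised so the grid maximum equals
    ``peak``.  ``peak=0`` returns the zero curve.
    """
    t = np.asarray(time_grid, dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0]):
        raise ValueError("time_grid must be uniform")
    if peak < 0:
        raise ValueError("peak must be >= 0")
    if peak == 0.0:
        return np.zeros_like(t)
    tau = t - shape.arrival_s
    curve = np.zeros_like(t)
    pos = tau > 0
    tp, a = shape.peak_delay_s, shape.sharpness
    g = (tau[pos] / tp) ** a * np.exp(a * (1.0 - tau[pos] / tp))
    (w1, w2), (k1, k2) = shape.washout_fracs, shape.washout_rates
    tail = (w1 * np.exp(-k1 * tau[pos]) + w2 * np.exp(-k2 * tau[pos])) * (
        1.0 - np.exp(-tau[pos] / shape.washin_tau_s)
    )
    curve[pos] = g + tail
    return peak * curve / curve.max()


def render_vfa_images(
    truth: PhantomTruth,
    acq: AcquisitionParams = AcquisitionParams(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """One 3D SPGR volume per precontrast flip angle, with optional noise."""
    rng = np.random.default_rng(seed)
    out = {}
    for a in acq.flip_angles_deg:
        vol = spgr_signal(truth.s0_map, truth.t10_map, a, acq.tr_ms)
        if noise_sd > 0:
            vol = vol + rng.normal(0.0, noise_sd, vol.shape)
        out[a] = vol
    return out


def render_dynamic_series(
    truth: PhantomTruth,
    aif: AIF,
    acq: AcquisitionParams = AcquisitionParams(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DynamicSeries:
    """Forward-render the 4D dynamic series from the ground truth and AIF.

    Tissue voxels follow the extended Kety model driven by the plasma input;
    blood-pool voxels carry the whole-blood curve Cb = Cp * (1 - Hct).  The
    concentration time course is mapped to T1(t) through the relaxivity and
    to signal through the SPGR equation at the dynamic flip angle; noise is
    additive Gaussian on the magnitude signal.
    """
    t = acq.time_grid
    if aif.time_grid.shape != t.shape or not np.allclose(aif.time_grid, t):
        raise ValueError("AIF must be defined on the acquisition time grid")
    if np.any(aif.cp_of_t[: acq.n_baseline] != 0.0):
        raise ValueError("AIF must be zero over the baseline frames")
    nx, ny, nz = truth.shape
    nt = acq.n_dynamics
    conc = np.zeros((nx, ny, nz, nt))

    cb = aif.cp_of_t * (1.0 - acq.hct)
    conc[truth.blood_mask()] = cb

    tissue = (truth.label_map > 0) & ~truth.blood_mask()
    # cache the Kety forward curve per unique parameter tuple (piecewise-
    # constant phantoms collapse to a handful of curves)
    cache: dict[tuple, np.ndarray] = {}
    for vox in np.argwhere(tissue):
        key = tuple(vox)
        p = (
            float(truth.ktrans_map[key]), float(truth.ve_map[key]),
            float(truth.vp_map[key]), float(truth.t0_map[key]),
        )
        ct = cache.get(p)
        if ct is None:
            ct = kety_forward(KetyParams(*p), aif)
            cache[p] = ct
        conc[key] = ct

    r1_t = 1.0 / truth.t10_map[..., None] + acq.r1 * conc
    sig = spgr_signal(truth.s0_map[..., None], 1.0 / r1_t, acq.dynamic_flip_deg, acq.tr_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, sig.shape)
    return DynamicSeries(data=sig, acq=acq, voxel_spacing=truth.voxel_spacing)


def sample_mvd(
    truth: PhantomTruth,
    link: MVDLink = MVDLink(),
    n_fields: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(tumor, region) MVD table from the linear Ktrans link.

    For PNA/VTA each of ``n_fields`` high-power-field counts is drawn around
    slope * (regional mean Ktrans) + intercept; CNA fields are drawn around
    ``cna_rate``.  Negative draws are truncated at zero and the reported MVD
    is the mean of the field counts.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in truth.region_means.iterrows():
        if not np.isfinite(rec.ktrans):
            continue
        base = link.cna_rate if rec.region == "CNA" else link.slope * rec.ktrans + link.intercept
        fields = np.maximum(rng.normal(base, link.noise_sd, n_fields), 0.0)
        rows.append({
            "tumor_id": int(rec.tumor_id), "region": rec.region,
            "mvd": float(fields.mean()),
        })
    return pd.DataFrame(rows)
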