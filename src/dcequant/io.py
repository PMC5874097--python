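"""On-disk formats, configuration, the bundled summary table, and the pipeline.

Volumes are NIfTI-1 (4D dynamic series, one 3D file per VFA angle, integer
3D labels) with the voxel spacing carried in the affine; acquisition
parameters travel in a JSON sidecar; tables (AIF, MVD, summaries, results)
are comma-separated UTF-8 CSV with one header row naming units.

``run_pipeline`` ties the stages together: VFA T1 mapping -> signal-to-
concentration conversion -> AIF extraction -> voxel-wise extended Kety
fitting -> subregion summaries -> cohort statistics, deterministically for
a given dataset, configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import kety, phantom, relaxometry, stats, subregions
from .aif import AIF, extract_aif, score_aif_candidates
from .concentration import ConcentrationSeries, blood_to_plasma, concentration_from_t1
from .phantom import LABELS, AcquisitionParams, DynamicSeries

__all__ = [
    "PipelineConfig",
    "load_table1_fixture",
    "read_dynamic",
    "read_labels",
    "read_mvd",
    "write_maps",
    "write_nifti",
    "read_nifti",
    "write_aif_csv",
    "read_aif_csv",
    "run_pipeline",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs beyond the data files themselves."""

    seed: int = 0
    aif_top_k: int = 5
    aif_voxels: tuple | None = None          # explicit voxel list bypasses scoring
    hct_convention: str = "divide"
    stats_mode: str = "mean"                 # 'mean' | 'pooled' for PNA+VTA
    multistart_ktrans: tuple[float, ...] = ()  # optional extra Ktrans inits

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aif_voxels"] = None if self.aif_voxels is None else [list(v) for v in self.aif_voxels]
        d["multistart_ktrans"] = list(self.multistart_ktrans)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("aif_voxels") is not None:
            d["aif_voxels"] = tuple(tuple(v) for v in d["aif_voxels"])
        if "multistart_ktrans" in d:
            d["multistart_ktrans"] = tuple(d["multistart_ktrans"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# --------------------------------------------------------------------------
# volumes

def _affine(spacing) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    return aff


def write_nifti(path, array, spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(array), _affine(spacing))
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def read_dynamic(path, sidecar_path) -> DynamicSeries:
    """Load a 4D dynamic series and validate it against its JSON sidecar."""
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    acq = AcquisitionParams(**meta["acquisition"])
    data, aff = read_nifti(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: dynamic series must be 4D, got {data.ndim}D")
    if data.shape[-1] != acq.n_dynamics:
        raise ValueError(
            f"{path}: series has {data.shape[-1]} frames but the sidecar "
            f"declares n_dynamics={acq.n_dynamics}"
        )
    spacing = tuple(float(x) for x in np.abs(np.diag(aff)[:3]))
    return DynamicSeries(data=data, acq=acq, voxel_spacing=spacing)


def read_labels(path) -> subregions.SubregionLabels:
    """Load an integer label volume restricted to the subregion codes."""
    data, _ = read_nifti(path)
    vol = np.rint(data).astype(np.int16)
    vol[~np.isin(vol, [1, 2, 3])] = 0
    return subregions.SubregionLabels(volume=vol)


def write_maps(maps: kety.ParameterMaps, out_dir, spacing=(1.0, 1.0, 1.0)) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("ktrans", "ve", "vp", "t0", "rss"):
        write_nifti(out / f"{name}.nii.gz", getattr(maps, f"{name}_map"), spacing)
    write_nifti(out / "converged.nii.gz", maps.converged_mask.astype(np.uint8), spacing)
    write_nifti(out / "roi_mask.nii.gz", maps.roi_mask.astype(np.uint8), spacing)


def read_maps(map_dir) -> kety.ParameterMaps:
    d = Path(map_dir)
    arrays = {name: read_nifti(d / f"{name}.nii.gz")[0] for name in ("ktrans", "ve", "vp", "t0", "rss")}
    conv, _ = read_nifti(d / "converged.nii.gz")
    roi, _ = read_nifti(d / "roi_mask.nii.gz")
    return kety.ParameterMaps(
        ktrans_map=arrays["ktrans"], ve_map=arrays["ve"], vp_map=arrays["vp"],
        t0_map=arrays["t0"], rss_map=arrays["rss"],
        converged_mask=conv.astype(bool), roi_mask=roi.astype(bool),
    )


# --------------------------------------------------------------------------
# tables

def read_mvd(path) -> pd.DataFrame:
    """MVD table with columns tumor_id, region, mvd (vessels/field)."""
    df = pd.read_csv(path, comment="#")
    missing = {"tumor_id", "region", "mvd"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: malformed MVD CSV, missing columns {sorted(missing)}")
    return df


def write_aif_csv(aif: AIF, path) -> None:
    pd.DataFrame({"time_s": aif.time_grid, "cp_mM": aif.cp_of_t}).to_csv(path, index=False)


def read_aif_csv(path) -> AIF:
    df = pd.read_csv(path, comment="#")
    if not {"time_s", "cp_mM"} <= set(df.columns):
        raise ValueError(f"{path}: AIF CSV needs columns time_s, cp_mM")
    return AIF(cp_of_t=df.cp_mM.to_numpy(), time_grid=df.time_s.to_numpy())


def load_table1_fixture() -> pd.DataFrame:
    """The bundled per-tumor subregion summary: 15 tumors x 3 regions.

    Columns: tumor_id, region (CNA/PNA/VTA), ktrans (1/min), ve, vp
    (fractions), mvd (vessels per x200 field, mean of five fields).
    """
    ref = resources.files("dcequant.data").joinpath("table1_vx2.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#")
    if len(df) != 45 or df.tumor_id.nunique() != 15:
        raise RuntimeError("bundled summary fixture is corrupt")
    return df


# --------------------------------------------------------------------------
# simulated datasets

def simulate_dataset(
    out_dir,
    config: phantom.PhantomConfig = phantom.PhantomConfig(),
    acq: AcquisitionParams = AcquisitionParams(),
    link: phantom.MVDLink = phantom.MVDLink(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> phantom.PhantomTruth:
    """Render a full synthetic study to ``out_dir`` in the pipeline layout.

    Writes the 4D dynamic series, per-angle VFA volumes, the label volume
    (subregions 1-3, liver 4, blood 5), the acquisition JSON sidecar, the
    MVD table, the true plasma input curve, and the ground-truth parameter
    maps under ``truth/``.  ``noise_sd`` is the additive Gaussian signal
    noise applied to both the VFA and dynamic images.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = phantom.make_ground_truth(config, seed=seed)
    cb = phantom.simulate_blood_curve(config.aif_peak_mM, acq.time_grid, config.bolus)
    aif_true = AIF(cp_of_t=blood_to_plasma(cb, acq.hct), time_grid=acq.time_grid)
    vfa = phantom.render_vfa_images(truth, acq, noise_sd=noise_sd, seed=seed + 1)
    series = phantom.render_dynamic_series(truth, aif_true, acq, noise_sd=noise_sd, seed=seed + 2)
    mvd = phantom.sample_mvd(truth, link=link, seed=seed + 3)

    sp = truth.voxel_spacing
    write_nifti(out / "dynamic.nii.gz", series.data, sp)
    for i, a in enumerate(acq.flip_angles_deg):
        write_nifti(out / f"vfa_{i}.nii.gz", vfa[a], sp)
    write_nifti(out / "labels.nii.gz", truth.label_map, sp)
    with open(out / "acquisition.json", "w") as fh:
        json.dump({"acquisition": dataclasses.asdict(acq)}, fh, indent=2)
    with open(out / "mvd.csv", "w") as fh:
        fh.write("# units: mvd vessels/field (mean of 5 fields)\n")
        mvd.to_csv(fh, index=False)
    write_aif_csv(aif_true, out / "aif_true.csv")
    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    for name in ("ktrans", "ve", "vp", "t0", "t10", "s0"):
        write_nifti(tdir / f"{name}.nii.gz", getattr(truth, f"{name}_map"), sp)
    truth.region_means.to_csv(tdir / "region_means.csv", index=False)
    return truth


# --------------------------------------------------------------------------
# pipeline

def _stage(name: str, t_start: float, timings: dict) -> None:
    timings[name] = round(time.perf_counter() - t_start, 3)
    log.info("stage %-14s %.2fs", name, timings[name])


def run_pipeline(data_dir, out_dir, config: PipelineConfig = PipelineConfig()) -> dict:
    """Run every stage on a simulated (or equivalently laid out) dataset.

    Expects in ``data_dir``: ``dynamic.nii.gz``, ``vfa_<i>.nii.gz`` per
    precontrast flip angle, ``labels.nii.gz`` (subregion codes 1-3, liver 4,
    blood 5), ``acquisition.json`` and ``mvd.csv``.  Writes parameter maps,
    the AIF, per-tumor summaries, the statistics grid and a text report to
    ``out_dir`` and returns the key objects in a dict.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    series = read_dynamic(data_dir / "dynamic.nii.gz", data_dir / "acquisition.json")
    acq = series.acq
    vfa = [read_nifti(data_dir / f"vfa_{i}.nii.gz")[0] for i in range(len(acq.flip_angles_deg))]
    labels_raw, _ = read_nifti(data_dir / "labels.nii.gz")
    labels_raw = np.rint(labels_raw).astype(np.int16)
    mvd = read_mvd(data_dir / "mvd.csv")
    _stage("load", t0, timings)

    t0 = time.perf_counter()
    t1set = relaxometry.fit_vfa_maps(vfa, acq.flip_angles_deg, acq.tr_ms)
    _stage("vfa_fit", t0, timings)

    t0 = time.perf_counter()
    t1_t, _valid = relaxometry.t1_from_signal(
        series.data, t1set.s0_map[..., None], acq.dynamic_flip_deg, acq.tr_ms
    )
    c_of_t, _cvalid = concentration_from_t1(t1_t, t1set.t10_map[..., None], acq.r1)
    conc = ConcentrationSeries(
        c_of_t=np.nan_to_num(c_of_t), time_grid=acq.time_grid, baseline_frames=acq.n_baseline
    )
    _stage("concentration", t0, timings)

    t0 = time.perf_counter()
    if config.aif_voxels is not None:
        aif_voxels = config.aif_voxels
    else:
        blood_mask = labels_raw == LABELS["blood"]
        if not blood_mask.any():
            raise RuntimeError("stage aif: no blood-pool label (5) in labels.nii.gz")
        cands = score_aif_candidates(conc, blood_mask)
        aif_voxels = [c.voxel for c in cands[: config.aif_top_k]]
    aif = extract_aif(conc, aif_voxels, hct=acq.hct, convention=config.hct_convention)
    write_aif_csv(aif, out_dir / "aif.csv")
    _stage("aif", t0, timings)

    t0 = time.perf_counter()
    roi = np.isin(labels_raw, [1, 2, 3])
    maps = kety.fit_map(conc, aif, roi)
    write_maps(maps, out_dir / "maps", series.voxel_spacing)
    _stage("kety_fit", t0, timings)

    t0 = time.perf_counter()
    sub_lab = labels_raw.copy()
    sub_lab[~roi] = 0
    summaries = []
    for k in range(labels_raw.shape[2]):
        sl = np.zeros_like(sub_lab)
        sl[:, :, k] = sub_lab[:, :, k]
        if not sl.any():
            continue
        summaries.append(subregions.summarize_tumor(maps, sl, mvd, tumor_id=k + 1))
    summary = pd.concat(summaries, ignore_index=True)
    summary_path = out_dir / "summary.csv"
    with open(summary_path, "w") as fh:
        fh.write("# units: ktrans 1/min; ve fraction; vp fraction; mvd vessels/field\n")
        summary.to_csv(fh, index=False)
    _stage("summarize", t0, timings)

    t0 = time.perf_counter()
    corr, paired, report = stats.run_full_analysis(summary, mode=config.stats_mode)
    corr.insert(0, "mode", config.stats_mode)
    corr.to_csv(out_dir / "correlations.csv", index=False)
    paired.to_csv(out_dir / "paired_tests.csv", index=False)
    (out_dir / "report.txt").write_text(report + "\n")
    _stage("stats", t0, timings)

    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]
    logpayload = {
        "config_hash": cfg_hash,
        "config": config.to_dict(),
        "timings_s": timings,
        "kety_convergence_rate": maps.convergence_rate(),
        "n_negative_concentrations": conc.n_negative(),
        "aif_voxels": [list(v) for v in aif.source_voxels],
    }
    (out_dir / "run_log.json").write_text(json.dumps(logpayload, indent=2))
    return {
        "aif": aif, "maps": maps, "summary": summary,
        "correlations": corr, "paired_tests": paired, "report": report,
    }
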