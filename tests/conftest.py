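"""Shared fixtures: a small noise-free phantom study processed end to end.

The expensive objects (rendered series, reconstructed concentration, fitted
parameter maps over every tumor voxel) are session-scoped so the recovery
tests and the acceptance checks share one computation.
"""

import numpy as np
import pytest

from dcequant import concentration as conc_mod
from dcequant import kety, phantom, relaxometry
from dcequant.aif import AIF, extract_aif, score_aif_candidates
from dcequant.io import load_table1_fixture


@pytest.fixture(scope="session")
def acq() -> phantom.AcquisitionParams:
    return phantom.AcquisitionParams()


@pytest.fixture(scope="session")
def small_config() -> phantom.PhantomConfig:
    return phantom.PhantomConfig(
        nx=48, ny=48, n_tumors=3, tumor_radii_vox=(3.0, 6.0, 9.0), blood_radius_vox=2.0
    )


@pytest.fixture(scope="session")
def truth(small_config) -> phantom.PhantomTruth:
    return phantom.make_ground_truth(small_config, seed=1)


@pytest.fixture(scope="session")
def true_aif(small_config, acq) -> AIF:
    cb = phantom.simulate_blood_curve(small_config.aif_peak_mM, acq.time_grid, small_config.bolus)
    return AIF(cp_of_t=cb / (1.0 - acq.hct), time_grid=acq.time_grid)


@pytest.fixture(scope="session")
def series(truth, true_aif, acq) -> phantom.DynamicSeries:
    return phantom.render_dynamic_series(truth, true_aif, acq, noise_sd=0.0, seed=2)


@pytest.fixture(scope="session")
def reconstructed_conc(truth, series, acq) -> conc_mod.ConcentrationSeries:
    """Concentration recovered from the rendered images, as the pipeline would."""
    vfa = phantom.render_vfa_images(truth, acq, noise_sd=0.0, seed=3)
    t1set = relaxometry.fit_vfa_maps(list(vfa.values()), acq.flip_angles_deg, acq.tr_ms)
    t1_t, _ = relaxometry.t1_from_signal(
        series.data, t1set.s0_map[..., None], acq.dynamic_flip_deg, acq.tr_ms
    )
    c, _ = conc_mod.concentration_from_t1(t1_t, t1set.t10_map[..., None], acq.r1)
    return conc_mod.ConcentrationSeries(
        c_of_t=np.nan_to_num(c), time_grid=acq.time_grid, baseline_frames=acq.n_baseline
    )


@pytest.fixture(scope="session")
def extracted_aif(reconstructed_conc, truth, acq) -> AIF:
    cands = score_aif_candidates(reconstructed_conc, truth.blood_mask())
    return extract_aif(reconstructed_conc, [c.voxel for c in cands[:5]], hct=acq.hct)


@pytest.fixture(scope="session")
def fitted_maps(reconstructed_conc, extracted_aif, truth) -> kety.ParameterMaps:
    """Extended Kety fit at every tumor voxel of the noise-free phantom."""
    return kety.fit_map(reconstructed_conc, extracted_aif, truth.tumor_mask())


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()
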