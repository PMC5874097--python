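"""Digital phantom: ground truth, bolus model, renderers, MVD sampling."""

import numpy as np
import pandas as pd
import pytest

from dcequant import phantom, relaxometry
from dcequant.phantom import (
    LABELS,
    AcquisitionParams,
    BolusShape,
    MVDLink,
    PhantomConfig,
    make_ground_truth,
    render_dynamic_series,
    render_vfa_images,
    sample_mvd,
    simulate_blood_curve,
)


class TestGroundTruth:
    def test_region_ktrans_ordering(self, truth):
        means = truth.region_means.pivot(index="tumor_id", columns="region", values="ktrans")
        assert (means.CNA < means.PNA).all() and (means.PNA < means.VTA).all()

    def test_deterministic_under_seed(self, small_config):
        a = make_ground_truth(small_config, seed=9)
        b = make_ground_truth(small_config, seed=9)
        np.testing.assert_array_equal(a.ktrans_map, b.ktrans_map)
        np.testing.assert_array_equal(a.label_map, b.label_map)
        pd.testing.assert_frame_equal(a.region_means, b.region_means)

    def test_different_seeds_differ(self, small_config):
        a = make_ground_truth(small_config, seed=1)
        b = make_ground_truth(small_config, seed=2)
        assert not np.array_equal(a.ktrans_map, b.ktrans_map)

    def test_zero_voxel_sd_gives_constant_regions(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config, ktrans_voxel_cv=0.0, ve_voxel_sd=0.0, vp_voxel_sd=0.0
        )
        tr = make_ground_truth(cfg, seed=3)
        for k in range(cfg.n_tumors):
            for code in (1, 2, 3):
                m = tr.label_map[:, :, k] == code
                vals = tr.ktrans_map[:, :, k][m]
                assert np.ptp(vals) == 0.0

    def test_background_has_zero_ktrans_and_valid_fractions(self, truth):
        assert np.all(truth.ktrans_map[truth.label_map == LABELS["background"]] == 0)
        assert np.all(truth.ve_map + truth.vp_map <= 1.0)
        assert np.all(truth.ve_map >= 0) and np.all(truth.vp_map >= 0)

    def test_subregion_labels_restricted_to_tumor_codes(self, truth):
        sub = truth.subregion_labels()
        assert set(np.unique(sub)) <= {0, 1, 2, 3}
        assert (sub > 0).sum() == truth.tumor_mask().sum()

    def test_rejects_overfull_fraction_budget(self):
        with pytest.raises(ValueError):
            PhantomConfig(region_ve={"CNA": 0.8, "PNA": 0.3, "VTA": 0.2},
                          region_vp={"CNA": 0.3, "PNA": 0.05, "VTA": 0.05})


class TestBloodCurve:
    T = np.arange(120) * 2.4

    def test_peak_is_scale_factor(self):
        cb = simulate_blood_curve(5.0, self.T)
        assert cb.max() == pytest.approx(5.0)
        np.testing.assert_allclose(simulate_blood_curve(2.5, self.T), cb / 2, rtol=1e-12)

    def test_zero_peak_zero_curve(self):
        assert np.all(simulate_blood_curve(0.0, self.T) == 0.0)

    def test_starts_at_zero_with_single_max(self):
        cb = simulate_blood_curve(5.0, self.T)
        assert cb[0] == 0.0
        peaks = np.sum((cb[1:-1] > cb[:-2]) & (cb[1:-1] > cb[2:]))
        assert peaks == 1

    def test_fast_bolus_shape(self):
        """Time-to-peak under 30 s and strong late washout on the default shape."""
        cb = simulate_blood_curve(5.0, self.T)
        assert self.T[np.argmax(cb)] < 30.0
        assert cb[-1] < 0.2 * cb.max()

    def test_monotone_decay_after_shoulder(self):
        cb = simulate_blood_curve(5.0, self.T)
        late = cb[self.T > 60.0]
        assert np.all(np.diff(late) <= 1e-12)

    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError):
            simulate_blood_curve(5.0, np.array([0.0, 1.0, 3.0]))


class TestRenderers:
    def test_vfa_noise_free_equals_forward_model(self, truth, acq):
        vols = render_vfa_images(truth, acq, noise_sd=0.0, seed=0)
        for a, vol in vols.items():
            expected = relaxometry.spgr_signal(truth.s0_map, truth.t10_map, a, acq.tr_ms)
            np.testing.assert_allclose(vol, expected, rtol=1e-13)

    def test_vfa_round_trip_recovers_t10(self, truth, acq):
        vols = render_vfa_images(truth, acq, noise_sd=0.0, seed=0)
        t1set = relaxometry.fit_vfa_maps(list(vols.values()), acq.flip_angles_deg, acq.tr_ms)
        assert t1set.fit_mask.all()
        np.testing.assert_allclose(t1set.t10_map, truth.t10_map, rtol=1e-6)

    def test_dynamic_baseline_is_flat_for_unperfused_voxel(self, series, truth, acq):
        bg = np.argwhere(truth.label_map == LABELS["background"])[0]
        curve = series.data[tuple(bg)]
        assert np.ptp(curve) == pytest.approx(0.0, abs=1e-9)

    def test_dynamic_baseline_frames_precontrast_everywhere(self, series, acq):
        base = series.data[..., : acq.n_baseline]
        np.testing.assert_allclose(base[..., 1], base[..., 0], rtol=1e-12)

    def test_dynamic_render_deterministic(self, truth, true_aif, acq):
        a = render_dynamic_series(truth, true_aif, acq, noise_sd=5.0, seed=7)
        b = render_dynamic_series(truth, true_aif, acq, noise_sd=5.0, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_dynamic_rejects_mismatched_aif_grid(self, truth, true_aif, acq):
        from dcequant.aif import AIF

        bad = AIF(cp_of_t=true_aif.cp_of_t[:-1], time_grid=true_aif.time_grid[:-1])
        with pytest.raises(ValueError):
            render_dynamic_series(truth, bad, acq)


class TestSampleMvd:
    def test_degenerate_noise_is_exact_link(self, truth):
        link = MVDLink(slope=15.0, intercept=2.0, noise_sd=0.0, cna_rate=1.0)
        mvd = sample_mvd(truth, link, seed=0)
        merged = truth.region_means.merge(mvd, on=["tumor_id", "region"])
        pv = merged[merged.region != "CNA"]
        np.testing.assert_allclose(pv.mvd, 15.0 * pv.ktrans + 2.0, rtol=1e-12)
        assert np.all(merged[merged.region == "CNA"].mvd == 1.0)

    def test_zero_slope_decouples_mvd_from_ktrans(self, truth):
        from dcequant.stats import pearson

        link = MVDLink(slope=0.0, intercept=10.0, noise_sd=1.5)
        rs = []
        for s in range(40):
            mvd = sample_mvd(truth, link, seed=s)
            m = truth.region_means.merge(mvd, on=["tumor_id", "region"])
            sub = m[m.region == "PNA"]
            rs.append(pearson(sub.ktrans, sub.mvd)[0])
        assert abs(np.mean(rs)) < 0.2

    def test_reported_value_is_mean_of_fields(self, truth):
        a = sample_mvd(truth, MVDLink(), n_fields=1, seed=5)
        b = sample_mvd(truth, MVDLink(), n_fields=5, seed=5)
        assert not np.allclose(a.mvd, b.mvd)

    def test_counts_truncated_at_zero(self, truth):
        link = MVDLink(slope=0.0, intercept=0.0, noise_sd=3.0, cna_rate=0.0)
        mvd = sample_mvd(truth, link, seed=1)
        assert (mvd.mvd >= 0).all()

    def test_rejects_bad_n_fields(self, truth):
        with pytest.raises(ValueError):
            sample_mvd(truth, MVDLink(), n_fields=0, seed=0)
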