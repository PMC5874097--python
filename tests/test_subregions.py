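"""ROI resampling, 9-voxel neighborhood averaging, and tumor summaries."""

import numpy as np
import pandas as pd
import pytest

from dcequant.subregions import (
    REGION_CODES,
    SubregionLabels,
    neighborhood_mean,
    pick_region_center,
    resample_roi,
    summarize_tumor,
)


def _affine(spacing):
    return np.diag([*spacing, 1.0])


class TestResampleRoi:
    def test_identity_on_identical_grids(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 4, (12, 12, 2)).astype(np.int16)
        out = resample_roi(mask, _affine((1, 1, 1)), mask.shape, _affine((1, 1, 1)))
        np.testing.assert_array_equal(out, mask)

    def test_disc_area_preserved_across_resolution(self):
        """A centered disc on a 512-grid keeps its physical area on a 160-grid."""
        n_hi, n_lo = 512, 160
        fov = 120.0  # mm
        sp_hi, sp_lo = fov / n_hi, fov / n_lo
        x, y = np.meshgrid(np.arange(n_hi), np.arange(n_hi), indexing="ij")
        r_mm = 20.0
        disc = ((x - n_hi / 2) ** 2 + (y - n_hi / 2) ** 2) <= (r_mm / sp_hi) ** 2
        mask = disc.astype(np.int16)[..., None]
        out = resample_roi(
            mask, _affine((sp_hi, sp_hi, 2.0)), (n_lo, n_lo, 1), _affine((sp_lo, sp_lo, 2.0))
        )
        area_hi = disc.sum() * sp_hi**2
        area_lo = out.sum() * sp_lo**2
        ring = 2 * np.pi * r_mm * sp_lo  # one target-voxel ring of slack
        assert abs(area_lo - area_hi) < ring

    def test_all_background_stays_background(self):
        mask = np.zeros((20, 20, 1), dtype=np.int16)
        out = resample_roi(mask, _affine((1, 1, 1)), (10, 10, 1), _affine((2, 2, 1)))
        assert not out.any()

    def test_disjoint_extents_rejected(self):
        mask = np.ones((4, 4, 1), dtype=np.int16)
        far = _affine((1, 1, 1))
        far[:3, 3] = 1000.0
        with pytest.raises(ValueError):
            resample_roi(mask, far, (4, 4, 1), _affine((1, 1, 1)))


class TestNeighborhoodMean:
    def test_constant_map(self):
        vol = np.full((5, 5, 1), 3.7)
        assert neighborhood_mean(vol, (2, 2, 0)) == pytest.approx(3.7)

    def test_center_spike(self):
        vol = np.zeros((3, 3, 1))
        vol[1, 1, 0] = 9.0
        assert neighborhood_mean(vol, (1, 1, 0)) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_map(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(size=(7, 6, 2))
        i, j, k = 3, 2, 1
        brute = np.mean([vol[i + di, j + dj, k] for di in (-1, 0, 1) for dj in (-1, 0, 1)])
        assert neighborhood_mean(vol, (i, j, k)) == pytest.approx(brute, rel=1e-15)

    def test_edge_window_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_mean(np.zeros((5, 5, 1)), (0, 2, 0))


class TestPickRegionCenter:
    def test_single_3x3_region_returns_its_center(self):
        lab = np.zeros((5, 5, 1), dtype=np.int16)
        lab[1:4, 1:4, 0] = REGION_CODES["PNA"]
        center, interior = pick_region_center(lab, "PNA", np.zeros((5, 5, 1)))
        assert interior and center == (2, 2, 0)

    def test_constant_ktrans_tie_breaks_to_lowest_linear_index(self):
        lab = np.zeros((8, 8, 1), dtype=np.int16)
        lab[1:7, 1:7, 0] = REGION_CODES["VTA"]
        center, interior = pick_region_center(lab, "VTA", np.ones((8, 8, 1)))
        assert interior
        eligible_min = (2, 2, 0)  # first voxel whose window stays inside the block
        assert center == eligible_min

    def test_fallback_to_centroid_when_no_interior_window(self):
        lab = np.zeros((6, 6, 1), dtype=np.int16)
        lab[2, 1:5, 0] = REGION_CODES["CNA"]  # one-voxel-thick line
        center, interior = pick_region_center(lab, "CNA", np.zeros((6, 6, 1)))
        assert not interior and center == (2, 2, 0)

    def test_phantom_window_mean_near_region_truth(self, truth, small_config):
        for region in ("CNA", "PNA", "VTA"):
            for k in range(small_config.n_tumors):
                lab = np.zeros_like(truth.label_map)
                lab[:, :, k] = truth.subregion_labels()[:, :, k]
                if not (lab == REGION_CODES[region]).any():
                    continue
                center, interior = pick_region_center(lab, region, truth.ktrans_map)
                win = neighborhood_mean(truth.ktrans_map, center)
                ref = truth.region_means.query(
                    "tumor_id == @k + 1 and region == @region"
                ).ktrans.iloc[0]
                assert abs(win - ref) / ref < 0.10

    def test_absent_region_rejected(self):
        with pytest.raises(ValueError):
            pick_region_center(np.zeros((4, 4, 1), dtype=np.int16), "VTA", np.zeros((4, 4, 1)))


class TestSummarizeTumor:
    def test_phantom_summary_preserves_region_ordering(self, fitted_maps, truth):
        # restrict to the first slice's tumor
        lab = np.zeros_like(truth.label_map)
        lab[:, :, 0] = truth.subregion_labels()[:, :, 0]
        rows = summarize_tumor(fitted_maps, lab, None, tumor_id=1)
        w = rows.set_index("region").ktrans
        assert w["CNA"] < w["PNA"] < w["VTA"]

    def test_single_region_yields_single_row(self, fitted_maps, truth):
        lab = np.zeros_like(truth.label_map)
        lab[:, :, 0] = np.where(
            truth.subregion_labels()[:, :, 0] == REGION_CODES["VTA"], REGION_CODES["VTA"], 0
        )
        rows = summarize_tumor(fitted_maps, lab, None, tumor_id=1)
        assert len(rows) == 1 and rows.region.iloc[0] == "VTA"

    def test_missing_mvd_row_warns_with_nan(self, fitted_maps, truth):
        lab = np.zeros_like(truth.label_map)
        lab[:, :, 0] = truth.subregion_labels()[:, :, 0]
        mvd = pd.DataFrame({"tumor_id": [1], "region": ["VTA"], "mvd": [15.0]})
        with pytest.warns(UserWarning):
            rows = summarize_tumor(fitted_maps, lab, mvd, tumor_id=1)
        assert rows.set_index("region").mvd.loc["VTA"] == 15.0
        assert np.isnan(rows.set_index("region").mvd.loc["CNA"])

    def test_fixture_round_trips_through_csv(self, table1, tmp_path):
        out = tmp_path / "t1.csv"
        table1.to_csv(out, index=False)
        back = pd.read_csv(out)
        pd.testing.assert_frame_equal(back, table1)

    def test_labels_type_rejects_foreign_codes(self):
        with pytest.raises(ValueError):
            SubregionLabels(volume=np.full((2, 2, 1), 7))
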