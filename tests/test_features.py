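"""Feature readout: inner radius, gray value, GVSD, distAZ, normalizations."""

import numpy as np
import pytest

from vesisort import features as feat
from vesisort.tomo_io import TomogramStack

from conftest import digital_ball


def _ball_labels(radius, pad=2):
    return digital_ball(radius, pad).astype(np.int32)


class TestInnerRadius:
    def test_single_voxel_region_has_zero_radius(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 1
        assert feat.inner_radius(labels, 1, (1.0,) * 3, membrane_nm=0.0) == 0.0

    def test_digital_ball_matches_brute_force_enumeration(self):
        radius = 8
        labels = _ball_labels(radius)
        # independent oracle: loop over all voxels, surface = any 6-neighbor
        # outside, radius = mean distance to the voxel-index centroid
        idx = np.argwhere(labels == 1)
        centroid = idx.mean(axis=0)
        surface = []
        inside = {tuple(i) for i in idx}
        for v in idx:
            for step in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                         (0, 0, 1), (0, 0, -1)]:
                if tuple(v + step) not in inside:
                    surface.append(v)
                    break
        expected = float(np.mean([np.linalg.norm(s - centroid) for s in surface]))
        got = feat.inner_radius(labels, 1, (1.0, 1.0, 1.0), membrane_nm=0.0)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(radius, abs=1.0)

    def test_membrane_erosion_shrinks_radius(self):
        labels = _ball_labels(10)
        r_full = feat.inner_radius(labels, 1, (1.0,) * 3, membrane_nm=0.0)
        r_eroded = feat.inner_radius(labels, 1, (1.0,) * 3, membrane_nm=3.0)
        assert r_full - r_eroded == pytest.approx(3.0, abs=1.0)

    def test_missing_id_raises(self):
        with pytest.raises(KeyError):
            feat.inner_radius(np.zeros((2, 2, 2), dtype=int), 5, (1.0,) * 3)


class TestMeanGray:
    def test_constant_region(self):
        labels = _ball_labels(4)
        stack = TomogramStack(np.full(labels.shape, 100.0))
        assert feat.mean_gray(stack, labels, 1, membrane_nm=0.0) == 100.0

    def test_symmetric_values_average(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        labels[0] = 1
        vox = np.zeros((2, 2, 2))
        vox[0, 0] = 90.0
        vox[0, 1] = 110.0
        stack = TomogramStack(vox)
        assert feat.mean_gray(stack, labels, 1, membrane_nm=0.0) == 100.0

    def test_dark_low_polarity_inverts(self):
        labels = _ball_labels(4)
        stack = TomogramStack(np.full(labels.shape, 100.0))
        gv = feat.mean_gray(stack, labels, 1, membrane_nm=0.0,
                            gv_polarity="dark_low", invert_reference=255.0)
        assert gv == 155.0


class TestGVSD:
    def test_uniform_footprint_gives_zero(self):
        labels = _ball_labels(4)
        stack = TomogramStack(np.full(labels.shape, 50.0))
        assert feat.gvsd_central_slice(stack, labels, 1) == 0.0

    def test_two_value_footprint_sample_sd(self):
        labels = np.zeros((3, 4, 4), dtype=np.int32)
        labels[1, 1, 1] = labels[1, 1, 2] = 1
        vox = np.zeros((3, 4, 4))
        vox[1, 1, 1], vox[1, 1, 2] = 4.0, 6.0
        stack = TomogramStack(vox)
        got = feat.gvsd_central_slice(stack, labels, 1, blur_sigma=0.0)
        assert got == pytest.approx(np.sqrt(2.0))

    def test_sub_two_voxel_footprint_gives_zero(self):
        labels = np.zeros((3, 3, 3), dtype=np.int32)
        labels[1, 1, 1] = 1
        stack = TomogramStack(np.random.default_rng(0).random((3, 3, 3)))
        assert feat.gvsd_central_slice(stack, labels, 1) == 0.0

    def test_phantom_ccv_gvsd_exceeds_dcv(self, segmented_phantom):
        # shell+lumen contrast of clear-core vesicles vs uniform dense core
        spec, truth, labels, scaled = segmented_phantom
        table = feat.extract_feature_table(scaled, labels, spec.az_point_nm,
                                           gv_polarity="dark_low")
        from scipy.spatial import cKDTree
        d, idx = cKDTree(table[["x", "y", "z"]].to_numpy()).query(
            truth[["x", "y", "z"]].to_numpy())
        matched = table.iloc[idx[d <= 2.0]]
        cls = truth.loc[d <= 2.0, "class"].to_numpy()
        gvsd_ccv = matched["GVSD"].to_numpy()[cls == "CCV"].mean()
        gvsd_dcv = matched["GVSD"].to_numpy()[cls == "DCV"].mean()
        gv_ccv = matched["gv"].to_numpy()[cls == "CCV"].mean()
        gv_dcv = matched["gv"].to_numpy()[cls == "DCV"].mean()
        assert gvsd_ccv > gvsd_dcv
        assert gv_dcv > gv_ccv  # denser core reads larger in density units


class TestDistAZ:
    def test_three_four_five(self):
        assert feat.distance_to_az((0, 0, 0), (3, 4, 0)) == 5.0

    def test_same_point_is_zero(self):
        assert feat.distance_to_az((1, 2, 3), (1, 2, 3)) == 0.0

    def test_anisotropic_z(self):
        # 3 slices at z spacing 2 nm = 6 nm apart in physical space
        assert feat.distance_to_az((0, 0, 0), (0, 0, 3 * 2.0)) == 6.0


class TestExtractTable:
    def test_one_record_per_vesicle_with_invariants(self, segmented_phantom):
        spec, truth, labels, scaled = segmented_phantom
        table = feat.extract_feature_table(scaled, labels, spec.az_point_nm,
                                           gv_polarity="dark_low")
        assert len(table) == labels.max()
        assert (table["r"] > 0).all()
        assert (table["GVSD"] >= 0).all()
        assert (table["distAZ"] >= 0).all()
        assert table["id"].is_unique

    def test_planted_distaz_recovered(self, segmented_phantom):
        spec, truth, labels, scaled = segmented_phantom
        table = feat.extract_feature_table(scaled, labels, spec.az_point_nm)
        from scipy.spatial import cKDTree
        d, idx = cKDTree(table[["x", "y", "z"]].to_numpy()).query(
            truth[["x", "y", "z"]].to_numpy())
        ok = d <= 2.0
        np.testing.assert_allclose(table["distAZ"].to_numpy()[idx[ok]],
                                   truth["distAZ"].to_numpy()[ok], atol=2.5)

    def test_label_permutation_leaves_feature_multiset(self):
        labels = np.zeros((6, 20, 20), dtype=np.int32)
        labels[1:4, 2:7, 2:7] = 1
        labels[2:5, 10:16, 10:16] = 2
        vox = np.random.default_rng(3).random((6, 20, 20)) * 100
        stack = TomogramStack(vox)
        t1 = feat.extract_feature_table(stack, labels, (0, 0, 0), membrane_nm=0.0)
        permuted = np.where(labels == 1, 2, np.where(labels == 2, 1, 0))
        t2 = feat.extract_feature_table(stack, permuted, (0, 0, 0), membrane_nm=0.0)
        for col in ("r", "gv", "GVSD", "distAZ"):
            assert sorted(t1[col]) == pytest.approx(sorted(t2[col]))

    def test_constant_shift_moves_gv_only(self):
        labels = np.zeros((6, 16, 16), dtype=np.int32)
        labels[1:5, 4:12, 4:12] = 1
        vox = np.random.default_rng(5).random((6, 16, 16)) * 50
        t1 = feat.extract_feature_table(TomogramStack(vox), labels, (0, 0, 0),
                                        membrane_nm=0.0)
        t2 = feat.extract_feature_table(TomogramStack(vox + 10.0), labels,
                                        (0, 0, 0), membrane_nm=0.0)
        assert t2["gv"].iloc[0] - t1["gv"].iloc[0] == pytest.approx(10.0)
        for col in ("r", "GVSD", "distAZ"):
            assert t2[col].iloc[0] == pytest.approx(t1[col].iloc[0])


class TestNormalizeAndOffset:
    def test_minmax_basic(self):
        np.testing.assert_allclose(feat.minmax_normalize([2, 4, 6]),
                                   [0.0, 0.5, 1.0])

    def test_single_value_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = feat.minmax_normalize([5.0])
        assert out == pytest.approx([0.0])

    def test_idempotent_on_unit_span(self):
        vals = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(feat.minmax_normalize(vals), vals)

    def test_per_tomogram_differs_from_joint(self):
        a, b = np.array([0.0, 10.0]), np.array([0.0, 20.0])
        sep = np.concatenate([feat.minmax_normalize(a), feat.minmax_normalize(b)])
        joint = feat.minmax_normalize(np.concatenate([a, b]))
        assert not np.allclose(sep, joint)

    def test_gv_offset_identity_when_at_threshold(self):
        import pandas as pd
        table = pd.DataFrame({"gv": [100.0, 130.0]})
        out = feat.apply_gv_offset(table, threshold=130.0)
        np.testing.assert_allclose(out["gv"], table["gv"])

    def test_gv_offset_shifts_all_by_deficit(self):
        import pandas as pd
        table = pd.DataFrame({"gv": [100.0, 123.0]})
        out = feat.apply_gv_offset(table, threshold=130.0)
        np.testing.assert_allclose(out["gv"], [107.0, 130.0])
        # translation: pairwise differences preserved
        assert np.ptp(out["gv"]) == np.ptp(table["gv"])


class TestCellVolume:
    def test_square_prism(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1)]
        outlines = {z: square for z in range(10)}
        assert feat.cell_volume(outlines, 2.0) == pytest.approx(20.0)

    def test_no_outlines_zero(self):
        assert feat.cell_volume({}, 1.0) == 0.0

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0, 0), (2, 2), (2, 0), (0, 2)]
        with pytest.raises(ValueError, match="polygon"):
            feat.cell_volume({0: bowtie}, 1.0)

    def test_shoelace_matches_rasterization(self):
        square = [(0, 0), (100, 0), (100, 100), (0, 100)]
        vol = feat.cell_volume({0: square}, 1.0)
        yy, xx = np.mgrid[0:100, 0:100]
        raster = np.count_nonzero((xx >= 0) & (xx < 100) & (yy >= 0) & (yy < 100))
        assert vol == pytest.approx(raster, rel=0.05)
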