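import numpy as np
import pytest

from voxeldegree import (
    ClusterMap,
    MaskGeometry,
    cluster_size_maps,
    icc,
    map_agreement_icc,
    rger,
    smooth_map,
    zscore_map,
)

from conftest import line_geometry, random_cluster_map, singleton_cluster_map


def _cluster_map(clusters):
    return ClusterMap(
        clusters=tuple(np.asarray(c) for c in clusters),
        flavor="combined",
        T_a_used=0.5,
        geometry=line_geometry(len(clusters)),
    )


class TestRger:
    def test_symmetric_membership_is_zero(self):
        cm = _cluster_map([[0, 1, 2], [0, 1, 2], [0, 1, 2]])
        assert rger(cm) == 0.0

    def test_single_asymmetric_pair(self):
        # C_0 = {0,1} but C_1 = {1}: one error over one pair
        cm = _cluster_map([[0, 1], [1]])
        assert rger(cm) == 1.0

    def test_matches_pair_enumeration_oracle(self, rng):
        cm = random_cluster_map(12, rng)
        errors = 0
        for i in range(12):
            for j in range(i + 1, 12):
                if (j in cm.clusters[i]) != (i in cm.clusters[j]):
                    errors += 1
        assert rger(cm) == pytest.approx(errors / (12 * 11 / 2), abs=0)


class TestClusterSizeMaps:
    def test_all_singletons(self):
        maps = cluster_size_maps(singleton_cluster_map(6))
        assert np.all(maps.type_I == 1) and np.all(maps.type_II == 1)

    def test_symmetric_cluster(self):
        cm = _cluster_map([[0, 1, 2], [0, 1, 2], [0, 1, 2], [3]])
        maps = cluster_size_maps(cm)
        assert maps.type_I.tolist() == [3, 3, 3, 1]
        assert maps.type_II.tolist() == [3, 3, 3, 1]

    def test_membership_count_oracle_and_sum_identity(self, rng):
        cm = random_cluster_map(15, rng)
        maps = cluster_size_maps(cm)
        for i in range(15):
            assert maps.type_I[i] == len(cm.clusters[i])
            assert maps.type_II[i] == sum(
                1 for j in range(15) if i in cm.clusters[j]
            )
        assert maps.type_I.sum() == maps.type_II.sum()


class TestZscore:
    def test_arithmetic(self):
        out = zscore_map(np.array([1.0, 2.0, 3.0]), ddof=1)
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0], atol=1e-15)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_map(np.full(5, 2.0))

    def test_population_standardization(self, rng):
        vals = rng.normal(5, 3, size=200)
        out = zscore_map(vals)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)


class TestSmooth:
    def test_constant_preserved(self):
        geom = MaskGeometry.from_mask(
            np.random.default_rng(0).random((6, 6, 6)) < 0.7,
            voxel_size=(3.0, 3.0, 3.0),
        )
        out = smooth_map(np.full(geom.V, 4.2), geom, fwhm_mm=8.0)
        np.testing.assert_allclose(out, 4.2, atol=1e-10)

    def test_zero_fwhm_is_identity(self, rng):
        geom = MaskGeometry.from_mask(np.ones((4, 4, 4), dtype=bool))
        vals = rng.normal(size=geom.V)
        np.testing.assert_array_equal(smooth_map(vals, geom, fwhm_mm=0.0), vals)

    def test_delta_matches_direct_kernel_oracle(self):
        geom = MaskGeometry.from_mask(
            np.ones((9, 9, 9), dtype=bool), voxel_size=(2.0, 2.0, 2.0)
        )
        vals = np.zeros(geom.V)
        center = int(geom.linear_index([[4, 4, 4]])[0])
        vals[center] = 1.0
        fwhm = 5.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / 2.0  # in voxel units
        out = smooth_map(vals, geom, fwhm_mm=fwhm, truncate=8.0)
        # direct normalized-kernel summation over the full grid
        d = geom.coords - geom.coords[center]
        kernel1d = {}
        radius = int(8.0 * sigma + 0.5)
        ax = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (ax / sigma) ** 2)
        k1 /= k1.sum()
        kv = lambda x: k1[x + radius] if abs(x) <= radius else 0.0
        num = np.array([kv(dx) * kv(dy) * kv(dz) for dx, dy, dz in d])
        den = np.array(
            [
                sum(
                    kv(px - cx) * kv(py - cy) * kv(pz - cz)
                    for px, py, pz in geom.coords
                    if max(abs(px - cx), abs(py - cy), abs(pz - cz)) <= radius
                )
                for cx, cy, cz in geom.coords
            ]
        )
        np.testing.assert_allclose(out, num / den, atol=1e-8)

    def test_linearity_and_positivity(self, rng):
        geom = MaskGeometry.from_mask(rng.random((5, 5, 5)) < 0.8)
        a, b = rng.normal(size=geom.V), rng.normal(size=geom.V)
        sa = smooth_map(a, geom, 6.0)
        sb = smooth_map(b, geom, 6.0)
        np.testing.assert_allclose(
            smooth_map(2 * a - 3 * b, geom, 6.0), 2 * sa - 3 * sb, atol=1e-10
        )
        pos = np.abs(a)
        assert np.all(smooth_map(pos, geom, 6.0) >= -1e-12)


class TestIcc:
    def test_perfect_agreement(self, rng):
        maps = rng.normal(size=(5, 30))
        out = map_agreement_icc(maps, maps.copy())
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_subject_permutation_destroys_agreement(self, rng):
        # maps_b from unrelated subjects: expected ICC ~ 0
        maps_a = rng.normal(size=(40, 400))
        maps_b = rng.normal(size=(40, 400))
        out = map_agreement_icc(maps_a, maps_b)
        assert abs(np.nanmean(out)) < 0.05

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        Y = rng.normal(size=(6, 2)) + rng.normal(size=(6, 1))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(6), 2),
                "raters": np.tile([0, 1], 6),
                "score": Y.ravel(),
            }
        )
        table = pg.intraclass_corr(df, "targets", "raters", "score")
        ref_a1 = float(table.loc[table.Type == "ICC(A,1)", "ICC"].iloc[0])
        ref_c1 = float(table.loc[table.Type == "ICC(C,1)", "ICC"].iloc[0])
        assert icc(Y[:, :, None])[0] == pytest.approx(ref_a1, abs=1e-10)
        assert icc(Y[:, :, None], variant="c1")[0] == pytest.approx(ref_c1, abs=1e-10)

    def test_hand_table_mean_squares_oracle(self):
        # 4 subjects x 2 raters, computed against the two-way ANOVA
        # mean-squares definition written out longhand
        Y = np.array([[1.0, 2.0], [3.0, 2.5], [5.0, 6.0], [7.0, 6.5]])
        n, k = Y.shape
        grand = Y.mean()
        msr = k * ((Y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((Y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sse = ((Y - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + mse + k * (msc - mse) / n)
        assert icc(Y[:, :, None])[0] == pytest.approx(expected, abs=1e-12)

    def test_needs_three_subjects(self, rng):
        with pytest.raises(ValueError, match="3 subjects"):
            map_agreement_icc(rng.normal(size=(2, 5)), rng.normal(size=(2, 5)))

    def test_affine_invariance(self, rng):
        Y = rng.normal(size=(8, 2, 10)) + rng.normal(size=(8, 1, 10))
        base = icc(Y)
        np.testing.assert_allclose(icc(3.0 * Y - 7.0), base, atol=1e-10)
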