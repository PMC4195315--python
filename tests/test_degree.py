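import numpy as np
import pytest

from voxeldegree import (
    DEFAULT_T_D_GRID,
    METRICS,
    ClusterMap,
    CorrelationMatrix,
    DegreeConfig,
    MaskGeometry,
    toy_network,
    indicator,
    rse_degree,
    threshold_sweep,
    traditional_degree,
    weight,
)

from conftest import (
    line_geometry,
    random_cluster_map,
    random_correlation_matrix,
    singleton_cluster_map,
)


def _weight_scalar(r, metric):
    return {
        "U": 1.0,
        "W": r,
        "WS": r * r,
        "WF": 0.5 * np.log((1 + r) / (1 - r)),
    }[metric]


def traditional_oracle(R, T_d, metric):
    """Direct double loop over voxel pairs."""
    V = R.shape[0]
    out = np.zeros(V)
    for i in range(V):
        for j in range(V):
            if j != i and R[i, j] >= T_d:
                out[i] += _weight_scalar(R[i, j], metric)
    return out


def rse_oracle(R, T_d, metric, clusters):
    """Direct triple loop over (i, j, k) following the corrected formula."""
    V = R.shape[0]
    out = np.zeros(V)
    for i in range(V):
        C_i = set(clusters[i].tolist())
        for j in range(V):
            if j == i or R[i, j] < T_d or j in C_i:
                continue
            s = sum(
                1
                for k in clusters[j].tolist()
                if k not in C_i and R[i, k] >= T_d
            )
            out[i] += _weight_scalar(R[i, j], metric) / s
    return out


class TestPrimitives:
    def test_indicator_inclusive_at_threshold(self):
        assert indicator(0.25, 0.25) == 1
        assert indicator(0.25 - 1e-9, 0.25) == 0
        assert indicator(-0.9, 0.2) == 0

    @pytest.mark.parametrize(
        "r,metric,expected",
        [
            (0.0, "WF", 0.0),
            (0.5, "WS", 0.25),
            (0.5, "W", 0.5),
            (0.5, "U", 1.0),
            (0.5, "WF", 0.5493061443340549),  # atanh(0.5)
        ],
    )
    def test_weights(self, r, metric, expected):
        assert weight(r, metric) == pytest.approx(expected, abs=1e-14)

    def test_wf_rejects_unit_correlation(self):
        with pytest.raises(ValueError, match="Fisher"):
            weight(1.0, "WF")


class TestToyNetwork:
    def test_traditional_degree_scales_with_region_size(self):
        _, matrix, _ = toy_network()
        u = traditional_degree(matrix, DegreeConfig(T_d=0.5, metric="U")).values
        assert u.tolist() == [3, 3, 3, 3, 1, 1]

    def test_corrected_degree_is_uniform(self):
        _, matrix, cluster_map = toy_network()
        u = rse_degree(
            matrix, DegreeConfig(T_d=0.5, metric="U", corrected=True), cluster_map
        ).values
        np.testing.assert_allclose(u, 1.0, atol=1e-15)

    def test_matches_region_level_graph(self):
        toy, _, _ = toy_network()
        assert set(toy.region_degrees().values()) == {1}

    def test_weighted_toy_values(self):
        _, matrix, cluster_map = toy_network()
        w = traditional_degree(matrix, DegreeConfig(T_d=0.5, metric="W")).values
        np.testing.assert_allclose(w, [2.7, 2.7, 2.7, 2.7, 0.9, 0.9], atol=1e-12)
        w_rse = rse_degree(
            matrix, DegreeConfig(T_d=0.5, metric="W", corrected=True), cluster_map
        ).values
        np.testing.assert_allclose(w_rse, 0.9, atol=1e-12)


class TestTraditional:
    def test_no_connections_gives_zero(self, rng):
        m = random_correlation_matrix(6, rng, lo=-0.5, hi=0.3)
        out = traditional_degree(m, DegreeConfig(T_d=0.4, metric="U")).values
        assert np.all(out == 0)

    @pytest.mark.parametrize("metric", METRICS)
    def test_matches_pairwise_oracle(self, rng, metric):
        m = random_correlation_matrix(8, rng)
        out = traditional_degree(m, DegreeConfig(T_d=0.2, metric=metric)).values
        np.testing.assert_allclose(
            out, traditional_oracle(m.values, 0.2, metric), atol=1e-12
        )

    def test_include_self_adds_constant_for_u(self, rng):
        m = random_correlation_matrix(5, rng)
        base = traditional_degree(m, DegreeConfig(T_d=0.3, metric="U")).values
        strict = traditional_degree(
            m, DegreeConfig(T_d=0.3, metric="U", include_self=True)
        ).values
        np.testing.assert_allclose(strict, base + 1, atol=1e-12)


class TestCorrected:
    def test_singleton_clusters_reduce_to_traditional(self, rng):
        for _ in range(5):
            m = random_correlation_matrix(12, rng)
            clusters = singleton_cluster_map(12)
            for metric in METRICS:
                trad = traditional_degree(
                    m, DegreeConfig(T_d=0.25, metric=metric)
                ).values
                rse = rse_degree(
                    m,
                    DegreeConfig(T_d=0.25, metric=metric, corrected=True),
                    clusters,
                ).values
                np.testing.assert_allclose(rse, trad, rtol=0, atol=1e-12)

    @pytest.mark.parametrize("metric", METRICS)
    def test_matches_triple_loop_oracle(self, rng, metric):
        m = random_correlation_matrix(10, rng)
        clusters = random_cluster_map(10, rng)
        out = rse_degree(
            m, DegreeConfig(T_d=0.2, metric=metric, corrected=True), clusters
        ).values
        np.testing.assert_allclose(
            out, rse_oracle(m.values, 0.2, metric, clusters.clusters), atol=1e-12
        )

    def test_region_level_equivalence_on_ideal_phantom(self):
        # regions of 3 and 2 voxels, fully cross-connected; clusters = regions:
        # the corrected degree equals the region-level degree (1) everywhere
        labels = np.array([0, 0, 0, 1, 1])
        R = np.where(labels[:, None] == labels[None, :], 0.9, 0.6)
        np.fill_diagonal(R, 1.0)
        geom = line_geometry(5)
        m = CorrelationMatrix(
            values=R, flavor="temporal", geometry=geom,
            degenerate=np.zeros(5, dtype=bool),
        )
        clusters = ClusterMap(
            clusters=tuple(np.flatnonzero(labels == labels[i]) for i in range(5)),
            flavor="combined",
            T_a_used=0.7,
            geometry=geom,
        )
        u = rse_degree(
            m, DegreeConfig(T_d=0.5, metric="U", corrected=True), clusters
        ).values
        np.testing.assert_allclose(u, 1.0, atol=1e-15)

    def test_provenance_recorded(self, rng):
        m = random_correlation_matrix(5, rng)
        clusters = singleton_cluster_map(5)
        res = rse_degree(
            m, DegreeConfig(T_d=0.3, metric="U", corrected=True), clusters
        )
        assert res.cluster_map_id is not None


class TestSweep:
    def test_default_grid(self):
        assert len(DEFAULT_T_D_GRID) == 8
        assert DEFAULT_T_D_GRID[0] == 0.15 and DEFAULT_T_D_GRID[-1] == 0.5
        np.testing.assert_allclose(np.diff(DEFAULT_T_D_GRID), 0.05)

    def test_traditional_monotone_nonincreasing_in_threshold(self, rng):
        # only the uncorrected metrics are monotone in T_d: for the corrected
        # ones a higher threshold can shrink s(i,j) and raise a 1/s weight
        m = random_correlation_matrix(10, rng, lo=0.0, hi=0.95)
        clusters = random_cluster_map(10, rng)
        results = [r for r in threshold_sweep(m, clusters) if not r.config.corrected]
        by_key = {}
        for res in results:
            by_key.setdefault(res.config.metric, []).append(
                (res.config.T_d, res.values)
            )
        for runs in by_key.values():
            runs.sort()
            for (_, lo_vals), (_, hi_vals) in zip(runs, runs[1:]):
                assert np.all(hi_vals <= lo_vals + 1e-12)

    def test_equals_independent_calls(self, rng):
        m = random_correlation_matrix(8, rng)
        clusters = random_cluster_map(8, rng)
        sweep = threshold_sweep(m, clusters, grid=(0.2, 0.4), metrics=("U", "WF"))
        assert len(sweep) == 8  # 2 thresholds x 2 metrics x {trad, rse}
        for res in sweep:
            c = res.config
            if c.corrected:
                ref = rse_degree(m, c, clusters).values
            else:
                ref = traditional_degree(m, c).values
            np.testing.assert_array_equal(res.values, ref)

    def test_weight_ordering_ws_w_wf(self, rng):
        # for included r in (0, 1): r^2 <= r <= atanh(r), so WS <= W <= WF
        m = random_correlation_matrix(9, rng, lo=0.3, hi=0.95)
        cfg = lambda metric: DegreeConfig(T_d=0.3, metric=metric)
        ws = traditional_degree(m, cfg("WS")).values
        w = traditional_degree(m, cfg("W")).values
        wf = traditional_degree(m, cfg("WF")).values
        assert np.all(ws <= w + 1e-12) and np.all(w <= wf + 1e-12)
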