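import numpy as np
import pytest

from irnet import (
    NO_DIRECTION,
    X_LEADS,
    Y_LEADS,
    EmbeddingSpec,
    RecurrencePlot,
    analyze_pair,
    build_irn,
    build_multiplex,
    classify_direction,
    cross_degree,
    cross_edge_density,
    global_cross_clustering,
    local_cross_clustering,
)
from conftest import random_irn


class TestToyExample:
    """The six-vertex worked example: all values are exact rationals."""

    def test_cross_degrees(self, toy_irn):
        assert [cross_degree(toy_irn, v) for v in range(6)] == [2, 1, 0, 2, 1, 0]

    def test_cross_edge_density(self, toy_irn):
        assert cross_edge_density(toy_irn) == 3 / 9

    def test_local_clustering(self, toy_irn):
        assert [local_cross_clustering(toy_irn, v) for v in range(3)] == [1, 0, 0]
        assert [local_cross_clustering(toy_irn, v) for v in range(3, 6)] == [0, 0, 0]

    def test_global_clustering(self, toy_irn):
        assert global_cross_clustering(toy_irn, "X") == 1 / 3
        assert global_cross_clustering(toy_irn, "Y") == 0.0


class TestBuildIRN:
    def test_composite_structure(self, toy_irn):
        a = toy_irn.adjacency
        assert a.shape == (6, 6)
        assert np.array_equal(a, a.T)
        assert not np.diag(a).any()

    def test_empty_cross_block_disconnects(self):
        eye = np.eye(4, dtype=np.uint8)
        blank = RecurrencePlot(eye, "auto", 0.1, 0.0)
        cr = RecurrencePlot(np.zeros((4, 4), dtype=np.uint8), "cross", 0.1, 0.0)
        g = build_irn(blank, blank, cr)
        assert all(cross_degree(g, v) == 0 for v in range(8))
        assert cross_edge_density(g) == 0.0

    def test_shape_mismatch(self):
        eye3 = RecurrencePlot(np.eye(3, dtype=np.uint8), "auto", 0.1, 0.0)
        eye4 = RecurrencePlot(np.eye(4, dtype=np.uint8), "auto", 0.1, 0.0)
        cr = RecurrencePlot(np.zeros((3, 3), dtype=np.uint8), "cross", 0.1, 0.0)
        with pytest.raises(ValueError, match="shape mismatch"):
            build_irn(eye3, eye4, cr)

    def test_complete_cross_block(self):
        eye = np.eye(3, dtype=np.uint8)
        auto = RecurrencePlot(eye, "auto", 0.1, 0.0)
        cr = RecurrencePlot(np.ones((3, 3), dtype=np.uint8), "cross", 9.0, 1.0)
        g = build_irn(auto, auto, cr)
        assert cross_edge_density(g) == 1.0
        assert all(cross_degree(g, v) == 3 for v in range(6))


def local_clustering_oracle(g, v):
    """Exhaustive triangle enumeration over all (v, u_i, u_j) triples."""
    a = g.adjacency
    n = a.shape[0]
    opposite = (
        range(g.n_x, n) if v < g.n_x else range(g.n_x)
    )
    nbrs = [u for u in opposite if a[v, u]]
    if len(nbrs) <= 1:
        return 0.0
    closed = sum(
        1 for ui in nbrs for uj in nbrs if ui != uj and a[ui, uj]
    )
    return closed / (len(nbrs) * (len(nbrs) - 1))


class TestClusteringOracle:
    def test_random_graphs_match_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = random_irn(rng)
            for v in range(g.n_x + g.n_y):
                assert local_cross_clustering(g, v) == pytest.approx(
                    local_clustering_oracle(g, v), abs=1e-12
                )
            cx = np.mean(
                [local_clustering_oracle(g, v) for v in range(g.n_x)]
            )
            assert global_cross_clustering(g, "X") == pytest.approx(cx, abs=1e-12)

    def test_unknown_vertex(self, toy_irn):
        with pytest.raises(KeyError):
            local_cross_clustering(toy_irn, 17)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "c_xy,c_yx,expected",
        [
            (0.131, 0.388, X_LEADS),
            (0.393, 0.109, Y_LEADS),
            (0.384, 0.379, NO_DIRECTION),  # |delta| = .005 inside the band
            (0.5, 0.5, NO_DIRECTION),
            (0.0, 0.011, X_LEADS),
        ],
    )
    def test_rule(self, c_xy, c_yx, expected):
        assert classify_direction(c_xy, c_yx) == expected

    def test_threshold_is_inclusive(self):
        assert classify_direction(0.21, 0.20) == NO_DIRECTION
        assert classify_direction(0.2101, 0.20) == Y_LEADS


class TestAnalyzePair:
    @pytest.mark.parametrize("convention", ["time", "graph"])
    def test_swap_law(self, convention):
        """Relabelling the systems swaps the two coefficients exactly."""
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(size=260))
        y = np.cumsum(rng.normal(size=260))
        spec = EmbeddingSpec(lag=4, dim=3)
        ab = analyze_pair(x, y, embedding=spec, convention=convention)
        ba = analyze_pair(y, x, embedding=spec, convention=convention)
        assert ab.c_xy == ba.c_yx
        assert ab.c_yx == ba.c_xy
        assert ab.rho_xy == ba.rho_xy

    def test_ranges_and_rho_identity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 300))
        s = analyze_pair(x, y, embedding=EmbeddingSpec(lag=2, dim=2))
        assert 0 <= s.c_xy <= 1 and 0 <= s.c_yx <= 1
        n = len(s.local_c_xy)
        # rho equals the realized cross recurrence rate by construction
        assert s.rho_xy == pytest.approx(0.03, abs=1 / (n * n) + 1e-12)

    def test_identical_series_zero_difference(self):
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.normal(size=300))
        s = analyze_pair(x, x.copy(), embedding=EmbeddingSpec(lag=3, dim=2))
        assert s.delta_c == 0.0
        assert s.direction == NO_DIRECTION

    def test_uncorrelated_cross_edges_match_density_expectation(self):
        """Randomly and independently distributed cross-edges make the
        expected cross-clustering equal the opposite block's edge density
        rho^Y (Monte-Carlo over independently redrawn cross blocks)."""
        from irnet import RecurrencePlot, auto_recurrence, build_irn

        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(size=200))
        y = np.cumsum(rng.normal(size=200))
        spec = EmbeddingSpec(lag=2, dim=2)
        from irnet import delay_embed

        r_x = auto_recurrence(delay_embed(x, spec), target_rr=0.05)
        r_y = auto_recurrence(delay_embed(y, spec), target_rr=0.05)
        n = r_x.shape[0]
        iu = np.triu_indices(n, 1)
        rho_y = r_y.matrix[iu].mean()
        values = []
        for _ in range(100):
            cr = RecurrencePlot(
                (rng.random((n, n)) < 0.03).astype(np.uint8), "cross", 1.0, 0.03
            )
            g = build_irn(r_x, r_y, cr)
            values.append(global_cross_clustering(g, "X"))
        assert np.mean(values) == pytest.approx(rho_y, abs=0.01)

    def test_scalar_series_require_embedding(self):
        with pytest.raises(ValueError, match="EmbeddingSpec"):
            analyze_pair(np.arange(50.0), np.arange(50.0))

    def test_time_convention_requires_equal_lengths(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="equal"):
            analyze_pair(
                rng.normal(size=(40, 2)),
                rng.normal(size=(50, 2)),
                convention="time",
            )


class TestAntiPersistenceLink:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_direction_of_inequality(self, seed):
        """A partner with anti-persistent (noise-like) dynamics depresses
        the cross-clustering far below the edge density; two persistent
        narrowband signals raise it far above. Direction of the
        inequalities only, across seeds."""
        rng = np.random.default_rng(seed)
        spec = EmbeddingSpec(lag=2, dim=3)
        rr = 0.05
        n = 600
        walk = np.cumsum(rng.normal(size=n))  # persistent
        anti = np.diff(rng.normal(size=n + 1))  # anti-persistent increments
        s_anti = analyze_pair(
            walk, anti, embedding=spec, rr_auto=rr, rr_cross=0.04
        )
        t = np.arange(n)
        per_x = np.sin(2 * np.pi * t / 60) + 0.05 * rng.normal(size=n)
        per_y = np.sin(2 * np.pi * t / 60 + 1.0) + 0.05 * rng.normal(size=n)
        s_per = analyze_pair(
            per_x, per_y, embedding=spec, rr_auto=rr, rr_cross=0.04
        )
        assert s_anti.c_xy < rr < s_per.c_xy
        assert s_anti.c_xy < rr / 2  # clearly below, not marginal
        assert s_per.c_xy > 2 * rr  # clearly above, not marginal


class TestMultiplex:
    def _series(self, rng, n=240):
        return np.cumsum(rng.normal(size=n))

    def test_edge_count_and_strengths(self):
        rng = np.random.default_rng(6)
        data = {
            name: (self._series(rng), self._series(rng))
            for name in ("ACC", "BVP", "EDA", "HR", "TEMP")
        }
        g = build_multiplex(data, embedding=EmbeddingSpec(lag=3, dim=2))
        assert g.number_of_edges() == 10
        for _, _, attrs in g.edges(data=True):
            assert attrs["weight"] == pytest.approx(
                abs(attrs["c_xy"] - attrs["c_yx"])
            )
        for node in g.nodes:
            incident = sum(g[node][other]["weight"] for other in g[node])
            assert g.nodes[node]["strength"] == pytest.approx(incident)

    def test_identical_series_everywhere_zero(self):
        rng = np.random.default_rng(7)
        base = self._series(rng)
        data = {name: (base.copy(), base.copy()) for name in ("a", "b", "c")}
        g = build_multiplex(data, embedding=EmbeddingSpec(lag=3, dim=2))
        assert all(w == 0.0 for _, _, w in g.edges(data="weight"))
        assert all(s == 0.0 for _, s in g.nodes(data="strength"))

    def test_needs_two_variables(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="two variables"):
            build_multiplex({"solo": (self._series(rng), self._series(rng))})

    def test_mismatched_lengths_rejected(self):
        rng = np.random.default_rng(9)
        data = {
            "a": (self._series(rng, 200), self._series(rng, 200)),
            "b": (self._series(rng, 150), self._series(rng, 150)),
        }
        with pytest.raises(ValueError, match="equal length"):
            build_multiplex(data, embedding=EmbeddingSpec(lag=3, dim=2))
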