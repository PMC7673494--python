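"""Resistor-network solver: toy circuits, a dense Laplacian oracle,
reciprocity, conservation and metric properties."""

import itertools

import numpy as np
import pytest

from conftest import make_grid
from sdmconnect.circuit import (
    build_network,
    cumulative_current,
    pinch_points,
    resistance_from_suitability,
    solve_pair,
    solve_all_pairs,
)
from sdmconnect.raster import NodeRaster


def _nodes(labels):
    return NodeRaster(np.asarray(labels, dtype=int))


def _network(resist_values, neighborhood=4, nodata=-9999.0):
    g = make_grid(resist_values, nodata=nodata, name="R")
    from sdmconnect.circuit import ResistanceGrid

    return build_network(ResistanceGrid(g), neighborhood)


def dense_solve(network, nodes, source, target):
    """Independent oracle: contract supernodes, build the dense graph
    Laplacian, solve via the Moore-Penrose pseudo-inverse."""
    node_labels = nodes.labels.ravel()[network.cell_index]
    n_cells = network.cell_index.size
    mapping = np.full(n_cells, -1)
    mapping[node_labels == source] = 0
    mapping[node_labels == target] = 1
    free = mapping < 0
    mapping[free] = 2 + np.arange(free.sum())
    n = 2 + int(free.sum())
    G = np.zeros((n, n))
    C = network.conductance.tocoo()
    # the symmetric sparse matrix holds both (i, j) and (j, i) entries
    for i, j, g in zip(C.row, C.col, C.data):
        a, b = mapping[i], mapping[j]
        if a != b:
            G[a, b] += g
    L = np.diag(G.sum(axis=1)) - G
    inj = np.zeros(n)
    inj[0], inj[1] = 1.0, -1.0
    v = np.linalg.pinv(L, rcond=1e-12) @ inj
    r_eff = v[0] - v[1]
    # per-node current: half-sum of incident branch currents
    cur = np.zeros(n)
    for a in range(n):
        for b in range(a + 1, n):
            if G[a, b] > 0:
                br = G[a, b] * abs(v[a] - v[b])
                cur[a] += br / 2
                cur[b] += br / 2
    cur[0] = cur[1] = 1.0
    return v, r_eff, cur, mapping


class TestResistance:
    def test_unit_suitability_unit_resistance(self):
        r = resistance_from_suitability(make_grid(np.ones((3, 3))))
        np.testing.assert_allclose(r.grid.values, 1.0)

    def test_zero_suitability_clamped(self):
        r = resistance_from_suitability(make_grid(np.zeros((3, 3))))
        np.testing.assert_allclose(r.grid.values, 100.0)

    def test_monotone_order_audit(self, rng):
        s = rng.random((10, 10))
        r = resistance_from_suitability(make_grid(s)).grid.values
        flat_s, flat_r = s.ravel(), r.ravel()
        order = np.argsort(flat_s)
        # where suitability strictly increases, resistance must not increase
        assert (np.diff(flat_r[order]) <= 1e-12).all()

    def test_linear_transform(self):
        r = resistance_from_suitability(
            make_grid(np.full((3, 3), 0.5)), transform="linear", c=99.0
        )
        np.testing.assert_allclose(r.grid.values, 1 + 99 * 0.5)

    def test_bad_floor(self):
        with pytest.raises(ValueError, match="floor"):
            resistance_from_suitability(make_grid(np.ones((3, 3))), floor=0.0)


class TestNetwork:
    def test_two_cell_series_average(self):
        net = _network(np.array([[2.0, 2.0]]))
        assert net.conductance[0, 1] == pytest.approx(2 / (2 + 2))

    def test_uniform_grid_uniform_conductance(self):
        net = _network(np.full((3, 3), 4.0), neighborhood=4)
        vals = net.conductance.tocoo().data
        np.testing.assert_allclose(vals, 2 / 8)

    def test_edge_enumeration_oracle(self, rng):
        R = rng.uniform(0.5, 5.0, size=(5, 5))
        net = _network(R, neighborhood=8)
        C = net.conductance.tocoo()
        got = {(min(i, j), max(i, j)): g for i, j, g in zip(C.row, C.col, C.data)}
        idx = np.arange(25).reshape(5, 5)
        expect = {}
        for r in range(5):
            for c in range(5):
                for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < 5 and 0 <= c2 < 5:
                        g = 2 / (R[r, c] + R[r2, c2])
                        if dr and dc:
                            g /= np.sqrt(2)
                        a, b = idx[r, c], idx[r2, c2]
                        expect[(min(a, b), max(a, b))] = g
        assert set(got) == set(expect)
        for k in expect:
            assert got[k] == pytest.approx(expect[k])


class TestSolvePair:
    def test_series_chain(self):
        net = _network(np.array([[1.0, 1.0, 1.0]]))
        labels = np.array([[1, 0, 2]])
        res = solve_pair(net, _nodes(labels), 1, 2)
        assert res.effective_resistance == pytest.approx(2.0)
        assert res.current.values[0, 1] == pytest.approx(1.0)

    def test_parallel_chains(self):
        # source spans column 0, target column 2; two 2-edge unit chains
        net = _network(np.ones((2, 3)), neighborhood=4)
        labels = np.array([[1, 0, 2], [1, 0, 2]])
        res = solve_pair(net, _nodes(labels), 1, 2)
        assert res.effective_resistance == pytest.approx(1.0)
        assert res.current.values[0, 1] == pytest.approx(0.5)
        assert res.current.values[1, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dense_pinv_oracle_random_grid(self, seed):
        rng = np.random.default_rng(seed)
        R = rng.uniform(0.2, 8.0, size=(4, 4))
        net = _network(R, neighborhood=8)
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = 1
        labels[3, 3] = 2
        res = solve_pair(net, _nodes(labels), 1, 2)
        v, r_eff, cur, mapping = dense_solve(net, _nodes(labels), 1, 2)
        assert res.effective_resistance == pytest.approx(r_eff, abs=1e-8)
        got = res.current.values.ravel()[net.cell_index]
        np.testing.assert_allclose(got, cur[mapping], atol=1e-8)

    def test_kirchhoff_conservation(self, rng):
        R = rng.uniform(0.5, 3.0, size=(6, 6))
        net = _network(R, neighborhood=8)
        labels = np.zeros((6, 6), dtype=int)
        labels[0, :2] = 1
        labels[5, 4:] = 2
        res = solve_pair(net, _nodes(labels), 1, 2)
        # recompute voltages via the oracle and check net current ~ 0
        v, _, _, mapping = dense_solve(net, _nodes(labels), 1, 2)
        C = net.conductance.tocoo()
        net_cur = np.zeros(2 + (mapping >= 2).sum())
        # each undirected edge contributes one (i, j) and one (j, i) entry,
        # so summing g (v_b - v_a) over all entries gives the net inflow
        for i, j, g in zip(C.row, C.col, C.data):
            a, b = mapping[i], mapping[j]
            if a != b:
                net_cur[a] += g * (v[b] - v[a])
        for node in range(2, len(net_cur)):
            assert abs(net_cur[node]) < 1e-8

    def test_reciprocity(self, rng):
        R = rng.uniform(0.2, 5.0, size=(5, 5))
        net = _network(R)
        labels = np.zeros((5, 5), dtype=int)
        labels[0, 0] = 1
        labels[4, 4] = 2
        ab = solve_pair(net, _nodes(labels), 1, 2)
        ba = solve_pair(net, _nodes(labels), 2, 1)
        assert ab.effective_resistance == pytest.approx(
            ba.effective_resistance, abs=1e-10
        )
        np.testing.assert_allclose(ab.current.values, ba.current.values, atol=1e-8)

    def test_resistance_metric_triangle(self, rng):
        R = rng.uniform(0.3, 4.0, size=(7, 7))
        net = _network(R)
        labels = np.zeros((7, 7), dtype=int)
        labels[0, 0], labels[0, 6], labels[6, 3] = 1, 2, 3
        nodes = _nodes(labels)
        r = {}
        for a, b in itertools.combinations([1, 2, 3], 2):
            r[(a, b)] = solve_pair(net, nodes, a, b).effective_resistance
        assert r[(1, 2)] <= r[(1, 3)] + r[(2, 3)] + 1e-10
        assert r[(1, 3)] <= r[(1, 2)] + r[(2, 3)] + 1e-10
        assert r[(2, 3)] <= r[(1, 2)] + r[(1, 3)] + 1e-10

    def test_doubling_resistance_scales_reff_not_current(self, rng):
        R = rng.uniform(0.5, 2.0, size=(5, 5))
        labels = np.zeros((5, 5), dtype=int)
        labels[0, 0], labels[4, 4] = 1, 2
        r1 = solve_pair(_network(R), _nodes(labels), 1, 2)
        r2 = solve_pair(_network(2 * R), _nodes(labels), 1, 2)
        assert r2.effective_resistance == pytest.approx(
            2 * r1.effective_resistance, rel=1e-10
        )
        np.testing.assert_allclose(r2.current.values, r1.current.values, atol=1e-10)

    def test_disconnected_pair_infinite(self):
        R = np.ones((3, 3))
        R[:, 1] = -9999.0  # barrier column
        net = _network(R, neighborhood=4)
        labels = np.zeros((3, 3), dtype=int)
        labels[1, 0], labels[1, 2] = 1, 2
        res = solve_pair(net, _nodes(labels), 1, 2)
        assert res.effective_resistance == np.inf
        assert (res.current.values[res.current.mask] == 0).all()


class TestCumulativeAndPinch:
    def test_single_pair_identity(self, rng):
        R = rng.uniform(0.5, 2.0, size=(4, 4))
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0], labels[3, 3] = 1, 2
        res = solve_pair(_network(R), _nodes(labels), 1, 2)
        cum = cumulative_current([res])
        np.testing.assert_array_equal(cum.values, res.current.values)

    def test_mirror_symmetric_corridors(self):
        # uniform resistance, mirror-symmetric landscape about the center row
        R = np.ones((5, 7))
        R[2, 1:6] = -9999.0  # central barrier creates two mirror corridors
        net = _network(R, neighborhood=4)
        labels = np.zeros((5, 7), dtype=int)
        labels[2, 0], labels[2, 6] = 1, 2
        res = solve_pair(net, _nodes(labels), 1, 2)
        cum = cumulative_current([res])
        pp = pinch_points(cum, quantile=0.5)
        np.testing.assert_array_equal(pp.values, pp.values[::-1, :])

    def test_median_quantile_threshold(self):
        cur = make_grid(np.array([[0.0, 1.0, 2.0, 3.0, 4.0]]))
        pp = pinch_points(cur, quantile=0.5)
        # median of nonzero currents {1,2,3,4} is 2.5: cells >= 2.5 flagged
        np.testing.assert_array_equal(pp.values, [[0, 0, 0, 1, 1]])

    def test_bad_quantile(self):
        with pytest.raises(ValueError, match="quantile"):
            pinch_points(make_grid(np.ones((2, 2))), quantile=1.5)

    def test_all_pairs_table(self, rng):
        R = rng.uniform(0.5, 2.0, size=(6, 6))
        labels = np.zeros((6, 6), dtype=int)
        labels[0, 0], labels[0, 5], labels[5, 0] = 1, 2, 3
        results, table = solve_all_pairs(_network(R), _nodes(labels))
        assert len(results) == 3
        assert set(zip(table["source"], table["target"])) == {
            ("node_1", "node_2"),
            ("node_1", "node_3"),
            ("node_2", "node_3"),
        }
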