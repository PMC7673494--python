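"""Circuit-theory landscape connectivity.

Each valid raster cell becomes a node of a resistor network; orthogonal
neighbors are joined by a resistor averaging the two cell resistances
(conductance ``g = 2 / (R_i + R_j)``), diagonal neighbors — included by
default — carry the same conductance divided by sqrt(2) for the longer
span.  All cells of a focal region (protected area) are contracted into
one supernode with zero internal resistance.  For a node pair, 1 A is
injected at the source supernode and the target is grounded; solving
the sparse Laplacian system gives node voltages, branch currents, a
per-cell current map and the pair's effective resistance.  Summing the
current maps over all pairs yields the cumulative current map whose
high-current cells are movement pinch points.

Resistance itself comes from inverting habitat suitability:
``R = 1 / max(s, floor)``, so the most suitable habitat is the cheapest
to traverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .raster import NodeRaster, RasterGrid

__all__ = [
    "ResistanceGrid",
    "CellNetwork",
    "PairwiseCurrentResult",
    "resistance_from_suitability",
    "build_network",
    "solve_pair",
    "solve_all_pairs",
    "cumulative_current",
    "pinch_points",
]


@dataclass
class ResistanceGrid:
    """Per-cell movement resistance (dimensionless ohm-equivalents)."""

    grid: RasterGrid
    derivation: str = "1/max(s, floor)"

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.mask]
        if vals.size and not (np.isfinite(vals).all() and (vals > 0).all()):
            raise ValueError("resistances must be positive and finite on valid cells")


def resistance_from_suitability(
    suitability: RasterGrid, floor: float = 0.01, transform: str = "inverse", c: float = 99.0
) -> ResistanceGrid:
    """Invert a suitability map into a resistance surface.

    ``transform='inverse'`` (default) gives ``R = 1 / max(s, floor)``,
    bounded in ``[1, 1/floor]``; ``transform='linear'`` gives
    ``R = 1 + c (1 - s)``.  Both are strictly decreasing in suitability.
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    s = suitability.values
    m = suitability.mask
    if s[m].size and (s[m].min() < 0 or s[m].max() > 1):
        raise ValueError("suitability must lie in [0, 1]")
    if transform == "inverse":
        r = 1.0 / np.maximum(s, floor)
    elif transform == "linear":
        r = 1.0 + c * (1.0 - s)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    out = np.where(m, r, suitability.nodata)
    return ResistanceGrid(
        suitability.with_values(out, name="resistance"),
        derivation=f"{transform}(floor={floor})",
    )


@dataclass
class CellNetwork:
    """Sparse resistor network over the valid cells of a grid."""

    conductance: sparse.csr_matrix  # (n_cells, n_cells), symmetric, no diagonal
    cell_index: np.ndarray  # flat raster index per network node
    shape: tuple[int, int]
    grid: RasterGrid


def build_network(R: ResistanceGrid, neighborhood: int = 8) -> CellNetwork:
    """Resistor network over valid cells.

    Orthogonal neighbors: ``g = 2 / (R_i + R_j)`` (series average of two
    half-cells).  With ``neighborhood=8`` diagonal neighbors get the
    same conductance divided by sqrt(2) for the longer span.  Nodata
    cells are barriers: no node, no edges.
    """
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    grid = R.grid
    mask = grid.mask
    n_valid = int(mask.sum())
    if n_valid < 2:
        raise ValueError("need at least 2 valid cells")
    idx = -np.ones(mask.shape, dtype=int)
    idx[mask] = np.arange(n_valid)
    r = grid.values
    rows_i, rows_j, g_vals = [], [], []
    offsets = [(0, 1), (1, 0)]
    if neighborhood == 8:
        offsets += [(1, 1), (1, -1)]
    n, m = mask.shape
    for dr, dc in offsets:
        r0 = slice(0, n - dr)
        r1 = slice(dr, n)
        if dc >= 0:
            c0, c1 = slice(0, m - dc), slice(dc, m)
        else:
            c0, c1 = slice(-dc, m), slice(0, m + dc)
        ok = mask[r0, c0] & mask[r1, c1]
        g = 2.0 / (r[r0, c0] + r[r1, c1])
        if dr != 0 and dc != 0:
            g = g / math.sqrt(2.0)
        rows_i.append(idx[r0, c0][ok])
        rows_j.append(idx[r1, c1][ok])
        g_vals.append(g[ok])
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    g = np.concatenate(g_vals)
    G = sparse.coo_matrix(
        (np.concatenate([g, g]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n_valid, n_valid),
    ).tocsr()
    return CellNetwork(G, np.flatnonzero(mask.ravel()), mask.shape, grid)


@dataclass
class PairwiseCurrentResult:
    """One solved node pair: current raster and effective resistance."""

    source: int
    target: int
    current: RasterGrid
    effective_resistance: float
    injected: float = 1.0


def _contract(network: CellNetwork, nodes: NodeRaster, labels_to_contract: list[int]):
    """Map cell-nodes to solver-nodes, merging each focal region into one.

    Returns (mapping array over network nodes, solver size, dict
    label -> solver node id).
    """
    node_labels = nodes.labels.ravel()[network.cell_index]
    n_cells = network.cell_index.size
    mapping = -np.ones(n_cells, dtype=int)
    super_id: dict[int, int] = {}
    next_id = 0
    for lab in labels_to_contract:
        cells = node_labels == lab
        if not cells.any():
            raise ValueError(f"focal node {lab} has no valid cells")
        super_id[lab] = next_id
        mapping[cells] = next_id
        next_id += 1
    free = mapping < 0
    mapping[free] = next_id + np.arange(int(free.sum()))
    return mapping, next_id + int(free.sum()), super_id


def solve_pair(
    network: CellNetwork, nodes: NodeRaster, source: int, target: int
) -> PairwiseCurrentResult:
    """Inject 1 A at the source supernode, ground the target, solve.

    Cell current is half the sum of incident branch currents (each
    branch contributes half to both endpoints); source and target
    supernode cells are assigned the full injected current by
    convention, so a map maximum at a terminal equals the total flow.
    A disconnected pair yields infinite effective resistance and a zero
    current map rather than an error.
    """
    if source == target:
        raise ValueError("source and target must differ")
    mapping, n_super, super_id = _contract(network, nodes, [source, target])
    s_id, t_id = super_id[source], super_id[target]

    # contracted conductance matrix
    G = network.conductance.tocoo()
    i2 = mapping[G.row]
    j2 = mapping[G.col]
    keep = i2 != j2  # internal supernode edges vanish (zero resistance)
    Gc = sparse.coo_matrix((G.data[keep], (i2[keep], j2[keep])), shape=(n_super, n_super)).tocsr()

    # connectivity check on the contracted graph
    n_comp, comp = connected_components(Gc, directed=False)
    if comp[s_id] != comp[t_id]:
        zero = np.where(network.grid.mask, 0.0, network.grid.nodata)
        return PairwiseCurrentResult(
            source, target, network.grid.with_values(zero, name="current"), math.inf
        )
    in_comp = comp == comp[s_id]

    deg = np.asarray(Gc.sum(axis=1)).ravel()
    L = sparse.diags(deg) - Gc
    # ground the target: delete its row/column
    keep_nodes = np.flatnonzero(in_comp)
    keep_nodes = keep_nodes[keep_nodes != t_id]
    pos = -np.ones(n_super, dtype=int)
    pos[keep_nodes] = np.arange(keep_nodes.size)
    Lr = L[keep_nodes][:, keep_nodes].tocsc()
    b = np.zeros(keep_nodes.size)
    b[pos[s_id]] = 1.0
    v_red = splu(Lr).solve(b)
    v = np.zeros(n_super)
    v[keep_nodes] = v_red

    # branch currents -> per-cell half-sum
    Gu = sparse.triu(Gc, k=1).tocoo()
    branch = Gu.data * np.abs(v[Gu.row] - v[Gu.col])
    node_cur = np.zeros(n_super)
    np.add.at(node_cur, Gu.row, branch)
    np.add.at(node_cur, Gu.col, branch)
    node_cur *= 0.5
    node_cur[s_id] = 1.0
    node_cur[t_id] = 1.0

    cell_cur = node_cur[mapping]
    flat = np.full(network.shape[0] * network.shape[1], network.grid.nodata)
    flat[network.cell_index] = cell_cur
    current = network.grid.with_values(
        flat.reshape(network.shape), name=f"current_{source}_{target}"
    )
    return PairwiseCurrentResult(source, target, current, float(v[s_id]))


def solve_all_pairs(
    network: CellNetwork, nodes: NodeRaster
) -> tuple[list[PairwiseCurrentResult], pd.DataFrame]:
    """Solve every unordered focal-node pair; returns results and a table
    (source, target, effective resistance, max cell current)."""
    ids = nodes.node_ids
    results = []
    rows = []
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1 :]:
            res = solve_pair(network, nodes, a, b)
            results.append(res)
            cur = res.current.values[res.current.mask]
            rows.append(
                {
                    "source": nodes.node_names[a],
                    "target": nodes.node_names[b],
                    "effective_resistance": res.effective_resistance,
                    "max_current": float(cur.max()) if cur.size else 0.0,
                }
            )
    return results, pd.DataFrame(rows)


def cumulative_current(results: list[PairwiseCurrentResult]) -> RasterGrid:
    """Per-cell sum of current over all solved pairs."""
    if not results:
        raise ValueError("need at least one solved pair")
    first = results[0].current
    acc = np.zeros_like(first.values)
    valid = np.ones(first.values.shape, dtype=bool)
    for res in results:
        valid &= res.current.mask
        acc += np.where(res.current.mask, res.current.values, 0.0)
    out = np.where(valid, acc, first.nodata)
    return first.with_values(out, name="cumulative_current")


def pinch_points(current: RasterGrid, quantile: float = 0.999) -> RasterGrid:
    """Cells whose (nonzero) current reaches the given quantile of the
    nonzero-current distribution — the narrow, irreplaceable corridors."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    vals = current.values
    m = current.mask
    nonzero = vals[m & (vals > 0)]
    if nonzero.size == 0:
        thresh = math.inf
    else:
        thresh = float(np.quantile(nonzero, quantile))
    # tolerant comparison so ties at the threshold are included even
    # under last-bit solver jitter
    tol = 1e-9 * max(1.0, abs(thresh))
    out = np.where(
        m, ((vals > 0) & (vals >= thresh - tol)).astype(float), current.nodata
    )
    return current.with_values(out, name="pinch_points")
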