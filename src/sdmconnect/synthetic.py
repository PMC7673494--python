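"""Synthetic landscapes with known species-environment truth.

Real occurrence records and the climate rasters behind a regional
habitat study are rarely redistributable, so the pipeline ships a
generator that reproduces their statistical structure: spatially
autocorrelated, partially cross-correlated environmental fields; a known
logistic suitability truth over a subset of them; presence points
sampled proportionally to that truth; disjoint quasi-circular focal
nodes standing in for protected areas; and "future climate" stacks
produced by additive/multiplicative shifts of the climatic layers.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .raster import NodeRaster, RasterGrid, RasterStack

__all__ = [
    "TruthModel",
    "ScenarioShift",
    "make_environment",
    "sample_occurrences",
    "make_nodes",
    "apply_scenario",
    "default_layer_names",
]

#: layer names used by the default synthetic landscape; the bio* layers
#: are flagged climatic and respond to scenario shifts
DEFAULT_LAYERS = (
    "bio3",
    "bio7",
    "bio11",
    "bio15",
    "bio17",
    "bio19",
    "altitude",
    "dist_streams",
    "fragmentation",
    "ndvi",
)

CLIMATIC_PREFIX = "bio"


def default_layer_names(n_layers: int) -> list[str]:
    if n_layers <= len(DEFAULT_LAYERS):
        return list(DEFAULT_LAYERS[:n_layers])
    extra = [f"env_{i}" for i in range(n_layers - len(DEFAULT_LAYERS))]
    return list(DEFAULT_LAYERS) + extra


@dataclass
class TruthModel:
    """The known species-environment relationship the models must recover.

    Suitability at a cell is ``sigmoid(beta0 + sum_j beta_j * z_j)`` where
    ``z_j`` are the named layers standardized over the valid study area.
    """

    beta0: float
    betas: Mapping[str, float]

    def __post_init__(self) -> None:
        if not any(v != 0 for v in self.betas.values()):
            raise ValueError("truth needs at least one nonzero coefficient")

    def suitability(self, stack: RasterStack) -> RasterGrid:
        """Per-cell true suitability in (0, 1); nodata outside the mask."""
        mask = stack.mask
        eta = np.full(mask.shape, self.beta0, dtype=float)
        for name, beta in self.betas.items():
            vals = stack[name].values
            mu = vals[mask].mean()
            sd = vals[mask].std()
            z = (vals - mu) / (sd if sd > 0 else 1.0)
            eta += beta * z
        suit = 1.0 / (1.0 + np.exp(-eta))
        out = np.where(mask, suit, -9999.0)
        return stack.template.with_values(out, name="truth_suitability")

    def to_dict(self) -> dict:
        return {"beta0": self.beta0, "betas": dict(self.betas)}

    @classmethod
    def from_dict(cls, d: dict) -> "TruthModel":
        return cls(beta0=d["beta0"], betas=d["betas"])


@dataclass
class ScenarioShift:
    """Per-layer additive delta / multiplicative factor for climate layers.

    Only layers flagged climatic (name starting with ``bio``, or listed
    in ``climatic_layers``) may be shifted; asking to shift any other
    layer is an error, mirroring the distinction between static terrain
    variables and scenario-dependent climate variables.
    """

    name: str = "scenario"
    deltas: dict[str, float] = field(default_factory=dict)
    factors: dict[str, float] = field(default_factory=dict)
    climatic_layers: Sequence[str] | None = None

    def is_climatic(self, layer: str) -> bool:
        if self.climatic_layers is not None:
            return layer in self.climatic_layers
        return layer.startswith(CLIMATIC_PREFIX)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "deltas": dict(self.deltas),
            "factors": dict(self.factors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioShift":
        return cls(
            name=d.get("name", "scenario"),
            deltas=d.get("deltas", {}),
            factors=d.get("factors", {}),
        )


def _gaussian_field(rng: np.random.Generator, shape: tuple[int, int], range_param: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    white = rng.standard_normal(shape)
    if range_param > 0:
        smooth = ndimage.gaussian_filter(white, sigma=range_param, mode="wrap")
    else:
        smooth = white
    smooth -= smooth.mean()
    sd = smooth.std()
    return smooth / (sd if sd > 0 else 1.0)


def make_environment(
    n_rows: int = 150,
    n_cols: int = 150,
    n_layers: int = 10,
    range_param: float = 8.0,
    cross_corr: np.ndarray | None = None,
    seed: int = 0,
    cell_size: float = 1000.0,
    layer_names: Sequence[str] | None = None,
) -> RasterStack:
    """Generate spatially autocorrelated, cross-correlated layers.

    Each layer is white noise convolved with a Gaussian kernel of sigma
    ``range_param`` cells; the independent fields are then linearly
    mixed by the Cholesky factor of ``cross_corr`` so that empirical
    inter-layer correlations approach the targets (within about 0.1 on
    grids of 100x100 and larger).
    """
    if cross_corr is None:
        cross_corr = np.eye(n_layers)
    cross_corr = np.asarray(cross_corr, dtype=float)
    if cross_corr.shape != (n_layers, n_layers):
        raise ValueError("cross_corr must be (n_layers, n_layers)")
    if not np.allclose(cross_corr, cross_corr.T):
        raise ValueError("cross_corr must be symmetric")
    eigvals = np.linalg.eigvalsh(cross_corr)
    if eigvals.min() < -1e-10:
        raise ValueError("cross_corr must be positive semi-definite")
    # PSD but singular matrices get a tiny ridge for the Cholesky factor
    L = np.linalg.cholesky(cross_corr + np.eye(n_layers) * max(1e-12, -eigvals.min() * 2 + 1e-12))

    rng = np.random.default_rng(seed)
    fields = np.stack(
        [_gaussian_field(rng, (n_rows, n_cols), range_param) for _ in range(n_layers)]
    )  # (k, r, c)
    # whiten the realized fields (smoothing induces chance correlations on
    # finite grids) so the mixed layers carry the target correlations
    flat = fields.reshape(n_layers, -1)
    emp = flat @ flat.T / flat.shape[1]
    white = np.linalg.solve(np.linalg.cholesky(emp), flat)
    mixed = (L @ white).reshape(n_layers, n_rows, n_cols)

    names = list(layer_names) if layer_names is not None else default_layer_names(n_layers)
    stack = RasterStack()
    for i, name in enumerate(names):
        stack.add(
            RasterGrid(
                mixed[i], x_min=0.0, y_min=0.0, cell_size=cell_size, name=name
            )
        )
    return stack


def sample_occurrences(
    truth: TruthModel,
    stack: RasterStack,
    n_presence: int = 80,
    seed: int = 0,
):
    """Draw presence cells without replacement, p proportional to truth.

    Points land on cell centers, so duplicates are impossible by
    construction.  Returns an :class:`~sdmconnect.occurrences.OccurrenceSet`
    of field presences.
    """
    from .occurrences import OccurrenceSet

    if n_presence < 1:
        raise ValueError("n_presence must be >= 1")
    mask = stack.mask
    valid_idx = np.flatnonzero(mask.ravel())
    if n_presence > valid_idx.size:
        raise ValueError(
            f"n_presence={n_presence} exceeds {valid_idx.size} valid cells"
        )
    # a precomputed suitability grid may stand in for the logistic truth
    if isinstance(truth, RasterGrid):
        suit = truth.values.ravel()[valid_idx]
    else:
        suit = truth.suitability(stack).values.ravel()[valid_idx]
    p = suit / suit.sum()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(valid_idx, size=n_presence, replace=False, p=p)
    t = stack.template
    rows, cols = np.unravel_index(chosen, mask.shape)
    records = []
    for r, c in zip(rows, cols):
        x, y = t.cell_center(int(r), int(c))
        records.append((x, y, "presence", "field"))
    return OccurrenceSet.from_records(records)


def make_nodes(
    template: RasterGrid,
    n_nodes: int = 6,
    mean_radius: float = 6.0,
    seed: int = 0,
    max_tries: int = 2000,
) -> NodeRaster:
    """Place disjoint quasi-circular focal-node blobs on the template grid.

    Radii vary +/-40% around ``mean_radius`` (cells); blobs are rejected
    if they touch an existing node, and a bounded number of retries
    guards against impossible packings.
    """
    rng = np.random.default_rng(seed)
    n, m = template.values.shape
    labels = np.zeros((n, m), dtype=int)
    rr, cc = np.mgrid[0:n, 0:m]
    placed = 0
    tries = 0
    while placed < n_nodes:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_nodes} disjoint nodes after {max_tries} tries"
            )
        tries += 1
        radius = mean_radius * rng.uniform(0.6, 1.4)
        r0 = rng.uniform(radius, n - radius)
        c0 = rng.uniform(radius, m - radius)
        blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        # keep a 1-cell moat so contracted nodes never touch
        dilated = ndimage.binary_dilation(blob)
        if not blob.any() or (labels[dilated] != 0).any():
            continue
        placed += 1
        labels[blob] = placed
    return NodeRaster(
        labels,
        {k: f"node_{k}" for k in range(1, n_nodes + 1)},
        x_min=template.x_min,
        y_min=template.y_min,
        cell_size=template.cell_size,
    )


def apply_scenario(stack: RasterStack, shift: ScenarioShift) -> RasterStack:
    """Shifted copy of the stack; only climatic layers change."""
    for name in list(shift.deltas) + list(shift.factors):
        if name not in stack.layers:
            raise KeyError(f"scenario shifts unknown layer {name!r}")
        if not shift.is_climatic(name):
            raise ValueError(f"layer {name!r} is not climatic; cannot be shifted")
    out = RasterStack()
    for name, grid in stack.layers.items():
        vals = grid.values
        if name in shift.factors or name in shift.deltas:
            factor = shift.factors.get(name, 1.0)
            delta = shift.deltas.get(name, 0.0)
            shifted = np.where(grid.mask, vals * factor + delta, vals)
            out.add(grid.with_values(shifted))
        else:
            out.add(grid.with_values(vals.copy()))
    return out
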