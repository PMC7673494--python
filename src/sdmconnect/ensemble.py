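"""Ensemble combination and binary-range bookkeeping.

Two ensembles are built: the continuous suitability ensemble, an
"accuracy rate as weight" average of the presence/absence model maps
with weights proportional to each model's AUC; and the presence-only
binary ensemble (majority vote of the three presence-only models) used
only to delimit where pseudo-absences may be drawn.  Continuous maps
are binarized at the max-TSS threshold, and suitable area is accounted
per scenario, inside and outside the focal-node (protected-area)
boundaries.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import AlignmentError, NodeRaster, RasterGrid, zonal_area

__all__ = [
    "ensemble_weights",
    "ensemble_continuous",
    "ensemble_binary_po",
    "binarize",
    "scenario_report",
]


def ensemble_weights(aucs: Mapping[str, float], rule: str = "auc") -> dict[str, float]:
    """Per-model weights from AUC values.

    ``rule='auc'`` uses ``w_i = AUC_i / sum AUC_j`` (the plain reading of
    accuracy-rate weighting); ``rule='skill'`` uses ``AUC_i - 0.5``
    renormalized, which rewards skill above chance more sharply.  Models
    with AUC <= 0.5 are worse than random and are rejected with a
    warning.
    """
    usable = {}
    for name, a in aucs.items():
        if a <= 0.5:
            warnings.warn(f"model {name!r} has AUC {a:.3f} <= 0.5; excluded")
            continue
        if a > 1.0:
            raise ValueError(f"AUC {a} > 1 for model {name!r}")
        usable[name] = a
    if not usable:
        raise ValueError("no model with AUC > 0.5")
    if rule == "auc":
        raw = {k: v for k, v in usable.items()}
    elif rule == "skill":
        raw = {k: v - 0.5 for k, v in usable.items()}
    else:
        raise ValueError(f"unknown weight rule {rule!r}")
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def ensemble_continuous(
    maps: Mapping[str, RasterGrid],
    aucs: Mapping[str, float],
    rule: str = "auc",
) -> RasterGrid:
    """AUC-weighted average of aligned continuous suitability maps.

    The output is a convex combination, so per cell it is bounded by the
    member maps; a nodata cell in any member is nodata in the output.
    """
    weights = ensemble_weights({k: aucs[k] for k in maps if k in aucs}, rule)
    grids = [maps[k] for k in weights]
    first = grids[0]
    for g in grids[1:]:
        if not g.aligned_with(first):
            raise AlignmentError(f"map {g.name!r} is not aligned")
    acc = np.zeros_like(first.values)
    valid = np.ones(first.values.shape, dtype=bool)
    for name, w in weights.items():
        g = maps[name]
        valid &= g.mask
        acc += w * np.where(g.mask, g.values, 0.0)
    out = np.where(valid, acc, first.nodata)
    return first.with_values(out, name="ensemble")


def ensemble_binary_po(
    binary_maps: Sequence[RasterGrid], rule: str = "majority"
) -> RasterGrid:
    """Combine the three presence-only binary maps into one.

    ``majority`` calls a cell suitable when at least 2 of 3 members do;
    ``unanimity`` requires all 3.
    """
    if rule not in ("majority", "unanimity"):
        raise ValueError(f"unknown rule {rule!r}")
    if len(binary_maps) != 3:
        raise ValueError(f"{rule} rule is defined for exactly 3 maps, got {len(binary_maps)}")
    first = binary_maps[0]
    for g in binary_maps[1:]:
        if not g.aligned_with(first):
            raise AlignmentError(f"map {g.name!r} is not aligned")
    valid = np.ones(first.values.shape, dtype=bool)
    votes = np.zeros(first.values.shape)
    for g in binary_maps:
        valid &= g.mask
        votes += np.where(g.mask, g.values, 0.0)
    need = 2 if rule == "majority" else 3
    out = np.where(valid, (votes >= need).astype(float), first.nodata)
    return first.with_values(out, name=f"po_ensemble_{rule}")


def binarize(grid: RasterGrid, threshold: float) -> RasterGrid:
    """Suitable (1) where ``score > threshold`` (strict), else 0."""
    out = np.where(grid.mask, (grid.values > threshold).astype(float), grid.nodata)
    return grid.with_values(out, name=f"{grid.name}_binary")


def scenario_report(
    binary_maps: Mapping[str, RasterGrid],
    nodes: NodeRaster,
    valid_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Suitable-area table per scenario: total km2, % of the study area,
    and the split inside/outside the focal-node boundaries.

    ``inside + outside == total`` holds exactly on every row.
    """
    rows = []
    for name, grid in binary_maps.items():
        za = zonal_area(grid, nodes).iloc[0]
        n_valid = int(
            (valid_mask if valid_mask is not None else grid.mask).sum()
        )
        n_suit = int((grid.mask & (grid.values == 1)).sum())
        rows.append(
            {
                "scenario": name,
                "area_km2": za["area_km2"],
                "pct_of_total": 100.0 * n_suit / n_valid if n_valid else 0.0,
                "inside_pa_km2": za["inside_km2"],
                "outside_pa_km2": za["outside_km2"],
            }
        )
    return pd.DataFrame(rows)
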