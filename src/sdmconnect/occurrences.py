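"""Occurrence records, predictor pruning, spatial thinning and
pseudo-absence generation.

Presence-only field records are prepared for presence/absence modelling
in three steps: collinear predictors are dropped by a greedy |r| > 0.75
rule, presences are thinned to a minimum nearest-neighbor distance to
damp spatial autocorrelation, and pseudo-absences are drawn from cells a
presence-only model ensemble classifies as unsuitable, at twice the
presence count and at least 5 km from every presence and from each
other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .raster import RasterGrid, RasterStack

__all__ = [
    "OccurrenceSet",
    "prune_correlated",
    "thin_occurrences",
    "generate_pseudo_absences",
    "QuotaError",
]

LABELS = ("presence", "pseudo_absence")
ORIGINS = ("field", "generated")


class QuotaError(RuntimeError):
    """Raised when the pseudo-absence quota cannot be met.

    Carries ``achievable``, the number of points that could be placed.
    """

    def __init__(self, msg: str, achievable: int):
        super().__init__(msg)
        self.achievable = achievable


@dataclass
class OccurrenceSet:
    """Labeled point records: presences and generated pseudo-absences."""

    data: pd.DataFrame
    crs_note: str = "projected equal-area, meters"

    def __post_init__(self) -> None:
        required = {"x", "y", "label", "origin"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"occurrence table needs columns {sorted(required)}")
        bad = set(self.data["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}")
        if self.data.duplicated(subset=["x", "y", "label"]).any():
            raise ValueError("duplicate (x, y, label) records")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[float, float, str, str]]
    ) -> "OccurrenceSet":
        return cls(pd.DataFrame(records, columns=["x", "y", "label", "origin"]))

    @property
    def presences(self) -> pd.DataFrame:
        return self.data[self.data["label"] == "presence"]

    @property
    def absences(self) -> pd.DataFrame:
        return self.data[self.data["label"] == "pseudo_absence"]

    def __len__(self) -> int:
        return len(self.data)

    def xy(self, label: str | None = None) -> np.ndarray:
        df = self.data if label is None else self.data[self.data["label"] == label]
        return df[["x", "y"]].to_numpy(dtype=float)

    def labels01(self) -> np.ndarray:
        """1 for presence, 0 for pseudo-absence."""
        return (self.data["label"] == "presence").to_numpy(dtype=int)

    def merge(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(pd.concat([self.data, other.data], ignore_index=True))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Predictor pruning
# ---------------------------------------------------------------------------


def prune_correlated(
    stack: RasterStack, threshold: float = 0.75
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Greedy removal of collinear layers until no pair has |r| > threshold.

    Pearson correlations are computed over jointly valid cells.  While a
    violating pair exists, the member with the larger mean absolute
    correlation to all remaining layers is dropped (ties broken
    alphabetically).  Deterministic and idempotent.
    """
    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least 2 layers to prune")
    mask = stack.mask
    if mask.sum() < 2:
        raise ValueError("fewer than 2 jointly valid cells")
    X = stack.env_matrix()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=names, columns=names)

    kept = list(names)
    dropped: list[str] = []
    while True:
        sub = corr_df.loc[kept, kept].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        mean_abs = sub.mean(axis=1)
        cand = sorted(
            [kept[i], kept[j]],
            key=lambda n: (-mean_abs[kept.index(n)], n),
        )
        loser = cand[0]
        kept.remove(loser)
        dropped.append(loser)
    return kept, dropped, corr_df


# ---------------------------------------------------------------------------
# Spatial thinning
# ---------------------------------------------------------------------------


def thin_occurrences(
    points: OccurrenceSet, min_dist: float, seed: int = 0
) -> OccurrenceSet:
    """Greedy spatial thinning to a minimum inter-point distance.

    Repeatedly finds the currently closest violating pair and deletes
    the member with more neighbors inside ``min_dist`` (ties broken by a
    seeded RNG).  The input is canonically sorted first so the result
    does not depend on record order.  The retained set is maximal: every
    removed point violated the distance against some retained point.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    df = points.data.sort_values(["x", "y", "label"]).reset_index(drop=True)
    n = len(df)
    if n <= 1 or min_dist == 0:
        return OccurrenceSet(df)
    xy = df[["x", "y"]].to_numpy(dtype=float)
    dist = squareform(pdist(xy))
    np.fill_diagonal(dist, np.inf)
    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    while True:
        d = dist[np.ix_(alive, alive)]
        if d.size == 0 or d.min() >= min_dist:
            break
        idx_alive = np.flatnonzero(alive)
        i_s, j_s = np.unravel_index(np.argmin(d), d.shape)
        i, j = idx_alive[i_s], idx_alive[j_s]
        # neighbor counts inside min_dist among the living
        ni = int((dist[i, alive] < min_dist).sum())
        nj = int((dist[j, alive] < min_dist).sum())
        if ni > nj:
            drop = i
        elif nj > ni:
            drop = j
        else:
            drop = int(rng.choice([i, j]))
        alive[drop] = False
    return OccurrenceSet(df[alive].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Pseudo-absences
# ---------------------------------------------------------------------------


def generate_pseudo_absences(
    stack: RasterStack,
    presences: OccurrenceSet,
    po_ensemble_binary: RasterGrid,
    multiplier: int = 2,
    min_dist: float = 5000.0,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw pseudo-absences from cells the presence-only ensemble calls
    unsuitable.

    Exactly ``multiplier * n_presence`` points are returned, each at
    least ``min_dist`` meters from every presence and from every other
    pseudo-absence (the stricter mutual reading, which prevents clumped
    absences).  Candidates are visited in a seeded random order;
    exhausting them before the quota raises :class:`QuotaError` with the
    achievable count.
    """
    t = stack.template
    if po_ensemble_binary.values.shape != t.values.shape:
        raise ValueError("presence-only binary map is not aligned with the stack")
    n_presence = len(presences.presences)
    quota = multiplier * n_presence
    eligible = (
        stack.mask
        & po_ensemble_binary.mask
        & (po_ensemble_binary.values == 0)
    )
    cand_idx = np.flatnonzero(eligible.ravel())
    if cand_idx.size == 0:
        raise QuotaError("no cells classified unsuitable by the PO ensemble", 0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(cand_idx.size)
    pres_xy = presences.xy("presence")
    chosen_xy: list[tuple[float, float]] = []
    for k in order:
        if len(chosen_xy) == quota:
            break
        r, c = np.unravel_index(cand_idx[k], t.values.shape)
        x, y = t.cell_center(int(r), int(c))
        p = np.array([[x, y]])
        if pres_xy.size and cdist(p, pres_xy).min() < min_dist:
            continue
        if chosen_xy and cdist(p, np.asarray(chosen_xy)).min() < min_dist:
            continue
        chosen_xy.append((x, y))
    if len(chosen_xy) < quota:
        raise QuotaError(
            f"only {len(chosen_xy)} of {quota} pseudo-absences placeable under "
            f"the {min_dist} m constraint",
            len(chosen_xy),
        )
    return OccurrenceSet.from_records(
        [(x, y, "pseudo_absence", "generated") for x, y in chosen_xy]
    )
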