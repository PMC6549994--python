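"""Change analysis between two categorical maps.

Cross-tabulation, per-class gains/losses/net change budgets, Boolean
transition masks and polynomial trend surfaces of change intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .grid import CategoricalRaster, ContinuousRaster, Legend, assert_coregistered

__all__ = [
    "TransitionCountMatrix",
    "ChangeBudget",
    "cross_tabulate",
    "change_budget",
    "transition_mask",
    "trend_surface",
]

MASK_LEGEND = Legend([(0, "no_change"), (1, "change")])


@dataclass
class TransitionCountMatrix:
    """Pixel counts for every ordered class pair between two dates.

    ``counts[i, j]`` is the number of pixels of legend class ``i`` at t1 that
    are legend class ``j`` at t2; the diagonal holds persistence counts.
    """

    counts: np.ndarray
    legend: Legend
    n_valid: int
    cell_area: float  # hectares per pixel

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.legend)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise ValueError("negative transition counts")
        if int(self.counts.sum()) != self.n_valid:
            raise ValueError(
                f"counts sum {int(self.counts.sum())} != n_valid {self.n_valid}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.legend.names, columns=self.legend.names)

    def dropped_transitions(self, min_cells: int) -> list[tuple[int, int, int]]:
        """Off-diagonal transitions with fewer than ``min_cells`` pixels."""
        out = []
        codes = self.legend.codes
        for i in range(len(codes)):
            for j in range(len(codes)):
                if i != j and 0 < self.counts[i, j] < min_cells:
                    out.append((codes[i], codes[j], int(self.counts[i, j])))
        return out


@dataclass
class ChangeBudget:
    """Per-class gains/losses/net change and pairwise contributions, in ha."""

    gains: pd.Series
    losses: pd.Series
    net: pd.Series
    contributions: pd.DataFrame  # contributions.loc[i, j]: class i's contribution to j's net

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"gains_ha": self.gains, "losses_ha": self.losses,
                             "net_ha": self.net})


def cross_tabulate(t1: CategoricalRaster, t2: CategoricalRaster) -> TransitionCountMatrix:
    """Cross-tabulate two co-registered maps into a transition count matrix."""
    assert_coregistered(t1, t2)
    if t1.legend != t2.legend:
        raise ValueError(f"legend mismatch: {t1.legend.names} vs {t2.legend.names}")
    legend = t1.legend
    valid = t1.valid & t2.valid
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("zero cells valid in both rasters")
    k = len(legend)
    lut = np.full(max(legend.codes) + 1, -1, dtype=np.int64)
    for idx, code in enumerate(legend.codes):
        lut[code] = idx
    i = lut[t1.values[valid]]
    j = lut[t2.values[valid]]
    counts = np.bincount(i * k + j, minlength=k * k).reshape(k, k)
    return TransitionCountMatrix(counts, legend, n_valid, t1.transform.cell_area_ha)


def change_budget(m: TransitionCountMatrix) -> ChangeBudget:
    """Gains, losses, net change (ha) per class, plus pairwise contributions."""
    c = m.counts.astype(float) * m.cell_area
    off = c - np.diag(np.diag(c))
    gains = pd.Series(off.sum(axis=0), index=m.legend.names)
    losses = pd.Series(off.sum(axis=1), index=m.legend.names)
    net = gains - losses
    contributions = pd.DataFrame(c - c.T, index=m.legend.names, columns=m.legend.names)
    return ChangeBudget(gains, losses, net, contributions)


def transition_mask(t1: CategoricalRaster, t2: CategoricalRaster,
                    from_set: Iterable[int], to_set: Iterable[int]) -> CategoricalRaster:
    """Boolean 0/1 map of cells changing from ``from_set`` into ``to_set``.

    A cell is 1 iff its t1 class is in ``from_set``, its t2 class is in
    ``to_set`` *and the class changed* — persistence is never change.  Nodata
    in either input propagates.
    """
    assert_coregistered(t1, t2)
    from_codes = {int(c) for c in from_set}
    to_codes = {int(c) for c in to_set}
    if not from_codes or not to_codes:
        raise ValueError("from_set and to_set must be non-empty")
    valid = t1.valid & t2.valid
    changed = (
        np.isin(t1.values, sorted(from_codes))
        & np.isin(t2.values, sorted(to_codes))
        & (t1.values != t2.values)
    )
    out = np.where(changed & valid, 1, 0).astype(np.int64)
    nodata = -1
    out[~valid] = nodata
    return CategoricalRaster(out, nodata, t1.transform, t1.crs_tag, MASK_LEGEND)


def _poly_terms(order: int) -> list[tuple[int, int]]:
    return [(a, b) for total in range(order + 1)
            for a in range(total + 1) for b in [total - a]]


def _design_matrix(xs: np.ndarray, ys: np.ndarray, order: int) -> np.ndarray:
    return np.column_stack([xs ** a * ys ** b for a, b in _poly_terms(order)])


def trend_surface(mask: CategoricalRaster, order: int = 3) -> ContinuousRaster:
    """Least-squares bivariate polynomial fit of a 0/1 change indicator.

    Pixel-centre coordinates are standardized to [-1, 1] per axis before
    fitting for numerical stability; the fitted surface is evaluated on the
    whole grid (nodata cells stay nodata).
    """
    if order < 1:
        raise ValueError(f"polynomial order must be >= 1, got {order}")
    nrows, ncols = mask.shape
    rows, cols = np.mgrid[0:nrows, 0:ncols]
    x, y = mask.transform.cell_center(rows, cols)
    xs = _standardize(x)
    ys = _standardize(y)
    valid = mask.valid
    n_terms = len(_poly_terms(order))
    if int(valid.sum()) < n_terms:
        raise ValueError(
            f"trend surface needs >= {n_terms} valid cells for order {order}, "
            f"got {int(valid.sum())}"
        )
    design = _design_matrix(xs[valid], ys[valid], order)
    z = (mask.values[valid] == 1).astype(float)
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    surface = _design_matrix(xs.ravel(), ys.ravel(), order) @ coef
    surface = surface.reshape(nrows, ncols)
    return ContinuousRaster(surface, ~valid, mask.transform, mask.crs_tag,
                            units="change density")


def _standardize(coord: np.ndarray) -> np.ndarray:
    lo, hi = coord.min(), coord.max()
    if hi == lo:
        return np.zeros_like(coord)
    return 2.0 * (coord - lo) / (hi - lo) - 1.0
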