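"""Explanatory-variable construction and screening.

Distance transforms (the dynamic variables), evidence-likelihood
transformation of categorical layers, and Cramer's V association screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import CategoricalRaster, ContinuousRaster, assert_coregistered

__all__ = [
    "DriverVariable",
    "ScreeningResult",
    "distance_to_class",
    "evidence_likelihood",
    "cramers_v",
    "screen_variables",
    "CRAMERS_V_THRESHOLD",
]

CRAMERS_V_THRESHOLD = 0.15


@dataclass
class DriverVariable:
    """A named explanatory variable with its screening statistic.

    ``dynamic`` marks distance-to-class variables that must be recomputed at
    each projection step as the landscape changes.
    """

    name: str
    raster: ContinuousRaster | CategoricalRaster
    dynamic: bool = False
    cramers_v: float | None = None
    # populated for dynamic distance variables so projection can rebuild them
    distance_target: frozenset | None = None

    def __post_init__(self) -> None:
        if self.cramers_v is not None and not (0.0 <= self.cramers_v <= 1.0):
            raise ValueError(f"cramers_v must lie in [0, 1], got {self.cramers_v}")


@dataclass
class ScreeningResult:
    """Partition of driver variables by the Cramer's V threshold."""

    retained: list[DriverVariable]
    dropped: list[DriverVariable]
    threshold: float

    def report(self) -> pd.DataFrame:
        rows = [(v.name, v.cramers_v, True) for v in self.retained]
        rows += [(v.name, v.cramers_v, False) for v in self.dropped]
        return pd.DataFrame(rows, columns=["name", "cramers_v", "retained"])


def distance_to_class(map: CategoricalRaster, target: Iterable[int]) -> ContinuousRaster:
    """Euclidean distance (map units, pixel centre to pixel centre) from every
    cell to the nearest cell of a target class; target cells score 0.
    """
    target_codes = sorted({int(c) for c in target})
    is_target = np.isin(map.values, target_codes) & map.valid
    if not is_target.any():
        raise ValueError(f"no cells of target classes {target_codes}: distance undefined")
    px = map.transform.pixel_size
    dist = ndimage.distance_transform_edt(~is_target, sampling=px)
    return ContinuousRaster(dist, ~map.valid, map.transform, map.crs_tag, units="m")


def evidence_likelihood(categorical: CategoricalRaster, change: CategoricalRaster,
                        mode: str = "relative_frequency") -> ContinuousRaster:
    """Evidence-likelihood transformation of a categorical layer.

    Every cell takes the value EL(c) of its category c.  With the default
    ``relative_frequency`` mode, EL(c) is the relative frequency with which
    category c occurs within change cells — counts of change cells in c over
    all change cells, so values sum to 1 over categories.  ``conditional``
    instead gives P(change | category c).
    """
    assert_coregistered(categorical, change)
    if mode not in ("relative_frequency", "conditional"):
        raise ValueError(f"unknown evidence-likelihood mode {mode!r}")
    valid = categorical.valid & change.valid
    changed = (change.values == 1) & valid
    n_change = int(changed.sum())
    if n_change == 0:
        raise ValueError("change mask has zero change cells: evidence likelihood undefined")
    codes = categorical.legend.codes
    el: dict[int, float] = {}
    for code in codes:
        in_cat = categorical.values == code
        n_cat_change = int((in_cat & changed).sum())
        if mode == "relative_frequency":
            el[code] = n_cat_change / n_change
        else:
            n_cat = int((in_cat & valid).sum())
            el[code] = n_cat_change / n_cat if n_cat else 0.0
    out = np.zeros(categorical.shape, dtype=float)
    for code, value in el.items():
        out[categorical.values == code] = value
    return ContinuousRaster(out, ~valid, categorical.transform, categorical.crs_tag,
                            units="evidence likelihood")


def _discretize(variable, n_bins: int, valid: np.ndarray) -> np.ndarray:
    """Integer bin labels for the valid cells of a driver layer."""
    if isinstance(variable, CategoricalRaster):
        return variable.values[valid]
    vals = variable.values[valid]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.zeros(vals.shape, dtype=np.int64)
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.digitize(vals, edges[1:-1], right=False)
    return bins


def cramers_v(variable, response: CategoricalRaster, n_bins: int = 256) -> float:
    """Cramer's V between a driver layer and a categorical response.

    Continuous variables are discretized into ``n_bins`` equal-interval bins
    over their valid range.  V = sqrt(chi2 / (n * (min(r, c) - 1))) on the
    bin-by-response contingency table with empty rows/columns removed.
    """
    assert_coregistered(variable, response)
    valid = variable.valid & response.valid
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no jointly valid cells")
    resp = response.values[valid]
    if np.unique(resp).size < 2:
        raise ValueError("response is constant: Cramer's V undefined")
    bins = _discretize(variable, n_bins, valid)
    table = pd.crosstab(bins, resp).to_numpy()
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if min(r, c) < 2:
        return 0.0  # variable constant after binning: no association
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    v = np.sqrt(chi2 / (n * (min(r, c) - 1)))
    return float(min(v, 1.0))


def screen_variables(variables: Sequence[DriverVariable],
                     threshold: float = CRAMERS_V_THRESHOLD) -> ScreeningResult:
    """Partition variables by V > threshold (ties dropped), preserving order."""
    retained, dropped = [], []
    for var in variables:
        if var.cramers_v is None:
            raise ValueError(f"variable {var.name!r} has no Cramer's V computed")
        (retained if var.cramers_v > threshold else dropped).append(var)
    return ScreeningResult(retained, dropped, threshold)
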