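"""Synthetic co-registered landscapes with known generating dynamics.

Generates a spatially autocorrelated categorical map (classes thresholded
from a smoothed Gaussian noise field at quantiles of the target shares),
driver covariates, and a second-date map evolved under a known row-stochastic
transition matrix whose off-diagonal probabilities are modulated per pixel by
a log-linear function of the drivers, renormalized so the landscape-expected
matrix equals the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grid import CategoricalRaster, ContinuousRaster, GridTransform, Legend

__all__ = ["DriverSpec", "SyntheticScenario", "generate_t1", "evolve"]

_SURFACE_KINDS = ("smooth-gradient", "smoothed-noise", "distance-to-random-lines")


@dataclass(frozen=True)
class DriverSpec:
    """One synthetic covariate surface and its effect on transition log-odds.

    ``beta`` multiplies the standardized surface value in the log-linear
    modulation of off-diagonal transition probabilities; 0 means the driver
    is pure noise with respect to change.
    """

    name: str
    surface: str = "smoothed-noise"
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.surface not in _SURFACE_KINDS:
            raise ValueError(f"surface must be one of {_SURFACE_KINDS}, got {self.surface!r}")


@dataclass
class SyntheticScenario:
    """Full description of a synthetic two-date landscape."""

    seed: int
    shape: tuple[int, int] = (100, 100)
    pixel_size: float = 25.0
    shares: Sequence[float] = (0.5, 0.5)
    autocorr_length: float = 5.0
    P_true: np.ndarray | None = None          # per base interval; identity if None
    drivers: Sequence[DriverSpec] = field(default_factory=list)
    legend: Legend | None = None
    nodata_margin: int = 0                     # width of a nodata border, pixels

    def __post_init__(self) -> None:
        shares = np.asarray(self.shares, dtype=float)
        if shares.ndim != 1 or shares.size < 2:
            raise ValueError("need at least 2 class shares")
        if (shares <= 0).any() or abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError(f"class shares must be positive and sum to 1, got {shares}")
        if self.autocorr_length < 1:
            raise ValueError("autocorrelation length must be >= 1 pixel")
        k = shares.size
        if self.legend is None:
            self.legend = Legend([(i + 1, f"class_{i + 1}") for i in range(k)])
        if len(self.legend) != k:
            raise ValueError("legend size != number of shares")
        if self.P_true is None:
            self.P_true = np.eye(k)
        self.P_true = np.asarray(self.P_true, dtype=float)
        if self.P_true.shape != (k, k):
            raise ValueError(f"P_true shape {self.P_true.shape} != ({k}, {k})")
        if (self.P_true < 0).any() or np.abs(self.P_true.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("P_true must be row-stochastic")
        min_cells = 1.0 / min(shares)
        if np.prod(self.shape) < min_cells:
            raise ValueError("grid too small for the requested shares")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(0.0, self.shape[0] * self.pixel_size, self.pixel_size)

    @property
    def nodata(self) -> int:
        return -9999


def _smooth_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=length, mode="reflect")


def _standardized(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    return (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)


def _driver_surface(spec: DriverSpec, scenario: SyntheticScenario,
                    rng: np.random.Generator) -> np.ndarray:
    nrows, ncols = scenario.shape
    if spec.surface == "smooth-gradient":
        angle = rng.uniform(0, 2 * np.pi)
        rows, cols = np.mgrid[0:nrows, 0:ncols]
        return np.cos(angle) * cols / max(ncols - 1, 1) + np.sin(angle) * rows / max(nrows - 1, 1)
    if spec.surface == "smoothed-noise":
        return _smooth_field(rng, scenario.shape, scenario.autocorr_length)
    # distance-to-random-lines: a few random straight lines rasterized, then EDT
    lines = np.zeros(scenario.shape, dtype=bool)
    for _ in range(rng.integers(2, 5)):
        if rng.random() < 0.5:
            lines[rng.integers(0, nrows), :] = True
        else:
            lines[:, rng.integers(0, ncols)] = True
    return ndimage.distance_transform_edt(~lines, sampling=scenario.pixel_size)


def generate_t1(scenario: SyntheticScenario) -> tuple[CategoricalRaster, dict[str, ContinuousRaster]]:
    """First-date map plus driver rasters, deterministic under the seed.

    Classes come from quantile-thresholding a smoothed noise field, so class
    shares match the targets exactly up to ties.
    """
    rng = np.random.default_rng(scenario.seed)
    legend = scenario.legend
    field_ = _smooth_field(rng, scenario.shape, scenario.autocorr_length)
    shares = np.asarray(scenario.shares, dtype=float)
    edges = np.quantile(field_, np.cumsum(shares)[:-1])
    classes = np.digitize(field_, edges)
    values = np.asarray(legend.codes)[classes]
    if scenario.nodata_margin > 0:
        m = scenario.nodata_margin
        values[:m, :] = scenario.nodata
        values[-m:, :] = scenario.nodata
        values[:, :m] = scenario.nodata
        values[:, -m:] = scenario.nodata
    t1 = CategoricalRaster(values, scenario.nodata, scenario.transform,
                           crs_tag="synthetic", legend=legend)
    drivers: dict[str, ContinuousRaster] = {}
    for spec in scenario.drivers:
        surface = _driver_surface(spec, scenario, rng)
        drivers[spec.name] = ContinuousRaster(surface, ~t1.valid, scenario.transform,
                                              crs_tag="synthetic", units="synthetic")
    return t1, drivers


def evolve(t1: CategoricalRaster, scenario: SyntheticScenario,
           drivers: Mapping[str, ContinuousRaster] | None = None,
           seed: int | None = None) -> CategoricalRaster:
    """Second-date map sampled from P_true with driver modulation.

    Off-diagonal transition probabilities of each class-i pixel are scaled by
    ``exp(sum_k beta_k * z_k)`` (z standardized driver values) divided by the
    class-i mean of that factor, so the landscape-expected transition matrix
    equals P_true; persistence absorbs the remainder.  Deterministic under
    the seed (``scenario.seed + 1`` by default).
    """
    legend = scenario.legend
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    k = len(legend)
    p_true = scenario.P_true
    betas = np.array([s.beta for s in scenario.drivers])
    if drivers is None and betas.any():
        raise ValueError("driver rasters required when any beta != 0")
    log_w = np.zeros(t1.shape, dtype=float)
    for spec in scenario.drivers:
        if spec.beta != 0.0:
            log_w += spec.beta * _standardized(drivers[spec.name].values)
    w = np.exp(np.clip(log_w, -20, 20))
    out = t1.values.copy()
    valid = t1.valid
    for i, code in enumerate(legend.codes):
        cells = (t1.values == code) & valid
        n_i = int(cells.sum())
        if n_i == 0:
            continue
        w_i = w[cells] / w[cells].mean()
        # per-pixel off-diagonal probabilities pinned to P_true in expectation
        probs = np.tile(p_true[i], (n_i, 1))
        off = np.arange(k) != i
        probs[:, off] *= w_i[:, None]
        off_sum = probs[:, off].sum(axis=1)
        overflow = np.where(off_sum > 1.0)[0]
        if overflow.size:  # clip pathological pixels; rare for moderate beta
            probs[np.ix_(overflow, np.where(off)[0])] /= off_sum[overflow, None]
            off_sum[overflow] = 1.0
        probs[:, i] = 1.0 - off_sum
        cum = probs.cumsum(axis=1)
        draws = rng.random(n_i)
        dest = (draws[:, None] < cum).argmax(axis=1)
        out[cells] = np.asarray(legend.codes)[dest]
    return CategoricalRaster(out, t1.nodata, t1.transform, t1.crs_tag, legend)
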