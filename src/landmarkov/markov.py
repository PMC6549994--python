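"""Markov transition matrices, horizon rescaling, scenario edits and demand.

The probability matrix is estimated from an observed transition count matrix,
rescaled from the observation window to the projection horizon, optionally
edited by declarative scenario rules, and converted to per-class change
demand in hectares.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .change import TransitionCountMatrix
from .grid import Legend

__all__ = [
    "TransitionProbabilityMatrix",
    "ScenarioEdit",
    "ChangeDemand",
    "estimate_matrix",
    "apply_scenario",
    "change_demand",
    "parse_scenario_file",
    "round_half_even",
    "PRINTED_ROUNDING_TOL",
    "STRICT_TOL",
]

#: per-row tolerance for matrices printed to 3 decimals
PRINTED_ROUNDING_TOL = 0.005
#: per-row tolerance for matrices computed in float arithmetic
STRICT_TOL = 1e-9


def round_half_even(x: float, decimals: int = 3) -> float:
    """Banker's rounding on the decimal (not binary) representation of x."""
    # squash float fuzz (0.315000000000000002) before quantizing
    d = Decimal(repr(float(x))).quantize(Decimal("1e-10"), rounding=ROUND_HALF_EVEN)
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass
class TransitionProbabilityMatrix:
    """Row-stochastic K x K matrix over the legend order with a time horizon.

    ``P[i, j]`` is the probability that a pixel of legend class i at the
    start of the horizon is class j at its end.
    """

    P: np.ndarray
    horizon_years: float
    legend: Legend

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.legend)
        if self.P.shape != (k, k):
            raise ValueError(f"matrix shape {self.P.shape} != ({k}, {k})")
        if self.horizon_years <= 0:
            raise ValueError(f"horizon must be positive, got {self.horizon_years}")

    def validate(self, tol: float = STRICT_TOL) -> None:
        """Check entries in [0, 1] and row sums within ``tol`` of 1."""
        if (self.P < -tol).any() or (self.P > 1 + tol).any():
            raise ValueError("matrix entries outside [0, 1]")
        sums = self.P.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > tol)[0]
        if bad.size:
            detail = ", ".join(f"{self.legend.names[i]}: {sums[i]:.6f}" for i in bad)
            raise ValueError(f"rows not stochastic within {tol}: {detail}")

    def is_row_stochastic(self, tol: float = STRICT_TOL) -> bool:
        try:
            self.validate(tol)
        except ValueError:
            return False
        return True

    def cell(self, origin, dest) -> float:
        i = self.legend.index(self.legend.resolve(origin))
        j = self.legend.index(self.legend.resolve(dest))
        return float(self.P[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.legend.names, columns=self.legend.names)

    def copy(self) -> "TransitionProbabilityMatrix":
        return TransitionProbabilityMatrix(self.P.copy(), self.horizon_years, self.legend)


def estimate_matrix(counts: TransitionCountMatrix, base_years: float,
                    target_years: float, rescale: str = "power") -> TransitionProbabilityMatrix:
    """Row-normalize observed counts and rescale to the projection horizon.

    ``rescale="power"`` takes the principal fractional matrix power
    ``P_base ** (target/base)`` (negative numerical residue clamped to 0,
    rows renormalized).  ``rescale="linear"`` scales off-diagonal mass by
    target/base and restores the diagonal.
    """
    if base_years <= 0 or target_years <= 0:
        raise ValueError("base_years and target_years must be positive")
    c = counts.counts.astype(float)
    row_sums = c.sum(axis=1)
    empty = np.where(row_sums == 0)[0]
    if empty.size:
        names = [counts.legend.names[i] for i in empty]
        raise ValueError(f"classes absent at t1 (empty matrix rows): {names}")
    p_base = c / row_sums[:, None]
    exponent = target_years / base_years
    if exponent == 1.0:
        p = p_base
    elif rescale == "power":
        p = _principal_power(p_base, exponent)
    elif rescale == "linear":
        p = _linear_rescale(p_base, exponent)
    else:
        raise ValueError(f"unknown rescale mode {rescale!r}")
    out = TransitionProbabilityMatrix(p, target_years, counts.legend)
    out.validate(tol=1e-6)
    return out


def _principal_power(p: np.ndarray, exponent: float) -> np.ndarray:
    raw = linalg.fractional_matrix_power(p, exponent)
    if np.iscomplexobj(raw):
        if np.abs(raw.imag).max() > 1e-8:
            raise ValueError(
                "principal fractional power is not real (complex/negative "
                "eigenvalues); rerun with rescale='linear'"
            )
        raw = raw.real
    clamped = np.clip(raw, 0.0, None)
    sums = clamped.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("degenerate row after clamping; rerun with rescale='linear'")
    return clamped / sums[:, None]


def _linear_rescale(p: np.ndarray, exponent: float) -> np.ndarray:
    off = (p - np.diag(np.diag(p))) * exponent
    diag = 1.0 - off.sum(axis=1)
    if (diag < 0).any():
        raise ValueError("linear rescale drives a diagonal negative; reduce the horizon ratio")
    return off + np.diag(diag)


@dataclass(frozen=True)
class ScenarioEdit:
    """One declarative rule transforming a probability matrix row.

    kinds:

    * ``fix_row_identity`` — origin row becomes the unit vector on its
      diagonal (the class can no longer change);
    * ``scale_cell`` — multiply P[origin, dest] by ``factor`` (result rounded
      half-even to 3 decimals); the increment is compensated from the donor
      cell of the same row (``donor="diagonal"`` by default);
    * ``scale_diagonal`` — same for the persistence cell, compensated from
      ``donor="largest_offdiagonal"`` by default.
    """

    kind: str
    origin: str | int
    dest: str | int | None = None
    factor: float = 1.0
    donor: str | int = "diagonal"

    def __post_init__(self) -> None:
        if self.kind not in ("fix_row_identity", "scale_cell", "scale_diagonal"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if not np.isfinite(self.factor) or self.factor <= 0:
            raise ValueError(f"factor must be finite and > 0, got {self.factor}")
        if self.kind == "scale_cell" and self.dest is None:
            raise ValueError("scale_cell needs a destination class")


def apply_scenario(matrix: TransitionProbabilityMatrix,
                   edits: Sequence[ScenarioEdit],
                   decimals: int | None = 3) -> TransitionProbabilityMatrix:
    """Apply scenario edits in order.

    Arithmetic is round-half-even at ``decimals`` so edits of printed
    3-decimal matrices reproduce printed scenario cells exactly; pass
    ``decimals=None`` for exact arithmetic on computed (unrounded) matrices,
    which preserves row sums to float precision.
    """
    matrix.validate(tol=PRINTED_ROUNDING_TOL)

    def _round(x: float) -> float:
        return round_half_even(x, decimals) if decimals is not None else float(x)

    p = matrix.P.copy()
    legend = matrix.legend
    for edit in edits:
        i = legend.index(legend.resolve(edit.origin))
        if edit.kind == "fix_row_identity":
            p[i, :] = 0.0
            p[i, i] = 1.0
            continue
        if edit.kind == "scale_cell":
            j = legend.index(legend.resolve(edit.dest))
        else:  # scale_diagonal
            j = i
        if edit.donor == "diagonal":
            d = i
        elif edit.donor == "largest_offdiagonal":
            row = p[i].copy()
            row[i] = -np.inf
            d = int(np.argmax(row))
        else:
            d = legend.index(legend.resolve(edit.donor))
        if d == j:
            raise ValueError(f"donor equals the edited cell in row {legend.names[i]!r}")
        new_val = _round(edit.factor * p[i, j])
        increment = new_val - p[i, j]
        donor_val = _round(p[i, d] - increment)
        if donor_val < -1e-12:
            raise ValueError(
                f"edit {edit.kind} on {legend.names[i]!r} would drive donor "
                f"{legend.names[d]!r} below zero ({donor_val:.3f})"
            )
        p[i, j] = min(new_val, 1.0)
        p[i, d] = min(max(donor_val, 0.0), 1.0)
    return TransitionProbabilityMatrix(p, matrix.horizon_years, legend)


@dataclass
class ChangeDemand:
    """Expected area (ha) of every ordered transition over the horizon."""

    D: np.ndarray
    legend: Legend

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        k = len(self.legend)
        if self.D.shape != (k, k):
            raise ValueError(f"demand shape {self.D.shape} != ({k}, {k})")
        if (self.D < 0).any():
            raise ValueError("negative demand")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.legend.names, columns=self.legend.names)


def change_demand(matrix: TransitionProbabilityMatrix,
                  baseline_areas: Mapping[int, float] | Sequence[float]) -> ChangeDemand:
    """Demand D[i, j] = baseline area of class i times P[i, j]."""
    legend = matrix.legend
    if isinstance(baseline_areas, Mapping):
        missing = [c for c in legend.codes if c not in baseline_areas]
        if missing:
            raise ValueError(f"baseline areas missing for classes {missing}")
        areas = np.array([float(baseline_areas[c]) for c in legend.codes])
    else:
        areas = np.asarray(baseline_areas, dtype=float)
        if areas.shape != (len(legend),):
            raise ValueError(f"baseline areas length {areas.shape} != {len(legend)} classes")
    if (areas < 0).any():
        raise ValueError("negative baseline area")
    return ChangeDemand(areas[:, None] * matrix.P, legend)


def parse_scenario_file(path) -> list[ScenarioEdit]:
    """Parse a plain-text scenario file, one edit per line.

    Lines look like::

        scale_cell conifer broadleaf 1.5 donor=diagonal
        scale_diagonal mountain_heath_bog 1.5 donor=largest_offdiagonal
        fix_row_identity broadleaf

    ``#`` starts a comment; class names use the legend's normalized names.
    """
    edits: list[ScenarioEdit] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kind = parts[0]
        kwargs: dict[str, str] = {}
        pos: list[str] = []
        for tok in parts[1:]:
            if "=" in tok:
                key, val = tok.split("=", 1)
                kwargs[key] = val
            else:
                pos.append(tok)
        try:
            if kind == "fix_row_identity":
                (origin,) = pos
                edits.append(ScenarioEdit(kind, origin))
            elif kind == "scale_cell":
                origin, dest, factor = pos
                edits.append(ScenarioEdit(kind, origin, dest, float(factor),
                                          kwargs.get("donor", "diagonal")))
            elif kind == "scale_diagonal":
                origin, factor = pos
                edits.append(ScenarioEdit(kind, origin, None, float(factor),
                                          kwargs.get("donor", "largest_offdiagonal")))
            else:
                raise ValueError(f"unknown edit kind {kind!r}")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad scenario line {raw!r}: {exc}") from exc
    return edits
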