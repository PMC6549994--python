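"""Core raster data model: georeferenced categorical and continuous grids.

Conventions used throughout the package:

* grids are row-major 2-D numpy arrays with cell ``(0, 0)`` at the map's
  upper-left corner;
* the georeference is axis-aligned and north-up with square pixels;
* all distance computations use pixel centres;
* a cell that is nodata in *any* input of a cross-raster operation is
  excluded from that operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GridTransform",
    "Legend",
    "CategoricalRaster",
    "ContinuousRaster",
    "CoregistrationError",
    "assert_coregistered",
]


class CoregistrationError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridTransform:
    """Axis-aligned, north-up georeference with square pixels.

    Parameters
    ----------
    x_origin, y_origin
        Map coordinates of the grid's upper-left *corner*.
    pixel_size
        Cell edge length in map units; strictly positive.
    """

    x_origin: float
    y_origin: float
    pixel_size: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError(f"pixel size must be strictly positive, got {self.pixel_size}")

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of pixel centres for (arrays of) row/col indices."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.x_origin + (col + 0.5) * self.pixel_size
        y = self.y_origin - (row + 0.5) * self.pixel_size
        return x, y

    def approx_equal(self, other: "GridTransform", rtol: float = 1e-9) -> bool:
        return bool(
            np.isclose(self.x_origin, other.x_origin, rtol=rtol, atol=1e-6)
            and np.isclose(self.y_origin, other.y_origin, rtol=rtol, atol=1e-6)
            and np.isclose(self.pixel_size, other.pixel_size, rtol=rtol, atol=0.0)
        )

    @property
    def cell_area_ha(self) -> float:
        """Area of one pixel in hectares (25 m pixel -> 0.0625 ha)."""
        return self.pixel_size * self.pixel_size / 10_000.0


class Legend:
    """Ordered class legend: the order fixes row/column order of all matrices.

    Codes and names must each be unique; the order is stable for the whole
    pipeline run.
    """

    def __init__(self, entries: Iterable[tuple[int, str]]):
        entries = [(int(c), str(n)) for c, n in entries]
        if not entries:
            raise ValueError("legend must contain at least one class")
        codes = [c for c, _ in entries]
        names = [n for _, n in entries]
        if len(set(codes)) != len(codes):
            raise ValueError(f"legend codes not unique: {codes}")
        if len(set(names)) != len(names):
            raise ValueError(f"legend names not unique: {names}")
        self._entries: tuple[tuple[int, str], ...] = tuple(entries)
        self._index: dict[int, int] = {c: i for i, (c, _) in enumerate(entries)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, str]) -> "Legend":
        return cls(sorted(mapping.items()))

    @classmethod
    def from_codes(cls, codes: Iterable[int]) -> "Legend":
        return cls([(c, f"class_{c}") for c in codes])

    @property
    def entries(self) -> tuple[tuple[int, str], ...]:
        return self._entries

    @property
    def codes(self) -> list[int]:
        return [c for c, _ in self._entries]

    @property
    def names(self) -> list[str]:
        return [n for _, n in self._entries]

    def index(self, code: int) -> int:
        return self._index[int(code)]

    def code_of(self, name: str) -> int:
        for c, n in self._entries:
            if n == name:
                return c
        raise KeyError(name)

    def name_of(self, code: int) -> str:
        return self._entries[self.index(code)][1]

    def resolve(self, key) -> int:
        """Resolve a class given as code, exact name, or normalized name/prefix.

        Normalization lowercases and collapses non-alphanumerics to ``_`` so
        scenario files can say ``mountain_heath_bog`` for
        ``mountain, heath and bog``.
        """
        if isinstance(key, (int, np.integer)):
            if int(key) not in self._index:
                raise KeyError(f"unknown class code {key}")
            return int(key)
        key_s = str(key)
        for c, n in self._entries:
            if n == key_s:
                return c
        norm = _normalize(key_s)
        exact = [c for c, n in self._entries if _normalize(n) == norm]
        if len(exact) == 1:
            return exact[0]
        pref = [c for c, n in self._entries if _normalize(n).startswith(norm)]
        if len(pref) == 1:
            return pref[0]
        sub = [c for c, n in self._entries if norm in _normalize(n)]
        if len(sub) == 1:
            return sub[0]
        raise KeyError(f"class {key!r} not found (or ambiguous) in legend {self.names}")

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[int, str]]:
        return iter(self._entries)

    def __contains__(self, code: int) -> bool:
        return int(code) in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, Legend) and self._entries == other._entries

    def __hash__(self) -> int:
        return hash(self._entries)

    def __repr__(self) -> str:
        return f"Legend({list(self._entries)!r})"


def _normalize(name: str) -> str:
    out = []
    prev_us = False
    for ch in name.lower().strip():
        if ch.isalnum():
            out.append(ch)
            prev_us = False
        elif not prev_us:
            out.append("_")
            prev_us = True
    tokens = [t for t in "".join(out).strip("_").split("_") if t and t != "and"]
    return "_".join(tokens)


@dataclass
class CategoricalRaster:
    """Integer-coded class grid with legend, nodata sentinel and georeference."""

    values: np.ndarray
    nodata: int
    transform: GridTransform
    crs_tag: str = ""
    legend: Legend | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster grid must be a non-empty 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded, atol=1e-6, equal_nan=True):
                raise ValueError("categorical raster has non-integer cell values")
            self.values = rounded.astype(np.int64)
        else:
            self.values = self.values.astype(np.int64)
        self.nodata = int(self.nodata)
        if self.legend is None:
            codes = np.unique(self.values[self.values != self.nodata])
            self.legend = Legend.from_codes(codes.tolist()) if codes.size else Legend([(0, "class_0")])
        self._check_legend_covers()

    def _check_legend_covers(self) -> None:
        present = np.unique(self.values[self.values != self.nodata])
        missing = [int(c) for c in present if int(c) not in self.legend]
        if missing:
            raise ValueError(f"cell codes {missing} missing from legend {self.legend.codes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def valid(self) -> np.ndarray:
        """Boolean grid, True where the cell carries data."""
        return self.values != self.nodata

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.values[self.valid], return_counts=True)
        return {int(c): int(k) for c, k in zip(codes, counts)}

    def class_areas_ha(self) -> dict[int, float]:
        """Area per legend class in hectares (absent classes report 0)."""
        counts = self.class_counts()
        area = self.transform.cell_area_ha
        return {c: counts.get(c, 0) * area for c in self.legend.codes}

    def copy(self) -> "CategoricalRaster":
        return CategoricalRaster(
            self.values.copy(), self.nodata, self.transform, self.crs_tag, self.legend
        )


@dataclass
class ContinuousRaster:
    """Real-valued grid with a nodata mask, georeference and units tag."""

    values: np.ndarray
    mask: np.ndarray  # True where the cell is NODATA
    transform: GridTransform
    crs_tag: str = ""
    units: str = ""
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster grid must be a non-empty 2-D array")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"nodata mask shape {self.mask.shape} != grid shape {self.values.shape}"
            )

    @classmethod
    def full_valid(cls, values, transform, crs_tag: str = "", units: str = "") -> "ContinuousRaster":
        values = np.asarray(values, dtype=float)
        return cls(values, np.zeros(values.shape, dtype=bool), transform, crs_tag, units)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def filled(self) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = self.nodata_value
        return out

    def copy(self) -> "ContinuousRaster":
        return ContinuousRaster(
            self.values.copy(), self.mask.copy(), self.transform,
            self.crs_tag, self.units, self.nodata_value,
        )


Raster = CategoricalRaster | ContinuousRaster


def assert_coregistered(a, b) -> None:
    """Verify two rasters share shape, transform and CRS tag.

    Raises :class:`CoregistrationError` naming the first differing property.
    """
    if a.shape != b.shape:
        raise CoregistrationError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.transform.approx_equal(b.transform):
        raise CoregistrationError(f"transform mismatch: {a.transform} vs {b.transform}")
    if a.crs_tag != b.crs_tag:
        raise CoregistrationError(f"crs mismatch: {a.crs_tag!r} vs {b.crs_tag!r}")
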