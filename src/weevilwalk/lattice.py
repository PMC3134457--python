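"""Habitat lattices: plot rasters, cell geometry and raster I/O.

A banana plot is a rectangular lattice of 1-m² cells, each carrying exactly
one of four mutually exclusive habitat codes:

* ``P`` — host plant (banana mat),
* ``C`` — crop residue (litter-covered soil),
* ``B`` — bare soil,
* ``D`` — ditch.

Coordinate convention (used consistently everywhere, including file I/O):
cells are indexed 0-based by ``(row, col)``; row 0 is the top line of an
ASCII raster file; the centre of cell ``(row, col)`` is at
``(x, y) = (col + 0.5, row + 0.5)`` metres.  Distances between cells are
Euclidean distances between centres, so horizontally or vertically adjacent
cells are exactly 1 m apart.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Canonical habitat codes, in canonical order.
HABITATS: tuple[str, ...] = ("P", "C", "B", "D")
HABITAT_INDEX: dict[str, int] = {h: i for i, h in enumerate(HABITATS)}
N_HABITATS = len(HABITATS)

HABITAT_NAMES = {
    "P": "host plant",
    "C": "crop residue",
    "B": "bare soil",
    "D": "ditch",
}


class RasterError(ValueError):
    """Malformed raster input (unknown token, ragged rows, bad indices)."""


@dataclass(frozen=True)
class CellIndex:
    """0-based (row, col) cell address within a plot."""

    row: int
    col: int

    def linear_id(self, n_cols: int) -> int:
        return self.row * n_cols + self.col


@dataclass
class PlotRaster:
    """A rectangular habitat lattice of 1-m² cells.

    Parameters
    ----------
    plot_id
        Identifier of the plot (e.g. ``"plot3"``).
    habitat
        2-D integer array (``n_rows × n_cols``) of habitat indices into
        :data:`HABITATS`.
    cell_size
        Cell side length in metres; the study design fixes this to 1.0.
    """

    plot_id: str
    habitat: np.ndarray
    cell_size: float = 1.0
    _dist: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.habitat = np.asarray(self.habitat)
        if self.habitat.ndim != 2 or self.habitat.size == 0:
            raise RasterError(
                f"habitat grid must be a non-empty 2-D array, got shape "
                f"{self.habitat.shape}"
            )
        if self.habitat.min() < 0 or self.habitat.max() >= N_HABITATS:
            raise RasterError("habitat indices must be in 0..3 (P, C, B, D)")
        self.habitat = self.habitat.astype(np.int8)

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.habitat.shape[0]

    @property
    def n_cols(self) -> int:
        return self.habitat.shape[1]

    @property
    def n_cells(self) -> int:
        return self.habitat.size

    @property
    def habitat_flat(self) -> np.ndarray:
        """Habitat index of every cell in linear (row-major) order."""
        return self.habitat.reshape(-1)

    def habitat_of(self, idx: CellIndex) -> str:
        self._check_bounds(idx)
        return HABITATS[self.habitat[idx.row, idx.col]]

    def linear_id(self, idx: CellIndex) -> int:
        self._check_bounds(idx)
        return idx.row * self.n_cols + idx.col

    def cell_of(self, linear_id: int) -> CellIndex:
        if not 0 <= linear_id < self.n_cells:
            raise RasterError(
                f"linear id {linear_id} out of bounds for plot "
                f"{self.plot_id!r} with {self.n_cells} cells"
            )
        return CellIndex(*divmod(int(linear_id), self.n_cols))

    def _check_bounds(self, idx: CellIndex) -> None:
        if not (0 <= idx.row < self.n_rows and 0 <= idx.col < self.n_cols):
            raise RasterError(
                f"cell ({idx.row}, {idx.col}) out of bounds for "
                f"{self.n_rows}×{self.n_cols} plot {self.plot_id!r}"
            )

    def cell_centre(self, idx: CellIndex) -> tuple[float, float]:
        """Centre coordinates ``(x, y)`` of a cell, in metres."""
        self._check_bounds(idx)
        s = self.cell_size
        return ((idx.col + 0.5) * s, (idx.row + 0.5) * s)

    def cell_centres(self) -> np.ndarray:
        """``(n_cells, 2)`` array of (x, y) centres in linear order."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        return np.column_stack(
            [(cols + 0.5) * self.cell_size, (rows + 0.5) * self.cell_size]
        )

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centre-to-centre distances (metres).

        Symmetric, zero diagonal; computed once and cached on the raster.
        """
        if self._dist is None:
            c = self.cell_centres()
            dx = c[:, 0][:, None] - c[:, 0][None, :]
            dy = c[:, 1][:, None] - c[:, 1][None, :]
            self._dist = np.hypot(dx, dy)
        return self._dist

    def composition(self) -> dict[str, float]:
        """Fraction of cells of each habitat type."""
        counts = np.bincount(self.habitat_flat, minlength=N_HABITATS)
        return {h: counts[i] / self.n_cells for i, h in enumerate(HABITATS)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlotRaster):
            return NotImplemented
        return (
            self.plot_id == other.plot_id
            and self.cell_size == other.cell_size
            and self.habitat.shape == other.habitat.shape
            and bool(np.all(self.habitat == other.habitat))
        )


def raster_from_codes(plot_id: str, rows: list[list[str]],
                      cell_size: float = 1.0) -> PlotRaster:
    """Build a raster from nested lists of single-letter habitat codes."""
    n_cols = len(rows[0])
    grid = np.empty((len(rows), n_cols), dtype=np.int8)
    for r, line in enumerate(rows):
        if len(line) != n_cols:
            raise RasterError(
                f"ragged raster: row {r} has {len(line)} cells, expected "
                f"{n_cols}"
            )
        for c, tok in enumerate(line):
            try:
                grid[r, c] = HABITAT_INDEX[tok]
            except KeyError:
                raise RasterError(
                    f"unknown habitat token {tok!r} at line {r + 1}, "
                    f"column {c + 1}"
                ) from None
    return PlotRaster(plot_id=plot_id, habitat=grid, cell_size=cell_size)


def read_raster(path: str | Path, format: str | None = None,
                plot_id: str | None = None) -> PlotRaster:
    """Read a habitat raster from disk.

    Two plain-text dialects are supported:

    * ``"ascii-grid"`` — whitespace-separated single-letter codes, one
      raster row per line; row 0 is the top line of the file.
    * ``"csv"`` — long format with header ``row,col,habitat`` and 0-based
      integer indices.

    ``format`` defaults to ``"csv"`` for ``.csv`` files, else ascii-grid.
    Lines starting with ``#`` are ignored in both dialects.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "ascii-grid"
    if plot_id is None:
        plot_id = path.stem
    if format == "ascii-grid":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rows.append(line.split())
        if not rows:
            raise RasterError(f"empty raster file: {path}")
        return raster_from_codes(plot_id, rows)
    if format == "csv":
        records: dict[tuple[int, int], str] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(
                row for row in fh if not row.startswith("#"))
            if reader.fieldnames is None or not {
                    "row", "col", "habitat"}.issubset(reader.fieldnames):
                raise RasterError(
                    f"CSV raster {path} must have header row,col,habitat")
            for rec in reader:
                records[(int(rec["row"]), int(rec["col"]))] = rec["habitat"]
        if not records:
            raise RasterError(f"empty raster file: {path}")
        n_rows = max(r for r, _ in records) + 1
        n_cols = max(c for _, c in records) + 1
        if len(records) != n_rows * n_cols:
            raise RasterError(
                f"incomplete CSV raster {path}: {len(records)} cells for a "
                f"{n_rows}×{n_cols} grid")
        rows = [[records[(r, c)] for c in range(n_cols)]
                for r in range(n_rows)]
        return raster_from_codes(plot_id, rows)
    raise ValueError(f"unknown raster format {format!r}")


def write_raster(raster: PlotRaster, path: str | Path,
                 format: str | None = None, header: str | None = None) -> None:
    """Write a raster in one of the dialects of :func:`read_raster`.

    ``read_raster(write_raster(r)) == r`` bit-exactly for both dialects.
    An optional ``header`` string is written as ``#``-prefixed lines.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "ascii-grid"
    with open(path, "w", newline="") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        if format == "ascii-grid":
            for r in range(raster.n_rows):
                fh.write(" ".join(
                    HABITATS[raster.habitat[r, c]]
                    for c in range(raster.n_cols)) + "\n")
        elif format == "csv":
            writer = csv.writer(fh)
            writer.writerow(["row", "col", "habitat"])
            for r in range(raster.n_rows):
                for c in range(raster.n_cols):
                    writer.writerow([r, c, HABITATS[raster.habitat[r, c]]])
        else:
            raise ValueError(f"unknown raster format {format!r}")
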