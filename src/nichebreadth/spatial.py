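"""Spatial distribution metrics from habitat-suitability rasters.

A species distribution model yields a grid of environmental suitabilities in
[0, 1].  Two summaries are derived from it:

* potential range size — the number of cells with suitability strictly above
  the species' minimum suitability floor ``s_min``;
* distribution homogeneity — the Hill evenness factor (q=1 Hill number over
  q=0 Hill number) of the normalised suitability distribution of qualifying
  cells.  It equals 1 when every qualifying cell is equally suitable and
  approaches 0 as suitability concentrates in few cells.

Cells are counted, not area-weighted; for geographic rasters in unprojected
coordinates this ignores latitude-dependent cell area.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .hill import hill_number

__all__ = [
    "SuitabilityRaster",
    "potential_range_size",
    "distribution_homogeneity",
    "breadth_profile",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
]

_ASCII_NODATA = -9999.0


@dataclasses.dataclass
class SuitabilityRaster:
    """A 2-D suitability grid with nodata as NaN and a minimum-suitability floor.

    ``s_min`` defaults to the smallest strictly positive suitability in the
    grid when not supplied (the per-species floor is study configuration and
    should normally be given explicitly).
    """

    values: np.ndarray
    s_min: float | None = None
    cellsize: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        data = v[np.isfinite(v)]
        if data.size == 0:
            raise ValueError("raster contains no data cells")
        if data.min() < 0 or data.max() > 1:
            raise ValueError("suitability values must lie in [0, 1]")
        self.values = v
        if self.s_min is None:
            positive = data[data > 0]
            self.s_min = float(positive.min()) if positive.size else 0.0
        if not 0 <= self.s_min < 1:
            raise ValueError(f"s_min must lie in [0, 1) (got {self.s_min})")

    @property
    def n_cells(self) -> int:
        """Number of data (non-nodata) cells."""
        return int(np.isfinite(self.values).sum())

    def qualifying(self) -> np.ndarray:
        """Suitabilities of data cells strictly above the floor."""
        data = self.values[np.isfinite(self.values)]
        return data[data > self.s_min]


def potential_range_size(raster: SuitabilityRaster) -> int:
    """Number of raster cells with suitability strictly above ``s_min``."""
    return int(raster.qualifying().size)


def distribution_homogeneity(raster: SuitabilityRaster) -> float:
    """Evenness factor qD(1)/qD(0) of the normalised cell-suitability vector."""
    cells = raster.qualifying()
    if cells.size == 0:
        raise ValueError("no cells above the minimum suitability floor")
    if np.ptp(cells) == 0:
        return 1.0  # defining limit: identical suitabilities everywhere
    return min(1.0, hill_number(cells, 1) / hill_number(cells, 0))


def breadth_profile(
    raster: SuitabilityRaster, q_grid, relative: bool = False
) -> np.ndarray:
    """Hill numbers of the cell-suitability distribution over a grid of q.

    With ``relative=True`` each value is divided by the qualifying cell count,
    giving a spatial breadth in [0, 1]; the q=0 entry of the absolute profile
    equals the potential range size.
    """
    cells = raster.qualifying()
    if cells.size == 0:
        raise ValueError("no cells above the minimum suitability floor")
    values = np.array([hill_number(cells, q) for q in np.atleast_1d(q_grid)])
    if relative:
        values = values / cells.size
    return values


# ---------------------------------------------------------------------------
# raster IO: ESRI ASCII grid and single-band float32 TIFF
# ---------------------------------------------------------------------------


def write_ascii_grid(raster: SuitabilityRaster, path) -> None:
    """Write an ESRI ASCII grid (.asc); values round-trip bit-exactly."""
    v = raster.values
    nodata = _ASCII_NODATA
    body = np.where(np.isfinite(v), v, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {v.shape[1]}\n")
        fh.write(f"nrows {v.shape[0]}\n")
        fh.write(f"xllcorner {raster.origin[0]!r}\n")
        fh.write(f"yllcorner {raster.origin[1]!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in body:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def read_ascii_grid(path, s_min: float | None = None) -> SuitabilityRaster:
    """Read an ESRI ASCII grid; the header's NODATA_value becomes NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    values = np.asarray(rows, dtype=float)
    if "ncols" in header and values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match header dimensions")
    nodata = header.get("nodata_value", _ASCII_NODATA)
    values[values == nodata] = np.nan
    return SuitabilityRaster(
        values=values,
        s_min=s_min,
        cellsize=header.get("cellsize", 1.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def write_geotiff(raster: SuitabilityRaster, path) -> None:
    """Write a single-band float32 TIFF with nodata stored as NaN."""
    import tifffile

    tifffile.imwrite(str(path), raster.values.astype(np.float32))


def read_geotiff(path, s_min: float | None = None) -> SuitabilityRaster:
    """Read a single-band float32 TIFF; NaN cells are treated as nodata."""
    import tifffile

    values = np.asarray(tifffile.imread(str(path)), dtype=float)
    return SuitabilityRaster(values=values, s_min=s_min)


def read_raster(path, s_min: float | None = None) -> SuitabilityRaster:
    """Dispatch on file suffix (.asc/.txt → ASCII grid, .tif/.tiff → TIFF)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return read_geotiff(path, s_min=s_min)
    return read_ascii_grid(path, s_min=s_min)
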