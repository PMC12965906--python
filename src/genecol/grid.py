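"""Multi-band climate rasters.

A :class:`ClimateGrid` is a stack of aligned 2-D float bands (one per
climate variable) on a regular lon/lat grid (WGS84 by default), with an
optional validity mask.  Rows are counted from the top-left origin
(0-based); a point maps to the cell containing it.

Two on-disk forms are supported behind one interface: GeoTIFF (written
with tifffile; georeferencing via ModelPixelScale/ModelTiepoint tags and a
JSON image description carrying band names, nodata and CRS) and a
plain-text directory format (one ESRI ASCII ``.asc`` per band plus a
``grid.json`` manifest) used for small, versionable fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class ClimateGrid:
    x0: float                       # lon of the top-left corner
    y0: float                       # lat of the top-left corner
    dx: float                       # cell width (degrees, > 0)
    dy: float                       # cell height (degrees, > 0; rows go south)
    bands: dict[str, np.ndarray] = field(default_factory=dict)
    crs: str = "EPSG:4326"
    nodata: float = NODATA
    mask: np.ndarray | None = None  # True = valid cell

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError(f"bands disagree on geometry: {shapes}")
        if self.mask is not None and self.bands:
            if self.mask.shape != self.shape:
                raise ValueError("mask shape does not match bands")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.bands.values()))
        return first.shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    def valid_mask(self) -> np.ndarray:
        """Combined validity: explicit mask AND finite, non-nodata bands."""
        ok = np.ones(self.shape, dtype=bool)
        for b in self.bands.values():
            ok &= np.isfinite(b) & (b != self.nodata)
        if self.mask is not None:
            ok &= self.mask
        return ok

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.x0) / self.dx))
        row = int(np.floor((self.y0 - lat) / self.dy))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside the grid")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.x0 + (col + 0.5) * self.dx,
                self.y0 - (row + 0.5) * self.dy)

    def band_stack(self, names: list[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.bands]
        if missing:
            raise KeyError(f"grid is missing band(s): {missing}")
        return np.stack([self.bands[n] for n in names])

    # ----------------------------------------------------------------- ASCII
    def write_ascii(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1, "kind": "climate_grid",
            "x0": self.x0, "y0": self.y0, "dx": self.dx, "dy": self.dy,
            "crs": self.crs, "nodata": self.nodata,
            "bands": list(self.bands),
            "mask": self.mask is not None,
        }
        (d / "grid.json").write_text(json.dumps(manifest, indent=1))
        for name, arr in self.bands.items():
            write_esri_ascii(d / f"{name}.asc", arr, self.x0, self.y0,
                             self.dx, self.dy, self.nodata)
        if self.mask is not None:
            write_esri_ascii(d / "mask.asc", self.mask.astype(float),
                             self.x0, self.y0, self.dx, self.dy, self.nodata)

    @classmethod
    def read_ascii(cls, directory: str | Path) -> "ClimateGrid":
        d = Path(directory)
        m = json.loads((d / "grid.json").read_text())
        bands = {name: read_esri_ascii(d / f"{name}.asc")[0]
                 for name in m["bands"]}
        mask = None
        if m.get("mask"):
            mask = read_esri_ascii(d / "mask.asc")[0].astype(bool)
        return cls(x0=m["x0"], y0=m["y0"], dx=m["dx"], dy=m["dy"],
                   bands=bands, crs=m["crs"], nodata=m["nodata"], mask=mask)

    # --------------------------------------------------------------- GeoTIFF
    def write_geotiff(self, path: str | Path) -> None:
        import tifffile

        names = list(self.bands)
        stack = np.stack(
            [np.asarray(self.bands[n], dtype=np.float32) for n in names]
        )
        if self.mask is not None:
            stack = np.concatenate(
                [stack, self.mask.astype(np.float32)[None]]
            )
            names = names + ["__mask__"]
        desc = json.dumps({
            "kind": "climate_grid", "format_version": 1,
            "bands": names, "crs": self.crs, "nodata": self.nodata,
            "x0": self.x0, "y0": self.y0, "dx": self.dx, "dy": self.dy,
        })
        extratags = [
            # ModelPixelScaleTag, ModelTiepointTag (GeoTIFF)
            (33550, "d", 3, (self.dx, self.dy, 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, self.x0, self.y0, 0.0)),
        ]
        tifffile.imwrite(path, stack, description=desc, extratags=extratags)

    @classmethod
    def read_geotiff(cls, path: str | Path) -> "ClimateGrid":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            page = tf.pages[0]
            desc = page.tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        if stack.ndim == 2:
            stack = stack[None]
        names = meta.get("bands", [f"band{i + 1}" for i in range(len(stack))])
        bands = {}
        mask = None
        for name, arr in zip(names, stack):
            if name == "__mask__":
                mask = arr.astype(bool)
            else:
                bands[name] = arr.astype(float)
        return cls(
            x0=meta.get("x0", 0.0), y0=meta.get("y0", 0.0),
            dx=meta.get("dx", 1.0), dy=meta.get("dy", 1.0),
            bands=bands, crs=meta.get("crs", "EPSG:4326"),
            nodata=meta.get("nodata", NODATA), mask=mask,
        )


def read_grid(path: str | Path) -> ClimateGrid:
    """Read a grid from either on-disk form (directory = ASCII, file =
    GeoTIFF)."""
    p = Path(path)
    if p.is_dir():
        return ClimateGrid.read_ascii(p)
    return ClimateGrid.read_geotiff(p)


def write_esri_ascii(
    path: str | Path, arr: np.ndarray,
    x0: float, y0: float, dx: float, dy: float, nodata: float = NODATA,
) -> None:
    nr, nc = arr.shape
    a = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {nc}\nnrows {nr}\n"
        f"xllcorner {x0!r}\nyllcorner {y0 - nr * dy!r}\n"
        f"cellsize {dx!r}\nNODATA_value {nodata!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in a)
    Path(path).write_text(header + body + "\n")


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, dict]:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    ):
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    arr = np.array(
        [[float(v) for v in ln.split()] for ln in lines[i:] if ln.strip()]
    )
    nod = hdr.get("nodata_value")
    if nod is not None:
        arr = np.where(arr == nod, np.nan, arr)
    return arr, hdr
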