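"""Spatial projection of fitted models with extrapolation masking.

Model projections are only trusted where the grid's climate resembles the
climates actually sampled by the source populations: a cell is masked when
any climate variable lies more than ``k`` standard deviations beyond the
sampled range (default k = 1).  Zone trees project to integer rasters with
a JSON legend (renderable at any hierarchy level by code-prefix merging);
transfer forests project to per-axis bands; a focal-point map is the
per-cell Euclidean distance in PC trait space from a chosen location.

Rasters are processed in fixed-order row blocks; outputs are identical
for any block size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import CLIMATE_VARIABLES
from .forest import ForestModel
from .grid import ClimateGrid, write_esri_ascii
from .zonetree import ZoneTreeModel

log = logging.getLogger(__name__)

ZONE_NODATA = -1


@dataclass
class SampledClimateRange:
    """Per-variable min, max and sample SD over the source populations."""

    table: pd.DataFrame  # index = variable, columns = min, max, sd

    @classmethod
    def from_normals(
        cls, climate: pd.DataFrame,
        variables: tuple[str, ...] = CLIMATE_VARIABLES,
    ) -> "SampledClimateRange":
        missing = [v for v in variables if v not in climate.columns]
        if missing:
            raise KeyError(f"climate table missing variables: {missing}")
        sub = climate[list(variables)].astype(float)
        t = pd.DataFrame({
            "min": sub.min(), "max": sub.max(), "sd": sub.std(ddof=1),
        })
        return cls(t)

    def to_dict(self) -> dict:
        return {"kind": "sampled_range",
                "table": self.table.to_dict(orient="index")}

    @classmethod
    def from_dict(cls, d: dict) -> "SampledClimateRange":
        return cls(pd.DataFrame.from_dict(d["table"], orient="index"))


@dataclass
class PCGrid:
    """Predicted axis values on a grid: K bands plus a validity mask."""

    grid: ClimateGrid
    axes: list[str]
    values: np.ndarray            # (K, n_rows, n_cols)
    mask: np.ndarray              # True = valid

    def band(self, axis: str) -> np.ndarray:
        return self.values[self.axes.index(axis)]


def build_mask(
    grid: ClimateGrid, ranges: SampledClimateRange, k: float = 1.0
) -> np.ndarray:
    """Validity mask: a cell survives iff every ranged variable lies within
    [min - k*sd, max + k*sd] (boundary inclusive); cells already invalid in
    the grid stay masked."""
    if k < 0:
        raise ValueError("k must be >= 0")
    valid = grid.valid_mask()
    for var, row in ranges.table.iterrows():
        if var not in grid.bands:
            raise KeyError(f"ranged variable {var!r} absent from grid")
        band = grid.bands[var]
        lo = row["min"] - k * row["sd"]
        hi = row["max"] + k * row["sd"]
        with np.errstate(invalid="ignore"):
            valid &= (band >= lo) & (band <= hi)
    return valid


def _iter_blocks(n_rows: int, block_size: int):
    for start in range(0, n_rows, block_size):
        yield start, min(start + block_size, n_rows)


def project_tree(
    model: ZoneTreeModel,
    grid: ClimateGrid,
    mask: np.ndarray,
    taxon_group: str | None = None,
    block_size: int = 256,
) -> tuple[np.ndarray, dict]:
    """Project a zone tree to an integer raster plus legend.

    Trees split on a categorical taxon cannot be painted as one mixed map
    (taxa overlap geographically); pass ``taxon_group`` to project the map
    conditional on one taxon value.
    """
    used = {n.split.predictor for n in model.nodes.values() if not n.is_leaf}
    cat_used = used & set(model.categorical)
    if cat_used and taxon_group is None:
        raise ValueError(
            f"tree splits on categorical predictor(s) {sorted(cat_used)}; "
            "choose a taxon group to project"
        )
    numeric = sorted(used - set(model.categorical))
    missing = [v for v in numeric if v not in grid.bands]
    if missing:
        raise ValueError(f"grid lacks band(s) used by the tree: {missing}")

    leaves = model.leaves()
    legend = {str(i): leaf.code for i, leaf in enumerate(leaves)}
    code_to_int = {leaf.code: i for i, leaf in enumerate(leaves)}
    out = np.full(grid.shape, ZONE_NODATA, dtype=np.int16)
    if not mask.any():
        log.warning("all cells masked; zone raster is empty")
        return out, legend
    for r0, r1 in _iter_blocks(grid.n_rows, block_size):
        sub_mask = mask[r0:r1]
        rows, cols = np.nonzero(sub_mask)
        if len(rows) == 0:
            continue
        records = {v: grid.bands[v][r0:r1][rows, cols] for v in numeric}
        if taxon_group is not None:
            for cat in model.categorical:
                records[cat] = np.full(len(rows), taxon_group, dtype=object)
        df = pd.DataFrame(records)
        codes = [model.assign(df.iloc[i]) for i in range(len(df))]
        out[r0:r1][rows, cols] = [code_to_int[c] for c in codes]
    return out, legend


def merge_zone_level(
    zone_raster: np.ndarray, legend: dict, level: int
) -> tuple[np.ndarray, dict]:
    """Re-render a zone raster at a coarser hierarchy level by merging
    zones sharing a code prefix (level = number of leading code parts)."""
    def prefix(code: str) -> str:
        return code[:level] if code else code

    prefixes = sorted({prefix(c) for c in legend.values()})
    new_legend = {str(i): p for i, p in enumerate(prefixes)}
    remap = {int(k): prefixes.index(prefix(v)) for k, v in legend.items()}
    out = np.full_like(zone_raster, ZONE_NODATA)
    for old, new in remap.items():
        out[zone_raster == old] = new
    return out, new_legend


def project_forest(
    models: dict[str, ForestModel],
    grid: ClimateGrid,
    mask: np.ndarray,
    block_size: int = 256,
) -> PCGrid:
    """Project per-axis transfer forests to a multi-band prediction grid."""
    axes = list(models)
    predictors = models[axes[0]].predictors
    missing = [v for v in predictors if v not in grid.bands]
    if missing:
        raise ValueError(f"grid lacks predictor band(s): {missing}")
    K = len(axes)
    values = np.full((K,) + grid.shape, np.nan)
    for r0, r1 in _iter_blocks(grid.n_rows, block_size):
        sub_mask = mask[r0:r1]
        rows, cols = np.nonzero(sub_mask)
        if len(rows) == 0:
            continue
        X = np.column_stack(
            [grid.bands[v][r0:r1][rows, cols] for v in predictors]
        )
        for ki, ax in enumerate(axes):
            values[ki, r0:r1][rows, cols] = models[ax].predict(X)
    return PCGrid(grid=grid, axes=axes, values=values, mask=mask.copy())


def nearest_unmasked(mask: np.ndarray, row: int, col: int) -> tuple[int, int]:
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("grid has no unmasked cells")
    d2 = (rows - row) ** 2 + (cols - col) ** 2
    i = int(np.argmin(d2))
    return int(rows[i]), int(cols[i])


def focal_distance(
    pc_grid: PCGrid,
    lon: float | None = None,
    lat: float | None = None,
    focal_climate: pd.Series | None = None,
    models: dict[str, ForestModel] | None = None,
) -> np.ndarray:
    """Euclidean distance in PC trait space from a focal point.

    The focal vector comes either from the cell containing (lon, lat) —
    which must be unmasked — or from an explicit climate record predicted
    through ``models``.  Masked cells are NaN in the result.
    """
    if focal_climate is not None:
        if models is None:
            raise ValueError("focal_climate requires the fitted models")
        rec = pd.DataFrame([focal_climate])
        focal = np.array(
            [float(models[ax].predict(rec)[0]) for ax in pc_grid.axes]
        )
    else:
        if lon is None or lat is None:
            raise ValueError("give either lon/lat or focal_climate")
        row, col = pc_grid.grid.cell_of(lon, lat)
        if not pc_grid.mask[row, col]:
            nr, nc = nearest_unmasked(pc_grid.mask, row, col)
            nlon, nlat = pc_grid.grid.cell_center(nr, nc)
            raise ValueError(
                f"focal point ({lon}, {lat}) falls in a masked cell; "
                f"nearest unmasked cell center is ({nlon:.4f}, {nlat:.4f})"
            )
        focal = pc_grid.values[:, row, col]
    d = np.sqrt(((pc_grid.values - focal[:, None, None]) ** 2).sum(axis=0))
    d[~pc_grid.mask] = np.nan
    return d


def write_zone_raster(
    path_base: str | Path,
    zone_raster: np.ndarray,
    legend: dict,
    grid: ClimateGrid,
    fmt: str = "ascii",
) -> None:
    """Write a zone raster (int16 + JSON legend) as ASCII or GeoTIFF."""
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ascii":
        write_esri_ascii(base.with_suffix(".asc"),
                         zone_raster.astype(float), grid.x0, grid.y0,
                         grid.dx, grid.dy, nodata=float(ZONE_NODATA))
    else:
        out = ClimateGrid(grid.x0, grid.y0, grid.dx, grid.dy,
                          bands={"zone": zone_raster.astype(float)},
                          crs=grid.crs, nodata=float(ZONE_NODATA))
        out.write_geotiff(base.with_suffix(".tif"))
    base.with_suffix(".legend.json").write_text(json.dumps(legend, indent=1))
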