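"""Source-location climate normals.

Populations are characterized by 30-year climate normals (ClimateWNA-style)
at their seed-collection locations.  The 23-variable set is closed: every
climate table must carry exactly these variables, and their declaration
order below is the deterministic tie-breaking order used wherever two
predictors are otherwise equivalent (e.g. equal-gain tree splits).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: The closed, ordered set of annual climate normals.
#: Precipitation: MAP, MSP, PAS, RH; temperature: EMT, EXT, MAT, MCMT,
#: MWMT, TD; degree-days: DD_0, DD_18, DD5, DD18; frost: NFFD, FFP, bFFP,
#: eFFP; aridity: AHM, SHM, CMD, Eref; radiation: MAR.
CLIMATE_VARIABLES: tuple[str, ...] = (
    "MAP", "MSP", "PAS", "RH",
    "EMT", "EXT", "MAT", "MCMT", "MWMT", "TD",
    "DD_0", "DD_18", "DD5", "DD18",
    "NFFD", "FFP", "bFFP", "eFFP",
    "AHM", "SHM", "CMD", "Eref",
    "MAR",
)

_META_COLS = ("population", "lon", "lat")


def validate_climate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-population climate table.

    Requires columns ``population``, ``lon``, ``lat``, optionally ``taxon``,
    and all 23 climate variables with finite values.  Returns the table
    indexed by population with variables in declaration order.
    """
    missing_meta = [c for c in _META_COLS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"climate table missing columns: {missing_meta}")
    missing = [v for v in CLIMATE_VARIABLES if v not in df.columns]
    if missing:
        raise ValueError(f"climate table missing variables: {missing}")
    if df["population"].duplicated().any():
        dups = df.loc[df["population"].duplicated(), "population"].tolist()
        raise ValueError(f"duplicate population ids in climate table: {dups}")
    out = df.set_index(df["population"].astype(str))
    out.index.name = "population"
    vals = out[list(CLIMATE_VARIABLES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        rows, cols = np.nonzero(~np.isfinite(vals))
        bad = [(out.index[r], CLIMATE_VARIABLES[c]) for r, c in zip(rows, cols)]
        raise ValueError(f"non-finite climate values: {bad[:10]}")
    cols = ["lon", "lat"] + (["taxon"] if "taxon" in out.columns else [])
    return out[cols + list(CLIMATE_VARIABLES)]


def read_climate_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a delimited per-population climate table (see
    :func:`validate_climate_table` for the contract)."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return validate_climate_table(df)


def write_climate_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.reset_index().to_csv(path, sep=sep, index=False, float_format="%.17g")
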