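"""Plant-level trait tables from common-garden experiments.

The experimental design is fully nested/crossed: populations (each with a
small number of maternal families) are replicated across common gardens,
with families assigned to blocks within gardens.  Trait measurement scales
(continuous / count / binary) determine the error family used downstream in
variance decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DESIGN_COLS = ("population", "family", "garden", "block")

#: Numeric sentinels that are rejected rather than treated as data.  Missing
#: values must be encoded as empty cells.
_SENTINELS = (-999.0, -9999.0)


@dataclass(frozen=True)
class TraitSpec:
    """A measured trait: its name, measurement scale and units.

    ``scale`` is one of ``continuous`` (Gaussian errors), ``count``
    (Poisson, log link) or ``binary`` (binomial, logit link).
    """

    name: str
    scale: str = "continuous"
    units: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("continuous", "count", "binary"):
            raise ValueError(f"unknown trait scale {self.scale!r}")


#: The default trait panel of a bunchgrass provenance trial: growth
#: (biomass, height), reproduction (inflorescence count), leaf morphology
#: (length, width, ratio), phenology (heading, maturation day-of-year) and
#: survival.
DEFAULT_TRAITS: tuple[TraitSpec, ...] = (
    TraitSpec("biomass", "continuous", "g"),
    TraitSpec("plant_height", "continuous", "cm"),
    TraitSpec("inflorescence_number", "count", "count"),
    TraitSpec("leaf_length", "continuous", "cm"),
    TraitSpec("leaf_width", "continuous", "cm"),
    TraitSpec("leaf_ratio", "continuous", "ratio"),
    TraitSpec("heading_date", "continuous", "day-of-year"),
    TraitSpec("maturation_date", "continuous", "day-of-year"),
    TraitSpec("survival", "binary", "proportion"),
)


def trait_names(specs: tuple[TraitSpec, ...] = DEFAULT_TRAITS) -> list[str]:
    return [t.name for t in specs]


def spec_by_name(name: str, specs=DEFAULT_TRAITS) -> TraitSpec:
    for t in specs:
        if t.name == name:
            return t
    raise KeyError(f"unknown trait {name!r}")


def validate_plant_table(df: pd.DataFrame, trait_specs=DEFAULT_TRAITS) -> pd.DataFrame:
    """Validate a plant-level trait table against the design contract."""
    missing = [c for c in DESIGN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"plant table missing design columns: {missing}")
    known = set(trait_names(trait_specs))
    extra = [c for c in df.columns if c not in DESIGN_COLS and c not in known]
    if extra:
        raise ValueError(f"unknown trait columns: {extra}")
    df = df.copy()
    for c in DESIGN_COLS:
        df[c] = df[c].astype(str)

    # family ids are unique labels: a family may not recur across populations
    fam_pop = df[["family", "population"]].drop_duplicates()
    dup = fam_pop["family"][fam_pop["family"].duplicated()]
    if len(dup):
        raise ValueError(
            f"family id(s) {sorted(set(dup))} appear in more than one population"
        )

    for spec in trait_specs:
        if spec.name not in df.columns:
            continue
        col = pd.to_numeric(df[spec.name], errors="coerce")
        had_value = df[spec.name].notna()
        bad_parse = had_value & col.isna()
        if bad_parse.any():
            raise ValueError(
                f"non-numeric value for trait {spec.name!r} at rows "
                f"{list(df.index[bad_parse][:5])}"
            )
        sentinel = col.isin(_SENTINELS)
        if sentinel.any():
            raise ValueError(
                f"sentinel value in trait {spec.name!r} at rows "
                f"{list(df.index[sentinel][:5])}; encode missing as empty cells"
            )
        present = col.dropna()
        if spec.scale == "binary":
            bad = present[~present.isin((0.0, 1.0))]
            if len(bad):
                raise ValueError(
                    f"binary trait {spec.name!r} has value {bad.iloc[0]} "
                    f"at row {bad.index[0]}"
                )
        elif spec.scale == "count":
            bad = present[(present < 0) | (present != np.floor(present))]
            if len(bad):
                raise ValueError(
                    f"count trait {spec.name!r} has non-count value "
                    f"{bad.iloc[0]} at row {bad.index[0]}"
                )
        df[spec.name] = col.astype(float)  # floats throughout (NaN = missing)
    return df


def read_plant_table(
    path: str | Path, trait_specs=DEFAULT_TRAITS, sep: str = ","
) -> pd.DataFrame:
    """Read and validate a delimited plant-level trait table.

    Columns: ``population, family, garden, block`` plus one column per
    trait; missing trait values are empty cells.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df = validate_plant_table(df, trait_specs)
    if len(df) == 0:
        log.warning("plant table %s is empty (header only)", path)
    log.info(
        "read %d plant records: %d populations, %d gardens",
        len(df), df["population"].nunique(), df["garden"].nunique(),
    )
    return df


def write_plant_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    # %.17g guarantees bit-exact float round-trips through text
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def population_means(
    records: pd.DataFrame, garden: str, trait_specs=DEFAULT_TRAITS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population arithmetic trait means within one garden.

    Returns ``(means, n)``: both population x trait frames, ``n`` counting
    the non-missing plants behind each mean.  Populations with zero
    non-missing plants for a trait get NaN means and are logged.
    """
    sub = records[records["garden"].astype(str) == str(garden)]
    if len(sub) == 0:
        raise ValueError(f"no records for garden {garden!r}")
    cols = [t.name for t in trait_specs if t.name in sub.columns]
    grouped = sub.groupby("population", sort=True)[cols]
    means = grouped.mean()
    n = grouped.count()
    empty = n == 0
    if empty.to_numpy().any():
        for pop, row in empty.iterrows():
            for trait in row.index[row]:
                log.warning(
                    "population %s has no non-missing %s at garden %s",
                    pop, trait, garden,
                )
    return means, n


def build_trait_matrix(
    means_by_garden: dict[str, pd.DataFrame],
    retained: list[tuple[str, str]],
) -> pd.DataFrame:
    """Assemble the population x (trait, garden) mean matrix.

    ``retained`` is the ordered list of (trait, garden) pairs surviving the
    population-variance screen.  Columns are named ``"<trait>@<garden>"``,
    ordered gardens-within-trait.  Populations with any missing retained
    cell are dropped (logged); fewer than 3 surviving populations is an
    error.
    """
    if not retained:
        raise ValueError("retained trait x garden set is empty")
    cols = {}
    for trait, garden in retained:
        if garden not in means_by_garden:
            raise KeyError(f"no means for garden {garden!r}")
        means = means_by_garden[garden]
        if trait not in means.columns:
            raise KeyError(f"no means for trait {trait!r} at garden {garden!r}")
        cols[f"{trait}@{garden}"] = means[trait]
    mat = pd.DataFrame(cols)
    incomplete = mat.isna().any(axis=1)
    if incomplete.any():
        log.warning(
            "dropping populations with incomplete cells: %s",
            list(mat.index[incomplete]),
        )
        mat = mat.loc[~incomplete]
    if len(mat) < 3:
        raise ValueError(
            f"only {len(mat)} populations remain after completeness filter"
        )
    assert not mat.isna().to_numpy().any()
    return mat
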