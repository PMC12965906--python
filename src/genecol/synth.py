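"""Synthetic genecological studies with known truth.

The generator emulates the structure of a three-garden bunchgrass
provenance trial: 98 source populations x 2 maternal families planted in
six blocks at each of three common gardens (one plant per family per
block per garden, 3528 plants).  Source climates arise from two latent
spatial gradients (continentality and an elevation-like field) combined
into the 23 standard normals with realistic correlation signs (e.g.
continentality TD anti-correlated with relative humidity), which
reproduces the collinearity regime of real climate predictors.  Population
genotypic trait values carry a 3-zone latent structure thresholded on TD
and then MWMT, with centroid separation expressed as a multiple of the
within-zone SD; garden-by-population interaction SDs grow linearly with a
climatic mildness index, emulating higher plasticity in populations from
milder climates.  Per-trait variance proportions default to values typical
of such trials (garden effects dominating, population shares of a few to
~25 percent).

Count traits are Poisson draws of an exponentiated linear predictor and
survival is Bernoulli of a logistic predictor, with the latent component
variances scaled so the link-scale proportions match the configured ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import CLIMATE_VARIABLES
from .grid import ClimateGrid
from .traits import DEFAULT_TRAITS, TraitSpec

# (garden, block, population, family, residual) per trait
DEFAULT_PROPORTIONS: dict[str, tuple[float, ...]] = {
    "biomass":              (.490, .010, .164, .019, .317),
    "plant_height":         (.723, .020, .062, .022, .173),
    "inflorescence_number": (.548, .010, .030, .024, .388),
    "leaf_length":          (.682, .003, .028, .019, .268),
    "leaf_width":           (.375, .016, .109, .030, .470),
    "leaf_ratio":           (.231, .010, .070, .048, .641),
    "heading_date":         (.394, .011, .245, .048, .302),
    "maturation_date":      (.696, .013, .073, .014, .204),
    "survival":             (.370, .057, .132, .066, .375),
}

# mean and total SD on the data scale for continuous traits; (log-mean,)
# for counts and (baseline logit,) for binary
TRAIT_SCALE: dict[str, tuple[float, float]] = {
    "biomass": (30.0, 25.0),
    "plant_height": (23.0, 10.0),
    "inflorescence_number": (3.4, 0.0),   # log mean count ~ 30
    "leaf_length": (10.0, 3.0),
    "leaf_width": (0.36, 0.09),
    "leaf_ratio": (29.0, 8.0),
    "heading_date": (139.0, 8.0),
    "maturation_date": (168.0, 10.0),
    "survival": (1.7, 0.0),               # baseline logit ~ 85% survival
}


@dataclass
class SimConfig:
    n_populations: int = 98
    n_families: int = 2
    n_gardens: int = 3
    n_blocks: int = 6
    plants_per_cell: int = 1           # plants per family x block x garden
    proportions: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    zone_separation: float = 2.0       # centroid separation / within-zone SD
    plasticity_max_ratio: float = 2.0  # interaction SD at mildness 1, in
                                       # units of the residual SD
    grid_shape: tuple[int, int] = (40, 40)
    grid_noise: float = 0.15           # cell-level noise of latent gradients
    seed: int = 0

    def validate(self) -> None:
        for t, p in self.proportions.items():
            if len(p) != 5 or any(v < 0 for v in p):
                raise ValueError(f"bad proportions for {t}: {p}")
            if abs(sum(p) - 1.0) > 1e-6:
                raise ValueError(f"proportions for {t} must sum to 1: {p}")


@dataclass
class Truth:
    zones: dict[str, str]                  # population -> zone label
    thresholds: list[tuple[str, float]]    # ordered latent split rules
    proportions: dict[str, tuple[float, ...]]
    informative_variables: list[str]
    mildness: dict[str, float]             # population -> mildness in [0, 1]
    interaction_sd: dict[str, dict[str, float]]  # trait -> pop -> SD

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Study:
    plants: pd.DataFrame
    climate: pd.DataFrame
    grid: ClimateGrid
    truth: Truth
    config: SimConfig


# latitude/longitude frame of the synthetic map
_LON0, _LAT0 = -120.0, 44.0
_EXTENT = 6.0  # degrees spanned by the map in each direction


def _latent_gradients(u: np.ndarray, v: np.ndarray, rng, noise: float):
    """Two standardized latent fields on map coordinates in [0, 1]^2:
    continentality (west-east) and an elevation-like ridge field."""
    cont = 2.0 * u - 1.0 + 0.3 * np.sin(2.5 * np.pi * v)
    elev = (np.sin(np.pi * v) * (0.6 + 0.8 * np.cos(2 * np.pi * (u - 0.3)))
            - 0.4)
    cont = cont + rng.normal(0.0, noise, np.shape(u))
    elev = elev + rng.normal(0.0, noise, np.shape(u))
    return cont, elev


def _climate_fields(cont, elev, rng, noise_scale=1.0):
    """The 23 normals as linear combinations of the latent gradients plus
    noise; several variables are exact functions of others (TD, eFFP, AHM,
    SHM), reproducing the strong collinearity of real normals."""
    n = lambda s: rng.normal(0.0, s * noise_scale, np.shape(cont))
    out: dict[str, np.ndarray] = {}
    out["MAT"] = 8.0 - 4.0 * elev - 1.0 * cont + n(0.3)
    out["MWMT"] = 22.0 - 4.0 * elev + 2.0 * cont + n(0.4)
    out["MCMT"] = -4.0 - 3.0 * elev - 3.0 * cont + n(0.4)
    out["TD"] = out["MWMT"] - out["MCMT"]
    out["EMT"] = out["MCMT"] - 12.0 + n(1.0)
    out["EXT"] = out["MWMT"] + 14.0 + n(1.0)
    out["MAP"] = 450.0 + 250.0 * elev - 150.0 * cont + n(30.0)
    out["MSP"] = 0.35 * out["MAP"] + n(10.0)
    out["PAS"] = np.maximum(80.0 + 90.0 * elev + 20.0 * cont + n(10.0), 0.0)
    out["RH"] = 55.0 + 5.0 * elev - 8.0 * cont + n(2.0)
    out["DD5"] = np.maximum(200.0 + 180.0 * out["MAT"] + n(50.0), 0.0)
    out["DD18"] = np.maximum(120.0 - 60.0 * elev + 20.0 * cont + n(15.0), 0.0)
    out["DD_0"] = np.maximum(350.0 + 250.0 * elev + 150.0 * cont + n(40.0), 0.0)
    out["DD_18"] = np.maximum(3000.0 - 180.0 * out["MAT"] + n(80.0), 0.0)
    out["NFFD"] = 190.0 - 60.0 * elev - 20.0 * cont + n(8.0)
    out["FFP"] = np.maximum(120.0 - 50.0 * elev - 15.0 * cont + n(6.0), 5.0)
    out["bFFP"] = 130.0 + 25.0 * elev + 8.0 * cont + n(4.0)
    out["eFFP"] = out["bFFP"] + out["FFP"]
    out["AHM"] = (out["MAT"] + 10.0) / np.maximum(out["MAP"], 50.0) * 1000.0
    out["SHM"] = out["MWMT"] / np.maximum(out["MSP"], 20.0) * 1000.0
    out["CMD"] = np.maximum(400.0 - 0.5 * out["MAP"] + 20.0 * cont + n(20.0), 0.0)
    out["Eref"] = 600.0 - 150.0 * elev + 50.0 * cont + n(20.0)
    out["MAR"] = 15.0 - 2.0 * elev + 1.0 * cont + n(0.5)
    return {v: out[v] for v in CLIMATE_VARIABLES}


def _zone_truth(climate: pd.DataFrame) -> tuple[pd.Series, list[tuple[str, float]]]:
    """Three latent zones from ordered thresholds: first TD (mild vs
    continental), then MWMT within the continental side."""
    td_thr = float(np.quantile(climate["TD"], 1.0 / 3.0))
    right = climate["TD"] >= td_thr
    mwmt_thr = float(np.quantile(climate.loc[right, "MWMT"], 0.5))
    zone = pd.Series("A", index=climate.index)
    zone[right & (climate["MWMT"] < mwmt_thr)] = "B"
    zone[right & (climate["MWMT"] >= mwmt_thr)] = "C"
    return zone, [("TD", td_thr), ("MWMT", mwmt_thr)]


def simulate_study(config: SimConfig | None = None,
                   seed: int | None = None) -> Study:
    """Generate a complete synthetic study (plants, climates, grid, truth)."""
    config = config or SimConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    nP, nF, nG, nB = (config.n_populations, config.n_families,
                      config.n_gardens, config.n_blocks)
    reps = config.plants_per_cell

    # ---- source locations and climates
    u = rng.uniform(0.02, 0.98, nP)
    v = rng.uniform(0.02, 0.98, nP)
    cont, elev = _latent_gradients(u, v, rng, config.grid_noise)
    clim = _climate_fields(cont, elev, rng)
    pops = [f"P{i + 1:03d}" for i in range(nP)]
    climate = pd.DataFrame(clim, index=pd.Index(pops, name="population"))
    climate.insert(0, "lon", _LON0 + u * _EXTENT)
    climate.insert(1, "lat", _LAT0 + v * _EXTENT)

    zone, thresholds = _zone_truth(climate)
    mild_raw = -climate["TD"]
    mild01 = (mild_raw.rank(method="average") - 0.5) / nP

    # ---- zone centroids in standardized trait space
    traits = [t for t in DEFAULT_TRAITS if t.name in config.proportions]
    T = len(traits)
    zlabels = ["A", "B", "C"]
    C = rng.normal(0.0, 1.0, (3, T))
    C -= C.mean(axis=0)
    # scale so the minimum pairwise centroid distance equals
    # zone_separation * sqrt(T) (within-zone SD is 1 per standardized trait)
    dmin = min(np.linalg.norm(C[i] - C[j])
               for i in range(3) for j in range(i + 1, 3))
    if dmin > 0 and config.zone_separation > 0:
        C *= config.zone_separation * np.sqrt(T) / dmin
    else:
        C[:] = 0.0

    zidx = zone.map({z: i for i, z in enumerate(zlabels)}).to_numpy()

    # ---- per-trait effects
    garden_ids = [f"G{g + 1}" for g in range(nG)]
    block_ids = [f"B{b + 1}" for b in range(nB)]
    fam_ids = {p: [f"{p}_F{f + 1}" for f in range(nF)] for p in pops}

    interaction_sd: dict[str, dict[str, float]] = {}
    trait_values: dict[str, np.ndarray] = {}
    # index order of the plant table: garden, block, population, family, rep
    for spec, _ in zip(traits, range(T)):
        name = spec.name
        pg, pb, pp, pf, pe = config.proportions[name]
        if spec.scale == "continuous":
            mean, total_sd = TRAIT_SCALE.get(name, (0.0, 1.0))
            link_total_var = total_sd ** 2
        elif spec.scale == "count":
            mean = TRAIT_SCALE.get(name, (3.0, 0.0))[0]
            lam = float(np.exp(mean))
            resid_var = float(np.log1p(1.0 / lam))
            link_total_var = resid_var / max(pe, 1e-6)
        else:  # binary
            mean = TRAIT_SCALE.get(name, (1.5, 0.0))[0]
            resid_var = np.pi ** 2 / 3.0
            link_total_var = resid_var / max(pe, 1e-6)
        sd_g = np.sqrt(pg * link_total_var)
        sd_b = np.sqrt(pb * link_total_var)
        sd_p = np.sqrt(pp * link_total_var)
        sd_f = np.sqrt(pf * link_total_var)
        sd_e = np.sqrt(pe * link_total_var)

        ti = [t.name for t in traits].index(name)
        raw = C[zidx, ti] + rng.normal(0.0, 1.0, nP)
        raw = (raw - raw.mean()) / max(raw.std(ddof=1), 1e-12)
        geno = sd_p * raw

        g_eff = rng.normal(0.0, sd_g, nG)
        b_eff = rng.normal(0.0, sd_b, (nG, nB))
        f_eff = rng.normal(0.0, sd_f, (nP, nF))
        int_sd_pop = config.plasticity_max_ratio * sd_e * mild01.to_numpy()
        gp_eff = rng.normal(0.0, 1.0, (nG, nP)) * int_sd_pop[None, :]
        interaction_sd[name] = {p: float(s) for p, s in zip(pops, int_sd_pop)}

        eta = (mean
               + g_eff[:, None, None, None, None]
               + b_eff[:, :, None, None, None]
               + geno[None, None, :, None, None]
               + f_eff[None, None, :, :, None]
               + gp_eff[:, None, :, None, None]
               + rng.normal(0.0, sd_e, (nG, nB, nP, nF, reps)))
        if spec.scale == "continuous":
            vals = eta
        elif spec.scale == "count":
            vals = rng.poisson(np.exp(eta)).astype(float)
        else:
            vals = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
        trait_values[name] = vals

    # ---- assemble the plant table
    gi, bi, pi, fi, ri = np.meshgrid(
        np.arange(nG), np.arange(nB), np.arange(nP), np.arange(nF),
        np.arange(reps), indexing="ij")
    plants = pd.DataFrame({
        "population": np.array(pops)[pi.ravel()],
        "family": np.array(
            [fam_ids[p][f] for p, f in zip(np.array(pops)[pi.ravel()],
                                           fi.ravel())]),
        "garden": np.array(garden_ids)[gi.ravel()],
        "block": np.array(block_ids)[bi.ravel()],
    })
    for name, vals in trait_values.items():
        plants[name] = vals.ravel()

    # ---- climate grid over the same map
    nr, nc = config.grid_shape
    gu, gv = np.meshgrid((np.arange(nc) + 0.5) / nc,
                         (np.arange(nr) + 0.5) / nr, indexing="xy")
    gv = 1.0 - gv  # row 0 = north = v near 1
    gcont, gelev = _latent_gradients(gu, gv, rng, config.grid_noise)
    gclim = _climate_fields(gcont, gelev, rng)
    grid = ClimateGrid(
        x0=_LON0, y0=_LAT0 + _EXTENT,
        dx=_EXTENT / nc, dy=_EXTENT / nr,
        bands={k: np.asarray(val) for k, val in gclim.items()},
    )

    truth = Truth(
        zones={p: z for p, z in zone.items()},
        thresholds=thresholds,
        proportions=dict(config.proportions),
        informative_variables=["TD", "MWMT"],
        mildness={p: float(m) for p, m in mild01.items()},
        interaction_sd=interaction_sd,
    )
    return Study(plants=plants, climate=climate, grid=grid,
                 truth=truth, config=config)


def simulate_zone_scores(
    n_populations: int = 98,
    n_axes: int = 2,
    separation: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Population-level PC scores with a 3-zone latent structure.

    Climates come from the standard synthetic gradients; zones from the
    ordered TD-then-MWMT threshold rule; scores are zone centroids (minimum
    pairwise distance = ``separation`` * sqrt(n_axes)) plus unit-SD
    within-zone noise.  Returns (scores, climate, zone labels) — the
    canonical recovery setting for zone-tree fitting.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.02, 0.98, n_populations)
    v = rng.uniform(0.02, 0.98, n_populations)
    cont, elev = _latent_gradients(u, v, rng, 0.15)
    clim = _climate_fields(cont, elev, rng)
    pops = [f"P{i + 1:03d}" for i in range(n_populations)]
    climate = pd.DataFrame(clim, index=pd.Index(pops, name="population"))
    zone, _ = _zone_truth(climate)
    C = rng.normal(0.0, 1.0, (3, n_axes))
    C -= C.mean(axis=0)
    dmin = min(np.linalg.norm(C[i] - C[j])
               for i in range(3) for j in range(i + 1, 3))
    C *= separation * np.sqrt(n_axes) / dmin
    zidx = zone.map({"A": 0, "B": 1, "C": 2}).to_numpy()
    Y = C[zidx] + rng.normal(0.0, 1.0, (n_populations, n_axes))
    scores = pd.DataFrame(Y, index=climate.index,
                          columns=[f"PC{k + 1}" for k in range(n_axes)])
    return scores, climate, zone


def simulate_gaussian_trait(
    proportions: tuple[float, float, float, float, float],
    n_populations: int = 98, n_families: int = 2,
    n_gardens: int = 3, n_blocks: int = 6,
    total_var: float = 1.0, seed: int = 0,
) -> pd.DataFrame:
    """A single Gaussian trait under the balanced nested design with exact
    generative variance proportions (garden, block, population, family,
    residual) — the workhorse for estimator-recovery checks."""
    if abs(sum(proportions) - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    nG, nB, nP, nF = n_gardens, n_blocks, n_populations, n_families
    sg, sb, sp, sf, se = np.sqrt(np.asarray(proportions) * total_var)
    y = (rng.normal(0, sg, (nG, 1, 1, 1))
         + rng.normal(0, sb, (nG, nB, 1, 1))
         + rng.normal(0, sp, (1, 1, nP, 1))
         + rng.normal(0, sf, (1, 1, nP, nF))
         + rng.normal(0, se, (nG, nB, nP, nF)))
    gi, bi, pi, fi = np.meshgrid(np.arange(nG), np.arange(nB),
                                 np.arange(nP), np.arange(nF), indexing="ij")
    return pd.DataFrame({
        "population": [f"P{i + 1:03d}" for i in pi.ravel()],
        "family": [f"P{i + 1:03d}_F{j + 1}" for i, j in
                   zip(pi.ravel(), fi.ravel())],
        "garden": [f"G{i + 1}" for i in gi.ravel()],
        "block": [f"B{i + 1}" for i in bi.ravel()],
        "trait": y.ravel(),
    })


def export_fixture(study: Study, directory: str | Path,
                   grid_bands: list[str] | None = None) -> None:
    """Write a study in the exact file formats the CLI consumes:
    ``plants.csv``, ``climate.csv``, a text grid directory and
    ``truth.json``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    from .climate import write_climate_table
    from .traits import write_plant_table

    write_plant_table(study.plants, d / "plants.csv")
    write_climate_table(study.climate, d / "climate.csv")
    grid = study.grid
    if grid_bands is not None:
        grid = ClimateGrid(grid.x0, grid.y0, grid.dx, grid.dy,
                           bands={b: grid.bands[b] for b in grid_bands},
                           crs=grid.crs, nodata=grid.nodata, mask=grid.mask)
    grid.write_ascii(d / "grid")
    (d / "truth.json").write_text(json.dumps(study.truth.to_dict(), indent=1))


def tiny_fixture(seed: int = 20260927) -> Study:
    """The pinned small study used for golden and end-to-end tests:
    12 populations, 2 families, 3 gardens, 2 blocks, 20x20 grid."""
    cfg = SimConfig(
        n_populations=12, n_families=2, n_gardens=3, n_blocks=2,
        grid_shape=(20, 20), seed=seed,
    )
    return simulate_study(cfg)
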