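"""Population-level plasticity and trait-climate correlation screens.

Plasticity of a trait for a population is the sample standard deviation of
that population's garden means across gardens — a coarse but robust G-by-E
summary suited to designs with few environments.  Correlations with source
climate are Pearson, with Benjamini-Hochberg false-discovery-rate control
applied across the full (response x climate variable) grid of one report.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .climate import CLIMATE_VARIABLES

log = logging.getLogger(__name__)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg false-discovery-rate adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def plasticity_sd(means_by_garden: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per (population, trait) SD of garden means across gardens.

    Populations present in fewer than 2 gardens for a trait are excluded
    (logged).  Returns a population x trait frame.
    """
    if len(means_by_garden) < 2:
        raise ValueError("plasticity needs >= 2 gardens")
    stacked = pd.concat(means_by_garden, names=["garden", "population"])
    counts = stacked.groupby(level="population").count()
    sd = stacked.groupby(level="population").std(ddof=1)
    few = counts < 2
    if few.to_numpy().any():
        for pop, row in few.iterrows():
            for trait in row.index[row]:
                log.info("population %s measured in <2 gardens for %s", pop, trait)
    return sd.where(~few)


def correlate_with_climate(
    values: pd.DataFrame,
    climate: pd.DataFrame,
    alpha: float = 0.05,
    min_n: int = 10,
) -> pd.DataFrame:
    """Pearson correlations of per-population responses with climate normals.

    ``values``: population x response frame (traits or plasticity SDs).
    Returns a tidy frame (response, variable, n, r, p, p_adj, significant);
    BH adjustment spans every finite test in the report.  Zero-variance
    inputs yield missing r (excluded from adjustment).
    """
    common = values.index.intersection(climate.index)
    if len(common) < min_n:
        raise ValueError(
            f"only {len(common)} populations shared between values and climate"
        )
    rows = []
    for resp in values.columns:
        y_all = values.loc[common, resp]
        for var in CLIMATE_VARIABLES:
            x_all = climate.loc[common, var]
            ok = y_all.notna() & x_all.notna()
            n = int(ok.sum())
            if n < min_n or y_all[ok].std() == 0 or x_all[ok].std() == 0:
                rows.append((resp, var, n, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(x_all[ok], y_all[ok])
            rows.append((resp, var, n, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["response", "variable", "n", "r", "p"])
    out["p_adj"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "p_adj"] = bh_adjust(out.loc[valid, "p"])
    out["significant"] = out["p_adj"] <= alpha
    return out


def correlation_matrix(report: pd.DataFrame, masked: bool = True) -> pd.DataFrame:
    """Pivot a correlation report to variable x response, optionally
    blanking non-significant cells (the conventional table layout)."""
    r = report.pivot(index="variable", columns="response", values="r")
    r = r.reindex(index=[v for v in CLIMATE_VARIABLES if v in r.index])
    if masked:
        sig = report.pivot(index="variable", columns="response",
                           values="significant").reindex(index=r.index)
        r = r.where(sig.astype(bool))
    return r


def semipartial_screen(
    response: pd.Series,
    nuisance: pd.DataFrame,
    climate: pd.DataFrame,
    alpha: float = 0.05,
    climate_vars: tuple[str, ...] = CLIMATE_VARIABLES,
    max_condition: float = 1e8,
) -> pd.DataFrame:
    """Semi-partial correlation of a response with nuisance covariates
    after removing climate.

    Each nuisance covariate (e.g. seed-collection year, days in
    greenhouse) is residualized on the climate covariate set; the Pearson
    correlation of that residual with the response is the semi-partial r.
    The t test uses n - 2 - k degrees of freedom, k = number of climate
    covariates removed.
    """
    common = response.dropna().index
    common = common.intersection(nuisance.dropna().index).intersection(climate.index)
    C = climate.loc[common, list(climate_vars)].to_numpy(dtype=float)
    Cs = (C - C.mean(0)) / C.std(0, ddof=1)
    # several standard normals are exact linear combinations of others
    # (TD = MWMT - MCMT, eFFP = bFFP + FFP), so the covariate set is
    # residualized onto its numerically effective column space: redundant
    # directions are discarded (rank-revealing SVD) and the condition
    # check applies to the retained spectrum
    U, s, _ = np.linalg.svd(Cs, full_matrices=False)
    keep = s > s[0] * 1e-10
    r = int(keep.sum())
    if r < len(s):
        log.info("climate set rank-deficient: %d of %d directions retained",
                 r, len(s))
    cond = s[0] / s[keep][-1]
    if cond > max_condition:
        raise ValueError(f"climate covariate set is collinear (cond={cond:.3g})")
    Ur = U[:, keep]
    y = response.loc[common].to_numpy(dtype=float)
    dof = len(common) - 2 - r
    if dof < 1:
        raise ValueError("not enough populations for the semi-partial screen")
    rows = []
    for col in nuisance.columns:
        z = nuisance.loc[common, col].to_numpy(dtype=float)
        z = z - z.mean()
        resid = z - Ur @ (Ur.T @ z)
        if np.allclose(resid, 0, atol=1e-10 * max(np.abs(z).max(), 1.0)):
            rows.append((col, 0.0, 1.0))
            continue
        r = float(np.corrcoef(resid, y)[0, 1])
        t = r * np.sqrt(dof / max(1.0 - r * r, 1e-12))
        p = 2.0 * stats.t.sf(abs(t), dof)
        rows.append((col, r, float(p)))
    out = pd.DataFrame(rows, columns=["covariate", "semipartial_r", "p"])
    out["significant"] = out["p"] <= alpha
    return out
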