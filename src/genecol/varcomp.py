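"""Nested random-effects variance decomposition and the trait-retention screen.

Model (all-garden scope): trait = garden + block(garden) + population
+ family(population) + residual, every term random.  Per-garden scope drops
the garden term and nests blocks directly.  Gaussian traits are fit by
REML; count and binary traits by a variational mixed GLM on the link scale
with a latent-scale residual convention (logit: pi^2/3; log: ln(1+1/ybar)).

For perfectly balanced complete designs the Gaussian REML optimum is
computed exactly and cheaply through the ANOVA-stratum decomposition: the
Gram matrices of all random terms are Kronecker products of identity and
all-ones factors, hence commute, and the REML deviance separates over the
joint eigenspaces ("strata").  Unbalanced data fall back to a general
mixed-model fit (statsmodels MixedLM), which agrees with the stratum path
on balanced data.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .traits import DEFAULT_TRAITS, TraitSpec, spec_by_name

log = logging.getLogger(__name__)

ALL_LEVELS = ("garden", "block", "population", "family", "residual")
GARDEN_LEVELS = ("block", "population", "family", "residual")


@dataclass
class VarianceDecomposition:
    """Variance components of one trait at one scope.

    ``components`` are absolute variances on the model's link scale;
    ``proportions`` are components divided by their sum.
    """

    trait: str
    scope: str                       # "all" or a garden id
    family: str                      # gaussian | poisson | binomial
    components: dict[str, float]
    proportions: dict[str, float] = field(init=False)
    converged: bool = True
    method: str = "reml"

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if total <= 0:
            raise ValueError(f"degenerate trait {self.trait!r}: zero total variance")
        self.proportions = {k: v / total for k, v in self.components.items()}
        assert abs(sum(self.proportions.values()) - 1.0) < 1e-6

    @property
    def levels(self) -> tuple[str, ...]:
        return ALL_LEVELS if self.scope == "all" else GARDEN_LEVELS


# ---------------------------------------------------------------- balanced REML

def _stratum_reml(y: np.ndarray, gram_coef: list[np.ndarray]) -> np.ndarray:
    """Exact REML for a balanced design given the tensor-shaped response.

    ``y`` has one axis per random factor layer (e.g. (G, B, P, F)).
    ``gram_coef[i]`` gives, per factor axis, whether component i's Gram
    matrix acts as J (all-ones, entry = axis length) or I on that axis;
    encoded as the per-axis multiplicity contributed when the stratum is in
    the constant subspace of that axis (0 = killed by a contrast subspace).
    The last component is the residual (all ones).
    """
    dims = y.shape
    n_comp = len(gram_coef)
    strata: list[tuple[float, np.ndarray, float]] = []
    for c in itertools.product((0, 1), repeat=len(dims)):
        if all(ci == 0 for ci in c):
            continue  # the grand-mean stratum is projected out by REML
        d = 1.0
        for n_i, ci in zip(dims, c):
            d *= (n_i - 1) if ci else 1
        if d == 0:
            continue
        a = np.empty(n_comp)
        for i, coef in enumerate(gram_coef):
            # coef[ax] = 0 where the component's Gram is J on that axis
            # (so a contrast there kills it); otherwise it passes through.
            alive = all(not (coef[ax] == 0 and c[ax] == 1) for ax in range(len(dims)))
            if alive:
                mult = 1.0
                for ax in range(len(dims)):
                    if coef[ax] == 0 and c[ax] == 0:
                        mult *= dims[ax]
                a[i] = mult
            else:
                a[i] = 0.0
        t = y.astype(float)
        for ax, ci in enumerate(c):
            m = t.mean(axis=ax, keepdims=True)
            t = t - m if ci else np.broadcast_to(m, t.shape).copy()
        strata.append((d, a, float((t ** 2).sum())))

    def neg2reml(sig: np.ndarray) -> float:
        tot = 0.0
        for d, a, ss in strata:
            lam = float(a @ sig)
            if lam <= 0:
                return np.inf
            tot += d * np.log(lam) + ss / lam
        return tot

    v0 = max(float(np.var(y)), 1e-8)
    x0 = np.full(n_comp, v0 / n_comp)
    res = minimize(
        neg2reml, x0, method="L-BFGS-B",
        bounds=[(1e-12 * v0, None)] * n_comp,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
    )
    out = np.asarray(res.x, dtype=float)
    out[out < 1e-10 * v0] = 0.0  # clamp at zero (REML boundary)
    return out


def _within_ordinal(df: pd.DataFrame, outer: str, inner: str) -> pd.Series:
    """Ordinal position of each inner-factor label within its outer group
    (nested factors carry globally unique labels; the tensor axes need
    within-group indices)."""
    return df.groupby(outer, sort=True)[inner].transform(
        lambda s: s.map({v: i for i, v in enumerate(sorted(s.unique()))})
    )


def _balanced_tensor(sub: pd.DataFrame, trait: str, factors: list[str]):
    """Reshape to a dense tensor if the design is balanced and complete
    (exactly one observation per cell); else return None."""
    if sub[trait].isna().any():
        return None
    sub = sub.copy()
    if "block" in factors and "garden" in factors:
        sub["block"] = _within_ordinal(sub, "garden", "block")
    if "family" in factors:
        sub["family"] = _within_ordinal(sub, "population", "family")
    levels = [np.sort(sub[f].unique()) for f in factors]
    size = int(np.prod([len(lv) for lv in levels]))
    if len(sub) != size:
        return None
    idx = pd.MultiIndex.from_arrays([sub[f] for f in factors])
    if idx.duplicated().any():
        return None
    full = pd.MultiIndex.from_product(levels, names=factors)
    try:
        y = sub.set_index(idx)[trait].reindex(full)
    except Exception:
        return None
    if y.isna().any():
        return None
    return y.to_numpy().reshape([len(lv) for lv in levels])


# ---------------------------------------------------------------- general path

def _mixedlm_components(
    df: pd.DataFrame, response: str, scope: str
) -> tuple[dict[str, float], bool]:
    import statsmodels.formula.api as smf

    d = df.copy()
    d["_one"] = 1
    d["_gb"] = d["garden"].astype(str) + ":" + d["block"].astype(str)
    if scope == "all":
        vcf = {
            "garden": "0 + C(garden)",
            "block": "0 + C(_gb)",
            "population": "0 + C(population)",
            "family": "0 + C(family)",
        }
        order = ("garden", "block", "population", "family")
    else:
        vcf = {
            "block": "0 + C(block)",
            "population": "0 + C(population)",
            "family": "0 + C(family)",
        }
        order = ("block", "population", "family")
    md = smf.mixedlm(
        f"{response} ~ 1", d, groups="_one", vc_formula=vcf, re_formula="0"
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = md.fit(reml=True)
    converged = not any("Converge" in str(w.message) for w in caught)
    names = list(md.exog_vc.names)
    comp = {k: max(float(fit.vcomp[names.index(k)]), 0.0) for k in order}
    comp["residual"] = float(fit.scale)
    return comp, converged


def _vb_glmm_components(
    df: pd.DataFrame, response: str, scope: str, family: str
) -> tuple[dict[str, float], bool]:
    """Link-scale components for count/binary traits via variational Bayes
    mixed GLM, with the documented latent-scale residual."""
    from statsmodels.genmod.bayes_mixed_glm import (
        BinomialBayesMixedGLM, PoissonBayesMixedGLM,
    )

    d = df.copy()
    d["_gb"] = d["garden"].astype(str) + ":" + d["block"].astype(str)
    if scope == "all":
        vcf = {
            "garden": "0 + C(garden)",
            "block": "0 + C(_gb)",
            "population": "0 + C(population)",
            "family": "0 + C(family)",
        }
        order = ("garden", "block", "population", "family")
    else:
        vcf = {
            "block": "0 + C(block)",
            "population": "0 + C(population)",
            "family": "0 + C(family)",
        }
        order = ("block", "population", "family")
    cls = PoissonBayesMixedGLM if family == "poisson" else BinomialBayesMixedGLM
    model = cls.from_formula(f"{response} ~ 1", vcf, d)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = model.fit_vb()
    converged = not any("converge" in str(w.message).lower() for w in caught)
    vcp_names = list(model.names[model.k_fep:model.k_fep + model.k_vcp])
    vcp = fit.params[model.k_fep:model.k_fep + model.k_vcp]
    comp = {}
    for k in order:
        comp[k] = float(np.exp(2.0 * vcp[vcp_names.index(k)]))  # log-SD params
    ybar = float(df[response].mean())
    if family == "binomial":
        comp["residual"] = np.pi ** 2 / 3.0
    else:
        comp["residual"] = float(np.log1p(1.0 / max(ybar, 1e-12)))
    return comp, converged


# ------------------------------------------------------------------ public API

def decompose_trait(
    records: pd.DataFrame,
    trait: str,
    scope: str = "all",
    trait_specs: tuple[TraitSpec, ...] = DEFAULT_TRAITS,
    method: str = "auto",
) -> VarianceDecomposition:
    """Variance decomposition of one trait.

    ``scope`` is ``"all"`` (five components) or a garden id (four).
    ``method``: ``auto`` (error-family default), ``gaussian`` (force
    Gaussian on transformed data: log1p for counts, identity otherwise).
    """
    spec = spec_by_name(trait, trait_specs)
    if scope == "all":
        sub = records
        if sub["garden"].nunique() < 2:
            raise ValueError("scope='all' requires >= 2 gardens")
        factors = ["garden", "block", "population", "family"]
        levels = ALL_LEVELS
    else:
        sub = records[records["garden"].astype(str) == str(scope)]
        if len(sub) == 0:
            raise ValueError(f"no records for garden {scope!r}")
        factors = ["block", "population", "family"]
        levels = GARDEN_LEVELS
    sub = sub.dropna(subset=[trait])
    for f in factors:
        if sub[f].nunique() < 2:
            raise ValueError(f"random factor {f!r} has < 2 levels in scope")
    y = sub[trait].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError(f"degenerate trait {trait!r}: constant values")

    glmm = spec.scale in ("count", "binary") and method != "gaussian"
    if glmm:
        fam = "poisson" if spec.scale == "count" else "binomial"
        comp, conv = _vb_glmm_components(sub, trait, scope, fam)
        used = "vb_glmm"
    else:
        work = sub.copy()
        if spec.scale == "count" and method == "gaussian":
            work[trait] = np.log1p(work[trait])
        fam = "gaussian"
        tensor = _balanced_tensor(work, trait, factors)
        if tensor is not None and method in ("auto", "gaussian", "balanced"):
            if scope == "all":
                G, B, P, F = tensor.shape
                # per-axis action of each component's Gram matrix:
                # 0 = J (collapsed by contrasts), 1 = I (passes through)
                gram = [
                    np.array([1, 0, 0, 0]),   # garden
                    np.array([1, 1, 0, 0]),   # block(garden)
                    np.array([0, 0, 1, 0]),   # population
                    np.array([0, 0, 1, 1]),   # family(population)
                    np.array([1, 1, 1, 1]),   # residual
                ]
            else:
                gram = [
                    np.array([1, 0, 0]),      # block
                    np.array([0, 1, 0]),      # population
                    np.array([0, 1, 1]),      # family
                    np.array([1, 1, 1]),      # residual
                ]
            est = _stratum_reml(tensor, gram)
            comp = dict(zip(levels, est))
            conv, used = True, "reml_balanced"
        else:
            comp, conv = _mixedlm_components(work, trait, scope)
            used = "reml_mixedlm"
    if not conv:
        log.warning("variance model for %s (scope %s) did not converge", trait, scope)
    out = VarianceDecomposition(
        trait=trait, scope=scope, family=fam, components=comp,
        converged=conv, method=used,
    )
    return out


def decompose_all(
    records: pd.DataFrame,
    trait_specs: tuple[TraitSpec, ...] = DEFAULT_TRAITS,
    scopes: list[str] | None = None,
    method: str = "auto",
) -> list[VarianceDecomposition]:
    """Decompose every trait at every scope ('all' plus each garden)."""
    if scopes is None:
        scopes = ["all"] + sorted(records["garden"].astype(str).unique())
    out = []
    for spec in trait_specs:
        if spec.name not in records.columns:
            continue
        for scope in scopes:
            try:
                out.append(
                    decompose_trait(records, spec.name, scope, trait_specs, method)
                )
            except ValueError as e:
                log.warning("skipping %s at scope %s: %s", spec.name, scope, e)
    return out


def screen_traits(
    decompositions: list[VarianceDecomposition],
    threshold: float = 1e-5,
    trait_specs: tuple[TraitSpec, ...] = DEFAULT_TRAITS,
) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Retain traits with non-negligible population-level variation.

    A trait whose population variance proportion falls below ``threshold``
    in ANY garden is dropped from ALL gardens.  Returns the retained
    (trait, garden) pairs in stable order (gardens within trait, trait
    declaration order) and an exclusion log {trait: [gardens below
    threshold]}.
    """
    per_garden = [d for d in decompositions if d.scope != "all"]
    gardens = sorted({d.scope for d in per_garden})
    excluded: dict[str, list[str]] = {}
    for d in per_garden:
        if d.proportions["population"] < threshold:
            excluded.setdefault(d.trait, []).append(d.scope)
    seen = {d.trait for d in per_garden}
    retained = []
    for spec in trait_specs:
        if spec.name not in seen or spec.name in excluded:
            continue
        for g in gardens:
            retained.append((spec.name, g))
    for trait, gs in excluded.items():
        log.info("excluding trait %s everywhere (below threshold at %s)", trait, gs)
    return retained, excluded


def decompositions_table(decomps: list[VarianceDecomposition]) -> pd.DataFrame:
    """Long-format report: one row per trait x scope, percent by component."""
    rows = []
    for d in decomps:
        row = {"trait": d.trait, "scope": d.scope, "family": d.family,
               "converged": d.converged}
        for lvl in d.levels:
            row[lvl] = 100.0 * d.proportions[lvl]
        rows.append(row)
    return pd.DataFrame(rows)
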