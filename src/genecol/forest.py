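"""Random-forest transfer functions linking PC trait axes to source climate.

One forest per significant trait axis: 500 trees, one third of the
predictors eligible at each split, bootstrap sampling with replacement,
minimum leaf size 5 (the standard regression-forest defaults).  Variable
importance is the total decrease in residual sum of squares contributed by
each predictor's splits, averaged over trees; marginal effects come from
partial dependence curves.

Trees are fitted with scikit-learn, then flattened to plain arrays so that
serialized models predict without scikit-learn and predictions are
bit-reproducible across sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

FORMAT_VERSION = 1


@dataclass
class ForestParams:
    n_trees: int = 500
    mtry: int | None = None          # None -> max(1, p // 3)
    min_leaf: int = 5

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, p // 3)
        if m > p:
            raise ValueError(f"mtry={m} exceeds number of predictors ({p})")
        return m


@dataclass
class _Tree:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        # vectorized simultaneous descent of all rows
        idx = np.zeros(len(X), dtype=np.intp)
        active = np.nonzero(self.children_left[idx] != -1)[0]
        while len(active):
            node = idx[active]
            go_left = (X[active, self.feature[node]] <= self.threshold[node])
            idx[active] = np.where(go_left, self.children_left[node],
                                   self.children_right[node])
            active = active[self.children_left[idx[active]] != -1]
        return self.value[idx]


@dataclass
class ForestModel:
    axis: str
    predictors: list[str]
    params: ForestParams
    seed: int
    trees: list[_Tree]
    y_min: float
    y_max: float
    x_range: dict[str, tuple[float, float]]
    oob_prediction: np.ndarray | None = None
    oob_r2: float | None = None
    importance_: dict[str, float] = field(default_factory=dict)
    training_X: np.ndarray | None = None

    def predict(self, records: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Forest prediction = mean of tree predictions."""
        X = self._as_matrix(records)
        acc = np.zeros(len(X))
        for t in self.trees:
            acc += t.predict(X)
        return acc / len(self.trees)

    def _as_matrix(self, records) -> np.ndarray:
        if isinstance(records, pd.DataFrame):
            missing = [p for p in self.predictors if p not in records.columns]
            if missing:
                raise KeyError(f"records missing predictor(s): {missing}")
            X = records[self.predictors].to_numpy(dtype=float)
        else:
            X = np.asarray(records, dtype=float)
            if X.shape[1] != len(self.predictors):
                raise ValueError("predictor count mismatch")
        if np.isnan(X).any():
            raise ValueError("missing predictor values in records")
        return X

    # --------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION, "kind": "transfer_forest",
            "axis": self.axis, "predictors": self.predictors,
            "params": {"n_trees": self.params.n_trees,
                       "mtry": self.params.mtry,
                       "min_leaf": self.params.min_leaf},
            "seed": self.seed,
            "y_min": self.y_min, "y_max": self.y_max,
            "x_range": {k: list(v) for k, v in self.x_range.items()},
            "oob_r2": self.oob_r2,
            "importance": self.importance_,
            "trees": [
                {"left": t.children_left.tolist(),
                 "right": t.children_right.tolist(),
                 "feature": t.feature.tolist(),
                 "threshold": t.threshold.tolist(),
                 "value": t.value.tolist()}
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForestModel":
        if d.get("kind") != "transfer_forest":
            raise ValueError("not a serialized transfer forest")
        trees = [
            _Tree(np.asarray(t["left"]), np.asarray(t["right"]),
                  np.asarray(t["feature"]), np.asarray(t["threshold"], float),
                  np.asarray(t["value"], float))
            for t in d["trees"]
        ]
        p = d["params"]
        return cls(
            axis=d["axis"], predictors=list(d["predictors"]),
            params=ForestParams(p["n_trees"], p["mtry"], p["min_leaf"]),
            seed=d["seed"], trees=trees,
            y_min=d["y_min"], y_max=d["y_max"],
            x_range={k: tuple(v) for k, v in d["x_range"].items()},
            oob_r2=d.get("oob_r2"),
            importance_=d.get("importance", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _extract_tree(est) -> _Tree:
    t = est.tree_
    return _Tree(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        value=t.value[:, 0, 0].copy(),
    )


def _rss_importance(rf: RandomForestRegressor, p: int) -> np.ndarray:
    """Per-predictor decrease in residual sum of squares from its splits,
    averaged over trees (node MSE x node weight recovers node RSS)."""
    total = np.zeros(p)
    for est in rf.estimators_:
        t = est.tree_
        w = t.weighted_n_node_samples
        imp = t.impurity
        for n in range(t.node_count):
            l, r = t.children_left[n], t.children_right[n]
            if l == -1:
                continue
            dec = w[n] * imp[n] - w[l] * imp[l] - w[r] * imp[r]
            total[t.feature[n]] += dec
    return total / len(rf.estimators_)


def axis_seed(master_seed: int, axis_index: int) -> int:
    """Per-axis fitting seed derived from the master seed; results are
    independent of the order in which axes are fitted."""
    return int(np.random.SeedSequence([master_seed, axis_index])
               .generate_state(1)[0] % (2 ** 31))


def fit_forest(
    y: pd.Series | np.ndarray,
    climate: pd.DataFrame,
    params: ForestParams | None = None,
    seed: int = 0,
    axis: str = "PC1",
) -> ForestModel:
    """Fit one transfer forest for one trait axis."""
    params = params or ForestParams()
    if isinstance(y, pd.Series):
        common = y.index.intersection(climate.index)
        yv = y.loc[common].to_numpy(dtype=float)
        X = climate.loc[common]
    else:
        yv = np.asarray(y, dtype=float)
        X = climate
    if len(yv) < 10:
        raise ValueError("need at least 10 populations to fit a forest")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    mtry = params.resolved_mtry(len(names))
    rf = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=mtry,
        min_samples_leaf=params.min_leaf,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(Xv, yv)
    imp = _rss_importance(rf, len(names))
    model = ForestModel(
        axis=axis, predictors=names, params=params, seed=seed,
        trees=[_extract_tree(e) for e in rf.estimators_],
        y_min=float(yv.min()), y_max=float(yv.max()),
        x_range={n: (float(Xv[:, j].min()), float(Xv[:, j].max()))
                 for j, n in enumerate(names)},
        oob_prediction=rf.oob_prediction_.copy(),
        oob_r2=float(rf.oob_score_),
        importance_={n: float(v) for n, v in zip(names, imp)},
        training_X=Xv,
    )
    return model


def fit_axis_forests(
    scores: pd.DataFrame,
    climate: pd.DataFrame,
    params: ForestParams | None = None,
    master_seed: int = 0,
) -> dict[str, ForestModel]:
    """One forest per axis column of ``scores`` with per-axis derived seeds."""
    clim = climate[[c for c in climate.columns
                    if np.issubdtype(climate[c].dtype, np.number)]]
    return {
        ax: fit_forest(scores[ax], clim, params,
                       seed=axis_seed(master_seed, i), axis=ax)
        for i, ax in enumerate(scores.columns)
    }


def importance(model: ForestModel) -> pd.Series:
    """Predictor importances, descending (average RSS decrease)."""
    s = pd.Series(model.importance_, name=model.axis)
    return s.sort_values(ascending=False)


def partial_dependence(
    model: ForestModel, predictor: str, n_grid: int = 51,
    training: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean prediction over the training set as one predictor sweeps an
    equally spaced grid across its observed range."""
    if predictor not in model.predictors:
        raise KeyError(f"unknown predictor {predictor!r}")
    if training is None:
        training = model.training_X
    if training is None:
        raise ValueError("no training data available; pass `training`")
    X = model._as_matrix(training)
    j = model.predictors.index(predictor)
    lo, hi = model.x_range[predictor]
    gridv = np.linspace(lo, hi, n_grid)
    out = np.empty(n_grid)
    W = X.copy()
    for i, g in enumerate(gridv):
        W[:, j] = g
        out[i] = model.predict(W).mean()
    return pd.DataFrame({predictor: gridv, "prediction": out})


def predict_axes(
    models: dict[str, ForestModel], records: pd.DataFrame
) -> pd.DataFrame:
    """Per-record vector of axis predictions (columns follow the model
    dict order)."""
    return pd.DataFrame(
        {ax: m.predict(records) for ax, m in models.items()},
        index=records.index,
    )
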