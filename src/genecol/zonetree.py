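"""Multivariate regression trees for fixed-boundary seed zones.

The tree recursively partitions populations, described by a multivariate
response (raw PC trait-axis scores), on climate predictors — at each node
choosing the binary split that minimizes the summed squared Euclidean
distance of responses to their child centroids.  Raw (unstandardized)
scores are used deliberately: each axis then carries its eigenvalue, so
axes are weighted by the trait variance they explain.

Determinism contract: numeric split candidates are midpoints of adjacent
distinct sorted values with the left branch taking strictly smaller
values; ties in gain are broken by predictor declaration order, then by
the smaller threshold; categorical ties by subset enumeration order.
Hierarchy levels group splits by decreasing gain under ancestor-closure
(a split is selectable only after its parent), so every level prefix is a
valid pruned subtree; terminal zones are coded letter / digit / lowercase
by level (e.g. "C1b").
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = 1
MAX_CATEGORICAL_LEVELS = 12

_ALPHABETS = (string.ascii_uppercase,
              tuple(str(i) for i in range(1, 100)),
              string.ascii_lowercase)


@dataclass
class SplitRule:
    predictor: str
    kind: str                      # "numeric" | "categorical"
    threshold: float | None = None
    left_levels: tuple[str, ...] | None = None
    gain: float = 0.0
    gain_fraction: float = 0.0     # gain / SS(root)

    def goes_left(self, value) -> bool:
        if self.kind == "numeric":
            return float(value) < self.threshold
        return str(value) in self.left_levels

    def describe(self) -> str:
        if self.kind == "numeric":
            return f"{self.predictor} < {self.threshold:g}"
        return f"{self.predictor} in {{{','.join(self.left_levels)}}}"


@dataclass
class ZoneNode:
    id: int
    depth: int
    members: list[str]             # population ids
    centroid: np.ndarray
    ss: float                      # within-node sum of squared distances
    parent: int | None = None
    split: SplitRule | None = None
    children: tuple[int, int] | None = None
    level: int | None = None       # hierarchy level of this node's split
    code: str = ""

    @property
    def is_leaf(self) -> bool:
        return self.children is None


def _node_ss(Y: np.ndarray) -> tuple[np.ndarray, float]:
    c = Y.mean(axis=0)
    return c, float(((Y - c) ** 2).sum())


def _best_numeric_split(Y: np.ndarray, x: np.ndarray, min_node: int):
    """Gain-maximizing threshold for one numeric predictor.

    Uses prefix sums: SS(node) - SS(L) - SS(R) =
    ||sum_L y||^2/n_L + ||sum_R y||^2/n_R - ||sum y||^2/n.
    Returns (gain, threshold) or None.  Among equal gains the smallest
    threshold wins.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    Ys = Y[order]
    csum = np.cumsum(Ys, axis=0)
    total = csum[-1]
    base = float((total ** 2).sum()) / n
    tol = 1e-12 * float((Y ** 2).sum())  # round-off floor for "no gain"
    best = None
    distinct = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
    for i in distinct:
        nl = i + 1
        nr = n - nl
        if nl < min_node or nr < min_node:
            continue
        sl = csum[i]
        sr = total - sl
        gain = float((sl ** 2).sum()) / nl + float((sr ** 2).sum()) / nr - base
        if gain > tol and (best is None or gain > best[0] + 1e-12):
            best = (gain, 0.5 * (xs[i] + xs[i + 1]))
    return best


def _best_categorical_split(Y: np.ndarray, x: np.ndarray, min_node: int):
    """Exhaustive binary level-set search for a categorical predictor.

    Levels are sorted lexicographically; subsets are enumerated by
    ascending bitmask restricted to masks containing the first level (each
    bipartition once).  Returns (gain, left_levels) or None.
    """
    levels = sorted(set(map(str, x)))
    L = len(levels)
    if L > MAX_CATEGORICAL_LEVELS:
        raise ValueError(
            f"categorical predictor has {L} levels (max {MAX_CATEGORICAL_LEVELS})"
        )
    if L < 2:
        return None
    codes = np.array([levels.index(str(v)) for v in x])
    n = len(x)
    total = Y.sum(axis=0)
    base = float((total ** 2).sum()) / n
    # per-level sums
    sums = np.zeros((L, Y.shape[1]))
    cnts = np.zeros(L, dtype=int)
    for lv in range(L):
        m = codes == lv
        cnts[lv] = m.sum()
        sums[lv] = Y[m].sum(axis=0)
    best = None
    for mask in range(1, 2 ** L):
        if not mask & 1:           # canonical: left set contains level 0
            continue
        if mask == 2 ** L - 1:
            continue
        idx = [lv for lv in range(L) if mask >> lv & 1]
        nl = int(cnts[idx].sum())
        nr = n - nl
        if nl < min_node or nr < min_node:
            continue
        sl = sums[idx].sum(axis=0)
        sr = total - sl
        gain = float((sl ** 2).sum()) / nl + float((sr ** 2).sum()) / nr - base
        if gain > 1e-12 * float((Y ** 2).sum()) and (
                best is None or gain > best[0] + 1e-12):
            best = (gain, tuple(levels[lv] for lv in idx))
    return best


def best_split(
    Y: np.ndarray,
    predictors: pd.DataFrame,
    min_node: int,
    categorical: tuple[str, ...] = (),
) -> SplitRule | None:
    """Best split of one node over all predictors (declaration order is the
    tie-break: the earlier predictor wins at equal gain)."""
    if len(Y) < 2 * min_node:
        return None
    best_rule: SplitRule | None = None
    for name in predictors.columns:
        x = predictors[name].to_numpy()
        if name in categorical:
            res = _best_categorical_split(Y, x, min_node)
            if res is None:
                continue
            gain, left = res
            rule = SplitRule(name, "categorical", left_levels=left, gain=gain)
        else:
            res = _best_numeric_split(Y, x.astype(float), min_node)
            if res is None:
                continue
            gain, thr = res
            rule = SplitRule(name, "numeric", threshold=float(thr), gain=gain)
        if best_rule is None or rule.gain > best_rule.gain + 1e-12:
            best_rule = rule
    return best_rule


@dataclass
class ZoneTreeModel:
    nodes: dict[int, ZoneNode]
    cp: float
    min_node: int
    predictors: list[str]
    categorical: tuple[str, ...]
    level_cut_points: tuple[int, ...]
    root_ss: float

    @property
    def root(self) -> ZoneNode:
        return self.nodes[0]

    def leaves(self) -> list[ZoneNode]:
        """Terminal nodes in left-to-right tree order."""
        out: list[ZoneNode] = []

        def walk(nid: int) -> None:
            node = self.nodes[nid]
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.children[0])
                walk(node.children[1])

        walk(0)
        return out

    def splits_by_gain(self) -> list[ZoneNode]:
        """Internal nodes ordered by decreasing split gain with
        ancestor-closure: a node is emitted only after its parent, so every
        prefix of the sequence is a valid pruned subtree."""
        internal = {nid: n for nid, n in self.nodes.items() if not n.is_leaf}
        emitted: set[int] = set()
        order: list[ZoneNode] = []
        while len(order) < len(internal):
            eligible = [
                n for nid, n in internal.items()
                if nid not in emitted and (n.parent is None or n.parent in emitted)
            ]
            nxt = max(eligible, key=lambda n: (n.split.gain, -n.id))
            emitted.add(nxt.id)
            order.append(nxt)
        return order

    # ---------------------------------------------------------------- output
    def assign(self, record) -> str:
        """Terminal zone code for one climate record (mapping-like).
        Descent is deterministic: left iff the split condition holds
        (numeric left = strictly less than the threshold)."""
        node = self.root
        while not node.is_leaf:
            name = node.split.predictor
            try:
                value = record[name]
            except (KeyError, IndexError):
                raise KeyError(f"record is missing predictor {name!r}") from None
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise KeyError(f"record is missing predictor {name!r}")
            node = self.nodes[
                node.children[0] if node.split.goes_left(value) else node.children[1]
            ]
        return node.code

    def leaf_for(self, record) -> ZoneNode:
        code = self.assign(record)
        return next(l for l in self.leaves() if l.code == code)

    def variance_by_level(self) -> tuple[list[float], float]:
        """Fraction of root SS explained by each hierarchy level's splits,
        plus the residual fraction; they sum to 1."""
        splits = self.splits_by_gain()
        n_levels = max([len(self.level_cut_points)]
                       + [n.level for n in splits if n.level])
        fracs = [0.0] * n_levels
        for node in splits:
            fracs[node.level - 1] += node.split.gain_fraction
        residual = 1.0 - sum(fracs)
        assert abs(sum(fracs) + residual - 1.0) < 1e-8
        return fracs, residual

    def render_text(self) -> str:
        lines: list[str] = []

        def walk(nid: int, indent: str) -> None:
            node = self.nodes[nid]
            if node.is_leaf:
                lines.append(
                    f"{indent}[{node.code}] n={len(node.members)} "
                    f"ss={node.ss:.3f}"
                )
            else:
                s = node.split
                lines.append(
                    f"{indent}{s.describe()}  (gain {100 * s.gain_fraction:.1f}%"
                    f", level {node.level})"
                )
                walk(node.children[0], indent + "  ")
                walk(node.children[1], indent + "  ")

        walk(0, "")
        return "\n".join(lines)

    # --------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        nodes = {}
        for nid, n in self.nodes.items():
            d = {
                "depth": n.depth, "members": n.members,
                "centroid": n.centroid.tolist(), "ss": n.ss,
                "parent": n.parent, "children": n.children,
                "level": n.level, "code": n.code,
            }
            if n.split is not None:
                d["split"] = {
                    "predictor": n.split.predictor, "kind": n.split.kind,
                    "threshold": n.split.threshold,
                    "left_levels": n.split.left_levels,
                    "gain": n.split.gain, "gain_fraction": n.split.gain_fraction,
                }
            nodes[str(nid)] = d
        return {
            "format_version": FORMAT_VERSION, "kind": "zone_tree",
            "cp": self.cp, "min_node": self.min_node,
            "predictors": self.predictors,
            "categorical": list(self.categorical),
            "level_cut_points": list(self.level_cut_points),
            "root_ss": self.root_ss, "nodes": nodes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZoneTreeModel":
        if d.get("kind") != "zone_tree":
            raise ValueError("not a serialized zone tree")
        nodes = {}
        for nid, nd in d["nodes"].items():
            split = None
            if "split" in nd:
                sp = nd["split"]
                split = SplitRule(
                    sp["predictor"], sp["kind"], sp["threshold"],
                    tuple(sp["left_levels"]) if sp["left_levels"] else None,
                    sp["gain"], sp["gain_fraction"],
                )
            nodes[int(nid)] = ZoneNode(
                id=int(nid), depth=nd["depth"], members=list(nd["members"]),
                centroid=np.asarray(nd["centroid"], float), ss=nd["ss"],
                parent=nd["parent"], split=split,
                children=tuple(nd["children"]) if nd["children"] else None,
                level=nd["level"], code=nd["code"],
            )
        return cls(
            nodes=nodes, cp=d["cp"], min_node=d["min_node"],
            predictors=list(d["predictors"]),
            categorical=tuple(d["categorical"]),
            level_cut_points=tuple(d["level_cut_points"]),
            root_ss=d["root_ss"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ZoneTreeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_zonetree(
    scores: pd.DataFrame,
    predictors: pd.DataFrame,
    cp: float = 0.015,
    min_node: int = 5,
    categorical: tuple[str, ...] = (),
    level_cut_points: tuple[int, ...] = (2, 7, 12),
) -> ZoneTreeModel:
    """Fit the multivariate regression tree.

    ``scores``: population x axis frame of raw PC scores; ``predictors``:
    population x predictor frame (climate normals, optional categorical
    taxon).  A split is kept iff its gain is at least ``cp`` times the root
    SS and both children hold at least ``min_node`` populations.
    """
    if min_node < 1:
        raise ValueError("min_node must be >= 1")
    if cp < 0:
        raise ValueError("cp must be >= 0")
    common = scores.index.intersection(predictors.index)
    if len(common) < 2 * min_node:
        raise ValueError("not enough populations to fit a tree")
    scores = scores.loc[common]
    predictors = predictors.loc[common]
    Y = scores.to_numpy(dtype=float)
    pops = [str(i) for i in scores.index]

    nodes: dict[int, ZoneNode] = {}
    counter = itertools.count()

    def grow(idx: np.ndarray, depth: int, parent: int | None, root_ss: float | None):
        nid = next(counter)
        c, ss = _node_ss(Y[idx])
        node = ZoneNode(
            id=nid, depth=depth, members=[pops[i] for i in idx],
            centroid=c, ss=ss, parent=parent,
        )
        nodes[nid] = node
        if root_ss is None:
            root_ss = ss
        rule = best_split(Y[idx], predictors.iloc[idx], min_node, categorical)
        if rule is None or root_ss <= 0 or rule.gain < cp * root_ss - 1e-12:
            return nid
        rule.gain_fraction = rule.gain / root_ss
        vals = predictors[rule.predictor].to_numpy()[idx]
        left_mask = np.array([rule.goes_left(v) for v in vals])
        node.split = rule
        lid = grow(idx[left_mask], depth + 1, nid, root_ss)
        rid = grow(idx[~left_mask], depth + 1, nid, root_ss)
        node.children = (lid, rid)
        return nid

    grow(np.arange(len(common)), 0, None, None)
    model = ZoneTreeModel(
        nodes=nodes, cp=cp, min_node=min_node,
        predictors=list(predictors.columns), categorical=tuple(categorical),
        level_cut_points=tuple(level_cut_points),
        root_ss=nodes[0].ss,
    )
    _assign_levels(model)
    assign_zone_codes(model)
    return model


def _assign_levels(model: ZoneTreeModel) -> None:
    """Assign each split a hierarchy level: splits are taken in
    gain-descending order (with ancestor-closure) and the cumulative
    cut-points close each level; splits past the last cut-point fall into
    one overflow level.  Levels are monotone non-decreasing along any
    root-to-leaf path because a child split is always emitted after its
    parent."""
    cuts = model.level_cut_points
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("level cut-points must be strictly increasing")
    for rank, node in enumerate(model.splits_by_gain()):
        node.level = next(
            (i + 1 for i, c in enumerate(cuts) if rank < c), len(cuts) + 1
        )


def assign_zone_codes(model: ZoneTreeModel) -> None:
    """Hierarchical zone codes for all nodes.

    Splits of level 1 partition populations into primary zones labeled
    A, B, C... in left-to-right tree order; level-2 splits refine each
    primary into digit-coded secondaries; level-3 splits into lowercase
    tertiaries.  A zone that is not further split at some level keeps its
    shorter code (e.g. a primary leaf is just "B")."""

    def frontier_of(nid: int, level: int) -> list[int]:
        """Maximal descendants reachable through splits of this level,
        left-to-right."""
        node = model.nodes[nid]
        if node.is_leaf or node.level > level:
            return [nid]
        return (frontier_of(node.children[0], level)
                + frontier_of(node.children[1], level))

    def label(nid: int, code: str) -> None:
        node = model.nodes[nid]
        node.code = code
        if node.is_leaf:
            return
        level = node.level
        alphabet = _ALPHABETS[(level - 1) % len(_ALPHABETS)]
        for pos, f in enumerate(frontier_of(nid, level)):
            label(f, code + alphabet[pos])
        # interior nodes of this level's frontier share the parent code
        def fill(i: int) -> None:
            nd = model.nodes[i]
            if nd.is_leaf or nd.level > level:
                return
            if not nd.code:
                nd.code = code
            fill(nd.children[0])
            fill(nd.children[1])

        fill(nid)

    root = model.root
    if root.is_leaf:
        root.code = "A"
    else:
        label(0, "")


def zone_codes(
    model: ZoneTreeModel, level_cut_points: tuple[int, ...] | None = None
) -> dict[str, str]:
    """Terminal node id -> hierarchical zone code.  Passing
    ``level_cut_points`` re-levels and re-codes the fitted tree."""
    if level_cut_points is not None:
        model.level_cut_points = tuple(level_cut_points)
        _assign_levels(model)
        assign_zone_codes(model)
    return {str(leaf.id): leaf.code for leaf in model.leaves()}
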