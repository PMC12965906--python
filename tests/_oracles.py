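"""Independent oracles used only by the test suite.

These deliberately use naive, closed-form or brute-force computations so
that agreement with the package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np


def ems_variance_components(y4: np.ndarray) -> dict[str, float]:
    """Closed-form ANOVA expected-mean-square estimators for the balanced
    crossed/nested design: garden x block(garden) x population x
    family(population), one observation per cell.

    ``y4`` has shape (G, B, P, F).  Returns absolute variance components
    (possibly negative: no clamping, that is the point of the oracle).
    """
    G, B, P, F = y4.shape
    grand = y4.mean()
    m_g = y4.mean(axis=(1, 2, 3))
    m_gb = y4.mean(axis=(2, 3))
    m_p = y4.mean(axis=(0, 1, 3))
    m_pf = y4.mean(axis=(0, 1))

    ss_g = B * P * F * ((m_g - grand) ** 2).sum()
    ss_b = P * F * ((m_gb - m_g[:, None]) ** 2).sum()
    ss_p = G * B * F * ((m_p - grand) ** 2).sum()
    ss_f = G * B * ((m_pf - m_p[:, None]) ** 2).sum()
    ss_tot = ((y4 - grand) ** 2).sum()
    df_g, df_b, df_p, df_f = G - 1, G * (B - 1), P - 1, P * (F - 1)
    df_e = G * B * P * F - 1 - df_g - df_b - df_p - df_f
    ss_e = ss_tot - ss_g - ss_b - ss_p - ss_f

    ms_g, ms_b = ss_g / df_g, ss_b / df_b
    ms_p, ms_f = ss_p / df_p, ss_f / df_f
    ms_e = ss_e / df_e
    return {
        "garden": (ms_g - ms_b) / (B * P * F),
        "block": (ms_b - ms_e) / (P * F),
        "population": (ms_p - ms_f) / (G * B * F),
        "family": (ms_f - ms_e) / (G * B),
        "residual": ms_e,
    }


def _ss(Y: np.ndarray) -> float:
    return float(((Y - Y.mean(axis=0)) ** 2).sum())


def brute_force_tree(
    Y: np.ndarray,
    X: np.ndarray,
    col_names: list[str],
    cp: float,
    min_node: int,
):
    """Naive recursive enumerator for the multivariate regression tree.

    Evaluates every candidate threshold of every predictor by explicitly
    recomputing child sums of squares around child centroids.  Tie-breaks:
    earlier predictor column wins; among its thresholds the smallest.
    Returns a nested dict: leaves carry sorted member index tuples,
    internal nodes carry (predictor, threshold, left, right).
    """
    root_ss = _ss(Y)

    def split_node(idx: np.ndarray):
        best = None  # (gain, col, threshold, left_idx, right_idx)
        node_ss = _ss(Y[idx])
        for j in range(X.shape[1]):
            vals = np.unique(X[idx, j])
            for a, b in zip(vals[:-1], vals[1:]):
                thr = (a + b) / 2.0
                left = idx[X[idx, j] < thr]
                right = idx[X[idx, j] >= thr]
                if len(left) < min_node or len(right) < min_node:
                    continue
                gain = node_ss - _ss(Y[left]) - _ss(Y[right])
                if gain <= 0:
                    continue
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, j, thr, left, right)
        return best

    def grow(idx: np.ndarray):
        if len(idx) < 2 * min_node:
            return {"members": tuple(sorted(idx.tolist()))}
        best = split_node(idx)
        if best is None or best[0] < cp * root_ss - 1e-12:
            return {"members": tuple(sorted(idx.tolist()))}
        gain, j, thr, left, right = best
        return {
            "predictor": col_names[j],
            "threshold": thr,
            "left": grow(left),
            "right": grow(right),
        }

    return grow(np.arange(len(Y)))


def tree_to_nested(model, index_of: dict[str, int]):
    """Flatten a fitted ZoneTreeModel to the same nested form as
    :func:`brute_force_tree` for structural comparison."""

    def walk(nid: int):
        node = model.nodes[nid]
        if node.is_leaf:
            return {"members": tuple(sorted(index_of[m] for m in node.members))}
        return {
            "predictor": node.split.predictor,
            "threshold": node.split.threshold,
            "left": walk(node.children[0]),
            "right": walk(node.children[1]),
        }

    return walk(0)


def trees_equal(a, b, tol: float = 1e-9) -> bool:
    if ("members" in a) != ("members" in b):
        return False
    if "members" in a:
        return a["members"] == b["members"]
    if a["predictor"] != b["predictor"]:
        return False
    if abs(a["threshold"] - b["threshold"]) > tol:
        return False
    return (trees_equal(a["left"], b["left"], tol)
            and trees_equal(a["right"], b["right"], tol))
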