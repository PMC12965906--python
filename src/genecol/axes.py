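"""Composite trait axes: correlation-matrix PCA of the population x
(trait, garden) mean matrix and a Monte Carlo test for the number of
significant axes.

The matrix is centered and scaled column-wise so eigenvalues sum to the
number of columns.  Significance of the leading axes is judged by a
permutation test on cumulative eigenvalue sums: each permutation shuffles
values independently within every column (preserving marginals, destroying
correlation), and axis k is significant when the observed sum of the first
k eigenvalues is extreme relative to the permutation null.  The number of
significant axes is the longest unbroken significant prefix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = 1


@dataclass
class TraitSpace:
    """A fitted PCA of the trait matrix.

    ``loadings`` (columns x axes) and ``scores`` (populations x axes) obey
    ``scores = standardized(X) @ loadings``; both carry all axes.  Raw
    (unstandardized) scores keep the eigenvalue weighting of the axes,
    which is what downstream zone trees and transfer forests consume.
    """

    columns: list[str]
    populations: list[str]
    centers: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    n_significant: int | None = None
    test_meta: dict = field(default_factory=dict)

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.eigenvalues) / self.eigenvalues.sum()

    def significant_scores(self) -> pd.DataFrame:
        """Scores on the significant axes (all axes if untested)."""
        k = self.n_significant if self.n_significant else self.scores.shape[1]
        return pd.DataFrame(
            self.scores[:, :k],
            index=pd.Index(self.populations, name="population"),
            columns=[f"PC{i + 1}" for i in range(k)],
        )

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "kind": "trait_space",
            "columns": self.columns,
            "populations": self.populations,
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "scores": self.scores.tolist(),
            "n_significant": self.n_significant,
            "test_meta": self.test_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TraitSpace":
        if d.get("kind") != "trait_space":
            raise ValueError("not a serialized trait space")
        return cls(
            columns=list(d["columns"]),
            populations=list(d["populations"]),
            centers=np.asarray(d["centers"], float),
            scales=np.asarray(d["scales"], float),
            loadings=np.asarray(d["loadings"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            scores=np.asarray(d["scores"], float),
            n_significant=d.get("n_significant"),
            test_meta=d.get("test_meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TraitSpace":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _standardize(X: np.ndarray, columns) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    # a constant column can have std ~1e-16 from centering round-off
    zero = np.where((scales == 0) | (np.ptp(X, axis=0) == 0))[0]
    if len(zero):
        names = [columns[i] for i in zero]
        raise ValueError(f"zero-variance column(s): {names}")
    return (X - centers) / scales, centers, scales


def _eigenvalues(Z: np.ndarray) -> np.ndarray:
    n = Z.shape[0]
    s = np.linalg.svd(Z, compute_uv=False)
    lam = np.zeros(Z.shape[1])
    lam[: len(s)] = s ** 2 / (n - 1)
    return lam


def fit_pca(matrix: pd.DataFrame) -> TraitSpace:
    """Correlation-matrix PCA of a complete trait matrix.

    Sign convention: each loading vector is flipped so its
    largest-magnitude element is positive, making outputs reproducible
    across linear-algebra backends.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("trait matrix has missing cells")
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need >= 3 populations and >= 2 columns")
    X = matrix.to_numpy(dtype=float)
    Z, centers, scales = _standardize(X, list(matrix.columns))
    n, p = Z.shape
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    lam = np.zeros(p)
    lam[: len(s)] = s ** 2 / (n - 1)
    V = Vt.T
    if V.shape[1] < p:  # n-1 < p: pad the null space with zeros
        V = np.hstack([V, np.zeros((p, p - V.shape[1]))])
        U = np.hstack([U, np.zeros((n, p - U.shape[1]))])
        s = np.concatenate([s, np.zeros(p - len(s))])
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = Z @ V
    return TraitSpace(
        columns=list(matrix.columns),
        populations=[str(i) for i in matrix.index],
        centers=centers,
        scales=scales,
        loadings=V,
        eigenvalues=lam,
        scores=scores,
    )


def test_axes(
    matrix: pd.DataFrame,
    B: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> TraitSpace:
    """Fit the PCA and count significant axes by Monte Carlo.

    For each k the statistic is S_k = sum of the k leading eigenvalues; the
    null draws B within-column permutations; p_k = (1 + #{S*_k >= S_k}) /
    (B + 1); axes are declared significant along the unbroken prefix with
    p_k <= alpha.
    """
    if B < 99:
        raise ValueError("B must be >= 99")
    space = fit_pca(matrix)
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    obs = np.cumsum(space.eigenvalues)
    exceed = np.zeros(p, dtype=int)
    Xp = X.copy()
    for _ in range(B):
        for j in range(p):
            Xp[:, j] = X[rng.permutation(n), j]
        Zp = (Xp - Xp.mean(axis=0)) / Xp.std(axis=0, ddof=1)
        lam = _eigenvalues(Zp)
        exceed += np.cumsum(lam) >= obs - 1e-12
    pvals = (1.0 + exceed) / (B + 1.0)
    k = 0
    while k < p and pvals[k] <= alpha:
        k += 1
    space.n_significant = k
    space.test_meta = {"B": B, "alpha": alpha, "seed": seed,
                       "pvalues": pvals.tolist()}
    return space
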