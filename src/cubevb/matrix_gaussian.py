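"""Multivariate normal distributions over log matrix entries.

A distribution over rooted time trees is represented by a multivariate
normal N(mu, Sigma) on the *logarithms* of a chosen set of matrix entries
(MRCA heights, or optionally pairwise path distances).  Sampling a tree
means drawing from the normal, exponentiating, filling the matrix, and
decoding with single-link clustering.  Setting z = 0 (i.e. the matrix
exp(mu)) gives a deterministic mode/summary tree.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .treespace import (
    EntryPattern,
    TimeTree,
    TreeMatrix,
    single_link_tree,
)

__all__ = ["MatrixGaussian", "TreeSample", "fit_matrix_gaussian"]

#: eigenvalues more negative than this trigger a warning before clipping
_NEG_EIG_TOL = -1e-8


def psd_sqrt(sigma: np.ndarray) -> np.ndarray:
    """A matrix square root A with A @ A.T = sigma, valid for singular sigma.

    Uses the Cholesky factor when sigma is positive definite; otherwise an
    eigendecomposition with negative eigenvalues clipped to zero (warning if
    they are more than rounding noise), so a zero covariance yields exactly
    the mean.
    """
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        lam, V = np.linalg.eigh(sigma)
        if lam.min() < _NEG_EIG_TOL * max(1.0, abs(lam.max())):
            warnings.warn(
                "covariance has negative eigenvalues; clipping to zero",
                RuntimeWarning,
                stacklevel=3,
            )
        return V * np.sqrt(np.clip(lam, 0.0, None))


@dataclass
class TreeSample:
    """A set of trees over a common taxon set, with optional weights."""

    trees: list[TimeTree]
    weights: np.ndarray | None = None

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree sample")
        taxa = self.trees[0].taxa
        for t in self.trees[1:]:
            if t.taxa != taxa:
                raise ValueError("all trees must share the identical taxon set")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.trees),) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be nonnegative, one per tree")
            self.weights = w / w.sum()

    @property
    def taxa(self) -> list[str]:
        return self.trees[0].taxa

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(len(self.trees), 1.0 / len(self.trees))
        return self.weights


@dataclass
class MatrixGaussian:
    """N(mu, Sigma) over the logs of ``k`` specified matrix entries.

    ``pairs[d]`` names the matrix entry carried by dimension ``d``;
    ``mu`` is on the log-height scale.
    """

    n: int
    pairs: list[tuple[int, int]]
    mu: np.ndarray
    sigma: np.ndarray
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pairs = [(min(i, j), max(i, j)) for i, j in self.pairs]
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        k = len(self.pairs)
        if self.mu.shape != (k,) or self.sigma.shape != (k, k):
            raise ValueError("mu must be length k and sigma k x k")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")
        if not self.taxa:
            self.taxa = [f"t{i}" for i in range(self.n)]

    @property
    def k(self) -> int:
        return len(self.pairs)

    # -- sampling -----------------------------------------------------------

    def _chol(self) -> np.ndarray:
        return psd_sqrt(self.sigma)

    def _matrix_from_x(self, x: np.ndarray) -> TreeMatrix:
        M = TreeMatrix(self.n, taxa=self.taxa)
        for (i, j), v in zip(self.pairs, np.exp(x)):
            M[i, j] = float(v)
        return M

    def sample_tree(self, rng: np.random.Generator) -> TimeTree:
        """Draw one tree: x = mu + A z with z standard normal, decode exp(x)."""
        z = rng.standard_normal(self.k)
        x = self.mu + self._chol() @ z
        return single_link_tree(self._matrix_from_x(x))

    def sample_trees(self, m: int, rng: np.random.Generator) -> TreeSample:
        A = self._chol()
        trees = []
        for _ in range(m):
            x = self.mu + A @ rng.standard_normal(self.k)
            trees.append(single_link_tree(self._matrix_from_x(x)))
        return TreeSample(trees)

    def summary_tree(self) -> TimeTree:
        """Deterministic tree at the distribution mode (z = 0)."""
        return single_link_tree(self._matrix_from_x(self.mu.copy()))

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "taxa": self.taxa,
                "pairs": [list(p) for p in self.pairs],
                "mu": self.mu.tolist(),
                "sigma": self.sigma.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "MatrixGaussian":
        d = json.loads(s)
        return cls(
            n=d["n"],
            pairs=[tuple(p) for p in d["pairs"]],
            mu=np.array(d["mu"]),
            sigma=np.array(d["sigma"]),
            taxa=d.get("taxa", []),
        )


def log_entries(
    tree: TimeTree, pairs: Sequence[tuple[int, int]], value: str = "mrca"
) -> np.ndarray:
    """Log entry values for one tree.

    ``value='mrca'`` uses MRCA heights; ``value='path'`` uses pairwise path
    distances, which for an ultrametric tree are exactly twice the MRCA
    height (a uniform log 2 shift of mu, same topology distribution).
    """
    H = tree.mrca_heights()
    vals = np.array([H[i, j] for i, j in pairs])
    if value == "path":
        vals = 2.0 * vals
    elif value != "mrca":
        raise ValueError("value must be 'mrca' or 'path'")
    bad = np.flatnonzero(vals <= 0)
    if bad.size:
        i, j = pairs[bad[0]]
        raise ValueError(
            f"cannot log-transform entry ({i},{j}): MRCA height is {vals[bad[0]]}"
        )
    return np.log(vals)


def fit_matrix_gaussian(
    sample: TreeSample,
    pattern: EntryPattern,
    value: str = "mrca",
) -> MatrixGaussian:
    """Moment-match a MatrixGaussian to a tree sample.

    For every tree, the specified entries are read off (MRCA heights by
    default), log-transformed, and the (weighted) mean vector and sample
    covariance are taken across trees.  The result is order-invariant in the
    tree set.
    """
    if len(sample) < 2:
        raise ValueError("need at least 2 trees to fit a covariance")
    n = sample.trees[0].n_leaves
    if pattern.n != n:
        raise ValueError("pattern size must match the taxon count")
    pairs = sorted(pattern.pairs)
    X = np.stack([log_entries(t, pairs, value=value) for t in sample.trees])
    w = sample.effective_weights()
    mu = w @ X
    D = X - mu
    # unbiased weighted covariance (reduces to np.cov for uniform weights)
    denom = 1.0 - float(w @ w)
    sigma = (D.T * w) @ D / denom if denom > 0 else np.zeros((len(pairs),) * 2)
    return MatrixGaussian(n=n, pairs=pairs, mu=mu, sigma=sigma, taxa=sample.taxa)
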