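"""Phylogenetic likelihoods, tree priors, and parameter transforms.

Substitution models are time-reversible nucleotide models (HKY, GTR) with
the rate matrix normalised to one expected substitution per time unit, so a
strict-clock rate multiplies branch lengths directly.  Site-rate
heterogeneity uses the discrete-gamma approximation with equal-probability
categories whose rates are the within-bin means (mean 1 by construction).
Likelihoods are computed by Felsenstein pruning over compressed site
patterns, with per-node rescaling to guard against underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import gamma as gamma_dist

from .treespace import TimeTree

__all__ = [
    "Alignment",
    "SubstModel",
    "hky_model",
    "gtr_model",
    "SiteModel",
    "TreePrior",
    "tree_log_likelihood",
    "tree_prior_log_density",
    "stick_breaking_forward",
    "stick_breaking_inverse",
    "PruningEngine",
]

_NUC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
# IUPAC ambiguity codes -> allowed states; anything else fully ambiguous
_AMBIG = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with taxon names."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("one sequence per taxon required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def state_vectors(self) -> np.ndarray:
        """Per-site partial-likelihood leaf vectors, shape (n_taxa, L, 4).

        Gaps and ambiguity codes become the union of their allowed states
        (all ones when fully ambiguous).
        """
        out = np.zeros((self.n_taxa, self.length, 4))
        for t, seq in enumerate(self.sequences):
            for s, ch in enumerate(seq):
                if ch in _NUC:
                    out[t, s, _NUC[ch]] = 1.0
                elif ch in _AMBIG:
                    for a in _AMBIG[ch]:
                        out[t, s, _NUC[a]] = 1.0
                else:  # gap, N, ?
                    out[t, s, :] = 1.0
        return out

    def compress(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their counts.

        Returns ``(patterns, weights)`` where ``patterns`` has shape
        ``(n_taxa, P, 4)`` (leaf partial vectors) and ``weights`` length P.
        """
        sv = self.state_vectors()  # (n, L, 4)
        cols = sv.transpose(1, 0, 2).reshape(self.length, -1)
        uniq, counts = np.unique(cols, axis=0, return_counts=True)
        patterns = uniq.reshape(len(uniq), self.n_taxa, 4).transpose(1, 0, 2)
        return np.ascontiguousarray(patterns), counts.astype(float)


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

_GTR_KEYS = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class SubstModel:
    """Time-reversible nucleotide model defined by exchangeabilities.

    ``rates`` holds the six exchangeabilities AC..GT (HKY sets the two
    transitions AG and CT to kappa and transversions to 1).  The rate
    matrix is scaled to mean rate 1 at stationarity; any overall rate
    constant is absorbed by the clock rate.
    """

    kind: str
    rates: dict[str, float]
    freqs: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("frequencies must be a positive 4-vector")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")
        for k in _GTR_KEYS:
            if self.rates.get(k, 0.0) <= 0:
                raise ValueError(f"rate {k} must be positive")

    @property
    def kappa(self) -> float:
        if self.kind != "HKY":
            raise AttributeError("kappa only defined for HKY")
        return self.rates["AG"]

    def q_matrix(self) -> np.ndarray:
        r = self.rates
        R = np.array(
            [
                [0, r["AC"], r["AG"], r["AT"]],
                [r["AC"], 0, r["CG"], r["CT"]],
                [r["AG"], r["CG"], 0, r["GT"]],
                [r["AT"], r["CT"], r["GT"], 0],
            ]
        )
        Q = R * self.freqs[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise to one expected substitution per unit time
        scale = -float(self.freqs @ np.diag(Q))
        return Q / scale

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Spectral decomposition Q = U diag(lam) Uinv via symmetrisation."""
        Q = self.q_matrix()
        sq = np.sqrt(self.freqs)
        B = (Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        U = V / sq[:, None]
        Uinv = V.T * sq[None, :]
        return lam, U, Uinv


def hky_model(kappa: float, freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> SubstModel:
    """HKY85: transition/transversion ratio kappa, arbitrary frequencies."""
    rates = {k: 1.0 for k in _GTR_KEYS}
    rates["AG"] = rates["CT"] = float(kappa)
    return SubstModel("HKY", rates, np.asarray(freqs, dtype=float))


def gtr_model(rates: dict[str, float], freqs: Sequence[float]) -> SubstModel:
    """General time-reversible model; conventionally rate CT is fixed to 1."""
    full = {k: float(rates[k]) for k in _GTR_KEYS}
    return SubstModel("GTR", full, np.asarray(freqs, dtype=float))


def transition_matrices(
    eigen: tuple[np.ndarray, np.ndarray, np.ndarray], t: np.ndarray
) -> np.ndarray:
    """P(t) for a batch of branch lengths, shape (len(t), 4, 4)."""
    lam, U, Uinv = eigen
    t = np.asarray(t, dtype=float)
    E = np.exp(np.multiply.outer(t, lam))  # (..., 4)
    return np.einsum("ij,...j,jk->...ik", U, E, Uinv)


# ---------------------------------------------------------------------------
# Site model (discrete gamma)
# ---------------------------------------------------------------------------


@dataclass
class SiteModel:
    """Gamma rate heterogeneity with equal-probability discrete categories.

    ``shape is None`` means a single rate-1 category (no heterogeneity).
    Category rates are the means within each gamma quantile bin, so they
    average exactly 1.
    """

    shape: float | None = None
    n_categories: int = 4

    def category_rates(self) -> np.ndarray:
        if self.shape is None:
            return np.ones(1)
        a = float(self.shape)
        if a <= 0:
            raise ValueError("gamma shape must be positive")
        k = self.n_categories
        edges = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        # partial expectation of Gamma(a, 1/a) up to q is CDF of Gamma(a+1, 1/a)
        cum = np.concatenate(([0.0], gamma_dist.cdf(edges, a + 1, scale=1.0 / a), [1.0]))
        return k * np.diff(cum)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


class PruningEngine:
    """Felsenstein pruning over compressed site patterns.

    Holds the pattern data for one alignment; ``log_likelihood`` evaluates
    any tree over the same taxa under a given model.  Partial likelihood
    vectors are rescaled per internal node to avoid underflow.
    """

    def __init__(self, alignment: Alignment):
        self.alignment = alignment
        self.leaf_partials, self.weights = alignment.compress()  # (n, P, 4), (P,)
        self.n_patterns = len(self.weights)

    def log_likelihood(
        self,
        tree: TimeTree,
        model: SubstModel,
        site: SiteModel | None = None,
        clock_rate: float = 1.0,
    ) -> float:
        if tree.taxa != self.alignment.taxa:
            raise ValueError("tree and alignment taxa differ")
        if clock_rate <= 0:
            raise ValueError("clock rate must be positive")
        site = site or SiteModel(shape=None)
        cat_rates = site.category_rates()
        eig = model.eigen()
        n = tree.n_leaves
        P = self.n_patterns
        C = len(cat_rates)

        order = tree.postorder_internal()
        # branch lengths for each node's two children
        kids = np.stack([tree.left[order], tree.right[order]])  # (2, n-1)
        blen = (tree.height[order][None, :] - tree.height[kids]) * clock_rate
        # (2, n-1, C, 4, 4)
        Pm = transition_matrices(eig, np.multiply.outer(blen, cat_rates))

        partials = np.empty((2 * n - 1, C, P, 4))
        partials[:n] = self.leaf_partials[:, None, :, :]
        logscale = np.zeros(P)
        for idx, v in enumerate(order):
            l, r = int(tree.left[v]), int(tree.right[v])
            pl = np.einsum("cij,cpj->cpi", Pm[0, idx], partials[l])
            pr = np.einsum("cij,cpj->cpi", Pm[1, idx], partials[r])
            prod = pl * pr
            mx = prod.max(axis=(0, 2))  # per-pattern scale
            mx = np.where(mx > 0, mx, 1.0)
            partials[v] = prod / mx[None, :, None]
            logscale += np.log(mx)
        root = partials[tree.root]  # (C, P, 4)
        site_lik = np.mean(root @ model.freqs, axis=0)  # equal-weight categories
        return float(self.weights @ (np.log(site_lik) + logscale))


def tree_log_likelihood(
    alignment: Alignment,
    tree: TimeTree,
    model: SubstModel,
    site: SiteModel | None = None,
    clock_rate: float = 1.0,
) -> float:
    """log P(alignment | tree, model); see :class:`PruningEngine`."""
    return PruningEngine(alignment).log_likelihood(tree, model, site, clock_rate)


# ---------------------------------------------------------------------------
# Tree priors
# ---------------------------------------------------------------------------


@dataclass
class TreePrior:
    """Yule (birth rate ``birth_rate``) or constant-size coalescent (``pop_size``)."""

    kind: str  # "yule" | "coalescent"
    birth_rate: float | None = None
    pop_size: float | None = None

    def __post_init__(self):
        if self.kind == "yule":
            if self.birth_rate is None or self.birth_rate <= 0:
                raise ValueError("Yule prior needs birth_rate > 0")
        elif self.kind == "coalescent":
            if self.pop_size is None or self.pop_size <= 0:
                raise ValueError("coalescent prior needs pop_size > 0")
        else:
            raise ValueError(f"unknown tree prior kind {self.kind!r}")


def _lineage_intervals(heights: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Inter-event intervals and lineage counts, from the present back to the root."""
    hs = np.sort(heights)
    times = np.concatenate(([0.0], hs))
    tau = np.diff(times)  # interval ending at each event, oldest last
    k = np.arange(n, 1, -1)  # n, n-1, ..., 2 lineages
    return tau, k


def tree_prior_log_density(T: TimeTree, prior: TreePrior) -> float:
    """Log density of the tree under its prior (heights + ranked topology).

    Yule (conditioned on n tips, labelled form): each inter-event interval
    with k lineages is Exponential(k * lambda), giving
    ``(n-1) log lambda - lambda * treeLength`` up to a constant.
    Coalescent (constant N): interval with k lineages is
    Exponential(choose(k,2)/N), giving
    ``-(n-1) log N - sum_k choose(k,2) tau_k / N``.
    """
    n = T.n_leaves
    internal = T.height[n:]
    if prior.kind == "yule":
        lam = float(prior.birth_rate)
        return (n - 1) * np.log(lam) - lam * T.total_branch_length()
    N = float(prior.pop_size)
    tau, k = _lineage_intervals(internal, n)
    return float(-(n - 1) * np.log(N) - np.sum(k * (k - 1) / 2.0 * tau) / N)


# ---------------------------------------------------------------------------
# Stick-breaking transform
# ---------------------------------------------------------------------------


def stick_breaking_forward(x: np.ndarray) -> np.ndarray:
    """Map a K-simplex point to K-1 unconstrained reals.

    Component c takes ``logit(x_c / remaining_c) + log(K - c)`` (1-based c);
    the centring term sends the uniform simplex point to the origin.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("simplex components must be strictly positive")
    if abs(x.sum() - 1.0) > 1e-8:
        raise ValueError("components must sum to 1")
    K = len(x)
    y = np.empty(K - 1)
    remaining = 1.0
    for c in range(K - 1):
        frac = x[c] / remaining
        y[c] = logit(frac) + np.log(K - c - 1)
        remaining -= x[c]
    return y


def stick_breaking_inverse(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`stick_breaking_forward`."""
    y = np.asarray(y, dtype=float)
    K = len(y) + 1
    x = np.empty(K)
    remaining = 1.0
    for c in range(K - 1):
        frac = expit(y[c] - np.log(K - c - 1))
        x[c] = frac * remaining
        remaining -= x[c]
    x[K - 1] = remaining
    return x
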