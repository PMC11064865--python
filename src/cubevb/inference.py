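"""Cube-based variational inference for rooted time trees.

The algorithm approximates a phylogenetic posterior by a multivariate
normal over transformed parameters, where the tree is transformed through a
*cube*: a fixed taxon ordering plus ``n - 1`` log gap heights.  The steps
are

0. initialise the tree by UPGMA on corrected pairwise distances;
1. find a high-posterior (approximately MAP) state by simulated annealing
   with temperature resets;
2. draw a random taxon ordering compatible with that tree;
3. run MCMC restricted to the cube of that ordering, using tree proposals
   that cannot leave the cube;
4. estimate the mean vector and covariance matrix of the transformed
   samples.

Sampling from the fitted distribution (and its z = 0 mode) goes through
:mod:`cubevb.matrix_gaussian` semantics: draw, exponentiate, decode by
single-link clustering.

Implementation notes: a cube state decodes to the Cartesian tree of its
gap heights (the maximum gap splits the ordering, recursively), so the
internal node "between" ordering positions g and g+1 keeps a stable
identity across proposals.  Partial likelihood vectors are cached per gap
node and only the nodes whose subtree changed are recomputed, which makes
single-gap proposals cheap; full recomputes (ordering refresh, substitution
parameter moves) are batched level by level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .matrix_gaussian import MatrixGaussian
from .phylo_models import (
    Alignment,
    SiteModel,
    SubstModel,
    gtr_model,
    hky_model,
    stick_breaking_forward,
    stick_breaking_inverse,
    transition_matrices,
)
from .treespace import (
    CubeOrdering,
    TimeTree,
    cube_decode,
    random_compatible_ordering,
)

__all__ = [
    "upgma_tree",
    "jc_distance_matrix",
    "AnnealingSchedule",
    "simulated_annealing",
    "PhyloPosterior",
    "ChainState",
    "find_map_state",
    "cube_narrow_exchange",
    "cube_subtree_slide",
    "run_cube_mcmc",
    "fit_variational",
    "VariationalPosterior",
]


# ---------------------------------------------------------------------------
# UPGMA initialisation
# ---------------------------------------------------------------------------


def jc_distance_matrix(alignment: Alignment) -> np.ndarray:
    """Jukes-Cantor-corrected pairwise distances from an alignment.

    Sites where either sequence is not a plain nucleotide are skipped.
    Saturated pairs (p-distance >= 3/4) are clamped just below saturation.
    """
    n = alignment.n_taxa
    codes = np.full((n, alignment.length), -1, dtype=np.int8)
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    for t, seq in enumerate(alignment.sequences):
        codes[t] = [lookup.get(c, -1) for c in seq]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            m = int(ok.sum())
            p = float(np.mean(codes[i][ok] != codes[j][ok])) if m else 0.0
            p = min(p, 0.749)
            D[i, j] = D[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return D


def upgma_tree(D: np.ndarray, taxa: Sequence[str]) -> TimeTree:
    """Average-linkage (UPGMA) rooted ultrametric tree from a distance matrix.

    Node heights are half the merge distance, so leaf-to-leaf path lengths
    approximate the input distances.  Tied or zero merge heights are nudged
    upward by a tiny epsilon so the result is a strictly ordered time tree.
    """
    D = np.asarray(D, dtype=float)
    n = len(taxa)
    if D.shape != (n, n):
        raise ValueError("distance matrix must be n x n")
    if n == 2:
        return TimeTree.from_merges(taxa, [(0, 1, max(D[0, 1] / 2.0, 1e-12))])
    Z = linkage(squareform(D, checks=False), method="average")
    heights = [0.0] * (2 * n - 1)
    fixed = []
    for k, (a, b, d, _) in enumerate(Z):
        a, b, h = int(a), int(b), d / 2.0
        lo = max(heights[a], heights[b])
        h = max(h, lo + 1e-9)
        heights[n + k] = h
        fixed.append((a, b, h))
    return TimeTree.from_merges(taxa, fixed)


# ---------------------------------------------------------------------------
# Fast prior densities (plain-math closures; evaluated every MCMC step)
# ---------------------------------------------------------------------------

_LOG_2PI = math.log(2.0 * math.pi)


def normal_logpdf(mean: float, sd: float) -> Callable[[float], float]:
    c = -0.5 * _LOG_2PI - math.log(sd)

    def f(x: float) -> float:
        return c - 0.5 * ((x - mean) / sd) ** 2

    return f


def lognormal_logpdf(meanlog: float, sdlog: float) -> Callable[[float], float]:
    c = -0.5 * _LOG_2PI - math.log(sdlog)

    def f(x: float) -> float:
        if x <= 0:
            return -math.inf
        lx = math.log(x)
        return c - lx - 0.5 * ((lx - meanlog) / sdlog) ** 2

    return f


def exponential_logpdf(mean: float = 1.0) -> Callable[[float], float]:
    lam = 1.0 / mean

    def f(x: float) -> float:
        return math.log(lam) - lam * x if x > 0 else -math.inf

    return f


def dirichlet_logpdf(alpha: float, k: int = 4) -> Callable[[np.ndarray], float]:
    c = math.lgamma(k * alpha) - k * math.lgamma(alpha)

    def f(x: np.ndarray) -> float:
        x = np.asarray(x)
        if np.any(x <= 0):
            return -math.inf
        return c + (alpha - 1.0) * float(np.sum(np.log(x)))

    return f


# ---------------------------------------------------------------------------
# Posterior model
# ---------------------------------------------------------------------------


@dataclass
class ParamSpec:
    """A scalar or simplex model parameter with its prior and transform."""

    name: str
    init: float | np.ndarray
    transform: str  # "log" | "none" | "stick"
    log_prior: Callable[[float | np.ndarray], float]
    affects_likelihood: bool = True


def default_hky_yule_params(
    kappa_meanlog: float = 1.0,
    kappa_sdlog: float = 1.25,
    birth_mean: float = 6.0,
    birth_sd: float = 0.1,
) -> list[ParamSpec]:
    """Parameter block for the HKY + Yule strict-clock model.

    The kappa prior is lognormal with the given parameters on the log scale;
    the birth-rate prior is normal (positive support enforced by the log
    transform used in proposals).
    """
    return [
        ParamSpec(
            "kappa",
            math.exp(kappa_meanlog),
            "log",
            lognormal_logpdf(kappa_meanlog, kappa_sdlog),
        ),
        ParamSpec(
            "birthRate",
            birth_mean,
            "log",
            normal_logpdf(birth_mean, birth_sd),
            affects_likelihood=False,
        ),
    ]


def default_gtr_coalescent_params() -> list[ParamSpec]:
    """Parameter block for GTR + gamma + constant coalescent.

    Rate CT is fixed to 1; the AG rate prior is lognormal with mean 1 in
    real space (sigma 1), the other transversion rates lognormal with real
    mean 0.5 (sigma 1); frequencies Dirichlet(4,4,4,4); gamma shape
    exponential(mean 1); population size lognormal(0.1, 0.1) on the log
    scale.
    """
    ag = lognormal_logpdf(-0.5, 1.0)  # real-space mean 1
    tv = lognormal_logpdf(math.log(0.5) - 0.5, 1.0)  # real-space mean 0.5
    return [
        ParamSpec("rateAG", 1.0, "log", ag),
        ParamSpec("rateAC", 0.5, "log", tv),
        ParamSpec("rateAT", 0.5, "log", tv),
        ParamSpec("rateCG", 0.5, "log", tv),
        ParamSpec("rateGT", 0.5, "log", tv),
        ParamSpec("freqs", np.full(4, 0.25), "stick", dirichlet_logpdf(4.0)),
        ParamSpec("gammaShape", 1.0, "log", exponential_logpdf(1.0)),
        ParamSpec(
            "popSize",
            math.exp(0.1),
            "log",
            lognormal_logpdf(0.1, 0.1),
            affects_likelihood=False,
        ),
    ]


class ChainState:
    """MCMC/annealing state: taxon ordering, gap heights, parameter values."""

    __slots__ = ("pi", "h", "params")

    def __init__(self, pi: Sequence[int], h: np.ndarray, params: dict):
        self.pi = list(int(i) for i in pi)
        self.h = np.asarray(h, dtype=float)
        self.params = dict(params)

    def copy(self) -> "ChainState":
        return ChainState(self.pi, self.h.copy(), {
            k: (v.copy() if isinstance(v, np.ndarray) else v)
            for k, v in self.params.items()
        })

    def tree(self, taxa: Sequence[str]) -> TimeTree:
        return cube_decode(CubeOrdering(self.pi, self.h, taxa=list(taxa)))


def _build_structure(pi: list[int], h: np.ndarray, n: int):
    """Cartesian-tree structure of a cube state.

    Gap ``g`` (between ordering positions g and g+1) is internal node code
    ``n + g``; leaves are taxon ids.  Returns (left, right, root_gap) with
    child codes.  Assumes distinct gap heights (ties have measure zero).
    """
    m = len(h)
    left = np.empty(m, dtype=np.int64)
    right = np.empty(m, dtype=np.int64)
    stack: list[int] = []
    for g in range(m):
        last = -1
        while stack and h[stack[-1]] < h[g]:
            t = stack.pop()
            right[t] = (n + last) if last >= 0 else pi[g]
            last = t
        left[g] = (n + last) if last >= 0 else pi[g]
        stack.append(g)
    last = -1
    while stack:
        t = stack.pop()
        right[t] = (n + last) if last >= 0 else pi[m]
        last = t
    return left, right, last


class PhyloPosterior:
    """Log posterior over cube states for one alignment and model.

    Use :meth:`evaluate` on a candidate state and :meth:`commit` on
    acceptance; rejected candidates leave the cache untouched.
    """

    def __init__(
        self,
        alignment: Alignment,
        tree_prior: str = "yule",
        subst: str = "hky",
        gamma_categories: int = 0,
        clock_rate: float = 1.0,
        params: list[ParamSpec] | None = None,
    ):
        self.alignment = alignment
        self.taxa = alignment.taxa
        self.n = alignment.n_taxa
        self.tree_prior = tree_prior
        self.subst = subst
        self.gamma_categories = gamma_categories
        self.clock_rate = clock_rate
        if params is None:
            params = (
                default_hky_yule_params()
                if subst == "hky"
                else default_gtr_coalescent_params()
            )
        self.param_specs = {p.name: p for p in params}
        lp, w = alignment.compress()  # (n, P, 4), (P,)
        self.leaf_partials = np.ascontiguousarray(lp.transpose(0, 2, 1))  # (n, 4, P)
        self.pattern_weights = w
        self.n_patterns = len(w)
        # committed cache
        self._c_pi: list[int] | None = None
        self._c_h: np.ndarray | None = None
        self._c_left = self._c_right = None
        self._c_partials: np.ndarray | None = None  # (m, C, 4, P)
        self._c_scale: np.ndarray | None = None  # (m, P)
        self._c_scale_sum: np.ndarray | None = None  # (P,)
        self._c_sig: tuple | None = None
        self._model_sig: tuple | None = None
        self._eigen = None
        self._cat_rates = None
        self._freqs = None
        self._parent_buf = np.empty(2 * self.n - 1, dtype=np.int64)
        self.n_likelihood_evals = 0

    # -- model assembly ----------------------------------------------------

    def subst_model(self, params: dict) -> SubstModel:
        if self.subst == "hky":
            return hky_model(params["kappa"])
        rates = {
            "AC": params["rateAC"],
            "AG": params["rateAG"],
            "AT": params["rateAT"],
            "CG": params["rateCG"],
            "CT": 1.0,
            "GT": params["rateGT"],
        }
        return gtr_model(rates, params["freqs"])

    def site_model(self, params: dict) -> SiteModel:
        if self.gamma_categories and "gammaShape" in params:
            return SiteModel(shape=params["gammaShape"], n_categories=self.gamma_categories)
        return SiteModel(shape=None)

    def _lik_signature(self, params: dict) -> tuple:
        sig = []
        for name, spec in self.param_specs.items():
            if spec.affects_likelihood:
                v = params[name]
                sig.append(tuple(v) if isinstance(v, np.ndarray) else v)
        return tuple(sig)

    def init_state(self, tree: TimeTree, rng: np.random.Generator) -> ChainState:
        ordering = random_compatible_ordering(tree, rng)
        params = {
            name: (spec.init.copy() if isinstance(spec.init, np.ndarray) else spec.init)
            for name, spec in self.param_specs.items()
        }
        return ChainState(ordering.order, ordering.heights, params)

    # -- prior -------------------------------------------------------------

    def log_prior(self, state: ChainState) -> float:
        h = state.h
        n = self.n
        lp = 0.0
        for name, spec in self.param_specs.items():
            lp += spec.log_prior(state.params[name])
        if not np.isfinite(lp):
            return -math.inf
        if self.tree_prior == "yule":
            lam = state.params["birthRate"]
            if lam <= 0:
                return -math.inf
            tree_length = float(h.sum() + h.max())
            lp += (n - 1) * math.log(lam) - lam * tree_length
        else:
            N = state.params["popSize"]
            hs = np.sort(h)
            tau = np.diff(np.concatenate(([0.0], hs)))
            k = np.arange(n, 1, -1)
            lp += -(n - 1) * math.log(N) - float(np.sum(k * (k - 1) * tau)) / (2.0 * N)
        return lp

    # -- likelihood with caching -------------------------------------------

    def _refresh_model(self, params: dict) -> None:
        model = self.subst_model(params)
        self._eigen = model.eigen()
        self._freqs = model.freqs
        cat = self.site_model(params).category_rates()
        if self._cat_rates is None or len(cat) != len(self._cat_rates):
            C = len(cat)
            # leaf partials materialised per category for fancy-index gathers
            self._leaf_all = np.broadcast_to(
                self.leaf_partials[:, None], (self.n, C, 4, self.n_patterns)
            ).copy()
        self._cat_rates = cat

    def _child_partial(self, code: int, cand: dict) -> np.ndarray:
        """Child partial as (C, 4, P)."""
        if code < self.n:
            return self._leaf_all[code]
        g = code - self.n
        return cand[g][0] if g in cand else self._c_partials[g]

    def _gather(self, codes: np.ndarray, new_gap: np.ndarray) -> np.ndarray:
        """Batch child partials for an array of child codes, (K, C, 4, P)."""
        K = len(codes)
        C = len(self._cat_rates)
        out = np.empty((K, C, 4, self.n_patterns))
        leaf = codes < self.n
        if leaf.any():
            out[leaf] = self._leaf_all[codes[leaf]]
        if (~leaf).any():
            out[~leaf] = new_gap[codes[~leaf] - self.n]
        return out

    def _full_recompute(self, left, right, h, order):
        """Level-batched pruning over all gap nodes.

        Returns (gap partial array (m, C, 4, P), per-node scale (m, P)).
        """
        n, m = self.n, len(h)
        child_h = np.zeros((m, 2))
        lg = left >= n
        rg = right >= n
        child_h[lg, 0] = h[left[lg] - n]
        child_h[rg, 1] = h[right[rg] - n]
        blen = (h[:, None] - child_h) * self.clock_rate
        Pm = transition_matrices(
            self._eigen, blen[:, :, None] * self._cat_rates[None, None, :]
        )  # (m, 2, C, 4, 4)
        # level = 1 + max(child levels); nodes of equal level batch together
        level = np.zeros(m, dtype=np.int64)
        for g in order:
            lv = 0
            if lg[g]:
                lv = level[left[g] - n] + 1
            if rg[g]:
                lv = max(lv, level[right[g] - n] + 1)
            level[g] = lv
        C = len(self._cat_rates)
        new_gap = np.empty((m, C, 4, self.n_patterns))
        new_scale = np.empty((m, self.n_patterns))
        for lv in range(int(level.max()) + 1):
            idx = np.flatnonzero(level == lv)
            K = len(idx)
            kids = self._gather(np.concatenate((left[idx], right[idx])), new_gap)
            Pk = Pm[idx].transpose(1, 0, 2, 3, 4).reshape(2 * K, C, 4, 4)
            both = np.matmul(Pk, kids)  # (2K, C, 4, P)
            prod = both[:K] * both[K:]
            mx = prod.max(axis=(1, 2))  # (K, P)
            mx = np.where(mx > 0, mx, 1.0)
            new_gap[idx] = prod / mx[:, None, None, :]
            new_scale[idx] = np.log(mx)
        return new_gap, new_scale

    def _node_partial(self, g, left, right, h, cand):
        C = len(self._cat_rates)
        a, b = int(left[g]), int(right[g])
        t = np.empty((2, C))
        ha = 0.0 if a < self.n else h[a - self.n]
        hb = 0.0 if b < self.n else h[b - self.n]
        t[0] = (h[g] - ha) * self.clock_rate * self._cat_rates
        t[1] = (h[g] - hb) * self.clock_rate * self._cat_rates
        Pm = transition_matrices(self._eigen, t)  # (2, C, 4, 4)
        kids = np.stack(
            (self._child_partial(a, cand), self._child_partial(b, cand))
        )  # (2, C, 4, P)
        both = np.matmul(Pm, kids)
        prod = both[0] * both[1]
        mx = prod.max(axis=(0, 1))
        mx = np.where(mx > 0, mx, 1.0)
        return prod / mx, np.log(mx)

    def log_likelihood(self, state: ChainState) -> tuple[float, dict]:
        """Evaluate log likelihood; returns (value, token) for :meth:`commit`."""
        self.n_likelihood_evals += 1
        pi, h = state.pi, state.h
        n, m = self.n, len(h)
        sig = self._lik_signature(state.params)
        left, right, root_gap = _build_structure(pi, h, n)
        if sig != self._model_sig:
            self._refresh_model(state.params)
            self._model_sig = sig
        full = self._c_pi is None or sig != self._c_sig or pi != self._c_pi
        order = np.argsort(h, kind="stable")  # children before parents
        cand: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        full_arrays = None
        if not full:
            dirty = (
                (left != self._c_left)
                | (right != self._c_right)
                | (h != self._c_h)
            )
            if dirty.sum() > m // 2:
                full = True
            else:
                parent = self._parent_buf
                parent.fill(-1)
                for g in range(m):
                    parent[left[g]] = g
                    parent[right[g]] = g
                for g in np.flatnonzero(dirty):
                    p = parent[n + g]
                    while p >= 0 and not dirty[p]:
                        dirty[p] = True
                        p = parent[n + p]
                scale_sum = self._c_scale_sum.copy()
                for g in order:
                    if dirty[g]:
                        g = int(g)
                        cand[g] = self._node_partial(g, left, right, h, cand)
                        scale_sum += cand[g][1] - self._c_scale[g]
        if full:
            new_gap, new_scale = self._full_recompute(left, right, h, order)
            full_arrays = (new_gap, new_scale)
            scale_sum = new_scale.sum(axis=0)
        if full_arrays is not None:
            root_p = full_arrays[0][root_gap]
        else:
            root_p = cand[root_gap][0] if root_gap in cand else self._c_partials[root_gap]
        site_lik = np.mean(
            np.tensordot(self._freqs, root_p, axes=(0, 1)), axis=0
        )  # (P,)
        with np.errstate(divide="ignore"):
            ll = float(self.pattern_weights @ (np.log(site_lik) + scale_sum))
        token = {
            "pi": list(pi),
            "h": h.copy(),
            "left": left,
            "right": right,
            "sig": sig,
            "cand": cand,
            "full": full_arrays,
            "scale_sum": scale_sum,
        }
        return ll, token

    def commit(self, token: dict) -> None:
        if token["full"] is not None:
            self._c_partials, self._c_scale = token["full"]
        else:
            for g, (p, s) in token["cand"].items():
                self._c_partials[g] = p
                self._c_scale[g] = s
        self._c_pi = token["pi"]
        self._c_h = token["h"]
        self._c_left = token["left"]
        self._c_right = token["right"]
        self._c_sig = token["sig"]
        self._c_scale_sum = token["scale_sum"]

    def evaluate(self, state: ChainState) -> tuple[float, dict | None]:
        """Log posterior of a state (prior short-circuits likelihood at -inf)."""
        lp = self.log_prior(state)
        if not np.isfinite(lp):
            return -math.inf, None
        ll, token = self.log_likelihood(state)
        return lp + ll, token


# ---------------------------------------------------------------------------
# Proposals
# ---------------------------------------------------------------------------


def cube_subtree_slide(
    state: ChainState, rng: np.random.Generator, window: float = 0.7
) -> tuple[ChainState, float]:
    """Scale one gap height on the log scale.

    Moves the internal node between two consecutive taxa up or down; when
    the new height crosses other gap heights the decoded topology changes,
    but the result is always inside the cube of the current ordering.
    Hastings log-ratio is ``log s`` for multiplier ``s``.
    """
    new = state.copy()
    i = rng.integers(len(new.h))
    s = math.exp(window * (rng.random() - 0.5))
    new.h[i] *= s
    return new, math.log(s)


def _tree_scale(state: ChainState, rng, window=0.25):
    new = state.copy()
    s = math.exp(window * (rng.random() - 0.5))
    new.h *= s
    return new, len(new.h) * math.log(s)


def cube_narrow_exchange(
    state: ChainState,
    rng: np.random.Generator,
) -> tuple[ChainState, float] | None:
    """Narrow exchange restricted to the cube of the current ordering.

    A nearest-neighbour interchange around a random internal edge with a
    fresh height for the moved node.  Around an edge between gap nodes
    ``p`` (parent) and ``c`` (child), exactly one of the two interchanges
    keeps all subtree blocks contiguous in the ordering: it exchanges the
    roles of the two gaps, the upper node moving to gap ``c`` at the old
    parent height and the moved node re-drawing its height at gap ``p``
    uniformly in its valid range.  Proposals picking the other (cube
    leaving) grandchild are rejected before evaluation (``None``).
    """
    h = state.h
    m = len(h)
    if m < 2:
        return None
    n = m + 1
    left, right, root = _build_structure(state.pi, h, n)
    # parent map over gap nodes
    parent = np.full(m, -1, dtype=np.int64)
    for g in range(m):
        for code in (int(left[g]), int(right[g])):
            if code >= n:
                parent[code - n] = g
    candidates = np.flatnonzero(parent >= 0)
    if candidates.size == 0:
        return None
    c = int(rng.choice(candidates))
    p = int(parent[c])
    if rng.random() < 0.5:
        return None  # the interchange with the non-adjacent grandchild leaves the cube
    if int(left[p]) == n + c:
        s_code = int(right[p])  # sibling block right of c's block
        adj = int(right[c])  # grandchild adjacent to the sibling
    else:
        s_code = int(left[p])
        adj = int(left[c])

    def code_h(code: int) -> float:
        return 0.0 if code < n else float(h[code - n])

    hp = float(h[p])
    lo_new = max(code_h(adj), code_h(s_code))
    lo_old = max(code_h(int(left[c])), code_h(int(right[c])))
    if hp - lo_new <= 0:
        return None
    new = state.copy()
    new.h[c] = hp  # upper node now sits at gap c, keeping the parent height
    new.h[p] = lo_new + rng.random() * (hp - lo_new)  # moved node, fresh height
    log_hr = math.log(hp - lo_new) - math.log(hp - lo_old)
    return new, log_hr


def _pi_refresh(state: ChainState, taxa, rng):
    """Redraw the taxon ordering uniformly among those compatible with the tree.

    The proposal is symmetric (every binary tree with distinct heights has
    exactly 2^(n-1) compatible orderings), so the Hastings ratio is 1.
    Used by unrestricted chains and annealing, where it makes the whole of
    tree space reachable.
    """
    T = state.tree(taxa)
    ordering = random_compatible_ordering(T, rng)
    new = state.copy()
    new.pi = ordering.order
    new.h = ordering.heights
    return new, 0.0


def _param_move(state: ChainState, name: str, spec: ParamSpec, rng, window: float):
    new = state.copy()
    if spec.transform == "stick":
        y = stick_breaking_forward(np.asarray(state.params[name]))
        y2 = y + window * rng.standard_normal(len(y))
        new.params[name] = stick_breaking_inverse(y2)
        return new, _stick_log_jacobian(y2) - _stick_log_jacobian(y)
    s = math.exp(window * (rng.random() - 0.5))
    new.params[name] = state.params[name] * s
    return new, math.log(s)


def _stick_log_jacobian(y: np.ndarray) -> float:
    """log |det dx/dy| of the stick-breaking inverse at y."""
    K = len(y) + 1
    remaining = 1.0
    out = 0.0
    for c in range(K - 1):
        z = 1.0 / (1.0 + math.exp(-(y[c] - math.log(K - c - 1))))
        out += math.log(z) + math.log(1.0 - z) + math.log(remaining)
        remaining *= 1.0 - z
    return out


class _OperatorSet:
    """Weighted proposal mixture with adaptive window tuning (target 0.234).

    Tree moves get 60% of proposals; cheap local moves (gap slide, narrow
    exchange) carry most of that weight, the whole-tree scaler (which
    invalidates every cached partial) less.  Parameter moves share the
    remaining 40%.
    """

    def __init__(self, model: PhyloPosterior, restrict: bool, rng: np.random.Generator):
        self.model = model
        self.rng = rng
        tree_ops: list[tuple[str, float]] = [
            ("slide", 2.5),
            ("narrow", 2.0),
            ("scale", 1.0),
        ]
        if not restrict:
            tree_ops.append(("pi", 1.0))
        tw = sum(w for _, w in tree_ops)
        self.ops: list[str] = [o for o, _ in tree_ops]
        weights = [0.6 * w / tw for _, w in tree_ops]
        pnames = list(model.param_specs)
        for name in pnames:
            self.ops.append(f"param:{name}")
            weights.append(0.4 / len(pnames))
        self.weights = np.array(weights) / np.sum(weights)
        self._cum = np.cumsum(self.weights)
        self.windows = {o: 0.7 for o in self.ops}
        self.windows["scale"] = 0.25
        for name, spec in model.param_specs.items():
            if spec.transform == "stick":
                self.windows[f"param:{name}"] = 0.2
        self.accepted = {o: 0 for o in self.ops}
        self.tried = {o: 0 for o in self.ops}
        self._batch_acc = {o: 0 for o in self.ops}
        self._batch_try = {o: 0 for o in self.ops}

    def propose(self, state: ChainState):
        u = self.rng.random()
        op = self.ops[int(np.searchsorted(self._cum, u))]
        w = self.windows[op]
        if op == "slide":
            out = cube_subtree_slide(state, self.rng, window=w)
        elif op == "scale":
            out = _tree_scale(state, self.rng, window=w)
        elif op == "narrow":
            out = cube_narrow_exchange(state, self.rng)
        elif op == "pi":
            out = _pi_refresh(state, self.model.taxa, self.rng)
        else:
            name = op.split(":", 1)[1]
            out = _param_move(state, name, self.model.param_specs[name], self.rng, w)
        return op, out

    def record(self, op: str, accepted: bool, tune: bool) -> None:
        self.tried[op] += 1
        self.accepted[op] += accepted
        if not tune or op in ("narrow", "pi"):
            return
        self._batch_try[op] += 1
        self._batch_acc[op] += accepted
        if self._batch_try[op] >= 50:
            rate = self._batch_acc[op] / self._batch_try[op]
            self.windows[op] *= math.exp(2.0 * (rate - 0.234))
            self.windows[op] = min(max(self.windows[op], 1e-3), 10.0)
            self._batch_try[op] = self._batch_acc[op] = 0

    def acceptance_rates(self) -> dict[str, float]:
        return {
            o: (self.accepted[o] / self.tried[o]) if self.tried[o] else float("nan")
            for o in self.ops
        }


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


@dataclass
class AnnealingSchedule:
    """Geometric cooling with periodic resets to the start temperature."""

    start: float = 0.1
    end: float = 0.01
    repeats: int = 25
    steps_per_segment: int = 200

    def __post_init__(self):
        if not (self.start > self.end > 0):
            raise ValueError("need start > end > 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def temperatures(self):
        decay = (self.end / self.start) ** (1.0 / max(self.steps_per_segment - 1, 1))
        for _ in range(self.repeats):
            t = self.start
            for _ in range(self.steps_per_segment):
                yield t
                t *= decay


def simulated_annealing(
    init_state,
    log_target: Callable,
    propose: Callable,
    schedule: AnnealingSchedule,
    rng: np.random.Generator,
):
    """Generic simulated annealing; returns the best state ever visited.

    Accepts uphill moves always; downhill moves with probability
    ``exp(delta / T)``.  ``propose(state, rng)`` may return ``None`` to
    signal an immediately rejected proposal.
    """
    state = init_state
    lp = log_target(state)
    if not np.isfinite(lp):
        raise ValueError("log target is -inf at the initial state")
    best, best_lp = state, lp
    for T in schedule.temperatures():
        prop = propose(state, rng)
        if prop is None:
            continue
        lp2 = log_target(prop)
        if lp2 >= lp or rng.random() < math.exp((lp2 - lp) / T):
            state, lp = prop, lp2
            if lp > best_lp:
                best, best_lp = state, lp
    return best, best_lp


def find_map_state(
    model: PhyloPosterior,
    init: ChainState,
    schedule: AnnealingSchedule | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ChainState, float]:
    """Approximate MAP state by simulated annealing over full tree space.

    The proposal mixture includes ordering refreshes, so the search is not
    confined to the initial cube.
    """
    rng = rng if rng is not None else np.random.default_rng()
    schedule = schedule or AnnealingSchedule()
    ops = _OperatorSet(model, restrict=False, rng=rng)
    lp0, tok = model.evaluate(init)
    if not np.isfinite(lp0):
        raise ValueError("posterior is -inf at the initial state")
    model.commit(tok)
    state, lp = init, lp0
    best, best_lp = state, lp
    for T in schedule.temperatures():
        op, out = ops.propose(state)
        if out is None:
            ops.record(op, False, tune=False)
            continue
        prop, _ = out
        lp2, tok = model.evaluate(prop)
        accept = np.isfinite(lp2) and (
            lp2 >= lp or rng.random() < math.exp((lp2 - lp) / T)
        )
        if accept:
            model.commit(tok)
            state, lp = prop, lp2
            if lp > best_lp:
                best, best_lp = state.copy(), lp
        ops.record(op, bool(accept), tune=False)
    return best, best_lp


# ---------------------------------------------------------------------------
# Cube-restricted MCMC
# ---------------------------------------------------------------------------


def run_cube_mcmc(
    model: PhyloPosterior,
    init: ChainState,
    chain_length: int,
    rng: np.random.Generator,
    *,
    restrict: bool = True,
    burnin_fraction: float = 0.1,
    n_samples: int = 2000,
    tune: bool = True,
) -> dict:
    """Metropolis-Hastings over cube states (optionally unrestricted).

    With ``restrict=True`` the taxon ordering is fixed and every sampled
    tree lies in its cube; with ``restrict=False`` an ordering-refresh move
    is mixed in, which makes the chain target the unrestricted posterior.
    Returns thinned post-burn-in samples of gap heights, parameters and the
    log-posterior trace.
    """
    ops = _OperatorSet(model, restrict=restrict, rng=rng)
    state = init.copy()
    lp, tok = model.evaluate(state)
    if not np.isfinite(lp):
        raise ValueError("posterior is -inf at the initial state")
    model.commit(tok)
    burnin = int(burnin_fraction * chain_length)
    thin = max(1, (chain_length - burnin) // n_samples)
    pi0 = list(state.pi)
    samples_h, samples_params, trace, sampled_pi = [], [], [], []
    for step in range(chain_length):
        op, out = ops.propose(state)
        if out is None:
            ops.record(op, False, tune and step < burnin)
        else:
            prop, log_hr = out
            lp2, tok = model.evaluate(prop)
            accept = np.isfinite(lp2) and (
                math.log(rng.random() + 1e-300) < lp2 - lp + log_hr
            )
            if accept:
                model.commit(tok)
                state, lp = prop, lp2
            ops.record(op, bool(accept), tune and step < burnin)
        if step >= burnin and (step - burnin) % thin == 0:
            if restrict and state.pi != pi0:
                raise AssertionError("cube-restricted chain left its cube")
            samples_h.append(state.h.copy())
            samples_params.append({
                k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in state.params.items()
            })
            sampled_pi.append(list(state.pi))
            trace.append(lp)
    return {
        "pi": pi0,
        "sampled_pi": sampled_pi,
        "h": np.array(samples_h),
        "params": samples_params,
        "log_posterior": np.array(trace),
        "acceptance": ops.acceptance_rates(),
        "final_state": state,
    }


def mcmc_trees(result: dict, taxa: Sequence[str]) -> list[TimeTree]:
    """Decode the thinned MCMC samples into trees."""
    return [
        cube_decode(CubeOrdering(pi, h, taxa=list(taxa)))
        for pi, h in zip(result["sampled_pi"], result["h"])
    ]


# ---------------------------------------------------------------------------
# Variational posterior and the full cube-VB fit
# ---------------------------------------------------------------------------


@dataclass
class VariationalPosterior:
    """Joint normal over log gap heights and transformed model parameters."""

    taxa: list[str]
    pi: list[int]
    dim_names: list[str]
    transforms: list[str]  # per dim: "log" | "none" | "stick"
    mu: np.ndarray
    sigma: np.ndarray
    param_layout: list[tuple[str, str, int]] = field(default_factory=list)
    # (param name, transform, n dims); tree gap dims come first

    @property
    def n_gaps(self) -> int:
        return len(self.taxa) - 1

    @property
    def k(self) -> int:
        return len(self.mu)

    def _chol(self) -> np.ndarray:
        from .matrix_gaussian import psd_sqrt

        return psd_sqrt(self.sigma)

    def draw(self, m: int, rng: np.random.Generator) -> np.ndarray:
        """Raw draws in the transformed space, shape (m, k)."""
        Z = rng.standard_normal((m, self.k))
        return self.mu + Z @ self._chol().T

    def draw_params(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Back-transform parameter dimensions of raw draws."""
        out: dict[str, np.ndarray] = {}
        at = self.n_gaps
        for name, transform, nd in self.param_layout:
            block = X[:, at:at + nd]
            if transform == "log":
                out[name] = np.exp(block[:, 0])
            elif transform == "none":
                out[name] = block[:, 0]
            else:  # stick
                out[name] = np.array([stick_breaking_inverse(y) for y in block])
            at += nd
        return out

    def sample_trees(self, m: int, rng: np.random.Generator) -> list[TimeTree]:
        X = self.draw(m, rng)
        return [
            cube_decode(CubeOrdering(self.pi, np.exp(x[: self.n_gaps]), taxa=self.taxa))
            for x in X
        ]

    def tree_gaussian(self) -> MatrixGaussian:
        """The tree block as a MatrixGaussian on the cube's matrix entries."""
        g = self.n_gaps
        pairs = [(self.pi[i], self.pi[i + 1]) for i in range(g)]
        return MatrixGaussian(
            n=len(self.taxa),
            pairs=pairs,
            mu=self.mu[:g],
            sigma=self.sigma[:g, :g],
            taxa=self.taxa,
        )

    def summary_tree(self) -> TimeTree:
        """Mode tree: decode exp(mu) of the gap dimensions (z = 0)."""
        return cube_decode(
            CubeOrdering(self.pi, np.exp(self.mu[: self.n_gaps]), taxa=self.taxa)
        )

    def derived_samples(self, m: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Monte-Carlo marginals of scalar quantities of interest.

        Returns tree height (the largest gap), tree length (sum of gaps plus
        the height) and each model parameter, all on their natural scales.
        """
        X = self.draw(m, rng)
        gaps = np.exp(X[:, : self.n_gaps])
        out = {
            "tree_height": gaps.max(axis=1),
            "tree_length": gaps.sum(axis=1) + gaps.max(axis=1),
        }
        for name, v in self.draw_params(X).items():
            if v.ndim == 1:
                out[name] = v
            else:
                for j in range(v.shape[1]):
                    out[f"{name}.{j + 1}"] = v[:, j]
        return out

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "taxa": self.taxa,
                "pi": self.pi,
                "dim_names": self.dim_names,
                "transforms": self.transforms,
                "mu": self.mu.tolist(),
                "sigma": self.sigma.tolist(),
                "param_layout": [list(t) for t in self.param_layout],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "VariationalPosterior":
        import json

        d = json.loads(s)
        return cls(
            taxa=d["taxa"],
            pi=d["pi"],
            dim_names=d["dim_names"],
            transforms=d["transforms"],
            mu=np.array(d["mu"]),
            sigma=np.array(d["sigma"]),
            param_layout=[tuple(t) for t in d["param_layout"]],
        )


def transform_samples(model: PhyloPosterior, result: dict) -> tuple[np.ndarray, list, list, list]:
    """Stack MCMC samples in transformed space: log gaps then parameters."""
    H = np.log(result["h"])
    cols = [H]
    names = [f"h{i}" for i in range(H.shape[1])]
    transforms = ["log"] * H.shape[1]
    layout: list[tuple[str, str, int]] = []
    for name, spec in model.param_specs.items():
        vals = [p[name] for p in result["params"]]
        if spec.transform == "stick":
            Y = np.array([stick_breaking_forward(np.asarray(v)) for v in vals])
            cols.append(Y)
            names += [f"{name}.y{j}" for j in range(Y.shape[1])]
            transforms += ["stick"] * Y.shape[1]
            layout.append((name, "stick", Y.shape[1]))
        elif spec.transform == "log":
            cols.append(np.log(np.asarray(vals))[:, None])
            names.append(name)
            transforms.append("log")
            layout.append((name, "log", 1))
        else:
            cols.append(np.asarray(vals)[:, None])
            names.append(name)
            transforms.append("none")
            layout.append((name, "none", 1))
    return np.hstack(cols), names, transforms, layout


def fit_variational(
    alignment: Alignment,
    *,
    tree_prior: str = "yule",
    subst: str = "hky",
    gamma_categories: int = 0,
    clock_rate: float = 1.0,
    params: list[ParamSpec] | None = None,
    multiplier: int = 1000,
    schedule: AnnealingSchedule | None = None,
    rng: np.random.Generator | None = None,
    return_mcmc: bool = False,
) -> VariationalPosterior | tuple[VariationalPosterior, dict]:
    """Run the full cube-VB pipeline on an alignment.

    UPGMA initialisation, simulated-annealing MAP search, a random
    tree-compatible taxon ordering, cube-restricted MCMC of length
    ``multiplier x (number of dimensions)``, and moment estimation of
    (mu, Sigma) from the transformed samples.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    model = PhyloPosterior(
        alignment,
        tree_prior=tree_prior,
        subst=subst,
        gamma_categories=gamma_categories,
        clock_rate=clock_rate,
        params=params,
    )
    # step 0: UPGMA initial tree
    T0 = upgma_tree(jc_distance_matrix(alignment), alignment.taxa)
    init = model.init_state(T0, rng)
    # step 1: MAP by simulated annealing (full tree space)
    schedule = schedule or AnnealingSchedule()
    map_state, _ = find_map_state(model, init, schedule, rng)
    # step 2: random cube ordering compatible with the MAP tree
    ordering = random_compatible_ordering(map_state.tree(alignment.taxa), rng)
    start = ChainState(ordering.order, ordering.heights, map_state.params)
    # step 3: cube-restricted MCMC
    n_dims = (alignment.n_taxa - 1) + sum(
        (len(np.asarray(s.init)) - 1 if s.transform == "stick" else 1)
        for s in model.param_specs.values()
    )
    chain_length = multiplier * n_dims
    result = run_cube_mcmc(model, start, chain_length, rng, restrict=True)
    # step 4: moment-match the transformed samples
    X, names, transforms, layout = transform_samples(model, result)
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False)
    post = VariationalPosterior(
        taxa=list(alignment.taxa),
        pi=list(ordering.order),
        dim_names=names,
        transforms=transforms,
        mu=mu,
        sigma=np.atleast_2d(sigma),
        param_layout=layout,
    )
    return (post, result) if return_mcmc else post
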