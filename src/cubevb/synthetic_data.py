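"""Simulators for trees, model parameters, and sequence alignments.

These generators define the study conditions used throughout the test
suite: Yule or constant-size coalescent trees conditioned on the number of
tips, HKY or GTR(+gamma) strict-clock sequence evolution, and hyperpriors
matching the two canonical simulation designs (Yule/HKY with birth rate ~
Normal(6, 0.1) and kappa ~ LogNormal(1, 1.25); coalescent/GTR+gamma with
population size ~ LogNormal(0.1, 0.1) on the log scale).

``run_wcss`` performs a well-calibrated simulation study: truth is drawn
from the priors, data simulated, the variational posterior fitted, and the
coverage of 95% HPD intervals recorded.  With R replicates and correct
calibration the coverage count is Binomial(R, 0.95); for R = 100 the
central band is 91-99.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phylo_models import Alignment, SiteModel, SubstModel, transition_matrices
from .treespace import TimeTree

__all__ = [
    "simulate_yule",
    "simulate_coalescent",
    "simulate_alignment",
    "SimulationDesign",
    "yule_hky_design",
    "coalescent_gtr_design",
    "run_wcss",
    "WcssReport",
]


# ---------------------------------------------------------------------------
# Tree simulators
# ---------------------------------------------------------------------------


def _merge_tree(
    taxa: list[str], rates: np.ndarray, rng: np.random.Generator
) -> TimeTree:
    """Random-pair merging with exponential inter-event times.

    ``rates[j]`` is the exponential rate of the j-th inter-event interval
    counting from the present (first interval has all n lineages extant).
    Both the Yule (conditioned on n) and the Kingman coalescent are of this
    form and share the uniform ranked-history topology distribution.
    """
    n = len(taxa)
    t = 0.0
    active = list(range(n))
    merges = []
    nxt = n
    for j in range(n - 1):
        t += rng.exponential(1.0 / rates[j])
        i1, i2 = rng.choice(len(active), size=2, replace=False)
        a, b = active[i1], active[i2]
        active = [x for x in active if x not in (a, b)] + [nxt]
        merges.append((a, b, t))
        nxt += 1
    return TimeTree.from_merges(taxa, merges)


def simulate_yule(
    n: int, birth_rate: float, rng: np.random.Generator, taxa: list[str] | None = None
) -> TimeTree:
    """Yule (pure-birth) tree conditioned on ``n`` tips.

    Going back from the present, the interval during which k lineages are
    extant is Exponential(k * birth_rate); the expected root height is
    ``(H_n - 1) / birth_rate`` with ``H_n`` the n-th harmonic number.
    Topologies are uniform over ranked labelled histories.
    """
    if n < 2 or birth_rate <= 0:
        raise ValueError("need n >= 2 and birth_rate > 0")
    taxa = taxa or [f"t{i}" for i in range(n)]
    rates = birth_rate * np.arange(n, 1, -1)
    return _merge_tree(taxa, rates, rng)


def simulate_coalescent(
    n: int, pop_size: float, rng: np.random.Generator, taxa: list[str] | None = None
) -> TimeTree:
    """Kingman coalescent with constant population size.

    The waiting time while k lineages remain is
    Exponential(choose(k, 2) / pop_size); the expected root height is
    ``2 N (1 - 1/n)``.
    """
    if n < 2 or pop_size <= 0:
        raise ValueError("need n >= 2 and pop_size > 0")
    taxa = taxa or [f"t{i}" for i in range(n)]
    k = np.arange(n, 1, -1)
    rates = k * (k - 1) / 2.0 / pop_size
    return _merge_tree(taxa, rates, rng)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------


def simulate_alignment(
    tree: TimeTree,
    model: SubstModel,
    site: SiteModel | None = None,
    clock_rate: float = 1.0,
    length: int = 250,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Evolve sequences down a time tree.

    The root state is drawn from the stationary frequencies; each branch
    applies the transition matrix for its length times the clock rate (and
    the site's gamma rate multiplier when heterogeneity is enabled).
    """
    rng = rng if rng is not None else np.random.default_rng()
    site = site or SiteModel(shape=None)
    cat_rates = site.category_rates()
    cats = rng.integers(len(cat_rates), size=length)
    eig = model.eigen()
    states = np.empty((tree.n_nodes, length), dtype=np.int8)
    root = tree.root
    states[root] = rng.choice(4, size=length, p=model.freqs)
    # preorder: parents before children
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        if not tree.is_leaf(v):
            stack.append(int(tree.left[v]))
            stack.append(int(tree.right[v]))
    u = rng.random((tree.n_nodes, length))
    for v in order:
        if v == root:
            continue
        p = int(tree.parent[v])
        t = (tree.height[p] - tree.height[v]) * clock_rate
        Pm = transition_matrices(eig, t * cat_rates)  # (C, 4, 4)
        probs = Pm[cats, states[p], :]  # (L, 4)
        states[v] = (u[v][:, None] > probs.cumsum(axis=1)).sum(axis=1)
    alpha = "ACGT"
    seqs = ["".join(alpha[s] for s in states[i]) for i in range(tree.n_leaves)]
    return Alignment(list(tree.taxa), seqs)


# ---------------------------------------------------------------------------
# Simulation designs
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """One well-calibrated-simulation-study design.

    ``draw_truth(rng)`` samples hyperparameters from their priors;
    ``simulate(truth, rng)`` produces (tree, alignment).  The lognormal
    hyperpriors are parameterised on the log scale (meanlog/sdlog) unless
    ``real_space_means`` is set, in which case the stated means are means
    of the distribution itself.
    """

    name: str
    n_taxa: int = 50
    length: int = 100
    tree_prior: str = "yule"
    subst: str = "hky"
    gamma_categories: int = 0
    clock_rate: float = 1.0
    real_space_means: bool = False

    def draw_truth(self, rng: np.random.Generator) -> dict:
        truth: dict[str, float | np.ndarray] = {}
        if self.tree_prior == "yule":
            lam = -1.0
            while lam <= 0:
                lam = rng.normal(6.0, 0.1)
            truth["birthRate"] = lam
        else:
            meanlog = math.log(0.1) - 0.005 if self.real_space_means else 0.1
            truth["popSize"] = float(np.exp(rng.normal(meanlog, 0.1)))
        if self.subst == "hky":
            meanlog = -1.25**2 / 2 if self.real_space_means else 1.0
            truth["kappa"] = float(np.exp(rng.normal(meanlog, 1.25)))
        else:
            truth["rateAG"] = float(np.exp(rng.normal(math.log(1.0) - 0.5, 1.0)))
            for r in ("rateAC", "rateAT", "rateCG", "rateGT"):
                truth[r] = float(np.exp(rng.normal(math.log(0.5) - 0.5, 1.0)))
            truth["freqs"] = rng.dirichlet([4.0] * 4)
            truth["gammaShape"] = float(rng.exponential(1.0))
        return truth

    def subst_model(self, truth: dict) -> SubstModel:
        from .phylo_models import gtr_model, hky_model

        if self.subst == "hky":
            return hky_model(truth["kappa"])
        rates = {
            "AC": truth["rateAC"],
            "AG": truth["rateAG"],
            "AT": truth["rateAT"],
            "CG": truth["rateCG"],
            "CT": 1.0,
            "GT": truth["rateGT"],
        }
        return gtr_model(rates, truth["freqs"])

    def simulate(self, truth: dict, rng: np.random.Generator) -> tuple[TimeTree, Alignment]:
        if self.tree_prior == "yule":
            tree = simulate_yule(self.n_taxa, truth["birthRate"], rng)
        else:
            tree = simulate_coalescent(self.n_taxa, truth["popSize"], rng)
        site = (
            SiteModel(shape=truth["gammaShape"], n_categories=self.gamma_categories)
            if self.gamma_categories
            else SiteModel(shape=None)
        )
        aln = simulate_alignment(
            tree, self.subst_model(truth), site, self.clock_rate, self.length, rng
        )
        return tree, aln


def yule_hky_design(length: int = 100, n_taxa: int = 50) -> SimulationDesign:
    """50-taxon Yule/HKY strict-clock design (birth rate ~ Normal(6, 0.1))."""
    return SimulationDesign("yule_hky", n_taxa=n_taxa, length=length)


def coalescent_gtr_design(length: int = 100, n_taxa: int = 50) -> SimulationDesign:
    """Coalescent/GTR+gamma design (population size ~ LogNormal(0.1, 0.1))."""
    return SimulationDesign(
        "coal_gtr",
        n_taxa=n_taxa,
        length=length,
        tree_prior="coalescent",
        subst="gtr",
        gamma_categories=4,
    )


# ---------------------------------------------------------------------------
# Well-calibrated simulation study
# ---------------------------------------------------------------------------


@dataclass
class WcssReport:
    """Coverage counts of 95% HPD intervals over replicates."""

    design: str
    replicates: int
    coverage: dict[str, int] = field(default_factory=dict)
    attempted: dict[str, int] = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)
    entropies: list[float] = field(default_factory=list)
    details: list[dict] = field(default_factory=list)

    def passes(self, lo_frac: float = 0.91, hi_frac: float = 0.99) -> dict[str, bool]:
        """Whether each parameter's coverage lies in the binomial pass band."""
        out = {}
        for name, c in self.coverage.items():
            n = self.attempted[name]
            out[name] = math.floor(lo_frac * n) <= c <= math.ceil(hi_frac * n)
        return out


def run_wcss(
    design: SimulationDesign,
    replicates: int,
    rng: np.random.Generator,
    *,
    multiplier: int = 1000,
    annealing_steps_per_segment: int = 200,
    posterior_draws: int = 2000,
    level: float = 0.95,
    compute_entropy: bool = False,
    parameters: tuple[str, ...] = ("tree_height", "tree_length"),
) -> WcssReport:
    """Draw truth from the priors, simulate data, fit cube-VB, check coverage.

    Per replicate, each monitored quantity is checked for membership of its
    95% HPD interval under the fitted variational posterior (HPDs computed
    from ``posterior_draws`` Monte-Carlo samples).  Scalar model parameters
    named in ``parameters`` are monitored alongside tree height and length.
    Individual replicate failures are logged, not fatal.
    """
    from .inference import AnnealingSchedule, fit_variational, mcmc_trees
    from .matrix_gaussian import TreeSample
    from .treeset_stats import ccd_entropy, hpd_interval

    report = WcssReport(design=design.name, replicates=replicates)
    schedule = AnnealingSchedule(steps_per_segment=annealing_steps_per_segment)
    for rep in range(replicates):
        sub = np.random.default_rng(rng.integers(2**31 - 1))
        truth = design.draw_truth(sub)
        tree, aln = design.simulate(truth, sub)
        truth["tree_height"] = tree.root_height
        truth["tree_length"] = tree.total_branch_length()
        try:
            post, mcmc = fit_variational(
                aln,
                tree_prior=design.tree_prior,
                subst=design.subst,
                gamma_categories=design.gamma_categories,
                clock_rate=design.clock_rate,
                multiplier=multiplier,
                schedule=schedule,
                rng=sub,
                return_mcmc=True,
            )
        except Exception as exc:  # replicate failures are reported, not fatal
            report.failures.append(f"replicate {rep}: {exc!r}")
            continue
        draws = post.derived_samples(posterior_draws, sub)
        detail = {"replicate": rep}
        for name in parameters:
            if name not in draws:
                continue
            true_val = truth.get(name)
            if true_val is None:
                continue
            lo, hi = hpd_interval(draws[name], level)
            inside = bool(lo <= true_val <= hi)
            report.attempted[name] = report.attempted.get(name, 0) + 1
            report.coverage[name] = report.coverage.get(name, 0) + int(inside)
            detail[name] = {"true": float(true_val), "hpd": (lo, hi), "inside": inside}
        if compute_entropy:
            trees = mcmc_trees(mcmc, aln.taxa)
            report.entropies.append(ccd_entropy(TreeSample(trees)))
        report.details.append(detail)
    return report
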