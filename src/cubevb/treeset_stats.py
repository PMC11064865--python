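"""Diagnostics for tree distributions.

Includes the conditional-clade-distribution (CCD) entropy of a tree sample,
clade-set comparison between two samples (supports, mean heights, HPD
intervals), highest-posterior-density intervals, and summary-tree quality
metrics (sum and log product of clade support), together with the maximum
clade credibility (MCC) tree as a baseline summariser.

Clades are represented as bitmasks over leaf indices; taxon sets of
compared samples must match exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix_gaussian import TreeSample
from .treespace import TimeTree

__all__ = [
    "ccd_entropy",
    "CladeTable",
    "compare_clade_sets",
    "hpd_interval",
    "summary_metrics",
    "mcc_tree",
    "cube_topology_coverage",
]


# ---------------------------------------------------------------------------
# Conditional clade distribution entropy
# ---------------------------------------------------------------------------


def _ccd_counts(sample: TreeSample):
    """Split counts: parent clade -> {(left, right): weight} with left < right."""
    splits: dict[int, dict[tuple[int, int], float]] = {}
    w = sample.effective_weights()
    for tree, wt in zip(sample.trees, w):
        if wt == 0.0:
            continue
        clades = tree.clades()
        masks = {v: m for v, m in clades.items()}
        for v, m in clades.items():
            l, r = int(tree.left[v]), int(tree.right[v])
            ml = masks[l] if l in masks else (1 << l)
            mr = masks[r] if r in masks else (1 << r)
            key = (min(ml, mr), max(ml, mr))
            splits.setdefault(m, {}).setdefault(key, 0.0)
            splits[m][key] += wt
    return splits


def ccd_entropy(sample: TreeSample) -> float:
    """Entropy (nats) of the tree distribution induced by the CCD.

    The conditional clade distribution factorises a tree distribution into
    independent split choices per clade; its entropy is

    ``H(clade) = H(split | clade) + sum_split p(split) (H(left) + H(right))``

    computed recursively from the root clade.  A single-topology sample has
    entropy 0.
    """
    splits = _ccd_counts(sample)
    n = sample.trees[0].n_leaves
    root = (1 << n) - 1
    memo: dict[int, float] = {}

    def H(clade: int) -> float:
        if clade not in splits:  # leaf or cherry resolved deterministically below
            return 0.0
        if clade in memo:
            return memo[clade]
        d = splits[clade]
        tot = sum(d.values())
        out = 0.0
        for (l, r), c in d.items():
            p = c / tot
            out += p * (-math.log(p) + H(l) + H(r))
        memo[clade] = out
        return out

    return H(root)


# ---------------------------------------------------------------------------
# HPD intervals
# ---------------------------------------------------------------------------


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``level`` of the samples.

    Chen-Shao estimator on sorted samples (the convention used by Tracer):
    slide a window of ``ceil(level * n)`` points and keep the narrowest.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = int(math.ceil(level * n))
    k = min(k, n)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


# ---------------------------------------------------------------------------
# Clade tables and comparison
# ---------------------------------------------------------------------------


@dataclass
class CladeTable:
    """Per-clade support and height summaries for one tree sample."""

    taxa: list[str]
    support: dict[int, float] = field(default_factory=dict)
    mean_height: dict[int, float] = field(default_factory=dict)
    hpd: dict[int, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_sample(cls, sample: TreeSample, level: float = 0.95) -> "CladeTable":
        w = sample.effective_weights()
        support: dict[int, float] = {}
        heights: dict[int, list[float]] = {}
        hw: dict[int, list[float]] = {}
        for tree, wt in zip(sample.trees, w):
            if wt == 0.0:
                continue
            for v, m in tree.clades().items():
                support[m] = support.get(m, 0.0) + wt
                heights.setdefault(m, []).append(float(tree.height[v]))
                hw.setdefault(m, []).append(wt)
        table = cls(taxa=sample.taxa)
        table.support = support
        for m, hs in heights.items():
            ws = np.asarray(hw[m])
            table.mean_height[m] = float(np.average(hs, weights=ws))
            if len(hs) >= 2:
                table.hpd[m] = hpd_interval(hs, level)
            else:
                table.hpd[m] = (hs[0], hs[0])
        return table

    def clade_names(self, mask: int) -> str:
        return "{" + ",".join(
            t for i, t in enumerate(self.taxa) if mask >> i & 1
        ) + "}"


@dataclass
class CladeComparison:
    """Result of comparing the clade sets of two tree samples."""

    table_a: CladeTable
    table_b: CladeTable
    max_support_diff: float
    mean_support_diff: float  # over clades with > min_support in either set
    mean_height_diff_pct: float  # over shared clades, relative to set A scale

    def rows(self):
        """Per-clade (mask, support_a, support_b, height_a, height_b)."""
        masks = sorted(set(self.table_a.support) | set(self.table_b.support))
        for m in masks:
            yield (
                m,
                self.table_a.support.get(m, 0.0),
                self.table_b.support.get(m, 0.0),
                self.table_a.mean_height.get(m, float("nan")),
                self.table_b.mean_height.get(m, float("nan")),
            )


def compare_clade_sets(
    a: TreeSample,
    b: TreeSample,
    min_support: float = 0.01,
    level: float = 0.95,
) -> CladeComparison:
    """Compare two tree samples clade by clade.

    Reports per-clade supports, mean heights and HPD intervals in each set,
    the maximum support difference over the union of clades, the mean
    absolute support difference over clades exceeding ``min_support`` in
    either set, and the mean relative height difference over shared clades.
    """
    if a.taxa != b.taxa:
        raise ValueError("tree samples must share the identical taxon set")
    ta = CladeTable.from_sample(a, level)
    tb = CladeTable.from_sample(b, level)
    masks = set(ta.support) | set(tb.support)
    diffs, sel_diffs, hdiffs = [], [], []
    for m in masks:
        sa, sb = ta.support.get(m, 0.0), tb.support.get(m, 0.0)
        diffs.append(abs(sa - sb))
        if max(sa, sb) > min_support:
            sel_diffs.append(abs(sa - sb))
        if m in ta.mean_height and m in tb.mean_height:
            ha, hb = ta.mean_height[m], tb.mean_height[m]
            if ha > 0:
                hdiffs.append(abs(ha - hb) / ha)
    return CladeComparison(
        table_a=ta,
        table_b=tb,
        max_support_diff=max(diffs) if diffs else 0.0,
        mean_support_diff=float(np.mean(sel_diffs)) if sel_diffs else 0.0,
        mean_height_diff_pct=100.0 * float(np.mean(hdiffs)) if hdiffs else 0.0,
    )


# ---------------------------------------------------------------------------
# Summary-tree metrics and MCC tree
# ---------------------------------------------------------------------------


def summary_metrics(
    tree: TimeTree,
    sample: TreeSample,
    skip_zero_support: bool = True,
) -> dict:
    """Sum and log product of clade support of a candidate summary tree.

    For every internal clade of ``tree``, its posterior support in
    ``sample`` is looked up.  The sum of supports is proportional to the
    number of internal nodes minus the mean Robinson-Foulds distance to the
    sample.  Zero-support clades make the log product -inf; with
    ``skip_zero_support`` they are excluded and counted separately.
    """
    if tree.taxa != sample.taxa:
        raise ValueError("summary tree taxa must match the sample")
    table = CladeTable.from_sample(sample)
    supports = [table.support.get(m, 0.0) for m in tree.clades().values()]
    total = float(sum(supports))
    zeros = sum(1 for s in supports if s == 0.0)
    pos = [s for s in supports if s > 0.0]
    if zeros and not skip_zero_support:
        log_prod = float("-inf")
    else:
        log_prod = float(sum(math.log(s) for s in pos))
    return {
        "sum_clade_support": total,
        "log_product_clade_support": log_prod,
        "n_zero_support_clades": zeros,
        "n_internal_clades": len(supports),
    }


def mcc_tree(sample: TreeSample) -> TimeTree:
    """Maximum clade credibility tree with mean-height annotation.

    The member tree maximising the log product of its clades' posterior
    supports; its node heights are replaced by the mean MRCA height of each
    clade across the trees that contain it (the TreeAnnotator convention,
    with arithmetic means of raw heights).
    """
    table = CladeTable.from_sample(sample)
    w = sample.effective_weights()
    best, best_score = None, -np.inf
    for tree, wt in zip(sample.trees, w):
        if wt == 0.0:
            continue
        score = sum(math.log(table.support[m]) for m in tree.clades().values())
        if score > best_score:
            best, best_score = tree, score
    out = best.copy()
    for v, m in out.clades().items():
        out.height[v] = table.mean_height[m]
    # mean heights can violate parent > child ordering in rare cases; repair
    for v in out.postorder_internal():
        lo = max(out.height[int(out.left[v])], out.height[int(out.right[v])])
        if out.height[v] <= lo:
            out.height[v] = lo + 1e-12
    return out


# ---------------------------------------------------------------------------
# Cube coverage of a tree sample
# ---------------------------------------------------------------------------


def cube_topology_coverage(sample: TreeSample, order: list[int]) -> float:
    """Posterior mass of trees representable in the cube of an ordering.

    The fraction (weighted) of trees in the sample whose topology is
    compatible with the given taxon ordering.  For the classic three-taxon
    illustration with supports 0.6/0.3/0.1 and alphabetical ordering, the
    cube captures 0.9.
    """
    from .treespace import is_cube_compatible

    w = sample.effective_weights()
    return float(
        sum(wt for tree, wt in zip(sample.trees, w) if is_cube_compatible(tree, order))
    )
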