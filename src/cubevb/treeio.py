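"""File formats: Newick/NEXUS trees, FASTA/NEXUS alignments, trace logs.

Trees are exchanged through dendropy; heights are reconstructed from branch
lengths assuming ultrametricity, with the deepest root-to-tip path defining
the height-zero reference.  Taxon order is taken from the input file and
preserved throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .matrix_gaussian import TreeSample
from .phylo_models import Alignment
from .treespace import TimeTree

__all__ = [
    "tree_from_dendropy",
    "tree_to_dendropy",
    "read_trees",
    "write_trees",
    "parse_newick",
    "read_alignment",
    "TraceWriter",
]


def tree_from_dendropy(dtree: dendropy.Tree, taxa: Sequence[str] | None = None) -> TimeTree:
    """Convert a dendropy tree to a TimeTree.

    Branch lengths are interpreted in time units; node heights are
    ``max_root_to_tip_depth - depth``.  The tree must be binary and
    (numerically) ultrametric.
    """
    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else lf.label for lf in leaves]
    if taxa is None:
        taxa = labels
    if sorted(taxa) != sorted(labels):
        raise ValueError("tree taxa do not match the expected taxon set")
    index = {name: i for i, name in enumerate(taxa)}
    n = len(taxa)

    depth: dict[int, float] = {}
    for nd in dtree.preorder_node_iter():
        d = 0.0 if nd.parent_node is None else depth[id(nd.parent_node)] + (
            nd.edge.length or 0.0
        )
        depth[id(nd)] = d
    max_depth = max(depth[id(lf)] for lf in leaves)

    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    left = np.full(2 * n - 1, -1, dtype=np.int64)
    right = np.full(2 * n - 1, -1, dtype=np.int64)
    height = np.zeros(2 * n - 1)
    nxt = n

    def rec(nd) -> int:
        nonlocal nxt
        kids = nd.child_nodes()
        if not kids:
            name = nd.taxon.label if nd.taxon else nd.label
            return index[name]
        if len(kids) != 2:
            raise ValueError(
                f"non-binary node with {len(kids)} children; only binary trees supported"
            )
        a, b = (rec(k) for k in kids)
        v = nxt
        nxt += 1
        left[v], right[v] = a, b
        parent[a] = parent[b] = v
        height[v] = max_depth - depth[id(nd)]
        return v

    rec(dtree.seed_node)
    T = TimeTree(list(taxa), parent, left, right, height)
    T.validate()
    return T


def tree_to_dendropy(
    tree: TimeTree, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    ns = taxon_namespace or dendropy.TaxonNamespace(tree.taxa)
    dtree = dendropy.Tree(taxon_namespace=ns)

    def rec(v: int) -> dendropy.Node:
        nd = dendropy.Node()
        if tree.is_leaf(v):
            nd.taxon = ns.get_taxon(tree.taxa[v])
        else:
            for c in (int(tree.left[v]), int(tree.right[v])):
                child = rec(c)
                child.edge.length = float(tree.height[v] - tree.height[c])
                nd.add_child(child)
        return nd

    dtree.seed_node = rec(tree.root)
    return dtree


def parse_newick(s: str, taxa: Sequence[str] | None = None) -> TimeTree:
    """Parse a single Newick string into a TimeTree."""
    dtree = dendropy.Tree.get(data=s, schema="newick")
    return tree_from_dendropy(dtree, taxa)


def _detect_schema(path: str | Path) -> str:
    with open(path) as fh:
        head = fh.read(512).lstrip()
    return "nexus" if head.lower().startswith("#nexus") else "newick"


def read_trees(
    path: str | Path,
    burnin_fraction: float = 0.0,
) -> TreeSample:
    """Read a tree log (Newick or NEXUS, detected by content).

    ``burnin_fraction`` drops that leading fraction of the trees (posterior
    logs conventionally include a burn-in to discard, default here 0).
    """
    schema = _detect_schema(path)
    tlist = dendropy.TreeList.get(path=str(path), schema=schema)
    if not tlist:
        raise ValueError(f"no trees found in {path}")
    taxa = [t.label for t in tlist.taxon_namespace]
    trees = [tree_from_dendropy(t, taxa) for t in tlist]
    skip = int(burnin_fraction * len(trees))
    trees = trees[skip:] or trees[-1:]
    return TreeSample(trees)


def write_trees(sample: TreeSample | list[TimeTree], path: str | Path,
                schema: str = "nexus") -> None:
    """Write trees as a NEXUS tree block (or plain Newick, one per line)."""
    trees = sample.trees if isinstance(sample, TreeSample) else sample
    if schema == "newick":
        with open(path, "w") as fh:
            for t in trees:
                fh.write(t.newick() + "\n")
        return
    ns = dendropy.TaxonNamespace(trees[0].taxa)
    tlist = dendropy.TreeList(taxon_namespace=ns)
    for t in trees:
        tlist.append(tree_to_dendropy(t, ns))
    tlist.write(path=str(path), schema="nexus", translate_tree_taxa=True,
                suppress_rooting=False)


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA or NEXUS alignment (detected by content)."""
    schema = _detect_schema(path)
    if schema == "newick":  # not NEXUS: sniff FASTA
        with open(path) as fh:
            head = fh.read(1).strip()
        schema = "fasta" if head.startswith(">") else "phylip"
    mat = dendropy.DnaCharacterMatrix.get(path=str(path), schema=schema)
    taxa = [t.label for t in mat.taxon_namespace]
    seqs = [str(mat[t]).replace(" ", "") for t in mat.taxon_namespace]
    return Alignment(taxa, seqs)


def read_config(path: str | Path) -> dict[str, str]:
    """Flat key=value model configuration file.

    Blank lines and ``#`` comments are ignored; values are returned as
    strings for the caller to coerce.
    """
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


class TraceWriter:
    """Appendable Tracer-compatible TSV log of numeric chain statistics."""

    def __init__(self, path: str | Path, columns: list[str], header_comment: str = ""):
        self.path = Path(path)
        self.columns = ["state"] + [c for c in columns if c != "state"]
        with open(self.path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("\t".join(self.columns) + "\n")

    def write_row(self, state: int, values: dict[str, float]) -> None:
        row = [str(state)] + [repr(float(values[c])) for c in self.columns[1:]]
        with open(self.path, "a") as fh:
            fh.write("\t".join(row) + "\n")
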