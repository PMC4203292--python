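"""Neighbor-joining trees, bootstrap supports, and monophyly scoring.

Tree-based barcode identification counts a species as successfully
identified when its specimens form a monophyletic group.  On an unrooted
tree this is a bipartition test: some edge must split exactly that
species' specimens from everything else.  When an outgroup is supplied the
test is performed on the side of each edge away from the outgroup, which
reproduces rooted-clade monophyly without building a rooted tree.

The NJ agglomeration is the standard Saitou–Nei procedure.  Two
reproducibility policies are fixed here: Q-matrix ties are broken by the
smallest (row, column) index pair, and negative branch lengths are clamped
to zero with the deficit transferred to the sister branch so the joined
pair keeps its observed distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distances import (
    DistanceMatrix,
    SaturationError,
    _pairwise_from_codes,
    pairwise_matrix,
)
from .io import BarcodeAlignment, TaxonomyMap

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "Tree",
    "MonophylyReport",
    "nj_tree",
    "bootstrap_supports",
    "monophyly_report",
]


@dataclass
class TreeNode:
    name: Optional[str] = None          # leaf label; None for internal nodes
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[int] = None       # % bootstrap on the edge above, 0-100

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal node as root.

    The root is trifurcating for n >= 4 leaves, so every represented edge
    is a real edge of the unrooted tree.
    """

    root: TreeNode

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def total_length(self) -> float:
        total = 0.0

        def walk(node: TreeNode) -> None:
            nonlocal total
            for child, length in node.children:
                total += length
                walk(child)

        walk(self.root)
        return total

    def _edge_sides(self) -> list[tuple[TreeNode, frozenset]]:
        """(child node, leaf set below it) for every edge."""
        sides: list[tuple[TreeNode, frozenset]] = []

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below: frozenset = frozenset()
            for child, _ in node.children:
                s = walk(child)
                sides.append((child, s))
                below = below | s
            return below

        walk(self.root)
        return sides

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset]:
        """Canonical bipartition sides.

        Each edge splits the leaves in two; the side not containing the
        lexicographically smallest leaf is the canonical representative,
        so sets are comparable across trees on the same leaves.
        """
        all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        for _, side in self._edge_sides():
            canon = all_leaves - side if ref in side else side
            if 0 < len(canon) < len(all_leaves):
                if include_trivial or 2 <= len(canon) <= len(all_leaves) - 2:
                    out.add(canon)
        return out

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode, length: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = (
                    str(node.support)
                    if include_support and node.support is not None
                    else ""
                )
                body = f"({inner}){label}"
            if length is None:
                return body
            return f"{body}:{length:.6f}"

        return fmt(self.root, None) + ";"


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Neighbor-joining tree from a finite distance matrix."""
    n = matrix.n
    if n < 2:
        raise ValueError("need at least 2 taxa")
    iu = np.triu_indices(n, k=1)
    if not np.all(np.isfinite(matrix.values[iu])):
        raise SaturationError(
            "distance matrix contains undefined (saturated) entries; "
            "exclude the affected specimens before building a tree"
        )
    D = matrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in matrix.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin over the row-major flattening picks the smallest (i, j)
        # among ties, with i < j reached before its mirror (j, i)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        # both-negative only when dij < 0 between merged nodes; floor at 0
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    if len(nodes) == 2:
        d = float(D[0, 1])
        root = TreeNode(
            children=[(nodes[0], d / 2.0), (nodes[1], d / 2.0)]
        )
    else:
        d01, d02, d12 = float(D[0, 1]), float(D[0, 2]), float(D[1, 2])
        l0 = max(0.0, (d01 + d02 - d12) / 2.0)
        l1 = max(0.0, (d01 + d12 - d02) / 2.0)
        l2 = max(0.0, (d02 + d12 - d01) / 2.0)
        root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    return Tree(root)


def bootstrap_supports(
    alignment: BarcodeAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
    max_redraws: Optional[int] = None,
) -> Tree:
    """NJ tree of the full alignment with % bootstrap supports.

    Columns are resampled with replacement per replicate; the support of
    each internal edge of the full-data tree is the percentage of
    replicate trees containing the same bipartition.  Replicates whose
    resampled matrix has an undefined pair (saturation or no comparable
    sites) are redrawn with a logged count.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    full = pairwise_matrix(alignment)
    tree = nj_tree(full)
    all_leaves = frozenset(alignment.ids)
    ref = min(all_leaves)
    target: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}

    rng = np.random.default_rng(seed)
    codes = alignment.codes4
    L = alignment.length
    if max_redraws is None:
        max_redraws = 10 * n_replicates
    redraws = 0
    done = 0
    while done < n_replicates:
        cols = rng.integers(0, L, size=L)
        d, _ = _pairwise_from_codes(codes[:, cols])
        iu = np.triu_indices(d.shape[0], k=1)
        if not np.all(np.isfinite(d[iu])):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    "too many bootstrap replicates with undefined distances"
                )
            continue
        rep_tree = nj_tree(DistanceMatrix(list(alignment.ids), d, np.zeros_like(d)))
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1
        done += 1
    if redraws:
        logger.warning("%d bootstrap replicates redrawn", redraws)

    def annotate(node: TreeNode, parent_side_known: bool) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below: frozenset = frozenset()
        for child, _ in node.children:
            below = below | annotate(child, True)
        canon = all_leaves - below if ref in below else below
        if 2 <= len(canon) <= len(all_leaves) - 2:
            node.support = round(100.0 * target.get(canon, 0) / n_replicates)
        return below

    for child, _ in tree.root.children:
        annotate(child, True)
    return tree


@dataclass
class MonophylyReport:
    rank: str
    status: dict[str, bool]          # taxon -> monophyletic?
    n_monophyletic: int
    n_total: int
    ratio: float                     # percentage

    def non_monophyletic(self) -> list[str]:
        return sorted(t for t, ok in self.status.items() if not ok)


def monophyly_report(
    tree: Tree,
    taxonomy: TaxonomyMap,
    rank: str = "species",
    outgroup: Optional[Sequence[str]] = None,
) -> MonophylyReport:
    """Score per-taxon monophyly on the (unrooted) tree.

    Without an outgroup a taxon is monophyletic iff some edge splits
    exactly its specimens from all others; singletons count as
    monophyletic.  With an outgroup the side of the edge away from the
    outgroup must equal the taxon (rooted-clade test); outgroup specimens
    are excluded from the report.
    """
    if rank not in ("species", "genus"):
        raise ValueError(f"rank must be 'species' or 'genus', got {rank!r}")
    leaves = set(tree.leaves())
    missing = leaves - set(taxonomy.entries)
    if missing:
        raise ValueError(f"tree leaves missing from taxonomy: {sorted(missing)}")
    out_ids = set(outgroup) if outgroup else set()
    groups = {
        taxon: [s for s in sids if s in leaves and s not in out_ids]
        for taxon, sids in taxonomy.groups(rank).items()
    }
    groups = {t: s for t, s in groups.items() if s}

    all_leaves = frozenset(tree.leaves())
    sides: set[frozenset] = set()
    for _, side in tree._edge_sides():
        sides.add(side)
        sides.add(all_leaves - side)

    status: dict[str, bool] = {}
    for taxon, sids in groups.items():
        s = frozenset(sids)
        if len(s) <= 1 or s == all_leaves:
            status[taxon] = True
        else:
            # With an outgroup, s never contains outgroup leaves, so the
            # complement side of any matching edge holds the whole
            # outgroup: the rooted clade test coincides with this
            # bipartition test.
            status[taxon] = s in sides
    n_mono = sum(status.values())
    n_total = len(status)
    return MonophylyReport(
        rank=rank,
        status=status,
        n_monophyletic=n_mono,
        n_total=n_total,
        ratio=100.0 * n_mono / n_total if n_total else 0.0,
    )


def monophyly_table(report: MonophylyReport, taxonomy: TaxonomyMap):
    """Per-taxon TSV-ready table (taxon, rank, n_specimens, monophyletic)."""
    import pandas as pd

    sizes = {t: len(s) for t, s in taxonomy.groups(report.rank).items()}
    return pd.DataFrame(
        [
            (t, report.rank, sizes.get(t, 0), "yes" if ok else "no")
            for t, ok in sorted(report.status.items())
        ],
        columns=["taxon", "rank", "n_specimens", "monophyletic"],
    )
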