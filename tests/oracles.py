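"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive scans, full topology
enumeration, direct least squares) and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

IUPAC_EXPAND = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"}, "-": set(),
}


def brute_diagnostics(seqs: dict[str, str], taxon_of: dict[str, str]):
    """Exhaustive (column x base x taxon) diagnostic scan.

    A base is diagnostic for a taxon iff every member shows exactly that
    base and no outsider's character expansion includes it.
    """
    length = len(next(iter(seqs.values())))
    taxa = sorted(set(taxon_of.values()))
    out: dict[str, list[tuple[int, str]]] = {t: [] for t in taxa}
    for taxon in taxa:
        members = [s for s, t in taxon_of.items() if t == taxon]
        outsiders = [s for s in seqs if s not in members]
        for col in range(length):
            for base in "ACGT":
                if not all(seqs[m][col] == base for m in members):
                    continue
                if any(base in IUPAC_EXPAND[seqs[o][col]] for o in outsiders):
                    continue
                out[taxon].append((col + 1, base))
    return out


# --- unrooted tree enumeration ---------------------------------------------


def all_topologies(labels: list[str]) -> list[dict]:
    """All unrooted binary topologies on the labels, as adjacency dicts.

    Internal nodes are negative ints.  1, 1, 3, 15, 105, 945, ... trees
    for 3, 4, 5, 6, 7, ... leaves.
    """
    if len(labels) < 3:
        raise ValueError("need >= 3 leaves")
    star = {-1: set(labels[:3])}
    for lab in labels[:3]:
        star[lab] = {-1}
    trees = [star]
    next_internal = -2
    for lab in labels[3:]:
        grown = []
        for adj in trees:
            edges = {
                tuple(sorted((u, v), key=str)) for u in adj for v in adj[u]
            }
            for u, v in edges:
                new = {k: set(vs) for k, vs in adj.items()}
                w = next_internal
                new[u].discard(v)
                new[v].discard(u)
                new[w] = {u, v, lab}
                new[u].add(w)
                new[v].add(w)
                new[lab] = {w}
                grown.append(new)
        trees = grown
        next_internal -= 1
    return trees


def topology_bipartitions(adj: dict) -> set[frozenset]:
    """Non-trivial bipartitions (canonical side excludes the min leaf)."""
    leaves = sorted(k for k in adj if not isinstance(k, int) or k >= 0)
    leaves = [k for k in adj if not (isinstance(k, int) and k < 0)]
    ref = min(map(str, leaves))
    out: set[frozenset] = set()
    edges = {tuple(sorted((u, v), key=str)) for u in adj for v in adj[u]}
    for u, v in edges:
        side = _side_leaves(adj, u, v)
        canon = frozenset(l for l in leaves if l not in side) \
            if ref in set(map(str, side)) else frozenset(side)
        if 2 <= len(canon) <= len(leaves) - 2:
            out.add(canon)
    return out


def _side_leaves(adj: dict, start, blocked) -> list:
    seen = {blocked, start}
    stack = [start]
    leaves = []
    while stack:
        node = stack.pop()
        if not (isinstance(node, int) and node < 0):
            leaves.append(node)
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return leaves


def path_edges(adj: dict, a, b) -> list[tuple]:
    """Edge list on the unique path from leaf a to leaf b."""
    parent = {a: None}
    stack = [a]
    while stack:
        node = stack.pop()
        if node == b:
            break
        for nxt in adj[node]:
            if nxt not in parent:
                parent[nxt] = node
                stack.append(nxt)
    path = []
    node = b
    while parent[node] is not None:
        path.append(tuple(sorted((node, parent[node]), key=str)))
        node = parent[node]
    return path


def ls_residual(adj: dict, labels: list[str], dmat: np.ndarray) -> float:
    """Least-squares branch-length fit residual of a topology to a matrix."""
    edges = sorted(
        {tuple(sorted((u, v), key=str)) for u in adj for v in adj[u]},
        key=str,
    )
    eidx = {e: k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for e in path_edges(adj, labels[i], labels[j]):
            A[row, eidx[e]] = 1.0
        y[row] = dmat[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.linalg.norm(A @ x - y))


def additive_matrix_from_topology(
    adj: dict, labels: list[str], rng
) -> np.ndarray:
    """Random positive branch lengths -> exact path-distance matrix."""
    edges = {tuple(sorted((u, v), key=str)) for u in adj for v in adj[u]}
    lengths = {e: float(rng.uniform(0.5, 3.0)) for e in edges}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(lengths[e] for e in path_edges(adj, labels[i], labels[j]))
            D[i, j] = D[j, i] = d
    return D
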