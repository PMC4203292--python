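"""Automatic barcode-gap partitioning of a distance matrix.

Given a prior maximum intraspecific divergence P, the method looks at the
ranked pairwise distances and searches, above P, for the first jump
between consecutive values that is disproportionately wide compared with
the local spacing of the curve below it (wider than X times the mean
spacing, X being the minimum relative gap width).  The midpoint of that
jump is the barcode-gap threshold; single-linkage connected components
under "distance < threshold" are the candidate species.

Two partition modes are produced.  The *initial* partition applies one
whole-matrix gap search.  The *recursive* partition re-runs the gap
search inside every resulting group (on its submatrix) and keeps
splitting until no group shows an internal gap, so it refines the initial
partition and can resolve heterogeneous groups that merge at the global
threshold.  Scanning a geometric grid of priors reproduces the familiar
group-count-versus-prior staircase.

This module is deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .io import TaxonomyMap

__all__ = [
    "AbgdConfig",
    "Partition",
    "find_gap",
    "initial_partition",
    "recursive_partition",
    "partition_grid",
    "partition_concordance",
    "grid_table",
    "partition_table",
]


@dataclass(frozen=True)
class AbgdConfig:
    """Web-form-style parameters of the gap partitioner.

    Defaults are the standard choices for COI barcodes: priors spanning
    0.001-0.1 over 10 geometric steps, minimum relative gap width 1.5,
    20 histogram bins, K80 distances with TS/TV 2.0 (distances are
    computed upstream by the distances module; ``ts_tv`` documents the
    model the matrix is expected to come from).
    """

    p_min: float = 0.001
    p_max: float = 0.1
    steps: int = 10
    relative_gap_width: float = 1.5
    n_bins: int = 20
    ts_tv: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_min < self.p_max < 1.0):
            raise ValueError("require 0 < p_min < p_max < 1")
        if self.steps < 2:
            raise ValueError("steps must be >= 2")
        if self.relative_gap_width <= 0:
            raise ValueError("relative gap width must be positive")

    def prior_grid(self) -> np.ndarray:
        """Geometric (log-spaced) grid of priors from p_min to p_max."""
        return np.geomspace(self.p_min, self.p_max, self.steps)


@dataclass
class Partition:
    """A grouping of all specimens into candidate species."""

    prior_p: float
    mode: str                     # "initial" or "recursive"
    groups: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set = set()
        for g in self.groups:
            if seen & g:
                raise ValueError("partition groups overlap")
            seen |= g
        # stable presentation: groups ordered by their smallest member
        self.groups = sorted(self.groups, key=lambda g: min(g))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self) -> dict[str, int]:
        return {sid: k for k, g in enumerate(self.groups) for sid in g}


def find_gap(
    distances, prior_p: float, relative_gap_width: float = 1.5
) -> Optional[float]:
    """Locate the barcode-gap threshold above ``prior_p``, or None.

    Candidate jumps are gaps between consecutive ranked distances whose
    upper value exceeds the prior; the first jump wider than
    ``relative_gap_width`` times the mean spacing of the ranked curve
    below it qualifies, and the threshold returned is its midpoint.
    Absence of a qualifying jump is a valid outcome (None).
    """
    v = np.sort(np.asarray(list(distances), dtype=float))
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("need at least one pairwise distance")
    for i in range(v.size - 1):
        lo, hi = v[i], v[i + 1]
        if hi <= prior_p:
            continue
        width = hi - lo
        if width <= 0.0:
            continue
        local_slope = (v[i] - v[0]) / i if i > 0 else 0.0
        if width > relative_gap_width * local_slope:
            return float((lo + hi) / 2.0)
    return None


def _components(matrix: DistanceMatrix, threshold: float) -> list[frozenset]:
    """Single-linkage components under edge rule d < threshold.

    nan (saturated) entries never connect a pair.
    """
    with np.errstate(invalid="ignore"):
        adj = matrix.values < threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, return_labels=True
    )
    groups: dict[int, set] = {}
    for sid, lab in zip(matrix.ids, labels):
        groups.setdefault(int(lab), set()).add(sid)
    return [frozenset(g) for g in groups.values()]


def initial_partition(
    matrix: DistanceMatrix, prior_p: float, config: AbgdConfig = AbgdConfig()
) -> Partition:
    """One whole-matrix gap search; no gap found means a single group."""
    threshold = find_gap(
        matrix.condensed(), prior_p, config.relative_gap_width
    )
    if threshold is None:
        groups = [frozenset(matrix.ids)]
    else:
        groups = _components(matrix, threshold)
    return Partition(prior_p=prior_p, mode="initial", groups=groups)


def _split_recursively(
    matrix: DistanceMatrix, group: frozenset, prior_p: float, config: AbgdConfig
) -> list[frozenset]:
    if len(group) < 2:
        return [group]
    sub = matrix.submatrix(sorted(group))
    threshold = find_gap(sub.condensed(), prior_p, config.relative_gap_width)
    if threshold is None:
        return [group]
    comps = _components(sub, threshold)
    if len(comps) == 1:
        return [group]
    out: list[frozenset] = []
    for comp in comps:
        out.extend(_split_recursively(matrix, comp, prior_p, config))
    return out


def recursive_partition(
    matrix: DistanceMatrix, prior_p: float, config: AbgdConfig = AbgdConfig()
) -> Partition:
    """Initial partition refined by repeated within-group gap searches."""
    initial = initial_partition(matrix, prior_p, config)
    groups: list[frozenset] = []
    for g in initial.groups:
        groups.extend(_split_recursively(matrix, g, prior_p, config))
    return Partition(prior_p=prior_p, mode="recursive", groups=groups)


def partition_grid(
    matrix: DistanceMatrix, config: AbgdConfig = AbgdConfig()
) -> list[Partition]:
    """Both partition modes for every prior on the geometric grid."""
    out: list[Partition] = []
    for p in config.prior_grid():
        out.append(initial_partition(matrix, float(p), config))
        out.append(recursive_partition(matrix, float(p), config))
    return out


def partition_concordance(
    partition: Partition, taxonomy: TaxonomyMap
) -> dict:
    """Compare a partition against the morphological species map.

    A group *matches* iff it equals exactly the specimen set of one
    species.  Raw counts are reported so any success-ratio convention can
    be derived from them.
    """
    specimens = {sid for g in partition.groups for sid in g}
    missing = specimens - set(taxonomy.entries)
    if missing:
        raise ValueError(f"specimens missing from taxonomy: {sorted(missing)}")
    species_sets = {
        frozenset(v) for v in taxonomy.subset(specimens).groups("species").values()
    }
    n_matching = sum(1 for g in partition.groups if g in species_sets)
    return {
        "n_groups": partition.n_groups,
        "n_species": len(species_sets),
        "n_matching_groups": n_matching,
        "match_ratio": 100.0 * n_matching / partition.n_groups,
    }


def grid_table(partitions: list[Partition]) -> pd.DataFrame:
    """Prior-versus-group-count table, one row per prior."""
    rows: dict[float, dict] = {}
    for p in partitions:
        row = rows.setdefault(round(p.prior_p, 6), {})
        row[p.mode] = p.n_groups
    return pd.DataFrame(
        [
            (prior, row.get("initial"), row.get("recursive"))
            for prior, row in sorted(rows.items())
        ],
        columns=["prior_p", "initial_n_groups", "recursive_n_groups"],
    )


def partition_table(partition: Partition) -> pd.DataFrame:
    """Long-format membership table for one partition."""
    rows = [
        (round(partition.prior_p, 6), partition.mode, k, sid)
        for k, group in enumerate(partition.groups)
        for sid in sorted(group)
    ]
    return pd.DataFrame(
        rows, columns=["prior_p", "mode", "group_index", "specimen_id"]
    )
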