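"""Synthetic multi-species barcode alignments with known ground truth.

The generator emulates the statistical structure of a curated COI
barcode study: K species sampled with 2-20 specimens each, a fixed
615-column alignment, small within-species divergence (mean K2P around
0.002-0.005) and an order of magnitude larger between-species divergence
(around 0.11-0.14), under a K80 substitution process with a transition
bias.

Species relationships are a star phylogeny by default — each species'
representative sequence evolves independently from one random ancestral
sequence — which is sufficient to reproduce the intra/inter distance
statistics; an optional coalescent mode draws a random species genealogy
for monophyly stress tests.  Branch lengths are calibrated directly in
expected substitutions per site, the same scale the K2P estimator
measures, so distance-recovery checks are self-consistent.  No indels
are simulated: the analysis operates on a fixed alignment frame.

Optionally, a number of columns per species is overwritten with a
private fixed base ("planted" diagnostics) that the diagnostics module
must recover exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .diagnostics import DiagnosticCharacter
from .distances import distance_summaries, pairwise_matrix
from .io import BarcodeAlignment, TaxonRecord, TaxonomyMap, _CODE4_TO_BASE

__all__ = ["SimConfig", "GroundTruth", "simulate_dataset", "fixture_library"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulator.

    ``target_intra`` / ``target_inter`` are mean pairwise K2P distances
    (substitutions per site); ``ts_tv`` is the transition/transversion
    ratio of the K80 process; ``specimens_per_species`` is a fixed count
    or an inclusive (low, high) range drawn per species.  The seed is
    mandatory: the same seed yields a byte-identical data set.
    """

    seed: int
    n_species: int = 80
    specimens_per_species: Union[int, tuple[int, int]] = (2, 20)
    seq_length: int = 615
    target_intra: float = 0.0046
    target_inter: float = 0.1368
    ts_tv: float = 2.0
    n_planted_diagnostics: int = 0
    tree_mode: str = "star"                    # "star" or "coalescent"
    n_genera: Optional[int] = None
    n_families: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 <= self.target_intra < self.target_inter:
            raise ValueError("require 0 <= target_intra < target_inter")
        if self.tree_mode not in ("star", "coalescent"):
            raise ValueError("tree_mode must be 'star' or 'coalescent'")
        if self.n_planted_diagnostics * self.n_species > self.seq_length:
            raise ValueError(
                "infeasible planting: n_planted_diagnostics * n_species "
                "exceeds the alignment length"
            )


@dataclass
class GroundTruth:
    """What the generator knows: the true partition, plants, realized means."""

    partition: list[frozenset]
    planted: dict[str, list[DiagnosticCharacter]] = field(default_factory=dict)
    realized_intra_mean: Optional[float] = None
    realized_inter_mean: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "partition": [sorted(g) for g in self.partition],
                "planted": {
                    sp: [c.label for c in chars] for sp, chars in self.planted.items()
                },
                "realized_intra_mean": self.realized_intra_mean,
                "realized_inter_mean": self.realized_inter_mean,
            },
            indent=2,
        )


def _k80_site_probs(d: float, ts_tv: float) -> tuple[float, float]:
    """(P transition, P each transversion) after a branch of length d.

    K80 with transition rate alpha and each-transversion rate beta;
    ts_tv = alpha / (2 beta) and d = (alpha + 2 beta) t.
    """
    if d < 0:
        raise ValueError("branch length must be >= 0")
    bt = d / (2.0 * ts_tv + 2.0)
    at = 2.0 * ts_tv * d / (2.0 * ts_tv + 2.0)
    e4b = np.exp(-4.0 * bt)
    e2ab = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b
    return float(p_ts), float(p_tv)


def _evolve(codes: np.ndarray, d: float, ts_tv: float, rng) -> np.ndarray:
    """Evolve a code-4 sequence along a branch of d substitutions/site."""
    if d == 0.0:
        return codes.copy()
    p_ts, p_tv = _k80_site_probs(d, ts_tv)
    u = rng.random(codes.size)
    out = codes.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2.0 * p_tv)
    out[ts] = codes[ts] ^ 1                     # A<->G, C<->T
    out[tv1] = (codes[tv1] + 2) % 4             # A->C, G->T, C->A, T->G
    out[tv2] = ((codes[tv2] + 2) % 4) ^ 1
    return out


def _coalescent_heights(K: int, rng) -> tuple[dict, int]:
    """Random Kingman genealogy over K species; returns node dict and root."""
    nodes: dict[int, dict] = {i: {"children": [], "height": 0.0} for i in range(K)}
    lineages = list(range(K))
    next_id = K
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        pick = sorted(rng.choice(k, size=2, replace=False))
        j, i = pick[1], pick[0]
        b = lineages.pop(j)
        a = lineages.pop(i)
        nodes[next_id] = {"children": [a, b], "height": t}
        lineages.append(next_id)
        next_id += 1
    return nodes, next_id - 1


def _coalescent_representatives(
    K: int, L: int, ancestor: np.ndarray, branch_scale_target: float, ts_tv: float, rng
) -> list[np.ndarray]:
    """Species representative sequences evolved down a random genealogy,
    rescaled so the mean pairwise path length hits the target."""
    nodes, root = _coalescent_heights(K, rng)

    # mean pairwise TMRCA for rescaling
    def leafset(n: int) -> list[int]:
        if not nodes[n]["children"]:
            return [n]
        out: list[int] = []
        for c in nodes[n]["children"]:
            out.extend(leafset(c))
        return out

    total, count = 0.0, 0
    for n, info in nodes.items():
        if info["children"]:
            a, b = info["children"]
            la, lb = leafset(a), leafset(b)
            total += 2.0 * info["height"] * len(la) * len(lb)
            count += len(la) * len(lb)
    scale = branch_scale_target / (total / count)

    seqs: dict[int, np.ndarray] = {}

    def walk(n: int, parent_seq: np.ndarray, parent_h: float) -> None:
        branch = (parent_h - nodes[n]["height"]) * scale
        seqs[n] = _evolve(parent_seq, branch, ts_tv, rng)
        for c in nodes[n]["children"]:
            walk(c, seqs[n], nodes[n]["height"])

    nodes_root_h = nodes[root]["height"]
    seqs[root] = ancestor.copy()
    for c in nodes[root]["children"]:
        walk(c, seqs[root], nodes_root_h)
    return [seqs[i] for i in range(K)]


def _assign_taxonomy(n_species: int, n_genera: Optional[int], n_families: Optional[int]):
    """Contiguous species->genus->family packing, emulating a study where
    most genera are monotypic and families hold a handful of genera."""
    if n_genera is None:
        n_genera = max(1, round(n_species * 7 / 8))
    if n_families is None:
        n_families = max(1, round(n_species * 14 / 80))
    n_genera = min(n_genera, n_species)
    n_families = min(n_families, n_genera)

    def blocks(n_items: int, n_groups: int) -> list[int]:
        base, extra = divmod(n_items, n_groups)
        return [base + (1 if k < extra else 0) for k in range(n_groups)]

    genus_of_species: list[int] = []
    for g, size in enumerate(blocks(n_species, n_genera)):
        genus_of_species.extend([g] * size)
    family_of_genus: list[int] = []
    for f, size in enumerate(blocks(n_genera, n_families)):
        family_of_genus.extend([f] * size)
    return genus_of_species, family_of_genus


def simulate_dataset(
    config: SimConfig,
) -> tuple[BarcodeAlignment, TaxonomyMap, GroundTruth]:
    """Generate an alignment, its taxonomy, and the ground truth."""
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    K = config.n_species
    ancestor = rng.integers(0, 4, size=L).astype(np.uint8)

    t_within = config.target_intra / 2.0
    between_target = config.target_inter - config.target_intra

    if config.tree_mode == "star":
        t_between = between_target / 2.0
        reps = [_evolve(ancestor, t_between, config.ts_tv, rng) for _ in range(K)]
    else:
        reps = _coalescent_representatives(
            K, L, ancestor, between_target, config.ts_tv, rng
        )

    if isinstance(config.specimens_per_species, int):
        counts = [config.specimens_per_species] * K
    else:
        lo, hi = config.specimens_per_species
        counts = [int(c) for c in rng.integers(lo, hi + 1, size=K)]

    genus_of, family_of_genus = _assign_taxonomy(
        K, config.n_genera, config.n_families
    )

    ids: list[str] = []
    rows: list[np.ndarray] = []
    entries: dict[str, TaxonRecord] = {}
    species_names: list[str] = []
    partition: list[frozenset] = []
    for s in range(K):
        sp = f"Species{s + 1:03d}"
        genus = f"Genus{genus_of[s] + 1:03d}"
        family = f"Family{family_of_genus[genus_of[s]] + 1:02d}"
        species_names.append(sp)
        members: list[str] = []
        for k in range(counts[s]):
            sid = f"SP{s + 1:03d}-{k + 1:02d}"
            ids.append(sid)
            rows.append(_evolve(reps[s], t_within, config.ts_tv, rng))
            entries[sid] = TaxonRecord(sp, genus, family)
            members.append(sid)
        partition.append(frozenset(members))

    codes = np.vstack(rows)

    planted: dict[str, list[DiagnosticCharacter]] = {}
    if config.n_planted_diagnostics > 0:
        cols = rng.choice(
            L, size=config.n_planted_diagnostics * K, replace=False
        )
        species_rows = np.repeat(np.arange(K), counts)
        for s in range(K):
            sp = species_names[s]
            planted[sp] = []
            for p in range(config.n_planted_diagnostics):
                col = int(cols[s * config.n_planted_diagnostics + p])
                base = int(rng.integers(0, 4))
                member_mask = species_rows == s
                codes[member_mask, col] = base
                clash = (~member_mask) & (codes[:, col] == base)
                codes[clash, col] = (base + 2) % 4   # transversion away
                planted[sp].append(
                    DiagnosticCharacter(
                        position=col + 1, nucleotide=_CODE4_TO_BASE[base]
                    )
                )
            planted[sp].sort()

    seqs = ["".join(_CODE4_TO_BASE[c] for c in row) for row in codes]
    alignment = BarcodeAlignment(ids, seqs)
    taxonomy = TaxonomyMap(entries)

    truth = GroundTruth(partition=partition, planted=planted)
    if alignment.n_records >= 2:
        intra, inter = distance_summaries(pairwise_matrix(alignment), taxonomy)
        truth.realized_intra_mean = intra.mean if not intra.empty else 0.0
        truth.realized_inter_mean = inter.mean if not inter.empty else None
    return alignment, taxonomy, truth


# ---------------------------------------------------------------------------
# deterministic tiny fixtures shared across test suites


def _transit(seq: str, positions) -> str:
    """Apply transitions (A<->G, C<->T) at the given 0-based positions."""
    ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    chars = list(seq)
    for p in positions:
        chars[p] = ts[chars[p]]
    return "".join(chars)


def _set_base(seq: str, position: int, base: str) -> str:
    chars = list(seq)
    chars[position] = base
    return "".join(chars)


def fixture_library() -> dict[str, tuple[BarcodeAlignment, TaxonomyMap]]:
    """Named deterministic miniature data sets.

    - ``two_clusters``: two well-separated species (positive gap; a
      partitioner and a tree method must both recover them).
    - ``no_gap``: one species with large internal divergence overlapping
      the interspecific range (no positive gap).
    - ``intermixed_species``: specimens of two species interleaved across
      clusters, breaking their monophyly (one control species is clean).
    - ``subset_effect``: species whose private bases are shared across
      families, so species diagnostics exist only within family subsets.
    """
    out: dict[str, tuple[BarcodeAlignment, TaxonomyMap]] = {}

    aln, tax, _ = simulate_dataset(
        SimConfig(
            seed=20100703,
            n_species=2,
            specimens_per_species=4,
            seq_length=300,
            target_intra=0.003,
            target_inter=0.12,
        )
    )
    out["two_clusters"] = (aln, tax)

    base60 = "ACGT" * 15
    no_gap = BarcodeAlignment(
        ["a1", "a2", "b1", "b2"],
        [
            base60,
            _transit(base60, range(0, 60, 5)),       # 12 changes: huge intra
            _transit(base60, [2, 7]),                 # close to a1: small inter
            _transit(base60, [2, 7]),
        ],
    )
    no_gap_tax = TaxonomyMap(
        {
            "a1": TaxonRecord("SpA", "GenA", "FamX"),
            "a2": TaxonRecord("SpA", "GenA", "FamX"),
            "b1": TaxonRecord("SpB", "GenB", "FamX"),
            "b2": TaxonRecord("SpB", "GenB", "FamX"),
        }
    )
    out["no_gap"] = (no_gap, no_gap_tax)

    clu2 = _transit(base60, range(30, 40))
    clu3 = _transit(base60, range(45, 55))
    intermixed = BarcodeAlignment(
        ["a1", "b1", "a2", "b2", "c1", "c2"],
        [
            base60,
            _transit(base60, [0]),
            clu2,
            _transit(clu2, [1]),
            clu3,
            _transit(clu3, [2]),
        ],
    )
    intermixed_tax = TaxonomyMap(
        {
            "a1": TaxonRecord("SpA", "GenA", "FamX"),
            "a2": TaxonRecord("SpA", "GenA", "FamX"),
            "b1": TaxonRecord("SpB", "GenB", "FamX"),
            "b2": TaxonRecord("SpB", "GenB", "FamX"),
            "c1": TaxonRecord("SpC", "GenC", "FamX"),
            "c2": TaxonRecord("SpC", "GenC", "FamX"),
        }
    )
    out["intermixed_species"] = (intermixed, intermixed_tax)

    base40 = "ACGT" * 10
    s1 = _set_base(base40, 0, "G")                    # G_1, shared with S3
    s2 = _set_base(base40, 1, "T")                    # T_2, shared with S4
    s3 = _set_base(_set_base(base40, 0, "G"), 4, "G")  # private G_5
    s4 = _set_base(_set_base(base40, 1, "T"), 5, "T")  # private T_6
    subset = BarcodeAlignment(
        ["s1a", "s1b", "s2a", "s2b", "s3a", "s3b", "s4a", "s4b"],
        [s1, s1, s2, s2, s3, s3, s4, s4],
    )
    subset_tax = TaxonomyMap(
        {
            "s1a": TaxonRecord("Sp1", "Gen1", "Fam1"),
            "s1b": TaxonRecord("Sp1", "Gen1", "Fam1"),
            "s2a": TaxonRecord("Sp2", "Gen2", "Fam1"),
            "s2b": TaxonRecord("Sp2", "Gen2", "Fam1"),
            "s3a": TaxonRecord("Sp3", "Gen3", "Fam2"),
            "s3b": TaxonRecord("Sp3", "Gen3", "Fam2"),
            "s4a": TaxonRecord("Sp4", "Gen4", "Fam2"),
            "s4b": TaxonRecord("Sp4", "Gen4", "Fam2"),
        }
    )
    out["subset_effect"] = (subset, subset_tax)
    return out
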