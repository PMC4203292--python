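"""Tree-free single-nucleotide diagnostic characters.

A nucleotide n at alignment column c is *diagnostic* for a taxon T when
every specimen of T carries exactly n at c and no specimen outside T can
carry n there.  Only single positions are considered; combinations of
columns are out of scope.

Handling of gaps and ambiguity codes is conservative, so a claimed
diagnostic can never be contradicted by resolving an ambiguity: a column
is ineligible for T if any member of T has a gap or ambiguity code there,
and an outside specimen whose ambiguity expansion includes n blocks n
from being diagnostic.

Because the member condition is a conjunction over specimens and the
exclusion condition a conjunction over outsiders, sampling more
specimens of a taxon can only remove its diagnostics, while removing
other taxa can only add them — which is why small data sets (or subsets)
show higher diagnostic success ratios than large ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import BarcodeAlignment, TaxonomyMap

__all__ = [
    "DiagnosticCharacter",
    "DiagnosticSet",
    "find_diagnostics",
    "diagnostic_success_ratio",
    "subset_rediagnosis",
    "diagnostics_table",
    "export_probes",
]

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_BITS_BASE = {v: k for k, v in _BASE_BITS.items()}
_LABEL_RE = re.compile(r"^([ACGT])_(\d+)$")


@dataclass(frozen=True, order=True)
class DiagnosticCharacter:
    """A (1-based position, nucleotide) pair, printed as e.g. ``G_5``."""

    position: int
    nucleotide: str

    def __post_init__(self) -> None:
        if self.nucleotide not in _BASE_BITS:
            raise ValueError(f"nucleotide must be one of ACGT, got {self.nucleotide!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.nucleotide}_{self.position}"

    @classmethod
    def from_label(cls, label: str) -> "DiagnosticCharacter":
        m = _LABEL_RE.match(label)
        if not m:
            raise ValueError(f"bad diagnostic label {label!r}")
        return cls(position=int(m.group(2)), nucleotide=m.group(1))


@dataclass
class DiagnosticSet:
    """Per-taxon diagnostic characters at one rank, with the success ratio."""

    rank: str
    characters: dict[str, list[DiagnosticCharacter]] = field(default_factory=dict)

    @property
    def n_taxa_total(self) -> int:
        return len(self.characters)

    @property
    def n_taxa_with_diagnostics(self) -> int:
        return sum(1 for chars in self.characters.values() if chars)

    @property
    def success_ratio(self) -> float:
        """Percentage of taxa with at least one diagnostic character."""
        if self.n_taxa_total == 0:
            return 0.0
        return 100.0 * self.n_taxa_with_diagnostics / self.n_taxa_total


def find_diagnostics(
    alignment: BarcodeAlignment,
    taxonomy: TaxonomyMap,
    rank: str = "species",
) -> DiagnosticSet:
    """Scan every column for per-taxon diagnostic nucleotides.

    Requires at least two taxa at the chosen rank: diagnosis is relative
    to the rest of the data set.
    """
    groups = taxonomy.groups(rank)
    groups = {t: [s for s in sids if s in set(alignment.ids)] for t, sids in groups.items()}
    groups = {t: s for t, s in groups.items() if s}
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 taxa at rank {rank!r} to search for diagnostics"
        )
    bits = alignment.bits          # (n, L) IUPAC bitmasks
    row_of = {sid: k for k, sid in enumerate(alignment.ids)}
    pure = np.isin(bits, [1, 2, 4, 8])

    out: dict[str, list[DiagnosticCharacter]] = {}
    for taxon in sorted(groups):
        members = np.array([row_of[s] for s in groups[taxon]])
        outside = np.setdiff1d(np.arange(alignment.n_records), members)
        sub = bits[members]
        # fixed unambiguous base across all members
        eligible = pure[members].all(axis=0) & (sub == sub[0]).all(axis=0)
        # an outside ambiguity whose expansion includes the base blocks it
        outside_bits = np.bitwise_or.reduce(bits[outside], axis=0)
        diagnostic = eligible & ((outside_bits & sub[0]) == 0)
        out[taxon] = [
            DiagnosticCharacter(position=int(col) + 1, nucleotide=_BITS_BASE[int(sub[0, col])])
            for col in np.flatnonzero(diagnostic)
        ]
    return DiagnosticSet(rank=rank, characters=out)


def diagnostic_success_ratio(diagset: DiagnosticSet) -> float:
    """100 x (taxa with >= 1 diagnostic character) / (total taxa)."""
    if diagset.n_taxa_total < 1:
        raise ValueError("empty diagnostic set")
    return diagset.success_ratio


def subset_rediagnosis(
    alignment: BarcodeAlignment,
    taxonomy: TaxonomyMap,
    taxon_subset: Optional[Iterable[str]] = None,
    n_taxa: Optional[int] = None,
    seed: Optional[int] = None,
    rank: str = "species",
) -> DiagnosticSet:
    """Re-run the diagnostic scan on a subset of taxa.

    Either pass ``taxon_subset`` explicitly, or ``n_taxa`` plus ``seed``
    to draw a reproducible random subset.  Fewer outsiders weaken the
    exclusion constraint, so subsets can only gain diagnostics.
    """
    groups = taxonomy.groups(rank)
    if taxon_subset is None:
        if n_taxa is None or seed is None:
            raise ValueError("give taxon_subset, or n_taxa with a seed")
        rng = np.random.default_rng(seed)
        names = sorted(groups)
        if n_taxa > len(names):
            raise ValueError(f"cannot draw {n_taxa} taxa from {len(names)}")
        taxon_subset = list(rng.choice(names, size=n_taxa, replace=False))
    taxon_subset = set(taxon_subset)
    if not taxon_subset:
        raise ValueError("taxon subset is empty")
    unknown = taxon_subset - set(groups)
    if unknown:
        raise ValueError(f"taxa not in taxonomy at rank {rank!r}: {sorted(unknown)}")
    keep = [s for t in taxon_subset for s in groups[t]]
    keep = [s for s in alignment.ids if s in set(keep)]   # alignment order
    return find_diagnostics(alignment.subset(keep), taxonomy.subset(keep), rank)


def diagnostics_table(
    diagset: DiagnosticSet, taxonomy: TaxonomyMap
) -> pd.DataFrame:
    """Per-taxon table: characters as space-separated labels, counts, sizes."""
    groups = taxonomy.groups(diagset.rank)
    family_of: dict[str, str] = {}
    if diagset.rank != "family":
        for taxon, sids in groups.items():
            fams = {taxonomy.rank_of(s, "family") for s in sids}
            family_of[taxon] = sorted(fams)[0] if len(fams) == 1 else "/".join(sorted(fams))
    rows = []
    for taxon in sorted(diagset.characters):
        chars = sorted(diagset.characters[taxon])
        rows.append(
            (
                taxon,
                family_of.get(taxon, taxon),
                " ".join(c.label for c in chars),
                len(chars),
                len(groups.get(taxon, [])),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon",
            "family",
            "diagnostic_characters",
            "n_characters",
            "n_individuals",
        ],
    )


def export_probes(
    diagset: DiagnosticSet,
    alignment: BarcodeAlignment,
    taxonomy: TaxonomyMap,
    flank: int = 10,
) -> list[tuple[str, str]]:
    """Probe sequences around each diagnostic site (biochip design aid).

    Returns (name, sequence) pairs where the sequence is the taxon's
    consensus (first member) slice of +-``flank`` columns around the
    diagnostic position.
    """
    groups = taxonomy.groups(diagset.rank)
    seq_of = dict(zip(alignment.ids, alignment.sequences))
    probes: list[tuple[str, str]] = []
    for taxon, chars in sorted(diagset.characters.items()):
        if not chars or taxon not in groups:
            continue
        rep = seq_of[groups[taxon][0]]
        for ch in sorted(chars):
            i = ch.position - 1
            lo = max(0, i - flank)
            hi = min(alignment.length, i + flank + 1)
            probes.append((f"{taxon}|{ch.label}", rep[lo:hi]))
    return probes
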