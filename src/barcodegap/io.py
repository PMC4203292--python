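"""Alignment and taxonomy input/output.

The two types defined here, :class:`BarcodeAlignment` and
:class:`TaxonomyMap`, are the shared data model of the package: every
downstream module (distances, trees, partitioning, diagnostics) consumes
these and never re-parses files.

A barcode alignment is a set of equal-length nucleotide sequences over the
IUPAC alphabet (plus ``-`` for alignment gaps), indexed by unique specimen
identifiers.  Alignment columns are the coordinate frame for all
user-facing position labels, which are 1-based (internally 0-based).

The taxonomy map carries the morphological determinations — specimen to
(species, genus, family) — that the molecular methods are compared
against.  It normally travels as a separate TSV so the FASTA stays
standard, but a pipe-delimited header dialect
``specimenID|species|genus|family`` is also accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentError",
    "TaxonomyError",
    "BarcodeAlignment",
    "TaxonRecord",
    "TaxonomyMap",
    "read_alignment",
    "write_alignment",
    "read_taxonomy",
    "write_taxonomy",
    "taxonomy_from_headers",
]


class AlignmentError(ValueError):
    """Malformed alignment: ragged lengths, duplicate ids, bad characters."""


class TaxonomyError(ValueError):
    """Malformed or incomplete taxonomy table."""


# One bit per base so ambiguity codes are unions; gap carries no bits.
IUPAC_BITS: dict[str, int] = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111, "-": 0b0000,
}

# Compact code for unambiguous bases: A=0, G=1, C=2, T=3.  Transitions are
# then ``code ^ 1`` and purine/pyrimidine is ``code >> 1``; anything
# ambiguous or gapped maps to the sentinel 255 and is excluded pairwise.
CODE4: dict[str, int] = {"A": 0, "G": 1, "C": 2, "T": 3}
CODE4_INVALID = 255
_CODE4_TO_BASE = "AGCT"

_BITS_LUT = np.full(256, 255, dtype=np.uint8)
for _ch, _b in IUPAC_BITS.items():
    _BITS_LUT[ord(_ch)] = _b
_CODE4_LUT = np.full(256, CODE4_INVALID, dtype=np.uint8)
for _ch, _c in CODE4.items():
    _CODE4_LUT[ord(_ch)] = _c


@dataclass
class BarcodeAlignment:
    """Equal-length barcode sequences keyed by unique specimen ids."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in count")
        if not self.ids:
            raise AlignmentError("alignment is empty")
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise AlignmentError(f"duplicate specimen id: {sid!r}")
            seen.add(sid)
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        if length < 1:
            raise AlignmentError(f"empty sequence for {self.ids[0]!r}")
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise AlignmentError(
                    f"unequal sequence lengths: {sid!r} has {len(seq)} "
                    f"columns, expected {length}"
                )
            bad = set(seq) - IUPAC_BITS.keys()
            if bad:
                raise AlignmentError(
                    f"invalid characters {sorted(bad)} in record {sid!r}"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.sequences[0])

    @property
    def n_records(self) -> int:
        return len(self.ids)

    @cached_property
    def bits(self) -> np.ndarray:
        """(n_records, length) uint8 matrix of IUPAC bitmasks."""
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_records, self.length)
        return _BITS_LUT[raw]

    @cached_property
    def codes4(self) -> np.ndarray:
        """(n_records, length) uint8 matrix, A/G/C/T -> 0..3, else 255."""
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_records, self.length)
        return _CODE4_LUT[raw]

    def sequence(self, specimen_id: str) -> str:
        return self.sequences[self.ids.index(specimen_id)]

    def subset(self, keep_ids) -> "BarcodeAlignment":
        """New alignment restricted to ``keep_ids``, preserving input order."""
        keep = set(keep_ids)
        missing = keep - set(self.ids)
        if missing:
            raise AlignmentError(f"ids not in alignment: {sorted(missing)}")
        pairs = [(i, s) for i, s in zip(self.ids, self.sequences) if i in keep]
        return BarcodeAlignment([p[0] for p in pairs], [p[1] for p in pairs])

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.sequences))


class TaxonRecord(NamedTuple):
    species: str
    genus: str
    family: str


@dataclass
class TaxonomyMap:
    """Specimen -> (species, genus, family) assignments."""

    entries: dict[str, TaxonRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, rec in self.entries.items():
            if not rec.species:
                raise TaxonomyError(f"empty species name for specimen {sid!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self.entries

    def rank_of(self, specimen_id: str, rank: str) -> str:
        rec = self.entries[specimen_id]
        try:
            return getattr(rec, rank)
        except AttributeError:
            raise TaxonomyError(f"unknown rank {rank!r}") from None

    def species_of(self, specimen_id: str) -> str:
        return self.entries[specimen_id].species

    def groups(self, rank: str = "species") -> dict[str, list[str]]:
        """Taxon name -> specimen ids at the given rank (insertion order)."""
        if rank not in ("species", "genus", "family"):
            raise TaxonomyError(f"unknown rank {rank!r}")
        out: dict[str, list[str]] = {}
        for sid, rec in self.entries.items():
            out.setdefault(getattr(rec, rank), []).append(sid)
        return out

    def subset(self, keep_ids) -> "TaxonomyMap":
        keep = set(keep_ids)
        return TaxonomyMap(
            {sid: rec for sid, rec in self.entries.items() if sid in keep}
        )

    def species_partition(self) -> list[frozenset]:
        """The morphological species partition as a list of specimen sets."""
        return [frozenset(v) for v in self.groups("species").values()]


def read_alignment(path) -> BarcodeAlignment:
    """Read a FASTA alignment, validating lengths, ids and characters."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return BarcodeAlignment(
        [r.id for r in records], [str(r.seq) for r in records]
    )


def write_alignment(alignment: BarcodeAlignment, path, line_width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in alignment
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


_TAXONOMY_COLUMNS = ["specimen_id", "species", "genus", "family"]


def read_taxonomy(path, alignment: BarcodeAlignment) -> TaxonomyMap:
    """Read a taxonomy TSV and check it covers the alignment.

    Specimens present in the table but absent from the alignment are
    dropped with a logged warning; specimens in the alignment that the
    table misses are an error (every method needs a reference label).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in _TAXONOMY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TaxonomyError(
            f"taxonomy table lacks required columns {missing_cols}"
        )
    table_ids = list(df["specimen_id"])
    if len(set(table_ids)) != len(table_ids):
        dupes = sorted({i for i in table_ids if table_ids.count(i) > 1})
        raise TaxonomyError(f"duplicate specimen ids in taxonomy: {dupes}")
    aln_ids = set(alignment.ids)
    extra = [i for i in table_ids if i not in aln_ids]
    if extra:
        logger.warning(
            "taxonomy table lists %d specimens absent from the alignment "
            "(dropped): %s", len(extra), ", ".join(extra[:10]),
        )
    by_id = {
        row.specimen_id: TaxonRecord(row.species, row.genus, row.family)
        for row in df.itertuples()
        if row.specimen_id in aln_ids
    }
    absent = [i for i in alignment.ids if i not in by_id]
    if absent:
        raise TaxonomyError(
            f"alignment specimens missing from taxonomy table: {absent}"
        )
    # keyed in alignment order so downstream group listings are stable
    return TaxonomyMap({sid: by_id[sid] for sid in alignment.ids})


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    df = pd.DataFrame(
        [(sid, r.species, r.genus, r.family) for sid, r in taxonomy.entries.items()],
        columns=_TAXONOMY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def taxonomy_from_headers(
    alignment: BarcodeAlignment,
) -> tuple[BarcodeAlignment, TaxonomyMap]:
    """Parse the ``specimenID|species|genus|family`` header dialect.

    Returns a new alignment with bare specimen ids plus the extracted
    taxonomy; used when no separate TSV is supplied.
    """
    ids: list[str] = []
    entries: dict[str, TaxonRecord] = {}
    for header, _ in alignment:
        parts = header.split("|")
        if len(parts) != 4:
            raise TaxonomyError(
                f"header {header!r} is not 'specimenID|species|genus|family'"
            )
        sid, species, genus, family = parts
        ids.append(sid)
        entries[sid] = TaxonRecord(species, genus, family)
    bare = BarcodeAlignment(ids, list(alignment.sequences))
    return bare, TaxonomyMap(entries)
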