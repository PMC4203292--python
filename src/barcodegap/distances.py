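"""Kimura two-parameter (K2P/K80) distances and barcoding-gap summaries.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the proportions of compared sites showing a transition and a
transversion respectively, the distance in expected substitutions per site
is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap or an IUPAC ambiguity code are
excluded from that pair's comparison (pairwise deletion).  When the log
argument is non-positive the pair is saturated: the distance is undefined
and the pair is flagged rather than silently dropped, so summary statistics
can report how many pairs were excluded.

Summaries split pairs into intraspecific (same species) and interspecific
(different species) sets; a *positive barcoding gap* means the largest
intraspecific distance is still smaller than the smallest interspecific
one, so a distance threshold can separate conspecifics from heterospecifics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import BarcodeAlignment, TaxonomyMap, _CODE4_LUT, CODE4_INVALID

logger = logging.getLogger(__name__)

__all__ = [
    "SaturationError",
    "K2PModel",
    "DistanceMatrix",
    "DistanceSummary",
    "GapReport",
    "GapHistogram",
    "k2p_distance",
    "pairwise_matrix",
    "distance_summaries",
    "barcoding_gap",
    "gap_histogram",
    "pair_table",
    "summary_table",
]


class SaturationError(ValueError):
    """K2P distance undefined: the corrected log argument is non-positive."""


@dataclass(frozen=True)
class K2PModel:
    """Transition/transversion proportions and the K2P distance of a pair."""

    P: float
    Q: float
    d: float
    comparable_sites: int


def _encode(seq: str) -> np.ndarray:
    return _CODE4_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _k2p_from_counts(n_sites: int, n_ts: int, n_tv: int) -> K2PModel:
    P = n_ts / n_sites
    Q = n_tv / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair: P={P:.4f}, Q={Q:.4f} leave no defined K2P distance"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # +0.0 kills -0.0
    return K2PModel(P=P, Q=Q, d=d, comparable_sites=n_sites)


def k2p_distance(seq_a: str, seq_b: str) -> K2PModel:
    """K2P distance between two aligned sequences (pairwise deletion).

    Raises :class:`SaturationError` when the distance is undefined and
    ``ValueError`` when no comparable sites remain or lengths differ.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    a = _encode(seq_a)
    b = _encode(seq_b)
    m = (a != CODE4_INVALID) & (b != CODE4_INVALID)
    n_sites = int(m.sum())
    if n_sites == 0:
        raise ValueError("no comparable sites between the two sequences")
    diff = m & (a != b)
    n_ts = int((diff & ((a >> 1) == (b >> 1))).sum())
    n_tv = int(diff.sum()) - n_ts
    return _k2p_from_counts(n_sites, n_ts, n_tv)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with per-pair comparable-site counts.

    Saturated pairs hold ``nan`` in ``values``; consumers must either
    exclude them (summaries do, with a logged count) or refuse to run
    (tree building does).
    """

    ids: list[str]
    values: np.ndarray
    comparable_sites: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_saturated_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def condensed(self) -> np.ndarray:
        """Upper-triangle values (i<j) in row-major order."""
        return self.values[np.triu_indices(self.n, k=1)]

    def submatrix(self, keep_ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep_ids]
        sel = np.ix_(idx, idx)
        return DistanceMatrix(
            list(keep_ids), self.values[sel].copy(), self.comparable_sites[sel].copy()
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _pairwise_from_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """K2P distances and site counts from a (n, L) code matrix.

    Vectorised row-against-later-rows; saturated pairs become nan.
    """
    n = codes.shape[0]
    valid = codes != CODE4_INVALID
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        a = codes[i]
        rest = codes[i + 1:]
        m = valid[i] & valid[i + 1:]
        ns = m.sum(axis=1)
        diff = m & (a != rest)
        ts = (diff & ((a >> 1) == (rest >> 1))).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = ts / ns
            Q = tv / ns
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            row = np.where(
                (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                np.nan,
            )
        row = np.where(ns == 0, np.nan, row) + 0.0  # +0.0 kills -0.0
        d[i, i + 1:] = row
        d[i + 1:, i] = row
        sites[i, i + 1:] = ns
        sites[i + 1:, i] = ns
    return d, sites


def pairwise_matrix(alignment: BarcodeAlignment) -> DistanceMatrix:
    """All-pairs K2P distance matrix for an alignment (>= 2 records)."""
    if alignment.n_records < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    d, sites = _pairwise_from_codes(alignment.codes4)
    dm = DistanceMatrix(list(alignment.ids), d, sites)
    if dm.n_saturated_pairs:
        logger.warning(
            "%d saturated pairs flagged (undefined K2P distance)",
            dm.n_saturated_pairs,
        )
    return dm


@dataclass
class DistanceSummary:
    """Mean/range/SD/SE of one distance level (intra- or interspecific)."""

    level: str
    n_pairs: int
    mean: Optional[float] = None
    minimum: Optional[float] = None
    maximum: Optional[float] = None
    sd: Optional[float] = None
    se: Optional[float] = None
    n_excluded_saturated: int = 0

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def _summarise(level: str, vals: np.ndarray) -> DistanceSummary:
    finite = vals[np.isfinite(vals)]
    n_excl = int(vals.size - finite.size)
    if n_excl:
        logger.warning(
            "%s summary excludes %d saturated pairs", level, n_excl
        )
    if finite.size == 0:
        return DistanceSummary(level, 0, n_excluded_saturated=n_excl)
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    return DistanceSummary(
        level=level,
        n_pairs=int(finite.size),
        mean=float(np.mean(finite)),
        minimum=float(np.min(finite)),
        maximum=float(np.max(finite)),
        sd=sd,
        se=sd / math.sqrt(finite.size),
        n_excluded_saturated=n_excl,
    )


def _level_mask(matrix: DistanceMatrix, taxonomy: TaxonomyMap) -> np.ndarray:
    species = np.array([taxonomy.species_of(i) for i in matrix.ids])
    return species[:, None] == species[None, :]


def distance_summaries(
    matrix: DistanceMatrix, taxonomy: TaxonomyMap
) -> tuple[DistanceSummary, DistanceSummary]:
    """(intraspecific, interspecific) summaries of a distance matrix."""
    same = _level_mask(matrix, taxonomy)
    iu = np.triu_indices(matrix.n, k=1)
    vals = matrix.values[iu]
    same_u = same[iu]
    intra = _summarise("intraspecific", vals[same_u])
    inter = _summarise("interspecific", vals[~same_u])
    return intra, inter


@dataclass(frozen=True)
class GapReport:
    positive: bool
    gap_range: Optional[tuple[float, float]]  # (max intra, min inter)


def barcoding_gap(intra: DistanceSummary, inter: DistanceSummary) -> GapReport:
    """Positive iff the largest intraspecific distance is below the
    smallest interspecific one."""
    if intra.empty or inter.empty:
        raise ValueError("cannot assess a barcoding gap from an empty summary")
    positive = intra.maximum < inter.minimum
    return GapReport(
        positive=positive,
        gap_range=(intra.maximum, inter.minimum) if positive else None,
    )


@dataclass
class GapHistogram:
    """Intra- and interspecific distance counts over shared bins."""

    bin_edges: np.ndarray
    intra_counts: np.ndarray
    inter_counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1].round(4),
                "bin_high": self.bin_edges[1:].round(4),
                "intraspecific": self.intra_counts,
                "interspecific": self.inter_counts,
            }
        )


def gap_histogram(
    matrix: DistanceMatrix, taxonomy: TaxonomyMap, n_bins: int = 20
) -> GapHistogram:
    """Histogram both distance levels over the pooled finite range."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    same = _level_mask(matrix, taxonomy)
    iu = np.triu_indices(matrix.n, k=1)
    vals = matrix.values[iu]
    same_u = same[iu]
    pooled = vals[np.isfinite(vals)]
    if pooled.size == 0:
        raise ValueError("no finite distances to histogram")
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    intra_vals = vals[same_u]
    inter_vals = vals[~same_u]
    intra_counts, _ = np.histogram(intra_vals[np.isfinite(intra_vals)], bins=edges)
    inter_counts, _ = np.histogram(inter_vals[np.isfinite(inter_vals)], bins=edges)
    return GapHistogram(edges, intra_counts, inter_counts)


def pair_table(matrix: DistanceMatrix, taxonomy: TaxonomyMap) -> pd.DataFrame:
    """Long-format per-pair table: ids, level, d, comparable sites."""
    same = _level_mask(matrix, taxonomy)
    rows = []
    for i in range(matrix.n - 1):
        for j in range(i + 1, matrix.n):
            rows.append(
                (
                    matrix.ids[i],
                    matrix.ids[j],
                    "intraspecific" if same[i, j] else "interspecific",
                    round(float(matrix.values[i, j]), 4)
                    if np.isfinite(matrix.values[i, j])
                    else float("nan"),
                    int(matrix.comparable_sites[i, j]),
                )
            )
    return pd.DataFrame(
        rows, columns=["pair_id1", "pair_id2", "level", "d", "comparable_sites"]
    )


def summary_table(intra: DistanceSummary, inter: DistanceSummary) -> pd.DataFrame:
    """Two-row summary table (Mean, Range, SD, SE per level)."""
    def row(s: DistanceSummary):
        if s.empty:
            return (s.level, s.n_pairs, None, None, None, None)
        return (
            s.level,
            s.n_pairs,
            round(s.mean, 4),
            f"{s.minimum:.4f}-{s.maximum:.4f}",
            round(s.sd, 4),
            s.se,
        )

    return pd.DataFrame(
        [row(intra), row(inter)],
        columns=["level", "n_pairs", "mean", "range", "sd", "se"],
    )
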