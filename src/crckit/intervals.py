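"""Genomic interval data model and overlap engine.

All coordinates are 0-based, half-open (BED dialect): an interval covers
bases ``start .. end-1``.  Inputs in 1-based conventions must be converted
at the reader boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneAnnotation",
    "overlap_bp",
    "intersect",
    "merge_components",
    "replicate_consensus",
    "filter_atac",
    "assign_nearest_gene",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosomal span with optional label, score and strand."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_bp(self, other) > 0


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus the caller's summit and pileup.

    ``summit_offset`` is measured in bp from ``interval.start``; ``pileup``
    is the peak caller's fragment-depth statistic (used for the ATAC
    pileup >= 40 retention filter).  Extra BED columns survive in
    ``extras``.
    """

    interval: GenomicInterval
    summit_offset: Optional[int] = None
    pileup: Optional[float] = None
    extras: tuple = ()

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )
        if self.pileup is not None and self.pileup < 0:
            raise ValueError("pileup must be non-negative")

    @property
    def center(self) -> int:
        """Summit position if known, else the interval midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: str = "+"
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Half-open overlap length; 0 for disjoint or different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _as_interval(x) -> GenomicInterval:
    return x.interval if isinstance(x, Peak) else x


def _group_by_chrom(items: Sequence) -> dict:
    out: dict = {}
    for idx, it in enumerate(items):
        out.setdefault(_as_interval(it).chrom, []).append((idx, it))
    return out


def intersect(set_a: Sequence, set_b: Sequence) -> list[tuple]:
    """All overlapping pairs (a, b, overlap_bp) under half-open semantics.

    Accepts GenomicInterval or Peak items.  Output is sorted by
    (chrom, a.start, a.end, b.start).
    """
    by_chrom_b = _group_by_chrom(set_b)
    pairs: list[tuple] = []
    for chrom, a_items in sorted(_group_by_chrom(set_a).items()):
        if chrom not in by_chrom_b:
            continue
        b_items = sorted(
            by_chrom_b[chrom], key=lambda t: (_as_interval(t[1]).start, t[0])
        )
        b_starts = np.array([_as_interval(b).start for _, b in b_items])
        b_ends = np.array([_as_interval(b).end for _, b in b_items])
        a_sorted = sorted(a_items, key=lambda t: (_as_interval(t[1]).start, t[0]))
        for _, a in a_sorted:
            ia = _as_interval(a)
            hi = int(np.searchsorted(b_starts, ia.end, side="left"))
            if hi == 0:
                continue
            mask = b_ends[:hi] > ia.start
            for j in np.nonzero(mask)[0]:
                b = b_items[int(j)][1]
                pairs.append((a, b, overlap_bp(ia, _as_interval(b))))
    return pairs


def merge_components(items: Sequence) -> list[list]:
    """Group items into connected components of the >=1 bp overlap graph.

    Returns components ordered by (chrom, span start); items within a
    component keep input order.  Linear sweep over start-sorted items with
    a running max end is exact for interval overlap graphs.
    """
    comps: list[list] = []
    for chrom, chrom_items in sorted(_group_by_chrom(items).items()):
        chrom_items.sort(key=lambda t: (_as_interval(t[1]).start, t[0]))
        cur: list = []
        cur_end = None
        for _, it in chrom_items:
            iv = _as_interval(it)
            if cur and iv.start < cur_end:
                cur.append(it)
                cur_end = max(cur_end, iv.end)
            else:
                if cur:
                    comps.append(cur)
                cur = [it]
                cur_end = iv.end
        if cur:
            comps.append(cur)
    return comps


def replicate_consensus(rep_a: Sequence, rep_b: Sequence) -> list[GenomicInterval]:
    """Merged consensus of two replicate peak sets.

    Every overlap-graph component containing at least one peak from each
    replicate yields one interval spanning the component union; peaks
    private to a single replicate are dropped (the merged-overlapping-peaks
    convention of HOMER mergePeaks).
    """
    tagged = [("A", p) for p in rep_a] + [("B", p) for p in rep_b]
    ivs = [
        replace(_as_interval(p), name=tag, score=None)
        for tag, p in tagged
    ]
    out = []
    for comp in merge_components(ivs):
        tags = {iv.name for iv in comp}
        if tags == {"A", "B"}:
            start = min(iv.start for iv in comp)
            end = max(iv.end for iv in comp)
            out.append(GenomicInterval(comp[0].chrom, start, end))
    return out


def filter_atac(peaks: Sequence[Peak], min_pileup: float = 40.0) -> list[Peak]:
    """Retain peaks with pileup >= min_pileup (order preserved)."""
    for p in peaks:
        if p.pileup is None:
            raise ValueError(
                f"peak {p.interval.chrom}:{p.interval.start}-{p.interval.end} "
                "has no pileup value"
            )
    return [p for p in peaks if p.pileup >= min_pileup]


def _distance_to_tss(iv: GenomicInterval, tss: int) -> int:
    return abs(iv.midpoint - tss)


def assign_nearest_gene(
    intervals: Sequence[GenomicInterval],
    annotation: Sequence[GeneAnnotation],
) -> dict[GenomicInterval, str]:
    """Map each interval to the gene whose TSS is nearest its midpoint.

    Ties break to the lexicographically smaller gene_id; chromosomes with
    no annotated gene map to the sentinel ``unassigned``.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: (g.tss, g.gene_id))
    out: dict[GenomicInterval, str] = {}
    for iv in intervals:
        genes = by_chrom.get(iv.chrom)
        if not genes:
            out[iv] = UNASSIGNED
            continue
        best = min(genes, key=lambda g: (_distance_to_tss(iv, g.tss), g.gene_id))
        out[iv] = best.gene_id
    return out
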