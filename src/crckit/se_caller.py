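"""ROSE-style super-enhancer identification.

Constituent H3K27ac peaks are stitched when separated by at most the stitch
distance (default 12.5 kb), quantified as background-subtracted H3K27ac
signal summed over constituent bases, ranked, and split into super-enhancers
(SEs) and typical enhancers (TEs) at the geometric "tangent slope 1" point
of the rank/signal curve rescaled to the unit square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coverage import Coverage
from .intervals import GeneAnnotation, GenomicInterval, Peak, merge_components

__all__ = [
    "StitchedEnhancer",
    "EnhancerRanking",
    "stitch",
    "quantify",
    "rank_and_cut",
    "assign_se_genes",
    "call_super_enhancers",
]

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_EXCLUSION_WINDOW = 2_500
DEFAULT_SE_GENE_WINDOW = 50_000


@dataclass
class StitchedEnhancer:
    span: GenomicInterval
    constituents: list[Peak]
    signal: float = 0.0
    rank: Optional[int] = None
    is_super: bool = False

    @property
    def enhancer_id(self) -> str:
        return f"{self.span.chrom}:{self.span.start}-{self.span.end}"

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass
class EnhancerRanking:
    """Stitched enhancers sorted by descending signal with the SE cutoff."""

    enhancers: list[StitchedEnhancer]
    cutoff_signal: float

    @property
    def n_super(self) -> int:
        return sum(e.is_super for e in self.enhancers)

    @property
    def supers(self) -> list[StitchedEnhancer]:
        return [e for e in self.enhancers if e.is_super]

    @property
    def typicals(self) -> list[StitchedEnhancer]:
        return [e for e in self.enhancers if not e.is_super]


def stitch(
    constituents: Sequence[Peak],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: Optional[tuple[Sequence[GeneAnnotation], int]] = None,
) -> list[StitchedEnhancer]:
    """Stitch constituent peaks into enhancers.

    Two constituents end up in the same stitched enhancer iff a chain of
    gaps each <= ``stitch_distance`` connects them (gap measured between
    half-open spans; overlapping peaks have gap <= 0).  With
    ``tss_exclusion=(annotation, window)`` constituents lying fully inside
    TSS +/- window are removed before stitching (ROSE's promoter exclusion;
    off by default, matching "default parameters").
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    peaks = list(constituents)
    if tss_exclusion is not None:
        annotation, window = tss_exclusion
        tss_by_chrom: dict[str, list[int]] = {}
        for g in annotation:
            tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        for v in tss_by_chrom.values():
            v.sort()
        kept = []
        for p in peaks:
            iv = p.interval
            tss_list = np.asarray(tss_by_chrom.get(iv.chrom, []))
            # fully inside [tss-window, tss+window] for some TSS
            if tss_list.size:
                lo = np.searchsorted(tss_list, iv.start - window, side="left")
                hi = np.searchsorted(tss_list, iv.end + window, side="right")
                inside = any(
                    t - window <= iv.start and iv.end <= t + window
                    for t in tss_list[lo:hi]
                )
                if inside:
                    continue
            kept.append(p)
        peaks = kept

    # widen each constituent by stitch_distance/2 on both sides: overlap of
    # widened spans == gap <= stitch_distance; merge_components then gives
    # exactly the chained-gap partition.
    half = stitch_distance / 2.0
    widened = []
    for idx, p in enumerate(peaks):
        iv = p.interval
        widened.append(
            GenomicInterval(
                iv.chrom,
                max(0, int(np.floor(iv.start - half))),
                int(np.ceil(iv.end + half)),
                name=str(idx),
            )
        )
    enhancers = []
    for comp in merge_components(widened):
        members = sorted(
            (peaks[int(iv.name)] for iv in comp),
            key=lambda p: (p.interval.start, p.interval.end),
        )
        span = GenomicInterval(
            members[0].interval.chrom,
            min(p.interval.start for p in members),
            max(p.interval.end for p in members),
        )
        enhancers.append(StitchedEnhancer(span=span, constituents=members))
    enhancers.sort(key=lambda e: (e.span.chrom, e.span.start))
    return enhancers


def _merged_constituent_spans(enh: StitchedEnhancer) -> list[GenomicInterval]:
    comps = merge_components([p.interval for p in enh.constituents])
    return [
        GenomicInterval(c[0].chrom, min(i.start for i in c), max(i.end for i in c))
        for c in comps
    ]


def quantify(
    enhancer: StitchedEnhancer,
    chip_cov: Coverage,
    control_cov: Optional[Coverage] = None,
    per_base_floor: bool = False,
) -> float:
    """Background-subtracted H3K27ac signal over constituent bases.

    signal = sum over (merged) constituent bases of (chip - control),
    floored at 0 over the enhancer sum (default) or per base
    (``per_base_floor``).  Without a control, the plain chip sum.
    """
    spans = _merged_constituent_spans(enhancer)
    for iv in spans:
        if not chip_cov.has_chrom(iv.chrom):
            raise KeyError(f"no chip coverage for chromosome {iv.chrom!r}")
    if control_cov is None:
        return float(sum(chip_cov.sum_over(iv) for iv in spans))
    if per_base_floor:
        total = 0.0
        for iv in spans:
            chip = chip_cov.values_array(iv.chrom, iv.start, iv.end)
            ctrl = control_cov.values_array(iv.chrom, iv.start, iv.end)
            total += float(np.maximum(chip - ctrl, 0.0).sum())
        return total
    total = sum(
        chip_cov.sum_over(iv) - control_cov.sum_over(iv) for iv in spans
    )
    return max(0.0, float(total))


def rank_and_cut(enhancers: Sequence[StitchedEnhancer]) -> EnhancerRanking:
    """Rank enhancers by signal and place the SE cutoff.

    Enhancers are sorted ascending by signal; the rank index and the signal
    are each rescaled to [0, 1].  Scanning from the low-signal end, the
    cutoff is the signal at the lower endpoint of the first segment whose
    discrete slope reaches 1 (the tangent-slope-1 point of the
    hockey-stick curve); enhancers with signal strictly above the cutoff
    are super-enhancers.  A flat curve (all signals equal) yields zero SEs.
    """
    if len(enhancers) < 2:
        raise ValueError("ranking needs at least 2 stitched enhancers")
    asc = sorted(
        enhancers, key=lambda e: (e.signal, e.span.chrom, e.span.start)
    )
    signals = np.array([e.signal for e in asc], dtype=float)
    n = len(asc)
    smin, smax = signals[0], signals[-1]
    if smax == smin:
        cutoff = float(smax)
    else:
        y = (signals - smin) / (smax - smin)
        slopes = np.diff(y) * (n - 1)
        crossing = np.nonzero(slopes >= 1.0)[0]
        # total rescaled rise is 1 over n-1 segments, so a crossing exists
        # whenever the curve is not flat
        cutoff = float(signals[crossing[0]])
    ranked = sorted(
        asc, key=lambda e: (-e.signal, e.span.chrom, e.span.start)
    )
    for i, e in enumerate(ranked):
        e.rank = i + 1
        e.is_super = e.signal > cutoff
    return EnhancerRanking(enhancers=ranked, cutoff_signal=cutoff)


def assign_se_genes(
    ranking: EnhancerRanking,
    annotation: Sequence[GeneAnnotation],
    window: int = DEFAULT_SE_GENE_WINDOW,
    include_typical: bool = False,
) -> dict[str, list[GeneAnnotation]]:
    """Map each SE to the genes whose TSS lies within span +/- window.

    SEs with no gene in the window fall back to the single nearest gene on
    the chromosome.  Returns {enhancer_id: [GeneAnnotation, ...]} with genes
    sorted by distance then gene_id.  ``include_typical`` extends the map to
    typical enhancers (used for transition bookkeeping, not CRC building).
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)

    def span_distance(iv: GenomicInterval, tss: int) -> int:
        if iv.start <= tss < iv.end:
            return 0
        return tss - iv.end + 1 if tss >= iv.end else iv.start - tss

    out: dict[str, list[GeneAnnotation]] = {}
    pool = ranking.enhancers if include_typical else ranking.supers
    for enh in pool:
        genes = by_chrom.get(enh.span.chrom, [])
        hits = [
            g for g in genes if span_distance(enh.span, g.tss) <= window
        ]
        if not hits and genes:
            hits = [
                min(genes, key=lambda g: (span_distance(enh.span, g.tss), g.gene_id))
            ]
        hits.sort(key=lambda g: (span_distance(enh.span, g.tss), g.gene_id))
        out[enh.enhancer_id] = hits
    return out


def call_super_enhancers(
    constituents: Sequence[Peak],
    chip_cov: Coverage,
    control_cov: Optional[Coverage] = None,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: Optional[tuple[Sequence[GeneAnnotation], int]] = None,
) -> EnhancerRanking:
    """Stitch, quantify and rank in one call."""
    enhancers = stitch(constituents, stitch_distance, tss_exclusion)
    for e in enhancers:
        e.signal = quantify(e, chip_cov, control_cov)
    return rank_and_cut(enhancers)
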