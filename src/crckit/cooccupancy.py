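"""Multi-TF co-occupancy: region-level Venn classes, SE co-binding, hotspots.

Overlap classes are computed on merged connected components of the pooled
peak union (the published counting follows replicate-consensus merged
regions); a per-peak counting mode is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    Peak,
    assign_nearest_gene,
    merge_components,
    overlap_bp,
)

__all__ = ["OccupancyClass", "venn", "se_cobinding", "hotspots", "Hotspot"]


@dataclass
class OccupancyClass:
    membership: frozenset[str]
    regions: list[GenomicInterval]

    @property
    def count(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class Hotspot:
    region: GenomicInterval
    membership: frozenset[str]
    gene_id: str = ""


def _components(peaksets: Mapping[str, Sequence]) -> list[tuple[GenomicInterval, frozenset[str], int]]:
    tagged: list[GenomicInterval] = []
    for name, peaks in peaksets.items():
        for p in peaks:
            iv = p.interval if isinstance(p, Peak) else p
            tagged.append(
                GenomicInterval(iv.chrom, iv.start, iv.end, name=name)
            )
    out = []
    for comp in merge_components(tagged):
        span = GenomicInterval(
            comp[0].chrom,
            min(iv.start for iv in comp),
            max(iv.end for iv in comp),
        )
        out.append((span, frozenset(iv.name for iv in comp), len(comp)))
    return out


def _check_names(peaksets) -> dict:
    if not isinstance(peaksets, Mapping):
        items = list(peaksets)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate peak set names in {names}")
        peaksets = dict(items)
    if len(peaksets) < 2:
        raise ValueError("need at least 2 named peak sets")
    return dict(peaksets)


def venn(peaksets, per_peak: bool = False) -> list[OccupancyClass]:
    """Overlap classes of the pooled peak union.

    Each merged component (>= 1 bp chaining) is classified by the set of
    TFs contributing at least one peak.  Classes partition the merged
    union; with ``per_peak`` the class counts weight each component by its
    number of contributing peaks instead of 1 (both reported via
    ``regions``/``count`` and the returned class list order is
    (size desc, alphabetical membership)).
    """
    peaksets = _check_names(peaksets)
    classes: dict[frozenset[str], list[GenomicInterval]] = {}
    for span, membership, n_peaks in _components(peaksets):
        bucket = classes.setdefault(membership, [])
        if per_peak:
            bucket.extend([span] * n_peaks)
        else:
            bucket.append(span)
    out = [OccupancyClass(m, r) for m, r in classes.items()]
    out.sort(key=lambda c: (-len(c.membership), tuple(sorted(c.membership))))
    return out


def se_cobinding(
    ses: Sequence,
    tf_peaksets,
) -> tuple[dict[str, frozenset[str]], dict[str, float]]:
    """Per-SE bound-TF sets and summary co-binding fractions.

    A TF binds an SE iff >= 1 of its peaks overlaps the SE span.  Returns
    ({se_id: bound TFs}, {"ge1": ..., "ge2": ..., "all": ...}) with
    fractions over all SEs.
    """
    tf_peaksets = _check_names(tf_peaksets)
    ses = list(ses)
    if not ses:
        raise ValueError("empty SE list")
    spans = []
    for se in ses:
        span = se.span if hasattr(se, "span") else se
        name = getattr(se, "enhancer_id", None) or span.name or (
            f"{span.chrom}:{span.start}-{span.end}"
        )
        spans.append((name, span))
    by_tf_chrom: dict[str, dict[str, list[GenomicInterval]]] = {}
    for tf, peaks in tf_peaksets.items():
        d: dict[str, list[GenomicInterval]] = {}
        for p in peaks:
            iv = p.interval if isinstance(p, Peak) else p
            d.setdefault(iv.chrom, []).append(iv)
        by_tf_chrom[tf] = d
    bound: dict[str, frozenset[str]] = {}
    for name, span in spans:
        tfs = set()
        for tf, per_chrom in by_tf_chrom.items():
            if any(overlap_bp(span, iv) > 0 for iv in per_chrom.get(span.chrom, ())):
                tfs.add(tf)
        bound[name] = frozenset(tfs)
    n = len(spans)
    n_sets = len(tf_peaksets)
    fractions = {
        "ge1": sum(len(v) >= 1 for v in bound.values()) / n,
        "ge2": sum(len(v) >= 2 for v in bound.values()) / n,
        "all": sum(len(v) == n_sets for v in bound.values()) / n,
    }
    return bound, fractions


def hotspots(
    peaksets,
    k_min: Optional[int] = None,
    annotation: Optional[Sequence[GeneAnnotation]] = None,
) -> list[Hotspot]:
    """Regions co-occupied by >= k_min TFs (default: all), gene-assigned."""
    peaksets = _check_names(peaksets)
    if k_min is None:
        k_min = len(peaksets)
    if k_min > len(peaksets):
        raise ValueError(
            f"k_min={k_min} exceeds the number of peak sets ({len(peaksets)})"
        )
    comps = [
        (span, membership)
        for span, membership, _ in _components(peaksets)
        if len(membership) >= k_min
    ]
    genes: dict[GenomicInterval, str] = {}
    if annotation is not None:
        genes = assign_nearest_gene([s for s, _ in comps], annotation)
    return [
        Hotspot(region=span, membership=m, gene_id=genes.get(span, ""))
        for span, m in comps
    ]
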