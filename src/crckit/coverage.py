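"""Stepwise genomic coverage (bedGraph model).

Coverage is piecewise-constant over non-overlapping, start-sorted segments
per chromosome; bases not covered by any segment have value 0.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np

from .intervals import GenomicInterval

__all__ = ["Coverage"]


class Coverage:
    """Per-chromosome stepwise coverage with interval aggregation."""

    def __init__(self, segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._seg: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping coverage segments on {chrom}")
            if np.any(ends <= starts):
                raise ValueError(f"empty coverage segment on {chrom}")
            self._seg[chrom] = (starts, ends, values)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "Coverage":
        per: dict[str, list] = {}
        for chrom, start, end, value in records:
            per.setdefault(chrom, []).append((start, end, value))
        seg = {}
        for chrom, rows in per.items():
            rows.sort()
            seg[chrom] = (
                np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]),
            )
        return cls(seg)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._seg)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._seg

    def sum_over(self, iv: GenomicInterval) -> float:
        """Sum of per-base coverage over the interval (value x bp)."""
        if iv.chrom not in self._seg:
            raise KeyError(f"no coverage for chromosome {iv.chrom!r}")
        starts, ends, values = self._seg[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], iv.start)
        e = np.minimum(ends[lo:hi], iv.end)
        w = np.maximum(e - s, 0)
        return float(np.dot(w, values[lo:hi]))

    def mean_over(self, iv: GenomicInterval) -> float:
        return self.sum_over(iv) / iv.length

    def values_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are 0."""
        if chrom not in self._seg:
            raise KeyError(f"no coverage for chromosome {chrom!r}")
        out = np.zeros(end - start, dtype=float)
        starts, ends, values = self._seg[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if e > s:
                out[s - start : e - start] = values[i]
        return out

    def scaled(self, factor: float, regions: Optional[list[GenomicInterval]] = None) -> "Coverage":
        """A copy with values multiplied by ``factor``.

        With ``regions``, only segments fully or partly inside a region are
        rescaled (segments are split at region boundaries).
        """
        if regions is None:
            return Coverage(
                {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self._seg.items()}
            )
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        records: list[tuple[str, int, int, float]] = []
        for chrom, (starts, ends, values) in self._seg.items():
            spans = sorted(by_chrom.get(chrom, []))
            for s, e, v in zip(starts, ends, values):
                s, e = int(s), int(e)
                pieces = [(s, e, float(v))]
                for rs, re_ in spans:
                    nxt = []
                    for ps, pe, pv in pieces:
                        if pe <= rs or ps >= re_ or pv != float(v):
                            nxt.append((ps, pe, pv))
                            continue
                        if ps < rs:
                            nxt.append((ps, rs, pv))
                        nxt.append((max(ps, rs), min(pe, re_), pv * factor))
                        if pe > re_:
                            nxt.append((re_, pe, pv))
                    pieces = nxt
                records.extend((chrom, ps, pe, pv) for ps, pe, pv in pieces)
        return Coverage.from_records(records)

    def iter_records(self):
        for chrom in self.chroms:
            starts, ends, values = self._seg[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)
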