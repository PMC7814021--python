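"""PWM representation, strand-aware log-odds scanning, exact score p-values.

Scores are log-odds in bits: sum_i log2(P_i(base_i) / bg(base_i)).  Tail
probabilities P(score >= s) under the background model are computed exactly
by dynamic programming over the per-position score distribution discretised
to an integer grid (default granularity 1e-4 bits).  Scanning uses the same
integer grid, so reported hit p-values are exactly consistent with the DP
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, Peak
from .sequences import BASES, SequenceSource, seq_to_indices

__all__ = [
    "PWM",
    "MotifHit",
    "read_meme",
    "write_meme",
    "logodds",
    "score_pvalue",
    "scan",
    "make_windows",
    "WINDOW_HALF_WIDTHS",
]

UNIFORM_BG = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 1e-3
DEFAULT_GRANULARITY = 1e-4
DEFAULT_P_THRESHOLD = 1e-4

# half-widths of the fixed scanning windows around peak centers
WINDOW_HALF_WIDTHS = {"se_te": 1000, "tf_peak": 100, "atac": 50}


@dataclass(frozen=True)
class PWM:
    """Base-probability matrix over {A,C,G,T} with a TF name.

    ``probs`` rows are positions; a pseudocount is added and rows are
    renormalised at construction.
    """

    name: str
    probs: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be a width x 4 matrix")
        if p.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        p = p + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def reverse_complement(self) -> "PWM":
        rc = self.probs[::-1, ::-1].copy()
        return PWM(name=self.name, probs=rc, pseudocount=0.0)

    def logodds_matrix(self, background: Optional[np.ndarray] = None) -> np.ndarray:
        """width x 5 log2-odds matrix; column 4 is the ambiguous-base (N)
        contribution, the background-weighted mean of the four scores."""
        bg = UNIFORM_BG if background is None else np.asarray(background, float)
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        lo = np.log2(self.probs / bg)
        mean_col = (lo * bg).sum(axis=1, keepdims=True)
        return np.hstack([lo, mean_col])


@dataclass(frozen=True)
class MotifHit:
    region: GenomicInterval
    pwm_name: str
    offset: int
    strand: str
    score: float
    pvalue: float

    @property
    def genomic_start(self) -> int:
        return self.region.start + self.offset


def logodds(
    pwm: PWM, word: str, background: Optional[np.ndarray] = None
) -> float:
    """Log2-odds score of a word of length = PWM width.

    N scores the background-weighted mean at its position (0 under a
    background-matched uniform column).
    """
    if len(word) != pwm.width:
        raise ValueError(
            f"word length {len(word)} != PWM width {pwm.width}"
        )
    bad = set(word.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in word: {sorted(bad)}")
    lo = pwm.logodds_matrix(background)
    idx = seq_to_indices(word)
    return float(lo[np.arange(pwm.width), idx].sum())


class _ScoreDistribution:
    """Exact integer-grid distribution of PWM scores under the background."""

    def __init__(self, pwm: PWM, background: Optional[np.ndarray], granularity: float):
        bg = UNIFORM_BG if background is None else np.asarray(background, float)
        lo = pwm.logodds_matrix(bg)[:, :4]
        self.granularity = granularity
        self.int_scores = np.rint(lo / granularity).astype(np.int64)
        offset = 0
        probs = np.array([1.0])
        lo_int = self.int_scores.min(axis=1)
        hi_int = self.int_scores.max(axis=1)
        self.min_total = int(lo_int.sum())
        size = int((hi_int - lo_int).sum()) + 1
        dist = np.zeros(size)
        dist[0] = 1.0
        pos_min = 0
        for i in range(pwm.width):
            new = np.zeros(size)
            for b in range(4):
                shift = int(self.int_scores[i, b] - lo_int[i])
                if bg[b] > 0:
                    new[shift:] += dist[: size - shift if shift else size] * bg[b]
            dist = new
        self.probs = dist
        # survival[k] = P(total int score >= min_total + k)
        self.survival = np.concatenate(
            [np.cumsum(dist[::-1])[::-1], [0.0]]
        )

    def tail(self, int_score: int) -> float:
        k = int_score - self.min_total
        if k <= 0:
            return 1.0
        if k >= len(self.probs):
            return 0.0
        return float(min(1.0, self.survival[k]))

    def threshold_for_pvalue(self, p: float) -> int:
        """Smallest integer score whose tail probability is <= p."""
        k = int(np.searchsorted(-self.survival[: len(self.probs) + 1], -p,
                                side="left"))
        return self.min_total + k


_DIST_CACHE: dict = {}


def _distribution(
    pwm: PWM, background: Optional[np.ndarray], granularity: float
) -> _ScoreDistribution:
    bg = UNIFORM_BG if background is None else np.asarray(background, float)
    key = (pwm.name, pwm.probs.tobytes(), bg.tobytes(), granularity)
    if key not in _DIST_CACHE:
        _DIST_CACHE[key] = _ScoreDistribution(pwm, bg, granularity)
    return _DIST_CACHE[key]


def score_pvalue(
    pwm: PWM,
    score: float,
    background: Optional[np.ndarray] = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> float:
    """Exact P(random background word scores >= score), no sampling."""
    dist = _distribution(pwm, background, granularity)
    return dist.tail(int(np.rint(score / granularity)))


def _dedupe_overlapping(hits: list[tuple[int, int]], width: int) -> list[tuple[int, int]]:
    """Keep the best-scoring offset per chain of mutually overlapping hits.

    ``hits`` are (offset, int_score) sorted by offset; ties break to the
    leftmost offset.
    """
    out = []
    cluster: list[tuple[int, int]] = []
    cluster_end = -1
    for off, sc in hits:
        if cluster and off < cluster_end:
            cluster.append((off, sc))
            cluster_end = max(cluster_end, off + width)
        else:
            if cluster:
                out.append(max(cluster, key=lambda t: (t[1], -t[0])))
            cluster = [(off, sc)]
            cluster_end = off + width
    if cluster:
        out.append(max(cluster, key=lambda t: (t[1], -t[0])))
    return out


def scan(
    regions: Sequence[GenomicInterval],
    genome: SequenceSource,
    pwms: Sequence[PWM],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    background: Optional[np.ndarray] = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Scan regions on both strands for PWM hits with p-value <= threshold.

    The reverse strand scores the reverse complement of each window.
    Overlapping hits of the same PWM on the same strand are deduplicated to
    the best-scoring offset.  Regions extending beyond chromosome bounds
    raise an error (``SequenceSource.fetch`` contract).
    """
    hits: list[MotifHit] = []
    for pwm in pwms:
        dist = _distribution(pwm, background, granularity)
        thr = dist.threshold_for_pvalue(p_threshold)
        mats = {
            "+": np.hstack([
                dist.int_scores,
                np.rint(
                    pwm.logodds_matrix(background)[:, 4:5] / granularity
                ).astype(np.int64),
            ]),
        }
        rc = pwm.reverse_complement()
        rc_int = np.rint(
            rc.logodds_matrix(background)[:, :4] / granularity
        ).astype(np.int64)
        rc_n = np.rint(
            rc.logodds_matrix(background)[:, 4:5] / granularity
        ).astype(np.int64)
        mats["-"] = np.hstack([rc_int, rc_n])
        w = pwm.width
        for region in regions:
            seq = genome.fetch(region.chrom, region.start, region.end)
            if len(seq) < w:
                continue
            idx = seq_to_indices(seq)
            n_off = len(seq) - w + 1
            for strand, mat in mats.items():
                # mat rows: + strand scores forward window directly; - strand
                # matrix scores the reverse complement of the forward window
                scores = np.zeros(n_off, dtype=np.int64)
                for i in range(w):
                    scores += mat[i, idx[i : i + n_off]]
                above = np.nonzero(scores >= thr)[0]
                kept = _dedupe_overlapping(
                    [(int(o), int(scores[o])) for o in above], w
                )
                for off, sc in kept:
                    hits.append(
                        MotifHit(
                            region=region,
                            pwm_name=pwm.name,
                            offset=off,
                            strand=strand,
                            score=sc * granularity,
                            pvalue=dist.tail(sc),
                        )
                    )
    hits.sort(
        key=lambda h: (
            h.region.chrom,
            h.region.start,
            h.pwm_name,
            h.offset,
            h.strand,
        )
    )
    return hits


def make_windows(
    peaks: Sequence[Peak],
    mode: str,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[GenomicInterval]:
    """Fixed windows around peak centers: +/-1000 (se_te), +/-100 (tf_peak)
    or +/-50 bp (atac); width 2001/201/101 before clipping to chromosome
    bounds.  The center is the summit when present, else the midpoint.
    """
    if mode not in WINDOW_HALF_WIDTHS:
        raise ValueError(
            f"unknown window mode {mode!r}; expected one of "
            f"{sorted(WINDOW_HALF_WIDTHS)}"
        )
    half = WINDOW_HALF_WIDTHS[mode]
    out = []
    for p in peaks:
        c = p.center
        start = max(0, c - half)
        end = c + half + 1
        if chrom_sizes is not None and p.interval.chrom in chrom_sizes:
            end = min(end, chrom_sizes[p.interval.chrom])
        out.append(
            GenomicInterval(p.interval.chrom, start, end, name=p.interval.name)
        )
    return out


def read_meme(path) -> list[PWM]:
    """Read PWMs from MEME motif text (minimal format)."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    expecting = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                parts = line.split()
                name = parts[1] if len(parts) > 1 else "motif"
                rows = []
                expecting = 0
            elif line.startswith("letter-probability matrix"):
                tokens = line.replace("=", " = ").split()
                expecting = -1
                if "w" in tokens:
                    expecting = int(tokens[tokens.index("w") + 2])
            elif name is not None and expecting != 0 and line:
                vals = [float(t) for t in line.split()]
                if len(vals) == 4:
                    rows.append(vals)
                    if expecting > 0 and len(rows) == expecting:
                        pwms.append(PWM(name=name, probs=np.array(rows)))
                        name, rows, expecting = None, [], 0
            elif name is not None and expecting == -1 and not line and rows:
                pwms.append(PWM(name=name, probs=np.array(rows)))
                name, rows, expecting = None, [], 0
    if name is not None and rows:
        pwms.append(PWM(name=name, probs=np.array(rows)))
    return pwms


def write_meme(path, pwms: Sequence[PWM]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
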