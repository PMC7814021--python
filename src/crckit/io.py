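"""Readers and writers for the tab-delimited formats the pipeline consumes.

BED records are 0-based half-open; columns 4 and 5 map to name and score,
extra columns are preserved verbatim.  All writers emit LF-terminated,
headerless, tab-delimited text (BED family) or headered TSV (tables).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .coverage import Coverage
from .intervals import GeneAnnotation, GenomicInterval, Peak

__all__ = [
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_annotation",
    "write_annotation",
    "read_expression",
    "read_counts",
    "read_design",
]


class BedParseError(ValueError):
    pass


def _parse_score(token: str, path, lineno: int) -> Optional[float]:
    if token in (".", ""):
        return None
    try:
        return float(token)
    except ValueError:
        raise BedParseError(f"{path}:{lineno}: non-numeric score {token!r}")


def read_bed(
    path,
    pileup_from_score: bool = False,
    summit_from_extra: bool = False,
) -> list[Peak]:
    """Read a BED3+ file into Peaks, in file order.

    With ``pileup_from_score`` the score column is interpreted as the peak
    caller's pileup statistic.  With ``summit_from_extra`` the first extra
    column (column 6 in a BED5+ file written by :func:`write_bed`) is read
    as a summit offset from the interval start.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                )
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 else ""
            score = _parse_score(fields[4], path, lineno) if len(fields) > 4 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            extras = tuple(fields[5:])
            iv = GenomicInterval(chrom, start, end, name=name, score=score,
                                 strand=strand)
            summit = None
            if summit_from_extra and extras:
                try:
                    summit = int(extras[0])
                except ValueError:
                    raise BedParseError(
                        f"{path}:{lineno}: non-integer summit {extras[0]!r}"
                    )
            peaks.append(
                Peak(
                    interval=iv,
                    summit_offset=summit,
                    pileup=score if pileup_from_score else None,
                    extras=extras,
                )
            )
    return peaks


def write_bed(path, items: Iterable, score_fmt: str = "%g") -> None:
    """Write intervals/peaks as headerless BED (name, score, extras kept)."""
    with open(path, "w") as fh:
        for it in items:
            iv = it.interval if isinstance(it, Peak) else it
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            extras = it.extras if isinstance(it, Peak) else ()
            score = iv.score
            if isinstance(it, Peak) and it.pileup is not None and score is None:
                score = it.pileup
            if iv.name or score is not None or extras:
                cols.append(iv.name or ".")
            if score is not None or extras:
                cols.append(score_fmt % score if score is not None else ".")
            cols.extend(extras)
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path) -> Coverage:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(
                    f"{path}:{lineno}: bedGraph needs 4 columns"
                )
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: malformed bedGraph record")
    return Coverage.from_records(records)


def write_bedgraph(path, cov: Coverage, value_fmt: str = "%.4f") -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in cov.iter_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value_fmt % value}\n")


_ANNOT_COLS = ["gene_id", "symbol", "chrom", "tss", "strand", "is_tf"]


def read_annotation(path) -> list[GeneAnnotation]:
    """Gene annotation TSV: gene_id, symbol, chrom, tss, strand, is_tf."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    if df["symbol"].duplicated().any():
        dups = df.loc[df["symbol"].duplicated(), "symbol"].tolist()
        raise ValueError(f"{path}: duplicate gene symbols {dups[:5]}")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            symbol=str(r.symbol),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=str(r.strand),
            is_tf=bool(r.is_tf),
        )
        for r in df.itertuples()
    ]


def write_annotation(path, annotation: Sequence[GeneAnnotation]) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.symbol, g.chrom, g.tss, g.strand, int(g.is_tf))
            for g in annotation
        ],
        columns=_ANNOT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.Series:
    """Gene-level TPM table (columns: symbol, tpm) -> Series keyed by symbol."""
    df = pd.read_csv(path, sep="\t")
    if not {"symbol", "tpm"} <= set(df.columns):
        raise ValueError(f"{path}: expression table needs columns symbol, tpm")
    return df.set_index("symbol")["tpm"].astype(float)


def read_counts(path) -> pd.DataFrame:
    """Region x sample count matrix; first column is the region id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValueError(f"{path}: counts must be non-negative")
    return df


def read_design(path) -> pd.DataFrame:
    """Sample sheet TSV with columns sample, condition[, replicate]."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "condition"} <= set(df.columns):
        raise ValueError(f"{path}: design needs columns sample, condition")
    return df
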