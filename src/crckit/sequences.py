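"""Genome sequence access: FASTA-backed or in-memory."""

from __future__ import annotations

from typing import Mapping, Protocol

import numpy as np

__all__ = [
    "SequenceSource",
    "InMemoryGenome",
    "FastaGenome",
    "revcomp",
    "seq_to_indices",
    "BASES",
]

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

# A=0 C=1 G=2 T=3, anything else (incl. N) = 4
_IDX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _IDX[ord(_b)] = _i
    _IDX[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3, N/other=4."""
    return _IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class SequenceSource(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> str: ...

    def chrom_size(self, chrom: str) -> int: ...


class InMemoryGenome:
    """Genome held as uppercase strings per chromosome."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    @property
    def chroms(self) -> list[str]:
        return sorted(self._seqs)

    def chrom_size(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(
                f"region {chrom}:{start}-{end} outside chromosome of size {len(seq)}"
            )
        return seq[start:end]

    def write_fasta(self, path, line_width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f">{chrom}\n")
                seq = self._seqs[chrom]
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


class FastaGenome:
    """pyfaidx-backed FASTA access with the same fetch interface."""

    def __init__(self, path):
        from pyfaidx import Fasta

        self._fa = Fasta(str(path), sequence_always_upper=True)

    def chrom_size(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > len(self._fa[chrom]):
            raise ValueError(
                f"region {chrom}:{start}-{end} outside chromosome of size "
                f"{len(self._fa[chrom])}"
            )
        return str(self._fa[chrom][start:end])
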