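"""Reference-genome access.

A single tiny abstraction so the rest of the package can take either an
indexed FASTA on disk (via pyfaidx) or an in-memory dict of chromosome
sequences (used heavily by the simulator and the tests).
"""

from __future__ import annotations

import os
from typing import Mapping


class ReferenceGenome:
    """1-based, inclusive-coordinate view of a reference genome."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def contigs(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive.

        Coordinates are clipped to the chromosome bounds.
        """
        seq = self._seqs[chrom]
        lo = max(start, 1)
        hi = min(end, len(seq))
        if hi < lo:
            return ""
        return seq[lo - 1 : hi]

    def base(self, chrom: str, pos: int) -> str:
        b = self.fetch(chrom, pos, pos)
        if not b:
            raise IndexError(f"position {chrom}:{pos} outside reference")
        return b

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
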