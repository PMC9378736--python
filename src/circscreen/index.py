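"""Exact-match k-mer index over named sequences.

Stands in for an external aligner: ``lookup`` returns every perfect-match
placement of a k-mer on both strands of the indexed references.  Positions
are 0-based on the forward strand (leftmost base of the match).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import ParameterError
from .seqtools import revcomp, seq_to_array


class Placement(NamedTuple):
    ref: str
    pos: int
    strand: str


class KmerIndex:
    """Hash index of all forward k-mers of a set of reference sequences."""

    def __init__(self, refs: dict[str, str], k: int = 20):
        if any(len(s) < k for s in refs.values()):
            raise ParameterError(f"k={k} exceeds the length of a reference sequence")
        self.k = k
        self.refs = dict(refs)
        self.arrays = {name: seq_to_array(seq) for name, seq in refs.items()}
        table: dict[bytes, list[tuple[str, int]]] = {}
        for name, seq in refs.items():
            b = seq.encode("ascii")
            for i in range(len(b) - k + 1):
                table.setdefault(b[i:i + k], []).append((name, i))
        self._table = table

    def lookup(self, kmer: str) -> list[Placement]:
        """All perfect placements of ``kmer`` on either strand."""
        if len(kmer) != self.k:
            raise ParameterError(f"query length {len(kmer)} != k={self.k}")
        out = [Placement(r, p, "+") for r, p in self._table.get(kmer.encode("ascii"), ())]
        rc = revcomp(kmer)
        out += [Placement(r, p, "-") for r, p in self._table.get(rc.encode("ascii"), ())]
        return out

    def seed_positions(self, read: str, n_seeds: int) -> list[tuple[int, list[tuple[str, int]]]]:
        """Forward-strand hits for ``n_seeds`` spread non-overlapping k-mers."""
        n = len(read)
        offs = np.linspace(0, n - self.k, n_seeds).astype(int)
        b = read.encode("ascii")
        return [(int(o), self._table.get(b[o:o + self.k], []))
                for o in offs]
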