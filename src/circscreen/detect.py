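"""Anchor-based backsplice junction detection.

The procedure mirrors the classical split-anchor approach: reads that fail
to align contiguously to any linear reference are split into terminal
20-mers; anchor pairs that place uniquely on the same chromosome and
strand in reversed genomic order (head-to-tail) nominate a backsplice,
whose exact breakpoint is found by sliding the split point until the whole
read aligns as circle-suffix + circle-prefix with the genomic donor flank
GT and acceptor flank AG on the template strand.  A candidate circRNA
requires at least two unique (distinct-sequence) back-spliced reads in at
least one sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .index import KmerIndex, Placement
from .seqtools import revcomp, seq_to_array

log = logging.getLogger(__name__)

DEFAULT_K = 20
DEFAULT_MISMATCH = 2
DEFAULT_SPAN_CAP = 100_000

# (upstream-of-acceptor, downstream-of-donor) flank dinucleotides on the
# forward genome strand, per detection strand.
_FLANKS = {"+": ("AG", "GT"), "-": ("AC", "CT")}


@dataclass(frozen=True)
class AnchorPair:
    """Terminal k-mers of an unmapped read with their genomic placements."""

    read_id: str
    left: str
    right: str
    left_placements: tuple[Placement, ...]
    right_placements: tuple[Placement, ...]

    def _status(self, placements) -> str:
        return "unplaced" if not placements else ("unique" if len(placements) == 1 else "ambiguous")

    @property
    def left_status(self) -> str:
        return self._status(self.left_placements)

    @property
    def right_status(self) -> str:
        return self._status(self.right_placements)


class ProvisionalJunction(NamedTuple):
    chrom: str
    strand: str
    left_pos: int   # placement of the read's left anchor
    right_pos: int  # placement of the read's right anchor


@dataclass(frozen=True)
class BacksplicedJunction:
    """A resolved backsplice: 0-based [acceptor_pos, donor_pos) circle span."""

    chrom: str
    strand: str
    acceptor_pos: int
    donor_pos: int
    flanks: tuple[str, str] = ("AG", "GT")

    def __post_init__(self) -> None:
        if self.acceptor_pos >= self.donor_pos:
            raise ParameterError("acceptor_pos must be < donor_pos")

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.acceptor_pos, self.donor_pos)


@dataclass
class CircCandidate:
    """A called circRNA with per-sample unique-read support."""

    junction: BacksplicedJunction
    support: dict[str, int]                 # sample -> distinct junction-read count
    read_ids: list[str] = field(default_factory=list)
    known: bool | None = None

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


# ----------------------------------------------------------------- stages

def build_index(genome_seqs: dict[str, str], k: int = DEFAULT_K) -> KmerIndex:
    """Exact-match anchor index over the genome (both strands on lookup)."""
    return KmerIndex(genome_seqs, k=k)


@dataclass
class PartitionResult:
    mapped_count: int
    unmapped: list[tuple[str, str]]

    @property
    def total(self) -> int:
        return self.mapped_count + len(self.unmapped)


def partition_linear(reads, ref_index: KmerIndex, m: int = DEFAULT_MISMATCH) -> PartitionResult:
    """Split reads into linearly mapped vs unmapped.

    A read is mapped iff it (or its reverse complement) matches some
    linear reference contiguously end-to-end with at most ``m``
    substitutions.  ``m+1`` spread seeds guarantee (pigeonhole) that any
    qualifying placement is found.  The mapped count per sample is the RPM
    denominator downstream.
    """
    k = ref_index.k
    n_seeds = m + 1
    mapped = 0
    unmapped: list[tuple[str, str]] = []
    for name, seq in reads:
        if _maps_linearly(seq, ref_index, m, n_seeds, k):
            mapped += 1
        else:
            unmapped.append((name, seq))
    return PartitionResult(mapped, unmapped)


def _maps_linearly(seq: str, ref_index: KmerIndex, m: int, n_seeds: int, k: int) -> bool:
    n = len(seq)
    if n < 2 * k:
        return False
    for query in (seq, revcomp(seq)):
        arr = seq_to_array(query)
        tried: set[tuple[str, int]] = set()
        for off, hits in ref_index.seed_positions(query, n_seeds):
            for ref, pos in hits:
                start = pos - off
                key = (ref, start)
                if key in tried or start < 0:
                    continue
                tried.add(key)
                ref_arr = ref_index.arrays[ref]
                if start + n > ref_arr.size:
                    continue
                if int(np.count_nonzero(ref_arr[start:start + n] != arr)) <= m:
                    return True
    return False


def extract_anchors(read_id: str, seq: str, genome_index: KmerIndex) -> AnchorPair | None:
    """Terminal k-mers of an unmapped read; None (logged) for short reads."""
    k = genome_index.k
    if len(seq) < 2 * k:
        log.info("read %s shorter than 2k=%d nt: skipped", read_id, 2 * k)
        return None
    left, right = seq[:k], seq[-k:]
    return AnchorPair(read_id, left, right,
                      tuple(genome_index.lookup(left)),
                      tuple(genome_index.lookup(right)))


def detect_headtotail(pair: AnchorPair, span_cap: int = DEFAULT_SPAN_CAP,
                      k: int = DEFAULT_K) -> ProvisionalJunction | None:
    """Reversed-order (head-to-tail) test on uniquely placed anchor pairs.

    On the + strand a backsplice read's right anchor lies genomically
    upstream of its left anchor; on the - strand the order flips.
    """
    if pair.left_status != "unique" or pair.right_status != "unique":
        return None
    (pl,), (pr,) = pair.left_placements, pair.right_placements
    if pl.ref != pr.ref or pl.strand != pr.strand:
        return None
    if pl.strand == "+":
        reversed_order = pr.pos < pl.pos
        span = pl.pos + k - pr.pos
    else:
        reversed_order = pr.pos > pl.pos
        span = pr.pos + k - pl.pos
    if not reversed_order or span > span_cap:
        return None
    return ProvisionalJunction(pl.ref, pl.strand, pl.pos, pr.pos)


def extend_to_breakpoint(seq: str, genome_seqs: dict[str, str],
                         provisional: ProvisionalJunction,
                         genome_arrays: dict[str, np.ndarray] | None = None,
                         k: int = DEFAULT_K, m: int = DEFAULT_MISMATCH) -> BacksplicedJunction | None:
    """Slide the split point to the GT/AG-consistent breakpoint.

    The read must align as genome suffix (ending at the donor) + genome
    prefix (starting at the acceptor) with at most ``m`` substitutions in
    total, and the breakpoint must be bracketed by GT/AG splice flanks on
    the template strand.  The junction's strand is called from the flank
    orientation (AG..GT on the forward strand means a + circle; AC..CT —
    the reverse complement — a - circle), so a read and its reverse
    complement carry identical evidence, as in an unstranded library.
    Returns the unique such breakpoint; on ties the leftmost acceptor wins
    (logged).
    """
    if provisional.strand == "+":
        r = seq
        pL, pR = provisional.left_pos, provisional.right_pos
    else:
        r = revcomp(seq)
        pL, pR = provisional.right_pos, provisional.left_pos
    chrom_seq = genome_seqs[provisional.chrom]
    G = (genome_arrays or {}).get(provisional.chrom)
    if G is None:
        G = seq_to_array(chrom_seq)
    n = len(r)
    arr = seq_to_array(r)
    start_suf = pR + k - n
    if pL < 0 or pL >= G.size:
        return None

    def window_mismatch(start: int) -> np.ndarray:
        # read vs G[start:start+n]; out-of-range genome positions count as
        # mismatches (they can never belong to a valid breakpoint's arm)
        mis = np.ones(n, dtype=bool)
        lo, hi = max(start, 0), min(start + n, G.size)
        if lo < hi:
            mis[lo - start:hi - start] = G[lo:hi] != arr[lo - start:hi - start]
        return mis

    pre = np.concatenate(([0], np.cumsum(window_mismatch(pL))))
    suf_mis = window_mismatch(start_suf)
    suf = np.concatenate((np.cumsum(suf_mis[::-1])[::-1], [0]))
    hits: list[tuple[int, int, int, str]] = []
    for i in range(k, n - k + 1):
        mm = int(pre[i] + suf[i])
        if mm > m:
            continue
        D = pL + i
        A = start_suf + i
        if A < 2 or D + 2 > len(chrom_seq) or A >= D:
            continue
        flank = (chrom_seq[A - 2:A], chrom_seq[D:D + 2])
        for strand, want in _FLANKS.items():
            if flank == want:
                hits.append((mm, A, D, strand))
    if not hits:
        return None
    hits.sort()
    # best alignment wins; a genuine tie (equal mismatches) goes to the
    # leftmost acceptor and is logged
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        log.info("breakpoint tie at %s (%d placements); keeping leftmost acceptor",
                 provisional.chrom, len(hits))
    _, A, D, strand = hits[0]
    return BacksplicedJunction(provisional.chrom, strand, A, D, _FLANKS[strand])


def call_candidates(evidence: list[tuple[BacksplicedJunction, str, str, str]],
                    min_unique: int = 2,
                    catalogue: set[tuple[str, str, int, int]] | None = None) -> list[CircCandidate]:
    """Group junction evidence and apply the unique-read support rule.

    ``evidence`` rows are (junction, sample, read_id, read_sequence).
    Reads with identical nucleotide sequence collapse to one (PCR-duplicate
    collapse); a candidate is kept iff some single sample contributes at
    least ``min_unique`` distinct junction reads.  With a ``catalogue`` of
    known junction keys, candidates are annotated known/novel.
    """
    groups: dict[tuple, dict[str, set[str]]] = {}
    ids: dict[tuple, list[str]] = {}
    juncs: dict[tuple, BacksplicedJunction] = {}
    for junction, sample, read_id, read_seq in evidence:
        key = junction.key
        groups.setdefault(key, {}).setdefault(sample, set()).add(read_seq)
        ids.setdefault(key, []).append(read_id)
        juncs[key] = junction
    out = []
    for key in sorted(groups):
        support = {s: len(seqs) for s, seqs in sorted(groups[key].items())}
        if max(support.values()) < min_unique:
            continue
        cand = CircCandidate(juncs[key], support, sorted(ids[key]))
        if catalogue is not None:
            cand.known = key in catalogue
        out.append(cand)
    return out


# ------------------------------------------------------------ driver

@dataclass
class DetectionResult:
    candidates: list[CircCandidate]
    mapped_totals: dict[str, int]
    samples: list[str]

    def support_matrix(self) -> pd.DataFrame:
        """Per-sample unique junction-read counts, one row per candidate."""
        rows = {}
        for c in self.candidates:
            j = c.junction
            name = f"{j.chrom}:{j.acceptor_pos}-{j.donor_pos}:{j.strand}"
            rows[name] = {s: c.support.get(s, 0) for s in self.samples}
        df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        if df.empty:
            df = pd.DataFrame(columns=self.samples, dtype=int)
        return df.reindex(columns=self.samples)


def run_detection(sample_reads: dict[str, "list[tuple[str, str]] | object"],
                  genome_seqs: dict[str, str],
                  transcript_seqs: dict[str, str] | None = None,
                  k: int = DEFAULT_K, m: int = DEFAULT_MISMATCH,
                  span_cap: int = DEFAULT_SPAN_CAP, min_unique: int = 2,
                  catalogue: set | None = None) -> DetectionResult:
    """Full detection across samples: partition, anchor, extend, call.

    ``sample_reads`` maps sample name to an iterable of (read_id, seq).
    Linear references are the genome chromosomes plus any provided spliced
    transcript sequences.
    """
    refs = dict(genome_seqs)
    for tid, seq in (transcript_seqs or {}).items():
        refs[f"tx::{tid}"] = seq
    ref_index = KmerIndex(refs, k=k)
    genome_index = KmerIndex(genome_seqs, k=k) if transcript_seqs else ref_index
    genome_arrays = {name: seq_to_array(s) for name, s in genome_seqs.items()}
    evidence: list[tuple[BacksplicedJunction, str, str, str]] = []
    mapped_totals: dict[str, int] = {}
    for sample in sorted(sample_reads):
        part = partition_linear(sample_reads[sample], ref_index, m=m)
        mapped_totals[sample] = part.mapped_count
        for read_id, seq in part.unmapped:
            pair = extract_anchors(read_id, seq, genome_index)
            if pair is None:
                continue
            prov = detect_headtotail(pair, span_cap=span_cap, k=k)
            if prov is None:
                continue
            junction = extend_to_breakpoint(seq, genome_seqs, prov,
                                            genome_arrays=genome_arrays, k=k, m=m)
            if junction is not None:
                evidence.append((junction, sample, read_id, seq))
    candidates = call_candidates(evidence, min_unique=min_unique, catalogue=catalogue)
    return DetectionResult(candidates, mapped_totals, sorted(sample_reads))
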