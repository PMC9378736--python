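"""Rolling-circle ORF enumeration on circRNA sequences.

A ribosome on a circular template can read through the backsplice junction
and, when the circle length is not a multiple of 3, re-enter already
translated sequence in a shifted reading frame — an ORF "spanning more than
360 degrees".  The frameshifted tail encodes a C-terminal peptide segment
that does not exist on the linear cognate mRNA.  Translation from any start
is periodic with period 3L nt, so an ORF with no stop within three full
passes has none: such ORFs are flagged infinite and truncated at 3L nt.

Conventions: the backsplice junction sits at offset 0 of the circular
sequence (base 0 is the acceptor-side first base); "junction-spanning"
means translation proceeds past the 0 boundary after the first codon.
Start codons are ATG only; stops are TAA/TAG/TGA (standard code).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import ParameterError
from .seqtools import CODON_TABLE, STOP_CODONS

MAX_PASSES = 3


@dataclass(frozen=True)
class CircSequence:
    """A circular RNA sequence (DNA alphabet) with the junction at offset 0."""

    sequence: str
    source_id: str = "circ"

    def __post_init__(self) -> None:
        if len(self.sequence) < 6:
            raise ParameterError(f"{self.source_id}: circle shorter than 6 nt")
        if not set(self.sequence) <= set("ACGTN"):
            raise ParameterError(f"{self.source_id}: non-nucleotide characters in sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CircOrf:
    """One rolling ORF on a circular sequence.

    ``nt_length`` runs from the start codon to the last sense codon
    (excluding the stop); ``passes`` counts how many times translation
    crosses offset 0 after the first codon; ``exceeds_360`` marks ORFs
    whose span including the stop exceeds the circumference.  For circles
    whose length is not a multiple of 3, ``unique_cterm`` is the peptide
    suffix translated from positions already traversed in an earlier pass
    but in a shifted frame.  Infinite ORFs (no stop within three passes)
    carry ``has_stop=False`` and a peptide truncated at 3L nt.
    """

    circ_id: str
    start_offset: int
    nt_length: int
    aa_length: int
    has_stop: bool
    passes: int
    spans_junction: bool
    exceeds_360: bool
    peptide: str
    unique_cterm: str
    truncated: bool = False
    invalid_codon: bool = False


class UniqueCterm(NamedTuple):
    segment: str
    reason: str  # "ok" | "no-junction-pass" | "frame-preserved" | "invalid"


@dataclass
class OrfScreenRecord:
    """Screen bookkeeping for one circRNA: its best ORF plus stage flags."""

    circ_id: str
    best_orf: CircOrf | None
    upregulated: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def passes_length_filter(self) -> bool:
        return self.best_orf is not None and self.best_orf.aa_length < 100

    @property
    def spans_junction(self) -> bool:
        return self.best_orf is not None and self.best_orf.spans_junction


def _count_passes(start: int, extent_nt: int, L: int) -> int:
    """Times translation crosses circle offset 0 strictly inside (start, start+extent)."""
    if extent_nt <= 0:
        return 0
    lo, hi = start, start + extent_nt
    # multiples of L in the open interval (lo, hi)
    return max(0, (hi - 1) // L - lo // L)


def enumerate_rolling_orfs(circ: CircSequence, max_passes: int = MAX_PASSES) -> list[CircOrf]:
    """Translate every ATG on the circle until a stop or ``max_passes`` laps.

    Returns one :class:`CircOrf` per ATG start offset in ``[0, L)``.  A
    codon containing a non-ACGT character terminates the ORF at that codon
    with ``invalid_codon=True``.
    """
    seq = circ.sequence
    L = circ.length
    # enough unrolled sequence for any start to read max_passes laps + stop
    unrolled = seq * (max_passes + 2)
    cap_codons = (max_passes * L) // 3
    orfs: list[CircOrf] = []
    for s in range(L):
        if unrolled[s:s + 3] != "ATG":
            continue
        peptide_parts: list[str] = []
        has_stop = False
        invalid = False
        pos = s
        n_codons = 0
        while n_codons < cap_codons:
            codon = unrolled[pos:pos + 3]
            aa = CODON_TABLE.get(codon)
            if aa is None:
                invalid = True
                break
            if codon in STOP_CODONS:
                has_stop = True
                break
            peptide_parts.append(aa)
            pos += 3
            n_codons += 1
        peptide = "".join(peptide_parts)
        nt_len = 3 * len(peptide)
        extent = nt_len + (3 if has_stop else 0)
        passes = _count_passes(s, extent, L)
        exceeds = nt_len + 3 > L
        unique = ""
        if L % 3 != 0:
            i0 = -(-L // 3)  # first codon whose start offset is >= L past the ORF start
            unique = peptide[i0:]
        orfs.append(CircOrf(circ.source_id, s, nt_len, len(peptide), has_stop,
                            passes, passes >= 1, exceeds, peptide, unique,
                            truncated=not has_stop and not invalid,
                            invalid_codon=invalid))
    return orfs


def unique_cterm(orf: CircOrf, circ: CircSequence) -> UniqueCterm:
    """Frameshift-derived unique C-terminal peptide segment of an ORF.

    Returns the peptide suffix starting at the first codon whose start
    offset (relative to the ORF start, modulo L) was already traversed in
    an earlier pass — necessarily in a shifted frame when ``L % 3 != 0``.
    Empty with a reason code when the ORF never re-enters traversed
    sequence or when the circle length is a multiple of 3 (frame never
    shifts).
    """
    L = circ.length
    if orf.passes < 1:
        return UniqueCterm("", "no-junction-pass")
    if L % 3 == 0:
        return UniqueCterm("", "frame-preserved")
    i0 = -(-L // 3)
    return UniqueCterm(orf.peptide[i0:], "ok" if orf.peptide[i0:] else "no-junction-pass")


def best_junction_orf(orfs: list[CircOrf]) -> CircOrf | None:
    """Longest junction-spanning ORF; ties broken by smallest start offset."""
    cands = [o for o in orfs if o.spans_junction and not o.invalid_codon]
    if not cands:
        return None
    return min(cands, key=lambda o: (-o.aa_length, o.start_offset))


def filter_circorfs(records: list[OrfScreenRecord],
                    require_junction: bool = True,
                    max_aa: int = 100) -> tuple[list[OrfScreenRecord], dict]:
    """Apply the screen filter: junction-spanning (optional) and < ``max_aa``.

    Returns the retained records plus a summary with counts and the
    retained fraction (as a percentage, 1 decimal).
    """
    kept = []
    for rec in records:
        if rec.best_orf is None:
            continue
        if require_junction and not rec.best_orf.spans_junction:
            continue
        if rec.best_orf.aa_length >= max_aa:
            continue
        kept.append(rec)
    n_in, n_kept = len(records), len(kept)
    summary = {"n_in": n_in, "n_kept": n_kept,
               "retained_fraction_pct": round(100.0 * n_kept / n_in, 1) if n_in else 0.0}
    return kept, summary


def enumerate_linear_morfs(transcript: str) -> list[int]:
    """ORF lengths (aa) of a linear sequence, longest ORF per stop.

    Standard ATG->stop ORFs scanned in the three forward frames; for each
    stop codon the ORF from the earliest in-frame ATG after the previous
    stop is reported.  ORFs lacking a stop are not reported.
    """
    lengths: list[int] = []
    n = len(transcript)
    for frame in range(3):
        start: int | None = None
        for p in range(frame, n - 2, 3):
            codon = transcript[p:p + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    lengths.append((p - start) // 3)
                start = None
            elif codon == "ATG" and start is None:
                start = p
    return lengths
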