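"""Operator-motif discovery and promoter coordinate arithmetic.

The transcription factor studied here recognizes a 15-nt operator built from
two TTAA boxes separated by seven arbitrary nucleotides (TTAA-N7-TTAA).  This
module scans promoter sequences for such paired sites and does the coordinate
bookkeeping around a transcription start site (TSS), where positions run
..., -2, -1, +1, +2, ... with no zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = set("ACGT")


def revcomp(bases: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return bases.translate(_COMPLEMENT)[::-1]


def is_palindromic(motif: str) -> bool:
    """True if the motif equals its own reverse complement."""
    return motif == revcomp(motif)


@dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence, optionally anchored to a TSS.

    ``tss_offset`` is the TSS-relative coordinate of base 1 under the no-zero
    convention (e.g. -120 for a promoter fragment starting 120 nt upstream).
    """

    name: str
    bases: str
    tss_offset: Optional[int] = None

    def __post_init__(self):
        if not self.bases:
            raise ValueError("empty sequence")
        if not self.bases.isupper() or not set(self.bases) <= _ALPHABET:
            raise ValueError(
                f"sequence {self.name!r} contains characters outside A/C/G/T "
                "(uppercase required)"
            )
        if self.tss_offset == 0:
            raise ValueError("TSS coordinates have no position 0")

    def __len__(self) -> int:
        return len(self.bases)

    def tss_position(self, index: int) -> Optional[int]:
        """TSS-relative coordinate of a 1-based sequence index (no zero)."""
        if self.tss_offset is None:
            return None
        pos = self.tss_offset + index - 1
        if self.tss_offset < 0 <= pos:
            pos += 1  # skip the non-existent position 0
        return pos


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, 1-based inclusive coordinates."""

    start: int
    end: int
    motif: str
    strand: str = "+"

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.motif):
            raise ValueError("hit span inconsistent with motif length")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class PairedSite:
    """Two motif hits separated by an exact spacer (nt between them)."""

    first: MotifHit
    second: MotifHit

    @property
    def spacer(self) -> int:
        return self.second.start - self.first.end - 1

    @property
    def span(self) -> int:
        return self.second.end - self.first.start + 1

    @property
    def center_distance(self) -> float:
        return self.second.center - self.first.center


def scan_motif(seq: DnaSequence, motif: str = "TTAA") -> list[MotifHit]:
    """All occurrences of a motif, 1-based, overlaps allowed, sorted by start.

    Palindromic motifs (such as TTAA) are scanned on one strand only, since a
    forward hit implies an identical reverse-strand hit at the same position.
    Non-palindromic motifs are scanned on both strands; reverse-strand hits
    are reported at their forward-strand coordinates with strand '-'.
    """
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    if not set(motif) <= _ALPHABET:
        raise ValueError("motif must be over A/C/G/T")

    def _find(pattern: str, strand: str) -> list[MotifHit]:
        hits = []
        start = seq.bases.find(pattern)
        while start != -1:
            hits.append(
                MotifHit(start=start + 1, end=start + len(pattern),
                         motif=motif, strand=strand)
            )
            start = seq.bases.find(pattern, start + 1)
        return hits

    hits = _find(motif, "+")
    if not is_palindromic(motif):
        hits += _find(revcomp(motif), "-")
    return sorted(hits, key=lambda h: (h.start, h.strand))


def find_paired_sites(seq: DnaSequence, spacer: int = 7,
                      motif: str = "TTAA") -> list[PairedSite]:
    """All pairs of motif hits with exactly `spacer` intervening nucleotides.

    For the canonical TTAA-N7-TTAA operator (spacer 7) each paired site spans
    15 nt and its box centers lie 11 bp apart, about one helical turn.
    """
    hits = scan_motif(seq, motif)
    pairs = []
    for i, first in enumerate(hits):
        for second in hits[i + 1:]:
            if second.start - first.end - 1 == spacer:
                pairs.append(PairedSite(first=first, second=second))
    return pairs


def tss_span_length(start: int, end: int) -> int:
    """Inclusive length of a TSS-relative span under the no-zero convention.

    (-120, +17) -> 137;  (-28, -14) -> 15;  (-1, +1) -> 2.
    """
    if start == 0 or end == 0:
        raise ValueError("TSS coordinates have no position 0")
    if start > end:
        raise ValueError("start must not exceed end in promoter order")
    length = end - start + 1
    if start < 0 < end:
        length -= 1  # the span crosses the TSS; there is no position 0
    return length


@dataclass(frozen=True)
class DirectRepeat:
    """Result of a direct-repeat check anchored on two motif boxes."""

    is_repeat: bool
    unit_first: str = ""
    unit_second: str = ""
    mismatches: int = -1
    offset: int = 0


def direct_repeat_check(site: DnaSequence, motif: str = "TTAA",
                        unit_length: int = 8,
                        max_mismatches: int = 2) -> DirectRepeat:
    """Test whether a site carries an approximate direct repeat on its boxes.

    For every pair of motif hits, windows of ``unit_length`` nt taken at the
    same offset relative to each box start are compared; the site is called a
    direct repeat if some alignment has at most ``max_mismatches``
    mismatches.  The <=2-in-8 tolerance operationalizes an "almost perfect"
    repeat and is a documented heuristic.
    """
    if len(site) < 2 * unit_length:
        raise ValueError(f"site shorter than {2 * unit_length} nt")
    hits = scan_motif(site, motif)
    best: Optional[DirectRepeat] = None
    for i, h1 in enumerate(hits):
        for h2 in hits[i + 1:]:
            for off in range(-unit_length + len(motif), 1):
                s1 = h1.start - 1 + off
                s2 = h2.start - 1 + off
                if s1 < 0 or s2 + unit_length > len(site):
                    continue
                u1 = site.bases[s1:s1 + unit_length]
                u2 = site.bases[s2:s2 + unit_length]
                mm = sum(a != b for a, b in zip(u1, u2))
                if best is None or mm < best.mismatches:
                    best = DirectRepeat(mm <= max_mismatches, u1, u2, mm, off)
    if best is None:
        return DirectRepeat(is_repeat=False)
    return best
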