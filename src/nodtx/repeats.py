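"""Direct-repeat and k-mer utilities for excision-element analysis.

An N in the genome never matches any k-mer base or repeat base: gap
characters in draft assemblies must not create phantom repeats.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .errors import CoordinateError, FormatError, ParameterError
from .io_formats import GenomeSequence
from .motifs import IUPAC_CLASSES, reverse_complement

__all__ = ["RepeatPair", "hamming", "count_kmer", "find_flanking_repeats"]


@dataclass(frozen=True)
class RepeatPair:
    """Two equal-length near-identical sequences flanking an element.

    Coordinates are 1-based inclusive; left_end < right_start.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    left_seq: str
    right_seq: str
    mismatches: int

    @property
    def length(self) -> int:
        return len(self.left_seq)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings
    (case-insensitive)."""
    if len(a) != len(b):
        raise ParameterError(f"unequal lengths {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    return sum(x != y for x, y in zip(a, b))


def count_kmer(
    genome: GenomeSequence,
    kmer: str,
    both_strands: bool = False,
    overlapping: bool = True,
) -> int:
    """Count occurrences of a k-mer (IUPAC-aware pattern, N-in-genome never
    matches). Overlapping occurrences are counted by default; with
    ``both_strands`` reverse-complement occurrences are added, without
    double-counting palindromes at the same site."""
    kmer = kmer.upper()
    if not kmer or len(kmer) > genome.length:
        raise ParameterError("k-mer length must be in [1, genome length]")
    bad = set(kmer) - set(IUPAC_CLASSES)
    if bad:
        raise FormatError(f"non-IUPAC character(s) in k-mer: {sorted(bad)}")
    patterns = [kmer]
    if both_strands:
        rc = reverse_complement(kmer)
        if rc != kmer:  # palindrome: one pattern suffices
            patterns.append(rc)
    total = 0
    seq = genome.sequence
    for pat in patterns:
        regex = "".join(IUPAC_CLASSES[c] for c in pat)
        if overlapping:
            total += sum(1 for _ in re.finditer("(?=" + regex + ")", seq))
        else:
            total += sum(1 for _ in re.finditer(regex, seq))
    return total


def find_flanking_repeats(
    genome: GenomeSequence,
    element_start: int,
    element_end: int,
    min_len: int = 8,
    max_len: int = 20,
    max_mismatch: int = 1,
    search_margin: int = 100,
) -> list[RepeatPair]:
    """Find equal-length direct repeats flanking an element.

    ``element_start``/``element_end`` are 1-based inclusive. The left
    repeat must lie fully within the ``search_margin`` nt upstream of the
    element, the right repeat fully within the margin downstream. Pairs
    contained in a longer reported pair at the same relative offset are
    suppressed; output sorted by length descending then mismatches
    ascending.
    """
    if not 1 <= element_start <= element_end <= genome.length:
        raise CoordinateError("element outside genome")
    if min_len < 1 or max_len < min_len:
        raise ParameterError("require 1 <= min_len <= max_len")
    seq = genome.sequence
    left_lo = element_start - 1 - search_margin  # 0-based window bounds
    if left_lo < 0:
        warnings.warn("left search margin truncated at contig start")
        left_lo = 0
    left_hi = element_start - 1  # exclusive
    right_lo = element_end  # 0-based inclusive
    right_hi = element_end + search_margin
    if right_hi > genome.length:
        warnings.warn("right search margin truncated at contig end")
        right_hi = genome.length

    candidates: list[RepeatPair] = []
    for length in range(max_len, min_len - 1, -1):
        for ls in range(left_lo, left_hi - length + 1):
            left = seq[ls : ls + length]
            if "N" in left:
                continue
            for rs in range(right_lo, right_hi - length + 1):
                right = seq[rs : rs + length]
                if "N" in right:
                    continue
                mm = hamming(left, right)
                if mm <= max_mismatch:
                    candidates.append(
                        RepeatPair(ls + 1, ls + length, rs + 1, rs + length, left, right, mm)
                    )
    kept: list[RepeatPair] = []
    for pair in candidates:  # longest first by construction
        if any(_contains(longer, pair) for longer in kept):
            continue
        kept.append(pair)
    kept.sort(key=lambda p: (-p.length, p.mismatches, p.left_start, p.right_start))
    return kept


def _contains(longer: RepeatPair, shorter: RepeatPair) -> bool:
    """True if `shorter` is a sub-pair of `longer` at the same alignment
    offset (same left/right shift)."""
    if shorter.length >= longer.length:
        return False
    shift_left = shorter.left_start - longer.left_start
    shift_right = shorter.right_start - longer.right_start
    return (
        shift_left == shift_right
        and shift_left >= 0
        and shorter.left_end <= longer.left_end
        and shorter.right_end <= longer.right_end
    )
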