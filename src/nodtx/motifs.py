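"""Spaced-dyad motif scanning upstream of TSS.

Offset convention: the TSS base is offset 0, the first upstream base is -1.
The motif center of an even-length motif is the left-of-center base, i.e.
``center_offset = start_offset + (motif_length - 1) // 2``; for the 14-nt
GTA-N8-TAC dyad the center sits 6 nt right of the motif start, so a motif
starting at -47 is centered at -41.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .errors import ParameterError
from .io_formats import GenomeSequence

IUPAC_CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")

__all__ = ["DyadMotifSpec", "MotifHit", "scan_upstream", "reverse_complement"]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> str:
    try:
        return "".join(IUPAC_CLASSES[c] for c in pattern.upper())
    except KeyError as exc:
        raise ParameterError(f"non-IUPAC character in motif box {pattern!r}") from exc


@dataclass(frozen=True)
class DyadMotifSpec:
    """A spaced dyad: left box, fixed spacer, right box (IUPAC-aware)."""

    left_box: str = "GTA"
    spacer_length: int = 8
    right_box: str = "TAC"
    variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.left_box or not self.right_box:
            raise ParameterError("motif boxes must be non-empty")
        if self.spacer_length < 0:
            raise ParameterError("spacer_length must be >= 0")

    @property
    def length(self) -> int:
        return len(self.left_box) + self.spacer_length + len(self.right_box)

    @classmethod
    def parse(cls, text: str, variants: tuple[str, ...] = ()) -> "DyadMotifSpec":
        """Parse 'GTA-N8-TAC' style notation."""
        m = re.fullmatch(r"([A-Za-z]+)-N(\d+)-([A-Za-z]+)", text)
        if not m:
            raise ParameterError(f"cannot parse dyad motif {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)), m.group(3).upper(), variants)


@dataclass(frozen=True)
class MotifHit:
    contig_id: str
    tss_position: int
    tss_strand: str
    matched_left_box: str
    matched_seq: str
    start_offset: int
    center_offset: int


def _upstream_context(genome: GenomeSequence, position: int, strand: str,
                      lo: int, hi: int) -> str:
    """Bases at offsets lo..hi (inclusive) on the TSS strand; out-of-contig
    positions are padded with N (with a warning)."""
    pos0 = position - 1
    n = genome.length
    padded = False
    chars = []
    for off in range(lo, hi + 1):
        gpos = pos0 + off if strand == "+" else pos0 - off
        if 0 <= gpos < n:
            base = genome.sequence[gpos]
            chars.append(base if strand == "+" else base.translate(COMPLEMENT))
        else:
            chars.append("N")
            padded = True
    if padded:
        warnings.warn(
            f"search window for TSS at {genome.contig_id}:{position}{strand} "
            "truncated at contig boundary"
        )
    return "".join(chars)


def scan_upstream(
    genome: GenomeSequence,
    tss,
    spec: DyadMotifSpec | None = None,
    search_from: int = -60,
    search_to: int = -20,
) -> list[MotifHit]:
    """All dyad matches whose start offset lies in [search_from, search_to].

    The scan is strand-aware: for a minus-strand TSS the reverse complement
    of the region is searched. Hits are sorted by center offset ascending.
    """
    spec = spec or DyadMotifSpec()
    if not search_from < search_to <= 0:
        raise ParameterError("require search_from < search_to <= 0")
    length = spec.length
    context = _upstream_context(
        genome, tss.position, tss.strand, search_from, search_to + length - 1
    )
    hits: list[MotifHit] = []
    seen: set[tuple[int, str]] = set()
    for box in (spec.left_box, *spec.variants):
        pattern = re.compile(
            "(?=("
            + iupac_regex(box)
            + "[ACGT]{%d}" % spec.spacer_length
            + iupac_regex(spec.right_box)
            + "))"
        )
        for m in pattern.finditer(context):
            start_offset = search_from + m.start()
            if start_offset > search_to or (start_offset, box) in seen:
                continue
            seen.add((start_offset, box))
            hits.append(
                MotifHit(
                    contig_id=tss.contig_id,
                    tss_position=tss.position,
                    tss_strand=tss.strand,
                    matched_left_box=box,
                    matched_seq=m.group(1),
                    start_offset=start_offset,
                    center_offset=start_offset + (length - 1) // 2,
                )
            )
    hits.sort(key=lambda h: (h.center_offset, h.matched_left_box))
    return hits
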