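"""TSS detection from strand-specific start/coverage profiles and
positional classification against a gene annotation.

Detection (per contig, per strand):

1. window sum ``W(p)`` of read starts over the centered window
   ``[p-(w-1)/2, p+(w-1)/2]``, truncated at contig ends;
2. ``p`` is a candidate iff ``W(p) >= min_window_reads`` and ``starts[p]``
   is the maximum of starts within that window, ties broken toward the
   5'-most position on that strand;
3. enrichment test: ``starts[p] >= (1+enrichment_factor) * upstream_cov``
   where ``upstream_cov`` is the read-through coverage at the
   strand-adjacent upstream position (``p-1`` on +, ``p+1`` on -): the
   coverage there minus the reads starting within the 5' half of the
   centered window (a sharp but slightly jittered peak must not mask
   itself). Zero read-through coverage passes automatically;
4. among surviving candidates closer than ``window`` nt apart on the same
   strand, only the one with greater starts is kept (tie -> 5'-most).

Classification assigns exactly one of gTSS/iTSS/aTSS/nTSS per record using
a configurable priority order, so the classes always partition the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import maximum_filter1d

from .errors import CoordinateError, ParameterError, StateError
from .io_formats import GeneFeature, StrandProfiles

CLASSES = ("gTSS", "iTSS", "aTSS", "nTSS")

__all__ = [
    "CLASSES",
    "DetectionParams",
    "ClassificationParams",
    "TSSRecord",
    "detect_candidates",
    "detect_tss",
    "classify_tss",
    "summarize_classes",
    "write_class_summary",
]


@dataclass(frozen=True)
class DetectionParams:
    min_window_reads: int = 280
    window: int = 7
    enrichment_factor: float = 0.5
    normalize_per_million: bool = False
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ParameterError(f"window must be odd and >= 1, got {self.window}")
        if self.enrichment_factor < 0:
            raise ParameterError("enrichment_factor must be >= 0")
        if self.normalize_per_million and not self.library_size:
            raise ParameterError("library_size required when normalizing per million")

    @property
    def effective_threshold(self) -> float:
        # threshold interpreted as reads-per-million when normalizing
        if self.normalize_per_million:
            return self.min_window_reads * self.library_size / 1e6
        return float(self.min_window_reads)


@dataclass(frozen=True)
class ClassificationParams:
    upstream_max: int = 200
    antisense_flank: int = 0
    priority: tuple[str, ...] = ("gTSS", "aTSS", "iTSS", "nTSS")

    def __post_init__(self) -> None:
        if self.upstream_max < 0:
            raise ParameterError("upstream_max must be >= 0")
        if sorted(self.priority) != sorted(CLASSES):
            raise ParameterError(f"priority must permute {CLASSES}, got {self.priority}")


@dataclass(frozen=True)
class TSSRecord:
    """A called transcriptional start site.

    ``position`` is the 1-based coordinate of the transcript's 5'
    nucleotide. ``enrichment`` is starts / upstream coverage, ``inf`` when
    the upstream coverage is zero. ``offset`` is signed nt relative to the
    associated gene's strand-aware start (negative = upstream), ``None``
    for nTSS/unclassified records.
    """

    contig_id: str
    position: int
    strand: str
    starts: int
    window_reads: int
    enrichment: float
    tss_class: str = "unclassified"
    gene_id: str = ""
    offset: int | None = None


def _candidates_one_strand(
    starts: np.ndarray,
    coverage: np.ndarray,
    strand: str,
    params: DetectionParams,
) -> list[tuple[int, int, int, float]]:
    """Return (pos0, starts, window_reads, enrichment) passing steps 1-3."""
    n = starts.size
    if n == 0:
        return []
    w, h = params.window, (params.window - 1) // 2
    wsum = np.convolve(starts, np.ones(w, dtype=np.int64), mode="same")
    wmax = maximum_filter1d(starts, size=w, mode="constant", cval=0)
    # 5'-most tie-break: no equal-or-larger value strictly 5' of p in window
    side = np.full(n, -1, dtype=np.int64)
    for k in range(1, h + 1):
        if strand == "+":  # max over [p-h, p-1]
            side[k:] = np.maximum(side[k:], starts[:-k] if k else starts)
        else:  # max over [p+1, p+h]
            side[:-k] = np.maximum(side[:-k], starts[k:])
    is_peak = (starts >= 1) & (starts == wmax) & (starts > side)
    passing = (wsum >= params.effective_threshold) & is_peak
    out = []
    factor = 1.0 + params.enrichment_factor
    cum = np.concatenate(([0], np.cumsum(starts)))
    for p in np.flatnonzero(passing):
        p = int(p)
        if strand == "+":
            if p > 0:
                lo = max(0, p - h)
                up = int(coverage[p - 1]) - int(cum[p] - cum[lo])
            else:
                up = 0
        else:
            if p < n - 1:
                hi = min(n - 1, p + h)
                up = int(coverage[p + 1]) - int(cum[hi + 1] - cum[p + 1])
            else:
                up = 0
        up = max(0, up)
        if up > 0 and starts[p] < factor * up:
            continue
        enrich = math.inf if up == 0 else starts[p] / up
        out.append((p, int(starts[p]), int(wsum[p]), enrich))
    return out


def detect_candidates(
    profiles: StrandProfiles, params: DetectionParams | None = None
) -> list[TSSRecord]:
    """Candidate TSS passing window-sum, peak and enrichment tests (no
    proximity deduplication — step 4 is applied by :func:`detect_tss`)."""
    params = params or DetectionParams()
    records = []
    for cid in sorted(profiles.contigs):
        prof = profiles.contigs[cid]
        for strand in "+-":
            for p, s, wr, e in _candidates_one_strand(
                prof.starts(strand), prof.coverage(strand), strand, params
            ):
                records.append(
                    TSSRecord(cid, p + 1, strand, s, wr, e)
                )
    records.sort(key=lambda r: (r.contig_id, r.position, r.strand))
    return records


def detect_tss(
    profiles: StrandProfiles, params: DetectionParams | None = None
) -> list[TSSRecord]:
    """Detect TSS; output sorted by contig then position."""
    params = params or DetectionParams()
    candidates = detect_candidates(profiles, params)
    # greedy proximity resolution: strongest first, 5'-most wins ties
    kept: list[TSSRecord] = []
    by_group: dict[tuple[str, str], list[int]] = {}

    def five_key(r: TSSRecord) -> int:
        return r.position if r.strand == "+" else -r.position

    for r in sorted(candidates, key=lambda r: (-r.starts, five_key(r), r.contig_id)):
        positions = by_group.setdefault((r.contig_id, r.strand), [])
        if any(abs(r.position - q) < params.window for q in positions):
            continue
        positions.append(r.position)
        kept.append(r)
    kept.sort(key=lambda r: (r.contig_id, r.position, r.strand))
    return kept


def classify_tss(
    tss: list[TSSRecord],
    genes: list[GeneFeature],
    params: ClassificationParams | None = None,
) -> list[TSSRecord]:
    """Assign exactly one class per TSS against the annotation.

    Candidate labels: gTSS for a same-strand TSS at most ``upstream_max``
    nt upstream of a gene's strand-aware start (offset 0 = at the first
    base, leaderless); iTSS strictly inside a same-strand gene body
    (excluding the first base); aTSS on the opposite strand within the
    gene body extended by ``antisense_flank``; nTSS otherwise. The
    priority order picks one class; the triggering gene is the nearest
    qualifying one (smaller \\|offset\\|, then lexicographic gene_id).
    """
    params = params or ClassificationParams()
    by_contig: dict[str, list[GeneFeature]] = {}
    contig_ids = {g.contig_id for g in genes}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    out: list[TSSRecord] = []
    for r in tss:
        if r.contig_id not in contig_ids and genes:
            raise CoordinateError(f"TSS on unknown contig {r.contig_id!r}")
        pos0 = r.position - 1
        found: dict[str, list[tuple[int, str]]] = {c: [] for c in CLASSES}
        for g in by_contig.get(r.contig_id, ()):
            sas = g.strand_aware_start0()
            if g.strand == r.strand:
                off = pos0 - sas if g.strand == "+" else sas - pos0
                if -params.upstream_max <= off <= 0:
                    found["gTSS"].append((off, g.gene_id))
                elif off > 0 and g.start0 <= pos0 < g.end0:
                    found["iTSS"].append((off, g.gene_id))
            else:
                if g.start0 - params.antisense_flank <= pos0 <= g.end0 - 1 + params.antisense_flank:
                    off = pos0 - sas if g.strand == "+" else sas - pos0
                    found["aTSS"].append((off, g.gene_id))
        assigned = "nTSS"
        gene_id, offset = "", None
        for cls in params.priority:
            if cls == "nTSS" or found[cls]:
                if cls != "nTSS":
                    offset, gene_id = min(found[cls], key=lambda t: (abs(t[0]), t[1]))
                assigned = cls
                break
        out.append(replace(r, tss_class=assigned, gene_id=gene_id, offset=offset))
    return out


def summarize_classes(tss: list[TSSRecord]) -> dict[str, int]:
    """Per-class counts plus total; raises if any record is unclassified."""
    counts = {c: 0 for c in CLASSES}
    for r in tss:
        if r.tss_class not in counts:
            raise StateError(f"unclassified record at {r.contig_id}:{r.position}")
        counts[r.tss_class] += 1
    counts["total"] = len(tss)
    return counts


def write_class_summary(counts: dict[str, int], path: str) -> None:
    with open(path, "w") as out:
        out.write("class\tcount\n")
        for c in CLASSES:
            out.write(f"{c}\t{counts[c]}\n")
        out.write(f"total\t{counts['total']}\n")
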