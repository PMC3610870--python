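"""Readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; each reader/writer
converts at the boundary to its format's native convention (GFF3/TSV 1-based
inclusive, BED 0-based half-open, SAM via pysam's 0-based API).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import CoordinateError, FormatError

IUPAC_NT = set("ACGTUNRYSWKMBDHV")

__all__ = [
    "GenomeSequence",
    "GeneFeature",
    "ReadAlignment",
    "HSPRecord",
    "ContigProfile",
    "StrandProfiles",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_alignments",
    "write_bed",
    "build_profiles",
    "write_tss_outputs",
    "read_tss_table",
]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: identifier plus an uppercase nucleotide string."""

    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """Annotated gene interval, 1-based inclusive coordinates as in GFF3."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise FormatError(
                f"gene {self.gene_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def start0(self) -> int:
        """0-based inclusive start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end."""
        return self.end

    def strand_aware_start0(self) -> int:
        """0-based position of the first transcribed base (start codon side)."""
        return self.start - 1 if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ReadAlignment:
    """A mapped read interval, 0-based half-open on the reference."""

    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise FormatError(f"invalid alignment interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand {self.strand!r}")

    def five_prime(self) -> int:
        """0-based position of the read's 5' end (rightmost base on minus)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class HSPRecord:
    """One local alignment block from a tabular (outfmt-6 style) hit file."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError(f"percent identity {self.percent_identity} outside [0,100]")
        if self.query_end < self.query_start:
            raise FormatError("query_end < query_start")
        if self.alignment_length < 1:
            raise FormatError("alignment length must be positive")


@dataclass
class ContigProfile:
    """Per-strand integer tracks of read 5'-end starts and read coverage."""

    length: int
    starts_plus: np.ndarray = field(default=None)
    starts_minus: np.ndarray = field(default=None)
    coverage_plus: np.ndarray = field(default=None)
    coverage_minus: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        for name in ("starts_plus", "starts_minus", "coverage_plus", "coverage_minus"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.length, dtype=np.int64))

    def starts(self, strand: str) -> np.ndarray:
        return self.starts_plus if strand == "+" else self.starts_minus

    def coverage(self, strand: str) -> np.ndarray:
        return self.coverage_plus if strand == "+" else self.coverage_minus


@dataclass
class StrandProfiles:
    """Start/coverage tracks per contig, both strands."""

    contigs: dict[str, ContigProfile] = field(default_factory=dict)

    def validate(self) -> None:
        for cid, prof in self.contigs.items():
            for strand in "+-":
                s, c = prof.starts(strand), prof.coverage(strand)
                if (s < 0).any() or (c < s).any():
                    raise CoordinateError(f"profile invariant violated on {cid}{strand}")


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a nucleotide FASTA; uppercase, U->T, reject non-IUPAC characters."""
    path = os.fspath(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}:{lineno}: expected FASTA header '>'")
                break
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_NT
        if bad:
            lineno = _find_bad_line(path, bad)
            raise FormatError(
                f"{path}:{lineno}: non-IUPAC nucleotide character(s) {sorted(bad)}"
            )
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, seq))
    return records


def _find_bad_line(path: str, bad: set[str]) -> int:
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith(">"):
                continue
            if bad & set(line.strip().upper()):
                return lineno
    return 0


def write_fasta(records: Iterable[GenomeSequence], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.contig_id}\n")
            for i in range(0, rec.length, width):
                out.write(rec.sequence[i : i + width] + "\n")


def read_gff(
    path: str | os.PathLike,
    feature_types: Sequence[str] = ("CDS",),
) -> list[GeneFeature]:
    """Read gene features of the configured types from a GFF3 file.

    gene_id is taken from the ID attribute, falling back to locus_tag.
    Duplicate identifiers raise :class:`FormatError`.
    """
    wanted = set(feature_types)
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    path = os.fspath(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            contig, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype not in wanted:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            attr_map = _parse_attributes(attrs)
            gene_id = attr_map.get("ID") or attr_map.get("locus_tag")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: feature lacks ID/locus_tag attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate feature identifier {gene_id!r}")
            seen.add(gene_id)
            feats.append(GeneFeature(gene_id, contig, start, end, strand, ftype))
    return feats


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, val = item.split("=", 1)
        out[key] = val
    return out


def write_gff(features: Iterable[GeneFeature], path: str | os.PathLike, source: str = "nodtx") -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in features:
            out.write(
                f"{f.contig_id}\t{source}\t{f.feature_type}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tID={f.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Mapped reads
# ---------------------------------------------------------------------------

def read_alignments(path: str | os.PathLike, fmt: str | None = None) -> list[ReadAlignment]:
    """Load mapped reads from SAM/BAM or 6-column BED.

    SAM/BAM: unmapped, secondary and supplementary records are skipped; the
    aligned reference span excludes soft-clipped bases. BED: 0-based
    half-open with strand in column 6. Duplicate reads are retained.
    """
    path = os.fspath(path)
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {".sam": "sam", ".bam": "bam", ".bed": "bed"}.get(ext)
        if fmt is None:
            raise FormatError(f"cannot infer alignment format from {path!r}")
    if fmt in ("sam", "bam"):
        return _read_sam(path, fmt)
    if fmt == "bed":
        return _read_bed(path)
    raise FormatError(f"unknown alignment format {fmt!r}")


def _read_sam(path: str, fmt: str) -> list[ReadAlignment]:
    import pysam

    mode = "rb" if fmt == "bam" else "r"
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            strand = "-" if rec.is_reverse else "+"
            out.append(
                ReadAlignment(rec.reference_name, rec.reference_start, rec.reference_end, strand)
            )
    return out


def _read_bed(path: str) -> list[ReadAlignment]:
    out: list[ReadAlignment] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires a strand in column 6")
            if cols[5] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {cols[5]!r}")
            out.append(ReadAlignment(cols[0], int(cols[1]), int(cols[2]), cols[5]))
    return out


def write_bed(alignments: Iterable[ReadAlignment], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for i, a in enumerate(alignments):
            out.write(f"{a.contig_id}\t{a.start}\t{a.end}\tr{i}\t0\t{a.strand}\n")


def build_profiles(
    alignments: Sequence[ReadAlignment],
    contigs: Sequence[GenomeSequence],
) -> StrandProfiles:
    """Tally per-position read 5'-end starts and read coverage, per strand.

    starts[p] counts reads whose 5' end is p (the rightmost aligned base for
    minus-strand reads); coverage[p] counts reads overlapping p on that
    strand. Every alignment must lie within its contig.
    """
    lengths = {c.contig_id: c.length for c in contigs}
    profiles = StrandProfiles({cid: ContigProfile(n) for cid, n in lengths.items()})
    # coverage accumulated as +1/-1 deltas, cumsum'd at the end
    deltas = {
        cid: {"+": np.zeros(n + 1, dtype=np.int64), "-": np.zeros(n + 1, dtype=np.int64)}
        for cid, n in lengths.items()
    }
    for a in alignments:
        n = lengths.get(a.contig_id)
        if n is None:
            raise CoordinateError(f"alignment on unknown contig {a.contig_id!r}")
        if a.end > n:
            raise CoordinateError(
                f"alignment [{a.start},{a.end}) beyond {a.contig_id} length {n}"
            )
        prof = profiles.contigs[a.contig_id]
        prof.starts(a.strand)[a.five_prime()] += 1
        d = deltas[a.contig_id][a.strand]
        d[a.start] += 1
        d[a.end] -= 1
    for cid, prof in profiles.contigs.items():
        prof.coverage_plus = np.cumsum(deltas[cid]["+"][:-1])
        prof.coverage_minus = np.cumsum(deltas[cid]["-"][:-1])
    profiles.validate()
    return profiles


# ---------------------------------------------------------------------------
# TSS tables
# ---------------------------------------------------------------------------

TSS_TSV_COLUMNS = (
    "contig",
    "position",
    "strand",
    "window_reads",
    "starts",
    "enrichment",
    "class",
    "gene_id",
    "offset",
)


def write_tss_outputs(
    records: Sequence,
    path_prefix: str | os.PathLike,
    header_comments: Sequence[str] = (),
) -> tuple[str, str]:
    """Write classified TSS records as a TSV table plus a GFF3 track.

    Returns (tsv_path, gff_path). The TSV round-trips through
    :func:`read_tss_table`.
    """
    prefix = os.fspath(path_prefix)
    tsv_path, gff_path = prefix + ".tsv", prefix + ".gff3"
    with open(tsv_path, "w") as out:
        for line in header_comments:
            out.write(f"# {line}\n")
        out.write("\t".join(TSS_TSV_COLUMNS) + "\n")
        for r in records:
            enrich = "inf" if r.enrichment == float("inf") else f"{r.enrichment:.4f}"
            offset = "" if r.offset is None else str(r.offset)
            out.write(
                f"{r.contig_id}\t{r.position}\t{r.strand}\t{r.window_reads}\t{r.starts}"
                f"\t{enrich}\t{r.tss_class}\t{r.gene_id or ''}\t{offset}\n"
            )
    with open(gff_path, "w") as out:
        out.write("##gff-version 3\n")
        for line in header_comments:
            out.write(f"# {line}\n")
        for i, r in enumerate(records, 1):
            attrs = f"ID=TSS{i:05d};class={r.tss_class}"
            if r.gene_id:
                attrs += f";gene={r.gene_id};offset={r.offset}"
            out.write(
                f"{r.contig_id}\tnodtx\tTSS\t{r.position}\t{r.position}\t.\t{r.strand}\t.\t{attrs}\n"
            )
    return tsv_path, gff_path


def read_tss_table(path: str | os.PathLike) -> list:
    """Read back a TSV written by :func:`write_tss_outputs`."""
    from .tss import TSSRecord

    records: list[TSSRecord] = []
    path = os.fspath(path)
    with open(path) as handle:
        header = None
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                if tuple(header) != TSS_TSV_COLUMNS:
                    raise FormatError(f"{path}:{lineno}: unexpected TSS table columns")
                continue
            if len(cols) != len(TSS_TSV_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            contig, pos, strand, wreads, starts, enrich, cls, gene, offset = cols
            records.append(
                TSSRecord(
                    contig_id=contig,
                    position=int(pos),
                    strand=strand,
                    starts=int(starts),
                    window_reads=int(wreads),
                    enrichment=float("inf") if enrich == "inf" else float(enrich),
                    tss_class=cls,
                    gene_id=gene or "",
                    offset=int(offset) if offset else None,
                )
            )
    return records
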