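"""Seeded generators for synthetic genomes, read layouts and protein-hit
tables with known planted truth.

Layout strategy of :func:`simulate_genome`: the genome is divided into
equal slots, one gene per slot, with generous margins so that every
planted TSS is unambiguous under the default classification parameters
(a planted nTSS is never within 200 nt upstream of a gene, planted
iTSS/aTSS sit deep enough inside gene bodies that read pile-ups from
neighbouring TSS cannot mask them, etc.). All generators draw from one
:class:`numpy.random.Generator` per call; nothing touches global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io_formats import GeneFeature, GenomeSequence, HSPRecord, ReadAlignment
from .motifs import reverse_complement
from .ortho import ProteinCatalog
from .repeats import RepeatPair

BASES = np.frombuffer(b"ACGT", dtype="S1")

__all__ = [
    "TrueTSS",
    "SimulationTruth",
    "simulate_genome",
    "simulate_reads",
    "simulate_hsp_tables",
]


@dataclass(frozen=True)
class TrueTSS:
    position: int  # 1-based 5' nucleotide
    strand: str
    tss_class: str
    mean_starts: float | None = None


@dataclass
class SimulationTruth:
    genome: GenomeSequence
    genes: list[GeneFeature] = field(default_factory=list)
    true_tss: list[TrueTSS] = field(default_factory=list)
    planted_motifs: list[tuple[int, int]] = field(default_factory=list)  # (tss idx, center offset)
    planted_elements: list[tuple[tuple[int, int], RepeatPair]] = field(default_factory=list)
    family_truth: dict[str, str] = field(default_factory=dict)


MIN_SLOT = 1300  # gene + promoter margin + intergenic clearance


def simulate_genome(
    n_genes: int,
    genome_length: int,
    seed: int,
    motif_fraction: float = 0.5,
    n_itss: int | None = None,
    n_atss: int | None = None,
    n_ntss: int | None = None,
    n_elements: int = 0,
    contig_id: str = "chr",
) -> SimulationTruth:
    """Random genome with non-overlapping genes, planted TSS of all four
    classes, optional promoter dyad motifs and direct-repeat elements."""
    rng = np.random.default_rng(seed)
    if n_genes < 0 or genome_length < 1:
        raise ParameterError("n_genes >= 0 and genome_length >= 1 required")
    seq = rng.choice(BASES, size=genome_length)
    if n_genes == 0:
        genome = GenomeSequence(contig_id, b"".join(seq).decode())
        return SimulationTruth(genome=genome)

    slot = genome_length // n_genes
    if slot < MIN_SLOT:
        raise ParameterError(
            f"gene density infeasible: slot {slot} nt < {MIN_SLOT} nt "
            f"({n_genes} genes in {genome_length} nt)"
        )
    if n_itss is None:
        n_itss = n_genes // 5
    if n_atss is None:
        n_atss = n_genes // 5
    if n_ntss is None:
        n_ntss = n_genes // 5
    if n_itss + n_atss > n_genes:
        raise ParameterError("n_itss + n_atss must not exceed n_genes")
    if n_ntss > n_genes or n_elements > n_genes:
        raise ParameterError("quotas must not exceed n_genes")

    genes: list[GeneFeature] = []
    true_tss: list[TrueTSS] = []
    planted_motifs: list[tuple[int, int]] = []
    planted_elements: list[tuple[tuple[int, int], RepeatPair]] = []

    glen_hi = min(900, slot - 800)
    for gi in range(n_genes):
        s0 = gi * slot
        glen = int(rng.integers(400, glen_hi + 1))
        gstart0 = s0 + 400
        gend0 = gstart0 + glen  # exclusive
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneFeature(f"g{gi:04d}", contig_id, gstart0 + 1, gend0, strand)
        )
        sas0 = gstart0 if strand == "+" else gend0 - 1
        d = int(rng.integers(20, 151))
        tss0 = sas0 - d if strand == "+" else sas0 + d
        idx = len(true_tss)
        true_tss.append(TrueTSS(tss0 + 1, strand, "gTSS"))
        if rng.random() < motif_fraction:
            _plant_motif(seq, tss0, strand, rng)
            planted_motifs.append((idx, -41))

    # iTSS and aTSS on disjoint host genes
    order = rng.permutation(n_genes)
    for gi in order[:n_itss]:
        g = genes[gi]
        glen = g.end - g.start + 1
        d = int(rng.integers(150, glen - 49))
        sas0 = g.strand_aware_start0()
        tss0 = sas0 + d if g.strand == "+" else sas0 - d
        true_tss.append(TrueTSS(tss0 + 1, g.strand, "iTSS"))
    for gi in order[n_itss : n_itss + n_atss]:
        g = genes[gi]
        tss0 = g.start0 + (g.end - g.start + 1) // 2
        strand = "-" if g.strand == "+" else "+"
        true_tss.append(TrueTSS(tss0 + 1, strand, "aTSS"))
    for gi in range(n_ntss):
        tss0 = gi * slot + 50
        strand = "+" if rng.random() < 0.5 else "-"
        true_tss.append(TrueTSS(tss0 + 1, strand, "nTSS"))

    for gi in range(n_elements):
        s0 = gi * slot
        rep_len = int(rng.integers(8, 17))
        body_len = int(rng.integers(80, 121))
        left0 = s0 + slot - 180
        repeat = rng.choice(BASES, size=rep_len)
        right_rep = repeat.copy()
        mpos = int(rng.integers(rep_len))  # single-nucleotide difference
        right_rep[mpos] = BASES[(np.flatnonzero(BASES == right_rep[mpos])[0] + 1) % 4]
        body0 = left0 + rep_len
        right0 = body0 + body_len
        seq[left0 : left0 + rep_len] = repeat
        seq[right0 : right0 + rep_len] = right_rep
        left_seq = b"".join(repeat).decode()
        right_seq = b"".join(right_rep).decode()
        pair = RepeatPair(
            left0 + 1, left0 + rep_len, right0 + 1, right0 + rep_len,
            left_seq, right_seq, 1,
        )
        planted_elements.append(((body0 + 1, right0), pair))

    genome = GenomeSequence(contig_id, b"".join(seq).decode())
    return SimulationTruth(genome, genes, true_tss, planted_motifs, planted_elements)


def _plant_motif(seq: np.ndarray, tss0: int, strand: str, rng: np.random.Generator) -> None:
    """Write GTA + N8 + TAC centered at offset -41 on the TSS strand."""
    spacer = b"".join(rng.choice(BASES, size=8)).decode()
    motif = "GTA" + spacer + "TAC"
    if strand == "+":
        start = tss0 - 47
        seq[start : start + 14] = np.frombuffer(motif.encode(), dtype="S1")
    else:
        start = tss0 + 34  # offsets -47..-34 upstream on the minus strand
        rc = reverse_complement(motif)
        seq[start : start + 14] = np.frombuffer(rc.encode(), dtype="S1")


def simulate_reads(
    truth: SimulationTruth,
    mean_tss_starts: float = 600.0,
    jitter_sd: float = 1.0,
    background_rate: float = 0.2,
    read_length: int = 100,
    seed: int = 0,
) -> list[ReadAlignment]:
    """Strand-specific reads: Poisson pile-ups with Normal positional jitter
    at every planted TSS, plus a uniform Poisson background per strand."""
    rng = np.random.default_rng(seed)
    n = truth.genome.length
    cid = truth.genome.contig_id
    reads: list[ReadAlignment] = []

    def add_read(p5: int, strand: str) -> None:
        p5 = min(max(p5, 0), n - 1)
        if strand == "+":
            start, end = p5, min(p5 + read_length, n)
        else:
            start, end = max(p5 - read_length + 1, 0), p5 + 1
        reads.append(ReadAlignment(cid, start, end, strand))

    for t in truth.true_tss:
        count = int(rng.poisson(mean_tss_starts))
        if jitter_sd > 0:
            offsets = np.rint(rng.normal(0.0, jitter_sd, size=count)).astype(int)
        else:
            offsets = np.zeros(count, dtype=int)
        for off in offsets:
            add_read(t.position - 1 + int(off), t.strand)
    for strand in "+-":
        count = int(rng.poisson(background_rate * n))
        for p5 in rng.integers(0, n, size=count):
            add_read(int(p5), strand)
    return reads


def simulate_hsp_tables(
    n_families: int,
    genomes: list[str],
    within_identity_mean: float = 80.0,
    within_identity_sd: float = 5.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> tuple[list[HSPRecord], ProteinCatalog, dict[str, str]]:
    """Planted multi-genome protein families as an all-vs-all hit table.

    One protein per present genome per family (each family misses each
    genome independently with probability ``dropout``, but never all of
    them); all within-family ordered pairs are emitted as single HSPs with
    identity ~ Normal(mean, sd) and coverage ~ Uniform(60, 100)%. There are
    no between-family hits.
    """
    if n_families < 1:
        raise ParameterError("n_families must be >= 1")
    if not 0 <= dropout < 1:
        raise ParameterError("dropout must be in [0, 1)")
    if not genomes:
        raise ParameterError("at least one genome id required")
    rng = np.random.default_rng(seed)
    hsps: list[HSPRecord] = []
    catalog = ProteinCatalog()
    family_truth: dict[str, str] = {}
    for fi in range(n_families):
        fam = f"F{fi:04d}"
        length = int(rng.integers(100, 601))
        present = [g for g in genomes if rng.random() >= dropout]
        if not present:
            present = [genomes[int(rng.integers(len(genomes)))]]
        members = []
        for g in present:
            pid = f"{g}|{fam}"
            catalog.add(pid, g, length)
            family_truth[pid] = fam
            members.append(pid)
        for a in members:
            for b in members:
                if a == b:
                    continue
                ident = float(np.clip(rng.normal(within_identity_mean, within_identity_sd), 1.0, 100.0))
                cov = float(rng.uniform(60.0, 100.0))
                alen = max(1, round(cov / 100.0 * length))
                hsps.append(
                    HSPRecord(
                        query_id=a,
                        subject_id=b,
                        percent_identity=round(ident, 2),
                        alignment_length=alen,
                        query_start=1,
                        query_end=alen,
                        subject_start=1,
                        subject_end=alen,
                        evalue=1e-50,
                        bitscore=round(ident * alen / 10.0, 1),
                    )
                )
    return hsps, catalog, family_truth
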