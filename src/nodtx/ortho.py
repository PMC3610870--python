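"""Comparative-proteome pipeline: HSP merging, best-hit filtering, Markov
clustering, and genome-subset (core/shared/unique) categorization.

The Markov clustering here is a small self-contained implementation over
scipy sparse matrices (expansion = matrix square, inflation = elementwise
power with column renormalization, pruning of tiny entries); clusters are
the connected components of the converged matrix. It is deliberately
independent of any external ``mcl`` binary.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .errors import FormatError, InconsistentInputError, NodtxError, ParameterError
from .io_formats import HSPRecord

__all__ = [
    "ProteinCatalog",
    "MergedHit",
    "FilterParams",
    "ClusterSet",
    "read_blast_tab",
    "read_length_table",
    "merge_hsps",
    "filter_hits",
    "mcl_cluster",
    "venn_categorize",
    "write_clusters",
    "write_subset_counts",
]


@dataclass
class ProteinCatalog:
    """protein_id -> (genome_id, length in residues)."""

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)

    def add(self, protein_id: str, genome_id: str, length: int) -> None:
        if length <= 0:
            raise FormatError(f"non-positive length for {protein_id!r}")
        if protein_id in self.entries:
            raise FormatError(f"duplicate protein id {protein_id!r}")
        self.entries[protein_id] = (genome_id, length)

    def genome_of(self, protein_id: str) -> str:
        return self.entries[protein_id][0]

    def length_of(self, protein_id: str) -> int:
        return self.entries[protein_id][1]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.entries)

    @property
    def genome_ids(self) -> list[str]:
        return sorted({g for g, _ in self.entries.values()})


@dataclass(frozen=True)
class MergedHit:
    """One query-subject pair after HSP merging.

    merged_identity is the raw-length-weighted mean of the input HSP
    identities; merged_length is the length of the union of the query-axis
    intervals; coverage is 100 * merged_length / longer sequence length.
    """

    query_id: str
    subject_id: str
    merged_identity: float
    merged_length: int
    coverage: float


@dataclass(frozen=True)
class FilterParams:
    min_coverage: float = 10.0
    identity_window: float = 10.0
    coverage_window: float = 20.0
    max_evalue: float = 1e-8

    def __post_init__(self) -> None:
        if min(self.min_coverage, self.identity_window, self.coverage_window) < 0:
            raise ParameterError("filter parameters must be non-negative")


@dataclass
class ClusterSet:
    """cluster_id -> sorted member protein ids (a partition of the catalog)."""

    clusters: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_proteins(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    def membership(self) -> dict[str, str]:
        return {p: cid for cid, members in self.clusters.items() for p in members}

    def genome_sets(self, catalog: ProteinCatalog) -> dict[str, frozenset[str]]:
        out = {}
        for cid, members in self.clusters.items():
            for p in members:
                if p not in catalog:
                    raise NodtxError(f"cluster member {p!r} missing from catalog")
            out[cid] = frozenset(catalog.genome_of(p) for p in members)
        return out


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | os.PathLike) -> list[HSPRecord]:
    """Read 12-column outfmt-6 style tabular hits."""
    out: list[HSPRecord] = []
    path = os.fspath(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 tab columns")
            out.append(
                HSPRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    query_start=int(cols[6]),
                    query_end=int(cols[7]),
                    subject_start=int(cols[8]),
                    subject_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            )
    return out


def read_catalog(path: str | os.PathLike) -> ProteinCatalog:
    """Read a 3-column (protein_id, genome_id, length) TSV catalog."""
    catalog = ProteinCatalog()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            pid, genome, length = line.split("\t")[:3]
            catalog.add(pid, genome, int(length))
    return catalog


def write_catalog(catalog: ProteinCatalog, path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        out.write("protein_id\tgenome_id\tlength\n")
        for pid in catalog.protein_ids:
            genome, length = catalog.entries[pid]
            out.write(f"{pid}\t{genome}\t{length}\n")


def read_clusters(path: str | os.PathLike) -> ClusterSet:
    """Read back a clusters TSV written by :func:`write_clusters`."""
    members: dict[str, list[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("cluster_id\t"):
                continue
            cid, pid = line.split("\t")[:2]
            members.setdefault(cid, []).append(pid)
    return ClusterSet({cid: tuple(sorted(ms)) for cid, ms in members.items()})


def read_length_table(path: str | os.PathLike, genome_id: str, catalog: ProteinCatalog) -> None:
    """Add a 2-column (protein_id, length) TSV to the catalog."""
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, length = line.split("\t")[:2]
            catalog.add(pid, genome_id, int(length))


# ---------------------------------------------------------------------------
# Merge / filter
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    # 1-based inclusive intervals
    total, cur_lo, cur_hi = 0, None, None
    for lo, hi in sorted(intervals):
        if cur_lo is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi + 1:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    if cur_lo is not None:
        total += cur_hi - cur_lo + 1
    return total


def merge_hsps(
    hsps: list[HSPRecord],
    catalog: ProteinCatalog,
    max_evalue: float | None = 1e-8,
) -> list[MergedHit]:
    """Merge HSPs per unordered sequence pair and recompute identity/length.

    Self-hits are dropped, as are HSPs above ``max_evalue``. Intervals are
    unioned on the axis of the lexicographically smaller id of the pair
    (one consistent axis per pair); identity is the alignment-length
    weighted mean over the input HSPs; coverage is measured against the
    longer of the two sequences.
    """
    groups: dict[tuple[str, str], list[HSPRecord]] = {}
    for h in hsps:
        if h.query_id == h.subject_id:
            continue
        if max_evalue is not None and h.evalue > max_evalue:
            continue
        for pid in (h.query_id, h.subject_id):
            if pid not in catalog:
                raise FormatError(f"hit references unknown protein {pid!r}")
        key = (h.query_id, h.subject_id) if h.query_id < h.subject_id else (h.subject_id, h.query_id)
        groups.setdefault(key, []).append(h)

    merged: list[MergedHit] = []
    for (qid, sid), group in sorted(groups.items()):
        intervals = []
        for h in group:
            if h.query_id == qid:
                lo, hi = h.query_start, h.query_end
            else:
                lo, hi = h.subject_start, h.subject_end
            if lo > hi:
                lo, hi = hi, lo
            intervals.append((lo, hi))
        mlen = _union_length(intervals)
        total_len = sum(h.alignment_length for h in group)
        ident = sum(h.percent_identity * h.alignment_length for h in group) / total_len
        longer = max(catalog.length_of(qid), catalog.length_of(sid))
        if mlen > longer:
            raise InconsistentInputError(
                f"merged alignment length {mlen} exceeds longer sequence ({longer}) "
                f"for pair {qid}/{sid}"
            )
        merged.append(MergedHit(qid, sid, ident, mlen, 100.0 * mlen / longer))
    return merged


def filter_hits(hits: list[MergedHit], params: FilterParams | None = None) -> list[MergedHit]:
    """Coverage pre-filter followed by dual best-hit window filtering.

    A hit survives only if it is retained in BOTH the group of hits sharing
    its query and the group sharing its subject: within each group the best
    hit (highest identity; ties by coverage then partner id) anchors an
    identity window and a coverage window.
    """
    params = params or FilterParams()
    hits = [h for h in hits if h.coverage >= params.min_coverage]

    def retained_in_group(group: list[MergedHit]) -> set[int]:
        # deterministic best: identity, then coverage, then partner-pair id
        best = sorted(
            group,
            key=lambda h: (-h.merged_identity, -h.coverage, h.query_id, h.subject_id),
        )[0]
        keep = set()
        for h in group:
            if (
                h.merged_identity >= best.merged_identity - params.identity_window
                and h.coverage >= best.coverage - params.coverage_window
            ):
                keep.add(id(h))
        return keep

    by_role: dict[str, list[MergedHit]] = {}
    for h in hits:
        by_role.setdefault(h.query_id, []).append(h)
        by_role.setdefault(h.subject_id, []).append(h)
    retained: dict[str, set[int]] = {
        pid: retained_in_group(group) for pid, group in by_role.items()
    }
    return [
        h
        for h in hits
        if id(h) in retained[h.query_id] and id(h) in retained[h.subject_id]
    ]


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(
    hits: list[MergedHit],
    catalog: ProteinCatalog,
    inflation: float = 2.0,
    prune_threshold: float = 1e-6,
    tolerance: float = 1e-8,
    max_iterations: int = 200,
) -> ClusterSet:
    """Cluster proteins by Markov clustering of the merged-identity graph.

    Edge weight = merged identity (max over the two directions when both
    occur); each node gets a self-loop equal to its max incident weight
    (1 for isolated nodes). Proteins without hits become singletons.
    """
    if inflation <= 1:
        raise ParameterError("inflation must be > 1")
    nodes = catalog.protein_ids
    index = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return ClusterSet({})

    weights: dict[tuple[int, int], float] = {}
    for h in hits:
        i, j = index[h.query_id], index[h.subject_id]
        if i == j:
            continue
        for key in ((i, j), (j, i)):
            weights[key] = max(weights.get(key, 0.0), h.merged_identity)
    loop = np.ones(n)
    for (i, j), w in weights.items():
        loop[i] = max(loop[i], w)
    rows = [i for (i, _ ) in weights] + list(range(n))
    cols = [j for (_, j) in weights] + list(range(n))
    vals = [w for w in weights.values()] + list(loop)
    m = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    m = _normalize_columns(m)
    converged = False
    for _ in range(max_iterations):
        prev = m.copy()
        m = m @ m  # expansion
        m = m.power(inflation)  # inflation
        m.data[m.data < prune_threshold] = 0.0
        m.eliminate_zeros()
        m = _normalize_columns(m)
        if abs(m - prev).max() < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within the iteration limit")

    _, labels = connected_components(m + m.T, directed=False)
    groups: dict[int, list[str]] = {}
    for p, i in index.items():
        groups.setdefault(labels[i], []).append(p)
    clusters = {}
    for k, members in enumerate(
        sorted((sorted(ms) for ms in groups.values()), key=lambda ms: ms[0]), 1
    ):
        clusters[f"C{k:05d}"] = tuple(members)
    return ClusterSet(clusters)


def _normalize_columns(m: sparse.csr_matrix) -> sparse.csr_matrix:
    colsums = np.asarray(m.sum(axis=0)).ravel()
    colsums[colsums == 0] = 1.0
    d = sparse.diags(1.0 / colsums)
    return (m @ d).tocsr()


# ---------------------------------------------------------------------------
# Genome-subset categorization
# ---------------------------------------------------------------------------

def venn_categorize(
    clusters: ClusterSet, catalog: ProteinCatalog
) -> dict[tuple[str, ...], tuple[int, int]]:
    """Counts of clusters and proteins per genome subset.

    Keys are sorted tuples of genome ids; values are (cluster count,
    protein count). Cluster counts sum to the number of clusters and
    protein counts to the number of proteins.
    """
    table: dict[tuple[str, ...], list[int]] = {}
    genome_sets = clusters.genome_sets(catalog)
    for cid, members in clusters.clusters.items():
        key = tuple(sorted(genome_sets[cid]))
        entry = table.setdefault(key, [0, 0])
        entry[0] += 1
        entry[1] += len(members)
    return {k: (v[0], v[1]) for k, v in sorted(table.items())}


def write_clusters(clusters: ClusterSet, catalog: ProteinCatalog, path: str,
                   header_comments: list[str] | None = None) -> None:
    with open(path, "w") as out:
        for line in header_comments or []:
            out.write(f"# {line}\n")
        out.write("cluster_id\tprotein_id\tgenome_id\n")
        for cid, members in clusters.clusters.items():
            for p in members:
                out.write(f"{cid}\t{p}\t{catalog.genome_of(p)}\n")


def write_subset_counts(table: dict[tuple[str, ...], tuple[int, int]], path: str,
                        header_comments: list[str] | None = None) -> None:
    with open(path, "w") as out:
        for line in header_comments or []:
            out.write(f"# {line}\n")
        out.write("genomes\tn_clusters\tn_proteins\n")
        for key, (nc, np_) in table.items():
            out.write(f"{','.join(key)}\t{nc}\t{np_}\n")
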