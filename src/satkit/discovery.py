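"""Repeat discovery from a random read sample.

A documented, simplified stand-in for graph-based read clustering pipelines
(RepeatExplorer2/TAREAN): reads become nodes of a k-mer sharing graph,
connected components become clusters, and a cluster is called tandem when a
greedily assembled representative shows self-shift periodicity.

The graph is materialized as a shared-k-mer count matrix (sparse), so the
edge set for any ``min_shared`` threshold is a cheap comparison and raising
the threshold can only remove edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from ._seq import (canonical_kmer_spans, canonical_kmers, revcomp,
                   seq_to_array, stable_seed)

logger = logging.getLogger(__name__)


@dataclass
class TandemCall:
    evaluable: bool
    is_tandem: bool = False
    period: int | None = None
    max_match_fraction: float = 0.0


@dataclass
class ReadCluster:
    """One read cluster (CL1, CL2, ... in decreasing member bp)."""

    cluster_id: str
    member_ids: list[str]
    member_indices: list[int] = field(repr=False)
    bp: int = 0
    proportion: float = 0.0
    representative: str | None = None
    is_tandem: bool | None = None
    period: int | None = None

    @property
    def n_reads(self) -> int:
        return len(self.member_ids)


class KmerGraph:
    """Read graph: edge iff two reads share >= min_shared canonical k-mers
    spread over a span of >= min_span bp.

    The span condition guards against chance micro-repeats: an i.i.d.
    genome of megabase scale contains many repeated ~(k+2)-bp substrings
    whose k-mer matches are consecutive, whereas genuine read overlaps (or
    shared repeat content) scatter matches across the read.  ``min_span=0``
    reduces the edge rule to pure k-mer counting.
    """

    def __init__(self, reads, k: int = 13, min_shared: int = 3,
                 min_span: int = 26):
        if k % 2 == 0 or not (11 <= k <= 31):
            raise ValueError("k must be odd and in [11, 31]")
        self.reads = list(reads)
        self.k = k
        self.min_shared = min_shared
        self.min_span = min_span
        self._span_cache: dict[int, dict[int, tuple[int, int]]] = {}
        self._adj: sp.csr_matrix | None = None
        self._shared = self._build_shared_counts()

    def _build_shared_counts(self) -> sp.csr_matrix:
        n = len(self.reads)
        kmer_col: dict[int, int] = {}
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        for i, (_rid, seq) in enumerate(self.reads):
            kms = canonical_kmers(seq, self.k)
            ci = np.empty(len(kms), dtype=np.int64)
            for j, km in enumerate(kms):
                c = kmer_col.get(km)
                if c is None:
                    c = len(kmer_col)
                    kmer_col[km] = c
                ci[j] = c
            cols.append(ci)
            rows.append(np.full(len(kms), i, dtype=np.int64))
        if not rows:
            return sp.csr_matrix((n, n), dtype=np.int32)
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        incidence = sp.csr_matrix(
            (np.ones(r.size, dtype=np.int32), (r, c)),
            shape=(n, len(kmer_col)))
        # k-mers seen in a single read cannot create edges; drop them to
        # keep the product sparse
        per_kmer = np.asarray(incidence.sum(axis=0)).ravel()
        keep = np.nonzero(per_kmer >= 2)[0]
        incidence = incidence[:, keep]
        shared = (incidence @ incidence.T).tocsr()
        shared.setdiag(0)
        shared.eliminate_zeros()
        return shared

    def _spans(self, i: int) -> dict[int, tuple[int, int]]:
        spans = self._span_cache.get(i)
        if spans is None:
            spans = canonical_kmer_spans(self.reads[i][1], self.k)
            self._span_cache[i] = spans
        return spans

    def _span_ok(self, i: int, j: int) -> bool:
        if self.min_span <= 0:
            return True
        shared = self._spans(i).keys() & self._spans(j).keys()
        for spans in (self._spans(i), self._spans(j)):
            lo = min(spans[km][0] for km in shared)
            hi = max(spans[km][1] for km in shared)
            if hi - lo >= self.min_span:
                return True
        return False

    @property
    def adjacency(self) -> sp.csr_matrix:
        if self._adj is not None:
            return self._adj
        cand = sp.triu(self._shared >= self.min_shared, k=1).tocoo()
        rows, cols = [], []
        for i, j in zip(cand.row.tolist(), cand.col.tolist()):
            if self._span_ok(i, j):
                rows.append(i)
                cols.append(j)
        n = len(self.reads)
        adj = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
        self._adj = adj + adj.T
        self._span_cache.clear()
        return self._adj

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self._shared[i, j] >= self.min_shared) \
            and self._span_ok(i, j)

    def shared_count(self, i: int, j: int) -> int:
        return int(self._shared[i, j])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self.reads)))
        coo = sp.triu(self.adjacency, k=1).tocoo()
        g.add_edges_from(zip(coo.row.tolist(), coo.col.tolist()))
        return g


def sample_reads(reads, n: int, seed: int):
    """Uniform sample of ``n`` reads without replacement (original order)."""
    reads = list(reads)
    if n > len(reads):
        raise ValueError(
            f"requested {n} reads but only {len(reads)} are available "
            f"(short by {n - len(reads)})")
    rng = np.random.default_rng(stable_seed(seed, "sample"))
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx]


def build_kmer_graph(reads, k: int = 13, min_shared: int = 3,
                     min_span: int = 26) -> KmerGraph:
    return KmerGraph(reads, k=k, min_shared=min_shared, min_span=min_span)


def cluster_reads(graph: KmerGraph, total_bp: int,
                  min_proportion: float = 1e-5) -> list[ReadCluster]:
    """Connected components above the genome-proportion floor, as clusters.

    Clusters are named CL1, CL2, ... by decreasing member bp (ties broken by
    the smallest member read id).  Discarded components are logged with bp
    accounting so the partition stays auditable.
    """
    n = len(graph.reads)
    if n == 0:
        return []
    n_comp, labels = connected_components(graph.adjacency, directed=False)
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    raw = []
    for members in groups.values():
        bp = sum(len(graph.reads[i][1]) for i in members)
        raw.append((bp, min(graph.reads[i][0] for i in members), members))
    raw.sort(key=lambda t: (-t[0], t[1]))
    clusters = []
    dropped_bp = dropped_n = 0
    for bp, _min_id, members in raw:
        prop = bp / total_bp
        if prop < min_proportion:
            dropped_bp += bp
            dropped_n += 1
            continue
        cid = f"CL{len(clusters) + 1}"
        clusters.append(ReadCluster(
            cluster_id=cid,
            member_ids=[graph.reads[i][0] for i in members],
            member_indices=members,
            bp=bp,
            proportion=prop,
        ))
    kept_bp = sum(c.bp for c in clusters)
    logger.info("clustering: %d clusters kept (%d bp), %d below floor "
                "(%d bp); total %d bp", len(clusters), kept_bp, dropped_n,
                dropped_bp, kept_bp + dropped_bp)
    return clusters


# ---------------------------------------------------------------------------
# Cluster representative
# ---------------------------------------------------------------------------

def _hamming_identity(a: str, b: str) -> float:
    arr_a = seq_to_array(a)
    arr_b = seq_to_array(b)
    return float((arr_a == arr_b).mean())


def build_representative(member_seqs: list[str], max_length: int = 2200,
                         min_overlap: int = 50, min_identity: float = 0.60,
                         k: int = 13, max_members: int = 800,
                         max_candidates: int = 60,
                         degrees: list[int] | None = None) -> str:
    """Greedy overlap extension of the best-connected member read.

    The seed is the member with the highest within-cluster degree (the
    read-graph analogue of the highest-coverage contig; ties to the longer,
    then earlier read) so that clusters that also swept up adjacent
    single-copy reads are still represented by their repeat core.  Members
    overlapping the current end of the representative by at least
    ``min_overlap`` bp at ``min_identity`` identity (both orientations are
    indexed) extend it; the candidate adding the most new sequence wins.
    The identity floor is deliberately permissive so that overlaps between
    different copies of a diverged family still chain, while wrong-phase
    joins (~25% identity) are rejected.
    """
    if not member_seqs:
        raise ValueError("empty cluster")
    members = member_seqs[:max_members]
    if degrees is not None:
        order = sorted(range(len(members)),
                       key=lambda i: (-degrees[i], -len(members[i]), i))
        seed_seq = members[order[0]]
    else:
        seed_seq = max(members, key=len)
    if len(members) == 1:
        return seed_seq

    oriented: list[str] = []
    for s in members:
        oriented.append(s)
        oriented.append(revcomp(s))
    index: dict[str, list[tuple[int, int]]] = {}
    for oi, s in enumerate(oriented):
        for pos in range(0, len(s) - k + 1):
            index.setdefault(s[pos : pos + k], []).append((oi, pos))

    def extend_right(rep: str) -> str:
        while len(rep) < max_length:
            window = min(len(rep), 160)
            seen: set[tuple[int, int]] = set()
            best_ext, best_id, best_seq = 0, 0.0, None
            n_checked = 0
            for p in range(len(rep) - window, len(rep) - k + 1):
                for oi, pos in index.get(rep[p : p + k], ()):
                    offset = p - pos
                    key = (oi, offset)
                    if key in seen or offset < 0:
                        continue
                    seen.add(key)
                    m = oriented[oi]
                    overlap = len(rep) - offset
                    ext = offset + len(m) - len(rep)
                    if overlap < min_overlap or overlap > len(m) or ext <= 0:
                        continue
                    n_checked += 1
                    if n_checked > max_candidates:
                        break
                    ident = _hamming_identity(rep[offset:], m[:overlap])
                    if ident < min_identity:
                        continue
                    if ext > best_ext or (ext == best_ext and ident > best_id):
                        best_ext, best_id, best_seq = ext, ident, m[overlap:]
                if n_checked > max_candidates:
                    break
            if best_seq is None:
                break
            rep = rep + best_seq
        return rep

    rep = extend_right(seed_seq)
    rep = revcomp(extend_right(revcomp(rep)))
    return rep[:max_length]


# ---------------------------------------------------------------------------
# Tandem detection by self-shift periodicity
# ---------------------------------------------------------------------------

def detect_tandem(seq: str, min_period: int = 4,
                  threshold: float = 0.7,
                  local_threshold: float = 0.7,
                  min_local_window: int = 90) -> TandemCall:
    """Self-shift match profile f(s); tandem iff max f(s) >= threshold.

    The reported period is the smallest shift that is a local maximum of
    f with f >= threshold; true periods below ``min_period`` surface as a
    multiple (documented behavior of the shift floor).

    Besides the global match fraction, a windowed variant (best sliding-
    window mean over windows of max(3s, ``min_local_window``) bp, judged
    against the stricter ``local_threshold``) catches short tandem blocks
    embedded in a longer representative — the situation of families whose
    arrays are much shorter than the reads that sample them.  The stricter
    local threshold keeps the maximum-over-windows statistic of random
    sequence (~0.45 at these sizes) well below the firing point.
    """
    L = len(seq)
    if L < 2 * min_period:
        return TandemCall(evaluable=False)
    arr = seq_to_array(seq)
    shifts = np.arange(min_period, L // 2 + 1)
    if shifts.size == 0:
        return TandemCall(evaluable=False)
    offset = local_threshold - threshold
    f = np.empty(shifts.size)
    for idx, s in enumerate(shifts):
        m = (arr[:-s] == arr[s:]).astype(np.float64)
        g = float(m.mean())
        w = min(max(3 * s, min_local_window), m.size)
        if w < m.size:
            c = np.cumsum(np.concatenate([[0.0], m]))
            local = float(((c[w:] - c[:-w]) / w).max())
        else:
            local = g
        # one profile, one threshold: a local block must clear the stricter
        # local_threshold to count as much as a global signal
        f[idx] = max(g, local - offset)
    fmax = float(f.max())
    if fmax < threshold:
        return TandemCall(evaluable=True, is_tandem=False,
                          max_match_fraction=fmax)
    # local maxima (boundary shifts qualify against their single neighbor)
    left_ok = np.empty(f.size, dtype=bool)
    right_ok = np.empty(f.size, dtype=bool)
    left_ok[0] = True
    left_ok[1:] = f[1:] >= f[:-1]
    right_ok[-1] = True
    right_ok[:-1] = f[:-1] >= f[1:]
    is_peak = left_ok & right_ok & (f >= threshold)
    period = int(shifts[np.nonzero(is_peak)[0][0]])
    return TandemCall(evaluable=True, is_tandem=True, period=period,
                      max_match_fraction=fmax)


def annotate_clusters(clusters: list[ReadCluster], reads,
                      rep_max_length: int = 2200, min_overlap: int = 50,
                      min_identity: float = 0.60, min_period: int = 4,
                      tandem_threshold: float = 0.7,
                      graph: KmerGraph | None = None) -> list[ReadCluster]:
    """Fill representative / tandem flag / period for each cluster in place.

    When the originating :class:`KmerGraph` is supplied, representative
    seeding uses within-cluster degrees (highest-coverage member).
    """
    adj = graph.adjacency if graph is not None else None
    for cl in clusters:
        seqs = [reads[i][1] for i in cl.member_indices]
        degrees = None
        if adj is not None:
            sub = adj[cl.member_indices][:, cl.member_indices]
            degrees = np.asarray(sub.sum(axis=1)).ravel().tolist()
        cl.representative = build_representative(
            seqs, max_length=rep_max_length, min_overlap=min_overlap,
            min_identity=min_identity, degrees=degrees)
        call = detect_tandem(cl.representative, min_period=min_period,
                             threshold=tandem_threshold)
        cl.is_tandem = call.is_tandem if call.evaluable else None
        cl.period = call.period
    return clusters
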