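"""Inter-family similarity screening and subfamily minimum spanning networks.

Similarity between family consensuses is screened with rotation-aware local
alignments (the shorter sequence against the doubled longer one, both
strands) and judged against an empirical shuffle null: the observed score is
compared with scores of shuffled queries and significance is read from a
Gumbel (extreme-value) fit to that null — the practical analogue of a
blastn expectation cutoff without reimplementing Karlin-Altschul theory.

Within a family, subfamily consensuses are related by a minimum spanning
network: the union of all minimum spanning trees of their rotation-minimized
edit-distance matrix (epsilon = 0), with edges labeled by mutational steps
and nodes weighted by genomic abundance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import align as _align
from ._seq import stable_seed

logger = logging.getLogger(__name__)


@dataclass
class SimilarityHit:
    family_a: str
    family_b: str
    length: int          # aligned columns of the best local alignment
    identity_pct: float
    score: float
    p_value: float


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def _best_score(short: str, target: str, aligner) -> float:
    from ._seq import revcomp

    return max(aligner.score(target, short),
               aligner.score(target, revcomp(short)))


def pairwise_similarity(consensuses: dict[str, str], threshold: float = 1e-3,
                        n_shuffles: int = 200, seed: int = 0,
                        aligner=None) -> list[SimilarityHit]:
    """All-vs-all similarity screen with a shuffle-null significance test.

    For each pair, the shorter consensus is aligned (both strands) against
    the doubled longer one; ``n_shuffles`` shuffled copies of the query give
    a null score sample, a Gumbel tail fit converts the observed score into
    a p-value, and pairs with p <= ``threshold`` are reported.
    """
    if len(consensuses) < 2:
        raise ValueError("need at least 2 consensuses")
    aligner = aligner or _align.default_aligner()
    names = sorted(consensuses)
    hits: list[SimilarityHit] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = consensuses[a], consensuses[b]
            short, long = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
            target = long + long
            hit, _strand, _cov = _align.rotation_aware_similarity(
                sa, sb, aligner)
            if hit is None:
                continue
            rng = np.random.default_rng(stable_seed(seed, "simnull", a, b))
            null = np.array([
                _best_score(_shuffled(short, rng), target, aligner)
                for _ in range(n_shuffles)])
            # Gumbel tail by method of moments
            beta = null.std(ddof=1) * math.sqrt(6.0) / math.pi
            if beta <= 0:
                p = 0.0 if hit.score > null.max() else 1.0
            else:
                mu = null.mean() - 0.5772156649 * beta
                z = (hit.score - mu) / beta
                p = 1.0 - math.exp(-math.exp(-z))
            if p <= threshold:
                hits.append(SimilarityHit(
                    family_a=a, family_b=b, length=hit.aligned_cols,
                    identity_pct=100.0 * hit.identity, score=hit.score,
                    p_value=p))
    return hits


def pairwise_distance(consensuses: dict[str, str]) -> pd.DataFrame:
    """Rotation-minimized edit-distance matrix between subfamily consensuses."""
    names = list(consensuses)
    if len(names) < 2:
        raise ValueError("need at least 2 subfamily consensuses")
    n = len(names)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = consensuses[names[i]], consensuses[names[j]]
            ratio = max(len(a), len(b)) / min(len(a), len(b))
            if ratio > 3:
                logger.warning("length ratio %.1f between %s and %s exceeds 3",
                               ratio, names[i], names[j])
            d = _align.rotation_distance(a, b)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


def build_msn(distances: pd.DataFrame,
              abundances: dict[str, float] | None = None,
              epsilon: int = 0) -> nx.Graph:
    """Minimum spanning network (union of all MSTs for epsilon = 0).

    Distinct distances are processed in ascending order; an edge at the
    current distance is added iff its endpoints are not yet connected
    through strictly smaller distances (``epsilon`` relaxes the cutoff by
    allowing edges up to ``epsilon`` distance classes beyond connection).
    Node attribute ``abundance``; edge attribute ``steps``.
    """
    mat = distances.to_numpy(dtype=float)
    names = list(distances.index)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.isfinite(mat).all():
        raise ValueError("distance matrix must be finite")
    n = len(names)
    g = nx.Graph()
    for name in names:
        g.add_node(name, abundance=(abundances or {}).get(name, 0.0))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = [(mat[i, j], i, j) for i in range(n) for j in range(i + 1, n)]
    levels = sorted({d for d, _i, _j in pairs})
    # snapshots[t] = component label of each node using distances < levels[t]
    snapshots: list[list[int]] = []
    for t, d in enumerate(levels):
        snapshots.append([find(x) for x in range(n)])
        ref = snapshots[max(t - epsilon, 0)]
        batch = [(i, j) for dd, i, j in pairs if dd == d]
        for i, j in batch:
            if ref[i] != ref[j]:
                g.add_edge(names[i], names[j],
                           steps=int(d) if d == int(d) else float(d))
        for i, j in batch:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return g
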