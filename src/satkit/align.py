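"""Shared alignment primitives.

Local (Smith-Waterman-style) alignments go through Biopython's
``PairwiseAligner``; plain edit distances through edlib.  Everything that
needs transition/transversion bookkeeping funnels through :func:`local_hit`,
so substitution classification lives in exactly one place.

Conventions: transitions are A<->G and C<->T; gap columns never contribute
to P (transition proportion) or Q (transversion proportion).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align

from ._seq import revcomp, seq_to_array

# base -> code such that code//2 identifies the purine/pyrimidine pair:
# A=0, G=1 (purines), C=2, T=3 (pyrimidines)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i


def make_aligner(match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -3.0, gap_extend: float = -1.0,
                 mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@lru_cache(maxsize=None)
def default_aligner() -> Align.PairwiseAligner:
    return make_aligner()


@dataclass
class LocalHit:
    """One local alignment of a query against a target sequence."""

    score: float
    q_start: int
    q_end: int          # 0-based half-open on the query
    t_start: int
    t_end: int
    aligned_cols: int   # matched columns, gaps excluded
    matches: int
    transitions: int
    transversions: int

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_cols if self.aligned_cols else 0.0

    @property
    def p_transitions(self) -> float:
        return self.transitions / self.aligned_cols if self.aligned_cols else 0.0

    @property
    def q_transversions(self) -> float:
        return self.transversions / self.aligned_cols if self.aligned_cols else 0.0


def _classify_blocks(target: str, query: str, t_blocks, q_blocks):
    """Count matches / transitions / transversions over aligned blocks."""
    t_arr = _CODE[seq_to_array(target)]
    q_arr = _CODE[seq_to_array(query)]
    matches = transitions = transversions = cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        a = t_arr[ts:te]
        b = q_arr[qs:qe]
        ok = (a >= 0) & (b >= 0)
        eq = (a == b) & ok
        diff = ~eq & ok
        ts_mask = diff & ((a >> 1) == (b >> 1))
        matches += int(eq.sum())
        transitions += int(ts_mask.sum())
        transversions += int((diff & ~ts_mask).sum())
        cols += int(ok.sum())
    return matches, transitions, transversions, cols


def local_hit(target: str, query: str,
              aligner: Align.PairwiseAligner | None = None) -> LocalHit | None:
    """Best local alignment of ``query`` against ``target``.

    Returns ``None`` when no positive-score alignment exists.
    """
    aligner = aligner or default_aligner()
    try:
        alignments = aligner.align(target, query)
        if len(alignments) == 0:
            return None
        aln = alignments[0]
    except (OverflowError, MemoryError):  # degenerate co-optimal explosion
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    m, ts, tv, cols = _classify_blocks(target, query, t_blocks, q_blocks)
    return LocalHit(
        score=float(aln.score),
        q_start=int(q_blocks[0][0]), q_end=int(q_blocks[-1][1]),
        t_start=int(t_blocks[0][0]), t_end=int(t_blocks[-1][1]),
        aligned_cols=cols, matches=m, transitions=ts, transversions=tv,
    )


def local_score(target: str, query: str,
                aligner: Align.PairwiseAligner | None = None) -> float:
    """Score-only local alignment (no traceback; much faster)."""
    aligner = aligner or default_aligner()
    return float(aligner.score(target, query))


# ---------------------------------------------------------------------------
# Rotations (tandem monomers are circular permutations of one another)
# ---------------------------------------------------------------------------

def rotate(seq: str, r: int) -> str:
    """Right rotation: the last ``r`` characters move to the front."""
    r %= len(seq)
    if r == 0:
        return seq
    return seq[-r:] + seq[:-r]


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def rotation_min_edit(monomer: str, reference: str) -> tuple[int, int]:
    """Rotation of ``monomer`` minimizing edit distance to ``reference``.

    Exhaustive over all rotations; ties broken by the smallest rotation
    offset.  Returns ``(rotation, distance)``.
    """
    if not monomer or not reference:
        raise ValueError("rotation_min_edit requires non-empty sequences")
    best_r, best_d = 0, None
    for r in range(len(monomer)):
        d = edit_distance(rotate(monomer, r), reference)
        if best_d is None or d < best_d:
            best_r, best_d = r, d
            if d == 0:
                break
    return best_r, int(best_d)


def rotation_distance(a: str, b: str) -> int:
    """Rotation-minimized edit distance (symmetrized by construction)."""
    _, d = rotation_min_edit(a, b)
    return d


def rotation_aware_similarity(a: str, b: str,
                              aligner: Align.PairwiseAligner | None = None):
    """Best local alignment of the shorter sequence against the doubled
    longer one, on both strands, exposing junction-spanning similarity.

    Returns ``(hit, strand, coverage_of_shorter)`` or ``(None, None, 0.0)``.
    """
    short, long = (a, b) if len(a) <= len(b) else (b, a)
    target = long + long
    best, best_strand = None, None
    for strand, query in (("+", short), ("-", revcomp(short))):
        hit = local_hit(target, query, aligner)
        if hit is not None and (best is None or hit.score > best.score):
            best, best_strand = hit, strand
    if best is None:
        return None, None, 0.0
    coverage = (best.q_end - best.q_start) / len(short)
    return best, best_strand, min(coverage, 1.0)
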