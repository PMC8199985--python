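"""RepeatMasker-style quantification of satellite families from reads.

Sampled reads are aligned (k-mer-seeded, gapped, local, both strands)
against the family reference collection (dimers / ~200-bp monomer
concatenations).  Overlapping hits on a read are resolved greedily by score
so every base is masked at most once; per-hit transition/transversion
proportions give a Kimura 2-parameter distance

    K = -1/2 ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P the transition and Q the transversion proportion over gap-free
aligned columns.  Genome proportion = masked bp / total sampled bp; repeat
landscapes bin masked bp by K in 1-percentage-point bins [0, 50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import align as _align
from ._seq import canonical_kmers, revcomp

LANDSCAPE_MAX_BIN = 49  # bins [i, i+1) percent for i = 0..49


@dataclass
class RepeatHit:
    """One read-vs-reference local alignment, after strand resolution."""

    read_id: str
    family: str
    start: int           # 0-based half-open interval on the read
    end: int
    aligned_cols: int    # gap-free aligned columns
    P: float             # transition proportion
    Q: float             # transversion proportion
    K: float             # Kimura-2P distance; NaN when outside the domain
    score: float
    strand: str

    @property
    def masked_bp(self) -> int:
        return self.end - self.start


def kimura2p(P: float, Q: float) -> float:
    """Kimura 2-parameter distance; NaN outside the formula's domain.

    Defined iff 1-2P-Q > 0 and 1-2Q > 0.  Out-of-domain hits are flagged
    (NaN) and excluded from divergence means but keep their masked bp.
    """
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValueError("require P >= 0, Q >= 0, P + Q <= 1")
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return math.nan
    return -0.5 * math.log(a * math.sqrt(b))


class ReferenceSet:
    """Reference collection with an 11-mer seed index for candidate lookup."""

    def __init__(self, references: Mapping[str, str], k: int = 11):
        if not references:
            raise ValueError("empty reference set")
        self.references = {name: seq.upper() for name, seq in references.items()}
        self.k = k
        self._index: dict[int, set[str]] = {}
        for name, seq in self.references.items():
            for km in canonical_kmers(seq, k):
                self._index.setdefault(km, set()).add(name)

    def candidates(self, read: str) -> list[str]:
        names: set[str] = set()
        for km in canonical_kmers(read, self.k):
            hit = self._index.get(km)
            if hit:
                names |= hit
        return sorted(names)


def map_reads(reads: Iterable[tuple[str, str]],
              references: Mapping[str, str] | ReferenceSet,
              min_score: float = 30.0, k: int = 11,
              aligner=None) -> list[RepeatHit]:
    """Map reads against the reference collection on both strands.

    Candidate references are pre-filtered by shared canonical k-mers
    (canonical = strand-symmetric, so the filter cannot miss a minus-strand
    hit).  For each read/reference pair the better strand is kept; hits
    below ``min_score`` are dropped.
    """
    refset = references if isinstance(references, ReferenceSet) \
        else ReferenceSet(references, k=k)
    aligner = aligner or _align.default_aligner()
    hits: list[RepeatHit] = []
    for read_id, seq in reads:
        cands = refset.candidates(seq)
        if not cands:
            continue
        rc = revcomp(seq)
        L = len(seq)
        for name in cands:
            target = refset.references[name]
            s_plus = aligner.score(target, seq)
            s_minus = aligner.score(target, rc)
            if max(s_plus, s_minus) < min_score:
                continue
            if s_plus >= s_minus:
                strand, query = "+", seq
            else:
                strand, query = "-", rc
            hit = _align.local_hit(target, query, aligner)
            if hit is None or hit.score < min_score:
                continue
            if strand == "+":
                start, end = hit.q_start, hit.q_end
            else:  # map back to forward-read coordinates
                start, end = L - hit.q_end, L - hit.q_start
            P, Q = hit.p_transitions, hit.q_transversions
            hits.append(RepeatHit(
                read_id=read_id, family=name, start=start, end=end,
                aligned_cols=hit.aligned_cols, P=P, Q=Q,
                K=kimura2p(P, Q) if hit.aligned_cols else math.nan,
                score=hit.score, strand=strand))
    return hits


def resolve_read_overlaps(hits: Sequence[RepeatHit],
                          max_overlap: int = 10) -> list[RepeatHit]:
    """Greedy per-read overlap resolution (each bp masked at most once).

    Hits are taken in descending score order (ties: family name, start); a
    hit is kept iff it overlaps every already-kept hit by fewer than
    ``max_overlap`` bp, and is then trimmed to remove residual overlap.
    """
    kept: list[RepeatHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.family, h.start)):
        start, end = hit.start, hit.end
        ok = True
        for other in kept:
            ov = min(end, other.end) - max(start, other.start)
            if ov >= max_overlap:
                ok = False
                break
        if not ok:
            continue
        for other in kept:  # trim residual overlap off the new hit
            ov = min(end, other.end) - max(start, other.start)
            if ov <= 0:
                continue
            if other.start <= start:
                start = other.end
            else:
                end = other.start
        if end - start <= 0:
            continue
        kept.append(RepeatHit(
            read_id=hit.read_id, family=hit.family, start=start, end=end,
            aligned_cols=hit.aligned_cols, P=hit.P, Q=hit.Q, K=hit.K,
            score=hit.score, strand=hit.strand))
    kept.sort(key=lambda h: h.start)
    return kept


def resolve_overlaps(hits: Iterable[RepeatHit],
                     max_overlap: int = 10) -> list[RepeatHit]:
    """Apply :func:`resolve_read_overlaps` to every read's hit set."""
    by_read: dict[str, list[RepeatHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    resolved: list[RepeatHit] = []
    for read_id in by_read:
        resolved.extend(resolve_read_overlaps(by_read[read_id], max_overlap))
    return resolved


def family_abundance(hits: Iterable[RepeatHit], total_bp: int,
                     family_of: Mapping[str, str] | None = None) -> pd.Series:
    """Genome proportion (fraction) per family: masked bp / total bp.

    ``family_of`` maps subfamily reference names to family names, so
    subfamily masked bp sums into its family.
    """
    masked: dict[str, int] = {}
    for h in hits:
        fam = family_of.get(h.family, h.family) if family_of else h.family
        masked[fam] = masked.get(fam, 0) + h.masked_bp
    return pd.Series({fam: bp / total_bp for fam, bp in sorted(masked.items())},
                     dtype=float)


def family_divergence(hits: Iterable[RepeatHit],
                      family_of: Mapping[str, str] | None = None) -> pd.Series:
    """Mean Kimura divergence (%) per family, weighted by aligned columns."""
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for h in hits:
        fam = family_of.get(h.family, h.family) if family_of else h.family
        den.setdefault(fam, 0.0)
        num.setdefault(fam, 0.0)
        if not math.isnan(h.K):
            num[fam] += h.K * h.aligned_cols
            den[fam] += h.aligned_cols
    out = {}
    for fam in num:
        out[fam] = 100.0 * num[fam] / den[fam] if den[fam] > 0 else math.nan
    return pd.Series(out, dtype=float).sort_index()


def landscape(hits: Iterable[RepeatHit], total_bp: int,
              family_of: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Repeat landscape: masked bp per family per 1%-wide divergence bin.

    Hits with undefined K land in the top bin so masked bp stays conserved.
    """
    acc: dict[tuple[str, int], int] = {}
    for h in hits:
        fam = family_of.get(h.family, h.family) if family_of else h.family
        if math.isnan(h.K):
            b = LANDSCAPE_MAX_BIN
        else:
            b = min(int(math.floor(100.0 * h.K)), LANDSCAPE_MAX_BIN)
        acc[(fam, b)] = acc.get((fam, b), 0) + h.masked_bp
    rows = [{"family": fam, "bin_low": b, "bin_high": b + 1, "bp": bp,
             "pct_genome": 100.0 * bp / total_bp}
            for (fam, b), bp in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["family", "bin_low", "bin_high",
                                       "bp", "pct_genome"])


@dataclass
class SummaryStats:
    """Summary-table footer: mean / sample SD (n-1) / median per column,
    plus the total genome proportion."""

    n_rows: int
    mean_length: float
    sd_length: float
    median_length: float
    mean_at: float
    sd_at: float
    median_at: float
    mean_divergence: float
    sd_divergence: float
    median_divergence: float
    total_proportion_pct: float


def summarize_table(table: pd.DataFrame) -> SummaryStats:
    """Footer statistics over a family table.

    Expects columns ``repeat_length_bp``, ``at_pct``, ``divergence_pct``,
    ``genome_proportion_pct``; all rows (including declared short-motif
    rows) enter the statistics.  SD is the sample SD (n-1); with fewer than
    2 rows it is NaN.
    """
    n = len(table)
    if n == 0:
        raise ValueError("empty family table")

    def col(name):
        return pd.to_numeric(table[name], errors="raise").to_numpy(dtype=float)

    length = col("repeat_length_bp")
    at = col("at_pct")
    div = col("divergence_pct")
    prop = col("genome_proportion_pct")

    def sd(x):
        return float(np.std(x, ddof=1)) if n >= 2 else math.nan

    return SummaryStats(
        n_rows=n,
        mean_length=float(length.mean()), sd_length=sd(length),
        median_length=float(np.median(length)),
        mean_at=float(at.mean()), sd_at=sd(at),
        median_at=float(np.median(at)),
        mean_divergence=float(div.mean()), sd_divergence=sd(div),
        median_divergence=float(np.median(div)),
        total_proportion_pct=float(prop.sum()),
    )
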