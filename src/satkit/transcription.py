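"""Satellite DNA transcription across tissue RNA-seq samples.

Reads are assigned to exactly one family reference each (best alignment
score, ties to the lexicographically first name; unassigned reads fall into
a background bucket standing in for the transcriptome).  Counts are
CPM-normalized against the total counted reads, families with more than
50 CPM in at least 2 samples are retained, and tissue-group means classify
each family into one of four patterns:

    P1 ubiquitous      no tissue group dominates
    P2 antenna-biased  antenna share of the group-mean total >= 0.7
    P3 gonad-biased    ovary+testis share >= 0.7, neither gonad alone >= 0.7
    P4 single-gonad    one gonad's share >= 0.7

Transcription level is finally correlated with genomic abundance by
Spearman rank correlation (exact permutation p for small n).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import quantify as _quantify

BACKGROUND = "__background__"

PATTERNS = {
    "P1": "ubiquitous",
    "P2": "antenna-biased",
    "P3": "gonad-biased",
    "P4": "single-gonad",
}


@dataclass
class CorrelationResult:
    rs: float
    p_value: float
    n: int


def count_rna_reads(reads, references, max_divergence: float = 0.35,
                    k: int = 11) -> tuple[pd.Series, int]:
    """Per-family read counts for one sample.

    Each read increments exactly one family: the reference with the best
    alignment (smallest semi-global edit distance of the read inside the
    reference, both strands; ties go to the lexicographically first name).
    Reads whose best distance exceeds ``max_divergence`` per read base —
    or that share no seed k-mer with any reference — count toward the
    background bucket.  Returns ``(counts, background_count)``.
    """
    import edlib

    from ._seq import revcomp

    reads = list(reads)
    if not reads:
        raise ValueError("empty sample")
    refset = references if isinstance(references, _quantify.ReferenceSet) \
        else _quantify.ReferenceSet(references, k=k)
    counts = {name: 0 for name in refset.references}
    background = 0
    for _rid, seq in reads:
        cands = refset.candidates(seq)
        best_name, best_d = None, None
        limit = int(max_divergence * len(seq))
        if cands:
            rc = revcomp(seq)
            for name in cands:  # sorted, so ties keep the first name
                target = refset.references[name]
                ds = [r["editDistance"] for r in (
                    edlib.align(seq, target, mode="HW", task="distance", k=limit),
                    edlib.align(rc, target, mode="HW", task="distance", k=limit),
                ) if r["editDistance"] >= 0]
                if not ds:
                    continue
                d = min(ds)
                if best_d is None or d < best_d:
                    best_name, best_d = name, d
        if best_name is None:
            background += 1
        else:
            counts[best_name] += 1
    return pd.Series(counts).sort_index(), background


def cpm_normalize(counts: pd.DataFrame,
                  totals: pd.Series | None = None) -> pd.DataFrame:
    """Counts-per-million: count / total counted reads x 1e6 per sample.

    ``totals`` defaults to the column sums of ``counts`` (which should then
    include the background bucket so CPM is relative to the whole library).
    """
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero library total for sample(s): {bad}")
    return counts.div(totals, axis=1) * 1e6


def filter_expressed(cpm: pd.DataFrame, min_cpm: float = 50.0,
                     min_samples: int = 2) -> pd.DataFrame:
    """Retain families with CPM strictly above ``min_cpm`` in at least
    ``min_samples`` samples."""
    if cpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return cpm.loc[keep]


def classify_pattern(antenna: float, ovary: float, testis: float,
                     dominance: float = 0.7) -> str:
    """Classify tissue-group means into one of the four patterns."""
    if antenna < 0 or ovary < 0 or testis < 0:
        raise ValueError("group means must be >= 0")
    total = antenna + ovary + testis
    if total == 0:
        raise ValueError("all tissue-group means are zero: not classifiable")
    a, o, t = antenna / total, ovary / total, testis / total
    if a >= dominance:
        return "P2"
    if o >= dominance or t >= dominance:
        return "P4"
    if o + t >= dominance:
        return "P3"
    return "P1"


def classify_families(cpm: pd.DataFrame, antenna_samples: list[str],
                      ovary_sample: str, testis_sample: str,
                      dominance: float = 0.7) -> pd.DataFrame:
    """Group means + pattern label per retained family.

    Antenna is the mean over its (typically three) samples; each gonad
    group is a single sample, mirroring a 3-antenna + 2-gonad design.
    """
    out = pd.DataFrame(index=cpm.index)
    out["antenna"] = cpm[antenna_samples].mean(axis=1)
    out["ovary"] = cpm[ovary_sample]
    out["testis"] = cpm[testis_sample]
    out["pattern"] = [
        classify_pattern(r.antenna, r.ovary, r.testis, dominance)
        for r in out.itertuples()
    ]
    return out


def _spearman_rs(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def correlate_abundance(expression: pd.Series, proportions: pd.Series,
                        exact_max_n: int = 9) -> CorrelationResult:
    """Spearman correlation between transcription level and genome
    proportion over the families present in both inputs.

    Two-sided p-value from the t approximation, or from exact enumeration
    of rank permutations when n <= ``exact_max_n``.
    """
    common = expression.index.intersection(proportions.index)
    n = len(common)
    if n < 5:
        raise ValueError(f"need at least 5 families, got {n}")
    x = expression.loc[common].to_numpy(dtype=float)
    y = proportions.loc[common].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector: correlation not available")
    rs = _spearman_rs(x, y)
    if n <= exact_max_n:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = abs(rs)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        p = count / total
    else:
        # t approximation on rs
        t = rs * math.sqrt((n - 2) / max(1e-300, 1.0 - rs * rs))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        p = min(p, 1.0)
    return CorrelationResult(rs=rs, p_value=p, n=n)
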