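"""Monomer consensus building and family assembly.

Tandem representatives are cut into monomer-length windows, rotation-
normalized (monomers of a tandem array are circular permutations of one
another), multiple-aligned with MAFFT, and collapsed to a majority-rule
consensus.  Cluster consensuses are then merged into families by
single-linkage similarity and named by decreasing genomic abundance
(``<Prefix>Sat<rank>-<length>``).

The consensus is concrete DNA (no IUPAC ambiguity codes): ties between
bases break alphabetically, and a column is dropped when the gap symbol is
the strict plurality.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import AlignIO

from . import align as _align
from ._seq import at_fraction, revcomp, seq_to_array

_BASE_ORDER = "ACGT"  # alphabetic tie-break order
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASE_ORDER):
    _CODE[ord(_b)] = _i


@dataclass
class SatFamilyRecord:
    """One named satellite DNA family (one summary-table row)."""

    name: str
    consensus: str
    genome_proportion_pct: float
    divergence_pct: float | None
    n_clusters: int
    subfamilies: list[tuple[str, str]] = field(default_factory=list)
    # (subfamily label, consensus) pairs; singleton families keep one entry

    @property
    def monomer_length(self) -> int:
        return len(self.consensus)

    @property
    def at_pct(self) -> float:
        return 100.0 * at_fraction(self.consensus)


def extract_monomers(representative: str, period: int) -> list[str]:
    """Cut a tandem representative into consecutive monomer windows."""
    if period < 2:
        raise ValueError("period must be >= 2")
    if len(representative) < 2 * period:
        raise ValueError(
            f"representative too short for two monomers "
            f"({len(representative)} bp < 2 x {period} bp)")
    n = len(representative) // period
    return [representative[i * period : (i + 1) * period] for i in range(n)]


def rotate_align(monomer: str, reference: str) -> tuple[int, int]:
    """Rotation of ``monomer`` minimizing edit distance to ``reference``.

    Exhaustive over rotations, ties to the smallest offset.
    """
    return _align.rotation_min_edit(monomer, reference)


def _fast_best_rotation(monomer: str, reference: str) -> str:
    """Approximate best rotation via an infix alignment on the doubled
    monomer (used internally for long monomers where the exhaustive scan
    is wasteful)."""
    import edlib

    res = edlib.align(reference, monomer + monomer, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return monomer
    start = res["locations"][0][0]
    return _align.rotate(monomer, start % len(monomer))


def _run_mafft(seqs: list[str]) -> list[str]:
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "monomers.fa"
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">m{i}\n{s}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--retree", "2", "--maxiterate", "0", str(path)],
            capture_output=True, text=True, check=True)
    aln = AlignIO.read(StringIO(proc.stdout), "fasta")
    ordered = sorted(aln, key=lambda r: int(r.id[1:]))
    return [str(r.seq).upper() for r in ordered]


def _majority_consensus(aligned: list[str]) -> str:
    mat = np.array([list(s) for s in aligned])
    out = []
    for col in mat.T:
        counts = {b: 0 for b in "ACGT-"}
        for ch in col:
            counts[ch if ch in counts else "-"] += 1
        gap = counts.pop("-")
        best_base = max("ACGT", key=lambda b: (counts[b], -_BASE_ORDER.index(b)))
        if gap > counts[best_base]:
            continue  # gap-majority column removed
        out.append(best_base)
    return "".join(out)


def build_consensus(monomers: list[str], max_monomers: int = 100) -> str:
    """Majority-rule consensus of rotation-normalized monomers.

    Monomers are rotated to best match the longest one, aligned with MAFFT,
    and collapsed column-wise (plurality base; alphabetic tie-break;
    gap-plurality columns removed).
    """
    if len(monomers) < 2:
        raise ValueError("need at least 2 monomers for a consensus")
    if len(monomers) > max_monomers:
        # deterministic even subsample preserving input order
        idx = np.linspace(0, len(monomers) - 1, max_monomers).astype(int)
        monomers = [monomers[i] for i in np.unique(idx)]
    reference = max(monomers, key=len)
    rotated = []
    for m in monomers:
        if len(m) > 300:
            rotated.append(_fast_best_rotation(m, reference))
        else:
            r, _ = rotate_align(m, reference)
            rotated.append(_align.rotate(m, r))
    aligned = _run_mafft(rotated)
    cons = _majority_consensus(aligned)
    return cons if cons else reference


def polish_consensus(consensus: str, reads: list[str], rounds: int = 2,
                     min_score: float = 30.0, max_reads: int = 2000) -> str:
    """Pileup-polish a consensus against cluster reads.

    Reads are locally aligned to the doubled consensus (both strands, best
    orientation kept) and each consensus column is replaced by the plurality
    base of its pileup.  Substitution-only: indel refinement is out of scope
    at the divergence levels the pipeline targets.  Converges in 1-2 rounds.
    """
    reads = reads[:max_reads]
    aligner = _align.default_aligner()
    for _ in range(rounds):
        L = len(consensus)
        target = consensus + consensus
        counts = np.zeros((4, 2 * L), dtype=np.int64)
        for read in reads:
            s_plus = aligner.score(target, read)
            s_minus = aligner.score(target, revcomp(read))
            if max(s_plus, s_minus) < min_score:
                continue
            best_seq = read if s_plus >= s_minus else revcomp(read)
            aln = aligner.align(target, best_seq)[0]
            t_blocks, q_blocks = aln.aligned
            q_codes = _CODE[seq_to_array(best_seq)]
            for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
                block = q_codes[qs:qe]
                ok = block >= 0
                np.add.at(counts, (block[ok], np.arange(ts, te)[ok]), 1)
        folded = counts[:, :L] + counts[:, L:]
        new = list(consensus)
        cur_codes = _CODE[seq_to_array(consensus)]
        for j in range(L):
            col = folded[:, j]
            if col.sum() == 0:
                continue
            top = int(col.max())
            winners = np.nonzero(col == top)[0]
            if cur_codes[j] in winners:
                continue  # current base ties or wins: keep for stability
            new[j] = _BASE_ORDER[int(winners[0])]
        new_cons = "".join(new)
        if new_cons == consensus:
            break
        consensus = new_cons
    return consensus


def assign_subfamilies(consensuses: list[str], min_identity: float = 0.80,
                       min_coverage: float = 0.50,
                       min_align_cols: int = 30) -> list[list[int]]:
    """Single-linkage grouping of cluster consensuses into families.

    Two consensuses join one family iff a rotation-aware local alignment
    covers at least ``min_coverage`` of the shorter at ``min_identity``
    identity over at least ``min_align_cols`` gap-free columns (the
    absolute floor keeps chance ~20-column alignments against short
    monomers from bridging unrelated families).  Returns groups of input
    indices; order-independent up to group ordering (groups are sorted by
    smallest index).
    """
    n = len(consensuses)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            hit, _strand, coverage = _align.rotation_aware_similarity(
                consensuses[i], consensuses[j])
            if hit is None:
                continue
            if (coverage >= min_coverage and hit.identity >= min_identity
                    and hit.aligned_cols >= min(min_align_cols,
                                                min(len(consensuses[i]),
                                                    len(consensuses[j])))):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: min(g))


def name_families(families: list[dict], prefix: str = "Rpro") -> list[SatFamilyRecord]:
    """Name families by decreasing abundance: ``<prefix>Sat<NN>-<length>``.

    ``families`` entries need: consensus, genome_proportion_pct,
    divergence_pct, n_clusters, subfamilies (optional).  Rank ties break by
    decreasing consensus length, then lexicographic consensus.
    """
    ordered = sorted(
        families,
        key=lambda f: (-f["genome_proportion_pct"], -len(f["consensus"]),
                       f["consensus"]))
    records = []
    for rank, fam in enumerate(ordered, start=1):
        name = f"{prefix}Sat{rank:02d}-{len(fam['consensus'])}"
        records.append(SatFamilyRecord(
            name=name,
            consensus=fam["consensus"],
            genome_proportion_pct=fam["genome_proportion_pct"],
            divergence_pct=fam.get("divergence_pct"),
            n_clusters=fam.get("n_clusters", 1),
            subfamilies=fam.get("subfamilies", []),
        ))
    return records


def build_reference(consensus: str) -> str:
    """Dimer / ~200-bp concatenation reference for read mapping.

    The consensus is repeated ``max(2, ceil(200 / L))`` times so that the
    reference is both at least two monomers and roughly 200 bp or longer.
    """
    if len(consensus) < 4:
        raise ValueError("consensus must be at least 4 bp")
    c = max(2, math.ceil(200 / len(consensus)))
    return consensus * c
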