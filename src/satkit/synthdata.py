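"""Synthetic satellitomes with machine-readable ground truth.

Generates (i) genomes whose satellite fraction is organized in tandem arrays
of mutated monomer copies, (ii) paired-end genomic reads, (iii) assembly
pseudo-reads, and (iv) RNA-seq libraries with per-family expression weights.
Every generator is a pure function of its parameters and a seed, and every
genome comes with an :class:`ArrayTruth` table so parameter-recovery tests
never have to re-derive what was planted.

Model notes
-----------
* ``divergence`` is the per-site substitution probability of a copy relative
  to its consensus (a p-distance).  Because downstream divergence estimates
  are Kimura-2P corrected, :class:`ArrayTruth` records the *realized* K2P
  divergence (computed from the realized transition/transversion counts) as
  the recovery target, alongside the raw p-distance.
* Substitutions choose a transition with probability ``ts_tv_ratio /
  (ts_tv_ratio + 1)``; transversions pick either partner equally.
* Indels are single-base, insertion/deletion equiprobable.
* Background sequence is i.i.d. uniform at a configurable A+T (default 0.65).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp, seq_to_array, stable_seed

logger = logging.getLogger(__name__)

_BASES_AGCT = np.frombuffer(b"AGCT", dtype=np.uint8)  # code: A=0 G=1 C=2 T=3
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i


class PlacementError(RuntimeError):
    """Raised when tandem arrays cannot be placed without overlap."""


@dataclass
class SatFamilySpec:
    """Parameters of one simulated satellite DNA family."""

    name: str
    monomer: str
    target_proportion: float
    divergence: float = 0.05
    ts_tv_ratio: float = 2.0
    indel_rate: float = 0.0
    n_arrays: int = 1
    subfamily_of: str | None = None

    def __post_init__(self) -> None:
        self.monomer = self.monomer.upper()
        if not (30 <= len(self.monomer) <= 1000):
            raise ValueError(f"{self.name}: monomer length must be in [30, 1000]")
        if set(self.monomer) - set("ACGT"):
            raise ValueError(f"{self.name}: monomer alphabet must be ACGT")
        if not (0.0 <= self.target_proportion <= 0.35):
            raise ValueError(f"{self.name}: target_proportion must be in [0, 0.35]")
        if not (0.0 <= self.divergence <= 0.3):
            raise ValueError(f"{self.name}: divergence must be in [0, 0.3]")
        if self.ts_tv_ratio < 0:
            raise ValueError(f"{self.name}: ts_tv_ratio must be >= 0")
        if not (0.0 <= self.indel_rate <= 0.05):
            raise ValueError(f"{self.name}: indel_rate must be in [0, 0.05]")
        if self.n_arrays < 1:
            raise ValueError(f"{self.name}: n_arrays must be >= 1")


@dataclass
class ArrayInterval:
    scaffold: str
    start: int          # 0-based half-open
    end: int
    family: str
    copies: int
    mean_divergence: float  # realized p-distance of the copies in this array


@dataclass
class ArrayTruth:
    """Ground truth emitted by :func:`build_genome`."""

    genome_length: int
    intervals: list[ArrayInterval]
    family_stats: pd.DataFrame = field(repr=False)
    # columns: family, realized_proportion, realized_p_distance,
    #          realized_divergence (K2P, fraction), n_copies, monomer_length

    def proportion(self, family: str) -> float:
        row = self.family_stats.loc[self.family_stats["family"] == family]
        return float(row["realized_proportion"].iloc[0])

    def divergence(self, family: str) -> float:
        row = self.family_stats.loc[self.family_stats["family"] == family]
        return float(row["realized_divergence"].iloc[0])

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.family}"
                         f"\t{iv.copies}\t.\n")

    def to_tsv(self, path) -> None:
        self.family_stats.to_csv(path, sep="\t", index=False)

    @property
    def satellite_fraction(self) -> float:
        return sum(iv.end - iv.start for iv in self.intervals) / self.genome_length


# ---------------------------------------------------------------------------
# Consensus + copy mutation
# ---------------------------------------------------------------------------

def make_consensus(length: int, at_content: float, seed: int) -> str:
    """Random monomer consensus of given length and expected A+T fraction."""
    if length < 4:
        raise ValueError("consensus length must be >= 4")
    if not (0.0 <= at_content <= 1.0):
        raise ValueError("at_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return random_dna(length, rng, at_content)


def _mutate_array(codes: np.ndarray, n_copies: int, divergence: float,
                  ts_tv_ratio: float, indel_rate: float,
                  rng: np.random.Generator):
    """Mutate ``n_copies`` copies of a monomer (given as AGCT codes) at once.

    Returns (concatenated sequence string, n_transitions, n_transversions,
    n_sites).  Sites = monomer length x copies (substitution opportunities);
    indels do not count as substitution sites.
    """
    L = codes.size
    tiled = np.tile(codes, n_copies).astype(np.int8)
    n = tiled.size
    sub_mask = rng.random(n) < divergence
    n_sub = int(sub_mask.sum())
    n_ts = n_tv = 0
    if n_sub:
        p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0) if ts_tv_ratio > 0 else 0.0
        is_ts = rng.random(n_sub) < p_ts
        orig = tiled[sub_mask]
        new = np.empty(n_sub, dtype=np.int8)
        # transition partner flips the low bit within the purine/pyrimidine pair
        new[is_ts] = orig[is_ts] ^ 1
        # transversion: jump to the other pair, either member equally
        n_tv_draw = int((~is_ts).sum())
        other_pair = (1 - (orig[~is_ts] >> 1)) * 2
        new[~is_ts] = other_pair + rng.integers(0, 2, size=n_tv_draw).astype(np.int8)
        tiled[sub_mask] = new
        n_ts = int(is_ts.sum())
        n_tv = n_tv_draw
    if indel_rate > 0:
        indel_mask = rng.random(n) < indel_rate
        idx = np.nonzero(indel_mask)[0]
        if idx.size:
            is_del = rng.random(idx.size) < 0.5
            del_idx = idx[is_del]
            ins_idx = idx[~is_del]
            ins_base = rng.integers(0, 4, size=ins_idx.size).astype(np.int8)
            keep = np.ones(n, dtype=bool)
            keep[del_idx] = False
            pieces: list[np.ndarray] = []
            last = 0
            for pos, base in zip(ins_idx, ins_base):
                pieces.append(tiled[last:pos][keep[last:pos]])
                pieces.append(np.array([base], dtype=np.int8))
                last = pos
            pieces.append(tiled[last:][keep[last:]])
            tiled = np.concatenate(pieces)
    seq = _BASES_AGCT[tiled].tobytes().decode("ascii")
    return seq, n_ts, n_tv, n

def mutate_copy(monomer: str, divergence: float, ts_tv_ratio: float = 2.0,
                indel_rate: float = 0.0,
                rng: np.random.Generator | None = None) -> str:
    """One mutated copy of ``monomer`` (see module notes for the model)."""
    if not (0.0 <= divergence <= 0.3):
        raise ValueError("divergence must be in [0, 0.3]")
    if rng is None:
        rng = np.random.default_rng()
    codes = _CODE[seq_to_array(monomer.upper())]
    if (codes < 0).any():
        raise ValueError("monomer alphabet must be ACGT")
    seq, _, _, _ = _mutate_array(codes, 1, divergence, ts_tv_ratio, indel_rate, rng)
    return seq


def kimura2p_from_counts(n_ts: int, n_tv: int, n_sites: int) -> float:
    """Pooled-count K2P distance; NaN outside the formula's domain."""
    if n_sites == 0:
        return float("nan")
    P = n_ts / n_sites
    Q = n_tv / n_sites
    a, b = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return float("nan")
    return -0.5 * math.log(a * math.sqrt(b))


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def build_genome(specs: Sequence[SatFamilySpec], genome_length: int, seed: int,
                 background_at: float = 0.65, n_scaffolds: int = 1,
                 max_retries: int = 1000) -> tuple[dict[str, str], ArrayTruth]:
    """Random background genome with planted tandem arrays.

    Each family's copies are concatenated into ``n_arrays`` arrays placed at
    random non-overlapping loci (arrays overwrite background, so the genome
    length is exactly ``genome_length``).  Subfamilies are independent specs,
    so by construction every array holds copies of a single variant.
    """
    total_target = sum(s.target_proportion for s in specs)
    if total_target > 0.5:
        raise ValueError(f"total target proportion {total_target:.3f} exceeds 0.5")
    rng = np.random.default_rng(stable_seed(seed, "genome"))
    # scaffold lengths: equal split, remainder to the first
    base = genome_length // n_scaffolds
    scaffold_lengths = [base + (genome_length - base * n_scaffolds) * (i == 0)
                        for i in range(n_scaffolds)]
    scaffold_names = [f"scf{i+1}" for i in range(n_scaffolds)]
    scaffolds = {
        name: bytearray(random_dna(ln, np.random.default_rng(stable_seed(seed, "bg", name)),
                                   background_at), "ascii")
        for name, ln in zip(scaffold_names, scaffold_lengths)
    }

    # build arrays first (largest placed first to ease packing)
    arrays: list[tuple[str, str, int, float]] = []  # (family, seq, copies, p_dist)
    stats_rows = []
    for spec in specs:
        codes = _CODE[seq_to_array(spec.monomer)]
        L = len(spec.monomer)
        total_copies = max(spec.n_arrays,
                           int(round(spec.target_proportion * genome_length / L)))
        per_array = [total_copies // spec.n_arrays] * spec.n_arrays
        for i in range(total_copies % spec.n_arrays):
            per_array[i] += 1
        frng = np.random.default_rng(stable_seed(seed, "fam", spec.name))
        fam_ts = fam_tv = fam_sites = 0
        fam_bp = 0
        for copies in per_array:
            seq, n_ts, n_tv, n_sites = _mutate_array(
                codes, copies, spec.divergence, spec.ts_tv_ratio,
                spec.indel_rate, frng)
            fam_ts += n_ts
            fam_tv += n_tv
            fam_sites += n_sites
            fam_bp += len(seq)
            p_dist = (n_ts + n_tv) / n_sites
            arrays.append((spec.name, seq, copies, p_dist))
        stats_rows.append({
            "family": spec.name,
            "monomer_length": L,
            "n_copies": total_copies,
            "realized_proportion": fam_bp / genome_length,
            "realized_p_distance": (fam_ts + fam_tv) / fam_sites,
            "realized_divergence": kimura2p_from_counts(fam_ts, fam_tv, fam_sites),
        })

    # placement by rejection sampling, longest arrays first
    order = sorted(range(len(arrays)), key=lambda i: -len(arrays[i][1]))
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in scaffold_names}
    intervals: list[ArrayInterval] = []
    weights = np.array(scaffold_lengths, dtype=float)
    weights /= weights.sum()
    for i in order:
        family, seq, copies, p_dist = arrays[i]
        alen = len(seq)
        for _attempt in range(max_retries):
            scf = scaffold_names[int(rng.choice(n_scaffolds, p=weights))]
            slen = len(scaffolds[scf])
            if slen < alen:
                continue
            start = int(rng.integers(0, slen - alen + 1))
            end = start + alen
            if any(start < e and s < end for s, e in placed[scf]):
                continue
            placed[scf].append((start, end))
            scaffolds[scf][start:end] = seq.encode("ascii")
            intervals.append(ArrayInterval(scf, start, end, family, copies, p_dist))
            break
        else:
            raise PlacementError(
                f"could not place a {alen}-bp array of {family} after "
                f"{max_retries} retries")
    intervals.sort(key=lambda iv: (iv.scaffold, iv.start))
    stats = pd.DataFrame(stats_rows,
                         columns=["family", "monomer_length", "n_copies",
                                  "realized_proportion", "realized_p_distance",
                                  "realized_divergence"])
    genome = {name: bytes(buf).decode("ascii") for name, buf in scaffolds.items()}
    truth = ArrayTruth(genome_length=genome_length, intervals=intervals,
                       family_stats=stats)
    return genome, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    codes = _CODE[seq_to_array(seq)].copy()
    mask = rng.random(codes.size) < error_rate
    n = int(mask.sum())
    if n == 0:
        return seq
    # substitute with one of the three other bases uniformly
    shift = rng.integers(1, 4, size=n).astype(np.int8)
    codes[mask] = (codes[mask] + shift) % 4
    return _BASES_AGCT[codes].tobytes().decode("ascii")


def sim_reads(genome: Mapping[str, str] | str, coverage: float, seed: int,
              read_len: int = 150, insert_mean: int = 300,
              error_rate: float = 0.0, skip_short: bool = False,
              name_prefix: str = "r") -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Paired-end reads at ``coverage``-fold depth.

    Returns a list of ((id1, seq1), (id2, seq2)) pairs in FR orientation,
    with the originating strand of each fragment chosen at random.  The
    number of pairs is ``ceil(coverage * genome_length / (2 * read_len))``.
    """
    if isinstance(genome, str):
        genome = {"genome": genome}
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_len > insert_mean:
        raise ValueError("read_len must be <= insert_mean")
    names = list(genome)
    usable = [n for n in names if len(genome[n]) >= insert_mean]
    skipped = [n for n in names if n not in usable]
    if skipped:
        if not skip_short:
            raise ValueError(
                f"scaffold(s) shorter than insert size {insert_mean}: "
                + ", ".join(skipped))
        for n in skipped:
            logger.warning("skipping scaffold %s: shorter than insert (%d < %d)",
                           n, len(genome[n]), insert_mean)
    if not usable:
        raise ValueError("no scaffold long enough for the insert size")
    total_len = sum(len(genome[n]) for n in names)
    n_pairs = math.ceil(coverage * total_len / (2 * read_len))
    rng = np.random.default_rng(stable_seed(seed, "reads"))
    lengths = np.array([len(genome[n]) for n in usable], dtype=float)
    probs = lengths / lengths.sum()
    scf_idx = rng.choice(len(usable), size=n_pairs, p=probs)
    pairs = []
    for i in range(n_pairs):
        scf = usable[int(scf_idx[i])]
        seq = genome[scf]
        pos = int(rng.integers(0, len(seq) - insert_mean + 1))
        frag = seq[pos : pos + insert_mean]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        r1 = _inject_errors(frag[:read_len], error_rate, rng)
        r2 = _inject_errors(revcomp(frag[-read_len:]), error_rate, rng)
        pairs.append(((f"{name_prefix}{i:08d}/1", r1),
                      (f"{name_prefix}{i:08d}/2", r2)))
    return pairs


def assembly_pseudo_reads(assembly: Mapping[str, str], coverage: float, seed: int,
                          read_len: int = 150, insert_mean: int = 300,
                          error_rate: float = 0.0):
    """PE150 pseudo-reads from an assembly (scaffolds sampled by length).

    Scaffolds shorter than the insert are skipped with a logged warning.
    """
    if not assembly:
        raise ValueError("empty assembly")
    return sim_reads(assembly, coverage, seed, read_len=read_len,
                     insert_mean=insert_mean, error_rate=error_rate,
                     skip_short=True, name_prefix="p")


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def sim_rnaseq(family_refs: Mapping[str, str],
               expression: Mapping[str, Mapping[str, float]],
               background_fraction: float, library_size: int, seed: int,
               read_len: int = 100, error_rate: float = 0.002,
               background_at: float = 0.5):
    """RNA-seq libraries with per-family expression weights.

    ``expression`` maps sample name -> {family: weight}.  Reads are drawn
    multinomially: a ``background_fraction`` slice from random sequence (the
    stand-in for the transcriptome) and the rest from the family references
    in proportion to their weights.  Each sample's stream is derived from
    (seed, sample name), so a rerun is reproducible read-for-read.

    Returns ``(reads, truth)`` where ``reads`` maps sample -> [(id, seq)]
    and ``truth`` is a DataFrame of planted per-family read counts.
    """
    if not (0.0 <= background_fraction < 1.0):
        raise ValueError("background_fraction must be in [0, 1)")
    fam_names = sorted(family_refs)
    for fam in fam_names:
        if len(family_refs[fam]) < read_len:
            raise ValueError(f"reference of {fam} shorter than read length")
    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for sample, weights in expression.items():
        w = np.array([max(float(weights.get(f, 0.0)), 0.0) for f in fam_names])
        if (w < 0).any():
            raise ValueError("weights must be >= 0")
        wsum = w.sum()
        if wsum == 0 and background_fraction == 0:
            raise ValueError(f"sample {sample}: all weights zero and no background")
        probs = np.concatenate([
            [background_fraction],
            (1.0 - background_fraction) * (w / wsum if wsum > 0 else w),
        ])
        probs /= probs.sum()
        rng = np.random.default_rng(stable_seed(seed, "rnaseq", sample))
        counts = rng.multinomial(library_size, probs)
        sample_reads: list[tuple[str, str]] = []
        idx = 0
        # background
        for _ in range(counts[0]):
            sample_reads.append((f"{sample}_bg{idx:07d}",
                                 random_dna(read_len, rng, background_at)))
            idx += 1
        for fam, cnt in zip(fam_names, counts[1:]):
            ref = family_refs[fam]
            span = len(ref) - read_len + 1
            for _ in range(cnt):
                pos = int(rng.integers(0, span))
                seq = ref[pos : pos + read_len]
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                sample_reads.append((f"{sample}_{fam}_{idx:07d}",
                                     _inject_errors(seq, error_rate, rng)))
                idx += 1
            truth_rows.append({"sample": sample, "family": fam,
                               "planted_count": int(cnt)})
        # shuffle so family reads are not grouped
        perm = rng.permutation(len(sample_reads))
        reads[sample] = [sample_reads[i] for i in perm]
    truth = pd.DataFrame(truth_rows, columns=["sample", "family", "planted_count"])
    return reads, truth
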