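"""Low-level sequence utilities shared across the pipeline.

DNA is handled as plain upper-case ``str`` over {A,C,G,T} (N only in external
input, never produced by the simulator).  FASTA/FASTQ round-trips go through
Biopython; the helpers here exist so the rest of the package never touches
file formats directly.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# transition partner of each base (A<->G, C<->T)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def at_fraction(seq: str) -> float:
    """A+T fraction of a sequence (ignores non-ACGT symbols in the count base)."""
    if not seq:
        raise ValueError("empty sequence")
    at = seq.count("A") + seq.count("T") + seq.count("a") + seq.count("t")
    return at / len(seq)


def random_dna(length: int, rng: np.random.Generator, at_content: float = 0.5) -> str:
    """i.i.d. random DNA with expected A+T fraction ``at_content``."""
    p_at = at_content / 2.0
    p_gc = (1.0 - at_content) / 2.0
    bases = np.frombuffer(b"ATGC", dtype=np.uint8)
    idx = rng.choice(4, size=length, p=[p_at, p_at, p_gc, p_gc])
    return bases[idx].tobytes().decode("ascii")


def seq_to_array(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array of ASCII codes (zero-copy-ish)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def canonical_kmers(seq: str, k: int) -> set[int]:
    """Set of canonical k-mers of ``seq`` as 2-bit packed integers.

    Canonical = min(kmer, revcomp(kmer)) on the packed encoding.  k-mers
    containing non-ACGT symbols are skipped.
    """
    n = len(seq)
    if n < k:
        return set()
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    arr = code[seq_to_array(seq)]
    if (arr < 0).any():
        # fall back to a masked scan around ambiguous symbols
        valid = arr >= 0
    else:
        valid = None
    fwd = np.zeros(n - k + 1, dtype=np.uint64)
    rev = np.zeros(n - k + 1, dtype=np.uint64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        col = arr[j : j + n - k + 1]
        if valid is not None:
            ok &= col >= 0
        fwd = (fwd << np.uint64(2)) | col.astype(np.uint64)
        rev = rev | ((np.uint64(3) ^ col.astype(np.uint64)) << np.uint64(2 * j))
    canon = np.minimum(fwd, rev)
    return set(canon[ok].tolist())


def canonical_kmer_spans(seq: str, k: int) -> dict[int, tuple[int, int]]:
    """Map canonical k-mer -> (first, last) start position in ``seq``."""
    n = len(seq)
    out: dict[int, tuple[int, int]] = {}
    if n < k:
        return out
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    arr = code[seq_to_array(seq)]
    fwd = np.zeros(n - k + 1, dtype=np.uint64)
    rev = np.zeros(n - k + 1, dtype=np.uint64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        col = arr[j : j + n - k + 1]
        ok &= col >= 0
        fwd = (fwd << np.uint64(2)) | col.astype(np.uint64)
        rev = rev | ((np.uint64(3) ^ col.astype(np.uint64)) << np.uint64(2 * j))
    canon = np.minimum(fwd, rev)
    for pos in np.nonzero(ok)[0].tolist():
        km = int(canon[pos])
        if km in out:
            out[km] = (out[km][0], pos)
        else:
            out[km] = (pos, pos)
    return out


def stable_seed(*parts) -> int:
    """Deterministic child seed (< 2**31) from a root seed and labels."""
    blob = "\x1f".join(str(p) for p in parts).encode()
    return zlib.crc32(blob) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, records: dict[str, str] | Iterable[tuple[str, str]],
                wrap: int = 60, header_lines: Sequence[str] = ()) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f";{line}\n")
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read a FASTQ file into (id, sequence) pairs; qualities are dropped."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def iter_fastx(path) -> Iterator[tuple[str, str]]:
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq).upper()
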