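"""Locate family monomers in an assembly and test subfamily co-occurrence.

Each subfamily consensus is searched against the assembly with blastn and a
hit is accepted only under the 90/90 rule: at least 90% query coverage in a
single HSP and at least 90% identity.  Accepted hits give per-scaffold
monomer counts; the co-occurrence of two subfamilies is the fraction of
scaffolds they share (Jaccard by default — the scaffold sets' intersection
over their union — or an asymmetric conditional fraction |A∩B|/|A|).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import math

import numpy as np
import pandas as pd

from ._seq import write_fasta

_BLAST_COLS = ["query", "scaffold", "pident", "qcovhsp", "length",
               "sstart", "send", "evalue", "bitscore"]


def _run_blastn(assembly: dict[str, str], queries: dict[str, str]) -> pd.DataFrame:
    for tool in ("makeblastdb", "blastn"):
        if shutil.which(tool) is None:
            raise RuntimeError(f"{tool} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db_fa, q_fa = tmp / "assembly.fa", tmp / "queries.fa"
        write_fasta(db_fa, assembly)
        write_fasta(q_fa, queries)
        subprocess.run(
            ["makeblastdb", "-in", str(db_fa), "-dbtype", "nucl",
             "-out", str(tmp / "db")],
            check=True, capture_output=True)
        min_len = min(len(s) for s in queries.values())
        word = 7 if min_len < 30 else 11
        proc = subprocess.run(
            ["blastn", "-query", str(q_fa), "-db", str(tmp / "db"),
             "-task", "blastn", "-word_size", str(word), "-dust", "no",
             "-evalue", "1e-3", "-max_target_seqs", "100000",
             "-outfmt", "6 qseqid sseqid pident qcovhsp length "
                        "sstart send evalue bitscore"],
            check=True, capture_output=True, text=True)
    from io import StringIO

    if not proc.stdout.strip():
        return pd.DataFrame(columns=_BLAST_COLS)
    df = pd.read_csv(StringIO(proc.stdout), sep="\t", names=_BLAST_COLS)
    return df


def filter_hits(hits: pd.DataFrame, min_coverage: float = 90.0,
                min_identity: float = 90.0) -> pd.DataFrame:
    """Apply the 90/90 acceptance rule to raw HSPs.

    ``qcovhsp`` is per-HSP query coverage (no HSP chaining); both thresholds
    are inclusive percentages.
    """
    mask = (hits["qcovhsp"] >= min_coverage) & (hits["pident"] >= min_identity)
    return hits.loc[mask].reset_index(drop=True)


def scan_assembly(assembly: dict[str, str], consensuses: dict[str, str],
                  min_coverage: float = 90.0,
                  min_identity: float = 90.0) -> pd.DataFrame:
    """Accepted (90/90) monomer hits of each subfamily consensus.

    Returns a DataFrame with columns query/scaffold/pident/qcovhsp/length/
    sstart/send/evalue/bitscore, plus ``strand`` and 0-based half-open
    ``start``/``end`` columns derived from the blast coordinates.
    """
    if not assembly:
        raise ValueError("empty assembly")
    if not consensuses:
        raise ValueError("no consensus queries")
    raw = _run_blastn(assembly, consensuses)
    acc = filter_hits(raw, min_coverage, min_identity).copy()
    if acc.empty:
        acc["strand"] = pd.Series(dtype=str)
        acc["start"] = pd.Series(dtype=int)
        acc["end"] = pd.Series(dtype=int)
        return acc
    fwd = acc["sstart"] <= acc["send"]
    acc["strand"] = np.where(fwd, "+", "-")
    acc["start"] = np.where(fwd, acc["sstart"], acc["send"]) - 1
    acc["end"] = np.where(fwd, acc["send"], acc["sstart"])
    return acc


def scaffold_hit_counts(hits: pd.DataFrame,
                        consensuses: dict[str, str]) -> pd.DataFrame:
    """Per-scaffold accepted-hit counts and monomer-equivalent counts.

    Monomer equivalents = non-redundant masked bp / monomer length, rounded
    down.  Raw hit counts are kept alongside.
    """
    rows = []
    if hits.empty:
        return pd.DataFrame(columns=["scaffold", "subfamily", "n_hits",
                                     "masked_bp", "monomer_equivalents"])
    for (scf, sub), grp in hits.groupby(["scaffold", "query"]):
        ivals = sorted(zip(grp["start"], grp["end"]))
        masked, cur_s, cur_e = 0, None, None
        for s, e in ivals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    masked += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            masked += cur_e - cur_s
        mlen = len(consensuses[sub])
        rows.append({"scaffold": scf, "subfamily": sub, "n_hits": len(grp),
                     "masked_bp": int(masked),
                     "monomer_equivalents": int(masked // mlen)})
    return pd.DataFrame(rows).sort_values(["scaffold", "subfamily"]) \
                             .reset_index(drop=True)


def cooccurrence(hits: pd.DataFrame, subfamilies: list[str] | None = None,
                 method: str = "jaccard") -> pd.DataFrame:
    """Shared-scaffold fraction matrix over subfamilies.

    ``jaccard``: |S_i ∩ S_j| / |S_i ∪ S_j| (symmetric).
    ``conditional``: |S_i ∩ S_j| / |S_i| (row-conditioned, asymmetric).
    Entries where both scaffold sets are empty are NaN; the diagonal is 1
    wherever the subfamily occurs at all.
    """
    if method not in {"jaccard", "conditional"}:
        raise ValueError("method must be 'jaccard' or 'conditional'")
    if subfamilies is None:
        subfamilies = sorted(hits["query"].unique()) if not hits.empty else []
    sets = {
        sub: set(hits.loc[hits["query"] == sub, "scaffold"]) if not hits.empty
        else set()
        for sub in subfamilies
    }
    n = len(subfamilies)
    mat = np.full((n, n), math.nan)
    for i, a in enumerate(subfamilies):
        for j, b in enumerate(subfamilies):
            sa, sb = sets[a], sets[b]
            if method == "jaccard":
                denom = len(sa | sb)
            else:
                denom = len(sa)
            if denom == 0:
                continue
            mat[i, j] = len(sa & sb) / denom
    return pd.DataFrame(mat, index=subfamilies, columns=subfamilies)
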