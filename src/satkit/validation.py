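"""Parameter-recovery experiments on synthetic satellitomes.

Defines the package's canonical recovery experiment: a 5-Mb genome carrying
eight satellite families whose proportions span 0.05-3% and whose
divergences span 2-20% (paired so the most abundant families are also the
most diverged, the pattern real satellitomes show), sequenced at 1X PE150
and pushed through the full discovery -> consensus -> quantification
pipeline.  Estimates are scored against the generator's ArrayTruth.

Family matching is sequence-based (rotation-aware edit distance between
planted monomer and recovered consensus), never by bookkeeping labels, so
the experiment measures what a user of the pipeline would measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from . import synthdata as _synthdata
from . import workflow as _workflow
from ._seq import revcomp, stable_seed

# (label, target proportion, divergence, monomer bp, A+T, n_arrays)
DEMO_FAMILIES = [
    ("fam1", 0.030, 0.20, 165, 0.72, 40),
    ("fam2", 0.020, 0.17, 169, 0.69, 30),
    ("fam3", 0.012, 0.13, 124, 0.62, 25),
    ("fam4", 0.008, 0.10, 133, 0.66, 20),
    ("fam5", 0.005, 0.08, 208, 0.53, 12),
    ("fam6", 0.003, 0.06, 293, 0.61, 8),
    ("fam7", 0.0015, 0.04, 104, 0.62, 10),
    ("fam8", 0.0005, 0.02, 41, 0.58, 10),
]


def demo_satellitome_specs(seed: int,
                           families=None) -> list[_synthdata.SatFamilySpec]:
    """The eight-family study conditions with monomers drawn per seed."""
    fams = families or DEMO_FAMILIES
    return [
        _synthdata.SatFamilySpec(
            name=label,
            monomer=_synthdata.make_consensus(length, at,
                                              stable_seed(seed, "monomer", label)),
            target_proportion=prop, divergence=div, n_arrays=n_arrays)
        for label, prop, div, length, at, n_arrays in fams
    ]


def consensus_identity(monomer: str, consensus: str) -> float:
    """Identity between a planted monomer and a recovered consensus,
    rotation- and strand-aware (edit distance on the doubled consensus)."""
    best = None
    for query in (monomer, revcomp(monomer)):
        res = edlib.align(query, consensus + consensus, mode="HW",
                          task="distance")
        d = res["editDistance"]
        if d >= 0 and (best is None or d < best):
            best = d
    if best is None:
        return 0.0
    return max(0.0, 1.0 - best / len(monomer))


def cooccurrence_experiment(seed: int, mode: str = "disjoint",
                            n_scaffolds: int = 20, scaffold_len: int = 10_000,
                            copies_per_array: int = 12,
                            subfamily_divergence: float = 0.20,
                            copy_divergence: float = 0.02):
    """Synthetic assembly with two subfamily variants, scanned at 90/90.

    ``disjoint``: each variant's arrays sit on its own scaffolds (the
    organization real subfamilies show); ``interleaved``: every array
    alternates copies of both variants on shared scaffolds (the
    deliberately mixed organization).  The two variants differ by
    ``subfamily_divergence`` so the 90/90 rule can tell them apart
    (nearly identical variants are exactly the artefact case the rule
    cannot resolve).  Returns ``(cooccurrence matrix, hits, assembly)``.
    """
    from . import assembly_scan as _scan

    if mode not in {"disjoint", "interleaved"}:
        raise ValueError("mode must be 'disjoint' or 'interleaved'")
    mono_a = _synthdata.make_consensus(133, 0.66, stable_seed(seed, "cooc-A"))
    rng = np.random.default_rng(stable_seed(seed, "cooc-mut"))
    mono_b = _synthdata.mutate_copy(mono_a, subfamily_divergence, rng=rng)
    assembly: dict[str, str] = {}
    for i in range(n_scaffolds):
        scf_rng = np.random.default_rng(stable_seed(seed, "cooc-scf", i))
        from ._seq import random_dna

        seq = random_dna(scaffold_len, scf_rng, 0.65)
        if mode == "disjoint":
            variants = [mono_a] if i % 2 == 0 else [mono_b]
        else:
            variants = [mono_a, mono_b]
        copies = []
        for c in range(copies_per_array):
            mono = variants[c % len(variants)]
            copies.append(_synthdata.mutate_copy(mono, copy_divergence,
                                                 rng=scf_rng))
        array = "".join(copies)
        pos = int(scf_rng.integers(0, scaffold_len - len(array)))
        seq = seq[:pos] + array + seq[pos + len(array):]
        assembly[f"scf{i+1}"] = seq
    hits = _scan.scan_assembly(assembly, {"subA": mono_a, "subB": mono_b})
    cooc = _scan.cooccurrence(hits, ["subA", "subB"])
    return cooc, hits, assembly


ANTENNA_SAMPLES = ["antenna_nymph", "antenna_male", "antenna_female"]
OVARY_SAMPLE, TESTIS_SAMPLE = "ovary", "testis"

# planted tissue shares (antenna, ovary, testis) per pattern
PATTERN_SHARES = {
    "P1": (0.40, 0.30, 0.30),
    "P2": (0.85, 0.075, 0.075),
    "P3": (0.16, 0.42, 0.42),
    "P4a": (0.075, 0.85, 0.075),   # ovary-dominant
    "P4b": (0.075, 0.075, 0.85),   # testis-dominant
}


def transcription_experiment(seed: int, n_per_pattern: int = 5,
                             library_size: int = 100_000,
                             background_fraction: float = 0.5,
                             config=None):
    """Plant the four transcription patterns (5 families each) and score
    how many retained families get their planted label back.

    The study design is mirrored: three antenna libraries plus one ovary
    and one testis library; the CPM>50-in->=2-samples filter is active.
    Returns ``(accuracy, patterns DataFrame, cpm DataFrame, truth labels)``.
    """
    from . import consensus as _consensus
    from . import quantify as _quantify
    from . import transcription as _transcription

    cfg = config or _workflow.PipelineConfig(seed=seed)
    rng = np.random.default_rng(stable_seed(seed, "expr"))
    pattern_cycle = (["P1"] * n_per_pattern + ["P2"] * n_per_pattern
                     + ["P3"] * n_per_pattern
                     + ["P4a", "P4b"] * ((n_per_pattern + 1) // 2))
    pattern_cycle = pattern_cycle[: 3 * n_per_pattern + n_per_pattern]
    lengths = [60, 104, 124, 133, 165, 169, 201, 208, 293, 375]
    refs, truth_label = {}, {}
    expression: dict[str, dict[str, float]] = {
        s: {} for s in ANTENNA_SAMPLES + [OVARY_SAMPLE, TESTIS_SAMPLE]}
    for i, pat in enumerate(pattern_cycle):
        fam = f"exprFam{i+1:02d}"
        mono = _synthdata.make_consensus(
            lengths[i % len(lengths)], float(rng.uniform(0.45, 0.75)),
            stable_seed(seed, "expr-mono", fam))
        refs[fam] = _consensus.build_reference(mono)
        truth_label[fam] = "P4" if pat.startswith("P4") else pat
        a, o, t = PATTERN_SHARES[pat]
        level = float(rng.uniform(0.5, 2.0))  # overall expression level
        for s in ANTENNA_SAMPLES:
            expression[s][fam] = level * a * float(rng.uniform(0.85, 1.15))
        expression[OVARY_SAMPLE][fam] = level * o
        expression[TESTIS_SAMPLE][fam] = level * t
    reads, _planted = _synthdata.sim_rnaseq(
        refs, expression, background_fraction=background_fraction,
        library_size=library_size, seed=seed)
    refset = _quantify.ReferenceSet(refs, k=cfg.seed_kmer)
    counts, totals = {}, {}
    for sample, rds in reads.items():
        c, bg = _transcription.count_rna_reads(rds, refset)
        counts[sample] = c
        totals[sample] = int(c.sum() + bg)
    counts_df = pd.DataFrame(counts)
    cpm = _transcription.cpm_normalize(counts_df, pd.Series(totals))
    retained = _transcription.filter_expressed(cpm, cfg.min_cpm,
                                               cfg.min_cpm_samples)
    patterns = _transcription.classify_families(
        retained, ANTENNA_SAMPLES, OVARY_SAMPLE, TESTIS_SAMPLE,
        dominance=cfg.dominance)
    correct = sum(patterns.loc[f, "pattern"] == truth_label[f]
                  for f in patterns.index)
    accuracy = correct / len(patterns) if len(patterns) else math.nan
    return accuracy, patterns, cpm, truth_label


@dataclass
class RecoveryOutcome:
    """Scores of one recovery experiment."""

    table: pd.DataFrame            # per planted family: truth vs estimate
    result: object                 # the SatellitomeResult
    truth: object                  # the ArrayTruth
    n_recovered: int
    max_abs_rel_abundance_err: float
    max_abs_divergence_err_pp: float
    rank_order_correct: bool


def run_recovery_experiment(seed: int, genome_length: int = 5_000_000,
                            coverage: float = 1.0,
                            cluster_sample: int = 10_000,
                            error_rate: float = 0.002,
                            min_match_identity: float = 0.65,
                            families=None,
                            config: _workflow.PipelineConfig | None = None
                            ) -> RecoveryOutcome:
    """Simulate the study conditions, run the pipeline, score the recovery.

    The clustering sample (default 10,000 reads = 0.3X of the 5-Mb genome)
    keeps the read-overlap graph sub-critical, the regime graph-based
    repeat clustering is designed for; quantification uses every read.
    """
    specs = demo_satellitome_specs(seed, families)
    genome, truth = _synthdata.build_genome(specs, genome_length, seed)
    pairs = _synthdata.sim_reads(genome, coverage, seed,
                                 error_rate=error_rate)
    reads = [p[0] for p in pairs] + [p[1] for p in pairs]
    cfg = config or _workflow.PipelineConfig(seed=seed,
                                             cluster_sample=cluster_sample)
    result = _workflow.characterize(reads, cfg)

    rows = []
    used: set[str] = set()
    est = result.family_table.set_index("name")
    for spec in specs:
        best_name, best_ident = None, min_match_identity
        for rec in result.records:
            ident = consensus_identity(spec.monomer, rec.consensus)
            if ident > best_ident and rec.name not in used:
                best_name, best_ident = rec.name, ident
        truth_prop = truth.proportion(spec.name)
        truth_div = 100.0 * truth.divergence(spec.name)
        if best_name is None:
            rows.append({
                "family": spec.name, "matched": None, "identity": math.nan,
                "truth_proportion_pct": 100 * truth_prop,
                "est_proportion_pct": math.nan, "rel_abundance_err": math.nan,
                "truth_divergence_pct": truth_div,
                "est_divergence_pct": math.nan, "divergence_err_pp": math.nan,
            })
            continue
        used.add(best_name)
        e_prop = float(est.loc[best_name, "genome_proportion_pct"])
        e_div = float(est.loc[best_name, "divergence_pct"])
        rows.append({
            "family": spec.name, "matched": best_name,
            "identity": best_ident,
            "truth_proportion_pct": 100 * truth_prop,
            "est_proportion_pct": e_prop,
            "rel_abundance_err": e_prop / (100 * truth_prop) - 1.0,
            "truth_divergence_pct": truth_div,
            "est_divergence_pct": e_div,
            "divergence_err_pp": e_div - truth_div,
        })
    table = pd.DataFrame(rows)
    recovered = table["matched"].notna()
    ok = table.loc[recovered]
    rank_correct = False
    if recovered.all():
        planted_rank = table["truth_proportion_pct"].rank(ascending=False)
        est_rank = table["est_proportion_pct"].rank(ascending=False)
        rank_correct = bool((planted_rank == est_rank).all())
    return RecoveryOutcome(
        table=table, result=result, truth=truth,
        n_recovered=int(recovered.sum()),
        max_abs_rel_abundance_err=float(ok["rel_abundance_err"].abs().max())
        if len(ok) else math.nan,
        max_abs_divergence_err_pp=float(ok["divergence_err_pp"].abs().max())
        if len(ok) else math.nan,
        rank_order_correct=rank_correct,
    )
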