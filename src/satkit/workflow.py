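"""Pipeline orchestration, configuration and standard-format I/O.

Ties the stages together: simulate -> discover -> consensus -> quantify ->
relations -> scan -> express.  A single :class:`PipelineConfig` carries all
thresholds; every emitted table starts with provenance comment lines
(tool version, config hash, seed) so a run can be audited and reproduced
byte-for-byte.

Also ships the packaged summary table of the *Rhodnius prolixus*
satellitome (39 families with cluster counts, genome proportions, repeat
lengths, A+T and Kimura divergence) used as a reference fixture.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assembly_scan as _scan
from . import consensus as _consensus
from . import discovery as _discovery
from . import quantify as _quantify
from . import relations as _relations
from . import synthdata as _synthdata
from . import transcription as _transcription
from ._seq import at_fraction, read_fastq, stable_seed, write_fasta, write_fastq

logger = logging.getLogger(__name__)

FIXTURE_NAME = "rhodnius_prolixus_satellitome.tsv"
TABLE_COLUMNS = ["name", "n_clusters", "genome_proportion_pct",
                 "repeat_length_bp", "at_pct", "divergence_pct"]


class MissingArtifactError(FileNotFoundError):
    """A stage input produced by a disabled/earlier stage is missing."""


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis, with study defaults."""

    seed: int = 0
    species_prefix: str = "Rpro"
    # discovery
    cluster_sample: int = 600_000
    kmer_size: int = 13
    min_shared_kmers: int = 3
    cluster_floor: float = 1e-5          # 0.001% of the sampled genome
    min_period: int = 4
    tandem_threshold: float = 0.55
    rep_max_length: int = 2200
    rep_min_overlap: int = 50
    rep_min_identity: float = 0.60
    # consensus / family assembly
    family_min_identity: float = 0.80
    family_min_coverage: float = 0.50
    polish_rounds: int = 2
    max_monomers: int = 100
    # quantification
    quant_sample: int = 1_000_000
    map_min_score: float = 30.0
    seed_kmer: int = 11
    # assembly scan
    scan_min_coverage: float = 90.0
    scan_min_identity: float = 90.0
    cooccurrence_method: str = "jaccard"
    # transcription
    min_cpm: float = 50.0
    min_cpm_samples: int = 2
    dominance: float = 0.7

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(config: PipelineConfig | None, seed: int | None) -> list[str]:
    parts = [f"satkit v{__version__}"]
    if config is not None:
        parts.append(f"config={config.config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return ["# " + " ".join(parts)]


def write_table(path, df: pd.DataFrame,
                config: PipelineConfig | None = None,
                seed: int | None = None, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Family-table fixture
# ---------------------------------------------------------------------------

def fixture_path() -> Path:
    return Path(resources.files("satkit.data") / FIXTURE_NAME)


def load_family_table(path: str | Path = "fixture") -> pd.DataFrame:
    """Load a family table TSV (or the packaged reference fixture).

    Columns: name, n_clusters (``-`` for families found only by read
    masking), genome_proportion_pct, repeat_length_bp, at_pct,
    divergence_pct.  Malformed rows raise with their 1-based line number.
    """
    p = fixture_path() if str(path) == "fixture" else Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    with open(p) as fh:
        lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(fh)
                 if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{p}: empty family table")
    header = lines[0][1].split("\t")
    if header != TABLE_COLUMNS:
        raise ValueError(f"{p}: line {lines[0][0]}: expected columns "
                         f"{TABLE_COLUMNS}, got {header}")
    rows = []
    for lineno, ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(TABLE_COLUMNS):
            raise ValueError(f"{p}: line {lineno}: expected "
                             f"{len(TABLE_COLUMNS)} fields, got {len(fields)}")
        name, n_cl, prop, length, at, div = fields
        try:
            rows.append({
                "name": name,
                "n_clusters": None if n_cl.strip() == "-" else int(n_cl),
                "genome_proportion_pct": float(prop.rstrip("%")),
                "repeat_length_bp": int(length),
                "at_pct": float(at.rstrip("%")),
                "divergence_pct": float(div.rstrip("%")),
            })
        except ValueError as exc:
            raise ValueError(f"{p}: line {lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df["n_clusters"] = df["n_clusters"].astype("Int64")
    return df


def table_stats(table: pd.DataFrame | str | Path = "fixture") -> _quantify.SummaryStats:
    if not isinstance(table, pd.DataFrame):
        table = load_family_table(table)
    return _quantify.summarize_table(table)


# ---------------------------------------------------------------------------
# End-to-end characterization (reads -> named family table)
# ---------------------------------------------------------------------------

@dataclass
class SatellitomeResult:
    """Everything the read-based characterization produces."""

    family_table: pd.DataFrame            # one row per named family
    records: list                          # SatFamilyRecord, same order
    clusters: list                         # annotated ReadClusters
    cluster_consensus: dict[str, str]      # cluster id -> polished consensus
    subfamily_groups: list[list[str]]      # cluster ids grouped per family
    family_of: dict[str, str]              # cluster id -> family name
    hits: list = field(repr=False, default_factory=list)
    quant_total_bp: int = 0
    landscape: pd.DataFrame | None = None


def characterize(reads: list[tuple[str, str]],
                 config: PipelineConfig | None = None,
                 declared_motifs: dict[str, str] | None = None) -> SatellitomeResult:
    """Run discovery -> consensus -> quantification -> naming on a read set.

    ``reads`` is the full read collection (R1+R2 as independent sequences);
    sampling for clustering and for quantification is taken from it.
    ``declared_motifs`` adds user-declared short motifs (e.g. telomeric
    TTAGG) that graph clustering cannot discover; they are quantified with
    references built by the same concatenation rule and appear as rows named
    ``(<motif>)n``.
    """
    cfg = config or PipelineConfig()
    n_cluster_sample = min(cfg.cluster_sample, len(reads))
    sample = _discovery.sample_reads(reads, n_cluster_sample,
                                     stable_seed(cfg.seed, "cluster-sample"))
    total_bp = sum(len(s) for _i, s in sample)
    graph = _discovery.build_kmer_graph(sample, k=cfg.kmer_size,
                                        min_shared=cfg.min_shared_kmers)
    clusters = _discovery.cluster_reads(graph, total_bp,
                                        min_proportion=cfg.cluster_floor)
    _discovery.annotate_clusters(
        clusters, sample, rep_max_length=cfg.rep_max_length,
        min_overlap=cfg.rep_min_overlap, min_identity=cfg.rep_min_identity,
        min_period=cfg.min_period, tandem_threshold=cfg.tandem_threshold,
        graph=graph)

    # consensus per tandem cluster, polished against its member reads
    cluster_consensus: dict[str, str] = {}
    for cl in clusters:
        if not cl.is_tandem or cl.period is None:
            continue
        if len(cl.representative) < 2 * cl.period:
            logger.warning("%s: representative too short for two %d-bp "
                           "monomers; skipped", cl.cluster_id, cl.period)
            continue
        monomers = _consensus.extract_monomers(cl.representative, cl.period)
        cons = _consensus.build_consensus(monomers,
                                          max_monomers=cfg.max_monomers)
        member_seqs = [sample[i][1] for i in cl.member_indices]
        cons = _consensus.polish_consensus(cons, member_seqs,
                                           rounds=cfg.polish_rounds,
                                           min_score=cfg.map_min_score)
        cluster_consensus[cl.cluster_id] = cons

    tandem_ids = list(cluster_consensus)
    groups_idx = _consensus.assign_subfamilies(
        [cluster_consensus[cid] for cid in tandem_ids],
        min_identity=cfg.family_min_identity,
        min_coverage=cfg.family_min_coverage) if tandem_ids else []
    subfamily_groups = [[tandem_ids[i] for i in grp] for grp in groups_idx]

    # references: one per subfamily cluster consensus (+ declared motifs)
    references = {cid: _consensus.build_reference(cluster_consensus[cid])
                  for cid in tandem_ids}
    motif_rows: dict[str, str] = {}
    if declared_motifs:
        for label, motif in declared_motifs.items():
            references[label] = _consensus.build_reference(motif.upper())
            motif_rows[label] = motif.upper()

    n_quant = min(cfg.quant_sample, len(reads))
    quant_sample = _discovery.sample_reads(reads, n_quant,
                                           stable_seed(cfg.seed, "quant-sample"))
    quant_bp = sum(len(s) for _i, s in quant_sample)
    hits: list = []
    if references:
        raw_hits = _quantify.map_reads(quant_sample, references,
                                       min_score=cfg.map_min_score,
                                       k=cfg.seed_kmer)
        hits = _quantify.resolve_overlaps(raw_hits)

    # aggregate per family group
    group_of = {cid: gi for gi, grp in enumerate(subfamily_groups)
                for cid in grp}
    fam_key = {cid: f"G{group_of[cid]}" for cid in tandem_ids}
    for label in motif_rows:
        fam_key[label] = label
    abundance = _quantify.family_abundance(hits, quant_bp, family_of=fam_key)
    divergence = _quantify.family_divergence(hits, family_of=fam_key)
    masked = {}
    for h in hits:
        masked[h.family] = masked.get(h.family, 0) + h.masked_bp

    fam_dicts = []
    for gi, grp in enumerate(subfamily_groups):
        key = f"G{gi}"
        prop = float(abundance.get(key, 0.0))
        # family consensus = consensus of the most-masked member cluster
        best = max(grp, key=lambda cid: (masked.get(cid, 0), cid))
        fam_dicts.append({
            "consensus": cluster_consensus[best],
            "genome_proportion_pct": 100.0 * prop,
            "divergence_pct": float(divergence.get(key, math.nan)),
            "n_clusters": len(grp),
            "subfamilies": [(cid, cluster_consensus[cid]) for cid in grp],
            "_group_key": key,
        })
    records = _consensus.name_families(fam_dicts, prefix=cfg.species_prefix)
    # recover group key -> assigned name (name_families preserves dict refs)
    family_of = {}
    name_by_key = {}
    ordered_dicts = sorted(
        fam_dicts, key=lambda f: (-f["genome_proportion_pct"],
                                  -len(f["consensus"]), f["consensus"]))
    for rec, fd in zip(records, ordered_dicts):
        name_by_key[fd["_group_key"]] = rec.name
        for cid, _cons in fd["subfamilies"]:
            family_of[cid] = rec.name

    rows = [{
        "name": rec.name,
        "n_clusters": rec.n_clusters,
        "genome_proportion_pct": rec.genome_proportion_pct,
        "repeat_length_bp": rec.monomer_length,
        "at_pct": rec.at_pct,
        "divergence_pct": rec.divergence_pct,
    } for rec in records]
    for label, motif in motif_rows.items():
        rows.append({
            "name": f"({motif})n" if not label.startswith("(") else label,
            "n_clusters": 0,
            "genome_proportion_pct": 100.0 * float(abundance.get(label, 0.0)),
            "repeat_length_bp": len(motif),
            "at_pct": 100.0 * at_fraction(motif),
            "divergence_pct": float(divergence.get(label, math.nan)),
        })
    family_table = pd.DataFrame(rows, columns=TABLE_COLUMNS)

    hit_family_of = {cid: name for cid, name in family_of.items()}
    land = _quantify.landscape(hits, quant_bp, family_of=hit_family_of) \
        if hits else None
    return SatellitomeResult(
        family_table=family_table, records=records, clusters=clusters,
        cluster_consensus=cluster_consensus,
        subfamily_groups=subfamily_groups, family_of=family_of,
        hits=hits, quant_total_bp=quant_bp, landscape=land)


# ---------------------------------------------------------------------------
# File-tree pipeline
# ---------------------------------------------------------------------------

def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name} (produced by stage '{producer}')")
    return path


def run_pipeline(run_config: dict, outdir: str | Path) -> dict[str, Path]:
    """Execute the toggled stages of the pipeline on a file tree.

    ``run_config`` is a dict (typically loaded from YAML) with optional
    sections ``simulate``, ``discover``, ``quantify``, ``relations``,
    ``scan``, ``express`` plus top-level ``seed`` and any
    :class:`PipelineConfig` overrides under ``params``.  Stage inputs that a
    disabled stage would have produced must exist in ``outdir`` already,
    otherwise a :class:`MissingArtifactError` names the missing file.

    Returns a mapping of artifact labels to paths.  Reruns with the same
    config produce byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(run_config.get("seed", 0))
    cfg = PipelineConfig.from_dict({"seed": seed,
                                    **run_config.get("params", {})})
    artifacts: dict[str, Path] = {}

    genome = None
    if "simulate" in run_config:
        sim = run_config["simulate"]
        specs = []
        for fam in sim["families"]:
            monomer = fam.get("monomer") or _synthdata.make_consensus(
                int(fam["monomer_length"]), float(fam.get("at_content", 0.6)),
                stable_seed(seed, "monomer", fam["name"]))
            specs.append(_synthdata.SatFamilySpec(
                name=fam["name"], monomer=monomer,
                target_proportion=float(fam["target_proportion"]),
                divergence=float(fam.get("divergence", 0.05)),
                ts_tv_ratio=float(fam.get("ts_tv_ratio", 2.0)),
                indel_rate=float(fam.get("indel_rate", 0.0)),
                n_arrays=int(fam.get("n_arrays", 1)),
                subfamily_of=fam.get("subfamily_of")))
        genome, truth = _synthdata.build_genome(
            specs, int(sim["genome_length"]), seed,
            background_at=float(sim.get("background_at", 0.65)),
            n_scaffolds=int(sim.get("n_scaffolds", 1)))
        pairs = _synthdata.sim_reads(genome, float(sim.get("coverage", 1.0)),
                                     seed,
                                     error_rate=float(sim.get("error_rate", 0.0)))
        write_fasta(outdir / "genome.fa", genome)
        truth.to_bed(outdir / "truth.bed")
        with open(outdir / "truth.tsv", "w") as fh:
            for line in provenance_lines(cfg, seed):
                fh.write(line + "\n")
            truth.family_stats.to_csv(fh, sep="\t", index=False)
        write_fastq(outdir / "reads_1.fq", [p[0] for p in pairs])
        write_fastq(outdir / "reads_2.fq", [p[1] for p in pairs])
        artifacts |= {"genome": outdir / "genome.fa",
                      "truth_bed": outdir / "truth.bed",
                      "truth_tsv": outdir / "truth.tsv",
                      "reads_1": outdir / "reads_1.fq",
                      "reads_2": outdir / "reads_2.fq"}

    result = None
    if "discover" in run_config or "quantify" in run_config:
        r1 = _require(outdir / "reads_1.fq", "simulate")
        r2 = _require(outdir / "reads_2.fq", "simulate")
        reads = read_fastq(r1) + read_fastq(r2)
        motifs = run_config.get("declared_motifs")
        result = characterize(reads, cfg, declared_motifs=motifs)
        write_table(outdir / "clusters.tsv", pd.DataFrame([{
            "cluster": cl.cluster_id, "n_reads": cl.n_reads, "bp": cl.bp,
            "proportion": cl.proportion, "tandem": bool(cl.is_tandem),
            "period": cl.period if cl.period is not None else "-",
        } for cl in result.clusters]), cfg, seed)
        write_fasta(outdir / "representatives.fa",
                    {cl.cluster_id: cl.representative
                     for cl in result.clusters if cl.representative})
        cons_records = {}
        for rec in result.records:
            cons_records[rec.name] = rec.consensus
            for cid, cons in rec.subfamilies:
                cons_records[f"{rec.name}_sub_{cid}"] = cons
        write_fasta(outdir / "consensus.fa", cons_records)
        write_table(outdir / "family_table.tsv", result.family_table, cfg, seed)
        if result.landscape is not None:
            write_table(outdir / "landscape.csv", result.landscape, cfg, seed,
                        sep=",")
        stats = _quantify.summarize_table(result.family_table) \
            if len(result.family_table) >= 1 else None
        if stats is not None:
            write_table(outdir / "summary.tsv",
                        pd.DataFrame([dataclasses.asdict(stats)]), cfg, seed)
        artifacts |= {"clusters": outdir / "clusters.tsv",
                      "consensus": outdir / "consensus.fa",
                      "family_table": outdir / "family_table.tsv"}

    if "relations" in run_config:
        if result is None:
            _require(outdir / "consensus.fa", "discover")
            result = _load_consensus_result(outdir / "consensus.fa")
        cons = {rec.name: rec.consensus for rec in result.records}
        if len(cons) >= 2:
            sims = _relations.pairwise_similarity(cons, seed=seed)
            write_table(outdir / "similarity.tsv", pd.DataFrame(
                [dataclasses.asdict(s) for s in sims]), cfg, seed)
            artifacts["similarity"] = outdir / "similarity.tsv"
        for rec in result.records:
            if len(rec.subfamilies) < 2:
                continue
            subs = {cid: c for cid, c in rec.subfamilies}
            dm = _relations.pairwise_distance(subs)
            ab = {cid: 0.0 for cid in subs}
            msn = _relations.build_msn(dm, ab)
            import networkx as nx

            base = outdir / f"msn_{rec.name}"
            nx.write_graphml(msn, f"{base}.graphml")
            write_table(Path(f"{base}_edges.tsv"), pd.DataFrame(
                [{"node_a": a, "node_b": b, "steps": d["steps"]}
                 for a, b, d in msn.edges(data=True)]), cfg, seed)
            dm.to_csv(f"{base}_distances.csv")
            artifacts[f"msn_{rec.name}"] = Path(f"{base}.graphml")

    if "scan" in run_config:
        scan_cfg = run_config["scan"] or {}
        if "assembly" in scan_cfg:
            from ._seq import read_fasta

            assembly = read_fasta(scan_cfg["assembly"])
        elif genome is not None:
            assembly = genome
        else:
            from ._seq import read_fasta

            assembly = read_fasta(_require(outdir / "genome.fa", "simulate"))
        if result is None:
            _require(outdir / "consensus.fa", "discover")
            result = _load_consensus_result(outdir / "consensus.fa")
        subs = {}
        for rec in result.records:
            for cid, cons in rec.subfamilies:
                subs[f"{rec.name}_{cid}"] = cons
        if subs:
            hits = _scan.scan_assembly(assembly, subs,
                                       min_coverage=cfg.scan_min_coverage,
                                       min_identity=cfg.scan_min_identity)
            counts = _scan.scaffold_hit_counts(hits, subs)
            cooc = _scan.cooccurrence(hits, sorted(subs),
                                      method=cfg.cooccurrence_method)
            write_table(outdir / "scaffold_counts.tsv", counts, cfg, seed)
            cooc.to_csv(outdir / "cooccurrence.csv")
            with open(outdir / "assembly_hits.bed", "w") as fh:
                for row in hits.itertuples():
                    fh.write(f"{row.scaffold}\t{row.start}\t{row.end}"
                             f"\t{row.query}\t0\t{row.strand}\n")
            artifacts |= {"scaffold_counts": outdir / "scaffold_counts.tsv",
                          "cooccurrence": outdir / "cooccurrence.csv"}

    if "express" in run_config:
        ex = run_config["express"]
        if result is None:
            _require(outdir / "consensus.fa", "discover")
            result = _load_consensus_result(outdir / "consensus.fa")
        refs = {rec.name: _consensus.build_reference(rec.consensus)
                for rec in result.records}
        reads_by_sample, _truth = _synthdata.sim_rnaseq(
            refs, ex["samples"],
            background_fraction=float(ex.get("background_fraction", 0.5)),
            library_size=int(ex.get("library_size", 100_000)), seed=seed)
        counts = {}
        totals = {}
        refset = _quantify.ReferenceSet(refs, k=cfg.seed_kmer)
        for sample, rds in reads_by_sample.items():
            c, bg = _transcription.count_rna_reads(rds, refset)
            counts[sample] = c
            totals[sample] = int(c.sum() + bg)
        counts_df = pd.DataFrame(counts)
        cpm = _transcription.cpm_normalize(counts_df, pd.Series(totals))
        retained = _transcription.filter_expressed(cpm, cfg.min_cpm,
                                                   cfg.min_cpm_samples)
        patterns = _transcription.classify_families(
            retained, ex["antenna_samples"], ex["ovary_sample"],
            ex["testis_sample"], dominance=cfg.dominance)
        write_table(outdir / "rna_counts.tsv",
                    counts_df.reset_index(names="family"), cfg, seed)
        write_table(outdir / "rna_cpm.tsv",
                    cpm.reset_index(names="family"), cfg, seed)
        write_table(outdir / "rna_patterns.tsv",
                    patterns.reset_index(names="family"), cfg, seed)
        prop = result.family_table.set_index("name")["genome_proportion_pct"]
        try:
            corr = _transcription.correlate_abundance(cpm.mean(axis=1), prop)
            corr_payload = dataclasses.asdict(corr)
        except ValueError as exc:
            corr_payload = {"error": str(exc)}
        with open(outdir / "rna_correlation.json", "w") as fh:
            json.dump(corr_payload, fh, indent=2)
        artifacts |= {"rna_counts": outdir / "rna_counts.tsv",
                      "rna_cpm": outdir / "rna_cpm.tsv",
                      "rna_patterns": outdir / "rna_patterns.tsv",
                      "rna_correlation": outdir / "rna_correlation.json"}

    return artifacts


def _load_consensus_result(path: Path) -> SatellitomeResult:
    """Rebuild the minimal record structure from a consensus FASTA written
    by an earlier run (family entries plus ``<name>_sub_<cluster>`` ones)."""
    from ._seq import read_fasta

    seqs = read_fasta(path)
    fam_names = [n for n in seqs if "_sub_" not in n]
    records = []
    for name in fam_names:
        subs = [(n.split("_sub_", 1)[1], s) for n, s in seqs.items()
                if n.startswith(name + "_sub_")]
        records.append(_consensus.SatFamilyRecord(
            name=name, consensus=seqs[name], genome_proportion_pct=0.0,
            divergence_pct=None, n_clusters=max(len(subs), 1),
            subfamilies=subs or [(name, seqs[name])]))
    table = pd.DataFrame([{
        "name": r.name, "n_clusters": r.n_clusters,
        "genome_proportion_pct": r.genome_proportion_pct,
        "repeat_length_bp": r.monomer_length, "at_pct": r.at_pct,
        "divergence_pct": r.divergence_pct,
    } for r in records], columns=TABLE_COLUMNS)
    return SatellitomeResult(
        family_table=table, records=records, clusters=[],
        cluster_consensus={}, subfamily_groups=[], family_of={})
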