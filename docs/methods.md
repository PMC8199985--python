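# Methods

This note documents the models, parameter choices and numerical decisions
behind `satkit`, in the order the pipeline runs them. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The analysis model

Satellite DNA is modeled as a set of **families**: each family has a
monomer consensus (30–1000 bp), and its genomic presence consists of
tandem arrays of mutated copies of that consensus. A family may comprise
several **subfamilies** — sequence variants that occupy their own arrays.
Three observables summarize a family: its *genome proportion* (fraction of
sequenced bases belonging to it), its *mean divergence* (average Kimura
2-parameter distance of genomic copies from the consensus), and its
*monomer length*. The analysis estimates all three from low-coverage
unassembled reads, because assemblies systematically collapse tandem
arrays.

## 2. Read clustering (discovery)

Reads are nodes of an undirected graph; an edge joins two reads that share
at least `min_shared` canonical k-mers (default `k=13`, `min_shared=3`;
canonical = lexicographic minimum of a k-mer and its reverse complement,
2-bit packed) **provided** the shared k-mers span at least `min_span=26` bp
in one of the reads. Connected components above the 0.001% genome-
proportion floor become clusters `CL1, CL2, …` (decreasing member bp; ties
to the smallest member read id).

Three of these choices deserve justification:

- **k = 13.** The probability that two reads from copies of the same
  family share an exact k-mer at a given offset is roughly `i^k`, where
  `i` is the copy-pair identity. At the highest divergence the pipeline
  targets (20% per copy, hence `i ≈ 0.66`), `k=21` gives an expected
  shared-k-mer count far below 1 per read pair — diverged families would
  shatter into singletons. `k=13` leaves an expected count near 0.6, which
  with hundreds of reads per family keeps the cluster connected.
- **The span guard.** A megabase-scale i.i.d. genome contains thousands of
  chance repeated ~15-bp substrings (birthday effect, worsened by biased
  A+T composition). Their k-mer matches are consecutive, whereas genuine
  read overlaps or shared repeat content scatter matches across the read.
  Requiring a ≥26-bp span for the shared set removes essentially all
  chance edges while leaving genuine ones; without it the background
  percolates into one giant cluster. This is the k-mer analogue of the
  alignment-overlap criterion real read-clustering pipelines apply.
- **Low-coverage sampling.** At read coverage above ~0.5X, genuine
  physical overlaps alone connect the whole genome (mean overlap degree
  > 1). Graph clustering therefore runs on a sub-critical sample —
  ~0.1–0.3X, the same regime the published pipelines use — while
  quantification (stage 4) uses every read. `PipelineConfig.cluster_sample`
  is a read count (default 600,000, ≈0.12X for a 730-Mb genome); choose it
  so sampled bp / genome length stays ≈0.3 or below.

**Representative.** Each cluster is represented by its best-connected
member read (within-cluster degree; the graph analogue of the
highest-coverage contig) extended greedily left and right by member reads
overlapping ≥50 bp at ≥60% identity, to at most 2200 bp. The 60% identity
floor admits overlaps between different copies of a 20%-diverged family
(expected pair identity 0.66) while rejecting wrong-phase joins (~25%).
The 2200-bp cap accommodates two copies of the largest supported monomer.

**Tandem calling.** For shifts `s` in `[4, L/2]` the profile
`f(s)` = fraction of positions where the representative matches itself
shifted by `s`. The cluster is tandem if `max f(s)` reaches the threshold;
the period is the smallest local maximum above it. Two thresholds apply:
the global default 0.7, and the pipeline default 0.55 — at the true period
`f` equals the copy-pair identity `≈ (1−d)² + d²/2`, which is 0.66 at
`d=0.20`, so a 0.7 floor would cap detectable divergence at ~15%; the
random-sequence maximum of `f` sits near 0.35–0.40, so 0.55 retains a wide
margin. A windowed variant (best sliding-window mean, window
`max(3s, 90)` bp, stricter 0.7 threshold) additionally catches short
tandem blocks embedded in a longer representative — the situation of
families organized in arrays shorter than two read lengths. Periods below
the `s ≥ 4` floor are reported as a multiple (documented behavior).

## 3. Consensus and family assembly

Monomers are consecutive `period`-length windows of the representative
(trailing fragment dropped). Because tandem monomers are circular
permutations of one another, each monomer is first rotated (right
rotation; exhaustive edit-distance minimization, ties to the smallest
offset) to best match the longest monomer, then the set (subsampled evenly
to ≤100) is aligned with MAFFT and collapsed column-wise: plurality base
over {A,C,G,T,−}; a column is dropped when the gap symbol is the strict
plurality; base ties break alphabetically. The consensus is then
**polished**: cluster reads are locally aligned to the doubled consensus
(both strands) and each column replaced by its pileup plurality, for 2
rounds. Polishing is what brings consensus error to ~0 even for
20%-diverged families, where ~10 monomers of majority vote would leave
several percent error — without it, divergence estimates inflate by the
consensus error.

Cluster consensuses merge into families by single linkage: a rotation- and
strand-aware local alignment covering ≥50% of the shorter consensus at
≥80% identity over ≥30 gap-free columns. The absolute 30-column floor
exists because for short monomers "50% of the shorter" can be a ~20-column
alignment, which random sequence attains at 80% identity often enough to
bridge unrelated families. Families are named
`<prefix>Sat<NN>-<consensus length>` by decreasing genome proportion (ties:
longer consensus, then lexicographic).

Short low-complexity motifs (monomer < ~8 bp, e.g. telomeric TTAGG or
GATA microsatellites) are not discoverable by read-graph clustering; they
enter as user-declared motifs and are quantified with references built by
the same rule.

## 4. Quantification

Every family/subfamily consensus is expanded to a mapping reference of
`max(2, ceil(200/L))` concatenated copies (≥2 monomers and ≥~200 bp, so a
150-bp read always fits inside, whatever the phase). Reads sharing an
11-mer with a reference are aligned to it on both strands
(Smith–Waterman-style local alignment, match +1, mismatch −1, gap open −3,
extend −1; hits below score 30 dropped — approximately 30 matched bp).
Overlapping hits on one read are resolved greedily by descending score
(ties: family name, then start): a hit is kept if it overlaps each kept
hit by <10 bp and is trimmed of residual overlap, so each read base is
masked at most once.

Per hit, transitions `P` and transversions `Q` are counted over gap-free
aligned columns (gaps never enter divergence, matching the RepeatMasker
divergence script's convention) and pooled into one Kimura 2-parameter
distance `K = −½ ln((1−2P−Q)·√(1−2Q))`, undefined (and excluded from
divergence means, but not from masked bp) outside the formula's domain.
Family abundance = masked bp / total sampled bp, with subfamily masked bp
summing into the family; family divergence = column-weighted mean of
per-hit `K`. Landscapes bin masked bp by `floor(100·K)` into 1%-wide bins
capped at [49,50); hits with undefined `K` land in the top bin so masked
bp is conserved. Summary statistics over a family table use the sample
(n−1) standard deviation, and include declared short-motif rows.

## 5. Relations and assembly scan

Similarity screening aligns the shorter consensus (both strands) against
the doubled longer one — doubling exposes junction-spanning similarity
between circular monomers — and judges the score against a Gumbel fit
(method of moments) to 200 shuffled-query scores, reporting pairs with
tail probability ≤ 0.001. This replaces blastn E-value theory with an
empirical null of the same intent.

Subfamily networks use rotation-minimized edit distances (unit costs)
between subfamily consensuses, and the ε=0 **minimum spanning network**:
distinct distances ascending, adding every edge whose endpoints are not
connected through strictly smaller distances — exactly the union of all
minimum spanning trees (verified in tests against exhaustive tree
enumeration).

The assembly scan runs blastn (word size 11, dust off; word size 7 for
queries < 30 bp) and accepts hits with ≥90% single-HSP query coverage and
≥90% identity. Subfamily co-occurrence is the Jaccard fraction of shared
scaffolds (an asymmetric conditional variant `|A∩B|/|A|` is available);
the symmetric choice matches the symmetric look of published heatmaps.
Note the rule's intrinsic limit: variants less than ~10% diverged cannot
be separated at 90% identity, an artefact the literature itself flags.

## 6. Transcription

Each RNA-seq read is assigned to exactly one family — the reference with
the smallest semi-global edit distance (read embedded in the reference,
both strands; ties to the lexicographically first name); reads above 0.35
distance per base, or sharing no seed k-mer, fall into a background bucket
that stands in for the transcriptome. CPM uses total counted reads
(families + background) as denominator. Families with CPM strictly above
50 in at least two samples are retained. Tissue groups follow the
3-antenna + 2-gonad design: antenna = mean of its three samples, each
gonad a single sample. With shares `a+o+t = 1`, the pattern is P2 if
`a ≥ 0.7`; else P4 if one gonad ≥ 0.7; else P3 if `o+t ≥ 0.7`; else P1.
The 0.7 dominance threshold quantifies patterns that the literature
describes qualitatively; it is configurable. Abundance–transcription
association uses Spearman correlation with average ranks; the two-sided
p-value comes from exact permutation enumeration for n ≤ 9 and the t
approximation otherwise. "Combined transcription" defaults to the mean
CPM across all five samples (an assumption; the source analyses do not
define it).

## 7. The synthetic-data generator

`synthdata` emulates exactly the statistical structure the analysis
assumes: i.i.d. background sequence at configurable A+T (default 0.65,
matching typical heteropteran read composition); families as tandem arrays
of independently mutated consensus copies; per-site substitution
probability = the `divergence` parameter, transitions chosen with
probability `R/(R+1)` for transition/transversion ratio `R` (default 2);
single-base indels, insertion/deletion equiprobable (default rate 0 —
the smallest model that exercises gapped alignment); constant base
qualities ("I"); fixed insert length; uniformly positioned fragments with
random strand. Every generator is a pure function of its parameters and a
seed (child streams derived per scaffold/family/sample), and `ArrayTruth`
records interval coordinates (0-based half-open BED), realized proportions
and realized divergences.

Because the generator applies at most one substitution per site, the
`divergence` parameter is a p-distance; the K2P distance of such copies is
larger (23.9% for a 20% p-distance). `ArrayTruth` therefore records the
**realized K2P divergence** computed from the realized
transition/transversion counts, and all recovery experiments score
estimates against that — the quantity the pipeline actually estimates.

What the generator does **not** emulate, and what passing tests therefore
do not show: transposable elements and segmental duplications (real
repeatomes contain both, and they enter real read clusters), position- and
context-dependent sequencing error profiles, PCR duplicates, insert-size
variance, heterozygosity and polyploidy, gene content in RNA-seq
(background reads are random sequence, so real transcriptome multireads
are unmodeled), and library-preparation differences between samples
(poly-A enrichment of gonad libraries in the motivating study — a
comparability caveat that survives in any CPM-based comparison).

## 8. Canonical experiments and problem sizes

`satkit.validation` pre-registers the package's three study-condition
experiments, shared by the test suite and `scripts/acceptance.py`:

- **Recovery**: 5-Mb genome, eight families with proportions
  3.0/2.0/1.2/0.8/0.5/0.3/0.15/0.05% paired with divergences
  20/17/13/10/8/6/4/2% (abundant families most diverged, the pattern real
  satellitome tables show), monomers 165/169/124/133/208/293/104/41 bp,
  arrays 40/30/25/20/12/8/10/10; 1X PE150 reads with 0.002 error;
  clustering sample 10,000 reads (0.3X). Scored by sequence-based matching
  of recovered consensuses to planted monomers. Note the statistical
  floor: at this scale the 0.05% family is covered by only ~20 read
  fragments, so its abundance estimate carries ~22% relative sampling
  noise *before any pipeline error* — estimates are unbiased but
  individual seeds can land outside ±20%.
- **Co-occurrence**: 20 10-kb scaffolds, two subfamily variants at 20%
  mutual divergence, 12-copy arrays, either on disjoint scaffolds or
  interleaved within every array.
- **Transcription**: 20 families (5 per pattern, P4 split between ovary-
  and testis-dominant), planted tissue shares 0.40/0.30/0.30 (P1),
  0.85-antenna (P2), 0.16/0.42/0.42 (P3), 0.85-single-gonad (P4), library
  size 100,000, 50% background.

These sizes were chosen so each experiment completes in minutes on one
CPU while leaving every estimator's signal-to-noise in a regime where the
documented tolerances are meaningful.

## 9. Known limitations

- The k-mer graph is a deliberate simplification of alignment-based read
  clustering; it has no notion of superclusters, TE annotation, or
  TAREAN's circular consensus scoring.
- Period detection reports multiples for periods below the shift floor
  (4 bp) and cannot see periods longer than half the representative.
- Local-alignment end trimming biases divergence slightly downward at high
  divergence (≈ −1 percentage point at 20%).
- Cluster-size abundance estimates are upward-biased (clusters absorb
  boundary and chained background reads); authoritative abundances come
  from the read-masking stage.
- The Gumbel shuffle null is an approximation to alignment score
  statistics; with 200 shuffles, reported p-values below ~1e-4 are
  extrapolations of the fitted tail.
- The 90/90 assembly rule cannot discriminate subfamilies less than ~10%
  diverged; the co-occurrence matrix for such pairs is inflated by
  cross-matching, not by genuine co-occurrence.
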