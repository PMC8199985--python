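"""Generator correctness: composition, mutation model, genome construction,
read simulation and the truth tables downstream recovery relies on."""

import math

import numpy as np
import pytest

from satkit import synthdata as sd
from satkit._seq import revcomp


class TestMakeConsensus:
    def test_extreme_at_composition(self):
        s = sd.make_consensus(4, 1.0, seed=1)
        assert len(s) == 4 and set(s) <= {"A", "T"}

    def test_at_content_within_binomial_ci(self):
        s = sd.make_consensus(165, 0.72, seed=7)
        assert len(s) == 165
        at = (s.count("A") + s.count("T")) / 165
        half = 2.576 * math.sqrt(0.72 * 0.28 / 165)  # 99% binomial CI
        assert abs(at - 0.72) <= half

    def test_deterministic(self):
        assert sd.make_consensus(80, 0.6, seed=3) == sd.make_consensus(80, 0.6, seed=3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sd.make_consensus(3, 0.5, seed=0)


class TestMutateCopy:
    def test_zero_divergence_identity(self, rng):
        m = sd.make_consensus(120, 0.6, seed=2)
        assert sd.mutate_copy(m, 0.0, indel_rate=0.0, rng=rng) == m

    def test_p_distance_matches_divergence(self, rng):
        m = sd.make_consensus(165, 0.6, seed=2)
        n_copies, d = 10_000, 0.05
        mism = sum(
            sum(a != b for a, b in zip(sd.mutate_copy(m, d, rng=rng), m))
            for _ in range(n_copies))
        sites = n_copies * len(m)
        p_hat = mism / sites
        half = 2.576 * math.sqrt(d * (1 - d) / sites)
        assert abs(p_hat - d) <= half

    def test_ts_tv_ratio(self, rng):
        m = sd.make_consensus(165, 0.5, seed=4)
        ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
        n_ts = n_tv = 0
        for _ in range(10_000):
            c = sd.mutate_copy(m, 0.1, ts_tv_ratio=2.0, rng=rng)
            for a, b in zip(m, c):
                if a != b:
                    if ts[a] == b:
                        n_ts += 1
                    else:
                        n_tv += 1
        n = n_ts + n_tv
        p_hat = n_ts / n  # expected 2/3 under ts:tv = 2
        half = 2.576 * math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(p_hat - 2 / 3) <= half

    def test_indels_change_length(self, rng):
        m = sd.make_consensus(200, 0.5, seed=5)
        lengths = {len(sd.mutate_copy(m, 0.0, indel_rate=0.04, rng=rng))
                   for _ in range(50)}
        assert lengths != {200}

    def test_divergence_out_of_range(self, rng):
        with pytest.raises(ValueError):
            sd.mutate_copy("ACGTACGTACGT", 0.5, rng=rng)


class TestBuildGenome:
    def test_single_family_proportion(self):
        spec = sd.SatFamilySpec("f", sd.make_consensus(100, 0.6, 1), 0.02,
                                divergence=0.03, n_arrays=4)
        genome, truth = sd.build_genome([spec], 1_000_000, seed=9)
        assert len(genome["scf1"]) == 1_000_000
        assert 0.0195 <= truth.proportion("f") <= 0.0205

    def test_zero_families(self):
        genome, truth = sd.build_genome([], 50_000, seed=1)
        assert truth.family_stats.empty and not truth.intervals
        assert len(genome["scf1"]) == 50_000

    def test_interval_conservation_is_exact(self):
        specs = [
            sd.SatFamilySpec("a", sd.make_consensus(90, 0.6, 1), 0.01, n_arrays=3),
            sd.SatFamilySpec("b", sd.make_consensus(150, 0.7, 2), 0.02, n_arrays=2),
        ]
        genome, truth = sd.build_genome(specs, 400_000, seed=4)
        interval_bp = sum(iv.end - iv.start for iv in truth.intervals)
        assert truth.satellite_fraction == interval_bp / 400_000
        stats_bp = (truth.family_stats["realized_proportion"] * 400_000).sum()
        assert interval_bp == pytest.approx(stats_bp)

    def test_intervals_non_overlapping_and_in_bounds(self):
        specs = [sd.SatFamilySpec("a", sd.make_consensus(80, 0.5, 3), 0.05,
                                  n_arrays=12)]
        genome, truth = sd.build_genome(specs, 300_000, seed=5)
        ivs = sorted((iv.start, iv.end) for iv in truth.intervals)
        assert all(0 <= s < e <= 300_000 for s, e in ivs)
        assert all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))

    def test_subfamily_arrays_never_mix(self):
        base = sd.make_consensus(120, 0.6, 6)
        rng = np.random.default_rng(0)
        var = sd.mutate_copy(base, 0.12, rng=rng)
        specs = [
            sd.SatFamilySpec("fam_s1", base, 0.01, divergence=0.01, n_arrays=5),
            sd.SatFamilySpec("fam_s2", var, 0.01, divergence=0.01, n_arrays=5,
                             subfamily_of="fam_s1"),
        ]
        genome, truth = sd.build_genome(specs, 500_000, seed=8)
        # each truth interval carries exactly one variant by construction
        for iv in truth.intervals:
            assert iv.family in {"fam_s1", "fam_s2"}
        assert sum(iv.family == "fam_s1" for iv in truth.intervals) == 5
        assert sum(iv.family == "fam_s2" for iv in truth.intervals) == 5

    def test_arrays_actually_spliced_into_genome(self):
        spec = sd.SatFamilySpec("f", sd.make_consensus(100, 0.6, 1), 0.02,
                                divergence=0.0, n_arrays=2)
        genome, truth = sd.build_genome([spec], 200_000, seed=2)
        iv = truth.intervals[0]
        segment = genome[iv.scaffold][iv.start : iv.start + 100]
        assert segment == spec.monomer

    def test_overfull_genome_rejected(self):
        spec = sd.SatFamilySpec("f", sd.make_consensus(100, 0.5, 1), 0.35)
        with pytest.raises(ValueError):
            sd.build_genome([spec, sd.SatFamilySpec(
                "g", sd.make_consensus(100, 0.5, 2), 0.2)], 100_000, seed=1)

    def test_placement_error_when_genome_too_small(self):
        # three 1000-bp arrays can only tile a 3-kb genome exactly, which
        # rejection sampling will not find
        spec = sd.SatFamilySpec("f", sd.make_consensus(1000, 0.5, 1), 0.3,
                                n_arrays=3)
        with pytest.raises(sd.PlacementError):
            sd.build_genome([spec], 3_000, seed=1, max_retries=50)


class TestSimReads:
    def test_pair_count_formula(self):
        genome = {"g": sd.make_consensus(10_000, 0.5, 1)}
        pairs = sd.sim_reads(genome, 0.5, seed=1)
        assert len(pairs) == math.ceil(0.5 * 10_000 / 300)
        genome_1mb = {"g": sd.make_consensus(1_000_000, 0.5, 2)}
        assert len(sd.sim_reads(genome_1mb, 0.5, seed=1)) == 1667

    def test_errorfree_reads_are_genome_substrings(self):
        g = sd.make_consensus(20_000, 0.6, 3)
        rc = revcomp(g)
        for (id1, r1), (id2, r2) in sd.sim_reads({"g": g}, 0.3, seed=2):
            assert r1 in g or r1 in rc
            assert r2 in g or r2 in rc

    def test_deterministic_per_seed(self):
        g = {"g": sd.make_consensus(5_000, 0.5, 4)}
        assert sd.sim_reads(g, 1.0, seed=7) == sd.sim_reads(g, 1.0, seed=7)
        assert sd.sim_reads(g, 1.0, seed=7) != sd.sim_reads(g, 1.0, seed=8)

    def test_genome_shorter_than_insert(self):
        with pytest.raises(ValueError):
            sd.sim_reads({"g": "ACGT" * 20}, 1.0, seed=1)


class TestAssemblyPseudoReads:
    def test_single_scaffold_count(self):
        asm = {"s1": sd.make_consensus(10_000, 0.5, 1)}
        assert len(sd.assembly_pseudo_reads(asm, 1.0, seed=1)) == 34

    def test_length_proportional_sampling(self):
        asm = {"big": sd.make_consensus(90_000, 0.5, 1),
               "small": sd.make_consensus(10_000, 0.5, 2)}
        pairs = sd.assembly_pseudo_reads(asm, 3.0, seed=3)
        big = sum(1 for (i1, r1), _p in pairs
                  if r1 in asm["big"] or revcomp(r1) in asm["big"])
        n = len(pairs)
        half = 2.576 * math.sqrt(0.9 * 0.1 / n)  # 99% binomial CI on 9:1
        assert abs(big / n - 0.9) <= half

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValueError):
            sd.assembly_pseudo_reads({}, 1.0, seed=1)

    def test_short_scaffold_skipped_with_warning(self, caplog):
        asm = {"ok": sd.make_consensus(5_000, 0.5, 1), "tiny": "ACGT" * 10}
        import logging

        with caplog.at_level(logging.WARNING, logger="satkit.synthdata"):
            pairs = sd.assembly_pseudo_reads(asm, 1.0, seed=1)
        assert any("tiny" in rec.message for rec in caplog.records)
        # total genome length (including the skipped scaffold) sets the count
        assert len(pairs) == math.ceil(5_040 / 300)


class TestSimRnaseq:
    def test_expected_family_count(self):
        refs = {"f": sd.make_consensus(300, 0.5, 1)}
        reads, truth = sd.sim_rnaseq(refs, {"s": {"f": 1.0}},
                                     background_fraction=0.9,
                                     library_size=100_000, seed=1)
        cnt = int(truth["planted_count"].iloc[0])
        half = 2.576 * math.sqrt(100_000 * 0.1 * 0.9)
        assert abs(cnt - 10_000) <= half
        assert len(reads["s"]) == 100_000

    def test_zero_weight_zero_reads(self):
        refs = {"f": sd.make_consensus(300, 0.5, 1),
                "g": sd.make_consensus(300, 0.5, 2)}
        reads, truth = sd.sim_rnaseq(refs, {"s": {"f": 1.0, "g": 0.0}},
                                     background_fraction=0.0,
                                     library_size=5_000, seed=2)
        assert int(truth.set_index("family").loc["g", "planted_count"]) == 0

    def test_rerun_determinism(self):
        refs = {"f": sd.make_consensus(250, 0.5, 1)}
        expr = {"s1": {"f": 1.0}, "s2": {"f": 1.0}}
        a, _ = sd.sim_rnaseq(refs, expr, 0.5, 2_000, seed=5)
        b, _ = sd.sim_rnaseq(refs, expr, 0.5, 2_000, seed=5)
        assert a == b

    def test_all_zero_rejected(self):
        refs = {"f": sd.make_consensus(250, 0.5, 1)}
        with pytest.raises(ValueError):
            sd.sim_rnaseq(refs, {"s": {"f": 0.0}}, 0.0, 1_000, seed=1)
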