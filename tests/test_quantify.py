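"""Read mapping, overlap resolution, Kimura-2P distances, abundance,
landscapes and the summary-table statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from satkit import consensus as cons
from satkit import quantify as q
from satkit import synthdata as sd
from satkit import workflow as wf
from satkit._seq import random_dna, revcomp


class TestKimura2P:
    def test_zero_distance(self):
        assert q.kimura2p(0.0, 0.0) == 0.0

    def test_closed_form_values(self):
        # independent evaluation of -1/2 ln((1-2P-Q) sqrt(1-2Q))
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert q.kimura2p(0.1, 0.05) == pytest.approx(expected, abs=1e-12)
        assert q.kimura2p(0.1, 0.05) == pytest.approx(0.170181, abs=1e-5)

    def test_single_transversion_in_four_columns(self):
        # ACGT vs ACGA: P=0, Q=0.25
        expected = -0.5 * math.log(0.75 * math.sqrt(0.5))
        assert q.kimura2p(0.0, 0.25) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("P,Q", [(0.5, 0.2), (0.2, 0.5), (0.46, 0.1)])
    def test_domain_violations_flagged(self, P, Q):
        assert math.isnan(q.kimura2p(P, Q))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            q.kimura2p(-0.1, 0.0)
        with pytest.raises(ValueError):
            q.kimura2p(0.6, 0.6)

    def test_exceeds_p_distance_and_monotone(self):
        ps = np.linspace(0.0, 0.30, 16)
        qs = np.linspace(0.0, 0.30, 16)
        prev_row = None
        for P in ps:
            row = []
            for Q in qs:
                K = q.kimura2p(P, Q)
                assert K >= P + Q - 1e-12  # Jensen/series bound
                row.append(K)
            assert all(row[i] < row[i + 1] for i in range(len(row) - 1))
            if prev_row is not None:
                assert all(a < b for a, b in zip(prev_row, row))
            prev_row = row


class TestMapReads:
    def setup_method(self):
        self.rng = np.random.default_rng(77)
        self.mono = sd.make_consensus(165, 0.6, 55)
        self.refs = {"fam": cons.build_reference(self.mono)}

    def test_exact_substring_full_hit(self):
        read = self.refs["fam"][40:190]
        hits = q.map_reads([("r1", read)], self.refs)
        assert len(hits) == 1
        h = hits[0]
        assert (h.P, h.Q) == (0.0, 0.0)
        assert (h.start, h.end) == (0, 150)
        assert h.K == 0.0 and h.strand == "+"

    def test_random_reads_yield_no_hits(self):
        reads = [(f"r{i}", random_dna(150, self.rng)) for i in range(50)]
        assert q.map_reads(reads, self.refs) == []

    def test_reverse_complement_strand_symmetric(self):
        rng = np.random.default_rng(3)
        read = sd.mutate_copy(self.refs["fam"][10:160], 0.05, rng=rng)
        fwd = q.map_reads([("r", read)], self.refs)
        rev = q.map_reads([("r", revcomp(read))], self.refs)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].P == rev[0].P and fwd[0].Q == rev[0].Q
        assert fwd[0].score == rev[0].score
        assert {fwd[0].strand, rev[0].strand} == {"+", "-"}

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            q.map_reads([("r", "ACGT" * 40)], {})


def _hit(read_id="r", family="f", start=0, end=100, score=50.0):
    return q.RepeatHit(read_id=read_id, family=family, start=start, end=end,
                       aligned_cols=end - start, P=0.0, Q=0.0, K=0.0,
                       score=score, strand="+")


class TestResolveOverlaps:
    def test_identical_intervals_keep_best_score(self):
        kept = q.resolve_read_overlaps([_hit(score=50), _hit(family="g", score=40)])
        assert len(kept) == 1 and kept[0].score == 50

    def test_disjoint_hits_both_kept(self):
        kept = q.resolve_read_overlaps([_hit(end=60), _hit(start=80, end=150)])
        assert len(kept) == 2

    def test_small_overlap_trimmed(self):
        kept = q.resolve_read_overlaps(
            [_hit(end=100, score=60), _hit(start=95, end=150, score=40)])
        assert len(kept) == 2
        assert sum(h.masked_bp for h in kept) == 150  # trimmed, not double-masked

    def test_matches_brute_force_greedy(self, rng):
        def oracle(hits, max_overlap=10):
            kept = []
            for h in sorted(hits, key=lambda x: (-x.score, x.family, x.start)):
                s, e = h.start, h.end
                if any(min(e, o[1]) - max(s, o[0]) >= max_overlap for o in kept):
                    continue
                for o in kept:
                    ov = min(e, o[1]) - max(s, o[0])
                    if ov > 0:
                        if o[0] <= s:
                            s = o[1]
                        else:
                            e = o[0]
                if e > s:
                    kept.append((s, e))
            return sorted(kept)

        for trial in range(30):
            hits = [_hit(family=f"f{i}",
                         start=int(rng.integers(0, 120)),
                         end=0, score=float(rng.integers(10, 90)))
                    for i in range(int(rng.integers(1, 6)))]
            hits = [q.RepeatHit(h.read_id, h.family, h.start,
                                h.start + int(rng.integers(10, 60)),
                                10, 0.0, 0.0, 0.0, h.score, "+")
                    for h in hits]
            kept = q.resolve_read_overlaps(hits)
            assert sorted((h.start, h.end) for h in kept) == oracle(hits)


class TestAbundanceDivergence:
    def test_abundance_arithmetic(self):
        hits = [_hit(end=100), _hit(read_id="r2", start=0, end=20)]
        prop = q.family_abundance(hits, total_bp=150_000)
        assert prop["f"] == pytest.approx(120 / 150_000)
        assert q.family_abundance([], 1000).empty

    def test_subfamily_bp_sums_into_family(self):
        hits = [_hit(family="s1", end=100), _hit(read_id="r2", family="s2", end=50)]
        prop = q.family_abundance(hits, 1000, family_of={"s1": "F", "s2": "F"})
        assert prop["F"] == pytest.approx(0.15)

    def test_divergence_weighted_mean(self):
        h1 = q.RepeatHit("r1", "f", 0, 100, 100, 0.05, 0.02, 0.10, 50, "+")
        h2 = q.RepeatHit("r2", "f", 0, 100, 300, 0.1, 0.05, 0.20, 50, "+")
        div = q.family_divergence([h1, h2])
        assert div["f"] == pytest.approx(100 * (0.10 * 100 + 0.20 * 300) / 400)

    def test_undefined_k_excluded_from_divergence_but_not_abundance(self):
        good = q.RepeatHit("r1", "f", 0, 100, 100, 0.0, 0.0, 0.0, 50, "+")
        bad = q.RepeatHit("r2", "f", 0, 100, 100, 0.5, 0.2, math.nan, 50, "+")
        assert q.family_divergence([good, bad])["f"] == 0.0
        assert q.family_abundance([good, bad], 1000)["f"] == pytest.approx(0.2)

    def test_masked_bp_conservation(self):
        mono = sd.make_consensus(120, 0.6, 5)
        refs = {"fam": cons.build_reference(mono)}
        rng = np.random.default_rng(9)
        reads = [("sat", refs["fam"][:150]), ("bg", random_dna(150, rng))]
        resolved = q.resolve_overlaps(q.map_reads(reads, refs))
        total = 300
        masked = sum(h.masked_bp for h in resolved)
        unmasked = total - masked
        assert masked + unmasked == total and masked == 150


class TestLandscape:
    def test_bin_assignment(self):
        h = q.RepeatHit("r", "f", 0, 100, 100, 0.03, 0.013, 0.043, 50, "+")
        land = q.landscape([h], total_bp=10_000)
        row = land.iloc[0]
        assert (row.bin_low, row.bin_high, row.bp) == (4, 5, 100)
        assert row.pct_genome == pytest.approx(1.0)

    def test_zero_divergence_in_first_bin(self):
        h = q.RepeatHit("r", "f", 0, 80, 80, 0.0, 0.0, 0.0, 50, "+")
        assert q.landscape([h], 1000).iloc[0].bin_low == 0

    def test_bin_bp_sums_to_family_masked_bp(self, rng):
        hits = []
        for i in range(40):
            K = float(rng.uniform(0, 0.6))
            hits.append(q.RepeatHit(f"r{i}", "f", 0, 100, 100, 0.0, 0.0,
                                    K if K < 0.55 else math.nan, 50, "+"))
        land = q.landscape(hits, 100_000)
        assert land["bp"].sum() == sum(h.masked_bp for h in hits)
        assert land["bin_high"].max() <= 50

    def test_planted_divergence_sets_landscape_mode(self, rng):
        mono = sd.make_consensus(165, 0.6, 66)
        refs = {"fam": cons.build_reference(mono)}
        array = "".join(sd.mutate_copy(mono, 0.05, rng=rng) for _ in range(60))
        reads = [(f"r{i}", array[s : s + 150])
                 for i, s in enumerate(rng.integers(0, len(array) - 150, size=80))]
        resolved = q.resolve_overlaps(q.map_reads(reads, refs))
        land = q.landscape(resolved, 80 * 150)
        mode_bin = land.loc[land["bp"].idxmax(), "bin_low"]
        assert 3 <= mode_bin < 7


class TestSummarizeTable:
    def test_fixture_reproduces_printed_footer(self):
        stats = q.summarize_table(wf.load_family_table("fixture"))
        assert round(stats.mean_length, 2) == 235.23
        assert round(stats.sd_length, 2) == 223.13
        assert stats.median_length == 165
        assert round(stats.mean_at, 2) == 65.72
        assert round(stats.median_at, 2) == 65.50
        assert round(stats.mean_divergence, 2) == 10.56
        assert round(stats.median_divergence, 2) == 10.03
        assert round(stats.total_proportion_pct, 2) == 8.05

    def test_sample_sd_convention_not_population(self):
        table = wf.load_family_table("fixture")
        pop_sd = float(np.std(table["repeat_length_bp"].to_numpy(float)))
        stats = q.summarize_table(table)
        assert round(pop_sd, 2) == 220.25  # population SD must NOT match
        assert round(stats.sd_length, 2) != round(pop_sd, 2)

    def test_identical_rows_zero_sd(self):
        df = pd.DataFrame({
            "repeat_length_bp": [100, 100], "at_pct": [60.0, 60.0],
            "divergence_pct": [5.0, 5.0], "genome_proportion_pct": [1.0, 1.0]})
        stats = q.summarize_table(df)
        assert stats.sd_length == 0.0 and stats.total_proportion_pct == 2.0

    def test_single_row_sd_not_available(self):
        df = pd.DataFrame({
            "repeat_length_bp": [100], "at_pct": [60.0],
            "divergence_pct": [5.0], "genome_proportion_pct": [1.0]})
        assert math.isnan(q.summarize_table(df).sd_length)
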