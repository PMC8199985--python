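"""Monomer extraction, rotation alignment, consensus building, family
grouping, naming and reference construction."""

import numpy as np
import pytest

from satkit import align as al
from satkit import consensus as cons
from satkit import synthdata as sd
from satkit._seq import random_dna


class TestExtractMonomers:
    def test_exact_windows(self):
        assert cons.extract_monomers("ATCATCATC", 3) == ["ATC", "ATC", "ATC"]

    def test_trailing_fragment_dropped(self):
        rep = random_dna(500, np.random.default_rng(1))
        monomers = cons.extract_monomers(rep, 165)
        assert len(monomers) == 3
        assert all(len(m) == 165 for m in monomers)

    def test_too_few_monomers_rejected(self):
        with pytest.raises(ValueError):
            cons.extract_monomers("ACGTACGTA", 8)

    def test_mutated_copies_stay_near_truth(self, rng):
        mono = sd.make_consensus(120, 0.6, 3)
        rep = "".join(sd.mutate_copy(mono, 0.05, rng=rng) for _ in range(10))
        for m in cons.extract_monomers(rep, 120):
            p_dist = sum(a != b for a, b in zip(m, mono)) / 120
            assert p_dist <= 0.1


class TestRotateAlign:
    @pytest.mark.parametrize("monomer,reference,expected", [
        ("CGTA", "ACGT", (1, 0)),
        ("ACGT", "ACGT", (0, 0)),
    ])
    def test_known_rotations(self, monomer, reference, expected):
        assert cons.rotate_align(monomer, reference) == expected

    def test_single_substitution_distance(self, rotation_oracle):
        assert cons.rotate_align("ACGT", "ACGA")[1] == 1
        assert cons.rotate_align("ACGT", "ACGA") == rotation_oracle("ACGT", "ACGA")

    def test_matches_brute_force_oracle(self, rng, rotation_oracle):
        for _ in range(15):
            a = random_dna(int(rng.integers(6, 14)), rng)
            b = random_dna(int(rng.integers(6, 14)), rng)
            r_pkg, d_pkg = cons.rotate_align(a, b)
            r_ora, d_ora = rotation_oracle(a, b)
            assert d_pkg == d_ora
            assert r_pkg == r_ora


class TestBuildConsensus:
    def test_simple_majority(self):
        assert cons.build_consensus(["ACGT", "ACGT", "ACGA"]) == "ACGT"

    def test_tie_broken_alphabetically(self):
        # column 1 splits 2/2 between A and C -> A by the documented rule
        monomers = ["AGGTTT", "AGGTTT", "CGGTTT", "CGGTTT"]
        assert cons.build_consensus(monomers)[0] == "A"

    def test_recovers_truth_from_diverged_copies(self, rng):
        mono = sd.make_consensus(150, 0.6, 9)
        copies = [sd.mutate_copy(mono, 0.10, rng=rng) for _ in range(50)]
        consensus = cons.build_consensus(copies)
        assert al.edit_distance(consensus, mono) <= 2

    def test_rotation_invariance_up_to_rotation(self, rng):
        mono = sd.make_consensus(90, 0.6, 10)
        copies = [sd.mutate_copy(mono, 0.05, rng=rng) for _ in range(20)]
        rotated = [m[17:] + m[:17] for m in copies]
        c1 = cons.build_consensus(copies)
        c2 = cons.build_consensus(rotated)
        assert al.rotation_distance(c1, c2) <= 2

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            cons.build_consensus(["ACGTACGT"])


class TestPolishConsensus:
    def test_polish_fixes_consensus_errors(self, rng):
        mono = sd.make_consensus(140, 0.6, 12)
        # corrupt 8 positions, then polish with reads drawn from clean copies
        corrupt = list(mono)
        for pos in rng.choice(140, size=8, replace=False):
            corrupt[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[corrupt[pos]]
        corrupt = "".join(corrupt)
        array = "".join(sd.mutate_copy(mono, 0.03, rng=rng) for _ in range(40))
        reads = [array[s : s + 150]
                 for s in rng.integers(0, len(array) - 150, size=120)]
        polished = cons.polish_consensus(corrupt, reads)
        assert al.edit_distance(polished, mono) <= 1


class TestAssignSubfamilies:
    def test_identical_consensuses_merge(self, rng):
        c = random_dna(160, rng)
        groups = cons.assign_subfamilies([c, c])
        assert groups == [[0, 1]]

    def test_unrelated_consensuses_stay_apart(self, rng):
        a, b = random_dna(160, rng), random_dna(160, rng)
        assert cons.assign_subfamilies([a, b]) == [[0], [1]]

    def test_three_subfamilies_one_family(self, rng):
        base = sd.make_consensus(165, 0.65, 13)
        subs = [sd.mutate_copy(base, 0.06, rng=rng) for _ in range(3)]
        groups = cons.assign_subfamilies(subs)
        assert groups == [[0, 1, 2]]

    def test_permutation_invariant(self, rng):
        base = sd.make_consensus(140, 0.6, 14)
        items = [sd.mutate_copy(base, 0.05, rng=rng) for _ in range(2)]
        items += [random_dna(140, rng)]
        g1 = cons.assign_subfamilies(items)
        g2 = cons.assign_subfamilies(items[::-1])
        sets1 = {frozenset(items[i] for i in g) for g in g1}
        sets2 = {frozenset(items[::-1][i] for i in g) for g in g2}
        assert sets1 == sets2


class TestNameFamilies:
    def test_rank_and_length_encoding(self):
        fams = [{"consensus": "A" * length, "genome_proportion_pct": prop,
                 "divergence_pct": 1.0, "n_clusters": 1}
                for length, prop in [(165, 2.13), (169, 1.94), (293, 0.067)]]
        records = cons.name_families(fams, prefix="Rpro")
        assert [r.name for r in records] == [
            "RproSat01-165", "RproSat02-169", "RproSat03-293"]

    def test_thirteenth_rank_zero_padding(self):
        fams = [{"consensus": "A" * (100 + i), "genome_proportion_pct": 5.0 - 0.1 * i,
                 "divergence_pct": 1.0, "n_clusters": 1} for i in range(12)]
        fams.append({"consensus": "G" * 293, "genome_proportion_pct": 0.067,
                     "divergence_pct": 28.28, "n_clusters": 1})
        records = cons.name_families(fams, prefix="Rpro")
        assert records[12].name == "RproSat13-293"

    def test_custom_prefix(self):
        fams = [{"consensus": "A" * 208, "genome_proportion_pct": 1.0,
                 "divergence_pct": 0.0, "n_clusters": 1} for _ in range(5)]
        for i, f in enumerate(fams):
            f["genome_proportion_pct"] = 5.0 - i
            f["consensus"] = "ACGT" * 52  # 208 bp
        assert cons.name_families(fams, prefix="Xabc")[4].name == "XabcSat05-208"

    def test_tie_broken_by_length_then_sequence(self):
        fams = [
            {"consensus": "A" * 100, "genome_proportion_pct": 1.0,
             "divergence_pct": 0.0, "n_clusters": 1},
            {"consensus": "C" * 150, "genome_proportion_pct": 1.0,
             "divergence_pct": 0.0, "n_clusters": 1},
        ]
        records = cons.name_families(fams)
        assert records[0].monomer_length == 150


class TestBuildReference:
    @pytest.mark.parametrize("length,expected_copies", [
        (165, 2), (31, 7), (980, 2), (100, 2), (67, 3),
    ])
    def test_copy_rule(self, rng, length, expected_copies):
        consensus = random_dna(length, rng)
        ref = cons.build_reference(consensus)
        assert ref == consensus * expected_copies
        assert len(ref) >= 200 or expected_copies == 2

    def test_short_motif_reference(self):
        ref = cons.build_reference("TTAGG")
        assert ref == "TTAGG" * 40 and len(ref) == 200

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cons.build_reference("ACG")
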