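import itertools

import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from thermobias import orthology, synthetic
from thermobias.seqio import HIT_COLUMNS


def hits(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


class TestReciprocalBestHits:
    def test_reciprocal_pair_found(self):
        ab = hits([("a1", "b1", 90, 100, 1e-30, 80)])
        ba = hits([("b1", "a1", 90, 100, 1e-28, 75)])
        (pair,) = orthology.reciprocal_best_hits(ab, ba)
        assert (pair.protein_a, pair.protein_b, pair.bitscore) == ("a1", "b1", 80.0)

    def test_non_reciprocal_pair_dropped(self):
        ab = hits([("a1", "b1", 90, 100, 1e-30, 80)])
        ba = hits([("b1", "a2", 90, 100, 1e-40, 90)])
        assert orthology.reciprocal_best_hits(ab, ba) == []

    def test_bitscore_tie_broken_by_evalue(self):
        # oracle: exhaustive check of the tie-break ladder over both orderings
        for order in ([0, 1], [1, 0]):
            rows = [
                ("a1", "b1", 90, 100, 1e-30, 80),
                ("a1", "b2", 90, 100, 1e-20, 80),
            ]
            ab = hits([rows[i] for i in order])
            ba = hits([("b1", "a1", 90, 100, 1e-30, 78), ("b2", "a1", 90, 100, 1e-20, 78)])
            (pair,) = orthology.reciprocal_best_hits(ab, ba)
            assert pair.protein_b == "b1"

    def test_full_tie_broken_by_subject_id(self):
        ab = hits([("a1", "b2", 90, 100, 1e-30, 80), ("a1", "b1", 90, 100, 1e-30, 80)])
        ba = hits([("b1", "a1", 90, 100, 1e-30, 78), ("b2", "a1", 90, 100, 1e-30, 78)])
        (pair,) = orthology.reciprocal_best_hits(ab, ba)
        assert pair.protein_b == "b1"

    def test_mirror_symmetry(self):
        ab = hits(
            [
                ("a1", "b1", 90, 100, 1e-30, 80),
                ("a2", "b2", 85, 90, 1e-25, 70),
                ("a2", "b1", 50, 90, 1e-5, 30),
            ]
        )
        ba = hits(
            [
                ("b1", "a1", 90, 100, 1e-30, 79),
                ("b2", "a2", 85, 90, 1e-25, 71),
                ("b1", "a2", 50, 90, 1e-5, 31),
            ]
        )
        fwd = orthology.reciprocal_best_hits(ab, ba, "A", "B")
        rev = orthology.reciprocal_best_hits(ba, ab, "B", "A")
        assert {(p.protein_a, p.protein_b) for p in fwd} == {
            (p.protein_b, p.protein_a) for p in rev
        }

    def test_recovers_known_orthology_on_synthetic_panel(self):
        cfg = synthetic.GeneratorConfig(n_species=3, n_proteins=80, seed=5)
        panel = synthetic.simulate_ortholog_panel(cfg)
        a, b = sorted(panel.proteomes)[:2]
        pairs = orthology.reciprocal_best_hits(
            panel.hit_table(a, b), panel.hit_table(b, a), a, b
        )
        truth = {(f[a], f[b]) for f in panel.families}
        found = {(p.protein_a, p.protein_b) for p in pairs}
        assert len(found & truth) / len(truth) >= 0.99


class TestLifestyleFilter:
    labels = {"h1": "hyper", "h2": "hyper", "m1": "meso"}

    def pair(self, sa, pa, sb, pb):
        return orthology.OrthologPair(sa, pa, sb, pb, 50.0)

    def test_within_group_only_protein_dropped(self):
        pairs = [self.pair("h1", "p1", "h2", "p2")]
        assert orthology.lifestyle_filtered_set(pairs, self.labels) == {}

    def test_cross_group_protein_retained(self):
        pairs = [self.pair("h1", "p1", "m1", "p3")]
        kept = orthology.lifestyle_filtered_set(pairs, self.labels)
        assert kept == {"h1": {"p1"}, "m1": {"p3"}}

    def test_unlabeled_species_rejected(self):
        with pytest.raises(ValueError, match="x1"):
            orthology.lifestyle_filtered_set([self.pair("x1", "p", "m1", "q")], self.labels)

    def test_rerun_on_own_output_is_noop(self):
        pairs = [
            self.pair("h1", "p1", "m1", "p3"),
            self.pair("h1", "p2", "h2", "p9"),
        ]
        kept = orthology.lifestyle_filtered_set(pairs, self.labels)
        surviving = [
            p
            for p in pairs
            if p.protein_a in kept.get(p.species_a, set())
            and p.protein_b in kept.get(p.species_b, set())
        ]
        assert orthology.lifestyle_filtered_set(surviving, self.labels) == kept


class TestCoOrthologGroups:
    def pair(self, ref_prot, sp, prot):
        return orthology.OrthologPair("ref", ref_prot, sp, prot, 40.0)

    def test_complete_panel_forms_group(self):
        pairs = [self.pair("r1", f"s{i}", f"p{i}") for i in range(10)]
        (grp,) = orthology.co_ortholog_groups(pairs, "ref")
        assert grp.reference_id == "r1" and len(grp.members) == 10

    def test_incomplete_panel_forms_no_group(self):
        pairs = [self.pair("r1", f"s{i}", f"p{i}") for i in range(9)]
        panel = ["ref"] + [f"s{i}" for i in range(10)]
        assert orthology.co_ortholog_groups(pairs, "ref", species_panel=panel) == []

    def test_empty_input_gives_empty_result(self):
        assert orthology.co_ortholog_groups([], "ref") == []

    def test_pair_not_involving_reference_rejected(self):
        alien = orthology.OrthologPair("s1", "p", "s2", "q", 10.0)
        with pytest.raises(ValueError):
            orthology.co_ortholog_groups([alien], "ref")


def brute_force_global_score(a, b, matrix, gap_open=11, gap_extend=1):
    """Enumerate all global alignments (recursive NW without memo) and
    return the optimal score under BLAST-style affine gaps."""
    best = -float("inf")

    def rec(i, j, score, in_gap_a, in_gap_b):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], False, False)
        if i < len(a):
            cost = gap_extend if in_gap_a else gap_open + gap_extend
            rec(i + 1, j, score - cost, True, False)
        if j < len(b):
            cost = gap_extend if in_gap_b else gap_open + gap_extend
            rec(i, j + 1, score - cost, False, True)

    rec(0, 0, 0.0, False, False)
    return best


class TestAlignPair:
    def test_identical_sequences_align_without_gaps(self):
        aln = orthology.align_pair("ERK", "ERK")
        assert aln.query == aln.subject == "ERK"

    def test_deletion_gives_one_gap_column(self):
        aln = orthology.align_pair("ERK", "EK")
        assert aln.query == "ERK" and aln.subject.count("-") == 1

    def test_single_substitution_column(self):
        aln = orthology.align_pair("A", "D")
        assert (aln.query, aln.subject) == ("A", "D")

    @pytest.mark.parametrize("a,b", [("ERK", "EK"), ("ACDE", "ADE"), ("WAK", "WK")])
    def test_score_matches_brute_force_enumeration(self, a, b):
        blosum = substitution_matrices.load("BLOSUM62")
        expected = brute_force_global_score(a, b, blosum)
        aln = orthology.align_pair(a, b)
        score = 0.0
        in_gap = None
        for qa, sa in zip(aln.query, aln.subject):
            if "-" not in (qa, sa):
                score += blosum[qa, sa]
                in_gap = None
            else:
                side = "q" if qa == "-" else "s"
                score -= 1 if in_gap == side else 12
                in_gap = side
        assert score == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            orthology.align_pair("", "ERK")
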