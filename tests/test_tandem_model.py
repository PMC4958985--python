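import random

import numpy as np
import pytest

from covpat.pair_model import (
    CovariantPair,
    Element,
    ElementIndex,
    build_element_index,
    confirmed_pairs,
    detect_pairs,
)
from covpat.tandem_model import (
    CovariantPattern,
    PurityMatrix,
    association_degrees,
    build_groups,
    format_pattern,
    harvest_patterns,
    parse_pattern,
    prune_group,
    purity_matrix,
    remove_subset_patterns,
)
from conftest import make_alignment
from oracle import brute_force_patterns, random_alignment


def pair(sa, ra, sb, rb, p=0.9):
    return CovariantPair(Element(sa, ra), Element(sb, rb), p, 5, 5, 4)


def matrix(elements, values):
    return PurityMatrix(tuple(elements), np.array(values, dtype=float))


class TestGroups:
    def test_shared_element_joins_pairs(self):
        groups = build_groups([pair(1, "A", 6, "T"), pair(6, "T", 7, "V")])
        assert len(groups) == 1
        assert groups[0].elements == (Element(1, "A"), Element(6, "T"), Element(7, "V"))

    def test_disjoint_pairs_stay_separate(self):
        groups = build_groups([pair(1, "A", 2, "T"), pair(3, "G", 4, "C")])
        assert len(groups) == 2
        assert groups[0].group_id == 1 and groups[1].group_id == 2

    def test_empty_input(self):
        assert build_groups([]) == []

    def test_union_find_oracle_on_random_pair_sets(self):
        rng = random.Random(17)
        for _ in range(20):
            edges = set()
            while len(edges) < rng.randint(1, 10):
                a = (rng.randint(1, 6), rng.choice("AC"))
                b = (rng.randint(1, 6), rng.choice("AC"))
                if a[0] < b[0]:
                    edges.add((a, b))
            pairs = [pair(a[0], a[1], b[0], b[1]) for a, b in sorted(edges)]
            groups = build_groups(pairs)
            # naive union-find
            parent = {}

            def find(x):
                parent.setdefault(x, x)
                while parent[x] != x:
                    x = parent[x]
                return x

            for p in pairs:
                ra, rb = find(p.a), find(p.b)
                parent[ra] = rb
            expected = {}
            for p in pairs:
                for e in (p.a, p.b):
                    expected.setdefault(find(e), set()).add(e)
            assert {frozenset(g.elements) for g in groups} == {
                frozenset(s) for s in expected.values()
            }
            # every confirmed pair lands in exactly one group
            assert sum(len(g.member_pairs) for g in groups) == len(pairs)


class TestPurityMatrix:
    def test_single_pair_group(self):
        idx = ElementIndex(
            {
                Element(1, "A"): frozenset({0, 1, 2, 3, 4}),
                Element(2, "T"): frozenset({0, 1, 2, 3, 5}),
            }
        )
        m = purity_matrix([Element(1, "A"), Element(2, "T")], idx)
        assert m.values[0, 1] == pytest.approx(0.8)

    def test_same_site_elements_have_zero_purity(self):
        idx = ElementIndex(
            {
                Element(1, "A"): frozenset({0, 1}),
                Element(1, "G"): frozenset({2, 3}),
                Element(2, "T"): frozenset({0, 1}),
            }
        )
        m = purity_matrix([Element(1, "A"), Element(1, "G"), Element(2, "T")], idx)
        assert m.values[0, 1] == 0.0

    def test_symmetry_on_random_groups(self):
        rng = random.Random(8)
        seqs = random_alignment(rng, max_sites=6, max_seqs=15)
        aln = make_alignment(seqs)
        sites = list(range(1, len(seqs[0]) + 1))
        idx = build_element_index(aln, sites)
        elements = sorted(idx.occurrences)[:5]
        m = purity_matrix(elements, idx)
        assert np.array_equal(m.values, m.values.T)


class TestAssociationDegrees:
    def test_hand_computed_row_means(self):
        m = matrix(
            [Element(1, "A"), Element(2, "B"), Element(3, "C")],
            [[0, 0.9, 0.8], [0.9, 0, 0.7], [0.8, 0.7, 0]],
        )
        degrees, d_m = association_degrees(m)
        assert degrees == pytest.approx([0.85, 0.80, 0.75])
        assert d_m == pytest.approx(0.75)

    def test_constant_matrix(self):
        p = 0.6
        m = matrix(
            [Element(1, "A"), Element(2, "B"), Element(3, "C"), Element(4, "D")],
            np.full((4, 4), p) - p * np.eye(4),
        )
        degrees, d_m = association_degrees(m)
        assert degrees == pytest.approx([p] * 4)
        assert d_m == pytest.approx(p)

    def test_permutation_invariance(self):
        vals = np.array([[0, 0.9, 0.4], [0.9, 0, 0.5], [0.4, 0.5, 0]])
        els = [Element(1, "A"), Element(2, "B"), Element(3, "C")]
        degrees, _ = association_degrees(matrix(els, vals))
        perm = [2, 0, 1]
        m2 = matrix([els[i] for i in perm], vals[np.ix_(perm, perm)])
        degrees2, _ = association_degrees(m2)
        assert degrees2 == pytest.approx([degrees[i] for i in perm])

    def test_requires_two_elements(self):
        with pytest.raises(ValueError):
            association_degrees(matrix([Element(1, "A")], [[0.0]]))


class TestPruneGroup:
    def test_weak_element_removed_then_pattern_harvested(self):
        # e4 is weakly associated (degree 0.3) and goes first; the rest pass
        els = [Element(1, "A"), Element(6, "T"), Element(7, "V"), Element(9, "W")]
        vals = [
            [0, 0.8, 0.8, 0.3],
            [0.8, 0, 0.8, 0.4],
            [0.8, 0.8, 0, 0.2],
            [0.3, 0.4, 0.2, 0],
        ]
        pat = prune_group(matrix(els, vals))
        assert pat is not None
        assert format_pattern(pat) == "(1-A 6-T 7-V)"

    def test_all_strong_matrix_untouched(self):
        els = [Element(1, "A"), Element(2, "B"), Element(3, "C"), Element(4, "D")]
        vals = np.full((4, 4), 0.9) - 0.9 * np.eye(4)
        pat = prune_group(matrix(els, vals))
        assert pat is not None and pat.size == 4

    def test_uniformly_weak_matrix_yields_none(self):
        els = [Element(1, "A"), Element(2, "B"), Element(3, "C")]
        vals = np.full((3, 3), 0.5) - 0.5 * np.eye(3)
        assert prune_group(matrix(els, vals)) is None

    def test_exact_threshold_terminates(self):
        els = [Element(1, "A"), Element(2, "B"), Element(3, "C")]
        vals = np.full((3, 3), 0.7) - 0.7 * np.eye(3)
        pat = prune_group(matrix(els, vals), degree_threshold=0.7)
        assert pat is not None and pat.size == 3

    def test_tie_break_removes_largest_site_then_residue(self):
        # all degrees equal and below threshold: the largest (site, residue)
        # goes first each round until fewer than 3 remain
        els = [Element(1, "A"), Element(2, "B"), Element(3, "C"), Element(3, "D")]
        # can't have two same-site in a pattern, but pruning happens first;
        # constant 0.5 entries (same-site pair set to 0 per construction)
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0)
        vals[2, 3] = vals[3, 2] = 0.0
        m = matrix(els, vals)
        assert prune_group(m, degree_threshold=0.7) is None

    def test_same_site_survivor_resolved_by_degree(self):
        # all associations pass the threshold, but sites must be unique:
        # the lower-degree duplicate at site 3 is removed
        els = [Element(1, "A"), Element(2, "B"), Element(3, "C"), Element(3, "D")]
        vals = np.array(
            [
                [0, 0.9, 0.9, 0.8],
                [0.9, 0, 0.9, 0.8],
                [0.9, 0.9, 0, 0.0],
                [0.8, 0.8, 0.0, 0],
            ]
        )
        pat = prune_group(matrix(els, vals), degree_threshold=0.5)
        assert pat is not None
        assert format_pattern(pat) == "(1-A 2-B 3-C)"


class TestPatternOutput:
    def test_subset_removed(self):
        big = CovariantPattern((Element(1, "A"), Element(6, "T"), Element(7, "V")))
        small = parse_pattern("(1-A 6-T)")
        assert remove_subset_patterns([big, small]) == [big]

    def test_duplicates_collapse(self):
        a = parse_pattern("(1-A 6-T 7-V)")
        b = parse_pattern("(1-A 6-T 7-V)")
        assert remove_subset_patterns([a, b]) == [a]

    def test_overlapping_non_subsets_both_kept(self):
        a = parse_pattern("(1-A 6-T 7-V)")
        b = parse_pattern("(1-A 6-T 8-K)")
        kept = remove_subset_patterns([a, b])
        assert {format_pattern(p) for p in kept} == {
            "(1-A 6-T 7-V)",
            "(1-A 6-T 8-K)",
        }

    def test_pairwise_subset_oracle(self):
        rng = random.Random(23)
        for _ in range(25):
            pats = []
            for _ in range(rng.randint(1, 6)):
                k = rng.randint(3, 5)
                sites = rng.sample(range(1, 10), k)
                pats.append(
                    CovariantPattern(tuple(Element(s, "A") for s in sorted(sites)))
                )
            kept = remove_subset_patterns(pats)
            sets = {p.element_set for p in pats}
            expected = {s for s in sets if not any(s < t for t in sets)}
            assert {p.element_set for p in kept} == expected

    def test_format_examples(self):
        p = CovariantPattern((Element(7, "V"), Element(1, "A"), Element(6, "T")))
        assert format_pattern(p) == "(1-A 6-T 7-V)"
        q = parse_pattern("(13-R 16-T 127-R 222-A 238-H)")
        assert format_pattern(q) == "(13-R 16-T 127-R 222-A 238-H)"

    def test_pattern_rejects_duplicate_site(self):
        with pytest.raises(ValueError):
            CovariantPattern((Element(1, "A"), Element(1, "G"), Element(2, "T")))


class TestHarvest:
    @staticmethod
    def run_package(seqs, min_count=1):
        aln = make_alignment(seqs)
        sites = list(range(1, len(seqs[0]) + 1))
        idx = build_element_index(aln, sites)
        pairs = confirmed_pairs(detect_pairs(aln, sites, min_count=min_count, index=idx))
        return harvest_patterns(pairs, idx)

    def test_matches_brute_force_on_random_alignments(self):
        rng = random.Random(31)
        for _ in range(40):
            seqs = random_alignment(rng, max_sites=8, max_seqs=25)
            got = {
                frozenset((e.site, e.residue) for e in p.elements)
                for p in self.run_package(seqs)
            }
            expected = brute_force_patterns(seqs, list(range(1, len(seqs[0]) + 1)))
            assert got == expected

    def test_reported_patterns_pass_posthoc_degree_check(self):
        rng = random.Random(37)
        checked = 0
        for _ in range(60):
            seqs = random_alignment(rng, max_sites=8, max_seqs=25)
            aln = make_alignment(seqs)
            sites = list(range(1, len(seqs[0]) + 1))
            idx = build_element_index(aln, sites)
            for pat in self.run_package(seqs):
                m = purity_matrix(pat.elements, idx)
                degrees, d_m = association_degrees(m)
                assert d_m >= 0.7
                # stored terminal degrees equal an independent recomputation
                assert pat.degrees == pytest.approx(tuple(degrees))
                checked += 1
        assert checked > 0  # the sweep actually exercised patterns

    def test_output_subset_free_and_site_unique(self):
        rng = random.Random(41)
        for _ in range(30):
            seqs = random_alignment(rng, max_sites=8, max_seqs=25)
            pats = self.run_package(seqs)
            sets = [p.element_set for p in pats]
            for i, s in enumerate(sets):
                sites = [e.site for e in pats[i].elements]
                assert len(set(sites)) == len(sites)
                assert not any(s <= t for j, t in enumerate(sets) if i != j)
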