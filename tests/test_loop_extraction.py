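"""Loop extraction: nested pairs, flankSS, loop finding, ids, QA."""

import itertools

import numpy as np
import pytest

from motif_atlas.loop_extraction import (IdSpaceExhaustedError, QAReport,
                                         RepresentativeConfigError,
                                         assign_loop_ids,
                                         default_representative_chains,
                                         extract_loops, flank_ss,
                                         nested_canonical_pairs, qa_filter,
                                         select_representative_chains)
from conftest import toy_structure


def _nt(structure, chain, number):
    for res in structure.chain(chain).residues:
        if res.ref.number == number:
            return res.ref
    raise KeyError((chain, number))


def _loop_shapes(loops):
    """(type, strand lengths, nucleotide numbers) for comparison."""
    return sorted((l.loop_type, tuple(len(s) for s in l.strands),
                   tuple(nt.number for s in l.strands for nt in s))
                  for l in loops)


class TestNestedPairs:
    def test_already_nested_all_retained(self):
        structure, ann = toy_structure("(((....)))")
        nested = nested_canonical_pairs(structure, ann)
        assert len(nested.pairs()) == 3
        assert not nested.pseudoknots

    def test_crossing_pair_removed_max_retained(self):
        # pairs (1,10) and (5,15) cross; the 5'-most pair wins the tie
        spec = "(...[....)....]"
        structure, ann = toy_structure(spec)
        nested = nested_canonical_pairs(structure, ann)
        kept = {(p.nt1.number, p.nt2.number) for p in nested.pairs()}
        assert kept == {(1, 10)}
        assert [(p.nt1.number, p.nt2.number)
                for p in nested.pseudoknots] == [(5, 15)]

    def test_max_cardinality_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = 14
            # random pairing of positions
            pos = list(rng.permutation(n))
            pairs = [(min(a, b), max(a, b))
                     for a, b in zip(pos[0::2], pos[1::2])][:4]
            spec = ["."] * n
            brackets = "([{"
            for k, (i, j) in enumerate(pairs):
                spec[i] = brackets[k % 3]
                spec[j] = {"(": ")", "[": "]", "{": "}"}[brackets[k % 3]]
            try:
                structure, ann = toy_structure("".join(spec))
            except ValueError:
                continue  # interleaved same-type brackets: skip layout
            nested = nested_canonical_pairs(structure, ann)

            def crossing(a, b):
                (i, j), (k, l) = sorted([a, b])
                return i < k < j < l

            best = 0
            cand = [(p.nt1.number, p.nt2.number) for p in
                    ann.canonical_pairs()]
            for r in range(len(cand), 0, -1):
                for sub in itertools.combinations(cand, r):
                    if not any(crossing(a, b) for a, b in
                               itertools.combinations(sub, 2)):
                        best = r
                        break
                if best:
                    break
            assert len(nested.pairs()) == best

    def test_conflicting_canonical_pairs_rejected(self):
        structure, ann = toy_structure("(....)....")
        # add a second canonical pair on nucleotide 1
        from motif_atlas.structure_io import PairAnnotation
        ann.add_pair(PairAnnotation(_nt(structure, "A", 1),
                                    _nt(structure, "A", 9), "cWW",
                                    canonical=True))
        nested = nested_canonical_pairs(structure, ann)
        assert not nested.pairs()
        assert len(nested.conflicts) == 2


class TestFlankSS:
    def test_matches_brute_force_definition(self):
        specs = ["((((....))))", "((..((..))..))", "(.(.).(.).)",
                 "(((...)))(((...)))"]
        for spec in specs:
            structure, ann = toy_structure(spec)
            nested = nested_canonical_pairs(structure, ann)
            chain = [r.ref for r in structure.chain("A").residues]
            paired = {nt.key() for nt in chain if nested.is_paired(nt)}
            for a, b in itertools.combinations(chain, 2):
                expected = (a.key() in paired and b.key() in paired
                            and not any(chain[p].key() in paired
                                        for p in range(chain.index(a) + 1,
                                                       chain.index(b))))
                assert flank_ss(a, b, nested) is expected
                assert flank_ss(b, a, nested) is expected

    def test_adjacent_paired_nucleotides(self):
        structure, ann = toy_structure("((....))")
        nested = nested_canonical_pairs(structure, ann)
        assert flank_ss(_nt(structure, "A", 1), _nt(structure, "A", 2),
                        nested)

    def test_unpaired_and_blocked_cases(self):
        # 5 paired, 6-9 unpaired, 10 paired
        structure, ann = toy_structure("((((((....))))))"[3:-3])
        structure, ann = toy_structure("(((((....)))))")
        nested = nested_canonical_pairs(structure, ann)
        assert flank_ss(_nt(structure, "A", 5), _nt(structure, "A", 10),
                        nested)
        assert not flank_ss(_nt(structure, "A", 5), _nt(structure, "A", 9),
                            nested)
        # an intervening nested-paired nucleotide blocks the relation
        assert not flank_ss(_nt(structure, "A", 4), _nt(structure, "A", 10),
                            nested)

    def test_different_chains_false(self):
        structure, ann = toy_structure("(((", ")))")
        nested = nested_canonical_pairs(structure, ann)
        assert not flank_ss(_nt(structure, "A", 1), _nt(structure, "B", 3),
                            nested)


class TestExtractLoops:
    @pytest.mark.parametrize("spec,expected", [
        # toy hairpin: 1 HL with closing pair + 4 loop nt
        ("((((....))))", [("HL", (6,))]),
        # bulge: 2 unpaired on one strand, 0 on the other
        ("((..((....))))", [("HL", (6,)), ("IL", (4, 2))]),
        # symmetric internal loop
        ("((..((....))..))", [("HL", (6,)), ("IL", (4, 4))]),
        # three-way junction with single-stranded linkers
        ("((.((...)).((...)).))",
         [("HL", (5,)), ("HL", (5,)), ("J3", (3, 3, 3))]),
        # two separate hairpins: no IL between them (exterior, not closed)
        ("(((...)))..(((...)))", [("HL", (5,)), ("HL", (5,))]),
        # pseudoknotted hairpin bases: hairpin still detected
        ("((((..[[..))))..]]", [("HL", (8,))]),
        # minimal hairpin under a bulge on the 3' strand
        ("((((...))..))", [("HL", (5,)), ("IL", (2, 4))]),
    ])
    def test_hand_enumerated_fixtures(self, spec, expected):
        structure, ann = toy_structure(spec)
        loops, _ = extract_loops(structure, ann)
        got = [(t, lens) for t, lens, _ in _loop_shapes(loops)]
        assert sorted(got) == sorted(expected)

    def test_hairpin_membership(self):
        structure, ann = toy_structure("((((....))))")
        (loop,), _ = extract_loops(structure, ann)
        assert [nt.number for nt in loop.strands[0]] == [4, 5, 6, 7, 8, 9]
        assert loop.closing_pairs[0].canonical

    def test_zero_interior_il_reported_not_returned(self):
        structure, ann = toy_structure("((((....))))")
        _, report = extract_loops(structure, ann)
        assert len(report.zero_interior_ils) == 3  # the helix steps

    def test_multi_chain_internal_loop(self):
        # two chains: helix A-B interrupted by unpaired residues on each
        structure, ann = toy_structure("((..((", "))..))")
        loops, _ = extract_loops(structure, ann)
        (il,) = [l for l in loops if l.loop_type == "IL"]
        assert set(il.chains()) == {"A", "B"}
        assert tuple(len(s) for s in il.strands) == (4, 4)

    def test_il_strand_order_5prime_first(self):
        structure, ann = toy_structure("((..((....))..))")
        loops, _ = extract_loops(structure, ann)
        (il,) = [l for l in loops if l.loop_type == "IL"]
        assert il.strands[0][0].number < il.strands[1][0].number
        # closing pair partners are the strand span ends
        first, last = il.strands[0][0], il.strands[1][-1]
        closing_keys = il.closing_nucleotides()
        assert first.key() in closing_keys and last.key() in closing_keys

    def test_partition_property(self):
        """Every nucleotide is in a helix, exactly one loop interior, or a
        closing position, on a pseudoknot-free structure."""
        spec = "((.((...)).((..((....))..)).))"
        structure, ann = toy_structure(spec)
        nested = nested_canonical_pairs(structure, ann)
        loops, _ = extract_loops(structure, ann)
        interior_count = {}
        closing = set()
        for loop in loops:
            for nt in loop.interior_nucleotides():
                interior_count[nt.key()] = interior_count.get(nt.key(),
                                                              0) + 1
            closing |= loop.closing_nucleotides()
        for res in structure.chain("A").residues:
            key = res.ref.key()
            if nested.is_paired(res.ref):
                assert key not in interior_count
            else:
                assert interior_count.get(key) == 1, key
                assert key not in closing

    def test_chain_permutation_invariance(self):
        s1, a1 = toy_structure("((..((", "))..))")
        # same construct with the chains swapped in file order
        s2 = type(s1)(s1.structure_id, list(reversed(s1.chains)))
        l1, _ = extract_loops(s1, a1)
        l2, _ = extract_loops(s2, a1)
        assert _loop_shapes(l1) == _loop_shapes(l2)


class TestLoopIds:
    def test_id_format_and_ordering(self):
        structure, ann = toy_structure("((..((....))))..((....))",
                                       structure_id="1S72")
        loops, _ = extract_loops(structure, ann)
        loops = assign_loop_ids(loops, "1S72")
        ids = sorted(l.loop_id for l in loops)
        assert ids == ["HL_1S72_001", "HL_1S72_002", "IL_1S72_001"]

    def test_idempotent_across_reruns(self):
        structure, ann = toy_structure("((..((....))))")
        a = assign_loop_ids(extract_loops(structure, ann)[0], "TOYS")
        b = assign_loop_ids(extract_loops(structure, ann)[0], "TOYS")
        assert sorted(l.loop_id for l in a) == sorted(l.loop_id for l in b)

    def test_zero_loops(self):
        assert assign_loop_ids([], "TOYS") == []

    def test_id_space_exhaustion(self):
        structure, ann = toy_structure("((((....))))")
        loops, _ = extract_loops(structure, ann)
        with pytest.raises(IdSpaceExhaustedError):
            from motif_atlas.loop_extraction import format_loop_id
            format_loop_id("HL", "TOYS", 1000)


class TestQA:
    def _loops(self, spec="((((....))))"):
        structure, ann = toy_structure(spec)
        loops, _ = extract_loops(structure, ann)
        return structure, assign_loop_ids(loops, "TOYS")

    def test_fully_resolved_loop_passes(self):
        structure, loops = self._loops()
        passing, reports = qa_filter(loops, structure)
        assert len(passing) == 1
        assert reports[0].verdict == "pass" and not reports[0].reasons

    def test_missing_coordinates_fail(self):
        structure, loops = self._loops()
        del structure.chain("A").residues[5].atoms["N1"]
        passing, reports = qa_filter(loops, structure)
        assert not passing
        assert ("missing_coordinates", 6) in [
            (code, nt.number) for code, nt in reports[0].reasons]

    def test_modified_nucleotide_fail(self):
        structure, loops = self._loops()
        structure.chain("A").residues[5].name = "PSU"
        passing, reports = qa_filter(loops, structure)
        assert not passing
        codes = {code for code, _ in reports[0].reasons}
        assert codes == {"modified_nucleotide"}

    def test_failing_report_requires_reasons(self):
        with pytest.raises(ValueError):
            QAReport("HL_TOYS_001", "fail", [])


class TestRepresentativeChains:
    def test_eight_identical_chains_keep_one(self):
        specs = ["((..((....))..))"] * 8
        structure, ann = toy_structure(*specs, structure_id="1KOG")
        loops, _ = extract_loops(structure, ann)
        loops = assign_loop_ids(loops, "1KOG")
        kept = select_representative_chains(loops, structure)
        types = sorted(l.loop_type for l in kept)
        assert types == ["HL", "IL"]
        assert all(l.chains() == ["A"] for l in kept)

    def test_different_sequences_both_kept(self):
        structure, ann = toy_structure("((((....))))", "((....))")
        loops, _ = extract_loops(structure, ann)
        kept = select_representative_chains(loops, structure)
        assert len(kept) == len(loops) == 2

    def test_cross_chain_loop_dropped_if_unrepresentative(self):
        structure, ann = toy_structure("((..((", "))..))")
        loops, _ = extract_loops(structure, ann)
        kept = select_representative_chains(
            loops, structure, {"TOYS": ["A"]})
        assert kept == []

    def test_unknown_representative_chain_rejected(self):
        structure, ann = toy_structure("((((....))))")
        loops, _ = extract_loops(structure, ann)
        with pytest.raises(RepresentativeConfigError):
            select_representative_chains(loops, structure, {"TOYS": ["Z"]})

    def test_default_representatives(self):
        structure, _ = toy_structure("((..))", "((..))", "(((())))")
        assert default_representative_chains(structure) == ["A", "C"]
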