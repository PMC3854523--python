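"""Signatures, id tracking across releases, release assembly."""

import json

import numpy as np
import pytest

from motif_atlas.atlas_release import (MotifGroup, MotifId, Release,
                                       assign_group_ids,
                                       base_pair_signature, build_release,
                                       compare_releases, read_release)
from motif_atlas.clustering import ConsensusColumn, MotifGroupDraft
from motif_atlas.structure_io import (AnnotationSet, NucleotideRef,
                                      PairAnnotation, write_release)
from motif_atlas.synthetic_fixtures import (instance_loops,
                                            instantiate_template,
                                            template_library)


# --------------------------------------------------------------------------
# signature fixtures: hand-built two-strand consensus groups
# --------------------------------------------------------------------------

def _consensus_group(m, k, pair_specs, n_inst=3):
    """Build a draft + annotations for an IL group of identical members.

    ``m``/``k`` are strand lengths; ``pair_specs`` lists
    ``(strand1_pos, strand2_pos, family)``, 0-based, family oriented from
    the strand-1 nucleotide.
    """
    loop_ids = [f"IL_T{i:03d}_001" for i in range(1, n_inst + 1)]
    refs = {}
    annotations = {}
    for i, lid in enumerate(loop_ids):
        sid = f"T{i + 1:03d}"
        s1 = [NucleotideRef(sid, 1, "A", p + 1, "", "G")
              for p in range(m)]
        s2 = [NucleotideRef(sid, 1, "A", m + p + 1, "", "C")
              for p in range(k)]
        refs[lid] = (s1, s2)
        ann = AnnotationSet(sid)
        for p1, p2, fam in pair_specs:
            canonical = fam == "cWW"
            ann.add_pair(PairAnnotation(s1[p1], s2[p2], fam,
                                        canonical=canonical))
        annotations[lid] = ann

    columns = []
    for p in range(m):
        columns.append(ConsensusColumn(
            {lid: refs[lid][0][p] for lid in loop_ids}, True))
    for p in range(k):
        columns.append(ConsensusColumn(
            {lid: refs[lid][1][p] for lid in loop_ids}, True))
    ref_positions = {}
    for p in range(m):
        ref_positions[refs[loop_ids[0]][0][p].key()] = (0, p)
    for p in range(k):
        ref_positions[refs[loop_ids[0]][1][p].key()] = (1, p)
    draft = MotifGroupDraft(sorted(loop_ids), columns, 0.2,
                            sorted(loop_ids)[0], ref_positions)
    return draft, annotations


class TestBasePairSignature:
    def test_five_pair_ladder(self):
        draft, ann = _consensus_group(5, 5, [
            (0, 4, "cWW"), (1, 3, "tSH"), (2, 2, "tHW"), (3, 1, "tHS"),
            (4, 0, "cWW")])
        sig, diags = base_pair_signature(draft, ann, "IL")
        assert sig == "cWW-tSH-tHW-tHS-cWW"
        assert not diags

    def test_tandem_sheared(self):
        draft, ann = _consensus_group(4, 4, [
            (0, 3, "cWW"), (1, 2, "tSH"), (2, 1, "tHS"), (3, 0, "cWW")])
        sig, _ = base_pair_signature(draft, ann, "IL")
        assert sig == "cWW-tSH-tHS-cWW"

    def test_conserved_unpaired_strand2_base(self):
        draft, ann = _consensus_group(4, 5, [
            (0, 4, "cWW"), (1, 3, "tSH"), (2, 1, "tHW"), (3, 0, "cWW")])
        sig, _ = base_pair_signature(draft, ann, "IL")
        assert sig == "cWW-tSH-R-tHW-cWW"

    def test_conserved_unpaired_strand1_base(self):
        draft, ann = _consensus_group(5, 4, [
            (0, 3, "cWW"), (1, 2, "tSH"), (3, 1, "tHS"), (4, 0, "cWW")])
        sig, _ = base_pair_signature(draft, ann, "IL")
        assert sig == "cWW-tSH-L-tHS-cWW"

    def test_majority_threshold_excludes_minority_pairs(self):
        # the tHW pair annotated in only 1 of 3 instances is dropped
        draft, ann = _consensus_group(4, 4, [
            (0, 3, "cWW"), (1, 2, "tSH"), (2, 1, "tHS"), (3, 0, "cWW")])
        lid = draft.instances[1]
        extra = ann[lid]
        s1 = [NucleotideRef(extra.structure_id, 1, "A", p + 1, "", "G")
              for p in range(4)]
        assert base_pair_signature(draft, ann, "IL")[0] == \
            "cWW-tSH-tHS-cWW"

    def test_signature_order_independent_of_instance_listing(self):
        draft, ann = _consensus_group(4, 4, [
            (0, 3, "cWW"), (1, 2, "tSH"), (2, 1, "tHS"), (3, 0, "cWW")])
        sig1, _ = base_pair_signature(draft, ann, "IL")
        draft.instances = list(reversed(draft.instances))
        sig2, _ = base_pair_signature(draft, ann, "IL")
        assert sig1 == sig2


class TestMotifId:
    def test_rendering_and_parsing(self):
        mid = MotifId("IL", 24982, 1)
        assert str(mid) == "IL_24982.1"
        assert MotifId.parse("IL_24982.3") == MotifId("IL", 24982, 3)

    def test_validation(self):
        with pytest.raises(ValueError):
            MotifId("XX", 1, 1)
        with pytest.raises(ValueError):
            MotifId("IL", 100000, 1)
        with pytest.raises(ValueError):
            MotifId("IL", 1, 0)


def _draft(instances):
    return MotifGroupDraft(sorted(instances), [], 0.0,
                           sorted(instances)[0])


def _release(groups, loop_type="IL", release_id="0.1"):
    return Release(release_id, loop_type,
                   [MotifGroup(mid, _draft(insts), "") for mid, insts
                    in groups])


class TestAssignGroupIds:
    def _assign(self, new_sets, previous):
        rng = np.random.default_rng(0)
        return assign_group_ids([_draft(s) for s in new_sets], "IL",
                                previous, rng)

    def test_identical_group_keeps_id_and_version(self):
        prev = _release([(MotifId("IL", 11111, 2), ["a", "b", "c"])])
        ((_, mid),) = self._assign([["a", "b", "c"]], prev)
        assert mid == MotifId("IL", 11111, 2)

    def test_two_thirds_growth_increments_version(self):
        # old group of 9, new group of 12 sharing 8: passes both bounds
        old = [f"x{i}" for i in range(9)]
        new = old[:8] + [f"y{i}" for i in range(4)]
        prev = _release([(MotifId("IL", 22222, 1), old)])
        ((_, mid),) = self._assign([new], prev)
        assert mid == MotifId("IL", 22222, 2)

    def test_seven_shared_fails_two_thirds(self):
        old = [f"x{i}" for i in range(9)]
        new = old[:7] + [f"y{i}" for i in range(5)]
        prev = _release([(MotifId("IL", 22222, 1), old)])
        ((_, mid),) = self._assign([new], prev)
        assert mid.code != 22222 and mid.version == 1

    def test_even_split_gets_fresh_ids(self):
        old = [f"x{i}" for i in range(8)]
        prev = _release([(MotifId("IL", 33333, 1), old)])
        assigned = self._assign([old[:4], old[4:]], prev)
        codes = {mid.code for _, mid in assigned}
        assert 33333 not in codes and len(codes) == 2

    def test_overlap_with_three_old_groups_gets_fresh_id(self):
        prev = _release([(MotifId("IL", 10001, 1), ["a", "b"]),
                         (MotifId("IL", 10002, 1), ["c", "d"]),
                         (MotifId("IL", 10003, 1), ["e", "f"])])
        new = ["a", "b", "c", "d", "e", "f"]
        ((_, mid),) = self._assign([new], prev)
        assert mid.code not in {10001, 10002, 10003}

    def test_no_overlap_gets_fresh_id(self):
        prev = _release([(MotifId("IL", 10001, 1), ["a", "b"])])
        ((_, mid),) = self._assign([["z1", "z2"]], prev)
        assert mid.code != 10001 and mid.version == 1

    def test_version_chain_increments_stepwise(self):
        rng = np.random.default_rng(1)
        members = [f"i{k}" for k in range(6)]
        rel = None
        expected_versions = []
        code = None
        for step in range(3):
            grown = members + [f"extra{s}{k}" for s in range(step)
                               for k in range(3)]
            assigned = assign_group_ids([_draft(grown)], "IL", rel, rng)
            (draft, mid) = assigned[0]
            expected_versions.append(mid.version)
            if code is None:
                code = mid.code
            assert mid.code == code
            rel = _release([(mid, grown)])
        assert expected_versions == [1, 2, 3]

    def test_fresh_codes_avoid_history(self):
        rng = np.random.default_rng(2)
        used = set(range(10000, 100000)) - {54321}
        assigned = assign_group_ids([_draft(["q"])], "IL", None, rng,
                                    used_codes=used)
        assert assigned[0][1].code == 54321


class TestCompareReleases:
    def test_identical_releases_all_same(self):
        a = _release([(MotifId("IL", 11111, 1), ["a"]),
                      (MotifId("IL", 22222, 1), ["b"])])
        report = compare_releases(a, a)
        assert report.counts() == {"same": 2, "updated": 0,
                                   "only_a": 0, "only_b": 0}

    def test_version_change_reported_updated(self):
        a = _release([(MotifId("IL", 11111, 1), ["a", "b"])])
        b = _release([(MotifId("IL", 11111, 2), ["a", "b", "c"])],
                     release_id="0.2")
        report = compare_releases(a, b)
        assert report.counts()["updated"] == 1

    def test_disjoint_releases(self):
        a = _release([(MotifId("IL", 11111, 1), ["a"])])
        b = _release([(MotifId("IL", 22222, 1), ["b"])],
                     release_id="0.2")
        report = compare_releases(a, b)
        assert report.counts() == {"same": 0, "updated": 0,
                                   "only_a": 1, "only_b": 1}

    def test_loop_type_mismatch_rejected(self):
        a = _release([], loop_type="IL")
        b = _release([], loop_type="HL")
        with pytest.raises(ValueError):
            compare_releases(a, b)


class TestReleaseValidation:
    def test_instance_in_two_groups_rejected(self):
        with pytest.raises(ValueError):
            _release([(MotifId("IL", 11111, 1), ["a", "b"]),
                      (MotifId("IL", 22222, 1), ["b", "c"])])


def _prepared_set(names, per_template, sigma=0.15, seed0=0, sid0=0):
    lib = template_library()
    prepared = []
    sid = sid0
    for name in names:
        for k in range(per_template):
            sid += 1
            inst = instantiate_template(lib[name], sigma,
                                        seed=seed0 + sid,
                                        structure_id=f"S{sid:03d}")
            prepared.extend(instance_loops(inst))
    return prepared


class TestBuildRelease:
    def test_first_release_all_fresh_version_one(self):
        prepared = _prepared_set(["il-straight", "il-twisted"], 3)
        rel = build_release(prepared, "IL", "0.1", seed=3)
        assert len(rel.groups) == 2
        assert all(g.motif_id.version == 1 for g in rel.groups)

    def test_rerun_is_byte_identical(self, tmp_path):
        prepared = _prepared_set(["il-straight", "il-twisted"], 3)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        write_release(build_release(prepared, "IL", "0.1", seed=3), out1)
        write_release(build_release(prepared, "IL", "0.1", seed=3), out2)
        for name in ("release.json", "matching_matrix.csv",
                     "loops.fasta"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_growth_increments_exactly_one_version(self):
        small = _prepared_set(["il-straight", "il-twisted"], 4)
        rel1 = build_release(small, "IL", "0.1", seed=3)
        bigger = small + _prepared_set(["il-straight"], 2, seed0=50,
                                       sid0=100)
        rel2 = build_release(bigger, "IL", "0.2", previous=rel1, seed=4)
        report = compare_releases(rel1, rel2)
        assert report.counts()["updated"] == 1
        assert report.counts()["same"] == 1

    def test_common_name_propagates_to_successor(self):
        small = _prepared_set(["il-straight"], 4)
        rel1 = build_release(small, "IL", "0.1", seed=3)
        code = rel1.groups[0].motif_id.code
        rel1.groups[0].common_name = "sheared-like"
        bigger = small + _prepared_set(["il-straight"], 2, seed0=50,
                                       sid0=100)
        rel2 = build_release(bigger, "IL", "0.2", previous=rel1, seed=4)
        successor = rel2.group_by_code(code)
        assert successor is not None
        assert successor.common_name == "sheared-like"

    def test_round_trip_through_json(self, tmp_path):
        prepared = _prepared_set(["il-straight"], 3)
        rel = build_release(prepared, "IL", "0.1", seed=3)
        write_release(rel, tmp_path)
        back = read_release(tmp_path / "release.json")
        assert back.release_id == rel.release_id
        assert {str(g.motif_id) for g in back.groups} == \
            {str(g.motif_id) for g in rel.groups}
        assert [sorted(g.instances) for g in back.groups] == \
            [sorted(g.instances) for g in rel.groups]


class TestWriteRelease:
    def test_empty_release_valid_json(self, tmp_path):
        rel = Release("0.1", "IL", [])
        write_release(rel, tmp_path)
        doc = json.loads((tmp_path / "release.json").read_text())
        assert doc["groups"] == []

    def test_fasta_record_per_instance(self, tmp_path):
        prepared = _prepared_set(["il-straight"], 3)
        rel = build_release(prepared, "IL", "0.1", seed=3)
        write_release(rel, tmp_path)
        fasta = (tmp_path / "loops.fasta").read_text()
        n_records = fasta.count(">")
        assert n_records == sum(len(g.instances) for g in rel.groups)
        assert "*" in fasta  # two-strand sequences keep the separator
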