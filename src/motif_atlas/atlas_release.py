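"""Versioned motif-group ids, base-pair signatures, and atlas releases.

Motif groups get ids of the form ``IL_24982.1``: a loop-type prefix, a
five-digit randomly assigned code unique across all history, and a
version.  Between releases a group keeps its id unchanged when its
instance set is identical; it keeps the code with an incremented version
when it shares at least two-thirds of the instances of both the old and
the new group with a predecessor among at most two overlapping old
groups; in every other case (overlap with more than two old groups, or
insufficient overlap) a fresh code is drawn.  At most one old group can
satisfy the two-thirds rule for a given new group, because two
two-thirds majorities cannot coexist.

Groups without common names are designated by their base-pair signature:
the consensus base pairs (those annotated in more than half of the
instances) listed in strand order, e.g. ``cWW-tSH-tHS-cWW``, with ``L`` /
``R`` marking conserved unpaired bases on strand 1 / strand 2 at the
position where they are passed as the pairs are read off.  Hairpin and
internal loop releases are versioned independently.
"""

from __future__ import annotations

import hashlib
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .clustering import (MatchingMatrix, MotifGroupDraft,
                         build_matching_matrix, consensus_alignment,
                         iterative_cliques)
from .compatibility import assess_records
from .geometric_alignment import PreparedLoop, SearchConfig, all_against_all

MOTIF_PREFIXES = ("HL", "IL", "J3", "J4", "J5")


@dataclass(frozen=True)
class MotifId:
    prefix: str
    code: int
    version: int

    def __post_init__(self) -> None:
        if self.prefix not in MOTIF_PREFIXES:
            raise ValueError(f"bad motif prefix {self.prefix!r}")
        if not 0 <= self.code <= 99999:
            raise ValueError("code must be a five-digit integer")
        if self.version < 1:
            raise ValueError("version must be >= 1")

    def __str__(self) -> str:
        return f"{self.prefix}_{self.code:05d}.{self.version}"

    @classmethod
    def parse(cls, text: str) -> "MotifId":
        prefix, rest = text.split("_")
        code, version = rest.split(".")
        return cls(prefix, int(code), int(version))


@dataclass
class MotifGroup:
    motif_id: MotifId
    draft: MotifGroupDraft
    signature: str
    common_name: Optional[str] = None

    @property
    def instances(self) -> list:
        return self.draft.instances

    def to_json_dict(self) -> dict:
        return {
            "motif_id": str(self.motif_id),
            "instances": list(self.instances),
            "consensus": [c.to_json_dict() for c in self.draft.columns],
            "signature": self.signature,
            "mean_discrepancy": round(self.draft.mean_discrepancy, 6),
            "common_name": self.common_name,
        }


# --------------------------------------------------------------------------
# Base-pair signatures
# --------------------------------------------------------------------------

class SignatureError(ValueError):
    pass


def _consensus_pairs(draft: MotifGroupDraft, annotations_by_loop: Mapping
                     ) -> list:
    """Pairs of core columns annotated as a true pair in >50% of instances.

    Returns ``[(col_a, col_b, family)]`` with the family oriented a -> b
    (most common across instances, ties lexicographic).
    """
    core = draft.core_columns()
    n_inst = len(draft.instances)
    out = []
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            a, b = core[i], core[j]
            fams = Counter()
            hits = 0
            for lid in draft.instances:
                ann = annotations_by_loop[lid]
                pairs = ann.true_pairs_between(a.members[lid], b.members[lid])
                if pairs:
                    hits += 1
                    for p in pairs:
                        fams[p.family] += 1
            if 2 * hits > n_inst:
                family = min(fams, key=lambda f: (-fams[f], f))
                out.append((a, b, family))
    return out


def base_pair_signature(draft: MotifGroupDraft, annotations_by_loop: Mapping,
                        loop_type: str) -> tuple[str, list]:
    """Signature string for a group, plus diagnostics.

    Tokens are ordered by the strand-1 core position of each pair's
    strand-1 partner; an unpaired core column contributes ``L`` (strand 1,
    at its own position) or ``R`` (strand 2, between the two pairs whose
    strand-2 partners bracket it).  The signature begins and ends with the
    closing cWW tokens.  Base triples (pairs sharing a strand-1 partner)
    are ordered by the strand-2 partner as a secondary key and flagged.
    """
    diagnostics: list = []
    core = draft.core_columns()
    if not core:
        raise SignatureError(
            f"group {draft.instances}: consensus has no core columns")
    ref = draft.reference

    def strand_pos(col) -> tuple:
        key = col.members[ref].key()
        try:
            return draft.ref_positions[key]
        except KeyError as exc:
            raise SignatureError(
                f"column nucleotide {key} missing from reference "
                f"positions") from exc

    # core-order position per strand (0-based along each strand's cores)
    by_strand: dict = {}
    for col in sorted(core, key=strand_pos):
        si, _ = strand_pos(col)
        by_strand.setdefault(si, []).append(col)
    corepos = {}
    for si, cols in by_strand.items():
        for k, col in enumerate(cols):
            corepos[id(col)] = (si, k)

    pairs = _consensus_pairs(draft, annotations_by_loop)

    tokens: list = []                  # (key tuple, text)
    paired_cols = set()
    pair_tokens = []                   # (key, s2pos or None, text)
    s1_partner_count = Counter()
    for a, b, family in pairs:
        (sa, pa), (sb, pb) = corepos[id(a)], corepos[id(b)]
        if (sa, pa) > (sb, pb):
            a, b = b, a
            family = family[0] + family[2] + family[1]
            (sa, pa), (sb, pb) = (sb, pb), (sa, pa)
        paired_cols.update((id(a), id(b)))
        # primary key: position of the 5'-most (strand-1) partner;
        # secondary: strand-2 partner position (base-triple tie-break)
        key = (sa, pa, sb, pb)
        pair_tokens.append((key, (sb, pb), family))
        s1_partner_count[(sa, pa)] += 1
    for anchor, cnt in s1_partner_count.items():
        if cnt > 1:
            diagnostics.append(f"base triple at strand-1 position {anchor}")

    pair_tokens.sort(key=lambda t: t[0])
    keyed = [((t[0][0], float(t[0][1]), t[0][3]), t[2])
             for t in pair_tokens]

    # conserved unpaired core columns
    for col in core:
        if id(col) in paired_cols:
            continue
        si, k = corepos[id(col)]
        if si == 0:
            keyed.append(((0, k + 0.0, math.inf), "L"))
        else:
            # strand 2: find adjacent pair tokens whose strand-2 partners
            # bracket position k (strand-2 positions fall as pairs are read)
            placed = False
            for idx in range(len(pair_tokens) - 1):
                (_, s2a, _), (_, s2b, _) = pair_tokens[idx], \
                    pair_tokens[idx + 1]
                hi = s2a[1] if s2a and s2a[0] == si else None
                lo = s2b[1] if s2b and s2b[0] == si else None
                if hi is not None and lo is not None and lo < k < hi:
                    ka = keyed[idx][0]
                    kb = keyed[idx + 1][0]
                    mid = (ka[1] + kb[1]) / 2.0
                    keyed.append(((ka[0], mid, 0), "R"))
                    placed = True
                    break
            if not placed:
                diagnostics.append(
                    f"unbracketed conserved strand-2 base at core "
                    f"position {k}")
                keyed.append(((1, float(k), math.inf), "R"))

    keyed.sort(key=lambda t: t[0])
    if not keyed:
        raise SignatureError(
            f"group {draft.instances}: no consensus pairs or conserved "
            f"bases to list")
    return "-".join(text for _, text in keyed), diagnostics


# --------------------------------------------------------------------------
# Release model
# --------------------------------------------------------------------------

@dataclass
class Release:
    release_id: str                    # "major.minor"
    loop_type: str                     # HL | IL
    groups: list                       # list[MotifGroup]
    parent_release: Optional[str] = None
    provenance: dict = field(default_factory=dict)
    matrix: Optional[MatchingMatrix] = None
    sequences: Optional[dict] = None

    def __post_init__(self) -> None:
        seen: set = set()
        for g in self.groups:
            for lid in g.instances:
                if lid in seen:
                    raise ValueError(
                        f"loop {lid} appears in more than one group")
                seen.add(lid)

    def group_by_code(self, code: int) -> Optional[MotifGroup]:
        for g in self.groups:
            if g.motif_id.code == code:
                return g
        return None

    def codes(self) -> set:
        return {g.motif_id.code for g in self.groups}

    def to_json_dict(self) -> dict:
        return {
            "release_id": self.release_id,
            "loop_type": self.loop_type,
            "parent_release": self.parent_release,
            "provenance": self.provenance,
            "groups": [g.to_json_dict()
                       for g in sorted(self.groups,
                                       key=lambda g: str(g.motif_id))],
        }


def read_release(path) -> Release:
    """Load a release written by :func:`motif_atlas.structure_io.write_release`.

    Consensus columns and the matching matrix are not reconstructed into
    live objects; instance sets, ids, signatures and provenance are."""
    doc = json.loads(Path(path).read_text())
    groups = []
    for g in doc["groups"]:
        draft = MotifGroupDraft(sorted(g["instances"]), [],
                                g.get("mean_discrepancy", 0.0),
                                min(g["instances"]))
        groups.append(MotifGroup(MotifId.parse(g["motif_id"]), draft,
                                 g.get("signature", ""),
                                 g.get("common_name")))
    return Release(doc["release_id"], doc["loop_type"], groups,
                   doc.get("parent_release"), doc.get("provenance", {}))


# --------------------------------------------------------------------------
# Id assignment across releases
# --------------------------------------------------------------------------

def _fresh_code(rng: np.random.Generator, used: set) -> int:
    while True:
        code = int(rng.integers(10000, 100000))
        if code not in used:
            used.add(code)
            return code


def assign_group_ids(drafts: Sequence[MotifGroupDraft], prefix: str,
                     previous: Optional[Release], rng: np.random.Generator,
                     used_codes: Optional[set] = None) -> list:
    """Apply the id-tracking rules and return ``[(draft, MotifId)]``.

    Rules, in order, for each new group G: (1) instance set identical to
    an old group -> same id, same version; (2) G overlaps exactly one or
    two old groups, and some old group O shares >= 2/3 of both |G| and
    |O| -> O's code with version + 1; (3) overlap with more than two old
    groups -> fresh code; (4) no overlap -> fresh code.  Fresh codes come
    from the seeded ``rng`` and are collision-checked against
    ``used_codes`` (all history).
    """
    used = used_codes if used_codes is not None else set()
    old = []
    if previous is not None:
        old = [(g.motif_id, frozenset(g.instances)) for g in previous.groups]
        used.update(mid.code for mid, _ in old)

    assigned = []
    for draft in sorted(drafts, key=lambda d: d.instances):
        new_set = frozenset(draft.instances)
        exact = [mid for mid, inst in old if inst == new_set]
        if exact:
            assigned.append((draft, exact[0]))
            continue
        overlapping = [(mid, inst) for mid, inst in old if inst & new_set]
        motif_id = None
        if 1 <= len(overlapping) <= 2:
            qualifying = []
            for mid, inst in overlapping:
                shared = len(inst & new_set)
                if 3 * shared >= 2 * len(new_set) and \
                        3 * shared >= 2 * len(inst):
                    qualifying.append(mid)
            assert len(qualifying) <= 1, \
                "two old groups cannot both hold a two-thirds majority"
            if qualifying:
                mid = qualifying[0]
                motif_id = MotifId(prefix, mid.code, mid.version + 1)
        if motif_id is None:
            motif_id = MotifId(prefix, _fresh_code(rng, used), 1)
        assigned.append((draft, motif_id))
    return assigned


@dataclass
class ReleaseComparison:
    same: list
    updated: list                      # (code, version_a, version_b)
    only_a: list
    only_b: list

    def counts(self) -> dict:
        return {"same": len(self.same), "updated": len(self.updated),
                "only_a": len(self.only_a), "only_b": len(self.only_b)}


def compare_releases(a: Release, b: Release) -> ReleaseComparison:
    """How many motif groups are the same, present in only one release,
    or updated (same code, different version)."""
    if a.loop_type != b.loop_type:
        raise ValueError(
            f"cannot compare {a.loop_type} with {b.loop_type} releases")
    ids_a = {g.motif_id.code: g.motif_id for g in a.groups}
    ids_b = {g.motif_id.code: g.motif_id for g in b.groups}
    same, updated = [], []
    for code in sorted(ids_a.keys() & ids_b.keys()):
        va, vb = ids_a[code].version, ids_b[code].version
        if va == vb:
            same.append(str(ids_a[code]))
        else:
            updated.append((code, va, vb))
    only_a = sorted(str(ids_a[c]) for c in ids_a.keys() - ids_b.keys())
    only_b = sorted(str(ids_b[c]) for c in ids_b.keys() - ids_a.keys())
    return ReleaseComparison(same, updated, only_a, only_b)


# --------------------------------------------------------------------------
# Release orchestration
# --------------------------------------------------------------------------

def _config_hash(config: SearchConfig) -> str:
    doc = json.dumps(vars(config), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def build_release(instances: Sequence[PreparedLoop], loop_type: str,
                  release_id: str, previous: Optional[Release] = None,
                  config: Optional[SearchConfig] = None, seed: int = 0,
                  common_names: Optional[Mapping] = None) -> Release:
    """Cluster prepared loop instances of one type into a release.

    Orchestrates the all-against-all search, incompatibility assessment,
    matching matrix, iterative maximum cliques, consensus alignments,
    signatures and id assignment.  Identical inputs (and seed) produce a
    byte-identical release; common names attached to predecessor codes
    are propagated to successor ids.
    """
    if loop_type not in ("HL", "IL"):
        raise ValueError("releases cover HL or IL loops")
    config = config or SearchConfig()
    pool = sorted((pl for pl in instances
                   if pl.loop.loop_type == loop_type),
                  key=lambda pl: pl.loop_id)
    ids = [pl.loop_id for pl in pool]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate loop ids in release input")
    by_id = {pl.loop_id: pl for pl in pool}
    annotations_by_loop = {lid: pl.annotations for lid, pl in by_id.items()}
    loops_by_id = {lid: pl.loop for lid, pl in by_id.items()}
    loop_types = {lid: loop_type for lid in ids}

    records = all_against_all(pool, config)
    assess_records(records, annotations_by_loop, loop_types)
    matrix = build_matching_matrix(records, ids) if ids else \
        MatchingMatrix([], np.zeros((0, 0)))
    cliques = iterative_cliques(matrix)

    drafts = [consensus_alignment(members, records, loops_by_id, matrix)
              for members in cliques]

    rng = np.random.default_rng(seed)
    used = set()
    if previous is not None:
        used.update(previous.provenance.get("code_history", []))
    assigned = assign_group_ids(drafts, loop_type, previous, rng, used)

    names = dict(common_names or {})
    if previous is not None:
        for g in previous.groups:
            if g.common_name:
                names.setdefault(g.motif_id.code, g.common_name)

    groups = []
    for draft, motif_id in assigned:
        signature, diags = base_pair_signature(draft, annotations_by_loop,
                                               loop_type)
        groups.append(MotifGroup(motif_id, draft, signature,
                                 names.get(motif_id.code)))

    release = Release(
        release_id, loop_type, groups,
        parent_release=previous.release_id if previous else None,
        provenance={
            "config_hash": _config_hash(config),
            "seed": seed,
            "input_manifest": ids,
            "code_history": sorted(used | {g.motif_id.code
                                           for g in groups}),
        },
        matrix=matrix,
        sequences={lid: by_id[lid].loop.sequence() for lid in ids},
    )
    return release
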