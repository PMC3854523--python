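"""Hairpin / internal / three-way junction loop extraction.

Loops are delimited by the canonical cWW pairs that are *nested* within the
secondary structure.  The central device is the flankSS ("flanks
single-stranded region") relation: it holds between two nucleotides of the
same chain when both make nested canonical cWW pairs (not necessarily with
each other) and no nucleotide between them in the chain makes such a pair.

* a hairpin loop (HL) is closed by one canonical cWW pair whose partners
  satisfy flankSS with each other;
* an internal loop (IL) is closed by two canonical cWW pairs such that on
  each strand the closing nucleotides satisfy flankSS or are adjacent
  (bulge loops have a zero-length strand);
* a three-way junction (J3) is closed by three canonical cWW pairs
  bounding up to three single-stranded regions.

Closing nucleotides are part of the loop.  Pairs excluded as pseudoknots
do not delimit loops, which lets hairpin bases make long-range
Watson-Crick pairs without suppressing the hairpin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .structure_io import (AnnotationSet, NucleotideRef, PairAnnotation,
                           Structure, compute_base_frames)

LOOP_TYPES = ("HL", "IL", "J3")


# --------------------------------------------------------------------------
# Loop model
# --------------------------------------------------------------------------

@dataclass
class Loop:
    """One loop instance: ordered strands (5'->3') plus closing pairs."""

    loop_type: str
    strands: list                       # list of list[NucleotideRef]
    closing_pairs: list                 # list[PairAnnotation], canonical cWW
    source: str                         # structure id
    loop_id: Optional[str] = None

    def nucleotides(self) -> list:
        return [nt for strand in self.strands for nt in strand]

    def closing_nucleotides(self) -> set:
        out = set()
        for p in self.closing_pairs:
            out.add(p.nt1.key())
            out.add(p.nt2.key())
        return out

    def interior_nucleotides(self) -> list:
        closing = self.closing_nucleotides()
        return [nt for nt in self.nucleotides() if nt.key() not in closing]

    def size(self) -> int:
        return sum(len(s) for s in self.strands)

    def chains(self) -> list:
        seen = []
        for strand in self.strands:
            for nt in strand:
                if nt.chain not in seen:
                    seen.append(nt.chain)
        return seen

    def sequence(self) -> str:
        return "*".join("".join(nt.base for nt in s) for s in self.strands)


def format_loop_id(prefix: str, pdb_id: str, serial: int) -> str:
    if not 1 <= serial <= 999:
        raise IdSpaceExhaustedError(
            f"serial {serial} outside 001..999 for {prefix}_{pdb_id}")
    return f"{prefix}_{pdb_id.upper()}_{serial:03d}"


def parse_loop_id(loop_id: str) -> tuple:
    prefix, pdb, serial = loop_id.split("_")
    if prefix not in LOOP_TYPES + ("J4", "J5"):
        raise ValueError(f"bad loop id prefix in {loop_id!r}")
    return prefix, pdb, int(serial)


class IdSpaceExhaustedError(ValueError):
    pass


@dataclass
class QAReport:
    loop_id: str
    verdict: str                        # "pass" | "fail"
    reasons: list = field(default_factory=list)   # (code, NucleotideRef)

    def __post_init__(self) -> None:
        if self.verdict == "fail" and not self.reasons:
            raise ValueError("failing QA report needs at least one reason")


# --------------------------------------------------------------------------
# Nested secondary structure
# --------------------------------------------------------------------------

@dataclass
class NestedStructure:
    """Canonical cWW pairs retained as the nested secondary structure."""

    chain_order: list                   # chain names, global ordering
    positions: dict                     # chain -> list[NucleotideRef]
    index: dict                         # ref key -> (chain_rank, pos)
    partner: dict                       # ref key -> NucleotideRef
    pair_lookup: dict                   # ref key -> PairAnnotation
    pseudoknots: list                   # removed crossing pairs
    conflicts: list                     # pairs rejected for shared nucleotide

    def is_paired(self, nt: NucleotideRef) -> bool:
        return nt.key() in self.partner

    def pairs(self) -> list:
        seen, out = set(), []
        for key, ann in self.pair_lookup.items():
            k = frozenset((ann.nt1.key(), ann.nt2.key()))
            if k not in seen:
                seen.add(k)
                out.append(ann)
        return out

    def global_pos(self, nt: NucleotideRef) -> tuple:
        return self.index[nt.key()]


def nested_canonical_pairs(structure: Structure, annotations: AnnotationSet,
                           chains: Optional[Iterable[str]] = None
                           ) -> NestedStructure:
    """Select the canonical cWW pairs forming a nested secondary structure.

    Nucleotides appearing in more than one canonical pair have all their
    canonical pairs rejected (reported as conflicts).  Crossing pairs are
    then resolved by maximizing the number of retained pairs (interval
    dynamic programming); ties are broken toward pairing the 5'-most
    nucleotide.  Removed pairs are reported as pseudoknots.
    """
    wanted = set(chains) if chains is not None else None
    chain_names = [c.name for c in structure.rna_chains()
                   if wanted is None or c.name in wanted]
    chain_names.sort()
    positions = {name: [r.ref for r in structure.chain(name).residues
                        if r.is_rna]
                 for name in chain_names}
    index = {}
    for rank, name in enumerate(chain_names):
        for pos, ref in enumerate(positions[name]):
            index[ref.key()] = (rank, pos)

    # candidate canonical pairs entirely within the selected chains
    candidates = []
    for ann in annotations.canonical_pairs():
        if ann.nt1.key() in index and ann.nt2.key() in index:
            candidates.append(ann)

    # one canonical pair per nucleotide, else reject all pairs of that nt
    count: dict = {}
    for ann in candidates:
        for nt in (ann.nt1, ann.nt2):
            count[nt.key()] = count.get(nt.key(), 0) + 1
    conflicts = [a for a in candidates
                 if count[a.nt1.key()] > 1 or count[a.nt2.key()] > 1]
    candidates = [a for a in candidates
                  if count[a.nt1.key()] == 1 and count[a.nt2.key()] == 1]

    # order pairs along the concatenated chains, compress endpoints
    endpoints = []
    for ann in candidates:
        i, j = index[ann.nt1.key()], index[ann.nt2.key()]
        if i > j:
            i, j = j, i
            ann = ann.reversed()
        endpoints.append((i, j, ann))
    endpoints.sort(key=lambda e: (e[0], e[1]))
    coords = sorted({p for i, j, _ in endpoints for p in (i, j)})
    rank = {p: r for r, p in enumerate(coords)}
    partner_rank = {}
    ann_at = {}
    for i, j, ann in endpoints:
        partner_rank[rank[i]] = rank[j]
        partner_rank[rank[j]] = rank[i]
        ann_at[rank[i]] = ann

    m = len(coords)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i > j:
            return 0
        score_skip = best(i + 1, j)
        k = partner_rank[i]
        if i < k <= j:
            score_pair = 1 + best(i + 1, k - 1) + best(k + 1, j)
        else:
            score_pair = -1
        return max(score_skip, score_pair)

    kept_ranks: set = set()

    def traceback(i: int, j: int) -> None:
        while i <= j:
            k = partner_rank[i]
            if i < k <= j and 1 + best(i + 1, k - 1) + best(k + 1, j) \
                    >= best(i + 1, j):
                kept_ranks.add(i)
                traceback(i + 1, k - 1)
                i = k + 1
            else:
                i += 1

    if m:
        traceback(0, m - 1)
    best.cache_clear()

    partner, pair_lookup, pseudoknots = {}, {}, []
    for i, j, ann in endpoints:
        if rank[i] in kept_ranks:
            partner[ann.nt1.key()] = ann.nt2
            partner[ann.nt2.key()] = ann.nt1
            pair_lookup[ann.nt1.key()] = ann
            pair_lookup[ann.nt2.key()] = ann.reversed()
        else:
            pseudoknots.append(ann)
    return NestedStructure(chain_names, positions, index, partner,
                           pair_lookup, pseudoknots, conflicts)


def flank_ss(nt_a: NucleotideRef, nt_b: NucleotideRef,
             nested: NestedStructure) -> bool:
    """The flankSS relation on the nested secondary structure.

    True iff both nucleotides are on the same chain, both make nested
    canonical cWW pairs, and no chain-intervening nucleotide makes one.
    Symmetric by construction; False across chains by contract.
    """
    if nt_a.chain != nt_b.chain:
        return False
    if not (nested.is_paired(nt_a) and nested.is_paired(nt_b)):
        return False
    if nt_a.key() == nt_b.key():
        return False
    (_, pa), (_, pb) = nested.global_pos(nt_a), nested.global_pos(nt_b)
    lo, hi = min(pa, pb), max(pa, pb)
    chain = nested.positions[nt_a.chain]
    return not any(nested.is_paired(chain[p]) for p in range(lo + 1, hi))


# --------------------------------------------------------------------------
# Loop extraction
# --------------------------------------------------------------------------

@dataclass
class ExtractionReport:
    pseudoknots: list = field(default_factory=list)
    conflicts: list = field(default_factory=list)
    zero_interior_ils: list = field(default_factory=list)
    higher_junctions: list = field(default_factory=list)


def _next_paired(nested: NestedStructure, nt: NucleotideRef):
    chain = nested.positions[nt.chain]
    _, pos = nested.global_pos(nt)
    for p in range(pos + 1, len(chain)):
        if nested.is_paired(chain[p]):
            return chain[p]
    return None


def extract_loops(structure: Structure, annotations: AnnotationSet,
                  chains: Optional[Iterable[str]] = None,
                  max_junction_order: int = 3
                  ) -> tuple[list, ExtractionReport]:
    """Extract all HL, IL and J3 loops delimited by nested canonical pairs.

    Returns ``(loops, report)``.  Loops are maximal (their interiors
    contain no nested canonical pair).  Internal loops consisting of two
    stacked closing pairs with no interior nucleotide on either strand are
    helix steps, not loops; they are reported, not returned.  Junctions of
    order above ``max_junction_order`` are reported and skipped.
    """
    nested = nested_canonical_pairs(structure, annotations, chains)
    report = ExtractionReport(pseudoknots=list(nested.pseudoknots),
                              conflicts=list(nested.conflicts))
    loops = []
    seen_cycles = set()

    # every paired nucleotide is a potential 5' segment start
    starts = sorted((ann.nt1 for ann in nested.pair_lookup.values()),
                    key=nested.global_pos)

    for start in starts:
        segments = []
        cur = start
        ok = False
        for _ in range(max(max_junction_order, 3) + 2):
            nxt = _next_paired(nested, cur)
            if nxt is None:
                break
            segments.append((cur, nxt))
            back = nested.partner[nxt.key()]
            if back.key() == start.key():
                ok = True
                break
            cur = back
        if not ok:
            continue
        cycle_key = frozenset(a.key() for a, _ in segments)
        if cycle_key in seen_cycles:
            continue
        seen_cycles.add(cycle_key)

        # canonical rotation: first strand starts at the globally 5'-most
        # closing nucleotide
        rot = min(range(len(segments)),
                  key=lambda r: nested.global_pos(segments[r][0]))
        segments = segments[rot:] + segments[:rot]

        k = len(segments)
        if k > max_junction_order:
            report.higher_junctions.append(
                [(a.unit_id(), b.unit_id()) for a, b in segments])
            continue
        loop_type = {1: "HL", 2: "IL", 3: "J3"}[k]

        strands = []
        for a, b in segments:
            chain = nested.positions[a.chain]
            (_, pa), (_, pb) = nested.global_pos(a), nested.global_pos(b)
            strands.append(chain[pa:pb + 1])
        closing = [nested.pair_lookup[b.key()] for _, b in segments]

        loop = Loop(loop_type, strands, closing, structure.structure_id)
        if loop_type == "IL" and all(len(s) == 2 for s in strands):
            report.zero_interior_ils.append(loop)
            continue
        loops.append(loop)
    return loops, report


def assign_loop_ids(loops: Sequence[Loop], pdb_id: str) -> list:
    """Assign ``PREFIX_PDBID_NNN`` serials, deterministic and idempotent.

    Serials are assigned per (prefix, pdb_id) in order of (chain, 5'
    position) of each loop's first strand, starting at 001.  Serial order
    carries no positional meaning beyond this determinism.
    """
    def sort_key(loop: Loop):
        nt = loop.strands[0][0]
        return (nt.chain, nt.number, nt.insertion_code)

    counters: dict = {}
    out = []
    for loop in sorted(loops, key=sort_key):
        serial = counters.get(loop.loop_type, 0) + 1
        counters[loop.loop_type] = serial
        loop.loop_id = format_loop_id(loop.loop_type, pdb_id, serial)
        out.append(loop)
    return out


def qa_filter(loops: Sequence[Loop], structure: Structure
              ) -> tuple[list, list]:
    """Set aside loops with unresolvable geometry or modified nucleotides.

    A loop fails iff any of its nucleotides is a modified residue or lacks
    a computable base frame (missing base atoms / coordinates).  Failures
    never reach clustering but are retained in the reports.
    """
    frames, failures = compute_base_frames(structure)
    failure_by_key = {f.ref.key(): f for f in failures}
    passing, reports = [], []
    for loop in loops:
        reasons = []
        for nt in loop.nucleotides():
            res = structure.residue(nt)
            if not res.is_standard:
                reasons.append(("modified_nucleotide", nt))
            elif nt not in frames:
                reasons.append(("missing_coordinates", nt))
        if reasons:
            reports.append(QAReport(loop.loop_id or "?", "fail", reasons))
        else:
            reports.append(QAReport(loop.loop_id or "?", "pass"))
            passing.append(loop)
    return passing, reports


class RepresentativeConfigError(ValueError):
    pass


def default_representative_chains(structure: Structure) -> list:
    """One chain per identical-sequence set: the alphabetically first."""
    by_seq: dict = {}
    for chain in structure.rna_chains():
        seq = structure.chain_sequence(chain.name)
        by_seq.setdefault(seq, []).append(chain.name)
    return sorted(min(names) for names in by_seq.values())


def select_representative_chains(loops: Sequence[Loop], structure: Structure,
                                 representatives: Optional[Mapping] = None
                                 ) -> list:
    """Keep only loops lying entirely in representative chains.

    ``representatives`` maps structure_id -> list of chain names (the
    stand-in for a nonredundant list).  When absent, for each set of
    chains with identical residue sequences the alphabetically first chain
    is kept.
    """
    sid = structure.structure_id
    if representatives is not None and sid in representatives:
        chains = list(representatives[sid])
        known = {c.name for c in structure.chains}
        missing = [c for c in chains if c not in known]
        if missing:
            raise RepresentativeConfigError(
                f"representative chains {missing} not present in {sid}")
    else:
        chains = default_representative_chains(structure)
    keep = set(chains)
    return [loop for loop in loops
            if all(nt.chain in keep for nt in loop.nucleotides())]
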