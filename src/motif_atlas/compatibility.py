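"""Structural-incompatibility criteria applied to geometric matches.

Two loop instances can superpose well yet differ in their interaction
networks; such pairs must not end up in the same motif group.  Five
criteria sever an aligned pair:

* ``FAMILY_CONFLICT`` — aligned positions form true base pairs of
  *different* Leontis-Westhof families in the two instances.  A pair
  present in one instance and absent in the other is tolerated, because
  base-pair annotations are rarely unanimous across a group.
* ``EXTRA_PAIRS`` — an unaligned ("extra") target nucleotide makes a true
  *or near* base pair with any nucleotide of the target loop.
* ``INTERCALATION`` — an extra nucleotide is involved in two or more
  stacking interactions with other bases of the loop.
* ``PAIR_VS_STACK`` — aligned bases pair in one instance but (only)
  stack in the other.
* ``HAIRPIN_EXTRA_STACK`` — hairpins only: an extra nucleotide stacks on
  an aligned one, or extra nucleotides stack on each other.

Severed pairs keep their flags so that related-but-distinct groups remain
explainable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .geometric_alignment import Alignment
from .structure_io import AnnotationSet

FLAG_CODES = ("FAMILY_CONFLICT", "EXTRA_PAIRS", "INTERCALATION",
              "PAIR_VS_STACK", "HAIRPIN_EXTRA_STACK")


@dataclass(frozen=True)
class IncompatibilityFlag:
    code: str
    detail: tuple                      # offending nucleotide unit ids

    def __post_init__(self) -> None:
        if self.code not in FLAG_CODES:
            raise ValueError(f"unknown flag code {self.code}")
        if not self.detail:
            raise ValueError("flag detail must be nonempty")


def _loop_keys(alignment: Alignment) -> set:
    keys = {tnt.key() for _, tnt in alignment.mapping}
    keys |= {nt.key() for nt in alignment.unaligned_target}
    return keys


def family_conflict(alignment: Alignment, annotations_q: AnnotationSet,
                    annotations_t: AnnotationSet
                    ) -> Optional[IncompatibilityFlag]:
    """True base pairs of different families at corresponding positions."""
    m = alignment.mapping
    for i in range(len(m)):
        for j in range(i + 1, len(m)):
            qi, ti = m[i]
            qj, tj = m[j]
            q_pairs = annotations_q.true_pairs_between(qi, qj)
            if not q_pairs:
                continue
            t_pairs = annotations_t.true_pairs_between(ti, tj)
            if not t_pairs:
                continue  # missing annotation is not a conflict
            q_fams = {p.family for p in q_pairs}
            t_fams = {p.family for p in t_pairs}
            if q_fams.isdisjoint(t_fams):
                return IncompatibilityFlag(
                    "FAMILY_CONFLICT",
                    (qi.unit_id(), qj.unit_id(), ti.unit_id(), tj.unit_id()))
    return None


def extra_base_pairing(alignment: Alignment, annotations_t: AnnotationSet
                       ) -> Optional[IncompatibilityFlag]:
    """An extra nucleotide pairs (true or near) into the target loop."""
    keys = _loop_keys(alignment)
    for extra in alignment.unaligned_target:
        for p in annotations_t.pairs_of(extra):
            if p.nt2.key() in keys:
                return IncompatibilityFlag(
                    "EXTRA_PAIRS", (extra.unit_id(), p.nt2.unit_id()))
    return None


def intercalation(alignment: Alignment, annotations_t: AnnotationSet
                  ) -> Optional[IncompatibilityFlag]:
    """An extra nucleotide with two or more stacks into the loop."""
    keys = _loop_keys(alignment)
    for extra in alignment.unaligned_target:
        stacked = [s.nt2 for s in annotations_t.stacks_of(extra)
                   if not s.near and s.nt2.key() in keys]
        if len(stacked) >= 2:
            return IncompatibilityFlag(
                "INTERCALATION",
                (extra.unit_id(),) + tuple(nt.unit_id() for nt in stacked))
    return None


def pair_stack_mismatch(alignment: Alignment, annotations_q: AnnotationSet,
                        annotations_t: AnnotationSet
                        ) -> Optional[IncompatibilityFlag]:
    """Aligned bases pair in one instance but only stack in the other."""
    m = alignment.mapping
    for i in range(len(m)):
        for j in range(i + 1, len(m)):
            qi, ti = m[i]
            qj, tj = m[j]
            q_pair = bool(annotations_q.true_pairs_between(qi, qj))
            t_pair = bool(annotations_t.true_pairs_between(ti, tj))
            q_stack = bool(annotations_q.true_stacks_between(qi, qj))
            t_stack = bool(annotations_t.true_stacks_between(ti, tj))
            if (q_pair and not t_pair and t_stack) or \
                    (t_pair and not q_pair and q_stack):
                return IncompatibilityFlag(
                    "PAIR_VS_STACK",
                    (qi.unit_id(), qj.unit_id(), ti.unit_id(), tj.unit_id()))
    return None


def hairpin_extra_stacking(alignment: Alignment,
                           annotations_t: AnnotationSet
                           ) -> Optional[IncompatibilityFlag]:
    """Hairpins: extra nucleotides stacked on aligned ones or each other."""
    aligned = {tnt.key(): tnt for _, tnt in alignment.mapping}
    extras = {nt.key(): nt for nt in alignment.unaligned_target}
    for extra in alignment.unaligned_target:
        for s in annotations_t.stacks_of(extra):
            if s.near:
                continue
            if s.nt2.key() in aligned:
                return IncompatibilityFlag(
                    "HAIRPIN_EXTRA_STACK",
                    (extra.unit_id(), s.nt2.unit_id()))
            if s.nt2.key() in extras:
                return IncompatibilityFlag(
                    "HAIRPIN_EXTRA_STACK",
                    (extra.unit_id(), s.nt2.unit_id()))
    return None


def assess(alignment: Alignment, annotations_q: AnnotationSet,
           annotations_t: AnnotationSet, loop_type: str) -> list:
    """All incompatibility flags of one directed match.

    Extra-nucleotide criteria run on the target side of this direction;
    the matching matrix merges both directions, so both sides are covered
    when both searches matched.  An empty list means compatible.
    """
    flags = []
    for fn in (lambda: family_conflict(alignment, annotations_q,
                                       annotations_t),
               lambda: extra_base_pairing(alignment, annotations_t),
               lambda: intercalation(alignment, annotations_t),
               lambda: pair_stack_mismatch(alignment, annotations_q,
                                           annotations_t)):
        flag = fn()
        if flag is not None:
            flags.append(flag)
    if loop_type == "HL":
        flag = hairpin_extra_stacking(alignment, annotations_t)
        if flag is not None:
            flags.append(flag)
    return flags


def assess_records(records: dict, annotations_by_loop: dict,
                   loop_types: dict) -> dict:
    """Annotate every matched :class:`MatchRecord` in place with flags and
    switch flagged matches to status ``incompatible``.  Returns the same
    mapping for convenience."""
    for (qid, tid), rec in records.items():
        if rec.status != "match" or rec.alignment is None:
            continue
        flags = assess(rec.alignment, annotations_by_loop[qid],
                       annotations_by_loop[tid], loop_types[qid])
        if flags:
            rec.incompatibility_flags = flags
            rec.status = "incompatible"
    return records
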