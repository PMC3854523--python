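"""Matching matrix assembly and maximum-clique motif grouping.

The symmetric matching matrix holds, for every unordered pair of loop
instances, either the lowest geometric discrepancy of the two directed
searches or infinity (no match in either direction, or an incompatibility
in either direction).  Its finite entries define a weighted graph; motif
groups are extracted by repeatedly taking an exact maximum clique,
removing it, and continuing on the remainder.  Equal-size cliques are
resolved toward the lowest sum of edge discrepancies, then toward the
lexicographically smallest id set, so the grouping is reproducible
regardless of instance ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np


# --------------------------------------------------------------------------
# Matching matrix
# --------------------------------------------------------------------------

class MatchingMatrix:
    """Symmetric discrepancy matrix with loop ids as labels."""

    def __init__(self, ids: Sequence[str], values: np.ndarray) -> None:
        ids = list(ids)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.array_equal(values, values.T):
            raise ValueError("matching matrix must be symmetric")
        if np.diagonal(values).any():
            raise ValueError("matching matrix diagonal must be zero")
        self.ids = ids
        self.values = values
        self._idx = {lid: i for i, lid in enumerate(ids)}

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self._idx[a], self._idx[b]])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                v = self.values[i, j]
                if math.isfinite(v):
                    g.add_edge(self.ids[i], self.ids[j], weight=float(v))
        return g


class IncompleteRecordsError(ValueError):
    pass


def build_matching_matrix(records: dict, ids: Optional[Sequence[str]] = None
                          ) -> MatchingMatrix:
    """Merge directed :class:`MatchRecord` results into the symmetric
    matrix.

    For each unordered pair: if either direction is incompatible the entry
    is infinite; else if neither direction matched it is infinite; else it
    is the lowest discrepancy among the matching directions.  Both ordered
    directions must be present for every pair.
    """
    if ids is None:
        ids = sorted({i for pair in records for i in pair})
    ids = list(ids)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            try:
                fwd, bwd = records[(a, b)], records[(b, a)]
            except KeyError as exc:
                raise IncompleteRecordsError(
                    f"missing search direction for ({a}, {b})") from exc
            if fwd.status == "incompatible" or bwd.status == "incompatible":
                v = math.inf
            else:
                ds = [r.discrepancy for r in (fwd, bwd)
                      if r.status == "match"]
                v = min(ds) if ds else math.inf
            values[i, j] = values[j, i] = v
    return MatchingMatrix(ids, values)


# --------------------------------------------------------------------------
# Maximum cliques
# --------------------------------------------------------------------------

def _clique_weight(graph: nx.Graph, clique: Sequence[str]) -> float:
    total = 0.0
    nodes = list(clique)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            total += graph[nodes[i]][nodes[j]].get("weight", 0.0)
    return total


def maximum_clique(graph: nx.Graph) -> list:
    """Exact maximum clique with deterministic tie-breaking.

    All maximal cliques are enumerated per connected component
    (Bron-Kerbosch); the maximum clique is selected by size, then lowest
    sum of edge discrepancies, then lexicographically smallest sorted id
    list.  The empty graph yields an empty list.
    """
    if graph.number_of_nodes() == 0:
        return []
    best = None
    best_key = None
    for clique in nx.find_cliques(graph):
        members = sorted(clique)
        key = (-len(members), round(_clique_weight(graph, members), 12),
               members)
        if best_key is None or key < best_key:
            best, best_key = members, key
    return best or []


def iterative_cliques(matrix: MatchingMatrix) -> list:
    """Greedy clique peeling: repeatedly take the maximum clique of the
    remaining graph.  Isolated instances end as singleton groups.  The
    result is invariant under permutation of the input instance order."""
    graph = matrix.graph()
    groups = []
    while graph.number_of_nodes():
        clique = maximum_clique(graph)
        groups.append(clique)
        graph.remove_nodes_from(clique)
    return groups


# --------------------------------------------------------------------------
# Consensus alignment
# --------------------------------------------------------------------------

@dataclass
class ConsensusColumn:
    members: dict                      # loop_id -> NucleotideRef
    is_core: bool

    def to_json_dict(self) -> dict:
        return {"core": self.is_core,
                "nucleotides": {lid: nt.unit_id()
                                for lid, nt in sorted(self.members.items())}}


@dataclass
class MotifGroupDraft:
    instances: list                    # sorted loop ids
    columns: list                      # ConsensusColumn, ordered
    mean_discrepancy: float
    reference: str                     # lowest loop id
    ref_positions: dict = field(default_factory=dict)
    # ^ reference nt key -> (strand index, position within strand)
    discarded_alignments: list = field(default_factory=list)
    orientation_conflicts: list = field(default_factory=list)

    def core_columns(self) -> list:
        return [c for c in self.columns if c.is_core]


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            self.parent[x] = p = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def consensus_alignment(instance_ids: Sequence[str], records: dict,
                        loops_by_id: dict,
                        matrix: Optional[MatchingMatrix] = None
                        ) -> MotifGroupDraft:
    """Merge the pairwise alignments of a clique into consensus columns.

    Nodes are (instance, nucleotide); edges come from the member pairwise
    alignments, added in order of increasing discrepancy.  An alignment
    whose edges would place two nucleotides of one instance in the same
    column is discarded (highest-discrepancy first, by construction of the
    insertion order) and reported.  Columns holding a nucleotide of every
    instance are core; the rest are insertion columns.  Column order
    follows strand and 5' position in the reference instance (the lowest
    loop id), with insertion columns placed after their nearest preceding
    core position.
    """
    instances = sorted(instance_ids)
    reference = instances[0]

    # collect one alignment per ordered member pair, sort by discrepancy
    alignments = []
    for a in instances:
        for b in instances:
            if a >= b:
                continue
            cands = []
            for key in ((a, b), (b, a)):
                rec = records.get(key)
                if rec is not None and rec.alignment is not None \
                        and rec.status in ("match",):
                    cands.append(rec)
            if not cands:
                continue
            rec = min(cands, key=lambda r: (r.discrepancy,
                                            r.query_id != a))
            alignments.append(rec)
    alignments.sort(key=lambda r: (r.discrepancy, r.query_id, r.target_id))

    uf = _UnionFind()
    kept, discarded = [], []
    orientation = {}                   # instance pair -> rotated flag
    orientation_conflicts = []
    for rec in alignments:
        qid, tid = rec.query_id, rec.target_id
        edges = [((qid, qnt.key()), (tid, tnt.key()))
                 for qnt, tnt in rec.alignment.mapping]
        # trial union on a copy: reject alignments creating intra-instance
        # merges (two nucleotides of one instance in one column)
        trial = _UnionFind()
        trial.parent = dict(uf.parent)
        for u, v in edges:
            trial.union(u, v)
        comp: dict = {}
        conflict = False
        for node in trial.parent:
            root = trial.find(node)
            inst = node[0]
            seen = comp.setdefault(root, {})
            if inst in seen and seen[inst] != node[1]:
                conflict = True
                break
            seen[inst] = node[1]
        if conflict:
            discarded.append((qid, tid, rec.discrepancy))
            continue
        for u, v in edges:
            uf.union(u, v)
        kept.append(rec)
        pair = tuple(sorted((qid, tid)))
        rot = rec.alignment.rotated
        if pair in orientation and orientation[pair] != rot:
            orientation_conflicts.append(pair)
        orientation[pair] = rot

    # make sure every nucleotide of every instance is a node
    for lid in instances:
        for nt in loops_by_id[lid].nucleotides():
            uf.find((lid, nt.key()))

    nt_lookup = {(lid, nt.key()): nt
                 for lid in instances
                 for nt in loops_by_id[lid].nucleotides()}
    components: dict = {}
    for node in list(uf.parent):
        components.setdefault(uf.find(node), []).append(node)

    columns = []
    for nodes in components.values():
        members = {inst: nt_lookup[(inst, key)] for inst, key in nodes}
        columns.append(ConsensusColumn(members,
                                       len(members) == len(instances)))

    # order columns by the reference instance, insertions by anchoring
    ref_loop = loops_by_id[reference]
    ref_pos = {}
    for si, strand in enumerate(ref_loop.strands):
        for pi, nt in enumerate(strand):
            ref_pos[nt.key()] = (si, pi)

    pos_by_instance = {}
    for lid in instances:
        pos_by_instance[lid] = {}
        for si, strand in enumerate(loops_by_id[lid].strands):
            for pi, nt in enumerate(strand):
                pos_by_instance[lid][nt.key()] = (si, pi)

    col_of = {}
    for col in columns:
        for inst, nt in col.members.items():
            col_of[(inst, nt.key())] = col

    def column_key(col: ConsensusColumn) -> tuple:
        if reference in col.members:
            si, pi = ref_pos[col.members[reference].key()]
            return (si, float(pi), 0)
        # anchor to the nearest preceding column (in its own instance)
        inst = min(col.members)
        nt = col.members[inst]
        si, pi = pos_by_instance[inst][nt.key()]
        strand = loops_by_id[inst].strands[si]
        for back in range(pi - 1, -1, -1):
            prev = col_of.get((inst, strand[back].key()))
            if prev is not None and prev is not col and \
                    reference in prev.members:
                rsi, rpi = ref_pos[prev.members[reference].key()]
                return (rsi, rpi + (pi - back) / 1000.0, 1)
        return (si, float(pi) - 0.5, 1)

    columns.sort(key=lambda c: (column_key(c),
                                sorted(nt.unit_id()
                                       for nt in c.members.values())))

    if matrix is not None and len(instances) > 1:
        vals = [matrix.entry(a, b) for i, a in enumerate(instances)
                for b in instances[i + 1:]]
        mean_disc = float(np.mean(vals))
    else:
        mean_disc = 0.0

    return MotifGroupDraft(instances, columns, mean_disc, reference,
                           ref_pos, discarded, orientation_conflicts)
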