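"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the production code paths: alignment is
enumerated with itertools over all admissible monotone mappings, and
cliques over all vertex subsets by bitmask.
"""

from __future__ import annotations

import itertools

from motif_atlas.geometric_alignment import SearchConfig, discrepancy


def brute_force_align(query, target, config=None):
    """Minimum discrepancy over all admissible mappings, or None.

    Enumerates every injective, per-strand order-preserving mapping of
    the query core into the target with endpoints pinned to endpoints,
    for both strand orders of internal loops.
    """
    config = config or SearchConfig()
    best = None
    orders = [tuple(range(len(query.loop.strands)))]
    if query.loop.loop_type == "IL" and config.allow_rotated_IL:
        orders = [(0, 1), (1, 0)]
    frames_q = [query.frame(nt) for nt in query.core]
    for order in orders:
        t_strands = [target.loop.strands[i] for i in order]
        if any(len(ts) < len(qs)
               for qs, ts in zip(query.core_strands, t_strands)):
            continue
        per_strand = []
        ok = True
        for qs, ts in zip(query.core_strands, t_strands):
            k = len(qs)
            T = len(ts)
            combos = [c for c in itertools.combinations(range(T), k)
                      if c[0] == 0 and c[-1] == T - 1]
            if not combos:
                ok = False
                break
            per_strand.append(combos)
        if not ok:
            continue
        for combo in itertools.product(*per_strand):
            frames_t = []
            for ts, positions in zip(t_strands, combo):
                frames_t.extend(target.frame(ts[p]) for p in positions)
            d = discrepancy(frames_q, frames_t, config.angle_weight)
            if d <= config.cutoff and (best is None or d < best):
                best = d
    return best


def brute_force_maximum_clique(graph):
    """Exact maximum clique by subset enumeration with the same tie-break
    key (size, lowest weight sum, lexicographically smallest ids)."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return []
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in graph.edges:
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]

    best = None
    best_key = None
    for mask in range(1, 1 << n):
        m = mask
        is_clique = True
        while m:
            v = (m & -m).bit_length() - 1
            if (adj[v] | (1 << v)) & mask != mask:
                is_clique = False
                break
            m &= m - 1
        if not is_clique:
            continue
        members = [nodes[i] for i in range(n) if mask >> i & 1]
        weight = 0.0
        for a, b in itertools.combinations(members, 2):
            weight += graph[a][b].get("weight", 0.0)
        key = (-len(members), round(weight, 12), members)
        if best_key is None or key < best_key:
            best, best_key = members, key
    return best


def brute_force_iterative_cliques(graph):
    """Greedy peeling with the brute-force maximum clique."""
    g = graph.copy()
    groups = []
    while g.number_of_nodes():
        clique = brute_force_maximum_clique(g)
        groups.append(clique)
        g.remove_nodes_from(clique)
    return groups


def random_weighted_graph(rng, max_nodes=15, p=0.45):
    """Seeded random graph with discrepancy-like edge weights."""
    import networkx as nx

    n = int(rng.integers(3, max_nodes + 1))
    g = nx.Graph()
    names = [f"L{i:02d}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                # coarse weights make exact weight ties common, which
                # exercises the lexicographic tie-break
                w = round(float(rng.integers(1, 8)) / 10.0, 1)
                g.add_edge(names[i], names[j], weight=w)
    return g
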