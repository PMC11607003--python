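"""Brute-force 1-mm discretization oracle for query operations.

Independent of the segment-graph implementation: every structure is cut
into 1-mm cells on the integer grid (all fixture and generated coordinates
are integer mm), an explicit cell graph is built with networkx, and
queries run as plain (weighted) BFS/Dijkstra on it.
"""

from fractions import Fraction

import networkx as nx

from sdmm.timeline_engine import RELATION_CLASS


def _int(x) -> int:
    f = Fraction(x)
    assert f.denominator == 1, f"non-integer coordinate {x}"
    return int(f)


def cell_graph(state, relation, undirected=False):
    g = nx.DiGraph()
    for sid in state.ba.structures:
        for a, b in state.residual_intervals(sid):
            ai, bi = _int(a), _int(b)
            for x in range(ai, bi):
                g.add_edge((sid, x), (sid, x + 1), w=1)
                if undirected:
                    g.add_edge((sid, x + 1), (sid, x), w=1)
    def add_link(u, v, w):
        if g.has_node(u) and g.has_node(v):
            g.add_edge(u, v, w=w)
            if undirected:
                g.add_edge(v, u, w=w)
    for l in state.ba.natural_links:
        if l.relation != relation:
            continue
        u = (l.from_id, _int(Fraction(l.from_offset_mm) * state.scale(l.from_id)))
        v = (l.to_id, _int(Fraction(l.to_offset_mm) * state.scale(l.to_id)))
        add_link(u, v, 0)
    for l in state.links:
        if l.relation != relation:
            continue
        add_link((l.from_id, _int(l.from_offset)), (l.to_id, _int(l.to_offset)),
                 _int(l.length))
    return g


def oracle_distance(state, a, b, relation, undirected=False):
    """(reachable, distance) between integer points a=(sid, off), b."""
    g = cell_graph(state, relation, undirected)
    a = (a[0], _int(a[1]))
    b = (b[0], _int(b[1]))
    if a == b:
        return True, 0
    if not (g.has_node(a) and g.has_node(b)):
        return False, None
    try:
        return True, nx.dijkstra_path_length(g, a, b, weight="w")
    except nx.NetworkXNoPath:
        return False, None


def oracle_residual_length(state, structure_ids):
    """Residual 1-mm cell count over the selection."""
    total = 0
    for sid in structure_ids:
        for a, b in state.residual_intervals(sid):
            total += _int(b) - _int(a)
    return total


def oracle_supplying_vessels(state, structure_id, relation="arterial"):
    """Reverse reachability over the cell graph onto a supersink."""
    g = cell_graph(state, relation)
    sink = ("__sink__", -1)
    for node in [n for n in g.nodes if n[0] == structure_id]:
        g.add_edge(node, sink, w=0)
    if not g.has_node(sink):
        return []
    vessel_class = RELATION_CLASS.get(relation, relation)
    reached = {n[0] for n in nx.ancestors(g, sink)}
    return sorted(
        sid for sid in reached
        if sid in state.ba.structures
        and state.ba.structures[sid].organ_class == vessel_class
        and sid != structure_id
        and state.residual_width(sid) > 0
    )
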