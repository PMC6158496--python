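"""State-sum invariants: the Kauffman bracket for knot diagrams and a
Yamada-type spatial-graph polynomial for theta-curves.

Kauffman bracket
----------------
Standard smoothing expansion with loop value delta = -A^2 - A^-2 and
<unknot> = 1.  The A-smoothing at a crossing with over flag ``f`` joins
slots (f, f+1) and (f+2, f+3) (rotate the over-strand counterclockwise).

Yamada-type polynomial
----------------------
Each crossing is expanded into the A-smoothing (weight A), B-smoothing
(weight A^-1) and the flat 4-valent vertex (weight 1); the resulting flat
graph G is evaluated by its integer flow polynomial F(G; k) at
k = 2 - A - A^-1 (so a disjoint circle contributes c = 1 - A - A^-1).
With these weights the sum is invariant under Reidemeister moves II-V and
picks up a unit +/-A^n under move I and vertex twists, which the
``normalized`` quotient removes.  The derivation of these constants is in
the methods note; all invariance claims are additionally verified
computationally in the test suite.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from .diagram import PlanarDiagram
from .laurent import LaurentPoly

BRACKET_DELTA = LaurentPoly({2: -1, -2: -1})
#: circle weight in the Yamada-type state sum
YAMADA_CIRCLE = LaurentPoly({0: 1, 1: -1, -1: -1})
#: flow variable k = 2 - A - A^-1
FLOW_K = LaurentPoly({0: 2, 1: -1, -1: -1})

DEFAULT_CROSSING_CAP = 14


class StateSumLimit(ValueError):
    """Raised when a diagram exceeds the state-sum crossing cap."""


# ----------------------------------------------------------------------
# union-find used for loop counting
# ----------------------------------------------------------------------

class _UF:
    __slots__ = ("p",)

    def __init__(self):
        self.p = {}

    def find(self, a):
        p = self.p
        while p.setdefault(a, a) != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[ra] = rb


# ----------------------------------------------------------------------
# Kauffman bracket
# ----------------------------------------------------------------------

def _smoothing_pairs(over: int, choice: str) -> list[tuple[int, int]]:
    f = over
    if choice == "A":
        return [(f % 4, (f + 1) % 4), ((f + 2) % 4, (f + 3) % 4)]
    return [((f + 1) % 4, (f + 2) % 4), ((f + 3) % 4, f % 4)]


def bracket(d: PlanarDiagram, cap: int = DEFAULT_CROSSING_CAP) -> LaurentPoly:
    """Kauffman bracket of a vertex-free diagram, <unknot> = 1."""
    if not d.is_knot:
        raise ValueError("bracket is defined for knot (vertex-free) diagrams")
    xs = sorted(d.crossings)
    n = len(xs)
    if n > cap:
        raise StateSumLimit(f"{n} crossings exceeds the state-sum cap {cap}")
    arc_pairs = [(ea, eb) for ea, eb, _l in d.arcs.values()]
    free = len(d.loops)
    total = LaurentPoly.zero()
    for state in product("AB", repeat=n):
        uf = _UF()
        for ea, eb in arc_pairs:
            uf.union(ea, eb)
        for x, ch in zip(xs, state):
            for k1, k2 in _smoothing_pairs(d.crossings[x], ch):
                uf.union(("x", x, k1), ("x", x, k2))
        roots = {uf.find(e) for e in list(uf.p)}
        loops = len(roots) + free
        exp = state.count("A") - state.count("B")
        total = total + LaurentPoly.monomial(exp) * (BRACKET_DELTA ** (loops - 1))
    return total


def normalized_bracket(d: PlanarDiagram, cap: int = DEFAULT_CROSSING_CAP) -> LaurentPoly:
    """Writhe-normalized bracket f(D) = (-A^3)^(-w) <D>, an ambient-isotopy
    invariant of knots."""
    w = d.writhe()
    br = bracket(d, cap)
    sign = 1 if w % 2 == 0 else -1
    return br.shift(-3 * w) * sign


# ----------------------------------------------------------------------
# flow polynomial of a multigraph
# ----------------------------------------------------------------------

def _canon_graph(edges: tuple[tuple[int, int], ...]) -> tuple[tuple[int, int], ...]:
    remap: dict[int, int] = {}
    out = []
    for u, v in edges:
        for w in (u, v):
            if w not in remap:
                remap[w] = len(remap)
        a, b = remap[u], remap[v]
        out.append((min(a, b), max(a, b)))
    return tuple(sorted(out))


@lru_cache(maxsize=200_000)
def _flow_poly_cached(edges: tuple[tuple[int, int], ...]) -> LaurentPoly:
    if not edges:
        return LaurentPoly.one()
    # split off loops first
    for i, (u, v) in enumerate(edges):
        if u == v:
            rest = edges[:i] + edges[i + 1:]
            return YAMADA_CIRCLE * _flow_poly_cached(_canon_graph(rest))
    # contract-delete on the first edge: F(G) = F(G/e) - F(G-e)
    (u, v), rest = edges[0], edges[1:]
    contracted = tuple((u if a == v else a, u if b == v else b) for a, b in rest)
    return _flow_poly_cached(_canon_graph(contracted)) - _flow_poly_cached(
        _canon_graph(rest)
    )


def flow_poly(edges) -> LaurentPoly:
    """Flow polynomial of a multigraph (list of (u,v) pairs, loops allowed)
    evaluated at k = 2 - A - A^-1, as a Laurent polynomial in A.

    Bridges evaluate to zero; a disjoint circle (vertexless cycle) must be
    passed as a loop edge.
    """
    return _flow_poly_cached(_canon_graph(tuple((u, v) for u, v in edges)))


# ----------------------------------------------------------------------
# Yamada-type state sum
# ----------------------------------------------------------------------

def yamada_raw(d: PlanarDiagram, cap: int = DEFAULT_CROSSING_CAP) -> LaurentPoly:
    """Unnormalized Yamada-type polynomial (defined up to +/-A^n)."""
    xs = sorted(d.crossings)
    n = len(xs)
    if n > cap:
        raise StateSumLimit(f"{n} crossings exceeds the state-sum cap {cap}")
    arc_pairs = [(ea, eb) for ea, eb, _l in d.arcs.values()]
    vset = sorted(d.vertices)
    free = len(d.loops)
    total = LaurentPoly.zero()
    for state in product("ABV", repeat=n):
        uf = _UF()
        for ea, eb in arc_pairs:
            uf.union(ea, eb)
        flat_nodes: list[tuple[str, int]] = [("v", v) for v in vset]
        for x, ch in zip(xs, state):
            if ch == "V":
                flat_nodes.append(("x", x))
                continue
            for k1, k2 in _smoothing_pairs(d.crossings[x], ch):
                uf.union(("x", x, k1), ("x", x, k2))
        # anchor node ends so node-incident chains become graph edges
        node_of_end: dict = {}
        for kind, nid in flat_nodes:
            deg = 3 if kind == "v" else 4
            for k in range(deg):
                node_of_end[(kind, nid, k)] = (kind, nid)
        # connected chains of ends: classify by the nodes they touch
        comp_nodes: dict = {}
        for e in list(uf.p):
            r = uf.find(e)
            comp_nodes.setdefault(r, [])
            if e in node_of_end:
                comp_nodes[r].append(node_of_end[e])
        edges = []
        circles = free
        for r, nodes in comp_nodes.items():
            if not nodes:
                circles += 1
            elif len(nodes) == 2:
                edges.append((nodes[0], nodes[1]))
            else:
                raise AssertionError(f"chain touching {len(nodes)} node-ends")
        nidx = {node: i for i, node in enumerate(sorted(set(flat_nodes)))}
        weight = LaurentPoly.monomial(state.count("A") - state.count("B"))
        val = weight * (YAMADA_CIRCLE ** circles) * flow_poly(
            [(nidx[u], nidx[v]) for u, v in edges]
        )
        total = total + val
    return total


def yamada(d: PlanarDiagram, cap: int = DEFAULT_CROSSING_CAP) -> LaurentPoly:
    """Normalized Yamada-type polynomial: unit +/-A^n removed (lowest
    exponent 0, lowest coefficient positive).  Invariant of the spatial
    graph under all moves I-V."""
    return yamada_raw(d, cap).normalized()
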