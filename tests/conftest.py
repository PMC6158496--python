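"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately separate implementations from the
package code paths they check: the bracket and Yamada oracles expand
states into explicit loop/edge sets, the flow-polynomial oracle uses the
subset-sum formula over networkx graphs, and the determinant oracle
evaluates the bracket at a primitive 8th root of unity.
"""

from __future__ import annotations

import cmath
from itertools import product as iproduct

import networkx as nx
import pytest

from thetaknot.catalog import load_catalog
from thetaknot.diagram import PlanarDiagram
from thetaknot.laurent import LaurentPoly


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


# ----------------------------------------------------------------------
# naive Kauffman bracket: explicit loop tracing per state
# ----------------------------------------------------------------------

def naive_bracket(d: PlanarDiagram) -> LaurentPoly:
    xs = sorted(d.crossings)
    delta = LaurentPoly({2: -1, -2: -1})
    total = LaurentPoly.zero()
    for state in iproduct("AB", repeat=len(xs)):
        # build an undirected multigraph on slot-ends and count cycles
        g = nx.MultiGraph()
        for ea, eb, _l in d.arcs.values():
            g.add_edge(ea, eb)
        for x, ch in zip(xs, state):
            f = d.crossings[x]
            if ch == "A":
                pairs = [(f % 4, (f + 1) % 4), ((f + 2) % 4, (f + 3) % 4)]
            else:
                pairs = [((f + 1) % 4, (f + 2) % 4), ((f + 3) % 4, f % 4)]
            for k1, k2 in pairs:
                g.add_edge(("x", x, k1), ("x", x, k2))
        loops = nx.number_connected_components(g) + len(d.loops)
        exp = state.count("A") - state.count("B")
        total = total + LaurentPoly.monomial(exp) * delta ** (loops - 1)
    return total


# ----------------------------------------------------------------------
# flow polynomial oracle: subset-sum formula on a networkx multigraph
# ----------------------------------------------------------------------

def subset_flow_poly(edges) -> LaurentPoly:
    """F(G; k) = sum over F subset E of (-1)^{|E|-|F|} k^{beta(F)} at
    k = 2 - A - 1/A."""
    k = LaurentPoly({0: 2, 1: -1, -1: -1})
    edges = list(edges)
    nodes = sorted({v for e in edges for v in e})
    total = LaurentPoly.zero()
    for mask in range(1 << len(edges)):
        sub = [e for i, e in enumerate(edges) if mask >> i & 1]
        g = nx.MultiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(sub)
        beta = len(sub) - len(nodes) + nx.number_connected_components(g)
        term = k ** beta
        if (len(edges) - len(sub)) % 2 == 1:
            term = -term
        total = total + term
    return total


# ----------------------------------------------------------------------
# naive Yamada state sum: fresh subset-formula evaluation per state
# ----------------------------------------------------------------------

def naive_yamada(d: PlanarDiagram) -> LaurentPoly:
    xs = sorted(d.crossings)
    circle = LaurentPoly({0: 1, 1: -1, -1: -1})
    total = LaurentPoly.zero()
    for state in iproduct("ABV", repeat=len(xs)):
        g = nx.MultiGraph()
        for ea, eb, _l in d.arcs.values():
            g.add_edge(ea, eb)
        flat = [("v", v) for v in d.vertices]
        for x, ch in zip(xs, state):
            if ch == "V":
                flat.append(("x", x))
                continue
            f = d.crossings[x]
            if ch == "A":
                pairs = [(f % 4, (f + 1) % 4), ((f + 2) % 4, (f + 3) % 4)]
            else:
                pairs = [((f + 1) % 4, (f + 2) % 4), ((f + 3) % 4, f % 4)]
            for k1, k2 in pairs:
                g.add_edge(("x", x, k1), ("x", x, k2))
        node_of = {}
        for kind, nid in flat:
            for k in range(3 if kind == "v" else 4):
                node_of[(kind, nid, k)] = (kind, nid)
        circles = len(d.loops)
        gedges = []
        for comp in nx.connected_components(g):
            touch = [node_of[e] for e in comp if e in node_of]
            if not touch:
                circles += 1
            else:
                assert len(touch) == 2
                gedges.append(tuple(touch))
        weight = LaurentPoly.monomial(state.count("A") - state.count("B"))
        total = total + weight * circle ** circles * subset_flow_poly(gedges)
    return total


def det_from_bracket(d: PlanarDiagram) -> int:
    """Determinant as the modulus of the bracket at A = exp(i pi/4)."""
    from thetaknot.statesum import bracket

    z = cmath.exp(1j * cmath.pi / 4)
    val = sum(c * z ** e for e, c in bracket(d).coeffs().items())
    return round(abs(val))
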