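"""Combinatorial planar diagrams of knots and theta-curves.

A diagram is a 4-valent/3-valent planar map: crossings have four arc-end
slots in counterclockwise cyclic order with a flag marking which opposite
slot pair carries the over-strand; trivalent vertices (the replication
forks of a theta-curve) have three slots in counterclockwise order.  Arcs
pair up slots; closed crossingless components are kept as labelled loops.

Slot conventions
----------------
* An *end* is a triple ``(kind, node_id, slot)`` with ``kind`` ``"x"`` for
  crossings (slots 0..3) and ``"v"`` for vertices (slots 0..2).
* At a crossing the two strands occupy the opposite slot pairs (0,2) and
  (1,3).  ``over == 0`` means the (0,2) strand passes over; ``over == 1``
  means (1,3) does.
* Faces are traced with the rotation rule "arrive at slot k, depart at
  slot k+1 (counterclockwise)"; a diagram is planar iff every connected
  component satisfies V - E + F = 2 under this tracing.

Edge labels are ``SISTER_A``/``SISTER_B``/``UNREPLICATED`` for theta-curves
and ``K`` for knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

SISTER_A = "SISTER_A"
SISTER_B = "SISTER_B"
UNREPLICATED = "UNREPLICATED"
KNOT_LABEL = "K"
THETA_LABELS = (SISTER_A, SISTER_B, UNREPLICATED)

End = tuple[str, int, int]  # (kind, node id, slot)


def _deg(kind: str) -> int:
    return 4 if kind == "x" else 3


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok


class PlanarDiagram:
    """Mutable planar diagram; all operations that "modify" return copies."""

    def __init__(
        self,
        crossings: dict[int, int] | None = None,
        vertices: Iterable[int] = (),
        arcs: dict[int, tuple[End, End, str]] | None = None,
        loops: dict[int, str] | None = None,
    ):
        self.crossings: dict[int, int] = dict(crossings or {})
        self.vertices: set[int] = set(vertices)
        self.arcs: dict[int, tuple[End, End, str]] = dict(arcs or {})
        self.loops: dict[int, str] = dict(loops or {})

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    def copy(self) -> "PlanarDiagram":
        return PlanarDiagram(self.crossings, self.vertices, self.arcs, self.loops)

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)

    @property
    def is_theta(self) -> bool:
        return len(self.vertices) == 2

    @property
    def is_knot(self) -> bool:
        return not self.vertices

    def fresh_arc_id(self) -> int:
        taken = set(self.arcs) | set(self.loops)
        i = 0
        while i in taken:
            i += 1
        return i

    def fresh_crossing_id(self) -> int:
        return max(self.crossings, default=-1) + 1

    def slot_map(self) -> dict[End, int]:
        """Map every arc end slot to the arc occupying it."""
        m: dict[End, int] = {}
        for aid, (ea, eb, _lab) in self.arcs.items():
            m[ea] = aid
            m[eb] = aid
        return m

    def all_ends(self) -> list[End]:
        ends: list[End] = []
        for x in self.crossings:
            ends.extend(("x", x, k) for k in range(4))
        for v in self.vertices:
            ends.extend(("v", v, k) for k in range(3))
        return ends

    def arc_label(self, aid: int) -> str:
        return self.arcs[aid][2]

    def other_end(self, aid: int, end: End) -> End:
        ea, eb, _ = self.arcs[aid]
        if end == ea:
            return eb
        if end == eb:
            return ea
        raise KeyError(f"arc {aid} has no end {end}")

    # ------------------------------------------------------------------
    # strand traversal
    # ------------------------------------------------------------------
    @staticmethod
    def continuation(end: End) -> Optional[End]:
        """Where a strand re-emerges after entering a node at ``end``.

        Through a crossing the strand continues at the opposite slot;
        at a trivalent vertex the strand terminates (returns None).
        """
        kind, n, k = end
        if kind == "x":
            return ("x", n, (k + 2) % 4)
        return None

    def walk_strand(self, start: End) -> list[tuple[int, End, End]]:
        """Follow a strand from an outgoing slot ``start``.

        Returns a list of (arc_id, from_end, to_end) hops, stopping at a
        trivalent vertex or on returning to ``start``.
        """
        smap = self.slot_map()
        hops: list[tuple[int, End, End]] = []
        cur = start
        while True:
            aid = smap[cur]
            nxt = self.other_end(aid, cur)
            hops.append((aid, cur, nxt))
            cont = self.continuation(nxt)
            if cont is None:
                return hops
            if cont == start:
                return hops
            cur = cont

    def theta_edges(self) -> dict[str, list[int]]:
        """For a theta-curve: map edge label -> ordered arc ids along the edge."""
        if not self.is_theta:
            raise ValueError("not a theta-curve diagram")
        v0 = min(self.vertices)
        edges: dict[str, list[int]] = {}
        for k in range(3):
            hops = self.walk_strand(("v", v0, k))
            label = self.arcs[hops[0][0]][2]
            if label in edges:
                raise ValueError(f"edge label {label} repeated at vertex {v0}")
            edges[label] = [h[0] for h in hops]
        return edges

    def knot_cycles(self) -> list[list[tuple[int, End, End]]]:
        """Closed strands of a vertex-free diagram (loops excluded)."""
        smap = self.slot_map()
        seen: set[End] = set()
        cycles = []
        for end in sorted(smap):
            if end in seen:
                continue
            hops = self.walk_strand(end)
            for _aid, fr, to in hops:
                seen.add(fr)
                seen.add(to)
            cycles.append(hops)
        return cycles

    # ------------------------------------------------------------------
    # faces & planarity
    # ------------------------------------------------------------------
    def faces(self) -> list[list[tuple[int, int]]]:
        """Faces as orbits of darts.

        A dart is ``(arc_id, direction)`` with direction 0 for end_a->end_b.
        The successor of a dart arriving at slot (n, k) departs from slot
        (n, k+1 mod deg).
        """
        smap = self.slot_map()
        darts = [(aid, d) for aid in sorted(self.arcs) for d in (0, 1)]
        succ: dict[tuple[int, int], tuple[int, int]] = {}
        for aid, d in darts:
            ea, eb, _ = self.arcs[aid]
            head = eb if d == 0 else ea
            kind, n, k = head
            out_slot = (kind, n, (k + 1) % _deg(kind))
            naid = smap[out_slot]
            nea, neb, _ = self.arcs[naid]
            nd = 0 if nea == out_slot else 1
            succ[(aid, d)] = (naid, nd)
        faces = []
        seen: set[tuple[int, int]] = set()
        for dart in darts:
            if dart in seen:
                continue
            face = []
            cur = dart
            while cur not in seen:
                seen.add(cur)
                face.append(cur)
                cur = succ[cur]
            faces.append(face)
        return faces

    def components(self) -> list[set[tuple[str, int]]]:
        """Connected components of the node graph (loops excluded)."""
        parent: dict[tuple[str, int], tuple[str, int]] = {}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for x in self.crossings:
            parent[("x", x)] = ("x", x)
        for v in self.vertices:
            parent[("v", v)] = ("v", v)
        for ea, eb, _ in self.arcs.values():
            union((ea[0], ea[1]), (eb[0], eb[1]))
        comps: dict[tuple[str, int], set[tuple[str, int]]] = {}
        for node in parent:
            comps.setdefault(find(node), set()).add(node)
        return list(comps.values())

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> ValidationReport:
        rep = ValidationReport()
        viol = rep.violations
        # slot usage
        expected = set(self.all_ends())
        used: list[End] = []
        for aid, (ea, eb, _lab) in self.arcs.items():
            used.extend((ea, eb))
        seen_once: set[End] = set()
        for e in used:
            if e not in expected:
                viol.append(f"arc end {e} refers to no crossing/vertex slot")
            elif e in seen_once:
                viol.append(f"slot {e} used by more than one arc end")
            else:
                seen_once.add(e)
        missing = expected - seen_once
        for e in sorted(missing):
            viol.append(f"slot {e} is unused")
        if viol:
            return rep  # structure too broken for further checks

        nv = len(self.vertices)
        if nv not in (0, 2):
            viol.append(f"vertex count != 2 (theta) or 0 (knot): found {nv}")
        labels = {lab for _, _, lab in self.arcs.values()} | set(self.loops.values())
        if nv == 2:
            if self.loops:
                viol.append("theta-curve diagram contains free loops")
            if labels != set(THETA_LABELS):
                viol.append(
                    f"theta-curve edge labels must be {set(THETA_LABELS)}, found {labels}"
                )
            else:
                # every label incident to both vertices, via edge traversal
                try:
                    for v in self.vertices:
                        at_v = []
                        smap = self.slot_map()
                        for k in range(3):
                            at_v.append(self.arcs[smap[("v", v, k)]][2])
                        if sorted(at_v) != sorted(THETA_LABELS):
                            viol.append(
                                f"vertex {v} not incident to all three edges: {at_v}"
                            )
                    if not viol:
                        self.theta_edges()
                except ValueError as exc:
                    viol.append(str(exc))
        elif nv == 0:
            if self.arcs and len(labels - set(self.loops.values())) > 1:
                viol.append(f"knot diagram carries multiple labels: {labels}")
            if self.arcs:
                cycles = self.knot_cycles()
                if len(cycles) != 1:
                    viol.append(
                        f"knot diagram must be a single closed strand, found {len(cycles)}"
                    )
        # label constancy through crossings
        if not viol:
            for x, _over in sorted(self.crossings.items()):
                smap = self.slot_map()
                for k in (0, 1):
                    l1 = self.arcs[smap[("x", x, k)]][2]
                    l2 = self.arcs[smap[("x", x, k + 2)]][2]
                    if l1 != l2:
                        viol.append(
                            f"crossing {x} strand ({k},{k+2}) changes label {l1}->{l2}"
                        )
        # planarity per component: V - E + F = 2
        if not viol and (self.crossings or self.vertices):
            comps = self.components()
            faces = self.faces()
            node_of_arc = {
                aid: (ea[0], ea[1]) for aid, (ea, eb, _l) in self.arcs.items()
            }
            for comp in comps:
                V = len(comp)
                E = sum(1 for aid, n in node_of_arc.items() if n in comp)
                F = sum(
                    1 for f in faces if node_of_arc[f[0][0]] in comp
                )
                if V - E + F != 2:
                    viol.append(
                        f"component {sorted(comp)[:4]}...: V-E+F = {V}-{E}+{F} != 2 (non-planar map)"
                    )
        return rep

    # ------------------------------------------------------------------
    # mirror, orientation, writhe
    # ------------------------------------------------------------------
    def mirror(self) -> "PlanarDiagram":
        """Change every crossing (flip over/under); an involution."""
        out = self.copy()
        out.crossings = {x: 1 - o for x, o in self.crossings.items()}
        return out

    def orientation(self) -> dict[int, int]:
        """Deterministic orientation: arc_id -> +1 (a->b) or -1 (b->a).

        Knot strands are oriented from the least slot they touch.  Theta
        edges are oriented as the replication bubble is traversed: SISTER_A
        and UNREPLICATED run from the lower-id fork to the higher, SISTER_B
        runs back (so the sister duplexes are antiparallel, the orientation
        the two edges inherit as the boundary cycle of the bubble).  Under
        this convention left-handed geometric winding of the sisters gives
        precatenane crossings of positive sign.
        """
        direction: dict[int, int] = {}
        if self.is_theta:
            starts = []
            for v in sorted(self.vertices):
                for k in range(3):
                    starts.append(("v", v, k))
        else:
            starts = sorted(self.slot_map())
        smap = self.slot_map()
        for start in starts:
            if start not in smap:
                continue
            if smap[start] in direction:
                continue
            flip = self.is_theta and self.arcs[smap[start]][2] == SISTER_B
            for aid, fr, _to in self.walk_strand(start):
                ea, _eb, _ = self.arcs[aid]
                fwd = 1 if fr == ea else -1
                direction[aid] = -fwd if flip else fwd
        return direction

    def crossing_sign(self, x: int, direction: dict[int, int] | None = None) -> int:
        """Sign of crossing ``x`` by the right-hand convention."""
        if direction is None:
            direction = self.orientation()
        smap = self.slot_map()

        def entering(k: int) -> bool:
            aid = smap[("x", x, k)]
            ea, eb, _ = self.arcs[aid]
            d = direction[aid]
            if ea == ("x", x, k):
                return d == -1
            return d == 1

        over = self.crossings[x]
        over_pair = (0, 2) if over == 0 else (1, 3)
        under_pair = (1, 3) if over == 0 else (0, 2)
        o_in = over_pair[0] if entering(over_pair[0]) else over_pair[1]
        u_in = under_pair[0] if entering(under_pair[0]) else under_pair[1]
        return 1 if (o_in - u_in) % 4 == 1 else -1

    def writhe(self, edge_subset: Iterable[str] | None = None) -> int:
        """Sum of crossing signs over crossings whose strands both lie in
        ``edge_subset`` (default: all crossings)."""
        subset = None if edge_subset is None else set(edge_subset)
        direction = self.orientation()
        smap = self.slot_map()
        total = 0
        for x in self.crossings:
            if subset is not None:
                labs = {self.arcs[smap[("x", x, k)]][2] for k in range(4)}
                if not labs <= subset:
                    continue
            total += self.crossing_sign(x, direction)
        return total

    # ------------------------------------------------------------------
    # edge deletion / constituents
    # ------------------------------------------------------------------
    def delete_edge(self, label: str) -> "PlanarDiagram":
        """Delete the arcs of one theta edge and smooth the two vertices,
        returning the knot diagram on the remaining pair of edges."""
        if not self.is_theta:
            raise ValueError("delete_edge requires a theta-curve diagram")
        labels = {lab for _, _, lab in self.arcs.values()}
        if label not in labels:
            raise KeyError(f"no edge labelled {label}")
        dead_arcs = {aid for aid, (_a, _b, lab) in self.arcs.items() if lab == label}
        smap = self.slot_map()

        # Decide fate of each crossing: drop (both strands dead) / smooth (one
        # strand dead) / keep.
        bonds: list[tuple[End, End]] = []  # pairs of surviving arc ends to glue
        dead_nodes: set[tuple[str, int]] = set()
        for x in sorted(self.crossings):
            s_dead = [smap[("x", x, k)] in dead_arcs for k in range(4)]
            strand02 = s_dead[0]  # label-constant: s_dead[0] == s_dead[2]
            strand13 = s_dead[1]
            if strand02 and strand13:
                dead_nodes.add(("x", x))
            elif strand02 or strand13:
                dead_nodes.add(("x", x))
                keep = (1, 3) if strand02 else (0, 2)
                bonds.append((("x", x, keep[0]), ("x", x, keep[1])))
        for v in sorted(self.vertices):
            dead_nodes.add(("v", v))
            keep_slots = [k for k in range(3) if smap[("v", v, k)] not in dead_arcs]
            if len(keep_slots) != 2:
                raise ValueError(f"vertex {v} does not touch edge {label} exactly once")
            bonds.append((("v", v, keep_slots[0]), ("v", v, keep_slots[1])))

        return self.glue(dead_arcs, dead_nodes, bonds, relabel=KNOT_LABEL)

    def glue(
        self,
        dead_arcs: set[int],
        dead_nodes: set[tuple[str, int]],
        bonds: list[tuple[End, End]],
        relabel: str | None = None,
    ) -> "PlanarDiagram":
        """Remove ``dead_nodes`` and ``dead_arcs``, splicing the surviving
        arcs along ``bonds`` (pairs of ends at removed nodes).  Chains keep
        the label of their first arc unless ``relabel`` is given."""
        smap = self.slot_map()
        bond_at: dict[End, End] = {}
        for e1, e2 in bonds:
            bond_at[e1] = e2
            bond_at[e2] = e1

        survivors = sorted(aid for aid in self.arcs if aid not in dead_arcs)
        new_arcs: dict[int, tuple[End, End, str]] = {}
        new_loops: dict[int, str] = {
            i: (relabel or lab) for i, lab in enumerate(sorted(self.loops.values()))
        }
        used: set[int] = set()

        def live(end: End) -> bool:
            return (end[0], end[1]) not in dead_nodes

        # open chains: walk from each live end to the opposite live end
        for aid in survivors:
            for end in self.arcs[aid][:2]:
                if aid in used or not live(end):
                    continue
                chain = [aid]
                cur_aid, cur_entry = aid, end
                while True:
                    other = self.other_end(cur_aid, cur_entry)
                    if live(other):
                        final = other
                        break
                    partner = bond_at[other]
                    cur_aid, cur_entry = smap[partner], partner
                    chain.append(cur_aid)
                used.update(chain)
                lab = relabel or self.arcs[chain[0]][2]
                new_arcs[min(chain)] = (end, final, lab)
        # closed chains (every end dead) become free loops
        for aid in survivors:
            if aid in used:
                continue
            start = (aid, self.arcs[aid][0])
            cur_aid, cur_entry = start
            while True:
                used.add(cur_aid)
                other = self.other_end(cur_aid, cur_entry)
                partner = bond_at[other]
                cur_aid, cur_entry = smap[partner], partner
                if (cur_aid, cur_entry) == start:
                    break
            lid = 0
            while lid in new_loops:
                lid += 1
            new_loops[lid] = relabel or self.arcs[aid][2]

        return PlanarDiagram(
            crossings={
                x: o for x, o in self.crossings.items() if ("x", x) not in dead_nodes
            },
            vertices={v for v in self.vertices if ("v", v) not in dead_nodes},
            arcs=new_arcs,
            loops=new_loops,
        )

    def constituents(self) -> dict[str, "PlanarDiagram"]:
        """The three constituent knots, keyed by the deleted edge label."""
        if not self.is_theta:
            raise ValueError("constituents requires a theta-curve diagram")
        return {lab: self.delete_edge(lab) for lab in THETA_LABELS}

    # ------------------------------------------------------------------
    # canonical renumbering & keys
    # ------------------------------------------------------------------
    def canonical(self) -> "PlanarDiagram":
        """Breadth-first renumbering from the lowest-id vertex (else
        crossing); defines syntactic diagram equality."""
        if not (self.vertices or self.crossings):
            loops = {i: lab for i, lab in enumerate(sorted(self.loops.values()))}
            return PlanarDiagram(loops=loops)
        if self.vertices:
            root = ("v", min(self.vertices))
        else:
            root = ("x", min(self.crossings))
        smap = self.slot_map()
        order: list[tuple[str, int]] = []
        seen = {root}
        queue = [root]
        while queue:
            kind, n = queue.pop(0)
            order.append((kind, n))
            for k in range(_deg(kind)):
                aid = smap[(kind, n, k)]
                oe = self.other_end(aid, (kind, n, k))
                nb = (oe[0], oe[1])
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        # unreached nodes (disconnected): append sorted
        for node in sorted(
            [("v", v) for v in self.vertices] + [("x", x) for x in self.crossings]
        ):
            if node not in seen:
                seen.add(node)
                order.append(node)
        vmap: dict[int, int] = {}
        xmap: dict[int, int] = {}
        for kind, n in order:
            if kind == "v":
                vmap[n] = len(vmap)
            else:
                xmap[n] = len(xmap)

        def remap(end: End) -> End:
            kind, n, k = end
            return (kind, vmap[n] if kind == "v" else xmap[n], k)

        tmp = []
        for aid, (ea, eb, lab) in self.arcs.items():
            na, nb = sorted((remap(ea), remap(eb)))
            tmp.append((na, nb, lab))
        tmp.sort()
        arcs = {i: t for i, t in enumerate(tmp)}
        loops = {i: lab for i, lab in enumerate(sorted(self.loops.values()))}
        return PlanarDiagram(
            crossings={xmap[x]: o for x, o in self.crossings.items()},
            vertices={vmap[v] for v in self.vertices},
            arcs=arcs,
            loops=loops,
        )

    def serialize(self) -> tuple:
        """Deterministic hashable form of this diagram (as numbered)."""
        return (
            tuple(sorted(self.crossings.items())),
            tuple(sorted(self.vertices)),
            tuple(sorted((min(a[:2]), max(a[:2]), a[2]) for a in self.arcs.values())),
            tuple(sorted(self.loops.values())),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlanarDiagram):
            return NotImplemented
        return self.canonical().serialize() == other.canonical().serialize()

    def __hash__(self) -> int:
        return hash(self.canonical().serialize())

    def canonical_key(self, labelled: bool = True) -> tuple:
        """Isomorphism-invariant key: minimum over all traversal roots and
        entry rotations of a relative encoding of the rotation system.

        Rotating a crossing's slot labels by one flips its over flag; the
        encoding stores flags relative to the entry slot so that equal maps
        produce equal keys regardless of slot numbering.
        """
        if not (self.vertices or self.crossings):
            return ("loops", tuple(sorted(self.loops.values())) if labelled else len(self.loops))
        # precomputed end -> (far end, label) adjacency
        partner: dict[End, tuple[End, str]] = {}
        for ea, eb, lab in self.arcs.values():
            partner[ea] = (eb, lab)
            partner[eb] = (ea, lab)
        # any isomorphism maps vertices to vertices, so when vertices
        # exist they suffice as traversal roots (a useful speedup)
        if self.vertices:
            nodes = [("v", v) for v in sorted(self.vertices)]
        else:
            nodes = [("x", x) for x in sorted(self.crossings)]
        crossings = self.crossings
        best: tuple | None = None
        for root in nodes:
            for rslot in range(_deg(root[0])):
                idx: dict[tuple[str, int], int] = {root: 0}
                entry: dict[tuple[str, int], int] = {root: rslot}
                queue = [root]
                code: list = []
                qi = 0
                while qi < len(queue):
                    kind, n = queue[qi]
                    qi += 1
                    base = entry[(kind, n)]
                    if kind == "x":
                        deg = 4
                        code.append((1, (crossings[n] - base) & 1))
                    else:
                        deg = 3
                        code.append((0,))
                    for dk in range(deg):
                        oe, lab = partner[(kind, n, (base + dk) % deg)]
                        nb = (oe[0], oe[1])
                        got = idx.get(nb)
                        if got is None:
                            got = idx[nb] = len(idx)
                            entry[nb] = oe[2]
                            queue.append(nb)
                        rel_slot = (oe[2] - entry[nb]) % (4 if oe[0] == "x" else 3)
                        code.append(
                            (got, rel_slot, lab) if labelled else (got, rel_slot)
                        )
                key = tuple(code)
                if best is None or key < best:
                    best = key
        loops = tuple(sorted(self.loops.values())) if labelled else len(self.loops)
        return (best, loops)

    def __repr__(self) -> str:
        kind = "theta" if self.is_theta else "knot"
        return (
            f"<PlanarDiagram {kind}: {len(self.crossings)} crossings, "
            f"{len(self.arcs)} arcs, {len(self.loops)} loops>"
        )
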