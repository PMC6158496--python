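"""Reidemeister moves I-V, the crossing-change operation, and a
deterministic simplification search.

Moves I-III are the classical knot-diagram moves; IV slides a strand
across a trivalent vertex (exchanging two crossings for one) and V twists
two adjacent edges at a vertex (one crossing).  A crossing change models a
single topoisomerase-mediated duplex-duplex passage and is the only
operation here that alters the underlying topology.

Every move is represented by a replayable :class:`MoveRecord`; applying a
record to the diagram it was enumerated on is deterministic, so move
sequences serve as certificates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .diagram import End, PlanarDiagram, _deg

REDUCING_KINDS = ("R1-", "R2-", "R4-", "R5-")
NEUTRAL_KINDS = ("R3",)
GROWING_KINDS = ("R1+", "R2+", "R4+", "R5+")
ALL_KINDS = REDUCING_KINDS + NEUTRAL_KINDS + GROWING_KINDS


@dataclass(frozen=True)
class MoveRecord:
    """One applicable move: ``kind`` plus a site tuple of ids."""

    kind: str
    site: tuple

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "site": list(self.site)}, separators=(",", ":"))

    @classmethod
    def from_json(cls, s: str) -> "MoveRecord":
        d = json.loads(s)
        return cls(d["kind"], tuple(tuple(x) if isinstance(x, list) else x for x in d["site"]))


class InapplicableMove(ValueError):
    pass


def _fresh_ids(d: PlanarDiagram, n: int) -> list[int]:
    """n distinct unused arc ids."""
    taken = set(d.arcs) | set(d.loops)
    out: list[int] = []
    i = 0
    while len(out) < n:
        if i not in taken:
            out.append(i)
            taken.add(i)
        i += 1
    return out


# ----------------------------------------------------------------------
# enumeration helpers
# ----------------------------------------------------------------------

def _strand_pair(k: int) -> tuple[int, int]:
    return (k % 2, k % 2 + 2)


def _is_over(d: PlanarDiagram, x: int, slot: int) -> bool:
    """Is the strand through ``slot`` the over-strand at crossing x?"""
    return d.crossings[x] == slot % 2


def _faces_with_darts(d: PlanarDiagram):
    return d.faces()


def _dart_ends(d: PlanarDiagram, dart: tuple[int, int]) -> tuple[End, End]:
    """(tail, head) ends of a dart."""
    aid, dr = dart
    ea, eb, _ = d.arcs[aid]
    return (ea, eb) if dr == 0 else (eb, ea)


# ----------------------------------------------------------------------
# individual move detection
# ----------------------------------------------------------------------

def _enum_r1_minus(d: PlanarDiagram, faces=None):
    out = []
    for aid, (ea, eb, _l) in sorted(d.arcs.items()):
        if ea[0] == "x" and eb[0] == "x" and ea[1] == eb[1]:
            x = ea[1]
            if (ea[2] - eb[2]) % 4 in (1, 3):  # adjacent slots: a monogon
                out.append(MoveRecord("R1-", (x,)))
    # deduplicate (one record per crossing)
    seen = set()
    uniq = []
    for m in out:
        if m.site not in seen:
            seen.add(m.site)
            uniq.append(m)
    return uniq


def _enum_r1_plus(d: PlanarDiagram, faces=None):
    out = []
    for aid in sorted(d.arcs):
        for over in (0, 1):
            out.append(MoveRecord("R1+", (aid, over)))
    for lid in sorted(d.loops):
        # kinking a free loop gives it its first crossing
        for over in (0, 1):
            out.append(MoveRecord("R1+", ("L", lid, over)))
    return out


def _bigon_faces(d: PlanarDiagram):
    """Faces of length 2 with their darts."""
    return [f for f in d.faces() if len(f) == 2]


def _enum_r2_minus(d: PlanarDiagram, faces=None):
    out = []
    faces = d.faces() if faces is None else faces
    for f in faces:
        if len(f) != 2:
            continue
        (a1, d1), (a2, d2) = f
        if a1 == a2:
            continue
        t1, h1 = _dart_ends(d, (a1, d1))
        t2, h2 = _dart_ends(d, (a2, d2))
        # bigon between two distinct crossings
        nodes = {(t1[0], t1[1]), (h1[0], h1[1])}
        if any(k != "x" for k, _ in nodes) or len(nodes) != 2:
            continue
        c1, c2 = t1[1], h1[1]
        # removable iff one arc's strand is over at both crossings
        ok = False
        for aid, tail, head in ((a1, t1, h1), (a2, t2, h2)):
            over_t = _is_over(d, tail[1], tail[2])
            over_h = _is_over(d, head[1], head[2])
            if over_t == over_h:
                ok = True
        if not ok:
            continue
        k1 = min(t1[2] if t1[1] == min(c1, c2) else h1[2],
                 t2[2] if t2[1] == min(c1, c2) else h2[2])
        out.append(MoveRecord("R2-", (min(c1, c2), max(c1, c2), k1)))
    seen = set()
    uniq = []
    for m in sorted(out, key=lambda m: m.site):
        if m.site not in seen:
            seen.add(m.site)
            uniq.append(m)
    return uniq


def _enum_r2_plus(d: PlanarDiagram, faces=None):
    out = []
    for f in (d.faces() if faces is None else faces):
        for i, (a1, d1) in enumerate(f):
            for j, (a2, d2) in enumerate(f):
                if i == j or a1 == a2:
                    continue
                for over in (0, 1):
                    out.append(MoveRecord("R2+", (a1, d1, a2, d2, over)))
    return sorted(out, key=lambda m: m.site)


def _triangle_info(d: PlanarDiagram, face):
    """Classify a 3-dart face: all-crossing triangle (R3) or
    two-crossings-plus-vertex (R4)."""
    ends = [_dart_ends(d, dart) for dart in face]
    nodes = [(e[0][0], e[0][1]) for e in ends]  # tail nodes
    return ends, nodes


def _enum_r3(d: PlanarDiagram, faces=None):
    out = []
    for f in (d.faces() if faces is None else faces):
        if len(f) != 3:
            continue
        arcs = [dart[0] for dart in f]
        if len(set(arcs)) != 3:
            continue
        ends, _ = _triangle_info(d, f)
        nodes = {(e[0], e[1]) for pair in ends for e in pair}
        if len(nodes) != 3 or any(k != "x" for k, _ in nodes):
            continue
        # candidate sliders: arc over at both its crossings or under at both
        for dart, (tail, head) in zip(f, ends):
            o_t = _is_over(d, tail[1], tail[2])
            o_h = _is_over(d, head[1], head[2])
            if o_t == o_h:
                out.append(MoveRecord("R3", dart))
    return sorted(out, key=lambda m: m.site)


def _enum_r4_minus(d: PlanarDiagram, faces=None):
    out = []
    for f in (d.faces() if faces is None else faces):
        if len(f) != 3:
            continue
        ends = [_dart_ends(d, dart) for dart in f]
        kinds = [(e[0][0], e[1][0]) for e in ends]  # (tail kind, head kind)
        # pattern: t: x->x, e2': x->v, e1': v->x (in face cyclic order)
        for r in range(3):
            t_i, p_i, q_i = r, (r + 1) % 3, (r + 2) % 3
            if kinds[t_i] == ("x", "x") and kinds[p_i] == ("x", "v") and kinds[q_i] == ("v", "x"):
                tail, head = ends[t_i]
                o_t = _is_over(d, tail[1], tail[2])
                o_h = _is_over(d, head[1], head[2])
                if o_t == o_h and len({tail[1], head[1]}) == 2:
                    # moving strand passes over (or under) both edges
                    out.append(MoveRecord("R4-", f[t_i]))
    return sorted(out, key=lambda m: m.site)


def _enum_r4_plus(d: PlanarDiagram, faces=None):
    out = []
    for aid, (ea, eb, _l) in sorted(d.arcs.items()):
        for e1, e2 in ((ea, eb), (eb, ea)):
            if e1[0] == "v" and e2[0] == "x":
                out.append(MoveRecord("R4+", (e1[1], aid)))
    seen = set()
    uniq = []
    for m in out:
        if m.site not in seen:
            seen.add(m.site)
            uniq.append(m)
    return uniq


def _enum_r5_plus(d: PlanarDiagram, faces=None):
    out = []
    for v in sorted(d.vertices):
        for i in range(3):
            for over in (0, 1):
                out.append(MoveRecord("R5+", (v, i, over)))
    return out


def _enum_r5_minus(d: PlanarDiagram, faces=None):
    out = []
    for f in (d.faces() if faces is None else faces):
        if len(f) != 2:
            continue
        (a1, d1), (a2, d2) = f
        ends = {e for dart in f for e in _dart_ends(d, dart)}
        nodes = {(e[0], e[1]) for e in ends}
        kindset = sorted(k for k, _ in nodes)
        if len(nodes) == 2 and kindset == ["v", "x"]:
            v = next(n for k, n in nodes if k == "v")
            x = next(n for k, n in nodes if k == "x")
            k = min(e[2] for e in ends if e[0] == "v")
            out.append(MoveRecord("R5-", (v, x, k)))
    seen = set()
    uniq = []
    for m in sorted(out, key=lambda m: m.site):
        if m.site not in seen:
            seen.add(m.site)
            uniq.append(m)
    return uniq


_ENUMERATORS = {
    "R1-": _enum_r1_minus,
    "R1+": _enum_r1_plus,
    "R2-": _enum_r2_minus,
    "R2+": _enum_r2_plus,
    "R3": _enum_r3,
    "R4-": _enum_r4_minus,
    "R4+": _enum_r4_plus,
    "R5-": _enum_r5_minus,
    "R5+": _enum_r5_plus,
}


def enumerate_moves(d: PlanarDiagram, kinds: Iterable[str] | None = None) -> list[MoveRecord]:
    """All applicable moves of the requested kinds, in deterministic
    (kind, site) order."""
    kinds = tuple(kinds) if kinds is not None else ALL_KINDS
    out: list[MoveRecord] = []
    faces = None
    if any(k in ("R2-", "R2+", "R3", "R4-", "R5-") for k in kinds):
        faces = d.faces()
    for k in kinds:
        if k == "X":
            out.extend(MoveRecord("X", (x,)) for x in sorted(d.crossings))
            continue
        found = _ENUMERATORS[k](d, faces)
        if k in ("R3", "R4+", "R4-", "R5+", "R5-"):
            # guard against degenerate sites (e.g. a strand that is itself
            # the edge it would slide across)
            kept = []
            for m in found:
                try:
                    _APPLIERS[k](d, m.site)
                except InapplicableMove:
                    continue
                kept.append(m)
            found = kept
        out.extend(found)
    return sorted(out, key=lambda m: (m.kind, m.site))


# ----------------------------------------------------------------------
# application
# ----------------------------------------------------------------------

def crossing_change(d: PlanarDiagram, crossing_id: int) -> PlanarDiagram:
    """Flip over/under at one crossing (a single strand passage)."""
    if crossing_id not in d.crossings:
        raise KeyError(f"no crossing {crossing_id}")
    out = d.copy()
    out.crossings[crossing_id] = 1 - out.crossings[crossing_id]
    return out


def _apply_r1_minus(d: PlanarDiagram, site) -> PlanarDiagram:
    (x,) = site
    smap = d.slot_map()
    mono = None
    for k in range(4):
        aid = smap[("x", x, k)]
        ea, eb, _l = d.arcs[aid]
        if {ea, eb} == {("x", x, k), ("x", x, (k + 1) % 4)}:
            mono = (aid, k)
            break
    if mono is None:
        raise InapplicableMove(f"no monogon at crossing {x}")
    aid, k = mono
    bonds = [(("x", x, (k + 2) % 4), ("x", x, (k + 3) % 4))]
    return d.glue({aid}, {("x", x)}, bonds)


def _apply_r1_plus(d: PlanarDiagram, site) -> PlanarDiagram:
    if site[0] == "L":
        _tag, lid, over = site
        if lid not in d.loops:
            raise InapplicableMove(f"no loop {lid}")
        out = d.copy()
        lab = out.loops.pop(lid)
        x = out.fresh_crossing_id()
        out.crossings[x] = over
        a1, a2 = _fresh_ids(out, 2)
        out.arcs[a1] = (("x", x, 2), ("x", x, 1), lab)
        out.arcs[a2] = (("x", x, 3), ("x", x, 0), lab)
        return out
    aid, over = site
    if aid not in d.arcs:
        raise InapplicableMove(f"no arc {aid}")
    out = d.copy()
    ea, eb, lab = out.arcs.pop(aid)
    x = out.fresh_crossing_id()
    out.crossings[x] = over
    a1 = out.fresh_arc_id()
    out.arcs[a1] = (ea, ("x", x, 0), lab)
    a2 = out.fresh_arc_id()
    out.arcs[a2] = (("x", x, 2), ("x", x, 1), lab)
    a3 = out.fresh_arc_id()
    out.arcs[a3] = (("x", x, 3), eb, lab)
    return out


def _apply_r2_minus(d: PlanarDiagram, site) -> PlanarDiagram:
    c1, c2, _k1 = site
    for x in (c1, c2):
        if x not in d.crossings:
            raise InapplicableMove(f"no crossing {x}")
    # verify a removable bigon exists between c1 and c2
    found = False
    for m in _enum_r2_minus(d):
        if m.site == site:
            found = True
    if not found:
        raise InapplicableMove(f"no removable bigon between {c1},{c2}")
    bonds = []
    for x in (c1, c2):
        bonds.append((("x", x, 0), ("x", x, 2)))
        bonds.append((("x", x, 1), ("x", x, 3)))
    return d.glue(set(), {("x", c1), ("x", c2)}, bonds)


def _apply_r2_plus(d: PlanarDiagram, site) -> PlanarDiagram:
    a1, d1, a2, d2, over = site
    if a1 not in d.arcs or a2 not in d.arcs or a1 == a2:
        raise InapplicableMove("bad R2+ site")
    # both darts must lie on one face
    target = None
    for f in d.faces():
        if (a1, d1) in f and (a2, d2) in f:
            target = f
            break
    if target is None:
        raise InapplicableMove("darts not on a common face")
    out = d.copy()
    P, Q = _dart_ends(d, (a1, d1))
    R, S = _dart_ends(d, (a2, d2))
    lab1 = d.arcs[a1][2]
    lab2 = d.arcs[a2][2]
    del out.arcs[a1], out.arcs[a2]
    c = out.fresh_crossing_id()
    cc = c + 1
    # finger of a1 pushed into the face (to the right of dart d1) across a2.
    # both new crossings: slots 0=E,1=N,2=W,3=S with the a1-finger on (1,3)
    # and a2 on (0,2); a2 runs R->S entering crossing cc then c.
    out.crossings[c] = 1 if over else 0
    out.crossings[cc] = 1 if over else 0
    aA, aB, aC, aD, aE, aF = _fresh_ids(out, 6)
    out.arcs[aA] = (P, ("x", c, 1), lab1)
    out.arcs[aB] = (("x", c, 3), ("x", cc, 3), lab1)
    out.arcs[aC] = (("x", cc, 1), Q, lab1)
    out.arcs[aD] = (R, ("x", cc, 0), lab2)
    out.arcs[aE] = (("x", cc, 2), ("x", c, 0), lab2)
    out.arcs[aF] = (("x", c, 2), S, lab2)
    return out


def _apply_r3(d: PlanarDiagram, site) -> PlanarDiagram:
    dart = tuple(site)
    face = None
    for f in d.faces():
        if dart in f:
            face = f
            break
    if face is None or len(face) != 3:
        raise InapplicableMove("R3 site is not on a triangle face")
    r = face.index(dart)
    face = face[r:] + face[:r]
    if MoveRecord("R3", face[0]) not in _enum_r3(d):
        raise InapplicableMove("R3 over/under pattern not satisfied")
    # internal ends: s: c1->c2, p: c2->c3, q: c3->c1
    (s_t, s_h) = _dart_ends(d, face[0])
    (p_t, p_h) = _dart_ends(d, face[1])
    (q_t, q_h) = _dart_ends(d, face[2])
    out = d.copy()

    def ext_end(e: End) -> End:
        return ("x", e[1], (e[2] + 2) % 4)

    # for each strand, swap the attachments of its two external ends
    swaps = [
        (ext_end(s_t), ext_end(s_h)),  # strand S externals at c1, c2
        (ext_end(p_t), ext_end(p_h)),  # strand P externals at c2, c3
        (ext_end(q_t), ext_end(q_h)),  # strand Q externals at c3, c1
    ]
    smap = d.slot_map()
    repl: dict[tuple[int, End], End] = {}
    for e1, e2 in swaps:
        x1, x2 = smap[e1], smap[e2]
        repl[(x1, e1)] = e2
        repl[(x2, e2)] = e1
    new_arcs = dict(out.arcs)
    for (aid, old), new in repl.items():
        ea, eb, lab = new_arcs[aid]
        if ea == old:
            new_arcs[aid] = (new, eb, lab)
        elif eb == old:
            new_arcs[aid] = (ea, new, lab)
        else:
            raise InapplicableMove("inconsistent R3 externals")
    out.arcs = new_arcs
    return out


def _apply_r4_minus(d: PlanarDiagram, site) -> PlanarDiagram:
    dart = tuple(site)
    face = None
    for f in d.faces():
        if dart in f:
            face = f
            break
    if face is None or len(face) != 3:
        raise InapplicableMove("R4- site is not on a triangle face")
    r = face.index(dart)
    face = face[r:] + face[:r]
    (t_t, t_h) = _dart_ends(d, face[0])   # T strand arc: c1 -> c2
    (p_t, p_h) = _dart_ends(d, face[1])   # edge2 arc: c2 -> v
    (q_t, q_h) = _dart_ends(d, face[2])   # edge1 arc: v -> c1
    if not (t_t[0] == "x" and t_h[0] == "x" and p_h[0] == "v" and q_t[0] == "v"):
        raise InapplicableMove("R4- pattern mismatch")
    c1, c2, v = t_t[1], t_h[1], p_h[1]
    over_T = _is_over(d, c1, t_t[2])
    if over_T != _is_over(d, c2, t_h[2]):
        raise InapplicableMove("strand not over/under both edges")
    smap = d.slot_map()
    # vertex slots: e2 head at (v,k); e1 departs at (v,k+1); e3 at (v,k+2)
    k = p_h[2]
    if q_t != ("v", v, (k + 1) % 3):
        raise InapplicableMove("vertex corner mismatch")
    slot_e3 = ("v", v, (k + 2) % 3)
    labT = d.arcs[face[0][0]][2]
    t_arc = face[0][0]
    # glue away c1, c2 (merging T, edge1 and edge2 with their externals)
    dead = {("x", c1), ("x", c2)}
    bonds = []
    for x in (c1, c2):
        bonds.append((("x", x, 0), ("x", x, 2)))
        bonds.append((("x", x, 1), ("x", x, 3)))
    chain_ids = _chain_ids_through(d, t_arc, dead, bonds)
    # identify the surviving ends of T on each side: the side beyond c2
    # (the crossing on edge1) attaches to the new crossing's slot 1 and
    # the side beyond c1 to slot 3 (see the wiring derivation in docs)
    T_closed = False
    try:
        top_live = _live_end_from(d, ("x", c2, (t_h[2] + 2) % 4), dead, bonds)
        bottom_live = _live_end_from(d, ("x", c1, (t_t[2] + 2) % 4), dead, bonds)
    except _ClosedChain:
        T_closed = True
    out = d.glue(set(), dead, bonds)
    smap2 = out.slot_map()
    e3_id = smap2[slot_e3]
    e3_far = out.other_end(e3_id, slot_e3)
    lab3 = out.arcs[e3_id][2]
    T_id = min(chain_ids)
    if not T_closed and T_id == e3_id:
        raise InapplicableMove("moving strand is the third edge itself")
    c = out.fresh_crossing_id()
    out.crossings[c] = 1 if over_T else 0
    # T passes through (1,3); e3 through (0,2) with near-v side at slot 2
    del out.arcs[e3_id]
    aT1, aT2, aN, aF = _fresh_ids(out, 4)
    if T_closed:
        # glue renumbers pre-existing loops to 0..n-1; the loop formed from
        # T is the appended one
        lid = max(i for i in out.loops if i >= len(d.loops))
        del out.loops[lid]
        out.arcs[aT1] = (("x", c, 1), ("x", c, 3), labT)
    else:
        out.arcs.pop(T_id)
        out.arcs[aT1] = (top_live, ("x", c, 1), labT)
        out.arcs[aT2] = (("x", c, 3), bottom_live, labT)
    out.arcs[aN] = (slot_e3, ("x", c, 2), lab3)
    out.arcs[aF] = (("x", c, 0), e3_far, lab3)
    return out


class _ClosedChain(Exception):
    pass


def _live_end_from(d: PlanarDiagram, end: End, dead_nodes, bonds) -> End:
    """Follow the strand leaving dead-node slot ``end`` through the glue
    bonds until a surviving arc end is reached."""
    smap = d.slot_map()
    bond_at = {}
    for e1, e2 in bonds:
        bond_at[e1] = e2
        bond_at[e2] = e1
    aid = smap[end]
    cur = d.other_end(aid, end)
    hops = 0
    while (cur[0], cur[1]) in dead_nodes:
        partner = bond_at[cur]
        aid = smap[partner]
        cur = d.other_end(aid, partner)
        hops += 1
        if hops > 2 * len(d.arcs) + 4:
            raise _ClosedChain
    return cur


def _chain_ids_through(d: PlanarDiagram, aid: int, dead_nodes, bonds) -> set[int]:
    """Arc ids that glue(dead_nodes, bonds) would merge with ``aid``."""
    smap = d.slot_map()
    bond_at = {}
    for e1, e2 in bonds:
        bond_at[e1] = e2
        bond_at[e2] = e1
    chain = {aid}
    for end0 in d.arcs[aid][:2]:
        cur_aid, cur_end = aid, end0
        hops = 0
        while (cur_end[0], cur_end[1]) in dead_nodes:
            partner = bond_at[cur_end]
            cur_aid = smap[partner]
            chain.add(cur_aid)
            cur_end = d.other_end(cur_aid, partner)
            hops += 1
            if hops > 2 * len(d.arcs) + 4:  # closed chain
                break
    return chain


def _apply_r4_plus(d: PlanarDiagram, site) -> PlanarDiagram:
    v, near_aid = site
    if near_aid not in d.arcs:
        raise InapplicableMove("no such arc")
    ea, eb, _lab = d.arcs[near_aid]
    if ea[0] == "v" and ea[1] == v and eb[0] == "x":
        v_end, c_end = ea, eb
    elif eb[0] == "v" and eb[1] == v and ea[0] == "x":
        v_end, c_end = eb, ea
    else:
        raise InapplicableMove("arc does not join the vertex to a crossing")
    c, w, a = c_end[1], c_end[2], v_end[2]
    over_T = not _is_over(d, c, w)  # T is the other strand at c
    smap = d.slot_map()
    # local slots at c: e3-near = w, e3-far = w+2, T-up = w+3, T-down = w+1
    labT = d.arcs[smap[("x", c, (w + 1) % 4)]][2]
    dead = {("x", c)}
    bonds = [(("x", c, 0), ("x", c, 2)), (("x", c, 1), ("x", c, 3))]
    T_chain = _chain_ids_through(d, smap[("x", c, (w + 1) % 4)], dead, bonds)
    T_closed0 = False
    try:
        top_live = _live_end_from(d, ("x", c, (w + 3) % 4), dead, bonds)
        bottom_live = _live_end_from(d, ("x", c, (w + 1) % 4), dead, bonds)
    except _ClosedChain:
        T_closed0 = True
    # step 1: smooth the crossing c away entirely (merging T and e3)
    out = d.glue(set(), dead, bonds)
    smap2 = out.slot_map()
    s_e1 = ("v", v, (a + 1) % 3)
    s_e2 = ("v", v, (a + 2) % 3)
    e1_id = smap2[s_e1]
    e2_id = smap2[s_e2]
    T_id = min(T_chain)
    T_closed = T_id not in out.arcs or T_closed0
    if not T_closed and T_id in (e1_id, e2_id):
        raise InapplicableMove("moving strand coincides with a vertex edge")
    e1_far = out.other_end(e1_id, s_e1)
    e2_far = out.other_end(e2_id, s_e2)
    lab1 = out.arcs[e1_id][2]
    lab2 = out.arcs[e2_id][2]
    # step 2: re-cross T over edges e1 and e2 next to the vertex
    c1 = out.fresh_crossing_id()
    c2 = c1 + 1
    out.crossings[c1] = 0 if over_T else 1   # T on (0,2) at c1
    out.crossings[c2] = 1 if over_T else 0   # T on (1,3) at c2
    merged_e = e1_id == e2_id
    for x in {e1_id, e2_id}:
        del out.arcs[x]
    if T_closed:
        lid = max(i for i in out.loops if i >= len(d.loops))
        del out.loops[lid]
    else:
        out.arcs.pop(T_id)
    a_t, a_t1, a_t2, a_e1n, a_e1f, a_e2n, a_e2f = _fresh_ids(out, 7)
    # T: bottom_live -> c2 -> t -> c1 -> top_live
    out.arcs[a_t] = (("x", c2, 1), ("x", c1, 2), labT)
    if T_closed:
        out.arcs[a_t1] = (("x", c1, 0), ("x", c2, 3), labT)
    else:
        out.arcs[a_t1] = (("x", c1, 0), top_live, labT)
        out.arcs[a_t2] = (("x", c2, 3), bottom_live, labT)
    out.arcs[a_e1n] = (s_e1, ("x", c1, 3), lab1)
    out.arcs[a_e2n] = (s_e2, ("x", c2, 0), lab2)
    if merged_e:
        # one arc ran from (v,a+1) straight to (v,a+2); its middle now
        # passes both new crossings
        out.arcs[a_e1f] = (("x", c1, 1), ("x", c2, 2), lab1)
    else:
        out.arcs[a_e1f] = (("x", c1, 1), e1_far, lab1)
        out.arcs[a_e2f] = (("x", c2, 2), e2_far, lab2)
    return out


def _apply_r5_plus(d: PlanarDiagram, site) -> PlanarDiagram:
    v, i, over = site
    if v not in d.vertices:
        raise InapplicableMove("no such vertex")
    smap = d.slot_map()
    s_i = ("v", v, i)
    s_j = ("v", v, (i + 1) % 3)
    ai = smap[s_i]
    aj = smap[s_j]
    X = d.other_end(ai, s_i)
    Y = d.other_end(aj, s_j)
    lab_i = d.arcs[ai][2]
    lab_j = d.arcs[aj][2]
    out = d.copy()
    if ai == aj:
        raise InapplicableMove("cannot twist an edge with itself")
    del out.arcs[ai], out.arcs[aj]
    c = out.fresh_crossing_id()
    # strand to X on (0,2); strand to Y on (1,3); over=1 puts edge i over
    out.crossings[c] = 0 if over else 1
    b1, b2, b3, b4 = _fresh_ids(out, 4)
    out.arcs[b1] = (s_j, ("x", c, 2), lab_i)
    out.arcs[b2] = (("x", c, 0), X, lab_i)
    out.arcs[b3] = (s_i, ("x", c, 3), lab_j)
    out.arcs[b4] = (("x", c, 1), Y, lab_j)
    return out


def _apply_r5_minus(d: PlanarDiagram, site) -> PlanarDiagram:
    v, x, _k = site
    if v not in d.vertices or x not in d.crossings:
        raise InapplicableMove("bad R5- site")
    if MoveRecord("R5-", tuple(site)) not in _enum_r5_minus(d):
        raise InapplicableMove("no vertex-crossing bigon")
    smap = d.slot_map()
    varcs = []
    for k in range(3):
        aid = smap[("v", v, k)]
        other = d.other_end(aid, ("v", v, k))
        if other[0] == "x" and other[1] == x:
            varcs.append((k, aid, other))
    if len(varcs) != 2:
        raise InapplicableMove("vertex and crossing not doubly connected")
    (k1, a1, o1), (k2, a2, o2) = varcs
    bonds = [(("x", x, 0), ("x", x, 2)), (("x", x, 1), ("x", x, 3))]
    out = d.glue(set(), {("x", x)}, bonds)
    # undo the slot swap at the vertex: the two surviving arcs at
    # (v,k1),(v,k2) exchange their vertex attachments
    smap2 = out.slot_map()
    b1 = smap2[("v", v, k1)]
    b2 = smap2[("v", v, k2)]
    def reattach(aid, old, new):
        ea, eb, lab = out.arcs[aid]
        if ea == old:
            out.arcs[aid] = (new, eb, lab)
        else:
            out.arcs[aid] = (ea, new, lab)
    if b1 == b2:
        # both ends of the same arc at v: swapping is a no-op topologically
        return out
    tmp = ("v", v, k1)
    reattach(b1, ("v", v, k1), ("v", v, k2))
    reattach(b2, ("v", v, k2), tmp)
    return out


def _apply_x(d: PlanarDiagram, site) -> PlanarDiagram:
    (x,) = site
    return crossing_change(d, x)


_APPLIERS = {
    "R1-": _apply_r1_minus,
    "R1+": _apply_r1_plus,
    "R2-": _apply_r2_minus,
    "R2+": _apply_r2_plus,
    "R3": _apply_r3,
    "R4-": _apply_r4_minus,
    "R4+": _apply_r4_plus,
    "R5-": _apply_r5_minus,
    "R5+": _apply_r5_plus,
    "X": _apply_x,
}


def apply_move(d: PlanarDiagram, m: MoveRecord) -> PlanarDiagram:
    """Apply one move; raises :class:`InapplicableMove` if the site does
    not support it."""
    try:
        out = _APPLIERS[m.kind](d, m.site)
    except KeyError as exc:
        raise InapplicableMove(f"unknown move or stale site: {m}") from exc
    return out


def replay(d: PlanarDiagram, seq: Sequence[MoveRecord]) -> PlanarDiagram:
    """Apply a recorded move sequence."""
    for m in seq:
        d = apply_move(d, m)
    return d


# ----------------------------------------------------------------------
# simplification
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Budget:
    """Search budget for :func:`simplify`.

    depth: BFS depth over crossing-neutral/expanding detours.
    slack: transient crossing growth allowed above the best-known count.
    max_states: hard cap on explored states (determinism-preserving).
    stop_at: return as soon as a diagram with at most this many
        crossings is reached (0 always stops the search).
    """

    depth: int = 8
    slack: int = 2
    max_states: int = 4000
    stop_at: int = 0


def _greedy_reduce(d: PlanarDiagram) -> tuple[PlanarDiagram, list[MoveRecord]]:
    trace: list[MoveRecord] = []
    while True:
        moves = enumerate_moves(d, REDUCING_KINDS)
        if not moves:
            return d, trace
        m = moves[0]
        d = apply_move(d, m)
        trace.append(m)


def simplify(d: PlanarDiagram, budget: Budget | None = None) -> tuple[PlanarDiagram, list[MoveRecord]]:
    """Deterministic crossing-minimizing search.

    Applies reducing moves (R1-, R2-, R4-, R5-) to a fixed point, then a
    bounded breadth-first search over R3/R5/R4 detours with limited R2+
    slack; ties broken by canonical form.  Never returns a diagram with
    more crossings than the input.
    """
    budget = budget or Budget()
    start, trace0 = _greedy_reduce(d)
    best = (start.n_crossings, start.canonical().serialize())
    best_state = (start, list(trace0))
    if start.n_crossings <= budget.stop_at:
        return best_state
    seen = {start.canonical_key()}
    frontier: list[tuple[PlanarDiagram, list[MoveRecord]]] = [(start, list(trace0))]
    states = 1
    detour_kinds = ("R3", "R5-", "R5+", "R4-", "R4+", "R2+")
    for _depth in range(budget.depth):
        nxt: list[tuple[PlanarDiagram, list[MoveRecord]]] = []
        for cur, trace in frontier:
            for m in enumerate_moves(cur, detour_kinds):
                if states >= budget.max_states:
                    break
                try:
                    stepped = apply_move(cur, m)
                except InapplicableMove:
                    continue
                if stepped.n_crossings > best_state[0].n_crossings + budget.slack:
                    continue
                red, rtrace = _greedy_reduce(stepped)
                if red.n_crossings <= budget.stop_at:
                    return red, trace + [m] + rtrace
                key = red.canonical_key()
                if key in seen:
                    continue
                seen.add(key)
                states += 1
                path = trace + [m] + rtrace
                cand = (red.n_crossings, red.canonical().serialize())
                if cand < best:
                    best = cand
                    best_state = (red, path)
                nxt.append((red, path))
            if states >= budget.max_states:
                break
        frontier = nxt
        if not frontier or states >= budget.max_states:
            break
    return best_state
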