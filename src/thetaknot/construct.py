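"""Parametric constructions of knot and theta-curve diagrams.

Every prime knot with at most seven crossings is a 2-bridge (rational)
knot, so the knot catalog is generated exactly from continued-fraction
twist diagrams (numerator closures of rational tangles).  Theta-curves are
built either by splicing two trivalent vertices and an extra edge into a
knot diagram ("thetafication") or by the replication-intermediate builder
in :mod:`thetaknot.ri_model`.
"""

from __future__ import annotations

from .diagram import (
    KNOT_LABEL,
    SISTER_A,
    SISTER_B,
    THETA_LABELS,
    UNREPLICATED,
    End,
    PlanarDiagram,
)


# ----------------------------------------------------------------------
# elementary diagrams
# ----------------------------------------------------------------------

def unknot() -> PlanarDiagram:
    """The 0-crossing unknot (one free loop)."""
    return PlanarDiagram(loops={0: KNOT_LABEL})


def trivial_theta() -> PlanarDiagram:
    """The planar theta-curve: two vertices, three parallel edges.

    Vertex slots counterclockwise; with v0 on the left and v1 on the
    right the bottom edge occupies (v0,0)-(v1,2), middle (v0,1)-(v1,1),
    top (v0,2)-(v1,0).
    """
    return PlanarDiagram(
        vertices={0, 1},
        arcs={
            0: (("v", 0, 0), ("v", 1, 2), UNREPLICATED),
            1: (("v", 0, 1), ("v", 1, 1), SISTER_B),
            2: (("v", 0, 2), ("v", 1, 0), SISTER_A),
        },
    )


# ----------------------------------------------------------------------
# rational tangles
# ----------------------------------------------------------------------

class _TangleBuilder:
    """Incremental 4-ended tangle with NW/NE/SW/SE corners.

    Crossing slots are counterclockwise 0=NE, 1=NW, 2=SW, 3=SE, so the
    two strands occupy the diagonals (0,2) and (1,3).
    """

    def __init__(self) -> None:
        self.d = PlanarDiagram()
        # loose pieces: id -> [attachment, attachment]; attachment is
        # ("end", End) or ("corner", name)
        self.pieces: dict[int, list] = {
            0: [("corner", "NW"), ("corner", "NE")],
            1: [("corner", "SW"), ("corner", "SE")],
        }
        self._next_piece = 2

    def _piece_of(self, corner: str) -> tuple[int, int]:
        for pid, atts in self.pieces.items():
            for i, att in enumerate(atts):
                if att == ("corner", corner):
                    return pid, i
        raise KeyError(corner)

    def _bind(self, corner: str, end: End) -> None:
        pid, i = self._piece_of(corner)
        self.pieces[pid][i] = ("end", end)
        self._collapse(pid)

    def _collapse(self, pid: int) -> None:
        a, b = self.pieces[pid]
        if a[0] == "end" and b[0] == "end":
            aid = self.d.fresh_arc_id()
            self.d.arcs[aid] = (a[1], b[1], KNOT_LABEL)
            del self.pieces[pid]

    def _open(self, corner: str, end: End) -> None:
        pid = self._next_piece
        self._next_piece += 1
        self.pieces[pid] = [("end", end), ("corner", corner)]

    def twist_bottom(self, over: int) -> None:
        """One crossing between the SW and SE strands (appended below)."""
        x = self.d.fresh_crossing_id()
        self.d.crossings[x] = over
        self._bind("SW", ("x", x, 1))
        self._bind("SE", ("x", x, 0))
        self._open("SW", ("x", x, 2))
        self._open("SE", ("x", x, 3))

    def twist_right(self, over: int) -> None:
        """One crossing between the NE and SE strands (appended right)."""
        x = self.d.fresh_crossing_id()
        self.d.crossings[x] = over
        self._bind("NE", ("x", x, 1))
        self._bind("SE", ("x", x, 2))
        self._open("NE", ("x", x, 0))
        self._open("SE", ("x", x, 3))

    def _join(self, c1: str, c2: str) -> None:
        p1, i1 = self._piece_of(c1)
        p2, i2 = self._piece_of(c2)
        if p1 == p2:
            lid = 0
            while lid in self.d.loops:
                lid += 1
            self.d.loops[lid] = KNOT_LABEL
            del self.pieces[p1]
            return
        other1 = self.pieces[p1][1 - i1]
        other2 = self.pieces[p2][1 - i2]
        del self.pieces[p1], self.pieces[p2]
        pid = self._next_piece
        self._next_piece += 1
        self.pieces[pid] = [other1, other2]
        if other1[0] == "end" and other2[0] == "end":
            self._collapse(pid)

    def numerator_closure(self) -> PlanarDiagram:
        """Join NW-NE and SW-SE."""
        self._join("NW", "NE")
        self._join("SW", "SE")
        assert not self.pieces, f"unclosed pieces remain: {self.pieces}"
        return self.d


def _odd_length_cf(cf: list[int]) -> list[int]:
    """Equivalent continued fraction of odd length (tangle canonical form
    needs the outermost and innermost twist blocks both horizontal)."""
    cf = list(cf)
    if len(cf) % 2 == 0:
        if cf[-1] == 1:
            cf = cf[:-2] + [cf[-2] + 1]
        else:
            cf = cf[:-1] + [cf[-1] - 1, 1]
    return cf


def rational_knot(cf: list[int], flip: bool = False) -> PlanarDiagram:
    """Alternating diagram of the 2-bridge knot with continued fraction
    ``cf`` = [a1, a2, ...] meaning a1 + 1/(a2 + 1/(...)).

    All entries must be positive; the diagram has sum(cf) crossings and is
    reduced alternating (hence minimal).  ``flip=True`` builds the mirror.
    """
    if not cf or any(a <= 0 for a in cf):
        raise ValueError("continued fraction entries must be positive")
    seq = list(reversed(_odd_length_cf(cf)))
    tb = _TangleBuilder()
    for i, a in enumerate(seq):
        pos = len(seq) - 1 - i  # 0 = outermost block (a1)
        horizontal = pos % 2 == 0  # odd length: innermost is horizontal too
        for _ in range(a):
            if horizontal:
                tb.twist_right(0 if not flip else 1)
            else:
                tb.twist_bottom(0 if not flip else 1)
    return tb.numerator_closure()


def continued_fraction_value(cf: list[int]) -> tuple[int, int]:
    """(p, q) with p/q = a1 + 1/(a2 + ...)."""
    p, q = cf[-1], 1
    for a in reversed(cf[:-1]):
        p, q = a * p + q, p
    return p, q


# ----------------------------------------------------------------------
# thetafication
# ----------------------------------------------------------------------

def insert_vertex_on_dart(d: PlanarDiagram, dart: tuple[int, int]) -> tuple[PlanarDiagram, int]:
    """Split the arc of ``dart`` with a new trivalent vertex whose free
    slot (slot 2) opens into the face to the right of the dart.

    Vertex slots counterclockwise: 0 = outgoing (dart direction),
    1 = incoming, 2 = free (to the right of travel).
    Returns (new diagram, vertex id).
    """
    aid, dr = dart
    ea, eb, lab = d.arcs[aid]
    tail, head = (ea, eb) if dr == 0 else (eb, ea)
    out = d.copy()
    v = max(out.vertices, default=-1) + 1
    out.vertices.add(v)
    del out.arcs[aid]
    a1 = out.fresh_arc_id()
    out.arcs[a1] = (tail, ("v", v, 1), lab)
    a2 = out.fresh_arc_id()
    out.arcs[a2] = (("v", v, 0), head, lab)
    return out, v


def thetafy(
    d: PlanarDiagram,
    dart1: tuple[int, int],
    dart2: tuple[int, int],
    first_label: str = SISTER_A,
) -> PlanarDiagram:
    """Make a theta-curve from a knot diagram by inserting two vertices on
    two darts of a common face and joining them with an unreplicated edge
    drawn inside that face.

    The two knot-strand paths between the vertices become the sister
    edges (the path leaving vertex 1 forward gets ``first_label``).
    """
    if not d.is_knot:
        raise ValueError("thetafy expects a knot diagram")
    if dart1[0] == dart2[0]:
        raise ValueError("darts must lie on distinct arcs")
    face_ok = any(dart1 in f and dart2 in f for f in d.faces())
    if not face_ok:
        raise ValueError("darts do not lie on a common face")
    out, v1 = insert_vertex_on_dart(d, dart1)
    out, v2 = insert_vertex_on_dart(out, dart2)
    u = out.fresh_arc_id()
    out.arcs[u] = (("v", v1, 2), ("v", v2, 2), UNREPLICATED)
    # relabel the two sister paths
    for start, lab in ((("v", v1, 0), first_label), (("v", v1, 1), SISTER_B if first_label == SISTER_A else SISTER_A)):
        for aid, _fr, _to in out.walk_strand(start):
            ea, eb, _old = out.arcs[aid]
            out.arcs[aid] = (ea, eb, lab)
    return out


def outer_thetafy(d: PlanarDiagram, face_index: int = 0) -> PlanarDiagram:
    """Thetafy on the first face (deterministic choice) using its first
    two darts on distinct arcs."""
    faces = [f for f in d.faces() if len({a for a, _ in f}) >= 2]
    faces.sort(key=lambda f: (-len(f), f[0]))
    f = faces[face_index]
    d1 = f[0]
    d2 = next(dd for dd in f[1:] if dd[0] != d1[0])
    return thetafy(d, d1, d2)


# ----------------------------------------------------------------------
# replication intermediates
# ----------------------------------------------------------------------

def build_ri(p: int = 0, s: int = 0, precatenane_flag: int = 0, supercoil_flag: int = 0) -> PlanarDiagram:
    """Idealized partially replicated molecule as a theta-curve diagram.

    Vertices 0 and 1 are the replication forks.  The freshly replicated
    sisters run from fork 0 through a 2-strand twist region of ``p``
    precatenane crossings (all with over flag ``precatenane_flag``) around
    the hairpin bend to fork 1; the unreplicated edge closes the bubble
    and carries ``s`` curl crossings (plectonemic supercoils, over flag
    ``supercoil_flag``).  With no passage applied the diagram is the
    trivial theta-curve.

    Braid crossing slots are the diagonal convention 0=NE,1=NW,2=SW,3=SE;
    the strand entering top-left (NW) leaves bottom-right (SE).
    """
    if p < 0 or s < 0:
        raise ValueError("p and s must be non-negative")
    d = PlanarDiagram(vertices={0, 1})
    aid = 0

    def add_arc(ea: End, eb: End, lab: str) -> None:
        nonlocal aid
        d.arcs[aid] = (ea, eb, lab)
        aid += 1

    if p == 0:
        add_arc(("v", 0, 2), ("v", 1, 0), SISTER_A)   # outer wire
        add_arc(("v", 0, 1), ("v", 1, 1), SISTER_B)   # inner wire
    else:
        for i in range(1, p + 1):
            d.crossings[i] = precatenane_flag
        add_arc(("v", 0, 2), ("x", 1, 1), SISTER_A)   # t_0
        add_arc(("v", 0, 1), ("x", 1, 2), SISTER_B)   # b_0
        for i in range(1, p):
            top_lab = SISTER_A if i % 2 == 0 else SISTER_B
            bot_lab = SISTER_A if i % 2 == 1 else SISTER_B
            add_arc(("x", i, 0), ("x", i + 1, 1), top_lab)   # t_i
            add_arc(("x", i, 3), ("x", i + 1, 2), bot_lab)   # b_i
        out_lab = SISTER_A if p % 2 == 0 else SISTER_B
        in_lab = SISTER_B if p % 2 == 0 else SISTER_A
        add_arc(("x", p, 0), ("v", 1, 0), out_lab)    # outer (around apex)
        add_arc(("x", p, 3), ("v", 1, 1), in_lab)     # inner
    add_arc(("v", 0, 0), ("v", 1, 2), UNREPLICATED)
    if s:
        from .moves import MoveRecord, apply_move

        for _ in range(s):
            u_arcs = sorted(
                a for a, (_ea, _eb, lab) in d.arcs.items() if lab == UNREPLICATED
            )
            d = apply_move(d, MoveRecord("R1+", (u_arcs[-1], supercoil_flag)))
    return d


def _braid_segment_arcs(p: int) -> dict[str, object]:
    """Arc ids of the named segments in build_ri(p) (p >= 1), matching the
    construction order above."""
    t = {0: 0}
    b = {0: 1}
    k = 2
    for i in range(1, p):
        t[i] = k
        b[i] = k + 1
        k += 2
    return {"t": t, "b": b, "outer": k, "inner": k + 1, "u": k + 2}


def _common_face_darts(d: PlanarDiagram, a1: int, a2: int, avoid_label: str | None = UNREPLICATED):
    """Darts of a face shared by both arcs; returns (dart1, dart2).

    Faces touching an ``avoid_label`` edge are deprioritized: the
    fluctuation overlap belongs to the replicated region, not to the face
    bounded by the unreplicated plectoneme.
    """
    shared = []
    for f in sorted(d.faces(), key=lambda f: sorted(f)):
        d1 = [dd for dd in f if dd[0] == a1]
        d2 = [dd for dd in f if dd[0] == a2]
        if d1 and d2:
            touches_avoid = avoid_label is not None and any(
                d.arcs[a][2] == avoid_label for a, _dr in f
            )
            shared.append((touches_avoid, sorted(d1)[0], sorted(d2)[0]))
    if not shared:
        raise ValueError(f"arcs {a1},{a2} share no face")
    shared.sort(key=lambda t: t[0])
    return shared[0][1], shared[0][2]


# ----------------------------------------------------------------------
# fluctuation overlap and single passage
# ----------------------------------------------------------------------

LOCI = ("INTRA_A", "INTRA_B", "INTER")
ROUTES = ("upper", "lower")

#: over flag producing +p inter-sister writhe (positive precatenanes)
POSITIVE_PRECATENANE_FLAG = 1


def _swap_sisters(d: PlanarDiagram) -> PlanarDiagram:
    out = d.copy()
    swap = {SISTER_A: SISTER_B, SISTER_B: SISTER_A}
    out.arcs = {
        aid: (ea, eb, swap.get(lab, lab)) for aid, (ea, eb, lab) in d.arcs.items()
    }
    return out


def insert_overlap(
    d: PlanarDiagram,
    p: int,
    side: str,
    finger: bool,
) -> tuple[PlanarDiagram, list, tuple[int, int]]:
    """Insert the thermal-fluctuation overlap (a cancelling two-crossing
    clasp) between a fork-adjacent sister segment and a returning-arm
    strand of ``build_ri(p)``.

    side "top": the segment of the sister leaving fork 0 on top engages
    the outer arm strand (or, with ``finger``, reaches through it to the
    inner one, leaving an extra cancelling crossing pair).  side
    "bottom": symmetric, from below.  Returns the new diagram, the move
    records applied, and the two candidate passage crossings, ordered so
    the first traps fewer precatenane windings.
    """
    from .moves import MoveRecord, apply_move

    segs = _braid_segment_arcs(p)
    if side == "top":
        seg, near, far = segs["t"][0], segs["outer"], segs["inner"]
    else:
        seg, near, far = segs["b"][0], segs["inner"], segs["outer"]
    records = []
    pre = set(d.crossings)
    da, db = _common_face_darts(d, seg, near)
    if not finger:
        rec = MoveRecord("R2+", (*da, *db, 0))
        d = apply_move(d, rec)
        records.append(rec)
        clasp = sorted(set(d.crossings) - pre)
    else:
        rec = MoveRecord("R2+", (*da, *db, 0))
        d1 = apply_move(d, rec)
        records.append(rec)
        first = sorted(set(d1.crossings) - pre)
        smap = d1.slot_map()
        tip = smap[("x", first[0], 3)]
        dt, df = _common_face_darts(d1, tip, far)
        rec2 = MoveRecord("R2+", (*dt, *df, 0))
        d = apply_move(d1, rec2)
        records.append(rec2)
        clasp = sorted(set(d.crossings) - pre - set(first))
    return d, records, (clasp[0], clasp[1])


def single_passage(
    w: int,
    locus: str,
    route: str = "upper",
    sign: int = +1,
    supercoils: int = 0,
) -> dict:
    """Build an RI, insert the overlap for (locus, trapped windings w),
    and perform the Topo IV passage at the requested route crossing.

    Intra-sister overlaps trap the winding pairs (odd, odd+1); inter-
    sister overlaps the pairs (even, even+1) -- the two routes of one
    overlap differ by one trapped winding.  The returned dict carries the
    base diagram, the move records (replayable certificate), the product
    (unsimplified), and bookkeeping.
    """
    from .moves import MoveRecord, apply_move

    if locus not in LOCI:
        raise ValueError(f"locus must be one of {LOCI}")
    if route not in ROUTES:
        raise ValueError(f"route must be one of {ROUTES}")
    if w < 0:
        raise ValueError("trapped windings must be non-negative")
    flag = POSITIVE_PRECATENANE_FLAG if sign > 0 else 1 - POSITIVE_PRECATENANE_FLAG
    intra = locus != "INTER"
    # overlap pair (a, a+1) with a odd for intra, even for inter
    if intra and w == 0:
        # closely spaced same-sister segments: nothing trapped either way
        a, p, side, finger = 0, 1, "bottom", True
    elif intra:
        a = w if w % 2 == 1 else w - 1
        p, side, finger = a + 1, ("top" if locus == "INTRA_A" else "bottom"), False
    else:
        a = w if w % 2 == 0 else w - 1
        p, side, finger = a + 1, "top", False
    swap = intra and w == 0 and locus == "INTRA_A"
    base = build_ri(p, s=abs(supercoils), precatenane_flag=flag,
                    supercoil_flag=0 if supercoils < 0 else 1)
    if swap:
        base = _swap_sisters(base)
    over, records, sites = insert_overlap(base, p, side, finger)
    trapped = a if route == "upper" else (a + 1 if not (intra and w == 0) else 0)
    site = sites[0] if route == "upper" else sites[1]
    xrec = MoveRecord("X", (site,))
    product = apply_move(over, xrec)
    records = records + [xrec]
    return {
        "base": base,
        "overlap": over,
        "sites": sites,
        "records": records,
        "product": product,
        "trapped": trapped,
        "p": p,
        "side": side,
        "finger": finger,
    }
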