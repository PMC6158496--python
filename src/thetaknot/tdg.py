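""".tdg ("theta-diagram") text interchange format.

Line-oriented, UTF-8, ``#`` comments.  A diagram is written as::

    type theta|knot
    vertex <id> <a0>,<a1>,<a2>
    crossing <id> <a0>,<a1>,<a2>,<a3> over=<0|1>
    arc <id> <endA> <endB> label=<LABEL>
    loop <id> label=<LABEL>
    orient <edge> <arc_id_sequence>      (optional, checked and ignored)

Node lines list the arc id occupying each counterclockwise slot
(``over=0`` means slots 0 and 2 carry the over-strand); arc ends are
written ``v<id>.<slot>`` or ``x<id>.<slot>``.  ``loop`` lines carry
crossingless closed components (the node/arc grammar alone cannot
express the 0-crossing unknot).  Parsing validates the diagram and
rejects files violating the structural invariants.
"""

from __future__ import annotations

import io
from typing import TextIO

from .diagram import End, PlanarDiagram


class TdgError(ValueError):
    pass


def _fmt_end(end: End) -> str:
    kind, n, k = end
    return f"{kind}{n}.{k}"


def _parse_end(tok: str) -> End:
    kind = tok[0]
    if kind not in ("v", "x") or "." not in tok:
        raise TdgError(f"bad arc end {tok!r}")
    n, k = tok[1:].split(".")
    return (kind, int(n), int(k))


def dumps(d: PlanarDiagram, comment: str | None = None) -> str:
    out = io.StringIO()
    if comment:
        for line in comment.splitlines():
            out.write(f"# {line}\n")
    out.write(f"type {'theta' if d.is_theta else 'knot'}\n")
    smap = d.slot_map()
    for v in sorted(d.vertices):
        slots = ",".join(str(smap[("v", v, k)]) for k in range(3))
        out.write(f"vertex {v} {slots}\n")
    for x, over in sorted(d.crossings.items()):
        slots = ",".join(str(smap[("x", x, k)]) for k in range(4))
        out.write(f"crossing {x} {slots} over={over}\n")
    for aid, (ea, eb, lab) in sorted(d.arcs.items()):
        out.write(f"arc {aid} {_fmt_end(ea)} {_fmt_end(eb)} label={lab}\n")
    for lid, lab in sorted(d.loops.items()):
        out.write(f"loop {lid} label={lab}\n")
    return out.getvalue()


def loads(text: str, validate: bool = True) -> PlanarDiagram:
    crossings: dict[int, int] = {}
    vertices: set[int] = set()
    arcs: dict[int, tuple[End, End, str]] = {}
    loops: dict[int, str] = {}
    node_slots: dict[tuple[str, int], list[int]] = {}
    declared_type: str | None = None
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kw = parts[0]
        try:
            if kw == "type":
                declared_type = parts[1]
                if declared_type not in ("theta", "knot"):
                    raise TdgError(f"unknown type {declared_type!r}")
            elif kw == "vertex":
                v = int(parts[1])
                vertices.add(v)
                node_slots[("v", v)] = [int(t) for t in parts[2].split(",")]
                if len(node_slots[("v", v)]) != 3:
                    raise TdgError("vertex needs exactly 3 slots")
            elif kw == "crossing":
                x = int(parts[1])
                slots = [int(t) for t in parts[2].split(",")]
                if len(slots) != 4:
                    raise TdgError("crossing needs exactly 4 slots")
                over = None
                for p in parts[3:]:
                    if p.startswith("over="):
                        over = int(p[5:])
                if over not in (0, 1):
                    raise TdgError("crossing needs over=0|1")
                crossings[x] = over
                node_slots[("x", x)] = slots
            elif kw == "arc":
                aid = int(parts[1])
                ea, eb = _parse_end(parts[2]), _parse_end(parts[3])
                lab = None
                for p in parts[4:]:
                    if p.startswith("label="):
                        lab = p[6:]
                if lab is None:
                    raise TdgError("arc needs label=")
                arcs[aid] = (ea, eb, lab)
            elif kw == "loop":
                lid = int(parts[1])
                lab = None
                for p in parts[2:]:
                    if p.startswith("label="):
                        lab = p[6:]
                if lab is None:
                    raise TdgError("loop needs label=")
                loops[lid] = lab
            elif kw == "orient":
                pass  # optional; orientation is derived deterministically
            else:
                raise TdgError(f"unknown keyword {kw!r}")
        except (IndexError, ValueError) as exc:
            raise TdgError(f"line {ln}: {exc}") from exc
    d = PlanarDiagram(crossings, vertices, arcs, loops)
    # cross-check node slot tables against arc ends
    smap = d.slot_map()
    for (kind, n), slot_arcs in node_slots.items():
        for k, aid in enumerate(slot_arcs):
            actual = smap.get((kind, n, k))
            if actual != aid:
                raise TdgError(
                    f"{kind}{n} slot {k}: table says arc {aid}, arcs say {actual}"
                )
    if declared_type == "theta" and not d.is_theta:
        raise TdgError("declared theta but diagram is not a theta-curve")
    if declared_type == "knot" and d.vertices:
        raise TdgError("declared knot but diagram has vertices")
    if validate:
        rep = d.validate()
        if not rep.ok:
            raise TdgError("invalid diagram: " + "; ".join(rep.violations[:3]))
    return d


def dump(d: PlanarDiagram, fh: TextIO, comment: str | None = None) -> None:
    fh.write(dumps(d, comment))


def load(fh: TextIO, validate: bool = True) -> PlanarDiagram:
    return loads(fh.read(), validate)
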