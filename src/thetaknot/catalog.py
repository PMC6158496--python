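"""Embedded catalog of prime knots (<= 7 crossings, both chiralities)
and the theta-curves the replication-intermediate model names.

All diagrams are constructed programmatically: knots from rational-tangle
continued fractions (every prime knot to seven crossings is 2-bridge),
theta-curves as simplified single-passage products of the RI model, plus
the trivial curve and a synthetic stand-in for the remaining 5-crossing
unknotting-number-one curve.  Naming conventions:

* Unbarred knot names denote the left-handed (negative reduced-writhe)
  chirality; the suffix ``bar`` denotes the mirror, so the right-handed
  (all-positive) trefoil is ``3_1bar``, matching the usage for knots
  observed in stalled replication intermediates.
* ``theta3_1`` and ``theta4_1`` are the positive-precatenane products;
  ``theta5_6bar`` is the positive product whose freshly-replicated
  constituent is ``5_2bar`` (its mirror is ``theta5_6``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

from .construct import rational_knot, single_passage, trivial_theta, unknot
from .diagram import PlanarDiagram, THETA_LABELS, UNREPLICATED
from .invariants import (
    KnotFingerprint,
    ThetaFingerprint,
    knot_fingerprint,
    theta_fingerprint,
)
from .moves import Budget, MoveRecord, crossing_change, simplify

#: continued fractions of the prime knots up to seven crossings
KNOT_CF: dict[str, list[int]] = {
    "3_1": [3],
    "4_1": [2, 2],
    "5_1": [5],
    "5_2": [3, 2],
    "6_1": [4, 2],
    "6_2": [3, 1, 2],
    "6_3": [2, 1, 1, 2],
    "7_1": [7],
    "7_2": [5, 2],
    "7_3": [4, 3],
    "7_4": [3, 1, 3],
    "7_5": [3, 2, 2],
    "7_6": [2, 2, 1, 2],
    "7_7": [2, 1, 1, 1, 2],
}
ACHIRAL_KNOTS = {"0_1", "4_1", "6_3"}


@dataclass
class KnotClass:
    name: str
    chirality: str                 # standard | mirror | achiral
    crossing_number: int
    diagram: PlanarDiagram
    fingerprint: KnotFingerprint
    source: str

    @property
    def base_name(self) -> str:
        return self.name[:-3] if self.name.endswith("bar") else self.name


@dataclass
class ThetaClass:
    name: str
    chirality: str
    crossing_number: int
    diagram: PlanarDiagram
    fingerprint: ThetaFingerprint
    constituent_names: tuple[str, str, str]
    unknotting_number: int
    source: str
    _unknotting_sites: Optional[tuple[int, ...]] = field(default=None, repr=False)

    @property
    def base_name(self) -> str:
        return self.name[:-3] if self.name.endswith("bar") else self.name

    @property
    def unknotting_sites(self) -> tuple[int, ...]:
        """Crossings of the catalog diagram whose change (plus
        simplification) yields the trivial curve; computed on demand."""
        if self._unknotting_sites is None:
            self._unknotting_sites = _depth1_unknotting_sites(self.diagram)
        return self._unknotting_sites


def _depth1_unknotting_sites(d: PlanarDiagram) -> tuple[int, ...]:
    triv = theta_fingerprint(trivial_theta()).key()
    sites = []
    for x in sorted(d.crossings):
        s, _ = simplify(crossing_change(d, x), Budget(depth=6))
        if s.n_crossings == 0 or theta_fingerprint(s).key() == triv:
            sites.append(x)
    return tuple(sites)


class Catalog:
    def __init__(self, knots: dict[str, KnotClass], thetas: dict[str, ThetaClass]):
        self.knots = knots
        self.thetas = thetas
        self.knot_by_fingerprint = {e.fingerprint.key(): e for e in knots.values()}
        self.theta_by_fingerprint = {e.fingerprint.key(): e for e in thetas.values()}

    def lookup(self, name: str):
        """Entry by name (knot names like ``3_1bar``, curve names like
        ``theta5_6``)."""
        if name in self.knots:
            return self.knots[name]
        if name in self.thetas:
            return self.thetas[name]
        raise KeyError(name)

    def mirror_name(self, name: str) -> str:
        e = self.lookup(name)
        if e.chirality == "achiral":
            return name
        return name[:-3] if name.endswith("bar") else name + "bar"

    def __repr__(self) -> str:
        return f"<Catalog: {len(self.knots)} knots, {len(self.thetas)} theta-curves>"


def _simplified_product(w: int, locus: str, route: str) -> PlanarDiagram:
    res = single_passage(w, locus, route)
    s, _ = simplify(res["product"], Budget(depth=6))
    return s.canonical()


def _theta57_diagram() -> PlanarDiagram:
    """Synthetic stand-in for the remaining 5-crossing prime theta-curve
    with unknotting number one.

    The published table's own diagram is not reproducible here, so this
    entry is a 5-crossing curve found by deterministic search over single
    crossing changes on expanded trivial-theta diagrams; it is distinct
    (by Yamada fingerprint) from every other catalog entry and mirror,
    and carries an unknotting certificate by construction.
    """
    from . import _theta57_data

    return _theta57_data.diagram()


def _knot_entries() -> dict[str, KnotClass]:
    entries: dict[str, KnotClass] = {}
    u = unknot()
    entries["0_1"] = KnotClass(
        "0_1", "achiral", 0, u, knot_fingerprint(u),
        "constructed: crossingless loop",
    )
    for name, cf in KNOT_CF.items():
        d_plain = rational_knot(cf).canonical()
        d_flip = rational_knot(cf, flip=True).canonical()
        n = sum(cf)
        src = f"constructed: rational knot, continued fraction {cf}"
        if name in ACHIRAL_KNOTS:
            entries[name] = KnotClass(
                name, "achiral", n, d_plain, knot_fingerprint(d_plain), src
            )
            continue
        # unbarred = left-handed (negative reduced writhe)
        if d_plain.writhe() < 0:
            left, right = d_plain, d_flip
        else:
            left, right = d_flip, d_plain
        entries[name] = KnotClass(
            name, "standard", n, left, knot_fingerprint(left), src
        )
        entries[name + "bar"] = KnotClass(
            name + "bar", "mirror", n, right, knot_fingerprint(right), src + " (mirror)"
        )
    return entries


def _constituent_names(d: PlanarDiagram, knots: dict[str, KnotClass]) -> tuple:
    by_fp = {e.fingerprint.key(): e.name for e in knots.values()}
    names = []
    for lab in THETA_LABELS:
        c, _ = simplify(d.delete_edge(lab), Budget(depth=6))
        names.append(by_fp.get(knot_fingerprint(c).key(), "UNCLASSIFIED"))
    return tuple(sorted(names))


def _theta_entries(knots: dict[str, KnotClass]) -> dict[str, ThetaClass]:
    entries: dict[str, ThetaClass] = {}

    def add(name: str, d: PlanarDiagram, chirality: str, u: int, source: str):
        fp = theta_fingerprint(d)
        entries[name] = ThetaClass(
            name, chirality, d.n_crossings, d, fp,
            _constituent_names(d, knots), u, source,
        )

    add("theta0_1", trivial_theta(), "achiral", 0, "constructed: planar theta-graph")

    t31 = _simplified_product(1, "INTRA_A", "upper")
    add("theta3_1", t31, "standard", 1,
        "constructed: single-passage product, one trapped positive winding")
    add("theta3_1bar", t31.mirror(), "mirror", 1,
        "constructed: mirror of theta3_1")

    t41 = _simplified_product(2, "INTRA_A", "lower")
    add("theta4_1", t41, "standard", 1,
        "constructed: single-passage product, two trapped positive windings")
    add("theta4_1bar", t41.mirror(), "mirror", 1,
        "constructed: mirror of theta4_1")

    t56bar = _simplified_product(3, "INTER", "lower")
    add("theta5_6bar", t56bar, "mirror", 1,
        "constructed: inter-sister single-passage product, three trapped "
        "positive windings (freshly-replicated constituent 5_2bar)")
    add("theta5_6", t56bar.mirror(), "standard", 1,
        "constructed: mirror of theta5_6bar")

    t57 = _theta57_diagram()
    add("theta5_7", t57, "standard", 1,
        "synthetic stand-in: 5-crossing unknotting-number-one curve from "
        "deterministic crossing-change search (published diagram unavailable)")
    add("theta5_7bar", t57.mirror(), "mirror", 1,
        "synthetic stand-in (mirror)")
    return entries


@lru_cache(maxsize=1)
def load_catalog() -> Catalog:
    knots = _knot_entries()
    thetas = _theta_entries(knots)
    return Catalog(knots, thetas)


# ----------------------------------------------------------------------
# verification
# ----------------------------------------------------------------------

@dataclass
class VerificationReport:
    failures: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def verify_catalog(cat: Catalog | None = None) -> VerificationReport:
    """Release gate: diagram validity, fingerprint recomputability and
    separation, constituent identities, unknotting certificates, and the
    single-nontrivial-constituent pattern (reported, not enforced)."""
    cat = cat or load_catalog()
    rep = VerificationReport()
    fps: dict[tuple, str] = {}
    for e in cat.knots.values():
        if not e.diagram.validate().ok:
            rep.failures.append(f"{e.name}: invalid diagram")
            continue
        if e.diagram.n_crossings != e.crossing_number:
            rep.failures.append(f"{e.name}: crossing count mismatch")
        k = knot_fingerprint(e.diagram).key()
        if k != e.fingerprint.key():
            rep.failures.append(f"{e.name}: fingerprint not recomputable")
        if k in fps:
            rep.failures.append(f"{e.name}: fingerprint collides with {fps[k]}")
        fps[k] = e.name
    tfps: dict[tuple, str] = {}
    for e in cat.thetas.values():
        if not e.diagram.validate().ok:
            rep.failures.append(f"{e.name}: invalid diagram")
            continue
        if e.diagram.n_crossings != e.crossing_number:
            rep.failures.append(f"{e.name}: crossing count mismatch")
        k = theta_fingerprint(e.diagram).key()
        if k != e.fingerprint.key():
            rep.failures.append(f"{e.name}: fingerprint not recomputable")
        if k in tfps:
            rep.failures.append(f"{e.name}: fingerprint collides with {tfps[k]}")
        tfps[k] = e.name
        names = _constituent_names(e.diagram, cat.knots)
        if names != e.constituent_names:
            rep.failures.append(
                f"{e.name}: constituents {names} != stored {e.constituent_names}"
            )
        nontrivial = [n for n in names if n != "0_1"]
        if len(nontrivial) > 1:
            rep.notes.append(
                f"{e.name}: more than one nontrivial constituent ({nontrivial})"
            )
        if e.unknotting_number == 1:
            if not e.unknotting_sites:
                rep.failures.append(f"{e.name}: no depth-1 unknotting site found")
        elif e.unknotting_number == 0:
            if e.diagram.n_crossings != 0:
                rep.failures.append(f"{e.name}: u=0 but crossings present")
    return rep
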