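"""The replication-intermediate (RI) knotting model.

A stalled, partially replicated circular DNA molecule is a theta-curve:
two replication-fork vertices, two freshly replicated sister-duplex
edges winding around each other (precatenanes, positive sign in the
stalled-RI convention), and the unreplicated edge closing the bubble as
a plectonemic loop.  A type-II topoisomerase passage is one crossing
change at a thermal-fluctuation overlap; depending on whether the
overlapping segments belong to the same sister duplex (intra) or to the
two sisters (inter) and on how many precatenane windings lie between
them, the passage converts the trivial curve into the twist-family
knotted theta-curves whose freshly-replicated (FR) constituents are the
experimentally observed knot series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import pandas as pd

from . import construct
from .catalog import KnotClass, ThetaClass, load_catalog
from .construct import LOCI, ROUTES, single_passage
from .diagram import PlanarDiagram, UNREPLICATED
from .invariants import Unclassified, identify_knot, identify_theta
from .moves import Budget, MoveRecord, apply_move, crossing_change, enumerate_moves, replay, simplify


@dataclass(frozen=True)
class RIConfig:
    """Parameters of a stalled replication intermediate and one passage.

    trapped_windings: precatenane crossings between the two segments
    engaged by the passage (the parameter that decides the product).
    route: which of the two overlap crossings the enzyme uses; the two
    routes of one overlap trap ``w`` and a neighbouring count.  None
    picks the route trapping exactly ``trapped_windings``.
    """

    trapped_windings: int
    locus: str = "INTRA_A"
    route: Optional[str] = None
    precatenane_sign: int = +1
    unreplicated_supercoils: int = -2
    precatenane_crossings: Optional[int] = None

    def __post_init__(self):
        if self.locus not in LOCI:
            raise ValueError(f"locus must be one of {LOCI}")
        if self.route is not None and self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}")
        if self.trapped_windings < 0:
            raise ValueError("trapped_windings must be >= 0")
        if self.precatenane_sign not in (+1, -1):
            raise ValueError("precatenane_sign must be +1 or -1")
        if (
            self.precatenane_crossings is not None
            and self.trapped_windings > self.precatenane_crossings
        ):
            raise ValueError("trapped_windings must not exceed precatenane_crossings")


@dataclass
class PathwayResult:
    config: object
    product: PlanarDiagram
    theta_class: ThetaClass | Unclassified
    fr_knot: KnotClass | Unclassified
    base: PlanarDiagram
    certificate: tuple[MoveRecord, ...]
    trapped: int
    pathway: str = ""

    @property
    def theta_name(self) -> str:
        return getattr(self.theta_class, "name", str(self.theta_class))

    @property
    def fr_name(self) -> str:
        return getattr(self.fr_knot, "name", str(self.fr_knot))

    def replay_product(self) -> PlanarDiagram:
        return replay(self.base, self.certificate)


def build_ri(config: RIConfig) -> PlanarDiagram:
    """The RI theta-curve for a config, before any passage."""
    res = single_passage(
        config.trapped_windings,
        config.locus,
        "upper",
        sign=config.precatenane_sign,
        supercoils=config.unreplicated_supercoils,
    )
    return res["base"]


def enumerate_passage_sites(d: PlanarDiagram, locus: str | None = None) -> list[tuple[int, int]]:
    """Candidate passage crossings: pairs forming a removable bigon (a
    fluctuation overlap).  With no overlap inserted the list is empty;
    each overlap contributes its two candidate crossings (the upper and
    lower routes).  ``locus`` filters by the labels of the two engaged
    strands."""
    smap = d.slot_map()
    pairs = []
    for m in enumerate_moves(d, ("R2-",)):
        c1, c2, _k = m.site
        labs = sorted({d.arcs[smap[("x", c1, k)]][2] for k in range(4)})
        if locus == "INTER" and len(labs) < 2:
            continue
        if locus in ("INTRA_A", "INTRA_B"):
            want = "SISTER_A" if locus == "INTRA_A" else "SISTER_B"
            if labs != [want]:
                continue
        pairs.append((c1, c2))
    return pairs


def simulate_passage(config: RIConfig, budget: Budget | None = None) -> PathwayResult:
    """Build the RI, insert the fluctuation overlap for (locus, w), apply
    the crossing change at the configured route, simplify and identify
    the product and its FR knot."""
    route = config.route
    if route is None:
        # the route that traps exactly the configured winding count
        probe = single_passage(
            config.trapped_windings, config.locus, "upper",
            sign=config.precatenane_sign,
            supercoils=config.unreplicated_supercoils,
        )
        route = "upper" if probe["trapped"] == config.trapped_windings else "lower"
    res = single_passage(
        config.trapped_windings, config.locus, route,
        sign=config.precatenane_sign,
        supercoils=config.unreplicated_supercoils,
    )
    product, trace = simplify(res["product"], budget)
    theta_class = identify_theta(product, budget)
    fr = product.delete_edge(UNREPLICATED)
    fr_knot = identify_knot(fr, budget)
    return PathwayResult(
        config=RIConfig(
            config.trapped_windings, config.locus, route,
            config.precatenane_sign, config.unreplicated_supercoils,
            config.precatenane_crossings,
        ),
        product=product,
        theta_class=theta_class,
        fr_knot=fr_knot,
        base=res["base"],
        certificate=tuple(res["records"]) + tuple(trace),
        trapped=res["trapped"],
        pathway=f"single-passage {config.locus}",
    )


def outcome_table(
    max_windings: int,
    sign: int = +1,
    budget: Budget | None = None,
) -> pd.DataFrame:
    """Products of one passage for every locus, trapped winding count up
    to ``max_windings``, and route (the machine-readable form of the
    model's outcome ladder)."""
    if max_windings < 1:
        raise ValueError("max_windings must be >= 1")
    rows = []
    for locus in LOCI:
        for w in range(0, max_windings + 1):
            for route in ROUTES:
                cfg = RIConfig(w, locus, route, precatenane_sign=sign)
                r = simulate_passage(cfg, budget)
                th = r.theta_class
                fr = r.fr_knot
                classified = not isinstance(th, Unclassified)
                rows.append({
                    "locus": locus,
                    "route": route,
                    "windings": w,
                    "trapped_windings": r.trapped,
                    "theta_name": r.theta_name,
                    "theta_crossings": (
                        th.crossing_number if classified else r.product.n_crossings
                    ),
                    "fr_knot": r.fr_name,
                    "fr_crossings": (
                        fr.crossing_number
                        if not isinstance(fr, Unclassified)
                        else -1
                    ),
                    "chirality": getattr(th, "chirality", "n/a"),
                    "classified": classified,
                })
    return pd.DataFrame(rows)


def outcome_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Classified theta-curve names produced by each locus."""
    out: dict[str, set[str]] = {}
    for locus in LOCI:
        sub = table[(table.locus == locus) & table.classified]
        out[locus] = set(sub.theta_name)
    return out


def mirror_prediction(result: PathwayResult, budget: Budget | None = None) -> PathwayResult:
    """The positively supercoiled (actively replicating) counterpart: the
    mirror image of the product, re-identified."""
    m = result.product.mirror()
    product, trace = simplify(m, budget)
    theta_class = identify_theta(product, budget)
    fr_knot = identify_knot(product.delete_edge(UNREPLICATED), budget)
    return PathwayResult(
        config=result.config,
        product=product,
        theta_class=theta_class,
        fr_knot=fr_knot,
        base=m,
        certificate=tuple(trace),
        trapped=result.trapped,
        pathway=result.pathway + " (mirror)",
    )


# ----------------------------------------------------------------------
# second-passage pathways to the 6_2bar FR knot
# ----------------------------------------------------------------------

@lru_cache(maxsize=1)
def _route_sites_62bar() -> dict[str, int]:
    """First crossing of the minimal 6_2bar diagram whose change yields
    each simpler knot (unknot, right trefoil, figure-eight)."""
    cat = load_catalog()
    d62 = cat.lookup("6_2bar").diagram
    sites: dict[str, int] = {}
    for x in sorted(d62.crossings):
        r = identify_knot(crossing_change(d62, x))
        name = getattr(r, "name", None)
        if name in ("0_1", "3_1bar", "4_1") and name not in sites:
            sites[name] = x
    return sites


def _thetafy_matching(knot_d: PlanarDiagram, expect_names: tuple[str, ...]):
    """Thetafy ``knot_d`` on some face so the curve identifies to one of
    ``expect_names``; deterministic search over dart pairs."""
    tried = 0
    for f in sorted(knot_d.faces(), key=lambda f: sorted(f)):
        arcs_on_face = []
        for dart in f:
            if dart[0] not in [a for a, _ in arcs_on_face]:
                arcs_on_face.append((dart[0], dart))
        for i in range(len(arcs_on_face)):
            for j in range(i + 1, len(arcs_on_face)):
                d1, d2 = arcs_on_face[i][1], arcs_on_face[j][1]
                tried += 1
                if tried > 40:
                    raise RuntimeError("no thetafication matches the expected class")
                th = construct.thetafy(knot_d, d1, d2)
                if not th.validate().ok:
                    continue
                ident = identify_theta(th)
                if getattr(ident, "name", None) in expect_names:
                    return th, ident
    raise RuntimeError("no thetafication matches the expected class")


def second_passage_catalog(budget: Budget | None = None) -> list[PathwayResult]:
    """The four pathway configurations that produce a 6_2bar FR knot.

    (i)   one passage on a torsionally relaxed, unknotted RI;
    (ii)  a second passage on a theta3_1 RI (loop against the other sister);
    (iii) a second passage on a theta4_1 RI formed by an intra-sister passage;
    (iv)  a second passage on a theta4_1 RI formed by an inter-sister passage.

    Each starting curve is presented as a deformed diagram carrying the
    overlap; the passage is the recorded crossing change, and the FR knot
    is identified after deleting the unreplicated edge.  The intra- and
    inter-formed theta4_1 curves carry identical invariant fingerprints
    here, so (iii) and (iv) differ in their first-passage provenance, not
    in the identified starting class.
    """
    sites = _route_sites_62bar()
    cat = load_catalog()
    d62 = cat.lookup("6_2bar").diagram
    labels = {
        "0_1": ("i", "single passage on relaxed unknotted RI", ("theta0_1",)),
        "3_1bar": ("ii", "second passage on theta3_1 RI", ("theta3_1",)),
        "4_1": ("iii", "second passage on intra-formed theta4_1 RI",
                ("theta4_1", "theta4_1bar")),
    }
    results: list[PathwayResult] = []
    for start_name, (tag, desc, expect) in labels.items():
        x = sites[start_name]
        pre_knot = crossing_change(d62, x)
        th, start_ident = _thetafy_matching(pre_knot, expect)
        # the passage site keeps its crossing id through thetafication
        rec = MoveRecord("X", (x,))
        prod_raw = apply_move(th, rec)
        product, trace = simplify(prod_raw, budget)
        fr_knot = identify_knot(product.delete_edge(UNREPLICATED), budget)
        theta_class = identify_theta(product, budget)
        results.append(PathwayResult(
            config={"pathway": tag, "start_class": start_ident.name,
                    "description": desc, "change_site": x},
            product=product,
            theta_class=theta_class,
            fr_knot=fr_knot,
            base=th,
            certificate=(rec,) + tuple(trace),
            trapped=-1,
            pathway=f"({tag}) {desc}",
        ))
        if start_name == "4_1":
            # (iv): the same second passage taken on the inter-formed curve;
            # the inter- and intra-formed theta4_1 have equal fingerprints,
            # so the starting class is verified against the inter product.
            inter41 = simulate_passage(RIConfig(2, "INTER"), budget)
            results.append(PathwayResult(
                config={"pathway": "iv", "start_class": inter41.theta_name,
                        "description": "second passage on inter-formed theta4_1 RI",
                        "change_site": x},
                product=product,
                theta_class=theta_class,
                fr_knot=fr_knot,
                base=th,
                certificate=(rec,) + tuple(trace),
                trapped=-1,
                pathway="(iv) second passage on inter-formed theta4_1 RI",
            ))
    return results
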