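"""Synthetic-data stage: seeded diagram perturbation and constructed
test vectors for the pathway analyses.

The perturbation operator realizes "many different diagrams for the same
curve": a seeded stream of random Reidemeister moves whose products keep
the invariant fingerprint.  The named fixtures are constructed
pre-passage diagrams, each built from the catalog and the passage model
so that it identifies to a stated starting class and its post-change
product to the stated product class (e.g. the three single-change knot
routes into the right-handed 6_2, or the unknotting change on the
5-crossing curve).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

from .catalog import load_catalog
from .construct import single_passage
from .diagram import PlanarDiagram
from .moves import MoveRecord, apply_move, crossing_change, enumerate_moves

DEFAULT_PERTURB_KINDS = ("R1+", "R1-", "R2+", "R2-", "R3", "R4+", "R4-", "R5+", "R5-")


@dataclass(frozen=True)
class PerturbSpec:
    """Seeded random move sequence: same seed + spec + input give the
    identical output diagram."""

    seed: int
    n_moves: int
    kinds: tuple[str, ...] = DEFAULT_PERTURB_KINDS
    max_crossings: int = 12   # moves that would exceed this are skipped


def perturb(d: PlanarDiagram, spec: PerturbSpec) -> PlanarDiagram:
    """Apply ``spec.n_moves`` seeded random Reidemeister moves.

    Deterministic per spec; the result is a different diagram of the
    same curve (identical fingerprint).  Moves are drawn kind-first so
    sparse kinds (vertex moves) are not drowned out by the many
    strand-slide sites.
    """
    rng = random.Random(spec.seed)
    kinds = tuple(k for k in spec.kinds if k != "X")
    for _ in range(spec.n_moves):
        grown = d.n_crossings >= spec.max_crossings
        active = tuple(k for k in kinds if not (grown and k.endswith("+")))
        by_kind: dict[str, list[MoveRecord]] = {}
        for m in enumerate_moves(d, active):
            by_kind.setdefault(m.kind, []).append(m)
        if not by_kind:
            break
        usable = sorted(by_kind)
        k = usable[rng.randrange(len(usable))]
        ms = by_kind[k]
        d = apply_move(d, ms[rng.randrange(len(ms))])
    return d


# ----------------------------------------------------------------------
# figure fixtures
# ----------------------------------------------------------------------

@dataclass
class FigureFixture:
    """A constructed pre-change diagram with its annotated passage site."""

    name: str
    diagram: PlanarDiagram
    change_site: Optional[int]
    expect_pre: str     # class the pre-change diagram identifies to
    expect_post: str    # class after the crossing change
    note: str = ""
    extra_sites: tuple[int, ...] = ()

    def changed(self) -> PlanarDiagram:
        if self.change_site is None:
            raise ValueError(f"fixture {self.name} has no change site")
        return crossing_change(self.diagram, self.change_site)


@lru_cache(maxsize=1)
def _registry() -> dict[str, FigureFixture]:
    from .ri_model import second_passage_catalog  # late import: heavy

    cat = load_catalog()
    reg: dict[str, FigureFixture] = {}

    # unknotting example: the 5-crossing curve with its unknotting change
    t57 = cat.lookup("theta5_7")
    reg["fig3_theta57"] = FigureFixture(
        "fig3_theta57", t57.diagram, t57.unknotting_sites[0],
        "theta5_7", "theta0_1",
        "constructed surrogate: synthetic theta5_7 with unknotting change",
    )

    # the three single-change knot routes to 6_2bar (unknot, right
    # trefoil, figure-eight starts)
    d62 = cat.lookup("6_2bar").diagram
    from .ri_model import _route_sites_62bar

    sites = _route_sites_62bar()
    for start, key in (("0_1", "fig7_unknot_pre"),
                       ("3_1bar", "fig7_31bar_pre"),
                       ("4_1", "fig7_41_pre")):
        x = sites[start]
        reg[key] = FigureFixture(
            key, crossing_change(d62, x), x, start, "6_2bar",
            "constructed surrogate: minimal 6_2bar diagram with one "
            f"crossing changed (starting knot {start})",
        )

    # single-passage overlap panels (intra and inter pathways)
    intra = single_passage(1, "INTRA_A", "upper")
    reg["fig4_overlap"] = FigureFixture(
        "fig4_overlap", intra["overlap"], intra["sites"][0],
        "theta0_1", "theta3_1",
        "constructed surrogate: intra-sister fluctuation overlap, one "
        "trapped positive winding",
        extra_sites=(intra["sites"][1],),
    )
    inter = single_passage(3, "INTER", "lower")
    reg["fig5_overlap"] = FigureFixture(
        "fig5_overlap", inter["overlap"], inter["sites"][1],
        "theta0_1", "theta5_6bar",
        "constructed surrogate: inter-sister fluctuation overlap, three "
        "trapped positive windings",
        extra_sites=(inter["sites"][0],),
    )

    # the four second-passage starting curves (rows of the 6_2bar table)
    for i, res in enumerate(second_passage_catalog(), start=1):
        key = f"fig8_row{i}"
        site = res.config["change_site"]
        reg[key] = FigureFixture(
            key, res.base, site, res.config["start_class"], "6_2bar",
            f"constructed surrogate: {res.pathway}",
        )
    return reg


def fixture_names() -> list[str]:
    return sorted(_registry())


def figure_fixture(name: str) -> FigureFixture:
    """Look up a constructed figure surrogate by name."""
    reg = _registry()
    if name not in reg:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(reg)}")
    return reg[name]
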