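"""Unknotting numbers of knots and theta-curves by iterative-deepening
search over crossing changes interleaved with simplification.

A crossing change models one topoisomerase-mediated intersegmental
passage; u(theta) is the least number of changes taking the curve to the
trivial theta-curve.  Upper bounds come with replayable certificates;
lower bounds come from fingerprint nontriviality (>= 1) and from
exhaustive failure of the bounded depth-k search (reported as
search-relative, never as a proof).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .construct import trivial_theta, unknot
from .diagram import PlanarDiagram
from .invariants import fingerprint
from .moves import Budget, MoveRecord, apply_move, crossing_change, enumerate_moves, simplify

_EXPAND_KINDS = ("R2+", "R5+", "R4+")


def _trivial_key(d: PlanarDiagram) -> tuple:
    ref = trivial_theta() if d.is_theta else unknot()
    return fingerprint(ref).key()


def is_trivial(d: PlanarDiagram) -> bool:
    s, _ = simplify(d)
    if s.n_crossings == 0:
        return True
    return fingerprint(s).key() == _trivial_key(d)


@dataclass
class UnknottingStep:
    expansion: tuple[MoveRecord, ...]     # crossing-increasing moves
    change: MoveRecord                    # the crossing change ("X")
    simplification: tuple[MoveRecord, ...]


@dataclass
class UnknottingCertificate:
    """Replayable witness that ``start`` unknots in len(steps) changes."""

    start: PlanarDiagram
    pre_simplification: tuple[MoveRecord, ...]
    steps: tuple[UnknottingStep, ...] = ()

    def replay(self) -> PlanarDiagram:
        d = self.start
        for m in self.pre_simplification:
            d = apply_move(d, m)
        for st in self.steps:
            for m in st.expansion:
                d = apply_move(d, m)
            d = apply_move(d, st.change)
            for m in st.simplification:
                d = apply_move(d, m)
        return d

    @property
    def n_changes(self) -> int:
        return len(self.steps)


def verify_certificate(cert: UnknottingCertificate) -> bool:
    """True iff the replay ends at a crossingless diagram with the
    trivial fingerprint."""
    try:
        end = cert.replay()
    except Exception:
        return False
    if end.n_crossings != 0:
        end, _ = simplify(end)
        if end.n_crossings != 0:
            return False
    return fingerprint(end).key() == _trivial_key(cert.start)


@dataclass
class UnknottingResult:
    u_upper: Optional[int]
    u_lower: int
    certificate: Optional[UnknottingCertificate]
    exhaustive: bool   # lower bound depth fully explored (no budget cap hit)

    @property
    def value(self) -> Optional[int]:
        """The unknotting number when the bounds meet, else None."""
        if self.u_upper is not None and self.u_upper == self.u_lower:
            return self.u_upper
        return None


def _expansions(d: PlanarDiagram, budget: int, cap: int):
    """Deterministic list of (diagram, expansion records) with at most
    ``budget`` crossing-increasing moves; the unexpanded diagram first."""
    out = [(d, ())]
    seen = {d.canonical_key()}
    frontier = [(d, ())]
    for _ in range(budget):
        nxt = []
        for cur, path in frontier:
            for m in enumerate_moves(cur, _EXPAND_KINDS):
                if len(out) >= cap:
                    return out, False
                stepped = apply_move(cur, m)
                key = stepped.canonical_key()
                if key in seen:
                    continue
                seen.add(key)
                item = (stepped, path + (m,))
                out.append(item)
                nxt.append(item)
        frontier = nxt
    return out, True


def unknotting_number(
    d: PlanarDiagram,
    max_depth: int = 2,
    expansion_budget: int = 2,
    expansion_cap: int = 150,
    simplify_budget: Budget | None = None,
) -> UnknottingResult:
    """Bounded search for u(d).

    Crossing changes are tried on the simplified diagram and on diagrams
    expanded by up to ``expansion_budget`` crossing-increasing moves (a
    minimal diagram need not expose an unknotting crossing).
    """
    s0, tr0 = simplify(d, simplify_budget)
    if s0.n_crossings == 0 or fingerprint(s0).key() == _trivial_key(d):
        cert = UnknottingCertificate(d, tuple(tr0))
        return UnknottingResult(0, 0, cert, True)

    exhaustive = True

    def search(cur: PlanarDiagram, depth: int):
        nonlocal exhaustive
        cands, complete = _expansions(cur, expansion_budget, expansion_cap)
        if not complete:
            exhaustive = False
        for exp_d, exp_path in cands:
            for x in sorted(exp_d.crossings):
                changed = crossing_change(exp_d, x)
                red, rtr = simplify(changed, simplify_budget)
                step = UnknottingStep(exp_path, MoveRecord("X", (x,)), tuple(rtr))
                if red.n_crossings == 0 or fingerprint(red).key() == _trivial_key(d):
                    return [step]
                if depth > 1:
                    deeper = search(red, depth - 1)
                    if deeper is not None:
                        return [step] + deeper
        return None

    for depth in range(1, max_depth + 1):
        steps = search(s0, depth)
        if steps is not None:
            cert = UnknottingCertificate(d, tuple(tr0), tuple(steps))
            lower = max(1, depth if exhaustive else 1)
            return UnknottingResult(depth, lower, cert, exhaustive)
    return UnknottingResult(None, max_depth + 1 if exhaustive else 1, None, exhaustive)
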