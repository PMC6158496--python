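"""State sums against independent oracles: naive loop-tracing bracket,
subset-formula flow polynomial, naive Yamada enumeration."""

import pytest

from thetaknot.construct import rational_knot, single_passage, trivial_theta, unknot
from thetaknot.fixtures import PerturbSpec, perturb
from thetaknot.laurent import LaurentPoly
from thetaknot.statesum import (
    bracket,
    flow_poly,
    normalized_bracket,
    yamada,
    yamada_raw,
)

from conftest import naive_bracket, naive_yamada, subset_flow_poly


class TestLaurent:
    def test_arithmetic_and_units(self):
        p = LaurentPoly({2: 1, 0: -1})
        q = LaurentPoly({-2: 3})
        assert (p * q)[0] == 3 and (p * q)[-2] == -3
        assert (p - p).is_zero()
        assert p.shift(4).min_exp == 4

    def test_normalized_form(self):
        p = LaurentPoly({-3: -2, 1: 4})
        n = p.normalized()
        assert n.min_exp == 0 and n[0] > 0

    def test_involution_is_mirror_map(self):
        p = LaurentPoly({-1: 2, 3: -5})
        assert p.involution().coeffs() == {1: 2, -3: -5}


class TestBracket:
    def test_unknot_normalization(self):
        assert bracket(unknot()) == LaurentPoly.one()

    def test_matches_naive_enumeration(self):
        # full 2^n state enumeration, independently implemented
        for cf in ([3], [2, 2], [3, 2], [3, 1, 2]):
            d = rational_knot(cf)
            assert bracket(d) == naive_bracket(d)

    def test_r1_multiplies_by_unit_monomial(self):
        from thetaknot import MoveRecord, apply_move

        d = rational_knot([3])
        b0 = bracket(d)
        for over, unit in ((0, LaurentPoly({3: -1})), (1, LaurentPoly({-3: -1}))):
            d2 = apply_move(d, MoveRecord("R1+", (0, over)))
            b2 = bracket(d2)
            assert b2 in (b0 * unit, b0 * unit.involution())

    def test_normalized_bracket_lives_in_fourth_powers(self):
        # f(D) of a knot is a polynomial in A^4: a structural check that
        # couples the writhe sign convention to the smoothing convention
        for cf in ([3], [2, 2], [3, 2], [2, 1, 1, 2]):
            f = normalized_bracket(rational_knot(cf))
            assert all(e % 4 == 0 for e in f.coeffs())

    def test_mirror_is_involution_image(self):
        d = rational_knot([3, 2])
        assert normalized_bracket(d.mirror()) == normalized_bracket(d).involution()


class TestFlowPoly:
    def test_matches_subset_formula(self):
        graphs = [
            [],                                  # empty
            [(0, 0)],                            # loop (circle)
            [(0, 1)],                            # bridge -> 0
            [(0, 1), (0, 1)],                    # digon
            [(0, 1), (0, 1), (0, 1)],            # theta graph
            [(0, 1), (1, 2), (2, 0)],            # triangle
            [(0, 1), (1, 2), (2, 0), (0, 1)],    # triangle + parallel
            [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)],
        ]
        for g in graphs:
            assert flow_poly(g) == subset_flow_poly(g), g

    def test_bridges_vanish(self):
        assert flow_poly([(0, 1), (1, 2), (2, 0), (0, 3)]).is_zero()


class TestYamada:
    def test_trivial_theta_closed_form(self):
        # frozen from the independent naive enumeration of the
        # 0-crossing state sum (flow polynomial of the theta graph)
        expect = naive_yamada(trivial_theta()).normalized()
        assert expect == LaurentPoly({0: 1, 1: -1, 2: 2, 3: -1, 4: 1})
        assert yamada(trivial_theta()) == expect

    def test_matches_naive_enumeration(self, catalog):
        for name in ("theta3_1", "theta4_1", "theta5_6bar", "theta5_7"):
            d = catalog.lookup(name).diagram
            assert yamada_raw(d).normalized() == naive_yamada(d).normalized()

    def test_distinguishes_knotted_from_trivial(self, catalog):
        assert yamada(catalog.lookup("theta3_1").diagram) != yamada(trivial_theta())

    def test_invariant_under_seeded_move_walks(self, catalog):
        d = catalog.lookup("theta3_1").diagram
        y0 = yamada(d)
        for seed in range(5):
            d2 = perturb(d, PerturbSpec(seed, 5, max_crossings=9))
            assert yamada(d2, cap=9 + 4) == y0

    def test_mirror_is_involution_image_up_to_units(self, catalog):
        d = catalog.lookup("theta5_6bar").diagram
        assert yamada(d.mirror()) == yamada(d).involution().normalized()
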