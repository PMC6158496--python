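"""Planar-diagram structure: validation, mirror, writhe, constituents,
edge deletion, canonical forms and the .tdg interchange format."""

import pytest

from thetaknot import tdg
from thetaknot.construct import rational_knot, trivial_theta, unknot
from thetaknot.diagram import (
    KNOT_LABEL,
    SISTER_A,
    SISTER_B,
    THETA_LABELS,
    UNREPLICATED,
    PlanarDiagram,
)


class TestValidate:
    def test_trivial_theta_is_clean(self):
        assert trivial_theta().validate().ok

    def test_zero_crossing_unknot_is_clean(self):
        assert unknot().validate().ok

    def test_missing_vertex_is_reported(self):
        d = trivial_theta()
        bad = PlanarDiagram(vertices={0}, arcs=d.arcs)
        rep = bad.validate()
        assert not rep.ok
        assert any("vertex count" in v or "unused" in v or "refers" in v
                   for v in rep.violations)

    def test_nonplanar_map_is_reported(self):
        # swap two slots at one vertex of the planar theta: V-E+F becomes 0
        d = trivial_theta()
        arcs = dict(d.arcs)
        (ea0, eb0, l0) = arcs[0]
        (ea1, eb1, l1) = arcs[1]
        arcs[0] = (ea0, eb1, l0)
        arcs[1] = (ea1, eb0, l1)
        bad = PlanarDiagram(vertices=d.vertices, arcs=arcs)
        rep = bad.validate()
        assert any("non-planar" in v for v in rep.violations)

    def test_rational_knots_are_valid(self):
        for cf in ([3], [2, 2], [3, 1, 2], [2, 1, 1, 1, 2]):
            assert rational_knot(cf).validate().ok


class TestMirror:
    def test_involution(self):
        for d in (trivial_theta(), rational_knot([3]), rational_knot([3, 2])):
            assert d.mirror().mirror() == d

    def test_trivial_theta_fixed(self):
        t = trivial_theta()
        assert t.mirror() == t

    def test_writhe_negates(self):
        for cf in ([3], [3, 2], [3, 1, 2]):
            d = rational_knot(cf)
            assert d.mirror().writhe() == -d.writhe()


class TestWrithe:
    def test_zero_crossing_unknot(self):
        assert unknot().writhe() == 0

    def test_all_positive_trefoil(self):
        # the right-handed trefoil diagram carries three positive crossings
        assert rational_knot([3]).writhe() == 3

    def test_edge_subset_on_theta(self):
        from thetaknot.construct import build_ri

        d = build_ri(3, precatenane_flag=1)
        assert d.writhe(edge_subset={SISTER_A, SISTER_B}) == 3


class TestConstituents:
    def test_trivial_theta_gives_three_unknots(self):
        cons = trivial_theta().constituents()
        assert set(cons) == set(THETA_LABELS)
        for c in cons.values():
            assert c.is_knot and c.n_crossings == 0 and len(c.loops) == 1

    def test_delete_edge_matches_constituents(self):
        from thetaknot.construct import single_passage

        d = single_passage(1, "INTRA_A", "upper")["product"]
        cons = d.constituents()
        for lab in THETA_LABELS:
            assert d.delete_edge(lab) == cons[lab]

    def test_deleted_label_absent_and_no_vertices(self):
        from thetaknot.construct import single_passage

        d = single_passage(2, "INTER", "lower")["product"]
        k = d.delete_edge(UNREPLICATED)
        assert k.is_knot
        labs = {lab for _, _, lab in k.arcs.values()} | set(k.loops.values())
        assert UNREPLICATED not in labs
        assert labs <= {KNOT_LABEL}

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            trivial_theta().delete_edge("NO_SUCH_EDGE")

    def test_constituents_of_model_product_contain_one_knot(self, catalog):
        t31 = catalog.lookup("theta3_1").diagram
        sizes = sorted(c.n_crossings for c in t31.constituents().values())
        # two constituents lose all crossings only after simplification;
        # the freshly-replicated one keeps the trefoil
        from thetaknot.moves import simplify
        from thetaknot.invariants import knot_fingerprint

        dets = sorted(
            knot_fingerprint(simplify(c)[0]).det
            for c in t31.constituents().values()
        )
        assert dets == [1, 1, 3]


class TestCanonical:
    def test_canonical_is_stable(self):
        d = rational_knot([3, 2])
        assert d.canonical().serialize() == d.canonical().canonical().serialize()

    def test_isomorphism_key_ignores_numbering(self):
        d = rational_knot([3])
        # renumber crossings by +10
        shift = {x + 10: o for x, o in d.crossings.items()}
        arcs = {
            aid: (("x", ea[1] + 10, ea[2]), ("x", eb[1] + 10, eb[2]), lab)
            for aid, (ea, eb, lab) in d.arcs.items()
        }
        d2 = PlanarDiagram(crossings=shift, arcs=arcs)
        assert d.canonical_key() == d2.canonical_key()


class TestTdg:
    @pytest.mark.parametrize("make", [
        trivial_theta,
        unknot,
        lambda: rational_knot([3, 1, 2]),
    ])
    def test_round_trip(self, make):
        d = make()
        text = tdg.dumps(d, comment="round trip")
        back = tdg.loads(text)
        assert back == d

    def test_rejects_invalid(self):
        d = trivial_theta()
        text = tdg.dumps(d)
        # drop an arc line: slots become unused
        lines = [ln for ln in text.splitlines() if not ln.startswith("arc 0")]
        with pytest.raises(tdg.TdgError):
            tdg.loads("\n".join(lines))

    def test_rejects_bad_slot_table(self):
        text = tdg.dumps(trivial_theta()).replace("vertex 0 0,1,2", "vertex 0 1,0,2")
        with pytest.raises(tdg.TdgError):
            tdg.loads(text)
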