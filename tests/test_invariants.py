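"""Fingerprints, determinants, identification and chirality evidence."""

import pytest

from thetaknot import MoveRecord, apply_move
from thetaknot.construct import rational_knot, trivial_theta, unknot
from thetaknot.fixtures import PerturbSpec, perturb
from thetaknot.invariants import (
    Unclassified,
    chirality_evidence,
    determinant,
    identify_knot,
    identify_theta,
    knot_fingerprint,
    theta_fingerprint,
)

from conftest import det_from_bracket


class TestDeterminant:
    @pytest.mark.parametrize("cf,expect", [
        ([3], 3), ([2, 2], 5), ([3, 2], 7), ([3, 1, 2], 11),
        ([2, 1, 1, 2], 13), ([5], 5), ([4, 2], 9),
    ])
    def test_goeritz_matches_bracket_specialization(self, cf, expect):
        d = rational_knot(cf)
        assert determinant(d) == expect
        assert det_from_bracket(d) == expect

    def test_unknot_and_kinked_unknot(self):
        assert determinant(unknot()) == 1
        kinked = apply_move(rational_knot([3]), MoveRecord("R1+", (0, 0)))
        assert determinant(kinked) == 3  # det is a knot invariant

    def test_mirror_preserves_determinant(self):
        d = rational_knot([3, 2])
        assert determinant(d.mirror()) == determinant(d)


class TestFingerprints:
    def test_unknot_with_kinks_matches_bare_unknot(self):
        # writhe normalization makes the bracket fingerprint blind to curls
        from thetaknot.construct import single_passage

        prod = single_passage(0, "INTER", "upper")["product"]
        fr = prod.delete_edge("UNREPLICATED")  # an unknot with clasp residue
        assert knot_fingerprint(fr).key() == knot_fingerprint(unknot()).key()

    def test_trefoil_differs_from_mirror(self):
        d = rational_knot([3])
        assert knot_fingerprint(d).key() != knot_fingerprint(d.mirror()).key()

    def test_theta_fingerprint_carries_constituents(self, catalog):
        fp = theta_fingerprint(catalog.lookup("theta3_1").diagram)
        assert len(fp.constituents) == 3

    def test_catalog_fingerprints_pairwise_distinct(self, catalog):
        keys = [e.fingerprint.key() for e in catalog.knots.values()]
        keys += [e.fingerprint.key() for e in catalog.thetas.values()]
        assert len(keys) == len(set(keys))


class TestIdentify:
    def test_minimal_figure_eight_is_achiral_classified(self):
        r = identify_knot(rational_knot([2, 2]))
        assert r.name == "4_1" and r.chirality == "achiral"

    def test_all_positive_trefoil_is_right_handed(self):
        d = rational_knot([3])
        assert d.writhe() == 3
        assert identify_knot(d).name == "3_1bar"

    def test_constituent_of_mirror_theta56(self, catalog):
        d = catalog.lookup("theta5_6bar").diagram
        from thetaknot.diagram import UNREPLICATED

        fr = d.delete_edge(UNREPLICATED)
        assert identify_knot(fr).name == "5_2bar"

    def test_perturbed_trivial_theta_round_trips(self):
        for seed in (0, 1, 2):
            d = perturb(trivial_theta(), PerturbSpec(seed, 6))
            r = identify_theta(d)
            assert getattr(r, "name", None) == "theta0_1", (seed, r)

    def test_large_product_reports_crossing_bound(self):
        from thetaknot.ri_model import RIConfig, simulate_passage

        r = simulate_passage(RIConfig(5, "INTER", "lower"))
        assert isinstance(r.theta_class, Unclassified)
        assert r.theta_class.crossing_bound >= 7
        assert "UNCLASSIFIED" in r.theta_class.name


class TestChirality:
    def test_figure_eight_achiral_with_certificate(self):
        ev = chirality_evidence(rational_knot([2, 2]))
        assert ev.achiral is True
        assert ev.certificate is not None

    def test_trefoil_chiral_by_fingerprint(self):
        ev = chirality_evidence(rational_knot([3]))
        assert ev.achiral is False
        assert "fingerprint" in ev.reason

    def test_six_three_achiral(self):
        ev = chirality_evidence(rational_knot([2, 1, 1, 2]), max_states=60000)
        assert ev.achiral is True

    def test_theta31_chiral(self, catalog):
        ev = chirality_evidence(catalog.lookup("theta3_1").diagram)
        assert ev.achiral is False
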