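"""The replication-intermediate passage model: construction, passage
sites, product identification, pathway convergence and the second-passage
routes to the 6_2bar FR knot."""

import pytest

from thetaknot.construct import build_ri as raw_build_ri
from thetaknot.diagram import SISTER_A, SISTER_B, UNREPLICATED
from thetaknot.invariants import Unclassified, identify_theta
from thetaknot.ri_model import (
    RIConfig,
    build_ri,
    enumerate_passage_sites,
    mirror_prediction,
    outcome_sets,
    outcome_table,
    second_passage_catalog,
    simulate_passage,
)


@pytest.fixture(scope="module")
def table3():
    return outcome_table(3)


@pytest.fixture(scope="module")
def second_passage():
    return second_passage_catalog()


class TestBuildRI:
    def test_no_windings_gives_trivial_theta(self):
        cfg = RIConfig(0, "INTER", "upper", unreplicated_supercoils=0)
        d = build_ri(cfg)
        assert d.validate().ok
        assert identify_theta(d).name == "theta0_1"

    def test_windings_and_supercoils_alone_do_not_knot(self):
        d = raw_build_ri(3, s=2, precatenane_flag=1)
        assert d.validate().ok
        assert identify_theta(d).name == "theta0_1"

    def test_positive_sign_gives_positive_inter_writhe(self):
        d = raw_build_ri(3, precatenane_flag=1)
        assert d.writhe(edge_subset={SISTER_A, SISTER_B}) == 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RIConfig(-1, "INTER")
        with pytest.raises(ValueError):
            RIConfig(1, "SIDEWAYS")
        with pytest.raises(ValueError):
            RIConfig(3, "INTER", precatenane_crossings=2)


class TestPassageSites:
    def test_overlap_exposes_exactly_two_sites(self):
        from thetaknot.construct import single_passage

        res = single_passage(1, "INTRA_A", "upper")
        sites = enumerate_passage_sites(res["overlap"])
        assert len(sites) == 1 and set(sites[0]) == set(res["sites"])

    def test_no_overlap_means_no_sites(self):
        assert enumerate_passage_sites(raw_build_ri(3, precatenane_flag=1)) == []

    def test_two_routes_have_distinct_products(self):
        up = simulate_passage(RIConfig(2, "INTER", "upper"))
        lo = simulate_passage(RIConfig(2, "INTER", "lower"))
        assert up.theta_name != lo.theta_name


class TestSinglePassage:
    def test_minimal_intra_gives_theta31_and_right_trefoil(self):
        r = simulate_passage(RIConfig(1, "INTRA_A"))
        assert r.theta_name == "theta3_1"
        assert r.fr_name == "3_1bar"

    def test_inter_three_windings_gives_mirror_theta56(self):
        r = simulate_passage(RIConfig(3, "INTER"))
        assert r.theta_name == "theta5_6bar"
        assert r.fr_name == "5_2bar"

    def test_large_windings_exceed_the_curve_table(self):
        r = simulate_passage(RIConfig(6, "INTER"))
        assert isinstance(r.theta_class, Unclassified)
        assert r.theta_class.crossing_bound > 7

    def test_certificate_replays_to_product_bit_exactly(self):
        from thetaknot.moves import replay

        r = simulate_passage(RIConfig(2, "INTRA_B"))
        assert replay(r.base, r.certificate).serialize() == r.product.serialize()

    def test_passage_locality_one_flag_flips(self):
        from thetaknot.construct import single_passage

        res = single_passage(2, "INTRA_A", "lower")
        before = res["overlap"].crossings
        after = res["product"].crossings
        assert sorted(before) == sorted(after)
        diffs = [x for x in before if before[x] != after[x]]
        assert len(diffs) == 1 and diffs[0] in res["sites"]


class TestOutcomeTable(object):
    def test_intra_and_inter_sets_agree(self, table3):
        sets = outcome_sets(table3)
        assert sets["INTRA_A"] == sets["INTER"]
        assert sets["INTRA_B"] == sets["INTER"]
        assert "theta3_1" in sets["INTER"]

    def test_fr_crossings_monotone_in_trapped_windings(self, table3):
        knotted = table3[table3.fr_crossings > 0]
        for locus in ("INTRA_A", "INTRA_B", "INTER"):
            sub = knotted[knotted.locus == locus].sort_values("trapped_windings")
            fr = list(sub.fr_crossings)
            assert fr == sorted(fr)

    def test_first_knotting_events_have_three_then_four_crossings(self, table3):
        knotted = table3[table3.fr_crossings > 0]
        ladder = sorted(set(knotted.fr_crossings))
        assert ladder[:2] == [3, 4]

    def test_positive_series_is_right_handed_or_achiral(self, table3, catalog):
        for name in set(table3[table3.classified].fr_knot) - {"0_1"}:
            e = catalog.lookup(name)
            assert e.chirality in ("mirror", "achiral"), name

    def test_trapped_windings_equal_fr_crossings_minus_two(self, table3):
        knotted = table3[table3.fr_crossings > 0]
        assert all(knotted.fr_crossings == knotted.trapped_windings + 2)


class TestMirrorPrediction:
    def test_maps_series_to_mirror_classes(self):
        r = simulate_passage(RIConfig(3, "INTER"))
        m = mirror_prediction(r)
        assert m.theta_name == "theta5_6"
        assert m.fr_name == "5_2"

    def test_achiral_fr_knot_is_fixed(self):
        r = simulate_passage(RIConfig(2, "INTRA_A"))
        m = mirror_prediction(r)
        assert m.fr_name == r.fr_name == "4_1"

    def test_double_mirror_restores_classes(self):
        r = simulate_passage(RIConfig(1, "INTRA_A"))
        mm = mirror_prediction(mirror_prediction(r))
        assert mm.theta_name == r.theta_name
        assert mm.fr_name == r.fr_name


class TestSecondPassage:
    def test_four_pathways_all_give_62bar_fr_knot(self, second_passage):
        assert len(second_passage) == 4
        assert all(p.fr_name == "6_2bar" for p in second_passage)

    def test_starting_classes(self, second_passage):
        starts = [p.config["start_class"] for p in second_passage]
        assert starts[0] == "theta0_1"
        assert starts[1] == "theta3_1"
        assert set(starts[2:]) <= {"theta4_1", "theta4_1bar"}

    def test_pathway_ii_starts_from_knotted_ri(self, second_passage):
        p = second_passage[1]
        assert identify_theta(p.base).name == "theta3_1"
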