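"""Catalog integrity: lookups, verification gate, negative controls."""

import dataclasses

import pytest

from thetaknot.catalog import load_catalog, verify_catalog


class TestLookup:
    def test_trivial_theta_entry(self, catalog):
        e = catalog.lookup("theta0_1")
        assert e.unknotting_number == 0
        assert e.crossing_number == 0
        assert e.constituent_names == ("0_1", "0_1", "0_1")

    def test_figure_eight_is_achiral(self, catalog):
        assert catalog.lookup("4_1").chirality == "achiral"
        assert catalog.lookup("6_3").chirality == "achiral"

    def test_unknotting_number_one_entries(self, catalog):
        for name in ("theta3_1", "theta4_1", "theta5_6", "theta5_7"):
            assert catalog.lookup(name).unknotting_number == 1

    def test_mirror_name_resolution(self, catalog):
        assert catalog.mirror_name("3_1") == "3_1bar"
        assert catalog.mirror_name("3_1bar") == "3_1"
        assert catalog.mirror_name("4_1") == "4_1"

    def test_knot_census_complete_to_seven_crossings(self, catalog):
        base = {e.base_name for e in catalog.knots.values()}
        assert base == {
            "0_1", "3_1", "4_1", "5_1", "5_2", "6_1", "6_2", "6_3",
            "7_1", "7_2", "7_3", "7_4", "7_5", "7_6", "7_7",
        }

    def test_unknown_name_raises(self, catalog):
        with pytest.raises(KeyError):
            catalog.lookup("theta9_99")


class TestVerification:
    def test_shipped_catalog_verifies_clean(self, catalog):
        rep = verify_catalog(catalog)
        assert rep.ok, rep.failures

    def test_mislabelled_constituent_is_caught(self, catalog):
        broken_entry = dataclasses.replace(
            catalog.thetas["theta3_1"],
            constituent_names=("0_1", "0_1", "4_1"),
        )
        broken = type(catalog)(
            catalog.knots, {**catalog.thetas, "theta3_1": broken_entry}
        )
        rep = verify_catalog(broken)
        assert any("theta3_1" in f and "constituents" in f for f in rep.failures)

    def test_wrong_unknotting_claim_is_caught(self, catalog):
        broken_entry = dataclasses.replace(
            catalog.thetas["theta0_1"],
            unknotting_number=1,
        )
        broken = type(catalog)(
            catalog.knots, {**catalog.thetas, "theta0_1": broken_entry}
        )
        rep = verify_catalog(broken)
        assert any("theta0_1" in f for f in rep.failures)

    def test_single_nontrivial_constituent_pattern_holds(self, catalog):
        rep = verify_catalog(catalog)
        # reported, not enforced; the shipped entries all satisfy it
        assert rep.notes == []
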