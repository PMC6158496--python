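"""Unknotting-number search: bounds, certificates, negative controls."""

import dataclasses

import pytest

from thetaknot.construct import rational_knot, trivial_theta
from thetaknot.unknotting import (
    UnknottingCertificate,
    unknotting_number,
    verify_certificate,
)


class TestSearch:
    def test_trivial_theta_has_u_zero(self):
        res = unknotting_number(trivial_theta())
        assert (res.u_upper, res.u_lower) == (0, 0)
        assert verify_certificate(res.certificate)

    def test_theta31_unknots_in_one_change(self, catalog):
        res = unknotting_number(catalog.lookup("theta3_1").diagram, max_depth=1)
        assert res.value == 1
        assert verify_certificate(res.certificate)

    def test_theta57_certificate_site_is_catalogued(self, catalog):
        e = catalog.lookup("theta5_7")
        res = unknotting_number(e.diagram, max_depth=1)
        assert res.value == 1
        site = res.certificate.steps[0].change.site[0]
        assert site in e.unknotting_sites

    def test_trefoil_knot_unknots_in_one_change(self):
        res = unknotting_number(rational_knot([3]), max_depth=1)
        assert res.value == 1

    def test_mirror_has_equal_unknotting_number(self, catalog):
        d = catalog.lookup("theta5_6").diagram
        r1 = unknotting_number(d, max_depth=1)
        r2 = unknotting_number(d.mirror(), max_depth=1)
        assert r1.value == r2.value == 1


class TestCertificates:
    def test_perturbed_change_site_fails_verification(self, catalog):
        e = catalog.lookup("theta5_7")
        res = unknotting_number(e.diagram, max_depth=1)
        good = res.certificate
        step = good.steps[0]
        other = next(
            x for x in sorted(e.diagram.crossings)
            if x not in e.unknotting_sites
        )
        bad_step = dataclasses.replace(
            step,
            change=dataclasses.replace(step.change, site=(other,)),
            simplification=(),
        )
        bad = UnknottingCertificate(good.start, good.pre_simplification, (bad_step,))
        assert not verify_certificate(bad)

    def test_empty_certificate_on_trivial_theta(self):
        cert = UnknottingCertificate(trivial_theta(), (), ())
        assert verify_certificate(cert)
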