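"""Property-based invariants: ring axioms of the polynomial arithmetic
and structural preservation under random move noise."""

from hypothesis import given, settings, strategies as st

from thetaknot.construct import rational_knot, trivial_theta
from thetaknot.fixtures import PerturbSpec, perturb
from thetaknot.laurent import LaurentPoly

SETTINGS = dict(derandomize=True, max_examples=25, deadline=None)

poly = st.dictionaries(
    st.integers(min_value=-6, max_value=6),
    st.integers(min_value=-9, max_value=9),
    max_size=5,
).map(LaurentPoly)


class TestLaurentRing:
    @given(p=poly, q=poly, r=poly)
    @settings(**SETTINGS)
    def test_distributivity_and_commutativity(self, p, q, r):
        assert p * (q + r) == p * q + p * r
        assert p * q == q * p
        assert p + q == q + p

    @given(p=poly)
    @settings(**SETTINGS)
    def test_involution_is_an_involution(self, p):
        assert p.involution().involution() == p

    @given(p=poly)
    @settings(**SETTINGS)
    def test_normalization_is_idempotent_and_unit_equivalent(self, p):
        n = p.normalized()
        assert n.normalized() == n
        if p:
            assert n.min_exp == 0 and n[0] > 0


class TestDiagramNoise:
    @given(seed=st.integers(min_value=0, max_value=10_000),
           n=st.integers(min_value=0, max_value=6))
    @settings(**SETTINGS)
    def test_perturbed_theta_stays_a_valid_planar_theta(self, seed, n):
        d = perturb(trivial_theta(), PerturbSpec(seed, n, max_crossings=8))
        rep = d.validate()
        assert rep.ok, rep.violations
        assert d.is_theta

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(**SETTINGS)
    def test_perturbed_knot_keeps_one_component_and_planarity(self, seed):
        d = perturb(rational_knot([3]), PerturbSpec(seed, 4, max_crossings=8))
        assert d.validate().ok
        assert d.is_knot

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(**SETTINGS)
    def test_mirror_commutes_with_perturbation_fingerprint(self, seed):
        from thetaknot.statesum import normalized_bracket

        d = perturb(rational_knot([3]), PerturbSpec(seed, 3, max_crossings=8))
        assert normalized_bracket(d.mirror()) == normalized_bracket(d).involution()
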