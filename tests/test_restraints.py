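"""Restraint-engine tests: averaging, target function, rigid-body optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domeq import (
    BiGaussianModel,
    Conformer,
    DistanceDistribution,
    DistanceGrid,
    DistanceRestraint,
    RigidDomain,
    TwoStateEnsemble,
    effective_deer_distance,
    ensemble_average_distance,
    karplus_backcalc,
    make_limits,
    optimize_two_state,
    target_function,
)
from domeq.restraints import KARPLUS_COEFFICIENTS


def two_point_ensemble(d1: float, d2: float, p1: float = 0.5) -> TwoStateEnsemble:
    """Two states, each a single conformer with one interatomic pair."""
    confs = [Conformer({(1, "CA"): np.zeros(3), (2, "CA"): np.array([d, 0.0, 0.0])})
             for d in (d1, d2)]
    return TwoStateEnsemble(confs, [1, 2], np.array([p1, 1.0 - p1]))


class TestEffectiveDistance:
    def test_delta_density(self):
        grid = DistanceGrid(15.0, 80.0, 131)
        j = int(np.argmin(np.abs(grid.r - 30.0)))
        dens = np.zeros(grid.n_points)
        dens[j] = 1.0 / grid.trapezoid_weights[j]
        d = DistanceDistribution(grid, dens)
        assert effective_deer_distance(d.normalized()) == pytest.approx(30.0, abs=0.05)

    def test_symmetric_mixture(self, grid):
        d = BiGaussianModel(20.0, 0.8, 0.5, 40.0, 0.8).density(grid)
        assert effective_deer_distance(d) == pytest.approx(30.0, abs=0.01)

    def test_apo_mixture_against_quadrature(self, grid):
        """68:32 mixture of G(22, 1.5) and G(45, 8): the linear average
        equals the quadrature value 29.36 A."""
        d = BiGaussianModel(22.0, 1.5, 0.68, 45.0, 8.0).density(grid)
        r_fine = np.linspace(15.0, 80.0, 20001)
        pdf = BiGaussianModel(22.0, 1.5, 0.68, 45.0, 8.0).pdf(r_fine)
        pdf /= np.trapezoid(pdf, r_fine)
        oracle = np.trapezoid(r_fine * pdf, r_fine)
        assert oracle == pytest.approx(29.36, abs=0.01)
        assert effective_deer_distance(d) == pytest.approx(oracle, abs=0.01)

    def test_unnormalized_warns_and_normalizes(self, grid):
        d = BiGaussianModel(22.0, 1.5, 0.68, 45.0, 8.0).density(grid)
        doubled = DistanceDistribution(grid, 2.0 * d.density)
        with pytest.warns(UserWarning, match="normaliz"):
            assert effective_deer_distance(doubled) == pytest.approx(
                effective_deer_distance(d), abs=1e-9)


class TestMakeLimits:
    def test_default_tolerance(self):
        assert make_limits(29.4) == (pytest.approx(24.4), pytest.approx(34.4))

    def test_zero_tolerance_degenerate(self):
        lo, hi = make_limits(30.0, tolerance=0.0)
        assert lo == hi == 30.0

    def test_clamps_lower_at_one(self):
        with pytest.warns(UserWarning, match="clamped"):
            lo, hi = make_limits(3.0, tolerance=5.0)
        assert lo == 1.0 and hi == 8.0

    def test_batch_preserves_order(self):
        values = [29.4, 45.0, 22.0]
        out = [make_limits(v) for v in values]
        assert [pytest.approx(v - 5) for v in values] == [lo for lo, _ in out]


class TestEnsembleAveraging:
    def test_identical_states_any_mode(self):
        ens = two_point_ensemble(10.0, 10.0)
        pair = ((1, "CA"), (2, "CA"))
        assert ensemble_average_distance(ens, pair, "r6") == pytest.approx(10.0)
        assert ensemble_average_distance(ens, pair, "linear") == pytest.approx(10.0)

    def test_r6_average_compact_dominates(self):
        ens = two_point_ensemble(3.0, 30.0)
        expected = (0.5 * 3.0**-6 + 0.5 * 30.0**-6) ** (-1.0 / 6.0)
        got = ensemble_average_distance(ens, ((1, "CA"), (2, "CA")), "r6")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3.367, abs=0.001)

    def test_linear_average(self):
        ens = two_point_ensemble(3.0, 30.0)
        assert ensemble_average_distance(ens, ((1, "CA"), (2, "CA")), "linear") == \
            pytest.approx(16.5)

    @settings(deadline=None, max_examples=50)
    @given(d1=st.floats(2.0, 60.0), d2=st.floats(2.0, 60.0), p1=st.floats(0.01, 0.99))
    def test_r6_never_exceeds_linear(self, d1, d2, p1):
        """Power-mean inequality: the exponent -6 mean is always <= the
        arithmetic mean for any two-state ensemble."""
        ens = two_point_ensemble(d1, d2, p1)
        pair = ((1, "CA"), (2, "CA"))
        assert ensemble_average_distance(ens, pair, "r6") <= \
            ensemble_average_distance(ens, pair, "linear") + 1e-9

    def test_missing_atom_raises_with_name(self):
        ens = two_point_ensemble(3.0, 30.0)
        with pytest.raises(KeyError, match="residue 9"):
            ensemble_average_distance(ens, ((1, "CA"), (9, "CB")), "r6")


class TestTargetFunction:
    def test_satisfied_restraints_zero(self):
        ens = two_point_ensemble(10.0, 10.0)
        rep = target_function(ens, [DistanceRestraint((1, "CA"), (2, "CA"), "NOE", 5.0, 15.0)])
        assert rep.tf == 0.0 and rep.n_violated == 0

    def test_violation_squared(self):
        ens = two_point_ensemble(10.0, 10.0)
        rep = target_function(ens, [DistanceRestraint((1, "CA"), (2, "CA"), "NOE", 1.0, 8.0)])
        assert rep.tf == pytest.approx(4.0)
        assert rep.n_violated == 1

    def test_pre_weight_rule(self):
        ens = two_point_ensemble(10.0, 10.0)
        rep = target_function(ens, [DistanceRestraint((1, "CA"), (2, "CA"), "PRE", 1.0, 8.0)])
        assert rep.tf == pytest.approx(0.04)

    def test_tf_equals_sum_of_contributions(self):
        ens = two_point_ensemble(4.0, 30.0)
        restraints = [
            DistanceRestraint((1, "CA"), (2, "CA"), "NOE", 1.0, 5.0),
            DistanceRestraint((1, "CA"), (2, "CA"), "DEER", 20.0, 25.0),
            DistanceRestraint((1, "CA"), (2, "CA"), "PRE", 1.0, 4.0),
        ]
        rep = target_function(ens, restraints)
        assert rep.tf == pytest.approx(sum(r["weighted_sq_A2"] for r in rep.per_restraint), abs=1e-9)

    def test_widening_bounds_never_increases_tf(self):
        ens = two_point_ensemble(4.0, 30.0)
        base = DistanceRestraint((1, "CA"), (2, "CA"), "DEER", 20.0, 25.0)
        wide = DistanceRestraint((1, "CA"), (2, "CA"), "DEER", 15.0, 30.0)
        assert target_function(ens, [wide]).tf <= target_function(ens, [base]).tf

    def test_empty_restraints_warn(self):
        ens = two_point_ensemble(10.0, 10.0)
        with pytest.warns(UserWarning, match="empty"):
            assert target_function(ens, []).tf == 0.0


@pytest.fixture(scope="module")
def domains(truth_module):
    return RigidDomain(truth_module.domain_a), RigidDomain(truth_module.domain_b_base)


@pytest.fixture(scope="module")
def truth_module():
    from domeq import make_two_domain_system
    return make_two_domain_system(seed=0)


@pytest.fixture(scope="module")
def compact_noes(truth_module):
    from domeq import truth_to_measurements
    from domeq.synthetic import NoiseConfig
    return truth_to_measurements(truth_module, NoiseConfig(0.0, 0.0), seed=1).noes


class TestOptimizer:
    def test_realizable_single_state(self, domains, truth_module, compact_noes):
        ens, rep = optimize_two_state(domains[0], domains[1], compact_noes,
                                      n_states=1, n_starts=8, seed=0)
        assert rep.tf <= 1e-3

    def test_two_state_necessity_contrast(self, domains, truth_module, compact_noes):
        """Compact-only NOEs plus an extended-state label distance cannot
        be satisfied by one placement but can by two."""
        la, lb = truth_module.label_atoms()
        restraints = list(compact_noes) + [
            DistanceRestraint(la, lb, "DEER", 40.0, 50.0, state=2)]
        _, rep1 = optimize_two_state(domains[0], domains[1], restraints,
                                     n_states=1, n_starts=8, seed=0)
        ens2, rep2 = optimize_two_state(domains[0], domains[1], restraints,
                                        n_states=2, n_starts=8, seed=0)
        assert rep1.tf >= 10.0
        assert rep2.tf <= 0.5
        assert rep2.tf <= rep1.tf  # two states always at least as good
        # recovered extended label distance near the planted 45 A
        conf = ens2.state_conformers(2)[0]
        d = np.linalg.norm(conf.position(la) - conf.position(lb))
        assert d == pytest.approx(45.0, abs=5.0)

    def test_rigid_body_contract(self, domains, truth_module, compact_noes):
        """Optimization moves domains, never distorts them: intradomain
        distances of the mobile domain are preserved in every state."""
        la, lb = truth_module.label_atoms()
        restraints = list(compact_noes) + [
            DistanceRestraint(la, lb, "DEER", 40.0, 50.0, state=2)]
        ens, _ = optimize_two_state(domains[0], domains[1], restraints,
                                    n_states=2, n_starts=2, seed=0)
        base = truth_module.domain_b_base
        keys = sorted(base.coords)[:20]
        ref = np.array([np.linalg.norm(base.coords[keys[i]] - base.coords[keys[j]])
                        for i in range(10) for j in range(10, 20)])
        for conf in ens.conformers:
            got = np.array([np.linalg.norm(conf.position(keys[i]) - conf.position(keys[j]))
                            for i in range(10) for j in range(10, 20)])
            assert np.allclose(got, ref, atol=1e-8)

    def test_fixed_populations_respected(self, domains, truth_module, compact_noes):
        la, lb = truth_module.label_atoms()
        restraints = list(compact_noes) + [
            DistanceRestraint(la, lb, "DEER", 40.0, 50.0, state=2)]
        ens, _ = optimize_two_state(domains[0], domains[1], restraints,
                                    n_states=2, n_starts=2, seed=0,
                                    populations=(0.7, 0.3))
        assert tuple(ens.populations) == (0.7, 0.3)

    def test_invalid_inputs(self, domains, compact_noes):
        with pytest.raises(ValueError, match="n_states"):
            optimize_two_state(domains[0], domains[1], compact_noes, n_states=3)
        intra = [DistanceRestraint((1, "CA"), (2, "CA"), "NOE", 1.0, 8.0)]
        with pytest.raises(ValueError, match="interdomain"):
            optimize_two_state(domains[0], domains[1], intra, n_states=1)


class TestKarplus:
    def test_zero_dihedral_sums_coefficients(self):
        a, b, c, offset = KARPLUS_COEFFICIENTS["3JNCG"]
        assert offset == 0.0
        assert karplus_backcalc(0.0, "3JNCG") == pytest.approx(a + b + c)

    def test_even_symmetry_of_cos_squared_term(self):
        KARPLUS_COEFFICIENTS["_TEST_B0"] = (8.0, 0.0, 1.0, 0.0)
        try:
            theta = np.linspace(-180.0, 180.0, 91)
            j = karplus_backcalc(theta, "_TEST_B0")
            assert np.allclose(j, karplus_backcalc(-theta, "_TEST_B0"))
        finally:
            del KARPLUS_COEFFICIENTS["_TEST_B0"]

    def test_hnha_matches_independent_evaluation(self):
        phi = np.linspace(-180.0, 180.0, 181)
        a, b, c, offset = KARPLUS_COEFFICIENTS["3JHNHA"]
        expected = a * np.cos(np.deg2rad(phi + offset)) ** 2 \
            + b * np.cos(np.deg2rad(phi + offset)) + c
        assert np.allclose(karplus_backcalc(phi, "3JHNHA"), expected, atol=1e-9)

    def test_unregistered_type_raises(self):
        with pytest.raises(ValueError, match="no Karplus"):
            karplus_backcalc(60.0, "3JXX")
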