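import numpy as np
import pytest
from scipy.integrate import solve_ivp

from coexdd.equilibria import (
    FEASIBILITY_TOL,
    ROOT_RESIDUAL_TOL,
    classify_coexistence,
    find_equilibria,
    invasion_growth_rate,
    jacobian,
    single_species_equilibria,
)
from coexdd.models import TwoSpeciesParams, evaluate_rhs, make_rhs
from coexdd.mortality import MortalitySpec, evaluate_mortality, mortality_density_slope


def asym(d, a1, s=0.0):
    return TwoSpeciesParams("asym_competition", d=d, alpha1=a1,
                            mortality=MortalitySpec("hyperbolic", s))


class TestSingleSpecies:
    def test_constant_mortality_gives_logistic_root(self):
        eqs = single_species_equilibria(0.4, MortalitySpec("hyperbolic", 0.0))
        assert (0.0, False) in eqs
        nz = [e for e in eqs if e[0] > 0]
        assert nz == [(pytest.approx(0.6), True)]

    def test_no_mortality_gives_carrying_capacity(self):
        for s in (0.0, 1.0, 1e3):
            eqs = single_species_equilibria(0.0, MortalitySpec("hyperbolic", s))
            nz = [e for e in eqs if e[0] > 0]
            assert nz == [(pytest.approx(1.0), True)]

    def test_hyperbolic_closed_form_root(self):
        # positive root of n^2 + 0 n - 0.5 = 0 is sqrt(0.5)
        spec = MortalitySpec("hyperbolic", 1.0)
        eqs = single_species_equilibria(0.5, spec)
        root = [e for e in eqs if e[0] > 0][0][0]
        assert root == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert abs(1 - root - 0.5 * evaluate_mortality(spec, root)) < 1e-12
        # independent oracle: long ODE integration
        sol = solve_ivp(lambda t, n: n * (1 - n - 0.5 / (1 + n)), (0, 500), [0.1],
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(root, abs=1e-6)

    def test_mortality_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            single_species_equilibria(1.2, MortalitySpec())

    @pytest.mark.parametrize("kind", ["exponential", "linear"])
    def test_generic_kinds_roots_have_zero_percapita_growth(self, kind):
        spec = MortalitySpec(kind, 2.0)
        for n, _ in single_species_equilibria(0.7, spec):
            if n > 0:
                assert abs(1 - n - 0.7 * evaluate_mortality(spec, n)) < 1e-10


class TestFindEquilibria:
    def test_interior_closed_form_at_zero_factor(self):
        recs = find_equilibria(asym(0.5, 0.5))
        interior = [r for r in recs if np.all(r.location > FEASIBILITY_TOL)]
        assert len(interior) == 1
        assert interior[0].location == pytest.approx([0.5, 0.25], abs=1e-10)
        assert interior[0].locally_stable

    def test_uncoupled_logistics(self):
        recs = find_equilibria(asym(0.0, 0.0))
        interior = [r for r in recs if np.all(r.location > FEASIBILITY_TOL)]
        assert len(interior) == 1
        assert interior[0].location == pytest.approx([1.0, 1.0], abs=1e-10)

    def test_interference_interior_roots_satisfy_equations(self):
        p = TwoSpeciesParams("repro_interference", d=0.5, alpha1p=0.5,
                             mortality=MortalitySpec("hyperbolic", 100.0))
        recs = find_equilibria(p)
        interior = [r for r in recs if np.all(r.location > FEASIBILITY_TOL)]
        assert interior  # the high-factor regime restores coexistence
        for r in interior:
            n1, n2 = r.location
            b1 = 1 - n1 - 0.5 * evaluate_mortality(p.mortality, n1)
            b2 = (n2 / (n2 + 0.5 * n1) - n2
                  - 0.5 * evaluate_mortality(p.mortality, n2))
            assert abs(b1) < 1e-9 and abs(b2) < 1e-9

    def test_all_records_have_tiny_residuals(self):
        for s in (0.0, 2.0, 50.0):
            for r in find_equilibria(asym(0.9, 0.5, s)):
                assert r.residual < ROOT_RESIDUAL_TOL
                resid = np.max(np.abs(evaluate_rhs(asym(0.9, 0.5, s), r.location)))
                assert resid < ROOT_RESIDUAL_TOL

    def test_least_competitive_never_denser(self, rng):
        # at a feasible interior equilibrium of the asymmetric model, n2 <= n1
        for _ in range(40):
            p = asym(rng.uniform(0, 0.95), rng.uniform(0, 1), rng.uniform(0, 200))
            for r in find_equilibria(p):
                if np.all(r.location > FEASIBILITY_TOL) and r.feasible:
                    n1, n2 = r.location
                    assert n2 <= n1 + 1e-9


def analytic_jacobian_asym(p: TwoSpeciesParams, n):
    """Independent closed-form Jacobian of the asymmetric-competition model."""
    n1, n2 = n
    D1 = evaluate_mortality(p.mortality, n1)
    D2 = evaluate_mortality(p.mortality, n2)
    Dp1 = mortality_density_slope(p.mortality, n1)
    Dp2 = mortality_density_slope(p.mortality, n2)
    return np.array([
        [1 - 2 * n1 - p.d * (D1 + n1 * Dp1), 0.0],
        [-p.alpha1 * n2, 1 - p.alpha1 * n1 - 2 * n2 - p.d * (D2 + n2 * Dp2)],
    ])


class TestJacobian:
    def test_single_species_stable_equilibrium_is_negative(self):
        import coexdd.models as m
        p = m.CommunityParams(comp=np.eye(1), ri=np.eye(1), delta=np.zeros(1), d=0.3)
        jac = jacobian(p, np.array([0.7]))
        assert jac.shape == (1, 1) and jac[0, 0] < 0

    def test_species_one_insensitive_to_species_two(self):
        p = asym(0.5, 0.5)
        jac = jacobian(p, np.array([0.5, 0.25]))
        assert abs(jac[0, 1]) < 1e-8

    def test_matches_analytic_on_random_interior_points(self, rng):
        for _ in range(100):
            p = asym(rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 50))
            n = rng.uniform(0.05, 1.2, size=2)
            fd = jacobian(p, n)
            an = analytic_jacobian_asym(p, n)
            assert np.allclose(fd, an, rtol=1e-5, atol=1e-6)

    def test_negative_coordinates_rejected(self):
        with pytest.raises(ValueError):
            jacobian(asym(0.5, 0.5), np.array([-0.1, 0.2]))


class TestInvasionRate:
    def test_closed_form_at_zero_factor(self):
        d, a1 = 0.5, 0.5
        rate = invasion_growth_rate(asym(d, a1), 1, np.array([1 - d, 0.0]))
        assert rate == pytest.approx((1 - d) * (1 - a1), abs=1e-12)
        assert rate > 0

    def test_interference_blocks_rare_invader(self):
        p = TwoSpeciesParams("repro_interference", d=0.5, alpha=0.2, alpha1p=0.6)
        recs = find_equilibria(p)
        res = [r for r in recs if r.location[1] == 0 and r.location[0] > 0][0]
        rate = invasion_growth_rate(p, 1, res.location)
        assert rate == pytest.approx(-0.2 * res.location[0] - 0.5, abs=1e-9)
        assert rate < 0

    def test_empty_community_rate(self):
        rate = invasion_growth_rate(asym(0.3, 0.5), 0, np.zeros(2))
        assert rate == pytest.approx(0.7, abs=1e-12)

    def test_non_equilibrium_resident_rejected(self):
        with pytest.raises(ValueError):
            invasion_growth_rate(asym(0.5, 0.5), 1, np.array([0.123, 0.0]))

    def test_sign_agrees_with_direct_simulation(self, rng):
        # integrate the would-be invader from density 1e-6 and compare signs
        checked = 0
        for _ in range(200):
            d = rng.uniform(0.05, 0.95)
            a1 = rng.uniform(0, 1)
            s = rng.uniform(0, 100)
            p = asym(d, a1, s)
            residents = [r for r in find_equilibria(p)
                         if r.location[1] == 0 and r.location[0] > 0
                         and r.locally_stable]
            if not residents:
                continue
            res = residents[0]
            rate = invasion_growth_rate(p, 1, res.location)
            if abs(rate) < 1e-6:
                continue
            y0 = np.array([res.location[0], 1e-6])
            f = make_rhs(p)
            grew = None
            t, y = 0.0, y0
            while grew is None and t < 5e3:
                sol = solve_ivp(f, (t, t + 100.0), y, rtol=1e-10, atol=1e-14,
                                method="LSODA")
                t, y = sol.t[-1], sol.y[:, -1]
                if y[1] > 1e-5:
                    grew = True
                elif y[1] < 1e-7:
                    grew = False
            assert grew is not None
            assert grew == (rate > 0)
            checked += 1
        assert checked >= 50


class TestClassify:
    def test_zero_factor_is_global_with_closed_form(self):
        d, a1 = 0.5, 0.5
        cls = classify_coexistence(asym(d, a1))
        assert cls.label == "global_attractor"
        expect = [1 - d, (1 - d) * (1 - a1)]
        assert cls.coexistence_eq.location == pytest.approx(expect, abs=1e-8)

    def test_high_factor_is_local(self):
        cls = classify_coexistence(asym(0.9, 0.5, 100.0))
        assert cls.label == "local_attractor"
        assert cls.coexistence_eq.feasible and cls.coexistence_eq.locally_stable

    def test_intermediate_factor_loses_coexistence(self):
        cls = classify_coexistence(asym(0.9, 0.5, 1.0))
        assert cls.label == "none"
        assert cls.coexistence_eq is None

    def test_interference_never_global(self):
        for a1p in (0.1, 0.6):
            for s in (0.0, 50.0):
                p = TwoSpeciesParams("repro_interference", d=0.5, alpha1p=a1p,
                                     mortality=MortalitySpec("hyperbolic", s))
                assert classify_coexistence(p).label != "global_attractor"

    def test_label_invariant(self):
        cls = classify_coexistence(asym(0.9, 0.5, 100.0))
        assert cls.label == "none" or (
            cls.coexistence_eq is not None
            and cls.coexistence_eq.feasible
            and cls.coexistence_eq.locally_stable
        )
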