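"""Closed-form rates, probabilities, and geometric approximations."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from patchadapt.params import ParameterError, Patch, PatchLayout, PopulationParams
from patchadapt import theory


class TestEstablishmentAndWidth:
    @pytest.mark.parametrize(
        "s_p, xi2, expected",
        [(0.05, 1.0, 0.1), (0.0, 1.0, 0.0), (0.01, 1.0, 0.02), (0.9, 1.0, 1.0)],
    )
    def test_panmictic_establishment(self, s_p, xi2, expected):
        assert theory.panmictic_establishment_prob(s_p, xi2) == pytest.approx(expected)

    def test_panmictic_establishment_rejects_bad_xi2(self):
        with pytest.raises(ParameterError):
            theory.panmictic_establishment_prob(0.05, 0.0)

    def test_critical_width_equal_coefficients(self):
        s = 0.04
        assert theory.critical_patch_width(1.0, s, s) == pytest.approx(
            (1.0 / math.sqrt(2 * s)) * math.pi / 4
        )

    def test_critical_width_values_and_limit(self):
        assert theory.critical_patch_width(1.0, 0.1, 0.02) == pytest.approx(
            (1 / math.sqrt(0.2)) * math.atan(math.sqrt(0.2)), rel=1e-12
        )
        assert theory.critical_patch_width(1.0, 0.1, 0.0) == 0.0


class TestRates:
    def test_lambda_mut_linearity_and_value(self, base_params):
        # no mutation, no influx
        p0 = PopulationParams(sigma=1, s_m=0.05, s_p=0.1, mu=0.0, rho=10)
        assert theory.lambda_mut(p0, 5.0) == 0.0
        # linear in rho (hence in rho * A)
        lam1 = theory.lambda_mut(base_params, 7.0)
        doubled = PopulationParams(sigma=1, s_m=0.05, s_p=0.1, mu=1e-5, rho=20.0)
        assert theory.lambda_mut(doubled, 7.0) == pytest.approx(2 * lam1)
        # value at the lattice-experiment scale: rho*A = 99000, s_p = 0.0023
        p = PopulationParams(sigma=1, s_m=0.05, s_p=0.0023, mu=1e-5, rho=1000.0)
        assert theory.lambda_mut(p, 99.0) == pytest.approx(0.0045540, rel=1e-4)

    def test_lambda_mig_hand_value(self):
        # C = A' = rho = 1, s_m = 0.05, p_e = 0.1, d = 1, R/sigma = 20
        p = PopulationParams(sigma=1.0, s_m=0.05, s_p=0.05, mu=1e-5, rho=1.0)
        assert p.p_e == pytest.approx(0.1)
        lam = theory.lambda_mig(20.0, p, 1.0)
        assert lam == pytest.approx(0.05 * 0.05 * math.exp(-20 * math.sqrt(0.1)), rel=1e-12)
        assert lam == pytest.approx(4.5e-6, rel=0.01)

    def test_lambda_mig_one_char_length_decay(self, base_params):
        ell = base_params.char_length
        r0 = 10.0
        ratio = theory.lambda_mig(r0 + ell, base_params, 1.0) / theory.lambda_mig(
            r0, base_params, 1.0
        )
        assert ratio == pytest.approx(math.exp(-1))

    def test_lambda_mig_min_branch(self):
        # p_e > s_m: the min() term equals s_m
        p = PopulationParams(sigma=1.0, s_m=0.02, s_p=0.2, mu=1e-5, rho=1.0)
        lam = theory.lambda_mig(30.0, p, 1.0)
        z = 30.0 / p.char_length
        assert lam == pytest.approx(0.02 * 0.02 * math.exp(-z))

    def test_lambda_mig_warns_close_in(self, base_params):
        with pytest.warns(UserWarning, match="characteristic length"):
            theory.lambda_mig(0.5 * base_params.char_length, base_params, 1.0)

    def test_rates_scale_linearly_in_rho(self, base_params):
        for factor in (3.0, 10.0):
            scaled = PopulationParams(
                sigma=1.0, s_m=0.05, s_p=0.1, mu=1e-5, rho=10.0 * factor
            )
            assert theory.lambda_mut(scaled, 4.0) == pytest.approx(
                factor * theory.lambda_mut(base_params, 4.0)
            )
            assert theory.lambda_mig(15.0, scaled, 2.0) == pytest.approx(
                factor * theory.lambda_mig(15.0, base_params, 2.0)
            )


class TestEquilibriumFrequency:
    def test_unit_characteristic_length(self):
        for d in (1, 2):
            p = PopulationParams(sigma=1.0, s_m=0.05, s_p=0.1, mu=1e-5, rho=1.0, d=d)
            assert theory.equilibrium_frequency(p.char_length, p) == pytest.approx(
                math.exp(-1)
            )

    def test_exponential_decay_1d(self, base_params):
        ell = base_params.char_length
        x = np.array([3.0, 3.0 + ell])
        q = theory.equilibrium_frequency(x, base_params)
        assert q[1] / q[0] == pytest.approx(math.exp(-1))

    def test_strictly_decreasing_and_log_identity(self):
        for d in (1, 2):
            p = PopulationParams(
                sigma=1.0, s_m=0.05, s_p=0.1, mu=1e-5, rho=1.0, C=2.5, d=d
            )
            x = np.linspace(1.0, 40.0, 200)
            q = theory.equilibrium_frequency(x, p)
            assert (np.diff(q) < 0).all()
            z = x / p.char_length
            recovered = np.log(q) + z + ((d - 1) / 2) * np.log(z)
            assert np.allclose(recovered, math.log(2.5))

    def test_origin_rejected_in_2d(self):
        p = PopulationParams(sigma=1.0, s_m=0.05, s_p=0.1, mu=1e-5, rho=1.0, d=2)
        with pytest.raises(ParameterError):
            theory.equilibrium_frequency(0.0, p)


class TestPatchIntegral:
    def test_effective_area_rules(self, base_params):
        ell = base_params.char_length
        small = Patch(area=0.5 * ell, w_lin=0.5 * ell)
        assert theory.effective_area(small, 10.0, base_params) == pytest.approx(0.5 * ell)
        wide = Patch(area=2 * ell, w_lin=2 * ell)
        assert theory.effective_area(wide, 10.0, base_params) == pytest.approx(ell)
        p2 = PopulationParams(sigma=1.0, s_m=0.05, s_p=0.1, mu=1e-5, rho=1.0, d=2)
        big2d = Patch(area=100.0, w_lin=20.0, w_perp=5.0)
        assert theory.effective_area(big2d, 10.0, p2) == pytest.approx(5.0 * ell)

    def test_integral_against_quadrature(self, base_params):
        patch = Patch(area=3.0, w_lin=3.0)
        R = 8.0
        closed = theory.q_patch_integral(R, patch, base_params)
        numeric, _ = quad(
            lambda x: theory.equilibrium_frequency(x, base_params), R, R + 3.0,
            epsabs=1e-14, epsrel=1e-12,
        )
        assert closed == pytest.approx(numeric, rel=1e-10)

    def test_integral_limits(self, base_params):
        ell = base_params.char_length
        R = 8.0
        # infinite-strip limit
        long_patch = Patch(area=1e4, w_lin=1e4)
        assert theory.q_patch_integral(R, long_patch, base_params) == pytest.approx(
            ell * math.exp(-R / ell), rel=1e-9
        )
        # small-patch limit ~ w * q(R)
        tiny = Patch(area=ell * 1e-4, w_lin=ell * 1e-4)
        assert theory.q_patch_integral(R, tiny, base_params) == pytest.approx(
            tiny.w_lin * theory.equilibrium_frequency(R, base_params), rel=1e-3
        )

    @pytest.mark.parametrize("d", [1, 2])
    def test_integral_bounded_by_area_times_qR(self, d):
        p = PopulationParams(sigma=1.0, s_m=0.03, s_p=0.1, mu=1e-5, rho=1.0, d=d)
        for R in (5.0, 12.0, 30.0):
            for w in (0.5, 2.0, 10.0):
                patch = Patch(area=w, w_lin=w, w_perp=1.0)
                assert theory.q_patch_integral(R, patch, p) <= (
                    patch.area * theory.equilibrium_frequency(R, p) * (1 + 1e-12)
                )


class TestMigrationFactor:
    def test_deterministic_family(self):
        assert theory.exact_migration_factor({1: 1.0}, 0.1, 0.05) == pytest.approx(
            2 * 0.05 * 0.1
        )

    def test_certain_establishment_limit(self):
        # p_e = 1: every arriving family establishes
        pmf = {k: 0.25 for k in (1, 2, 3, 4)}
        assert theory.exact_migration_factor(pmf, 1.0, 0.05) == pytest.approx(
            2 * 0.05 / 2.5
        )

    def test_matches_monte_carlo_geometric(self, rng):
        mean_K = 20.0
        p_geo = 1.0 / mean_K
        ks = np.arange(1, 400)
        pmf = dict(zip(ks.tolist(), (p_geo * (1 - p_geo) ** (ks - 1)).tolist()))
        p_e, s_m = 0.1, 0.05
        factor = theory.exact_migration_factor(pmf, p_e, s_m)
        draws = rng.geometric(p_geo, size=100_000)
        est = 1.0 - (1.0 - p_e) ** draws
        mc = est.mean() / (draws.mean() / (2 * s_m))
        se = est.std() / math.sqrt(draws.size) / (draws.mean() / (2 * s_m))
        assert abs(factor - mc) < 3 * se + 1e-4

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ParameterError):
            theory.exact_migration_factor({0: 1.0}, 0.1, 0.05)


class TestCriticalGapAndParallel:
    @pytest.mark.parametrize(
        "s_m, mu, expected",
        [(0.05, 1e-5, 21.8), (0.001, 1e-5, 67.0), (0.05, 1e-3, 7.3)],
    )
    def test_printed_gap_values(self, s_m, mu, expected):
        gap = theory.critical_gap_distance(s_m, mu, 10.0, 1.0)
        assert not gap.mutation_always_faster
        assert float(gap) == pytest.approx(expected, abs=0.05 if expected < 60 else 0.5)

    def test_mutation_always_faster_flag(self):
        gap = theory.critical_gap_distance(0.001, 1e-3, 10.0, 1.0)
        assert gap.mutation_always_faster and float(gap) == 0.0

    def test_prob_parallel_limits_and_monotonicity(self, base_params):
        R = np.linspace(5.0, 80.0, 100)
        p = theory.prob_parallel(R, base_params, w=10.0)
        assert (np.diff(p) > 0).all()
        assert 0 < p[0] < p[-1] < 1
        assert theory.prob_parallel(1e4, base_params, w=10.0) == pytest.approx(1.0)

    def test_half_probability_at_critical_gap(self):
        p = PopulationParams(sigma=1.0, s_m=0.05, s_p=0.02, mu=1e-5, rho=1.0)
        gap = theory.critical_gap_distance(0.05, 1e-5, 10.0, 1.0)
        assert theory.prob_parallel(
            float(gap) * p.sigma, p, w=10.0, gamma=1.0
        ) == pytest.approx(0.5, rel=1e-12)

    def test_invariant_to_rho_and_joint_sp_rho_rescaling(self):
        # in the gamma = 1 branch the probability depends on neither rho nor s_p
        R = np.linspace(10.0, 50.0, 7)
        base = PopulationParams(sigma=1.0, s_m=0.1, s_p=0.01, mu=1e-5, rho=5.0)
        ref = theory.prob_parallel(R, base, w=10.0)
        for c in (2.0, 5.0):
            rescaled = PopulationParams(
                sigma=1.0, s_m=0.1, s_p=0.01 * c, mu=1e-5, rho=5.0 / c
            )
            assert rescaled.gamma == 1.0
            assert np.allclose(theory.prob_parallel(R, rescaled, w=10.0), ref)


class TestFitCline:
    def test_exact_recovery_1d_and_2d(self):
        for d in (1, 2):
            p = PopulationParams(
                sigma=2.0, s_m=0.02, s_p=0.1, mu=1e-5, rho=1.0, C=0.7, d=d
            )
            x = np.linspace(3.0, 40.0, 12)
            q = theory.equilibrium_frequency(x, p)
            C_hat, ell_hat = theory.fit_cline(x, q, d=d)
            assert C_hat == pytest.approx(0.7, rel=1e-9)
            assert ell_hat == pytest.approx(p.char_length, rel=1e-9)

    @pytest.mark.parametrize(
        "x2, f2, expected_ell",
        [(12.0, 0.03, 12.0 / math.log(0.5 / 0.03)), (10.0, 0.34, 10.0 / math.log(0.5 / 0.34))],
    )
    def test_two_point_fits(self, x2, f2, expected_ell):
        _, ell = theory.fit_cline([0.0, x2], [0.5, f2], d=1)
        assert ell == pytest.approx(expected_ell, rel=1e-12)

    def test_rejects_duplicates_and_zero_frequency(self):
        with pytest.raises(ParameterError):
            theory.fit_cline([1.0, 1.0], [0.5, 0.4])
        with pytest.raises(ParameterError):
            theory.fit_cline([1.0, 2.0], [0.5, 0.0])


class TestAssumptionChecks:
    def test_clean_parameter_set_raises_no_flags(self):
        # the occupancy-simulation regime: strong patch benefit, dense demes
        params = PopulationParams(
            sigma=0.95, s_m=0.02, s_p=0.1, mu=1e-5, rho=1000.0
        )
        layout = PatchLayout(patches=(Patch(area=10.0, w_lin=10.0),))
        assert theory.check_assumptions(params, layout) == []

    def test_distance_flag(self):
        params = PopulationParams(sigma=1.0, s_m=0.04, s_p=0.1, mu=1e-5, rho=1000.0)
        short = 0.5 * params.sigma / math.sqrt(params.s_m)
        layout = PatchLayout(
            patches=(Patch(area=10.0, w_lin=10.0),) * 2,
            distances=np.array([[0.0, short], [short, 0.0]]),
        )
        assert "interpatch_distance_short" in theory.check_assumptions(params, layout)

    def test_neighborhood_flag_threshold(self):
        # flag exactly when s_m <= 1/(rho sigma^d)
        layout = PatchLayout(patches=(Patch(area=50.0, w_lin=50.0),))
        ok = PopulationParams(sigma=1.0, s_m=0.3, s_p=0.2, mu=1e-5, rho=5.0)
        assert "neighborhood_size_small" not in theory.check_assumptions(ok, layout)
        weak = PopulationParams(sigma=1.0, s_m=0.1, s_p=0.2, mu=1e-5, rho=5.0)
        assert "neighborhood_size_small" in theory.check_assumptions(weak, layout)

    def test_narrow_patch_flag(self):
        params = PopulationParams(sigma=1.0, s_m=0.1, s_p=0.01, mu=1e-5, rho=1000.0)
        layout = PatchLayout(patches=(Patch(area=0.5, w_lin=0.5),))
        assert "patch_below_critical_width" in theory.check_assumptions(params, layout)
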