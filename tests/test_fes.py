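"""Free-energy-surface reconstruction: fits, closed forms, envelopes."""

import numpy as np
import pytest
from scipy import stats

from chlquench.fes import (
    Axis,
    QuadraticFES,
    build_sampled_fes,
    companion_surface,
    crossfit_es_surface,
    fit_gap_distribution,
    fit_gap_relation,
    propagate_uncertainty,
    summarize_surface_pair,
)
from chlquench.synthetic import GapModelSpec, generate_gs_trajectory


def numerical_argmin(fes, lo=-20.0, hi=20.0):
    """Black-box minimizer: coarse scan, then bisect the numerical derivative.

    The central difference is exact for a parabola, so the minimum is located
    to root-finder precision (~1e-14) without using the surface coefficients.
    """
    from scipy.optimize import brentq

    grid = np.linspace(lo, hi, 4001)
    x0 = grid[np.argmin([fes(x) for x in grid])]
    h = 1e-4
    deriv = lambda x: (fes(x + h) - fes(x - h)) / (2 * h)  # noqa: E731
    x_star = brentq(deriv, x0 - 0.02, x0 + 0.02, xtol=1e-14)
    return x_star, fes(x_star)


class TestFitGapDistribution:
    def test_symmetric_three_point_sample(self):
        fit = fit_gap_distribution([0.0, 1.0, 2.0])
        assert fit.mu == pytest.approx(1.0)
        assert fit.sigma == pytest.approx(1.0)  # ddof=1 sample SD

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_gap_distribution([1.0, 1.0, 1.0])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            fit_gap_distribution([0.0, 1.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fit_gap_distribution([0.0, np.nan, 1.0])

    def test_ci_coverage_near_nominal(self):
        # oracle: standard CI coverage simulation at n=500 draws
        hits = 0
        n_rep = 200
        root = np.random.SeedSequence(42)
        for ss in root.spawn(n_rep):
            x = np.random.default_rng(ss).normal(0.27, 0.185, 500)
            fit = fit_gap_distribution(x)
            hits += fit.mu_ci[0] <= 0.27 <= fit.mu_ci[1]
        # binomial(200, 0.95) 3-sigma band
        assert hits / n_rep > 0.95 - 3 * np.sqrt(0.95 * 0.05 / n_rep)


class TestSampledSurface:
    def test_unit_variance_reduction(self, kt300):
        fit = fit_gap_distribution(
            np.random.default_rng(0).normal(0.0, 1.0, 100)
        )
        # mu=0, sigma=sqrt(kT) => V(x) = x^2/2
        fes = QuadraticFES(
            c2=kt300 / (2 * kt300), c1=0.0, c0=0.0, x_ref=0.0,
            axis=Axis.ES_MINUS_CS,
        )
        assert fes(2.0) == pytest.approx(2.0)
        del fit

    def test_value_one_sigma_from_minimum_is_half_kt(self, kt300):
        fit = fit_gap_distribution([0.27 - 0.1847, 0.27, 0.27 + 0.1847])
        fes = build_sampled_fes(fit, 300.0)
        assert fes(fit.mu + fit.sigma) == pytest.approx(kt300 / 2, rel=1e-12)
        assert fes(fit.mu + fit.sigma) == pytest.approx(0.0129, abs=2e-4)

    def test_even_about_mean(self):
        fit = fit_gap_distribution([0.0, 0.27, 0.54])
        fes = build_sampled_fes(fit, 300.0)
        for d in (0.01, 0.3, 2.7):
            assert fes(fit.mu + d) == pytest.approx(fes(fit.mu - d), rel=1e-12)

    def test_boltzmann_inversion_identity(self, kt300):
        # exp(-V/kT), renormalized, equals the fitted normal density
        rng = np.random.default_rng(17)
        fit = fit_gap_distribution(rng.normal(0.3, 0.2, 400))
        fes = build_sampled_fes(fit, 300.0)
        grid = np.linspace(fit.mu - 4 * fit.sigma, fit.mu + 4 * fit.sigma, 200)
        # identity by construction: exp(-V/kT) = exp(-((x-mu)/sigma)^2/2),
        # i.e. the fitted normal density up to its normalization constant
        lhs = np.exp(-fes(grid) / kt300)
        rhs = stats.norm.pdf(grid, fit.mu, fit.sigma) * (
            fit.sigma * np.sqrt(2 * np.pi)
        )
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestCompanionConstruction:
    def test_unit_parabola_minimum(self, kt300):
        # V_CS = x^2/2 in reduced units (mu=0, sigma^2=kT): companion min at
        # x* = -sigma^2/kT -> reduced -1, with V_ES(x*) = -1/2
        sigma = np.sqrt(kt300)
        cs = QuadraticFES(c2=kt300 / (2 * sigma**2), c1=0, c0=0, x_ref=0.0,
                          axis=Axis.ES_MINUS_CS)
        es = companion_surface(cs)
        assert es.argmin == pytest.approx(-sigma**2 / kt300, rel=1e-12)
        # with sigma^2 = kT the gap coordinate is already in "reduced" units
        # of kT per eV: the companion minimum sits at -1 with value -1/2 eV
        assert es.min_value == pytest.approx(-0.5, rel=1e-12)

    @pytest.mark.parametrize("mu,sigma", [(0.27, 0.1847), (-0.1, 0.05), (1.0, 0.4)])
    def test_closed_forms_match_numerical_minimization(self, mu, sigma, kt300):
        fit = fit_gap_distribution([mu - sigma, mu, mu + sigma])
        cs = build_sampled_fes(fit, 300.0)
        es = companion_surface(cs)
        summary = summarize_surface_pair(es, cs)
        lam_expected = fit.sigma**2 / (2 * kt300)
        da_expected = fit.sigma**2 / (2 * kt300) - fit.mu
        assert summary.lambda_reorg == pytest.approx(lam_expected, abs=1e-10)
        assert summary.delta_a == pytest.approx(da_expected, abs=1e-10)
        # independent oracle: numerical minimization of both parabolas
        x_es, v_es = numerical_argmin(es)
        x_cs, v_cs = numerical_argmin(cs)
        assert abs((v_cs - v_es) - summary.delta_a) < 1e-10
        assert abs((cs(x_es) - cs(x_cs)) - summary.lambda_reorg) < 1e-10

    def test_axis_mismatch_rejected(self):
        fes = QuadraticFES(c2=1.0, c1=0, c0=0, x_ref=0.0, axis=Axis.CS_MINUS_GS)
        with pytest.raises(ValueError, match="axis"):
            companion_surface(fes)


class TestGapRelation:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        rel = fit_gap_relation(x, 2 * x)
        assert rel.slope_a == pytest.approx(2.0, abs=1e-12)
        assert rel.intercept_b == pytest.approx(0.0, abs=1e-12)
        assert rel.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_synthetic_recovery_within_ci(self):
        spec = GapModelSpec(slope_a=-0.5, intercept_b=1.9, resid_sd=0.02,
                            n_frames=500, seed=7)
        table = generate_gs_trajectory(spec)
        x = (table["E_CS_eV"] - table["E_GS_eV"]).to_numpy()
        y = (table["E_ES_eV"] - table["E_CS_eV"]).to_numpy()
        rel = fit_gap_relation(x, y)
        assert rel.a_ci[0] <= -0.5 <= rel.a_ci[1]
        assert rel.b_ci[0] <= 1.9 <= rel.b_ci[1]

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gap_relation([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestCrossfit:
    def test_rigid_shift_when_slope_zero(self, kt300):
        fit = fit_gap_distribution([3.0, 3.26, 3.52], axis=Axis.CS_MINUS_GS)
        cs = build_sampled_fes(fit, 300.0)
        from chlquench.fes import LinearGapRelation

        rel = LinearGapRelation(slope_a=0.0, intercept_b=1.9, residual_sd=0.0,
                                r_value=0.0, a_ci=(0.0, 0.0), b_ci=(1.9, 1.9),
                                n=3)
        result = crossfit_es_surface(cs, rel)
        assert not result.reexpressed
        assert result.surface_es_axis is None
        summary = summarize_surface_pair(result.surface, cs)
        assert summary.delta_a == pytest.approx(-1.9, abs=1e-12)
        assert summary.lambda_reorg == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "mu_x,sigma_x,a,b", [(3.26, 0.3695, -0.5, 1.9), (1.0, 0.2, 0.8, -0.4)]
    )
    def test_closed_forms_and_numerical_oracle(self, mu_x, sigma_x, a, b, kt300):
        fit = fit_gap_distribution(
            [mu_x - sigma_x, mu_x, mu_x + sigma_x], axis=Axis.CS_MINUS_GS
        )
        cs = build_sampled_fes(fit, 300.0)
        rel_stub = fit_gap_relation(
            np.array([0.0, 1.0, 2.0, 3.0]),
            a * np.array([0.0, 1.0, 2.0, 3.0]) + b,
        )
        result = crossfit_es_surface(cs, rel_stub)
        es = result.surface
        sig = fit.sigma
        assert es.argmin == pytest.approx(fit.mu - a * sig**2 / kt300, abs=1e-10)
        summary = summarize_surface_pair(es, cs)
        assert summary.lambda_reorg == pytest.approx(
            a**2 * sig**2 / (2 * kt300), abs=1e-10
        )
        assert summary.delta_a == pytest.approx(
            a**2 * sig**2 / (2 * kt300) - a * fit.mu - b, abs=1e-10
        )
        x_es, v_es = numerical_argmin(es)
        assert abs(x_es - es.argmin) < 1e-6

    def test_noiseless_pipeline_matches_closed_form(self, kt300):
        spec = GapModelSpec(resid_sd=0.0, n_frames=300, seed=13)
        table = generate_gs_trajectory(spec)
        x = (table["E_CS_eV"] - table["E_GS_eV"]).to_numpy()
        y = (table["E_ES_eV"] - table["E_CS_eV"]).to_numpy()
        rel = fit_gap_relation(x, y)
        fit = fit_gap_distribution(x, axis=Axis.CS_MINUS_GS, trajectory="GS")
        cs = build_sampled_fes(fit, 300.0)
        summary = summarize_surface_pair(crossfit_es_surface(cs, rel).surface, cs)
        lam_closed = rel.slope_a**2 * fit.sigma**2 / (2 * kt300)
        da_closed = lam_closed - rel.slope_a * fit.mu - rel.intercept_b
        assert summary.lambda_reorg == pytest.approx(lam_closed, abs=1e-10)
        assert summary.delta_a == pytest.approx(da_closed, abs=1e-10)

    def test_reexpression_preserves_surface_values(self):
        fit = fit_gap_distribution([3.0, 3.26, 3.52], axis=Axis.CS_MINUS_GS)
        cs = build_sampled_fes(fit, 300.0)
        rel = fit_gap_relation(
            np.array([3.0, 3.2, 3.4, 3.6]),
            -0.5 * np.array([3.0, 3.2, 3.4, 3.6]) + 1.9,
        )
        result = crossfit_es_surface(cs, rel)
        assert result.reexpressed
        for x in (3.0, 3.26, 3.5):
            u = rel.slope_a * x + rel.intercept_b
            assert result.surface_es_axis(u) == pytest.approx(
                result.surface(x), rel=1e-10
            )


class TestSummarize:
    def test_equal_curvature_barrier_identity(self, kt300):
        # Marcus activation identity: barrier above ES min = (lambda+dA)^2/(4 lambda)
        sigma = 0.1847
        fit = fit_gap_distribution([0.27 - sigma, 0.27, 0.27 + sigma])
        cs = build_sampled_fes(fit, 300.0)
        es = companion_surface(cs)
        s = summarize_surface_pair(es, cs)
        expected = (s.lambda_reorg + s.delta_a) ** 2 / (4 * s.lambda_reorg)
        assert s.crossing_energy_above_es_min == pytest.approx(expected, abs=1e-10)
        # oracle: numerical root finding on the surface difference
        from scipy.optimize import brentq
        root = brentq(lambda x: es(x) - cs(x), es.argmin - 5, cs.argmin + 5)
        assert es(root) - es.min_value == pytest.approx(expected, abs=1e-8)

    def test_identical_surfaces(self):
        fes = QuadraticFES(c2=2.0, c1=0, c0=0, x_ref=0.1, axis=Axis.ES_MINUS_CS)
        s = summarize_surface_pair(fes, fes)
        assert s.delta_a == 0.0
        assert s.lambda_reorg == 0.0
        assert s.crossing_energy_above_es_min == 0.0

    def test_no_real_crossing_reported_absent(self):
        a = QuadraticFES(c2=1.0, c1=0, c0=0.0, x_ref=0.0, axis=Axis.ES_MINUS_CS)
        b = QuadraticFES(c2=1.0, c1=0.0, c0=1.0, x_ref=0.0,
                         axis=Axis.ES_MINUS_CS, provenance="companion")
        s = summarize_surface_pair(b, a)
        assert s.crossing_energy_above_es_min is None

    def test_inverted_region_classification(self):
        # deeply exergonic: -dA > lambda
        cs = QuadraticFES(c2=5.0, c1=0, c0=0, x_ref=0.0, axis=Axis.ES_MINUS_CS)
        es = QuadraticFES(c2=5.0, c1=0.0, c0=1.0, x_ref=0.05,
                          axis=Axis.ES_MINUS_CS, provenance="companion")
        s = summarize_surface_pair(es, cs)
        assert s.delta_a < 0 and -s.delta_a > s.lambda_reorg
        assert s.marcus_region == "inverted"

    def test_axis_mismatch_rejected(self):
        a = QuadraticFES(c2=1.0, c1=0, c0=0, x_ref=0.0, axis=Axis.ES_MINUS_CS)
        b = QuadraticFES(c2=1.0, c1=0, c0=0, x_ref=0.0, axis=Axis.CS_MINUS_GS)
        with pytest.raises(ValueError, match="axes"):
            summarize_surface_pair(a, b)


class TestPropagation:
    def test_identity_returns_the_ci(self):
        lo, hi, failed = propagate_uncertainty(
            {"p": (1.0, (0.5, 1.5))}, lambda p: p
        )
        assert (lo, hi) == (0.5, 1.5)
        assert failed == []

    def test_monotone_envelope_at_endpoints(self):
        lo, hi, _ = propagate_uncertainty(
            {"p": (2.0, (1.0, 3.0))}, lambda p: p**3
        )
        assert (lo, hi) == (1.0, 27.0)

    def test_lambda_envelope_closed_form(self, kt300):
        sci = (0.17, 0.20)
        lo, hi, _ = propagate_uncertainty(
            {"sigma": (0.1847, sci)}, lambda sigma: sigma**2 / (2 * kt300)
        )
        assert lo == pytest.approx(sci[0] ** 2 / (2 * kt300), rel=1e-12)
        assert hi == pytest.approx(sci[1] ** 2 / (2 * kt300), rel=1e-12)

    def test_failing_corner_flagged_not_dropped(self):
        def evaluator(p):
            if p < 0:
                raise ValueError("negative")
            return p

        lo, hi, failed = propagate_uncertainty(
            {"p": (1.0, (-1.0, 2.0))}, evaluator
        )
        assert (lo, hi) == (1.0, 2.0)
        assert len(failed) == 1 and failed[0]["p"] == -1.0

    def test_envelope_recovery_rate_over_replicates(self, kt300):
        """Synthetic pipeline recovers generator lambda/dA within 95% envelopes
        in >= 90% of 100 seeded replicates (n_frames=500)."""
        from chlquench.synthetic import default_cs_spec, generate_cs_trajectory

        lam_true, da_true = 0.66, 0.39
        hits = 0
        for seed in range(100):
            spec = default_cs_spec(lambda_reorg=lam_true, delta_a=da_true,
                                   n_frames=500, seed=seed)
            table = generate_cs_trajectory(spec)
            fit = fit_gap_distribution(
                (table["E_ES_eV"] - table["E_CS_eV"]).to_numpy()
            )
            lam_lo, lam_hi, _ = propagate_uncertainty(
                {"sigma": (fit.sigma, fit.sigma_ci)},
                lambda sigma: sigma**2 / (2 * kt300),
            )
            da_lo, da_hi, _ = propagate_uncertainty(
                {"mu": (fit.mu, fit.mu_ci), "sigma": (fit.sigma, fit.sigma_ci)},
                lambda mu, sigma: sigma**2 / (2 * kt300) - mu,
            )
            hits += (lam_lo <= lam_true <= lam_hi) and (da_lo <= da_true <= da_hi)
        assert hits >= 90
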