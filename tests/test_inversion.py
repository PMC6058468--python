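import numpy as np
import pytest

from cicdls import (
    CorrelationTrace,
    GroundTruthMixture,
    InversionSettings,
    NoiseModel,
    SizeGrid,
    build_kernel,
    cumulant_check,
    decay_rate,
    invert,
    select_lambda,
    simulate_trace,
    window_contribution,
)
from cicdls.inversion import _field_correlation, difference_operator


class TestKernel:
    def test_toy_kernel_matches_hand_exponentials(self, config, mono_trace):
        grid = SizeGrid(np.array([80.0, 160.0, 320.0]))
        kernel = build_kernel(grid, mono_trace, config)
        gammas = decay_rate(grid.centers_nm, config)
        for i in [0, 5]:
            for j in [0, 1]:
                assert kernel[i, j] == pytest.approx(
                    np.exp(-gammas[j] * mono_trace.tau_s[i])
                )

    def test_entries_in_unit_interval_and_monotone(self, mono_trace):
        grid = SizeGrid.logspaced(1, 1e4, 32)
        kernel = build_kernel(grid, mono_trace)
        assert np.all(kernel > 0) and np.all(kernel <= 1)
        assert np.all(np.diff(kernel, axis=0) <= 0)  # decays along tau

    def test_short_lag_row_near_one(self, config):
        trace = CorrelationTrace(
            tau_s=np.geomspace(1e-12, 1e-10, 8),
            g2=np.full(8, 1.8),
            beta=0.8,
            meta={"instrument": config.to_dict()},
        )
        kernel = build_kernel(SizeGrid.logspaced(1, 1e4, 16), trace)
        assert kernel[0] == pytest.approx(np.ones(16), abs=1e-6)

    def test_overflow_safe_for_huge_decay_rates(self, config):
        trace = CorrelationTrace(
            tau_s=np.geomspace(1.0, 1e3, 8),
            g2=np.full(8, 1.0),
            beta=0.8,
            meta={"instrument": config.to_dict()},
        )
        kernel = build_kernel(SizeGrid.logspaced(0.01, 1.0, 16), trace)
        assert np.all(np.isfinite(kernel)) and np.all(kernel >= 0)


class TestInvert:
    def test_monodisperse_mass_within_one_bin(self, mono_trace):
        dist = invert(mono_trace)
        b = dist.grid.bin_of(121.0)
        assert dist.contribution_pct[b - 1 : b + 2].sum() >= 99.0
        assert dist.contribution_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_noise_free_two_component_within_one_point(self, premeal_trace):
        dist = invert(premeal_trace)
        assert window_contribution(dist, (100, 400)) == pytest.approx(5.9, abs=1.0)
        assert window_contribution(dist, (1, 100)) == pytest.approx(94.1, abs=1.0)
        assert dist.peak_radius_nm((100, 400)) == pytest.approx(121, rel=0.05)

    def test_ridge_limit_shrinks_solution_norm(self, premeal_trace):
        norms = []
        for lam in [1e-4, 1e-1, 1e2, 1e5]:
            dist = invert(
                premeal_trace,
                InversionSettings(lambda_reg=lam, penalty_order=0, refine=False),
            )
            # recover the unnormalized solution norm via the stored percents
            norms.append(np.linalg.norm(dist.contribution_pct))
        # heavy ridge spreads mass: the histogram norm decreases monotonically
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_penalized_seminorm_monotone_in_lambda(self, premeal_trace):
        from cicdls.inversion import _solve_penalized, build_kernel

        settings = InversionSettings(refine=False)
        grid = settings.make_grid()
        kernel = build_kernel(grid, premeal_trace)
        g1, wts, _, _ = _field_correlation(premeal_trace, settings)
        lmat = difference_operator(grid.n_bins, 2)
        seminorms = []
        for lam in np.geomspace(1e-6, 1e2, 9):
            w, _ = _solve_penalized(kernel, g1, wts, lam, lmat)
            seminorms.append(np.linalg.norm(lmat @ w))
        assert all(a >= b - 1e-9 for a, b in zip(seminorms, seminorms[1:]))

    def test_degenerate_trace_rejected(self, config):
        flat = CorrelationTrace(
            tau_s=np.geomspace(1e-6, 1, 32),
            g2=np.ones(32),
            beta=0.8,
            meta={"instrument": config.to_dict()},
        )
        with pytest.raises(ValueError, match="degenerate trace"):
            invert(flat, InversionSettings(lambda_reg=1e-3))

    def test_baseline_above_data_rejected(self, config):
        low = CorrelationTrace(
            tau_s=np.geomspace(1e-6, 1, 32),
            g2=np.full(32, 0.5),
            beta=0.8,
            meta={"instrument": config.to_dict()},
        )
        with pytest.raises(ValueError, match="baseline exceeds data"):
            invert(low)

    def test_fitted_baseline_and_beta(self, premeal_mixture, config):
        trace = simulate_trace(premeal_mixture, config)
        trace.beta = None
        dist = invert(trace, InversionSettings(fit_beta=True, fit_baseline=True))
        assert window_contribution(dist, (100, 400)) == pytest.approx(5.9, abs=1.5)


class TestSelectLambda:
    def test_chosen_lambda_is_ladder_member(self, premeal_trace):
        ladder = np.geomspace(1e-8, 1e2, 26)
        lam = select_lambda(premeal_trace, InversionSettings(), ladder)
        assert any(np.isclose(lam, ladder))

    def test_deterministic_for_fixed_trace(self, premeal_trace):
        a = select_lambda(premeal_trace, InversionSettings())
        b = select_lambda(premeal_trace, InversionSettings())
        assert a == b

    def test_noise_free_choice_not_above_noisy_choice(self, premeal_mixture):
        clean = simulate_trace(premeal_mixture)
        noisy = simulate_trace(premeal_mixture, noise=NoiseModel(0.01, seed=2))
        settings = InversionSettings()
        assert select_lambda(clean, settings) <= select_lambda(noisy, settings)


class TestCumulantCheck:
    def test_monodisperse_radius_within_one_percent(self, mono_trace):
        radius, pdi = cumulant_check(mono_trace)
        assert radius == pytest.approx(121.0, rel=0.01)
        assert pdi == pytest.approx(0.0, abs=1e-6)

    def test_bimodal_mean_between_component_radii(self):
        mix = GroundTruthMixture(((50.0, 50.0), (200.0, 50.0)))
        trace = simulate_trace(mix)
        radius, pdi = cumulant_check(trace)
        assert 50.0 < radius < 200.0
        assert pdi > 0.01

    def test_agrees_with_inversion_on_monodisperse(self, mono_trace):
        dist = invert(mono_trace)
        cum_radius, _ = cumulant_check(mono_trace)
        grid = dist.grid
        assert abs(grid.bin_of(cum_radius) - grid.bin_of(121.0)) <= 1


class TestTraceValidation:
    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="8 channels"):
            CorrelationTrace(np.geomspace(1e-6, 1, 4), np.ones(4))

    def test_non_monotone_tau_rejected(self):
        tau = np.array([1e-6, 1e-5, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            CorrelationTrace(tau, np.ones(8))
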