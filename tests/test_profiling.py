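import numpy as np
import pytest

from cicdls import (
    GroundTruthMixture,
    MixtureComponent,
    SampleProfile,
    apply_depletion,
    detect_ic_fraction,
    find_subfractions,
    human_plasma_mixture,
    isotype_panel_table,
    isotype_proportion,
    mixture_distribution,
    window_contribution,
)
from cicdls.simulate import (
    HUMAN_ISOTYPE_IC_WINDOW,
    apply_isotype_panel,
)
from cicdls.inversion import InversionSettings, SizeDistribution


def planted_profile(mixture, subject="S", treatment="native", **kw):
    return SampleProfile(
        mixture_distribution(mixture), subject, treatment=treatment, **kw
    )


@pytest.fixture(scope="module")
def grid():
    return InversionSettings().make_grid()


class TestFindSubfractions:
    def test_single_bin_distribution_is_one_full_subfraction(self, grid):
        pct = np.zeros(grid.n_bins)
        pct[20] = 100.0
        subs = find_subfractions(SizeDistribution(grid, pct))
        assert len(subs) == 1
        assert subs[0].contribution_pct == pytest.approx(100.0)
        lo, hi = subs[0].window_nm
        assert lo <= subs[0].peak_nm < hi

    def test_premeal_fixture_reports_small_ic_subfraction(self):
        dist = mixture_distribution(human_plasma_mixture(5.9, 117.0))
        subs = find_subfractions(dist, min_pct=1.0)
        ic = [s for s in subs if 100 <= s.peak_nm < 400]
        assert len(ic) == 1
        assert ic[0].contribution_pct == pytest.approx(5.9)

    def test_threshold_above_100_empties_result(self, grid):
        pct = np.zeros(grid.n_bins)
        pct[10] = 100.0
        assert find_subfractions(SizeDistribution(grid, pct), min_pct=101) == []


class TestWindowContribution:
    def test_full_grid_window_totals_100(self, premeal_mixture):
        dist = mixture_distribution(premeal_mixture)
        edges = dist.grid.edges_nm
        assert window_contribution(dist, (edges[0], edges[-1])) == pytest.approx(100)

    def test_disjoint_windows_are_additive(self, premeal_mixture):
        dist = mixture_distribution(premeal_mixture)
        edges = dist.grid.edges_nm
        left = window_contribution(dist, (edges[0], 50.0))
        right = window_contribution(dist, (50.0, edges[-1]))
        assert left + right == pytest.approx(100.0)

    def test_fed_rat_portal_window_near_planted(self):
        from cicdls import generate_rat_experiment

        portal = generate_rat_experiment(fed=True, seed=0)["portal_vein"]
        dist = mixture_distribution(portal)
        assert window_contribution(dist, (100, 400)) == pytest.approx(73.3, abs=5)

    def test_window_outside_grid_rejected(self, premeal_mixture):
        dist = mixture_distribution(premeal_mixture)
        with pytest.raises(ValueError, match="outside the grid"):
            window_contribution(dist, (1e5, 1e6))


class TestDetectIcFraction:
    def make_pair(self, mixture, window=(100.0, 400.0), efficiency=1.0):
        native = planted_profile(mixture, treatment="native")
        depleted = planted_profile(
            apply_depletion(mixture, window, efficiency), treatment="depleted"
        )
        return native, depleted

    def test_fed_portal_detected(self):
        mix = GroundTruthMixture(
            (
                MixtureComponent(3.5, 26.7, ig_bearing=False),
                MixtureComponent(250.0, 73.3),
            )
        )
        res = detect_ic_fraction(*self.make_pair(mix))
        assert res.detected
        assert res.native_pct == pytest.approx(73.3)
        assert res.depleted_pct == pytest.approx(0.0)
        assert res.ic_size_nm == pytest.approx(250, rel=0.1)

    def test_starved_inert_fraction_not_detected(self):
        mix = GroundTruthMixture(
            (
                MixtureComponent(3.5, 93.9, ig_bearing=False),
                MixtureComponent(250.0, 6.1, ig_bearing=False),
            )
        )
        res = detect_ic_fraction(*self.make_pair(mix), ratio_min=2.0)
        assert not res.detected
        assert res.native_pct == pytest.approx(res.depleted_pct)

    def test_self_comparison_never_detects(self, premeal_mixture):
        native = planted_profile(premeal_mixture, treatment="native")
        same = planted_profile(premeal_mixture, treatment="depleted")
        assert not detect_ic_fraction(native, same).detected

    def test_swapping_roles_cannot_both_detect(self):
        mix = human_plasma_mixture(50.0, 200.0)
        native, depleted = self.make_pair(mix, efficiency=0.9)
        fwd = detect_ic_fraction(native, depleted)
        native_r = planted_profile(
            apply_depletion(mix, (100, 400), 0.9), treatment="native"
        )
        depleted_r = planted_profile(mix, treatment="depleted")
        rev = detect_ic_fraction(native_r, depleted_r)
        assert fwd.detected and not rev.detected

    def test_raising_ratio_min_never_creates_detection(self):
        mix = human_plasma_mixture(30.0, 150.0)
        native, depleted = self.make_pair(mix, efficiency=0.6)
        detections = [
            detect_ic_fraction(native, depleted, ratio_min=r).detected
            for r in [1.5, 2.0, 3.0, 5.0, 10.0]
        ]
        assert detections == sorted(detections, reverse=True)

    def test_mismatched_subjects_rejected(self, premeal_mixture):
        a = planted_profile(premeal_mixture, subject="A", treatment="native")
        b = planted_profile(premeal_mixture, subject="B", treatment="depleted")
        with pytest.raises(ValueError, match="incomparable"):
            detect_ic_fraction(a, b)


class TestIsotyping:
    peak = human_plasma_mixture(78.7, 121.1)

    def treated_profile(self, panel):
        return planted_profile(
            apply_isotype_panel(self.peak, panel),
            treatment="antibody",
            panel=panel,
        )

    def test_iga_proportion_and_size(self):
        native = planted_profile(self.peak)
        res = isotype_proportion(
            native, self.treated_profile("IgA"), (50, 200), (200, 500)
        )
        assert res.proportion_pct == pytest.approx(42.0)
        assert res.shifted_size_nm == pytest.approx(267.2, rel=0.1)

    def test_absent_isotype_gives_zero(self):
        native = planted_profile(self.peak)
        treated = planted_profile(self.peak, treatment="antibody", panel="IgG2")
        res = isotype_proportion(native, treated, (50, 200), (200, 500))
        assert res.proportion_pct == 0.0

    def test_full_shift_equals_native_ic_contribution(self):
        from cicdls import apply_antibody_shift

        native = planted_profile(self.peak)
        shifted = apply_antibody_shift(
            self.peak, 1.0, 300.0, HUMAN_ISOTYPE_IC_WINDOW
        )
        res = isotype_proportion(
            native,
            planted_profile(shifted, treatment="antibody", panel="IgA"),
            (50, 200),
            (200, 500),
        )
        assert res.proportion_pct == pytest.approx(78.7)

    def test_overlapping_windows_rejected(self):
        native = planted_profile(self.peak)
        with pytest.raises(ValueError, match="overlaps"):
            isotype_proportion(
                native, self.treated_profile("IgA"), (50, 250), (200, 500)
            )

    def test_panel_table_reproduces_planted_panel_means(self):
        profiles = [planted_profile(self.peak)] + [
            self.treated_profile(p)
            for p in ("IgG1", "IgG3", "IgA", "IgG1+IgG3", "IgG1+IgA")
        ]
        table = isotype_panel_table(profiles)
        assert list(table.panel) == ["IgG1", "IgG3", "IgA", "IgG1+IgG3", "IgG1+IgA"]
        got = dict(zip(table.panel, table.proportion_pct))
        assert got["IgG1"] == pytest.approx(33.1)
        assert got["IgG3"] == pytest.approx(4.1)
        assert got["IgA"] == pytest.approx(42.0)
        assert got["IgG1+IgG3"] == pytest.approx(37.2)
        assert got["IgG1+IgA"] == pytest.approx(3.2)

    def test_combined_panel_additive_without_dual_positives(self):
        # zero dual-positive fraction: IgG1+IgG3 equals the sum of singles
        profiles = [planted_profile(self.peak)] + [
            self.treated_profile(p) for p in ("IgG1", "IgG3", "IgG1+IgG3")
        ]
        table = isotype_panel_table(profiles)
        got = dict(zip(table.panel, table.proportion_pct))
        assert got["IgG1+IgG3"] == pytest.approx(
            got["IgG1"] + got["IgG3"], abs=1e-6
        )

    def test_duplicate_panel_rejected(self):
        profiles = [
            planted_profile(self.peak),
            self.treated_profile("IgA"),
            self.treated_profile("IgA"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            isotype_panel_table(profiles)

    def test_empty_panel_list_gives_empty_table(self):
        table = isotype_panel_table([planted_profile(self.peak)])
        assert len(table) == 0


class TestIsotypingThroughInversion:
    """Single-isotype proportions recovered end-to-end stay additive."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_single_panel_proportions_sum_to_ic_total(self, seed):
        from cicdls.pipeline import profile_mixture

        sigma0 = 3e-5  # high-quality acquisition; shifts are ratio-2 in radius
        peak = human_plasma_mixture(78.7, 121.1)
        native = profile_mixture(peak, "D", "native", seed=seed * 100,
                                 sigma0=sigma0)
        total = 0.0
        for i, panel in enumerate(("IgG1", "IgG3", "IgA")):
            treated = profile_mixture(
                apply_isotype_panel(peak, panel), "D", "antibody",
                seed=seed * 100 + 10 + i, sigma0=sigma0, panel=panel,
            )
            res = isotype_proportion(native, treated, (50, 200), (200, 500))
            total += res.proportion_pct
        ic_total = window_contribution(native.distribution, (50, 200))
        assert total == pytest.approx(ic_total, abs=2.0)


class TestSampleProfileValidation:
    def test_panel_requires_antibody_treatment(self, premeal_mixture):
        dist = mixture_distribution(premeal_mixture)
        with pytest.raises(ValueError, match="panel"):
            SampleProfile(dist, "S", treatment="native", panel="IgA")
        with pytest.raises(ValueError, match="panel"):
            SampleProfile(dist, "S", treatment="antibody")
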