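"""Synthetic FLIM scene and feature-table generation."""

import numpy as np
import pytest

import omiflim as of
from omiflim.cells import OMI_VARIABLES
from omiflim.core import NADPH, TimeAxis
from omiflim.multivariate import train_classifier
from omiflim.simulate import (ConditionSpec, MetabolicProfile, SceneSpec,
                              baseline_omi_cov, baseline_omi_mean,
                              generate_decay_cube, generate_feature_table,
                              make_condition_spec, synth_irf)


def small_scene(**overrides) -> SceneSpec:
    profiles = {NADPH: MetabolicProfile(
        NADPH, alpha1_mean=0.75, alpha1_sd=0.0, tau1_mean=400.0, tau1_sd=0.0,
        tau2_mean=2400.0, tau2_sd=0.0, offset_rate=0.0,
        photons_per_pixel=2000.0, intensity_cv=0.0)}
    defaults = dict(shape=(24, 24), n_cells=2, radius_range=(4.0, 5.0),
                    profiles=profiles, seed=7)
    defaults.update(overrides)
    return SceneSpec(**defaults)


class TestSynthIrf:
    @pytest.mark.parametrize("fwhm", [100.0, 250.0, 800.0])
    def test_normalized_and_nonnegative(self, fwhm):
        irf = of.synth_irf(fwhm, 600.0)
        assert irf.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(irf.values >= 0)

    def test_narrow_fwhm_warns_and_collapses_to_delta(self):
        with pytest.warns(UserWarning, match="delta"):
            irf = of.synth_irf(1.0, 600.0)
        assert irf.values.max() == pytest.approx(1.0, abs=1e-9)

    def test_second_moment_matches_gaussian_sigma(self):
        irf = of.synth_irf(250.0, 2000.0, 256, 48.8)
        t = irf.axis.centers
        mu = (irf.values * t).sum()
        sigma = np.sqrt((irf.values * (t - mu) ** 2).sum())
        assert sigma == pytest.approx(250.0 / 2.3548, rel=0.02)

    def test_center_outside_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            of.synth_irf(250.0, 1e6)


class TestGenerateDecayCube:
    def test_fixed_seed_bitwise_identity(self, irf):
        scene = small_scene()
        c1, t1 = generate_decay_cube(scene, irf)
        c2, t2 = generate_decay_cube(small_scene(), irf)
        np.testing.assert_array_equal(c1[NADPH].counts, c2[NADPH].counts)
        assert t1.table.equals(t2.table)

    def test_total_foreground_photons_near_expectation(self, irf):
        scene = small_scene(shape=(32, 32), n_cells=3)
        cubes, truth = generate_decay_cube(scene, irf)
        fg = truth.mask > 0
        m, p = int(fg.sum()), 2000.0
        total = cubes[NADPH].counts[fg].sum()
        assert abs(total - m * p) < 4.0 * np.sqrt(m * p)

    def test_mono_exponential_limit_histogram(self):
        """Near-pure single component, delta IRF, no offset: the pooled
        cell histogram follows e^(−t/τ) to within Poisson error."""
        axis = TimeAxis.from_period()
        irf = of.IRFCurve.delta(axis, 0)
        profiles = {NADPH: MetabolicProfile(
            NADPH, alpha1_mean=1.0 - 1e-9, alpha1_sd=0.0, tau1_mean=500.0,
            tau1_sd=0.0, tau2_mean=2500.0, tau2_sd=0.0, offset_rate=0.0,
            photons_per_pixel=5000.0, intensity_cv=0.0)}
        scene = small_scene(profiles=profiles, shape=(20, 20), n_cells=1)
        cubes, truth = generate_decay_cube(scene, irf)
        pooled = cubes[NADPH].counts[truth.mask > 0].sum(axis=0).astype(float)
        expected = np.exp(-axis.centers / 500.0)
        expected *= pooled.sum() / expected.sum()
        resid = (pooled - expected) / np.sqrt(np.maximum(expected, 1.0))
        assert np.abs(resid[expected > 5]).max() < 5.0

    def test_background_is_offset_only(self, irf):
        scene = small_scene()
        profiles = {NADPH: MetabolicProfile(
            NADPH, 0.75, 0.0, 400.0, 0.0, 2400.0, 0.0, offset_rate=0.5,
            photons_per_pixel=2000.0, intensity_cv=0.0)}
        scene = small_scene(profiles=profiles)
        cubes, truth = generate_decay_cube(scene, irf)
        bg = cubes[NADPH].counts[truth.mask == 0].mean()
        assert bg == pytest.approx(0.5, rel=0.1)

    def test_poisson_variance_matches_mean(self, irf):
        """Across 200 seeds, per-bin count variance ≈ mean (Poisson)."""
        stack = []
        for seed in range(200):
            cubes, truth = generate_decay_cube(
                small_scene(shape=(16, 16), n_cells=1,
                            radius_range=(5.0, 5.5), seed=seed), irf)
            # fixed pixel: brightest pixel histogram
            fg = np.argwhere(truth.mask > 0)
            y, x = fg[len(fg) // 2]
            stack.append(cubes[NADPH].counts[y, x])
        stack = np.array(stack, dtype=float)
        mean = stack.mean(axis=0)
        var = stack.var(axis=0, ddof=1)
        sel = mean >= 20
        assert sel.any()
        ratio = (var[sel] / mean[sel]).mean()
        assert abs(ratio - 1.0) < 0.10

    def test_truth_tau_m_is_exact_weighted_average(self, irf):
        _, truth = generate_decay_cube(small_scene(n_cells=3), irf)
        t = truth.table
        recomputed = t["nadph_alpha1"] * t["nadph_tau1"] + \
            (1 - t["nadph_alpha1"]) * t["nadph_tau2"]
        np.testing.assert_array_equal(t["nadph_tau_m"].to_numpy(),
                                      recomputed.to_numpy())

    def test_long_lifetime_without_wrap_rejected(self, irf):
        profiles = {NADPH: MetabolicProfile(
            NADPH, 0.75, 0.0, 400.0, 0.0, 20000.0, 0.0,
            photons_per_pixel=2000.0)}
        scene = small_scene(profiles=profiles, periodic=False)
        with pytest.raises(ValueError, match="period"):
            generate_decay_cube(scene, irf)


class TestProfileInvariants:
    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="alpha1"):
            MetabolicProfile(NADPH, 1.2, 0.0, 400.0, 0.0, 2400.0, 0.0)

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError, match="strictly"):
            MetabolicProfile(NADPH, 0.7, 0.0, 2400.0, 0.0, 400.0, 0.0)


class TestGenerateFeatureTable:
    def test_seeded_determinism(self):
        specs = [make_condition_spec(20.0), make_condition_spec(70.0)]
        a = generate_feature_table(100, specs, seed=3)
        b = generate_feature_table(100, specs, seed=3)
        assert a.equals(b)

    def test_physical_clipping_and_alpha_normalization(self):
        spec = ConditionSpec(efficiency=70.0, mean=baseline_omi_mean(),
                             cov=baseline_omi_cov() * 25.0)
        tab = generate_feature_table(400, [spec], seed=0)
        for ch in ("nadph", "fad"):
            a1 = tab[f"{ch}_alpha1"]
            assert ((a1 >= 0) & (a1 <= 1)).all()
            np.testing.assert_allclose(
                a1 + tab[f"{ch}_alpha2"], 1.0, atol=1e-12)
        assert (tab["nadph_tau1"] > 0).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            ConditionSpec(efficiency=10.0, mean=np.ones(5),
                          cov=baseline_omi_cov())
        with pytest.raises(ValueError, match="symmetric"):
            cov = baseline_omi_cov()
            cov[0, 1] = 1e6
            ConditionSpec(efficiency=10.0, mean=baseline_omi_mean(), cov=cov)

    def test_class_assignment_follows_50pct_rule(self):
        tab = generate_feature_table(
            10, [make_condition_spec(49.9), make_condition_spec(50.0)],
            seed=0)
        by = tab.groupby("condition")["efficiency_class"].first()
        assert by["eff_49.9"] == "low" and by["eff_50"] == "high"

    def test_shifted_variable_tops_chi2_ranking(self):
        specs = [make_condition_spec(20.0, name="low"),
                 make_condition_spec(70.0, shift={"nadph_tau_m": 5.0},
                                     name="high")]
        tab = generate_feature_table(300, specs, seed=1)
        scores = of.chi2_scores(tab)
        assert scores.idxmax() == "nadph_tau_m"

    def test_class_separation_dial_is_monotone_in_auc(self):
        aucs = []
        for shift in (0.5, 2.0, 6.0):
            specs = [make_condition_spec(20.0, name="low"),
                     make_condition_spec(70.0,
                                         shift={"nadph_tau_m": shift},
                                         name="high")]
            tab = generate_feature_table(400, specs, seed=11)
            aucs.append(train_classifier(tab).auc)
        assert aucs[0] <= aucs[1] <= aucs[2]
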