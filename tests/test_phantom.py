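"""Phantom generator: ground truth, tensors, simulators, cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomri.dsc import DSCAcquisition, gamma_variate
from gliomri.dti import DiffusionScheme, fa_from_eigenvalues, md_from_eigenvalues
from gliomri.groupstats import mask_volume
from gliomri.mt import compute_mtr
from gliomri.phantom import (GROUPS, PhantomGeometry, RERConfig,
                             default_effects, dsc_gamma_parameters,
                             make_truth, simulate_cohort, simulate_dsc,
                             simulate_dwi, simulate_mt_pair, simulate_rer,
                             simulate_rer_cohort, tensor_from_md_fa)


class TestGeometry:
    def test_masks_are_disjoint_and_inside_brain(self, geometry):
        m = geometry.masks()
        assert not (m["core"].data & m["periphery"].data).any()
        for name in ("core", "periphery", "tumour", "reference"):
            assert (m[name].data <= m["brain"].data).all()
        assert not (m["reference"].data & m["tumour"].data).any()

    def test_tumour_volume_matches_scan_trigger_range(self, geometry):
        vol = mask_volume(geometry.masks()["tumour"])
        assert 75.0 <= vol <= 100.0

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            PhantomGeometry(in_plane_mm=-1.0)
        with pytest.raises(ValueError):
            PhantomGeometry(tumour_radius_mm=0.5, periphery_ring_mm=0.6)


class TestMakeTruth:
    def test_core_roi_mean_matches_group_effect(self, geometry, effects):
        truth = make_truth(geometry, effects, "female/tumour", seed=1)
        core = truth.masks["core"].data
        assert truth.maps["MD"][core].mean() == pytest.approx(1120.0)
        assert truth.maps["MTR"][core].mean() == pytest.approx(13.02)

    def test_deterministic_given_seed(self, small_geometry, effects):
        a = make_truth(small_geometry, effects, "male/tumour", seed=3,
                       perturbation_sd=0.02)
        b = make_truth(small_geometry, effects, "male/tumour", seed=3,
                       perturbation_sd=0.02)
        for p in a.maps:
            np.testing.assert_array_equal(a.maps[p], b.maps[p])

    def test_unknown_group_error_names_valid_labels(self, small_geometry, effects):
        with pytest.raises(ValueError, match="male/tumour"):
            make_truth(small_geometry, effects, "male/gliom", seed=0)

    def test_sham_truth_has_no_tumour_contrast_beyond_table(self, small_geometry,
                                                            effects):
        # sham maps carry the sham table values in both regions: the only
        # core/periphery difference is the (small) tabulated one
        truth = make_truth(small_geometry, effects, "male/sham", seed=7)
        core = truth.maps["MTR"][truth.masks["core"].data].mean()
        peri = truth.maps["MTR"][truth.masks["periphery"].data].mean()
        assert core == pytest.approx(20.13)
        assert peri == pytest.approx(20.10)


class TestTensorFromMdFa:
    def test_zero_fa_gives_isotropic_tensor(self):
        T = tensor_from_md_fa(1000.0, 0.0)
        np.testing.assert_allclose(T, 1000.0 * np.eye(3), rtol=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(md=st.floats(1.0, 3000.0), fa=st.floats(0.0, 0.999),
           seed=st.integers(0, 100))
    def test_md_fa_round_trip(self, md, fa, seed):
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        T = tensor_from_md_fa(md, fa, axis)
        ev = np.sort(np.linalg.eigvalsh(T))[::-1]
        assert ev[-1] >= -1e-9 * md
        assert md_from_eigenvalues(ev) == pytest.approx(md, rel=1e-9)
        assert fa_from_eigenvalues(ev) == pytest.approx(fa, abs=1e-9)

    def test_boundary_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tensor_from_md_fa(1000.0, 1.0)
        with pytest.raises(ValueError):
            tensor_from_md_fa(-5.0, 0.3)
        with pytest.raises(ValueError):
            tensor_from_md_fa(1000.0, 0.3, (0, 0, 0))


class TestSimulateMT:
    def test_noiseless_ratio_inverts_mtr(self, truth_male_tumour):
        pair = simulate_mt_pair(truth_male_tumour)
        brain = truth_male_tumour.masks["brain"].data
        ratio = pair.smt.data[brain] / pair.s0.data[brain]
        expected = 1.0 - truth_male_tumour.maps["MTR"][brain] / 100.0
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)

    def test_noiseless_round_trip_recovers_truth(self, truth_male_tumour):
        pair = simulate_mt_pair(truth_male_tumour)
        mtr = compute_mtr(pair, mask=truth_male_tumour.masks["brain"])
        brain = truth_male_tumour.masks["brain"].data
        np.testing.assert_allclose(mtr.data[brain],
                                   truth_male_tumour.maps["MTR"][brain],
                                   atol=1e-12)

    def test_rician_bias_matches_monte_carlo_oracle(self, truth_male_tumour):
        """The noisy ROI mean should deviate from truth by no more than the
        Rician bias predicted by a 10,000-draw Monte-Carlo mean, plus
        sampling slack."""
        snr = 40.0
        truth = truth_male_tumour
        core = truth.masks["core"].data
        pair = simulate_mt_pair(truth, snr=snr, seed=3)
        mtr = compute_mtr(pair, mask=truth.masks["brain"])
        measured = mtr.data[core].mean()

        # oracle: E[MTR] under Rician magnitudes of the two channels
        rng = np.random.default_rng(12345)
        s0_true, sigma = 1000.0, 1000.0 / snr
        smt_true = s0_true * (1.0 - truth.maps["MTR"][core].mean() / 100.0)
        n = 10_000
        s0 = np.hypot(s0_true + rng.normal(0, sigma, n), rng.normal(0, sigma, n))
        smt = np.hypot(smt_true + rng.normal(0, sigma, n), rng.normal(0, sigma, n))
        oracle_mean = ((s0 - smt) / s0 * 100.0).mean()
        oracle_sd = ((s0 - smt) / s0 * 100.0).std(ddof=1)
        tol = 4.0 * oracle_sd / np.sqrt(core.sum())
        assert measured == pytest.approx(oracle_mean, abs=tol)

    def test_nonpositive_snr_rejected(self, truth_male_tumour):
        with pytest.raises(ValueError):
            simulate_mt_pair(truth_male_tumour, snr=0.0)


class TestSimulateDWI:
    def test_isotropic_truth_gives_direction_independent_signal(
            self, small_geometry, effects):
        # FA override = 0 in both regions -> isotropic tensors everywhere
        truth = make_truth(small_geometry, effects, "male/sham", seed=0,
                           region_values={("core", "FA"): 0.0,
                                          ("periphery", "FA"): 0.0})
        truth.maps["FA"][:] = 0.0
        series = simulate_dwi(truth).data
        brain = truth.masks["brain"].data
        shell = series[brain][:, 1:8]          # the 7 b=300 volumes
        assert np.ptp(shell, axis=1).max() < 1e-9 * shell.max()

    def test_b0_volume_equals_reference_signal(self, truth_male_tumour):
        series = simulate_dwi(truth_male_tumour, s0_reference=500.0)
        brain = truth_male_tumour.masks["brain"].data
        np.testing.assert_array_equal(series.data[brain][:, 0], 500.0)

    def test_nonunit_directions_rejected(self):
        with pytest.raises(ValueError, match="unit-norm"):
            DiffusionScheme(bvals=[0, 300], bvecs=[[0, 0, 0], [1, 1, 0]])

    def test_seeded_noise_is_reproducible(self, truth_male_tumour):
        a = simulate_dwi(truth_male_tumour, snr=30, seed=5).data
        b = simulate_dwi(truth_male_tumour, snr=30, seed=5).data
        np.testing.assert_array_equal(a, b)


class TestSimulateDSC:
    def test_zero_amplitude_gives_flat_signal(self, small_geometry, effects):
        truth = make_truth(small_geometry, effects, "male/sham", seed=0)
        truth.maps["CBV"][:] = 0.0              # K = 0 everywhere
        series = simulate_dsc(truth).data
        brain = truth.masks["brain"].data
        assert np.ptp(series[brain], axis=1).max() == 0.0

    def test_gamma_cbv_integral_matches_closed_form(self, truth_male_tumour,
                                                    acq):
        from scipy.integrate import quad
        from scipy.special import gamma as gamma_fn
        K, alpha, beta = dsc_gamma_parameters(truth_male_tumour)
        core = truth_male_tumour.masks["core"].data
        k, a, b = K[core].mean(), alpha[core].mean(), beta[core].mean()
        closed = k * b ** (a + 1) * gamma_fn(a + 1)
        numeric, _ = quad(lambda t: gamma_variate(np.array([t]), k, a, b, 10.0)[0],
                          10.0, 200.0, limit=200)
        assert numeric == pytest.approx(closed, rel=1e-6)

    def test_first_moment_is_t0_plus_beta_alpha_plus_one(self):
        from scipy.integrate import quad
        k, a, b, t0 = 1.0, 2.0, 2.0, 10.0
        area, _ = quad(lambda t: gamma_variate(np.array([t]), k, a, b, t0)[0],
                       t0, 300.0, limit=500)
        moment, _ = quad(lambda t: t * gamma_variate(np.array([t]), k, a, b, t0)[0],
                         t0, 300.0, limit=500)
        assert moment / area == pytest.approx(t0 + b * (a + 1), rel=1e-6)

    def test_bolus_outside_window_rejected(self, truth_male_tumour):
        bad = DSCAcquisition(injection_time_s=10.0, n_repetitions=41)
        bad.injection_time_s = 10.4             # beyond the last frame (10.0 s)
        with pytest.raises(ValueError, match="outside"):
            simulate_dsc(truth_male_tumour, acq=bad)


class TestSimulateCohort:
    def test_group_mean_converges_to_effect(self, effects):
        table, _ = simulate_cohort(effects, n_per_group=400, seed=11,
                                   groups=("male/tumour",))
        cell = table[(table.region == "core") & (table.parameter == "MTR")]
        sd = 0.35 * np.sqrt(8)
        assert cell.value.mean() == pytest.approx(14.29,
                                                  abs=4 * sd / np.sqrt(400))

    def test_zero_sd_gives_identical_subjects(self, effects):
        sd0 = effects.assign(sd=0.0)
        table, _ = simulate_cohort(effects, n_per_group=3, seed=2,
                                   subject_sd=sd0, groups=("female/sham",))
        for (_, _), grp in table.groupby(["region", "parameter"]):
            assert grp.value.nunique() == 1

    def test_small_cohort_rejected(self, effects):
        with pytest.raises(ValueError, match="n >= 2"):
            simulate_cohort(effects, n_per_group=1, seed=0)

    def test_delta_md_recovery_over_replicates(self, effects):
        """With n = 8 per group the simulated core-MD percent change for
        males lands within 3 generating-SEMs of the generating value in at
        least 95% of seeded replicates."""
        from gliomri.groupstats import percent_change, summarize_values
        gen_delta = (1200.0 - 1028.0) / 1028.0 * 100.0
        # SEM of the delta under the generating model (first-order)
        gen_sem = 100.0 * np.hypot(9.0 / 1028.0, 1200.0 * 4.0 / 1028.0**2)
        hits = 0
        n_rep = 500
        for rep in range(n_rep):
            table, _ = simulate_cohort(
                effects[effects.parameter.eq("MD") & effects.region.eq("core")],
                n_per_group=8, seed=1000 + rep,
                groups=("male/tumour", "male/sham"))
            g = summarize_values(table[table.group == "male/tumour"].value)
            s = summarize_values(table[table.group == "male/sham"].value)
            d = percent_change(g, s)
            hits += abs(d.delta - gen_delta) <= 3.0 * gen_sem
        assert hits / n_rep >= 0.95


class TestSimulateRER:
    def test_bin_count_matches_duration(self):
        rec = simulate_rer("male/sham", hours=60.0, seed=0)
        assert len(rec) == 120
        # 60 h = 2.5 light/dark cycles starting in light: 36 h of light
        assert rec.light.sum() == 72
        rec24 = simulate_rer("male/sham", hours=24.0, seed=0)
        assert rec24.light.sum() == 24          # half of a full cycle's bins

    def test_constant_configuration_equalizes_cycles(self):
        cfg = RERConfig(sham_day_mean=0.9, sham_night_mean=0.9,
                        bin_noise_sd=0.0, subject_sd_frac=0.0)
        rec = simulate_rer("female/sham", hours=48.0, seed=1, config=cfg)
        assert rec[rec.light].rer.mean() == pytest.approx(
            rec[~rec.light].rer.mean(), abs=1e-12)

    def test_tumour_offsets_shift_day_mean(self):
        cfg = RERConfig(bin_noise_sd=0.0, subject_sd_frac=0.0)
        sham = simulate_rer("male/sham", hours=60.0, seed=0, config=cfg)
        tum = simulate_rer("male/tumour", hours=60.0, seed=0, config=cfg)
        delta = (tum[tum.light].rer.mean() / sham[sham.light].rer.mean()
                 - 1.0) * 100.0
        assert delta == pytest.approx(-4.85, abs=0.02)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            simulate_rer("male/sham", hours=0.0)
        with pytest.raises(ValueError, match="valid groups"):
            simulate_rer("male/shamm", hours=24.0)

    def test_cohort_is_tidy_and_seeded(self):
        a = simulate_rer_cohort(n_per_group=2, hours=30.0, seed=4)
        b = simulate_rer_cohort(n_per_group=2, hours=30.0, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.group.unique()) == set(GROUPS)
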