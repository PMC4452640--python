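"""ROI statistics, percent change, Welch tests, RER aggregation, reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomri.groupstats import (GroupSummary, build_report, holm_adjust,
                                mask_volume, percent_change, rer_day_night,
                                roi_summary, significance_stars,
                                summarize_values, welch_test)
from gliomri.phantom import RERConfig, simulate_cohort, simulate_rer_cohort
from gliomri.volumes import ParametricMap, ROIMask

VS = (0.136, 0.136, 1.5)


def pmap(data, valid=None):
    return ParametricMap(data=np.asarray(data, float), voxel_size=VS,
                         quantity="x", valid=valid)


class TestRoiSummary:
    def test_constant_map(self):
        roi = ROIMask(np.ones((4, 4, 1), bool), VS)
        s = roi_summary(pmap(np.full((4, 4, 1), 3.25)), roi)
        assert s.mean == 3.25 and s.sem == 0.0 and s.n_voxels == 16

    def test_checkerboard_mean(self):
        data = np.indices((4, 4, 1)).sum(axis=0) % 2 * 10.0 + 10.0   # 10/20
        s = roi_summary(pmap(data), ROIMask(np.ones((4, 4, 1), bool), VS))
        assert s.mean == pytest.approx(15.0)

    def test_invalid_voxels_excluded_and_counted(self):
        data = np.full((3, 3, 1), 5.0)
        data[0, 0, 0] = 999.0
        valid = np.ones((3, 3, 1), bool)
        valid[0, 0, 0] = False
        s = roi_summary(pmap(data, valid), ROIMask(np.ones((3, 3, 1), bool), VS))
        assert s.mean == 5.0 and s.n_invalid == 1 and s.n_voxels == 8

    def test_no_valid_voxels_raises(self):
        valid = np.zeros((2, 2, 1), bool)
        with pytest.raises(ValueError, match="no valid"):
            roi_summary(pmap(np.ones((2, 2, 1)), valid),
                        ROIMask(np.ones((2, 2, 1), bool), VS))


class TestMaskVolume:
    def test_voxel_arithmetic(self):
        mask = np.zeros((20, 20, 2), bool)
        mask.flat[:100] = True
        assert mask_volume(ROIMask(mask, VS)) == pytest.approx(
            100 * 0.136 * 0.136 * 1.5)

    def test_empty_mask(self):
        assert mask_volume(ROIMask(np.zeros((2, 2, 1), bool), VS)) == 0.0


class TestPercentChange:
    def test_table_cells(self):
        # group-mean mode on the published periphery/core MTR means
        d = percent_change(GroupSummary("g", 8, 22.00, 0.16),
                           GroupSummary("s", 8, 20.10, 0.20))
        assert d.delta == pytest.approx(9.4527, abs=1e-4)
        d = percent_change(GroupSummary("g", 8, 13.02, 0.07),
                           GroupSummary("s", 8, 18.57, 0.22))
        assert d.delta == pytest.approx(-29.8869, abs=1e-4)

    def test_equal_means_give_zero(self):
        d = percent_change(GroupSummary("g", 8, 5.0, 0.1),
                           GroupSummary("s", 8, 5.0, 0.1))
        assert d.delta == 0.0

    def test_zero_sham_mean_rejected(self):
        with pytest.raises(ValueError, match="sham"):
            percent_change(GroupSummary("g", 8, 5.0, 0.1),
                           GroupSummary("s", 8, 0.0, 0.1))

    def test_modes_agree_on_symmetric_values(self):
        g = summarize_values([11.0, 9.0, 10.0, 10.0], "g")
        s = summarize_values([5.0, 5.0, 5.0, 5.0], "s")
        gm = percent_change(g, s, mode="group-mean")
        ps = percent_change(g, s, mode="per-subject")
        assert gm.delta == pytest.approx(ps.delta)     # mean of ratios = ratio of means here

    def test_per_subject_needs_values(self):
        with pytest.raises(ValueError, match="raw"):
            percent_change(GroupSummary("g", 8, 5.0, 0.1),
                           GroupSummary("s", 8, 4.0, 0.1), mode="per-subject")

    def test_sign_convention(self):
        up = percent_change(GroupSummary("g", 8, 6.0, 0.0),
                            GroupSummary("s", 8, 5.0, 0.0))
        down = percent_change(GroupSummary("g", 8, 4.0, 0.0),
                              GroupSummary("s", 8, 5.0, 0.0))
        assert up.delta > 0 > down.delta


class TestWelch:
    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 1, 8)
        r = welch_test(summarize_values(v, "a"), summarize_values(v, "b"))
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_published_summary_example(self):
        # periphery MTR deltas: 9.44 +/- 0.42 vs 8.09 +/- 0.41, n = 8
        r = welch_test(GroupSummary("m", 8, 9.44, 0.42),
                       GroupSummary("f", 8, 8.09, 0.41))
        assert r.t == pytest.approx(2.3001, abs=1e-3)
        assert r.df == pytest.approx(13.99, abs=0.05)
        assert r.p == pytest.approx(0.03736, abs=1e-4)
        assert r.stars == "*"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="SEM"):
            welch_test(GroupSummary("a", 8, 1.0, 0.0),
                       GroupSummary("b", 8, 2.0, 0.0))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_raw_mode_equals_summary_mode(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 10)
        raw = welch_test(summarize_values(a, "a"), summarize_values(b, "b"))
        sa, sb = summarize_values(a, "a"), summarize_values(b, "b")
        summ = welch_test(GroupSummary("a", sa.n, sa.mean, sa.sem),
                          GroupSummary("b", sb.n, sb.mean, sb.sem))
        assert raw.t == pytest.approx(summ.t, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-12)

    def test_matches_scipy_welch(self):
        from scipy import stats
        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 8)
        r = welch_test(summarize_values(a, "a"), summarize_values(b, "b"))
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert r.t == pytest.approx(t_ref) and r.p == pytest.approx(p_ref)

    def test_raw_mode_matches_permutation_oracle(self):
        """Welch p agrees with a 100,000-draw permutation p within
        Monte-Carlo error on a small synthetic case."""
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(1.1, 1.0, 8)
        r = welch_test(summarize_values(a, "a"), summarize_values(b, "b"))
        pooled = np.concatenate([a, b])
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[idx]
        pa, pb = perm[:, :8], perm[:, 8:]
        va = pa.var(axis=1, ddof=1) / 8
        vb = pb.var(axis=1, ddof=1) / 8
        t_perm = (pa.mean(axis=1) - pb.mean(axis=1)) / np.sqrt(va + vb)
        p_perm = (np.abs(t_perm) >= abs(r.t)).mean()
        mc_err = 3.0 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01
        assert r.p == pytest.approx(p_perm, abs=max(mc_err, 0.015))

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha = 0.05 stays within 0.05 +/- 0.01
        for n = 8 per group over 10,000 replicates."""
        from scipy import stats
        rng = np.random.default_rng(2024)
        a = rng.normal(0, 1, (10_000, 8))
        b = rng.normal(0, 1, (10_000, 8))
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06


class TestStarsAndHolm:
    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(5e-5) == "****"
        assert significance_stars(0.2) == "ns"

    def test_holm_monotone_and_bounded(self):
        p = np.array([0.001, 0.04, 0.03, 0.6])
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        assert adj[np.argsort(p)][0] == pytest.approx(0.004)


class TestRerDayNight:
    def test_constant_rer_gives_zero_delta(self):
        cfg = RERConfig(sham_day_mean=0.9, sham_night_mean=0.9,
                        tumour_day_offset_pct={"male": 0.0, "female": 0.0},
                        tumour_night_offset_pct={"male": 0.0, "female": 0.0},
                        bin_noise_sd=0.0, subject_sd_frac=0.0)
        rec = simulate_rer_cohort(n_per_group=3, hours=48.0, seed=0, config=cfg)
        deltas, _ = rer_day_night(rec)
        np.testing.assert_allclose(deltas.delta_pct, 0.0, atol=1e-10)

    def test_configured_day_offsets_recovered(self):
        rec = simulate_rer_cohort(n_per_group=5, hours=60.0, seed=3)
        deltas, comps = rer_day_night(rec)
        day = deltas[deltas.cycle == "day"].set_index("sex")
        assert day.loc["male", "delta_pct"] == pytest.approx(-4.85, abs=1.0)
        assert day.loc["female", "delta_pct"] == pytest.approx(-1.22, abs=1.0)
        assert set(comps.cycle) == {"day", "night"}

    def test_phase_shift_swaps_day_and_night(self):
        rec = simulate_rer_cohort(n_per_group=2, hours=48.0, seed=5)
        shifted = rec.copy()
        shifted["light"] = ~shifted["light"]     # 12-h phase shift
        d0, _ = rer_day_night(rec)
        d1, _ = rer_day_night(shifted)
        m0 = d0.set_index(["sex", "cycle"]).delta_pct
        m1 = d1.set_index(["sex", "cycle"]).delta_pct
        for sex in ("male", "female"):
            assert m1[(sex, "day")] == pytest.approx(m0[(sex, "night")])
            assert m1[(sex, "night")] == pytest.approx(m0[(sex, "day")])

    def test_short_records_rejected(self):
        rec = simulate_rer_cohort(n_per_group=2, hours=20.0, seed=0)
        with pytest.raises(ValueError, match="24"):
            rer_day_night(rec)


class TestBuildReport:
    def test_zero_sd_cohort_reproduces_effect_table(self, effects):
        sd0 = effects.assign(sd=0.0)
        table, _ = simulate_cohort(effects, n_per_group=2, seed=0,
                                   subject_sd=sd0)
        summary, deltas = build_report(table)
        for row in effects.itertuples(index=False):
            cell = summary[(summary.region == row.region)
                           & (summary.parameter == row.parameter)]
            assert cell[f"{row.group}:mean"].iloc[0] == pytest.approx(
                row.mean, rel=1e-12)
        assert len(deltas) == 9                  # 6 map cells + 3 perfusion

    def test_missing_group_listed(self, effects):
        table, _ = simulate_cohort(effects, n_per_group=2, seed=0,
                                   groups=("male/tumour", "male/sham"))
        with pytest.raises(ValueError, match="female/sham"):
            build_report(table)

    def test_empty_cohort_rejected(self):
        empty = pd.DataFrame(columns=["subject", "sex", "condition", "group",
                                      "region", "parameter", "value"])
        with pytest.raises(ValueError, match="missing groups"):
            build_report(empty)

    def test_welch_stars_present_with_spread(self, effects):
        table, _ = simulate_cohort(effects, n_per_group=8, seed=7)
        _, deltas = build_report(table)
        md_core = deltas[(deltas.region == "core") & (deltas.parameter == "MD")]
        assert md_core.p.iloc[0] < 0.01          # strong simulated MD effect
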