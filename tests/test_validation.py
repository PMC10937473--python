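"""Consensus, dispersion and bias statistics, and the full summary builder."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from echolv.annotation import Annotation, Dataset, Phase
from echolv.measure import measurement_rows
from echolv.phantom import PhantomSpec, RaterModel, generate_phantom, simulate_raters
from echolv.validation import (
    DegenerateDispersionError,
    bias_test,
    build_summary,
    consensus,
    deviations,
    levene_dispersion_test,
    measurement_table,
    rms_dispersion,
)


def brute_force_levene(a, b, center):
    """Independent implementation of the two-group W statistic from its formula."""
    groups = [np.asarray(a, float), np.asarray(b, float)]
    cfun = np.median if center == "median" else np.mean
    z = [np.abs(g - cfun(g)) for g in groups]
    n = [g.size for g in groups]
    N, k = sum(n), 2
    zbar_i = [zi.mean() for zi in z]
    zbar = sum(zi.sum() for zi in z) / N
    between = sum(ni * (zi - zbar) ** 2 for ni, zi in zip(n, zbar_i))
    within = sum(((zi - zb) ** 2).sum() for zi, zb in zip(z, zbar_i))
    w = (N - k) / (k - 1) * between / within
    p = float(stats.f.sf(w, k - 1, N - k))
    return w, p


class TestConsensus:
    def test_identical_values(self):
        assert consensus([1.3] * 26) == pytest.approx(1.3)

    def test_mean(self):
        assert consensus([1.0, 1.2, 1.4, 1.0, 1.4]) == pytest.approx(1.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            consensus([1.0, math.nan, 1.2])

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            consensus([1.0])


class TestDeviations:
    def test_signed_and_order_preserving(self):
        d = deviations([1.0, 1.2, 1.4, 1.0, 1.4], 1.2)
        assert d == pytest.approx([-0.2, 0.0, 0.2, -0.2, 0.2])

    def test_sum_zero_when_consensus_is_mean(self):
        vals = [0.7, 1.1, 0.9, 1.5, 1.3]
        assert deviations(vals, consensus(vals)).sum() == pytest.approx(0.0, abs=1e-12)


class TestRmsDispersion:
    def test_hand_value(self):
        assert rms_dispersion([-0.2, 0, 0.2, -0.2, 0.2]) == pytest.approx(
            math.sqrt(0.032), abs=1e-12)

    def test_zeros_and_single(self):
        assert rms_dispersion([0.0, 0.0]) == 0.0
        assert rms_dispersion([-0.7]) == pytest.approx(0.7)


class TestLevene:
    def test_hand_case_w_and_p(self):
        w, p = levene_dispersion_test([0, 2, 4], [1, 2, 3], center="mean")
        assert w == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(float(stats.f.sf(0.8, 1, 4)), abs=1e-9)

    def test_identical_groups_give_zero_w(self):
        w, _ = levene_dispersion_test([0, 2, 4], [0, 2, 4], center="mean")
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_spread_raises(self):
        with pytest.raises(DegenerateDispersionError):
            levene_dispersion_test([1, 5], [3, 3], center="mean")

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_matches_brute_force_on_random_groups(self, center):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            a = rng.normal(0, rng.uniform(0.5, 3), size=rng.integers(3, 40))
            b = rng.normal(0, rng.uniform(0.5, 3), size=rng.integers(3, 40))
            w, p = levene_dispersion_test(a, b, center=center)
            wb, pb = brute_force_levene(a, b, center)
            assert w == pytest.approx(wb, abs=1e-8)
            assert p == pytest.approx(pb, abs=1e-8)


class TestBiasTest:
    def test_candidate_equal_consensus(self):
        r = bias_test([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert (r.mean_bias, r.t, r.p) == (0.0, 0.0, 1.0)

    def test_closed_form_t_and_p(self):
        r = bias_test([1.1, 1.2, 1.0], [1.0, 1.0, 1.0])
        assert r.mean_bias == pytest.approx(0.1)
        assert r.t == pytest.approx(math.sqrt(3), abs=1e-9)
        assert r.p == pytest.approx(0.2254, abs=2e-4)

    def test_constant_nonzero_differences_flagged(self):
        r = bias_test([1.1, 1.1], [1.0, 1.0])
        assert r.degenerate
        assert math.isnan(r.p)

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            c = rng.normal(1.0, 0.2, n)
            r = rng.normal(1.0, 0.2, n)
            ours = bias_test(c, r)
            ref = stats.ttest_rel(c, r)
            assert ours.t == pytest.approx(float(ref.statistic), abs=1e-9)
            assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-9)


def make_simulated_table(n_frames=10, sigma_t=1.5, sigma_l=4.0, bias_sd=2.0,
                         seed=0, with_candidate=True, candidate_is_truth=True):
    spec_kw = dict(size_px=320, axis_origin=(60.0, 160.0), axis_angle=0.0,
                   ivs_cm=0.5, lvd_cm=3.0, fw_cm=0.5, spacing_cm_per_px=0.02,
                   speckle_strength=0.0)
    model = RaterModel(sigma_transverse_px=sigma_t, sigma_longitudinal_px=sigma_l,
                       rater_longitudinal_bias_sd_px=bias_sd)
    frames, annotations = [], []
    for i in range(n_frames):
        frame, _, truth = generate_phantom(
            PhantomSpec(**spec_kw), seed=i, frame_id=f"F{i:03d}",
            study_id=f"S{i // 2:03d}",
            phase=Phase.ED if i % 2 == 0 else Phase.ES)
        frames.append(frame)
        annotations.extend(simulate_raters(truth, frame, model, seed=seed))
        if with_candidate:
            annotations.append(Annotation(
                frame_id=frame.frame_id, rater_id="AI", repeat_index=1,
                points=truth.points))
    ds = Dataset(frames=frames, annotations=annotations)
    return measurement_table(measurement_rows(ds))


class TestBuildSummary:
    def test_pooled_expert_deviation_mean_is_structurally_zero(self):
        table = make_simulated_table(n_frames=8, seed=3)
        result = build_summary(table, candidate_id="AI")
        assert not result.summary.empty
        assert np.all(np.abs(result.summary["expert_dev_mean"]) < 1e-9)

    def test_zero_noise_panel_degenerate_tests_flagged(self):
        table = make_simulated_table(n_frames=4, sigma_t=0.0, sigma_l=0.0,
                                     bias_sd=0.0, seed=1)
        result = build_summary(table, candidate_id="AI")
        assert np.all(result.summary["expert_dev_sd"] == 0.0)
        assert "degenerate_dispersion" in result.summary.columns
        assert result.summary["degenerate_dispersion"].fillna(False).all()

    def test_row_order_invariance(self):
        table = make_simulated_table(n_frames=6, seed=9)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = build_summary(table, candidate_id="AI").summary
        b = build_summary(shuffled, candidate_id="AI").summary
        pd.testing.assert_frame_equal(a, b)

    def test_missing_candidate_frames_reported_not_dropped(self):
        table = make_simulated_table(n_frames=6, seed=2)
        drop_frame = "F000"
        table = table[~((table["rater_id"] == "AI")
                        & (table["frame_id"] == drop_frame))]
        result = build_summary(table, candidate_id="AI")
        assert any(drop_frame in v for v in result.excluded_frames.values())
        sub = result.records.query("frame_id == @drop_frame")
        assert len(sub) == 3  # still present in per-frame records
        assert sub["candidate_deviation_cm"].isna().all()

    def test_duplicate_candidate_rejected(self):
        table = make_simulated_table(n_frames=4, seed=0)
        dup = table[table["rater_id"] == "AI"].iloc[[0]].copy()
        dup["repeat_index"] = 2
        with pytest.raises(ValueError, match="at most one"):
            build_summary(pd.concat([table, dup], ignore_index=True),
                          candidate_id="AI")

    def test_expert_dispersion_recovers_closed_form(self):
        """Thickness-site expert SD ~ sqrt(2) * sigma_t * spacing for an
        axis-aligned phantom panel (two independent endpoint displacements)."""
        table = make_simulated_table(n_frames=50, sigma_t=2.0, sigma_l=0.0,
                                     bias_sd=0.0, seed=4)
        result = build_summary(table, candidate_id="AI")
        expected = math.sqrt(2) * 2.0 * 0.02
        thick = result.summary.query("site in ('IVS', 'FW')")
        for sd in thick["expert_dev_sd"]:
            assert sd == pytest.approx(expected, rel=0.15)


class TestMeasurementTable:
    def test_duplicate_key_rejected(self):
        rows = [("F1", "ED", "IVS", "E0", 1, 0.5),
                ("F1", "ED", "IVS", "E0", 1, 0.6)]
        with pytest.raises(ValueError, match="duplicate"):
            measurement_table(rows)

    def test_unknown_phase_or_site_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            measurement_table([("F1", "XX", "IVS", "E0", 1, 0.5)])
        with pytest.raises(ValueError, match="site"):
            measurement_table([("F1", "ED", "XYZ", "E0", 1, 0.5)])
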