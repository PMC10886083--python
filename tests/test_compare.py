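"""Agreement metrics against brute-force oracles; cohort aggregation; ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitkin import (ComparisonResult, JointAngleSeries, compare_trial, mae,
                     pearson, position_effect_test, summarize_cohort)
from gaitkin.errors import DataError


def mae_oracle(m, h):
    total = 0.0
    for a, b in zip(m, h):
        total += abs(a - b)
    return total / len(m)


def pearson_oracle(m, h):
    mm, hm = sum(m) / len(m), sum(h) / len(h)
    cov = sum((a - mm) * (b - hm) for a, b in zip(m, h))
    vm = sum((a - mm) ** 2 for a in m)
    vh = sum((b - hm) ** 2 for b in h)
    return cov / (vm ** 0.5 * vh ** 0.5)


class TestMae:
    def test_identity_zero(self):
        x = np.random.default_rng(0).normal(size=50)
        assert mae(x, x) == 0.0

    def test_hand_example(self):
        assert mae([10.0, 20.0], [12.0, 18.0]) == pytest.approx(2.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(3, 2000))
            m, h = rng.normal(size=n) * 30, rng.normal(size=n) * 30
            assert mae(m, h) == pytest.approx(mae_oracle(m, h), abs=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30),
           st.floats(-50, 50), st.floats(-3, 3))
    @settings(deadline=None, max_examples=60)
    def test_symmetry_translation_scale(self, trace, c, a):
        m = np.asarray(trace)
        h = m[::-1].copy()
        assert mae(m, h) == pytest.approx(mae(h, m), abs=1e-9)
        assert mae(m + c, h + c) == pytest.approx(mae(m, h), abs=1e-7)
        assert mae(a * m, a * h) == pytest.approx(abs(a) * mae(m, h), rel=1e-9,
                                                  abs=1e-9)

    def test_length_mismatch_reports_both(self):
        with pytest.raises(DataError, match="3.*vs.*4|\\(3,\\).*\\(4,\\)"):
            mae(np.zeros(3), np.zeros(4))


class TestPearson:
    def test_perfect_and_inverse(self):
        x = np.arange(10.0)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=500)
        assert pearson(m, 3.2 * m + 7.0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(3, 2000))
            m, h = rng.normal(size=n), rng.normal(size=n)
            assert pearson(m, h) == pytest.approx(pearson_oracle(m, h), abs=1e-12)

    def test_antisymmetric_under_negation(self):
        rng = np.random.default_rng(6)
        m, h = rng.normal(size=40), rng.normal(size=40)
        assert pearson(m, -h) == pytest.approx(-pearson(m, h), abs=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(DataError, match="zero variance"):
            pearson(np.ones(10), np.arange(10.0))


def _angle_series(data, fps=30.0, subject="S01", position="P3"):
    from gaitkin import TrialMetadata
    n = data.shape[0]
    return JointAngleSeries(fps=fps, times=np.arange(n) / fps, data=data,
                            meta=TrialMetadata(subject_id=subject,
                                               camera_position=position))


class TestCompareTrial:
    def _pair(self, offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(300) / 30.0
        base = 20 * np.sin(2 * np.pi * t)[:, None, None] + rng.normal(0, 5, (1, 2, 3))
        return _angle_series(base), _angle_series(base + offset)

    def test_identical_series(self):
        m, h = self._pair()
        res = compare_trial(m, h)
        assert (res.table["mae"] == 0.0).all()
        assert res.table["rho"].to_numpy() == pytest.approx(1.0)

    def test_constant_offset(self):
        m, h = self._pair(offset=3.0)
        res = compare_trial(m, h)
        assert res.table["mae"].to_numpy() == pytest.approx(3.0)
        assert res.table["rho"].to_numpy() == pytest.approx(1.0)

    def test_matches_oracle_on_noisy_pair(self):
        rng = np.random.default_rng(11)
        m, h = self._pair()
        h.data = h.data + rng.normal(0, 2, h.data.shape)
        res = compare_trial(m, h)
        mm = m.trace("knee", "left")
        hh = h.trace("knee", "left")
        assert res.cell("knee", "left")["mae"] == pytest.approx(
            mae_oracle(mm, hh), abs=1e-12)
        assert res.cell("knee", "left")["rho"] == pytest.approx(
            pearson_oracle(mm, hh), abs=1e-12)


def _result(subject, position, mae_val, rho_val):
    idx = pd.MultiIndex.from_product([("hip", "knee", "ankle"),
                                      ("left", "right")],
                                     names=["joint", "side"])
    table = pd.DataFrame({"mae": mae_val, "rho": rho_val, "n_frames": 1000},
                         index=idx)
    return ComparisonResult(subject_id=subject, position=position, table=table)


class TestSummarizeCohort:
    def test_identical_subjects_zero_sd(self):
        results = [_result(s, p, 2.5, 0.9)
                   for s in ("S1", "S2", "S3") for p in ("P1", "P2")]
        summary = summarize_cohort(results, with_p=False)
        assert (summary.mae_mean == 2.5).all().all()
        assert (summary.mae_sd == 0.0).all().all()

    def test_two_subject_sample_sd(self):
        results = [_result("S1", "P1", 2.0, 0.9), _result("S2", "P1", 4.0, 0.9)]
        summary = summarize_cohort(results, with_p=False)
        assert summary.mae_mean.loc[("hip", "left"), "P1"] == pytest.approx(3.0)
        assert summary.mae_sd.loc[("hip", "left"), "P1"] == pytest.approx(
            np.sqrt(2.0))  # (n-1) estimator

    def test_single_subject_sd_undefined(self):
        summary = summarize_cohort([_result("S1", "P1", 2.0, 0.9)], with_p=False)
        assert np.isnan(summary.mae_sd.loc[("hip", "left"), "P1"])

    def test_best_position_tracks_planted_minimum(self):
        rng = np.random.default_rng(13)
        results = []
        for s in range(6):
            for p, noise in (("P1", 3.0), ("P2", 1.0), ("P3", 2.0)):
                results.append(_result(f"S{s}", p,
                                       noise + rng.normal(0, 0.1), 0.9))
        summary = summarize_cohort(results, with_p=False)
        assert (summary.best_position["min_mae"] == "P2").all()


class TestPositionEffectTest:
    def test_matches_statsmodels_anova_rm(self):
        sm = pytest.importorskip("statsmodels.stats.anova")
        rng = np.random.default_rng(17)
        grid = rng.normal(size=(12, 5)) + rng.normal(size=(12, 1))
        df = pd.DataFrame([
            {"subject": i, "position": j, "value": grid[i, j]}
            for i in range(12) for j in range(5)])
        ref = sm.AnovaRM(df, "value", "subject", within=["position"]).fit()
        expected = float(ref.anova_table["Pr > F"].iloc[0])
        assert position_effect_test(grid) == pytest.approx(expected, abs=1e-10)

    def test_matches_permutation_oracle(self):
        # permute condition labels within subjects; compare p-values
        rng = np.random.default_rng(19)
        grid = rng.normal(size=(8, 4))
        grid[:, 2] += 0.9

        def f_stat(v):
            n, k = v.shape
            grand = v.mean()
            ss_c = n * np.sum((v.mean(axis=0) - grand) ** 2)
            resid = v - v.mean(axis=0) - v.mean(axis=1, keepdims=True) + grand
            ss_e = np.sum(resid ** 2)
            return (ss_c / (k - 1)) / (ss_e / ((k - 1) * (n - 1)))

        obs = f_stat(grid)
        count = 0
        n_perm = 3000
        for _ in range(n_perm):
            perm = np.array([row[rng.permutation(grid.shape[1])] for row in grid])
            if f_stat(perm) >= obs:
                count += 1
        perm_p = (count + 1) / (n_perm + 1)
        anova_p = position_effect_test(grid)
        mc_sd = np.sqrt(perm_p * (1 - perm_p) / n_perm)
        assert abs(anova_p - perm_p) < max(4 * mc_sd, 0.02)

    def test_no_effect_boundary_p_is_one(self):
        grid = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 4))
        assert position_effect_test(grid) == 1.0

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(23)
        grid = rng.normal(0, 0.3, size=(20, 5))
        grid[:, 4] += 2.0
        assert position_effect_test(grid) < 1e-3

    def test_incomplete_grid_lists_missing(self):
        grid = np.ones((4, 3))
        grid[1, 2] = np.nan
        with pytest.raises(DataError, match="missing"):
            position_effect_test(grid)
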