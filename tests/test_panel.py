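"""Biomarker panel: attribution, filters, intersection, annotation."""

import numpy as np
import pandas as pd
import pytest

from smfkit.containers import FeatureMatrix
from smfkit.panel import (integrated_gradients, rank_signals, fold_change,
                          t_tests, select_panel, evaluate_panel, annotate,
                          AttributionMatrix)


class LinearScorer:
    """F(x) = w.x with exact gradients — a closed-form attribution oracle."""

    def __init__(self, w):
        self.w = np.asarray(w, float)

    def decision_scores(self, x):
        return np.atleast_2d(x) @ self.w

    def input_gradient(self, x):
        return np.tile(self.w, (len(np.atleast_2d(x)), 1))


def label_matrix(values, labels, mz=None):
    values = np.asarray(values, float)
    mz = np.arange(values.shape[1], dtype=float) + 100 if mz is None else mz
    return FeatureMatrix(values, mz, [f"s{i}" for i in range(len(values))],
                         labels=np.asarray(labels))


class TestIntegratedGradients:
    def test_linear_model_closed_form(self, rng):
        w = rng.normal(0, 1, 9)
        x = rng.normal(0, 1, (6, 9))
        for n_steps in (1, 10, 300):
            attr = integrated_gradients(LinearScorer(w), x, n_steps=n_steps)
            np.testing.assert_allclose(attr.values, x * w, rtol=1e-10)
            assert attr.completeness_gap.max() < 1e-9

    def test_zero_path_gives_zero_attribution(self, rng):
        w = rng.normal(0, 1, 5)
        b = rng.normal(0, 1, 5)
        attr = integrated_gradients(LinearScorer(w), b[None, :], baseline=b)
        np.testing.assert_allclose(attr.values, 0.0, atol=1e-12)

    def test_nn_completeness_axiom(self, panel_cohort):
        """Attributions sum to F(x) - F(baseline) within 1% at 300 steps."""
        _, _, _, attr, _, _ = panel_cohort
        rel = attr.completeness_gap / np.maximum(np.abs(attr.delta_f), 1e-9)
        assert rel.max() <= 0.01

    def test_non_differentiable_model_rejected(self):
        class Opaque:
            def decision_scores(self, x):
                return np.zeros(len(x))
        with pytest.raises(TypeError, match="gradient"):
            integrated_gradients(Opaque(), np.ones((2, 3)))


class TestRankSignals:
    def make_attr(self, values):
        values = np.asarray(values, float)
        return AttributionMatrix(values, np.zeros(values.shape[1]), 10,
                                 np.zeros(len(values)))

    def test_top_fraction_count(self, rng):
        attr = self.make_attr(rng.normal(0, 1, (5, 134)))
        top = rank_signals(attr, np.arange(134.0), 0.20)
        assert len(top) == 27  # ceil(0.2 * 134)

    def test_ranking_by_mean_absolute_attribution(self):
        attr = self.make_attr([[0.0, 5.0, -1.0], [0.0, -5.0, 1.0]])
        top = rank_signals(attr, np.array([100.0, 200.0, 300.0]), 0.30)
        assert top.tolist() == [1]  # ceil(0.3 * 3) = 1, highest mean |IG|

    def test_all_zero_attributions_fall_back_to_mz_order(self):
        attr = self.make_attr(np.zeros((3, 10)))
        top = rank_signals(attr, np.arange(10.0), 0.3)
        assert top.tolist() == [0, 1, 2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_signals(self.make_attr(np.zeros((0, 0))), np.empty(0))


class TestFoldChangeAndTests:
    def test_simple_ratio(self):
        fm = label_matrix([[8.0], [8.0], [2.0], [2.0]],
                          ["case", "case", "control", "control"])
        assert fold_change(fm)[0] == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        fm = label_matrix([[5.0], [5.0], [5.0], [5.0]],
                          ["case", "case", "control", "control"])
        assert fold_change(fm)[0] == 0.0

    def test_zero_group_mean_uses_pseudo_intensity(self):
        fm = label_matrix([[4.0], [4.0], [0.0], [0.0]],
                          ["case", "case", "control", "control"])
        # control mean 0 -> eps = 2.0 (half the smallest nonzero), log2(4/2) = 1
        assert fold_change(fm)[0] == pytest.approx(1.0)

    def test_planted_fold_change_recovered(self):
        from smfkit.synthgen import SynthConfig, cohort_feature_matrix
        cfg = SynthConfig(n_case=100, n_control=100, n_differential=10,
                          log2fc_range=(2.5, 2.5), height_sigma_log=0.4,
                          noise_cv=0.0, batch_scale_sd=0.0, seed=17)
        fm, truth = cohort_feature_matrix(cfg)
        est = fold_change(fm)[truth.differential_index]
        # log2 of arithmetic-mean ratio exceeds the planted (geometric) log2FC
        # by the identical lognormal-mean offset in both groups, so the signed
        # values still center on truth
        np.testing.assert_allclose(est, truth.true_log2fc, atol=0.35)
        assert abs((est - truth.true_log2fc).mean()) < 0.1

    def test_t_test_trivial_cases(self):
        fm = label_matrix(np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]]),
                          ["case"] * 3 + ["control"] * 3)
        assert t_tests(fm)[0] == pytest.approx(1.0)

    def test_t_test_large_effect(self, rng):
        vals = np.r_[np.zeros((4, 1)), 10.0 + rng.normal(0, 1e-3, (4, 1))]
        fm = label_matrix(vals, ["case"] * 4 + ["control"] * 4)
        assert t_tests(fm)[0] < 1e-6

    def test_t_test_type_i_calibration(self, rng):
        """Null signals rejected at ~5%: pooled over 134 signals x sims."""
        hits, total = 0, 0
        for _ in range(40):
            vals = rng.normal(100, 10, (30, 134))
            fm = label_matrix(vals, ["case"] * 15 + ["control"] * 15)
            p = t_tests(fm)
            hits += (p < 0.05).sum()
            total += len(p)
        assert 0.04 <= hits / total <= 0.06


class TestSelectPanel:
    def brute_force(self, top, fc, p, fc_min=1.8, alpha=0.05):
        return sorted(set(map(int, top))
                      & {i for i in range(len(fc)) if abs(fc[i]) > fc_min}
                      & {i for i in range(len(p)) if p[i] < alpha})

    def test_disjoint_filters_empty_panel(self):
        pan = select_panel([0, 1], np.array([0.0, 0.0, 3.0]),
                           np.array([0.5, 0.5, 0.001]), np.arange(3.0))
        assert len(pan) == 0

    def test_singleton_panel_direction(self):
        pan = select_panel([2], np.array([0.0, 0.0, -2.5]),
                           np.array([0.5, 0.5, 0.001]), np.arange(3.0))
        assert len(pan) == 1
        assert pan.direction == ["down"]

    def test_matches_brute_force_on_random_instances(self, rng):
        """Triple intersection equals an independent set computation on 100
        random instances, and is invariant to signal order."""
        for _ in range(100):
            m = int(rng.integers(5, 200))
            fc = rng.normal(0, 2.5, m)
            p = rng.uniform(0, 0.2, m)
            top = rng.choice(m, size=max(1, m // 5), replace=False)
            pan = select_panel(top, fc, p, np.arange(m, dtype=float))
            assert pan.indices.tolist() == self.brute_force(top, fc, p)

    def test_relaxing_thresholds_never_removes_members(self, rng):
        m = 60
        fc = rng.normal(0, 2.5, m)
        p = rng.uniform(0, 0.2, m)
        top_small = rng.choice(m, size=12, replace=False)
        top_big = np.union1d(top_small, rng.choice(m, size=12, replace=False))
        strict = set(select_panel(top_small, fc, p, np.arange(m, dtype=float),
                                  fc_min=2.0, alpha=0.03).indices.tolist())
        loose = set(select_panel(top_big, fc, p, np.arange(m, dtype=float),
                                 fc_min=1.5, alpha=0.08).indices.tolist())
        assert strict <= loose

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError, match="same signal set"):
            select_panel([0], np.zeros(3), np.zeros(2), np.zeros(3))


class TestPanelRecovery:
    def test_planted_strong_signals_recovered(self, panel_cohort):
        """>= 5 of the 6 planted strong signals survive the triple filter,
        and most appear in the attribution top-20%."""
        fm, truth, clf, attr, xz, y = panel_cohort
        top = rank_signals(attr, fm.signal_mz, 0.20)
        planted = set(truth.differential_index.tolist())
        assert len(planted & set(top.tolist())) >= 5
        pan = select_panel(top, fold_change(fm), t_tests(fm), fm.signal_mz,
                           attr=attr)
        assert len(planted & set(pan.indices.tolist())) >= 5

    def test_panel_beats_best_single_member(self, panel_cohort):
        fm, truth, clf, attr, xz, y = panel_cohort
        top = rank_signals(attr, fm.signal_mz, 0.20)
        pan = select_panel(top, fold_change(fm), t_tests(fm), fm.signal_mz)
        ev = evaluate_panel(fm, pan, "nn", k=10, repeats=1, seed=0)
        assert ev["panel_auc"] > ev["best_single_auc"]

    def test_empty_panel_rejected(self, panel_cohort):
        fm = panel_cohort[0]
        empty = select_panel([], np.zeros(fm.n_signals),
                             np.ones(fm.n_signals), fm.signal_mz)
        with pytest.raises(ValueError, match="empty"):
            evaluate_panel(fm, empty)


class TestAnnotate:
    @pytest.fixture
    def mass_table(self):
        # synthetic reference masses chosen so [M+Na]+ of valine-like entry
        # lands at the observed 140.14
        return pd.DataFrame({
            "name": ["valine-like", "faraway"],
            "monoisotopic_mass": [140.14 - 22.989218, 450.0],
        })

    def panel_at(self, mzs):
        m = np.asarray(mzs, float)
        k = len(m)
        from smfkit.panel import Panel
        return Panel(np.arange(k), m, np.ones(k), np.full(k, 0.01),
                     np.full(k, 0.01), np.arange(1, k + 1), ["up"] * k)

    def test_adduct_match_within_tolerance(self, mass_table):
        out = annotate(self.panel_at([140.14]), mass_table, ppm_tol=150)
        assert len(out) == 1
        assert out.loc[0, "name"] == "valine-like"
        assert out.loc[0, "adduct"] == "[M+Na]+"

    def test_distant_mass_unmatched(self, mass_table):
        out = annotate(self.panel_at([1000.0]), mass_table, ppm_tol=150)
        assert len(out) == 0

    def test_zero_tolerance_requires_exact(self, mass_table):
        assert len(annotate(self.panel_at([140.1400001]), mass_table,
                            ppm_tol=0)) == 0
        assert len(annotate(self.panel_at([140.14]), mass_table,
                            ppm_tol=0)) == 1

    def test_empty_table_warns_and_skips(self):
        with pytest.warns(UserWarning, match="empty mass table"):
            out = annotate(self.panel_at([140.14]), pd.DataFrame(), ppm_tol=150)
        assert len(out) == 0
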