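"""Inferential layer: contrasts, midpoint classification, validity, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import blockfc as b

from conftest import quiet_truth


def toy_table(values, sequences=None, speeds=None, subject=1):
    n = len(values)
    return pd.DataFrame({
        "block_id": range(n), "subject": subject, "y": values,
        "sequence": sequences if sequences is not None else ["synchronous"] * n,
        "speed_hz": speeds if speeds is not None else [2.0] * n,
        "coordination": [{"unimanual": 1, "synchronous": 2, "alternating": 3,
                          "unbalanced": 4}[s] for s in
                         (sequences if sequences is not None else ["synchronous"] * n)],
    })


class TestContrastGlm:
    def _graded(self, per_level, noise=0.0, seed=0, reps=8):
        rng = np.random.default_rng(seed)
        seqs, ys = [], []
        for seq, v in per_level.items():
            seqs += [seq] * reps
            ys += list(v + rng.normal(0, noise, reps))
        return toy_table(ys, sequences=seqs)

    def test_linear_increase_without_noise(self):
        tab = self._graded({"unimanual": 1, "synchronous": 2, "alternating": 3,
                            "unbalanced": 4})
        lin = b.contrast_glm(tab, "y", "coordination", "linear")
        quad = b.contrast_glm(tab, "y", "coordination", "quadratic")
        assert lin.F == np.inf and lin.p == 0.0 and lin.direction > 0
        assert quad.F == 0.0

    def test_u_shape_loads_on_quadratic_only(self):
        tab = self._graded({"unimanual": 2, "synchronous": 1, "alternating": 1,
                            "unbalanced": 2}, noise=0.01, seed=1)
        lin = b.contrast_glm(tab, "y", "coordination", "linear")
        quad = b.contrast_glm(tab, "y", "coordination", "quadratic")
        assert quad.F > 100
        assert lin.p > 0.05

    def test_group_fixed_equals_subject_scope_for_one_subject(self):
        tab = self._graded({"unimanual": 1, "synchronous": 3, "alternating": 2,
                            "unbalanced": 4}, noise=0.5, seed=2)
        r_subj = b.contrast_glm(tab, "y", "coordination", scope="subject")
        r_grp = b.contrast_glm(tab, "y", "coordination", scope="group_fixed")
        assert r_subj.F == r_grp.F and r_subj.p == r_grp.p

    def test_group_fixed_uses_per_subject_intercepts(self):
        t1 = self._graded({"unimanual": 1, "synchronous": 2, "alternating": 3,
                           "unbalanced": 4}, noise=0.3, seed=3)
        t2 = self._graded({"unimanual": 1, "synchronous": 2, "alternating": 3,
                           "unbalanced": 4}, noise=0.3, seed=4)
        t2["y"] += 100.0   # subject offset must be absorbed
        t2["subject"] = 2
        both = pd.concat([t1, t2], ignore_index=True)
        res = b.contrast_glm(both, "y", "coordination", scope="group_fixed")
        assert res.p < 1e-10 and res.direction > 0

    def test_missing_values_dropped_and_counted(self):
        tab = self._graded({"unimanual": 1, "synchronous": 2, "alternating": 3,
                            "unbalanced": 4}, noise=0.1, seed=5)
        tab.loc[:3, "y"] = np.nan
        res = b.contrast_glm(tab, "y", "coordination")
        assert res.n_dropped == 4 and res.n_obs == len(tab) - 4

    def test_single_level_rejected(self):
        tab = toy_table([1.0] * 8)
        with pytest.raises(ValueError, match="2 levels"):
            b.contrast_glm(tab, "y", "coordination")

    def test_f_matches_sse_oracle_on_simulated_measures(self, measure_table):
        table, _ = measure_table
        col = "left_M1-right_M1__full_task__z"
        res = b.contrast_glm(table, col, "speed")
        y = table[col].values
        lv = table["speed_hz"].values
        levels = np.sort(np.unique(lv))
        # Gram-Schmidt polynomial codes, independently derived
        idx = np.searchsorted(levels, lv).astype(float)
        cols = [np.ones_like(idx)]
        for d in (1, 2, 3):
            c = idx ** d
            for prev in cols:
                c = c - (c @ prev) / (prev @ prev) * prev
            cols.append(c)
        X_full = np.column_stack(cols)
        X_red = np.delete(X_full, 1, axis=1)

        def sse(X):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            return float((y - X @ beta) @ (y - X @ beta))
        f_oracle = (sse(X_red) - sse(X_full)) / (sse(X_full) / (len(y) - 4))
        assert res.F == pytest.approx(f_oracle, rel=1e-8)

    def test_p_values_and_f_in_valid_range(self, measure_table):
        table, _ = measure_table
        for dim in ("speed", "coordination"):
            for shape in ("linear", "quadratic"):
                res = b.contrast_glm(table, "left_M1__psc", dim, shape)
                assert res.F >= 0 and 0.0 <= res.p <= 1.0


class TestThresholdClassify:
    def test_threshold_is_midpoint_of_class_means(self):
        seqs = ["unimanual"] * 4 + ["synchronous"] * 4
        tab = toy_table([1.0] * 4 + [3.0] * 4, sequences=seqs)
        res = b.threshold_classify(tab, "y")
        assert res.threshold == pytest.approx(2.0)
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_inverted_measure_still_classified_correctly(self):
        seqs = ["unimanual"] * 4 + ["synchronous"] * 4
        tab = toy_table([3.0] * 4 + [1.0] * 4, sequences=seqs)   # bimanual lower
        res = b.threshold_classify(tab, "y", direction="auto")
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        fixed = b.threshold_classify(tab, "y")   # a-priori side is wrong here
        assert fixed.sensitivity == 0.0

    def test_one_class_missing_rejected(self):
        tab = toy_table([1.0] * 8, sequences=["synchronous"] * 8)
        with pytest.raises(ValueError, match="both classes"):
            b.threshold_classify(tab, "y")

    def test_gaussian_separation_matches_closed_form(self):
        # equal-SD Gaussians Delta apart: sens ~ spec ~ Phi(Delta / 2 sigma)
        delta, sigma, n_rep = 1.0, 0.5, 300
        rng = np.random.default_rng(12)
        accs = []
        for _ in range(n_rep):
            x = np.r_[rng.normal(0, sigma, 64), rng.normal(delta, sigma, 64)]
            tab = toy_table(x, sequences=["unimanual"] * 64 + ["alternating"] * 64)
            res = b.threshold_classify(tab, "y")
            accs.append((res.sensitivity, res.specificity))
        mean_sens, mean_spec = np.mean(accs, axis=0)
        expected = norm.cdf(delta / (2 * sigma)) * 100
        assert mean_sens == pytest.approx(expected, abs=2.0)
        assert mean_spec == pytest.approx(expected, abs=2.0)

    def test_classification_on_simulated_session_above_chance(self, measure_table):
        table, _ = measure_table
        res = b.threshold_classify(table, "left_M1-right_M1__full_task__z")
        assert res.balanced_accuracy > 75.0
        assert res.p < 0.001
        assert res.n_positive == 96 and res.n_negative == 32


class TestCriterionValidity:
    def test_perfectly_linear_measure(self):
        tab = toy_table(np.arange(8.0) * 2.0)
        tab["actual_speed_hz"] = np.arange(8.0)
        res = b.criterion_validity(tab, "y")
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        tab = toy_table(rng.normal(0, 1, 40))
        tab["actual_speed_hz"] = tab["y"] * 0.5 + rng.normal(0, 1, 40)
        r1 = b.criterion_validity(tab, "y").r
        tab["y"] = tab["y"] * 7.0 - 3.0
        r2 = b.criterion_validity(tab, "y").r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_speed_variance_gives_missing(self):
        tab = toy_table(np.arange(8.0))
        tab["actual_speed_hz"] = 2.0
        res = b.criterion_validity(tab, "y")
        assert np.isnan(res.r) and np.isnan(res.p)

    def test_speed_coupled_condition_ranks_higher_over_seeds(self):
        # coupling increases with speed during unbalanced only; validity r must
        # rank unbalanced above the flat-coupling synchronous condition
        from conftest import PAIR
        cfg0 = b.SimulationConfig()
        lam = {}
        for c in cfg0.conditions:
            seq, v = c.rsplit("_", 1)
            speed = float(v[:-2])
            lam[c] = 0.2 + (0.15 * (speed - 1) if seq == "unbalanced" else 0.2)
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = b.SimulationConfig(seed=100 + seed)
            truth = quiet_truth(coupling=lam, noise_sd=0.4,
                                error_prob={s: 0.0 for s in b.simulate.SEQUENCES})
            design = b.generate_design(cfg)
            log = b.generate_tapping_log(design, truth, seed=cfg.seed)
            tcs = b.generate_roi_timecourses(design, truth, seed=cfg.seed)
            beh = b.score_log(log, design)
            tab = b.build_block_measure_table(tcs, design, pairs=[PAIR], behavior=beh)
            col = "left_M1-right_M1__steady_state__z"
            r_unb = b.criterion_validity(tab, col, ["unbalanced"]).r
            r_syn = b.criterion_validity(tab, col, ["synchronous"]).r
            wins += r_unb > r_syn
        assert wins == n_seeds

    def test_validity_by_sequence_layout(self, measure_table):
        table, _ = measure_table
        out = b.validity_by_sequence(table, "left_M1__psc")
        assert set(out.sequence) == {"synchronous", "alternating", "unbalanced"}
        assert out.r.between(-1, 1).all()


class TestMeasureComparisonAnova:
    def test_identical_measures_yield_null_interactions(self, measure_table):
        table, _ = measure_table
        tab = table.copy()
        tab["copy1"] = tab["left_M1__psc"]
        tab["copy2"] = tab["left_M1__psc"]
        res = b.measure_comparison_anova(tab, ("copy1", "copy2"))
        assert res.f_measure_speed < 1e-6
        assert res.f_measure_coordination < 1e-6

    def test_opposite_coordination_trends_give_large_interaction(self):
        rng = np.random.default_rng(8)
        seqs = (["unimanual"] * 16 + ["synchronous"] * 16
                + ["alternating"] * 16 + ["unbalanced"] * 16)
        coord = np.repeat([1, 2, 3, 4], 16).astype(float)
        tab = toy_table(coord + rng.normal(0, 0.3, 64), sequences=seqs,
                        speeds=list(np.tile([1, 2, 3, 4], 16)))
        tab["up"] = tab["y"]
        tab["down"] = -coord + rng.normal(0, 0.3, 64)
        res = b.measure_comparison_anova(tab, ("up", "down"))
        assert res.f_measure_coordination > 50
        assert res.p_measure_coordination < 1e-10

    def test_dissociation_detected_on_simulated_session(self, measure_table):
        # activation is speed-driven, connectivity coordination-driven
        table, _ = measure_table
        res = b.measure_comparison_anova(
            table, ("left_M1__psc", "left_M1-right_M1__steady_state__z"))
        assert res.p_measure_coordination < 0.05
        assert (res.cell_counts.n > 0).all()


class TestStatsReport:
    def test_tidy_output_and_report(self, measure_table):
        table, _ = measure_table
        tidy, report = b.stats_report(table, alpha=0.05)
        assert {"scope", "measure", "dimension", "term", "F", "p"} <= set(tidy.columns)
        assert (tidy.p.dropna() <= 1).all() and (tidy.p.dropna() >= 0).all()
        assert "Block-measure statistics" in report
        tidy_b, _ = b.stats_report(table, bonferroni=True)
        assert (tidy_b.p_adj >= tidy_b.p - 1e-15).all()
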