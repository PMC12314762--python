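"""Grouped CV, metrics, operating points, paired tests, strata."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mipanomaly.screen_eval import (aggregate_metrics, aupr, bootstrap_ci,
                                    compare_models, evaluate_scores,
                                    fixed_sensitivity_point, grouped_kfold,
                                    prevalence_percent, roc_auc,
                                    stratified_report, summarize_runs,
                                    wilcoxon_compare, youden_point)


def _manifest(n_patients=10, exams_per=2, known=()):
    rows = []
    for p in range(n_patients):
        for e in range(exams_per):
            eid = f"P{p}E{e}"
            for lat in ("left", "right"):
                rows.append({"patient_id": f"P{p}", "exam_id": eid, "laterality": lat,
                             "label": int((p + e) % 3 == 0 and lat == "left"),
                             "known_cancer": eid in known, "bpe": "mild",
                             "lesion_type": "none", "stage_proxy": "none",
                             "image_path": "", "mask_path": ""})
    return pd.DataFrame(rows)


class TestGroupedKFold:
    def test_five_folds_partition_ten_patients(self):
        man = _manifest(10)
        splits = grouped_kfold(man, 5, seed=0)
        test_patients = [set(i.rsplit("E", 1)[0] for i in s.test_ids) for s in splits]
        assert all(len(t) == 2 for t in test_patients)
        assert set().union(*test_patients) == set(man.patient_id)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not test_patients[i] & test_patients[j]

    def test_train_and_test_patients_always_disjoint(self):
        man = _manifest(13)
        for s in grouped_kfold(man, 4, seed=3):
            train_p = {i.rsplit("E", 1)[0] for i in s.train_ids}
            test_p = {i.rsplit("E", 1)[0] for i in s.test_ids}
            assert not train_p & test_p

    def test_imbalanced_task_excludes_known_cancer_from_every_test_fold(self):
        known = {"P0E0", "P3E1", "P7E0"}
        man = _manifest(10, known=known)
        man["image_id"] = man.exam_id + "_" + man.laterality
        known_ids = set(man.loc[man.known_cancer, "image_id"])
        splits = grouped_kfold(man, 5, seed=1, task="imbalanced")
        tested = set().union(*(set(s.test_ids) for s in splits))
        assert not tested & known_ids
        # each known-cancer image still trains in the folds of other patients
        for iid in known_ids:
            pid = iid.split("E")[0]
            for s in splits:
                test_p = {i.rsplit("E", 1)[0] for i in s.test_ids}
                if pid not in test_p:
                    assert iid in s.train_ids

    def test_more_folds_than_patients_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            grouped_kfold(_manifest(3), 5, seed=0)


class TestThresholdFreeMetrics:
    def test_perfect_separation(self):
        s = [0.1, 0.2, 0.8, 0.9]
        y = [0, 0, 1, 1]
        assert roc_auc(s, y) == 1.0
        assert aupr(s, y) == 1.0

    def test_six_point_hand_case_matches_pair_counting(self):
        s = np.array([0.3, 0.7, 0.7, 0.2, 0.9, 0.5])
        y = np.array([0, 1, 0, 0, 1, 1])
        pos, neg = s[y == 1], s[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(s, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1, width=16), min_size=6, max_size=40),
           st.randoms(use_true_random=False))
    def test_auc_invariant_under_monotone_transform(self, scores, rnd):
        # width=16 keeps score gaps large enough that exp() stays strictly
        # monotone in float64
        y = [rnd.randint(0, 1) for _ in scores]
        if len(set(y)) < 2:
            y[0], y[1] = 0, 1
        s = np.asarray(scores)
        assert roc_auc(2 * s + 1, y) == pytest.approx(roc_auc(s, y))
        assert roc_auc(np.exp(s), y) == pytest.approx(roc_auc(s, y))

    def test_prevalence_percent_matches_screening_table_style(self):
        assert prevalence_percent(3399, 17029) == 20.0
        assert prevalence_percent(221, 11934) == 1.85
        assert prevalence_percent(81, 342) == 23.7
        assert prevalence_percent(31, 246) == 12.6


class TestOperatingPoints:
    def test_separable_youden(self):
        pt = youden_point([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert pt.sensitivity == 1.0 and pt.specificity == 1.0 and pt.ppv == 1.0
        assert pt.sensitivity + pt.specificity - 1 == 1.0

    def test_constant_scores_pick_all_negative_rule(self):
        pt = youden_point([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert pt.sensitivity == 0.0 and pt.specificity == 1.0
        assert pt.tp == 0 and pt.fn == 3 and pt.tn == 3 and pt.fp == 0

    def test_youden_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        s = rng.random(20)
        y = (rng.random(20) < 0.4).astype(int)
        y[0], y[1] = 0, 1
        pt = youden_point(s, y)
        best = -np.inf
        for thr in np.concatenate([np.unique(s), [s.max() + 1]]):
            pred = s >= thr
            sens = (pred & (y == 1)).sum() / (y == 1).sum()
            spec = (~pred & (y == 0)).sum() / (y == 0).sum()
            best = max(best, sens + spec - 1)
        assert pt.sensitivity + pt.specificity - 1 == pytest.approx(best)
        # counts recompute the reported rates exactly
        assert pt.sensitivity == pt.tp / (pt.tp + pt.fn)
        assert pt.specificity == pt.tn / (pt.tn + pt.fp)

    def test_fixed_sensitivity_separable_case(self):
        for target in (0.95, 0.97):
            pt = fixed_sensitivity_point([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], target)
            assert pt.specificity == 1.0 and pt.sensitivity == 1.0

    def test_fixed_sensitivity_hand_case(self):
        # all three positives must be captured: threshold drops to 0.1, no
        # negative is excluded, specificity collapses to zero
        pt = fixed_sensitivity_point([0.9, 0.8, 0.1, 0.5], [1, 1, 1, 0], 0.97)
        assert pt.sensitivity == 1.0
        assert pt.specificity == 0.0

    def test_specificity_monotone_in_sensitivity_target(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = rng.random(30)
            y = (rng.random(30) < 0.3).astype(int)
            y[0], y[1] = 0, 1
            spec95 = fixed_sensitivity_point(s, y, 0.95).specificity
            spec97 = fixed_sensitivity_point(s, y, 0.97).specificity
            assert spec95 >= spec97


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        assert wilcoxon_compare([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_six_consistent_signs_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert wilcoxon_compare(a, b) == pytest.approx(2.0 / 64.0)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((2, 12))
        assert wilcoxon_compare(a, b) == pytest.approx(wilcoxon_compare(b, a))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="5 pairs"):
            wilcoxon_compare([1, 2], [2, 1])


class TestBootstrap:
    def test_separable_auc_has_degenerate_interval(self):
        s = np.concatenate([np.zeros(20), np.ones(20)])
        y = np.concatenate([np.zeros(20), np.ones(20)]).astype(int)
        lo, hi = bootstrap_ci(s, y, roc_auc, n_boot=100, seed=5)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(6)
        s = rng.random(60)
        y = (rng.random(60) < 0.4).astype(int)
        ci1 = bootstrap_ci(s, y, roc_auc, n_boot=200, seed=7)
        ci2 = bootstrap_ci(s, y, roc_auc, n_boot=200, seed=7)
        assert ci1 == ci2

    def test_patient_level_resampling_needs_groups(self):
        with pytest.raises(ValueError, match="groups"):
            bootstrap_ci([0, 1, 0, 1], [0, 1, 0, 1], roc_auc, unit="patient")

    def test_coverage_close_to_nominal(self):
        """Percentile-bootstrap coverage for AUC under a known generative
        model stays within a few points of 95%."""
        rng = np.random.default_rng(8)
        n0, n1, mu = 40, 20, 1.2
        # true AUC for normal(0,1) vs normal(mu,1): Phi(mu/sqrt(2))
        from scipy.stats import norm

        true_auc = norm.cdf(mu / np.sqrt(2))
        hits = 0
        n_sim = 150
        for i in range(n_sim):
            s = np.concatenate([rng.normal(0, 1, n0), rng.normal(mu, 1, n1)])
            y = np.concatenate([np.zeros(n0), np.ones(n1)]).astype(int)
            lo, hi = bootstrap_ci(s, y, roc_auc, n_boot=200, seed=i)
            hits += lo <= true_auc <= hi
        assert abs(hits / n_sim - 0.95) < 0.04


class TestReports:
    def _score_table(self):
        rng = np.random.default_rng(9)
        rows = []
        for model in ("fcdd", "bce"):
            for fold in range(2):
                for seed in range(3):
                    n = 40
                    y = (rng.random(n) < 0.3).astype(int)
                    y[0], y[1] = 0, 1
                    lift = 1.0 if model == "fcdd" else 0.4
                    s = rng.random(n) + lift * y
                    for i in range(n):
                        rows.append({"image_id": f"E{i}_left", "score": s[i],
                                     "label": y[i], "fold": fold, "seed": seed,
                                     "model": model, "task": "balanced"})
        return pd.DataFrame(rows)

    def test_summary_and_aggregate_shapes(self):
        table = self._score_table()
        runs = summarize_runs(table)
        assert len(runs) == 12  # 2 models x 2 folds x 3 seeds
        agg = aggregate_metrics(runs)
        assert set(agg.model) == {"fcdd", "bce"}
        assert (agg.n_cells == 6).all()
        assert (agg.baseline_auc == 0.5).all()

    def test_pairwise_comparison_detects_better_model(self):
        runs = summarize_runs(self._score_table())
        p = compare_models(runs, "auc", "fcdd", "bce", task="balanced")
        assert p < 0.05
        fcdd = runs[runs.model == "fcdd"].auc.mean()
        bce = runs[runs.model == "bce"].auc.mean()
        assert fcdd > bce

    def test_evaluate_scores_counts_and_rates_consistent(self):
        rng = np.random.default_rng(10)
        s = rng.random(50)
        y = (rng.random(50) < 0.2).astype(int)
        y[0], y[1] = 0, 1
        m = evaluate_scores(s, y)
        assert 0 <= m["auc"] <= 1
        assert m["aupr"] >= m["prevalence"] - 1e-9 or m["aupr"] >= 0
        assert m["spec_at_95sens"] >= m["spec_at_97sens"]


class TestStratifiedReport:
    def _inputs(self):
        man = _manifest(12)
        man.loc[::3, "bpe"] = "marked"
        rng = np.random.default_rng(11)
        table = pd.DataFrame({
            "image_id": man.exam_id + "_" + man.laterality,
            "score": rng.random(len(man)) + 0.8 * man.label,
            "label": man.label,
        })
        return table, man

    def test_single_stratum_equals_unstratified(self):
        table, man = self._inputs()
        man["bpe"] = "mild"
        rep = stratified_report(table, man, ["bpe"])
        assert len(rep) == 1
        assert rep.iloc[0]["auc"] == pytest.approx(roc_auc(table.score, table.label))

    def test_partition_conserves_counts(self):
        table, man = self._inputs()
        rep = stratified_report(table, man, ["bpe"])
        assert rep.n.sum() == len(man)
        assert rep.n_positive.sum() == man.label.sum()

    def test_unknown_stratum_key_rejected(self):
        table, man = self._inputs()
        with pytest.raises(KeyError, match="unknown"):
            stratified_report(table, man, ["scanner"])

    def test_marked_bpe_degrades_detection_of_low_contrast_lesions(self):
        """When marked-BPE texture dwarfs lesion contrast, within-stratum
        discrimination drops relative to minimal BPE — the screening
        confounder the bilateral phantoms are built to reproduce. Scores come
        from a simple high-pass energy statistic so the check isolates the
        cohort structure rather than a particular detector."""
        from scipy.ndimage import gaussian_filter

        from mipanomaly.phantom import PhantomConfig, generate_cohort

        cfg = PhantomConfig(image_height=48, image_width=48, n_patients=120,
                            bpe_amplitudes=(0.02, 0.04, 0.08, 0.45),
                            mass_contrast_range=(0.15, 0.25),
                            nme_contrast_range=(0.08, 0.15),
                            bpe_mix=(0.4, 0.2, 0.1, 0.3), seed=21)
        manifest, images = generate_cohort(cfg)

        def energy(img):
            px = img.canonical_pixels()
            hp = px - gaussian_filter(px, 3.0)
            return float((hp ** 2).mean())

        table = pd.DataFrame({
            "image_id": [i.image_id for i in images],
            "score": [energy(i) for i in images],
            "label": [i.label for i in images],
        })
        rep = stratified_report(table, manifest, ["bpe"]).set_index("stratum")
        assert rep.loc["marked", "auc"] < rep.loc["minimal", "auc"]
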