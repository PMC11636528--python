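"""CV splitting, voting, permutation machinery, importance, group table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clozanet.evalstats import (ImportanceRecord, RunRecord, RunSet,
                                VotedResult, _child_seeds,
                                aggregate_importance, compare_analyses,
                                confusion_metrics, draw_cv_split,
                                mean_accuracy_with_ci, permutation_pvalue,
                                prepare_inputs, run_pairwise_cv,
                                univariate_table, vote_labels)
from clozanet.models import TrainConfig
from clozanet.syncohort import ClinicalTable


def _runset(accs, preds=None):
    """RunSet with given accuracies on a 4-subject cohort [1,1,0,0]."""
    records = []
    for i, a in enumerate(accs):
        pp, pn = (1, 0) if a == 100 else ((1, 1) if a == 50 else (0, 1))
        if preds is not None:
            pp, pn = preds[i]
        records.append(RunRecord(run=i, test_pos=i % 2, test_neg=2 + i % 2,
                                 omitted=np.empty(0, int), pred_pos=pp,
                                 pred_neg=pn, accuracy=a))
    return RunSet(records=records, model="nn", selection=("clinical",),
                  seed=0)


class TestSplit:
    def test_imbalanced_cohort_balances_training(self):
        labels = np.array([1] * 7 + [0] * 31)
        test, train, omitted = draw_cv_split(labels, 0)
        assert labels[test[0]] == 1 and labels[test[1]] == 0
        assert (labels[train] == 1).sum() == 6
        assert (labels[train] == 0).sum() == 6
        assert omitted.size == 24
        assert not np.intersect1d(test, train).size
        assert not np.intersect1d(train, omitted).size

    def test_balanced_cohort_omits_none(self):
        labels = np.array([1] * 5 + [0] * 5)
        _, train, omitted = draw_cv_split(labels, 1)
        assert (labels[train] == 1).sum() == 4
        assert (labels[train] == 0).sum() == 4
        assert omitted.size == 0

    def test_same_seed_same_split(self):
        labels = np.array([1] * 7 + [0] * 31)
        a = draw_cv_split(labels, 42)
        b = draw_cv_split(labels, 42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_too_few_per_class_rejected(self):
        with pytest.raises(ValueError, match="two subjects"):
            draw_cv_split(np.array([1, 0, 0, 0]), 0)


class TestRunCV:
    def test_accuracies_take_three_values_and_reproduce(self, planted_bundle):
        inputs = prepare_inputs(planted_bundle, ("clinical",))
        cfg = TrainConfig(iterations=100)
        a = run_pairwise_cv(inputs, n_runs=6, train_cfg=cfg, seed=5)
        b = run_pairwise_cv(inputs, n_runs=6, train_cfg=cfg, seed=5)
        assert set(a.accuracies) <= {0.0, 50.0, 100.0}
        assert [r.accuracy for r in a.records] == \
            [r.accuracy for r in b.records]
        assert [r.test_pos for r in a.records] == \
            [r.test_pos for r in b.records]

    def test_svm_backend_runs(self, planted_bundle):
        inputs = prepare_inputs(planted_bundle, ("clinical",))
        rs = run_pairwise_cv(inputs, model="svm", n_runs=4, seed=1)
        assert rs.n_runs == 4 and set(rs.accuracies) <= {0.0, 50.0, 100.0}

    def test_test_subject_features_never_leak_into_training(
            self, planted_bundle):
        """Perturbing one subject's clinical values changes nothing in runs
        where that subject is neither trained nor tested."""
        inputs = prepare_inputs(planted_bundle, ("clinical",))
        cfg = TrainConfig(iterations=100)
        base = run_pairwise_cv(inputs, n_runs=4, train_cfg=cfg, seed=9)

        # find a subject untouched by some run's training set and test pair
        target = run_idx = None
        split_seeds = _child_seeds(9, 4, 0)
        for i, rec in enumerate(base.records):
            labels = planted_bundle.labels
            test, train, _ = draw_cv_split(labels, int(split_seeds[i]))
            touched = set(train) | set(test)
            free = set(range(len(labels))) - touched
            if free:
                run_idx, target = i, free.pop()
                break
        assert target is not None

        mutated = planted_bundle.clinical.data.copy()
        mutated.iloc[target] = 123.0
        inputs2 = prepare_inputs(planted_bundle, ("clinical",))
        inputs2.clinical = ClinicalTable(data=mutated,
                                         kinds=planted_bundle.clinical.kinds,
                                         special=planted_bundle.clinical.special)
        alt = run_pairwise_cv(inputs2, n_runs=4, train_cfg=cfg, seed=9)
        r0, r1 = base.records[run_idx], alt.records[run_idx]
        assert (r0.pred_pos, r0.pred_neg, r0.accuracy) == \
            (r1.pred_pos, r1.pred_neg, r1.accuracy)


class TestMeanCI:
    def test_trivial_mean(self):
        rs = _runset([0, 50, 100, 50])
        mean, lo, hi = mean_accuracy_with_ci(rs, n_boot=200, seed=0)
        assert mean == 50.0

    def test_constant_accuracy_degenerate_ci(self):
        rs = _runset([50] * 8)
        mean, lo, hi = mean_accuracy_with_ci(rs, n_boot=200, seed=0)
        assert (mean, lo, hi) == (50.0, 50.0, 50.0)

    def test_two_point_distribution_brackets_half(self):
        rs = _runset([0, 100] * 100)
        mean, lo, hi = mean_accuracy_with_ci(rs, n_boot=2000, seed=1)
        assert lo < 50 < hi
        assert hi - lo < 30


class TestVoting:
    def test_majority_and_tie_rule(self):
        # subject 0 tested twice, predicted 1 then 0 -> tie -> positive
        rs = _runset([100, 0], preds=[(1, 0), (0, 1)])
        v = vote_labels(rs, np.array([1, 1, 0, 0]))
        assert v.voted[0] == 1

    def test_votes_sum_to_appearances(self, planted_bundle):
        inputs = prepare_inputs(planted_bundle, ("clinical",))
        rs = run_pairwise_cv(inputs, n_runs=8,
                             train_cfg=TrainConfig(iterations=50), seed=2)
        v = vote_labels(rs, planted_bundle.labels)
        assert v.appearances.sum() == 2 * rs.n_runs
        assert (v.votes_pos <= v.appearances).all()
        tested = v.appearances > 0
        assert v.tp + v.fn + v.tn + v.fp == int(tested.sum())

    def test_perfect_runs_give_clean_confusion(self):
        rs = _runset([100] * 10)
        v = vote_labels(rs, np.array([1, 1, 0, 0]))
        assert (v.tp, v.fn, v.tn, v.fp) == (2, 0, 2, 0)

    def test_never_tested_subject_excluded(self):
        rs = _runset([100])  # only subjects 0 and 2 appear
        v = vote_labels(rs, np.array([1, 1, 0, 0]))
        assert v.voted[1] == -1 and v.voted[3] == -1
        assert v.tp + v.fn + v.tn + v.fp == 2


class TestConfusionMetrics:
    def test_study_scale_counts(self):
        """6 of 7 positives and 25 of 31 negatives correct give 81.58 %
        accuracy, 85.71 % sensitivity, 80.65 % specificity, 50 % precision."""
        v = VotedResult(voted=None, votes_pos=None, appearances=None,
                        truth=None, tp=6, fn=1, tn=25, fp=6)
        m = confusion_metrics(v)
        assert m == {"accuracy": 81.58, "sensitivity": 85.71,
                     "specificity": 80.65, "precision": 50.0}

    def test_perfect_classifier(self):
        v = VotedResult(None, None, None, None, tp=4, fn=0, tn=6, fp=0)
        assert all(x == 100.0 for x in confusion_metrics(v).values())

    def test_zero_denominator_reported_as_nan(self):
        v = VotedResult(None, None, None, None, tp=0, fn=4, tn=6, fp=0)
        assert np.isnan(confusion_metrics(v)["precision"])


class TestPermutation:
    def test_floor_and_ceiling(self):
        labels = np.array([1, 1, 0, 0] * 3)
        always_low = lambda lab, s: 0.0
        always_high = lambda lab, s: 100.0
        assert permutation_pvalue(always_low, labels, observed=50.0,
                                  n_perm=1000, seed=0) == \
            pytest.approx(1 / 1001)
        assert permutation_pvalue(always_high, labels, observed=50.0,
                                  n_perm=10, seed=0) == 1.0

    def test_addone_convention_small_case(self):
        labels = np.array([1, 1, 0, 0])
        vals = iter([10.0, 99.0, 10.0])  # exactly one of three >= observed
        p = permutation_pvalue(lambda lab, s: next(vals), labels,
                               observed=50.0, n_perm=3, seed=0)
        assert p == pytest.approx(0.5)

    def test_null_pvalues_roughly_uniform(self):
        """With a statistic independent of the labels, permutation p-values
        over repeated analyses are approximately uniform."""
        labels = np.array([1] * 5 + [0] * 5)
        ps = []
        for seed in range(150):
            rng = np.random.default_rng(seed)
            draws = rng.normal(size=41)

            def analysis(lab, s, draws=draws):
                return draws[1 + (s % 40)]
            ps.append(permutation_pvalue(analysis, labels, draws[0],
                                         n_perm=40, seed=seed))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_compare_identical_runsets_p_one(self):
        rs = _runset([0, 50, 100, 50])
        assert compare_analyses(rs, rs, n_perm=50, seed=0) == 1.0

    def test_compare_disjoint_runsets_hits_floor(self):
        a = _runset([100] * 12)
        b = _runset([0] * 12)
        p = compare_analyses(a, b, n_perm=1000, seed=0)
        assert p == pytest.approx(1 / 1001)
        assert round(p, 6) == 0.000999


class TestImportance:
    def _layout(self, R=5):
        layout = {"clinical": (0, 3)}
        pos = 3
        for mod in ("vbm", "isc"):
            for s in ("min", "max", "mean", "sd"):
                layout[f"{mod}_{s}"] = (pos, pos + R)
                pos += R
        return layout

    def test_single_record_sums_equal_record(self):
        layout = self._layout()
        rel = np.arange(43, dtype=float)
        rep = aggregate_importance(
            [ImportanceRecord(run=0, subject=1, true_class=1, relevance=rel)],
            layout)
        np.testing.assert_array_equal(rep.sums[1], rel)
        np.testing.assert_array_equal(rep.sums[0], 0.0)

    def test_eight_importance_values_per_region(self):
        layout = self._layout(R=5)
        rng = np.random.default_rng(0)
        recs = [ImportanceRecord(run=i, subject=i, true_class=i % 2,
                                 relevance=rng.normal(size=43))
                for i in range(6)]
        rep = aggregate_importance(recs, layout)
        region_maps = [n for n in rep.layout if n != "clinical"]
        assert len(region_maps) == 8
        assert len(rep.per_map_mean[1]) == 8

    def test_top10_length_with_12_features(self):
        layout = {"clinical": (0, 12)}
        rel = np.arange(12, dtype=float)
        rep = aggregate_importance(
            [ImportanceRecord(run=0, subject=0, true_class=1, relevance=rel)],
            layout)
        top = rep.top10[1]["clinical"]
        assert len(top) == 10
        assert top[0] == (11, 11.0)  # sorted descending
        assert [v for _, v in top] == sorted(
            [v for _, v in top], reverse=True)

    def test_pooled_regions_union_of_map_top_lists(self):
        layout = self._layout(R=12)
        rel = np.zeros(3 + 8 * 12)
        # make region 12 dominant in isc_mean, region 1 in isc_sd
        layout_isc_mean = layout["isc_mean"]
        rel[layout_isc_mean[0] + 11] = 100.0
        rel[layout["isc_sd"][0] + 0] = 50.0
        rep = aggregate_importance(
            [ImportanceRecord(run=0, subject=0, true_class=1, relevance=rel)],
            layout)
        assert 12 in rep.pooled_regions[1]["isc"]
        assert 1 in rep.pooled_regions[1]["isc"]


class TestImportanceRecovery:
    def test_planted_regions_dominate_relevance_contrast(self):
        """Regions with planted ISC attenuation carry a larger between-class
        relevance contrast than unaffected regions, and that contrast
        shrinks under a label-shuffled baseline."""
        from scipy import stats as sps

        from clozanet.syncohort import CohortConfig, generate_cohort

        cfg = CohortConfig(seed=31, grid_shape=(8, 8, 8), n_timepoints=80,
                           isc_attenuation={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0})
        bundle = generate_cohort(cfg)
        inputs = prepare_inputs(bundle, ("isc",))
        tc = TrainConfig(iterations=2000)

        def contrast(labels, seed):
            rr = run_pairwise_cv(inputs, n_runs=30, train_cfg=tc, seed=seed,
                                 labels=labels, collect_importance=True)
            recs = rr.importance
            n1 = sum(1 for r in recs if r.true_class == 1)
            s1 = sum(r.relevance for r in recs if r.true_class == 1) / n1
            s0 = sum(r.relevance for r in recs
                     if r.true_class == 0) / (len(recs) - n1)
            a, b = rr.layout["isc_mean"]
            return np.abs(s1 - s0)[a:b]

        d_true = contrast(None, 32)
        shuffled = np.random.default_rng(33).permutation(bundle.labels)
        d_null = contrast(shuffled, 34)
        planted = np.zeros(cfg.n_regions, bool)
        planted[:4] = True
        u = sps.mannwhitneyu(d_true[planted], d_true[~planted],
                             alternative="greater")
        assert u.pvalue < 0.05
        assert d_true[planted].mean() > d_null[planted].mean()


class TestUnivariateTable:
    def _clinical(self):
        rng = np.random.default_rng(8)
        n = 40
        data = pd.DataFrame({
            "same": rng.normal(size=n),
            "shifted": rng.normal(size=n),
            "flag": np.r_[np.ones(20), np.zeros(20)],
            "const": np.ones(n),
        }, index=[f"s{i}" for i in range(n)])
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        data.loc[labels == 1, "shifted"] += 3.0
        kinds = {"same": "scalar", "shifted": "scalar", "flag": "binary",
                 "const": "scalar"}
        return ClinicalTable(data=data, kinds=kinds), labels

    def test_statistics_and_bonferroni(self):
        table, labels = self._clinical()
        out = univariate_table(table, labels)
        assert out.loc["same", "p"] > 0.05
        assert out.loc["shifted", "p"] < 1e-4
        # binary flag perfectly aligned with groups: 2x2 chi-square
        expected = stats.chi2_contingency(
            [[20, 0], [0, 20]], correction=False)
        assert out.loc["flag", "statistic"] == pytest.approx(
            expected.statistic)
        assert out.loc["flag", "p"] < 0.01
        assert np.isnan(out.loc["const", "p"])
        obs = out.loc["shifted", "p"]
        assert out.loc["shifted", "p_bonferroni"] == pytest.approx(
            min(1.0, obs * len(out)))

    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        data = pd.DataFrame({"v": np.r_[x, x]},
                            index=[f"s{i}" for i in range(20)])
        table = ClinicalTable(data=data, kinds={"v": "scalar"})
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        out = univariate_table(table, labels)
        assert out.loc["v", "p"] > 0.9
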