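"""Randomized-pair cross-validation, inference, and importance aggregation.

Evaluation protocol.  Because only seven of 38 subjects are in the positive
class, conventional k-fold CV would be dominated by the majority class.
Instead, each CV run draws one random test subject per class, balances the
training set by randomly omitting majority-class subjects, refits the
clinical preprocessor on the training rows, retrains the model from scratch
and scores the held-out pair — so every run's accuracy is 0, 50 or 100 %.
Repeating this (2000 runs in the full protocol) yields a mean accuracy with
a bootstrap confidence interval, and an ensemble hard vote per subject over
all runs in which it was tested.

Inference is permutation-based throughout: the significance of an accuracy
is the one-sided rank of the observed value among re-analyses under shuffled
labels, and two analyses are compared two-sidedly by shuffling their per-run
accuracies.  Both use the add-one convention p = (1 + k) / (1 + P), whose
floor for P = 1000 is 0.000999.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .features import (FeatureSet, RegionFeatureBlock, apply_clinical_preprocessor,
                       assemble_feature_set, fit_clinical_preprocessor,
                       pool_modality)
from .iscmap import cohort_isc_maps
from .models import (TrainConfig, build_network, lrp_relevance, predict,
                     predict_svm, train_network, train_svm_baseline)
from .syncohort import ClinicalTable, CohortBundle

__all__ = [
    "AnalysisInputs",
    "RunRecord",
    "RunSet",
    "VotedResult",
    "ImportanceRecord",
    "ImportanceReport",
    "prepare_inputs",
    "draw_cv_split",
    "run_pairwise_cv",
    "mean_accuracy_with_ci",
    "vote_labels",
    "confusion_metrics",
    "permutation_pvalue",
    "accuracy_permutation_test",
    "compare_analyses",
    "aggregate_importance",
    "univariate_table",
]

logger = logging.getLogger(__name__)


def _child_seeds(seed: int, n: int, *tag: int) -> np.ndarray:
    """n reproducible child seeds (< 2^31) derived from one master seed."""
    ss = np.random.SeedSequence([int(seed), *tag])
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31 - 1)


@dataclass
class AnalysisInputs:
    """Everything one analysis needs, before any train/test split.

    The imaging blocks are pooled once up front — ISC maps are computed
    against the independent reference group and pooling is per-subject
    arithmetic, so neither depends on other subjects of the cohort.  The raw
    clinical table is kept so each CV run can refit its preprocessor on that
    run's training rows only.
    """

    selection: tuple[str, ...]
    labels: np.ndarray
    subject_ids: list[str]
    clinical: ClinicalTable | None = None
    vbm_blocks: list[RegionFeatureBlock] | None = None
    isc_blocks: list[RegionFeatureBlock] | None = None


def prepare_inputs(bundle: CohortBundle, selection) -> AnalysisInputs:
    """Compute ISC maps and pooled imaging blocks for a cohort."""
    selection = tuple(selection)
    vbm_blocks = isc_blocks = None
    atlas = bundle.volumes.atlas
    if "vbm" in selection:
        vbm_blocks = pool_modality(bundle.volumes.vbm, atlas, "vbm")
    if "isc" in selection:
        maps = cohort_isc_maps(bundle.volumes.subject_ts,
                               bundle.volumes.reference_ts,
                               grid_shape=atlas.shape)
        isc_blocks = pool_modality(maps, atlas, "isc")
    return AnalysisInputs(
        selection=selection, labels=np.asarray(bundle.labels, int),
        subject_ids=bundle.subject_ids,
        clinical=bundle.clinical if "clinical" in selection else None,
        vbm_blocks=vbm_blocks, isc_blocks=isc_blocks)


def draw_cv_split(labels, seed) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One randomized-pair split: (test pair indices, balanced training
    indices, omitted majority indices).

    The test pair is one random subject per class; the training set is every
    remaining minority-class subject plus an equal-size random subset of the
    majority class.
    """
    labels = np.asarray(labels, int)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least two subjects per class")
    test = np.array([rng.choice(pos), rng.choice(neg)])
    rest_pos = pos[pos != test[0]]
    rest_neg = neg[neg != test[1]]
    minority, majority = sorted((rest_pos, rest_neg), key=len)
    kept = rng.choice(majority, size=len(minority), replace=False)
    train = np.sort(np.concatenate([minority, kept]))
    omitted = np.setdiff1d(majority, kept)
    return test, train, omitted


@dataclass
class RunRecord:
    run: int
    test_pos: int          # subject index of the positive test subject
    test_neg: int
    omitted: np.ndarray
    pred_pos: int
    pred_neg: int
    accuracy: float        # 0, 50 or 100


@dataclass
class ImportanceRecord:
    run: int
    subject: int
    true_class: int
    relevance: np.ndarray  # per-feature, toward the true class


@dataclass
class RunSet:
    records: list[RunRecord]
    model: str
    selection: tuple[str, ...]
    seed: int
    layout: dict[str, tuple[int, int]] | None = None
    importance: list[ImportanceRecord] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.records)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.records])


def _subset_table(table: ClinicalTable, idx) -> ClinicalTable:
    return ClinicalTable(data=table.data.iloc[idx], kinds=table.kinds,
                         special=table.special)


def _build_features(inputs: AnalysisInputs, labels, train, test) -> tuple:
    """Leakage-safe per-run features: preprocessor fitted on training rows."""
    clin = None
    if inputs.clinical is not None:
        model = fit_clinical_preprocessor(_subset_table(inputs.clinical, train))
        clin = apply_clinical_preprocessor(model, inputs.clinical)
    fs = assemble_feature_set(
        inputs.selection, inputs.subject_ids, labels,
        clinical=clin, vbm_blocks=inputs.vbm_blocks,
        isc_blocks=inputs.isc_blocks)
    return fs


def run_pairwise_cv(inputs: AnalysisInputs,
                    model: str = "nn",
                    n_runs: int = 2000,
                    train_cfg: TrainConfig = TrainConfig(),
                    seed: int = 0,
                    labels: np.ndarray | None = None,
                    collect_importance: bool = False) -> RunSet:
    """The full randomized-pair CV: retrain ``model`` on every balanced
    split and score the held-out pair.

    ``labels`` overrides the cohort labels (used by permutation analyses).
    With ``collect_importance`` every run also records the LRP relevance of
    both test subjects toward their true class.
    """
    if model not in ("nn", "svm"):
        raise ValueError(f"unknown model {model!r}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    labels = np.asarray(inputs.labels if labels is None else labels, int)
    split_seeds = _child_seeds(seed, n_runs, 0)
    train_seeds = _child_seeds(seed, n_runs, 1)

    records: list[RunRecord] = []
    importance: list[ImportanceRecord] = []
    layout = None
    for run in range(n_runs):
        test, train, omitted = draw_cv_split(labels, int(split_seeds[run]))
        fs = _build_features(inputs, labels, train, test)
        layout = fs.layout
        Xtr, ytr = fs.X[train], labels[train]
        Xte = fs.X[test]
        if model == "nn":
            spec = build_network(fs.layout)
            cfg = replace(train_cfg, seed=int(train_seeds[run]),
                          batch_size=min(train_cfg.batch_size, len(train)))
            w = train_network(spec, Xtr, ytr, cfg)
            pred, _ = predict(w, Xte)
        else:
            svm = train_svm_baseline(Xtr, ytr)
            pred = predict_svm(svm, Xte)
        acc = 50.0 * (int(pred[0] == 1) + int(pred[1] == 0))
        records.append(RunRecord(run=run, test_pos=int(test[0]),
                                 test_neg=int(test[1]), omitted=omitted,
                                 pred_pos=int(pred[0]), pred_neg=int(pred[1]),
                                 accuracy=acc))
        if collect_importance and model == "nn":
            for subj, cls in ((test[0], 1), (test[1], 0)):
                importance.append(ImportanceRecord(
                    run=run, subject=int(subj), true_class=cls,
                    relevance=lrp_relevance(w, fs.X[subj], target_class=cls)))
    return RunSet(records=records, model=model, selection=inputs.selection,
                  seed=seed, layout=layout, importance=importance)


def mean_accuracy_with_ci(runs: RunSet, n_boot: int = 10_000,
                          seed: int = 0) -> tuple[float, float, float]:
    """Mean per-run accuracy (%) with a 95 % percentile bootstrap CI over runs."""
    acc = runs.accuracies
    if acc.size == 0:
        raise ValueError("empty RunSet")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, acc.size, size=(n_boot, acc.size))
    boots = acc[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(acc.mean()), float(lo), float(hi)


@dataclass
class VotedResult:
    """Ensemble hard vote per subject with confusion counts vs truth."""

    voted: np.ndarray        # -1 where a subject was never tested
    votes_pos: np.ndarray
    appearances: np.ndarray
    truth: np.ndarray
    tp: int
    fn: int
    tn: int
    fp: int


def vote_labels(runs: RunSet, truth) -> VotedResult:
    """Majority class per subject over the runs in which it was tested.

    Ties go to the positive class: missing a treatment-resistant patient is
    the costlier error.  Subjects never tested (possible at very small
    n_runs) are excluded from the confusion counts with a warning.
    """
    truth = np.asarray(truth, int)
    n = truth.shape[0]
    votes_pos = np.zeros(n, dtype=int)
    appearances = np.zeros(n, dtype=int)
    for r in runs.records:
        appearances[r.test_pos] += 1
        votes_pos[r.test_pos] += r.pred_pos
        appearances[r.test_neg] += 1
        votes_pos[r.test_neg] += r.pred_neg
    voted = np.where(votes_pos * 2 >= appearances, 1, 0)
    never = appearances == 0
    voted[never] = -1
    if never.any():
        logger.warning("%d subject(s) never appeared in a test pair; "
                       "excluded from the voted confusion", int(never.sum()))
    tested = ~never
    tp = int(((voted == 1) & (truth == 1) & tested).sum())
    fn = int(((voted == 0) & (truth == 1) & tested).sum())
    tn = int(((voted == 0) & (truth == 0) & tested).sum())
    fp = int(((voted == 1) & (truth == 0) & tested).sum())
    return VotedResult(voted=voted, votes_pos=votes_pos,
                       appearances=appearances, truth=truth,
                       tp=tp, fn=fn, tn=tn, fp=fp)


def confusion_metrics(v: VotedResult) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and precision in %, rounded to two
    decimals; ratios with a zero denominator are reported as NaN."""
    def ratio(num: int, den: int) -> float:
        return round(100.0 * num / den, 2) if den else float("nan")

    total = v.tp + v.fn + v.tn + v.fp
    if total == 0:
        raise ValueError("confusion counts are all zero")
    return {
        "accuracy": ratio(v.tp + v.tn, total),
        "sensitivity": ratio(v.tp, v.tp + v.fn),
        "specificity": ratio(v.tn, v.tn + v.fp),
        "precision": ratio(v.tp, v.tp + v.fp),
    }


def permutation_pvalue(analysis, labels, observed: float,
                       n_perm: int = 1000, seed: int = 0) -> float:
    """One-sided permutation p-value for an accuracy-like statistic.

    ``analysis(permuted_labels, seed)`` must re-run the full analysis and
    return its statistic.  p = (1 + #{permuted >= observed}) / (1 + P), so
    the smallest attainable value is 1 / (P + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels, int)
    perm_seeds = _child_seeds(seed, n_perm, 7)
    rng = np.random.default_rng(_child_seeds(seed, 1, 8)[0])
    k = 0
    for p in range(n_perm):
        shuffled = rng.permutation(labels)
        if analysis(shuffled, int(perm_seeds[p])) >= observed:
            k += 1
    return (1 + k) / (1 + n_perm)


def accuracy_permutation_test(inputs: AnalysisInputs, observed: float,
                              model: str = "nn",
                              n_perm: int = 1000,
                              runs_per_perm: int = 2000,
                              train_cfg: TrainConfig = TrainConfig(),
                              seed: int = 0) -> float:
    """Significance of a mean CV accuracy by re-running the CV under
    shuffled labels ``n_perm`` times."""
    def analysis(perm_labels, s):
        rs = run_pairwise_cv(inputs, model=model, n_runs=runs_per_perm,
                             train_cfg=train_cfg, seed=s, labels=perm_labels)
        return rs.accuracies.mean()
    return permutation_pvalue(analysis, inputs.labels, observed,
                              n_perm=n_perm, seed=seed)


def compare_analyses(runsA: RunSet, runsB: RunSet,
                     n_perm: int = 1000, seed: int = 0) -> float:
    """Two-sided permutation p for the absolute mean-accuracy difference,
    shuffling per-run accuracies between the two analyses."""
    a, b = runsA.accuracies, runsB.accuracies
    if a.size == 0 or b.size == 0:
        raise ValueError("both RunSets must be nonempty")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:a.size].mean() - perm[a.size:].mean()) >= observed:
            k += 1
    return (1 + k) / (1 + n_perm)


@dataclass
class ImportanceReport:
    """Aggregated LRP importance: per-feature sums toward each true class,
    per-map means over regions, top-10 features per block, and the pooled
    per-modality region lists."""

    layout: dict[str, tuple[int, int]]
    sums: dict[int, np.ndarray]
    per_map_mean: dict[int, dict[str, float]]
    top10: dict[int, dict[str, list[tuple[int, float]]]]
    pooled_regions: dict[int, dict[str, list[int]]]


def aggregate_importance(records: list[ImportanceRecord],
                         layout: dict[str, tuple[int, int]],
                         top_k: int = 10) -> ImportanceReport:
    """Sum per-variable relevance over runs toward each subject's true class,
    then derive per-map means, per-block top-k lists (k = 10 in the full
    protocol), and — for each imaging modality — the regions present in any
    of its four maps' top list."""
    if not records:
        raise ValueError("no importance records")
    width = max(b for _, b in layout.values())
    sums = {0: np.zeros(width), 1: np.zeros(width)}
    for rec in records:
        if rec.relevance.shape[0] != width:
            raise ValueError("relevance width does not match layout")
        sums[rec.true_class] += rec.relevance

    per_map_mean: dict[int, dict[str, float]] = {}
    top10: dict[int, dict[str, list[tuple[int, float]]]] = {}
    pooled: dict[int, dict[str, list[int]]] = {}
    for cls in (0, 1):
        per_map_mean[cls] = {}
        top10[cls] = {}
        pooled[cls] = {}
        for name, (a, b) in layout.items():
            block = sums[cls][a:b]
            if name != "clinical":
                per_map_mean[cls][name] = float(block.mean())
            order = np.argsort(block)[::-1][:top_k]
            top10[cls][name] = [(int(i), float(block[i])) for i in order]
        for mod in ("vbm", "isc"):
            maps = [n for n in layout if n.startswith(mod + "_")]
            if maps:
                regions = sorted({i + 1 for m in maps
                                  for i, _ in top10[cls][m]})
                pooled[cls][mod] = regions
    return ImportanceReport(layout=dict(layout), sums=sums,
                            per_map_mean=per_map_mean, top10=top10,
                            pooled_regions=pooled)


def univariate_table(clinical: ClinicalTable, labels) -> pd.DataFrame:
    """Per-variable two-group comparison: Mann-Whitney U for scalar and
    ordinal variables, Pearson chi-square for binary and categorical ones,
    with Bonferroni-adjusted p-values (min(1, p x m) over all m variables).

    Missing values are dropped per variable; constant variables get NaN."""
    labels = np.asarray(labels, int)
    rows = []
    for col, kind in clinical.kinds.items():
        x = clinical.data[col]
        obs = x.notna().to_numpy()
        g0 = x[obs & (labels == 0)].to_numpy(float)
        g1 = x[obs & (labels == 1)].to_numpy(float)
        stat = p = float("nan")
        if g0.size and g1.size and np.unique(np.concatenate([g0, g1])).size > 1:
            if kind in ("scalar", "ordinal"):
                res = stats.mannwhitneyu(g1, g0, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
            else:
                values = np.unique(np.concatenate([g0, g1]))
                table = np.array([[np.sum(g == v) for v in values]
                                  for g in (g0, g1)])
                res = stats.chi2_contingency(table, correction=False)
                stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"variable": col, "kind": kind, "statistic": stat,
                     "p": p})
    df = pd.DataFrame(rows).set_index("variable")
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * len(df))
    return df
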