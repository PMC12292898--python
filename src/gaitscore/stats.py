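"""Subject-wise cross-validation and the statistical toolkit.

The evaluation protocol mirrors the study design: from a 10 HC / 5 PD-1 /
6 PD-2 cohort, each of 21 folds randomly holds out 2 controls, 1 UPDRS-1
and 1 UPDRS-2 subject (every subject must be held out at least twice),
pooling 84 subject-level test predictions.  Head-to-head comparisons use a
paired t-test on the per-fold accuracies and a continuity-corrected McNemar
test on the pooled predictions; group separations of kinematic features are
quantified with Cohen's d and post-hoc power from the noncentral-t
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .core import GaitScoreError, PlanningError, SchemaError
from .fusion import FusionRuleConfig, ablate, fuse
from .heads import (
    HeadConfig,
    default_head_config,
    HeadProbabilities,
    build_balance_head,
    build_diagnosis_head,
    build_evaluation_head,
    occlusion_sensitivity,
    predict_subject,
    train_head,
)


@dataclass(frozen=True)
class CVPlan:
    folds: Tuple[Tuple[Tuple[int, ...], Tuple[int, ...]], ...]
    test_composition: Tuple[int, int, int] = (2, 1, 1)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class MetricsReport:
    overall_accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    confusion_matrix: np.ndarray  # rows = truth
    per_fold_accuracies: Optional[np.ndarray] = None


def make_cv_plan(
    levels: Sequence[int],
    seed: int = 0,
    n_folds: int = 21,
    test_composition: Tuple[int, int, int] = (2, 1, 1),
    min_appearances: int = 2,
    max_retries: int = 500,
) -> CVPlan:
    """Random subject-wise folds with fixed per-group test composition.

    Resamples (bounded retries) until every subject appears in the test set
    at least ``min_appearances`` times.  Deterministic given ``seed``.
    """
    levels = np.asarray(levels, dtype=int)
    groups = [np.flatnonzero(levels == k) for k in range(3)]
    for k, need in enumerate(test_composition):
        if len(groups[k]) < max(need, 1):
            raise PlanningError(
                f"group {k} has {len(groups[k])} subjects, need >= {need}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        folds = []
        for _f in range(n_folds):
            test: List[int] = []
            for k, need in enumerate(test_composition):
                test.extend(rng.choice(groups[k], size=need, replace=False))
            train = tuple(i for i in range(len(levels)) if i not in set(test))
            folds.append((train, tuple(sorted(test))))
        counts = np.zeros(len(levels), dtype=int)
        for _, test in folds:
            counts[list(test)] += 1
        if counts.min() >= min_appearances:
            return CVPlan(folds=tuple(folds), test_composition=test_composition)
    raise PlanningError(
        f"could not satisfy the >= {min_appearances}-appearances constraint "
        f"in {max_retries} attempts")


def compute_metrics(predictions: Sequence[int], labels: Sequence[int],
                    n_classes: int = 3) -> MetricsReport:
    """Overall accuracy, per-class precision/recall, confusion matrix.

    Undefined (0/0) precision or recall is reported as 0.
    """
    y_pred = np.asarray(predictions, dtype=int)
    y_true = np.asarray(labels, dtype=int)
    if y_pred.shape != y_true.shape:
        raise SchemaError("predictions/labels length mismatch")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    tp = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / np.maximum(col, 1), 0.0)
        recall = np.where(row > 0, tp / np.maximum(row, 1), 0.0)
    return MetricsReport(
        overall_accuracy=float(tp.sum() / cm.sum()),
        precision=precision,
        recall=recall,
        confusion_matrix=cm,
    )


def paired_t_folds(acc_a: Sequence[float], acc_b: Sequence[float]
                   ) -> Tuple[float, int, float, float, Tuple[float, float]]:
    """Classical paired t-test on per-fold accuracies.

    Returns ``(t, df, p_two_sided, mean_diff, ci95)`` with df = n − 1.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise SchemaError("need equal-length fold accuracies with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise GaitScoreError("zero-variance differences: paired t undefined")
    n = d.size
    mean = float(d.mean())
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    ci = (mean - tcrit * se, mean + tcrit * se)
    return float(t), int(df), float(p), mean, (float(ci[0]), float(ci[1]))


def mcnemar(a: int, b: int) -> Tuple[float, float]:
    """Continuity-corrected McNemar test on discordant counts.

    ``a``/``b`` are the two discordant-pair counts; the statistic is
    ``(|a − b| − 1)² / (a + b)`` referred to chi-square with 1 df.
    """
    if a < 0 or b < 0:
        raise SchemaError("discordant counts must be nonnegative")
    if a + b == 0:
        raise GaitScoreError("no discordant pairs: McNemar test undefined")
    chi2 = (abs(a - b) - 1) ** 2 / (a + b)
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d with pooled SD, sign = mean(a) − mean(b)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SchemaError("each group needs n >= 2")
    na, nb = a.size, b.size
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s2 == 0:
        if a.mean() == b.mean():
            return 0.0
        raise GaitScoreError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / np.sqrt(s2))


def posthoc_power(d: float, n_a: int, n_b: int, alpha: float = 0.05) -> float:
    """Two-sided two-sample t-test power via the noncentral t distribution."""
    if n_a < 2 or n_b < 2:
        raise SchemaError("each group needs n >= 2")
    df = n_a + n_b - 2
    nc = d * np.sqrt(n_a * n_b / (n_a + n_b))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


@dataclass
class ExperimentReport:
    baseline: MetricsReport
    fusion: MetricsReport
    paired_t: Optional[Tuple[float, int, float, float, Tuple[float, float]]]
    mcnemar_counts: Tuple[int, int]  # (a, b) discordant counts
    mcnemar_stat: Optional[Tuple[float, float]]
    ablation_matrix: np.ndarray
    ablation_table: List[dict]
    occlusion: Dict[str, Tuple[float, float]]  # channel -> (mean drop, sd)
    pooled_probs: List[HeadProbabilities] = field(default_factory=list)
    pooled_labels: List[int] = field(default_factory=list)


def run_experiment(
    subject_features: Sequence[Sequence[Dict[str, np.ndarray]]],
    labels: Sequence[int],
    seed: int = 0,
    head_configs: Optional[Dict[str, HeadConfig]] = None,
    rules: Optional[FusionRuleConfig] = None,
    n_folds: int = 21,
    occlusion_channels: Sequence[str] = ("ta_l", "ta_r", "ga_l", "ga_r"),
) -> ExperimentReport:
    """Full subject-wise CV: train the three heads per fold, score with and
    without fusion, and compile metrics, paired statistics, the 16-way rule
    ablation and per-channel occlusion sensitivity.

    ``subject_features[i]`` holds per-trial dicts with keys ``ftf``, ``etff``
    and ``mf`` for subject ``i``.
    """
    labels = np.asarray(labels, dtype=int)
    plan = make_cv_plan(labels, seed=seed, n_folds=n_folds)
    rules = rules or FusionRuleConfig()
    cfgs = head_configs or {}

    def stacked(idx: Sequence[int], key: str) -> Tuple[np.ndarray, np.ndarray]:
        X, y = [], []
        for i in idx:
            for trial in subject_features[i]:
                X.append(trial[key])
                y.append(labels[i])
        return np.stack(X), np.asarray(y)

    pooled_probs: List[HeadProbabilities] = []
    pooled_labels: List[int] = []
    acc_base, acc_fused = [], []
    base_preds_all, fused_preds_all = [], []
    occ_drops: Dict[str, List[float]] = {c: [] for c in occlusion_channels}

    for k, (train_idx, test_idx) in enumerate(plan.folds):
        fold_seed = seed * 1000 + k
        models = {}
        for head, target, builder in (
            ("diagnosis", lambda lv: (lv > 0).astype(int), build_diagnosis_head),
            ("evaluation", lambda lv: lv, build_evaluation_head),
            ("balance", lambda lv: (lv == 2).astype(int), build_balance_head),
        ):
            cfg = cfgs.get(head, default_head_config(head))
            cfg = HeadConfig(**{**cfg.__dict__, "head": head, "seed": fold_seed})
            key = {"diagnosis": "ftf", "evaluation": "etff", "balance": "mf"}[head]
            X, y_lv = stacked(train_idx, key)
            model = builder(cfg)
            train_head(model, X, target(y_lv), cfg)
            models[head] = model

        fold_base, fold_fused, fold_true = [], [], []
        for i in test_idx:
            probs = predict_subject(models, subject_features[i])
            pooled_probs.append(probs)
            pooled_labels.append(int(labels[i]))
            fold_base.append(int(np.argmax(probs.p_level)))
            fold_fused.append(fuse(probs, rules).level)
            fold_true.append(int(labels[i]))
        base_preds_all.extend(fold_base)
        fused_preds_all.extend(fold_fused)
        acc_base.append(float(np.mean(np.array(fold_base) == fold_true)))
        acc_fused.append(float(np.mean(np.array(fold_fused) == fold_true)))

        Xo, yo = stacked(test_idx, "ftf")
        for ch in occlusion_channels:
            occ_drops[ch].append(
                occlusion_sensitivity(models["diagnosis"], Xo,
                                      (yo > 0).astype(int), ch))

    base_report = compute_metrics(base_preds_all, pooled_labels)
    base_report.per_fold_accuracies = np.asarray(acc_base)
    fused_report = compute_metrics(fused_preds_all, pooled_labels)
    fused_report.per_fold_accuracies = np.asarray(acc_fused)

    try:
        t_result = paired_t_folds(acc_fused, acc_base)
    except GaitScoreError:
        t_result = None
    a = sum(1 for pb, pf, t in zip(base_preds_all, fused_preds_all, pooled_labels)
            if pb == t and pf != t)
    b = sum(1 for pb, pf, t in zip(base_preds_all, fused_preds_all, pooled_labels)
            if pf == t and pb != t)
    try:
        mc = mcnemar(a, b)
    except GaitScoreError:
        mc = None
    matrix, table = ablate(pooled_probs, pooled_labels, base=rules)
    occ = {c: (float(np.mean(v)), float(np.std(v))) for c, v in occ_drops.items()}
    return ExperimentReport(
        baseline=base_report, fusion=fused_report, paired_t=t_result,
        mcnemar_counts=(a, b), mcnemar_stat=mc,
        ablation_matrix=matrix, ablation_table=table, occlusion=occ,
        pooled_probs=pooled_probs, pooled_labels=pooled_labels,
    )
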