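"""End-to-end orchestration: trials → calibration → cycles → features →
heads → fusion → evaluation report."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import events as _events
from .calibration import calibrate_trial
from .core import GaitScoreError, RawTrial
from .emg import build_etff, build_ftf
from .fusion import FusionRuleConfig
from .heads import HeadConfig
from .io import FeatureStore, load_trial, read_manifest, trial_paths
from .kinematics import cycle_kinematics, summarize_mf
from .stats import ExperimentReport, run_experiment
from .synthetic import generate_cohort

log = logging.getLogger("gaitscore")


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        log.info("stage %-12s %.2f s", self.name, time.perf_counter() - self.t0)


def detect_cycles(trial: RawTrial, side: str) -> List[Tuple[int, int, int]]:
    """Heel-strike→heel-strike cycles from the calibrated sagittal gyro."""
    gyro_z = trial.imu(side)[:, 5]
    evs = _events.detect_events(
        gyro_z, trial.config.fs_imu,
        static_windows=(trial.static_pre, trial.static_post), side=side)
    return _events.segment_cycles(evs, trial.config.fs_imu)


def extract_trial_features(trial: RawTrial, seed: int = 0) -> Dict[str, np.ndarray]:
    """FTF, ETFF and MF tensors for one raw trial (calibrates internally)."""
    calibrated, _angles = calibrate_trial(trial)
    cycles = {side: detect_cycles(calibrated, side) for side in ("left", "right")}
    kin = []
    for side in ("left", "right"):
        for cyc in cycles[side]:
            try:
                kin.append(cycle_kinematics(calibrated.imu(side), cyc,
                                            trial.config, side=side))
            except GaitScoreError:
                continue
    mf = summarize_mf(kin, trial.subject.height_m, seed=seed)
    ftf = build_ftf(calibrated, cycles)
    etff = build_etff(calibrated, cycles)
    return {"ftf": ftf.values, "etff": etff.values, "mf": mf,
            "scale_freqs": etff.scale_freqs}


def extract_cohort_features(
    subjects_trials: Sequence[Sequence[RawTrial]],
    seed: int = 0,
    store: Optional[FeatureStore] = None,
) -> List[List[Dict[str, np.ndarray]]]:
    out = []
    for trials in subjects_trials:
        per_subject = []
        for trial in trials:
            feats = extract_trial_features(trial, seed=seed)
            per_subject.append(feats)
            if store is not None:
                for name in ("ftf", "etff", "mf"):
                    store.put(trial.subject.subject_id, trial.trial_id,
                              name, feats[name])
        out.append(per_subject)
    return out


def load_cohort(cohort_dir: str | Path) -> Tuple[List[List[RawTrial]], List[int]]:
    """Read a cohort directory (manifest.csv + trial CSVs)."""
    cohort_dir = Path(cohort_dir)
    manifest = read_manifest(cohort_dir / "manifest.csv")
    subjects, labels = [], []
    for _, row in manifest.iterrows():
        subjects.append([load_trial(p) for p in trial_paths(row, cohort_dir)])
        labels.append(int(row["updrs_level"]))
    return subjects, labels


def run_all(
    out_dir: str | Path,
    seed: int = 0,
    simulate: bool = True,
    cohort_dir: Optional[str | Path] = None,
    n_hc: int = 10,
    n_pd1: int = 5,
    n_pd2: int = 6,
    n_folds: int = 21,
    head_configs: Optional[Dict[str, HeadConfig]] = None,
    rules: Optional[FusionRuleConfig] = None,
) -> ExperimentReport:
    """Simulate (optionally) → extract features → CV experiment → report files.

    Writes metrics, per-fold accuracies, the ablation matrix and occlusion
    table as CSVs plus a JSON summary under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if simulate:
        with _StageTimer("simulate"):
            cohort, _rows = generate_cohort(n_hc=n_hc, n_pd1=n_pd1, n_pd2=n_pd2,
                                            seed=seed)
        subjects = [trials for trials, _ in cohort]
        labels = [truth.subject.updrs_level for _, truth in cohort]
    elif cohort_dir is not None:
        with _StageTimer("load"):
            subjects, labels = load_cohort(cohort_dir)
    else:
        raise GaitScoreError("no cohort: pass simulate=True or cohort_dir")

    with _StageTimer("features"):
        feats = extract_cohort_features(subjects, seed=seed)
    with _StageTimer("experiment"):
        report = run_experiment(feats, labels, seed=seed,
                                head_configs=head_configs, rules=rules,
                                n_folds=n_folds)

    _write_report(report, out_dir)
    return report


def _write_report(report: ExperimentReport, out_dir: Path) -> None:
    rows = []
    for name, rep in (("baseline", report.baseline), ("fusion", report.fusion)):
        rows.append(dict(model=name, overall_accuracy=rep.overall_accuracy,
                         **{f"precision_{k}": rep.precision[k] for k in range(3)},
                         **{f"recall_{k}": rep.recall[k] for k in range(3)}))
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
    pd.DataFrame({
        "fold": np.arange(len(report.baseline.per_fold_accuracies)),
        "baseline": report.baseline.per_fold_accuracies,
        "fusion": report.fusion.per_fold_accuracies,
    }).to_csv(out_dir / "fold_accuracies.csv", index=False)
    pd.DataFrame(report.ablation_matrix,
                 index=["00", "01", "10", "11"],
                 columns=["00", "01", "10", "11"]).to_csv(
        out_dir / "ablation_matrix.csv")
    pd.DataFrame([dict(channel=c, mean_drop=m, sd=s)
                  for c, (m, s) in report.occlusion.items()]).to_csv(
        out_dir / "occlusion.csv", index=False)
    summary = dict(
        baseline_accuracy=report.baseline.overall_accuracy,
        fusion_accuracy=report.fusion.overall_accuracy,
        mcnemar_a=report.mcnemar_counts[0],
        mcnemar_b=report.mcnemar_counts[1],
    )
    if report.paired_t is not None:
        t, df, p, mean_diff, ci = report.paired_t
        summary.update(paired_t=t, paired_t_df=df, paired_t_p=p,
                       mean_diff=mean_diff, ci95_low=ci[0], ci95_high=ci[1])
    if report.mcnemar_stat is not None:
        summary.update(mcnemar_chi2=report.mcnemar_stat[0],
                       mcnemar_p=report.mcnemar_stat[1])
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
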