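"""Subject-level feature assembly, group statistics, and classifier evaluation.

This module turns per-subject recordings into the 16-column feature table
(whole-brain SC and NI in the five canonical bands from resting EEG; N1 and
MMN amplitude/latency plus ESC and ENI from the auditory task), runs
channel-wise Welch t-tests with Benjamini–Hochberg FDR correction, evaluates
feature sets by stratified cross-validated RBF-SVM metrics, and orchestrates
the end-to-end pipeline: synthesis → preprocessing → features → statistics →
the four feature-set evaluations (resting-only, ERP-only, combined, and
MFFS-selected).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .erp import erp_scalar_features, average_erp, mmn_difference, task_sc_ni
from .mffs import FeatureTable, FitnessEvaluator, MFFSConfig, run_mffs
from .montage import REGIONS
from .ndf import compute_sc_ni
from .preprocess import (DEFAULT_BANDS, baseline_and_reject,
                         common_average_reference, butterworth_bandpass,
                         extract_epochs, TASK_BAND, REST_BAND)
from .synth import (Cohort, GroupParams, MCS_DEFAULTS, UWS_DEFAULTS,
                    generate_cohort)

#: Feature-set definitions (columns of the assembled table).
RESTING_FEATURES = tuple(f"{kind}-{b.name}" for kind in ("SC", "NI")
                         for b in DEFAULT_BANDS)
ERP_FEATURES = ("N1-Amplitude", "N1-Latency", "MMN-Amplitude", "MMN-Latency",
                "ESC", "ENI")
COMBINED_FEATURES = RESTING_FEATURES + ERP_FEATURES

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "resting": RESTING_FEATURES,
    "erp": ERP_FEATURES,
    "combined": COMBINED_FEATURES,
}


@dataclass
class ChannelStats:
    """Channel-wise Welch t-test with BH-FDR adjustment."""

    channels: list[str]
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray  # adjusted p < alpha
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "t": self.t,
                             "p_raw": self.p_raw, "p_adj": self.p_adj,
                             "significant": self.significant})


@dataclass
class ClassMetrics:
    """Pooled-fold confusion counts and the derived classification metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    specificity: float
    recall: float
    accuracy: float
    f1: float
    auc: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int,
                    auc: float = float("nan")) -> "ClassMetrics":
        total = tp + fp + tn + fn
        return cls(tp=tp, fp=fp, tn=tn, fn=fn,
                   specificity=tn / (tn + fp) if tn + fp else 0.0,
                   recall=tp / (tp + fn) if tp + fn else 0.0,
                   accuracy=(tp + tn) / total if total else 0.0,
                   f1=2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
                   auc=auc)


def extract_subject_features(rest, task, T_rest: float = 2.0,
                             T_task: float = 1.0) -> dict[str, float]:
    """All 16 subject-level scalar features from preprocessed recordings.

    ``rest`` must be resting-state data (CAR + 0.1–45 Hz), ``task`` the
    auditory run (CAR + 1–30 Hz) with its events. Whole-brain values are
    channel means.
    """
    feats: dict[str, float] = {}
    per_band = compute_sc_ni(rest, bands=DEFAULT_BANDS, T=T_rest)
    for name, bf in per_band.items():
        feats[f"SC-{name}"] = bf.sc.whole_brain
        feats[f"NI-{name}"] = bf.ni.whole_brain
    epochs = baseline_and_reject(extract_epochs(task))
    std = average_erp(epochs, "STD")
    dev = average_erp(epochs, "DEV")
    feats.update(erp_scalar_features(std, mmn_difference(dev, std)))
    esc, eni = task_sc_ni(task, T=T_task)
    feats["ESC"] = esc.whole_brain
    feats["ENI"] = eni.whole_brain
    return feats


def assemble_feature_table(subject_features: list[dict[str, float]],
                           labels: list[str],
                           feature_set: str | tuple[str, ...] = "combined",
                           ) -> FeatureTable:
    """Stack per-subject feature dicts into a labelled table.

    ``feature_set`` is one of ``"resting"``, ``"erp"``, ``"combined"`` or an
    explicit tuple of feature names. Missing features raise with the exact
    gaps listed. Labels map MCS → 1, UWS → 0.
    """
    if not subject_features:
        raise ValueError("empty cohort: no subject features")
    names = FEATURE_SETS[feature_set] if isinstance(feature_set, str) \
        else tuple(feature_set)
    gaps = [(i, n) for i, d in enumerate(subject_features)
            for n in names if n not in d]
    if gaps:
        raise ValueError(f"missing features: {gaps}")
    X = np.array([[d[n] for n in names] for d in subject_features])
    y = np.array([1 if lb == "MCS" else 0 for lb in labels])
    return FeatureTable(X=X, y=y, feature_names=list(names))


def group_ttests(values: np.ndarray, labels: list[str],
                 channels: list[str], alpha: float = 0.05) -> ChannelStats:
    """Welch two-sample t per channel, BH step-up FDR across channels.

    ``values`` is subjects × channels; ``labels`` are the group labels
    (the t statistic is MCS minus UWS).
    """
    y = np.asarray([1 if lb == "MCS" else 0 for lb in labels])
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    a, b = values[y == 1], values[y == 0]
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return ChannelStats(channels=list(channels), t=np.atleast_1d(t),
                        p_raw=np.atleast_1d(p), p_adj=np.atleast_1d(p_adj),
                        significant=np.atleast_1d(reject), alpha=alpha)


def region_summarize(values: np.ndarray, channel_labels: list[str],
                     region_map: dict[str, tuple[str, ...]] | None = None,
                     ) -> pd.DataFrame:
    """Per-subject regional means plus the whole-brain mean.

    Regions must be non-empty within the montage; the whole-brain column is
    the mean over all channels and is independent of the partition.
    """
    if region_map is None:
        region_map = {k: v for k, v in REGIONS.items()}
    df = pd.DataFrame(values, columns=channel_labels)
    out = {}
    for region, chans in region_map.items():
        present = [c for c in chans if c in channel_labels]
        if not present:
            raise ValueError(f"region {region!r} has no channels in montage")
        out[region] = df[present].mean(axis=1)
    out["whole-brain"] = df.mean(axis=1)
    return pd.DataFrame(out)


def crossval_metrics(table: FeatureTable, bits: np.ndarray | None = None,
                     config: MFFSConfig | None = None) -> ClassMetrics:
    """Stratified k-fold RBF-SVM metrics with fold predictions pooled.

    Uses the same fold construction as the MFFS fitness (seeded stratified
    k-fold, per-fold standardization), so a subset found by the search can
    be evaluated on exactly the folds it was optimized on. MCS (label 1) is
    the positive class. AUC is computed from the pooled decision values.
    """
    if config is None:
        config = MFFSConfig()
    if bits is None:
        bits = np.ones(table.n_features, dtype=np.uint8)
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.sum() == 0:
        raise ValueError("empty feature mask")
    cols = np.nonzero(bits)[0]
    X, y = table.X[:, cols], table.y
    evaluator = FitnessEvaluator(table, config)  # reuse its fold layout
    y_pred = np.empty_like(y)
    scores = np.empty(y.size, dtype=float)
    for tr, te in evaluator.folds:
        clf = make_pipeline(StandardScaler(),
                            SVC(C=config.svm_C, kernel="rbf", gamma="scale"))
        clf.fit(X[tr], y[tr])
        y_pred[te] = clf.predict(X[te])
        scores[te] = clf.decision_function(X[te])
    tp = int(((y == 1) & (y_pred == 1)).sum())
    fn = int(((y == 1) & (y_pred == 0)).sum())
    tn = int(((y == 0) & (y_pred == 0)).sum())
    fp = int(((y == 0) & (y_pred == 1)).sum())
    auc = float(roc_auc_score(y, scores))
    return ClassMetrics.from_counts(tp=tp, fp=fp, tn=tn, fn=fn, auc=auc)


@dataclass
class PipelineConfig:
    """End-to-end run settings: cohort scale, paradigm scale, analysis knobs.

    The defaults describe a desk-scale evaluation cohort: 30 subjects per
    group, 40 s of resting data and a 64-stimulus oddball run per subject,
    with the group contrasts of the study conditions.
    """

    n_per_group: int = 30
    rest_duration_s: float = 36.0
    oddball: tuple[int, int, int, float] = (46, 8, 3, 1000.0)
    n_channels: int = 30
    fs: float = 500.0
    T_rest: float = 2.0
    T_task: float = 1.0
    mffs: MFFSConfig | None = None
    mcs: GroupParams | None = None
    uws: GroupParams | None = None


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0,
                 out_path: str | Path | None = None) -> dict:
    """Synthesize a cohort, extract features, and evaluate the feature sets.

    Returns a JSON-serializable report with the group statistics of every
    feature, the four feature-set evaluations (resting-only, ERP-only,
    combined, MFFS-selected) on shared folds, and the MFFS selection.
    """
    if config is None:
        config = PipelineConfig()
    mcs = config.mcs or GroupParams(**{**asdict(MCS_DEFAULTS),
                                       "n_subjects": config.n_per_group})
    uws = config.uws or GroupParams(**{**asdict(UWS_DEFAULTS),
                                       "n_subjects": config.n_per_group})
    cohort: Cohort = generate_cohort(
        mcs, uws, n_channels=config.n_channels, fs=config.fs,
        rest_duration_s=config.rest_duration_s, oddball=config.oddball,
        seed=seed)

    feats: list[dict[str, float]] = []
    for subj in cohort.subjects:
        rest = subj.make_rest()
        rest = butterworth_bandpass(common_average_reference(rest),
                                    REST_BAND.low_hz, REST_BAND.high_hz)
        task = subj.make_task()
        task = butterworth_bandpass(common_average_reference(task),
                                    TASK_BAND.low_hz, TASK_BAND.high_hz)
        feats.append(extract_subject_features(rest, task,
                                              T_rest=config.T_rest,
                                              T_task=config.T_task))
    labels = cohort.labels

    combined = assemble_feature_table(feats, labels, "combined")
    feature_stats = group_ttests(combined.X, labels,
                                 channels=combined.feature_names)

    mffs_cfg = config.mffs or MFFSConfig(
        subpop_size=20, iterations=20, elite_count=2, seed=seed,
        cv_folds=min(5, mcs.n_subjects, uws.n_subjects))
    evaluations: dict[str, dict] = {}
    for set_name in ("resting", "erp", "combined"):
        table = assemble_feature_table(feats, labels, set_name)
        m = crossval_metrics(table, config=mffs_cfg)
        evaluations[set_name] = asdict(m)
    solution = run_mffs(combined, mffs_cfg)
    m_sel = crossval_metrics(combined, bits=solution.bits, config=mffs_cfg)
    evaluations["mffs"] = asdict(m_sel)

    report = {
        "seed": seed,
        "n_subjects": {"MCS": mcs.n_subjects, "UWS": uws.n_subjects},
        "config": {
            "rest_duration_s": config.rest_duration_s,
            "oddball": list(config.oddball),
            "n_channels": config.n_channels, "fs": config.fs,
            "T_rest": config.T_rest, "T_task": config.T_task,
        },
        "feature_stats": feature_stats.to_frame().to_dict(orient="records"),
        "evaluations": evaluations,
        "mffs_selection": {
            "features": solution.feature_names,
            "cv_error": solution.cv_error,
            "cv_accuracy": solution.cv_accuracy,
            "feature_fraction": solution.feature_fraction,
        },
        "features_by_subject": [
            {"group": lb, **{k: float(v) for k, v in d.items()}}
            for lb, d in zip(labels, feats)],
    }
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    return report
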