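"""Leave-one-subject-out evaluation, classifier fusion and metrics.

For each of the N subjects, the six channel classifiers are trained on
the other N-1 subjects' per-cycle feature vectors (with an inner
80/20 train/validation split drawn at the *subject* level, so no
subject contributes cycles to both sides), then applied to the
held-out subject; the mean per-cycle CAD probability is that
subject's per-channel risk.  Fused risks average the six, the three
SCG, and the three GCG channel risks.  Cohort metrics: AUC with
DeLong 95% CI, confusion-matrix metrics at a fixed threshold with
Wilson 95% CIs, F1, and the discrimination slope (mean risk in the
CAD group minus mean risk in the non-CAD group).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cnn import CnnSpec, predict_proba, train_channel
from .config import RunConfig
from .errors import (
    AggregationError,
    ComparisonError,
    FoldError,
    FusionError,
    LeakageError,
    MetricsError,
    TrainingError,
    ValidationError,
)
from .features import extract_features, feature_matrix
from .io import GCG_CHANNELS, SCG_CHANNELS, RawRecording
from .preprocess import preprocess_recording

logger = logging.getLogger("cardiomech")

#: the nine reported models: six single channels plus three fusions
MODEL_NAMES = (
    "all_axes", "scg_axes", "gcg_axes",
    "scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z",
)


@dataclass
class SubjectRisk:
    """Predicted CAD risks for one held-out subject."""

    subject_id: str
    label: str  # "CAD" or "nonCAD"
    channel_risks: Dict[str, float]
    fused: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, p in self.channel_risks.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"risk for {name} outside [0, 1]: {p}")
        if not self.fused:
            self.fused = fuse(self.channel_risks)

    def risk(self, model: str) -> float:
        if model in self.fused:
            return self.fused[model]
        return self.channel_risks[model]


def aggregate_subject(cycle_probs: Sequence[float]) -> float:
    """Subject-level risk: the arithmetic mean of per-cycle probabilities."""
    probs = np.asarray(cycle_probs, dtype=float)
    if probs.size == 0:
        raise AggregationError("no cycle probabilities to aggregate")
    return float(probs.mean())


def fuse(channel_risks: Dict[str, float]) -> Dict[str, float]:
    """Ensemble risks: mean of all six, of the SCG trio, of the GCG trio."""
    for name in SCG_CHANNELS + GCG_CHANNELS:
        if name not in channel_risks:
            raise FusionError(f"missing channel risk: {name}")
    scg = [channel_risks[c] for c in SCG_CHANNELS]
    gcg = [channel_risks[c] for c in GCG_CHANNELS]
    return {
        "all_axes": float(np.mean(scg + gcg)),
        "scg_axes": float(np.mean(scg)),
        "gcg_axes": float(np.mean(gcg)),
    }


# ---------------------------------------------------------------------------
# DeLong AUC machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components (v01, v10) and AUC of one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    return float(auc), v01, v10


def delong_auc_ci(
    scores: Sequence[float], labels: Sequence[int], alpha: float = 0.05
) -> Tuple[float, Tuple[float, float]]:
    """AUC with its DeLong asymptotic confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise MetricsError("AUC undefined with a single class")
    auc, v01, v10 = _delong_components(scores, labels)
    var = (np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0) + (
        np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def delong_paired_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> float:
    """Two-sided p-value for a paired difference of correlated AUCs."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc_a, v01_a, v10_a = _delong_components(scores_a, labels)
    auc_b, v01_b, v10_b = _delong_components(scores_b, labels)
    m, n = v01_a.size, v10_a.size
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s01 / m + s10 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# metrics report
# ---------------------------------------------------------------------------

@dataclass
class ModelMetrics:
    auc: float
    auc_ci: Tuple[float, float]
    f1: float
    sensitivity: float
    sensitivity_ci: Tuple[float, float]
    specificity: float
    specificity_ci: Tuple[float, float]
    ppv: float
    ppv_ci: Tuple[float, float]
    npv: float
    npv_ci: Tuple[float, float]
    discrimination_slope: float
    threshold: float


@dataclass
class MetricsReport:
    models: Dict[str, ModelMetrics]
    n_cad: int
    n_noncad: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in MODEL_NAMES:
            m = self.models[name]
            rows.append(
                {
                    "model": name,
                    "auc": m.auc, "auc_lo": m.auc_ci[0], "auc_hi": m.auc_ci[1],
                    "f1": m.f1,
                    "sensitivity": m.sensitivity,
                    "sensitivity_lo": m.sensitivity_ci[0],
                    "sensitivity_hi": m.sensitivity_ci[1],
                    "specificity": m.specificity,
                    "specificity_lo": m.specificity_ci[0],
                    "specificity_hi": m.specificity_ci[1],
                    "ppv": m.ppv, "ppv_lo": m.ppv_ci[0], "ppv_hi": m.ppv_ci[1],
                    "npv": m.npv, "npv_lo": m.npv_ci[0], "npv_hi": m.npv_ci[1],
                    "discrimination_slope": m.discrimination_slope,
                    "threshold": m.threshold,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_cad": self.n_cad,
            "n_noncad": self.n_noncad,
            "models": {
                name: {
                    "auc": m.auc, "auc_ci": list(m.auc_ci), "f1": m.f1,
                    "sensitivity": m.sensitivity,
                    "sensitivity_ci": list(m.sensitivity_ci),
                    "specificity": m.specificity,
                    "specificity_ci": list(m.specificity_ci),
                    "ppv": m.ppv, "ppv_ci": list(m.ppv_ci),
                    "npv": m.npv, "npv_ci": list(m.npv_ci),
                    "discrimination_slope": m.discrimination_slope,
                    "threshold": m.threshold,
                }
                for name, m in self.models.items()
            },
        }


def _wilson(count: int, nobs: int) -> Tuple[float, float]:
    if nobs == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return (float(lo), float(hi))


def _one_model_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ModelMetrics:
    auc, auc_ci = delong_auc_ci(scores, labels)
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    f1 = (
        2 * ppv * sens / (ppv + sens)
        if np.isfinite(ppv) and np.isfinite(sens) and (ppv + sens) > 0
        else float("nan")
    )
    slope = float(scores[labels == 1].mean() - scores[labels == 0].mean())
    return ModelMetrics(
        auc=auc, auc_ci=auc_ci, f1=f1,
        sensitivity=sens, sensitivity_ci=_wilson(tp, tp + fn),
        specificity=spec, specificity_ci=_wilson(tn, tn + fp),
        ppv=ppv, ppv_ci=_wilson(tp, tp + fp),
        npv=npv, npv_ci=_wilson(tn, tn + fn),
        discrimination_slope=slope, threshold=threshold,
    )


def risks_to_arrays(risks: Sequence[SubjectRisk], model: str):
    scores = np.array([r.risk(model) for r in risks])
    labels = np.array([1 if r.label == "CAD" else 0 for r in risks])
    return scores, labels


def compute_metrics(
    risks: Sequence[SubjectRisk], threshold: float = 0.5
) -> MetricsReport:
    """The full nine-model metrics table for a scored cohort."""
    if not risks:
        raise MetricsError("no subject risks given")
    labels = np.array([1 if r.label == "CAD" else 0 for r in risks])
    if np.unique(labels).size < 2:
        raise MetricsError("metrics require both classes")
    models = {}
    for name in MODEL_NAMES:
        scores, labels = risks_to_arrays(risks, name)
        models[name] = _one_model_metrics(scores, labels, threshold)
    return MetricsReport(
        models=models, n_cad=int(labels.sum()), n_noncad=int((1 - labels).sum())
    )


def compare_models(
    risks: Sequence[SubjectRisk], model_a: str, model_b: str
) -> float:
    """Paired DeLong p-value for the AUC difference of two models."""
    ids_a = [r.subject_id for r in risks]
    if len(set(ids_a)) != len(ids_a):
        raise ComparisonError("duplicate subjects in the risk list")
    scores_a, labels = risks_to_arrays(risks, model_a)
    scores_b, _ = risks_to_arrays(risks, model_b)
    return delong_paired_test(scores_a, scores_b, labels)


# ---------------------------------------------------------------------------
# leave-one-subject-out orchestration
# ---------------------------------------------------------------------------

def _feature_hash(x: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(x, dtype=np.float32).tobytes()).hexdigest()


def subject_features(
    cohort: Sequence[RawRecording], cfg: RunConfig
) -> Dict[str, Dict[str, np.ndarray]]:
    """Preprocess + extract features once per subject: id -> channel -> matrix."""
    out = {}
    for rec in cohort:
        clean = preprocess_recording(rec, cfg)
        feats = extract_features(clean, cfg)
        out[rec.subject_id] = {ch: feature_matrix(v) for ch, v in feats.items()}
    return out


def _inner_split(
    train_ids: List[str], labels: Dict[str, int], fraction: float, rng
) -> Tuple[List[str], List[str]]:
    """Stratified subject-level split of the N-1 training subjects."""
    tr, va = [], []
    for cls in (0, 1):
        ids = sorted(i for i in train_ids if labels[i] == cls)
        ids = [ids[k] for k in rng.permutation(len(ids))]
        n_val = int(round((1 - fraction) * len(ids)))
        if len(ids) - n_val < 1:
            n_val = max(0, len(ids) - 1)
        va.extend(ids[:n_val])
        tr.extend(ids[n_val:])
    if not va:  # degenerate tiny cohorts: validate on the training subjects
        va = list(tr)
    return tr, va


def loso_run(
    cohort: Sequence[RawRecording],
    cfg: RunConfig = None,
    progress: bool = False,
) -> List[SubjectRisk]:
    """Leave-one-subject-out evaluation of the full pipeline.

    Returns one :class:`SubjectRisk` per subject.  Folds whose
    training pool lacks a class are skipped with a warning.  Identical
    recordings under different subject ids are rejected outright, and
    a hash check asserts that no held-out subject's feature vectors
    enter its own fold's training or validation data.
    """
    cfg = cfg or RunConfig()
    labels = {}
    for rec in cohort:
        if rec.label not in ("CAD", "nonCAD"):
            raise TrainingError(f"subject {rec.subject_id} has no usable label")
        if not rec.is_pipeline_eligible():
            raise ValidationError(
                f"recording {rec.subject_id} shorter than the 30 s minimum"
            )
        labels[rec.subject_id] = 1 if rec.label == "CAD" else 0
    if len(set(labels)) != len(cohort):
        raise ValidationError("subject ids must be unique")
    counts = np.bincount(list(labels.values()), minlength=2)
    if counts.min() < 2:
        raise ValidationError("need at least 2 subjects per class")
    checksums = {}
    for rec in cohort:
        c = rec.checksum()
        if c in checksums:
            raise LeakageError(
                f"recordings {checksums[c]} and {rec.subject_id} are identical"
            )
        checksums[c] = rec.subject_id

    feats = subject_features(cohort, cfg)
    hashes = {
        sid: {ch: _feature_hash(x) for ch, x in per_ch.items()}
        for sid, per_ch in feats.items()
    }
    spec = CnnSpec(
        conv_dropout=cfg.conv_dropout,
        fc_dropout=cfg.fc_dropout,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        input_len=cfg.feature_len,
    )
    subject_ids = [rec.subject_id for rec in cohort]
    risks: List[SubjectRisk] = []
    for fold, test_id in enumerate(subject_ids):
        train_ids = [s for s in subject_ids if s != test_id]
        pool_labels = {labels[s] for s in train_ids}
        if len(pool_labels) < 2:
            logger.warning("fold %s skipped: a class is missing from training", test_id)
            continue
        fold_seed = int(
            np.random.SeedSequence([cfg.seed, fold]).generate_state(1)[0] % 2**31
        )
        rng = np.random.default_rng(fold_seed)
        tr_ids, va_ids = _inner_split(train_ids, labels, cfg.train_fraction, rng)
        if {labels[s] for s in tr_ids} != {0, 1}:
            logger.warning("fold %s skipped: single-class inner train set", test_id)
            continue
        channel_risks = {}
        for channel in cfg.channels:
            for sid in tr_ids + va_ids:
                if hashes[sid][channel] == hashes[test_id][channel]:
                    raise LeakageError(
                        f"features of held-out subject {test_id} found in "
                        f"fold training data (as {sid})"
                    )
            x_tr = np.concatenate([feats[s][channel] for s in tr_ids])
            y_tr = np.concatenate(
                [np.full(len(feats[s][channel]), labels[s]) for s in tr_ids]
            )
            x_va = np.concatenate([feats[s][channel] for s in va_ids])
            y_va = np.concatenate(
                [np.full(len(feats[s][channel]), labels[s]) for s in va_ids]
            )
            model = train_channel(
                x_tr, y_tr, x_va, y_va, spec=spec, epochs=cfg.epochs,
                seed=fold_seed, channel=channel,
            )
            probs = predict_proba(model.network(), feats[test_id][channel])[:, 1]
            channel_risks[channel] = aggregate_subject(probs)
        risks.append(
            SubjectRisk(
                subject_id=test_id,
                label="CAD" if labels[test_id] else "nonCAD",
                channel_risks=channel_risks,
            )
        )
        if progress:
            logger.info(
                "fold %d/%d (%s): all_axes risk %.3f",
                fold + 1, len(subject_ids), test_id, risks[-1].fused["all_axes"],
            )
    if not risks:
        raise FoldError("every fold was skipped")
    return risks


def risks_to_frame(risks: Sequence[SubjectRisk]) -> pd.DataFrame:
    rows = []
    for r in risks:
        row = {"subject_id": r.subject_id, "label": r.label}
        row.update({ch: r.channel_risks[ch] for ch in sorted(r.channel_risks)})
        row.update(r.fused)
        rows.append(row)
    return pd.DataFrame(rows)
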