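"""Model evaluation: ROC/AUC, sensitivity at fixed specificity, score
comparisons, CA19-9 stratification, and the depth-downsampling experiment."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_curve

from .fragments import QCConfig, downsample
from .motifs import MotifConfig
from .pipeline import FAMILIES, build_feature_matrix


@dataclass
class EvalReport:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_positive: int
    n_negative: int
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "auc": self.auc,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "roc": [list(map(float, p)) for p in zip(self.fpr, self.tpr, self.thresholds)],
            **self.extras,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def roc_auc(scores, labels) -> EvalReport:
    """Empirical ROC with trapezoidal AUC.

    Ties step simultaneously, so the AUC equals the Mann-Whitney U statistic
    normalized by n1*n0 (half credit for tied pairs).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(auc, fpr, tpr, thr, int(labels.sum()), int((1 - labels).sum()))


def sensitivity_at_specificity(scores, labels, target_spec: float = 0.95) -> tuple[float, float]:
    """Max sensitivity subject to specificity >= target, plus its threshold.

    Scanning candidate thresholds from high to low, the smallest threshold
    still meeting the specificity constraint is the operating point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    controls = scores[labels == 0]
    cases = scores[labels == 1]
    best = (0.0, np.inf)
    for t in np.concatenate([[np.inf], np.unique(scores)[::-1]]):
        spec = (controls < t).mean()
        if spec >= target_spec:
            best = (float((cases >= t).mean()), float(t))
        else:
            break
    return best


def compare_groups(values, grouping) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between groups.

    U is reported for the first-named group of each pair; the p-value is
    exact for combined n <= 20 without ties, otherwise a tie-corrected
    normal approximation (scipy's automatic policy).
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    names = pd.unique(grouping)
    if len(names) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    rows = []
    for a, b in combinations(names, 2):
        x, y = values[grouping == a], values[grouping == b]
        if len(x) == 0 or len(y) == 0:
            raise ValueError("empty group")
        res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["group1", "group2", "U", "p_value"])


def fold_auc_interval(cv_aucs, lo: float = 0.025, hi: float = 0.975) -> dict:
    """Fold-wise percentile interval for cross-validated AUC (the interval
    construction is labelled, since percentile and bootstrap CIs differ)."""
    arr = np.asarray(cv_aucs, dtype=float)
    return {
        "mean_auc": float(arr.mean()),
        "ci_low": float(np.quantile(arr, lo)),
        "ci_high": float(np.quantile(arr, hi)),
        "method": "fold-wise percentile",
    }


def ca19_9_stratified_report(
    scores, labels, ca19_9, score_cutoff: float, ca_cutoff: float = 39.0
) -> pd.DataFrame:
    """Model performance within CA19-9 strata (boundary value -> negative).

    Samples are split at the clinical CA19-9 cutoff (negative: <= 39 U/mL);
    within each stratum the model's confusion counts at ``score_cutoff`` are
    reported along with sensitivity/specificity where defined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ca19_9 = np.asarray(ca19_9, dtype=float)
    rows = []
    for name, mask in (("ca19_9_negative", ca19_9 <= ca_cutoff), ("ca19_9_positive", ca19_9 > ca_cutoff)):
        y, s = labels[mask], scores[mask]
        pred = s >= score_cutoff
        tp = int((pred & (y == 1)).sum())
        fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        fp = int((pred & (y == 0)).sum())
        rows.append(
            {
                "stratum": name,
                "n": int(mask.sum()),
                "n_cancer": int(y.sum()),
                "tp": tp, "fn": fn, "tn": tn, "fp": fp,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
            }
        )
    return pd.DataFrame(rows)


def downsampling_experiment(
    train_cohort,
    val_cohort,
    fractions,
    seed: int,
    qc: QCConfig | None = None,
    motif_cfg: MotifConfig | None = None,
    min_presence: float = 0.5,
) -> pd.DataFrame:
    """Re-run the full pipeline at reduced coverage.

    For each keep-fraction: every sample's fragments are independently
    downsampled, all features re-extracted, the stack retrained on the
    training cohort and evaluated on the validation cohort. Returns one row
    per (fraction, model) with the validation AUC. The NF presence filter is
    relaxed (default 0.5) because aggressive downsampling empties reference
    windows in some samples; missing values are mean-imputed as usual.
    """
    from .models import CANCER_LABELS, train_stacked

    art = train_cohort.artifacts
    rows = []
    for fraction in fractions:
        if not (0 < fraction <= 1):
            raise ValueError(f"invalid fraction {fraction}")
        def thin(cohort, offset):
            return {
                sid: downsample(frame, fraction, seed + offset + i)
                for i, (sid, frame) in enumerate(cohort.samples.items())
            }
        tr_samples = thin(train_cohort, 0)
        va_samples = thin(val_cohort, 10_000)
        tr = build_feature_matrix(
            tr_samples, train_cohort.metadata, art.genome, art.bins, art.genes, qc, motif_cfg,
            min_presence=min_presence,
        )
        va = build_feature_matrix(
            va_samples, val_cohort.metadata, art.genome, art.bins, art.genes,
            qc, motif_cfg, nf_assembly=tr.nf_assembly,
        )
        stacked = train_stacked(tr, seed)
        y_val = va.binary_labels(CANCER_LABELS)
        for fam in FAMILIES:
            auc = roc_auc(stacked.base[fam].model.predict_score(va.blocks[fam]), y_val).auc
            rows.append({"fraction": fraction, "model": fam, "validation_auc": auc})
        rows.append(
            {
                "fraction": fraction,
                "model": "stacked",
                "validation_auc": roc_auc(stacked.stacked_scores(va), y_val).auc,
            }
        )
    return pd.DataFrame(rows)
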