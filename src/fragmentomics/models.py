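"""Stacked detection models and the CA19-9 fusion (CF) model.

Per feature family a base learner is trained — a linear max-margin classifier
(LinearSVC) for the fragment-size and NF blocks, a random forest for the
motif block — under seeded, stratified ten-fold cross-validation, so every
training sample receives exactly one out-of-fold score. Margins of the linear
learners are mapped to [0, 1] through a logistic calibration fit on
training-fold margins, making them commensurate with forest vote fractions.
A logistic-regression meta-learner stacks the three out-of-fold score
columns; the decision cutoff minimizes size-weighted Gini impurity over the
training scores. The CF model is a linear max-margin classifier over two
inputs: the out-of-fold stacked score and log2(CA19-9 + 1).

Standardization, calibration and NF imputation are always fit on training
folds only; held-out data is transformed with stored parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .pipeline import FAMILIES, CohortFeatureMatrix

CANCER_LABELS = frozenset({"CCA", "GBC", "PAC"})

FAMILY_LEARNERS = {"fragment": "linear_svc", "motif": "random_forest", "nf": "linear_svc"}


# ---------------------------------------------------------------------------
# base learners


@dataclass
class FittedFamilyModel:
    """Scaler + estimator (+ margin calibrator for linear learners)."""

    family: str
    scaler: StandardScaler
    estimator: object
    calibrator: LogisticRegression | None

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.scaler.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != {self.scaler.n_features_in_} seen in training"
            )
        Z = self.scaler.transform(X)
        if self.calibrator is not None:
            margin = self.estimator.decision_function(Z).reshape(-1, 1)
            return self.calibrator.predict_proba(margin)[:, 1]
        return self.estimator.predict_proba(Z)[:, 1]


def _fit_family(X: np.ndarray, y: np.ndarray, family: str, seed: int) -> FittedFamilyModel:
    kind = FAMILY_LEARNERS[family]
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    if kind == "linear_svc":
        est = LinearSVC(C=1.0, random_state=seed, max_iter=20000).fit(Z, y)
        margin = est.decision_function(Z).reshape(-1, 1)
        cal = LogisticRegression(max_iter=1000).fit(margin, y)
        return FittedFamilyModel(family, scaler, est, cal)
    est = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1).fit(Z, y)
    return FittedFamilyModel(family, scaler, est, None)


@dataclass
class BaseModelResult:
    family: str
    model: FittedFamilyModel
    oof_scores: np.ndarray
    folds: np.ndarray
    cv_aucs: list


def _fold_assignment(y: np.ndarray, seed: int, n_splits: int) -> list:
    counts = np.bincount(y)
    k = min(n_splits, int(counts[counts > 0].min()))
    if k < n_splits:
        warnings.warn(f"reducing folds from {n_splits} to {k} (smallest class has {k} samples)")
    if k < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def train_base_model(
    X: np.ndarray, y: np.ndarray, family: str, seed: int, n_splits: int = 10,
    splits: list | None = None,
) -> BaseModelResult:
    """Fit one family's base learner with out-of-fold scoring.

    Within each fold, standardization (and calibration) are fit on the
    training portion only; the final learner is refit on all samples.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class input")
    splits = splits if splits is not None else _fold_assignment(y, seed, n_splits)
    from .evaluate import roc_auc  # local import to avoid a cycle

    oof = np.empty(len(y))
    folds = np.empty(len(y), dtype=int)
    cv_aucs = []
    for f, (tr, te) in enumerate(splits):
        fam = _fit_family(X[tr], y[tr], family, seed)
        oof[te] = fam.predict_score(X[te])
        folds[te] = f
        if len(np.unique(y[te])) == 2:
            cv_aucs.append(roc_auc(oof[te], y[te]).auc)
    final = _fit_family(X, y, family, seed)
    return BaseModelResult(family, final, oof, folds, cv_aucs)


# ---------------------------------------------------------------------------
# cutoff


def gini_impurity(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    p = y.mean()
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def select_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold minimizing size-weighted mean Gini impurity of the split.

    Candidates are midpoints between consecutive sorted unique scores; ties
    are broken toward the larger cutoff (higher specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to select a cutoff")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(labels)
    best_cut, best_imp = candidates[0], np.inf
    for c in candidates:
        right = scores >= c
        imp = (
            right.sum() / n * gini_impurity(labels[right])
            + (~right).sum() / n * gini_impurity(labels[~right])
        )
        if imp < best_imp or (imp == best_imp):
            best_imp, best_cut = imp, c  # equal impurity -> keep larger cutoff
    return float(best_cut)


# ---------------------------------------------------------------------------
# stacking


@dataclass
class StackedModel:
    base: dict  # family -> BaseModelResult
    meta: LogisticRegression
    cutoff: float
    oof_stacked: np.ndarray
    folds: np.ndarray
    cv_aucs: list
    seed: int

    def base_scores(self, matrix: CohortFeatureMatrix) -> np.ndarray:
        return np.column_stack(
            [self.base[f].model.predict_score(matrix.blocks[f]) for f in FAMILIES]
        )

    def stacked_scores(self, matrix: CohortFeatureMatrix) -> np.ndarray:
        return self.meta.predict_proba(self.base_scores(matrix))[:, 1]


def train_stacked(
    matrix: CohortFeatureMatrix,
    seed: int,
    positive: frozenset = CANCER_LABELS,
    n_splits: int = 10,
) -> StackedModel:
    """Train the three base models and the logistic meta-learner.

    All families share one stratified fold assignment. The meta-learner is
    fit on the out-of-fold score columns; out-of-fold *stacked* scores (for
    the cutoff and for CF training) come from per-fold meta-learners fit on
    the remaining folds' scores only.
    """
    for fam in FAMILIES:
        if fam not in matrix.blocks:
            raise ValueError(f"missing feature block {fam!r}")
    y = matrix.binary_labels(positive)
    splits = _fold_assignment(y, seed, n_splits)
    base = {
        fam: train_base_model(matrix.blocks[fam], y, fam, seed, splits=splits)
        for fam in FAMILIES
    }
    Z = np.column_stack([base[f].oof_scores for f in FAMILIES])
    meta = LogisticRegression(C=1e6, max_iter=2000).fit(Z, y)
    folds = base[FAMILIES[0]].folds
    oof_stacked = np.empty(len(y))
    from .evaluate import roc_auc

    cv_aucs = []
    for f, (tr, te) in enumerate(splits):
        meta_f = LogisticRegression(C=1e6, max_iter=2000).fit(Z[tr], y[tr])
        oof_stacked[te] = meta_f.predict_proba(Z[te])[:, 1]
        if len(np.unique(y[te])) == 2:
            cv_aucs.append(roc_auc(oof_stacked[te], y[te]).auc)
    cutoff = select_cutoff(oof_stacked, y)
    return StackedModel(base, meta, cutoff, oof_stacked, folds, cv_aucs, seed)


def predict(model, matrix: CohortFeatureMatrix, ca19_9: np.ndarray | None = None) -> pd.DataFrame:
    """Score samples with a StackedModel or CFModel; returns the score report.

    For a CFModel, ``matrix`` must be accompanied by CA19-9 values (taken
    from the matrix when not passed explicitly).
    """
    if isinstance(model, CFModel):
        ca = matrix.ca19_9 if ca19_9 is None else ca19_9
        if ca is None:
            raise ValueError("CF model needs CA19-9 values")
        stacked = model.stacked.stacked_scores(matrix)
        cf = model.predict_score(stacked, ca)
        return pd.DataFrame(
            {
                "sample_id": matrix.sample_ids,
                "stacked_score": stacked,
                "cf_score": cf,
                "predicted": (cf >= model.cutoff).astype(int),
            }
        )
    scores = model.base_scores(matrix)
    stacked = model.stacked_scores(matrix)
    report = pd.DataFrame({"sample_id": matrix.sample_ids})
    for i, fam in enumerate(FAMILIES):
        report[f"{fam}_score"] = scores[:, i]
    report["stacked_score"] = stacked
    report["predicted"] = (stacked >= model.cutoff).astype(int)
    return report


# ---------------------------------------------------------------------------
# CF model


def log2_ca19_9(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("CA19-9 values must be non-negative")
    return np.log2(values + 1.0)


@dataclass
class CFModel:
    stacked: StackedModel
    scaler: StandardScaler
    estimator: LinearSVC
    calibrator: LogisticRegression
    cutoff: float

    def predict_score(self, stacked_scores: np.ndarray, ca19_9: np.ndarray) -> np.ndarray:
        X = np.column_stack([stacked_scores, log2_ca19_9(ca19_9)])
        margin = self.estimator.decision_function(self.scaler.transform(X)).reshape(-1, 1)
        return self.calibrator.predict_proba(margin)[:, 1]

    def decision_line(self) -> tuple[float, float, float]:
        """(a, b, c) with a*stacked + b*log2(CA19-9+1) + c = 0 in the
        untransformed 2-D feature plane (the figure-ready boundary)."""
        w = self.estimator.coef_[0] / self.scaler.scale_
        c = self.estimator.intercept_[0] - np.sum(
            self.estimator.coef_[0] * self.scaler.mean_ / self.scaler.scale_
        )
        return float(w[0]), float(w[1]), float(c)


def train_cf(
    matrix: CohortFeatureMatrix,
    stacked: StackedModel,
    seed: int,
    positive: frozenset = CANCER_LABELS,
) -> CFModel:
    """Fuse the out-of-fold stacked score with log2(CA19-9 + 1)."""
    if matrix.ca19_9 is None:
        raise ValueError("feature matrix has no CA19-9 values")
    y = matrix.binary_labels(positive)
    X = np.column_stack([stacked.oof_stacked, log2_ca19_9(matrix.ca19_9)])
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    est = LinearSVC(C=1.0, random_state=seed, max_iter=20000).fit(Z, y)
    margin = est.decision_function(Z).reshape(-1, 1)
    cal = LogisticRegression(max_iter=1000).fit(margin, y)
    # out-of-fold CF scores for the cutoff, reusing the stacked fold layout
    oof = np.empty(len(y))
    for f in np.unique(stacked.folds):
        tr, te = stacked.folds != f, stacked.folds == f
        sc = StandardScaler().fit(X[tr])
        e = LinearSVC(C=1.0, random_state=seed, max_iter=20000).fit(sc.transform(X[tr]), y[tr])
        m_tr = e.decision_function(sc.transform(X[tr])).reshape(-1, 1)
        c = LogisticRegression(max_iter=1000).fit(m_tr, y[tr])
        oof[te] = c.predict_proba(e.decision_function(sc.transform(X[te])).reshape(-1, 1))[:, 1]
    cutoff = select_cutoff(oof, y)
    return CFModel(stacked, scaler, est, cal, cutoff)


# ---------------------------------------------------------------------------
# subtype contrasts and coefficient export


def train_subtype_models(
    matrix: CohortFeatureMatrix,
    positive,
    negative,
    seed: int,
    n_splits: int = 10,
) -> StackedModel:
    """Train the same stack on a label contrast, e.g. PAC vs CCA, or
    PAC vs (CCA, GBC), or one cancer type vs non_cancer."""
    pos = frozenset([positive] if isinstance(positive, str) else positive)
    neg = frozenset([negative] if isinstance(negative, str) else negative)
    mask = np.array([l in pos | neg for l in matrix.labels])
    if not mask.any() or not any(l in pos for l in matrix.labels[mask]) or not any(
        l in neg for l in matrix.labels[mask]
    ):
        raise ValueError("both contrast groups must be non-empty")
    return train_stacked(matrix.subset(mask), seed, positive=pos, n_splits=n_splits)


def export_nf_coefficients(
    nf_result: BaseModelResult, gene_ids, top_n: int = 500
) -> pd.DataFrame:
    """Ranked gene table from the linear NF learner's coefficients.

    Coefficients are mapped back through the standardization scale so they
    refer to raw NF units; zero-variance genes get coefficient 0. Ranked by
    |coefficient|, descending.
    """
    model = nf_result.model
    if model.calibrator is None or not hasattr(model.estimator, "coef_"):
        raise ValueError("NF coefficient export requires a linear learner")
    coef = model.estimator.coef_[0].copy()
    zero_var = model.scaler.var_ == 0
    coef = np.where(zero_var, 0.0, coef / model.scaler.scale_)
    df = pd.DataFrame({"gene_id": list(gene_ids), "coefficient": coef})
    df["abs_coefficient"] = df["coefficient"].abs()
    df = df.sort_values("abs_coefficient", ascending=False, kind="stable")
    return df.head(top_n).drop(columns="abs_coefficient").reset_index(drop=True)
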