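"""Logistic-regression classifier and the repeated-split evaluation battery.

A final (unpenalized) logistic model is fit on the selected features;
each subject's radiomics score is the linear predictor, converted to a
probability through the sigmoid and thresholded at 0.5.  Performance
is summarized by AUC, specificity, sensitivity, PPV, NPV, precision,
recall and F-score over 10 shuffled stratified 0.7/0.3 train/test
splits, reported per repetition and as mean +/- SD.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from hipporad.selection import split_train_test, standardize

POSITIVE_LABEL = "aMCI"

METRICS = ["auc", "specificity", "sensitivity", "ppv", "npv",
           "precision", "recall", "f_score"]


def binarize_labels(labels, positive: str = POSITIVE_LABEL) -> np.ndarray:
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    if positive not in present:
        positive = sorted(present)[-1]
    return (labels == positive).astype(int)


@dataclasses.dataclass
class FittedModel:
    intercept: float
    coefficients: pd.Series
    stabilized: bool = False   # ridge fallback used (perfect separation)

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Radiomics score: the linear predictor."""
        return self.intercept + X[self.coefficients.index].to_numpy() @ \
            self.coefficients.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit
        return expit(self.score(X))


def fit_logistic(X: pd.DataFrame, y: np.ndarray) -> FittedModel:
    """Maximum-likelihood (unpenalized) logistic fit.

    Under perfect separation the MLE diverges; a tiny ridge
    stabilizer is used instead and flagged on the returned model.
    """
    if len(np.unique(y)) != 2:
        raise ValueError("need both classes to fit")
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000,
                             tol=1e-10)
    clf.fit(X.to_numpy(), y)
    stabilized = False
    scores = X.to_numpy() @ clf.coef_[0] + clf.intercept_[0]
    separated = scores[y == 1].min() > scores[y == 0].max()
    if separated or clf.n_iter_[0] >= 2000:
        clf = LogisticRegression(C=1e3, l1_ratio=0.0, solver="lbfgs",
                                 max_iter=2000)
        clf.fit(X.to_numpy(), y)
        stabilized = True
    return FittedModel(
        intercept=float(clf.intercept_[0]),
        coefficients=pd.Series(clf.coef_[0], index=list(X.columns)),
        stabilized=stabilized,
    )


def auc_midrank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic with midranks
    for ties (the rank/trapezoid method)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined with a single class")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=float)
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def evaluate(probabilities: np.ndarray, y: np.ndarray,
             threshold: float = 0.5) -> dict:
    """Confusion matrix at the threshold plus the eight metrics.

    Identities sensitivity = recall = TP/(TP+FN) and precision = PPV
    hold by construction; undefined ratios (empty denominators) are
    reported as NaN.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    y = np.asarray(y)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f = (2 * prec * sens / (prec + sens)
         if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
         else np.nan)
    return {
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        "auc": auc_midrank(p, y),
        "specificity": spec,
        "sensitivity": sens,
        "ppv": prec,
        "npv": npv,
        "precision": prec,
        "recall": sens,
        "f_score": f,
    }


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return np.nan
    return 2.0 * precision * recall / (precision + recall)


def roc_points(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Standard ROC step curve over score thresholds (FPR, TPR, thr)."""
    from sklearn.metrics import roc_curve
    fpr, tpr, thr = roc_curve(y, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def score_plot(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Subjects ordered by radiomics score with their group labels.

    The 0 score line corresponds to probability 0.5; bars below it on
    the control side (and above it on the case side) are correct
    predictions.
    """
    df = pd.DataFrame({"score": np.asarray(scores, float),
                       "is_case": np.asarray(y, int)})
    df = df.sort_values("score", kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(len(df))
    return df


@dataclasses.dataclass
class RepetitionPlan:
    n_repetitions: int = 10
    train_fraction: float = 0.7
    base_seed: int = 0

    def seeds(self) -> list[int]:
        return [(self.base_seed * 1009 + 7919 * k) % (2**31 - 1)
                for k in range(self.n_repetitions)]


def run_repetitions(table: pd.DataFrame, features: list,
                    plan: RepetitionPlan,
                    label_column: str = "label") -> dict:
    """Repeated shuffled-split evaluation of a fixed feature set.

    For each repetition the cohort is split 0.7/0.3 (stratified), the
    model refit on train and evaluated on both splits.  Returns
    per-repetition reports plus mean +/- SD aggregates and the
    train-test AUC gap (an overfitting indicator).
    """
    reps = []
    for seed in plan.seeds():
        train, test = split_train_test(table, plan.train_fraction, seed,
                                       label_column=label_column)
        train, test, _ = standardize(train, test, features)
        feats = [f for f in features if f in train.columns]
        y_tr = binarize_labels(train[label_column])
        y_te = binarize_labels(test[label_column])
        model = fit_logistic(train[feats], y_tr)
        rep = {"seed": seed, "stabilized": model.stabilized}
        for split_name, frame, yy in (("train", train, y_tr),
                                      ("test", test, y_te)):
            pr = model.predict_proba(frame[feats])
            ev = evaluate(pr, yy)
            rep[split_name] = ev
        reps.append(rep)
    agg = {}
    for split_name in ("train", "test"):
        for m in METRICS:
            vals = np.array([r[split_name][m] for r in reps], dtype=float)
            agg[f"{split_name}_{m}_mean"] = float(np.nanmean(vals))
            agg[f"{split_name}_{m}_sd"] = float(np.nanstd(vals))
    agg["auc_gap_mean"] = agg["train_auc_mean"] - agg["test_auc_mean"]
    return {"repetitions": reps, "aggregate": agg,
            "features": list(features)}


def report_to_json(report: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(report, indent=1, default=default))
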