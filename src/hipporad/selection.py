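"""Preprocessing and the three-stage feature-selection cascade.

On a subjects x features table the cascade runs:

1. univariate screen — Welch two-sample t-test and Mann-Whitney rank
   test per feature at alpha = 0.05; survivors are by default the
   union of the two tests' survivor sets,
2. redundancy filter — for feature pairs with |Spearman rho| above
   0.9, one member of each still-live pair is removed by a seeded
   random draw (pairs visited in descending |rho|),
3. embedded selection — an L1-penalized logistic-regression path over
   a log-spaced penalty grid with stratified 10-fold cross-validation;
   the penalty minimizing mean CV deviance is chosen and features with
   nonzero coefficients at it survive.

All statistics (imputation means, scaler, p-values, correlations, the
LASSO path) are computed from training rows only; the test split is
transformed with the training scaler, never refit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)


@dataclasses.dataclass
class SelectionConfig:
    train_fraction: float = 0.7
    alpha: float = 0.05
    correlation_threshold: float = 0.9
    integration_rule: str = "union"     # union | intersection
    n_lambdas: int = 40
    lambda_min: float = 1e-3
    lambda_max: float = 1e2
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.integration_rule not in ("union", "intersection"):
            raise ValueError("integration_rule must be union or intersection")


@dataclasses.dataclass
class SelectionResult:
    """Audit trail of the cascade: survivors per stage and diagnostics."""

    univariate_survivors: list
    correlation_survivors: list
    final_features: list
    coefficients: dict                  # final nonzero coefficients
    chosen_lambda: float
    p_values: pd.DataFrame              # per-feature t and rank p
    removed_pairs: list                 # (kept, removed, rho)
    lambda_grid: np.ndarray
    coef_path: np.ndarray               # n_lambdas x n_features
    cv_error: np.ndarray                # mean CV deviance per lambda
    integration_rule: str = "union"

    def stage_counts(self) -> dict:
        return {
            "univariate": len(self.univariate_survivors),
            "correlation": len(self.correlation_survivors),
            "lasso": len(self.final_features),
        }

    def to_json(self, path: str | Path) -> None:
        obj = {
            "univariate_survivors": list(self.univariate_survivors),
            "correlation_survivors": list(self.correlation_survivors),
            "final_features": list(self.final_features),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "chosen_lambda": float(self.chosen_lambda),
            "integration_rule": self.integration_rule,
            "removed_pairs": [[a, b, float(r)] for a, b, r in self.removed_pairs],
            "lambda_grid": [float(x) for x in self.lambda_grid],
            "cv_error": [float(x) for x in self.cv_error],
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def impute_abnormal(table: pd.DataFrame,
                    feature_columns: list | None = None,
                    means: pd.Series | None = None):
    """Replace non-finite entries by the per-feature mean of finite ones.

    Returns ``(table, means)``; pass the returned ``means`` back in to
    impute a held-out split with training statistics.  Features with
    no finite entry are dropped (logged).
    """
    table = table.copy()
    if feature_columns is None:
        feature_columns = [c for c in table.columns
                           if pd.api.types.is_float_dtype(table[c])]
    sub = table[feature_columns].replace([np.inf, -np.inf], np.nan)
    if means is None:
        means = sub.mean(axis=0, skipna=True)
    dead = means.index[means.isna()].tolist()
    if dead:
        log.warning("dropping %d all-missing features: %s…",
                    len(dead), dead[:3])
        sub = sub.drop(columns=dead)
        means = means.drop(index=dead)
    sub = sub.fillna(means)
    for c in sub.columns:
        table[c] = sub[c]
    table = table.drop(columns=dead)
    return table, means


def split_train_test(table: pd.DataFrame, fraction: float, seed: int,
                     label_column: str = "label"):
    """Stratified random split into train/test row subsets.

    Per class, round(fraction * n_class) rows go to train (so 42+44
    subjects at 0.7 give a 29+31 train and 13+13 test split);
    deterministic given the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx = []
    test_idx = []
    for _, grp in table.groupby(label_column, sort=True):
        if len(grp) < 2:
            raise ValueError("each class needs at least 2 members")
        n_train = int(round(fraction * len(grp)))
        n_train = min(max(n_train, 1), len(grp) - 1)
        perm = rng.permutation(len(grp))
        train_idx.extend(grp.index[perm[:n_train]])
        test_idx.extend(grp.index[perm[n_train:]])
    return table.loc[sorted(train_idx)], table.loc[sorted(test_idx)]


def standardize(train: pd.DataFrame, test: pd.DataFrame | None,
                feature_columns: list):
    """Z-score features using training means/SDs only.

    Zero-variance training features are dropped from both splits.
    Returns ``(train, test, scaler)`` where scaler is a (mean, sd)
    DataFrame usable to transform further data.
    """
    mu = train[feature_columns].mean(axis=0)
    sd = train[feature_columns].std(axis=0, ddof=0)
    keep = sd.index[sd > 0].tolist()
    dropped = [c for c in feature_columns if c not in keep]
    if dropped:
        log.info("dropping %d zero-variance features", len(dropped))
    train = train.copy()
    train[keep] = (train[keep] - mu[keep]) / sd[keep]
    train = train.drop(columns=dropped)
    if test is not None:
        test = test.copy()
        test[keep] = (test[keep] - mu[keep]) / sd[keep]
        test = test.drop(columns=dropped)
    scaler = pd.DataFrame({"mean": mu[keep], "sd": sd[keep]})
    return train, test, scaler


def univariate_filter(train: pd.DataFrame, feature_columns: list,
                      alpha: float = 0.05, rule: str = "union",
                      label_column: str = "label"):
    """Welch t-test + Mann-Whitney rank test screen.

    Returns ``(survivors, p_values)`` where p_values has one row per
    feature with columns ``t_p`` and ``rank_p``.  Under the union rule
    a feature survives if either test is significant at alpha.
    """
    classes = sorted(train[label_column].unique())
    if len(classes) != 2:
        raise ValueError("univariate filter needs exactly two classes")
    a = train.loc[train[label_column] == classes[0], feature_columns].to_numpy()
    b = train.loc[train[label_column] == classes[1], feature_columns].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tp = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
        rp = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided").pvalue
    # features constant in both classes carry no evidence
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    tp = np.where(degenerate | ~np.isfinite(tp), 1.0, tp)
    rp = np.where(degenerate | ~np.isfinite(rp), 1.0, rp)
    pvals = pd.DataFrame({"t_p": tp, "rank_p": rp},
                         index=pd.Index(feature_columns, name="feature"))
    sig_t = pvals["t_p"] < alpha
    sig_r = pvals["rank_p"] < alpha
    mask = (sig_t | sig_r) if rule == "union" else (sig_t & sig_r)
    survivors = [c for c in feature_columns if mask[c]]
    return survivors, pvals


def correlation_filter(train: pd.DataFrame, survivors: list,
                       threshold: float = 0.9, seed: int = 0):
    """Spearman redundancy filter.

    Unordered pairs with |rho| > threshold are visited in descending
    |rho| (ties broken by name); for each pair whose members are both
    still alive, one is removed by a seeded coin flip.  Returns
    ``(survivors, removed_log)`` with the survivor list order-stable
    and the log holding (kept, removed, rho) triples.
    """
    if len(survivors) < 2:
        return list(survivors), []
    rho = stats.spearmanr(train[survivors].to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(len(survivors)):
        for j in range(i + 1, len(survivors)):
            r = rho[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                pairs.append((abs(r), survivors[i], survivors[j], r))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(survivors)
    removed_log = []
    for _, fi, fj, r in pairs:
        if fi in alive and fj in alive:
            drop = fi if rng.integers(2) == 0 else fj
            keep = fj if drop == fi else fi
            alive.discard(drop)
            removed_log.append((keep, drop, float(r)))
    return [c for c in survivors if c in alive], removed_log


def lasso_path(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray):
    """Coefficient path of L1-penalized logistic regression.

    The penalty is parameterized as lambda = 1 / (C * n) so that the
    objective is mean deviance + lambda * ||w||_1.
    """
    n = len(y)
    path = np.zeros((len(lambdas), X.shape[1]))
    for k, lam in enumerate(lambdas):
        clf = LogisticRegression(
            C=1.0 / (lam * n), l1_ratio=1.0, solver="liblinear",
            max_iter=5000, tol=1e-6)
        clf.fit(X, y)
        path[k] = clf.coef_[0]
    return path


def lasso_select(train: pd.DataFrame, survivors: list,
                 config: SelectionConfig,
                 label_column: str = "label",
                 p_values: pd.DataFrame | None = None,
                 prior_stages: tuple[list, list] | None = None,
                 removed_pairs: list | None = None) -> SelectionResult:
    """Cross-validated LASSO over the surviving features.

    The penalty weight minimizing the mean 10-fold CV deviance
    ("minimum criterion") is chosen; survivors are the features with
    nonzero coefficients there.
    """
    if len(survivors) < 2:
        raise ValueError("need at least 2 surviving features")
    classes = sorted(train[label_column].unique())
    y = (train[label_column] == classes[0]).to_numpy().astype(int)
    X = train[survivors].to_numpy()
    lambdas = np.geomspace(config.lambda_max, config.lambda_min,
                           config.n_lambdas)
    n_folds = min(config.cv_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=config.seed)
    cv_err = np.zeros(len(lambdas))
    for tr_idx, va_idx in skf.split(X, y):
        for k, lam in enumerate(lambdas):
            clf = LogisticRegression(
                C=1.0 / (lam * len(tr_idx)), l1_ratio=1.0,
                solver="liblinear", max_iter=5000, tol=1e-6)
            clf.fit(X[tr_idx], y[tr_idx])
            p = clf.predict_proba(X[va_idx])[:, 1]
            cv_err[k] += log_loss(y[va_idx], p, labels=[0, 1])
    cv_err /= n_folds
    best = int(np.argmin(cv_err))
    chosen_lambda = float(lambdas[best])
    path = lasso_path(X, y, lambdas)
    coefs = path[best]
    nz = np.flatnonzero(np.abs(coefs) > 1e-10)
    final = [survivors[i] for i in nz]
    if not final:
        log.warning("LASSO selected no features at the CV-optimal penalty")
    uni, corr = prior_stages if prior_stages is not None else (list(survivors),
                                                               list(survivors))
    return SelectionResult(
        univariate_survivors=uni,
        correlation_survivors=corr,
        final_features=final,
        coefficients={survivors[i]: float(coefs[i]) for i in nz},
        chosen_lambda=chosen_lambda,
        p_values=p_values if p_values is not None else pd.DataFrame(),
        removed_pairs=removed_pairs or [],
        lambda_grid=lambdas,
        coef_path=path,
        cv_error=cv_err,
        integration_rule=config.integration_rule,
    )


def run_selection(train: pd.DataFrame, feature_columns: list,
                  config: SelectionConfig,
                  label_column: str = "label") -> SelectionResult:
    """Run the full three-stage cascade on (already standardized)
    training data and return its audit trail."""
    uni, pvals = univariate_filter(
        train, feature_columns, alpha=config.alpha,
        rule=config.integration_rule, label_column=label_column)
    if not uni:
        raise ValueError("no features survive the univariate screen")
    corr, removed = correlation_filter(
        train, uni, threshold=config.correlation_threshold,
        seed=config.seed)
    result = lasso_select(
        train, corr, config, label_column=label_column,
        p_values=pvals, prior_stages=(uni, corr), removed_pairs=removed)
    log.info("cascade: %d -> %d -> %d -> %d features",
             len(feature_columns), len(uni), len(corr),
             len(result.final_features))
    return result
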