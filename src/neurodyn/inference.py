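"""Statistical reduction and the inequality-vs-individual-factors layer.

Three building blocks:

* sign-flipping permutation tests of a mean against zero (5000
  randomisations by default) with Benjamini-Hochberg FDR control, used to
  reduce the ROI x metric analytical space;
* hierarchical OLS regressions of EEG outcomes on the Gini coefficient
  alone and combined with one demographic/cognitive factor at a time,
  reporting R-squared, Cohen's f-squared = R2/(1-R2), the model F and p;
* median-binarized gradient-boosted classification (80/20 stratified
  splits, k repeats) with gain-based feature importance, quantifying how
  well inequality separates high from low values of each EEG outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import CohortFeatureTable, log_stage

__all__ = [
    "permutation_mean_test", "bh_fdr", "reduce_rois", "cohens_f2",
    "hierarchical_regression", "classify_outcomes",
    "RegressionReport", "ClassifierReport",
]


def permutation_mean_test(values: np.ndarray, n_perm: int = 5000,
                          seed: int | None = None) -> float:
    """Two-sided sign-flipping permutation test of mean(values) vs zero.

    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm).  The smallest
    attainable p is 1/(n_perm + 1).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("values must be a non-empty 1-D array")
    rng = np.random.default_rng(seed)
    t_obs = abs(values.mean())
    if np.all(values == 0):
        return 1.0
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(values)))
    t_perm = np.abs((signs * values).mean(axis=1))
    return float((1 + np.sum(t_perm >= t_obs)) / (1 + n_perm))


def bh_fdr(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags.

    Reject all hypotheses with sorted rank i <= max{i : p_(i) <= i*alpha/m}.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) * alpha / m)
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        flags[order[: k + 1]] = True
    return flags


def reduce_rois(band_metric_table: pd.DataFrame, alpha: float = 0.05,
                n_perm: int = 5000, seed: int | None = None) -> list[str]:
    """Retain the ROIs (columns) whose subject values have a mean
    significantly different from zero, after BH-FDR across ROIs."""
    if band_metric_table.shape[1] == 0:
        return []
    rng = np.random.default_rng(seed)
    cols = list(band_metric_table.columns)
    p = np.array([
        permutation_mean_test(band_metric_table[c].dropna().to_numpy(),
                              n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        for c in cols
    ])
    keep = bh_fdr(p, alpha=alpha)
    return [c for c, k in zip(cols, keep) if k]


def cohens_f2(r_squared: float) -> float:
    """Cohen's effect size f2 = R2 / (1 - R2)."""
    if not 0 <= r_squared < 1:
        raise ValueError("R-squared must lie in [0, 1)")
    return r_squared / (1.0 - r_squared)


@dataclass
class RegressionReport:
    outcome: str
    features: list[str]
    estimates: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    f_squared: float
    model_f: float
    model_p: float
    n_used: int


def _design_matrix(df: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """z-score continuous predictors, code sex female=1/male=0, and build
    any 'a:b' interaction from the standardized mains."""
    cols = {}
    mains = [f for f in features if ":" not in f]
    for f in mains:
        if f == "sex":
            cols[f] = (df[f] == "female").astype(float)
        else:
            v = df[f].astype(float)
            sd = v.std(ddof=0)
            cols[f] = (v - v.mean()) / sd if sd > 0 else v * 0.0
    for f in features:
        if ":" in f:
            a, b = f.split(":")
            cols[f] = cols[a] * cols[b]
    return pd.DataFrame(cols, index=df.index)


def hierarchical_regression(table: CohortFeatureTable, outcome: str,
                            features: list[str],
                            covariates_extra: list[str] | None = None
                            ) -> RegressionReport:
    """OLS of `outcome` on standardized `features` (plus optional extra
    covariates such as gdp/oqd/n_channels), with listwise deletion.

    Interactions are written ``"gini:age"``.  Raises on rank-deficient
    designs, naming the collinear columns.
    """
    feats = list(features) + list(covariates_extra or [])
    needed = sorted({outcome} | {p for f in feats for p in f.split(":")})
    df = table.df[needed].dropna()
    if len(df) <= len(feats) + 2:
        raise ValueError(f"too few complete cases ({len(df)}) for {len(feats)} predictors")
    X = _design_matrix(df, feats)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        a, b = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(f"rank-deficient design; collinear columns "
                         f"{X.columns[a]!r} and {X.columns[b]!r}")
    model = sm.OLS(df[outcome].astype(float), sm.add_constant(X)).fit()
    r2 = float(model.rsquared)
    report = RegressionReport(
        outcome=outcome, features=feats,
        estimates={f: float(model.params[f]) for f in X.columns},
        t_values={f: float(model.tvalues[f]) for f in X.columns},
        p_values={f: float(model.pvalues[f]) for f in X.columns},
        r_squared=r2, f_squared=cohens_f2(min(r2, 1 - 1e-12)),
        model_f=float(model.fvalue), model_p=float(model.f_pvalue),
        n_used=int(model.nobs),
    )
    log_stage("hierarchical_regression", outcome=outcome, features=feats,
              n=report.n_used, r2=round(r2, 4))
    return report


@dataclass
class ClassifierReport:
    outcome: str
    features: list[str]
    auc: list[float]
    accuracy: list[float]
    precision: list[float]
    recall: list[float]
    f1: list[float]
    importances: dict[str, float]
    k: int
    seed: int
    mean_auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_auc = float(np.mean(self.auc))


def classify_outcomes(table: CohortFeatureTable, outcome: str,
                      features: list[str], k: int = 10, test_size: float = 0.2,
                      seed: int = 0, n_estimators: int = 100, max_depth: int = 3,
                      learning_rate: float = 0.1) -> ClassifierReport:
    """Median-binarized gradient-boosted classification of one EEG outcome.

    The label is ``outcome > median`` (ties to class 0).  Each of `k`
    repeats draws a fresh stratified 80/20 split and trains an XGBoost
    classifier; AUC/accuracy/precision/recall/F1 are collected per repeat
    and gain importances are averaged and normalized to sum to one.
    """
    from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                                 recall_score, roc_auc_score)
    from sklearn.model_selection import train_test_split
    from xgboost import XGBClassifier

    needed = sorted(set([outcome] + features))
    df = table.df[needed].dropna()
    if len(df) < 50:
        raise ValueError("need at least 50 complete cases")
    y_raw = df[outcome].astype(float)
    if y_raw.nunique() < 2:
        raise ValueError("degenerate (constant) outcome")
    y = (y_raw > y_raw.median()).astype(int).to_numpy()
    X = _design_matrix(df, features).to_numpy()

    rng = np.random.default_rng(seed)
    auc, acc, prec, rec, f1s = [], [], [], [], []
    importances = np.zeros(len(features))
    for rep in range(k):
        rs = int(rng.integers(2**31 - 1))
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=test_size,
                                              stratify=y, random_state=rs)
        clf = XGBClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            learning_rate=learning_rate, random_state=rs,
            eval_metric="logloss", importance_type="gain", verbosity=0,
        )
        clf.fit(Xtr, ytr)
        prob = clf.predict_proba(Xte)[:, 1]
        pred = (prob > 0.5).astype(int)
        auc.append(float(roc_auc_score(yte, prob)))
        acc.append(float(accuracy_score(yte, pred)))
        prec.append(float(precision_score(yte, pred, zero_division=0)))
        rec.append(float(recall_score(yte, pred, zero_division=0)))
        f1s.append(float(f1_score(yte, pred, zero_division=0)))
        imp = clf.feature_importances_
        importances += np.nan_to_num(imp)
    total = importances.sum()
    imp_norm = importances / total if total > 0 else np.full(len(features),
                                                            1.0 / len(features))
    report = ClassifierReport(
        outcome=outcome, features=list(features), auc=auc, accuracy=acc,
        precision=prec, recall=rec, f1=f1s,
        importances=dict(zip(features, imp_norm.tolist())), k=k, seed=seed,
    )
    log_stage("classify_outcomes", outcome=outcome, features=features,
              mean_auc=round(report.mean_auc, 3))
    return report
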