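"""Same/different identity analyses.

In the arrangement task each trial carries an "identity line": the screen
position below which the participant judges face pairs to depict the same
person.  This module summarizes where observers place that threshold and
asks how well three geometric predictors discriminate same- from
different-identity pairs: the Euclidean distance between the faces, the
angle theta between their vectors, and the absolute radial difference
|r1 - r2|.  Each predictor is first passed through a univariate logistic
regression; the ROC curve of the classifier's output over a grid of
probability thresholds in [0, 1] yields the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .facespace import GeometricDesign
from .synthetic_data import JudgmentDataset

__all__ = [
    "LogisticFit",
    "RocResult",
    "identity_threshold_summary",
    "fit_identity_classifier",
    "roc_auc",
    "identity_auc_comparison",
    "same_different_histogram",
]

PREDICTORS = ("euclidean", "theta", "abs_radius_diff")


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    probabilities: np.ndarray
    separable: bool


@dataclass
class RocResult:
    name: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def identity_threshold_summary(dataset: JudgmentDataset) -> tuple[float, float]:
    """Mean identity-line placement and its SEM over participants.

    Lines are first averaged over trials (and sessions) within each
    participant, then summarized across participants.
    """
    df = dataset.frame
    if "identity_line" not in df.columns or df["identity_line"].isna().all():
        raise ValueError("dataset carries no identity-line placements")
    lines = df.drop_duplicates(["participant_id", "session", "trial"])
    per_part = lines.groupby("participant_id")["identity_line"].mean()
    n = per_part.size
    mean = float(per_part.mean())
    sem = float(per_part.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem


def fit_identity_classifier(predictor_values, same_identity) -> LogisticFit:
    """Univariate logistic regression of the identity label on a predictor.

    Maximum-likelihood fit with a vanishingly small L2 ridge (1e-6) that
    also caps the coefficients under perfect separation; separable data are
    flagged.  Returns the coefficients and per-observation probabilities of
    the "same identity" class.
    """
    x = np.asarray(predictor_values, dtype=float).reshape(-1, 1)
    y = np.asarray(same_identity, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both identity classes must be present")
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10000, tol=1e-12)
    clf.fit(x, y)
    slope = float(clf.coef_[0, 0])
    intercept = float(clf.intercept_[0])
    probs = clf.predict_proba(x)[:, list(clf.classes_).index(1)]
    xf = x.ravel()
    if slope > 0:
        separable = xf[y == 1].min() > xf[y == 0].max()
    elif slope < 0:
        separable = xf[y == 1].max() < xf[y == 0].min()
    else:
        separable = False
    return LogisticFit(intercept=intercept, slope=slope, probabilities=probs, separable=bool(separable))


def roc_auc(scores, labels, thresholds=None, name: str = "") -> RocResult:
    """ROC curve over a threshold grid and its trapezoidal AUC.

    ``scores`` live in [0, 1] (classifier probabilities); an observation is
    called positive when its score >= threshold.  The grid defaults to 101
    evenly spaced thresholds in [0, 1], augmented above 1 so the curve
    reaches (0, 0).  Linear interpolation between ROC points gives tied
    scores half credit, matching the rank-statistic convention
    AUC = P(s+ > s-) + P(s+ = s-)/2 as the grid becomes dense.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    t = np.sort(np.unique(np.append(np.asarray(thresholds, dtype=float), 1.0 + 1e-9)))[::-1]
    pos, neg = s[y == 1], s[y == 0]
    tpr = np.array([(pos >= ti).mean() for ti in t])
    fpr = np.array([(neg >= ti).mean() for ti in t])
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(name=name, thresholds=t, fpr=fpr, tpr=tpr, auc=auc)


def _pair_predictors(design: GeometricDesign) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "euclidean": [g.euclidean for g in design],
            "theta": [g.theta_deg for g in design],
            "abs_radius_diff": [abs(g.r2 - g.r1) for g in design],
        },
        index=pd.Index(design.pair_ids, name="pair_id"),
    )


def identity_auc_comparison(
    dataset: JudgmentDataset,
    design: GeometricDesign,
    per_participant: bool = False,
    thresholds=None,
) -> tuple[pd.DataFrame, dict]:
    """AUC of each geometric predictor for the same/different judgments.

    Judgments are pooled across participants and sessions by default (a
    per-participant variant averages AUCs instead).  Returns a summary table
    (predictor, auc, n_same, n_different) and the per-predictor RocResult
    objects (pooled mode only).
    """
    feats = _pair_predictors(design)
    df = dataset.frame.merge(feats, left_on="pair_id", right_index=True, how="left")
    if df[list(PREDICTORS)].isna().any().any():
        raise ValueError("dataset contains pairs absent from the design")
    rows, curves = [], {}
    for pred in PREDICTORS:
        if per_participant:
            aucs = []
            for _, sub in df.groupby("participant_id"):
                fit = fit_identity_classifier(sub[pred], sub["same_identity"])
                aucs.append(
                    roc_auc(fit.probabilities, sub["same_identity"], thresholds, name=pred).auc
                )
            auc = float(np.mean(aucs))
        else:
            fit = fit_identity_classifier(df[pred], df["same_identity"])
            roc = roc_auc(fit.probabilities, df["same_identity"], thresholds, name=pred)
            curves[pred] = roc
            auc = roc.auc
        rows.append(
            {
                "predictor": pred,
                "auc": auc,
                "n_same": int(df["same_identity"].sum()),
                "n_different": int((1 - df["same_identity"]).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("predictor"), curves


def same_different_histogram(
    dataset: JudgmentDataset, values: pd.Series, n_bins: int = 10
) -> pd.DataFrame:
    """Counts of same- and different-identity judgments binned by a per-pair
    quantity (distance, angle, ...).  Total counts are conserved per
    participant by construction."""
    df = dataset.frame.merge(
        pd.Series(values, name="value"), left_on="pair_id", right_index=True
    )
    edges = np.linspace(df["value"].min(), df["value"].max(), n_bins + 1)
    df["bin"] = pd.cut(df["value"], edges, include_lowest=True)
    out = (
        df.groupby(["bin", "same_identity"], observed=False)
        .size()
        .unstack(fill_value=0)
        .rename(columns={0: "different", 1: "same"})
    )
    return out
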