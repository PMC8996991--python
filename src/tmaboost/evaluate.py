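"""Evaluation of core-level predictions: classification metrics, ROC, and
survival comparison of the predicted groups.

The positive class throughout is Effective (treatment worked).  Survival
analysis treats the binary model prediction as the grouping variable:
Kaplan-Meier curves and the log-rank test compare progression-free
survival between predicted-effective and predicted-invalid patients, and
a Cox proportional-hazards fit gives the adjusted hazard ratio of the
prediction (optionally alongside clinical covariates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import auc as sk_auc, roc_curve

__all__ = [
    "ConfusionCounts",
    "SurvivalRecord",
    "classification_metrics",
    "roc_auc",
    "km_logrank",
    "cox_ph",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positive class = Effective."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt, yp = np.asarray(y_true), np.asarray(y_pred)
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
        )


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time (months), event indicator (1 =
    progressed/died, 0 = censored) and predicted group (1 = effective)."""

    subject_id: str
    time: float
    event: int
    group: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1) or self.group not in (0, 1):
            raise ValueError("event and group must be binary")


def classification_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, precision, recall and F-measure from confusion counts.

    Ratios with an empty denominator are reported as None (absent), never
    silently as 0.  Values carry full precision; round to 2 decimals for
    tabulation.
    """
    if counts.total == 0:
        raise ValueError("no evaluated cores")
    acc = (counts.tp + counts.tn) / counts.total
    prec = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if prec is not None and rec is not None and (prec + rec) > 0:
        f = 2 * prec * rec / (prec + rec)
    else:
        f = None
    return {"accuracy": acc, "precision": prec, "recall": rec, "f_measure": f}


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, pd.DataFrame]:
    """ROC curve and AUC of core scores against true outcomes.

    AUC is the trapezoidal area under the ROC swept over all score
    thresholds, which equals the probability a random Effective core
    outscores a random Invalid one with half credit for ties.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    return float(sk_auc(fpr, tpr)), pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _records_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
        }
    )


def km_logrank(records: Sequence[SurvivalRecord]) -> dict:
    """Kaplan-Meier curves per predicted group plus the two-sample
    log-rank test (1-df chi-square).

    Returns ``{"curves": {group: DataFrame(time, survival, at_risk)},
    "chi2": float, "p": float}``.
    """
    df = _records_frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("log-rank comparison needs exactly two non-empty groups")
    if df["event"].sum() == 0:
        raise ValueError("no events observed; survival comparison undefined")
    curves = {}
    for g in groups:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=f"group_{g}")
        ev = kmf.event_table
        curves[int(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.values,
                "survival": kmf.survival_function_.iloc[:, 0].values,
                "at_risk": ev["at_risk"].reindex(kmf.survival_function_.index).values,
            }
        )
    a, b = (df[df["group"] == g] for g in groups)
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return {"curves": curves, "chi2": float(res.test_statistic), "p": float(res.p_value)}


def cox_ph(
    records: Sequence[SurvivalRecord],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit of the predicted group (plus optional
    clinical covariates) against the event hazard.

    Returns one row per covariate with the hazard ratio ``exp(coef)``,
    its 95% CI and p-value.  Delegates the partial-likelihood fit to
    lifelines; degenerate designs (zero-variance columns) are rejected
    up front, and non-convergence propagates as an error rather than a
    silent result.
    """
    df = _records_frame(records).drop(columns=["subject_id"])
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        df = pd.concat([df.reset_index(drop=True), covariates], axis=1)
    design = df.drop(columns=["time", "event"])
    for col in design.columns:
        if np.isclose(design[col].var(), 0.0):
            raise ValueError(f"zero-variance covariate {col!r}")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    out = cph.summary[["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    return out.rename(
        columns={
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "hr_lo",
            "exp(coef) upper 95%": "hr_hi",
        }
    )
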