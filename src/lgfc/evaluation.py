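"""Threshold metrics, ROC/PR curves, and the random-forest
feature-combination ranking harness.

Metric formulas (on confusion counts TP/FP/TN/FN):

    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1  = 2*TP / (2*TP + FP + FN)
    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    PPV = TP / (TP + FP)

MCC is defined as 0 (flagged) when any denominator factor vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    acc: float
    mcc: float
    f1: float
    sn: float
    sp: float
    ppv: float
    auroc: float | None = None
    auprc: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "acc": self.acc, "mcc": self.mcc, "f1": self.f1, "sn": self.sn,
            "sp": self.sp, "ppv": self.ppv, "auroc": self.auroc,
            "auprc": self.auprc, "flags": self.flags,
        }


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with predicted-positive meaning score >= threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from confusion counts (curve fields left unset)."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    flags = []
    if c.total == 0:
        raise ValueError("empty confusion table")
    if tp + fn == 0 or tn + fp == 0:
        flags.append("single-class")

    acc = (tp + tn) / c.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
        flags.append("mcc-zero-denominator")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    return MetricsReport(acc=acc, mcc=mcc, f1=f1, sn=sn, sp=sp, ppv=ppv, flags=flags)


def roc_pr(labels, scores) -> tuple[float, float, dict[str, np.ndarray]]:
    """AUROC (trapezoidal, equal scores grouped) and AUPRC (step-wise).

    Returns ``(auroc, auprc, curves)`` where ``curves`` holds the fpr/tpr and
    precision/recall point arrays.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to draw curves")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    auroc = float(_sk_auc(fpr, tpr))
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    auprc = float(average_precision_score(labels, scores))
    curves = {
        "fpr": fpr, "tpr": tpr, "roc_thresholds": roc_thr,
        "precision": precision, "recall": recall, "pr_thresholds": pr_thr,
    }
    return auroc, auprc, curves


def evaluate_scores(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold metrics plus curve areas."""
    report = metrics(confusion(labels, scores, threshold))
    try:
        report.auroc, report.auprc, _ = roc_pr(labels, scores)
    except ValueError:
        report.flags.append("curves-undefined")
    return report


# --------------------------------------------------------------------------
# random-forest feature-combination ranking
# --------------------------------------------------------------------------

EncoderFn = Callable[[str], np.ndarray]


@dataclass
class CombinationRanking:
    """Mean CV accuracy per (lncRNA encoder, protein encoder) combination."""

    matrix: pd.DataFrame  # rows: lnc encoders, cols: prot encoders
    lnc_ranking: list[str]  # lnc encoders by descending row mean
    prot_ranking: list[str]  # prot encoders by descending column mean

    def top(self, side: str, k: int = 3) -> list[str]:
        ranking = self.lnc_ranking if side == "lnc" else self.prot_ranking
        return ranking[:k]


def rank_feature_combinations(
    dataset,
    lnc_encoders: Mapping[str, EncoderFn],
    prot_encoders: Mapping[str, EncoderFn],
    rf_params: dict | None = None,
    cv: int = 5,
    seed: int = 0,
) -> CombinationRanking:
    """Rank encoder combinations by mean random-forest CV accuracy.

    Every (lnc, prot) encoder pair is scored by fitting a random forest on
    the concatenated per-pair features under seeded stratified CV.  A failing
    encoder marks its matrix cells NaN and the run continues.
    """
    if not lnc_encoders or not prot_encoders:
        raise ValueError("need at least one encoder per side")
    rf_params = {"n_estimators": 500, "n_jobs": 1, **(rf_params or {})}
    labels = dataset.labels

    lnc_feats = {}
    for name, fn in lnc_encoders.items():
        try:
            lnc_feats[name] = {
                sid: np.asarray(fn(dataset.registry[sid].seq), dtype=float)
                for sid in dataset.lnc_ids()
            }
        except Exception:
            lnc_feats[name] = None
    prot_feats = {}
    for name, fn in prot_encoders.items():
        try:
            prot_feats[name] = {
                sid: np.asarray(fn(dataset.registry[sid].seq), dtype=float)
                for sid in dataset.prot_ids()
            }
        except Exception:
            prot_feats[name] = None

    matrix = pd.DataFrame(
        np.nan, index=list(lnc_encoders), columns=list(prot_encoders), dtype=float
    )
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    for lname in lnc_encoders:
        if lnc_feats[lname] is None:
            continue
        lmat = np.stack([lnc_feats[lname][lnc] for lnc, _, _ in dataset.pairs])
        for pname in prot_encoders:
            if prot_feats[pname] is None:
                continue
            pmat = np.stack([prot_feats[pname][prot] for _, prot, _ in dataset.pairs])
            X = np.hstack([lmat, pmat])
            clf = RandomForestClassifier(random_state=seed, **rf_params)
            try:
                scores = cross_val_score(clf, X, labels, cv=skf, scoring="accuracy")
                matrix.loc[lname, pname] = float(np.mean(scores))
            except Exception:
                pass

    lnc_ranking = list(matrix.mean(axis=1).sort_values(ascending=False).index)
    prot_ranking = list(matrix.mean(axis=0).sort_values(ascending=False).index)
    return CombinationRanking(matrix=matrix, lnc_ranking=lnc_ranking, prot_ranking=prot_ranking)
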