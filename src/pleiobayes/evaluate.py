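"""Validation metrics: confusion summaries, Mann-Whitney AUC, DeLong CI,
and model-composition-by-rank curves.

Phenotype value 2 is the positive (case) class everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AssociationModel
from .search import RankedSNPList

_Z = {0.95: 1.959963984540054, 0.90: 1.6448536269514722, 0.99: 2.5758293035489004}


@dataclass
class ConfusionSummary:
    sensitivity: float
    specificity: float
    accuracy: float
    mean_sens_spec: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def confusion_metrics(predicted: np.ndarray, truth: np.ndarray) -> ConfusionSummary:
    """Standard confusion-matrix rates with class 2 as positive."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth lengths differ")
    tp = int(np.sum((predicted == 2) & (truth == 2)))
    fn = int(np.sum((predicted == 1) & (truth == 2)))
    tn = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 2) & (truth == 1)))
    pos, neg = tp + fn, tn + fp
    sens = tp / pos if pos else np.nan
    spec = tn / neg if neg else np.nan
    return ConfusionSummary(
        sensitivity=sens,
        specificity=spec,
        accuracy=(tp + tn) / len(truth),
        mean_sens_spec=(sens + spec) / 2.0,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def mean_sens_spec(sensitivity: float, specificity: float) -> float:
    """(sensitivity + specificity) / 2, the linear transform (J + 1)/2 of
    Youden's J used for unbalanced phenotypes."""
    return (sensitivity + specificity) / 2.0


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic: P(case score > control score),
    ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    cases = scores[labels == 2]
    controls = scores[labels == 1]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([cases, controls]))
    m = len(cases)
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(u / (m * len(controls)))


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: per-case fraction of controls it beats (ties
    half) and the mirrored per-control values."""
    order = np.argsort(controls, kind="stable")
    sc = controls[order]
    lo = np.searchsorted(sc, cases, side="left")
    hi = np.searchsorted(sc, cases, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / len(controls)
    order = np.argsort(cases, kind="stable")
    ss = cases[order]
    lo = np.searchsorted(ss, controls, side="left")
    hi = np.searchsorted(ss, controls, side="right")
    v01 = 1.0 - (lo + 0.5 * (hi - lo)) / len(cases)
    return v10, v01


def delong_ci(
    scores: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """DeLong normal-approximation confidence interval for the AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    cases = scores[labels == 2]
    controls = scores[labels == 1]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("DeLong CI needs at least 2 cases and 2 controls")
    v10, v01 = _placements(cases, controls)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(cases) + v01.var(ddof=1) / len(controls)
    z = _Z.get(level)
    if z is None:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    cases, controls = scores[labels == 2], scores[labels == 1]
    v10, v01 = _placements(cases, controls)
    return float(v10.var(ddof=1) / len(cases) + v01.var(ddof=1) / len(controls))


#: composition categories, in output order
COMPOSITION_CATEGORIES = (
    "pleiotropic_correct",
    "da_correct",
    "db_correct",
    "causal_mismodeled",
    "non_causal",
)

_CORRECT_MODEL = {
    "both": AssociationModel.Mab,
    "a": AssociationModel.Ma,
    "b": AssociationModel.Mb,
}


def composition_by_rank(
    ranked: RankedSNPList, truth: dict[int, str | None]
) -> pd.DataFrame:
    """Model-composition fractions of each nested set Sigma_r.

    ``truth`` maps SNP index to its causal type: "both" (pleiotropic), "a"
    (Da-only), "b" (Db-only), or None (non-causal).  Returns one row per rank
    with the cumulative category fractions (summing to 1) and the per-rank
    causal indicator (the color-bar statistic).
    """
    rows = []
    tallies = dict.fromkeys(COMPOSITION_CATEGORIES, 0)
    for r, a in enumerate(ranked.assignments, start=1):
        if a.snp_index not in truth:
            raise KeyError(f"truth missing for ranked SNP index {a.snp_index}")
        kind = truth[a.snp_index]
        if kind is None:
            tallies["non_causal"] += 1
        elif _CORRECT_MODEL[kind] is a.model:
            tallies[
                {"both": "pleiotropic_correct", "a": "da_correct", "b": "db_correct"}[kind]
            ] += 1
        else:
            tallies["causal_mismodeled"] += 1
        row = {"r": r, "rank_causal": int(kind is not None)}
        row.update({k: v / r for k, v in tallies.items()})
        rows.append(row)
    return pd.DataFrame(rows, columns=["r", "rank_causal", *COMPOSITION_CATEGORIES])
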