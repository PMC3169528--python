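"""Concordance between metabolic-reconstruction predictions and observed growth.

A compound is a true positive when the reconstruction encodes a complete
degradation pathway for it and the growth screen calls it a substrate; a
true negative when neither holds; false positives and negatives are the
mismatches, named with respect to the prediction. Six metrics (precision,
recall, false-positive rate, false-negative rate, specificity, accuracy)
summarize each model version, and delta-by-refinement is the refined
minus initial value of each metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

METRICS = ["precision", "recall", "false_positive_rate", "false_negative_rate",
           "specificity", "accuracy"]


@dataclass
class ConcordanceReport:
    TP: int
    FP: int
    TN: int
    FN: int
    model_version: str = ""

    @property
    def n_compounds(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else math.nan

    @property
    def precision(self) -> float:
        return self._ratio(self.TP, self.TP + self.FP)

    @property
    def recall(self) -> float:
        return self._ratio(self.TP, self.TP + self.FN)

    @property
    def false_positive_rate(self) -> float:
        return self._ratio(self.FP, self.FP + self.TN)

    @property
    def false_negative_rate(self) -> float:
        return self._ratio(self.FN, self.FN + self.TP)

    @property
    def specificity(self) -> float:
        return self._ratio(self.TN, self.TN + self.FP)

    @property
    def accuracy(self) -> float:
        return self._ratio(self.TP + self.TN, self.n_compounds)

    def metrics(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}

    def to_frame(self) -> pd.DataFrame:
        row = {"model_version": self.model_version, "TP": self.TP, "FP": self.FP,
               "TN": self.TN, "FN": self.FN, "n_compounds": self.n_compounds}
        row.update(self.metrics())
        return pd.DataFrame([row])


def confusion(
    predictions: pd.DataFrame,
    calls: pd.Series,
    compound_set: list[str] | None = None,
    model_version: str | None = None,
    exclude_unannotated: bool = False,
) -> ConcordanceReport:
    """Confusion counts and metrics for one model version against growth calls.

    ``predictions`` has columns (compound, predicted_degradable) and
    optionally model_version; ``calls`` maps compound -> bool (growth).
    Compounds absent from the prediction table are treated as
    predicted-non-degradable (no annotated pathway) unless
    ``exclude_unannotated`` drops them from the comparison instead.
    Undefined ratios (zero denominator) are reported as NaN, never 0.
    """
    pred = predictions
    if "model_version" in pred.columns and model_version is not None:
        pred = pred[pred["model_version"] == model_version]
    if pred["compound"].duplicated().any():
        dups = pred.loc[pred["compound"].duplicated(), "compound"].tolist()
        raise ValueError(f"duplicate predictions for compounds: {dups}")
    pred_map = dict(zip(pred["compound"], pred["predicted_degradable"].astype(bool)))

    if compound_set is None:
        compound_set = sorted(calls.index)
    missing_calls = [c for c in compound_set if c not in calls.index]
    if missing_calls:
        raise ValueError(f"compounds missing a growth call: {missing_calls}")
    if exclude_unannotated:
        compound_set = [c for c in compound_set if c in pred_map]
    else:
        missing_pred = [c for c in compound_set if c not in pred_map]
        for c in missing_pred:
            pred_map[c] = False

    tp = fp = tn = fn = 0
    for c in compound_set:
        p, g = pred_map[c], bool(calls[c])
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return ConcordanceReport(TP=tp, FP=fp, TN=tn, FN=fn,
                             model_version=model_version or "")


def delta_by_refinement(
    refined: ConcordanceReport, initial: ConcordanceReport
) -> dict[str, float]:
    """Refined-minus-initial difference of each concordance metric."""
    if refined.n_compounds != initial.n_compounds:
        raise ValueError(
            f"reports cover different compound sets "
            f"({refined.n_compounds} vs {initial.n_compounds} compounds)"
        )
    r, i = refined.metrics(), initial.metrics()
    return {m: r[m] - i[m] for m in METRICS}
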