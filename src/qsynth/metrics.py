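"""Validation metrics for synthetic questionnaire data.

Three views of fidelity are provided: a per-label classification report
(precision / recall / F1 / support with macro and support-weighted
averages), the signed mean error of questionnaire totals (how much the
generator over- or under-scores overall), and a two-sample t-test comparing
the per-question answer-sum series of real versus synthetic data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationReport",
    "EvaluationReport",
    "classification_report",
    "mean_error",
    "sum_ttest",
    "evaluate_cascade",
]


@dataclass
class ClassificationReport:
    """Per-label precision/recall/F1/support plus accuracy and averages."""

    labels: list[int]
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    support: dict[int, int]
    accuracy: float

    @property
    def n(self) -> int:
        return sum(self.support.values())

    @property
    def macro_avg(self) -> dict[str, float]:
        k = len(self.labels)
        return {
            "precision": sum(self.precision.values()) / k,
            "recall": sum(self.recall.values()) / k,
            "f1": sum(self.f1.values()) / k,
        }

    @property
    def weighted_avg(self) -> dict[str, float]:
        n = self.n
        return {
            m: sum(getattr(self, m)[l] * self.support[l] for l in self.labels) / n
            for m in ("precision", "recall", "f1")
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": str(l),
                "precision": self.precision[l],
                "recall": self.recall[l],
                "f1-score": self.f1[l],
                "support": self.support[l],
            }
            for l in self.labels
        ]
        rows.append({"label": "accuracy", "precision": np.nan, "recall": np.nan,
                     "f1-score": self.accuracy, "support": self.n})
        for name, avg in (("macro avg", self.macro_avg), ("weighted avg", self.weighted_avg)):
            rows.append({"label": name, "precision": avg["precision"],
                         "recall": avg["recall"], "f1-score": avg["f1"], "support": self.n})
        return pd.DataFrame(rows).set_index("label")

    def __str__(self) -> str:
        return self.to_frame().round(2).to_string()


def classification_report(y_true, y_pred, labels=None) -> ClassificationReport:
    """Multiclass classification report.

    precision_i = TP_i / (TP_i + FP_i) and recall_i = TP_i / (TP_i + FN_i)
    (0 where undefined); F1 is their harmonic mean; accuracy is the fraction
    of exact matches.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be non-empty and aligned")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = [int(l) for l in labels]
    observed = set(np.unique(np.concatenate([y_true, y_pred])).tolist())
    if not observed <= set(labels):
        raise ValueError(f"labels {sorted(labels)} do not cover observed values {sorted(observed)}")

    from sklearn.metrics import precision_recall_fscore_support

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f, s = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0
        )
    return ClassificationReport(
        labels=labels,
        precision={l: float(v) for l, v in zip(labels, p)},
        recall={l: float(v) for l, v in zip(labels, r)},
        f1={l: float(v) for l, v in zip(labels, f)},
        support={l: int(v) for l, v in zip(labels, s)},
        accuracy=float((y_true == y_pred).mean()),
    )


def mean_error(real, synthetic) -> float:
    """Signed percentage difference of questionnaire grand totals.

    100 * (sum(synthetic) - sum(real)) / sum(real); negative means the
    generator under-scores relative to the real cohort.
    """
    real = np.asarray(real, dtype=float)
    synthetic = np.asarray(synthetic, dtype=float)
    if real.shape != synthetic.shape:
        raise ValueError(f"shape mismatch {real.shape} vs {synthetic.shape}")
    if np.isnan(real).any() or np.isnan(synthetic).any():
        raise ValueError("blocks must not contain missing entries")
    total = real.sum()
    if total == 0:
        logger.warning("mean_error undefined: real block totals zero")
        return float("nan")
    return float(100.0 * (synthetic.sum() - total) / total)


def sum_ttest(real, synthetic, paired: bool = False) -> float:
    """Two-sided t-test on the per-question answer-sum series.

    Each question's answers are summed over records, giving one series per
    block (length = number of questions); the real and synthetic series are
    compared with Welch's two-sample t-test (or a paired t-test).  Identical
    series give p = 1 by convention; two constant but different series give
    p = 0 with a warning.
    """
    real = np.asarray(real, dtype=float)
    synthetic = np.asarray(synthetic, dtype=float)
    if real.shape != synthetic.shape or real.ndim != 2:
        raise ValueError("real and synthetic must be equal-shape records x items blocks")
    if real.shape[1] < 2:
        raise ValueError("need at least 2 items to form the sum series")
    a = real.sum(axis=0)
    b = synthetic.sum(axis=0)
    if np.array_equal(a, b):
        return 1.0
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        logger.warning("sum_ttest: both series constant with unequal means; p = 0 by convention")
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if paired:
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 0.0 if np.isnan(p) else p


@dataclass
class EvaluationReport:
    """Per-step fidelity summary shaped like the final-model results table.

    Per-step accuracy/precision/recall/F1 pool every (record, question)
    decision of the step's target questionnaire (precision/recall/F1 are the
    support-weighted averages over pooled answer labels); mean_error and t_p
    compare questionnaire totals and per-question sum series.
    """

    steps: list[str]
    records: list[int]
    accuracy: list[float]
    precision: list[float]
    recall: list[float]
    f1: list[float]
    mean_error: list[float]
    t_p: list[float]
    reports: list[ClassificationReport] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Accuracy": self.accuracy,
                "Precision": self.precision,
                "Recall": self.recall,
                "F1 score": self.f1,
                "Mean error (%)": self.mean_error,
                "t-student (p)": self.t_p,
                "records": self.records,
            },
            index=pd.Index(
                [f"STEP {i + 1} ({q})" for i, q in enumerate(self.steps)], name="step"
            ),
        ).T

    def __str__(self) -> str:
        return self.to_frame().round(3).to_string()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def evaluate_cascade(model, cohort: CohortTable, mode: str = "argmax", seed: int = 0) -> EvaluationReport:
    """Evaluate a fitted cascade against a cohort's real blocks, step by step.

    For each step, the records with both the cascade's input block and the
    step's real target block are synthesized end-to-end from the input
    questionnaire and compared with the real target block.
    """
    from .cascade import generate

    schema = model.schema
    input_q = model.order[0]
    steps, records, acc, prec, rec, f1s, merr, tps, reports = [], [], [], [], [], [], [], [], []
    for spec in model.steps:
        target = schema.questionnaire(spec.target_questionnaire)
        ids = cohort.records_with([input_q, target.name])
        if len(ids) == 0:
            raise ValueError(f"no records with both {input_q} and {target.name} blocks")
        sf36 = cohort.values.loc[ids, schema.block_columns(input_q)]
        synth = generate(model, sf36, mode=mode, seed=seed)
        y_pred = synth[target.columns].to_numpy(dtype=int)
        y_true = cohort.values.loc[ids, target.columns].to_numpy(dtype=float).astype(int)
        report = classification_report(
            y_true.ravel(), y_pred.ravel(),
            labels=range(target.answer_min, target.answer_max + 1),
        )
        steps.append(target.name)
        records.append(len(ids))
        acc.append(report.accuracy)
        prec.append(report.weighted_avg["precision"])
        rec.append(report.weighted_avg["recall"])
        f1s.append(report.weighted_avg["f1"])
        merr.append(mean_error(y_true, y_pred))
        tps.append(sum_ttest(y_true, y_pred))
        reports.append(report)
    logger.info("evaluation pooled all (record, question) decisions per step; "
                "precision/recall/F1 are support-weighted label averages")
    return EvaluationReport(steps, records, acc, prec, rec, f1s, merr, tps, reports)
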