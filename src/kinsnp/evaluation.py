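"""Scoring of kinship inferences against simulation truth.

An inference is correct when its degree ordinal equals the true degree
(relationships within a degree are interchangeable).  Abstentions count as
incorrect.  The unrelated class uses ordinal 10 throughout the margin
arithmetic and is rendered as "unrelated" in reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship_methods import InferenceResult
from .pedigree_sim import UNRELATED_ORDINAL

__all__ = [
    "results_frame",
    "degree_accuracy",
    "collapse_unrelated",
    "margin_roc",
    "evaluation_report",
    "EvaluationReport",
]


def results_frame(results: list[InferenceResult]) -> pd.DataFrame:
    """Tabulate InferenceResults (one method) into a scoring frame."""
    return pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in results],
            "method": [r.method for r in results],
            "relationship": [r.relationship for r in results],
            "degree": [np.nan if r.degree is None else r.degree for r in results],
            "score": [np.nan if r.score is None else r.score for r in results],
            "abstained": [r.abstained for r in results],
        }
    )


def _join_truth(results: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    merged = results.merge(
        truth[["pair_id", "degree"]].rename(columns={"degree": "true_degree"}),
        on="pair_id",
        how="left",
    )
    if merged["true_degree"].isna().any():
        missing = merged.loc[merged["true_degree"].isna(), "pair_id"].iloc[0]
        raise KeyError(f"pair {missing!r} has no truth row")
    return merged


def degree_accuracy(results: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    """Fraction of pairs per true degree whose inferred degree matches.

    Abstentions (NaN inferred degree) are incorrect.  Index is the true
    degree ordinal; unrelated appears as ordinal 10.
    """
    merged = _join_truth(results, truth)
    correct = merged["degree"] == merged["true_degree"]
    return correct.groupby(merged["true_degree"]).mean()


def collapse_unrelated(
    results: pd.DataFrame, cutoff_degree: int = 6
) -> pd.DataFrame:
    """Relabel inferences of ``cutoff_degree`` or more distant as unrelated."""
    out = results.copy()
    mask = out["degree"] >= cutoff_degree
    out.loc[mask, "degree"] = UNRELATED_ORDINAL
    out.loc[mask, "relationship"] = "unrelated"
    return out


def margin_roc(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    margins: range = range(0, 6),
) -> tuple[pd.DataFrame, float]:
    """Margin-sweep ROC: tolerance of ±t degrees as the moving threshold.

    For margin t, TPR(t) is the fraction of truly related pairs inferred
    within t degrees of truth, and FPR(t) the fraction of truly unrelated
    pairs inferred closer than t degrees from unrelated (an alarm).
    Points are augmented with (0,0) and (1,1); AUROC is the trapezoid over
    FPR-sorted points.  Abstentions never count as within-margin and never
    raise an alarm.
    """
    merged = _join_truth(results, truth)
    related = merged["true_degree"] < UNRELATED_ORDINAL
    if not (~related).any():
        raise ValueError("ROC undefined without unrelated pairs")
    if not related.any():
        raise ValueError("ROC undefined without related pairs")
    rows = []
    dev = (merged["degree"] - merged["true_degree"]).abs()
    for t in margins:
        tpr = float((dev[related] <= t).mean())
        alarm = merged.loc[~related, "degree"] < UNRELATED_ORDINAL - t
        fpr = float(alarm.fillna(False).mean())
        rows.append((t, fpr, tpr))
    pts = pd.DataFrame(rows, columns=["margin", "fpr", "tpr"])
    xs = np.concatenate(([0.0], pts["fpr"].to_numpy(), [1.0]))
    ys = np.concatenate(([0.0], pts["tpr"].to_numpy(), [1.0]))
    order = np.lexsort((ys, xs))
    auroc = float(np.trapezoid(ys[order], xs[order]))
    return pts, auroc


@dataclass
class EvaluationReport:
    """Bundled per-method evaluation, serialisable to JSON."""

    accuracy: dict[str, dict[int, float]]
    confusion: dict[str, pd.DataFrame]
    roc: dict[str, pd.DataFrame]
    auroc: dict[str, float]
    abstentions: dict[str, int]
    options: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "options": self.options,
            "accuracy": {
                m: {str(k): v for k, v in acc.items()}
                for m, acc in self.accuracy.items()
            },
            "auroc": self.auroc,
            "abstentions": self.abstentions,
            "roc": {m: df.to_dict(orient="list") for m, df in self.roc.items()},
            "confusion": {
                m: {str(k): df[k].to_dict() for k in df.columns}
                for m, df in self.confusion.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def evaluation_report(
    results_by_method: dict[str, pd.DataFrame],
    truth: pd.DataFrame,
    collapse: bool = False,
    cutoff_degree: int = 6,
) -> EvaluationReport:
    """Accuracy, confusion, ROC and abstention counts per method."""
    if not results_by_method or all(len(df) == 0 for df in results_by_method.values()):
        raise ValueError("no inference results to evaluate")
    accuracy, confusion, roc, auroc, abst = {}, {}, {}, {}, {}
    for method, df in results_by_method.items():
        if collapse:
            df = collapse_unrelated(df, cutoff_degree)
        merged = _join_truth(df, truth)
        accuracy[method] = degree_accuracy(df, truth).to_dict()
        confusion[method] = pd.crosstab(
            merged["true_degree"], merged["degree"], dropna=False
        )
        pts, a = margin_roc(df, truth)
        roc[method], auroc[method] = pts, a
        abst[method] = int(df["abstained"].sum())
    return EvaluationReport(
        accuracy=accuracy,
        confusion=confusion,
        roc=roc,
        auroc=auroc,
        abstentions=abst,
        options={"collapse": collapse, "cutoff_degree": cutoff_degree},
    )
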