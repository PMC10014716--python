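"""Accuracy, explained variance and the cross-country transfer harness.

Implements the discrimination and calibration summaries used to judge the
country networks — Mann–Whitney AUC, predictive values at a posterior
threshold, Nagelkerke pseudo-R² — plus the train-on-one-country /
test-on-the-other evaluation (prediction shrinkage = within-sample AUC
minus out-of-sample AUC) and the risk/protective annotation of each
predictor from the direction of its bin-wise posterior trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import AnalysisTable
from .selection import FinalModel, ImportanceRanking, variable_importance
from .tan import TANResults

__all__ = [
    "auc",
    "ppv_npv",
    "nagelkerke_r2",
    "EvaluationReport",
    "evaluate_within",
    "cross_country_evaluate",
    "transfer_report",
    "annotate_directions",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    pass


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + ½ P(tie), via rank sums."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both outcome classes present")
    r = rankdata(scores)
    rank_sum_pos = float(r[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def ppv_npv(scores, labels, threshold: float = 0.5) -> tuple[float, float]:
    """Positive/negative predictive value with positive ⇔ score >= threshold.

    An empty predicted class yields NaN for the affected value (with a
    warning) rather than an exception, so reports stay completable.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    ppv = npv = float("nan")
    if pred.any():
        ppv = float(labels[pred].mean())
    else:
        warnings.warn("no predicted positives: PPV undefined")
    if (~pred).any():
        npv = float((1 - labels[~pred]).mean())
    else:
        warnings.warn("no predicted negatives: NPV undefined")
    return ppv, npv


def nagelkerke_r2(probs, y, warn: bool = True, clip: float = 0.0) -> float:
    """Nagelkerke pseudo-R² of predicted probabilities against a base-rate null.

    R²_CS = 1 − exp((2/n)(ℓ0 − ℓ1)) with ℓ1 the model log-likelihood and ℓ0
    that of the outcome base rate alone; the Nagelkerke form divides by its
    maximum 1 − exp((2/n)ℓ0).  A model beaten by the null reports 0.

    ``clip`` bounds each probability into [clip, 1-clip] before scoring.
    Product-form classifiers are overconfident, and on small held-out folds a
    handful of near-zero probabilities on observed outcomes can dominate ℓ1;
    clipping caps any single row's influence at |ln clip|.  The held-out
    importance scorer uses clip=0.01; headline R² values are unclipped.
    """
    probs = np.clip(np.asarray(probs, dtype=float), clip, 1.0 - clip if clip else 1.0)
    y = np.asarray(y)
    n = len(y)
    with np.errstate(divide="ignore"):
        ll1 = float(np.where(y == 1, np.log(probs), np.log1p(-probs)).sum())
    base = y.mean()
    if base in (0.0, 1.0):
        raise UndefinedMetricError("null model undefined for single-class outcome")
    ll0 = float(n * (base * np.log(base) + (1 - base) * np.log(1 - base)))
    if ll1 < ll0:
        if warn:
            warnings.warn("model log-likelihood below the null; reporting R2 = 0")
        return 0.0
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    max_cs = 1.0 - np.exp((2.0 / n) * ll0)
    return float(min(r2_cs / max_cs, 1.0))


# ------------------------------------------------------------- reporting

@dataclass
class EvaluationReport:
    """Within/out-of-sample accuracy of one trained country network."""

    auc_within: float
    auc_out: float | None
    ppv_within: float
    npv_within: float
    ppv_out: float | None
    npv_out: float | None
    nagelkerke: float
    threshold: float
    prevalence_within: float
    prevalence_out: float | None = None
    importance: ImportanceRanking | None = None
    directions: dict[str, dict] | None = None
    train_country: str | None = None
    test_country: str | None = None

    @property
    def shrinkage(self) -> float | None:
        if self.auc_out is None:
            return None
        return self.auc_within - self.auc_out

    def to_dict(self) -> dict:
        d = {
            "train_country": self.train_country,
            "test_country": self.test_country,
            "threshold": self.threshold,
            "auc_within": self.auc_within,
            "auc_out": self.auc_out,
            "shrinkage": self.shrinkage,
            "ppv_within": self.ppv_within,
            "npv_within": self.npv_within,
            "ppv_out": self.ppv_out,
            "npv_out": self.npv_out,
            "nagelkerke_r2": self.nagelkerke,
            "prevalence_within": self.prevalence_within,
            "prevalence_out": self.prevalence_out,
        }
        if self.importance is not None:
            d["importance"] = self.importance.as_frame().to_dict(orient="records")
        if self.directions is not None:
            d["directions"] = self.directions
        return d

    def metrics_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        rows = [(k, v) for k, v in d.items()
                if isinstance(v, (int, float)) or v is None]
        return pd.DataFrame(rows, columns=["metric", "value"])


def evaluate_within(results: TANResults, table: AnalysisTable,
                    threshold: float = 0.5, importance_seed: int = 0
                    ) -> EvaluationReport:
    """Within-sample-only report (no transfer half)."""
    scores = results.predict_proba(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ppv, npv = ppv_npv(scores, table.y, threshold)
    return EvaluationReport(
        auc_within=auc(scores, table.y), auc_out=None,
        ppv_within=ppv, npv_within=npv, ppv_out=None, npv_out=None,
        nagelkerke=nagelkerke_r2(scores, table.y, warn=False),
        threshold=threshold,
        prevalence_within=float(table.y.mean()),
        importance=variable_importance(results, table, seed=importance_seed),
        directions=annotate_directions(results, table),
    )


def cross_country_evaluate(results: TANResults, table_within: AnalysisTable,
                           table_out: AnalysisTable, threshold: float = 0.5,
                           importance_seed: int = 0) -> EvaluationReport:
    """Evaluate one fitted network within-sample and on the mapped other country.

    ``table_out`` must already be expressed in the training country's
    variable set and bins (the frozen training discretizer applied to the
    test country); unmapped levels surface as a validation error naming the
    offending column.
    """
    missing = [c for c in results.structure.predictors
               if c not in table_out.columns]
    if missing:
        raise ValueError(f"test table lacks mapped variables {missing}")
    s_in = results.predict_proba(table_within)
    s_out = results.predict_proba(table_out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ppv_in, npv_in = ppv_npv(s_in, table_within.y, threshold)
        ppv_out, npv_out = ppv_npv(s_out, table_out.y, threshold)
    return EvaluationReport(
        auc_within=auc(s_in, table_within.y),
        auc_out=auc(s_out, table_out.y),
        ppv_within=ppv_in, npv_within=npv_in,
        ppv_out=ppv_out, npv_out=npv_out,
        nagelkerke=nagelkerke_r2(s_in, table_within.y, warn=False),
        threshold=threshold,
        prevalence_within=float(table_within.y.mean()),
        prevalence_out=float(table_out.y.mean()),
        importance=variable_importance(results, table_within,
                                       seed=importance_seed),
        directions=annotate_directions(results, table_within),
    )


def transfer_report(model: FinalModel, frame_within, frame_out,
                    threshold: float = 0.5, importance_seed: int = 0
                    ) -> EvaluationReport:
    """Convenience wrapper mapping the raw test-country frame through the
    training country's frozen discretizer before evaluation."""
    report = cross_country_evaluate(
        model.results, model.transform(frame_within),
        model.transform(frame_out), threshold=threshold,
        importance_seed=importance_seed)
    report.train_country = frame_within.country or model.country
    report.test_country = frame_out.country
    return report


# ------------------------------------------------------------- directions

#: tolerated backward step, as a fraction of the first-to-last trend, before
#: an ordered variable is called non-monotone
MONOTONE_TOLERANCE = 0.15


def annotate_directions(results: TANResults, table: AnalysisTable
                        ) -> dict[str, dict]:
    """Label each predictor risk / protective / non-monotone.

    The model posterior P(Y=1|x) is averaged within each bin of the variable
    (empirically marginalising the remaining predictors).  Ordered variables
    whose first-to-last difference is positive and whose bin trend is weakly
    monotone (backward steps under ``MONOTONE_TOLERANCE`` of the total trend
    tolerated) are risk factors; negative differences are protective;
    everything else — including unordered categoricals with more than two
    levels — is non-monotone.  The magnitude is reported so a flat trend can
    be recognised as such by the consumer.
    """
    scores = results.predict_proba(table)
    out = {}
    for v in results.structure.predictors:
        codes = table.column(v)
        meta = table.meta[v]
        L = table.n_levels(v)
        means = np.full(L, np.nan)
        for lev in range(L):
            mask = codes == lev
            if mask.any():
                means[lev] = scores[mask].mean()
        observed = means[~np.isnan(means)]
        diff = float(observed[-1] - observed[0]) if len(observed) >= 2 else 0.0
        if not meta.ordered and L > 2:
            label = "non-monotone"
        elif len(observed) < 2 or diff == 0.0:
            label = "non-monotone"
        else:
            steps = np.diff(observed)
            tol = MONOTONE_TOLERANCE * abs(diff)
            if diff > 0 and (steps >= -tol).all():
                label = "risk"
            elif diff < 0 and (steps <= tol).all():
                label = "protective"
            else:
                label = "non-monotone"
        out[v] = {
            "label": label,
            "difference": diff,
            "bin_posteriors": [None if np.isnan(m) else float(m) for m in means],
        }
    return out
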