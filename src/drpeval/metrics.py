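"""Overall, per-drug and per-cell scoring of drug-response predictions.

An overall correlation across all (cell, drug) pairs mostly rewards a
model for separating potent drugs from impotent ones; the clinically
relevant question — does the model rank *cell lines* correctly within one
drug? — is answered only by per-drug metrics. This module computes both,
plus the threshold-exceedance summary (fraction of drugs whose per-drug
Spearman exceeds a threshold, the number a waterfall plot annotates) and
the standard binary-task metric battery for sensitive/resistant calls.

Undefined values (too few pairs, zero variance, single-class truths)
propagate as NaN markers and are excluded from summary denominators —
never silently coerced to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .datasets import TripletDataset, as_prediction_table
from .dose_response import SensitivityCall

logger = logging.getLogger("drpeval")

OVERALL_METRICS = ("pcc", "scc", "rmse", "mae", "r2")


def _join(truth: TripletDataset, pred: pd.DataFrame) -> pd.DataFrame:
    """Inner-join truth and predictions on (cell, drug); log the losses."""
    pred = as_prediction_table(pred)
    merged = truth.df.merge(pred, on=["cell_id", "drug_id"], how="inner")
    n_truth_only = truth.n_pairs - len(merged)
    n_pred_only = len(pred) - len(merged)
    if n_truth_only or n_pred_only:
        logger.info(
            "metrics join: %d matched pairs; %d truth-only, %d prediction-only dropped",
            len(merged), n_truth_only, n_pred_only,
        )
    return merged


def _corrs(y: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """Pearson and Spearman (average-rank ties); NaN on zero variance."""
    if np.ptp(y) == 0.0 or np.ptp(p) == 0.0:
        return math.nan, math.nan
    pcc = float(stats.pearsonr(y, p).statistic)
    scc = float(stats.spearmanr(y, p).statistic)
    return pcc, scc


def overall_metrics(truth: TripletDataset, pred: pd.DataFrame) -> dict[str, float]:
    """PCC, SCC, RMSE, MAE and R^2 over the matched (cell, drug) pairs.

    Requires at least two matched pairs; zero-variance truth or
    predictions leave the correlations as NaN markers. ``n_pairs`` is
    included for reporting.
    """
    merged = _join(truth, pred)
    if len(merged) < 2:
        raise ValueError(
            f"need >= 2 matched (cell, drug) pairs to score; got {len(merged)}"
        )
    y = merged["response"].to_numpy()
    p = merged["predicted"].to_numpy()
    pcc, scc = _corrs(y, p)
    return {
        "pcc": pcc,
        "scc": scc,
        "rmse": float(skm.root_mean_squared_error(y, p)),
        "mae": float(skm.mean_absolute_error(y, p)),
        "r2": float(skm.r2_score(y, p)) if np.ptp(y) != 0.0 else math.nan,
        "n_pairs": float(len(merged)),
    }


def _per_entity(
    truth: TripletDataset, pred: pd.DataFrame, by: str, min_pairs: int
) -> pd.DataFrame:
    merged = _join(truth, pred)
    rows = []
    for entity, grp in merged.groupby(by, sort=False):
        n = len(grp)
        row = {by: entity, "n_pairs": n,
               "pcc": math.nan, "scc": math.nan, "rmse": math.nan}
        if n >= min_pairs:
            y = grp["response"].to_numpy()
            p = grp["predicted"].to_numpy()
            row["pcc"], row["scc"] = _corrs(y, p)
            row["rmse"] = float(skm.root_mean_squared_error(y, p))
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=[by, "n_pairs", "pcc", "scc", "rmse"])
    return pd.DataFrame(rows)


def per_drug_metrics(
    truth: TripletDataset, pred: pd.DataFrame, min_pairs: int = 3
) -> pd.DataFrame:
    """Metrics restricted to each drug's own cell-line pairs.

    Drugs with fewer than ``min_pairs`` matched pairs (default 3: a
    two-point Spearman is always +-1) are reported with their pair count
    and NaN metrics, never fabricated values.
    """
    return _per_entity(truth, pred, "drug_id", min_pairs)


def per_cell_metrics(
    truth: TripletDataset, pred: pd.DataFrame, min_pairs: int = 3
) -> pd.DataFrame:
    """Metrics restricted to each cell line's own drug pairs."""
    return _per_entity(truth, pred, "cell_id", min_pairs)


def fraction_above(
    table: pd.DataFrame, metric: str = "scc", threshold: float = 0.5
) -> float:
    """Fraction of scorable entities whose ``metric`` strictly exceeds ``threshold``.

    The denominator counts entities with a defined (non-NaN) metric only;
    returns NaN if none is scorable.
    """
    if metric not in table.columns:
        raise ValueError(f"no column {metric!r} in per-entity table")
    vals = table[metric].to_numpy(dtype=float)
    scorable = np.isfinite(vals)
    if not scorable.any():
        return math.nan
    return float((vals[scorable] > threshold).sum() / scorable.sum())


# ---------------------------------------------------------------------------
# Bundled report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Overall plus per-drug / per-cell tables with exceedance summary."""

    overall: dict[str, float]
    per_drug: pd.DataFrame
    per_cell: pd.DataFrame
    scc_threshold: float = 0.5

    @property
    def fraction_scc_above(self) -> float:
        return fraction_above(self.per_drug, "scc", self.scc_threshold)

    @property
    def n_scorable_drugs(self) -> int:
        return int(np.isfinite(self.per_drug["scc"].to_numpy(dtype=float)).sum())

    @property
    def n_unscorable_drugs(self) -> int:
        return len(self.per_drug) - self.n_scorable_drugs

    def summary(self) -> str:
        lines = ["Prediction evaluation", "---------------------"]
        for key in (*OVERALL_METRICS, "n_pairs"):
            lines.append(f"overall {key:>7}: {self.overall[key]:.4f}")
        frac = self.fraction_scc_above
        lines.append(
            f"drugs with per-drug SCC > {self.scc_threshold:g}: "
            f"{'undefined' if math.isnan(frac) else format(100 * frac, '.1f') + '%'} "
            f"({self.n_scorable_drugs} scorable, {self.n_unscorable_drugs} unscorable)"
        )
        if len(self.per_drug):
            med = np.nanmedian(self.per_drug["scc"].to_numpy(dtype=float))
            lines.append(f"median per-drug SCC: {med:.4f}")
        return "\n".join(lines)


def evaluate(
    truth: TripletDataset,
    pred: pd.DataFrame,
    min_pairs: int = 3,
    scc_threshold: float = 0.5,
) -> MetricReport:
    """One-call evaluation: overall + per-drug + per-cell + summary."""
    return MetricReport(
        overall=overall_metrics(truth, pred),
        per_drug=per_drug_metrics(truth, pred, min_pairs),
        per_cell=per_cell_metrics(truth, pred, min_pairs),
        scc_threshold=scc_threshold,
    )


# ---------------------------------------------------------------------------
# Binary-task metrics
# ---------------------------------------------------------------------------

@dataclass
class BinaryMetricReport:
    """Threshold and ranking metrics for sensitive/resistant classification.

    ``gm`` is the geometric mean sqrt(sen * spc); ``dor`` the diagnostic
    odds ratio (TP*TN)/(FP*FN) with a Haldane 0.5 continuity correction
    whenever a contingency cell is zero. Undefined quantities are NaN.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    acc: float
    sen: float
    spc: float
    pre: float
    f1: float
    fpr: float
    gm: float
    mcc: float
    auroc: float
    auprc: float
    dor: float
    n_undefined_calls: int = 0


def _safe_div(num: float, den: float) -> float:
    return num / den if den else math.nan


def contingency_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """Threshold metrics from a 2x2 contingency table."""
    sen = _safe_div(tp, tp + fn)
    spc = _safe_div(tn, tn + fp)
    pre = _safe_div(tp, tp + fp)
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    fpr = _safe_div(fp, fp + tn)
    gm = math.sqrt(sen * spc) if not (math.isnan(sen) or math.isnan(spc)) else math.nan
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else math.nan
    if min(tp, fn, fp, tn) == 0:
        tp_, fn_, fp_, tn_ = (v + 0.5 for v in (tp, fn, fp, tn))
    else:
        tp_, fn_, fp_, tn_ = float(tp), float(fn), float(fp), float(tn)
    dor = (tp_ * tn_) / (fp_ * fn_)
    return {
        "acc": acc, "sen": sen, "spc": spc, "pre": pre, "f1": f1,
        "fpr": fpr, "gm": gm, "mcc": mcc, "dor": dor,
    }


def binary_metrics(
    truth_calls: pd.DataFrame,
    scores: pd.DataFrame,
    positive_label: str = SensitivityCall.SENSITIVE.value,
    score_threshold: float = 0.5,
) -> BinaryMetricReport:
    """Score continuous predictions against sensitive/resistant calls.

    ``truth_calls`` has columns cell_id, drug_id, call; undefined calls
    are excluded and counted. ``scores`` is a prediction table whose
    values are oriented so that larger means more likely positive;
    predictions at or above ``score_threshold`` are called positive for
    the threshold metrics. AUROC/AUPRC are rank-based; a single-class
    truth leaves them NaN.
    """
    scores = as_prediction_table(scores)
    calls = truth_calls.copy()
    calls["call"] = calls["call"].astype(str)
    n_undef = int((calls["call"] == SensitivityCall.UNDEFINED.value).sum())
    calls = calls[calls["call"] != SensitivityCall.UNDEFINED.value]
    merged = calls.merge(scores, on=["cell_id", "drug_id"], how="inner")
    if merged.empty:
        raise ValueError("no matched sensitive/resistant pairs to score")
    y = (merged["call"] == positive_label).to_numpy()
    s = merged["predicted"].to_numpy()
    yhat = s >= score_threshold
    tp = int((y & yhat).sum())
    fn = int((y & ~yhat).sum())
    fp = int((~y & yhat).sum())
    tn = int((~y & ~yhat).sum())
    thr = contingency_metrics(tp, fn, fp, tn)
    if y.all() or not y.any():
        auroc = auprc = math.nan
    else:
        auroc = float(skm.roc_auc_score(y, s))
        auprc = float(skm.average_precision_score(y, s))
    return BinaryMetricReport(
        tp=tp, fn=fn, fp=fp, tn=tn, auroc=auroc, auprc=auprc,
        n_undefined_calls=n_undef, **thr,
    )
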