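"""Diagnostic plots: per-drug scatter, SCC waterfall, cross-dataset heatmap.

Each plotting function renders a matplotlib figure and, when given an
output path, writes the image together with a sidecar CSV holding the
exact numbers plotted. Tests and downstream tooling validate the sidecar
tables, not pixels.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; no display required

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datasets import TripletDataset, as_prediction_table
from .harmonization import CrossDatasetMatrix
from .metrics import fraction_above, per_drug_metrics

__all__ = ["plot_per_drug_scatter", "plot_waterfall", "plot_cross_dataset_heatmap"]


def _save(fig, sidecar: pd.DataFrame, path: str | Path | None):
    if path is not None:
        path = Path(path)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        sidecar.to_csv(path.with_suffix(".csv"), index=False)
        plt.close(fig)
    return fig, sidecar


def plot_per_drug_scatter(
    truth: TripletDataset,
    pred: pd.DataFrame,
    k_highlight: int = 2,
    min_pairs: int = 3,
    path: str | Path | None = None,
):
    """Predicted-vs-true scatter with best/worst per-drug trend lines.

    All pairs are drawn as gray background points; the ``k_highlight``
    drugs with the highest per-drug SCC get green least-squares trend
    lines and the ``k_highlight`` lowest get red ones, labelled with drug
    and SCC. Returns (figure, sidecar table of highlighted drugs).
    """
    table = per_drug_metrics(truth, pred, min_pairs=min_pairs)
    scorable = table.dropna(subset=["scc"]).sort_values("scc", ascending=False)
    if scorable.empty:
        raise ValueError("no scorable drug to highlight")
    k = min(k_highlight, len(scorable))
    best = scorable.head(k)
    worst = scorable.tail(k)
    merged = truth.df.merge(as_prediction_table(pred), on=["cell_id", "drug_id"])

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(merged["response"], merged["predicted"], s=8, c="0.7",
               label="_background")
    rows = []
    for sub, color in ((best, "tab:green"), (worst, "tab:red")):
        for _, r in sub.iterrows():
            grp = merged[merged["drug_id"] == r["drug_id"]]
            coeffs = np.polyfit(grp["response"], grp["predicted"], deg=1)
            xs = np.linspace(grp["response"].min(), grp["response"].max(), 20)
            ax.plot(xs, np.polyval(coeffs, xs), color=color, lw=2,
                    label=f"{r['drug_id']} (SCC={r['scc']:.2f})")
            rows.append({"drug_id": r["drug_id"], "scc": r["scc"],
                         "group": "best" if color == "tab:green" else "worst",
                         "slope": coeffs[0], "intercept": coeffs[1]})
    rtype = truth.response_type.value
    ax.set_xlabel(f"measured response ({rtype})")
    ax.set_ylabel(f"predicted response ({rtype})")
    ax.legend(fontsize=8)
    return _save(fig, pd.DataFrame(rows), path)


def plot_waterfall(
    per_drug: pd.DataFrame,
    metric: str = "scc",
    threshold: float = 0.5,
    path: str | Path | None = None,
):
    """Sorted per-drug metric bars with a threshold line.

    The annotation reports the fraction of scorable drugs strictly above
    the threshold; unscorable drugs are listed in the caption text.
    Returns (figure, sidecar table in plotted order).
    """
    frac = fraction_above(per_drug, metric, threshold)
    scorable = per_drug.dropna(subset=[metric]).sort_values(metric, ascending=False)
    unscorable = per_drug[per_drug[metric].isna()]
    fig, ax = plt.subplots(figsize=(max(6, 0.12 * len(scorable)), 4))
    ax.bar(np.arange(len(scorable)), scorable[metric], width=0.9, color="tab:blue")
    ax.axhline(threshold, color="k", ls="--", lw=1)
    pct = "undefined" if math.isnan(frac) else f"{100 * frac:.0f}%"
    ax.set_title(f"{pct} of drugs with {metric.upper()} > {threshold:g}")
    ax.set_xlabel("drugs (sorted)")
    ax.set_ylabel(metric.upper())
    if len(unscorable):
        fig.text(0.01, 0.01,
                 f"unscorable: {', '.join(map(str, unscorable['drug_id'].head(10)))}",
                 fontsize=7)
    sidecar = scorable.reset_index(drop=True).copy()
    sidecar["rank"] = np.arange(1, len(sidecar) + 1)
    sidecar["fraction_above"] = frac
    return _save(fig, sidecar, path)


def plot_cross_dataset_heatmap(
    matrix: CrossDatasetMatrix,
    path: str | Path | None = None,
):
    """Red-to-green heatmap of cross-dataset Spearman with n annotations.

    Undefined cells (overlap below the matrix's floor) render neutral
    gray with an "n<min" annotation. Returns (figure, sidecar long table
    of dataset_a, dataset_b, scc, n).
    """
    names = matrix.dataset_names
    vals = matrix.scc.to_numpy(dtype=float)
    counts = matrix.n_overlap.to_numpy()
    m = len(names)
    fig, ax = plt.subplots(figsize=(1.2 * m + 2, 1.0 * m + 1))
    masked = np.ma.masked_invalid(vals)
    cmap = plt.get_cmap("RdYlGn").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(masked, vmin=-1, vmax=1, cmap=cmap)
    ax.set_xticks(range(m), names, rotation=45, ha="right")
    ax.set_yticks(range(m), names)
    rows = []
    for i in range(m):
        for j in range(m):
            if np.isfinite(vals[i, j]):
                txt = f"{vals[i, j]:.2f}\nn={counts[i, j]}"
            else:
                txt = f"n<{matrix.min_overlap}"
            ax.text(j, i, txt, ha="center", va="center", fontsize=7)
            rows.append({"dataset_a": names[i], "dataset_b": names[j],
                         "scc": vals[i, j], "n": int(counts[i, j])})
    fig.colorbar(im, ax=ax, shrink=0.8, label="Spearman correlation")
    return _save(fig, pd.DataFrame(rows), path)
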