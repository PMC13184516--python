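"""Cross-dataset comparison of drug-response measurements.

Public pharmacogenomic screens disagree substantially even on shared
cell-drug pairs (different assays, ranges, summary statistics). Before
pooling screens for training, the rank agreement between every pair of
datasets should be inspected together with the number of matched pairs
backing it. This module matches pairs across datasets (after identifier
canonicalization and optional alias tables) and assembles the pairwise
Spearman matrix with overlap counts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import TripletDataset

logger = logging.getLogger("drpeval")

_NON_ALNUM = re.compile(r"[^0-9A-Z]+")


def canonical_id(raw: str) -> str:
    """Uppercase and strip non-alphanumerics: 'MCF-7' and 'mcf7' agree."""
    return _NON_ALNUM.sub("", str(raw).upper())


def _alias_mapper(alias: pd.DataFrame | dict | None) -> dict[str, str]:
    """Build canonical-raw -> canonical-target map; reject ambiguous tables."""
    if alias is None:
        return {}
    if isinstance(alias, dict):
        items = list(alias.items())
    else:
        if not {"raw", "canonical"} <= set(alias.columns):
            raise ValueError("alias table needs columns 'raw' and 'canonical'")
        items = list(zip(alias["raw"], alias["canonical"]))
    out: dict[str, str] = {}
    for raw, target in items:
        key = canonical_id(raw)
        val = canonical_id(target)
        if key in out and out[key] != val:
            raise ValueError(
                f"alias table maps {raw!r} to both {out[key]!r} and {val!r}"
            )
        out[key] = val
    return out


def _canonical_pairs(
    ds: TripletDataset,
    cell_map: dict[str, str],
    drug_map: dict[str, str],
) -> pd.DataFrame:
    df = ds.df[["cell_id", "drug_id", "response"]].copy()
    df["cell_key"] = df["cell_id"].map(lambda s: cell_map.get(canonical_id(s), canonical_id(s)))
    df["drug_key"] = df["drug_id"].map(lambda s: drug_map.get(canonical_id(s), canonical_id(s)))
    return df


@dataclass
class MatchedPairs:
    """Aligned response vectors for the pairs two datasets share."""

    values_a: np.ndarray
    values_b: np.ndarray
    n_unmatched_a: int
    n_unmatched_b: int

    @property
    def n(self) -> int:
        return len(self.values_a)

    def spearman(self) -> float:
        if self.n < 2 or np.ptp(self.values_a) == 0 or np.ptp(self.values_b) == 0:
            return math.nan
        return float(stats.spearmanr(self.values_a, self.values_b).statistic)


def match_pairs(
    a: TripletDataset,
    b: TripletDataset,
    cell_map: pd.DataFrame | dict | None = None,
    drug_map: pd.DataFrame | dict | None = None,
    allow_mixed: bool = False,
) -> MatchedPairs:
    """Inner-join two datasets on canonicalized (cell, drug) identifiers.

    Identifiers are uppercased and stripped of punctuation before
    matching; alias tables (raw -> canonical) are applied first. Datasets
    carrying different response types are refused unless ``allow_mixed``
    is set — Spearman's rank invariance makes a mixed comparison
    defensible, but it must be explicit.
    """
    if a.response_type != b.response_type and not allow_mixed:
        raise ValueError(
            f"response types differ ({a.response_type.value} vs "
            f"{b.response_type.value}); pass allow_mixed=True to compare anyway"
        )
    cmap = _alias_mapper(cell_map)
    dmap = _alias_mapper(drug_map)
    da = _canonical_pairs(a, cmap, dmap)
    db = _canonical_pairs(b, cmap, dmap)
    merged = da.merge(db, on=["cell_key", "drug_key"], suffixes=("_a", "_b"))
    return MatchedPairs(
        values_a=merged["response_a"].to_numpy(),
        values_b=merged["response_b"].to_numpy(),
        n_unmatched_a=len(da) - len(merged),
        n_unmatched_b=len(db) - len(merged),
    )


@dataclass
class CrossDatasetMatrix:
    """Pairwise Spearman matrix with matched-pair counts.

    ``scc`` is symmetric where defined with unit diagonal (given >= 2
    pairs with variance); ``n_overlap`` is symmetric with each dataset's
    own pair count on the diagonal. Cells with fewer than ``min_overlap``
    matched pairs carry NaN.
    """

    dataset_names: list[str]
    scc: pd.DataFrame
    n_overlap: pd.DataFrame
    min_overlap: int


def cross_dataset_matrix(
    datasets: list[TripletDataset],
    min_overlap: int = 10,
    cell_map: pd.DataFrame | dict | None = None,
    drug_map: pd.DataFrame | dict | None = None,
    allow_mixed: bool = False,
) -> CrossDatasetMatrix:
    """Spearman agreement between every pair of datasets.

    For each ordered pair the rank correlation is computed over matched
    pairs when at least ``min_overlap`` of them exist, otherwise left
    undefined; the count matrix is returned alongside for annotation.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    names = []
    for i, ds in enumerate(datasets):
        names.append(ds.name or f"dataset_{i}")
    if len(set(names)) != len(names):
        names = [f"{n}_{i}" for i, n in enumerate(names)]
    m = len(datasets)
    scc = np.full((m, m), math.nan)
    n_ov = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i, m):
            mp = match_pairs(
                datasets[i], datasets[j],
                cell_map=cell_map, drug_map=drug_map, allow_mixed=allow_mixed,
            )
            n_ov[i, j] = n_ov[j, i] = mp.n
            if mp.n >= min_overlap:
                scc[i, j] = scc[j, i] = mp.spearman()
    return CrossDatasetMatrix(
        dataset_names=names,
        scc=pd.DataFrame(scc, index=names, columns=names),
        n_overlap=pd.DataFrame(n_ov, index=names, columns=names),
        min_overlap=min_overlap,
    )
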