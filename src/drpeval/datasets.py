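"""Triplet response datasets and raw dose-response tables.

Pharmacogenomic screens are exchanged as long tables of (cell, drug,
response) triplets — the ``S = {c, d, r}`` structure — optionally annotated
with a cancer type, plus raw viability tables of (experiment, cell, drug,
concentration, viability) rows. This module provides the in-memory
containers for both, delimited-text I/O with replicate aggregation, and a
coverage report for quantifying how sparse a screen is.

Cells and drugs are opaque string identifiers throughout: the toolkit never
interprets them as accessions or structures.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("drpeval")

TRIPLET_COLUMNS = ("cell_id", "drug_id", "response")
DOSE_RESPONSE_COLUMNS = (
    "experiment_id",
    "cell_id",
    "drug_id",
    "concentration",
    "viability",
)

#: multiplicative factor to molar for each supported input unit
_UNIT_TO_MOLAR = {"molar": 1.0, "micromolar": 1e-6, "nanomolar": 1e-9}


class ResponseType(str, enum.Enum):
    """Semantic tag for the response column of a triplet dataset."""

    LN_IC50 = "ln_ic50"
    AUDRC = "audrc"
    AADRC = "aadrc"
    NORMALIZED = "normalized"
    BINARY = "binary"


#: response types whose values are constrained to the unit interval
_UNIT_INTERVAL_TYPES = frozenset(
    {ResponseType.AUDRC, ResponseType.AADRC, ResponseType.NORMALIZED}
)


class TripletDatasetError(ValueError):
    """Raised for malformed triplet tables (schema, parse, duplicates)."""


def _infer_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


class TripletDataset:
    """An ordered collection of (cell_id, drug_id, response) records.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``cell_id``, ``drug_id``, ``response`` and optionally
        ``cancer_type``. At most one row per (cell, drug) pair.
    response_type : ResponseType or str
        Single response semantics shared by every record.
    name : str
        Label used in reports and cross-dataset comparisons.
    validate : bool
        Check the type invariants (finite responses, unit-interval ranges
        for bounded types, {0, 1} for binary). Centering transforms
        legitimately push bounded values outside their nominal range and
        construct with ``validate=False``.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        response_type: ResponseType | str = ResponseType.LN_IC50,
        name: str = "",
        validate: bool = True,
    ) -> None:
        missing = [c for c in TRIPLET_COLUMNS if c not in df.columns]
        if missing:
            raise TripletDatasetError(f"missing required column(s): {missing}")
        cols = list(TRIPLET_COLUMNS) + (
            ["cancer_type"] if "cancer_type" in df.columns else []
        )
        df = df.loc[:, cols].reset_index(drop=True).copy()
        df["cell_id"] = df["cell_id"].astype(str)
        df["drug_id"] = df["drug_id"].astype(str)
        df["response"] = pd.to_numeric(df["response"], errors="raise").astype(float)
        self.df = df
        self.response_type = ResponseType(response_type)
        self.name = name
        if validate:
            self._validate()

    # -- invariants -----------------------------------------------------
    def _validate(self) -> None:
        df = self.df
        if (df["cell_id"].str.len() == 0).any() or (df["drug_id"].str.len() == 0).any():
            raise TripletDatasetError("cell_id and drug_id must be non-empty strings")
        if not np.isfinite(df["response"]).all():
            raise TripletDatasetError("responses must be finite")
        dup = df.duplicated(subset=["cell_id", "drug_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["cell_id", "drug_id"]].tolist()
            raise TripletDatasetError(
                f"duplicate (cell, drug) pair after aggregation: {pair}"
            )
        r = df["response"].to_numpy()
        if self.response_type is ResponseType.BINARY:
            if not np.isin(r, (0.0, 1.0)).all():
                raise TripletDatasetError("binary responses must be 0 or 1")
        elif self.response_type in _UNIT_INTERVAL_TYPES:
            if r.size and (r.min() < 0.0 or r.max() > 1.0):
                raise TripletDatasetError(
                    f"{self.response_type.value} responses must lie in [0, 1]"
                )

    # -- basic accessors ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_pairs(self) -> int:
        return len(self.df)

    @property
    def cells(self) -> list[str]:
        return self.df["cell_id"].unique().tolist()

    @property
    def drugs(self) -> list[str]:
        return self.df["drug_id"].unique().tolist()

    @property
    def has_cancer_type(self) -> bool:
        return "cancer_type" in self.df.columns

    def pairs(self) -> pd.DataFrame:
        """The (cell_id, drug_id) key frame, row order preserved."""
        return self.df[["cell_id", "drug_id"]].copy()

    def with_df(self, df: pd.DataFrame, validate: bool = True) -> "TripletDataset":
        return TripletDataset(df, self.response_type, self.name, validate=validate)

    def coverage_report(self) -> "CoverageReport":
        return CoverageReport.from_counts(
            n_records=self.n_pairs,
            n_cells=len(self.cells),
            n_drugs=len(self.drugs),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TripletDataset(name={self.name!r}, n_pairs={self.n_pairs}, "
            f"cells={len(self.cells)}, drugs={len(self.drugs)}, "
            f"response_type={self.response_type.value})"
        )


@dataclass(frozen=True)
class CoverageReport:
    """How densely a screen covers its cell x drug grid."""

    n_records: int
    n_cells: int
    n_drugs: int

    @classmethod
    def from_counts(cls, n_records: int, n_cells: int, n_drugs: int) -> "CoverageReport":
        return cls(n_records=n_records, n_cells=n_cells, n_drugs=n_drugs)

    @property
    def n_possible(self) -> int:
        return self.n_cells * self.n_drugs

    @property
    def measured_fraction(self) -> float:
        return self.n_records / self.n_possible

    @property
    def unmeasured_fraction(self) -> float:
        return 1.0 - self.measured_fraction

    @property
    def unmeasured_pct(self) -> float:
        """Percentage of possible (cell, drug) pairs that were never assayed."""
        return 100.0 * self.unmeasured_fraction


def unmeasured_fraction(n_records: int, n_cells: int, n_drugs: int) -> float:
    """Fraction of the cell x drug grid with no measured response."""
    return CoverageReport.from_counts(n_records, n_cells, n_drugs).unmeasured_fraction


@dataclass
class DoseResponseExperiment:
    """Viability measured across concentrations for one cell-drug pair.

    Concentrations are molar, strictly positive, strictly ascending; at
    least four points are required for a four-parameter fit. Viabilities
    are fractions of untreated control and may exceed 1 on input
    (control-normalized assays do); clamping happens only inside the
    standardized-area integral.
    """

    experiment_id: str
    cell_id: str
    drug_id: str
    concentrations: np.ndarray
    viabilities: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        v = np.asarray(self.viabilities, dtype=float)
        if c.shape != v.shape or c.ndim != 1:
            raise ValueError("concentrations and viabilities must be equal-length 1-D")
        if len(c) < 4:
            raise ValueError("a 4-parameter fit needs at least 4 points")
        if (c <= 0).any():
            raise ValueError("concentrations must be strictly positive (molar)")
        if (np.diff(c) <= 0).any():
            raise ValueError("concentrations must be strictly ascending, no duplicates")
        if not (np.isfinite(c).all() and np.isfinite(v).all()):
            raise ValueError("concentrations and viabilities must be finite")
        self.concentrations = c
        self.viabilities = v

    @property
    def n_points(self) -> int:
        return len(self.concentrations)

    @property
    def log10_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations)


# ---------------------------------------------------------------------------
# Triplet I/O
# ---------------------------------------------------------------------------

def read_triplets(
    path: str | Path,
    response_type: ResponseType | str = ResponseType.LN_IC50,
    aggregate: str = "median",
    name: str | None = None,
) -> TripletDataset:
    """Read a triplet CSV/TSV, collapsing replicate (cell, drug) rows.

    The file must carry a header with columns ``cell_id``, ``drug_id`` and
    ``response`` (``cancer_type`` optional); the delimiter is inferred from
    the extension. ``aggregate`` is one of ``median``, ``mean`` or
    ``error`` (raise on any duplicate pair). Row order is preserved by
    first occurrence and the number of collapsed rows is logged.
    """
    path = Path(path)
    if aggregate not in ("median", "mean", "error"):
        raise ValueError(f"unknown aggregate mode: {aggregate!r}")
    df = pd.read_csv(path, sep=_infer_delimiter(path), dtype={0: str})
    missing = [c for c in TRIPLET_COLUMNS if c not in df.columns]
    if missing:
        raise TripletDatasetError(
            f"{path.name}: missing required column(s): {missing}"
        )
    df["cell_id"] = df["cell_id"].astype(str)
    df["drug_id"] = df["drug_id"].astype(str)
    bad = pd.to_numeric(df["response"], errors="coerce").isna() & df["response"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TripletDatasetError(
            f"{path.name}: non-numeric response at data row {row + 1}: "
            f"{df['response'].iloc[row]!r}"
        )
    df["response"] = pd.to_numeric(df["response"], errors="raise")

    dup_mask = df.duplicated(subset=["cell_id", "drug_id"], keep=False)
    n_dup_rows = int(dup_mask.sum())
    if n_dup_rows:
        if aggregate == "error":
            pair = df.loc[dup_mask.idxmax(), ["cell_id", "drug_id"]].tolist()
            raise TripletDatasetError(
                f"{path.name}: duplicate (cell, drug) pair {pair} with aggregate='error'"
            )
        agg_spec = {"response": aggregate}
        if "cancer_type" in df.columns:
            agg_spec["cancer_type"] = "first"
        # sort=False keeps first-occurrence order
        df = df.groupby(["cell_id", "drug_id"], sort=False, as_index=False).agg(agg_spec)
        logger.info(
            "read_triplets(%s): collapsed %d replicate rows by %s",
            path.name, n_dup_rows, aggregate,
        )
    return TripletDataset(df, response_type, name=name if name is not None else path.stem)


def write_triplets(dataset: TripletDataset, path: str | Path) -> None:
    """Write a dataset back to CSV/TSV with full float precision.

    Round-trip guarantee: ``read_triplets`` on the written file reproduces
    the dataset's records exactly (responses serialized with repr
    precision).
    """
    path = Path(path)
    dataset.df.to_csv(
        path, sep=_infer_delimiter(path), index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Dose-response I/O
# ---------------------------------------------------------------------------

def read_dose_response(
    path: str | Path,
    concentration_unit: str = "molar",
) -> list[DoseResponseExperiment]:
    """Read a long-format viability table into per-experiment curves.

    Rows are grouped by ``experiment_id``; concentrations are converted to
    molar and sorted ascending with viabilities reordered in lockstep.
    Experiments with fewer than four points are excluded and logged.
    """
    path = Path(path)
    try:
        factor = _UNIT_TO_MOLAR[concentration_unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {concentration_unit!r}; "
            f"expected one of {sorted(_UNIT_TO_MOLAR)}"
        ) from None
    df = pd.read_csv(path, sep=_infer_delimiter(path))
    missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise TripletDatasetError(f"{path.name}: missing required column(s): {missing}")
    conc = pd.to_numeric(df["concentration"], errors="raise")
    nonpos = conc <= 0
    if nonpos.any():
        row = int(np.flatnonzero(nonpos.to_numpy())[0])
        raise TripletDatasetError(
            f"{path.name}: non-positive concentration at data row {row + 1}"
        )
    df = df.assign(concentration=conc * factor)

    experiments: list[DoseResponseExperiment] = []
    n_excluded = 0
    for exp_id, grp in df.groupby("experiment_id", sort=False):
        if len(grp) < 4:
            n_excluded += 1
            logger.warning(
                "read_dose_response(%s): experiment %r has %d < 4 points; excluded",
                path.name, exp_id, len(grp),
            )
            continue
        grp = grp.sort_values("concentration", kind="stable")
        experiments.append(
            DoseResponseExperiment(
                experiment_id=str(exp_id),
                cell_id=str(grp["cell_id"].iloc[0]),
                drug_id=str(grp["drug_id"].iloc[0]),
                concentrations=grp["concentration"].to_numpy(),
                viabilities=grp["viability"].to_numpy(dtype=float),
            )
        )
    if n_excluded:
        logger.info(
            "read_dose_response(%s): excluded %d experiment(s) with < 4 points",
            path.name, n_excluded,
        )
    return experiments


def write_dose_response(
    experiments: Iterable[DoseResponseExperiment], path: str | Path
) -> None:
    """Serialize experiments back to the long-format table (molar units)."""
    path = Path(path)
    frames = []
    for e in experiments:
        frames.append(
            pd.DataFrame(
                {
                    "experiment_id": e.experiment_id,
                    "cell_id": e.cell_id,
                    "drug_id": e.drug_id,
                    "concentration": e.concentrations,
                    "viability": e.viabilities,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(DOSE_RESPONSE_COLUMNS)
    )
    out.to_csv(path, sep=_infer_delimiter(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Prediction tables
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ("cell_id", "drug_id", "predicted")


def as_prediction_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a prediction table (one finite value per pair)."""
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise TripletDatasetError(f"prediction table missing column(s): {missing}")
    out = df.loc[:, list(PREDICTION_COLUMNS)].copy()
    out["cell_id"] = out["cell_id"].astype(str)
    out["drug_id"] = out["drug_id"].astype(str)
    out["predicted"] = pd.to_numeric(out["predicted"], errors="raise").astype(float)
    if not np.isfinite(out["predicted"]).all():
        raise TripletDatasetError("predictions must be finite")
    if out.duplicated(subset=["cell_id", "drug_id"]).any():
        raise TripletDatasetError("prediction table has duplicate (cell, drug) pairs")
    return out.reset_index(drop=True)


def read_predictions(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return as_prediction_table(pd.read_csv(path, sep=_infer_delimiter(path)))
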