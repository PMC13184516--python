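"""Entity-aware K-fold cross-validation for drug-response screens.

Random K-fold splitting of (cell, drug) pairs leaks information: the same
cell lines and drugs appear on both sides of the split, so a model is
never asked the clinically relevant questions — "how will a *new* patient
respond?" (cell-blind), "what will a *new* compound do?" (drug-blind), or
both at once (completely-blind). This module constructs fold assignments
under five strategies and makes the disjointness guarantees
machine-checkable with :func:`verify_assignment`.

Strategies
----------
random
    Pairs dealt into k folds (sizes differ by at most 1).
cell_blind / drug_blind
    Distinct cells (drugs) dealt into k groups; a fold's test set is every
    pair of its group's entities, so no test cell (drug) ever appears in
    training.
completely_blind
    Cells and drugs are both grouped; fold f tests cell-group f x
    drug-group f and trains on pairs touching neither group. Pairs mixing
    groups are discarded for that fold and accounted for explicitly.
cancer_type_blind
    All cells of a cancer type share a fold; types are placed by seeded
    greedy balancing (largest type first into the currently smallest
    fold).

A validation carve-out for hyperparameter selection is taken from training
pairs (random) or training entities (blind strategies), so the blind
guarantee extends to the validation set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TripletDataset

logger = logging.getLogger("drpeval")

STRATEGIES = (
    "random",
    "cell_blind",
    "drug_blind",
    "completely_blind",
    "cancer_type_blind",
)

ROLE_TRAIN = "train"
ROLE_VALIDATION = "validation"
ROLE_TEST = "test"
ROLE_DISCARDED = "discarded"


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of a cross-validation split.

    ``validation_fraction`` (in [0, 0.5)) is carved out of each fold's
    training side for model selection; k defaults to 5, the field's
    conventional fold count.
    """

    strategy: str = "random"
    k: int = 5
    seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0.0 <= self.validation_fraction < 0.5):
            raise ValueError("validation_fraction must lie in [0, 0.5)")


class FoldAssignment:
    """Per-pair fold roles for a K-fold split.

    Internally a pairs-by-folds role matrix (values train / validation /
    test / discarded). ``pairs`` is the (cell_id, drug_id) frame in dataset
    order; ``roles`` has one column per fold.
    """

    def __init__(
        self,
        pairs: pd.DataFrame,
        roles: np.ndarray,
        strategy: str,
        spec: SplitSpec,
        excluded: pd.DataFrame | None = None,
        entity_groups: dict[str, list[np.ndarray]] | None = None,
    ) -> None:
        self.pairs = pairs.reset_index(drop=True)
        self.roles = np.asarray(roles, dtype=object)
        if self.roles.shape != (len(self.pairs), spec.k):
            raise ValueError("roles must be (n_pairs, k)")
        self.strategy = strategy
        self.spec = spec
        #: pairs excluded from the split entirely (e.g. cells without a
        #: cancer-type annotation under cancer_type_blind)
        self.excluded = excluded if excluded is not None else pairs.iloc[0:0]
        #: per-fold entity groups the blind strategies dealt
        #: ({"cell_id": [...], "drug_id": [...]}); balance guarantees hold
        #: on these groups, not on which pairs happen to be measured
        self.entity_groups = entity_groups or {}

    @property
    def k(self) -> int:
        return self.spec.k

    def _mask(self, fold: int, role: str) -> np.ndarray:
        return self.roles[:, fold] == role

    def fold_pairs(self, fold: int, role: str) -> pd.DataFrame:
        """Pairs playing ``role`` in fold ``fold``."""
        return self.pairs.loc[self._mask(fold, role)].reset_index(drop=True)

    def test_pairs(self, fold: int) -> pd.DataFrame:
        return self.fold_pairs(fold, ROLE_TEST)

    def train_pairs(self, fold: int) -> pd.DataFrame:
        return self.fold_pairs(fold, ROLE_TRAIN)

    def validation_pairs(self, fold: int) -> pd.DataFrame:
        return self.fold_pairs(fold, ROLE_VALIDATION)

    def discarded_pairs(self, fold: int) -> pd.DataFrame:
        return self.fold_pairs(fold, ROLE_DISCARDED)

    def fold_counts(self) -> pd.DataFrame:
        """Per-fold counts of each role (discarded accounting included)."""
        rows = []
        for f in range(self.k):
            col = self.roles[:, f]
            rows.append(
                {
                    "fold": f,
                    "n_train": int((col == ROLE_TRAIN).sum()),
                    "n_validation": int((col == ROLE_VALIDATION).sum()),
                    "n_test": int((col == ROLE_TEST).sum()),
                    "n_discarded": int((col == ROLE_DISCARDED).sum()),
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self, expand_train: bool = False) -> pd.DataFrame:
        """Long-format table: cell_id, drug_id, fold, role.

        By default only test and validation rows are materialized (train
        membership is derivable); ``expand_train`` adds train rows too.
        """
        keep = {ROLE_TEST, ROLE_VALIDATION}
        if expand_train:
            keep |= {ROLE_TRAIN, ROLE_DISCARDED}
        frames = []
        for f in range(self.k):
            for role in sorted(keep):
                sub = self.fold_pairs(f, role)
                if len(sub):
                    sub = sub.assign(fold=f, role=role)
                    frames.append(sub)
        if not frames:
            return pd.DataFrame(columns=["cell_id", "drug_id", "fold", "role"])
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _deal(items: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle and deal items into k groups with sizes differing by <= 1."""
    perm = rng.permutation(len(items))
    return [items[idx] for idx in np.array_split(perm, k)]


def _sorted_unique(values: pd.Series) -> np.ndarray:
    """Deterministic entity order: sorted unique values (row-order free)."""
    return np.sort(values.unique())


def _carve_entities(
    entities: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Select a validation subset of entities (floor of the fraction)."""
    n_val = int(np.floor(fraction * len(entities)))
    if n_val == 0:
        return entities[:0]
    return rng.choice(entities, size=n_val, replace=False)


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

def split_random(dataset: TripletDataset, spec: SplitSpec) -> FoldAssignment:
    """Deal (cell, drug) pairs into k folds at random (seeded)."""
    n = dataset.n_pairs
    if n == 0:
        raise ValueError("dataset is empty")
    if spec.k > n:
        raise ValueError(f"k={spec.k} exceeds the number of pairs ({n})")
    rng = np.random.default_rng(spec.seed)
    groups = _deal(np.arange(n), spec.k, rng)
    roles = np.full((n, spec.k), ROLE_TRAIN, dtype=object)
    for f, idx in enumerate(groups):
        roles[idx, f] = ROLE_TEST
        if spec.validation_fraction > 0:
            train_idx = np.flatnonzero(roles[:, f] == ROLE_TRAIN)
            val_idx = _carve_entities(train_idx, spec.validation_fraction, rng)
            roles[val_idx, f] = ROLE_VALIDATION
    return FoldAssignment(dataset.pairs(), roles, "random", spec)


def _split_entity_blind(
    dataset: TripletDataset, spec: SplitSpec, column: str, strategy: str
) -> FoldAssignment:
    entities = _sorted_unique(dataset.df[column])
    if len(entities) < spec.k:
        raise ValueError(
            f"{strategy}: k={spec.k} exceeds the number of distinct "
            f"{column} values ({len(entities)})"
        )
    rng = np.random.default_rng(spec.seed)
    groups = _deal(entities, spec.k, rng)
    values = dataset.df[column].to_numpy()
    roles = np.full((dataset.n_pairs, spec.k), ROLE_TRAIN, dtype=object)
    for f, group in enumerate(groups):
        in_test = np.isin(values, group)
        roles[in_test, f] = ROLE_TEST
        if spec.validation_fraction > 0:
            train_entities = entities[~np.isin(entities, group)]
            val_entities = _carve_entities(train_entities, spec.validation_fraction, rng)
            roles[np.isin(values, val_entities), f] = ROLE_VALIDATION
    return FoldAssignment(dataset.pairs(), roles, strategy, spec,
                          entity_groups={column: groups})


def split_cell_blind(dataset: TripletDataset, spec: SplitSpec) -> FoldAssignment:
    """Fold by cells: test cells never occur in that fold's training pairs.

    Folds are balanced by cell count (difference at most 1), not by pair
    count. ``k = number of cells`` gives leave-one-cell-line-out.
    """
    return _split_entity_blind(dataset, spec, "cell_id", "cell_blind")


def split_drug_blind(dataset: TripletDataset, spec: SplitSpec) -> FoldAssignment:
    """Fold by drugs; ``k = number of drugs`` gives leave-one-drug-out."""
    return _split_entity_blind(dataset, spec, "drug_id", "drug_blind")


def split_completely_blind(dataset: TripletDataset, spec: SplitSpec) -> FoldAssignment:
    """Disjoint folds over both entities (diagonal cell-group/drug-group pairing).

    Fold f tests the measured pairs of cell-group f x drug-group f and
    trains on pairs whose cell *and* drug lie outside group f; everything
    mixing the two sides is discarded for that fold. On a full n x m grid
    each fold's test share is ~1/k^2 of pairs (~1/k combined over folds)
    and its training share ~((k-1)/k)^2.
    """
    cells = _sorted_unique(dataset.df["cell_id"])
    drugs = _sorted_unique(dataset.df["drug_id"])
    if len(cells) < spec.k or len(drugs) < spec.k:
        raise ValueError(
            f"completely_blind: k={spec.k} exceeds distinct cells "
            f"({len(cells)}) or drugs ({len(drugs)})"
        )
    rng = np.random.default_rng(spec.seed)
    cell_groups = _deal(cells, spec.k, rng)
    drug_groups = _deal(drugs, spec.k, rng)
    cvals = dataset.df["cell_id"].to_numpy()
    dvals = dataset.df["drug_id"].to_numpy()
    roles = np.full((dataset.n_pairs, spec.k), ROLE_DISCARDED, dtype=object)
    for f in range(spec.k):
        c_in = np.isin(cvals, cell_groups[f])
        d_in = np.isin(dvals, drug_groups[f])
        roles[c_in & d_in, f] = ROLE_TEST
        roles[~c_in & ~d_in, f] = ROLE_TRAIN
        if spec.validation_fraction > 0:
            train_cells = cells[~np.isin(cells, cell_groups[f])]
            val_cells = _carve_entities(train_cells, spec.validation_fraction, rng)
            train_mask = roles[:, f] == ROLE_TRAIN
            roles[train_mask & np.isin(cvals, val_cells), f] = ROLE_VALIDATION
    return FoldAssignment(dataset.pairs(), roles, "completely_blind", spec,
                          entity_groups={"cell_id": cell_groups,
                                         "drug_id": drug_groups})


def split_cancer_type_blind(dataset: TripletDataset, spec: SplitSpec) -> FoldAssignment:
    """All cells of a cancer type share a fold (greedy cell-count balancing).

    Types are sorted by descending cell count (ties broken by a seeded
    shuffle) and each is placed into the fold currently holding the fewest
    cells. Cells with a missing type are excluded from the split entirely,
    with a logged count.
    """
    if not dataset.has_cancer_type:
        raise ValueError("cancer_type_blind requires a cancer_type column")
    df = dataset.df
    has_type = df["cancer_type"].notna() & (df["cancer_type"].astype(str) != "")
    n_excluded_cells = df.loc[~has_type, "cell_id"].nunique()
    if n_excluded_cells:
        logger.info(
            "cancer_type_blind: excluding %d cell(s) with missing cancer type",
            n_excluded_cells,
        )
    typed = df.loc[has_type]
    cell_type = typed.drop_duplicates("cell_id").set_index("cell_id")["cancer_type"]
    type_sizes = cell_type.value_counts()  # cells per type
    types = type_sizes.index.to_numpy()
    if len(types) < spec.k:
        raise ValueError(
            f"cancer_type_blind: k={spec.k} exceeds distinct types ({len(types)})"
        )
    rng = np.random.default_rng(spec.seed)
    # seeded tie-break, then stable sort by descending size
    order = rng.permutation(len(types))
    types = types[order]
    sizes = type_sizes.to_numpy()[order]
    desc = np.argsort(-sizes, kind="stable")
    fold_of_type: dict[str, int] = {}
    fold_cells = np.zeros(spec.k, dtype=int)
    for i in desc:
        f = int(np.argmin(fold_cells))  # ties -> lowest fold index
        fold_of_type[types[i]] = f
        fold_cells[f] += sizes[i]

    roles = np.full((dataset.n_pairs, spec.k), ROLE_TRAIN, dtype=object)
    pair_type = df["cancer_type"].where(has_type)
    pair_fold = pair_type.map(fold_of_type)
    for f in range(spec.k):
        roles[(pair_fold == f).to_numpy(), f] = ROLE_TEST
    roles[(~has_type).to_numpy(), :] = ROLE_DISCARDED
    excluded = df.loc[~has_type, ["cell_id", "drug_id"]].reset_index(drop=True)
    if spec.validation_fraction > 0:
        cvals = df["cell_id"].to_numpy()
        for f in range(spec.k):
            train_cells = np.sort(
                df.loc[(roles[:, f] == ROLE_TRAIN), "cell_id"].unique()
            )
            val_cells = _carve_entities(train_cells, spec.validation_fraction, rng)
            roles[(roles[:, f] == ROLE_TRAIN) & np.isin(cvals, val_cells), f] = (
                ROLE_VALIDATION
            )
    return FoldAssignment(dataset.pairs(), roles, "cancer_type_blind", spec,
                          excluded=excluded)


_SPLITTERS = {
    "random": split_random,
    "cell_blind": split_cell_blind,
    "drug_blind": split_drug_blind,
    "completely_blind": split_completely_blind,
    "cancer_type_blind": split_cancer_type_blind,
}


def split(dataset: TripletDataset, spec: SplitSpec) -> FoldAssignment:
    """Dispatch to the splitter named by ``spec.strategy``."""
    return _SPLITTERS[spec.strategy](dataset, spec)


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    """Pass/fail per invariant, with human-readable failure details."""

    strategy: str
    checks: dict[str, bool] = field(default_factory=dict)
    details: dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    def record(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks[name] = bool(ok)
        if detail:
            self.details[name] = detail

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"verification ({self.strategy}): {'PASS' if self.passed else 'FAIL'}"]
        for name, ok in self.checks.items():
            lines.append(f"  {name}: {'ok' if ok else 'FAIL ' + self.details.get(name, '')}")
        return "\n".join(lines)


def verify_assignment(
    dataset: TripletDataset,
    assignment: FoldAssignment,
    strategy: str | None = None,
) -> VerificationReport:
    """Machine-check the invariants applicable to a split strategy.

    Checks: pair coverage (each measured pair tests exactly once, or at
    most once under completely_blind), fold balance (test units differ by
    at most one), cell/drug disjointness for the blind strategies (no test
    entity in any train or validation pair of the same fold) and type
    cohesion for cancer_type_blind.
    """
    strategy = strategy or assignment.strategy
    rep = VerificationReport(strategy=strategy)
    roles = assignment.roles
    k = assignment.k
    test_counts = (roles == ROLE_TEST).sum(axis=1)

    considered = np.ones(len(roles), dtype=bool)
    if strategy == "cancer_type_blind":
        considered = ~(roles == ROLE_DISCARDED).all(axis=1)

    # pair coverage
    if strategy == "completely_blind":
        ok = bool((test_counts <= 1).all())
        rep.record("pair_coverage", ok,
                   "" if ok else "a pair is test in more than one fold")
    else:
        ok = bool((test_counts[considered] == 1).all())
        rep.record("pair_coverage", ok,
                   "" if ok else "pairs not test in exactly one fold")

    # fold balance, in the strategy's own unit: pairs for random, dealt
    # entity groups for the blind strategies (the <=1 guarantee holds on
    # the groups, not on which pairs happen to be measured)
    if strategy == "random":
        counts = [int((roles[:, f] == ROLE_TEST).sum()) for f in range(k)]
        ok = max(counts) - min(counts) <= 1
        rep.record("fold_balance", ok, f"fold pair counts: {counts}")
    elif strategy == "cancer_type_blind":
        counts = [
            assignment.pairs.loc[roles[:, f] == ROLE_TEST, "cell_id"].nunique()
            for f in range(k)
        ]
        rep.record("fold_balance", all(c > 0 for c in counts),
                   f"fold test-cell counts: {counts}")
    else:
        unit = "drug_id" if strategy == "drug_blind" else "cell_id"
        if unit in assignment.entity_groups:
            counts = [len(g) for g in assignment.entity_groups[unit]]
        else:
            counts = [
                assignment.pairs.loc[roles[:, f] == ROLE_TEST, unit].nunique()
                for f in range(k)
            ]
        ok = max(counts) - min(counts) <= 1
        rep.record("fold_balance", ok, f"fold {unit} group sizes: {counts}")

    # entity disjointness per fold
    def _disjoint(column: str) -> tuple[bool, str]:
        for f in range(k):
            test_mask = roles[:, f] == ROLE_TEST
            other_mask = np.isin(roles[:, f], (ROLE_TRAIN, ROLE_VALIDATION))
            test_ent = set(assignment.pairs.loc[test_mask, column])
            other_ent = set(assignment.pairs.loc[other_mask, column])
            overlap = test_ent & other_ent
            if overlap:
                return False, f"fold {f}: {column} overlap {sorted(overlap)[:5]}"
        return True, ""

    if strategy in ("cell_blind", "completely_blind", "cancer_type_blind"):
        ok, why = _disjoint("cell_id")
        rep.record("cell_disjointness", ok, why)
    if strategy in ("drug_blind", "completely_blind"):
        ok, why = _disjoint("drug_id")
        rep.record("drug_disjointness", ok, why)

    # type cohesion: every type's cells test in exactly one fold
    if strategy == "cancer_type_blind" and dataset.has_cancer_type:
        df = dataset.df
        ok, why = True, ""
        typed = df["cancer_type"].notna() & (df["cancer_type"].astype(str) != "")
        for ctype, grp in df.loc[typed].groupby("cancer_type"):
            idx = grp.index.to_numpy()
            fold_ids = {
                f for f in range(k) if (roles[idx, f] == ROLE_TEST).any()
            }
            if len(fold_ids) != 1:
                ok, why = False, f"type {ctype!r} tests in folds {sorted(fold_ids)}"
                break
        rep.record("type_cohesion", ok, why)

    return rep
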