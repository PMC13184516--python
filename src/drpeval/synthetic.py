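"""Synthetic screens, viability curves and reference baseline predictors.

Every component of the toolkit is testable without downloading a public
screen: this module generates (a) triplet screens from an additive
variance-components model with known latent effects, (b) raw dose-response
experiments from known 4PL parameters, and (c) two reference predictors —
the drug-mean baseline that reproduces the classic "great overall
correlation, useless per drug" pathology, and a tunable oracle whose noise
dials per-drug accuracy continuously.

The screen model is

    r_cd = grand_mean + alpha_d + beta_c + gamma_cd + eps_cd

with independent zero-mean Gaussian drug effects alpha (sd ``sigma_drug``),
cell effects beta (``sigma_cell``), interactions gamma
(``sigma_interaction``) and measurement noise eps (``sigma_noise``). The
default configuration makes the drug effect dominant (sd 2 vs 0.1 for the
rest, 50 cells x 20 drugs) — exactly the regime in which overall
correlation is driven by between-drug potency differences rather than by
any within-drug signal. A seeded fraction of pairs can be deleted to
emulate screen sparsity; missing pairs are absent rows, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .datasets import DoseResponseExperiment, ResponseType, TripletDataset
from .dose_response import four_pl

logger = logging.getLogger("drpeval")

Predictor = Callable[..., pd.DataFrame]


@dataclass(frozen=True)
class ScreenConfig:
    """Variance-components configuration of a synthetic screen."""

    n_cells: int = 50
    n_drugs: int = 20
    n_types: int = 5
    sigma_drug: float = 2.0
    sigma_cell: float = 0.1
    sigma_interaction: float = 0.1
    sigma_noise: float = 0.1
    grand_mean: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_drugs < 1:
            raise ValueError("need at least one cell and one drug")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")
        sigmas = (self.sigma_drug, self.sigma_cell,
                  self.sigma_interaction, self.sigma_noise)
        if any(s < 0 for s in sigmas):
            raise ValueError("sigmas must be non-negative")


@dataclass
class LatentEffects:
    """Ground-truth effect components of a generated screen."""

    grand_mean: float
    alpha: pd.Series  # drug main effects, indexed by drug_id
    beta: pd.Series   # cell main effects, indexed by cell_id
    gamma: pd.DataFrame  # interaction, cells x drugs
    cancer_type: pd.Series  # cell_id -> type label

    def noiseless(self, cells: np.ndarray, drugs: np.ndarray) -> np.ndarray:
        """mu + alpha_d + beta_c + gamma_cd for aligned id arrays."""
        a = self.alpha.loc[drugs].to_numpy()
        b = self.beta.loc[cells].to_numpy()
        g = self.gamma.to_numpy()[
            self.gamma.index.get_indexer(cells), self.gamma.columns.get_indexer(drugs)
        ]
        return self.grand_mean + a + b + g


def generate_screen(config: ScreenConfig) -> tuple[TripletDataset, LatentEffects]:
    """Draw one screen and return it with its generating latent effects.

    Cancer types are assigned to cells round-robin over ``n_types``
    labels. All randomness flows from one generator seeded by
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cells = np.array([f"C{i:04d}" for i in range(config.n_cells)])
    drugs = np.array([f"D{j:04d}" for j in range(config.n_drugs)])
    types = pd.Series(
        [f"T{i % config.n_types:02d}" for i in range(config.n_cells)], index=cells
    )
    alpha = pd.Series(rng.normal(0.0, config.sigma_drug, config.n_drugs), index=drugs)
    beta = pd.Series(rng.normal(0.0, config.sigma_cell, config.n_cells), index=cells)
    gamma = pd.DataFrame(
        rng.normal(0.0, config.sigma_interaction, (config.n_cells, config.n_drugs)),
        index=cells, columns=drugs,
    )
    eps = rng.normal(0.0, config.sigma_noise, (config.n_cells, config.n_drugs))

    grid = (
        config.grand_mean
        + alpha.to_numpy()[None, :]
        + beta.to_numpy()[:, None]
        + gamma.to_numpy()
        + eps
    )
    cell_idx, drug_idx = np.meshgrid(
        np.arange(config.n_cells), np.arange(config.n_drugs), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "cell_id": cells[cell_idx.ravel()],
            "drug_id": drugs[drug_idx.ravel()],
            "response": grid.ravel(),
        }
    )
    df["cancer_type"] = types.loc[df["cell_id"]].to_numpy()
    if config.missing_fraction > 0:
        keep = rng.random(len(df)) >= config.missing_fraction
        df = df.loc[keep].reset_index(drop=True)
    latents = LatentEffects(
        grand_mean=config.grand_mean, alpha=alpha, beta=beta, gamma=gamma,
        cancer_type=types,
    )
    dataset = TripletDataset(df, ResponseType.LN_IC50, name=f"screen_seed{config.seed}")
    return dataset, latents


@dataclass(frozen=True)
class CurveSetConfig:
    """Configuration for synthetic 4PL viability experiments.

    Nine log-spaced concentrations across the standard 100 pM - 100 uM
    window by default (screens typically measure 8-10 doses). Parameter
    priors are uniform: asymptotes near 1 and 0, log10 EC50 within the
    window interior, Hill slope in [0.5, 3].
    """

    n_experiments: int = 50
    n_points: int = 9
    cmin: float = 1e-10
    cmax: float = 1e-4
    upper_range: tuple[float, float] = (0.9, 1.1)
    lower_range: tuple[float, float] = (0.0, 0.15)
    log10_inflection_range: tuple[float, float] = (-9.0, -5.0)
    hill_range: tuple[float, float] = (0.5, 3.0)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("need at least 4 concentrations per curve")
        if not (0 < self.cmin < self.cmax):
            raise ValueError("require 0 < cmin < cmax")


def generate_curves(
    config: CurveSetConfig,
) -> tuple[list[DoseResponseExperiment], pd.DataFrame]:
    """Draw viability curves with known 4PL parameters.

    Viabilities are the generating curve plus Gaussian noise, clipped at 0
    from below (a plate cannot report negative viability). Returns the
    experiments and a table of generating parameters for recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    conc = np.logspace(np.log10(config.cmin), np.log10(config.cmax), config.n_points)
    experiments = []
    rows = []
    for i in range(config.n_experiments):
        upper = rng.uniform(*config.upper_range)
        lower = rng.uniform(*config.lower_range)
        inflection = 10.0 ** rng.uniform(*config.log10_inflection_range)
        hill = rng.uniform(*config.hill_range)
        clean = four_pl(conc, upper, lower, inflection, hill)
        noisy = clean + rng.normal(0.0, config.noise_sd, config.n_points)
        noisy = np.clip(noisy, 0.0, None)
        exp_id = f"E{i:05d}"
        experiments.append(
            DoseResponseExperiment(
                experiment_id=exp_id,
                cell_id=f"C{i:04d}",
                drug_id=f"D{i % 10:04d}",
                concentrations=conc,
                viabilities=noisy,
            )
        )
        rows.append(
            {
                "experiment_id": exp_id,
                "upper": upper, "lower": lower,
                "inflection": inflection, "hill": hill,
            }
        )
    return experiments, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference predictors
# ---------------------------------------------------------------------------

def drug_mean_predictor(
    train: TripletDataset,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> Predictor:
    """Baseline that predicts each drug's training-mean response.

    Unseen drugs fall back to the training grand mean. This is the
    canonical pathology baseline: because between-drug differences usually
    dwarf within-drug structure, the drug mean alone earns a high overall
    correlation while carrying zero information about which cells a drug
    will work in. With ``jitter_sd > 0`` a small seeded Gaussian jitter is
    added so that within-drug ranks are defined (a strictly constant
    per-drug prediction has no rank order at all); the jitter is
    independent of the truth, so per-drug correlations hover near zero.
    """
    if train.n_pairs == 0:
        raise ValueError("training dataset is empty")
    means = train.df.groupby("drug_id")["response"].mean()
    grand = float(train.df["response"].mean())

    def predict(pairs: pd.DataFrame) -> pd.DataFrame:
        out = pairs[["cell_id", "drug_id"]].copy()
        out["predicted"] = (
            out["drug_id"].map(means).fillna(grand).to_numpy(dtype=float)
        )
        if jitter_sd > 0:
            rng = np.random.default_rng(seed)
            out["predicted"] += rng.normal(0.0, jitter_sd, len(out))
        return out

    return predict


def oracle_predictor(
    latents: LatentEffects,
    noise_sd_pred: float = 0.0,
    seed: int = 0,
) -> Predictor:
    """Upper-bound reference: the noiseless truth plus controllable noise.

    ``predict(pairs, train=None)`` returns the latent noiseless response
    plus Gaussian noise of sd ``noise_sd_pred``, which tunes achievable
    per-drug rank accuracy continuously downward from ~1.

    When a ``train`` dataset is supplied, the oracle only "knows" the
    effect components of entities it saw in training: unseen cells
    contribute neither their cell effect nor interactions, unseen drugs
    neither their drug effect nor interactions (the components are
    replaced by their prior mean, 0). This mimics how a learned model
    degrades under cell-blind and drug-blind evaluation and lets the split
    strategies be compared on one screen.
    """

    def predict(pairs: pd.DataFrame, train: TripletDataset | None = None) -> pd.DataFrame:
        out = pairs[["cell_id", "drug_id"]].copy()
        cells = out["cell_id"].to_numpy()
        drugs = out["drug_id"].to_numpy()
        a = latents.alpha.reindex(drugs).to_numpy()
        b = latents.beta.reindex(cells).to_numpy()
        gi = latents.gamma.index.get_indexer(cells)
        gj = latents.gamma.columns.get_indexer(drugs)
        g = np.where(
            (gi >= 0) & (gj >= 0),
            latents.gamma.to_numpy()[np.clip(gi, 0, None), np.clip(gj, 0, None)],
            0.0,
        )
        a = np.nan_to_num(a)
        b = np.nan_to_num(b)
        if train is not None:
            seen_cells = np.isin(cells, train.df["cell_id"].unique())
            seen_drugs = np.isin(drugs, train.df["drug_id"].unique())
            a = np.where(seen_drugs, a, 0.0)
            b = np.where(seen_cells, b, 0.0)
            g = np.where(seen_cells & seen_drugs, g, 0.0)
        pred = latents.grand_mean + a + b + g
        if noise_sd_pred > 0:
            rng = np.random.default_rng(seed)
            pred = pred + rng.normal(0.0, noise_sd_pred, len(out))
        out["predicted"] = pred
        return out

    return predict
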