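import numpy as np
import pandas as pd
import pytest

from drpeval import (
    DoseResponseExperiment,
    ResponseType,
    ScreenConfig,
    TripletDataset,
    generate_screen,
)


@pytest.fixture
def grid_dataset():
    """Full 6-cell x 4-drug grid with distinct responses and cancer types."""
    cells = [f"C{i}" for i in range(6)]
    drugs = [f"D{j}" for j in range(4)]
    rows = [
        {"cell_id": c, "drug_id": g, "response": float(i * 4 + j),
         "cancer_type": f"T{i % 3}"}
        for i, c in enumerate(cells)
        for j, g in enumerate(drugs)
    ]
    return TripletDataset(pd.DataFrame(rows), ResponseType.LN_IC50, name="grid")


@pytest.fixture
def sparse_screen():
    """Seeded synthetic screen with 20% missing pairs."""
    cfg = ScreenConfig(n_cells=20, n_drugs=12, missing_fraction=0.2, seed=11)
    dataset, latents = generate_screen(cfg)
    return dataset, latents


@pytest.fixture
def symmetric_curve_experiment():
    """Noiseless 4PL data, symmetric about the standard window midpoint."""
    conc = np.logspace(-10, -4, 9)
    viab = 1.0 / (1.0 + conc / 1e-7)
    return DoseResponseExperiment("sym", "C1", "D1", conc, viab)


def random_sparse_dataset(rng: np.random.Generator, with_types: bool = True):
    """A random sparse screen for property suites (5-60 entities, <=40% missing)."""
    n_cells = int(rng.integers(5, 61))
    n_drugs = int(rng.integers(5, 61))
    n_types = int(rng.integers(5, n_cells + 1))
    cfg = ScreenConfig(
        n_cells=n_cells,
        n_drugs=n_drugs,
        n_types=n_types,
        sigma_drug=1.0,
        sigma_cell=0.5,
        sigma_interaction=0.5,
        sigma_noise=0.2,
        missing_fraction=float(rng.uniform(0.0, 0.4)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    dataset, _ = generate_screen(cfg)
    if not with_types:
        dataset = TripletDataset(
            dataset.df.drop(columns="cancer_type"), dataset.response_type
        )
    return dataset
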