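"""Shared fixtures: a small synthetic cohort and planted-structure factories.

Everything is generated programmatically at test time; no stored data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from placentome.simulate import SimConfig, simulate_cohort

LAYER_NAMES = ("UC", "AN", "CN", "CP", "VF", "VI", "VM")

SMALL_ARCH = {
    "shared": dict(zip(LAYER_NAMES, (2, 2, 2, 2, 20, 40, 2))),
    "male": dict(zip(LAYER_NAMES, (50, 20, 2, 2, 20, 2, 2))),
    "female": dict(zip(LAYER_NAMES, (5, 2, 1, 1, 2, 1, 1))),
}


def small_config(**overrides) -> SimConfig:
    """Down-scaled cohort: full 69-pair x 7-layer shape, reduced gene/SNP
    universe so the whole pipeline runs in seconds."""
    kwargs = dict(
        n_genes=1500,
        n_snps=300,
        deg_architecture={k: dict(v) for k, v in SMALL_ARCH.items()},
        n_modules=2,
        module_sizes=(60, 40),
        trait_loadings={1: {"BW": 0.6}, 2: {"AFI": 0.5}},
        module_pop_shift={1: 0.8},
        seed=7,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


def planted_expression(
    rng: np.random.Generator,
    n_samples: int = 50,
    block_sizes: tuple = (60, 60, 60),
    n_noise: int = 120,
    rho: float = 0.7,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Correlated blocks plus i.i.d. noise genes; returns (expr, truth labels).

    Block genes share a latent factor with within-block correlation ``rho``;
    truth label 0 marks noise genes.
    """
    cols, truth = [], []
    for b, size in enumerate(block_sizes, start=1):
        latent = rng.standard_normal(n_samples)
        for _ in range(size):
            cols.append(np.sqrt(rho) * latent + np.sqrt(1 - rho) * rng.standard_normal(n_samples))
            truth.append(b)
    for _ in range(n_noise):
        cols.append(rng.standard_normal(n_samples))
        truth.append(0)
    expr = pd.DataFrame(
        np.column_stack(cols), columns=[f"g{i:04d}" for i in range(len(cols))]
    )
    return expr, np.asarray(truth)


def one_layer_metadata(
    n_pop1: int = 16, n_pop2: int = 21, layer: str = "UC", seed: int = 0
) -> pd.DataFrame:
    """Single-layer, single-sex metadata for focused DE tests (16 vs 21 is
    the male-stratum sample split of the reference cohort)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pop1 + n_pop2):
        rows.append(
            {
                "sample_id": f"S{i:03d}_{layer}",
                "pair_id": f"S{i:03d}",
                "population": "Tibetan" if i < n_pop1 else "Han",
                "infant_sex": "male",
                "layer": layer,
                "maternal_age": float(np.round(rng.normal(28, 4), 1)),
            }
        )
    return pd.DataFrame(rows)


def nb_counts(
    rng: np.random.Generator,
    metadata: pd.DataFrame,
    n_genes: int = 2000,
    lfc: dict | None = None,
) -> pd.DataFrame:
    """NB counts with optional injected population log2 fold changes."""
    baseline = 2.0 ** rng.normal(5, 2, n_genes)
    disp = np.maximum(rng.gamma(2.0, 0.05, n_genes), 1e-4)
    lib = np.exp(rng.normal(0, 0.3, len(metadata)))
    beta = np.zeros(n_genes)
    for idx, v in (lfc or {}).items():
        beta[idx] = v
    is_pop1 = (metadata["population"] == "Tibetan").to_numpy(float)
    mu = lib[None, :] * baseline[:, None] * 2.0 ** np.outer(beta, is_pop1)
    r = 1.0 / disp
    y = rng.negative_binomial(r[:, None], r[:, None] / (r[:, None] + mu))
    return pd.DataFrame(
        y, index=[f"G{i:05d}" for i in range(n_genes)], columns=metadata["sample_id"]
    )
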