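"""Shared fixtures: small seeded genotype datasets and cohort pairs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gremlkit.datasets import MISSING, GenotypeDataset, VariantRecord


def make_dataset(
    n_variants: int,
    n_samples: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    prefix: str = "f",
    alleles: tuple[str, str] = ("A", "G"),
) -> GenotypeDataset:
    """Random hard-call dataset with Hardy-Weinberg-ish genotypes."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_variants)
    calls = rng.binomial(2, p[:, None], size=(n_variants, n_samples)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING
    variants = [
        VariantRecord(f"rs{i}", "1", (i + 1) * 1000, alleles[0], alleles[1])
        for i in range(n_variants)
    ]
    samples = pd.DataFrame(
        {
            "fid": [prefix] * n_samples,
            "iid": [f"{prefix}{j}" for j in range(n_samples)],
            "sex": np.zeros(n_samples, dtype=int),
            "phenotype": [-9] * n_samples,
        }
    )
    return GenotypeDataset(variants=variants, samples=samples, calls=calls)


@pytest.fixture
def small_dataset() -> GenotypeDataset:
    return make_dataset(20, 12, seed=7)


@pytest.fixture
def dataset_with_missing() -> GenotypeDataset:
    return make_dataset(30, 25, seed=11, missing_rate=0.1)
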