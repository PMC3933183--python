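"""Shared fixtures: a session-scoped synthetic data set and small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from plastidphylo.simulate import SimConfig, simulate_dataset
from plastidphylo.types import Alignment

SUITE_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """The default-scale synthetic data set (40 taxa, 12 genes)."""
    return simulate_dataset(SimConfig(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    """Ground-truth concatenated codon supermatrix of the default data set."""
    return default_dataset.aligned_matrix()


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_codon_rows(n_taxa: int, n_codons: int, seed: int) -> Alignment:
    """A phased nt alignment of random stop-free codons (gap-free)."""
    rng = np.random.default_rng(seed)
    codons = np.asarray(_SENSE_CODONS)
    rows = [
        "".join(codons[rng.integers(len(codons), size=n_codons)])
        for _ in range(n_taxa)
    ]
    taxa = [f"t{i}" for i in range(n_taxa)]
    return Alignment(taxa, rows, "nt",
                     codon_phase=np.tile([1, 2, 3], n_codons))
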