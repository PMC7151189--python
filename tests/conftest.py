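"""Shared fixtures: hand-written matrices and simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from distscreen.nested_logit_sim import (
    DesignCell,
    sample_item_bank,
    simulate_scored,
)
from distscreen.response_data import ResponseMatrix, score


@pytest.fixture
def tiny_matrix() -> ResponseMatrix:
    """3 persons x 2 items, codes {A,B,C,D}, key (i1->A, i2->C)."""
    df = pd.DataFrame(
        {"i1": ["A", "B", "A"], "i2": ["C", "D", "D"]},
        index=["p1", "p2", "p3"],
    )
    return ResponseMatrix(responses=df, key={"i1": "A", "i2": "C"})


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def simulated_scored(
    seed,
    n_persons=300,
    n_items=10,
    n_distractors=3,
    difficulty="difficult",
    discrimination="moderate",
    nrm="high",
):
    """One simulated, scored dataset under explicit design-cell conditions."""
    cell = DesignCell(
        n_persons=n_persons,
        n_items=n_items,
        n_distractors=n_distractors,
        difficulty=difficulty,
        discrimination=discrimination,
        nrm=nrm,
    )
    gen = np.random.default_rng(seed)
    bank = sample_item_bank(cell, gen)
    return simulate_scored(bank, n_persons, gen)


@pytest.fixture
def scored_small():
    """Moderately sized simulated dataset with discriminating distractors."""
    return simulated_scored(11)
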