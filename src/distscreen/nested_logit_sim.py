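"""2PNL (nested logit) response simulator.

The data-generating model has two stages.  Solution behaviour follows a
two-parameter logistic (2PL) model: person ``j`` with ability ``theta_j``
solves item ``i`` with probability

    P(solve) = 1 / (1 + exp(-(beta_i + alpha_i * theta_j)))

where ``beta_i`` is an easiness intercept (larger = easier) and ``alpha_i``
the discrimination slope.  Conditional on *not* solving, distractor choice
follows Bock's nominal response model (NRM): distractor ``v`` is chosen with
probability

    P(v | not solved) = softmax(zeta_iv + lambda_iv * theta_j)

over the item's ``m_i`` distractors.  The ``lambda`` slopes are the
distractor discrimination parameters the package's effect sizes try to
detect; ``lambda == 0`` for all distractors makes distractor choice
independent of ability given non-solution.

Abilities are drawn i.i.d. standard normal — the conventional default for
IRT simulation.  Design cells cross sample size, test length, number of
distractors, 2PL difficulty and discrimination levels, and an NRM
discrimination level whose fixed lambda grids are tabulated in
:data:`LAMBDA_GRIDS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from distscreen.response_data import ResponseMatrix, ScoredData

__all__ = [
    "Item2PLParams",
    "ItemNRMParams",
    "DesignCell",
    "ItemBank",
    "LAMBDA_GRIDS",
    "BETA_RANGES",
    "ALPHA_RANGES",
    "p_correct",
    "p_options",
    "sample_item_bank",
    "simulate_dataset",
    "example_item_bank",
    "bank_to_frame",
    "bank_from_frame",
]

# Fixed NRM slope grids per (discrimination level, number of distractors).
# Within a level the slopes form an equally spaced, zero-centred ladder; the
# step size (0, 0.40, 1.00, 1.75) indexes overall distractor discrimination.
LAMBDA_GRIDS: dict[tuple[str, int], tuple[float, ...]] = {
    ("zero", 3): (0.0, 0.0, 0.0),
    ("moderate", 3): (-0.40, 0.0, 0.40),
    ("high", 3): (-1.00, 0.0, 1.00),
    ("very_high", 3): (-1.75, 0.0, 1.75),
    ("zero", 7): (0.0,) * 7,
    ("moderate", 7): (-1.20, -0.80, -0.40, 0.0, 0.40, 0.80, 1.20),
    ("high", 7): (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0),
    ("very_high", 7): (-5.25, -3.50, -1.75, 0.0, 1.75, 3.50, 5.25),
}

# Uniform sampling ranges for the 2PL easiness intercept beta per difficulty
# level (negative beta = hard) and the slope alpha per discrimination level.
BETA_RANGES: dict[str, tuple[float, float]] = {
    "moderate": (-0.15, 0.15),
    "difficult": (-1.15, -0.85),
    "very_difficult": (-2.25, -1.85),
}
ALPHA_RANGES: dict[str, tuple[float, float]] = {
    "low": (0.25, 0.55),
    "moderate": (0.85, 1.15),
    "high": (1.60, 1.90),
}

ZETA_RANGE = (-1.0, 1.0)

N_PERSONS_LEVELS = (100, 200, 500)
N_ITEMS_LEVELS = (10, 20, 50)
N_DISTRACTORS_LEVELS = (3, 7)
DIFFICULTY_LEVELS = ("moderate", "difficult", "very_difficult")
DISCRIMINATION_LEVELS = ("low", "moderate", "high")
NRM_LEVELS = ("zero", "moderate", "high", "very_high")


@dataclass(frozen=True)
class Item2PLParams:
    """Solution-stage parameters: slope ``alpha`` and easiness intercept ``beta``."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("alpha and beta must be finite")


@dataclass(frozen=True)
class ItemNRMParams:
    """Distractor-stage parameters: per-distractor intercepts and slopes."""

    zeta: tuple[float, ...]
    lamb: tuple[float, ...]

    def __post_init__(self):
        if len(self.zeta) != len(self.lamb):
            raise ValueError("zeta and lamb must have equal length")
        if len(self.zeta) < 2:
            raise ValueError("an item needs at least two distractors")
        object.__setattr__(self, "zeta", tuple(float(z) for z in self.zeta))
        object.__setattr__(self, "lamb", tuple(float(l) for l in self.lamb))

    @property
    def n_distractors(self) -> int:
        return len(self.zeta)


@dataclass(frozen=True)
class DesignCell:
    """One cell of the factorial simulation design."""

    n_persons: int = 200
    n_items: int = 10
    n_distractors: int = 3
    difficulty: str = "difficult"
    discrimination: str = "moderate"
    nrm: str = "zero"

    def __post_init__(self):
        if self.n_distractors not in N_DISTRACTORS_LEVELS:
            raise ValueError(f"n_distractors must be one of {N_DISTRACTORS_LEVELS}")
        if self.difficulty not in BETA_RANGES:
            raise ValueError(f"unknown difficulty level {self.difficulty!r}")
        if self.discrimination not in ALPHA_RANGES:
            raise ValueError(f"unknown discrimination level {self.discrimination!r}")
        if (self.nrm, self.n_distractors) not in LAMBDA_GRIDS:
            raise ValueError(f"unknown NRM level {self.nrm!r}")
        if self.n_persons < 0 or self.n_items < 1:
            raise ValueError("n_persons must be >= 0 and n_items >= 1")

    def label(self) -> str:
        return (
            f"N{self.n_persons}_I{self.n_items}_D{self.n_distractors}"
            f"_{self.difficulty}_{self.discrimination}_{self.nrm}"
        )


@dataclass(frozen=True)
class ItemBank:
    """Sampled item parameters for one simulated test.

    Arrays are ordered by item; ``zeta``/``lamb`` have one column per
    distractor.  Option codes follow the package convention: ``"0"`` is the
    correct option, ``"1"``..``"m"`` label the distractors in slope order.
    """

    alpha: np.ndarray          # (I,)
    beta: np.ndarray           # (I,)
    zeta: np.ndarray           # (I, m)
    lamb: np.ndarray           # (I, m)
    cell: DesignCell | None = None
    seed: object | None = None

    @property
    def n_items(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_distractors(self) -> int:
        return self.zeta.shape[1]

    @property
    def item_ids(self) -> list[str]:
        return [f"i{k + 1}" for k in range(self.n_items)]

    @property
    def option_codes(self) -> tuple[str, ...]:
        return tuple(str(k) for k in range(self.n_distractors + 1))

    def item_params(self, j: int) -> tuple[Item2PLParams, ItemNRMParams]:
        return (
            Item2PLParams(alpha=float(self.alpha[j]), beta=float(self.beta[j])),
            ItemNRMParams(zeta=tuple(self.zeta[j]), lamb=tuple(self.lamb[j])),
        )


def p_correct(theta, item: Item2PLParams):
    """2PL solving probability: logistic(beta + alpha * theta)."""
    return expit(item.beta + item.alpha * np.asarray(theta, dtype=float))


def p_options(theta: float, item_2pl: Item2PLParams, item_nrm: ItemNRMParams) -> np.ndarray:
    """Full option-probability vector at ability *theta*.

    Entry 0 is the probability of the correct option; entries 1..m are the
    distractor probabilities ``(1 - P_correct) * softmax(zeta + lamb * theta)``.
    The vector sums to one by construction.
    """
    pc = float(p_correct(theta, item_2pl))
    logits = np.asarray(item_nrm.zeta) + np.asarray(item_nrm.lamb) * float(theta)
    cond = softmax(logits)
    return np.concatenate(([pc], (1.0 - pc) * cond))


def sample_item_bank(cell: DesignCell, rng: np.random.Generator) -> ItemBank:
    """Draw an item bank for one design cell.

    Betas and alphas come from the uniform range of the cell's difficulty
    and discrimination level; NRM intercepts are i.i.d. U(-1, 1); NRM slopes
    are the fixed grid for the cell's NRM level (identical for every item in
    the bank, assigned to distractor slots in grid order).
    """
    I, m = cell.n_items, cell.n_distractors
    beta = rng.uniform(*BETA_RANGES[cell.difficulty], size=I)
    alpha = rng.uniform(*ALPHA_RANGES[cell.discrimination], size=I)
    zeta = rng.uniform(*ZETA_RANGE, size=(I, m))
    lamb = np.tile(np.asarray(LAMBDA_GRIDS[(cell.nrm, m)], dtype=float), (I, 1))
    return ItemBank(alpha=alpha, beta=beta, zeta=zeta, lamb=lamb, cell=cell)


def simulate_dataset(
    bank: ItemBank,
    n_persons: int,
    rng: np.random.Generator,
    return_theta: bool = False,
):
    """Simulate a response matrix from an item bank under the 2PNL.

    Each person draws ``theta ~ N(0, 1)``; solution indicators come from the
    2PL stage and, where the item is unsolved, a distractor is drawn from
    the NRM stage.  Returns a :class:`ResponseMatrix` (option codes "0" for
    correct, "1".."m" for distractors); with ``return_theta=True`` the
    latent ability vector is returned alongside for diagnostics.
    """
    theta = rng.standard_normal(n_persons)
    labels = simulate_labels(bank, theta, rng)
    codes = np.char.mod("%d", labels)
    df = pd.DataFrame(
        codes.astype(object),
        index=[f"p{k + 1}" for k in range(n_persons)],
        columns=bank.item_ids,
    )
    key = {item: "0" for item in bank.item_ids}
    universe = {item: bank.option_codes for item in bank.item_ids}
    matrix = ResponseMatrix(responses=df, key=key, option_universe=universe)
    if return_theta:
        return matrix, theta
    return matrix


def simulate_labels(
    bank: ItemBank, theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Integer response labels (0 = correct, 1..m = distractor) for given thetas.

    Vectorised core of :func:`simulate_dataset`; exposed for the Monte-Carlo
    engine, which skips the string/DataFrame round trip.
    """
    theta = np.asarray(theta, dtype=float)
    n, I, m = theta.shape[0], bank.n_items, bank.n_distractors
    if n == 0:
        return np.zeros((0, I), dtype=np.int16)
    p_solve = expit(bank.beta[None, :] + bank.alpha[None, :] * theta[:, None])
    solved = rng.random((n, I)) < p_solve
    # NRM stage: conditional distractor probabilities via softmax over slots
    logits = bank.zeta[None, :, :] + bank.lamb[None, :, :] * theta[:, None, None]
    logits -= logits.max(axis=2, keepdims=True)
    w = np.exp(logits)
    cum = np.cumsum(w, axis=2)
    u = rng.random((n, I)) * cum[:, :, -1]
    choice = (u[:, :, None] > cum).sum(axis=2)  # 0-based distractor slot
    labels = np.where(solved, 0, choice + 1).astype(np.int16)
    return labels


def scored_from_labels(bank: ItemBank, labels: np.ndarray) -> ScoredData:
    """Wrap integer response labels in a :class:`ScoredData` directly.

    Equivalent to ``score(simulate_dataset(...))`` — the option codes
    "0".."m" map one-to-one onto the integer labels — but skips the string
    DataFrame round trip.  Used by the Monte-Carlo engine.
    """
    n, I = labels.shape
    correct = labels == 0
    return ScoredData(
        persons=np.asarray([f"p{k + 1}" for k in range(n)], dtype=object),
        items=np.asarray(bank.item_ids, dtype=object),
        correct=correct,
        labels=labels.astype(np.int16),
        distractor_codes=tuple(
            tuple(str(k) for k in range(1, bank.n_distractors + 1))
            for _ in range(I)
        ),
        total_score=correct.sum(axis=1).astype(np.int64),
    )


def simulate_scored(
    bank: ItemBank,
    n_persons: int,
    rng: np.random.Generator,
    return_theta: bool = False,
):
    """Simulate and score in one step (same draws as :func:`simulate_dataset`)."""
    theta = rng.standard_normal(n_persons)
    labels = simulate_labels(bank, theta, rng)
    scored = scored_from_labels(bank, labels)
    if return_theta:
        return scored, theta
    return scored


def example_item_bank(nrm: str, rng: np.random.Generator) -> ItemBank:
    """Item bank for the worked illustration datasets.

    Ten difficult items with moderate 2PL discrimination and three
    distractors; the NRM level distinguishes the non-discriminating
    (``"zero"``) from the discriminating (``"high"``) illustration.  The
    illustration reports item 1 of the bank, analysed at N = 10,000.
    """
    cell = DesignCell(
        n_persons=10_000,
        n_items=10,
        n_distractors=3,
        difficulty="difficult",
        discrimination="moderate",
        nrm=nrm,
    )
    return sample_item_bank(cell, rng)


def bank_to_frame(bank: ItemBank) -> pd.DataFrame:
    """Item-parameter table (item, alpha, beta, zeta_1..m, lambda_1..m)."""
    m = bank.n_distractors
    data = {"item": bank.item_ids, "alpha": bank.alpha, "beta": bank.beta}
    for k in range(m):
        data[f"zeta_{k + 1}"] = bank.zeta[:, k]
    for k in range(m):
        data[f"lambda_{k + 1}"] = bank.lamb[:, k]
    return pd.DataFrame(data)


def bank_from_frame(df: pd.DataFrame) -> ItemBank:
    """Inverse of :func:`bank_to_frame`."""
    zcols = sorted(
        (c for c in df.columns if c.startswith("zeta_")),
        key=lambda c: int(c.split("_")[1]),
    )
    lcols = sorted(
        (c for c in df.columns if c.startswith("lambda_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if len(zcols) != len(lcols) or not zcols:
        raise ValueError("parameter table needs matching zeta_*/lambda_* columns")
    return ItemBank(
        alpha=df["alpha"].to_numpy(dtype=float),
        beta=df["beta"].to_numpy(dtype=float),
        zeta=df[zcols].to_numpy(dtype=float),
        lamb=df[lcols].to_numpy(dtype=float),
    )
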