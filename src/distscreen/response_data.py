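"""Response-matrix container, scoring and delimited-text I/O.

Everything downstream (effect sizes, the simulation study) consumes the two
types defined here: :class:`ResponseMatrix` holds raw categorical option
codes together with the scoring key, and :class:`ScoredData` holds the
derived binary correctness, distractor labels and number-correct scores.
Scores are plain number-correct sums; no latent ability estimates are used
anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseMatrix",
    "ScoredData",
    "read_responses",
    "write_responses",
    "score",
    "nonsolver_view",
]


class ResponseDataError(ValueError):
    """Raised for malformed response files or inconsistent keys/universes."""


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items matrix of categorical option codes plus scoring key.

    Parameters
    ----------
    responses
        DataFrame with one row per person (index = person identifiers) and
        one column per item (columns = item identifiers); cells are opaque
        string option codes.
    key
        Mapping from item identifier to the correct option code.
    option_universe
        Mapping from item identifier to the tuple of legal codes for that
        item (the correct code plus ``m_i`` distractor codes).  When not
        supplied it is derived as codes observed in the data united with the
        key code.
    """

    responses: pd.DataFrame
    key: Mapping[str, str]
    option_universe: Mapping[str, tuple[str, ...]] = field(default=None)

    def __post_init__(self) -> None:
        resp = self.responses
        if resp.index.has_duplicates:
            dupes = resp.index[resp.index.duplicated()].unique().tolist()
            raise ResponseDataError(f"duplicate person identifier(s): {dupes}")
        if resp.columns.has_duplicates:
            raise ResponseDataError("duplicate item identifiers in response matrix")
        items = list(resp.columns)
        missing_key = [i for i in items if i not in self.key]
        if missing_key:
            raise ResponseDataError(f"items without a key entry: {missing_key}")
        unknown = [i for i in self.key if i not in set(items)]
        if unknown:
            raise ResponseDataError(f"unknown item(s) in key: {unknown}")
        if resp.isna().any().any():
            raise ResponseDataError("missing response cells in ResponseMatrix")
        if self.option_universe is None:
            universe = {}
            for item in items:
                observed = set(resp[item].unique())
                universe[item] = tuple(sorted(observed | {self.key[item]}))
            object.__setattr__(self, "option_universe", universe)
        else:
            for item in items:
                if item not in self.option_universe:
                    raise ResponseDataError(f"no option universe for item {item!r}")
                legal = set(self.option_universe[item])
                if self.key[item] not in legal:
                    raise ResponseDataError(
                        f"key code {self.key[item]!r} for item {item!r} "
                        "is outside its option universe"
                    )
                observed = set(resp[item].unique())
                illegal = observed - legal
                if illegal:
                    raise ResponseDataError(
                        f"item {item!r}: codes {sorted(illegal)} outside the "
                        "declared option universe"
                    )

    @property
    def persons(self) -> list:
        return list(self.responses.index)

    @property
    def items(self) -> list:
        return list(self.responses.columns)

    @property
    def n_persons(self) -> int:
        return len(self.responses.index)

    @property
    def n_items(self) -> int:
        return len(self.responses.columns)

    def distractor_codes(self, item) -> tuple[str, ...]:
        """Legal distractor codes of *item*, in deterministic (sorted) order."""
        correct = self.key[item]
        return tuple(c for c in self.option_universe[item] if c != correct)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        return (
            self.responses.equals(other.responses)
            and dict(self.key) == dict(other.key)
            and {k: tuple(v) for k, v in self.option_universe.items()}
            == {k: tuple(v) for k, v in other.option_universe.items()}
        )


@dataclass(frozen=True)
class ScoredData:
    """Derived scores for a :class:`ResponseMatrix`.

    ``labels`` encodes each cell as an integer: 0 for the correct option and
    ``k`` (1-based) for the k-th distractor of that item in the order given
    by ``distractor_codes``.  A distractor label is meaningful exactly where
    ``correct`` is False.
    """

    persons: np.ndarray          # person identifiers, file order
    items: np.ndarray            # item identifiers, file order
    correct: np.ndarray          # bool, persons x items
    labels: np.ndarray           # int16, persons x items; 0 = correct
    distractor_codes: tuple      # per item: tuple of distractor codes
    total_score: np.ndarray      # int, per person

    @cached_property
    def rest_score(self) -> np.ndarray:
        """Persons x items: total score minus the item's own correctness."""
        return self.total_score[:, None] - self.correct.astype(np.int64)

    @property
    def n_persons(self) -> int:
        return self.correct.shape[0]

    @property
    def n_items(self) -> int:
        return self.correct.shape[1]

    def item_index(self, item) -> int:
        idx = np.flatnonzero(self.items == item)
        if idx.size == 0:
            raise KeyError(f"unknown item {item!r}")
        return int(idx[0])

    def distractor_label(self, item) -> np.ndarray:
        """Per-person distractor code for *item*; None where the item was solved."""
        j = self.item_index(item)
        codes = self.distractor_codes[j]
        out = np.empty(self.n_persons, dtype=object)
        lab = self.labels[:, j]
        for k, code in enumerate(codes, start=1):
            out[lab == k] = code
        out[self.correct[:, j]] = None
        return out


def read_responses(
    path,
    key_path,
    universe_path=None,
    missing: str = "error",
) -> ResponseMatrix:
    """Read a response CSV and key CSV into a validated :class:`ResponseMatrix`.

    The response file has a header row of item identifiers, a first column
    of person identifiers, and option codes as cells.  The key file has two
    columns (item, correct code).  An optional universe file lists one
    (item, code) pair per row and fixes the legal codes explicitly.

    Parameters
    ----------
    missing
        ``"error"`` (default) rejects any empty cell; ``"drop"`` removes
        persons with incomplete rows (the number dropped is recorded on the
        returned matrix via the ``attrs`` of its DataFrame).
    """
    if missing not in {"error", "drop"}:
        raise ValueError(f"missing policy must be 'error' or 'drop', got {missing!r}")
    resp = pd.read_csv(path, dtype=str, index_col=0, keep_default_na=False)
    resp = resp.replace("", np.nan)
    if resp.isna().any().any():
        if missing == "error":
            n_bad = int(resp.isna().any(axis=1).sum())
            raise ResponseDataError(
                f"missing response cells for {n_bad} person(s) "
                f"(policy=error) in {path}"
            )
        before = len(resp)
        resp = resp.dropna(axis=0, how="any")
        resp.attrs["n_dropped_persons"] = before - len(resp)
    else:
        resp.attrs["n_dropped_persons"] = 0

    key_df = pd.read_csv(key_path, dtype=str, keep_default_na=False)
    if key_df.shape[1] < 2:
        raise ResponseDataError(f"key file {key_path} needs (item, code) columns")
    key = dict(zip(key_df.iloc[:, 0], key_df.iloc[:, 1]))

    universe = None
    if universe_path is not None:
        uni_df = pd.read_csv(universe_path, dtype=str, keep_default_na=False)
        universe = {}
        for item, sub in uni_df.groupby(uni_df.columns[0], sort=False):
            universe[item] = tuple(dict.fromkeys(sub.iloc[:, 1]))
    return ResponseMatrix(responses=resp, key=key, option_universe=universe)


def write_responses(
    matrix: ResponseMatrix,
    path,
    key_path=None,
    universe_path=None,
) -> None:
    """Write a :class:`ResponseMatrix` back to CSV (inverse of :func:`read_responses`)."""
    matrix.responses.to_csv(path, index_label="person")
    if key_path is not None:
        pd.DataFrame(
            {"item": matrix.items, "correct_code": [matrix.key[i] for i in matrix.items]}
        ).to_csv(key_path, index=False)
    if universe_path is not None:
        rows = [
            {"item": item, "code": code}
            for item in matrix.items
            for code in matrix.option_universe[item]
        ]
        pd.DataFrame(rows).to_csv(universe_path, index=False)


def score(matrix: ResponseMatrix) -> ScoredData:
    """Number-correct scoring of a response matrix.

    Produces the binary correctness matrix, integer-encoded distractor
    labels, total scores and (lazily) rest scores used by every statistic in
    :mod:`distscreen.distractor_stats`.
    """
    items = matrix.items
    n_persons = matrix.n_persons
    n_items = matrix.n_items
    correct = np.zeros((n_persons, n_items), dtype=bool)
    labels = np.zeros((n_persons, n_items), dtype=np.int16)
    codes_per_item = []
    values = matrix.responses.to_numpy(dtype=object)
    for j, item in enumerate(items):
        col = values[:, j]
        key_code = matrix.key[item]
        correct[:, j] = col == key_code
        dcodes = matrix.distractor_codes(item)
        codes_per_item.append(dcodes)
        for k, code in enumerate(dcodes, start=1):
            labels[col == code, j] = k
    total = correct.sum(axis=1).astype(np.int64)
    return ScoredData(
        persons=np.asarray(matrix.persons, dtype=object),
        items=np.asarray(items, dtype=object),
        correct=correct,
        labels=labels,
        distractor_codes=tuple(codes_per_item),
        total_score=total,
    )


def nonsolver_view(scored: ScoredData, item):
    """Distractor labels and scores of the persons who did not solve *item*.

    Returns ``(labels, total_score, rest_score)`` restricted to non-solvers,
    in stable person order.  ``labels`` are the 1-based integer distractor
    indices of :class:`ScoredData`.
    """
    j = scored.item_index(item)
    mask = ~scored.correct[:, j]
    return (
        scored.labels[mask, j],
        scored.total_score[mask],
        scored.rest_score[mask, j],
    )
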