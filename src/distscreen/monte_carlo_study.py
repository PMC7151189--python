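"""Factorial simulation study of the distractor effect sizes.

The design crosses six data-generating facets — sample size (100/200/500),
test length (10/20/50), distractors per item (3/7), 2PL difficulty
(moderate/difficult/very difficult), 2PL discrimination (low/moderate/high)
and NRM distractor discrimination (zero/moderate/high/very high) — into
3 x 3 x 2 x 3 x 3 x 4 = 648 cells.  Each cell is replicated by simulating
datasets, analysing every item, and pooling the item x replicate effect
sizes into:

* detection rates — the proportion of non-missing effect sizes exceeding a
  threshold (type-I error under NRM level "zero", power otherwise);
* substance diagnostics — proportions of sparse distractors (< 5% choice),
  missing effect sizes (with the share attributable to the 5% screen), and
  realized ability groups.

Summaries report the percentage of design cells with acceptable type-I
error (rate <= 0.05) and adequate power (>= 0.80), the latter optionally
under boundary conditions on the item's mean Goodman-Kruskal gamma
(> 0.30) or mean PB_DC (< -0.30).

Reproducibility: each (cell, replicate) pair derives its own RNG substream
from the master seed and the cell's position in the canonical 648-cell
cross, so results are bit-identical regardless of execution order or which
subset of cells is run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from distscreen.distractor_stats import (
    NA_INSUFFICIENT,
    AnalysisConfig,
    analyze_item,
)
from distscreen.nested_logit_sim import (
    DIFFICULTY_LEVELS,
    DISCRIMINATION_LEVELS,
    N_DISTRACTORS_LEVELS,
    N_ITEMS_LEVELS,
    N_PERSONS_LEVELS,
    NRM_LEVELS,
    DesignCell,
    sample_item_bank,
    simulate_scored,
)

__all__ = [
    "StudyConfig",
    "StudyCellResult",
    "build_design",
    "cell_index",
    "run_cell",
    "run_cells",
    "aggregate_records",
    "summarize_type1",
    "summarize_power",
    "substance_summary",
    "MEASURES",
]

MEASURES = ("r_cc", "omega2", "omega5")

# facet order of the canonical full cross
_FACETS = (
    ("n_persons", N_PERSONS_LEVELS),
    ("n_items", N_ITEMS_LEVELS),
    ("n_distractors", N_DISTRACTORS_LEVELS),
    ("difficulty", DIFFICULTY_LEVELS),
    ("discrimination", DISCRIMINATION_LEVELS),
    ("nrm", NRM_LEVELS),
)


@dataclass(frozen=True)
class StudyConfig:
    """Replication counts, thresholds and decision rules of the study."""

    reps: int = 1000
    thresholds: tuple[float, ...] = (0.10, 0.30, 0.50)
    alpha_acceptable: float = 0.05
    power_adequate: float = 0.80
    boundary_gamma: float = 0.30
    boundary_pb_dc: float = -0.30
    master_seed: int = 0
    measures: tuple[str, ...] = MEASURES
    compute_boundary: bool = True
    analysis: AnalysisConfig = field(default=None)

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for t in self.thresholds:
            if not 0 < t < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")
        if self.analysis is None:
            groups = tuple(
                int(m[len("omega"):]) for m in self.measures if m.startswith("omega")
            )
            object.__setattr__(
                self,
                "analysis",
                AnalysisConfig(
                    omega_groups=groups,
                    per_distractor=False,
                    boundary_stats=self.compute_boundary,
                    # empty measures = substance-only mode (screens and
                    # missingness bookkeeping without effect-size values)
                    effect_sizes=bool(self.measures),
                ),
            )


@dataclass(frozen=True)
class StudyCellResult:
    """Pooled item x replicate records and aggregate rates for one cell.

    ``records`` holds one row per simulated item (columns: the effect-size
    measures, ``mean_gamma``/``mean_pb_dc`` when boundary statistics were
    computed, ``n_below_5pct``, per-measure 5%-screen missingness flags and
    realized group counts).  Aggregates follow the study's dependent
    variables: detection rates over non-missing effect sizes, missingness
    and sparse-distractor proportions, and group-realization rates.
    """

    cell: DesignCell
    reps: int
    records: pd.DataFrame
    detection_rate: Mapping[tuple[str, float], float]
    missing_rate: Mapping[str, float]
    missing_due_to_5pct_rate: Mapping[str, float]
    below_5pct_distractor_rate: float
    group_realization_rate: Mapping[str, float]

    @property
    def n_records(self) -> int:
        return len(self.records)


def build_design(filter: Callable[[DesignCell], bool] | None = None) -> list[DesignCell]:
    """The full 648-cell cross (canonical order), optionally filtered.

    The filter receives a :class:`DesignCell` and keeps it on True; e.g.
    ``lambda c: c.nrm == "zero"`` selects the 162 null cells.
    """
    names = [n for n, _ in _FACETS]
    cells = [
        DesignCell(**dict(zip(names, combo)))
        for combo in itertools.product(*(levels for _, levels in _FACETS))
    ]
    if filter is not None:
        cells = [c for c in cells if filter(c)]
    return cells


def cell_index(cell: DesignCell) -> int:
    """Position of a cell in the canonical full cross (seed derivation)."""
    idx = 0
    for name, levels in _FACETS:
        idx = idx * len(levels) + levels.index(getattr(cell, name))
    return idx


def _rep_rng(config: StudyConfig, cell: DesignCell, rep: int) -> np.random.Generator:
    return np.random.default_rng([config.master_seed, cell_index(cell), rep])


def run_cell(cell: DesignCell, config: StudyConfig) -> StudyCellResult:
    """Replicate one design cell: sample bank, simulate, analyse every item.

    Each replicate draws a fresh item bank and dataset from the cell's RNG
    substream, runs :func:`distscreen.distractor_stats.analyze_item` on
    every item, and appends one record per item.  Aggregation pools all
    item x replicate effect sizes; detection denominators exclude missing
    values.
    """
    acfg = config.analysis
    want = {m: m in config.measures for m in MEASURES}
    rows_measure: dict[str, list] = {m: [] for m in MEASURES if want[m]}
    rows_5pct: dict[str, list] = {m: [] for m in MEASURES if want[m]}
    rows_realized: dict[str, list] = {
        m: [] for m in ("omega2", "omega5") if want.get(m)
    }
    mean_gamma_rows: list = []
    mean_pbdc_rows: list = []
    n_below_rows: list = []

    for rep in range(config.reps):
        rng = _rep_rng(config, cell, rep)
        bank = sample_item_bank(cell, rng)
        scored = simulate_scored(bank, cell.n_persons, rng)
        for item in scored.items:
            res = analyze_item(scored, item, acfg)
            if want["r_cc"]:
                rows_measure["r_cc"].append(res.r_cc)
                rows_5pct["r_cc"].append(
                    res.na_reasons.get("r_cc") == NA_INSUFFICIENT
                )
            for G, key in ((2, "omega2"), (5, "omega5")):
                if want[key]:
                    rows_measure[key].append(res.omega_by_G.get(G, np.nan))
                    rows_5pct[key].append(
                        res.na_reasons.get(key) == NA_INSUFFICIENT
                    )
                    rows_realized[key].append(res.omega_realized_groups.get(G, 0))
            if config.compute_boundary:
                mean_gamma_rows.append(res.mean_gamma)
                mean_pbdc_rows.append(res.mean_pb_dc)
            n_below_rows.append(res.n_below_5pct)

    records = pd.DataFrame({m: np.asarray(v, dtype=float) for m, v in rows_measure.items()})
    for m, flags in rows_5pct.items():
        records[f"{m}_missing_5pct"] = np.asarray(flags, dtype=bool)
    for m, counts in rows_realized.items():
        records[f"{m}_realized_groups"] = np.asarray(counts, dtype=int)
    if config.compute_boundary:
        records["mean_gamma"] = np.asarray(mean_gamma_rows, dtype=float)
        records["mean_pb_dc"] = np.asarray(mean_pbdc_rows, dtype=float)
    records["n_below_5pct"] = np.asarray(n_below_rows, dtype=int)
    return aggregate_records(cell, config.reps, records, config)


def aggregate_records(
    cell: DesignCell, reps: int, records: pd.DataFrame, config: StudyConfig
) -> StudyCellResult:
    """Recompute all cell-level rates from an item-record table.

    Used by :func:`run_cell` and when reloading archived records (e.g. on
    resumption): the stored aggregates are always exactly reproducible from
    the records.
    """
    measures = [m for m in MEASURES if m in records.columns]
    detection: dict[tuple[str, float], float] = {}
    missing: dict[str, float] = {}
    missing5: dict[str, float] = {}
    realized_rate: dict[str, float] = {}
    for m in measures:
        vals = records[m].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        missing[m] = float(1.0 - ok.mean()) if vals.size else np.nan
        missing5[m] = (
            float(records[f"{m}_missing_5pct"].to_numpy().mean()) if vals.size else np.nan
        )
        for t in config.thresholds:
            detection[(m, t)] = float((vals[ok] > t).mean()) if ok.any() else np.nan
        col = f"{m}_realized_groups"
        if col in records.columns:
            G = int(m[len("omega"):])
            arr = records[col].to_numpy(dtype=float)
            realized_rate[m] = float(arr.sum() / (G * arr.size)) if arr.size else np.nan
    n_below = records["n_below_5pct"].to_numpy(dtype=float)
    below_rate = (
        float(n_below.sum() / (cell.n_distractors * n_below.size))
        if n_below.size
        else np.nan
    )
    return StudyCellResult(
        cell=cell,
        reps=reps,
        records=records,
        detection_rate=detection,
        missing_rate=missing,
        missing_due_to_5pct_rate=missing5,
        below_5pct_distractor_rate=below_rate,
        group_realization_rate=realized_rate,
    )


def run_cells(
    cells: Sequence[DesignCell],
    config: StudyConfig,
    progress: Callable[[DesignCell, int, int], None] | None = None,
) -> list[StudyCellResult]:
    """Run a list of cells sequentially (substreams make order irrelevant)."""
    out = []
    for k, cell in enumerate(cells):
        out.append(run_cell(cell, config))
        if progress is not None:
            progress(cell, k + 1, len(cells))
    return out


def _non_nrm_facets(cell: DesignCell) -> tuple:
    return (
        cell.n_persons,
        cell.n_items,
        cell.n_distractors,
        cell.difficulty,
        cell.discrimination,
    )


def summarize_type1(
    results: Sequence[StudyCellResult], config: StudyConfig
) -> pd.DataFrame:
    """Percentage of null cells with acceptable type-I error, per measure x threshold.

    Only accepts results from NRM level "zero" cells.  Besides one row per
    threshold, an ``"all"`` row aggregates the 0.30 and 0.50 thresholds by
    counting cell x threshold combinations.
    """
    bad = [r.cell.label() for r in results if r.cell.nrm != "zero"]
    if bad:
        raise ValueError(f"type-I summary requires nrm='zero' cells only; got {bad[:3]}")
    measures = [m for m in MEASURES if m in config.measures]
    rows = {}
    for t in config.thresholds:
        rows[t] = {
            m: 100.0
            * np.mean(
                [r.detection_rate[(m, t)] <= config.alpha_acceptable for r in results]
            )
            for m in measures
        }
    agg = [t for t in (0.30, 0.50) if t in config.thresholds]
    if agg:
        rows["all"] = {
            m: 100.0
            * np.mean(
                [
                    r.detection_rate[(m, t)] <= config.alpha_acceptable
                    for r in results
                    for t in agg
                ]
            )
            for m in measures
        }
    return pd.DataFrame(rows).T[measures]


def _cell_power(
    result: StudyCellResult, measure: str, threshold: float, boundary: str, config: StudyConfig
) -> float:
    vals = result.records[measure].to_numpy()
    ok = ~np.isnan(vals)
    if not ok.any():
        return np.nan
    detected = vals > threshold
    if boundary == "gamma":
        b = result.records["mean_gamma"].to_numpy()
        detected &= b > config.boundary_gamma
    elif boundary == "pb_dc":
        b = result.records["mean_pb_dc"].to_numpy()
        detected &= b < config.boundary_pb_dc
    elif boundary != "none":
        raise ValueError(f"unknown boundary {boundary!r}")
    return float(detected[ok].mean())


def summarize_power(
    results: Sequence[StudyCellResult],
    config: StudyConfig,
    boundary: str = "none",
    null_results: Sequence[StudyCellResult] | None = None,
) -> pd.DataFrame:
    """Percentage of cells with adequate power, per NRM level x measure x threshold.

    Only accepts non-null cells.  When ``null_results`` is given, any
    (measure, threshold, non-NRM facet combination) whose null counterpart
    exceeded the acceptable type-I rate is screened out first; screened
    cells stay in the denominator but cannot count as adequate.  A
    detection under ``boundary="gamma"``/``"pb_dc"`` additionally requires
    the item's mean gamma > 0.30 / mean PB_DC < -0.30, so boundary power
    never exceeds unconditional power.
    """
    bad = [r.cell.label() for r in results if r.cell.nrm == "zero"]
    if bad:
        raise ValueError(f"power summary requires non-null cells; got {bad[:3]}")
    measures = [m for m in MEASURES if m in config.measures]
    unacceptable: set[tuple, str, float] = set()
    if null_results is not None:
        for r in null_results:
            for m in measures:
                for t in config.thresholds:
                    if r.detection_rate[(m, t)] > config.alpha_acceptable:
                        unacceptable.add((_non_nrm_facets(r.cell), m, t))
    rows = []
    levels = sorted({r.cell.nrm for r in results}, key=NRM_LEVELS.index)
    for level in levels:
        level_results = [r for r in results if r.cell.nrm == level]
        for t in config.thresholds:
            row = {"nrm": level, "threshold": t}
            for m in measures:
                adequate = 0
                for r in level_results:
                    if (_non_nrm_facets(r.cell), m, t) in unacceptable:
                        continue
                    p = _cell_power(r, m, t, boundary, config)
                    if not np.isnan(p) and p >= config.power_adequate:
                        adequate += 1
                row[m] = 100.0 * adequate / len(level_results)
            rows.append(row)
    return pd.DataFrame(rows)


def substance_summary(results: Sequence[StudyCellResult]) -> dict:
    """Empirical-substance diagnostics aggregated over cells.

    Returns a dict with:

    * ``below_5pct`` — per NRM level, mean percentage of distractors with
      relative choice frequency < 5% (equal cell weights);
    * ``missing`` — per cell x measure, percentage of missing effect sizes,
      with per-measure across-cell maxima in ``max_missing``;
    * ``group_realization_min`` — per measure, the minimum realized-group
      proportion across cells.
    """
    levels = sorted({r.cell.nrm for r in results}, key=NRM_LEVELS.index)
    below = {
        level: 100.0
        * float(
            np.mean(
                [r.below_5pct_distractor_rate for r in results if r.cell.nrm == level]
            )
        )
        for level in levels
    }
    missing_rows = []
    for r in results:
        row = {"cell": r.cell.label(), "nrm": r.cell.nrm}
        for m, v in r.missing_rate.items():
            row[m] = 100.0 * v
            row[f"{m}_due_to_5pct"] = 100.0 * r.missing_due_to_5pct_rate[m]
        missing_rows.append(row)
    missing = pd.DataFrame(missing_rows)
    measures = [m for m in MEASURES if m in missing.columns]
    max_missing = {}
    for m in measures:
        k = int(missing[m].idxmax())
        max_missing[m] = {"cell": missing.loc[k, "cell"], "pct": float(missing[m].max())}
    realization_min = {}
    for m in ("omega2", "omega5"):
        vals = [
            r.group_realization_rate[m]
            for r in results
            if m in r.group_realization_rate
        ]
        if vals:
            realization_min[m] = float(np.min(vals))
    return {
        "below_5pct": below,
        "missing": missing,
        "max_missing": max_missing,
        "group_realization_min": realization_min,
    }
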