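"""Item-level and distractor-level discrimination statistics.

Two effect sizes quantify *ability-related* distractor discrimination at the
item level, using only the non-solvers of an item:

* ``omega_G`` — Cohen's omega, ``sqrt(chi2 / n)``, from the Pearson chi-square
  of the (retained distractor) x (ability group) contingency table of
  non-solvers.  Ability groups are score quantiles (G = 2 and G = 5 by
  default).
* ``R_CC`` — the canonical correlation between the set of distractor-choice
  indicator variables and the non-solvers' total scores.  With one
  continuous variable on the second side this equals the correlation ratio
  (eta) of the one-way distractor-group layout.

Classical per-distractor indices are provided alongside: the point-biserial
against all participants (``PB_D``) and against solvers only (``PB_DC``),
the Haladyna-Downing uniformity omega (``omega_D``), and Goodman-Kruskal's
gamma for the rising-selection-ratio check.  A 5% relative-choice-frequency
screen removes sparse distractors before any item-level statistic is
computed.

All statistics return ``nan`` when undefined; :func:`analyze_item` records
an enumerated ``na_reason`` instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from distscreen.response_data import ScoredData

__all__ = [
    "AnalysisConfig",
    "AbilityGrouping",
    "ItemAnalysisResult",
    "ability_groups",
    "screen_distractors",
    "cohen_omega_G",
    "canonical_correlation",
    "point_biserial_d",
    "point_biserial_dc",
    "haladyna_omega_d",
    "goodman_kruskal_gamma",
    "trace_table",
    "analyze_item",
    "analyze_all_items",
    "item_report_frame",
    "distractor_report_frame",
    "trace_report_frame",
]

# enumerated causes for missing statistics
NA_NO_NONSOLVERS = "no_nonsolvers"
NA_INSUFFICIENT = "insufficient_distractors"
NA_ZERO_VARIANCE = "zero_variance"
NA_DEGENERATE = "degenerate_groups"


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable choices of the item analysis.

    ``min_rel_freq`` is the distractor retention screen (proportion of all
    participants, boundary inclusive).  ``omega_groups`` lists the group
    counts G for which Cohen's omega is reported.  ``grouping_population``
    selects whose scores define the omega quantile breakpoints: the item's
    non-solvers (default, keeps the table columns balanced) or all persons.
    ``per_distractor`` switches the classical per-distractor indices on or
    off; ``boundary_stats`` controls the mean PB_DC / mean gamma summaries
    used as boundary conditions in the simulation study.
    """

    min_rel_freq: float = 0.05
    screen_inclusive: bool = True
    omega_groups: tuple[int, ...] = (2, 5)
    grouping_population: str = "nonsolvers"  # or "all"
    haladyna_groups: int = 5
    per_distractor: bool = True
    boundary_stats: bool = True
    effect_sizes: bool = True
    gamma_weighted: bool = False

    def __post_init__(self):
        if not 0 <= self.min_rel_freq < 1:
            raise ValueError("min_rel_freq must be in [0, 1)")
        if self.grouping_population not in {"nonsolvers", "all"}:
            raise ValueError("grouping_population must be 'nonsolvers' or 'all'")


DEFAULT_CONFIG = AnalysisConfig()


@dataclass(frozen=True)
class AbilityGrouping:
    """Quantile grouping of a score vector into at most G ordered groups."""

    G_requested: int
    breakpoints: np.ndarray   # G_requested - 1 upper breakpoints (scores)
    labels: np.ndarray        # 0-based group index per person
    G_realized: int           # number of non-empty groups


def ability_groups(scores, G: int) -> AbilityGrouping:
    """Assign persons to G ability groups by score quantiles.

    Breakpoint k (k = 1..G-1) is the smallest observed score whose empirical
    CDF reaches k/G; a person falls in the first group whose upper
    breakpoint is >= their score.  With heavily tied integer scores some
    groups can stay empty (``G_realized < G``); ties are never split.
    """
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("cannot group an empty score vector")
    if G < 2:
        raise ValueError("G must be >= 2")
    s = np.sort(scores)
    n = s.size
    idx = np.ceil(n * np.arange(1, G) / G).astype(int) - 1
    breakpoints = s[idx]
    labels = np.searchsorted(breakpoints, scores, side="left")
    realized = np.unique(labels).size
    return AbilityGrouping(
        G_requested=G, breakpoints=breakpoints, labels=labels, G_realized=realized
    )


# ---------------------------------------------------------------------------
# internal cores operating on one item's label/score columns


def _item_columns(scored: ScoredData, item):
    j = scored.item_index(item)
    return (
        j,
        scored.labels[:, j],
        scored.correct[:, j],
        scored.total_score,
        scored.rest_score[:, j],
    )


def _screen(labels_col: np.ndarray, n_distractors: int, config: AnalysisConfig):
    """Retained-distractor mask (length m, slot k-1 = distractor k) and n_below."""
    n = labels_col.shape[0]
    counts = np.bincount(labels_col, minlength=n_distractors + 1)[1:]
    if n == 0:
        retained = np.zeros(n_distractors, dtype=bool)
    else:
        freq = counts / n
        if config.screen_inclusive:
            retained = freq >= config.min_rel_freq
        else:
            retained = freq > config.min_rel_freq
    return retained, int(n_distractors - retained.sum()), counts


def _omega_from_groups(labels_ns, group_labels, retained, G):
    """Cohen's omega given precomputed non-solver group labels.

    Returns (value, na_reason, realized_groups); ``realized_groups`` counts
    the non-empty ability groups among non-solvers regardless of whether
    the statistic itself is computable (it feeds the group-realization
    diagnostic of the simulation study).
    """
    if labels_ns.size == 0:
        return np.nan, NA_NO_NONSOLVERS, 0
    realized_groups = int(np.unique(group_labels).size)
    if retained.sum() < 2:
        return np.nan, NA_INSUFFICIENT, realized_groups
    in_table = retained[labels_ns - 1]
    rows = labels_ns[in_table] - 1
    cols = group_labels[in_table]
    if rows.size == 0:
        return np.nan, NA_INSUFFICIENT, realized_groups
    m = retained.shape[0]
    table = np.bincount(rows * G + cols, minlength=m * G).reshape(m, G)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        reason = NA_INSUFFICIENT if table.shape[0] < 2 else NA_DEGENERATE
        return np.nan, reason, realized_groups
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = ((table - expected) ** 2 / expected).sum()
    return float(np.sqrt(chi2 / n)), None, realized_groups


def _omega_core(labels_ns, totals_ns, retained, G, config):
    """Cohen's omega with quantile groups from the non-solver scores."""
    if labels_ns.size == 0:
        return np.nan, NA_NO_NONSOLVERS, 0
    group_labels = ability_groups(totals_ns, G).labels
    return _omega_from_groups(labels_ns, group_labels, retained, G)


def _omega_core_all_persons(labels_ns, retained, G, grouping_all, ns_mask):
    """Cohen's omega variant with quantile breakpoints from all persons."""
    if labels_ns.size == 0:
        return np.nan, NA_NO_NONSOLVERS, 0
    return _omega_from_groups(labels_ns, grouping_all.labels[ns_mask], retained, G)


def _rcc_core(labels_ns, totals_ns, retained):
    """Canonical correlation of distractor indicators vs. total score.

    Restricted to non-solvers choosing a retained distractor.  Builds K-1
    drop-one indicator variables, forms the vector of their correlations
    with the score and the Cholesky factor of their correlation matrix, and
    takes the (single) singular value of the whitened correlation row.
    Returns (value, na_reason).
    """
    if labels_ns.size == 0:
        return np.nan, NA_NO_NONSOLVERS
    if retained.sum() < 2:
        return np.nan, NA_INSUFFICIENT
    in_table = retained[labels_ns - 1]
    lab = labels_ns[in_table]
    y = totals_ns[in_table].astype(float)
    present = np.unique(lab)
    if present.size < 2:
        return np.nan, NA_INSUFFICIENT
    if y.size < 2:
        return np.nan, NA_INSUFFICIENT
    if np.ptp(y) == 0:
        return np.nan, NA_ZERO_VARIANCE
    X = (lab[:, None] == present[None, :-1]).astype(float)  # drop-one coding
    n = y.size
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    r12 = (Xc.T @ yc) / (sx * sy)
    R1 = (Xc.T @ Xc) / np.outer(sx, sx)
    L = cholesky(R1, lower=True)
    w = solve_triangular(L, r12, lower=True)
    # w is the 1 x (K-1) whitened correlation row; its sole singular value
    # is its Euclidean norm
    val = float(np.linalg.norm(w))
    return min(val, 1.0), None


def _pb_d_core(ind, totals):
    n = totals.size
    if n < 2:
        return np.nan
    p = ind.mean()
    if p <= 0 or p >= 1:
        return np.nan
    s = totals.std(ddof=0)
    if s == 0:
        return np.nan
    m_d = totals[ind].mean()
    m = totals.mean()
    return float((m_d - m) / s * np.sqrt(p / (1 - p)))


def _gamma_core(rest_sub, is_correct_sub, weighted=False):
    """Goodman-Kruskal gamma over the 2 x J (correct vs. D) x rest-score table."""
    if rest_sub.size == 0:
        return np.nan
    scores, inv = np.unique(rest_sub, return_inverse=True)
    J = scores.size
    if J < 2:
        return np.nan
    a = np.bincount(inv[is_correct_sub], minlength=J).astype(float)  # correct row
    b = np.bincount(inv[~is_correct_sub], minlength=J).astype(float)  # D row
    tot = a + b
    p = a / tot
    if weighted:
        wgt = tot
    else:
        wgt = np.ones(J)
    C = 0.0
    D = 0.0
    for jlo in range(J - 1):
        diff = p[jlo + 1 :] - p[jlo]
        wpair = wgt[jlo] * wgt[jlo + 1 :]
        C += wpair[diff > 0].sum()
        D += wpair[diff < 0].sum()
    if C + D == 0:
        return np.nan
    return float((C - D) / (C + D))


# ---------------------------------------------------------------------------
# public per-statistic operations


def screen_distractors(
    scored: ScoredData, item, min_rel_freq: float = 0.05, inclusive: bool = True
):
    """Apply the 5% relative-choice-frequency screen to an item's distractors.

    A distractor is retained iff the proportion of *all* participants who
    chose it reaches ``min_rel_freq`` (boundary inclusive by default).
    Returns ``(retained_codes, n_below)``.
    """
    j, labels_col, _, _, _ = _item_columns(scored, item)
    codes = scored.distractor_codes[j]
    cfg = AnalysisConfig(min_rel_freq=min_rel_freq, screen_inclusive=inclusive)
    retained, n_below, _ = _screen(labels_col, len(codes), cfg)
    return tuple(c for c, keep in zip(codes, retained) if keep), n_below


def cohen_omega_G(
    scored: ScoredData,
    item,
    G: int,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Cohen's omega over G ability groups for one item (nan when undefined).

    The contingency table crosses retained distractors (rows) with score
    quantile groups (columns) over the item's non-solvers; omega is
    ``sqrt(chi2 / n)`` with n the table total.  Empty rows/columns are
    dropped; the statistic is missing with fewer than two retained
    distractors or fewer than two realized groups.
    """
    j, labels_col, correct_col, totals, _ = _item_columns(scored, item)
    retained, _, _ = _screen(labels_col, len(scored.distractor_codes[j]), config)
    ns = ~correct_col
    if config.grouping_population == "all":
        grouping = ability_groups(totals, G)
        val, _, _ = _omega_core_all_persons(labels_col[ns], retained, G, grouping, ns)
    else:
        val, _, _ = _omega_core(labels_col[ns], totals[ns], retained, G, config)
    return val


def canonical_correlation(
    scored: ScoredData, item, config: AnalysisConfig = DEFAULT_CONFIG
) -> float:
    """Canonical correlation R_CC between distractor choice and score (nan when undefined).

    Computed over non-solvers choosing a retained distractor, from K-1
    choice indicator variables against the total score.  Identical to the
    correlation ratio eta of the one-way distractor-group layout.
    """
    j, labels_col, correct_col, totals, _ = _item_columns(scored, item)
    retained, _, _ = _screen(labels_col, len(scored.distractor_codes[j]), config)
    ns = ~correct_col
    val, _ = _rcc_core(labels_col[ns], totals[ns], retained)
    return val


def point_biserial_d(scored: ScoredData, item, distractor) -> float:
    """Point-biserial PB_D: choosers of *distractor* vs. all other participants.

    Equals the Pearson correlation between the choice indicator and the
    total score (population-SD convention).
    """
    j, labels_col, _, totals, _ = _item_columns(scored, item)
    k = scored.distractor_codes[j].index(distractor) + 1
    return _pb_d_core(labels_col == k, totals.astype(float))


def point_biserial_dc(scored: ScoredData, item, distractor) -> float:
    """Point-biserial PB_DC: choosers of *distractor* vs. item solvers only.

    Computed within the subgroup choosing either the distractor or the
    correct option; equals the Pearson correlation between the choice
    indicator and the total score restricted to that subgroup.
    """
    j, labels_col, correct_col, totals, _ = _item_columns(scored, item)
    k = scored.distractor_codes[j].index(distractor) + 1
    chose_d = labels_col == k
    sub = chose_d | correct_col
    if chose_d.sum() == 0 or correct_col.sum() == 0:
        return np.nan
    return _pb_d_core(chose_d[sub], totals[sub].astype(float))


def haladyna_omega_d(scored: ScoredData, item, distractor, G: int = 5) -> float:
    """Haladyna-Downing omega_D: uniformity of one distractor across ability groups.

    Groups all persons into G score-quantile groups, then measures the
    goodness of fit of the distractor's choice counts across the realized
    groups against a uniform distribution: ``sqrt(chi2_D / n_D)``.
    """
    j, labels_col, _, totals, _ = _item_columns(scored, item)
    k = scored.distractor_codes[j].index(distractor) + 1
    grouping = ability_groups(totals, G)
    realized_ids = np.unique(grouping.labels)
    if realized_ids.size < 2:
        return np.nan
    chose = labels_col == k
    n_d = int(chose.sum())
    if n_d == 0:
        return np.nan
    counts = np.array(
        [np.count_nonzero(chose & (grouping.labels == g)) for g in realized_ids],
        dtype=float,
    )
    expected = n_d / realized_ids.size
    chi2 = ((counts - expected) ** 2 / expected).sum()
    return float(np.sqrt(chi2 / n_d))


def goodman_kruskal_gamma(
    scored: ScoredData, item, distractor, weighted: bool = False
) -> float:
    """Goodman-Kruskal gamma for the rising-selection-ratio check.

    Restricted to persons choosing either the correct option or the given
    distractor, a 2 x J table over observed rest-score values yields the
    estimated probability of choosing the correct option at each score
    level; gamma counts concordant/discordant score-level pairs of those
    probabilities (ties dropped; unweighted over levels by default).
    """
    j, labels_col, correct_col, _, _ = _item_columns(scored, item)
    rest = scored.rest_score[:, j]
    k = scored.distractor_codes[j].index(distractor) + 1
    chose_d = labels_col == k
    if chose_d.sum() == 0 or correct_col.sum() == 0:
        return np.nan
    sub = chose_d | correct_col
    return _gamma_core(rest[sub], correct_col[sub], weighted=weighted)


def trace_table(scored: ScoredData, item, G: int = 5) -> pd.DataFrame:
    """Option x ability-group relative-choice-frequency table (trace lines).

    Groups all persons by total-score quantiles; each column (group) gives
    the relative frequency of every response option within that group and
    sums to one.  Index: the correct code first, then distractor codes.
    """
    j, labels_col, _, totals, _ = _item_columns(scored, item)
    grouping = ability_groups(totals, G)
    realized_ids = np.unique(grouping.labels)
    codes = ["correct"] + [f"distractor_{c}" for c in scored.distractor_codes[j]]
    m = len(scored.distractor_codes[j])
    cols = {}
    for g in realized_ids:
        in_g = grouping.labels == g
        counts = np.bincount(labels_col[in_g], minlength=m + 1).astype(float)
        cols[int(g) + 1] = counts / counts.sum()
    return pd.DataFrame(cols, index=codes)


@dataclass(frozen=True)
class ItemAnalysisResult:
    """Full per-item report: screen outcome, effect sizes, classical indices."""

    item: object
    n_persons: int
    n_nonsolvers: int
    retained_distractors: tuple
    n_below_5pct: int
    omega_by_G: Mapping[int, float]
    r_cc: float
    pb_d: Mapping[str, float] = field(default_factory=dict)
    pb_dc: Mapping[str, float] = field(default_factory=dict)
    omega_d: Mapping[str, float] = field(default_factory=dict)
    gamma: Mapping[str, float] = field(default_factory=dict)
    mean_pb_dc: float = np.nan
    mean_gamma: float = np.nan
    na_reason: str | None = None
    na_reasons: Mapping[str, str] = field(default_factory=dict)
    omega_realized_groups: Mapping[int, int] = field(default_factory=dict)


def _nanmean(values) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(np.mean(vals)) if vals else np.nan


def analyze_item(
    scored: ScoredData, item, config: AnalysisConfig = DEFAULT_CONFIG
) -> ItemAnalysisResult:
    """Run the screen and every configured statistic for one item.

    Applies the 5% screen, computes omega_G for each configured G, R_CC,
    and (if configured) the per-distractor indices on retained distractors;
    fills nan plus an enumerated ``na_reason`` where a statistic is
    undefined.
    """
    j, labels_col, correct_col, totals, rest = _item_columns(scored, item)
    codes = scored.distractor_codes[j]
    retained, n_below, _ = _screen(labels_col, len(codes), config)
    retained_codes = tuple(c for c, keep in zip(codes, retained) if keep)
    ns = ~correct_col
    labels_ns = labels_col[ns]
    totals_ns = totals[ns]

    omega_by_G: dict[int, float] = {}
    realized_by_G: dict[int, int] = {}
    na_reasons: dict[str, str] = {}
    r_cc = np.nan
    if config.effect_sizes:
        for G in config.omega_groups:
            if config.grouping_population == "all" and totals.size > 0:
                grouping = ability_groups(totals, G)
                val, reason, realized = _omega_core_all_persons(
                    labels_ns, retained, G, grouping, ns
                )
            else:
                val, reason, realized = _omega_core(
                    labels_ns, totals_ns, retained, G, config
                )
            omega_by_G[G] = val
            realized_by_G[G] = realized
            if reason is not None:
                na_reasons[f"omega{G}"] = reason
        r_cc, rcc_reason = _rcc_core(labels_ns, totals_ns, retained)
        if rcc_reason is not None:
            na_reasons["r_cc"] = rcc_reason
    na_reason = na_reasons.get("r_cc") or next(iter(na_reasons.values()), None)

    pb_d: dict[str, float] = {}
    pb_dc: dict[str, float] = {}
    omega_d: dict[str, float] = {}
    gamma: dict[str, float] = {}
    mean_pb_dc = np.nan
    mean_gamma = np.nan

    if config.per_distractor or config.boundary_stats:
        totals_f = totals.astype(float)
        grouping_all = ability_groups(totals, config.haladyna_groups) if totals.size else None
        n_correct = int(correct_col.sum())
        for k, code in enumerate(codes, start=1):
            if not retained[k - 1]:
                continue
            chose = labels_col == k
            sub = chose | correct_col
            if n_correct > 0 and chose.any():
                pb_dc[code] = _pb_d_core(chose[sub], totals_f[sub])
                gamma[code] = _gamma_core(
                    rest[sub], correct_col[sub], weighted=config.gamma_weighted
                )
            else:
                pb_dc[code] = np.nan
                gamma[code] = np.nan
            if config.per_distractor:
                pb_d[code] = _pb_d_core(chose, totals_f)
                if grouping_all is not None:
                    omega_d[code] = haladyna_omega_d(
                        scored, item, code, G=config.haladyna_groups
                    )
                else:
                    omega_d[code] = np.nan
        mean_pb_dc = _nanmean(pb_dc.values())
        mean_gamma = _nanmean(gamma.values())
        if not config.per_distractor:
            pb_dc = {}
            gamma = {}

    return ItemAnalysisResult(
        item=item,
        n_persons=scored.n_persons,
        n_nonsolvers=int(ns.sum()),
        retained_distractors=retained_codes,
        n_below_5pct=n_below,
        omega_by_G=omega_by_G,
        r_cc=r_cc,
        pb_d=pb_d,
        pb_dc=pb_dc,
        omega_d=omega_d,
        gamma=gamma,
        mean_pb_dc=mean_pb_dc,
        mean_gamma=mean_gamma,
        na_reason=na_reason,
        na_reasons=na_reasons,
        omega_realized_groups=realized_by_G,
    )


def analyze_all_items(
    scored: ScoredData, config: AnalysisConfig = DEFAULT_CONFIG
) -> list[ItemAnalysisResult]:
    """:func:`analyze_item` for every item, in item order."""
    return [analyze_item(scored, item, config) for item in scored.items]


# ---------------------------------------------------------------------------
# tabular report builders (CSV-ready frames)


def item_report_frame(results: Sequence[ItemAnalysisResult]) -> pd.DataFrame:
    """One row per item with the headline screening columns."""
    rows = []
    for r in results:
        row = {
            "item": r.item,
            "n_persons": r.n_persons,
            "n_nonsolvers": r.n_nonsolvers,
            "n_below_5pct": r.n_below_5pct,
            "r_cc": r.r_cc,
            "mean_pb_dc": r.mean_pb_dc,
            "mean_gamma": r.mean_gamma,
            "na_reason": r.na_reason if r.na_reason else "",
        }
        for G, val in r.omega_by_G.items():
            row[f"omega_{G}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def distractor_report_frame(results: Sequence[ItemAnalysisResult]) -> pd.DataFrame:
    """Long per-distractor table: pb_d, pb_dc, omega_d, gamma."""
    rows = []
    for r in results:
        for code in r.retained_distractors:
            rows.append(
                {
                    "item": r.item,
                    "distractor": code,
                    "pb_d": r.pb_d.get(code, np.nan),
                    "pb_dc": r.pb_dc.get(code, np.nan),
                    "omega_d": r.omega_d.get(code, np.nan),
                    "gamma": r.gamma.get(code, np.nan),
                }
            )
    return pd.DataFrame(rows, columns=["item", "distractor", "pb_d", "pb_dc", "omega_d", "gamma"])


def trace_report_frame(scored: ScoredData, G: int = 5) -> pd.DataFrame:
    """Long trace-line table (item, group, option, rel_freq) for all items."""
    rows = []
    for item in scored.items:
        tab = trace_table(scored, item, G=G)
        for option in tab.index:
            for group in tab.columns:
                rows.append(
                    {
                        "item": item,
                        "group": group,
                        "option": option,
                        "rel_freq": tab.loc[option, group],
                    }
                )
    return pd.DataFrame(rows)
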