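"""Effect sizes and classical indices against independent oracles.

Each statistic is checked against a mathematically independent route:
R_CC against the one-way correlation ratio (eta), the point-biserials
against Pearson correlations of choice indicators, Cohen's omega against a
cell-by-cell chi-square recomputation, and gamma against a brute-force
concordance count.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from distscreen.distractor_stats import (
    AnalysisConfig,
    ability_groups,
    analyze_item,
    canonical_correlation,
    cohen_omega_G,
    goodman_kruskal_gamma,
    haladyna_omega_d,
    point_biserial_d,
    point_biserial_dc,
    screen_distractors,
    trace_table,
)
from distscreen.nested_logit_sim import DesignCell, sample_item_bank, simulate_scored
from distscreen.response_data import ResponseMatrix, nonsolver_view, score

from conftest import simulated_scored


def scored_from_codes(columns: dict, key: dict):
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns, index=[f"p{i}" for i in range(n)])
    return score(ResponseMatrix(responses=df, key=key))


# ---------------------------------------------------------------------------
# ability grouping


def test_even_scores_split_in_half():
    g = ability_groups(np.arange(1, 11), 2)
    assert np.bincount(g.labels).tolist() == [5, 5]
    assert g.G_realized == 2


def test_identical_scores_collapse_to_one_group():
    g = ability_groups(np.full(20, 7), 5)
    assert g.G_realized == 1


def test_tied_scores_hand_worked_assignment():
    # scores (0,0,0,1,2,2,3,9), G=4; breakpoints = smallest score with
    # ECDF >= k/4: (0, 1, 2); closed-above intervals give sizes (3,1,2,2)
    g = ability_groups(np.array([0, 0, 0, 1, 2, 2, 3, 9]), 4)
    assert g.breakpoints.tolist() == [0, 1, 2]
    assert g.labels.tolist() == [0, 0, 0, 1, 2, 2, 3, 3]
    assert g.G_realized == 4


def test_empty_scores_rejected():
    with pytest.raises(ValueError):
        ability_groups(np.array([]), 2)


# ---------------------------------------------------------------------------
# 5% screen


def test_screen_boundary_inclusive():
    cols = {"i1": ["B"] * 5 + ["C"] * 4 + ["A"] * 91, "i2": ["X"] * 100}
    scored = scored_from_codes(cols, {"i1": "A", "i2": "X"})
    retained, n_below = screen_distractors(scored, "i1")
    assert retained == ("B",)  # 5/100 kept, 4/100 dropped
    assert n_below == 1


# ---------------------------------------------------------------------------
# Cohen's omega


def test_omega_perfect_association_is_one():
    # 2 distractors x 2 groups, table [[10,0],[0,10]]: chi2=20, n=20
    cols = {
        "i1": ["B"] * 10 + ["C"] * 10,
        **{f"f{k}": ["1"] * 10 + ["0"] * 10 for k in range(4)},
    }
    scored = scored_from_codes(cols, {"i1": "A", **{f"f{k}": "1" for k in range(4)}})
    assert cohen_omega_G(scored, "i1", G=2) == pytest.approx(1.0)


def test_omega_zero_under_proportional_columns():
    # choice shares identical in both groups -> independence -> omega = 0
    half = ["B"] * 6 + ["C"] * 6
    cols = {
        "i1": half + half,
        **{f"f{k}": ["1"] * 12 + ["0"] * 12 for k in range(4)},
    }
    scored = scored_from_codes(cols, {"i1": "A", **{f"f{k}": "1" for k in range(4)}})
    assert cohen_omega_G(scored, "i1", G=2) == pytest.approx(0.0, abs=1e-12)


def test_omega_matches_chi2_recomputed_cell_by_cell():
    for seed in range(40):
        scored = simulated_scored(seed, n_persons=120, n_items=8)
        for item in scored.items:
            for G in (2, 5):
                val = cohen_omega_G(scored, item, G=G)
                oracle = _omega_oracle(scored, item, G)
                if np.isnan(val):
                    assert np.isnan(oracle)
                else:
                    assert val == pytest.approx(oracle, abs=1e-10)


def _omega_oracle(scored, item, G):
    """Independent omega: explicit table loop + scipy chi2_contingency."""
    labels, totals, _ = nonsolver_view(scored, item)
    retained, _ = screen_distractors(scored, item)
    j = scored.item_index(item)
    keep_idx = [scored.distractor_codes[j].index(c) + 1 for c in retained]
    if labels.size == 0 or len(keep_idx) < 2:
        return np.nan
    grouping = ability_groups(totals, G)
    mask = np.isin(labels, keep_idx)
    lab, grp = labels[mask], grouping.labels[mask]
    table = pd.crosstab(lab, grp).to_numpy()
    table = table[table.sum(1) > 0][:, table.sum(0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    return np.sqrt(chi2 / table.sum())


# ---------------------------------------------------------------------------
# canonical correlation


def _eta_oracle(scored, item):
    """Correlation ratio of the one-way distractor-group layout."""
    labels, totals, _ = nonsolver_view(scored, item)
    retained, _ = screen_distractors(scored, item)
    j = scored.item_index(item)
    keep_idx = [scored.distractor_codes[j].index(c) + 1 for c in retained]
    mask = np.isin(labels, keep_idx)
    lab, y = labels[mask], totals[mask].astype(float)
    if np.unique(lab).size < 2 or y.size < 2 or np.ptp(y) == 0:
        return np.nan
    ss_total = ((y - y.mean()) ** 2).sum()
    ss_within = sum(
        ((y[lab == g] - y[lab == g].mean()) ** 2).sum() for g in np.unique(lab)
    )
    return np.sqrt(1 - ss_within / ss_total)


def test_rcc_equals_correlation_ratio():
    for seed in range(60):
        scored = simulated_scored(
            seed,
            n_persons=100,
            n_items=6,
            n_distractors=7 if seed % 2 else 3,
            nrm=("zero", "moderate", "high", "very_high")[seed % 4],
        )
        for item in scored.items:
            val = canonical_correlation(scored, item)
            oracle = _eta_oracle(scored, item)
            if np.isnan(val):
                assert np.isnan(oracle)
            else:
                assert val == pytest.approx(oracle, abs=1e-10)


def test_rcc_invariant_to_dropped_indicator():
    """Dropping any indicator column gives the same canonical correlation."""
    for seed in range(10):
        scored = simulated_scored(seed, n_persons=150, n_items=4)
        for item in scored.items:
            labels, totals, _ = nonsolver_view(scored, item)
            present = np.unique(labels)
            if present.size < 2 or np.ptp(totals) == 0:
                continue
            vals = []
            for drop in range(present.size):
                keep = np.delete(present, drop)
                X = (labels[:, None] == keep[None, :]).astype(float)
                y = totals.astype(float)
                Xc = X - X.mean(0)
                yc = y - y.mean()
                sx = np.sqrt((Xc**2).sum(0))
                r12 = Xc.T @ yc / (sx * np.sqrt((yc**2).sum()))
                R1 = (Xc.T @ Xc) / np.outer(sx, sx)
                vals.append(float(np.sqrt(r12 @ np.linalg.solve(R1, r12))))
            assert np.ptp(vals) < 1e-10


def test_rcc_zero_within_group_variance_is_one():
    # B choosers all score 1, C choosers all score 3: eta = 1
    cols = {
        "i1": ["B", "B", "C", "C"],
        "f1": ["1", "1", "1", "1"],
        "f2": ["0", "0", "1", "1"],
        "f3": ["0", "0", "1", "1"],
    }
    key = {"i1": "A", "f1": "1", "f2": "1", "f3": "1"}
    scored = scored_from_codes(cols, key)
    val = canonical_correlation(scored, "i1", AnalysisConfig(min_rel_freq=0.0))
    assert val == pytest.approx(1.0, abs=1e-10)
    assert val == pytest.approx(_eta_oracle_nofilter(scored, "i1"), abs=1e-12)


def _eta_oracle_nofilter(scored, item):
    labels, totals, _ = nonsolver_view(scored, item)
    y = totals.astype(float)
    ss_total = ((y - y.mean()) ** 2).sum()
    ss_within = sum(
        ((y[labels == g] - y[labels == g].mean()) ** 2).sum() for g in np.unique(labels)
    )
    return np.sqrt(1 - ss_within / ss_total)


def test_rcc_equal_group_means_is_zero():
    cols = {
        "i1": ["B", "B", "C", "C"],
        "f1": ["1", "0", "1", "0"],
        "f2": ["1", "0", "1", "0"],
    }
    key = {"i1": "A", "f1": "1", "f2": "1"}
    scored = scored_from_codes(cols, key)
    # both groups have scores {2, 0}: no between-group variance
    val = canonical_correlation(scored, "i1", AnalysisConfig(min_rel_freq=0.0))
    assert val == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# point-biserials


def test_pb_d_equals_indicator_pearson():
    for seed in range(30):
        scored = simulated_scored(seed, n_persons=90, n_items=6)
        for item in scored.items:
            j = scored.item_index(item)
            for code in scored.distractor_codes[j]:
                ind = (scored.labels[:, j] == int(code)).astype(float)
                if ind.sum() in (0, len(ind)):
                    continue
                r = stats.pearsonr(ind, scored.total_score)[0]
                assert point_biserial_d(scored, item, code) == pytest.approx(r, abs=1e-12)


def test_pb_dc_equals_subgroup_indicator_pearson():
    for seed in range(30):
        scored = simulated_scored(seed, n_persons=90, n_items=6)
        for item in scored.items:
            j = scored.item_index(item)
            correct = scored.correct[:, j]
            for code in scored.distractor_codes[j]:
                chose = scored.labels[:, j] == int(code)
                sub = chose | correct
                val = point_biserial_dc(scored, item, code)
                if chose.sum() == 0 or correct.sum() == 0:
                    assert np.isnan(val)
                    continue
                y = scored.total_score[sub].astype(float)
                if np.ptp(y) == 0:
                    assert np.isnan(val)
                    continue
                r = stats.pearsonr(chose[sub].astype(float), y)[0]
                assert val == pytest.approx(r, abs=1e-12)


def test_pb_zero_when_choice_unrelated_to_score():
    # balanced: half choose B at every score level
    cols = {
        "i1": ["B", "C"] * 10,
        "f1": (["1"] * 10 + ["0"] * 10),
    }
    scored = scored_from_codes(cols, {"i1": "A", "f1": "1"})
    assert point_biserial_d(scored, "i1", "B") == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Haladyna-Downing omega_D


def test_omega_d_uniform_is_zero():
    # 20 persons in 5 distinct score bands, distractor B chosen 4x per band
    cols = {"i1": ["B"] * 20}
    n_extra = 8
    others = np.zeros((20, n_extra), dtype=int)
    for i, s in enumerate(np.repeat([0, 2, 4, 6, 8], 4)):
        others[i, :s] = 1
    for k in range(n_extra):
        cols[f"f{k}"] = ["1" if others[i, k] else "0" for i in range(20)]
    key = {"i1": "A", **{f"f{k}": "1" for k in range(n_extra)}}
    scored = scored_from_codes(cols, key)
    assert haladyna_omega_d(scored, "i1", "B", G=5) == pytest.approx(0.0, abs=1e-12)


def test_omega_d_maximal_concentration_is_one():
    # two realized groups, all 10 choosers in one group: chi2 = 10, n = 10
    cols = {"i1": ["B"] * 10 + ["C"] * 10}
    cols["f1"] = ["0"] * 10 + ["1"] * 10
    scored = scored_from_codes(cols, {"i1": "A", "f1": "1"})
    assert haladyna_omega_d(scored, "i1", "B", G=2) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Goodman-Kruskal gamma


def _gamma_oracle(p_values):
    C = D = 0
    J = len(p_values)
    for a in range(J):
        for b in range(a + 1, J):
            if p_values[b] > p_values[a]:
                C += 1
            elif p_values[b] < p_values[a]:
                D += 1
    return np.nan if C + D == 0 else (C - D) / (C + D)


def test_gamma_monotone_probabilities():
    for seed in range(20):
        scored = simulated_scored(seed, n_persons=120, n_items=6)
        for item in scored.items:
            j = scored.item_index(item)
            correct = scored.correct[:, j]
            rest = scored.rest_score[:, j]
            for code in scored.distractor_codes[j]:
                chose = scored.labels[:, j] == int(code)
                if chose.sum() == 0 or correct.sum() == 0:
                    continue
                sub = chose | correct
                levels = np.unique(rest[sub])
                p_hat = [
                    correct[sub & (rest == s)].sum() / (sub & (rest == s)).sum()
                    for s in levels
                ]
                oracle = _gamma_oracle(p_hat)
                val = goodman_kruskal_gamma(scored, item, code)
                if np.isnan(oracle):
                    assert np.isnan(val)
                else:
                    assert val == pytest.approx(oracle, abs=1e-12)


def test_gamma_extremes():
    # p_hat strictly rising in rest score -> gamma = 1
    cols = {
        "i1": ["B"] * 3 + ["A"] * 3,
        "f1": ["0", "0", "1", "0", "1", "1"],
        "f2": ["0", "1", "1", "1", "1", "1"],
    }
    key = {"i1": "A", "f1": "1", "f2": "1"}
    scored = scored_from_codes(cols, key)
    # rest scores: B-choosers (0,1,2), A-choosers (1,2,2):
    # p_hat by rest level: 0 -> 0/1, 1 -> 1/2, 2 -> 2/3  (rising)
    assert goodman_kruskal_gamma(scored, "i1", "B") == pytest.approx(1.0)
    # reversing the roles makes p_hat strictly falling -> gamma = -1
    key_flipped = {"i1": "B", "f1": "1", "f2": "1"}
    scored2 = scored_from_codes(cols, key_flipped)
    assert goodman_kruskal_gamma(scored2, "i1", "A") == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# trace table


def test_trace_table_columns_sum_to_one(scored_small):
    for item in scored_small.items:
        tab = trace_table(scored_small, item, G=5)
        np.testing.assert_allclose(tab.sum(axis=0), 1.0, atol=1e-12)


def test_trace_correct_option_rises_with_ability_at_large_n():
    scored = simulated_scored(3, n_persons=10_000, n_items=10, discrimination="high")
    tab = trace_table(scored, "i1", G=5)
    correct_row = tab.loc["correct"].to_numpy()
    assert (np.diff(correct_row) >= 0).all()


# ---------------------------------------------------------------------------
# analyze_item composition and NA handling


def test_analyze_item_matches_individual_operations(scored_small):
    for item in scored_small.items:
        res = analyze_item(scored_small, item)
        retained, n_below = screen_distractors(scored_small, item)
        assert res.retained_distractors == retained
        assert res.n_below_5pct == n_below
        for G in (2, 5):
            expected = cohen_omega_G(scored_small, item, G=G)
            if np.isnan(expected):
                assert np.isnan(res.omega_by_G[G])
            else:
                assert res.omega_by_G[G] == pytest.approx(expected, abs=1e-14)
        e_rcc = canonical_correlation(scored_small, item)
        if np.isnan(e_rcc):
            assert np.isnan(res.r_cc)
        else:
            assert res.r_cc == pytest.approx(e_rcc, abs=1e-14)
        for code in res.retained_distractors:
            assert res.pb_d[code] == pytest.approx(
                point_biserial_d(scored_small, item, code), nan_ok=True, abs=1e-14
            )
            assert res.gamma[code] == pytest.approx(
                goodman_kruskal_gamma(scored_small, item, code), nan_ok=True, abs=1e-14
            )


def test_single_retained_distractor_yields_na():
    # one dominant distractor, others below 5%
    cols = {"i1": ["B"] * 96 + ["C", "C", "D", "D"]}
    cols["f1"] = ["1"] * 50 + ["0"] * 50
    scored = scored_from_codes(cols, {"i1": "A", "f1": "1"})
    res = analyze_item(scored, "i1")
    assert np.isnan(res.r_cc)
    assert all(np.isnan(v) for v in res.omega_by_G.values())
    assert res.na_reason == "insufficient_distractors"
    assert res.retained_distractors == ("B",)
    assert res.n_below_5pct == 2


def test_item_solved_by_everyone_yields_no_nonsolvers():
    cols = {"i1": ["A"] * 10, "f1": ["1"] * 5 + ["0"] * 5}
    scored = scored_from_codes(cols, {"i1": "A", "f1": "1"})
    res = analyze_item(scored, "i1")
    assert res.n_nonsolvers == 0
    assert np.isnan(res.r_cc)
    assert res.na_reason == "no_nonsolvers"


# ---------------------------------------------------------------------------
# range properties


@given(seed=st.integers(0, 10_000))
@settings(derandomize=True, max_examples=25, deadline=None)
def test_statistic_ranges_on_random_datasets(seed):
    scored = simulated_scored(
        seed, n_persons=60, n_items=5,
        nrm=("zero", "high")[seed % 2], difficulty=("moderate", "very_difficult")[seed % 2],
    )
    for item in scored.items:
        res = analyze_item(scored, item)
        if not np.isnan(res.r_cc):
            assert 0 <= res.r_cc <= 1
        for v in res.omega_by_G.values():
            if not np.isnan(v):
                assert v >= 0
        for v in list(res.pb_d.values()) + list(res.pb_dc.values()):
            if not np.isnan(v):
                assert -1 - 1e-12 <= v <= 1 + 1e-12
        for v in res.gamma.values():
            if not np.isnan(v):
                assert -1 <= v <= 1


def test_null_calibration_rcc_95th_percentile():
    """Under zero NRM slopes (N=500, difficult, moderate 2PL), the 95th
    percentile of R_CC over 1000 items stays below the 0.30 threshold."""
    vals = []
    for b in range(20):
        cell = DesignCell(
            n_persons=500, n_items=50, n_distractors=3,
            difficulty="difficult", discrimination="moderate", nrm="zero",
        )
        gen = np.random.default_rng([555, b])
        bank = sample_item_bank(cell, gen)
        scored = simulate_scored(bank, 500, gen)
        for item in scored.items:
            r = canonical_correlation(scored, item)
            if not np.isnan(r):
                vals.append(r)
    assert len(vals) >= 950
    assert np.percentile(vals, 95) < 0.30


def test_mean_rcc_increases_with_nrm_discrimination():
    """Mean R_CC rises strictly across NRM levels at fixed other facets."""
    means = []
    for nrm in ("zero", "moderate", "high", "very_high"):
        vals = []
        for b in range(10):
            cell = DesignCell(
                n_persons=500, n_items=50, n_distractors=3,
                difficulty="difficult", discrimination="moderate", nrm=nrm,
            )
            gen = np.random.default_rng([321, b])
            bank = sample_item_bank(cell, gen)
            scored = simulate_scored(bank, 500, gen)
            vals.extend(
                v for v in (canonical_correlation(scored, i) for i in scored.items)
                if not np.isnan(v)
            )
        means.append(np.mean(vals))
    assert means == sorted(means)
    assert means[-1] > means[0] + 0.2
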