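"""Tests for cohort filtering rules, rank tests and survival analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import gamquant as gq
from gamquant import cohort as cs
from gamquant import synthetic as syn


def _make_table(rows):
    base = {
        "marker": "Iba1",
        "necrosis_fraction": 0.0,
        "region": "T",
        "group": "GBM",
    }
    return pd.DataFrame([{**base, **r} for r in rows])


# ---------------------------------------------------------------------------
# filter rules
# ---------------------------------------------------------------------------

def test_first_core_keeps_core_one():
    t = _make_table(
        [
            {"patient_id": "P1", "core_index": c, "value": 10.0 * c,
             "survival_months": 12.0, "event": 1}
            for c in (1, 2, 3)
        ]
    )
    out = cs.first_core_select(t)
    assert len(out) == 1
    assert out.iloc[0]["core_index"] == 1
    assert not out.iloc[0]["core_fallback"]


def test_first_core_single_core_identity():
    t = _make_table([{"patient_id": "P1", "core_index": 1, "value": 5.0,
                      "survival_months": 3.0, "event": 0}])
    out = cs.first_core_select(t)
    assert out.iloc[0]["value"] == 5.0


def test_first_core_fallback_flagged():
    t = _make_table(
        [
            {"patient_id": "P1", "core_index": c, "value": 1.0 * c,
             "survival_months": 9.0, "event": 1}
            for c in (2, 3)
        ]
    )
    out = cs.first_core_select(t)
    assert out.iloc[0]["core_index"] == 2
    assert out.iloc[0]["core_fallback"]


def test_exclude_necrotic_boundary():
    t = _make_table(
        [
            {"patient_id": "P1", "core_index": 1, "value": 1.0,
             "necrosis_fraction": 0.30, "survival_months": 5.0, "event": 1},
            {"patient_id": "P2", "core_index": 1, "value": 2.0,
             "necrosis_fraction": 0.31, "survival_months": 5.0, "event": 1},
        ]
    )
    with pytest.warns(UserWarning):
        out = cs.exclude_necrotic(t)
    assert list(out["patient_id"]) == ["P1"]  # exactly 30% retained (strict >)
    assert out.attrs["n_excluded_necrotic"] == 1


def test_exclude_necrotic_all_removed_warns():
    t = _make_table([{"patient_id": "P1", "core_index": 1, "value": 1.0,
                      "necrosis_fraction": 0.9, "survival_months": 5.0, "event": 1}])
    with pytest.warns(UserWarning):
        out = cs.exclude_necrotic(t)
    assert out.empty


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _enumeration_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    obs_u = 0.0
    for xi in x:
        obs_u += sum(xi > v for v in y) + 0.5 * sum(xi == v for v in y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum((xi > v) for xi in xs for v in ys)
        us.append(u)
    us = np.asarray(us, dtype=float)
    lo = np.mean(us <= obs_u)
    hi = np.mean(us >= obs_u)
    return min(1.0, 2 * min(lo, hi))


def test_rank_sum_identical_samples():
    r = gq.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert r.statistic == pytest.approx(4.5)
    assert r.p_value == pytest.approx(1.0)


def test_rank_sum_separated_exact():
    r = gq.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert r.method == "wilcoxon-rank-sum-exact"
    assert r.p_value == pytest.approx(0.1, abs=1e-12)
    assert r.extra["W"] == pytest.approx(6.0)


def test_rank_sum_matches_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(30):
        nx, ny = rng.integers(3, 8, size=2)
        pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # no ties
        x, y = pooled[:nx], pooled[nx:]
        r = gq.wilcoxon_rank_sum(x, y)
        assert r.p_value == pytest.approx(_enumeration_p(x, y), abs=1e-12)


def test_rank_sum_empty_sample():
    with pytest.raises(gq.InputError):
        gq.wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Holm adjustment
# ---------------------------------------------------------------------------

def test_holm_hand_example():
    assert gq.holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])


def test_holm_identity_and_cap():
    assert gq.holm_adjust([0.03]) == pytest.approx([0.03])
    assert gq.holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_holm_out_of_range():
    with pytest.raises(gq.InputError):
        gq.holm_adjust([0.5, 1.5])


@settings(derandomize=True, max_examples=40, deadline=None)
@given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
def test_holm_bracketed_by_raw_and_bonferroni(ps):
    adj = np.asarray(gq.holm_adjust(ps))
    raw = np.asarray(ps)
    bonf = np.minimum(raw * len(ps), 1.0)
    assert (adj >= raw - 1e-15).all()
    assert (adj <= bonf + 1e-15).all()


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone_and_reverse():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert gq.spearman_rho(x, x**2).statistic == pytest.approx(1.0)
    assert gq.spearman_rho(x, -x).statistic == pytest.approx(-1.0)


def test_spearman_tied_matches_midrank_formula():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 5, size=20).astype(float)
    y = rng.integers(0, 5, size=20).astype(float)
    import scipy.stats as st

    rho = gq.spearman_rho(x, y).statistic
    rx, ry = st.rankdata(x), st.rankdata(y)
    manual = np.corrcoef(rx, ry)[0, 1]  # Pearson of mid-ranks
    assert rho == pytest.approx(manual, abs=1e-12)


def test_spearman_constant_input():
    with pytest.raises(gq.UndefinedStatisticError):
        gq.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def test_km_all_censored():
    km = gq.kaplan_meier([3.0, 5.0, 8.0], [0, 0, 0])
    assert np.allclose(km.survival, 1.0)


def test_km_hand_product_limit():
    km = gq.kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
    np.testing.assert_allclose(km.survival[-3:], [2 / 3, 1 / 3, 0.0])
    km = gq.kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
    np.testing.assert_allclose(km.survival[-3:], [2 / 3, 2 / 3, 0.0])


def test_km_no_censoring_equals_empirical():
    rng = np.random.default_rng(4)
    t = rng.exponential(10, size=40)
    km = gq.kaplan_meier(t, np.ones(40, dtype=int))
    for time, s in zip(km.timeline, km.survival):
        assert s == pytest.approx(np.mean(t > time), abs=1e-12)


def test_km_input_validation():
    with pytest.raises(gq.InputError):
        gq.kaplan_meier([], [])
    with pytest.raises(gq.InputError):
        gq.kaplan_meier([0.0, 1.0], [1, 1])


# ---------------------------------------------------------------------------
# log-rank and Gehan–Wilcoxon
# ---------------------------------------------------------------------------

def test_logrank_identical_arms():
    t = np.array([2.0, 4.0, 6.0, 9.0])
    e = np.array([1, 0, 1, 1])
    r = gq.logrank_test(t, e, t, e)
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == pytest.approx(1.0)


def test_logrank_gehan_hand_example():
    """4-subject table: A events at 1, 3; B events at 2, 4.

    Hand-computed hypergeometric sums give chi2 = (2/3)^2 / (13/18) = 8/13
    for the log-rank and 4/7 for the Gehan (at-risk-weighted) variant.
    """
    lr = gq.logrank_test([1.0, 3.0], [1, 1], [2.0, 4.0], [1, 1])
    assert lr.statistic == pytest.approx(8 / 13, abs=1e-12)
    gw = gq.gehan_wilcoxon_test([1.0, 3.0], [1, 1], [2.0, 4.0], [1, 1])
    assert gw.statistic == pytest.approx(4 / 7, abs=1e-12)


def test_logrank_gehan_match_lifelines_oracle():
    from lifelines.statistics import logrank_test as ll_test

    rng = np.random.default_rng(5)
    checked = 0
    while checked < 100:
        na, nb = rng.integers(4, 20, size=2)
        ta = rng.exponential(10, na).round(1) + 0.1
        tb = rng.exponential(14, nb).round(1) + 0.1
        ea = rng.integers(0, 2, na)
        eb = rng.integers(0, 2, nb)
        if ea.sum() + eb.sum() == 0:
            continue
        try:
            mine_lr = gq.logrank_test(ta, ea, tb, eb)
            mine_gw = gq.gehan_wilcoxon_test(ta, ea, tb, eb)
        except gq.UndefinedStatisticError:
            continue
        ref_lr = ll_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        ref_gw = ll_test(ta, tb, event_observed_A=ea, event_observed_B=eb,
                         weightings="wilcoxon")
        assert mine_lr.statistic == pytest.approx(ref_lr.test_statistic, abs=1e-10)
        assert mine_gw.statistic == pytest.approx(ref_gw.test_statistic, abs=1e-10)
        checked += 1


def test_logrank_time_rescaling_invariance():
    rng = np.random.default_rng(6)
    t1 = rng.exponential(10, 15)
    t2 = rng.exponential(15, 12)
    e1 = rng.integers(0, 2, 15)
    e2 = np.ones(12, dtype=int)
    a = gq.logrank_test(t1, e1, t2, e2).statistic
    b = gq.logrank_test(7.3 * t1, e1, 7.3 * t2, e2).statistic
    assert a == pytest.approx(b, abs=1e-12)


def test_logrank_no_events():
    with pytest.raises(gq.UndefinedStatisticError):
        gq.logrank_test([1.0], [0], [2.0], [0])


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _survival_table(values, times, events):
    return _make_table(
        [
            {"patient_id": f"P{i}", "core_index": 1, "value": v,
             "survival_months": t, "event": e}
            for i, (v, t, e) in enumerate(zip(values, times, events))
        ]
    )


def test_median_split_even_n_cutpoint():
    t = _survival_table([10, 20, 30, 40], [5, 6, 7, 8], [1, 1, 1, 1])
    comp = gq.median_split(t)
    assert comp.cutpoint == 25.0
    assert comp.n_high == 2 and comp.n_low == 2


def test_median_split_tie_goes_low():
    t = _survival_table([12, 12, 15, 20], [5, 6, 7, 8], [1, 1, 1, 1])
    comp = gq.median_split(t)
    assert comp.cutpoint == pytest.approx(13.5)
    t2 = _survival_table([10, 12, 12, 20, 30], [5, 6, 7, 8, 9], [1, 1, 1, 1, 1])
    comp2 = gq.median_split(t2)
    # cutpoint = 12; the two patients exactly at 12 belong to the low arm
    assert comp2.cutpoint == 12.0
    assert comp2.n_low == 3 and comp2.n_high == 2


def test_median_split_degenerate():
    t = _survival_table([5, 5, 5], [1, 2, 3], [1, 1, 1])
    with pytest.raises(gq.DegenerateSplitError):
        gq.median_split(t)


def test_median_split_requires_unique_patients():
    t = _survival_table([1, 2, 3], [1, 2, 3], [1, 1, 1])
    t = pd.concat([t, t])
    with pytest.raises(gq.InputError):
        gq.median_split(t)


def test_best_split_scan_matches_exhaustive():
    cohort = syn.generate_cohort(
        syn.CohortSpec(n_patients=60, log_hazard_ratio_high_vs_low=-0.8,
                       hazard_cutpoint=30.0, seed=17)
    )
    cohort = cs.first_core_select(cohort)
    comp = gq.best_split(cohort)
    # recompute every admissible cutpoint independently
    for _, row in comp.scan.iterrows():
        lo = cohort[cohort["value"] <= row["cutpoint"]]
        hi = cohort[cohort["value"] > row["cutpoint"]]
        ref = gq.logrank_test(lo["survival_months"], lo["event"],
                              hi["survival_months"], hi["event"])
        assert row["logrank_chi2"] == pytest.approx(ref.statistic, abs=1e-10)
    assert comp.logrank.statistic == pytest.approx(comp.scan["logrank_chi2"].max())
    assert comp.multiplicity_unadjusted


def test_best_split_dominates_median_split():
    cohort = cs.first_core_select(
        syn.generate_cohort(syn.CohortSpec(n_patients=80, seed=23))
    )
    best = gq.best_split(cohort)
    med = gq.median_split(cohort)
    assert best.logrank.statistic >= med.logrank.statistic - 1e-12


def test_best_split_min_arm_fraction():
    t = _survival_table([1, 2, 3], [1, 2, 3], [1, 1, 1])
    with pytest.raises(gq.DegenerateSplitError):
        gq.best_split(t, min_arm_fraction=0.5)


# ---------------------------------------------------------------------------
# regions: Kruskal–Wallis + Dunn
# ---------------------------------------------------------------------------

def test_dunn_hand_formula():
    groups = {
        "T": np.array([1.0, 2, 3, 4, 5]),
        "IZ": np.array([2.0, 3, 4, 5, 6]),
        "NAB": np.array([10.0, 11, 12, 13, 14]),
    }
    omnibus, pw = gq.kruskal_dunn(groups)
    import scipy.stats as st

    pooled = np.concatenate(list(groups.values()))
    ranks = st.rankdata(pooled)
    mean_ranks = {g: ranks[i * 5:(i + 1) * 5].mean() for i, g in enumerate(groups)}
    _, tc = np.unique(pooled, return_counts=True)
    tie = (tc**3 - tc).sum() / (12 * (len(pooled) - 1))
    se = np.sqrt((len(pooled) * (len(pooled) + 1) / 12 - tie) * (2 / 5))
    z_hand = (mean_ranks["T"] - mean_ranks["IZ"]) / se
    row = pw[(pw.group_a == "T") & (pw.group_b == "IZ")].iloc[0]
    assert row["z"] == pytest.approx(z_hand, abs=1e-12)
    assert omnibus.p_value < 0.05  # NAB clearly shifted


def test_kruskal_null_calibration():
    """Identical region distributions: KW rejection rate near nominal 5%."""
    rej = 0
    n_sims = 1000
    for i in range(n_sims):
        t = syn.generate_cohort(
            syn.CohortSpec(n_patients=30, regions=("T", "IZ", "NAB"), seed=100_000 + i)
        )
        groups = {r: s["value"].to_numpy() for r, s in t.groupby("region")}
        omnibus, _ = gq.kruskal_dunn(groups)
        rej += omnibus.p_value < 0.05
    assert 0.035 <= rej / n_sims <= 0.065


def test_region_stratified_structure():
    t = syn.generate_cohort(
        syn.CohortSpec(n_patients=40, regions=("T", "IZ", "NAB"), seed=31)
    )
    t = cs.first_core_select(t)
    out = gq.region_stratified_analysis(t)
    assert set(out["per_region"]) <= {"T", "IZ", "NAB"}
    assert len(out["dunn"]) == 3
    assert "p_holm" in out["dunn"].columns


def test_significance_stars():
    assert cs.significance_stars(0.2) == ""
    assert cs.significance_stars(0.05) == "*"
    assert cs.significance_stars(0.01) == "**"
    assert cs.significance_stars(0.0005) == "***"
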