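"""Cohort-level statistics for marker measurements on TMA patients.

Implements the filtering and testing rules used on per-patient,
per-core marker tables: first-core selection, exclusion of mostly
necrotic cores (> 30% necrotic area), two-sample rank tests with
Bonferroni–Holm adjustment, Spearman agreement, and dichotomized
Kaplan–Meier survival analysis (median split and maximally selected
"best split") compared by log-rank and Gehan–Breslow–Wilcoxon tests.

The expected table layout (one row per patient x core x marker x region):

==================  =======================================================
column              meaning
==================  =======================================================
patient_id          patient identifier (survival constant within patient)
core_index          1-3, repeat cores of the same patient
marker              marker name (Iba1, CD68, CD163, CD206, ...)
value               % positive cells (manual) or DAB area ratio (automated)
necrosis_fraction   fraction of the core that is necrotic, 0-1
region              T (vital tumor), IZ (infiltration zone), NAB
group               entity / WHO grade / molecular-subclass label
survival_months     overall survival, months
event               1 = death observed, 0 = censored
==================  =======================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import KaplanMeierFitter
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateSplitError,
    InputError,
    UndefinedStatisticError,
)

__all__ = [
    "TestResult",
    "KMCurve",
    "SurvivalComparison",
    "first_core_select",
    "exclude_necrotic",
    "wilcoxon_rank_sum",
    "holm_adjust",
    "spearman_rho",
    "kaplan_meier",
    "logrank_test",
    "gehan_wilcoxon_test",
    "median_split",
    "best_split",
    "region_stratified_analysis",
    "kruskal_dunn",
    "significance_stars",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...] = ()
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)


def significance_stars(p: float) -> str:
    """Star annotation: * P<=0.05, ** P<=0.01, *** P<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# filtering rules
# ---------------------------------------------------------------------------

def first_core_select(table: pd.DataFrame) -> pd.DataFrame:
    """Keep one core per patient x marker x region: the first core.

    Repeat cores exist to check intra-patient consistency; analyses use
    the first core to avoid selection bias.  If core 1 is missing for a
    patient, the lowest available core index is kept and the row is
    flagged (``core_fallback = True``).
    """
    if table.empty:
        raise InputError("empty cohort table")
    keys = [k for k in ("patient_id", "marker", "region") if k in table.columns]
    idx = table.groupby(keys, sort=False, dropna=False)["core_index"].idxmin()
    out = table.loc[idx].copy()
    out["core_fallback"] = out["core_index"] != 1
    return out.reset_index(drop=True)


def exclude_necrotic(
    table: pd.DataFrame, max_necrosis: float = 0.30
) -> pd.DataFrame:
    """Drop cores with a necrotic area strictly greater than the cutoff.

    A core with exactly ``max_necrosis`` necrosis is retained (the rule
    is "> 30%", strict).  The number of removed rows is attached as
    ``DataFrame.attrs['n_excluded_necrotic']`` and warned about.
    """
    drop = table["necrosis_fraction"] > max_necrosis
    out = table.loc[~drop].reset_index(drop=True)
    out.attrs["n_excluded_necrotic"] = int(drop.sum())
    if drop.any():
        warnings.warn(
            f"excluded {int(drop.sum())} cores with necrosis > {max_necrosis:.0%}",
            stacklevel=2,
        )
    if out.empty:
        warnings.warn("all cores excluded as necrotic", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney) test, two-sided.

    ``mode='auto'`` uses the exact null distribution when both samples
    have <= 10 observations and there are no ties, and the tie-corrected
    normal approximation (with continuity correction) otherwise.  The
    Mann–Whitney U of ``x`` and the rank sum W of ``x`` are reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise InputError("mode must be auto|exact|approx")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    if mode == "exact" or (mode == "auto" and x.size <= 10 and y.size <= 10 and no_ties):
        method, tag = "exact", "wilcoxon-rank-sum-exact"
    else:
        method, tag = "asymptotic", "wilcoxon-rank-sum-normal"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    w = u + x.size * (x.size + 1) / 2.0
    return TestResult(
        statistic=u,
        p_value=float(res.pvalue),
        method=tag,
        n=(x.size, y.size),
        extra={"U": u, "W": w},
    )


def holm_adjust(p_values) -> list[float]:
    """Bonferroni–Holm step-down adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with two-sided t-approximation p-value.

    Used for repeat-core, intra-/inter-rater and manual-vs-automated
    agreement.  Ties are handled through mid-ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need paired samples of equal length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedStatisticError("correlation undefined for constant input")
    rho, p = st.spearmanr(x, y)
    return TestResult(
        statistic=float(rho), p_value=float(p), method="spearman", n=(x.size,)
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate of one arm."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def to_records(self) -> list[dict]:
        return [
            {"time": float(t), "survival": float(s), "at_risk": int(r)}
            for t, s, r in zip(self.timeline, self.survival, self.at_risk)
        ]


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    ``S(t)`` steps down only at observed event times; subjects censored
    at an event time are still at risk for that event (events processed
    first).  Greenwood variance is available through lifelines if needed;
    the curve itself is the package-level contract.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise InputError("no subjects")
    if (times <= 0).any():
        raise InputError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise InputError("event flags must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    return KMCurve(
        timeline=timeline,
        survival=surv,
        at_risk=np.nan_to_num(at_risk).astype(int),
        n=times.size,
    )


def _weighted_logrank(times_a, events_a, times_b, events_b, weighting: str):
    """Weighted two-sample log-rank statistic over pooled event times.

    weight 1 per event time for the classical log-rank; weight = number
    at risk for the Gehan–Breslow–Wilcoxon variant.  Returns
    ``(chi2, p, O, E, V)`` for arm A.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise InputError("both arms need at least one subject")
    if ea.sum() + eb.sum() == 0:
        raise UndefinedStatisticError("no events in either arm")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    sa, sb = np.sort(ta), np.sort(tb)
    n_a = ta.size - np.searchsorted(sa, event_times, side="left").astype(float)
    n_b = tb.size - np.searchsorted(sb, event_times, side="left").astype(float)

    def _event_counts(times, events):
        u, c = np.unique(times[events == 1], return_counts=True)
        d = np.zeros(event_times.size)
        d[np.searchsorted(event_times, u)] = c
        return d

    d_a = _event_counts(ta, ea)
    d_b = _event_counts(tb, eb)
    n = n_a + n_b
    d = d_a + d_b

    keep = n > 0
    n_a, n_b, n, d, d_a = n_a[keep], n_b[keep], n[keep], d[keep], d_a[keep]
    e_a = d * n_a / n
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    v = np.nan_to_num(v)  # n == 1 contributes no variance

    if weighting == "logrank":
        w = np.ones_like(d)
    elif weighting == "wilcoxon":
        w = n.copy()
    else:  # pragma: no cover - internal
        raise ValueError(weighting)

    num = float((w * (d_a - e_a)).sum())
    den = float((w**2 * v).sum())
    if den == 0:
        raise UndefinedStatisticError("zero variance: arms have no comparable events")
    chi2 = num**2 / den
    p = float(st.chi2.sf(chi2, df=1))
    return chi2, p, float(d_a.sum()), float(e_a.sum()), float(v.sum())


def logrank_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-sample log-rank test (weight 1), chi-square on 1 df."""
    chi2, p, o, e, v = _weighted_logrank(times_a, events_a, times_b, events_b, "logrank")
    return TestResult(
        statistic=chi2,
        p_value=p,
        method="logrank",
        n=(len(times_a), len(times_b)),
        extra={"observed_a": o, "expected_a": e, "variance": v},
    )


def gehan_wilcoxon_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Gehan–Breslow–Wilcoxon test: log-rank weighted by numbers at risk.

    Up-weights early event times; the standard "Wilcoxon" companion to
    the log-rank in clinical survival software.
    """
    chi2, p, o, e, v = _weighted_logrank(times_a, events_a, times_b, events_b, "wilcoxon")
    return TestResult(
        statistic=chi2,
        p_value=p,
        method="gehan-wilcoxon",
        n=(len(times_a), len(times_b)),
        extra={"observed_a": o, "expected_a": e, "variance": v},
    )


@dataclass
class SurvivalComparison:
    """Two-arm dichotomized survival comparison.

    The low arm holds patients with marker value <= cutpoint, the high
    arm those strictly above (ties at the cutpoint go low).
    """

    cutpoint: float
    n_low: int
    n_high: int
    km_low: KMCurve
    km_high: KMCurve
    logrank: TestResult
    gehan: TestResult
    split: str = "median"
    scan: pd.DataFrame | None = None
    multiplicity_unadjusted: bool = False

    def to_dict(self) -> dict:
        d = {
            "split": self.split,
            "cutpoint": self.cutpoint,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "logrank_chi2": self.logrank.statistic,
            "logrank_p": self.logrank.p_value,
            "gehan_chi2": self.gehan.statistic,
            "gehan_p": self.gehan.p_value,
            "km_low": self.km_low.to_records(),
            "km_high": self.km_high.to_records(),
            "multiplicity_unadjusted": self.multiplicity_unadjusted,
        }
        return d


def _one_row_per_patient(table: pd.DataFrame, marker: str | None) -> pd.DataFrame:
    t = table
    if marker is not None and "marker" in t.columns:
        t = t[t["marker"] == marker]
    if t.empty:
        raise InputError("no rows for requested marker")
    if t["patient_id"].duplicated().any():
        raise InputError(
            "expected one row per patient; run first_core_select (and restrict "
            "to one region) before splitting"
        )
    return t


def _split_at(t: pd.DataFrame, cut: float, split: str) -> SurvivalComparison:
    high = t["value"] > cut
    lo, hi = t[~high], t[high]
    if lo.empty or hi.empty:
        raise DegenerateSplitError("cutpoint leaves an empty arm")
    lr = logrank_test(
        lo["survival_months"], lo["event"], hi["survival_months"], hi["event"]
    )
    gw = gehan_wilcoxon_test(
        lo["survival_months"], lo["event"], hi["survival_months"], hi["event"]
    )
    return SurvivalComparison(
        cutpoint=float(cut),
        n_low=len(lo),
        n_high=len(hi),
        km_low=kaplan_meier(lo["survival_months"], lo["event"]),
        km_high=kaplan_meier(hi["survival_months"], hi["event"]),
        logrank=lr,
        gehan=gw,
        split=split,
    )


def median_split(table: pd.DataFrame, marker: str | None = None) -> SurvivalComparison:
    """Dichotomize a marker at its sample median and compare survival.

    High arm: value strictly greater than the median; ties at the
    cutpoint are assigned to the low arm.  Runs KM on each arm plus the
    log-rank and Gehan–Wilcoxon tests.
    """
    t = _one_row_per_patient(table, marker)
    if t["value"].nunique() < 2:
        raise DegenerateSplitError("all marker values equal: no median split")
    cut = float(t["value"].median())
    return _split_at(t, cut, split="median")


def best_split(
    table: pd.DataFrame,
    marker: str | None = None,
    min_arm_fraction: float = 0.10,
) -> SurvivalComparison:
    """Maximally selected log-rank cutpoint ("best split").

    Evaluates the log-rank chi-square at every distinct observed marker
    value that leaves at least ``min_arm_fraction`` of patients in each
    arm, and returns the comparison at the maximizing cutpoint together
    with the full scan table.  The reported p-value is *not* adjusted for
    the maximal selection and is flagged as such: scanning many cutpoints
    inflates the type-I error well beyond the nominal level.
    """
    t = _one_row_per_patient(table, marker)
    n = len(t)
    min_arm = max(1, int(np.ceil(min_arm_fraction * n)))
    values = t["value"].to_numpy(dtype=float)
    times = t["survival_months"].to_numpy(dtype=float)
    events = t["event"].to_numpy(dtype=int)
    order = np.argsort(values, kind="stable")
    v_s, t_s, e_s = values[order], times[order], events[order]

    rows = []
    best_cut: float | None = None
    best_chi2 = -np.inf
    for cut in np.unique(v_s):
        k = int(np.searchsorted(v_s, cut, side="right"))  # size of low arm
        if k < min_arm or n - k < min_arm:
            continue
        try:
            chi2, p, *_ = _weighted_logrank(t_s[:k], e_s[:k], t_s[k:], e_s[k:], "logrank")
        except UndefinedStatisticError:
            continue
        rows.append(
            {
                "cutpoint": float(cut),
                "n_low": k,
                "n_high": n - k,
                "logrank_chi2": chi2,
                "logrank_p": p,
            }
        )
        if chi2 > best_chi2:
            best_chi2, best_cut = chi2, float(cut)
    if best_cut is None:
        raise DegenerateSplitError("no admissible cutpoint for best split")
    best = _split_at(t, best_cut, split="best")
    best.scan = pd.DataFrame(rows)
    best.multiplicity_unadjusted = True
    return best


# ---------------------------------------------------------------------------
# region stratification (T / IZ / NAB)
# ---------------------------------------------------------------------------

def kruskal_dunn(groups: dict[str, np.ndarray]) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal–Wallis across groups followed by Dunn's pairwise z-tests.

    Dunn's z uses pooled mid-ranks with tie correction; pairwise p-values
    are Holm-adjusted.  Returns the omnibus result and a pairwise table.
    """
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise InputError("need >= 2 non-empty groups")
    h, p = st.kruskal(*samples)
    omnibus = TestResult(
        statistic=float(h),
        p_value=float(p),
        method="kruskal-wallis",
        n=tuple(s.size for s in samples),
    )

    pooled = np.concatenate(samples)
    ranks = st.rankdata(pooled)
    N = pooled.size
    bounds = np.cumsum([0] + [s.size for s in samples])
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(samples))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for i, j in combinations(range(len(samples)), 2):
        se = np.sqrt(
            (N * (N + 1) / 12.0 - tie_term)
            * (1.0 / samples[i].size + 1.0 / samples[j].size)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "z": float(z),
                "p": float(2 * st.norm.sf(abs(z))),
            }
        )
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p"]) if len(pairwise) else []
    return omnibus, pairwise


def region_stratified_analysis(
    table: pd.DataFrame, marker: str | None = None
) -> dict:
    """Per-region survival splits plus cross-region marker comparison.

    Runs a median-split survival comparison separately in each region
    (vital tumor T, infiltration zone IZ, normal-appearing brain NAB;
    regions with < 2 patients are skipped with a warning), and compares
    marker levels across regions with Kruskal–Wallis followed by Dunn's
    pairwise tests (Holm-adjusted).
    """
    if "region" not in table.columns:
        raise InputError("table has no region column")
    t = table if marker is None else table[table["marker"] == marker]
    out: dict = {"per_region": {}, "skipped_regions": []}
    groups = {}
    for region, sub in t.groupby("region", sort=True):
        groups[region] = sub["value"].to_numpy(dtype=float)
        if sub["patient_id"].nunique() < 2:
            warnings.warn(f"region {region}: < 2 patients, skipped", stacklevel=2)
            out["skipped_regions"].append(region)
            continue
        try:
            out["per_region"][region] = median_split(sub)
        except (DegenerateSplitError, UndefinedStatisticError) as exc:
            out["skipped_regions"].append(region)
            warnings.warn(f"region {region}: {exc}", stacklevel=2)
    if len(groups) >= 2:
        omnibus, pairwise = kruskal_dunn(groups)
        out["kruskal"] = omnibus
        out["dunn"] = pairwise
    return out
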