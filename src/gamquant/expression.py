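"""Expression-side statistics for GAM vs. reference-microglia profiling.

Covers the downstream computations run on already-normalized log2
expression matrices: the absolute-log2-fold-change DEG screen, Ward
minimum-variance clustering for heatmaps, Pearson coexpression, the
rank-product permutation test (pfp = proportion of false predictions),
and relative qPCR quantification (dCT / ddCT / R with standard-curve
amplification efficiencies).

Upstream probe-level processing (background correction, quantile
normalization) is out of scope; the matrix is assumed log2-normalized.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st

from .errors import InputError, ParameterError, UndefinedStatisticError

__all__ = [
    "ExpressionMatrix",
    "deg_filter",
    "ward_cluster",
    "WardResult",
    "pearson_coexpression",
    "rank_product_pfp",
    "ddct_quantify",
    "standard_curve",
    "StandardCurveResult",
]


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with condition labels.

    ``case_samples`` are the condition of interest (e.g. GAMs isolated
    from tumors), ``reference_samples`` the baseline (e.g. pooled normal
    white-matter microglia, possibly a single pooled column).
    """

    data: pd.DataFrame
    case_samples: list[str]
    reference_samples: list[str]

    def __post_init__(self) -> None:
        self.case_samples = list(self.case_samples)
        self.reference_samples = list(self.reference_samples)
        missing = (set(self.case_samples) | set(self.reference_samples)) - set(
            self.data.columns
        )
        if missing:
            raise InputError(f"condition samples not in matrix: {sorted(missing)}")
        if not self.case_samples or not self.reference_samples:
            raise InputError("both conditions need at least one sample")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise InputError("expression matrix contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def log2fc(self) -> pd.Series:
        """Per-gene log2 fold change: mean(case) - mean(reference)."""
        case = self.data[self.case_samples].mean(axis=1)
        ref = self.data[self.reference_samples].mean(axis=1)
        return (case - ref).rename("log2fc")

    def swap_conditions(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data, self.reference_samples, self.case_samples)


def deg_filter(matrix: ExpressionMatrix, threshold: float = 2.0) -> pd.DataFrame:
    """Screen genes by absolute log2 fold change.

    A gene passes iff ``|log2FC| >= threshold`` (boundary inclusive).
    Returns a per-gene table with ``log2fc`` and ``passed`` columns.
    """
    if threshold < 0:
        raise ParameterError("threshold must be non-negative")
    lfc = matrix.log2fc()
    return pd.DataFrame({"log2fc": lfc, "passed": lfc.abs() >= threshold})


@dataclass
class WardResult:
    linkage: np.ndarray          # scipy linkage matrix (Z)
    leaf_order: list             # item labels in dendrogram order
    labels: list = field(default_factory=list)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def ward_cluster(matrix: ExpressionMatrix, axis: str = "genes") -> WardResult:
    """Agglomerative clustering with Ward's minimum-variance criterion.

    Euclidean distances; merge heights are non-decreasing.  ``axis``
    selects whether genes (rows) or samples (columns) are clustered; the
    leaf order is reported for heatmap display.
    """
    if axis == "genes":
        X = matrix.data.to_numpy(dtype=float)
        labels = list(matrix.data.index)
    elif axis == "samples":
        X = matrix.data.to_numpy(dtype=float).T
        labels = list(matrix.data.columns)
    else:
        raise ParameterError("axis must be 'genes' or 'samples'")
    if X.shape[0] < 2:
        raise InputError("need at least two items to cluster")
    Z = sch.linkage(X, method="ward")
    order = [labels[i] for i in sch.leaves_list(Z)]
    return WardResult(linkage=Z, leaf_order=order, labels=labels)


def pearson_coexpression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlation matrix across all samples.

    Constant genes have undefined correlations and are reported as NaN
    (except the unit diagonal).
    """
    X = matrix.data.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise InputError("need at least three samples for coexpression")
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.asarray(corr, dtype=float)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.genes, columns=matrix.genes)


# ---------------------------------------------------------------------------
# rank products
# ---------------------------------------------------------------------------

def _rank_products(fc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean fold-change ranks per gene, up and down directions.

    ``fc`` is genes x case-samples.  Rank 1 = most upregulated (resp.
    most downregulated) within a sample; ties get mid-ranks.
    """
    k = fc.shape[1]
    up = np.empty_like(fc)
    dn = np.empty_like(fc)
    for j in range(k):
        up[:, j] = st.rankdata(-fc[:, j])
        dn[:, j] = st.rankdata(fc[:, j])
    return np.exp(np.log(up).mean(axis=1)), np.exp(np.log(dn).mean(axis=1))


def _pfp_from_null(rp: np.ndarray, null_cdf) -> np.ndarray:
    """pfp(g) = E[false predictions at rp(g)] / observed rank of g."""
    order = np.argsort(rp, kind="stable")
    obs_rank = np.empty(rp.size)
    obs_rank[order] = np.arange(1, rp.size + 1)
    expected_fp = np.array([null_cdf(v) for v in rp])
    return expected_fp / obs_rank


def rank_product_pfp(
    matrix: ExpressionMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    exact: bool = False,
) -> pd.DataFrame:
    """Rank-product differential-expression test with permutation pfp.

    Per case sample, genes are ranked by fold change against the mean of
    the reference samples; the rank product is the geometric mean of a
    gene's ranks across case samples (up- and downregulation scored
    separately).  Significance is the pfp — the expected number of false
    predictions at a gene's rank product divided by its observed rank —
    estimated by permuting expression values within each sample.

    With ``exact=True`` the null distribution is computed by exhaustive
    enumeration of all per-sample rank combinations (each equally likely
    under within-sample permutation), feasible only for tiny matrices
    (``n_genes ** n_case <= 2e6``).
    """
    if n_permutations < 10:
        raise ParameterError("need at least 10 permutations")
    if len(matrix.case_samples) < 2:
        raise InputError("rank products need at least two case samples")

    X = matrix.data[matrix.case_samples].to_numpy(dtype=float)
    ref = matrix.data[matrix.reference_samples].to_numpy(dtype=float).mean(axis=1)
    fc = X - ref[:, None]
    n, k = fc.shape
    rp_up, rp_dn = _rank_products(fc)

    if exact:
        if n**k > 2_000_000:
            raise ParameterError("matrix too large for exact enumeration")
        # Marginal null of one gene's rank product: iid uniform ranks per sample.
        all_rp = np.sort(
            [
                float(np.prod(t)) ** (1.0 / k)
                for t in itertools.product(range(1, n + 1), repeat=k)
            ]
        )
        def null_cdf(v: float) -> float:
            return n * np.searchsorted(all_rp, v * (1 + 1e-12), side="right") / all_rp.size
        pfp_up = _pfp_from_null(rp_up, null_cdf)
        pfp_dn = _pfp_from_null(rp_dn, null_cdf)
    else:
        rng = np.random.default_rng(seed)
        sorted_null_up = []
        sorted_null_dn = []
        for _ in range(n_permutations):
            perm_fc = np.column_stack(
                [fc[rng.permutation(n), j] for j in range(k)]
            )
            pu, pd_ = _rank_products(perm_fc)
            sorted_null_up.append(pu)
            sorted_null_dn.append(pd_)
        null_up = np.sort(np.concatenate(sorted_null_up))
        null_dn = np.sort(np.concatenate(sorted_null_dn))

        def cdf_factory(null_sorted):
            def cdf(v: float) -> float:
                return (
                    np.searchsorted(null_sorted, v * (1 + 1e-12), side="right")
                    / n_permutations
                )
            return cdf

        pfp_up = _pfp_from_null(rp_up, cdf_factory(null_up))
        pfp_dn = _pfp_from_null(rp_dn, cdf_factory(null_dn))

    return pd.DataFrame(
        {
            "rank_product_up": rp_up,
            "rank_product_down": rp_dn,
            "pfp_up": pfp_up,
            "pfp_down": pfp_dn,
        },
        index=matrix.genes,
    )


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def ddct_quantify(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_samples: list[str],
    replicate_tolerance: float = 0.5,
) -> pd.DataFrame:
    """Relative qPCR quantification by the ddCT method.

    ``ct_table`` has columns ``sample, gene, ct`` (and optionally
    ``replicate``); technical replicates are averaged first, wells more
    than ``replicate_tolerance`` cycles from their triplicate median are
    flagged.  Then per sample and target gene:

    - ``dct  = mean CT(target) - mean CT(reference_gene)``
    - ``ddct = dct(sample) - mean dct over the control-group samples``
    - ``R    = 2 ** (-ddct) * 100``  (% of the control group)
    """
    req = {"sample", "gene", "ct"}
    if not req <= set(ct_table.columns):
        raise InputError(f"CT table needs columns {sorted(req)}")
    if (ct_table["ct"] <= 0).any():
        raise InputError("CT values must be positive")
    if reference_gene not in set(ct_table["gene"]):
        raise InputError(f"reference gene {reference_gene!r} absent from CT table")
    samples = set(ct_table["sample"])
    if not set(control_samples) <= samples:
        raise InputError("control-group samples absent from CT table")

    def summarize(g: pd.DataFrame) -> pd.Series:
        med = g["ct"].median()
        return pd.Series(
            {
                "ct": g["ct"].mean(),
                "ct_sd": g["ct"].std(ddof=1) if len(g) > 1 else 0.0,
                "flagged_wells": int(((g["ct"] - med).abs() > replicate_tolerance).sum()),
            }
        )

    agg = (
        ct_table.groupby(["sample", "gene"])[["ct"]]
        .apply(summarize)
        .reset_index()
    )
    ref = agg[agg["gene"] == reference_gene].set_index("sample")["ct"]
    out = agg[agg["gene"] != reference_gene].copy()
    missing_ref = set(out["sample"]) - set(ref.index)
    if missing_ref:
        raise InputError(f"samples without reference-gene wells: {sorted(missing_ref)}")
    out["dct"] = out["ct"] - out["sample"].map(ref)
    ctrl_mean = (
        out[out["sample"].isin(control_samples)].groupby("gene")["dct"].mean()
    )
    missing_ctrl = set(out["gene"]) - set(ctrl_mean.index)
    if missing_ctrl:
        raise InputError(f"genes without control-group wells: {sorted(missing_ctrl)}")
    out["ddct"] = out["dct"] - out["gene"].map(ctrl_mean)
    out["r_value"] = 2.0 ** (-out["ddct"]) * 100.0
    return out.reset_index(drop=True)


@dataclass
class StandardCurveResult:
    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # fraction: 1.0 = perfect doubling per cycle


def standard_curve(
    concentrations: np.ndarray, cts: np.ndarray
) -> StandardCurveResult:
    """Fit a qPCR standard curve from a serial dilution.

    Least-squares CT vs. log10(concentration); amplification efficiency
    ``E = 10 ** (-1/slope) - 1`` (1.0 for perfect doubling, i.e. a slope
    of -3.3219 per 10-fold dilution).  Requires >= 3 points spanning at
    least 2 log10 units and a negative slope.
    """
    conc = np.asarray(concentrations, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if conc.size != ct.size or conc.size < 3:
        raise InputError("need >= 3 matched dilution points")
    if (conc <= 0).any():
        raise InputError("concentrations must be positive")
    logc = np.log10(conc)
    if logc.max() - logc.min() < 2.0:
        raise InputError("dilution series must span >= 2 log10 units")
    fit = st.linregress(logc, ct)
    if fit.slope >= 0:
        raise UndefinedStatisticError(
            "non-negative slope: efficiency undefined (CT must fall with concentration)"
        )
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurveResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=float(eff),
    )
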