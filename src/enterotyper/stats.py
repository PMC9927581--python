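"""Two-group statistics for phenotypes, taxa and predicted functions.

Phenotypes (ADG, DMI, fecal VFA, NH3-N, serum panel) are compared with an
independent-samples t test (Welch by default). Taxon and pathway relative
abundances are compared with the Wilcoxon rank-sum test, with
Benjamini-Hochberg false-discovery-rate adjustment across features, and
assembled into differential tables reporting per-cluster mean +/- SE in
percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment
from .tables import FeatureTable

__all__ = [
    "t_test_independent",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "differential_table",
    "phenotype_table",
]

EXACT_MAX_N = 20


def t_test_independent(x, y, variant: str = "welch") -> tuple[float, float, float]:
    """Two-sided independent-samples t test.

    Returns (t, df, p). ``variant="welch"`` uses the Welch-Satterthwaite
    degrees of freedom; ``"pooled"`` assumes equal variances. Two groups with
    zero variance and equal means return t=0, p=1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2
            return 0.0, float(df), 1.0
        return float("inf") * np.sign(x.mean() - y.mean()), float(x.size + y.size - 2), 0.0
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null enumeration when both samples together have <= 20
    observations and no ties; otherwise the normal approximation with
    tie-corrected variance and continuity correction. Returns (U, p) with U
    the statistic for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "normal"
    if mode not in ("exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if has_ties and np.unique(pooled).size == 1:
        return float(x.size * y.size / 2.0), 1.0
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(1.0, res.pvalue))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialResult:
    """One row of a differential-abundance table (means as percent)."""

    feature: str
    mean_1: float
    se_1: float
    mean_2: float
    se_2: float
    p_raw: float
    q_fdr: float
    enriched_in: str  # cluster1 | cluster2 | ns


def _mean_se_pct(v: np.ndarray) -> tuple[float, float]:
    return float(v.mean() * 100.0), float(v.std(ddof=1) / np.sqrt(v.size) * 100.0)


def differential_table(
    table: FeatureTable,
    assignment: ClusterAssignment,
    top_n: int | None = None,
    min_mean_pct: float | None = None,
    alpha: float = 0.05,
    scope: str = "overall",
) -> pd.DataFrame:
    """Per-feature two-group Wilcoxon comparison with BH-FDR.

    Features are pre-selected by mean relative abundance: either the top
    ``top_n`` features or those whose mean exceeds ``min_mean_pct`` percent.
    ``scope`` controls whether the selection mean is taken over all samples
    ("overall") or is the max of the two per-cluster means ("per_cluster").
    Means and SEs are reported in percent; ``enriched_in`` is called at
    ``q < alpha`` on the FDR-adjusted p.
    """
    if table.kind != "relative":
        raise ValueError("differential table requires a relative-abundance table")
    clusters = sorted(assignment.labels.unique())
    if len(clusters) != 2:
        raise ValueError(f"exactly 2 clusters required, got {len(clusters)}")
    c1, c2 = clusters
    m1, m2 = assignment.members(c1), assignment.members(c2)
    if len(m1) < 2 or len(m2) < 2:
        raise ValueError("each cluster needs at least 2 samples")
    if scope not in ("overall", "per_cluster"):
        raise ValueError(f"unknown scope {scope!r}")

    data = table.data
    if scope == "overall":
        sel_mean = data[m1 + m2].mean(axis=1)
    else:
        sel_mean = pd.concat([data[m1].mean(axis=1), data[m2].mean(axis=1)], axis=1).max(axis=1)
    order = sel_mean.sort_values(ascending=False, kind="mergesort")
    if top_n is not None:
        chosen = list(order.index[:top_n])
    elif min_mean_pct is not None:
        chosen = list(order.index[order * 100.0 > min_mean_pct])
    else:
        chosen = list(order.index)

    rows = []
    pvals = []
    for fid in chosen:
        v1 = data.loc[fid, m1].to_numpy()
        v2 = data.loc[fid, m2].to_numpy()
        _, p = wilcoxon_rank_sum(v1, v2)
        pvals.append(p)
        (mu1, se1), (mu2, se2) = _mean_se_pct(v1), _mean_se_pct(v2)
        rows.append({"feature": fid, "mean_1": mu1, "se_1": se1, "mean_2": mu2, "se_2": se2, "p_raw": p})
    q = bh_adjust(pvals) if rows else np.array([])
    out = pd.DataFrame(rows)
    if len(out):
        out["q_fdr"] = q
        out["enriched_in"] = np.where(
            out["q_fdr"] >= alpha, "ns", np.where(out["mean_1"] > out["mean_2"], "cluster1", "cluster2")
        )
    return out


def phenotype_table(
    metadata: pd.DataFrame,
    assignment: ClusterAssignment,
    traits=None,
    variant: str = "welch",
) -> pd.DataFrame:
    """Per-trait t-test comparison of numeric phenotypes between two clusters."""
    clusters = sorted(assignment.labels.unique())
    if len(clusters) != 2:
        raise ValueError("exactly 2 clusters required")
    m1, m2 = (assignment.members(c) for c in clusters)
    num = metadata.select_dtypes(include=[np.number])
    cols = list(traits) if traits is not None else list(num.columns)
    rows = []
    for t in cols:
        v1 = num.loc[num.index.intersection(m1), t].dropna().to_numpy()
        v2 = num.loc[num.index.intersection(m2), t].dropna().to_numpy()
        if v1.size < 2 or v2.size < 2:
            continue
        tstat, df, p = t_test_independent(v1, v2, variant=variant)
        rows.append(
            {
                "trait": t,
                "mean_1": v1.mean(),
                "se_1": v1.std(ddof=1) / np.sqrt(v1.size),
                "mean_2": v2.mean(),
                "se_2": v2.std(ddof=1) / np.sqrt(v2.size),
                "t": tstat,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
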