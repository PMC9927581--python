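"""Alpha-diversity indices and beta-diversity distance matrices.

Alpha diversity reports observed richness (Sobs), the Chao1 and ACE richness
estimators, Shannon entropy (natural log) and both Simpson variants
(dominance sum p_i^2 and its complement). Beta diversity provides the
square-root Jensen-Shannon distance used for enterotyping and Bray-Curtis
dissimilarity.

The estimator variants are pinned rather than delegated to a library:

* Chao1: classic ``S + F1^2 / (2 F2)`` when doubletons exist, else the
  bias-style fallback ``S + F1 (F1 - 1) / 2``.
* ACE: abundance-based coverage estimator with rare cutoff 10,
  ``C_ace = 1 - F1 / N_rare``; falls back to Chao1 when coverage is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import FeatureTable

__all__ = [
    "DistanceMatrix",
    "alpha_diversity",
    "jsd_divergence",
    "jsd_distance",
    "bray_curtis",
]

JSD_MAX = float(np.sqrt(np.log(2.0)))
DEFAULT_PSEUDOCOUNT = 1e-6
ACE_RARE_CUTOFF = 10


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with named metric."""

    sample_ids: list
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-15).any():
            raise ValueError("negative distance")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, metric_name: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError(f"{path}: row and column sample ids differ")
        return cls(list(df.index.astype(str)), df.to_numpy(), metric_name)

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=self.sample_ids)

    def submatrix(self, sample_ids) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[str(s)] for s in sample_ids]
        return DistanceMatrix(
            [self.sample_ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.metric_name,
        )


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _chao1(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    s = counts.size
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    if f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    return s + f1 * (f1 - 1) / 2.0


def _ace(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    rare = counts[counts <= ACE_RARE_CUTOFF]
    s_abund = int(np.sum(counts > ACE_RARE_CUTOFF))
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return _chao1(counts)
    sum_k = sum(k * (k - 1) * int(np.sum(rare == k)) for k in range(1, ACE_RARE_CUTOFF + 1))
    gamma2 = (s_rare / c_ace) * sum_k / (n_rare * (n_rare - 1)) - 1.0 if n_rare > 1 else 0.0
    gamma2 = max(0.0, gamma2)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample richness and diversity indices from a counts table.

    Returns a DataFrame indexed by sample with columns sobs, chao1, ace,
    shannon, simpson_dominance (sum p^2) and simpson_diversity (1 - sum p^2).
    Richness estimators are undefined on relative abundances, so only
    integer counts are accepted.
    """
    if table.kind != "counts":
        raise ValueError("alpha diversity requires a counts table")
    arr = table.values
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("alpha diversity requires integer counts")
    arr = np.round(arr).astype(np.int64)
    if (arr.sum(axis=0) <= 0).any():
        j = int(np.argmax(arr.sum(axis=0) <= 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero total count")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        c = arr[:, j]
        nz = c[c > 0]
        p = nz / nz.sum()
        dom = float((p * p).sum())
        rows.append(
            {
                "sobs": int(nz.size),
                "chao1": _chao1(c),
                "ace": _ace(c),
                "shannon": _shannon(c),
                "simpson_dominance": dom,
                "simpson_diversity": 1.0 - dom,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample_id"))


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def _prep_profiles(table: FeatureTable, pseudocount: float) -> np.ndarray:
    if table.kind != "relative":
        raise ValueError("JSD requires a relative-abundance table")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    p = table.values.T.copy()  # samples x features
    p[p == 0.0] = pseudocount
    p /= p.sum(axis=1, keepdims=True)
    return p


def jsd_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log) of two probability vectors."""
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log(p / m), 0.0).sum()
        kl_qm = np.where(q > 0, q * np.log(q / m), 0.0).sum()
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def jsd_distance(table: FeatureTable, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> DistanceMatrix:
    """Square-root Jensen-Shannon distance between all sample pairs.

    Zeros are replaced by *pseudocount* and each profile renormalised before
    the divergence is computed, so all Kullback-Leibler terms are finite.
    The result is a metric bounded by sqrt(ln 2).
    """
    prof = _prep_profiles(table, pseudocount)
    n = prof.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        pi = prof[i]
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.sqrt(max(0.0, jsd_divergence(pi, prof[j])))
    return DistanceMatrix(table.sample_ids, d, "jsd")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y) per sample pair."""
    arr = table.values.T
    totals = arr.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size >= 2:
        a, b = (table.sample_ids[i] for i in zero[:2])
        raise ValueError(f"all-zero samples {a!r} and {b!r}: Bray-Curtis undefined")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d, "braycurtis")
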