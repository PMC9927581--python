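"""Enterotype discovery on a precomputed distance matrix.

Samples are clustered with partitioning around medoids (PAM) on the
Jensen-Shannon distance matrix; the number of enterotypes is chosen by
maximising the Calinski-Harabasz (CH) index, evaluated in the
positive-eigenvalue principal-coordinate embedding of the distances (CH is a
ratio of Euclidean dispersions, so it needs a Euclidean geometry to live in).
Each cluster's driver taxon is the feature with the highest within-cluster
mean relative abundance. Group separation in ordination space is tested with
ANOSIM.

PAM here is fully deterministic: a greedy BUILD phase followed by
steepest-descent SWAP, with ties broken by the lowest sample index. There are
no random restarts, so a given distance matrix always yields the same
medoids and the same labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .tables import FeatureTable

__all__ = [
    "ClusterAssignment",
    "ModelSelectionTrace",
    "OrdinationResult",
    "pam",
    "calinski_harabasz",
    "select_k",
    "identify_drivers",
    "pcoa",
    "anosim",
]


@dataclass
class ClusterAssignment:
    """Sample -> enterotype labels (1..k) plus medoids and PAM objective."""

    labels: pd.Series  # index sample_id, values 1..k
    medoid_ids: list
    objective: float

    @property
    def k(self) -> int:
        return len(self.medoid_ids)

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])

    def sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()

    def to_tsv(self, path) -> None:
        df = self.labels.rename("enterotype").to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclass
class ModelSelectionTrace:
    """CH score per candidate k; optimal_k attains the maximum (ties -> smallest k)."""

    k_values: list
    ch_scores: list

    @property
    def optimal_k(self) -> int:
        best = max(self.ch_scores)
        for k, s in zip(self.k_values, self.ch_scores):
            if s == best:
                return k
        raise RuntimeError("empty trace")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "ch": self.ch_scores})


@dataclass
class OrdinationResult:
    """Classical-scaling coordinates, eigenvalues and explained proportions."""

    coordinates: pd.DataFrame  # samples x axes (positive-eigenvalue axes only)
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending
    proportion_explained: np.ndarray  # per retained axis, over positive eigvals

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.coordinates.to_csv(path, sep="\t", float_format="%.17g")
        if sidecar_path is not None:
            pd.DataFrame(
                {
                    "eigenvalue": self.eigenvalues,
                    "proportion_explained": np.concatenate(
                        [
                            self.proportion_explained,
                            np.full(len(self.eigenvalues) - len(self.proportion_explained), np.nan),
                        ]
                    ),
                }
            ).to_csv(sidecar_path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def _assign(d: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    sub = d[:, medoids]
    nearest = np.argmin(sub, axis=1)  # argmin takes first on ties -> deterministic
    cost = float(sub[np.arange(d.shape[0]), nearest].sum())
    return nearest, cost


def _build(d: np.ndarray, k: int, first: int) -> list[int]:
    """Greedy BUILD from a fixed first medoid; ties to the lowest index."""
    medoids = [first]
    nearest_d = d[:, first].copy()
    while len(medoids) < k:
        # cost decrease from adding each candidate
        gains = np.maximum(nearest_d[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        cand = int(np.argmax(gains))  # argmax: first index on ties
        medoids.append(cand)
        nearest_d = np.minimum(nearest_d, d[:, cand])
    return medoids


def _swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Steepest-descent SWAP until no (medoid, non-medoid) exchange improves.

    For each medoid m, precompute every sample's distance to its nearest
    *remaining* medoid; the cost after swapping m for candidate h is then
    sum(min(that, d[:, h])), evaluated vectorised over h.
    """
    k = len(medoids)
    _, cost = _assign(d, medoids)
    while True:
        eps = 1e-12 * (1.0 + abs(cost))
        best_delta = -eps
        best_swap = None
        sub = d[:, medoids]  # n x k
        for mi in range(k):
            rest = np.delete(sub, mi, axis=1)
            dmin_rest = rest.min(axis=1)
            trial_costs = np.minimum(dmin_rest[:, None], d).sum(axis=0)  # per candidate h
            trial_costs[medoids] = np.inf
            h = int(np.argmin(trial_costs))
            delta = float(trial_costs[h]) - cost
            if delta < best_delta:
                best_delta = delta
                best_swap = (mi, h)
        if best_swap is None:
            return medoids, cost
        mi, h = best_swap
        old = medoids[mi]
        medoids[mi] = h
        _, new_cost = _assign(d, medoids)
        if new_cost >= cost - eps:  # guard against summation-order rounding
            medoids[mi] = old
            return medoids, cost
        cost = new_cost


def pam(dist: DistanceMatrix, k: int) -> ClusterAssignment:
    """Partitioning around medoids, deterministic multi-start BUILD + SWAP.

    BUILD greedily adds the medoid giving the largest decrease in total
    distance-to-nearest-medoid; SWAP repeatedly applies the single
    (medoid, non-medoid) exchange with the largest strict decrease until no
    improving exchange exists. Because steepest-descent SWAP can stall in a
    one-exchange local optimum, BUILD is restarted once from every sample as
    the forced first medoid and the lowest-objective solution kept — still
    fully deterministic (ties resolve to the lowest sample index, then to
    the lexicographically smallest medoid set).
    """
    n = len(dist)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n={n}, got {k}")
    d = dist.values

    best_cost = np.inf
    best_medoids: list[int] | None = None
    for first in range(n):
        medoids, cost = _swap(d, _build(d, k, first))
        key = sorted(medoids)
        if cost < best_cost - 1e-12 * (1.0 + abs(cost)) or (
            abs(cost - best_cost) <= 1e-12 * (1.0 + abs(cost)) and key < sorted(best_medoids)
        ):
            best_cost = cost
            best_medoids = medoids

    medoids = sorted(best_medoids)
    nearest, cost = _assign(d, medoids)
    labels = pd.Series(nearest + 1, index=pd.Index(dist.sample_ids, name="sample_id"))
    return ClusterAssignment(
        labels=labels,
        medoid_ids=[dist.sample_ids[m] for m in medoids],
        objective=cost,
    )


# ---------------------------------------------------------------------------
# PCoA (classical scaling)
# ---------------------------------------------------------------------------

def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical multidimensional scaling of a distance matrix.

    Double-centres -D^2/2, eigendecomposes, and keeps coordinates on
    positive-eigenvalue axes (eigenvector * sqrt(eigenvalue)). Negative
    eigenvalues are reported in ``eigenvalues`` but excluded from both the
    coordinates and the explained-proportion denominator.
    """
    d2 = dist.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * max(abs(eigvals[0]), 1.0)) if n else 0.0
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=pd.Index(dist.sample_ids, name="sample_id"), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# Calinski-Harabasz
# ---------------------------------------------------------------------------

def calinski_harabasz(dist: DistanceMatrix, assignment: ClusterAssignment) -> float:
    """CH index [B/(k-1)] / [W/(n-k)] in PCoA positive-eigenvalue space.

    B and W are between- and within-cluster sums of squared Euclidean
    deviations from centroids in the embedding. Returns ``inf`` (with a
    warning) when W is exactly zero.
    """
    k = assignment.k
    n = len(dist)
    if k < 2:
        raise ValueError("CH undefined for k < 2")
    coords = pcoa(dist).coordinates.loc[dist.sample_ids].to_numpy()
    labels = assignment.labels.loc[dist.sample_ids].to_numpy()
    grand = coords.mean(axis=0)
    b = w = 0.0
    for c in np.unique(labels):
        pts = coords[labels == c]
        cen = pts.mean(axis=0)
        b += pts.shape[0] * float(((cen - grand) ** 2).sum())
        w += float(((pts - cen) ** 2).sum())
    if w <= 1e-12 * max(b, 1e-300):  # W exactly zero up to embedding round-off
        warnings.warn("within-cluster dispersion is zero; CH is infinite")
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def select_k(dist: DistanceMatrix, k_range=range(2, 11)) -> tuple[ModelSelectionTrace, ClusterAssignment]:
    """Scan k, cluster with PAM, score with CH; return trace + best assignment.

    Ties in CH resolve to the smallest k.
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    assignments, scores = [], []
    for k in ks:
        a = pam(dist, k)
        assignments.append(a)
        scores.append(calinski_harabasz(dist, a))
    trace = ModelSelectionTrace(ks, scores)
    return trace, assignments[ks.index(trace.optimal_k)]


def identify_drivers(table: FeatureTable, assignment: ClusterAssignment) -> pd.DataFrame:
    """Driver taxon per cluster: highest within-cluster mean relative abundance.

    Returns a tidy frame (cluster, feature, mean_abundance, rank) holding the
    full ranked contribution list; rank 1 is the driver. Ties on the mean
    resolve to the lexicographically smallest feature ID.
    """
    if table.kind != "relative":
        raise ValueError("driver identification requires a relative table")
    out = []
    for c in sorted(assignment.labels.unique()):
        members = assignment.members(c)
        if not members:
            raise ValueError(f"cluster {c} is empty")
        means = table.data[members].mean(axis=1)
        # descending means; exact ties break lexicographically on feature ID
        ranked = (
            means.to_frame("mean_abundance")
            .assign(feature=means.index)
            .sort_values(["mean_abundance", "feature"], ascending=[False, True])
        )
        for r, (fid, row) in enumerate(ranked.iterrows(), start=1):
            out.append(
                {"cluster": int(c), "feature": fid, "mean_abundance": row["mean_abundance"], "rank": r}
            )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim(dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """ANOSIM R statistic and permutation p-value on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4);
    p = (1 + #{permuted R >= observed}) / (1 + n_perm). Delegates to
    scikit-bio's implementation (identical formulation), seeded.
    """
    from skbio.stats.distance import anosim as _sk_anosim

    g = pd.Series(groups)
    if len(g) == len(dist) and not g.index.equals(pd.Index(dist.sample_ids)):
        g.index = dist.sample_ids if g.index.inferred_type == "integer" else g.index
    g = g.reindex(dist.sample_ids)
    if g.isna().any():
        missing = list(g.index[g.isna()])
        raise ValueError(f"group labels missing for samples: {missing}")
    counts = g.value_counts()
    if len(counts) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = counts.index[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    res = _sk_anosim(dist.to_skbio(), list(g.values), permutations=n_perm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])
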