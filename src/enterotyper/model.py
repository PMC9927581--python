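"""Model/Results front end for the enterotyping pipeline.

:class:`EnterotypeModel` is built from a feature table (plus optional
taxonomy and sample metadata); :meth:`EnterotypeModel.fit` runs
Jensen-Shannon + PAM clustering with Calinski-Harabasz model selection and
returns an :class:`EnterotypeResults` carrying the assignment, the selection
trace, the ordination and diagnostics. Downstream analyses — alpha-diversity
comparison, differential abundance, phenotype tests, trait correlations and
per-enterotype co-occurrence networks — hang off the results object.

Example
-------
>>> from enterotyper import EnterotypeModel, simulate
>>> table, tax, meta, truth = simulate.simulate_cohort(simulate.default_config(seed=1))
>>> res = EnterotypeModel(table, taxonomy=tax, metadata=meta).fit()
>>> res.optimal_k
2
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import diversity as _div
from . import network as _net
from . import stats as _stats
from .tables import FeatureTable, TaxonomyMap, aggregate_by_rank, to_relative

__all__ = ["EnterotypeModel", "EnterotypeResults"]


class EnterotypeModel:
    """Enterotype clustering model over a features-by-samples table.

    Parameters
    ----------
    table : FeatureTable
        Counts or relative abundances. Counts are converted to relative
        abundances for clustering; the counts are kept for alpha diversity.
    taxonomy : TaxonomyMap, optional
        Needed for rank-aggregated (family/genus) differential tables when
        the input features are finer than the target rank.
    metadata : pandas.DataFrame, optional
        Sample-indexed numeric phenotypes for group comparison and
        trait-correlation analyses.
    """

    def __init__(self, table: FeatureTable, taxonomy: TaxonomyMap | None = None,
                 metadata: pd.DataFrame | None = None):
        self.counts = table if table.kind == "counts" else None
        self.table = to_relative(table) if table.kind == "counts" else table
        self.taxonomy = taxonomy
        self.metadata = metadata
        if metadata is not None:
            missing = [s for s in self.table.sample_ids if s not in metadata.index]
            extra = [s for s in metadata.index if s not in self.table.sample_ids]
            if missing or extra:
                raise ValueError(
                    f"metadata/table sample mismatch; only in table: {missing}; "
                    f"only in metadata: {extra}"
                )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "counts", **kw) -> "EnterotypeModel":
        return cls(FeatureTable(df, kind=kind), **kw)

    def fit(self, k_range=range(2, 11), pseudocount: float = _div.DEFAULT_PSEUDOCOUNT,
            k: int | None = None) -> "EnterotypeResults":
        """Cluster samples on the square-root Jensen-Shannon distance.

        Scans ``k_range`` with PAM and picks the k maximising the
        Calinski-Harabasz index (or uses a fixed ``k`` when given).
        """
        dist = _div.jsd_distance(self.table, pseudocount=pseudocount)
        if k is not None:
            assignment = _cluster.pam(dist, k)
            trace = _cluster.ModelSelectionTrace([k], [_cluster.calinski_harabasz(dist, assignment)])
        else:
            trace, assignment = _cluster.select_k(dist, k_range)
        ordination = _cluster.pcoa(dist)
        return EnterotypeResults(self, dist, assignment, trace, ordination)


@dataclass
class EnterotypeResults:
    """Fitted enterotype assignment plus downstream analyses."""

    model: EnterotypeModel
    distance: _div.DistanceMatrix
    assignment: _cluster.ClusterAssignment
    trace: _cluster.ModelSelectionTrace
    ordination: _cluster.OrdinationResult
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def optimal_k(self) -> int:
        return self.assignment.k

    @property
    def labels(self) -> pd.Series:
        return self.assignment.labels

    def cluster_sizes(self) -> dict[int, int]:
        return self.assignment.sizes()

    # -- downstream analyses -------------------------------------------------

    def drivers(self, rank: str | None = None) -> pd.DataFrame:
        table = self._rank_table(rank)
        return _cluster.identify_drivers(table, self.assignment)

    def alpha_diversity(self) -> pd.DataFrame:
        if self.model.counts is None:
            raise ValueError("alpha diversity needs the original counts table")
        return _div.alpha_diversity(self.model.counts)

    def alpha_comparison(self) -> pd.DataFrame:
        """Wilcoxon + BH comparison of alpha indices between two enterotypes."""
        alpha = self.alpha_diversity()
        clusters = sorted(self.labels.unique())
        if len(clusters) != 2:
            raise ValueError("alpha comparison requires exactly 2 enterotypes")
        m1, m2 = (self.assignment.members(c) for c in clusters)
        rows = []
        for col in alpha.columns:
            u, p = _stats.wilcoxon_rank_sum(alpha.loc[m1, col], alpha.loc[m2, col])
            rows.append({"index": col, "mean_1": alpha.loc[m1, col].mean(),
                         "mean_2": alpha.loc[m2, col].mean(), "U": u, "p_raw": p})
        out = pd.DataFrame(rows)
        out["q_fdr"] = _stats.bh_adjust(out["p_raw"])
        return out

    def anosim(self, metric: str = "braycurtis", n_perm: int = 999, seed: int = 0):
        """ANOSIM of enterotype separation on a beta-diversity matrix."""
        key = ("anosim", metric, n_perm, seed)
        if key not in self._cache:
            dist = self.distance if metric == "jsd" else _div.bray_curtis(self.model.table)
            self._cache[key] = _cluster.anosim(dist, self.labels, n_perm=n_perm, seed=seed)
        return self._cache[key]

    def _rank_table(self, rank: str | None) -> FeatureTable:
        if rank is None:
            return self.model.table
        if self.model.taxonomy is None:
            raise ValueError("rank aggregation needs a taxonomy map")
        return aggregate_by_rank(self.model.table, self.model.taxonomy, rank)

    def differential_table(self, rank: str | None = "genus", top_n: int | None = None,
                           min_mean_pct: float | None = 1.0, alpha: float = 0.05,
                           scope: str = "overall") -> pd.DataFrame:
        """Wilcoxon + BH differential-abundance table at a taxonomic rank."""
        return _stats.differential_table(
            self._rank_table(rank), self.assignment,
            top_n=top_n, min_mean_pct=min_mean_pct, alpha=alpha, scope=scope,
        )

    def phenotype_table(self, traits=None, variant: str = "welch") -> pd.DataFrame:
        if self.model.metadata is None:
            raise ValueError("phenotype comparison needs sample metadata")
        return _stats.phenotype_table(self.model.metadata, self.assignment,
                                      traits=traits, variant=variant)

    def trait_correlations(self, rank: str | None = "genus", genera=None, traits=None):
        if self.model.metadata is None:
            raise ValueError("trait correlations need sample metadata")
        return _net.trait_correlations(self._rank_table(rank), self.model.metadata,
                                       genera=genera, traits=traits)

    def networks(self, rank: str | None = "genus", node_whitelist=None, **kw):
        """Per-enterotype co-occurrence networks (dict cluster -> nx.Graph)."""
        table = self._rank_table(rank)
        return {
            int(c): _net.build_network(table, subgroup=self.assignment.members(c),
                                       node_whitelist=node_whitelist, **kw)
            for c in sorted(self.labels.unique())
        }

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        sizes = self.cluster_sizes()
        lines = [
            "Enterotype clustering (sqrt Jensen-Shannon distance, PAM)",
            "=" * 60,
            f"samples: {len(self.distance)}   features: {self.model.table.shape[0]}",
            f"optimal k (max Calinski-Harabasz): {self.optimal_k}",
            "cluster sizes: " + ", ".join(f"{c}: n={n}" for c, n in sizes.items()),
            "medoids: " + ", ".join(map(str, self.assignment.medoid_ids)),
            f"PAM objective: {self.assignment.objective:.6f}",
            "",
            "CH trace:",
        ]
        for k, s in zip(self.trace.k_values, self.trace.ch_scores):
            mark = "  <-- optimal" if k == self.optimal_k else ""
            lines.append(f"  k={k:>2d}  CH={s:10.3f}{mark}")
        drv = self.drivers()
        lines.append("")
        lines.append("driver taxa (highest within-cluster mean abundance):")
        for c in sorted(sizes):
            row = drv[(drv["cluster"] == c) & (drv["rank"] == 1)].iloc[0]
            lines.append(f"  cluster {c}: {row['feature']} ({row['mean_abundance'] * 100:.2f}%)")
        if len(self.ordination.proportion_explained) >= 2:
            pe = self.ordination.proportion_explained
            lines.append("")
            lines.append(f"PCoA axes 1-2 explain {pe[0] * 100:.1f}% + {pe[1] * 100:.1f}%")
        return "\n".join(lines)

    # -- plotting (optional extra) -------------------------------------------

    def plot_ordination(self, ax=None):
        """Scatter the first two PCoA axes coloured by enterotype."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        coords = self.ordination.coordinates
        for c in sorted(self.labels.unique()):
            m = self.assignment.members(c)
            ax.scatter(coords.loc[m, "PCo1"], coords.loc[m, "PCo2"], label=f"cluster {c}", s=20)
        pe = self.ordination.proportion_explained
        ax.set_xlabel(f"PCo1 ({pe[0] * 100:.1f}%)")
        ax.set_ylabel(f"PCo2 ({pe[1] * 100:.1f}%)")
        ax.legend()
        return ax

    def plot_ch_trace(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace.k_values, self.trace.ch_scores, "o-")
        ax.axvline(self.optimal_k, ls="--", c="grey")
        ax.set_xlabel("number of enterotypes")
        ax.set_ylabel("Calinski-Harabasz index")
        return ax
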