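"""Microbe-trait correlations and genus co-occurrence networks.

Associations between genus relative abundances and host traits (growth rate,
gut fermentation, serum biochemistry) use Spearman's rank correlation.
Per-enterotype co-occurrence networks connect genus pairs whose abundance
profiles correlate with |rho| > 0.2 at P < 0.05 (raw, two-sided), after a
node filter keeping genera with mean relative abundance > 0.1% that are
present in more than half of the subgroup's samples. Positive edges are
co-occurrence, negative edges co-exclusion.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .tables import FeatureTable

__all__ = [
    "spearman",
    "trait_correlations",
    "build_network",
    "export_network",
]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; two-sided t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance: Spearman undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def trait_correlations(
    genus_table: FeatureTable,
    metadata: pd.DataFrame,
    genera=None,
    traits=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All (genus, trait) Spearman correlations over pooled samples.

    Missing trait values are dropped pairwise; traits with fewer than 3
    non-missing values (or zero variance) are skipped with a warning.
    Returns (rho, p) DataFrames with genera as rows and traits as columns.
    """
    if genus_table.kind != "relative":
        raise ValueError("trait correlations require a relative table")
    genera = list(genera) if genera is not None else genus_table.feature_ids
    missing = [g for g in genera if g not in genus_table.data.index]
    if missing:
        raise KeyError(f"genera not in table: {missing}")
    num = metadata.select_dtypes(include=[np.number])
    traits = list(traits) if traits is not None else list(num.columns)
    samples = [s for s in genus_table.sample_ids if s in num.index]
    rho = pd.DataFrame(index=genera, columns=traits, dtype=float)
    pmat = pd.DataFrame(index=genera, columns=traits, dtype=float)
    for t in traits:
        tv = num.loc[samples, t]
        ok = tv.notna()
        if ok.sum() < 3 or tv[ok].nunique() < 2:
            warnings.warn(f"trait {t!r} skipped: <3 values or constant")
            rho.drop(columns=t, inplace=True)
            pmat.drop(columns=t, inplace=True)
            continue
        keep = list(tv.index[ok])
        for g in genera:
            gv = genus_table.data.loc[g, keep].to_numpy()
            if np.unique(gv).size < 2:
                rho.at[g, t] = np.nan
                pmat.at[g, t] = np.nan
                continue
            r, p = spearman(gv, tv[ok].to_numpy())
            rho.at[g, t] = r
            pmat.at[g, t] = p
    return rho, pmat


def significance_flags(pmat: pd.DataFrame) -> pd.DataFrame:
    """Star flags: '**' for p<0.01, '*' for p<0.05, '' otherwise."""
    return pmat.map(lambda p: "**" if p < 0.01 else ("*" if p < 0.05 else ""))


def build_network(
    genus_table: FeatureTable,
    subgroup=None,
    min_mean_abundance: float = 0.001,
    min_prevalence: float = 0.5,
    rho_threshold: float = 0.2,
    alpha: float = 0.05,
    node_whitelist=None,
) -> nx.Graph:
    """Genus co-occurrence network for a sample subgroup.

    Node filter: mean relative abundance > ``min_mean_abundance`` AND nonzero
    in more than ``min_prevalence`` of the subgroup samples (both computed
    within the subgroup). Edge criterion: Spearman |rho| > ``rho_threshold``
    and raw two-sided p < ``alpha`` (strict inequalities). Edge weight is the
    signed rho; ``sign`` is "pos"/"neg". An optional ``node_whitelist``
    restricts nodes (e.g. to differential genera) before filtering.
    """
    if genus_table.kind != "relative":
        raise ValueError("network construction requires a relative table")
    sub = genus_table if subgroup is None else genus_table.filter_samples(subgroup)
    if sub.shape[1] < 4:
        raise ValueError("subgroup needs at least 4 samples")
    data = sub.data
    if node_whitelist is not None:
        data = data.loc[[g for g in data.index if g in set(node_whitelist)]]
    mean_ok = data.mean(axis=1) > min_mean_abundance
    prev_ok = (data > 0).mean(axis=1) > min_prevalence
    nodes = list(data.index[mean_ok & prev_ok])

    g = nx.Graph()
    for n in nodes:
        g.add_node(n, mean_abundance=float(data.loc[n].mean()))
    if len(nodes) < 2:
        warnings.warn("fewer than 2 genera survive the node filters; empty network")
        return g
    for i, a in enumerate(nodes):
        va = data.loc[a].to_numpy()
        for b in nodes[i + 1:]:
            vb = data.loc[b].to_numpy()
            if np.unique(va).size < 2 or np.unique(vb).size < 2:
                continue
            rho, p = spearman(va, vb)
            if abs(rho) > rho_threshold and p < alpha:
                g.add_edge(a, b, rho=float(rho), p=float(p), sign="pos" if rho > 0 else "neg")
    return g


def export_network(net: nx.Graph, path, fmt: str = "tsv") -> None:
    """Write a network as SIF, GraphML, or an edge TSV (lexicographic order)."""
    edges = sorted((min(a, b), max(a, b), d) for a, b, d in net.edges(data=True))
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b, d in edges:
                fh.write(f"{a}\t{d.get('sign', 'pos')}\t{b}\n")
    elif fmt == "graphml":
        h = nx.Graph()
        h.add_nodes_from(sorted(net.nodes(data=True)))
        for a, b, d in edges:
            h.add_edge(a, b, **d)
        nx.write_graphml(h, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\trho\tp\tsign\n")
            for a, b, d in edges:
                fh.write(f"{a}\t{b}\t{d['rho']:.17g}\t{d['p']:.17g}\t{d['sign']}\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (use sif, graphml or tsv)")


def node_table(net: nx.Graph) -> pd.DataFrame:
    rows = [{"genus": n, **d} for n, d in sorted(net.nodes(data=True))]
    return pd.DataFrame(rows)
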