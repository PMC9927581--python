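"""Feature tables, taxonomy maps and sample metadata.

The canonical in-memory currency of the pipeline is :class:`FeatureTable`,
a features-by-samples abundance matrix (raw counts or per-sample relative
abundances) carried as a :class:`pandas.DataFrame`. All other modules assume
the alignment contracts enforced here: unique feature and sample identifiers,
non-negative values, and (for relative tables) columns summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "TaxonomyMap",
    "RANKS",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "to_relative",
    "aggregate_by_rank",
]

RANKS = ("phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"

_REL_TOL = 1e-9


@dataclass
class FeatureTable:
    """Features x samples abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features, columns are samples. Non-negative.
    kind : {"counts", "relative"}
        ``counts`` for raw (integer) counts, ``relative`` for per-sample
        proportions; relative columns must sum to 1 within 1e-9.
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        self.data = self.data.astype(float)
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite value in feature table")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value at feature {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.kind == "relative" and vals.size:
            sums = vals.sum(axis=0)
            bad = np.abs(sums - 1.0) > _REL_TOL
            if bad.any():
                j = int(np.argmax(bad))
                raise ValueError(
                    f"relative table column {cols[j]!r} sums to {sums[j]!r}, not 1"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def filter_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return FeatureTable(self.data.loc[:, list(sample_ids)].copy(), kind=self.kind)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        f, s = self.shape
        return f"FeatureTable(kind={self.kind!r}, {f} features x {s} samples)"


@dataclass
class TaxonomyMap:
    """feature_id -> ranked lineage (phylum..genus); missing ranks unassigned."""

    lineages: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RANKS))

    def __post_init__(self) -> None:
        if self.lineages.index.has_duplicates:
            dup = self.lineages.index[self.lineages.index.duplicated()][0]
            raise ValueError(f"duplicate feature id in taxonomy: {dup!r}")
        for r in RANKS:
            if r not in self.lineages.columns:
                self.lineages[r] = UNASSIGNED
        self.lineages = self.lineages[list(RANKS)].fillna(UNASSIGNED)
        self.lineages = self.lineages.replace("", UNASSIGNED)

    def label(self, feature_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; valid: {RANKS}")
        if feature_id not in self.lineages.index:
            return UNASSIGNED
        return str(self.lineages.at[feature_id, rank])


def read_feature_table(path, orientation: str = "features") -> FeatureTable:
    """Read a TSV abundance table.

    First column holds feature IDs (``orientation="features"``, the amplicon
    convention) or sample IDs (``orientation="samples"``; the table is
    transposed on read). Integer-valued tables are auto-detected as counts.
    """
    if orientation not in ("features", "samples"):
        raise ValueError("orientation must be 'features' or 'samples'")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged or malformed TSV {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples":
        df = df.T
    try:
        vals = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    arr = vals.to_numpy()
    is_counts = arr.size > 0 and np.allclose(arr, np.round(arr), atol=0) and arr.max(initial=0) > 1
    if arr.size and np.allclose(arr, np.round(arr), atol=0):
        # all-integer tables are counts even if tiny
        is_counts = True
    colsums = arr.sum(axis=0) if arr.size else np.array([])
    kind = "counts"
    if not is_counts:
        kind = "relative" if arr.size and np.allclose(colsums, 1.0, atol=1e-6) else "counts"
    if kind == "relative":
        vals = vals / colsums  # exact renormalisation against TSV rounding
    return FeatureTable(vals, kind=kind)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.data.copy()
    if table.kind == "counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a 2-column TSV (feature_id, semicolon-delimited lineage).

    Lineage ranks are phylum;class;order;family;genus; trailing ranks may be
    omitted and are recorded as unassigned.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"taxonomy TSV {path} needs 2 columns (feature_id, lineage)")
    rows = {}
    for _, (fid, lineage) in df.iloc[:, :2].iterrows():
        parts = [p.strip() for p in str(lineage).split(";")]
        parts = parts + [UNASSIGNED] * (len(RANKS) - len(parts))
        rows[str(fid)] = {r: (p if p else UNASSIGNED) for r, p in zip(RANKS, parts)}
    lin = pd.DataFrame.from_dict(rows, orient="index")
    return TaxonomyMap(lin)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tlineage\n")
        for fid, row in tax.lineages.iterrows():
            fh.write(f"{fid}\t{';'.join(row[r] for r in RANKS)}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (first column sample_id; phenotypes numeric)."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    return df


def to_relative(table: FeatureTable) -> FeatureTable:
    """Convert a counts table to per-sample relative abundances."""
    if table.kind == "relative":
        return table
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    return FeatureTable(table.data / sums, kind="relative")


def aggregate_by_rank(table: FeatureTable, tax: TaxonomyMap, rank: str) -> FeatureTable:
    """Sum features sharing a taxonomic label at *rank*.

    Features without a label at that rank pool into a single ``unassigned``
    row so per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid: {RANKS}")
    mapped = set(tax.lineages.index)
    if mapped and not (set(table.feature_ids) & mapped):
        raise ValueError("no overlap between table features and taxonomy map")
    labels = [tax.label(f, rank) for f in table.feature_ids]
    out = table.data.groupby(pd.Index(labels, name=rank)).sum()
    return FeatureTable(out, kind=table.kind)
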