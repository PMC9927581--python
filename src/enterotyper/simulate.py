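"""Synthetic enterotype-structured cohorts with known ground truth.

The generator emulates a two-community goat-kid cohort: 39 + 37 fecal
samples whose genus-level compositions are drawn from a Dirichlet-
multinomial around two fixed community mean profiles (the 27-genus panel of
abundant fecal genera, with the residual mass pooled as ``Other``), plus a
host-phenotype panel (growth rate, fecal fermentation acids, serum
biochemistry) whose means shift between the communities and which can be
rank-coupled to selected genera through a Gaussian copula so Spearman
associations are recoverable by construction.

Per sample: proportions ~ Dirichlet(concentration * community_mean), then
counts ~ Multinomial(depth, proportions). The concentration scalar controls
overdispersion (theta = 1/(1+concentration)); depth is the sequencing depth.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import RANKS, FeatureTable, TaxonomyMap

__all__ = ["SimulationConfig", "simulate_cohort", "compute_adg", "GENUS_PANEL", "default_config"]

# Abundant fecal genus panel: (genus, family, community-1 mean %, community-2 mean %).
GENUS_PANEL: list[tuple[str, str, float, float]] = [
    ("Oscillospiraceae_UCG-005", "Oscillospiraceae", 10.82, 10.38),
    ("unclassified_f_Lachnospiraceae", "Lachnospiraceae", 7.84, 8.62),
    ("Rikenellaceae_RC9_gut_group", "Rikenellaceae", 4.18, 7.96),
    ("Christensenellaceae_R-7_group", "Christensenellaceae", 3.17, 8.23),
    ("Treponema", "Spirochaetaceae", 4.93, 5.31),
    ("Bacteroides", "Bacteroidaceae", 2.49, 4.82),
    ("Norank_f_Muribaculaceae", "Muribaculaceae", 4.72, 1.78),
    ("Norank_f_UCG-010", "Oscillospirales_UCG-010", 2.80, 3.50),
    ("Turicibacter", "Erysipelotrichaceae", 3.53, 1.99),
    ("Succinivibrio", "Succinivibrionaceae", 3.84, 1.60),
    ("Norank_f_norank_o_Clostridia_UCG-014", "Clostridia_UCG-014", 2.74, 1.96),
    ("Ruminococcus", "Ruminococcaceae", 2.07, 2.45),
    ("Norank_f_Bacteroidales_RF16_group", "Bacteroidales_RF16_group", 2.02, 2.47),
    ("Alistipes", "Rikenellaceae", 1.96, 2.43),
    ("Prevotella", "Prevotellaceae", 3.32, 0.93),
    ("Norank_f_Eubacterium_coprostanoligenes_group", "Eubacterium_coprostanoligenes_group", 1.88, 2.14),
    ("Oscillospiraceae_UCG-002", "Oscillospiraceae", 1.69, 1.70),
    ("Oscillospiraceae_NK4A214_group", "Oscillospiraceae", 1.02, 1.78),
    ("Phascolarctobacterium", "Acidaminococcaceae", 1.65, 1.21),
    ("Norank_f_F082", "F082", 0.84, 1.88),
    ("Romboutsia", "Peptostreptococcaceae", 1.15, 1.44),
    ("Monoglobus", "Monoglobaceae", 1.05, 1.51),
    ("Roseburia", "Lachnospiraceae", 1.91, 0.52),
    ("Prevotellaceae_UCG-003", "Prevotellaceae", 1.75, 0.78),
    ("Clostridium_sensu_stricto_1", "Clostridiaceae", 0.95, 1.37),
    ("Norank_f_Ruminococcaceae", "Ruminococcaceae", 1.54, 0.76),
    ("Prevotellaceae_NK3B31_group", "Prevotellaceae", 2.08, 0.16),
]

# Phenotype panel: trait -> (community-1 mean, community-2 mean, sd, unit).
# Traits with equal means differ only by noise between communities.
PHENOTYPES: dict[str, tuple[float, float, float, str]] = {
    "ADG": (0.132, 0.118, 0.020, "kg/d"),
    "DMI": (0.75, 0.75, 0.08, "kg/d"),
    "acetate": (35.0, 30.0, 6.0, "mmol/kg"),
    "propionate": (10.0, 8.5, 2.0, "mmol/kg"),
    "butyrate": (4.5, 4.4, 1.0, "mmol/kg"),
    "valerate": (1.00, 0.85, 0.20, "mmol/kg"),
    "total_VFA": (50.5, 43.8, 8.0, "mmol/kg"),
    "NH3_N": (4.0, 4.0, 1.0, "mmol/kg"),
    "Alb": (32.0, 30.0, 2.5, "g/L"),
    "Glob": (30.0, 30.0, 3.0, "g/L"),
    "TP": (62.0, 62.0, 4.0, "g/L"),
    "IgG": (9.0, 10.5, 1.5, "g/L"),
    "glucose": (3.6, 3.3, 0.35, "mmol/L"),
    "urea_N": (5.2, 5.9, 0.8, "mmol/L"),
    "total_cholesterol": (2.10, 1.85, 0.30, "mmol/L"),
    "HDL_C": (1.20, 1.05, 0.15, "mmol/L"),
    "LDL_C": (0.70, 0.60, 0.12, "mmol/L"),
    "triglycerides": (0.35, 0.35, 0.08, "mmol/L"),
}

# Rank coupling (genus, trait, spearman rho) through a Gaussian copula.
DEFAULT_COUPLING: list[tuple[str, str, float]] = [
    ("Succinivibrio", "ADG", 0.35),
    ("Norank_f_Muribaculaceae", "total_VFA", 0.35),
    ("Norank_f_Muribaculaceae", "acetate", 0.30),
    ("Christensenellaceae_R-7_group", "urea_N", 0.35),
]


@dataclass
class SimulationConfig:
    """Parameters of the two-community cohort generator."""

    n_samples: tuple[int, int] = (39, 37)
    mean_1: dict[str, float] = field(default_factory=dict)  # genus -> mean %, community 1
    mean_2: dict[str, float] = field(default_factory=dict)
    concentration: float = 200.0
    depth: int = 20_000
    phenotypes: dict[str, tuple[float, float, float, str]] = field(
        default_factory=lambda: dict(PHENOTYPES)
    )
    coupling: list[tuple[str, str, float]] = field(default_factory=lambda: list(DEFAULT_COUPLING))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_1:
            self.mean_1 = {g: m1 for g, _, m1, _ in GENUS_PANEL}
            self.mean_1["Other"] = max(0.0, 100.0 - sum(self.mean_1.values()))
        if not self.mean_2:
            self.mean_2 = {g: m2 for g, _, _, m2 in GENUS_PANEL}
            self.mean_2["Other"] = max(0.0, 100.0 - sum(self.mean_2.values()))
        if set(self.mean_1) != set(self.mean_2):
            raise ValueError("mean_1 and mean_2 must cover the same genera")
        for d in (self.mean_1, self.mean_2):
            if any(v < 0 for v in d.values()):
                raise ValueError("negative mean abundance")
            if sum(d.values()) <= 0:
                raise ValueError("community mean vector sums to zero")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for t, (_, _, sd, _) in self.phenotypes.items():
            if sd <= 0:
                raise ValueError(f"phenotype {t!r} sd must be > 0")

    @property
    def genera(self) -> list[str]:
        return list(self.mean_1)

    def mean_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        g = self.genera
        v1 = np.array([self.mean_1[x] for x in g], dtype=float)
        v2 = np.array([self.mean_2[x] for x in g], dtype=float)
        return v1 / v1.sum(), v2 / v2.sum()


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    return SimulationConfig(seed=seed, **overrides)


def default_taxonomy(genera) -> TaxonomyMap:
    fam = {g: f for g, f, _, _ in GENUS_PANEL}
    rows = {}
    for g in genera:
        rows[g] = {r: "unassigned" for r in RANKS}
        rows[g]["genus"] = g
        rows[g]["family"] = fam.get(g, "unassigned")
    return TaxonomyMap(pd.DataFrame.from_dict(rows, orient="index"))


def _normal_scores(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rank-based normal scores, random tie-break for exact ties."""
    from scipy.stats import norm

    jitter = rng.normal(0.0, 1e-12, size=values.size)
    order = np.argsort(values + jitter)
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, values.size + 1)
    return norm.ppf((ranks - 0.5) / values.size)


def simulate_cohort(cfg: SimulationConfig):
    """Draw a cohort; returns (counts FeatureTable, TaxonomyMap, metadata, labels).

    ``labels`` is a pandas Series of ground-truth community labels (1/2)
    indexed by sample; it is returned separately and never written into the
    metadata frame, so recovery analyses cannot leak it.
    """
    rng = np.random.default_rng(cfg.seed)
    genera = cfg.genera
    v1, v2 = cfg.mean_vectors()
    n1, n2 = cfg.n_samples
    n = n1 + n2
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    labels = np.array([1] * n1 + [2] * n2)

    counts = np.zeros((len(genera), n), dtype=np.int64)
    for j in range(n):
        base = v1 if labels[j] == 1 else v2
        p = rng.dirichlet(cfg.concentration * base)
        counts[:, j] = rng.multinomial(cfg.depth, p)
    table = FeatureTable(
        pd.DataFrame(counts, index=pd.Index(genera, name="genus"), columns=sample_ids),
        kind="counts",
    )

    rel = counts / counts.sum(axis=0, keepdims=True)
    genus_scores = {
        g: _normal_scores(rel[genera.index(g)], rng)
        for g, _, _ in cfg.coupling
        if g in genera
    }
    meta = {}
    for trait, (m1, m2, sd, _unit) in cfg.phenotypes.items():
        mu = np.where(labels == 1, m1, m2).astype(float)
        couple = [(g, r) for g, t, r in cfg.coupling if t == trait and g in genus_scores]
        eps = rng.normal(size=n)
        if couple:
            g, r = couple[0]
            z = genus_scores[g]
            meta[trait] = mu + sd * (r * z + np.sqrt(1.0 - r * r) * eps)
        else:
            meta[trait] = mu + sd * eps
    metadata = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))
    truth = pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"), name="true_community")
    return table, default_taxonomy(genera), metadata, truth


def compute_adg(birth_weight: float, final_weight: float, days: int) -> float:
    """Average daily gain: (final - birth) / days, in kg/day."""
    if days <= 0:
        raise ValueError("days must be > 0")
    if birth_weight < 0 or final_weight < 0:
        raise ValueError("weights must be non-negative")
    return (final_weight - birth_weight) / days
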