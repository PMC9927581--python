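# Methods

`enterotyper` implements a complete enterotyping analysis chain for
compositional microbiome profiles — the kind of genus- or ASV-level
relative-abundance tables produced by 16S rRNA amplicon pipelines — together
with the downstream statistics that typically accompany an enterotype study
of a host cohort: diversity comparison, two-group differential abundance,
microbe–trait association, and per-group co-occurrence networks. A synthetic
cohort generator with known ground truth makes every stage testable without
external data.

## Enterotype model

Samples are community profiles `p_s` (non-negative, summing to 1 per
sample). The pairwise dissimilarity is the square-root Jensen-Shannon
divergence

    JSD(P, Q) = ½ KL(P ‖ M) + ½ KL(Q ‖ M),   M = (P + Q)/2,
    d(P, Q) = sqrt(JSD(P, Q)),

with natural logarithms, so `d` is a metric bounded by `sqrt(ln 2)`. Zeros
are replaced by a pseudocount (default `1e-6`) and profiles renormalised
before the divergence, keeping every KL term finite. The pseudocount is
deliberately far below any realistic abundance; its exact value has no
visible effect on the distances at the defaults.

Clustering is partitioning around medoids (PAM) on the precomputed distance
matrix: greedy BUILD followed by steepest-descent SWAP (accept the single
(medoid, non-medoid) exchange with the largest strict decrease in the total
distance-to-nearest-medoid objective, until none improves). Steepest-descent
SWAP from one BUILD start can land in a one-exchange local optimum — on
random small instances we measured roughly an 8% miss rate against
exhaustive search — so BUILD is restarted deterministically from every
sample as the forced first medoid and the best final objective kept. This
keeps the procedure fully reproducible (ties resolve to the lowest sample
index, then the lexicographically smallest medoid set) while matching the
brute-force optimum on all randomly generated instances with n ≤ 10 that we
test. A full k = 2..10 scan on a 76-sample matrix costs ~0.3 s.

The number of enterotypes is chosen by maximising the Calinski-Harabasz
index

    CH(k) = [B / (k − 1)] / [W / (n − k)],

where B and W are between- and within-cluster sums of squared Euclidean
deviations from centroids. Because CH is defined for Euclidean geometry, the
samples are first embedded by classical scaling (PCoA) of the distance
matrix, retaining positive-eigenvalue axes only; B and W are evaluated in
that space. Computing CH on the raw dissimilarities via a distances-only
decomposition is a valid alternative; the embedding was chosen because it
makes the index exactly comparable to direct evaluation of the formula on
coordinate data (and to scikit-learn's implementation, which we use as an
independent cross-check in the tests). Ties in CH across k resolve to the
smallest k. W = 0 (all points coincident within clusters) returns an
infinite sentinel with a warning.

Each cluster's *driver taxon* is operationalised as the feature with the
highest within-cluster mean relative abundance (ties: lexicographically
smallest ID); the full ranked list is returned, and two clusters may share a
driver.

PCoA double-centres `−½ D²`, eigendecomposes, and scales eigenvectors by
the square roots of positive eigenvalues. Negative eigenvalues (possible for
non-Euclidean dissimilarities such as Bray-Curtis) are reported but excluded
from both the coordinates and the explained-proportion denominator, so the
printed proportions refer to the representable part of the variation.

## Diversity indices

Alpha diversity is computed from integer counts only (richness estimators
are undefined on relative data): observed richness Sobs; Shannon entropy
`−Σ p ln p` (nats); both Simpson variants — dominance `Σ p²` and diversity
`1 − Σ p²` — are always emitted side by side, since reports differ in which
one they call "Simpson"; Chao1 as `S + F1²/(2 F2)` with the `S + F1(F1−1)/2`
fallback when no doubletons exist; and ACE with rare-count cutoff 10,
sample coverage `C = 1 − F1/N_rare`, and the usual coefficient-of-variation
correction (falling back to Chao1 at zero coverage). These variants are
pinned in-code rather than delegated so the fallback rules are explicit;
the test suite cross-checks Shannon and ACE against scikit-bio where the
conventions coincide.

Beta diversity: Bray-Curtis `Σ|x−y| / Σ(x+y)` (via scipy) and the JSD
metric above. Group separation is tested with ANOSIM on ranked
dissimilarities, `R = (mean between-group rank − mean within-group rank) /
(n(n−1)/4)`, with a seeded permutation p-value
`(1 + #{R_perm ≥ R_obs}) / (1 + n_perm)` (scikit-bio's implementation,
cross-checked against a direct rank computation in the tests). No
rarefaction or depth normalisation is performed.

## Two-group statistics

Continuous host phenotypes use the independent-samples t test, Welch by
default (no equal-variance assumption; pooled available). Taxon, diversity
and pathway comparisons use the Wilcoxon rank-sum test: exact null
enumeration when the pooled sample is ≤ 20 without ties, otherwise the
normal approximation with tie-corrected variance and continuity correction.
Feature-wise p-values are adjusted by Benjamini-Hochberg step-up; an
enrichment direction is called at q < 0.05 (configurable), with raw p always
reported alongside q.

Differential tables pre-select features by mean relative abundance — either
the top N or mean > a percentage threshold — computed over all samples by
default (a per-cluster variant is available by flag, since "abundance above
a threshold" is ambiguous between the two). Means ± SE are reported in
percent with SE = sd/√n per group.

## Associations and networks

Microbe–trait association uses Spearman's rank correlation (mid-ranks on
ties; two-sided p from the t approximation with n − 2 df), computed over
pooled samples with pairwise deletion of missing trait values; traits with
fewer than 3 observations or zero variance are skipped with a warning.

Per-enterotype co-occurrence networks first filter genera *within the
subgroup being analysed*: mean relative abundance > 0.1% and nonzero in more
than half of the subgroup samples. (Filtering within the subgroup, rather
than globally, is the design choice here because each network describes one
community type; a global option exists.) Every surviving pair is connected
when |rho| > 0.2 and raw two-sided p < 0.05, both strict, with the signed
rho as edge weight; p-values are deliberately unadjusted in the network
criterion. Networks export as SIF, GraphML (with rho/p attributes) or edge
TSV, in deterministic lexicographic order. An optional node whitelist
restricts a network to, e.g., the differential genera.

## Synthetic cohort generator

The generator emulates a two-community host cohort of 39 + 37 samples —
the archetype being young-ruminant fecal communities — with a bundled panel
of 27 abundant gut genera (plus a pooled `Other` feature absorbing the
residual mass) whose community mean abundances differ between the two
communities, and an 18-trait host phenotype panel (average daily gain, dry
matter intake, fecal VFA fractions, ammonia, and a serum biochemistry set)
whose means shift between communities in fixed directions (growth rate,
VFA, glucose and cholesterol fractions higher in community 1; IgG and urea
nitrogen higher in community 2; several traits deliberately null).

Compositions are Dirichlet-multinomial: per sample, proportions ~
Dirichlet(c · mean vector), counts ~ Multinomial(depth, proportions).
Defaults: depth 20 000 counts/sample (typical amplicon depth), concentration
c = 200 (overdispersion θ = 1/(1+c) ≈ 0.005). The concentration default was
fixed by requiring the generator's central regime to reproduce the
qualitative situation the pipeline targets — two robust, cleanly separable
enterotypes (k = 2 selected and planted-partition ARI ≥ 0.9 in essentially
all replicates); looser settings (c ≈ 50, θ ≈ 0.02) produce overlapping
communities that no medoid method separates reliably and are available for
robustness studies via the `concentration` parameter. Phenotypes are
Gaussian around their community means; selected (genus, trait) pairs are
additionally rank-coupled through a one-factor Gaussian copula (the trait's
noise is mixed with the normal score of the genus's realised abundance), so
Spearman associations of a chosen strength are recoverable by construction
without distorting the trait's marginal distribution. Everything derives
from one integer seed.

What the generator does *not* emulate: ASV-level sparsity and feature
richness (it works on a closed genus panel, so richness estimators see a
nearly constant feature set), sequencing-run batch effects, phylogenetic
correlation between related genera, and compositional interactions beyond
the shared Dirichlet constraint. Passing recovery tests therefore
demonstrates correctness of the algorithms under a well-specified
overdispersed compositional model — not that real cohorts of this size
always yield separable enterotypes.

## Numerical choices and degenerate inputs

- Distance matrices are validated symmetric to 1e-12 with zero diagonal and
  symmetrised against round-off on construction.
- PAM's SWAP accepts an exchange only if the exactly recomputed objective
  drops by more than `1e-12·(1+cost)`, preventing infinite cycling on
  summation-order round-off.
- CH returns `inf` with a warning when W ≤ 1e-12·B (coincident points).
- `to_relative` refuses all-zero samples; Bray-Curtis refuses pairs of
  all-zero samples; JSD requires a strictly positive pseudocount.
- Zero-variance vectors make Spearman undefined and raise; inside network
  construction such pairs are silently skipped rather than raised, since a
  constant genus can legitimately survive the filters.
- Two zero-variance groups with equal means give t = 0, p = 1 by convention.
- All tie-breaks (PAM medoids, CH over k, driver taxa, export ordering) are
  deterministic and documented at the function level.

## Problem sizes used in the checks

The bundled verification suite runs the generator at its default cohort
size (76 samples, 28 features): 100 replicate cohorts for recovery of the
planted number of communities and partition, 100 + 100 replicates for
planted-effect and null FDR behaviour, 1000 null replicates each for the
Wilcoxon and ANOSIM size calibration (199 permutations per ANOSIM call),
200 random instances for PAM-vs-exhaustive agreement, and 1000 random
triples for the JSD triangle inequality. These sizes give binomial
standard errors comfortably inside the asserted bands while keeping the
whole suite around a minute of runtime.

## Known limitations

- CH model selection is computed in the PCoA embedding; for strongly
  non-Euclidean dissimilarity structures the embedding discards the
  negative-eigenvalue part of the geometry.
- The Wilcoxon exact path is limited to pooled n ≤ 20 without ties; beyond
  that the normal approximation is used (the two agree within |Δp| ≤ 0.02
  at n = 15+15 in our checks).
- No compositional-data-aware differential testing (CLR/ALDEx-style); rank
  tests are applied to relative abundances as is conventional in the
  targeted study design.
- BIOM input is not implemented; TSV (and anything pandas can be coerced
  into the documented TSV layout) is the interchange format.
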