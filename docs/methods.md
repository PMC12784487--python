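# Methods

This note documents the statistical procedures implemented in `traclon`,
the synthetic data model used to test them, and the design decisions taken
where the procedure left genuine freedom.

## The analysis unit

A clonotype is the triple (V gene, J gene, CDR3 amino acid sequence), after
normalisation. Gene symbols are normalised by stripping the allele
designation (`*NN`), removing zero padding from family/gene numbers, and —
for J segments, which carry no gene subnumber in the reference
nomenclature — dropping a dialect `-NN` suffix (`TRAJ06-01` → `TRAJ6`,
`TRAV01-02` → `TRAV1-2`, `TRAV12-01*01` → `TRAV12-1`). `/DV` composite
designations are preserved verbatim. This unifies the immunoSEQ-style and
IMGT-style spellings that co-occur in real multi-platform datasets.

Preprocessing applies three rules, in order: (1) remove non-productive
records (a junction containing a stop `*` or frameshift `_` marker when no
explicit productivity flag is present); (2) collapse records sharing a
clonotype key, summing template counts — nucleotide-level encodings of the
same protein chain become one clonotype; (3) drop samples with fewer than
1,000 distinct productive clonotypes (strictly fewer: a sample at exactly
the threshold is kept). The threshold counts **distinct clonotypes**, not
total templates; this is the natural reading of a "productive clonotypes"
depth requirement and is configurable. CDR3s containing ambiguity letters
(B, J, O, U, X, Z) are dropped at read time with a warning: they cannot
take part in motif or edit-distance analyses.

## Invariant-cell quantification

CAIT cells are defined as TRAV12-1/TRAJ6 chains whose CDR3 matches
`CVV**A*GGSYIPTF` (`*` = exactly one arbitrary residue, length must match);
MAIT cells as TRAV1-2/TRAJ33 with no CDR3 constraint. Both are shipped as
data (`InvariantCellDefinition`) and overridable by a YAML/TSV definitions
file. "Expansion" is reported as the summed template-count frequency of
matching clonotypes within the productive repertoire — an abundance
measure — with a clonotype-fraction alternative behind
`metric="clonotype_fraction"`. The frequency default reflects that
"expansion" denotes abundance; the unit of published group-comparison
figures in this literature is not always stated, so both metrics are kept.

## Incidence association

The tested quantity is carrier incidence, not abundance: a sample carries a
clonotype iff its productive collapsed count is ≥ 1. For each clonotype
carried by at least 2 of the compared samples (publicity is computed on the
union of the two compared groups), the one-sided Fisher's exact p is the
upper hypergeometric tail

    p = P(X ≥ a),  X ~ Hypergeom(N = n₁+n₂, K = a+b, n = n₁),

where a, b are carrier counts among the n₁ cases and n₂ controls. The
discovery cutoff is p < 10⁻³, uncorrected — multiplicity is deliberately
deferred to the meta-analysis stage. Results are sorted by p with
lexicographic key tie-breaks so output is reproducible. `fisher_one_sided`
is exact (scipy's hypergeometric survival function, validated exhaustively
against brute-force enumeration for all tables with group sizes ≤ 25); the
vectorised form evaluates whole cohorts at once. For cohorts without
controls, the same machinery compares one case phenotype against the other
(e.g. CD vs UC) in both directions.

## Meta-clonotypes (seeded clustering)

Each associated clonotype (seed) is expanded in three steps: candidate
search (same V and J, CDR3 within Levenshtein distance 1, over **all**
distinct clonotypes observed in the compared repertoires); union-presence
scoring (a sample is positive iff it carries the seed **or** the
candidate); and purification (candidate kept iff union p ≤ seed p). Three
decisions here were genuinely open:

* **Pairwise, not cumulative, purification** — each candidate is judged
  against the seed alone, not against previously accepted members; the
  purification rule names exactly two entities, and pairwise evaluation
  keeps the result independent of candidate ordering.
* **Ties keep** — exclusion is conditioned on the union p being strictly
  larger; a candidate adding no new carriers yields an identical table and
  stays.
* **No exclusivity** — a clonotype may be a member of several
  meta-clonotypes; downstream set scoring deduplicates keys before summing
  so nothing is double-counted.

Levenshtein distance is computed with `edlib` (unit-cost edit distance) and
cross-checked against a dynamic-programming oracle in the tests.

## Cross-cohort meta-analysis

Candidates are the union of the cohorts' associated seeds, restricted to
clonotypes detected (≥ 1 carrier, configurable) in **every** cohort's
compared groups. For each candidate the per-cohort p is recomputed from
that cohort's incidence index — candidates need not have been public in
every cohort. Per-cohort p-values are combined with Fisher's method,
accumulated in log space so p-values near the underflow limit survive, and
the combined p is the χ²(2k) upper tail. Benjamini–Hochberg is applied over
exactly this presence-filtered candidate list (statsmodels' step-up
implementation, validated against a hand oracle); adjusted p < 0.05 is
significant. k = 1 reduces to the discovery p; any k ≥ 1 is supported, so
leave-one-cohort-out variants are a config change. Exact-test p-values
cannot be 0 (the minimum is a point-mass tail), so no clipping is needed —
the domain check asserts rather than patches.

## Group comparisons

Unpaired comparisons use the two-sided Mann–Whitney U test: exact
enumeration of the U null when the pooled sample size is ≤ 12 and tie-free,
otherwise the tie-corrected normal approximation with continuity
correction. Paired comparisons use the two-sided Wilcoxon signed-rank test
with zero differences dropped before ranking (classic treatment), exact for
≤ 15 tie-free nonzero differences; an all-zero difference vector is a
degenerate comparison reported as p = 1 with a warning rather than an
error. The exact/approximate thresholds are fixed module constants so runs
are bit-for-bit reproducible.

## Similarity graph and motifs

Nodes are clonotypes; an edge requires identical V and J genes and
equal-length CDR3s at Hamming distance exactly 1 (unequal lengths get no
edge). Components are ordered by size, ties by smallest member, so output
is deterministic. Each component's motif is a per-position residue count
matrix over members of the modal CDR3 length; off-modal-length members
(indel neighbours that enter a component through shared contacts) are
reported but excluded from the matrix, because column-aligning them would
require an alignment step the edge rule does not define. The consensus
writes a column's residue where unanimous and `*` where ≥ 2 residues
occur. The graph built for reporting covers the significant hit set
augmented with its meta-clonotype members.

## Synthetic data model

The generator targets the statistical structure the pipeline tests —
nothing more (no V(D)J recombination biophysics, no generation
probabilities).

* **Background carriage**: each of `background_pool_size` pool clonotypes
  gets a population carriage probability q ~ Beta(0.3, 15) (mean ≈ 0.02,
  strongly right-skewed), identical in cases and controls. This shape
  encodes that most public clonotypes are rare while a few are common; it
  also determines how often the discrete Fisher test can reach p < 10⁻³
  under the null, which the calibration tests account for exactly
  (see below).
* **Clonal abundance**: a present clonotype's template count is
  1 + Poisson(w) with w ~ LogNormal(μ=1, σ=1.5) — heavy-tailed relative
  abundances with a guaranteed positive count.
* **Spiked clonotypes** (default 20) are shared across cohorts and carried
  with probability `q_case` = 0.4 vs `q_control` = 0.05 (per-cohort values
  may differ to model attenuation). Spiking is on the **incidence** scale
  because that is the scale the association test operates on.
* **CAIT-like family** (default 8): a base CDR3 drawn on the CAIT motif
  plus variants differing at exactly one wildcard position — a Hamming-1
  star that the graph stage should recover as one component. The family
  carries both a carriage differential (0.75 vs 0.35) and a 5× case
  multiplier on the clonal weight, because CAIT claims concern expansion,
  not just incidence.
* **Private filler** clonotypes (random catalogue V/J, random C...F CDR3s)
  top each repertoire up to `repertoire_size` distinct clonotypes; a 2%
  fraction of non-productive decoy rows exercises preprocessing. A paired
  option emits follow-up partners that reuse the baseline sample's carriage
  and clonal weights with fresh count noise (correlated pairs for the
  Wilcoxon path).

Defaults (3 cohorts, 60 cases/60 controls, 2,000-clonotype repertoires over
a 20,000-clonotype pool) are the package's desk-scale study conditions; the
`spiked-100` preset (100/100 per cohort, 4,000-clonotype pool,
1,200-clonotype repertoires) is the scale at which recovery and power are
measured, and the small null preset (30/30, 1,000-clonotype pool) is used
for replicate calibration. What passing tests on these data do **not**
show: robustness to platform batch effects, to abundance-dependent
detection (carriage and expansion are independent here except where
planted), to HLA-driven population structure, or to sequencing-depth
variation across samples — none of which the generator models.

## Calibration and recovery checks

Because the Fisher test is discrete, its null false-positive rate at a
fixed cutoff is far below the cutoff and depends on each clonotype's
carrier margin. The null-calibration test therefore computes, for every
public clonotype, the largest achievable tail probability below 10⁻³
conditional on its realized margin (conditioning on the margin makes the
carrier allocation exchangeable, hence hypergeometric, even though carriage
is binomial), sums these into an exact expected false-positive count, and
bounds the observed count by 99% Poisson quantiles (the Poisson
approximation to this Poisson-binomial sum errs by O(Σp²) ≪ 1). Replicate
nulls for the meta-analysis use background-only pools: planted
invariant-family clonotypes are deliberately common, which legitimately
raises the discrete attainable level, and that channel is covered by the
margin-conditioned bound instead. Recovery tests compare empirical
discovery power against exact power enumerated over binomial carrier
counts.

## Determinism and artifacts

A fixed config + seed yields byte-identical simulated trees and pipeline
artifacts (single `numpy` Generator, sorted iteration everywhere, mergesort
for all tie-bearing sorts). Every pipeline TSV carries a `# config_hash=…
seed=…` provenance header; the hash excludes the output directory path,
which has no analytical meaning. The run manifest records per-stage wall
times and row counts and is the one file excluded from byte-identity
comparisons.

## Known limitations

* Purification is pairwise by design; a cumulative variant could prune
  differently for seeds with many interacting neighbours.
* The meta-analysis recomputes per-cohort p-values for all candidates; if
  a cohort's comparison design differs (case-vs-case), its p-values answer
  a slightly different question, and set-level validation in independent
  cohorts (the scoring module) is the intended guard.
* Exact Mann–Whitney/Wilcoxon enumeration bounds are conservative; large
  tied datasets fall back to normal approximations.
* The MAIT-vs-age correlation reported qualitatively in the IBD literature
  has no stated statistic and is not implemented.
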