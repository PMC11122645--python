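# Methods

This note documents the models and procedures `herbnet` implements, the
parameters that matter, the design choices made where the method was
genuinely open, what the synthetic generators emulate, and the package's
known limitations.

## Herb specificity by TF-IDF

A prescription corpus is a document collection: prescriptions are documents,
herbs are terms. A designated subset of *representative* (disease-specific)
prescriptions is **pooled into a single document**; the term frequency of an
herb is its occurrence count in that pool divided by the pool size, and the
inverse document frequency is `ln(|P|/df)` over the whole corpus. The
specificity score is `tf × idf × 100`, and herbs are selected by a strict
`> threshold` comparison (default 10), so a score exactly at the threshold
is not selected.

Two readings of the term frequency exist when several representative
prescriptions are designated: score each prescription separately and
aggregate, or pool them into one document. The pooled reading is
implemented as the default because the tf denominator ("total number of
herbs in the representative prescription") is well defined for the pool,
and because it makes tf a proper distribution over herbs (Σ tf = 1, an
invariant the tests assert). Within one prescription an herb counts once
(prescriptions list each herb once); multiset input is accepted for
generality. Herb identifiers are case-folded and trimmed on ingest, but
synonyms are *not* resolved — herbal nomenclature equivalences are editorial
decisions that belong to the caller.

## Network assembly and disease-gene overlap

Compound drug-likeness uses the QED score, a [0,1] summary of molecular
descriptors consumed here as an input column (the package never computes it
from structures). The cutoff 0.35 is the mean QED of FDA-approved oral
drugs; compound–target interaction confidences are cut at 0.7. Both cutoffs
are **strict** inequalities, so boundary rows are excluded — the tests pin
this at 0.35/0.70 exactly. Filtering is idempotent and monotone in the
cutoff, and interactions whose compound disappears (filtered out or never
present) are dropped with a warning rather than an error, because database
exports routinely contain orphans.

The tripartite network keeps every supplied herb in its layer index even
when all of the herb's compounds fail the QED filter; such herbs appear
with zero edges, mirroring how bookkeeping tables report them. In overlap
tables, an herb's count for disease gene *g* is the number of its
compounds' compound–target edges to *g* — multiple compounds of one herb
hitting the same gene count separately. This multiplicity reading is the
only one consistent with the bundled reference tallies (e.g. 7 genes / 27
interactions for the top herb).

Disease genes come from two sources: a curated direct-evidence list and a
scored list filtered at association score strictly above 0.3. "Satisfying
both conditions" is read as the **intersection** of the two sources
(default), with union exposed as a flag; the phrase is genuinely ambiguous
and both modes are first-class. An elbow-method helper selects thresholds
on sorted score curves: it returns the score maximizing perpendicular
distance to the chord joining the curve's endpoints, smallest index on
ties, and degenerates (with a warning) to the first interior point on
collinear input.

## Enrichment statistics

Over-representation uses the one-sided upper-tail hypergeometric
probability `P(X ≥ k)` with `N = |background|`, `K = |set|`, `n = |query|`,
`k = |overlap|`, adjusted across a library with Benjamini–Hochberg (the
default of the web tools this workflow mirrors; the source workflow says
only "adjusted p-values"). The background universe defaults to the union
of library genes and is overridable; genes outside it are dropped from
sets and queries with logged counts.

The rank-deviation z-score asks how much earlier a term ranks (by p-value)
for the observed query than for random queries of the same size. The
reference web tool precomputes expected ranks; here the null is a **seeded
permutation null**: `n_null` (default 500) uniform same-size queries are
drawn from the background, every term is ranked per draw (stable sort,
ties broken by term order), and `z = (observed_rank − mean_null_rank) /
sd_null_rank` (population sd; z defined as 0 with a warning when the sd
vanishes). Enriched terms therefore get negative z, and the combined score
`c = ln(p)·z` is positive for them. p-values are floored at 1e-300 before
the logarithm. The permutation null is a documented approximation of the
cited tool's lookup table, not a reproduction of it.

An herb's combined score for a term sums the combined scores of its
compounds whose adjusted p is **strictly** below 0.05; it is computed per
term, and aggregation across terms is left to the caller. Result lists are
sorted by adjusted p, ties by combined score descending then term name;
top-k reporting is a slice of the full ranking, never a re-computation.

## Herb clustering

Herbs are binary vectors over compounds or over targets (target level: 1
iff any compound of the herb hits the gene — union semantics). Cosine
similarity matrices are computed for both levels and exported for heatmap
plotting. Clustering pairs a cosine heatmap with a Ward dendrogram, but
Ward's minimum-variance criterion is defined for Euclidean geometry, so
the default linkage runs **Ward on Euclidean distances of the binary
rows** — the behavior of the standard toolkit the workflow uses — while
`linkage_on="cosine"` provides average linkage on 1 − cosine as a variant.
Cutting the dendrogram "at level L" removes the top L merges, yielding
L + 1 groups; the default level 2 gives three groups. Group labels are
assigned by descending size with ties broken on the smallest member id,
and assignments are invariant to herb input order (rows are canonically
sorted before linkage).

## PPI modules

The PPI graph is induced on the predicted target set; self-loops and
duplicate edges are dropped with logged counts and isolated targets are
retained as degree-0 nodes (reported separately). Modularity is computed
directly from the Newman–Girvan definition `Q = Σ_c [e_c/m − (d_c/2m)²]`;
Louvain community detection runs at resolution 1.0, unweighted by default
(a weighted flag exists), with a **mandatory seed** recorded in the output
metadata — Louvain is stochastic and unseeded runs would break the
pipeline's byte-identity guarantee. Module ids are relabeled by descending
size for stable reports, and the returned partition is guaranteed not to
score below the one-module and all-singletons baselines.

A herb group "includes" a module when the group's targets exceed a
configurable floor of the module's size (default 5%, strict) — the rule
behind such statements is never published, so it is an explicit config
knob, not an inference. Per-module GO profiles run the enrichment machinery
on each module's gene set (modules under 3 genes are skipped with a
warning) and report the top 10 terms by adjusted p.

## Synthetic data and what passing tests show

Each generator is a pure function of its parameters and a seed (a root seed
fans out through `SeedSequence([seed, salt])` with fixed per-generator
salts), returns a serializable truth record, and writes the same TSV/GMT
formats the pipeline reads.

- **Corpus**: 500 background + 12 representative prescriptions over 200
  herbs, ~12 herbs each; 10 planted specific herbs enter representative
  prescriptions with probability 0.9 and background ones with 0.02. The
  0.9 rate was frozen by the bundled calibration sweep
  (`scripts/calibrate.py`): it is the regime in which a planted herb's
  binomial draw essentially never leaves its score near the selection
  threshold, giving exact recovery in ≥ 95% of 20 seeds as required of the
  defaults.
- **Compounds**: per-herb counts uniform in [6, 40], QED ~ Beta(2, 2) —
  a broad unimodal score distribution straddling the 0.35 cutoff.
- **Interactions**: the target universe splits into one disjoint pool per
  planted herb group plus a shared background pool; group-g compounds hit
  their pool at rate 0.3 with confidence 0.9 and the background pool at
  0.01 with confidence 0.5, so confidence filtering retains exactly the
  planted within-group structure and within-group target vectors are
  near-identical at the herb level.
- **Disease genes**: two sources with a planted overlap; scores default to
  Uniform(0,1), straddling the 0.3 cutoff.
- **Gene-set library**: planted terms share a fixed fraction of the query;
  the rest are uniform draws overlapping only by chance.
- **PPI**: an assortative stochastic block model (p_in 0.5, p_out 0.02 at
  n = 60 for the recovery benchmark; blocks aligned with the group target
  pools in the end-to-end dataset).

These generators emulate the *planted structure* of the real databases —
not their marginal distributions, degree heterogeneity, annotation bias, or
name synonymy. Passing recovery tests therefore show that the pipeline's
statistics and algorithms do what they claim under known signal; they do
not certify performance on real corpus/database snapshots, whose headline
counts depend on proprietary versions and are out of scope.

## Numerical and operational choices

- Problem sizes in tests and the acceptance script (corpus 512
  prescriptions, 300-gene target universe, 50-term libraries, 60-node SBM,
  20-seed sweeps, 1000 null queries) are chosen so the whole validation
  suite runs in well under a minute while keeping every recovery margin
  wide; all are parameters, not constants.
- All TSV output uses a fixed `%.10g` float format, which (with seeded
  randomness everywhere) gives byte-identical result tables across runs.
- The global-null calibration of the Fisher test sits slightly *below* the
  nominal 0.05 (≈ 0.033–0.038 under the default library geometry) because
  the hypergeometric is discrete and the test conservative; the accepted
  band 0.05 ± 0.02 reflects that.
- `combined_score` rejects p = 0; upstream callers floor p at 1e-300.
- The elbow helper requires ≥ 3 points and a descending-sorted input.
- The pipeline validates all input paths before running any stage, records
  SHA-256 hashes of inputs in the manifest, and supports `--from-stage`
  resumption by reloading earlier stages' tables from the run directory.

## Known limitations

- No live database retrieval of any kind; all sources are consumed as
  tables, and QED values are inputs, never computed.
- No synonym/ortholog resolution for herb names or gene symbols.
- The rank-deviation z-score is approximated by a permutation null; absolute
  z and combined-score magnitudes are therefore not comparable to the web
  tool's, though signs and rankings are.
- Ward-on-Euclidean is the default linkage even though similarity is
  reported as cosine; the cosine/average-linkage variant may group
  differently on data with strong size effects.
- The dendrogram cut is by merge level, not by a visually chosen height;
  on dendrograms whose top merges are nearly tied the two rules can
  disagree.
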