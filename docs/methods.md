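# Methods

This note documents the models and procedures tilscope implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Quality control

For every cell we compute the number of detected genes (nonzero counts),
total UMIs, and the mitochondrial fraction (counts on genes whose symbol
starts with `MT-`, case-insensitively, divided by total counts; 0 for an
all-zero cell). Cells are removed when they detect fewer than `min_genes`
genes (default 500) **or** exceed `max_mito_fraction` (default 0.1).
Removal thresholds are strict inequalities, so a cell at exactly 500 genes
or exactly 0.10 mitochondrial fraction is kept. The mitochondrial prefix is
configurable for non-human nomenclatures. Filtering is monotone in both
thresholds, and removing every cell is an explicit error rather than an
empty result.

## Ranked GLSF normalization

Size factors follow the median-of-ratios construction used by bulk RNA-seq
tools, restricted to a top-ranked gene panel: genes are ranked by raw base
mean (ties broken by input order), the top `top_n_rank` (default 500) form
the panel, and panel genes with a zero in any cell are excluded because
their geometric mean vanishes. The size factor of cell *j* is the median
over the remaining reference genes of `count(g,j) / geomean(g)`; the
normalized matrix divides each cell by its factor. Restricting to highly
expressed genes is what makes the construction usable on sparse UMI data,
where dropout zeros would annihilate most genes' geometric means.

Two conventions to note. First, base-mean ranking uses **raw** counts (the
quantity exists before normalization does). Second, an optional
pseudocount-1 mode keeps all panel genes usable when no gene is nonzero
everywhere; it is off by default, and the no-reference-genes condition is a
distinct error suggesting the remedy.

A subtlety worth stating: multiplying one cell's counts by *c* multiplies
its size factor by *c* **relative to every other cell**, not absolutely —
the scaled cell contributes a factor c^(1/n) to every reference gene's
geometric mean, so its own factor scales by c^(1−1/n) and all others by
c^(−1/n). Size factors are therefore meaningful up to a common scale, and
the tests assert the exact ratio form.

## Gene statistics and the gene model

Per-gene statistics on the normalized matrix are the base mean, the Fano
factor (population variance / mean, defined as 0 for an all-zero gene) as
the dispersion measure, and coverage (cells with nonzero expression). The
gene model for dimensionality reduction is the **intersection** of the top
`top_coverage` genes by coverage (default 500) with genes whose dispersion
strictly exceeds `min_dispersion` (default 1.5), ordered by descending
coverage; a union mode exists but is off by default. An empty model is an
explicit error suggesting threshold relaxation.

## Two-round PCA

Round one: genes of the model are mean-centered and decomposed by exact SVD.
Round two re-runs PCA on a refined gene set: for each of the first
`n_dims_scan` (default 10) components, the `top_k` (20) genes with the
largest signed loadings and the `bottom_k` (20) with the most negative,
de-duplicated in first-appearance order. "Top and bottom" is read as signed
ordering, not |loading| magnitude — the two tails of a component are its two
transcriptional poles. Round two re-centers on the refined set, and the
final embedding keeps the leading `n_pcs` (default 10) components.

Numerical conventions: components are sign-stabilized (the
largest-magnitude loading of each component is forced positive) so repeated
runs and tests are bit-reproducible; requesting more components than the
matrix rank truncates with a warning; total variance of the scores equals
total variance of the centered input.

## Clustering and model selection

k-means (euclidean, `n_init=10` restarts, caller-supplied seed) is run on
the top PCs for every k in `[k_min, k_max]` (default [2, 10]; the scanned
range and restart count are package defaults, stated rather than inherited
from any source). Each k is scored by mean silhouette width; the maximizing
k wins, ties going to the smaller k. Cluster ids are renumbered 1..k by
first appearance. An embedding whose points are all identical is an
explicit "no cluster structure" error.

Known behavior: because expression is not variance-stabilized (no log
transform — the upstream procedure this package follows normalizes but does
not log-transform), clusters are elongated along their own high-variance
marker axes, and on some datasets the silhouette criterion prefers
splitting such a cluster, over-estimating k while leaving phenotype calls
intact (the split pieces inherit the same panel argmax). The seeded
benchmark fixture recovers the planted k exactly; the cohort-level
acceptance run reports whatever the criterion selects, honestly.

2-D visualization (UMAP or t-SNE) is a thin delegation contract — cells × 2
finite coordinates, deterministic under a fixed seed — and its internals
are out of scope.

## Markers and phenotype assignment

For each cluster and gene we report `log2((mean_in + ε)/(mean_out + ε))`
with ε = 1e-9 on the normalized scale, a Welch (unequal-variance) t-test of
in-cluster vs all other cells, and Benjamini–Hochberg adjustment **within
each cluster** (markers are reported per cluster, so the family is the
cluster's gene list). When both groups have zero variance the p-value is 1
for equal means and 0 otherwise; clusters with fewer than two cells get
missing p-values and a log entry.

Cluster phenotypes use the four canonical CD8+ panels (cytotoxic, naive,
exhausted, regulatory; IFN-γ is encoded as HGNC symbol IFNG, PD-1 as
PDCD1). Each gene is z-scored across cells (population SD; constant genes
get z = 0 with a warning); a cluster's score for a phenotype is the mean z
over panel genes and cluster cells, and the label is the argmax, ties
resolved by a fixed priority order (cytotoxic, naive, exhausted,
regulatory) and logged. The argmax-of-mean-z rule is this package's design
choice — transparent, affine-invariant per gene, and directly testable —
rather than a convention inherited from elsewhere. Per-sample phenotype
proportions sum to 1; group summaries are unweighted means over samples.

Group differences in a phenotype's abundance are reported both ways because
the correct unit of analysis is genuinely ambiguous: a two-proportion
z-test on cells pooled per group (sensitive, treats cells as independent)
and a Welch t-test on per-sample proportions (conservative, requires ≥ 2
samples per group; flagged not computable otherwise).

## Clonotypes and repertoire statistics

A cell's clonotype key is the sorted, semicolon-joined set of
`chain:CDR3aa` tokens over its productive TRA/TRB contigs (cells with two
productive chains of one locus keep both tokens); cells with no productive
chain are excluded with a logged count. The upstream `raw_clonotype_id` can
be used instead. The unit of counting is the **cell** (barcode); a
UMI-weighted mode exists but is off by default.

Frequency classes partition clonotypes: singletons (1 cell), doubletons
(2), "top10" (rank ≤ 10 with ≥ 3 cells), "other" (≥ 3 cells, rank > 10).
The repertoire partition reports each top-10 clonotype individually (absent
rather than zero-padded when fewer exist) plus the three pooled classes,
summing to 100%. Top-n share is the percentage of cells in the n most
frequent clonotypes. The upper-quintile statistic sorts clonotypes by
descending frequency (ties by key) and counts how many are consumed before
the running cell total reaches 20%, including the clonotype that crosses
the boundary — whole clonotypes cover the quintile.

Linkage of expanded clonotypes to phenotypes carries member barcodes
through the expression↔VDJ barcode mapping (GEM-well `-<digit>` suffixes
are stripped on both sides before matching) and counts matched cells per
phenotype; a clonotype "spans" phenotypes when at least two phenotypes each
hold ≥ 20% of its matched cells. The 20% threshold is purely descriptive
annotation. Richness between groups compares per-sample clonotype counts by
Welch t-test, flagged not computable with fewer than two samples per group.

## Antigen matching

Queries default to the ten most expanded clonotypes per sample. Distances
are unit-cost Levenshtein on uppercased, whitespace-stripped CDR3
amino-acid strings; conserved anchor residues are not trimmed (a trimming
flag exists). Under the default `best_of_both` policy the distance to a
database row is the minimum over chains present on both sides (beta
reported on ties); rows lacking every comparable chain are excluded from
that query's ranking, and queries with no comparable rows are flagged. Hits
are sorted by (distance, database row order) and ranked densely within each
query.

A clonotype is called a known-antigen match iff its best distance is at
most `max_distance` (default 0 = exact); everything else — including
no-comparable-row queries — is a putative neoantigen. No published cutoff
exists for this call, so the threshold is a mandatory, logged parameter of
every report, and the known/neoantigen percentages are meaningful only
relative to it.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes, at
desk scale. Counts are negative binomial (the standard model for UMI data),
parameterized by mean and size per gene class:

| gene class | n | mean | NB size | Fano | role |
|---|---|---|---|---|---|
| background | 1000 | 2 | 8 | 1.25 | below the dispersion cut; bulk of detected genes |
| housekeeping | 50 | 50 | 100 | 1.5 | nonzero in every cell → the size-factor reference panel |
| marker panels | 16 | 4 (×8 in own phenotype) | 10 | ≫1.5 | the planted cluster signal |
| mitochondrial | 13 | from target fraction | — | — | QC signal |

These values were chosen once as a realistic desk-scale caricature of CD8+
TIL 5' expression data: most genes are low-mean and near-Poisson, a small
high-expression block anchors size factors, and the marker effect size
(8-fold) matches the default planted effect. Each cell draws a phenotype
from the configured mixture (default uniform over the four), and its
panel genes' means are multiplied by the effect size. Mitochondrial
fractions are drawn Beta(2, 38) (mean 0.05), clipped below the QC threshold
for ordinary cells and converted to counts. Deliberately low-quality cells
strictly violate the thresholds by construction — gene-dropout cells keep
only 250 background genes, high-mito cells get fractions in (0.15, 0.3) —
and the generator verifies the planted flags against the default
thresholds, so QC removes exactly the flagged set.

TCR repertoires assign each VDJ cell (default 90% of cells, minus a 2%
non-productive set) a clonotype from a Zipf rank-frequency law with
per-group exponent — 1.5 for the expanded (immunocompetent-like) group,
0.2 for the flat (transplant-like) group — over paired TRA/TRB CDR3s
(lengths 8–16, beta prefixed `CASS`). The antigen table contains, for each
sample's top-10 clonotypes, either an exact copy of the beta (and sometimes
alpha) CDR3 or a copy perturbed by 1–3 substitutions at distinct positions;
the planted distance recorded in the ground truth is the realized edit
distance of the emitted entry, so threshold behavior is checkable exactly.
Twenty decoy records are appended. All randomness flows from one seed
through spawned generator streams; identical configuration gives
byte-identical outputs.

The default cohort is two groups × three samples × 400 cells — a
deliberate desk-scale stand-in for a real study's thousands of cells per
tumor, small enough that the full pipeline and its tests run in seconds.

What passing on this generator does **not** show about real data: no
ambient RNA, doublets, batch effects, cell-cycle structure, or continuous
differentiation gradients; phenotypes are discrete and balanced; CDR3s are
uniform random strings without V/J-biased composition; and the antigen
table's hit structure is planted rather than biological. The benchmark
validates the statistical machinery, not biological discovery.

## Determinism

Every stochastic component (k-means restarts, 2-D embeddings, the
generator) takes an explicit seed; pipeline outputs are plain CSV/JSON with
stable ordering, and repeated runs of the same configuration are
byte-identical (verified in the acceptance tests). All stage parameters are
echoed into the report bundle so every number is traceable to the
configuration that produced it.
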