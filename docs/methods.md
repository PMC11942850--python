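# Methods

This note documents the models and procedures implemented in
`symbiopart`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and
do not demonstrate.

## Transcript source partitioning

Each transcript's similarity hits (nucleotide search against a
taxonomy-labelled database, E-value ≤ 1e-5, 12 standard tabular columns
plus subject taxid) are reduced to a three-way call:

* **termite** — best hit (maximal bitscore; ties broken by lower
  E-value, higher identity, then smallest subject id, so calls are
  deterministic and invariant to row order) inside Blattodea
  (taxid 85823), and conflict-free;
* **flagellate** — best hit inside Metamonada (taxid 2611341), and
  conflict-free;
* **unclear** — everything else, including no-hit transcripts.  Unclear
  is a fallback, never an error: in mixed metatranscriptomes the
  unassignable pool is large and biologically meaningful ("dark matter"
  that likely includes many unrepresented flagellate genes).

**Conflict rule.**  Let B be the union of query intervals of all
alignments to the best-scoring subject (a multi-HSP subject is one
biological match).  The call is vetoed if any hit from outside the focal
clade covers more than `tolerance_bp` query bases outside B.  The
tolerance (default 30 bp, 0 = strict) absorbs alignment-end jitter; the
underlying rule — no foreign evidence beyond the best-hit region — is
what distinguishes a clean assignment from a chimeric or conserved-region
match.

**Order/genus consensus.**  For flagellate calls, the five top-ranking
Metamonada hits are examined.  Order is assigned only if there are
exactly five qualifying hits, all with identity strictly > 80%, mapping
to a single order; genus additionally requires all five > 90% and a
single genus, and the genus must be lineage-consistent with the assigned
order (otherwise the genus is dropped).  The strict five-hit reading is
the default; `min_consensus_hits` relaxes it for sparser databases.
Percent-identity thresholds are strict inequalities.

Properties verified by tests: permutation invariance, exhaustive
trichotomy, monotonicity (extra off-clade evidence can only move a call
toward unclear), and 100% source/order/genus recovery on noise-free
synthetic bundles.

## Taxonomy

A minimal rooted taxonomy keyed by integer taxid, with free-text rank
labels (the classifier queries "order" and "genus" exactly).  Two
dialects: a four-column TSV and the pipe-delimited NCBI dump pair
(scientific names only).  Merged/deleted taxids are not resolved; inputs
must be pre-resolved.  Validation checks a single root, presence of all
parents, and acyclicity.

## Expression and TMM normalization

CPM is `x / N * 1e6` per sample.  The low-expression filter keeps a
transcript when strictly more than `min_samples` (default 10, matching
the 20-sample design) samples have CPM strictly above `min_cpm`
(default 1.0); it is idempotent and never drops samples.

TMM factors are computed against a reference sample (the one whose
upper-quartile CPM is closest to the mean upper-quartile).  For sample j
vs reference r, over transcripts positive in both (no pseudocounts),

    M_g = log2((x_gj/N_j)/(x_gr/N_r)),  A_g = 1/2 log2((x_gj/N_j)(x_gr/N_r))

the 30% most extreme M and 5% most extreme A (average ranks on ties) are
trimmed, and the factor is the precision-weighted mean of the remaining
M.  **Weights** are binomial precision weights evaluated on a fixed
per-million scale — i.e. on CPM rather than raw counts.  With raw-count
weights the factors depend (weakly) on sequencing depth and the TMM
matrix is only approximately invariant to rescaling one sample's
library; with per-million weights the factors depend on count
proportions alone and the invariance is exact (verified at 1e-9
relative), which is the contract the downstream stages assume.  Factors
are rescaled to geometric mean one; the TMM matrix entry is
`x / (N f) * 1e6`.

## Differential abundance

Counts are modelled per transcript as NB(mu, phi) with
Var = mu + phi mu², log link, design [intercept, caste], and offset
log(N_j f_j) (effective library size).  The caste coefficient / ln 2 is
the log2 fold change of soldiers relative to workers; a Wald z-test
gives two-sided normal p-values; non-converged fits are reported with
p = 1 and flagged.  The GLM fitting itself is delegated to statsmodels;
the surrounding machinery is package code.

**Dispersion** is estimated by the method of moments on counts scaled to
a common effective library size, *within each caste* (residual variance
around the group mean, pooled with n_c − 1 weights) — estimating across
groups would absorb genuine caste effects into dispersion and cost
power.  Raw estimates are shrunk 50% toward the mean of their abundance
bin (20 quantile bins) and floored at 1e-8.  This is a deliberately
simple, testable stand-in for the empirical-Bayes dispersion machinery
of dedicated DE tools: the module promises parameter recovery and error
control on synthetic truth, not numeric identity with any external tool.

**DET rule.**  BH-adjusted q < 0.05 and fold change > 2 or < 0.5, both
strict: soldier-biased iff log2FC > 1, worker-biased iff log2FC < −1.
BH is the textbook step-up; it matches exhaustive enumeration for all
inputs of length ≤ 8 and statsmodels' implementation on random vectors.

Measured on the generator's study conditions (planted |log2FC| = 2,
phi = 0.1, n = 10+10, five seeds): power ≈ 0.93–0.97, empirical
FDR ≈ 0–0.01 (computed fresh by `scripts/acceptance.py`).

## Biomarker selection

Features are log2(TMM+1), standardized per transcript (raw-scale mode by
flag; the heavy-tailed raw scale would let a few highly expressed
transcripts dominate the penalty).  The lasso-logistic path

    min (1/n) sum_i deviance_i + lambda ||beta||_1

is fit by cyclic coordinate descent on the IRLS quadratic approximation,
warm-started along 50 log-spaced lambdas from lambda_max (the smallest
penalty with an all-zero solution) down to 0.01·lambda_max, with
convergence at max coefficient change < 1e-7 and a step-halving
safeguard that keeps the penalized objective non-increasing.  Solutions
match a general-purpose convex optimizer to ~1e-10 in objective on small
problems (tests assert 1e-4).

The penalty is chosen by stratified k-fold (default 10) cross-validation
minimizing held-out deviance ("min" rule; "1se" available); the fold
seed is mandatory.  With 20 samples and hundreds of features selection
is intrinsically unstable, so the report records each transcript's
selection frequency across folds rather than claiming a unique set.  The
report joins each selected transcript's putative source, caste TMM
means, and DET flag; a positive coefficient corresponds to a
soldier-biased transcript and must agree with the direction of the caste
TMM means for well-separated biomarkers (asserted in tests).

## Co-expression networks and strong pairs

Per caste (that caste's 10 samples only): Pearson correlation of
log2(TMM+1) (constant transcripts get correlation 0 and are flagged),
unsigned soft-thresholded adjacency `a = |cor|^beta` with beta = 12
(signed variants out of scope), zero diagonal, and the topological
overlap measure

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with TOM_ii = 1.  The consensus network scales the soldier TOM so its
0.95 off-diagonal quantile matches the worker's (power transform), then
takes the element-wise minimum; modules are detected on 1 − consensus
by average-linkage clustering with a static cut (default height 0.995,
minimum size 10; clusters below the minimum are "grey"/unassigned).
Static cutting replaces the dynamic hybrid tree-cut algorithm: module
identity is cosmetic for the headline pair analysis and the
simplification keeps the module step small and testable.

**Strong pairs** are transcript pairs with per-caste TOM ≥ 0.5
(inclusive) where one member is a classified flagellate and the partner
is anything else — termite, unclear, or a flagellate whose order is
unresolved; pairs of two order-resolved flagellates are the
within-symbiont network and are excluded.  "Edge weight" is interpreted
as the per-caste TOM (the conventional exported co-expression edge
weight); a raw-adjacency mode is available by flag and recorded in
output metadata.  Worker and soldier pair lists are compared directly
and via their unordered-pair intersection.

## Enrichment

Optional true-path propagation up an acyclic term DAG (transcripts
annotated to a term count for all ancestors; recorded in metadata since
published analyses are often silent on this).  The universe is the
annotated background only; unannotated transcripts are dropped with a
logged count.  Each term with at least one background member is tested
with the exact hypergeometric upper tail `P(X ≥ k)`, BH-adjusted across
tested terms, significant at q < 0.05.  There is no minimum term-size
filter at test time; the "> 5 associated foreground transcripts" filter
used in network-wide summaries is a reporting filter only.

## Synthetic data generator

The generator defines the conditions every recovery test runs under; it
emulates the study design — 10 workers and 10 soldiers, each
an individual whole-body sample — at a desk scale of 600 transcripts
(380 termite, 100 flagellate, 120 unclear; the full study scale is
config-reachable).

**Taxonomy and hits.**  A fixed small taxonomy holds Blattodea,
Metamonada with the four flagellate orders (Cristamonadida, Oxymonadida,
Trichomonadida, Tritrichomonadida) and genera including *Devescovina*,
*Oxymonas* and *Blattamonas*, plus fungal/bacterial outgroups.  Hit
tables realize each transcript's planted resolution tier: termite
transcripts get host-clade best hits; genus-resolvable flagellates get
five same-genus hits at > 90% identity; order-resolvable ones five
same-order hits in (81, 90]; source-only flagellates six hits mixing two
orders; unclear transcripts get no hits, above-cutoff hits, or decoy
cross-clade conflicts (an off-clade hit extending well beyond the
best-hit region).  Bitscores are generated consistent with
identity × length so best-hit ordering is unambiguous outside dedicated
tie tests.

**Counts.**  log2 mean model per transcript and sample:

    log2 mu = base + soldier * lfc
            + load * (gamma_caste * z + delta * w)      [coupled pairs]
            + load * (gamma_caste * v + delta * v2)     [other flagellates]
            + pload * u_program                         [host & unclear]

with NB noise (Var = mu + phi mu², phi log-normal around the configured
dispersion, default 0.1) and samples scaled to library sizes drawn from
(0.8M, 1.2M).  The latent factors are the substance of the design:

* `z` is the host–flagellate coupling factor shared by the planted
  coupled pairs (default 20 flagellate × host/unclear pairs), entering
  with caste-dependent loading gamma_w = 0.8 vs gamma_s = 0.1 — the
  planted asymmetry the network stage must recover.
* `v, v2` make the remaining flagellate transcripts track the latent
  flagellate load of each individual termite, again far more tightly in
  workers — mirroring the empirical pattern that flagellate ×
  unclassified-flagellate co-expression is worker-specific.
* `u` are three broad caste-independent expression programs over host
  and unclear transcripts, emulating the pervasive correlated variation
  of whole-body RNA-seq (tissue composition, physiological state).
  Besides realism, they give every node appreciable network
  connectivity, which the TOM denominator needs in order to suppress
  isolated correlation spikes: with only 10 samples per caste, a null
  transcript pair occasionally shows |r| > 0.95, and without background
  connectivity such a pair would spuriously clear the 0.5 edge-weight
  threshold.
* Every latent multiplicative factor is centered within caste and
  normalized to within-caste mean one on the *count* scale.  Without
  this, caste-asymmetric latent variance inflates the arithmetic mean
  counts of the high-variance caste (a Jensen effect), turning
  planted-null transcripts into genuine count-scale caste differences
  and corrupting the FDR benchmark.  With it, `planted_lfc = 0` means
  exactly null for the caste contrast.

Planted caste effects (fraction 0.15, |log2FC| ~ N(2, 0.25), random
sign) go on host and unclear transcripts by default: the emulated study
found no significant flagellate abundance differences between castes,
and flagellate expression in this model is dominated by the load
factors; a flag plants effects on flagellates too.  A small
low-expression tail (8%, ~2^11 below typical abundance) exercises the
CPM filter.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: read-level artifacts, assembly chimerism
and isoform redundancy, rRNA/mRNA library chemistry, GC or length
biases, batch effects that are *not* orthogonal to caste, and real
phylogenetic structure in hit identities.  The classifier recovery tests
certify the decision rules, not database completeness; the DE benchmarks
certify error control under NB noise with orthogonal latent structure,
not robustness to confounded designs.

## Numerical choices and degenerate inputs

Strict inequalities wherever the rules say "greater than"; the
strong-pair threshold is inclusive (≥ 0.5).  Best-hit ties are broken by
a fixed composite key.  TMM pairs with a zero in either member are
excluded (no pseudocounts); an all-trimmed pair falls back to factor 1.
Dispersion floor 1e-8; GLM non-convergence after 50 iterations yields
p = 1 with a flag.  Coordinate-descent tolerance 1e-7 with objective
step-halving.  Constant transcripts correlate 0 with everything.
Empty inputs (no hits, empty call sets, empty foregrounds, zero-transcript
bundles) produce empty, well-formed outputs rather than errors.

## Problem sizes used in checks

The bundled analyses run at 600 transcripts × 20 samples; the
differential-abundance benchmark pools five seeded replicates
(~450 planted positives, ~2500 nulls) and the network comparison twenty
seeded replicates.  These sizes give binomial standard errors of a few
percent on the recovery rates while keeping a full run in seconds, and
all of them are configuration values, not code constants.

## Known limitations

* The taxonomy loader does not resolve merged/deleted taxids.
* The DE engine does not implement shrinkage estimators, exact tests or
  multi-factor designs, and does not promise numeric identity with any
  external DE tool.
* Module detection uses a static tree cut; dynamic tree cutting and
  eigengene-based module merging are out of scope.
* The lasso report quantifies selection instability but does not provide
  inference (p-values) for selected coefficients.
* Enrichment covers flat term maps with optional parent propagation; no
  full ontology parsing or semantic-similarity clustering.
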