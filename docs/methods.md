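# Methods

## Overview

`coexnet` packages a comparative molecular workflow for two diseases
observed through case/control expression cohorts (the motivating setting
is Alzheimer's vs Parkinson's brain microarray data): moderated
differential expression selects genes, six dependence measures score every
gene pair, a rank-averaged consensus yields a high-confidence
co-expression network, modularity clustering identifies gene groups,
hypergeometric enrichment names each group's functions, and the Jaccard
index between function sets quantifies cross-disease similarity.
Alongside the expression pipeline, curated published lists (GWAS loci and
miRNA studies, packaged as verbatim fixtures) are harmonized and
intersected to produce the shared-gene and shared-miRNA counts.

## Differential expression

Each gene is tested case vs control with a moderated t-statistic.  Under
a scaled inverse-chi-square prior on the gene variances
(sigma_g^2 ~ s0^2 * d0 / chi2_{d0}), the posterior variance is

    s_post^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),    d = n1 + n2 - 2,

and t_g = mean_diff_g / (s_post * sqrt(1/n1 + 1/n2)) has d0 + d degrees
of freedom.  (d0, s0^2) are fitted by moment matching on log s_g^2: the
excess of var(log s_g^2) over trigamma(d/2) equals trigamma(d0/2), which
is inverted by monotone bisection (tolerance 1e-8); the mean of log s_g^2
then fixes s0^2 through the digamma bias terms.  When the empirical excess
spread is <= 0 the prior is degenerate: d0 = infinity and s0^2 is taken as
the geometric mean variance (equal to the common variance when all
variances coincide), with a normal reference distribution.  d0 = 0
recovers the ordinary pooled t exactly.  Multiple testing uses
Benjamini–Hochberg; genes constant in both groups with d0 = 0 are reported
with p = 1 and a degeneracy flag rather than NaN.

Gene selection for network inference is the union of genes with raw
p < alpha (default 0.05; an adjusted-p mode is available via
`de_use_adjusted`) and curated GWAS genes present in the matrix.  Raw p is
the default because the selection step is a screening filter, not an
inferential claim.

## Network inference

Six symmetric, nonnegative, zero-diagonal score matrices:

* **pearson / spearman** — absolute (rank) correlation; co-expression is
  treated sign-agnostically because downstream clustering is
  sign-agnostic.  Constant genes score 0 against everything.
* **dcor** — Szekely distance correlation: each gene's n x n matrix of
  absolute sample differences is double-centered and dCor^2 is the
  normalized inner product of two centered matrices; O(n^2) per pair.
  Zero distance variance (constant gene) scores 0 by convention.
* **clr / mrnetb** — both consume one mutual-information matrix.  MI uses
  equal-frequency discretization into B = ceil(sqrt(n_samples)) bins
  (rank-based, stable tie-breaking) and the maximum-likelihood plug-in
  estimate in nats.  The plug-in estimator carries a positive null bias of
  about (B-1)^2/(2n); this bias is common to all pairs and cancels in both
  downstream methods, which use MI only relatively.  CLR z-scores each
  MI(i,j) against the off-diagonal background of row i (population sd;
  sd = 0 gives z = 0), clips at zero, and scores sqrt(z_i^2 + z_j^2).
  MRNETB scores each target's candidate neighbors by the
  relevance-minus-mean-redundancy objective u_j - mean_{k in S} MI(j,k):
  starting from all candidates it backward-eliminates the worst candidate
  while that objective is negative, applies one forward-swap refinement
  pass over the eliminated variables, scores the surviving neighbors by
  their final objective (clipped at 0), and symmetrizes directed scores by
  max.
* **genie3** — per target, an extremely randomized tree ensemble
  (default 100 trees, sqrt(p) candidate features per split) regresses the
  target on all other genes; impurity-reduction importances are normalized
  to sum 1 per target and symmetrized by max, which preserves strong
  one-directional signals.  Per-target seeds derive deterministically from
  the run seed.

**Consensus.**  The six score scales are incommensurable, so each method's
edge list is rank-normalized to [0, 1] (descending scores; average ranks on
ties; best edge 1, worst 0) and the consensus is the arithmetic mean of
the six normalized scores — a Borda-style wisdom-of-crowds average.  The
disease presets cut this consensus at 0.90 (AD) / 0.96 (PD), i.e. keep the
top edges by average normalized rank; the cutoff scale is declared to be
the rank-normalized one.  Edges at or above the cutoff form the weighted
graph; genes left isolated are dropped (and logged).  Final edge ordering
ties are broken lexicographically by gene pair so outputs are
reproducible.

## Network analysis

* **Communities** — weighted Newman–Girvan modularity with resolution
  gamma (default 1).  Graphs with <= 8 nodes are partitioned by exhaustive
  enumeration over all set partitions (Bell(8) = 4140, cheap), which
  returns the exact modularity optimum; larger graphs use seeded Louvain.
  Labels are canonicalized by descending community size, then smallest
  member, so partitions are comparable across runs.
* **Centrality** — damped random-walk (PageRank) centrality, damping 0.85,
  power iteration to 1e-10; values sum to 1.
* **Enrichment** — one-sided hypergeometric tail P(X >= k) per gene set,
  with the universe fixed to the genes that entered network inference
  (not the whole genome), which avoids selection-bias inflation; BH across
  sets within each cluster; a cluster's "functions" are the sets with
  adjusted p < 0.05.
* **Cross-disease similarity** — J = |A ∩ B| / |A ∪ B| between the
  function sets of every cluster pair, laid out disease-A clusters first.
  A pair in which both clusters have no significant function is flagged
  undefined and reported as 0 rather than NaN.  The summary reports the
  max and mean of the cross-disease block.

## Curated-list harmonization

Fixture files transcribe the published GWAS and miRNA tables verbatim,
one row per study, together with the curated tokens; a test re-runs the
tokenizers on the raw strings and requires identity, so curation is
checked in rather than manual.  Gene loci split on "/", ",", en-dash and
whitespace, and on hyphen-minus unless a data-driven exception file
protects the hyphen (HLA- family prefixes, antisense -AS1-style suffixes,
listed official hyphenated symbols).  miRNA names are lowercased, the
"hsa-" prefix is stripped, and continuation shorthand ("miR-9, -29a")
expands against the most recent family prefix.  Arm suffixes (-5p/-3p)
are retained exactly; typography is never repaired (e.g. the printed
token "miR-27a3p" stays distinct from "mir-27a-3p").  Matching is exact
on normalized tokens — the unique simple rule consistent with the printed
shared-miRNA list; collapsing arm suffixes would inflate the overlap.
The per-disease list totals depend on how a reader resolves shorthand and
typos, so the package reports but does not assert them; the intersections
are the audited quantities.

## Synthetic data

The generator emulates the structure the pipeline is meant to detect:
modules driven by one shared latent factor each (gene = loading * factor
+ noise), background genes as unit-variance independent noise, and DE as
an additive mean shift on cases.  Defaults — 4 modules x 12 genes, 40
background genes, 50 + 50 samples, loadings uniform in (0.6, 1.0), noise
sd 0.5 (within-module correlations ~0.6–0.8, a realistic moderate
co-expression), DE fraction 0.1 with shift 1.0 log-units — are the study
conditions used by the recovery analyses.  One master seed spawns fixed
per-stage child seeds (loadings, factors, noise, DE choice), so datasets
are bit-reproducible.

What the generator does not emulate: probe-level noise, batch effects,
heavy-tailed intensities, correlated background, multi-factor modules, or
region-structured cohorts.  Passing recovery tests therefore show the
pipeline recovers clean single-factor modules at moderate noise — not that
it reproduces any particular result on public microarray cohorts, whose
preprocessing is outside this package's scope (expression input is
assumed already log-transformed and normalized; missing values are an
error, never imputed).

**Recovery metric.**  Module recovery is scored as the adjusted Rand index
between planted module assignments and detected communities over the
planted module genes; a module gene dropped at thresholding counts as its
own singleton (penalized), while background genes — which are not part of
the planted structure — are excluded from the score.

## Numerical choices and degenerate inputs

* Rank ties everywhere use average ranks; a single edge rank-normalizes
  to 1.0.
* Score matrices are validated symmetric to 1e-10 relative tolerance and
  then symmetrized exactly to remove BLAS float asymmetry.
* Tabular output is TSV with '.' decimals; expression matrices are written
  with %.17g and read with round-trip float parsing, so file round trips
  are bit-exact.
* BH output is clamped to be >= the raw p-values, guarding the
  adjusted >= raw invariant against last-rank rounding.
* Empty graphs after thresholding, empty gene selections, empty
  enrichment universes and kind-mismatched list intersections raise
  errors with actionable messages instead of returning empty results.

## Problem sizes

The recovery analyses run the full six-method pipeline on 88-gene,
100-sample datasets across 20 seeds; oracle-equivalence checks use <= 6
gene instances (CLR/MRNETB) and <= 8-node graphs (exhaustive modularity);
calibration uses 1000 null genes with 20 + 20 samples.  These sizes give
stable estimates while keeping a full run in minutes on one CPU.

## Known limitations

* The consensus scale (and hence the 0.90/0.96 cutoffs) is defined on
  rank-normalized scores; a raw-scale consensus would need different
  cutoffs.
* MRNETB is O(p^3) per target in the worst case and is intended for the
  post-selection gene subset, not genome-wide matrices.
* The miRNA tokenizer trusts the printed tables; entries whose family
  prefix is itself a typo propagate that typo (by design — no repair).
* Cluster counts and DE counts on real cohorts depend on preprocessing
  decisions (probe collapsing, region selection) this package deliberately
  does not make.
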