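# Methods

This note documents the models and procedures implemented in `cartx`, the
assumptions behind them, the defaults that matter, and what the synthetic
benchmark does and does not establish.

## Study design and units

The package targets paired pre/post bulk expression data from small
clinical cohorts: `n` patients (default 4, three remissive and one
non-remissive) each sampled at two timepoints (D0 and D14), with gene-level
and miRNA-level count matrices and a feature annotation carrying lengths,
biotypes (coding / lncRNA / miRNA) and functional flags (TF, histone,
membrane, CAR transgene, CD19).

Counts are converted to FPKM, `10^9 · C_gs / (N_s · L_g)` with `N_s` the
per-sample total assigned counts and `L_g` the feature length in bp (no
effective-length correction — the simplest contract consistent with the
unit's definition), and to TPM, `10^6 · (C_gs/L_g) / Σ_g (C_gs/L_g)`. With
equal lengths, as for miRNAs, TPM reduces to counts-per-million.
Expressed-feature filters use strict inequalities — FPKM > 1 (genes),
TPM > 10 (miRNAs), FPKM > 100 in *every* sample for the highly-expressed
call — with `min_samples = 1` by default (expressed in at least one
sample); both threshold and `min_samples` are exposed in configuration.
Ties anywhere (top-k rankings, module labelling, pair ranking) break
lexicographically on feature id, for determinism.

## Paired differential expression without replicates

With one sample per condition per patient there is nothing to estimate a
dispersion from, so replicate-aware models are out of design. Calling is
fold-change based: feature `g` is differential for a patient when
`|log2((post + c)/(pre + c))| ≥ 1` and `max(pre, post)` exceeds the unit's
expressed floor (FPKM 1 / TPM 10). The pseudocount `c = 0.1` (expression
units) bounds fold changes at zero expression; all three knobs are
configurable. The same caller, on miRNA TPM with floor 10, produces the
differential-miRNA (DEM) tables. Cross-patient summaries are plain set
operations: the intersection of per-patient DEG sets and its same-trend
subset (identical direction in every selected patient).

A known property of this caller, visible in the synthetic benchmark: any
biological sample-to-sample variation (module factors, cell-composition
changes) that moves a gene by more than the threshold between a patient's
two samples is indistinguishable from condition response. This is inherent
to n = 1 paired designs, not an implementation artifact.

PLS-DA fits partial least squares (NIPALS, via scikit-learn) to a one-hot
class response on feature-standardised data; constant features are dropped
with a warning. Variable importance in projection is
`VIP_j = sqrt(p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a)` with `SS_a` the
response variance explained by component `a`; the formula implies
`mean(VIP²) = 1`, which the tests assert as an algebraic identity.

## Weighted co-expression analysis

The network chain is authored in-package (only the clustering solver and
probability distributions come from scipy):

1. **Correlation**: Pearson `r` across all 8 samples pooled; two-sided p
   from `t = r·sqrt(n−2)/sqrt(1−r²)` on `n−2` df; `|r| = 1 → p = 0`.
2. **Soft power**: for each candidate β, connectivity `k_i = Σ_j |r_ij|^β`
   is binned into equal-count bins of log10 k and log10(frequency) is
   regressed on bin means; the signed scale-free fit is `sign(−slope)·R²`.
   The smallest β reaching 0.8 wins, otherwise the best fit, flagged. The
   *default* pipeline power is **β = 9**, the widely used unsigned-network
   recommendation for cohorts under ~20 samples: at n = 8 the null
   expectation of `|r|^6` (≈ 0.02) is large enough that unstructured
   features acquire non-trivial topological overlap with genuine modules
   and bridge them under the static cut; β = 9 suppresses that
   chance-correlation floor.
3. **Adjacency and TOM**: unsigned `a_ij = |r_ij|^β`, zero diagonal;
   `TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, `TOM_ii = 1`. The
   vectorised implementation is tested against a triple-loop oracle at
   1e−12.
4. **Modules**: average-linkage clustering of `1 − TOM` with a *static* cut
   at `cut_height × max merge height` (default 0.99); clusters below
   `min_module_size` (default 30) are labelled grey. A static cut is fully
   specifiable and deterministic, which we prefer over dynamic tree cutting
   for a testable artifact; it is adequate for planted-module recovery.
   Surviving clusters take the conventional colour names (turquoise, blue,
   brown, ...) by decreasing size, ties broken by smallest member id.
5. **Eigengenes**: first principal component of the per-feature z-scored
   module submatrix, unit variance (ddof = 1 throughout), sign-oriented to
   correlate non-negatively with the module mean profile.
6. **Module–pathway correlation**: pathway activity is the per-sample mean
   z-score of the set's member features — the simplest transparent score —
   correlated with eigengenes and flagged at r > 0.9, p < 1e−6.
7. **Gene–lncRNA pairs**: all cross-set pairs with r > 0.9 and p < 1e−6,
   ranked by |r| (ties: smaller p, then lexicographic), truncated to the
   top 200 by default.

## Enrichment statistics

Over-representation uses the one-sided hypergeometric tail
`P(X ≥ k)` with the background defaulting to all expressed features of the
matching biotype; sets are intersected with the background first and
zero-overlap sets skipped with a note. BH FDR is reported alongside raw p
(raw p is what such studies usually print; FDR is the modern default).
Class enrichment of a gene family within assigned modules (e.g. histones)
uses Pearson chi-square without continuity correction on the 2×2 table
{in class, not} × {in a module, grey}; expected cells below 1 attach a
warning but the statistic is still returned. When module detection leaves
no grey features the table is degenerate and the test is reported as
undefined rather than computed.

## Immune profiling

Cell-type scores are marker means: per feature, z-score
`log2(value + 0.1)` across samples; per sample and cell type, average over
the type's markers. Marker-mean scoring was chosen over reference-profile
regression deconvolution because it is transparent, dependency-free and
directly testable against planted mixtures; the interface admits a
regression-based estimator later. The proportion table is a display
convention — per sample, shift scores to zero minimum and renormalise —
with raw scores always retained; flat score rows become uniform proportions
with a warning.

The membrane screen correlates membrane-flagged genes with anchor profiles
(CAR transgene and CD19), retaining `|r| ≥ 0.5` (inclusive) and `p < 0.05`
(strict). Microenvironment panels report paired fold changes with a strict
`> 2` flag.

## Regulatory networks

Consistent DEMs are miRNAs called differential with an identical direction
in every remissive patient. The miRNA–TF–gene network takes these as seeds;
their targets (from an external regulator→target table) are included only
when they are DEGs (union across patients; configurable), TF nodes are
flagged from annotation, co-expression edges (|r| ≥ 0.9) connect included
genes of *different* modules, and gene→pathway edges attach set membership,
dropping isolated pathway nodes. The within-module TF–gene–lncRNA view
instead uses within-module top pairs and attaches only the module's
significantly enriched pathways (BH FDR < 0.05) — the two assembly modes
are deliberately distinct. miRNA–target anti-correlation is recorded as an
edge attribute, never used as a filter. Crosstalk nodes are gene/TF nodes
with pathway edges to ≥ 2 distinct pathways, ordered by pathway degree.
Networks are validated containers (typed endpoints, no duplicate
(source, target, kind) triples) and round-trip byte-stably through GraphML
and paired TSVs.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes and
emits the truth tables every stage is scored against. Gene expression is a
latent-factor model on the log2 scale:

    x_gs = base_g + loading_g · e_{m(g),s} + DE_g·[s ∈ D14] + repression + ε_gs

with `base_g ~ N(4, 1.5²)` (log2 intensity units), loadings uniform on
±[0.7, 1.0], `ε ~ N(0, noise_sd²)` (default 0.1), and planted DE shifts of
±2 log2 units applied at D14 to 10% of *background* features (80% coding /
20% lncRNA). Targets of planted differential miRNAs receive
`−0.5 × (regulator shift)` at D14. Marker genes scale linearly with the
planted per-sample cell-type proportions. Intensities are exponentiated,
multiplied by feature length, scaled to a fixed library size (5 × 10⁶) and
rounded — so FPKM/TPM arithmetic on the counts recovers the latent
intensities up to rounding, without a negative-binomial dependency in the
truth model. The CAR transgene is an ordinary feature row: zero at D0,
high at D14 in remissive patients and low in the non-remissive one.

Three calibration choices deserve explanation:

* **Orthogonalised factors.** Module eigengene profiles are drawn i.i.d.
  Gaussian, mean-centred, and Gram-Schmidt orthogonalised — against each
  other *and* against the D0/D14 contrast — then rescaled to sample sd
  `eigengene_sd`. With only 8 samples, independently drawn factors are
  frequently correlated at |r| > 0.7 by chance; no correlation-based method
  could attribute such collinear factors to separate modules, and factors
  correlated with the condition contrast would bleed into the separately
  planted DE signal. Orthogonalisation makes the planted structure mean
  what it says. It requires `n_modules < n_samples − 1`.
* **Signed loadings.** Loading signs are random by default, giving each
  module anti-correlated halves (the structure unsigned networks are built
  for) and keeping each module's total linear-scale mass nearly constant
  across samples. With all-positive loadings, module mass is a convex
  function of the factor, so factor fluctuations masquerade as library-
  composition shifts that bias every other gene's fold change by a
  per-sample constant. `signed_loadings=False` restores strictly
  positively correlated modules (used by the noise-free |r| = 1
  calibration check).
* **Balanced mixtures.** Default cell-type proportions cycle the profile
  (0.6, 0.3, 0.1) across samples, so every population spans the same
  dynamic range — the regime in which z-score-based marker scoring is an
  unbiased readout. Remissive patients show the B-cell collapse with
  cytotoxic expansion at D14; the non-remissive patient stays B-cell
  dominated.

What the generator does *not* emulate: overdispersed counting noise,
batch effects, isoform structure, length-coupled expression biases,
correlated (structured) background genes, or partially consistent DE
directions across patients. Passing the recovery criteria therefore shows
the chain is correct and calibrated under its own assumptions, not that it
is robust to real-data violations of them.

## Scoring against planted truth

* **Module recovery** is the adjusted Rand index between detected and
  planted labels over the features the truth assigns to a planted module.
  Background features are excluded: how unstructured features fragment
  under average linkage is not part of the planted module signal.
* **DE recovery** (sensitivity and false-discovery proportion) is computed
  over background features. Planted module members, cell-type markers, the
  CAR row and miRNA-coupled targets are excluded from both sides: each of
  those carries planted signal of a different kind (factor variation,
  composition, transgene kinetics, repression coupling) that an n = 1
  fold-change caller cannot and should not be scored on, and each has its
  own check.
* **Proportion recovery** is the per-sample mean absolute error between
  estimated and planted proportions.
* **Network soundness/completeness**: every assembled regulatory edge must
  come from the input tables, and every planted miRNA→target edge whose
  regulator was selected and whose target was called differential must be
  present.

## Statistical cross-checks

The analytic correlation p-value is verified two ways. Against a
quadrature oracle (numerical integration of the t density) it agrees to
9+ digits at fixed r and n. Against a 10,000-draw permutation oracle on
random 5–10-sample datasets the comparison is made *in aggregate* — the
mean analytic-minus-permutation difference across 50 datasets lies within
three standard errors of zero — because per dataset the exact conditional
permutation distribution of r at such small n differs from the t
distribution by amounts (up to ~0.1 in p) far exceeding Monte-Carlo error;
the analytic p is the unconditional null probability, unbiased for the
permutation p across datasets but not equal to it conditionally. The
hypergeometric tail is compared with exact integer-arithmetic enumeration
over every instance with N ≤ 60 at 1e−12.

## Pipeline, determinism, problem sizes

The orchestrator derives all randomness from one seed, logs every
parameter actually used (including defaulted ones), writes flat-text
intermediates only, and emits a manifest of SHA-256 checksums; identical
configuration and seed reproduce identical checksums. Default problem
sizes — 900 gene features, 150 miRNAs, 8 samples, 5 planted modules of
100 — keep a full run under a few seconds and the entire test suite under
a minute on one CPU while leaving every stage's statistics in a regime
where the recovery criteria are informative.

## Known limitations

* The static-cut module detector absorbs background features into adjacent
  modules rather than leaving them grey when their chance topological
  overlap is high; dynamic tree cutting and eigengene merging are out of
  scope.
* Fold-change DE calling cannot separate condition response from any other
  within-patient variation (see above); thresholds are heuristics, not
  error-controlled tests.
* Marker-mean deconvolution returns relative, min-shifted proportions; it
  is not a substitute for reference-profile regression on real data.
* Enrichment p-values depend strongly on the chosen background universe;
  the package defaults to expressed features of the matching biotype and
  exposes the choice.
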