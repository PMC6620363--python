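# cartx

Paired pre/post bulk-transcriptome and regulatory-network analysis for small
clinical cohorts, built around the kind of study where a handful of patients
are sampled before (D0) and two weeks after (D14) an intervention — here, a
CD19-directed CAR-T infusion into the bone marrow of B-ALL patients — and
everything downstream has to work with one sample per patient per condition.

The package implements the full analysis chain as a tested library plus CLI:

* **Quantification** — FPKM (`10^9 · C_gs / (N_s · L_g)`) and TPM
  (length-normalised rates rescaled to 10^6 per sample), expressed-feature
  filters with the conventional strict thresholds (FPKM > 1 for genes,
  TPM > 10 for miRNAs), highly-expressed calls (FPKM > 100 in all samples)
  and top-k abundance shares.
* **Paired differential expression without replicates** — fold-change calling
  per patient (`|log2 (post+c)/(pre+c)| ≥ 1` above an expression floor),
  cross-patient intersections (common and same-trend DEG sets), class
  summaries, and PLS-DA with VIP scores
  `VIP_j = sqrt(p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a)`.
* **Weighted co-expression analysis from first principles** — Pearson
  correlation with t-based p-values, scale-free soft-power selection,
  unsigned adjacency `|r|^β`, topological overlap
  `TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, average-linkage
  module detection with a static cut, module eigengenes (first PC of the
  z-scored module), module–pathway correlation (R > 0.9, P < 1e−6), and
  top gene–lncRNA pair ranking.
* **Enrichment** — one-sided Fisher exact (hypergeometric-tail) gene-set
  tests with BH FDR, top-terms reporting (20 KEGG / 15 GO-BP), and
  chi-square class enrichment within modules.
* **Immune profiling** — marker-based cell-type scoring (mean z-score of
  log2 marker expression), proportion tables, membrane-gene correlation
  screens against CAR/CD19 anchors (|r| ≥ 0.5, p < 0.05), and
  microenvironment fold-change panels (fold change > 2).
* **Regulatory networks** — consistent differential miRNAs across remissive
  patients, miRNA–TF–gene network assembly (targets restricted to DEGs,
  cross-module co-expression edges, pathway membership edges), within-module
  TF–gene–lncRNA networks, crosstalk-node detection, GraphML/TSV export.
* **Synthetic cohorts with planted truth** — a generator that emulates the
  4-patient (3 remissive / 1 non-remissive) × 2-timepoint design with
  planted co-expression modules, DE shifts, miRNA-mediated repression,
  TF→target edges, cell-type mixtures and a CAR transgene row, emitting the
  ground-truth tables every stage is scored against.

## Worked example

```python
from cartx import ScenarioConfig, generate_cohort
from cartx.quantify import fpkm, tpm, filter_expressed, top_abundance_share
from cartx.diffexpr import call_features_per_patient, intersect_common
from cartx.coexpression import adjacency, topological_overlap, detect_modules
from cartx.evaluation import score_module_recovery

config = ScenarioConfig(seed=1)
counts, mirna_counts, annotation, metadata, truth = generate_cohort(config)

fpkm_m = fpkm(counts, annotation)
expressed = filter_expressed(fpkm_m)            # FPKM > 1 in >= 1 sample
print(f"expressed genes: {expressed.n_features} / {fpkm_m.n_features}")

tpm_m = tpm(mirna_counts, annotation)
share = top_abundance_share(tpm_m, k=8)
print(f"top-8 miRNA abundance share (mean): {share.share.mean():.2f}")

deg = call_features_per_patient(fpkm_m, metadata)
print(f"DEGs per patient: {({p: len(t) for p, t in deg.items()})}")
common, same_trend = intersect_common(deg, metadata.remissive_patients())
print(f"common DEGs in remissive patients: {len(common)} "
      f"({len(same_trend)} with the same trend)")

log_expr = expressed.log2(1.0)
modules = detect_modules(topological_overlap(adjacency(log_expr, power=9)))
print(f"modules detected: {len(set(modules) - {'grey'})}; recovery ARI vs "
      f"planted truth: {score_module_recovery(modules, truth):.2f}")
```

prints

```
expressed genes: 901 / 901
top-8 miRNA abundance share (mean): 0.87
DEGs per patient: {'P1': 382, 'P2': 347, 'P3': 373, 'P4': 340}
common DEGs in remissive patients: 115 (101 with the same trend)
modules detected: 6; recovery ARI vs planted truth: 1.00
```

Reading the output: every synthetic gene clears the FPKM > 1 filter (the
generator plants well-expressed features); a few dominant miRNA species
carry ~87% of miRNA reads; each patient yields a few hundred fold-change
DEGs, of which 115 are shared by all three remissive patients (101 moving
in the same direction — planted DE shifts share direction across patients,
plus composition-driven marker changes); and module detection recovers the
five planted modules perfectly (a sixth detected module is the block of
co-shifted DE genes, which genuinely co-vary).

The same run is available from the shell:

```bash
cartx run-all --seed 1 --outdir out/
cartx simulate --seed 1 --outdir out_sim/     # generator outputs only
```

Every stage writes flat TSV/GMT/GraphML artifacts plus `manifest.json`
with per-file SHA-256 checksums; identical configuration and seed reproduce
identical checksums.

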