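"""End-to-end pipeline orchestration with a manifest of produced artifacts.

A :class:`PipelineConfig` names either a ``simulate`` block (scenario
parameters) or paths to existing input tables, plus per-stage parameter
blocks. :func:`run_pipeline` executes the requested stages in dependency
order, writes every intermediate as flat text (TSV/GMT/GraphML) under the
output directory, and emits ``manifest.json`` mapping each stage to its
files and their SHA-256 checksums. Reruns with an identical configuration
and seed reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import coexpression, diffexpr, enrichment, immune, network, quantify
from .matrix import CartxError, ExpressionMatrix, FeatureAnnotation, SampleMetadata
from .simulate import (
    CellType,
    ScenarioConfig,
    generate_cohort,
    generate_edge_tables,
    generate_gene_sets,
)

logger = logging.getLogger("cartx")

STAGES = ("simulate", "quantify", "de", "coexpress", "enrich", "immune", "network")

STAGE_DEPENDENCIES = {
    "simulate": (),
    "quantify": ("simulate",),
    "de": ("quantify",),
    "coexpress": ("quantify",),
    "enrich": ("de", "coexpress", "simulate"),
    "immune": ("quantify", "simulate"),
    "network": ("de", "coexpress", "simulate"),
}

_STAGE_PARAM_KEYS = {
    "simulate": set(),
    "quantify": {"gene_threshold", "mirna_threshold", "min_samples"},
    "de": {"min_abs_log2fc", "min_expression", "pseudocount", "n_components"},
    "coexpress": {"power", "auto_power", "min_module_size", "cut_height"},
    "enrich": {"top_kegg", "top_bp", "gene_set_overlap"},
    "immune": {"r_min", "p_max", "fc_threshold"},
    "network": {"coexpr_r_min", "min_pathways", "decoy_fraction", "significant_fdr"},
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``simulate`` (a :class:`ScenarioConfig`) or ``inputs``
    (paths to counts/annotation/metadata tables) must be set. ``params``
    holds per-stage parameter blocks; unknown stage names or keys are
    rejected.
    """

    simulate: ScenarioConfig | None = None
    inputs: dict[str, str] | None = None
    params: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)
    seed: int = 1
    outdir: str = "cartx_out"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise CartxError("exactly one of a simulate block or input paths is required")
        for stage, block in self.params.items():
            if stage not in _STAGE_PARAM_KEYS:
                raise CartxError(f"unknown parameter block {stage!r}")
            unknown = set(block) - _STAGE_PARAM_KEYS[stage]
            if unknown:
                raise CartxError(f"unknown key(s) in {stage!r} block: {sorted(unknown)}")

    def stage_params(self, stage: str) -> dict[str, Any]:
        return dict(self.params.get(stage, {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known_top = {"simulate", "inputs", "params", "seed", "outdir"}
        unknown = set(raw) - known_top
        if unknown:
            raise CartxError(f"unknown configuration key(s): {sorted(unknown)}")
        sim = None
        if "simulate" in raw and raw["simulate"] is not None:
            block = dict(raw["simulate"])
            if "cell_types" in block:
                block["cell_types"] = tuple(
                    CellType(ct["name"], int(ct["n_markers"]), tuple(ct["proportions"]))
                    for ct in block["cell_types"]
                )
            for key in ("remission_labels", "module_sizes"):
                if key in block:
                    block[key] = tuple(block[key])
            for key in ("loading_range", "gene_length_range"):
                if key in block:
                    block[key] = tuple(block[key])
            known = {f.name for f in dataclasses.fields(ScenarioConfig)}
            bad = set(block) - known
            if bad:
                raise CartxError(f"unknown simulate key(s): {sorted(bad)}")
            sim = ScenarioConfig(**block)
        return cls(
            simulate=sim,
            inputs=raw.get("inputs"),
            params=raw.get("params", {}),
            seed=int(raw.get("seed", 1)),
            outdir=str(raw.get("outdir", "cartx_out")),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, seed: int):
        self.outdir = outdir
        self.data: dict[str, Any] = {"seed": seed, "stages": {}, "parameters": {}}

    def record(self, stage: str, files: Mapping[str, Path], params: Mapping[str, Any]) -> None:
        self.data["stages"][stage] = {
            name: {"path": str(p.relative_to(self.outdir)), "sha256": _sha256(p)}
            for name, p in sorted(files.items())
        }
        self.data["parameters"][stage] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in sorted(params.items())
        }
        logger.info("stage %s: %d file(s); parameters %s", stage, len(files), dict(params))

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return path


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str] | None = None
) -> dict[str, Any]:
    """Run the requested stages in order; returns the manifest dict.

    Stage dependencies are checked up front: requesting a stage without its
    prerequisites (in this run) is an error.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise CartxError(f"unknown stage(s): {unknown}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    requested = set(stages)
    for s in stages:
        missing = [d for d in STAGE_DEPENDENCIES[s] if d not in requested]
        if config.inputs is not None:
            # external inputs stand in for the simulate stage
            missing = [d for d in missing if d != "simulate"]
        if missing:
            raise CartxError(f"stage {s!r} requires stage(s) {missing} in the same run")
    if config.inputs is not None and "simulate" in requested:
        raise CartxError("the simulate stage needs a simulate block, not input paths")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config.seed)
    state: dict[str, Any] = {}

    for stage in stages:
        _STAGE_RUNNERS[stage](config, state, outdir, manifest)

    manifest.data["stages_run"] = stages
    path = manifest.write()
    logger.info("manifest written to %s", path)
    return manifest.data


# --------------------------------------------------------------------------
# stage runners


def _run_simulate(config: PipelineConfig, state: dict, outdir: Path, manifest: _Manifest) -> None:
    scenario = config.simulate
    if scenario is None:
        raise CartxError("simulate stage requires a simulate block")
    scenario = dataclasses.replace(scenario, seed=config.seed)
    counts, mirna_counts, annotation, metadata, truth = generate_cohort(scenario)
    decoy = config.stage_params("network").get("decoy_fraction", 0.2)
    tf_targets, mirna_targets = generate_edge_tables(scenario, truth, decoy)
    overlap = config.stage_params("enrich").get("gene_set_overlap", 0.8)
    gene_sets = generate_gene_sets(scenario, truth, overlap=overlap)

    d = outdir / "simulate"
    d.mkdir(exist_ok=True)
    files: dict[str, Path] = {}
    counts.to_tsv(files.setdefault("gene_counts", d / "gene_counts.tsv"))
    mirna_counts.to_tsv(files.setdefault("mirna_counts", d / "mirna_counts.tsv"))
    annotation.to_tsv(files.setdefault("annotation", d / "annotation.tsv"))
    metadata.to_tsv(files.setdefault("metadata", d / "metadata.tsv"))
    tf_targets.to_csv(files.setdefault("tf_targets", d / "tf_targets.tsv"), sep="\t", index=False)
    mirna_targets.to_csv(
        files.setdefault("mirna_targets", d / "mirna_targets.tsv"), sep="\t", index=False
    )
    gene_sets.to_gmt(files.setdefault("gene_sets", d / "gene_sets.gmt"))
    files.update(truth.write(d))

    state.update(
        counts=counts, mirna_counts=mirna_counts, annotation=annotation,
        metadata=metadata, truth=truth, tf_targets=tf_targets,
        mirna_targets=mirna_targets, gene_sets=gene_sets,
    )
    manifest.record(
        "simulate", files,
        {**dataclasses.asdict(scenario), "decoy_fraction": decoy, "gene_set_overlap": overlap},
    )


def _load_inputs(config: PipelineConfig, state: dict) -> None:
    inputs = config.inputs or {}
    required = ("gene_counts", "mirna_counts", "annotation", "metadata")
    missing = [k for k in required if k not in inputs]
    if missing:
        raise CartxError(f"missing input path(s): {missing}")
    state["counts"] = ExpressionMatrix.from_tsv(inputs["gene_counts"], "raw_count")
    state["mirna_counts"] = ExpressionMatrix.from_tsv(inputs["mirna_counts"], "raw_count")
    state["annotation"] = FeatureAnnotation.from_tsv(inputs["annotation"])
    state["metadata"] = SampleMetadata.from_tsv(inputs["metadata"])
    if "tf_targets" in inputs:
        state["tf_targets"] = pd.read_csv(inputs["tf_targets"], sep="\t")
    if "mirna_targets" in inputs:
        state["mirna_targets"] = pd.read_csv(inputs["mirna_targets"], sep="\t")
    if "gene_sets" in inputs:
        state["gene_sets"] = enrichment.GeneSetCollection.from_gmt(inputs["gene_sets"])


def _run_quantify(config: PipelineConfig, state: dict, outdir: Path, manifest: _Manifest) -> None:
    if "counts" not in state:
        _load_inputs(config, state)
    p = config.stage_params("quantify")
    gene_thr = p.get("gene_threshold", 1.0)
    mir_thr = p.get("mirna_threshold", 10.0)
    min_samples = p.get("min_samples", 1)

    fpkm_m = quantify.fpkm(state["counts"], state["annotation"])
    tpm_m = quantify.tpm(state["mirna_counts"], state["annotation"])
    expressed = quantify.filter_expressed(fpkm_m, gene_thr, min_samples)
    expressed_mir = quantify.filter_expressed(tpm_m, mir_thr, min_samples)
    high = quantify.highly_expressed(fpkm_m, 100.0)
    share = quantify.top_abundance_share(tpm_m, k=min(8, tpm_m.n_features))

    d = outdir / "quantify"
    d.mkdir(exist_ok=True)
    files: dict[str, Path] = {}
    fpkm_m.to_tsv(files.setdefault("fpkm", d / "fpkm.tsv"))
    tpm_m.to_tsv(files.setdefault("mirna_tpm", d / "mirna_tpm.tsv"))
    expressed.to_tsv(files.setdefault("expressed_fpkm", d / "expressed_fpkm.tsv"))
    expressed_mir.to_tsv(files.setdefault("expressed_mirna_tpm", d / "expressed_mirna_tpm.tsv"))
    pd.Series(high, name="feature_id").to_csv(
        files.setdefault("highly_expressed", d / "highly_expressed.tsv"), sep="\t", index=False
    )
    share.share.to_frame().assign(
        top_features=[",".join(share.top_features[s]) for s in share.share.index]
    ).to_csv(files.setdefault("mirna_top_share", d / "mirna_top_share.tsv"), sep="\t")

    state.update(fpkm=fpkm_m, tpm=tpm_m, expressed=expressed, expressed_mir=expressed_mir)
    manifest.record(
        "quantify", files,
        {"gene_threshold": gene_thr, "mirna_threshold": mir_thr, "min_samples": min_samples},
    )


def _run_de(config: PipelineConfig, state: dict, outdir: Path, manifest: _Manifest) -> None:
    p = config.stage_params("de")
    min_lfc = p.get("min_abs_log2fc", 1.0)
    min_expr = p.get("min_expression")
    pc = p.get("pseudocount", diffexpr.DEFAULT_PSEUDOCOUNT)
    n_comp = p.get("n_components", 2)

    deg = diffexpr.call_features_per_patient(
        state["fpkm"], state["metadata"], min_lfc, min_expr, pc
    )
    dem = diffexpr.call_features_per_patient(
        state["tpm"], state["metadata"], min_lfc, min_expr, pc
    )
    common, same_trend = diffexpr.intersect_common(deg, state["metadata"].remissive_patients())
    labels = state["metadata"].table["timepoint"]
    vip = diffexpr.plsda_vip(state["expressed"].log2(1.0), labels, n_components=n_comp)

    d = outdir / "de"
    d.mkdir(exist_ok=True)
    files: dict[str, Path] = {}
    deg_all = pd.concat(deg.values(), ignore_index=True)
    dem_all = pd.concat(dem.values(), ignore_index=True)
    deg_all.to_csv(files.setdefault("deg", d / "deg.tsv"), sep="\t", index=False, float_format="%.6g")
    dem_all.to_csv(files.setdefault("dem", d / "dem.tsv"), sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"feature_id": sorted(common)}).assign(
        same_trend=lambda t: t["feature_id"].isin(same_trend)
    ).to_csv(files.setdefault("common_degs", d / "common_degs.tsv"), sep="\t", index=False)
    vip.to_csv(files.setdefault("vip", d / "vip.tsv"), sep="\t", index=False, float_format="%.6g")

    state.update(deg_tables=deg, dem_tables=dem, common=common, same_trend=same_trend, vip=vip)
    manifest.record(
        "de", files,
        {"min_abs_log2fc": min_lfc, "min_expression": min_expr, "pseudocount": pc,
         "n_components": n_comp},
    )


def _run_coexpress(config: PipelineConfig, state: dict, outdir: Path, manifest: _Manifest) -> None:
    p = config.stage_params("coexpress")
    auto = p.get("auto_power", False)
    min_size = p.get("min_module_size", 30)
    cut = p.get("cut_height", 0.99)

    log_expr = state["expressed"].log2(1.0)
    diag_table = None
    if auto:
        diag = coexpression.pick_soft_power(log_expr)
        power = diag.power
        diag_table = diag.table
    else:
        power = p.get("power", 9)

    adj = coexpression.adjacency(log_expr, power)
    tom = coexpression.topological_overlap(adj)
    modules = coexpression.detect_modules(tom, min_size, cut)
    eigen = coexpression.module_eigengene(log_expr, modules)

    d = outdir / "coexpress"
    d.mkdir(exist_ok=True)
    files: dict[str, Path] = {}
    modules.rename("module").to_frame().rename_axis("feature_id").to_csv(
        files.setdefault("modules", d / "modules.tsv"), sep="\t"
    )
    eigen.to_csv(files.setdefault("eigengenes", d / "eigengenes.tsv"), sep="\t", float_format="%.6g")
    if diag_table is not None:
        diag_table.to_csv(
            files.setdefault("power_diagnostics", d / "power_diagnostics.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )

    state.update(log_expr=log_expr, modules=modules, eigengenes=eigen, power=power)
    manifest.record(
        "coexpress", files,
        {"power": power, "auto_power": auto, "min_module_size": min_size, "cut_height": cut},
    )


def _run_enrich(config: PipelineConfig, state: dict, outdir: Path, manifest: _Manifest) -> None:
    p = config.stage_params("enrich")
    top_kegg = p.get("top_kegg", 20)
    top_bp = p.get("top_bp", 15)

    background = set(state["expressed"].feature_ids)
    gene_sets = state["gene_sets"]
    deg_union = set().union(*(set(t["feature_id"]) for t in state["deg_tables"].values()))
    deg_union &= background

    d = outdir / "enrich"
    d.mkdir(exist_ok=True)
    files: dict[str, Path] = {}

    deg_enrich = enrichment.fisher_enrich(deg_union, background, gene_sets) if deg_union else pd.DataFrame()
    if len(deg_enrich):
        top = enrichment.top_terms(deg_enrich, top_kegg, top_bp)
        top.to_csv(files.setdefault("deg_top_terms", d / "deg_top_terms.tsv"),
                   sep="\t", index=False, float_format="%.6g")
        deg_enrich.to_csv(files.setdefault("deg_enrichment", d / "deg_enrichment.tsv"),
                          sep="\t", index=False, float_format="%.6g")

    module_rows = []
    module_enrichments: dict[str, pd.DataFrame] = {}
    for label in sorted(set(state["modules"]) - {"grey"}):
        members = set(state["modules"].index[state["modules"] == label]) & background
        if not members:
            continue
        tab = enrichment.fisher_enrich(members, background, gene_sets)
        module_enrichments[label] = tab
        tab.insert(0, "module", label)
        module_rows.append(tab)
    if module_rows:
        mod_enrich = pd.concat(module_rows, ignore_index=True)
        mod_enrich.to_csv(files.setdefault("module_enrichment", d / "module_enrichment.tsv"),
                          sep="\t", index=False, float_format="%.6g")

    activity = coexpression.pathway_activity(state["log_expr"], gene_sets.as_dict())
    assoc = coexpression.module_feature_correlation(
        state["eigengenes"].loc[:, state["log_expr"].sample_ids], activity
    )
    assoc.to_csv(files.setdefault("module_pathway_correlation", d / "module_pathway_correlation.tsv"),
                 sep="\t", index=False, float_format="%.6g")

    ann = state["annotation"]
    hist = set(ann.features_with_flag("histone")) & set(state["modules"].index)
    chisq_row: dict[str, Any] = {"class": "histone", "n_class": len(hist)}
    if hist and (state["modules"] == "grey").any():
        chi = enrichment.class_chisq(state["modules"], hist)
        chisq_row.update(statistic=chi.statistic, p=chi.p,
                         low_expected=chi.low_expected_warning)
    else:
        chisq_row.update(statistic=float("nan"), p=float("nan"), low_expected=False)
    pd.DataFrame([chisq_row]).to_csv(
        files.setdefault("class_chisq", d / "class_chisq.tsv"),
        sep="\t", index=False, float_format="%.6g",
    )

    state.update(deg_union=deg_union, module_enrichments=module_enrichments, pathway_assoc=assoc)
    manifest.record("enrich", files, {"top_kegg": top_kegg, "top_bp": top_bp})


def _run_immune(config: PipelineConfig, state: dict, outdir: Path, manifest: _Manifest) -> None:
    p = config.stage_params("immune")
    r_min = p.get("r_min", 0.5)
    p_max = p.get("p_max", 0.05)
    fc_thr = p.get("fc_threshold", 2.0)

    ann = state["annotation"]
    panel = immune.MarkerPanel.from_annotation(ann)
    scores = immune.cell_scores(state["fpkm"], panel)
    proportions = immune.scores_to_proportions(scores)

    d = outdir / "immune"
    d.mkdir(exist_ok=True)
    files: dict[str, Path] = {}
    scores.to_csv(files.setdefault("cell_scores", d / "cell_scores.tsv"), sep="\t", float_format="%.6g")
    proportions.to_csv(files.setdefault("proportions", d / "proportions.tsv"), sep="\t", float_format="%.6g")

    anchors = sorted(
        set(ann.features_with_flag("CAR")) | set(ann.features_with_flag("CD19"))
    )
    candidates = [
        f for f in ann.features_with_flag("membrane") if f in state["fpkm"].data.index
    ]
    anchors = [a for a in anchors if a in state["fpkm"].data.index]
    if anchors and candidates:
        corr = immune.anchor_correlation(state["fpkm"], anchors, candidates, r_min, p_max)
        corr.to_csv(files.setdefault("anchor_correlation", d / "anchor_correlation.tsv"),
                    sep="\t", index=False, float_format="%.6g")

    meta = state["metadata"]
    pairs = {
        pt: (meta.sample_for(pt, "D0"), meta.sample_for(pt, "D14")) for pt in meta.patients
    }
    env_genes = sorted(
        set(ann.features_with_flag("membrane")) & set(state["fpkm"].data.index)
    )
    if env_genes:
        env_panel = immune.MarkerPanel({"membrane": env_genes})
        report = immune.panel_foldchange_report(state["fpkm"], env_panel, pairs, fc_thr)
        report.to_csv(files.setdefault("panel_foldchange", d / "panel_foldchange.tsv"),
                      sep="\t", index=False, float_format="%.6g")

    state.update(cell_scores=scores, proportions=proportions)
    manifest.record("immune", files, {"r_min": r_min, "p_max": p_max, "fc_threshold": fc_thr})


def _run_network(config: PipelineConfig, state: dict, outdir: Path, manifest: _Manifest) -> None:
    p = config.stage_params("network")
    coexpr_r_min = p.get("coexpr_r_min", 0.9)
    min_pathways = p.get("min_pathways", 2)
    significant_fdr = p.get("significant_fdr", 0.05)

    meta = state["metadata"]
    consistent = network.select_consistent_dems(state["dem_tables"], meta.remissive_patients())
    deg_union = set().union(*(set(t["feature_id"]) for t in state["deg_tables"].values()))

    directions: dict[str, str] = {}
    for t in state["deg_tables"].values():
        for f, direc in zip(t["feature_id"], t["direction"]):
            prev = directions.get(f)
            directions[f] = direc if prev in (None, direc) else "mixed"

    net = network.assemble_mirna_tf_gene(
        consistent, state["mirna_targets"], state["tf_targets"], deg_union,
        state["modules"], state["gene_sets"], state["log_expr"], state["annotation"],
        coexpr_r_min=coexpr_r_min, directions=directions,
        mirna_expr=state["tpm"].log2(1.0),
    )
    crosstalk = network.find_crosstalk_nodes(net, min_pathways)

    d = outdir / "network"
    d.mkdir(exist_ok=True)
    files: dict[str, Path] = {}
    net.to_graphml(files.setdefault("mirna_tf_gene_graphml", d / "mirna_tf_gene.graphml"))
    net.to_tsvs(
        files.setdefault("mirna_tf_gene_nodes", d / "mirna_tf_gene_nodes.tsv"),
        files.setdefault("mirna_tf_gene_edges", d / "mirna_tf_gene_edges.tsv"),
    )
    consistent.to_csv(files.setdefault("consistent_dems", d / "consistent_dems.tsv"),
                      sep="\t", index=False)
    pd.Series(crosstalk, name="feature_id").to_csv(
        files.setdefault("crosstalk_nodes", d / "crosstalk_nodes.tsv"), sep="\t", index=False
    )

    # module-centric TF-gene-lncRNA network for the lncRNA-richest module
    modules = state["modules"]
    lnc_counts = {
        label: sum(1 for f in modules.index[modules == label] if f.startswith("L"))
        for label in set(modules) - {"grey"}
    }
    if lnc_counts:
        target_module = max(sorted(lnc_counts), key=lambda k: lnc_counts[k])
        members = modules.index[modules == target_module]
        ann = state["annotation"]
        coding = [f for f in members if ann.table.loc[f, "biotype"] == "coding"]
        lncs = [f for f in members if ann.table.loc[f, "biotype"] == "lncRNA"]
        pairs = coexpression.top_corr_pairs(coding, lncs, state["log_expr"], n_top=200)
        enr = state.get("module_enrichments", {}).get(target_module, pd.DataFrame())
        mod_net = network.assemble_tf_gene_lncrna(
            target_module, modules, pairs, state["tf_targets"], state["gene_sets"],
            enr, ann, significant_fdr=significant_fdr, directions=directions,
        )
        mod_net.to_graphml(
            files.setdefault("tf_gene_lncrna_graphml", d / "tf_gene_lncrna.graphml")
        )
        pairs.to_csv(files.setdefault("top_gene_lncrna_pairs", d / "top_gene_lncrna_pairs.tsv"),
                     sep="\t", index=False, float_format="%.6g")
        state["module_network"] = mod_net

    state.update(network=net, consistent_dems=consistent, crosstalk=crosstalk)
    manifest.record(
        "network", files,
        {"coexpr_r_min": coexpr_r_min, "min_pathways": min_pathways,
         "significant_fdr": significant_fdr},
    )


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "quantify": _run_quantify,
    "de": _run_de,
    "coexpress": _run_coexpress,
    "enrich": _run_enrich,
    "immune": _run_immune,
    "network": _run_network,
}
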