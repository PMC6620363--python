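"""Synthetic paired pre/post cohort generator with planted ground truth.

Emulates the study design the analysis stages assume: a small cohort of
patients sampled at two timepoints (D0 = pre-infusion, D14 = post-infusion)
with bulk bone-marrow gene and miRNA count matrices. The generator plants,
and records in a :class:`SyntheticTruth`:

* co-expression modules — a latent-factor model: per-module eigengene values
  drawn per sample, per-gene loadings, Gaussian noise on the log2 scale;
* differential expression — an additive log2 shift of ``de_log2fc`` at D14
  for a planted fraction of background features, with recorded direction;
* miRNA-mediated repression — targets of planted differential miRNAs receive
  ``mirna_repression_strength`` times the regulator's log2 shift at D14;
* TF→target and miRNA→target regulatory edges;
* cell-type mixtures — marker genes scale linearly with the planted
  per-sample cell-type proportions;
* a CAR transgene feature: zero counts at D0, positive at D14 (high in
  remissive patients, low in the non-remissive one).

Counts are produced by scaling log-normal linear intensities (times feature
length) to a fixed library size and rounding, so FPKM/TPM arithmetic on the
output recovers the latent intensities exactly up to rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .matrix import (
    CartxError,
    ExpressionMatrix,
    FeatureAnnotation,
    SampleMetadata,
)


class ConfigError(CartxError):
    """Raised when a scenario configuration violates its invariants."""


class CellType(NamedTuple):
    """A simulated cell population: name, marker count, per-sample proportions.

    ``proportions`` is ordered like the generated samples
    (patient 1 D0, patient 1 D14, patient 2 D0, ...).
    """

    name: str
    n_markers: int
    proportions: tuple[float, ...]


#: Default per-sample proportions for 4 patients x 2 timepoints, ordered
#: (P1-D0, P1-D14, P2-D0, P2-D14, P3-D0, P3-D14, P4-D0, P4-D14).
#: The mixtures follow a cyclically balanced design over the profile
#: (0.6, 0.3, 0.1): every population spans the same dynamic range across the
#: cohort, which is the regime z-score-based marker scoring is calibrated
#: for, and remissive patients (P1, P4) show the B-cell collapse with
#: cytotoxic expansion at D14 while the non-remissive patient (P2) stays
#: B-cell dominated post infusion.
DEFAULT_CELL_TYPES: tuple[CellType, ...] = (
    CellType("B_cell", 10, (0.60, 0.10, 0.30, 0.60, 0.10, 0.30, 0.60, 0.10)),
    CellType("CD8_T", 10, (0.30, 0.60, 0.10, 0.30, 0.60, 0.10, 0.30, 0.60)),
    CellType("NK", 10, (0.10, 0.30, 0.60, 0.10, 0.30, 0.60, 0.10, 0.30)),
)

TIMEPOINTS = ("D0", "D14")

CAR_FEATURE_ID = "CAR-transgene"
MIRNA_LENGTH_BP = 22


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic cohort.

    The defaults mirror the study shape the analysis was designed around:
    4 patients (3 remissive, 1 non-remissive) sampled at D0 and D14, five
    planted co-expression modules of 100 features each, 10% of background
    features differentially expressed with a log2 fold change of 2, and
    three immune cell populations with 10 markers each.
    """

    n_patients: int = 4
    remission_labels: tuple[str, ...] = ("R", "NR", "R", "R")
    n_coding: int = 800
    n_lncrna: int = 100
    n_tf: int = 60
    n_histone: int = 30
    n_membrane: int = 60
    n_mirna: int = 150
    n_modules: int = 5
    module_sizes: tuple[int, ...] = (100, 100, 100, 100, 100)
    eigengene_sd: float = 1.0
    loading_range: tuple[float, float] = (0.7, 1.0)
    #: draw loading signs at random (unsigned-module structure with
    #: anti-correlated halves; keeps module linear-scale mass nearly constant
    #: across samples). Disable for strictly positively correlated modules.
    signed_loadings: bool = True
    noise_sd: float = 0.1
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    mirna_repression_strength: float = -0.5
    cell_types: tuple[CellType, ...] = DEFAULT_CELL_TYPES
    gene_length_range: tuple[int, int] = (500, 5000)
    library_size: int = 5_000_000
    seed: int = 1

    @property
    def n_samples(self) -> int:
        return self.n_patients * len(TIMEPOINTS)

    @property
    def patients(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_patients)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{p}-{t}" for p in self.patients for t in TIMEPOINTS]

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("need at least 2 patients")
        if len(self.remission_labels) != self.n_patients:
            raise ConfigError("remission_labels length must equal n_patients")
        if set(self.remission_labels) - {"R", "NR"}:
            raise ConfigError("remission labels must be 'R' or 'NR'")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes length must equal n_modules")
        if any(s < 2 for s in self.module_sizes):
            raise ConfigError("module sizes must be >= 2")
        if sum(self.module_sizes) > self.n_coding + self.n_lncrna:
            raise ConfigError(
                f"module sizes sum to {sum(self.module_sizes)} but only "
                f"{self.n_coding + self.n_lncrna} gene features exist"
            )
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must be in [0, 1]")
        if self.de_log2fc <= 0:
            raise ConfigError("de_log2fc must be positive")
        if self.mirna_repression_strength > 0:
            raise ConfigError("mirna_repression_strength must be non-positive")
        if self.eigengene_sd <= 0:
            raise ConfigError("eigengene_sd must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        if self.gene_length_range[0] < 1 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ConfigError("invalid gene_length_range")
        n_samples = self.n_samples
        props = np.array([ct.proportions for ct in self.cell_types], dtype=float)
        if props.shape != (len(self.cell_types), n_samples):
            raise ConfigError(
                f"each cell type needs {n_samples} proportions (one per sample)"
            )
        if (props < 0).any() or (props > 1).any():
            raise ConfigError("cell-type proportions must lie in [0, 1]")
        if not np.allclose(props.sum(axis=0), 1.0, atol=1e-9):
            raise ConfigError("per-sample cell-type proportions must sum to 1")
        n_markers = sum(ct.n_markers for ct in self.cell_types)
        if sum(self.module_sizes) + n_markers > self.n_coding + self.n_lncrna:
            raise ConfigError("modules plus markers exceed available gene features")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort.

    ``module_of`` maps every gene-level feature to its planted module label
    (``grey`` = unstructured background). ``de_direction`` records the planted
    shift direction per (patient, feature) for genes and miRNAs; features
    absent from the map are non-DE. Edge lists hold the planted regulatory
    couplings, and ``true_proportions`` the per-sample cell-type mixture.
    """

    module_of: dict[str, str]
    de_direction: dict[tuple[str, str], str]
    tf_target_edges: list[tuple[str, str]]
    mirna_target_edges: list[tuple[str, str]]
    true_proportions: pd.DataFrame  # samples x cell types

    def module_labels(self) -> list[str]:
        labels = sorted({m for m in self.module_of.values() if m != "grey"})
        return labels

    def module_members(self, label: str) -> list[str]:
        return sorted(f for f, m in self.module_of.items() if m == label)

    def de_features(self, patient: str) -> dict[str, str]:
        """Planted direction map (feature -> up/down) for one patient."""
        return {f: d for (p, f), d in self.de_direction.items() if p == patient}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        mod = pd.DataFrame(
            {"feature_id": list(self.module_of), "module": list(self.module_of.values())}
        ).sort_values("feature_id")
        paths["true_modules"] = out_dir / "true_modules.tsv"
        mod.to_csv(paths["true_modules"], sep="\t", index=False)

        de = pd.DataFrame(
            [(p, f, d) for (p, f), d in sorted(self.de_direction.items())],
            columns=["patient", "feature_id", "direction"],
        )
        paths["true_de"] = out_dir / "true_de.tsv"
        de.to_csv(paths["true_de"], sep="\t", index=False)

        for name, edges in (
            ("true_tf_targets", self.tf_target_edges),
            ("true_mirna_targets", self.mirna_target_edges),
        ):
            df = pd.DataFrame(sorted(edges), columns=["regulator", "target"])
            paths[name] = out_dir / f"{name}.tsv"
            df.to_csv(paths[name], sep="\t", index=False)

        paths["true_proportions"] = out_dir / "true_proportions.tsv"
        out = self.true_proportions.copy()
        out.index.name = "sample_id"
        out.to_csv(paths["true_proportions"], sep="\t")
        return paths


def _gene_ids(config: ScenarioConfig) -> tuple[list[str], list[str], list[str]]:
    coding = [f"G{i + 1:04d}" for i in range(config.n_coding)]
    lncrna = [f"L{i + 1:04d}" for i in range(config.n_lncrna)]
    mirna = [f"mir-{i + 1:03d}" for i in range(config.n_mirna)]
    return coding, lncrna, mirna


def generate_cohort(
    config: ScenarioConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, FeatureAnnotation, SampleMetadata, SyntheticTruth]:
    """Generate one synthetic cohort.

    Returns ``(counts, mirna_counts, annotation, metadata, truth)``. The same
    ``config`` (including its seed) always reproduces identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    coding, lncrna, mirna_ids = _gene_ids(config)
    samples = config.sample_ids
    patients = config.patients
    n_samples = config.n_samples
    d14_mask = np.array([s.endswith("D14") for s in samples])

    # ---- feature layout -------------------------------------------------
    # modules: ~90% coding, ~10% lncRNA per module, taken sequentially
    module_of: dict[str, str] = {}
    cod_ptr = 0
    lnc_ptr = 0
    module_names = [f"M{i + 1}" for i in range(config.n_modules)]
    for name, size in zip(module_names, config.module_sizes):
        n_lnc = min(size // 10, config.n_lncrna - lnc_ptr)
        n_cod = size - n_lnc
        for g in coding[cod_ptr : cod_ptr + n_cod]:
            module_of[g] = name
        for g in lncrna[lnc_ptr : lnc_ptr + n_lnc]:
            module_of[g] = name
        cod_ptr += n_cod
        lnc_ptr += n_lnc

    # markers come from the coding pool, after module members
    marker_of: dict[str, str] = {}
    for ct in config.cell_types:
        take = coding[cod_ptr : cod_ptr + ct.n_markers]
        if len(take) < ct.n_markers:
            raise ConfigError(f"not enough coding genes for markers of {ct.name}")
        for g in take:
            marker_of[g] = ct.name
        cod_ptr += ct.n_markers

    for g in coding + lncrna:
        module_of.setdefault(g, "grey")

    # planted DE features: background (non-module, non-marker) genes,
    # 80% coding / 20% lncRNA to mirror a coding-dominant DEG pool
    free_coding = coding[cod_ptr:]
    free_lncrna = lncrna[lnc_ptr:]
    n_de = round(config.de_fraction * (config.n_coding + config.n_lncrna))
    n_de_cod = min(math.ceil(0.8 * n_de), len(free_coding))
    n_de_lnc = min(n_de - n_de_cod, len(free_lncrna))
    if n_de_cod + n_de_lnc < n_de:
        raise ConfigError("not enough background features for the requested de_fraction")
    de_genes = free_coding[:n_de_cod] + free_lncrna[:n_de_lnc]
    de_sign = {g: (1 if rng.random() < 0.5 else -1) for g in de_genes}

    # miRNAs: first few are constitutively dominant (let-7-like); DE miRNAs
    # drawn from the rest with a shared direction across patients
    n_dominant = min(8, config.n_mirna)
    n_de_mir = round(config.de_fraction * config.n_mirna)
    de_mirnas = list(mirna_ids[n_dominant : n_dominant + n_de_mir])
    if len(de_mirnas) < n_de_mir:
        raise ConfigError("not enough miRNAs for the requested de_fraction")
    mir_sign = {m: (1 if rng.random() < 0.5 else -1) for m in de_mirnas}

    # repression targets: background coding genes untouched by planted DE
    target_pool = free_coding[n_de_cod:]
    mirna_target_edges: list[tuple[str, str]] = []
    for m in de_mirnas:
        if not target_pool:
            break
        k = int(rng.integers(2, 6))
        k = min(k, len(target_pool))
        targets = sorted(rng.choice(target_pool, size=k, replace=False))
        mirna_target_edges.extend((m, t) for t in targets)
    mirna_targets_of = _group_edges(mirna_target_edges)

    # TF flags: a slice of DE coding genes, a couple of miRNA-coupled targets
    # (so TF nodes can sit inside the assembled miRNA network), a few module
    # genes, rest background
    tf_flags: set[str] = set()
    n_tf_de = min(max(1, round(0.05 * n_de_cod)), len(free_coding[:n_de_cod]))
    tf_flags.update(free_coding[:n_tf_de])
    coupled_targets = sorted({t for _, t in mirna_target_edges})
    tf_flags.update(coupled_targets[: min(2, len(coupled_targets))])
    remaining_tf = config.n_tf - len(tf_flags)
    module_coding = [g for g in coding if module_of[g] != "grey"]
    n_tf_mod = min(max(remaining_tf // 2, 0), len(module_coding))
    tf_flags.update(module_coding[:n_tf_mod])
    still = config.n_tf - len(tf_flags)
    extra_pool = [g for g in target_pool if g not in tf_flags]
    tf_flags.update(extra_pool[: max(0, still)])

    # TF->target edges: DE TFs regulate other DE genes; coupled-target TFs
    # regulate other miRNA-coupled targets
    tf_target_edges: list[tuple[str, str]] = []
    de_tfs = sorted(tf_flags & set(de_genes))
    other_de = [g for g in de_genes if g not in tf_flags]
    for tf in de_tfs:
        if not other_de:
            break
        k = min(int(rng.integers(2, 5)), len(other_de))
        targets = sorted(rng.choice(other_de, size=k, replace=False))
        tf_target_edges.extend((tf, t) for t in targets)
    for tf in sorted(tf_flags & set(coupled_targets)):
        pool = [g for g in coupled_targets if g != tf and g not in tf_flags]
        if not pool:
            continue
        k = min(int(rng.integers(1, 4)), len(pool))
        targets = sorted(rng.choice(pool, size=k, replace=False))
        tf_target_edges.extend((tf, t) for t in targets)

    # histone flags concentrate in the first module (planted class enrichment)
    if module_names:
        first_module_coding = [g for g in coding if module_of[g] == module_names[0]]
    else:
        first_module_coding = []
    histone_flags = set(first_module_coding[: config.n_histone])
    if len(histone_flags) < config.n_histone:
        spill = [g for g in module_coding + extra_pool if g not in histone_flags]
        histone_flags.update(spill[: config.n_histone - len(histone_flags)])

    # membrane flags on background coding genes (disjoint from markers)
    membrane_pool = [g for g in free_coding if g not in marker_of]
    membrane_flags = set(membrane_pool[: config.n_membrane])

    # ---- expression model (log2 scale) ----------------------------------
    genes = coding + lncrna
    n_genes = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    base = rng.normal(4.0, 1.5, size=n_genes)
    X = np.tile(base[:, None], (1, n_samples))

    # module factor: eigengene profiles drawn per sample, then mean-centred
    # and orthogonalised across samples so planted modules are empirically
    # uncorrelated (requires n_modules < n_samples); DE truth is unaffected
    # because planted DE features are background genes
    if config.n_modules >= n_samples - 1:
        raise ConfigError("n_modules must be smaller than the sample count minus one")
    # factors are additionally orthogonalised against the D0/D14 contrast:
    # module structure is planted independently of the condition response,
    # which carries the separately planted DE shifts
    contrast = d14_mask.astype(float)[None, :]
    eigengene = _orthogonal_factors(
        np.vstack([contrast, rng.normal(0.0, 1.0, size=(config.n_modules, n_samples))]),
        config.eigengene_sd,
    )[1:]
    # loadings carry random signs: unsigned-module structure (anti-correlated
    # halves), which also keeps each module's total linear-scale mass nearly
    # constant across samples so planted factors do not masquerade as
    # library-composition shifts
    loadings = rng.uniform(*config.loading_range, size=n_genes)
    if config.signed_loadings:
        loadings *= rng.choice([-1.0, 1.0], size=n_genes)
    patient_of_sample = np.repeat(np.arange(config.n_patients), len(TIMEPOINTS))
    for g, m in module_of.items():
        if m == "grey":
            continue
        mi = module_names.index(m)
        X[gene_index[g]] += loadings[gene_index[g]] * eigengene[mi]

    # planted DE shift at D14 (all patients, shared direction)
    for g, s in de_sign.items():
        X[gene_index[g], d14_mask] += s * config.de_log2fc

    # miRNA-mediated repression: coupling to the regulator's planted D14 shift
    for m, targets in mirna_targets_of.items():
        shift = config.mirna_repression_strength * mir_sign[m] * config.de_log2fc
        for t in targets:
            X[gene_index[t], d14_mask] += shift

    X += rng.normal(0.0, config.noise_sd, size=X.shape)

    # linear intensities; markers scale linearly with cell-type proportions
    Y = np.power(2.0, X)
    prop = np.array([ct.proportions for ct in config.cell_types], dtype=float)
    ct_index = {ct.name: i for i, ct in enumerate(config.cell_types)}
    for g, ct_name in marker_of.items():
        Y[gene_index[g]] *= prop[ct_index[ct_name]]

    # CAR transgene row: zero at D0; positive at D14, high in remissive patients
    car_level = np.zeros(n_samples)
    for si, s in enumerate(samples):
        if s.endswith("D14"):
            p = patient_of_sample[si]
            car_level[si] = 2.0 ** (8.0 if config.remission_labels[p] == "R" else 5.0)
    genes_all = genes + [CAR_FEATURE_ID]
    Y = np.vstack([Y, car_level[None, :]])
    module_of[CAR_FEATURE_ID] = "grey"

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=len(genes_all)
    )

    counts = _scale_to_counts(Y, lengths.astype(float), config.library_size)
    counts_df = pd.DataFrame(counts, index=genes_all, columns=samples)

    # ---- miRNA matrix ----------------------------------------------------
    mir_base = rng.normal(5.0, 1.5, size=config.n_mirna)
    mir_base[:n_dominant] += 6.0  # a handful of dominant species carry most reads
    Xm = np.tile(mir_base[:, None], (1, n_samples))
    for m, s in mir_sign.items():
        Xm[mirna_ids.index(m), d14_mask] += s * config.de_log2fc
    Xm += rng.normal(0.0, config.noise_sd, size=Xm.shape)
    Ym = np.power(2.0, Xm)
    mir_lengths = np.full(config.n_mirna, float(MIRNA_LENGTH_BP))
    mir_counts = _scale_to_counts(Ym, np.ones(config.n_mirna), config.library_size)
    mirna_df = pd.DataFrame(mir_counts, index=mirna_ids, columns=samples)

    # ---- annotation ------------------------------------------------------
    ann_rows = []
    for i, g in enumerate(genes_all):
        flags = []
        if g in tf_flags:
            flags.append("TF")
        if g in histone_flags:
            flags.append("histone")
        if g in membrane_flags:
            flags.append("membrane")
        if g == CAR_FEATURE_ID:
            flags.append("CAR")
        biotype = "coding"
        if g.startswith("L"):
            biotype = "lncRNA"
        symbol = g
        if g == CAR_FEATURE_ID:
            symbol = "CAR"
        ann_rows.append(
            {
                "feature_id": g,
                "symbol": symbol,
                "biotype": biotype,
                "length_bp": int(lengths[i]),
                "flags": ",".join(flags),
                "marker_of": marker_of.get(g, ""),
            }
        )
    # CD19: first B-cell marker doubles as the antigen gene
    b_markers = [g for g, c in marker_of.items() if c == config.cell_types[0].name]
    if b_markers:
        cd19 = sorted(b_markers)[0]
        for row in ann_rows:
            if row["feature_id"] == cd19:
                row["flags"] = ",".join(filter(None, [row["flags"], "CD19"]))
                row["symbol"] = "CD19"
    for i, m in enumerate(mirna_ids):
        ann_rows.append(
            {
                "feature_id": m,
                "symbol": m,
                "biotype": "miRNA",
                "length_bp": MIRNA_LENGTH_BP,
                "flags": "",
                "marker_of": "",
            }
        )
    annotation = FeatureAnnotation(pd.DataFrame(ann_rows).set_index("feature_id"))

    # ---- metadata and truth ---------------------------------------------
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "patient": [s.rsplit("-", 1)[0] for s in samples],
            "timepoint": [s.rsplit("-", 1)[1] for s in samples],
            "remission": [
                config.remission_labels[patient_of_sample[i]] for i in range(n_samples)
            ],
        }
    ).set_index("sample_id")
    metadata = SampleMetadata(meta)

    de_direction: dict[tuple[str, str], str] = {}
    for p in patients:
        for g, s in de_sign.items():
            de_direction[(p, g)] = "up" if s > 0 else "down"
        for m, s in mir_sign.items():
            de_direction[(p, m)] = "up" if s > 0 else "down"

    true_prop = pd.DataFrame(
        prop.T, index=samples, columns=[ct.name for ct in config.cell_types]
    )

    truth = SyntheticTruth(
        module_of=module_of,
        de_direction=de_direction,
        tf_target_edges=sorted(tf_target_edges),
        mirna_target_edges=sorted(mirna_target_edges),
        true_proportions=true_prop,
    )

    return (
        ExpressionMatrix(counts_df, "raw_count"),
        ExpressionMatrix(mirna_df, "raw_count"),
        annotation,
        metadata,
        truth,
    )


def _orthogonal_factors(E: np.ndarray, sd: float) -> np.ndarray:
    """Mean-centre rows, Gram-Schmidt orthogonalise, rescale to sample sd ``sd``.

    Centred vectors stay centred under Gram-Schmidt, so the result has
    zero-mean, mutually uncorrelated rows with unit-free sample sd ``sd``.
    """
    n_factors, n = E.shape
    out = np.empty_like(E)
    for i in range(n_factors):
        v = E[i] - E[i].mean()
        for j in range(i):
            v = v - np.dot(v, out[j]) / np.dot(out[j], out[j]) * out[j]
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            raise ConfigError("degenerate factor draw; use fewer modules or more samples")
        out[i] = v / norm * np.sqrt(n - 1) * sd
    return out


def _scale_to_counts(Y: np.ndarray, lengths: np.ndarray, library_size: int) -> np.ndarray:
    """Scale linear intensities to integer counts at a fixed library size.

    Counts are proportional to intensity x length, so FPKM computed from the
    output recovers the intensity scale.
    """
    weighted = Y * lengths[:, None]
    totals = weighted.sum(axis=0)
    totals[totals == 0] = 1.0
    return np.rint(weighted / totals * library_size)


def _group_edges(edges: Sequence[tuple[str, str]]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for r, t in edges:
        out.setdefault(r, []).append(t)
    return out


def generate_edge_tables(
    config: ScenarioConfig,
    truth: SyntheticTruth,
    decoy_fraction: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regulator→target tables: all planted edges plus decoys.

    Decoy edges use real regulators but point at features that are not
    planted targets of any regulator of that class, so truth recovery stays
    unambiguous. ``round(decoy_fraction * n_true)`` decoys are added per
    table. Returns ``(tf_targets, mirna_targets)`` DataFrames with columns
    ``regulator`` and ``target``.
    """
    if decoy_fraction < 0:
        raise ConfigError("decoy_fraction must be >= 0")
    rng = np.random.default_rng(config.seed + 104729)
    coding, _, mirna_ids = _gene_ids(config)

    def build(edges: list[tuple[str, str]], regulators: list[str]) -> pd.DataFrame:
        n_decoy = round(decoy_fraction * len(edges))
        coupled = {t for _, t in edges}
        pool = [g for g in coding if g not in coupled]
        decoys: set[tuple[str, str]] = set()
        existing = set(edges)
        while len(decoys) < n_decoy and pool and regulators:
            r = regulators[int(rng.integers(len(regulators)))]
            t = pool[int(rng.integers(len(pool)))]
            if (r, t) not in existing and (r, t) not in decoys:
                decoys.add((r, t))
        rows = sorted(set(edges) | decoys)
        return pd.DataFrame(rows, columns=["regulator", "target"])

    tf_regs = sorted({r for r, _ in truth.tf_target_edges})
    mir_regs = sorted({r for r, _ in truth.mirna_target_edges}) or mirna_ids
    tf_df = build(list(truth.tf_target_edges), tf_regs)
    mir_df = build(list(truth.mirna_target_edges), mir_regs)
    return tf_df, mir_df


def generate_gene_sets(
    config: ScenarioConfig,
    truth: SyntheticTruth,
    overlap: float = 0.8,
    n_random: int = 5,
    random_set_size: int = 30,
):
    """Gene-set collection with module-derived pathways plus random sets.

    One pathway per planted module, constructed to have Jaccard index
    ``overlap`` with the module's member list (members needed to dilute the
    set are drawn from non-module features), plus ``n_random`` random
    background sets. Module-derived sets carry category ``KEGG``; random
    sets carry ``GO-BP``.
    """
    from .enrichment import GeneSetCollection

    if not 0.0 <= overlap <= 1.0:
        raise ConfigError("overlap must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 7919)
    coding, lncrna, _ = _gene_ids(config)
    all_genes = coding + lncrna

    sets: dict[str, tuple[str, list[str]]] = {}
    for label in truth.module_labels():
        members = truth.module_members(label)
        size = len(members)
        # |A∩B| = k with |A| = |B| = size gives J = k / (2*size - k)
        k = round(2 * size * overlap / (1 + overlap)) if overlap > 0 else 0
        k = min(k, size)
        outside = [g for g in all_genes if truth.module_of.get(g, "grey") != label]
        n_extra = size - k
        if n_extra > len(outside):
            raise ConfigError(f"cannot build overlap-{overlap} set for module {label}")
        core = members[:k]
        extra = sorted(rng.choice(outside, size=n_extra, replace=False)) if n_extra else []
        sets[f"PW_{label}"] = ("KEGG", sorted(core + list(extra)))

    background_pool = [g for g in all_genes if truth.module_of.get(g, "grey") == "grey"]
    for i in range(n_random):
        size = min(random_set_size, len(background_pool))
        members = sorted(rng.choice(background_pool, size=size, replace=False))
        sets[f"BP_random_{i + 1}"] = ("GO-BP", members)

    return GeneSetCollection(sets)
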