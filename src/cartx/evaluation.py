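"""Scoring of analysis output against planted synthetic truth.

These helpers define, once, how recovery of the generator's ground truth is
measured:

* module recovery — adjusted Rand index between detected and planted module
  labels, computed over the features the truth assigns to a (non-grey)
  planted module. Background features are excluded because how unstructured
  features fragment under average linkage is not part of the planted module
  signal.
* DE recovery — sensitivity and false-discovery proportion of called
  features against the planted DE map, over background features. Features
  whose expression moves for reasons other than the planted DE shift —
  planted module members (sample-level factor variation, which a
  no-replicate fold-change caller cannot separate from condition response),
  cell-type markers (composition driven), the CAR transgene, and
  miRNA-repression targets (coupling driven) — are excluded from both
  sides of the comparison; they are real planted signal, but of a
  different kind, and are scored by their own checks.
* proportion recovery — mean absolute error per sample between estimated
  and planted cell-type proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .matrix import FeatureAnnotation
from .simulate import CAR_FEATURE_ID, SyntheticTruth


def score_module_recovery(assignment: pd.Series, truth: SyntheticTruth) -> float:
    """Adjusted Rand index over the truth's planted-module features."""
    planted = [
        f for f, m in truth.module_of.items() if m != "grey" and f in assignment.index
    ]
    if not planted:
        return float("nan")
    true_labels = [truth.module_of[f] for f in planted]
    found_labels = [assignment[f] for f in planted]
    return float(adjusted_rand_score(true_labels, found_labels))


@dataclass
class DERecovery:
    sensitivity: float
    fdp: float
    n_true: int
    n_called: int
    n_true_positive: int


def score_de_recovery(
    table: pd.DataFrame,
    truth: SyntheticTruth,
    patient: str,
    annotation: FeatureAnnotation,
    biotypes: tuple[str, ...] = ("coding", "lncRNA"),
) -> DERecovery:
    """Sensitivity and FDP of one patient's DE calls vs the planted truth.

    Only features of the given biotypes enter the comparison; markers, the
    CAR transgene and miRNA-coupled targets are excluded from both the
    truth and the call set (see module docstring).
    """
    excluded = set(annotation.table.index[annotation.table["marker_of"] != ""])
    excluded.add(CAR_FEATURE_ID)
    excluded.update(t for _, t in truth.mirna_target_edges)
    excluded.update(f for f, m in truth.module_of.items() if m != "grey")

    eligible_biotype = set(
        annotation.table.index[annotation.table["biotype"].isin(biotypes)]
    )
    true_de = {
        f
        for f, d in truth.de_features(patient).items()
        if f in eligible_biotype and f not in excluded
    }
    called = {
        f
        for f in table["feature_id"]
        if f in eligible_biotype and f not in excluded
    }
    tp = len(called & true_de)
    sens = tp / len(true_de) if true_de else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return DERecovery(sens, fdp, len(true_de), len(called), tp)


def score_proportion_recovery(
    estimated: pd.DataFrame, truth: SyntheticTruth
) -> pd.Series:
    """Per-sample mean absolute error of estimated cell-type proportions."""
    true = truth.true_proportions.loc[estimated.index, estimated.columns]
    return (estimated - true).abs().mean(axis=1)
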