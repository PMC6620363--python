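"""Paired no-replicate differential expression and PLS-DA discrimination.

With one sample per patient per timepoint there is no dispersion to
estimate, so DE calling is fold-change based: a feature is called when its
pseudocount-regularised |log2 fold change| (post over pre) reaches
``min_abs_log2fc`` and it is expressed (``max(pre, post)`` strictly above an
expression floor — FPKM 1 for genes, TPM 10 for miRNAs by convention).

PLS-DA fits partial least squares to a one-hot class response and scores
features by VIP (variable importance in projection):

    VIP_j = sqrt( p * sum_a [ SS_a * (w_aj / ||w_a||)^2 ] / sum_a SS_a )

with ``p`` the number of features, ``w_a`` the X-weights of component ``a``
and ``SS_a`` the response variance explained by component ``a``. The
formula implies mean(VIP^2) = 1 over features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .matrix import CartxError, ExpressionMatrix, FeatureAnnotation
from .quantify import EXPRESSED_THRESHOLD

DEFAULT_PSEUDOCOUNT = 0.1


def log2_fold_change(pre: float, post: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((post + pseudocount) / (pre + pseudocount))."""
    if pre < 0 or post < 0:
        raise CartxError("expression values must be non-negative")
    if pseudocount <= 0:
        raise CartxError("pseudocount must be positive")
    return float(np.log2((post + pseudocount) / (pre + pseudocount)))


def call_features(
    pre_matrix: ExpressionMatrix,
    post_matrix: ExpressionMatrix,
    min_abs_log2fc: float = 1.0,
    min_expression: float | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    patient: str = "",
) -> pd.DataFrame:
    """Call DE features between one pre and one post sample.

    Both matrices must carry the same unit and exactly one sample column.
    Returns a table with columns ``patient, feature_id, log2fc, direction,
    pre, post`` holding every feature with ``|log2fc| >= min_abs_log2fc``
    and ``max(pre, post) > min_expression``.
    """
    if pre_matrix.unit != post_matrix.unit:
        raise CartxError(
            f"unit mismatch: pre is {pre_matrix.unit!r}, post is {post_matrix.unit!r}"
        )
    if pre_matrix.n_samples != 1 or post_matrix.n_samples != 1:
        raise CartxError("call_features expects one sample column per matrix (paired design)")
    if pre_matrix.feature_ids != post_matrix.feature_ids:
        raise CartxError("pre and post matrices must share the same features in order")
    if min_expression is None:
        min_expression = EXPRESSED_THRESHOLD.get(pre_matrix.unit, 0.0)

    pre = pre_matrix.data.iloc[:, 0].astype(float)
    post = post_matrix.data.iloc[:, 0].astype(float)
    lfc = np.log2((post + pseudocount) / (pre + pseudocount))
    expressed = np.maximum(pre, post) > min_expression
    called = (lfc.abs() >= min_abs_log2fc) & expressed

    out = pd.DataFrame(
        {
            "patient": patient,
            "feature_id": pre.index[called],
            "log2fc": lfc[called].values,
            "direction": np.where(lfc[called] > 0, "up", "down"),
            "pre": pre[called].values,
            "post": post[called].values,
        }
    ).reset_index(drop=True)
    return out


def call_features_per_patient(
    matrix: ExpressionMatrix,
    metadata,
    min_abs_log2fc: float = 1.0,
    min_expression: float | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    pre_timepoint: str = "D0",
    post_timepoint: str = "D14",
) -> dict[str, pd.DataFrame]:
    """Run :func:`call_features` for every patient in the metadata table."""
    tables = {}
    for p in metadata.patients:
        pre_s = metadata.sample_for(p, pre_timepoint)
        post_s = metadata.sample_for(p, post_timepoint)
        tables[p] = call_features(
            matrix.subset_samples([pre_s]),
            matrix.subset_samples([post_s]),
            min_abs_log2fc=min_abs_log2fc,
            min_expression=min_expression,
            pseudocount=pseudocount,
            patient=p,
        )
    return tables


def intersect_common(
    tables: dict[str, pd.DataFrame], patients: list[str] | None = None
) -> tuple[set[str], set[str]]:
    """Common DE features across patients and the same-trend subset.

    ``common`` is the intersection of called feature sets over the selected
    patients; ``same_trend`` keeps only those whose direction agrees in
    every selected patient.
    """
    if patients is None:
        patients = list(tables)
    unknown = [p for p in patients if p not in tables]
    if unknown:
        raise CartxError(f"unknown patient name(s): {unknown}")
    if len(patients) < 2:
        raise CartxError("need at least 2 patients to intersect")

    feature_sets = []
    directions = []
    for p in patients:
        t = tables[p]
        feature_sets.append(set(t["feature_id"]))
        directions.append(dict(zip(t["feature_id"], t["direction"])))
    common = set.intersection(*feature_sets)
    same_trend = {
        f for f in common if len({d[f] for d in directions}) == 1
    }
    return common, same_trend


@dataclass
class DEGClassSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    empty: bool


def summarize_deg_classes(table: pd.DataFrame, annotation: FeatureAnnotation) -> DEGClassSummary:
    """Per-class composition of a DE table: coding, TF, lncRNA, up-fraction."""
    features = list(table["feature_id"]) if len(table) else []
    missing = [f for f in features if f not in annotation.table.index]
    if missing:
        raise CartxError(f"unannotated feature(s) in DE table: {missing[:5]}")
    total = len(features)
    if total == 0:
        zero = {"total": 0, "coding": 0, "TF": 0, "lncRNA": 0, "up": 0}
        return DEGClassSummary(zero, {k: 0.0 for k in zero}, empty=True)
    sub = annotation.table.loc[features]
    n_coding = int((sub["biotype"] == "coding").sum())
    n_lnc = int((sub["biotype"] == "lncRNA").sum())
    n_tf = int(annotation.has_flag("TF").loc[features].sum())
    n_up = int((table["direction"] == "up").sum())
    counts = {"total": total, "coding": n_coding, "TF": n_tf, "lncRNA": n_lnc, "up": n_up}
    fractions = {k: v / total for k, v in counts.items()}
    return DEGClassSummary(counts, fractions, empty=False)


def plsda_vip(
    matrix: ExpressionMatrix, labels: dict[str, str] | pd.Series, n_components: int = 2
) -> pd.DataFrame:
    """PLS-DA on samples with one-hot class response; VIP-ranked features.

    Features are centred and unit-variance scaled before the fit (constant
    features are dropped with a warning). Returns a table with columns
    ``feature_id, vip, rank`` sorted by VIP descending (ties broken by
    feature id ascending).
    """
    labels = pd.Series(labels).loc[matrix.sample_ids]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise CartxError("need at least 2 classes for PLS-DA")
    counts = labels.value_counts()
    single = sorted(counts.index[counts < 2])
    if single:
        raise CartxError(f"class(es) with a single sample: {single}")
    if n_components < 1:
        raise CartxError("n_components must be >= 1")
    max_comp = min(matrix.n_samples - 1, matrix.n_features)
    if n_components > max_comp:
        raise CartxError(f"n_components must be <= {max_comp}")

    X = matrix.data.T.values  # samples x features
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}")
    feats = [f for f, k in zip(matrix.feature_ids, keep) if k]
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Y = np.stack([(labels.values == c).astype(float) for c in classes], axis=1)

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)

    W = pls.x_weights_  # (n_features, n_components)
    T = pls.x_scores_  # (n_samples, n_components)
    Q = pls.y_loadings_  # (n_targets, n_components)
    # response variance explained by each component
    ss = (Q**2).sum(axis=0) * (T**2).sum(axis=0)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    p = len(feats)
    vip = np.sqrt(p * ((W**2 / wnorm2) @ ss) / ss.sum())

    out = pd.DataFrame({"feature_id": feats, "vip": vip})
    out = out.sort_values(["vip", "feature_id"], ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
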