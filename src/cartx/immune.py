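"""Marker-based immune profiling of bulk expression.

Cell-type abundance is scored per sample as the mean, over the type's
marker genes, of the per-feature z-score of log2(expression + pseudocount)
across samples. Scores are converted to a display proportion table by
shifting each sample's scores to zero minimum and renormalising; raw scores
are always retained. The module also screens membrane-protein genes for
correlation with anchor features (the CAR transgene and the CD19 antigen)
and reports microenvironment panel genes whose paired fold change exceeds a
threshold.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpression import pearson_with_p
from .matrix import CartxError, ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 0.1

#: Microenvironment gene-panel categories.
MICROENVIRONMENT_CATEGORIES = (
    "chemokine", "immunostimulator", "IL/ILR", "IFNR", "GF/GFR",
    "TNF/TNFR", "TLR", "MMP/IMP",
)


@dataclass
class MarkerPanel:
    """Groups of feature ids: cell types -> markers, or panel categories -> genes.

    A feature may belong to only one group.
    """

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for group, members in self.groups.items():
            if not members:
                raise CartxError(f"group {group!r} is empty")
            for m in members:
                if m in seen:
                    raise CartxError(
                        f"feature {m!r} assigned to both {seen[m]!r} and {group!r}"
                    )
                seen[m] = group

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"group": g, "feature_id": m}
            for g, members in self.groups.items()
            for m in members
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t")
        groups: dict[str, list[str]] = {}
        for g, m in zip(df.iloc[:, 0], df.iloc[:, 1]):
            groups.setdefault(str(g), []).append(str(m))
        return cls(groups)

    @classmethod
    def from_annotation(cls, annotation) -> "MarkerPanel":
        """Cell-type panel from the ``marker_of`` annotation column."""
        groups: dict[str, list[str]] = {}
        sub = annotation.table[annotation.table["marker_of"] != ""]
        for fid, ct in zip(sub.index, sub["marker_of"]):
            groups.setdefault(ct, []).append(fid)
        return cls(groups)


def cell_scores(
    expr: ExpressionMatrix,
    panel: MarkerPanel,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Marker-mean z-scores per sample and cell type (samples x cell types)."""
    log = np.log2(expr.data + pseudocount)
    mu = log.mean(axis=1)
    sd = log.std(axis=1, ddof=1)
    z = log.sub(mu, axis=0)
    nonconstant = sd > 0
    z.loc[nonconstant] = z.loc[nonconstant].div(sd[nonconstant], axis=0)
    z.loc[~nonconstant] = 0.0

    scores = {}
    for ct, markers in panel.groups.items():
        present = [m for m in markers if m in z.index]
        if not present:
            raise CartxError(f"cell type {ct!r} has no markers present in the matrix")
        scores[ct] = z.loc[present].mean(axis=0)
    out = pd.DataFrame(scores)
    out.index.name = "sample_id"
    return out


def scores_to_proportions(scores: pd.DataFrame) -> pd.DataFrame:
    """Min-shift scores to a per-sample proportion table (display convention).

    Per sample, subtract the minimum score across cell types and divide by
    the total; a sample whose shifted scores are all zero gets uniform
    proportions with a warning.
    """
    if scores.shape[1] < 1:
        raise CartxError("need at least one cell type")
    shifted = scores.sub(scores.min(axis=1), axis=0)
    totals = shifted.sum(axis=1)
    flat = totals == 0
    if flat.any():
        _warnings.warn(
            f"uniform proportions assigned to sample(s) with flat scores: "
            f"{list(scores.index[flat])}"
        )
        shifted.loc[flat] = 1.0
        totals = shifted.sum(axis=1)
    return shifted.div(totals, axis=0)


def anchor_correlation(
    expr: ExpressionMatrix,
    anchors: Sequence[str],
    candidates: Sequence[str],
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Screen candidate genes for correlation with anchor profiles.

    Retains candidates with ``|r| >= r_min`` AND ``p < p_max`` against at
    least one anchor (the |r| bound is inclusive, the p bound strict) and
    reports per-anchor ``r``/``p`` columns for the union.
    """
    if not candidates:
        raise CartxError("candidate list is empty")
    missing = [a for a in anchors if a not in expr.data.index]
    if missing:
        raise CartxError(f"anchor(s) missing from matrix: {missing}")
    for a in anchors:
        if np.ptp(expr.data.loc[a].values) == 0:
            raise CartxError(f"anchor {a!r} is constant across samples")

    rows = []
    for cand in candidates:
        if cand in anchors:
            continue
        y = expr.data.loc[cand].values
        if np.ptp(y) == 0:
            continue
        rec: dict[str, object] = {"feature_id": cand}
        hit = False
        for a in anchors:
            res = pearson_with_p(expr.data.loc[a].values, y)
            rec[f"r_{a}"] = res.r
            rec[f"p_{a}"] = res.p
            if abs(res.r) >= r_min and res.p < p_max:
                hit = True
        if hit:
            rows.append(rec)
    cols = ["feature_id"] + [f"{s}_{a}" for a in anchors for s in ("r", "p")]
    return pd.DataFrame(rows, columns=cols)


def panel_foldchange_report(
    expr: ExpressionMatrix,
    panel: MarkerPanel,
    pairs: Mapping[str, tuple[str, str]],
    fc_threshold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-category report of panel genes exceeding a paired fold change.

    ``pairs`` maps a pair label (typically the patient) to (pre sample,
    post sample). Fold change is ``(post + pc) / (pre + pc)``; a gene is
    flagged for a pair when its fold change strictly exceeds
    ``fc_threshold``. Returns one row per (category, gene, pair).
    """
    for label, (pre_s, post_s) in pairs.items():
        for s in (pre_s, post_s):
            if s not in expr.data.columns:
                raise CartxError(f"sample {s!r} (pair {label!r}) not in matrix")
    rows = []
    for category, genes in panel.groups.items():
        present = [g for g in genes if g in expr.data.index]
        for g in present:
            for label, (pre_s, post_s) in pairs.items():
                pre = float(expr.data.loc[g, pre_s])
                post = float(expr.data.loc[g, post_s])
                fc = (post + pseudocount) / (pre + pseudocount)
                rows.append(
                    {
                        "category": category,
                        "feature_id": g,
                        "pair": label,
                        "fold_change": fc,
                        "flagged": fc > fc_threshold,
                    }
                )
        if not present:
            rows.append(
                {
                    "category": category,
                    "feature_id": "",
                    "pair": "",
                    "fold_change": float("nan"),
                    "flagged": False,
                }
            )
    return pd.DataFrame(rows, columns=["category", "feature_id", "pair", "fold_change", "flagged"])
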