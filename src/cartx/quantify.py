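"""Expression-unit computation and filtering.

FPKM and TPM are computed from raw counts and feature lengths:

* ``FPKM_gs = 1e9 * C_gs / (N_s * L_g)`` with ``N_s`` the per-sample total
  assigned counts and ``L_g`` the feature length in bp.
* ``TPM_gs = 1e6 * (C_gs / L_g) / sum_g (C_gs / L_g)``; with equal lengths
  (miRNA matrices) this reduces to counts-per-million.

Expression filters use strict inequalities (``> threshold``), matching the
conventional "FPKM > 1" / "TPM > 10" phrasing of expressed-feature calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matrix import CartxError, ExpressionMatrix, FeatureAnnotation

#: Conventional expressed-feature thresholds by unit (strict >).
EXPRESSED_THRESHOLD = {"FPKM": 1.0, "TPM": 10.0}


def _check_counts(counts: ExpressionMatrix) -> None:
    if counts.unit != "raw_count":
        raise CartxError(f"expected raw_count unit, got {counts.unit!r}")
    totals = counts.data.sum(axis=0)
    zero = list(totals.index[totals == 0])
    if zero:
        raise CartxError(f"zero total counts in sample(s): {zero}")


def fpkm(counts: ExpressionMatrix, annotation: FeatureAnnotation) -> ExpressionMatrix:
    """Fragments per kilobase of feature per million assigned reads."""
    _check_counts(counts)
    lengths = annotation.lengths(counts.feature_ids)
    totals = counts.data.sum(axis=0)
    values = 1e9 * counts.data.div(totals, axis=1).div(lengths.values, axis=0)
    return ExpressionMatrix(values, "FPKM")


def tpm(counts: ExpressionMatrix, annotation: FeatureAnnotation) -> ExpressionMatrix:
    """Transcripts per million: length-normalised rates rescaled per sample."""
    _check_counts(counts)
    lengths = annotation.lengths(counts.feature_ids)
    rates = counts.data.div(lengths.values, axis=0)
    values = 1e6 * rates.div(rates.sum(axis=0), axis=1)
    return ExpressionMatrix(values, "TPM")


def filter_expressed(
    matrix: ExpressionMatrix, threshold: float | None = None, min_samples: int = 1
) -> ExpressionMatrix:
    """Retain features strictly above ``threshold`` in >= ``min_samples`` samples.

    ``threshold`` defaults to the unit's conventional expressed cutoff
    (FPKM 1, TPM 10). Feature order is preserved; the operation is
    idempotent.
    """
    if matrix.unit not in ("FPKM", "TPM"):
        raise CartxError(f"filter_expressed needs FPKM or TPM, got {matrix.unit!r}")
    if threshold is None:
        threshold = EXPRESSED_THRESHOLD[matrix.unit]
    if threshold < 0:
        raise CartxError("threshold must be >= 0")
    if not 1 <= min_samples <= matrix.n_samples:
        raise CartxError(
            f"min_samples must be in [1, {matrix.n_samples}], got {min_samples}"
        )
    keep = (matrix.data > threshold).sum(axis=1) >= min_samples
    return ExpressionMatrix(matrix.data.loc[keep], matrix.unit)


def highly_expressed(matrix: ExpressionMatrix, threshold: float = 100.0) -> list[str]:
    """Features strictly above ``threshold`` in EVERY sample (FPKM > 100 call)."""
    if matrix.unit != "FPKM":
        raise CartxError(f"highly_expressed expects FPKM, got {matrix.unit!r}")
    if matrix.n_features == 0:
        return []
    mask = (matrix.data > threshold).all(axis=1)
    return list(matrix.data.index[mask])


@dataclass
class AbundanceShare:
    """Per-sample share of total abundance captured by the top-k features."""

    share: pd.Series  # sample -> share in [0, 1]
    top_features: dict[str, list[str]]  # sample -> top-k feature ids
    warnings: list[str]


def top_abundance_share(matrix: ExpressionMatrix, k: int) -> AbundanceShare:
    """Share of each sample's total abundance held by its top-k features.

    Features are ranked per sample by value descending, ties broken by
    feature id ascending. An all-zero sample yields share 0 with a warning
    record.
    """
    if k < 1:
        raise CartxError("k must be >= 1")
    shares = {}
    tops = {}
    warnings: list[str] = []
    for s in matrix.sample_ids:
        col = matrix.data[s]
        order = sorted(zip(-col.values, col.index))  # value desc, id asc
        top_ids = [fid for _, fid in order[:k]]
        total = float(col.sum())
        if total == 0:
            shares[s] = 0.0
            warnings.append(f"sample {s} has zero total abundance")
        else:
            shares[s] = float(col.loc[top_ids].sum()) / total
        tops[s] = top_ids
    return AbundanceShare(pd.Series(shares, name="share"), tops, warnings)
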