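"""Gene-set over-representation statistics.

Fisher's exact test for over-representation is the one-sided hypergeometric
tail: with a background of ``N`` features of which ``K`` belong to the set,
and a query of ``n`` features with ``k`` in the set,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

Benjamini-Hochberg FDR is reported across all tested sets alongside the raw
p-value. Class enrichment within co-expression modules (e.g. histone genes
concentrating in assigned modules) uses the Pearson chi-square test on the
2x2 classification {in class, not} x {in a module, grey}, without
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CartxError

VALID_CATEGORIES = ("KEGG", "GO-BP", "custom")


class GeneSetCollection:
    """Named gene sets with a category tag (KEGG / GO-BP / custom).

    Stored as ``name -> (category, sorted unique members)``. Reads and
    writes GMT (name, description, members; tab-separated). The category is
    carried in the GMT description field.
    """

    def __init__(self, sets: Mapping[str, tuple[str, Iterable[str]]]):
        self._sets: dict[str, tuple[str, list[str]]] = {}
        for name, (category, members) in sets.items():
            members = list(members)
            if not members:
                raise CartxError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise CartxError(f"gene set {name!r} has duplicate members")
            if category not in VALID_CATEGORIES:
                raise CartxError(f"unknown category {category!r} for set {name!r}")
            self._sets[name] = (category, sorted(members))

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def members(self, name: str) -> list[str]:
        return list(self._sets[name][1])

    def category(self, name: str) -> str:
        return self._sets[name][0]

    def items(self):
        return self._sets.items()

    def as_dict(self) -> dict[str, list[str]]:
        return {name: list(members) for name, (_, members) in self._sets.items()}

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, (category, members) in self._sets.items():
                fh.write("\t".join([name, category] + members) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                name, category = parts[0], parts[1]
                if category not in VALID_CATEGORIES:
                    category = "custom"
                sets[name] = (category, parts[2:])
        return cls(sets)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided over-representation tail P(X >= k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and k >= 0):
        raise CartxError("invalid hypergeometric parameters")
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def fisher_enrich(
    query: set[str] | Iterable[str],
    background: set[str] | Iterable[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided over-representation test per gene set.

    The query must be a subset of the background; each set is intersected
    with the background before testing, and sets with no background overlap
    are skipped (recorded in ``result.attrs['skipped']``). Rows are sorted
    by raw p ascending, ties broken lexicographically by set name.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise CartxError("empty query")
    stray = query - background
    if stray:
        raise CartxError(f"query not contained in background: {sorted(stray)[:5]}")

    N = len(background)
    n = len(query)
    rows = []
    skipped = []
    for name in sets.names:
        members = set(sets.members(name)) & background
        K = len(members)
        if K == 0:
            skipped.append(name)
            continue
        k = len(members & query)
        p = hypergeom_tail(k, N, K, n)
        odds = _odds_ratio(k, n, K, N)
        rows.append(
            {
                "set": name,
                "category": sets.category(name),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "odds_ratio": odds,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "category", "k", "n", "K", "N", "odds_ratio", "p"]
    )
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "set"]).reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    table.attrs["skipped"] = skipped
    return table


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if b == 0 or c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def top_terms(table: pd.DataFrame, k_pathways: int = 20, k_bp: int = 15) -> pd.DataFrame:
    """First ``k`` rows per category from a sorted enrichment table.

    Defaults report the top 20 KEGG pathways and top 15 GO biological
    processes; other categories are returned in full.
    """
    if len(table) == 0:
        return table.copy()
    limits = {"KEGG": k_pathways, "GO-BP": k_bp}
    parts = []
    for category, sub in table.groupby("category", sort=False):
        limit = limits.get(category)
        parts.append(sub.head(limit) if limit is not None else sub)
    out = pd.concat(parts).sort_values(["p", "set"]).reset_index(drop=True)
    return out


@dataclass
class ChiSquareResult:
    statistic: float
    p: float
    table: np.ndarray  # 2x2 observed counts
    expected: np.ndarray
    low_expected_warning: bool


def class_chisq(assignment: pd.Series, class_members: set[str] | Iterable[str]) -> ChiSquareResult:
    """Chi-square enrichment of a feature class within assigned modules.

    Builds the 2x2 table {in class, not in class} x {in a non-grey module,
    grey} over all assigned features and applies the Pearson chi-square
    test (1 df, no continuity correction). Expected cells below 1 attach a
    warning flag; the statistic is still returned.
    """
    class_members = set(class_members)
    if not class_members:
        raise CartxError("empty class")
    assigned = set(assignment.index)
    stray = class_members - assigned
    if stray:
        raise CartxError(f"class members missing from assignment: {sorted(stray)[:5]}")

    in_module = assignment != "grey"
    is_class = assignment.index.isin(class_members)
    a = int((is_class & in_module).sum())  # class, in module
    b = int((is_class & ~in_module).sum())  # class, grey
    c = int((~is_class & in_module).sum())
    d = int((~is_class & ~in_module).sum())
    observed = np.array([[a, b], [c, d]], dtype=float)

    total = observed.sum()
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / total
    if (expected == 0).any():
        raise CartxError("degenerate 2x2 table (zero marginal)")
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return ChiSquareResult(stat, p, observed, expected, bool((expected < 1).any()))
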