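"""Chi-square contingency enrichment of gene categories among EDGs.

For a gene category, the 2x2 table contrasts category membership inside
the ecotype-differentiated gene (EDG) set against the genome-wide
background:

    [[a, b - a], [c - a, (d - b) - (c - a)]]

where ``a`` = category genes among EDGs, ``b`` = EDG total, ``c`` =
category genes genome-wide and ``d`` = genome gene total.  A gene
counts once however many differentiated SNPs it carries.  The statistic
is the chi-square test of independence without continuity correction;
``fold = (a/b)/(c/d)``.  Raw P values are reported by default;
Benjamini-Hochberg adjustment across categories is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one category: EDG-set vs genome background."""

    a: int  # category genes in the EDG set
    b: int  # EDG total
    c: int  # category genes genome-wide
    d: int  # genome gene total

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.b <= self.d and self.a <= self.c <= self.d):
            raise ValueError(f"inconsistent contingency counts {self}")

    def cells(self) -> np.ndarray:
        t = np.array(
            [[self.a, self.b - self.a], [self.c - self.a, (self.d - self.b) - (self.c - self.a)]],
            dtype=float,
        )
        if (t < 0).any():
            raise ValueError(f"negative derived cell in {self}")
        return t


def chisq_enrichment(table: ContingencyTable) -> tuple[float, float, float]:
    """Chi-square enrichment test; returns (statistic, P, fold).

    Identical proportions give (0, 1, fold=1).  A warning is logged
    when any expected cell is below 1 (the asymptotic should then be
    treated cautiously).
    """
    cells = table.cells()
    fold = (
        (table.a / table.b) / (table.c / table.d)
        if table.b > 0 and table.c > 0
        else float("nan")
    )
    if cells.sum(axis=0).min() == 0 or cells.sum(axis=1).min() == 0:
        return 0.0, 1.0, fold
    stat, p, _, expected = stats.chi2_contingency(cells, correction=False)
    if expected.min() < 1:
        warnings.warn(
            f"expected cell below 1 for {table}; chi-square approximation unreliable",
            stacklevel=2,
        )
    return float(stat), float(p), float(fold)


def enrichment_table(
    edg_ids: set[str],
    categories: pd.DataFrame,
    genome_gene_ids: set[str],
    fdr: bool = False,
) -> pd.DataFrame:
    """Test every category in ``categories`` (columns gene_id, category).

    Returns one row per category with counts, statistic, raw P, fold
    and optionally Benjamini-Hochberg adjusted P.
    """
    d = len(genome_gene_ids)
    b = len(edg_ids & genome_gene_ids)
    rows = []
    for cat, grp in categories.groupby("category"):
        members = set(grp["gene_id"]) & genome_gene_ids
        c = len(members)
        a = len(members & edg_ids)
        stat, p, fold = chisq_enrichment(ContingencyTable(a=a, b=b, c=c, d=d))
        rows.append((cat, a, b, c, d, stat, p, fold))
    out = pd.DataFrame(
        rows, columns=["category", "a", "b", "c", "d", "statistic", "p", "fold"]
    )
    if fdr and len(out):
        out["p_adj"] = false_discovery_adjust(out["p"].to_numpy())
    return out


def false_discovery_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
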