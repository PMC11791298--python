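"""Differential-expression filtering and the SE-proximity contingency test.

Genes are significant when |log2FC| >= 1.5 (inclusive) AND padj < 0.05
(strict; missing padj is non-significant). Significant genes are crossed
with SE proximity (within 50 kb, via the consensus module's links) in a
2x2 table tested by Pearson chi-square WITHOUT continuity correction —
the convention of spreadsheet chi-square functions — with df = 1. The
table counts genes, not SE-gene links: a gene near two SEs counts once.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "filter_de",
    "annotate_se_proximity",
    "direction_se_contingency",
    "contingency_table_result",
    "contingency_summary",
]

REQUIRED_COLS = ("gene_id", "log2fc", "padj")


@dataclass
class ContingencyResult:
    """2x2 association between DE direction and SE proximity."""

    table: pd.DataFrame  # rows down/up, columns se/non_se
    chi2: float
    p_value: float
    dof: int
    ratio_down_up_se: float
    ratio_down_up_non_se: float
    degenerate: bool = False


def filter_de(
    table: pd.DataFrame, lfc_cutoff: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Set significance and direction flags on a DESeq2-style results table.

    Boundary conventions: |log2fc| exactly at the cutoff is significant
    (inclusive); padj exactly at alpha is not (strict <); missing padj is
    non-significant. Idempotent and order-invariant.
    """
    missing = [c for c in REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing required columns {missing}")
    df = table.copy()
    lfc = pd.to_numeric(df["log2fc"], errors="coerce")
    padj = pd.to_numeric(df["padj"], errors="coerce")
    df["significant"] = (lfc.abs() >= lfc_cutoff) & (padj < alpha) & padj.notna()
    df["direction"] = "none"
    df.loc[df["significant"] & (lfc > 0), "direction"] = "up"
    df.loc[df["significant"] & (lfc < 0), "direction"] = "down"
    return df


def annotate_se_proximity(
    de_genes: pd.DataFrame, se_gene_links
) -> pd.DataFrame:
    """Flag genes appearing in any SE-gene link.

    ``se_gene_links`` may be a links DataFrame with a ``gene_id`` column,
    a sequence of link objects with ``.gene.gene_id``, or a plain iterable
    of gene ids.
    """
    if isinstance(se_gene_links, pd.DataFrame):
        ids = set(se_gene_links["gene_id"].astype(str))
    else:
        links = list(se_gene_links)
        if links and hasattr(links[0], "gene"):
            ids = {ln.gene.gene_id for ln in links}
        else:
            ids = {str(g) for g in links}
    df = de_genes.copy()
    df["se_associated"] = df["gene_id"].astype(str).isin(ids)
    return df


def direction_se_contingency(de_genes: pd.DataFrame) -> ContingencyResult:
    """Build and test the direction x SE-proximity 2x2 over significant
    genes only. A zero margin flags the result degenerate (chi2 = NaN)."""
    for col in ("significant", "direction", "se_associated"):
        if col not in de_genes.columns:
            raise ValueError(f"DE table missing column {col!r}; run the "
                             "filter and proximity annotation first")
    sig = de_genes[de_genes["significant"]].drop_duplicates("gene_id")
    counts = np.zeros((2, 2), dtype=int)
    for i, direction in enumerate(("down", "up")):
        sub = sig[sig["direction"] == direction]
        counts[i, 0] = int(sub["se_associated"].sum())
        counts[i, 1] = int((~sub["se_associated"]).sum())
    return contingency_table_result(counts)


def contingency_table_result(counts) -> ContingencyResult:
    """Chi-square (Pearson, no continuity correction, df 1) and down/up
    ratios for a 2x2 array ``[[down_se, down_non], [up_se, up_non]]``."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    table = pd.DataFrame(
        counts.astype(int), index=["down", "up"], columns=["se", "non_se"]
    )
    degenerate = bool((counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any())
    if degenerate:
        logger.warning("contingency table has a zero margin; chi2 undefined")
        chi2 = p = math.nan
    else:
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)

    def _ratio(down, up):
        if up == 0:
            return math.inf if down > 0 else math.nan
        return down / up

    return ContingencyResult(
        table=table,
        chi2=float(chi2),
        p_value=float(p),
        dof=1,
        ratio_down_up_se=_ratio(counts[0, 0], counts[1, 0]),
        ratio_down_up_non_se=_ratio(counts[0, 1], counts[1, 1]),
        degenerate=degenerate,
    )


def contingency_summary(result: ContingencyResult) -> pd.DataFrame:
    t = result.table
    return pd.DataFrame(
        [
            {
                "down_se": t.loc["down", "se"],
                "down_non_se": t.loc["down", "non_se"],
                "up_se": t.loc["up", "se"],
                "up_non_se": t.loc["up", "non_se"],
                "chi2": result.chi2,
                "p_value": result.p_value,
                "df": result.dof,
                "ratio_down_up_se": result.ratio_down_up_se,
                "ratio_down_up_non_se": result.ratio_down_up_non_se,
                "degenerate": result.degenerate,
            }
        ]
    )
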