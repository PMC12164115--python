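"""Benchmarking machinery: rank-weighted CGC score, Fisher contingency
enrichment, expression odds ratios relative to synonymous mutations in
non-cancer genes, and a rank-based AUC of per-mutation RNA VAF against
external driver/passenger labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .io import CohortTable, GeneAnnotation, VarClass
from .preprocess import classify_expression


@dataclass
class RankedGeneList:
    """Genes ordered by ascending p with cancer-gene membership flags."""

    genes: list[str]
    is_cgc: list[bool]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.is_cgc):
            raise ValueError("genes and is_cgc must be parallel")

    @classmethod
    def from_results(cls, df: pd.DataFrame, cgc: set[str]) -> "RankedGeneList":
        ordered = df.sort_values(["p_geomean", "gene"], kind="mergesort")
        genes = ordered["gene"].tolist()
        return cls(genes=genes, is_cgc=[g in cgc for g in genes])


def cgc_score(ranked: RankedGeneList, N: int = 250, log_base: float | None = None) -> float:
    """Rank-weighted enrichment of known cancer genes among the top hits.

    ``E(R) = sum_{i=1..N} P_i / log(i + 1)`` where ``P_i`` is the proportion
    of the i best-ranked genes that are in the CGC list.  ``N`` truncates to
    the top ranks (clamped to the list length).  Natural log by default;
    ``log_base`` switches the base.
    """
    if len(ranked.genes) == 0:
        raise ValueError("empty ranked gene list")
    if N < 1:
        raise ValueError("N must be >= 1")
    N = min(N, len(ranked.genes))
    flags = np.asarray(ranked.is_cgc[:N], dtype=float)
    i = np.arange(1, N + 1)
    p_i = np.cumsum(flags) / i
    logs = np.log(i + 1) if log_base is None else np.log(i + 1) / math.log(log_base)
    return float(np.sum(p_i / logs))


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Conditional odds ratio and two-sided Fisher exact p for [[a,b],[c,d]].

    Two-sided p sums hypergeometric probabilities no larger than the
    observed table's (the standard convention).
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum(axis=0).min() == 0 and table.sum(axis=1).min() == 0:
        raise ValueError("degenerate table: an all-zero margin")
    orr, p = stats.fisher_exact(table, alternative="two-sided")
    return float(orr), float(p)


def expression_odds_ratio(
    cohort: CohortTable,
    var_class: str | VarClass,
    in_cgc: bool,
    annotation: GeneAnnotation,
) -> tuple[float, tuple[float, float]] | None:
    """Odds of a mutation class being expressed, relative to synonymous
    mutations in non-CGC genes.

    "Expressed" means >= 2 RNA reads on the mutant allele; wild-type-only
    positions count as not expressed.  Returns the conditional-MLE odds
    ratio with its exact 95% CI, or ``None`` (with a warning) when the
    target stratum is empty.
    """
    if isinstance(var_class, VarClass):
        var_class = var_class.value
    df = cohort.df
    expressed = (
        classify_expression(df["rna_alt"].to_numpy(), df["rna_ref"].to_numpy())
        == "expressed"
    )
    cgc_mask = df["gene"].isin(annotation.cgc_genes).to_numpy()
    ref = (df["var_class"] == VarClass.SYNONYMOUS.value).to_numpy() & ~cgc_mask
    target = (df["var_class"] == var_class).to_numpy() & (cgc_mask == in_cgc)
    if ref.sum() == 0:
        raise ValueError("reference stratum (synonymous, non-CGC) is empty")
    if target.sum() == 0:
        import logging

        logging.getLogger(__name__).warning(
            "empty stratum %s/in_cgc=%s; no odds ratio", var_class, in_cgc
        )
        return None
    a = int((target & expressed).sum())
    b = int((target & ~expressed).sum())
    c = int((ref & expressed).sum())
    d = int((ref & ~expressed).sum())
    res = _odds_ratio([[a, b], [c, d]], kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return float(res.statistic), (float(ci.low), float(ci.high))


def vaf_label_auc(
    vafs,
    labels,
    mutation_keys=None,
) -> float:
    """Rank-based AUC of RNA VAF against boolean driver labels.

    When ``mutation_keys`` is given, recurrent mutations (same key) are
    collapsed to their median VAF (label taken from the first occurrence,
    which must be consistent within a key) before scoring.  Ties are
    mid-ranked (Mann-Whitney AUC).
    """
    vafs = np.asarray(vafs, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if mutation_keys is not None:
        df = pd.DataFrame({"key": mutation_keys, "vaf": vafs, "label": labels})
        agg = df.groupby("key").agg(vaf=("vaf", "median"), label=("label", "first"))
        conflicts = df.groupby("key")["label"].nunique()
        if (conflicts > 1).any():
            raise ValueError("a recurrent mutation carries conflicting labels")
        vafs = agg["vaf"].to_numpy()
        labels = agg["label"].to_numpy()
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    ranks = stats.rankdata(vafs)  # mid-ranks for ties
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)
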