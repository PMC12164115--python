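"""Cohort preprocessing: SNV filtering, multinucleotide removal, per-gene
per-sample caps, RNA VAF, expression classes, depth weights, and selection
of testable genes.

The pipeline order is fixed: :func:`filter_snvs` ->
:func:`remove_multinucleotide` -> :func:`cap_mutations_per_gene_sample` ->
:func:`compute_weights`; weights are computed on the final retained set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import NONSYNONYMOUS, CohortTable, VarClass

NONSYN_VALUES = frozenset(v.value for v in NONSYNONYMOUS)
RETAINED_VALUES = NONSYN_VALUES | {VarClass.SYNONYMOUS.value}


def compute_rna_vaf(rna_alt, rna_ref):
    """RNA VAF: alt reads / (alt + ref) non-duplicated reads; 0 at zero depth.

    Accepts scalars or arrays.
    """
    alt = np.asarray(rna_alt, dtype=float)
    ref = np.asarray(rna_ref, dtype=float)
    if (alt < 0).any() or (ref < 0).any():
        raise ValueError("allele counts must be non-negative")
    depth = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.where(depth > 0, depth, 1), 0.0)
    if np.ndim(rna_alt) == 0 and np.ndim(rna_ref) == 0:
        return float(vaf)
    return vaf


def classify_expression(rna_alt, rna_ref):
    """Three-way expression class of a mutated position.

    ``expressed``      : >= 2 reads support the mutant allele.
    ``not_expressed``  : < 2 reads in total at the position.
    ``wt_only``        : otherwise (position covered, mutant allele not).
    """
    alt = np.asarray(rna_alt)
    ref = np.asarray(rna_ref)
    out = np.where(
        alt >= 2, "expressed", np.where(alt + ref < 2, "not_expressed", "wt_only")
    )
    if np.ndim(rna_alt) == 0 and np.ndim(rna_ref) == 0:
        return str(out)
    return out


def filter_snvs(cohort: CohortTable) -> CohortTable:
    """Keep synonymous and nonsynonymous SNVs; drop everything else."""
    df = cohort.df
    keep = df["var_class"].isin(RETAINED_VALUES)
    return CohortTable(cohort.cancer_type, df[keep].reset_index(drop=True))


def remove_multinucleotide(cohort: CohortTable) -> CohortTable:
    """Drop di/tri-nucleotide events: within a sample and chromosome, every
    maximal run of SNVs at strictly consecutive positions (neighbouring rows
    1 bp apart) of length >= 2 is removed entirely."""
    df = cohort.df
    if df.empty:
        return cohort.copy()
    order = df.sort_values(["sample_id", "chrom", "pos"]).index
    s = df.loc[order]
    same_group = (s["sample_id"].shift() == s["sample_id"]) & (
        s["chrom"].shift() == s["chrom"]
    )
    adjacent_prev = same_group & (s["pos"].diff() == 1)
    adjacent_next = adjacent_prev.shift(-1, fill_value=False)
    in_run = (adjacent_prev | adjacent_next).to_numpy()
    keep_idx = order[~in_run]
    out = df.loc[df.index.isin(keep_idx)].reset_index(drop=True)
    return CohortTable(cohort.cancer_type, out)


def cap_mutations_per_gene_sample(
    cohort: CohortTable, cap: int = 3
) -> CohortTable:
    """Keep at most ``cap`` mutations per (sample, gene).

    Ranked by RNA depth descending, ties broken by position ascending, so the
    retained set is deterministic.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    df = cohort.df.copy()
    depth = df["rna_alt"] + df["rna_ref"]
    df["_depth"] = depth
    df = df.sort_values(
        ["sample_id", "gene", "_depth", "pos"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    kept = df.groupby(["sample_id", "gene"], sort=False).head(cap)
    kept = kept.sort_index().drop(columns="_depth").reset_index(drop=True)
    return CohortTable(cohort.cancer_type, kept)


def compute_weights(cohort: CohortTable, depth_percentile: float = 90.0) -> CohortTable:
    """Attach ``rna_depth``, ``rna_vaf``, ``weight`` and ``expression_class``.

    Depths are capped at the cohort's ``depth_percentile`` (linear-
    interpolation percentile) before the log transform, so extremely highly
    expressed genes do not dominate::

        log_coverage    = log2(capped_depth + 1)
        mutation_weight = log_coverage / max(log_coverage)

    Zero-coverage mutations still enter the model: they receive the weight of
    a depth-1 mutation.
    """
    df = cohort.df.copy()
    if df.empty:
        raise ValueError("cannot compute weights on an empty cohort")
    depth = (df["rna_alt"] + df["rna_ref"]).to_numpy()
    if depth.max() == 0:
        raise ValueError("all RNA depths are zero; weights undefined")
    p90 = float(np.percentile(depth, depth_percentile))  # type-7 linear interpolation
    capped = np.minimum(depth, p90).astype(float)
    capped[depth == 0] = min(1.0, p90)  # depth-0 treated as depth 1
    log_cov = np.log2(capped + 1.0)
    weights = log_cov / log_cov.max()
    df["rna_depth"] = depth
    df["rna_vaf"] = compute_rna_vaf(df["rna_alt"].to_numpy(), df["rna_ref"].to_numpy())
    df["weight"] = weights
    df["expression_class"] = classify_expression(
        df["rna_alt"].to_numpy(), df["rna_ref"].to_numpy()
    )
    return CohortTable(cohort.cancer_type, df)


def select_testable_genes(
    cohort: CohortTable, min_nonsyn: int = 2, min_depth: int = 8
) -> list[str]:
    """Genes with >= ``min_nonsyn`` nonsynonymous mutations each covered by
    >= ``min_depth`` non-duplicated RNA reads."""
    df = cohort.df
    depth = df["rna_depth"] if "rna_depth" in df else df["rna_alt"] + df["rna_ref"]
    eligible = df[df["var_class"].isin(NONSYN_VALUES) & (depth >= min_depth)]
    counts = eligible.groupby("gene").size()
    return sorted(counts.index[counts >= min_nonsyn])


def preprocess_cohort(
    cohort: CohortTable,
    cap: int = 3,
    depth_percentile: float = 90.0,
) -> CohortTable:
    """Run the fixed preprocessing chain and return the weighted cohort."""
    out = filter_snvs(cohort)
    out = remove_multinucleotide(out)
    out = cap_mutations_per_gene_sample(out, cap=cap)
    return compute_weights(out, depth_percentile=depth_percentile)
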