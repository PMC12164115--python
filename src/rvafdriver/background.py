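"""Background mutation model: cohort-scaled sampling rate, synonymous
scaling factor k, and the six-tier hierarchical background sampler.

Each tested gene's nonsynonymous RNA VAFs are compared against synonymous
mutations sampled without replacement, preferentially from the same tumors
(controlling for purity and tumor-fraction expression differences between
samples), falling back through a fixed hierarchy of pools when a sample has
too few eligible synonymous mutations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTable, GeneAnnotation, VarClass
from .preprocess import NONSYN_VALUES

logger = logging.getLogger(__name__)

RATE_CAP = 0.202

#: mutation classes entering each test subset
CLASS_SUBSETS: dict[str, frozenset[str]] = {
    "missense_only": frozenset({VarClass.MISSENSE.value}),
    "nonsense_only": frozenset({VarClass.NONSENSE.value}),
    "splice_only": frozenset({VarClass.SPLICE_SITE.value}),
    "all_nonsyn": frozenset(NONSYN_VALUES),
}

TIER_SAME_SAMPLE = "i_same_sample"
TIER_MUTATED_SAMPLES = "ii_mutated_samples"
TIER_COHORT = "iii_cohort"
TIER_SAME_CLASS = "iv_same_class_same_sample"
TIER_INCOMPLETE = "v_incomplete"
TIER_GENE_SYN = "vi_gene_syn"


@dataclass
class SamplingPlan:
    """Cohort-level parameters of one background-sampling run."""

    rate: float
    k_syn_scale: float = 1.0
    min_bg_depth: int = 8
    include_gene_syn: bool = False


@dataclass
class BackgroundDraw:
    """One sampled background set with per-mutation provenance."""

    indices: np.ndarray          # row labels into the cohort frame
    vafs: np.ndarray             # unscaled background RNA VAFs
    weights: np.ndarray
    tiers: list[str]
    is_synonymous: np.ndarray    # True for tiers i-iii and vi
    target_n: int                # full quota
    incomplete: bool = False

    def __len__(self) -> int:
        return len(self.indices)


def compute_sampling_rate(cohort_size: int, rate_cap: float = RATE_CAP) -> float:
    """Exponential sampling rate, ``min(ln(10)/(0.05 * cohort_size), cap)``.

    Calibrated so a gene mutated in 5% of the cohort draws 10 synonymous
    mutations per nonsynonymous mutation; the cap keeps small cohorts from
    exploding (0.202 is the largest 3-decimal rate still yielding a single
    background mutation per case mutation when only 2 samples are mutated).
    """
    if cohort_size < 2:
        raise ValueError("cohort must contain at least 2 samples")
    return min(math.log(10.0) / (0.05 * cohort_size), rate_cap)


def n_background_per_mutation(rate: float, n_samples: int) -> int:
    """Synonymous mutations sampled per case mutation.

    ``min(round(exp(rate * n_samples)), 2 * n_samples)`` with round-half-to-
    even; ``n_samples`` is the number of samples carrying a tested-class
    mutation in the gene.
    """
    if n_samples < 1:
        raise ValueError("need at least one mutated sample")
    return int(min(round(math.exp(rate * n_samples)), 2 * n_samples))


def apply_syn_scaling(vaf, k: float):
    """Scale background VAF(s) by k, capped at 1."""
    if k <= 0:
        raise ValueError("k must be positive")
    return np.minimum(1.0, np.asarray(vaf, dtype=float) * k) if np.ndim(vaf) else min(
        1.0, float(vaf) * k
    )


def compute_syn_scaling_factor(
    cohort: CohortTable,
    tested_genes: list[str],
    annotation: GeneAnnotation,
    min_bg_depth: int = 8,
    k_grid: tuple[float, float, float] = (0.25, 4.0, 0.001),
) -> float:
    """Synonymous scaling factor k.

    Synonymous background VAFs differ systematically from nonsynonymous VAFs
    in tested genes (expression, selection on gene context).  k minimises

        |k*mean(S) - mean(G)| + |k*median(S) - median(G)|

    over a fixed grid, where S are the depth-eligible synonymous VAFs and G
    the per-gene mean nonsynonymous VAFs of tested genes outside the known
    cancer-gene list (so real driver signal does not inflate the background).
    Ties resolve to the smallest k.
    """
    df = cohort.df
    vaf_col = "scaled_vaf" if "scaled_vaf" in df else "rna_vaf"
    syn = df[
        (df["var_class"] == VarClass.SYNONYMOUS.value)
        & (df["rna_depth"] >= min_bg_depth)
    ]
    non_cgc = [g for g in tested_genes if g not in annotation.cgc_genes]
    if not non_cgc:
        logger.warning("no non-CGC tested genes; synonymous scaling factor k = 1")
        return 1.0
    if len(syn) < 10:
        logger.warning(
            "only %d background-eligible synonymous mutations; k = 1", len(syn)
        )
        return 1.0
    nonsyn = df[df["var_class"].isin(NONSYN_VALUES) & df["gene"].isin(non_cgc)]
    gene_means = nonsyn.groupby("gene")[vaf_col].mean().to_numpy()

    s = syn[vaf_col].to_numpy()
    s_mean, s_med = float(np.mean(s)), float(np.median(s))
    g_mean, g_med = float(np.mean(gene_means)), float(np.median(gene_means))
    lo, hi, step = k_grid
    ks = np.round(np.arange(lo, hi + step / 2, step), 6)
    obj = np.abs(ks * s_mean - g_mean) + np.abs(ks * s_med - g_med)
    return float(ks[int(np.argmin(obj))])  # argmin returns first -> smallest k


class GeneTestContext:
    """Precomputed pools for one (gene, class subset), reused across the
    bootstrap draws so repeated sampling stays cheap."""

    def __init__(
        self,
        gene: str,
        class_subset: str,
        cohort: CohortTable,
        plan: SamplingPlan,
    ):
        if class_subset not in CLASS_SUBSETS:
            raise ValueError(f"unknown class subset {class_subset!r}")
        df = cohort.df
        self.gene = gene
        self.class_subset = class_subset
        self.vaf_col = "scaled_vaf" if "scaled_vaf" in df else "rna_vaf"
        classes = CLASS_SUBSETS[class_subset]

        case_mask = (df["gene"] == gene) & df["var_class"].isin(classes)
        self.case = df[case_mask]
        self.case_samples = self.case.groupby("sample_id").size()  # muts per sample
        self.n_samples = len(self.case_samples)

        depth_ok = df["rna_depth"] >= plan.min_bg_depth
        syn_mask = (df["var_class"] == VarClass.SYNONYMOUS.value) & depth_ok
        own_syn = syn_mask & (df["gene"] == gene)
        if not plan.include_gene_syn:
            syn_mask &= df["gene"] != gene
        self.syn = df[syn_mask]
        self.own_syn_index = set(df.index[own_syn]) if plan.include_gene_syn else set()
        # tier iv: same-class nonsynonymous mutations outside the tested gene
        self.same_class = df[
            df["var_class"].isin(classes) & (df["gene"] != gene) & depth_ok
        ]
        self._syn_by_sample = {
            s: grp.index.to_numpy() for s, grp in self.syn.groupby("sample_id")
        }
        self._same_class_by_sample = {
            s: grp.index.to_numpy() for s, grp in self.same_class.groupby("sample_id")
        }
        self._df = df
        self._plan = plan

    @property
    def runnable(self) -> bool:
        return len(self.case) >= 2

    def case_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.case[self.vaf_col].to_numpy(dtype=float),
            self.case["weight"].to_numpy(dtype=float),
        )


def _draw_from(pool: np.ndarray, used: set, need: int, rng: np.random.Generator):
    avail = np.array([i for i in pool if i not in used], dtype=pool.dtype if len(pool) else int)
    if len(avail) == 0 or need <= 0:
        return []
    take = min(need, len(avail))
    picked = rng.choice(avail, size=take, replace=False)
    return list(np.sort(picked))


def sample_background(
    ctx: GeneTestContext,
    plan: SamplingPlan,
    rng: np.random.Generator,
) -> BackgroundDraw:
    """Draw one background set for a gene/class-subset test.

    For each sample carrying a tested-class mutation in the gene, the quota
    is ``n_background_per_mutation(rate, n_samples)`` times that sample's
    in-gene mutation count, filled without replacement through the tiers:

    i.   synonymous mutations from that sample,
    ii.  synonymous mutations from the other mutated samples,
    iii. synonymous mutations from any cohort sample,
    iv.  same-class nonsynonymous mutations from that sample (other genes),
    v.   proceed with an incomplete background,
    vi.  (optional) the gene's own synonymous mutations, labelled as such.

    The draw is reproducible bit-for-bit for a fixed generator state.
    """
    n_per = n_background_per_mutation(plan.rate, ctx.n_samples)
    used: set = set()
    indices: list = []
    tiers: list[str] = []
    target_total = 0
    mutated_samples = list(ctx.case_samples.index)
    mutated_set = set(mutated_samples)
    all_syn_pool = ctx.syn.index.to_numpy()

    for sample in mutated_samples:
        quota = n_per * int(ctx.case_samples[sample])
        target_total += quota
        got = 0

        def record(picked: list, tier: str) -> None:
            nonlocal got
            for i in picked:
                used.add(i)
                indices.append(i)
                tiers.append(TIER_GENE_SYN if i in ctx.own_syn_index else tier)
                got += 1

        record(
            _draw_from(ctx._syn_by_sample.get(sample, np.array([], int)),
                       used, quota - got, rng),
            TIER_SAME_SAMPLE,
        )
        if got < quota:
            pool = np.concatenate(
                [ctx._syn_by_sample.get(s, np.array([], int))
                 for s in mutated_samples if s != sample]
            ) if len(mutated_samples) > 1 else np.array([], int)
            record(_draw_from(pool, used, quota - got, rng), TIER_MUTATED_SAMPLES)
        if got < quota:
            record(_draw_from(all_syn_pool, used, quota - got, rng), TIER_COHORT)
        if got < quota:
            record(
                _draw_from(ctx._same_class_by_sample.get(sample, np.array([], int)),
                           used, quota - got, rng),
                TIER_SAME_CLASS,
            )

    incomplete = len(indices) < target_total
    if incomplete:
        logger.debug(
            "gene %s: incomplete background (%d/%d), proceeding (tier v)",
            ctx.gene, len(indices), target_total,
        )
    idx = np.array(indices, dtype=int)
    sub = ctx._df.loc[idx] if len(idx) else ctx._df.iloc[0:0]
    return BackgroundDraw(
        indices=idx,
        vafs=sub[ctx.vaf_col].to_numpy(dtype=float),
        weights=sub["weight"].to_numpy(dtype=float),
        tiers=tiers,
        is_synonymous=(sub["var_class"] == VarClass.SYNONYMOUS.value).to_numpy(),
        target_n=target_total,
        incomplete=incomplete,
    )
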