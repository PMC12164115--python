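"""Gene-level driver test: weighted one-sided group comparison of RNA VAFs
against the sampled background, bootstrapped 25 times, aggregated by the
geometric mean of p-values, BH-corrected, called at q < 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .background import (
    CLASS_SUBSETS,
    BackgroundDraw,
    GeneTestContext,
    SamplingPlan,
    apply_syn_scaling,
    compute_sampling_rate,
    compute_syn_scaling_factor,
    sample_background,
)
from .io import CohortTable, GeneAnnotation, GeneTestResult
from .preprocess import select_testable_genes

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300
Q_THRESHOLD = 0.25
N_BOOTSTRAP = 25

#: class-specific subsets tried before falling back to the combined test
PER_CLASS_SUBSETS = ("missense_only", "nonsense_only", "splice_only")


def weighted_group_test(
    case_vafs: np.ndarray,
    case_weights: np.ndarray,
    bg_vafs: np.ndarray,
    bg_weights: np.ndarray,
) -> tuple[float, float]:
    """Weighted linear model ``vaf ~ group`` with a one-sided test.

    Fits weighted least squares of VAF on a case indicator (1 = tested gene,
    0 = background) with the per-mutation depth weights.  The group
    coefficient equals the difference of weighted group means; its one-sided
    p (upper tail, case above background) uses the t distribution with
    ``n_total - 2`` degrees of freedom.

    Returns ``(effect_size, p_one_sided)``.  A fully degenerate input (all
    VAFs identical) returns ``(0.0, 0.5)``.
    """
    y = np.concatenate([np.asarray(bg_vafs, float), np.asarray(case_vafs, float)])
    w = np.concatenate([np.asarray(bg_weights, float), np.asarray(case_weights, float)])
    g = np.concatenate([np.zeros(len(bg_vafs)), np.ones(len(case_vafs))])
    n = len(y)
    if len(case_vafs) < 2 or len(bg_vafs) < 1:
        raise ValueError("need >= 2 case and >= 1 background mutations")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    if np.all(y == y[0]):
        return 0.0, 0.5  # degenerate: every VAF identical

    w_case = w[g == 1].sum()
    w_bg = w[g == 0].sum()
    mean_case = float(np.average(y[g == 1], weights=w[g == 1]))
    mean_bg = float(np.average(y[g == 0], weights=w[g == 0]))
    effect = mean_case - mean_bg

    fitted = np.where(g == 1, mean_case, mean_bg)
    rss = float(np.sum(w * (y - fitted) ** 2))
    dof = n - 2
    if dof <= 0:
        return effect, 0.5
    sigma2 = rss / dof
    if sigma2 <= 0:
        return effect, 0.0 if effect > 0 else 1.0
    se = np.sqrt(sigma2 * (1.0 / w_case + 1.0 / w_bg))
    t = effect / se
    p = float(stats.t.sf(t, dof))
    return effect, p


def geometric_mean_p(ps) -> float:
    """Geometric mean of p-values, floored at 1e-300 before the logs."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("empty p-value collection")
    if (ps <= 0).any() or (ps > 1).any():
        ps = np.clip(ps, P_FLOOR, 1.0)
    ps = np.maximum(ps, P_FLOOR)
    gm = float(np.exp(np.mean(np.log(ps))))
    # exp/log round-trip can drift past the extremes by ~1 ulp
    return float(min(max(gm, ps.min()), ps.max()))


def bh_qvalues(ps) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps
    return multipletests(ps, method="fdr_bh")[1]


def bootstrap_gene_test(
    gene: str,
    class_subset: str,
    cohort: CohortTable,
    plan: SamplingPlan,
    rng: np.random.Generator,
    B: int = N_BOOTSTRAP,
) -> GeneTestResult | None:
    """Run the B-fold bootstrapped background comparison for one gene.

    Each bootstrap independently resamples the background through the tier
    hierarchy, scales the synonymous background VAFs by k, and refits the
    weighted model; the gene's p is the geometric mean of the B one-sided
    p-values and the effect size the mean of the B fitted coefficients.
    Returns ``None`` when no background mutation is available at any tier.
    """
    ctx = GeneTestContext(gene, class_subset, cohort, plan)
    if not ctx.runnable:
        return None
    case_vafs, case_weights = ctx.case_arrays()
    effects = np.empty(B)
    pvals = np.empty(B)
    for b in range(B):
        draw = sample_background(ctx, plan, rng)
        if len(draw) == 0:
            logger.warning("gene %s (%s): empty background at all tiers; skipped",
                           gene, class_subset)
            return None
        bg = draw.vafs.copy()
        bg[draw.is_synonymous] = np.minimum(
            1.0, bg[draw.is_synonymous] * plan.k_syn_scale
        )
        effects[b], pvals[b] = weighted_group_test(
            case_vafs, case_weights, bg, draw.weights
        )
    return GeneTestResult(
        gene=gene,
        class_subset=class_subset,
        n_case=len(case_vafs),
        effect_size=float(effects.mean()),
        p_boot=[float(p) for p in pvals],
        p_geomean=geometric_mean_p(pvals),
    )


@dataclass
class RunInfo:
    """Provenance of one cohort run (for the manifest/log)."""

    cancer_type: str
    n_cohort: int
    rate: float
    k: float
    tested_genes: list[str] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)


def run_cancer_type(
    cohort: CohortTable,
    annotation: GeneAnnotation,
    mode: str = "per_class_min",
    rng: np.random.Generator | None = None,
    min_nonsyn: int = 2,
    min_depth: int = 8,
    min_bg_depth: int = 8,
    min_class_n: int = 2,
    B: int = N_BOOTSTRAP,
    rate_cap: float = 0.202,
    include_gene_syn: bool = False,
    q_threshold: float = Q_THRESHOLD,
) -> tuple[list[GeneTestResult], RunInfo]:
    """Test every testable gene of one preprocessed cohort.

    ``cohort`` must carry the preprocessing columns (``rna_depth``,
    ``rna_vaf``, ``weight``; ``scaled_vaf`` if NMD scaling was applied).
    ``mode='per_class_min'`` runs each mutation-class subset with at least
    ``min_class_n`` mutations and reports the smallest p (falling back to
    the combined all-nonsynonymous test when no class subset is runnable);
    ``mode='combined'`` always reports the all-nonsynonymous test.  Gene
    p-values are then BH-corrected within the run and genes with
    q < ``q_threshold`` flagged as putative drivers.
    """
    if mode not in ("per_class_min", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng()
    tested = select_testable_genes(cohort, min_nonsyn=min_nonsyn, min_depth=min_depth)
    rate = compute_sampling_rate(cohort.n_cohort, rate_cap=rate_cap)
    k = compute_syn_scaling_factor(cohort, tested, annotation, min_bg_depth=min_bg_depth)
    plan = SamplingPlan(rate=rate, k_syn_scale=k, min_bg_depth=min_bg_depth,
                        include_gene_syn=include_gene_syn)
    info = RunInfo(cancer_type=cohort.cancer_type, n_cohort=cohort.n_cohort,
                   rate=rate, k=k, tested_genes=tested)
    if not tested:
        logger.warning("no testable genes in cohort %s", cohort.cancer_type)
        return [], info

    results: list[GeneTestResult] = []
    for gene in tested:
        if mode == "combined":
            res = bootstrap_gene_test(gene, "all_nonsyn", cohort, plan, rng, B=B)
        else:
            candidates = []
            for subset in PER_CLASS_SUBSETS:
                ctx_n = (
                    (cohort.df["gene"] == gene)
                    & cohort.df["var_class"].isin(CLASS_SUBSETS[subset])
                ).sum()
                if ctx_n >= min_class_n:
                    r = bootstrap_gene_test(gene, subset, cohort, plan, rng, B=B)
                    if r is not None:
                        candidates.append(r)
            if candidates:
                res = min(candidates, key=lambda r: r.p_geomean)
            else:
                res = bootstrap_gene_test(gene, "all_nonsyn", cohort, plan, rng, B=B)
        if res is None:
            info.skipped[gene] = "no background mutations available at any tier"
            continue
        results.append(res)

    if results:
        qs = bh_qvalues([r.p_geomean for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
            r.driver_flag = bool(q < q_threshold)
    return results, info
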