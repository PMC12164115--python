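"""Mutation-level allelic statistics: cancer cell fraction (CCF) and
clonality, mutant copy number and its fraction of total copy number, and a
copy-number-aware beta-binomial test for allele-specific expression (ASE).

All quantities derive from the DNA VAF, tumor purity ``p``, the normal copy
number ``Ncn`` at the position (2 on autosomes) and the tumor total copy
number ``Tcn``:

    CCF     = VAF/p * ((1 - p) * Ncn + p * Tcn)
    mut_cn  = VAF/p * (p * Tcn + Ncn * (1 - p))          (same expression)
    CPNratio = min(1, mut_cn / Tcn)

The ASE test asks whether the RNA alt-read count exceeds what the genomic
mutant copy fraction predicts, under a beta-binomial with over-dispersion
rho = 0.05 — mutations expressed beyond their copy-number expectation show
copy-number-independent allele-specific expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable
from .preprocess import classify_expression

ASE_RHO = 0.05
ASE_ALPHA = 0.05
CPN_EPS = 0.001
CCF_GRID = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)


@dataclass
class AllelicResult:
    """Per-mutation allelic summary."""

    ccf: float
    ccf_ci: tuple[float, float]
    clonal: bool
    mut_cn: float
    mut_cn_fraction: float
    cpn_ratio: float
    ase_p: float
    ase_flag: bool


def ccf_point_estimate(vaf: float, purity: float, ncn: float = 2, tcn: float = 2) -> float:
    """Point estimate of the cancer cell fraction (uncapped)."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    return vaf / purity * ((1.0 - purity) * ncn + purity * tcn)


def mutant_cn(vaf: float, purity: float, ncn: float = 2, tcn: float = 2) -> float:
    """Estimated number of chromosomal copies carrying the mutation."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    return (vaf / purity) * (purity * tcn + ncn * (1.0 - purity))


def mutant_cn_fraction(vaf: float, purity: float, ncn: float = 2, tcn: float = 2) -> float:
    """Mutant copy number over total copy number, capped at 1."""
    return min(1.0, mutant_cn(vaf, purity, ncn, tcn) / tcn)


def _expected_vaf(ccf: np.ndarray, purity: float, ncn: float, tcn: float) -> np.ndarray:
    # single mutated copy: DNA VAF expected from a mutation at cell fraction c
    return ccf * purity / ((1.0 - purity) * ncn + purity * tcn)


def ccf_interval_clonality(
    dna_alt: int,
    dna_depth: int,
    purity: float,
    ncn: float = 2,
    tcn: float = 2,
    grid: np.ndarray = CCF_GRID,
) -> tuple[tuple[float, float], bool]:
    """95% credible interval for the CCF and the clonality call.

    The binomial likelihood of the observed DNA alt count is evaluated over
    a CCF grid (0.01..1.00, step 0.01), normalised to a posterior under a
    uniform prior; the central 95% interval is read off the cumulative
    distribution.  A mutation is clonal when the interval reaches 1 (the
    grid maximum).
    """
    if dna_depth < 1:
        raise ValueError("dna_depth must be >= 1")
    if dna_alt > dna_depth:
        raise ValueError("dna_alt exceeds dna_depth")
    mu = np.clip(_expected_vaf(grid, purity, ncn, tcn), 1e-12, 1 - 1e-12)
    like = stats.binom.pmf(dna_alt, dna_depth, mu)
    total = like.sum()
    if total <= 0:
        raise ValueError("likelihood vanished on the whole CCF grid")
    post = like / total
    cdf = np.cumsum(post)
    lower = float(grid[int(np.searchsorted(cdf, 0.025))])
    upper = float(grid[min(int(np.searchsorted(cdf, 0.975)), len(grid) - 1)])
    clonal = upper >= grid[-1]
    return (lower, upper), bool(clonal)


def _betabinom_params(mu: float, rho: float) -> tuple[float, float]:
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return a, b


def betabinom_upper_tail(m: int, t: int, mu: float, rho: float = ASE_RHO) -> float:
    """P(X >= m) for X ~ beta-binomial(t, mu, rho).

    ``mu`` is the mean success fraction and ``rho`` the intraclass
    correlation (shapes a = mu(1-rho)/rho, b = (1-mu)(1-rho)/rho).
    Degenerate means return the exact point-mass tail.
    """
    if not 0 <= m <= t:
        raise ValueError("require 0 <= m <= t")
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0,1)")
    if m == 0:
        return 1.0
    if mu <= 0.0:
        return 0.0  # X is identically 0 and m >= 1
    if mu >= 1.0:
        return 1.0  # X is identically t and m <= t
    a, b = _betabinom_params(mu, rho)
    return float(stats.betabinom.sf(m - 1, t, a, b))


def ase_test(
    rna_alt: int,
    rna_depth: int,
    vaf: float,
    purity: float,
    ncn: float = 2,
    tcn: float = 2,
    rho: float = ASE_RHO,
    alpha: float = ASE_ALPHA,
) -> tuple[float, bool]:
    """Copy-number-aware ASE test for one mutation.

    Tests whether ``rna_alt`` of ``rna_depth`` RNA reads on the mutant
    allele exceeds the genomic expectation ``CPNratio = mut_cn / tcn``
    (clipped into (0,1) to keep the beta-binomial proper).
    """
    if rna_depth < 1:
        raise ValueError("rna_depth must be >= 1")
    cpn = float(np.clip(mutant_cn(vaf, purity, ncn, tcn) / tcn, CPN_EPS, 1 - CPN_EPS))
    p = betabinom_upper_tail(rna_alt, rna_depth, cpn, rho)
    return p, bool(p < alpha)


def annotate_mutation(
    vaf: float,
    purity: float,
    dna_alt: int,
    dna_depth: int,
    rna_alt: int,
    rna_ref: int,
    ncn: float = 2,
    tcn: float = 2,
    rho: float = ASE_RHO,
) -> AllelicResult:
    """Full allelic summary of one mutation."""
    ccf = ccf_point_estimate(vaf, purity, ncn, tcn)
    ci, clonal = ccf_interval_clonality(dna_alt, dna_depth, purity, ncn, tcn)
    mcn = mutant_cn(vaf, purity, ncn, tcn)
    frac = min(1.0, mcn / tcn)
    cpn = float(np.clip(mcn / tcn, CPN_EPS, 1 - CPN_EPS))
    depth = rna_alt + rna_ref
    if depth >= 1:
        ase_p, ase_flag = ase_test(rna_alt, depth, vaf, purity, ncn, tcn, rho)
    else:
        ase_p, ase_flag = np.nan, False
    return AllelicResult(
        ccf=ccf, ccf_ci=ci, clonal=clonal, mut_cn=mcn, mut_cn_fraction=frac,
        cpn_ratio=cpn, ase_p=ase_p, ase_flag=ase_flag,
    )


def annotate_cohort(cohort: CohortTable, rho: float = ASE_RHO) -> pd.DataFrame:
    """Per-mutation allelic annotation table for a whole cohort.

    Rows lacking purity or DNA depth get NaN allelic fields but keep their
    expression class.
    """
    rows = []
    for idx, r in cohort.df.iterrows():
        expr = classify_expression(int(r["rna_alt"]), int(r["rna_ref"]))
        base = {
            "sample_id": r["sample_id"], "gene": r["gene"], "chrom": r["chrom"],
            "pos": r["pos"], "var_class": r["var_class"],
            "expression_class": expr,
        }
        if (
            pd.notna(r.get("purity"))
            and r.get("purity", 0) > 0
            and r.get("dna_depth", 0) >= 1
            and pd.notna(r.get("dna_vaf"))
        ):
            res = annotate_mutation(
                float(r["dna_vaf"]), float(r["purity"]), int(r["dna_alt"]),
                int(r["dna_depth"]), int(r["rna_alt"]), int(r["rna_ref"]),
                float(r["ncn"]), float(r["tcn"]), rho,
            )
            base.update(
                ccf=res.ccf, ccf_lower=res.ccf_ci[0], ccf_upper=res.ccf_ci[1],
                clonal=res.clonal, mut_cn=res.mut_cn,
                mut_cn_fraction=res.mut_cn_fraction, cpn_ratio=res.cpn_ratio,
                ase_p=res.ase_p, ase_flag=res.ase_flag,
            )
        else:
            base.update(
                ccf=np.nan, ccf_lower=np.nan, ccf_upper=np.nan, clonal=False,
                mut_cn=np.nan, mut_cn_fraction=np.nan, cpn_ratio=np.nan,
                ase_p=np.nan, ase_flag=False,
            )
        rows.append(base)
    return pd.DataFrame(rows)
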