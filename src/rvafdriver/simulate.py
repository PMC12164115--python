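"""Synthetic paired DNA/RNA tumor cohorts with known ground truth.

The generator reproduces the data-generating structure the driver test
assumes: per-sample tumor purity, per-mutation clonality (cancer cell
fraction), local copy number, binomial DNA read counts at the implied DNA
VAF, and over-dispersed (beta-binomial) RNA allele counts whose expected
allele fraction follows the DNA-implied fraction — shifted upward by a
planted effect ``delta`` for nonsynonymous mutations in driver genes, and
suppressed by a decile-dependent NMD factor for nonsense mutations.

It emulates count tables, not reads: library/mapping artifacts, positional
biases and shared-sample correlations beyond purity are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTable, GeneAnnotation, MUTATION_COLUMNS, VarClass
from .nmd import apply_nmd_scaling, fit_nmd_model
from .preprocess import NONSYN_VALUES, preprocess_cohort

_BASES = np.array(list("ACGT"))


@dataclass
class DriverSpec:
    """A planted driver gene: RNA-VAF elevation and mutation-rate boost."""

    delta: float  # additive RNA-VAF elevation of nonsynonymous mutations
    rate_multiplier: float = 3.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized solid-tumor cohort: 60 samples, 160 genes
    at a 5% per-gene per-sample mutation probability, a synonymous /
    missense / nonsense / splice-site mix of .30/.55/.10/.05, purities around
    0.67 (Beta(8,4)), 70% clonal mutations, RNA coverage in four expression
    tiers (15% silent), and beta-binomial RNA counts with rho = 0.05 — the
    same over-dispersion the ASE test assumes.
    """

    n_samples: int = 60
    n_genes: int = 160
    driver_genes: dict[str, DriverSpec] = field(default_factory=dict)
    base_mut_rate: float = 0.05
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "synonymous": 0.30, "missense": 0.55, "nonsense": 0.10,
            "splice_site": 0.05,
        }
    )
    purity_beta: tuple[float, float] = (8.0, 4.0)
    # (probability, NB mean, NB size) per expression tier; mean 0 = silent
    rna_depth_tiers: tuple[tuple[float, float, float], ...] = (
        (0.15, 0.0, 1.0), (0.25, 6.0, 2.0), (0.40, 30.0, 3.0), (0.20, 100.0, 4.0),
    )
    dna_depth_nb: tuple[float, float] = (80.0, 10.0)  # mean, size
    rho_rna: float = 0.05
    nmd_effect: tuple[float, ...] = tuple(np.round(np.linspace(1.0, 0.25, 10), 4))
    ccf_clonal_prob: float = 0.7
    tcn_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.60, 3: 0.20, 4: 0.10}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("need >= 2 samples and >= 1 gene")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if abs(sum(p for p, _, _ in self.rna_depth_tiers) - 1.0) > 1e-9:
            raise ValueError("rna_depth_tiers probabilities must sum to 1")
        if abs(sum(self.tcn_probs.values()) - 1.0) > 1e-9:
            raise ValueError("tcn_probs must sum to 1")
        for name, spec in self.driver_genes.items():
            if not 0.0 <= spec.delta <= 1.0:
                raise ValueError(f"delta out of [0,1] for {name}")
        if not 0.0 < self.rho_rna < 1.0:
            raise ValueError("rho_rna must lie in (0,1)")

    def annotation(self) -> GeneAnnotation:
        """Driver genes treated as the known cancer-gene list, so the
        synonymous scaling factor k is fit on non-driver genes only."""
        return GeneAnnotation(cgc_genes=set(self.driver_genes))


def _neg_binom(rng: np.random.Generator, mean: float, size_param: float, n: int):
    if mean <= 0:
        return np.zeros(n, dtype=int)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _beta_binom(rng: np.random.Generator, depth: np.ndarray, mu: np.ndarray, rho: float):
    """Beta-binomial counts; degenerate means fall back to point masses."""
    out = np.zeros(len(depth), dtype=int)
    ok = (depth > 0) & (mu > 0) & (mu < 1)
    a = mu[ok] * (1 - rho) / rho
    b = (1 - mu[ok]) * (1 - rho) / rho
    frac = rng.beta(a, b)
    out[ok] = rng.binomial(depth[ok], frac)
    out[(depth > 0) & (mu >= 1)] = depth[(depth > 0) & (mu >= 1)]
    return out


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None, cancer_type: str = "SIM"
) -> tuple[CohortTable, pd.DataFrame]:
    """Generate one cohort and its per-mutation truth table.

    Returns the cohort in the canonical mutation-table layout plus a truth
    frame recording each mutation's planted ``delta`` and expected DNA/RNA
    allele fractions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = [f"G{g:04d}" for g in range(config.n_genes)]
    gene_delta = np.zeros(config.n_genes)
    gene_mult = np.ones(config.n_genes)
    for i, g in enumerate(genes):
        if g in config.driver_genes:
            spec = config.driver_genes[g]
            gene_delta[i] = spec.delta
            gene_mult[i] = spec.rate_multiplier

    purity = rng.beta(*config.purity_beta, size=config.n_samples)
    purity = np.clip(purity, 0.05, 1.0)

    # presence matrix: gene x sample Bernoulli with driver rate boost
    p_mut = np.clip(config.base_mut_rate * gene_mult, 0, 0.9)
    present = rng.random((config.n_genes, config.n_samples)) < p_mut[:, None]
    gi, si = np.nonzero(present)
    n = len(gi)
    if n == 0:
        raise ValueError("simulated zero mutations; raise base_mut_rate")

    classes = list(config.class_mix)
    cls = rng.choice(classes, size=n, p=[config.class_mix[c] for c in classes])
    clonal = rng.random(n) < config.ccf_clonal_prob
    ccf = np.where(clonal, 1.0, rng.uniform(0.2, 0.8, size=n))
    tcn_vals = np.array(list(config.tcn_probs))
    tcn = rng.choice(tcn_vals, size=n, p=list(config.tcn_probs.values()))
    ncn = np.full(n, 2)
    pur = purity[si]

    mu_dna = ccf * pur / ((1 - pur) * ncn + pur * tcn)
    mu_dna = np.clip(mu_dna, 0.0, 1.0)
    dna_depth = np.maximum(_neg_binom(rng, *config.dna_depth_nb, n), 8)
    dna_alt = rng.binomial(dna_depth, mu_dna)
    dna_vaf = dna_alt / dna_depth

    is_nonsyn = np.isin(cls, list(NONSYN_VALUES))
    mu_rna = np.clip(mu_dna + gene_delta[gi] * is_nonsyn, 0.0, 1.0)
    nmd_score = np.full(n, np.nan)
    is_non = cls == VarClass.NONSENSE.value
    scores = rng.uniform(0, 1, size=int(is_non.sum()))
    nmd_score[is_non] = scores
    deciles = np.minimum((scores * 10).astype(int), 9)
    mu_rna[is_non] = mu_rna[is_non] * np.asarray(config.nmd_effect)[deciles]

    tier_probs = [p for p, _, _ in config.rna_depth_tiers]
    tier_idx = rng.choice(len(tier_probs), size=n, p=tier_probs)
    rna_depth = np.zeros(n, dtype=int)
    for t, (_, mean, size_param) in enumerate(config.rna_depth_tiers):
        sel = tier_idx == t
        rna_depth[sel] = _neg_binom(rng, mean, size_param, int(sel.sum()))
    rna_alt = _beta_binom(rng, rna_depth, mu_rna, config.rho_rna)
    rna_ref = rna_depth - rna_alt

    # each gene owns a disjoint 10^6 bp locus; offsets rarely adjacent
    chrom = np.array([f"chr{(g % 22) + 1}" for g in gi])
    pos = gi * 1_000_000 + rng.integers(1, 500_000, size=n)
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4

    df = pd.DataFrame(
        {
            "sample_id": [f"S{s:03d}" for s in si],
            "gene": [genes[g] for g in gi],
            "chrom": chrom,
            "pos": pos,
            "ref_allele": _BASES[ref_i],
            "alt_allele": _BASES[alt_i],
            "var_class": cls,
            "dna_vaf": dna_vaf,
            "dna_alt": dna_alt,
            "dna_depth": dna_depth,
            "rna_alt": rna_alt,
            "rna_ref": rna_ref,
            "nmd_score": nmd_score,
            "purity": pur,
            "ncn": ncn,
            "tcn": tcn,
        }
    )[MUTATION_COLUMNS]
    # enforce (sample, chrom, pos, alt) uniqueness — collisions are rare
    df = df.drop_duplicates(subset=["sample_id", "chrom", "pos", "alt_allele"])
    df = df.reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "gene": [genes[g] for g in gi],
            "sample_id": [f"S{s:03d}" for s in si],
            "chrom": chrom,
            "pos": pos,
            "var_class": cls,
            "delta": gene_delta[gi],
            "ccf": ccf,
            "mu_dna": mu_dna,
            "mu_rna": mu_rna,
        }
    ).loc[df.index].reset_index(drop=True)
    return CohortTable(cancer_type=cancer_type, df=df), truth


def run_simulated_pipeline(
    config: SimulationConfig,
    seed: int,
    mode: str = "combined",
    cancer_type: str = "SIM",
):
    """Simulate one cohort and push it through the full driver pipeline.

    Returns ``(results, info, truth)`` — see
    :func:`rvafdriver.driver_test.run_cancer_type`.
    """
    from .driver_test import run_cancer_type

    cohort, truth = simulate_cohort(config, seed=seed, cancer_type=cancer_type)
    pre = preprocess_cohort(cohort)
    model = fit_nmd_model(pre)
    scaled = apply_nmd_scaling(pre, model)
    rng = np.random.default_rng(seed + 1)
    results, info = run_cancer_type(scaled, config.annotation(), mode=mode, rng=rng)
    return results, info, truth


def calibration_experiment(
    config: SimulationConfig,
    n_reps: int = 3,
    seed: int = 0,
    mode: str = "combined",
    alpha: float = 0.05,
    q_threshold: float = 0.25,
    min_driver_samples: int = 5,
) -> dict:
    """Monte-Carlo calibration of the full pipeline.

    Pools replicate cohorts and reports: empirical type-I error (fraction of
    null genes with geometric-mean p < ``alpha``), power (fraction of planted
    drivers mutated in >= ``min_driver_samples`` samples called at
    q < ``q_threshold``), and the slope of estimated effect size on true
    delta.
    """
    rows = []
    for rep in range(n_reps):
        rep_seed = seed + 1000 * rep
        results, info, truth = run_simulated_pipeline(config, rep_seed, mode=mode)
        n_mut_samples = (
            truth[truth["var_class"].isin(NONSYN_VALUES)]
            .groupby("gene")["sample_id"].nunique()
        )
        delta_of = truth.groupby("gene")["delta"].first()
        for r in results:
            rows.append(
                {
                    "rep": rep,
                    "gene": r.gene,
                    "delta": float(delta_of.get(r.gene, 0.0)),
                    "n_mut_samples": int(n_mut_samples.get(r.gene, 0)),
                    "p_geomean": r.p_geomean,
                    "q_value": r.q_value,
                    "effect_size": r.effect_size,
                    "driver_flag": r.driver_flag,
                }
            )
    df = pd.DataFrame(rows)
    null = df[df["delta"] == 0]
    spiked = df[(df["delta"] > 0) & (df["n_mut_samples"] >= min_driver_samples)]
    report: dict = {
        "n_tested": int(len(df)),
        "n_null": int(len(null)),
        "n_spiked": int(len(spiked)),
        "type_i_error": float((null["p_geomean"] < alpha).mean()) if len(null) else np.nan,
        "power": float((spiked["q_value"] < q_threshold).mean()) if len(spiked) else np.nan,
    }
    if df["delta"].nunique() > 1:
        slope, intercept = np.polyfit(df["delta"], df["effect_size"], 1)
        report["effect_slope"] = float(slope)
        report["effect_intercept"] = float(intercept)
    report["table"] = df
    return report
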