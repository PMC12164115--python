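import math

import numpy as np
import pytest

from rvafdriver.background import (
    CLASS_SUBSETS,
    GeneTestContext,
    SamplingPlan,
    TIER_COHORT,
    TIER_GENE_SYN,
    TIER_MUTATED_SAMPLES,
    TIER_SAME_CLASS,
    TIER_SAME_SAMPLE,
    apply_syn_scaling,
    compute_sampling_rate,
    compute_syn_scaling_factor,
    n_background_per_mutation,
    sample_background,
)
from rvafdriver.io import GeneAnnotation
from rvafdriver.preprocess import compute_weights


class TestSamplingRate:
    def test_cohort_240(self):
        assert compute_sampling_rate(240) == pytest.approx(math.log(10) / 12)

    def test_small_cohort_capped(self):
        assert compute_sampling_rate(20) == 0.202

    def test_non_increasing_in_cohort_size(self):
        rates = [compute_sampling_rate(n) for n in range(2, 500, 7)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_tiny_cohort_errors(self):
        with pytest.raises(ValueError):
            compute_sampling_rate(1)


class TestNBackground:
    def test_five_percent_gene_draws_ten(self):
        rate = compute_sampling_rate(240)
        assert n_background_per_mutation(rate, 12) == 10

    def test_two_samples_at_cap_draw_one(self):
        assert n_background_per_mutation(0.202, 2) == 1

    def test_cap_binds_for_large_genes(self):
        # brute-force comparison of the exponential curve vs the 2x cap
        for n_samples in range(2, 51):
            n = n_background_per_mutation(0.202, n_samples)
            expected = min(round(math.exp(0.202 * n_samples)), 2 * n_samples)
            assert n == expected
            if math.exp(0.202 * n_samples) > 2 * n_samples:
                assert n == 2 * n_samples


def _syn_cohort(mk, syn_vafs, gene_vafs_by_gene, depth=100):
    """Synonymous background VAFs plus per-gene nonsynonymous VAFs."""
    rows = []
    for i, v in enumerate(syn_vafs):
        alt = int(round(v * depth))
        rows.append(
            {"gene": f"BG{i}", "var_class": "synonymous", "rna_alt": alt,
             "rna_ref": depth - alt, "pos": 10_000 + 10 * i}
        )
    p = 0
    for gene, vafs in gene_vafs_by_gene.items():
        for v in vafs:
            alt = int(round(v * depth))
            rows.append(
                {"gene": gene, "var_class": "missense", "rna_alt": alt,
                 "rna_ref": depth - alt, "pos": 50_000 + 10 * p}
            )
            p += 1
    return compute_weights(mk(rows))


class TestSynScalingFactor:
    def test_identical_distributions_give_one(self, mk):
        vals = list(np.linspace(0.1, 0.5, 12))
        cohort = _syn_cohort(mk, vals, {"A": vals, "B": vals})
        k = compute_syn_scaling_factor(cohort, ["A", "B"], GeneAnnotation())
        assert k == pytest.approx(1.0, abs=0.002)

    def test_halved_background_gives_two(self, mk):
        g = list(np.linspace(0.2, 0.6, 12))
        s = [v / 2 for v in g]
        # per-gene means equal the pooled values when each gene holds one VAF
        cohort = _syn_cohort(mk, s, {f"G{i}": [v] for i, v in enumerate(g)})
        k = compute_syn_scaling_factor(
            cohort, [f"G{i}" for i in range(len(g))], GeneAnnotation()
        )
        assert k == pytest.approx(2.0, abs=0.002)

    def test_objective_at_k_no_worse_than_one(self, mk, rng):
        s = list(rng.uniform(0.05, 0.4, size=30))
        genes = {f"G{i}": list(rng.uniform(0.1, 0.8, size=3)) for i in range(8)}
        cohort = _syn_cohort(mk, s, genes)
        k = compute_syn_scaling_factor(cohort, list(genes), GeneAnnotation())

        vaf = cohort.df
        syn = vaf[(vaf["var_class"] == "synonymous") & (vaf["rna_depth"] >= 8)]["rna_vaf"]
        gm = (
            vaf[vaf["var_class"] == "missense"].groupby("gene")["rna_vaf"].mean()
        )

        def obj(kk):
            return abs(kk * syn.mean() - gm.mean()) + abs(
                kk * syn.median() - gm.median()
            )

        assert obj(k) <= obj(1.0) + 1e-12

    def test_all_cgc_genes_fall_back_to_one(self, mk):
        cohort = _syn_cohort(mk, [0.1] * 12, {"TP53": [0.5, 0.6]})
        ann = GeneAnnotation(cgc_genes={"TP53"})
        assert compute_syn_scaling_factor(cohort, ["TP53"], ann) == 1.0


class TestApplySynScaling:
    @pytest.mark.parametrize(
        "vaf,k,expected", [(0.3, 1.0, 0.3), (0.6, 2.0, 1.0), (0.2, 1.5, 0.3)]
    )
    def test_examples(self, vaf, k, expected):
        assert apply_syn_scaling(vaf, k) == pytest.approx(expected)


def _sampling_cohort(mk):
    """5-sample toy cohort: gene X mutated in S1 (2 missense) and S2 (1).

    S1 carries 4 eligible synonymous mutations, S2 none; S3-S5 carry 3 each.
    """
    rows = []
    rows.append({"sample_id": "S1", "gene": "X", "var_class": "missense",
                 "rna_alt": 10, "rna_ref": 10, "pos": 100})
    rows.append({"sample_id": "S1", "gene": "X", "var_class": "missense",
                 "rna_alt": 10, "rna_ref": 10, "pos": 120})
    rows.append({"sample_id": "S2", "gene": "X", "var_class": "missense",
                 "rna_alt": 10, "rna_ref": 10, "pos": 140})
    p = 1000
    for s, n_syn in (("S1", 4), ("S3", 3), ("S4", 3), ("S5", 3)):
        for j in range(n_syn):
            rows.append({"sample_id": s, "gene": f"B{s}{j}", "var_class": "synonymous",
                         "rna_alt": 6, "rna_ref": 6, "pos": p})
            p += 10
    # same-class fallback material in S2
    rows.append({"sample_id": "S2", "gene": "OTHER", "var_class": "missense",
                 "rna_alt": 8, "rna_ref": 8, "pos": 9000})
    return compute_weights(mk(rows))


class TestSampleBackground:
    def _plan(self, rate=0.202, **kw):
        return SamplingPlan(rate=rate, **kw)

    def test_all_tier_i_when_sample_pools_suffice(self, mk, rng):
        rows = []
        for s in ("S1", "S2"):
            rows.append({"sample_id": s, "gene": "X", "var_class": "missense",
                         "rna_alt": 10, "rna_ref": 10, "pos": 100})
        p = 1000
        for s in ("S1", "S2"):
            for j in range(10):
                rows.append({"sample_id": s, "gene": f"B{s}{j}",
                             "var_class": "synonymous", "rna_alt": 6,
                             "rna_ref": 6, "pos": p})
                p += 10
        cohort = compute_weights(mk(rows))
        plan = self._plan()
        ctx = GeneTestContext("X", "all_nonsyn", cohort, plan)
        draw = sample_background(ctx, plan, rng)
        assert set(draw.tiers) == {TIER_SAME_SAMPLE}
        assert not draw.incomplete
        assert len(draw) == draw.target_n

    def test_tier_fallback_meets_quota_exactly(self, mk, rng):
        cohort = _sampling_cohort(mk)
        plan = self._plan()
        ctx = GeneTestContext("X", "all_nonsyn", cohort, plan)
        # n_samples=2 -> n=1 per mutation; S1 quota 2 (tier i), S2 quota 1
        draw = sample_background(ctx, plan, rng)
        assert len(draw) == draw.target_n == 3
        # S1's quota (2) fills from its own synonymous pool; S2 has none and
        # falls through to the other mutated sample's spare synonymous
        assert draw.tiers == [TIER_SAME_SAMPLE, TIER_SAME_SAMPLE, TIER_MUTATED_SAMPLES]
        s2_draw = cohort.df.loc[draw.indices[2]]
        assert s2_draw["sample_id"] == "S1" and s2_draw["var_class"] == "synonymous"

    def test_exhaustion_flags_incomplete(self, mk, rng):
        rows = [
            {"sample_id": s, "gene": "X", "var_class": "missense",
             "rna_alt": 50, "rna_ref": 50, "pos": 100 + i}
            for i, s in enumerate(
                [f"S{j}" for j in range(12) for _ in (0, 1)]
            )
        ]
        # fix adjacent positions
        for i, r in enumerate(rows):
            r["pos"] = 100 + 10 * i
        rows.append({"sample_id": "S0", "gene": "B", "var_class": "synonymous",
                     "rna_alt": 6, "rna_ref": 6, "pos": 9000})
        cohort = compute_weights(mk(rows))
        plan = self._plan()
        ctx = GeneTestContext("X", "all_nonsyn", cohort, plan)
        draw = sample_background(ctx, plan, rng)
        assert draw.incomplete
        assert len(draw) < draw.target_n

    def test_reproducible_for_fixed_seed(self, mk):
        cohort = _sampling_cohort(mk)
        plan = self._plan()
        ctx = GeneTestContext("X", "all_nonsyn", cohort, plan)
        d1 = sample_background(ctx, plan, np.random.default_rng(99))
        d2 = sample_background(ctx, plan, np.random.default_rng(99))
        assert np.array_equal(d1.indices, d2.indices)
        assert d1.tiers == d2.tiers

    def test_draws_unique_and_depth_eligible(self, mk, rng):
        cohort = _sampling_cohort(mk)
        plan = self._plan()
        ctx = GeneTestContext("X", "all_nonsyn", cohort, plan)
        draw = sample_background(ctx, plan, rng)
        assert len(set(draw.indices)) == len(draw.indices)
        sub = cohort.df.loc[draw.indices]
        syn_rows = sub[np.array(draw.tiers) != TIER_SAME_CLASS]
        assert (syn_rows["var_class"] == "synonymous").all()
        assert (sub["rna_depth"] >= plan.min_bg_depth).all()
        assert (sub["gene"] != "X").all()  # tested gene never in background

    def test_include_gene_syn_labelled_tier_vi(self, mk, rng):
        rows = [
            {"sample_id": "S1", "gene": "X", "var_class": "missense",
             "rna_alt": 10, "rna_ref": 10, "pos": 100},
            {"sample_id": "S2", "gene": "X", "var_class": "missense",
             "rna_alt": 10, "rna_ref": 10, "pos": 120},
            # the only eligible synonymous mutation belongs to gene X itself
            {"sample_id": "S1", "gene": "X", "var_class": "synonymous",
             "rna_alt": 6, "rna_ref": 6, "pos": 900},
        ]
        cohort = compute_weights(mk(rows))
        plan = self._plan(include_gene_syn=True)
        ctx = GeneTestContext("X", "all_nonsyn", cohort, plan)
        draw = sample_background(ctx, plan, rng)
        assert TIER_GENE_SYN in draw.tiers

    def test_class_subset_tier_iv_matches_class(self, mk, rng):
        rows = [
            {"sample_id": "S1", "gene": "X", "var_class": "nonsense",
             "rna_alt": 10, "rna_ref": 10, "pos": 100, "nmd_score": 0.5},
            {"sample_id": "S1", "gene": "X", "var_class": "nonsense",
             "rna_alt": 10, "rna_ref": 10, "pos": 150, "nmd_score": 0.5},
            # no synonymous anywhere; same-sample nonsense in another gene
            {"sample_id": "S1", "gene": "Y", "var_class": "nonsense",
             "rna_alt": 8, "rna_ref": 8, "pos": 5000, "nmd_score": 0.5},
            {"sample_id": "S1", "gene": "Z", "var_class": "missense",
             "rna_alt": 8, "rna_ref": 8, "pos": 7000},
        ]
        cohort = compute_weights(mk(rows))
        plan = self._plan()
        ctx = GeneTestContext("X", "nonsense_only", cohort, plan)
        draw = sample_background(ctx, plan, rng)
        sub = cohort.df.loc[draw.indices]
        assert set(draw.tiers) == {TIER_SAME_CLASS}
        assert (sub["var_class"] == "nonsense").all()
        assert (sub["gene"] == "Y").all()
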