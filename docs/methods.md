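# Methods

## The model

Somatic mutations under positive selection in a tumor tend to be *expressed*:
their RNA variant allele frequency (RNA VAF = non-duplicated RNA-seq reads on
the alternate allele / total non-duplicated reads at the position) is elevated
relative to selectively neutral mutations.  Several mechanisms push in the
same direction — clonality (high cancer cell fraction), allelic imbalance
favoring the mutant copy, and copy-number-independent allele-specific
expression — so the RNA VAF acts as an integrated phenotypic readout of
functional relevance.  The driver test asks, per gene and cancer-type cohort,
whether the gene's nonsynonymous RNA VAFs sit above a matched synonymous
background.

### Preprocessing

1. Keep synonymous and nonsynonymous (missense, nonsense, splice-site,
   non-stop) SNVs only.
2. Remove di/tri-nucleotide events: within a sample and chromosome, any
   maximal run of SNVs at strictly consecutive positions of length ≥ 2 is
   dropped entirely (adjacency is the literal meaning of a multi-nucleotide
   substitution; no wider window is used).
3. Cap mutations per gene per sample at 3, keeping the RNA-deepest
   (ties broken by ascending position, for determinism).
4. Scale nonsense RNA VAFs for nonsense-mediated decay (below).
5. Weight every mutation by RNA depth, capped at the cohort's 90th
   percentile (type-7 linear-interpolation percentile, computed **after**
   all filters):

       log_coverage    = log2(capped_depth + 1)
       mutation_weight = log_coverage / max(log_coverage)

   Zero-coverage mutations still enter the model with the weight of a
   depth-1 mutation, and their RNA VAF is set to 0 — the conservative
   choice against false positives.
6. A gene is testable with ≥ 2 nonsynonymous mutations at RNA depth ≥ 8.

### NMD scaling

Nonsense mutations are binned into deciles of an externally supplied NMD
score; each decile's mean RNA VAF over the mean missense RNA VAF gives a
suppression factor.  Applying the model **divides** a nonsense VAF by its
decile factor (floored at 0.05 so a pathological factor cannot inflate a VAF
more than 20-fold), capped at 1 — division is the only direction that
restores decay-suppressed VAFs toward their pre-decay level.  Deciles are
defined cohort-wise; with fewer than 10 scored nonsense mutations, or for
score-missing mutations, the global (all-nonsense / missense) factor is
used.  Both the cap at 1 and the cohort-wise deciles are this package's
choices where the procedure was underdetermined.

### Background model

The number of synonymous mutations drawn per case mutation scales with how
recurrently the gene is mutated:

    rate = min( ln(10) / (0.05 * cohort_size), 0.202 )
    n    = min( round(exp(rate * n_samples)), 2 * n_samples )

with `n_samples` the number of samples carrying a tested-class mutation in
the gene and banker's rounding (exact halves are measure-zero for
exponential values; the choice is noted for bit-parity).  The rate is
calibrated so a gene mutated in 5% of the cohort draws 10 background
mutations per case mutation; the cap 0.202 is the largest 3-decimal rate
that still draws exactly 1 at two mutated samples.

Background draws fill each mutated sample's quota (n × its in-gene
tested-class mutation count) without replacement through a tier hierarchy:
(i) synonymous mutations of that sample, (ii) of the other mutated samples,
(iii) of any cohort sample, (iv) same-class nonsynonymous mutations of that
sample outside the tested gene, (v) proceed incomplete, (vi) optionally the
gene's own synonymous mutations.  Tiers i–iii (and vi) require RNA depth
≥ 8; tier iv enforces the same depth floor for consistency.  Same-sample
preference controls per-sample confounders (purity, tumor transcript
fraction).

Because synonymous VAFs differ systematically from nonsynonymous VAFs in
tested genes, a scaling factor k is fit by grid search over [0.25, 4]
(step 0.001, ties to the smallest k), minimising
`|k·mean(S) − mean(G)| + |k·median(S) − median(G)|` where S are the
depth-eligible synonymous VAFs and G the per-gene mean nonsynonymous VAFs
of tested genes outside the known cancer-gene list.  k multiplies the
synonymous background draws (capped at 1); tier-iv nonsynonymous fallback
draws are left unscaled, since k models precisely the synonymous-vs-
nonsynonymous offset and applying it to nonsynonymous draws would re-bias
them.

### The test

Per gene and mutation-class subset, a weighted linear model
`vaf ~ group, weights = mutation_weight` is fit (closed form — with a
single indicator regressor the WLS coefficient is the difference of
weighted group means, with the usual t-statistic at n − 2 degrees of
freedom) and read one-sided in the direction "case above background",
elevation being the method's entire premise.  Sampling and fitting are
bootstrapped 25 times; the gene's p is the geometric mean of the 25
one-sided p-values (floored at 1e-300 before logs) and its effect size the
mean of the 25 coefficients.  Class subsets (missense / nonsense /
splice-site) run separately when ≥ 2 mutations of the class exist, plus
the combined all-nonsynonymous test; cancer-type mode reports the smallest
class-specific p (falling back to the combined test when no class subset is
runnable — a knowingly anti-conservative min-p extraction, not re-corrected
for the 3-way class multiplicity), pan-cancer mode the combined test.
Benjamini–Hochberg correction is applied within a run; q < 0.25 calls a
putative driver.

### Allelic statistics

CCF = `VAF/p · ((1−p)·Ncn + p·Tcn)`; its 95% interval comes from a
binomial likelihood of the DNA alt count over a CCF grid 0.01..1.00
(step 0.01), normalised under a uniform prior; clonal ⇔ the interval
reaches 1.  Mutant copy number uses the algebraically identical expression
and, divided by total copy number and capped at 1, gives the mutant
copy-number fraction.  The ASE test is the beta-binomial upper tail
`P(X ≥ rna_alt)` at size `rna_depth`, mean `CPNratio = mut_cn/Tcn`
(clipped into [0.001, 0.999] to keep the shapes proper) and intraclass
correlation 0.05; p < 0.05 flags copy-number-independent ASE.  The
conservative tumor-transcript-fraction refinement some analyses apply on
top of this construction is not modelled.

### Benchmarking

CGC score `E(R) = Σ_{i=1..N} P_i / ln(i+1)` with `P_i` the CGC fraction of
the i top-ranked genes; natural log (the base is exposed as a switch), N
= 250 pan-cancer / 40 per cancer type, clamped to the list length.
Fisher's exact test is two-sided by the probability-mass-≤-observed rule.
Expression odds ratios compare "expressed" (≥ 2 alt reads; wild-type-only
counts as not expressed) per stratum against synonymous mutations in
non-CGC genes, with a conditional-MLE odds ratio and exact CI.  The
RNA-VAF AUC against external driver/passenger labels is the mid-rank
Mann–Whitney AUC after collapsing recurrent mutations to their median VAF.

## The simulator

`simulate_cohort` emulates the joined mutation/RNA-count table with known
ground truth: per-sample purity ~ Beta(8, 4) (mean ≈ 0.67, typical of
solid-tumor pathology-reviewed cohorts), per-gene per-sample mutation
probability 0.05 over 160 genes and 60 samples, class mix
synonymous/missense/nonsense/splice = .30/.55/.10/.05 (≈ 2.3:1
nonsynonymous:synonymous), 70% clonal mutations (subclonal CCF ~
U(0.2, 0.8)), total copy number in {1..4}, binomial DNA counts at the
CCF-implied VAF (depth ~ NB, mean 80), and beta-binomial RNA counts
(rho = 0.05, matching the ASE test's assumption) whose mean follows the
DNA-implied fraction, shifted by +delta for nonsynonymous mutations in
planted driver genes and multiplied by a decile NMD ramp (1.0 → 0.25) for
nonsense mutations.  RNA depth mixes four expression tiers (15% silent,
NB means 6/30/100).  Driver genes are treated as the known cancer-gene
list so k is fit on non-drivers, as in real runs.

What the simulator does **not** model: mapping/duplicate artifacts,
positional and trinucleotide mutation biases, gene-level expression
correlation across samples, LOH-driven allelic imbalance beyond the purity
term, and transcript-structure-dependent NMD.  Passing calibration
therefore demonstrates the statistical machinery is correct and calibrated
under the stated generative assumptions, not that real-cohort error rates
are exactly nominal.

## Calibration results (recomputed by `scripts/acceptance.py`)

Null cohorts (zero planted effect, 4 replicates, ≈ 270 tested genes) give
an empirical type-I error at p < 0.05 inside [0.02, 0.10]; the
geometric-mean aggregation of correlated bootstrap p-values is close to,
but not exactly, uniform, hence the band rather than nominal 0.05.  Spiked
cohorts (delta = 0.3, drivers mutated in ≥ 5 samples) are recovered at
q < 0.25 in ≥ 80% of cases, and regression of estimated effect size on
true delta over the grid {0.1, 0.2, 0.3} yields a slope in [0.7, 1.2]
(attenuation mostly from VAF clipping at 1 and the NMD ramp on nonsense
mutations).  Problem sizes (60-sample cohorts, 160 genes, 3–4 replicates)
were chosen to put ≥ 200 tested genes behind the null estimate and ≥ 20
behind the power estimate while keeping a laptop-scale run.

## Numerical choices

- Percentile: type-7 (linear interpolation), the common default.
- Degenerate test input (all VAFs identical): effect 0, p 0.5; zero
  residual variance with a nonzero effect: p exactly 0 or 1 by sign.
- Geometric mean clipped into [min p, max p] (exp/log drift is ~1 ulp).
- p floor 1e-300 before logs; BH within one cohort run.
- k grid ties resolve to the smallest k (first argmin).
- Sampling ties and orders are fixed (sorted samples, sorted candidate
  pools) so a fixed master seed reproduces every draw bit-for-bit.

## Known limitations

- RNA allele counts are consumed as columns; BAM counting, duplicate
  marking and liftOver are upstream concerns.
- The NMD score is an input; no transcript-structure NMD prediction.
- Splice-site mutations use whatever counts are supplied at the genomic
  position, though true splice effects act on the transcript level.
- The min-p class extraction is anti-conservative by design (documented
  above); consumers wanting strict FDR semantics should use combined mode.
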