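# Methods

## Pipeline and model

`permde` analyses a two-group (case/control) gene-level count matrix with a
companion FPKM matrix. The stages run in a fixed order; permuting them
changes results, and an integration test pins the order.

1. **Expressed-gene filter** (on FPKM). A gene is kept iff it has nonzero
   FPKM in at least ⌈f·n⌉ samples of the case *or* the control group
   (default f = 0.5) *and* its maximum nonzero FPKM exceeds a cutoff
   (default 1.0). The filter is computed on the FPKM matrix and applied to
   the count matrix by gene id; a mismatch between the two gene universes
   is an error, never a silent drop.
2. **TMM scale factors** (on counts of retained genes). Trimmed mean of
   M-values: with library-size-scaled proportions, per gene
   M = log2 ratio vs a reference sample and A = mean log2 abundance; genes
   zero in either sample are excluded, both tails of M (30%) and A (5%)
   are trimmed by rank (average ranks for ties), and the kept M are
   averaged with inverse asymptotic-variance weights
   1/v = [(N_s−y_s)/(N_s y_s) + (N_r−y_r)/(N_r y_r)]⁻¹. The reference
   sample is the one whose upper-quartile count fraction is closest to the
   mean (configurable). Factors are rescaled to geometric mean 1. The
   implementation agrees with edgeR 4.0.16 `calcNormFactors` to 1e-8 on a
   mixed depth/composition fixture and exactly with a hand-derived
   composition-shift fixture (both frozen in the tests).
3. **Log transform.** value = log2(count / s + 1) where
   s = (library size × TMM factor) / geometric mean of the same — i.e.
   depth and composition scaling are folded into one per-sample divisor
   with geometric mean 1, keeping values on the count scale. This is the
   simplest reading of "counts normalized by TMM, then log2(count+1)";
   it matters because the divisor directly rescales log2 fold-changes.
4. **Quantile normalization.** Each sample's sorted values are replaced by
   the across-sample means of sorted values (rank means); tied values
   within a sample receive the mean of their tied positions' rank means,
   which makes the result deterministic. Note the tie rule and the
   "all sorted columns identical" postcondition cannot both hold on tied
   inputs; we follow the tie rule. On tie-free columns the operation
   leaves all samples with one shared sorted vector and is idempotent
   (property-tested).

### Differential expression

For each gene, on the quantile-normalized log2 matrix:

- log2FC = mean(case) − mean(control); t = Student pooled-variance
  two-sample statistic (Welch available via `t_flavor="welch"`). A
  variance floor — the 1st percentile of the per-gene scale estimates —
  keeps t finite for zero-variance genes.
- **Empirical nulls**: group labels are reassigned uniformly at random
  (group sizes preserved, identity allowed), default 300 times. Since
  C(10,5) = 252 < 300, assignments are sampled with replacement (a warning
  notes this). Both statistics are recomputed per permutation, with the
  variance floor re-derived within each permutation, and draws are
  **pooled across genes**: at 300 permutations a gene-specific null is far
  too coarse for p < 0.05, and the statistics are pivotal enough (t is
  scale-free; log2FC spreads are comparable under a common dispersion)
  for pooling to calibrate well — the empirical t p-value fires at
  0.050 ± 0.002 under the null and passes KS uniformity (computed by the
  acceptance script).
- **Empirical ("adjusted") p-values** are two-tailed with the +1 rule,
  p = (#{|null| ≥ |stat|} + 1)/(N + 1) ∈ (0, 1]; no additional BH step is
  applied.
- **Stouffer combination**: z_i = Φ⁻¹(1 − p_i), z = (z_t + z_fc)/√2,
  p = 1 − Φ(z). Inputs are clipped to [1e-15, 1 − 1e-15] (a p of exactly 1
  arises from the +1 rule and is clipped, not rejected); clipping is
  logged.
- **DEG call**: p_combined < 0.05 ∧ p_t < 0.05 ∧ |log2FC| > cutoff;
  direction = sign(log2FC). The default cutoff is 0.58 (1.5-fold). The
  **adaptive cutoff** for datasets with a different null fold-change
  spread is the mean of the *absolute values* of a symmetric percentile
  pair (10/90 or 2.5/97.5) of the pooled null log2FC distribution. The
  literal "mean of the 10th and 90th percentiles" of a near-symmetric
  null would be ≈ 0 and could never act as a positive cutoff, so the
  absolute-value reading is used; for a N(0, σ) null the 10/90 pair gives
  1.2816σ (checked against the closed form).

### Enrichment

One-sided hypergeometric over-representation of a query gene list against
a background, per term: p_fisher = P(X ≥ k), and the **EASE score**
p_ease = P(X ≥ max(k−1, 0)) — one success removed, so a single-gene
overlap can never look significant and p_ease ≥ p_fisher always. A term
is flagged enriched iff p_ease < α (default 0.05) *and* overlap count
k ≥ 5; no multiple-testing correction enters the flag (a BH column is
emitted for information). The background defaults to the expressed-gene
universe from the filter — the statistically defensible choice when the
queries are themselves drawn from that universe — and is configurable.
The "count ≥ 5" reading (rather than "> 5") is used and exposed as a
flag. Up- and down-regulated lists are tested separately.

### Integration

Gene-level: exact set arithmetic over the 2^m − 1 Venn regions of m DEG
lists. Pathway-level: a term is shared iff its *enriched flag* (i.e. after
the p and count filters) is true in every cohort for the given direction;
term identity is the id string, with no ontology-aware matching or graph
propagation. A presence matrix with each cohort's p_ease accompanies the
shared set.

### Validation statistics

ΔΔCT with amplification efficiency fixed at 2 (the classical assumption):
ΔCT = CT_target − CT_reference per sample (technical replicates sharing a
sample id are averaged first), ΔΔCT = ΔCT − mean control ΔCT,
RQ = 2^(−ΔΔCT); groups are compared by Welch's t on the RQ values (the
comparison is reported as NaN on degenerate plates, e.g. noiseless
constant groups). Student's t (pooled, df = n_a + n_b − 2) and Pearson χ²
without continuity correction serve the clinical tables; Yates correction
and a Fisher exact alternative are exposed for small cells. Percentages
are reported to one decimal; continuous variables as mean ± SE with
SE = sd/√n.

## Synthetic data

The generator emulates a small whole-blood-style RNA-seq study:

- counts_gs ~ NB(mean = lib_s · q_g · 2^(±effect/2), dispersion φ) via a
  Gamma–Poisson mixture, with Var = μ + φμ². Defaults: 5 vs 5 samples,
  φ = 0.1 (BCV ≈ 0.32, typical for human cohort samples), mean library
  size 10⁶ at 2000 genes (so per-gene depth matches a ~20M-read,
  ~20k-gene study). φ is constant across genes — the simplest structure
  that stresses the test.
- baseline abundances q_g log-normal (σ = 1.5) so the FPKM filter has
  bite; gene lengths uniform 0.5–10 kb; FPKM = count / (length_kb ·
  mapped_millions), with lengths carried in the output for round-trips.
- planted effects split symmetrically (±effect/2 per group) so library
  totals stay balanced; up/down genes disjoint.
- multi-cohort scenarios plant each cohort's up-genes inside one shared
  annotation term with a controlled pairwise overlap (a common core of
  round(f·m) genes, the remainder disjoint across cohorts where capacity
  allows); decoy terms of matched size are sampled without regard to DE
  status so enrichment nulls hold. Down-genes follow the same scheme
  outside the term.
- qPCR plates put independent N(0, σ) noise on each CT channel and shift
  the case group's target CT down by the planted ΔCT.

What the generator does *not* model: batch effects, paired designs,
gene-wise dispersion trends, correlated genes, library-preparation
artefacts, or read-level error. Passing tests therefore demonstrate the
statistical machinery under the assumed NB model, not robustness to these
real-data features.

## Type-I behaviour of the three-criterion rule

Each criterion is individually calibrated, but the rule's *joint* null
rate is dominated by the correlation between t and log2FC: under a common
dispersion the per-gene SE is nearly constant, corr(|t|, |fc|) ≈ 0.9, and
the combined-p criterion is implied by the other two. At φ = 0.1 the null
log2FC sd is ≈ 0.29, so P(|fc| > 0.58) ≈ 0.05–0.07, and the full-criteria
null rate settles near P(p_t < 0.05) · P(|fc| > 0.58 | t in top 5%) ≈
0.03 — the acceptance script computes ≈ 0.032, with a corresponding
false-discovery proportion ≈ 0.26 at planted effect 1 with 10% DE genes.
The fold-change cutoff only suppresses false positives when the null
fold-change spread sits well below it (lower dispersion, larger n, or an
adaptive cutoff at wider percentiles).

## Numerical choices

- Variance floor quantile 0.01 (configurable; 0 disables while still
  guarding exact-zero variance via the floating-point tiny).
- Stouffer clip 1e-15; empirical p's never 0 by the +1 rule.
- Quantile-normalization ties: mean of tied rank means (deterministic).
- TMM: genes zero in sample or reference excluded; all-zero samples are
  an error; a sample identical to the reference short-circuits to
  factor 1 when max |M| < 1e-6.
- Adaptive cutoff percentiles are linear-interpolated sample percentiles.
- Seeds: every stochastic component takes an explicit seed; experiment
  harnesses derive child seeds (< 2³¹) from one base seed via
  `SeedSequence`, and identical configurations reproduce outputs
  byte-identically.

## Experiment harnesses and problem sizes

`permde.experiments` packages the three reproducibility studies used by
`scripts/acceptance.py` and the test suite, at desk-scale sizes chosen to
make Monte-Carlo error small relative to the effects measured: null
calibration (20 replicate cohorts × 2000 genes, 300 permutations),
planted-effect recovery (5 replicates × effects {0.5, 1, 2}, 10% DE), and
three-cohort shared-pathway integration (10 replicates, shared term of
200 genes, pairwise planted overlap 5%, 20 decoy terms).
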