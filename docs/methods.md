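# Methods

This note documents the models and procedures implemented in `refstab`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Screening cascade

The screening substrate is a genes × samples FPKM matrix partitioned into
datasets, each with condition groups defined by the distinct
(variety, tissue, treatment) combinations of its samples.

**Abundance (criterion i).** A gene passes in a dataset iff its mean FPKM
exceeds `abundance_fraction` (default 0.70) times the dataset's grand-mean
FPKM over all genes and samples. We read "the whole sample's average" as
that grand mean; a per-sample percentile reading is the main alternative
and would demand a different threshold semantics entirely.

**Ratio window (criterion ii).** Per dataset, every condition group's mean
FPKM divided by the gene's dataset-wide mean must lie in
[`ratio_low`, `ratio_high`] (default [0.75, 1.25]). Group means — not
individual replicates — are compared, so replicate noise is not conflated
with treatment response. A zero dataset-wide mean marks the gene "not
expressed" (fail) rather than raising a division error.

**ANOVA (criterion iii).** One-way ANOVA of the gene's FPKM across the
dataset's condition groups; the gene passes iff p > `anova_alpha`
(default 0.05). The filter deliberately *retains* non-significant genes,
so no multiple-testing correction is applied — correction would loosen,
not tighten, the criterion. Degenerate inputs follow a fixed convention:
zero within-group variance everywhere with equal means ⇒ p = 1 (pass);
with differing means ⇒ p = 0 (fail). Datasets with fewer than two
condition groups (or without two replicated groups) cannot support ANOVA;
they are excluded with a warning and do not count toward presence,
because a gene cannot demonstrate within-dataset stability there.

**Presence.** A gene is kept iff it passes all three filters in at least
`min_dataset_presence` datasets (default 2).

**Correlation selection.** Each kept gene's profile is its mean
log₂(FPKM+1) per (dataset, tissue, treatment) cell; the +1 offset and log
transform stabilize variance across the expression range. Pairwise
Pearson r is computed between profiles; a partner contributes r² when
r > 0 and 0 otherwise (anti-correlated genes are not co-expressed). The
default score is the **maximum** contribution — the best positively
correlated partner — and selection requires score ≥ `corr_r2_threshold`
(default 0.95) with best-partner p < `corr_alpha` (default 0.01).
Median and mean aggregations are available but cannot serve as defaults:
the kept pool is legitimately dominated by genes that are stable within
datasets yet mutually uncorrelated across them, so any averaging over
partners is pinned near zero for *every* gene and the selection stage
would return the empty set no matter how good the candidates are.
Identifying "the genes with the highest positive correlation
coefficients" is inherently a top-partner criterion. A zero-variance
profile gets score 0 with a reason flag.

A consequence of partner-dependent scoring worth knowing: loosening an
upstream threshold enlarges the kept pool and thereby changes every
gene's partner list, so the *selected* set is only guaranteed monotone in
the two correlation thresholds; the *kept* set is monotone in every
threshold.

## Stability algorithms

All methods operate per tissue on a complete gene × sample Cq grid after
technical replicates are aggregated by arithmetic-mean Cq (mean on the
cycle scale = geometric mean of template quantity; the conventional
choice for triplicate designs — no outlier rejection is applied, since no
principled rule is available without raw fluorescence data).

Relative quantities are Q_gs = E_g^(minCq_g − Cq_gs), so Q ∈ (0, 1] with
per-gene maximum 1. Amplification efficiency defaults to E = 2 for every
gene (the classic convention); per-gene efficiencies from standard curves
can be attached to the Cq table and are then used throughout. The
defaults keep E = 2 even when efficiencies are known, because the
stability literature ranks on uncorrected quantities and mixing
conventions changes none of the rankings materially while complicating
comparisons.

* **geNorm.** V_jk = SD over samples of log₂(Q_j/Q_k); M_j = mean over
  partners. The exclusion ranking repeatedly removes the highest-M gene
  (ties broken by gene id, lexicographically last removed, so the
  procedure is deterministic) until two remain; those two tie at rank
  1.5. Both the full-panel M and the exclusion ranks are reported, and
  the V_n/n+1 series for choosing how many references to use is
  available. With all E = 2, V_jk equals the SD of per-sample Cq
  differences exactly, and M equals the comparative ΔCt statistic — an
  algebraic identity asserted numerically in the tests.
* **NormFinder.** On y = log₂ Q, each sample is centered by its
  across-gene mean (removing loading offsets). Per gene × group the mean
  a_ig and variance s²_ig of centered values are computed. Centering
  correlates residuals — Var(z_i) = σ²_i(1 − 2/k) + Σσ²/k² for k genes —
  so intra-group variances are de-biased by inverting that relation
  (requires k ≥ 3; negative estimates clip to zero). Inter-group
  differences d_ig = a_ig − mean_g(a_ig) are shrunk toward zero by an
  empirical-Bayes factor γ²/(γ² + σ̂²_ig/n_g), with γ² the inter-group
  variance net of sampling. The stability value is
  ρ_i = mean_g(|d̃_ig| + SD(d_ig)); with one group the model degenerates
  to the SD of the gene's centered values. The correction constants live
  in one documented helper and are validated by the degenerate-case
  oracle and by simulation recovery.
* **BestKeeper.** Sample SD of raw Cq is the ranking statistic (the mean
  absolute deviation of the original tool is available behind a flag);
  CV% and the Pearson correlation with the per-sample geometric-mean
  index are reported but not ranked on. A constant index makes the
  correlation undefined; it is reported missing, not raised.
* **Comparative ΔCt.** Mean over partners of the SD of per-sample Cq
  differences.
* **Comprehensive rank.** Geometric mean of the per-method ranks (all
  four methods by default; the set is configurable). Final ordering
  breaks ties by mean z-score of the raw stability values, then gene id.

The tissue ranking pools both varieties and all treatments (treatment is
the NormFinder group factor); ranking per variety would halve the sample
size per run without changing the group structure.

**The methodological fingerprint** the tests pin down: adding an
arbitrary per-sample constant to all genes (loading/pipetting variation)
leaves geNorm, ΔCt and NormFinder values unchanged — ratios and sample
centering cancel it — while BestKeeper's SD must change, since raw-Cq
scatter is exactly what it measures.

## Quantification

Standard curves are least-squares fits of Cq against log₁₀(dilution);
E = 10^(−1/slope), reported as a percentage (E = 2 ⇔ 100%, slope
−3.3219). Fits require ≥ 3 points spanning ≥ 2 decades and a negative
slope.

Relative expression of a target against references r ∈ R in sample s is

    FC_s = E_t^(Cq_t,cal − Cq_t,s) / ∏_r [E_r^(Cq_r,cal − Cq_r,s)]^(1/|R|)

with the calibrator Cq the arithmetic-mean Cq of the tissue's mock (CK)
biological replicates, per gene. This makes the CK geometric-mean fold
change exactly 1 under every scheme. Replicate statistics are computed on
log₂ fold changes (symmetric errors) and the mean is reported back on the
linear scale. Efficiency correction is off by default (plain 2^(−ΔΔCq));
enabling it uses per-gene fitted efficiencies. Duplicate references
collapse to the distinct set, so a scheme listing one gene three times
equals the singleton scheme.

`compare_normalizations` runs several schemes and summarizes divergence
as the maximum over conditions of |log₂ FC − log₂ FC_baseline| on the
per-condition mean profiles — the quantitative version of "the response
pattern looks different under a bad reference".

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth at the reference design's scale: six
RNA-seq datasets (2 varieties × 3 treatments × 3 replicates each, one
organ per dataset) and a Cq experiment over 2 varieties × 3 tissues ×
3 treatments (mock/salt/drought) × 3 biological × 3 technical replicates.
All noise is Normal on the log scale (log₂-FPKM, Cq cycles) — both are
log-quantities, and multiplicative noise is the natural model. Every
generator is deterministic given its seed.

**FPKM panels.** Candidate genes sit at high expression (log₂ FPKM
6.5–8) and follow a shared expression context per dataset: organ-anchored
offsets evenly spaced over ±`shared_profile_sd` (default 1 log₂ unit)
plus N(0, 0.3·sd) per-dataset jitter. Organ identity is the dominant,
systematic axis of expression variation in plant atlases; anchoring it
guarantees the across-dataset spread that genuinely co-expressed genes
exhibit, where freely resampled contexts would occasionally produce six
near-identical datasets and erase the correlation signal by sampling
accident. Background genes instead get independent per-(gene, dataset)
deviations (SD 1.5 log₂) — dataset-specific regulation — so they pass the
within-dataset filters at null rates yet decorrelate across datasets;
their expression levels span a low stratum (log₂ −1 to 3.5) that the
abundance filter removes. Unstable candidates add condition-group shifts
(zero in the control group, sign random, magnitude 0.5–1 ×
`treatment_effect` per group).

**Cq experiments.** Per gene a base Cq is drawn in 24–34 cycles (inside
the span observed for abundantly expressed genes; well below the
44-cycle ceiling, at which a reaction counts as not-detected and is
rejected for reference candidates). Every gene in a sample shares a
loading offset (SD 0.3 cycles) — the structure ratio methods cancel —
plus per-gene biological noise (`stable_noise_sd`, default 0.15 cycles)
and technical noise (0.1 cycles per technical replicate). Planted
unstable genes model *failed reference candidates*: each
(variety × stress) group independently perturbs the gene with
probability 0.7 (at least one group guaranteed) by a random sign times
1–1.5 × `treatment_effect` cycles. Two modeling points matter here.
First, magnitudes must vary: identical shift magnitudes leave only a
handful of possible response patterns, and genes sharing a pattern are
perfectly co-regulated — a degenerate panel that defeats ratio-based
ranking by construction, not by biology (geNorm's documented weakness).
Second, perturbations are per-group rather than coherent stress
responses shared across varieties, because an unsuitable reference gene
is one whose expression wanders erratically across conditions; coherent
stress-marker behavior is a special case users can approximate with a
response probability of 1.

**What passing tests do not show.** The generator does not simulate
reads, mapping, or FPKM estimation; count-based overdispersion,
between-gene correlation beyond the single shared context, batch
structure, or Cq outliers from pipetting failures are absent. Recovery
rates measured here therefore bound what these algorithms do under clean
log-normal noise at these sample sizes, not their behavior on
arbitrary real data.

## Problem sizes and numerical choices

Oracle-equivalence checks run 100 random instances of ≤ 8 genes × ≤ 12
samples at 1e-9 (identities at 1e-12). Stability ground-truth recovery
uses 200 replicates of the 12-candidate, 18-sample-per-tissue design;
screening recovery uses 100 replicates of the six-dataset panel
(52 genes); ANOVA null calibration uses 240 Bernoulli trials — at that
size the binomial 99% interval comfortably covers the mild miscalibration
the F-test shows on raw (log-normally noised) FPKM, which is also how the
filter is applied in practice. Quantification bias uses 200 replicates at
0.1-cycle noise. Sample SDs use ddof = 1 throughout. All stochastic tests
fix their seeds.

## Known limitations

* NormFinder's variance combination follows the original
  variance-components formulation but is validated against its degenerate
  case and simulation recovery, not against the historical binary;
  third-party implementations differ in small bias terms.
* The screening ANOVA is one-way over the flattened condition groups;
  factorial (two-way) structure is out of scope.
* BestKeeper's index correlation is reported but never ranked on; the
  original tool's significance machinery around it is not reproduced.
* Instrument-native export formats are not parsed; inputs must be
  pre-converted to the documented CSV/TSV layouts.
* Missing Cq cells are a hard error (drop-the-sample is available via
  subsetting); no imputation is offered, since every stability algorithm
  assumes a complete grid.
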