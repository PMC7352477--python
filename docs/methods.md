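# Methods

This note records the models, conventions and numerical choices behind
`tepswarm`, and what the synthetic cohorts do and do not establish.

## Input contract

The molecular input is a transcripts × samples matrix of **spliced-junction
read counts** (intron-spanning reads only). Working at transcript level
from junction totals means no gene-length normalization applies anywhere in
the pipeline. Sample annotation carries the class (`sarcoma` / `control`),
a control subtype (`healthy` / `former-sarcoma` — former patients are
pooled into the control class and the subtype is reporting metadata only),
age, gender, and the series assignment (`training` / `evaluation` /
`validation`).

## Normalization and filtering

- **Coverage filter**: a transcript is "detected" if its total count is
  ≥ `min_total_reads` (default 30) and it is nonzero in at least
  `min_samples_expressed` (default 3) samples. These defaults are the
  package's own choice of a conventional low-coverage screen; they are
  deliberately mild and logged with every run.
- **Normalization** is log₂ counts-per-million with pseudocount 1,
  `log2(1e6·c/L + 1)`. This is a fully specified, invertible transform; no
  latent-factor (RUV/ComBat-style) correction is attempted. Library-size
  artifacts are instead controlled by the tunable correlation filter below.
- **Library-size correlation filter**: Pearson r of each transcript's
  normalized values against log₂ library size; keep r ∈ [c_lib, 1].
  Correlating against the log of depth keeps the relation linear on the
  modeling scale. Zero-variance transcripts get r = 0 so the filter is
  total (a constant transcript is neither kept nor dropped for spurious
  reasons).

## Differential statistics

Per transcript, one-way fixed-effects ANOVA between the two classes on the
normalized scale. With two groups F = t² of the pooled-variance two-sample
t statistic and p comes from F(1, n−2); the implementation is vectorized
and verified against an independent t-test oracle. Constant transcripts are
assigned F = 0, p = 1 (no evidence) rather than NaN. Multiplicity is
handled by Benjamini–Hochberg step-up (via statsmodels), and significance
uses the strict rule q < threshold. Ranking for panel construction is
ascending (q, p, transcript id) — fully deterministic. Covariate-adjusted
models are out of scope: the study design this package targets controls age
and gender by cohort matching, not by modeling.

## Panel construction and the TEP-score

The selection pipeline (library-size filter → ANOVA/BH → FDR cut → label
correlation cut → top-k) runs on the **training series only**. "Correlated
transcripts" is interpreted as |point-biserial correlation| with the 0/1
class label ≥ the threshold. An FDR threshold at the top of its range
(q\* ≥ 1.0) disables the FDR cut entirely rather than dropping q = 1 ties,
so the widest particle reduces to "everything passing the correlation
filters". A particle whose filters leave nothing yields a **degenerate
panel** that scores every sample 0.5 (chance) — degeneracy is a valid,
traversable region of the search space, not an error.

Selected transcripts are z-scaled by training mean/sd (sd 0 is stored as 1)
and an RBF-SVM is fitted with C = 1 and γ = 1/panel-size; the swarm tunes
only the four selection parameters, so the classifier itself is held fixed.
Probability calibration is an explicit Platt fit: a 1-D logistic regression
of the training labels on the SVM decision values, giving
TEP-score = σ(a·f(x) + b). Scoring uses only the arrays stored in the panel
(support vectors, dual coefficients, intercept, scaling constants,
calibration line), so a panel serializes losslessly to one JSON artifact
and the in-memory and reloaded panels give bit-identical scores.

Calls use score ≥ cutoff → sarcoma (default cutoff 0.5); the tie at exactly
the cutoff goes to the positive class, the high-sensitivity direction.

**Locking.** `optimize` returns the winning panel locked. Held-out scoring
paths require a locked panel and refuse otherwise; locked panels are frozen
dataclasses whose content hash is unaffected by any amount of scoring. The
leakage guarantee is structural — the optimizer never receives validation
samples — and is asserted by a test that deletes the validation series and
checks the locked artifact is byte-identical.

**LOOCV.** Each training sample is scored by a panel selected *and* fitted
on the other n−1 samples, so feature selection cannot leak the held-out
sample. A fold whose removal leaves fewer than two samples in a class is
flagged and scored 0.5.

## Particle-swarm optimizer

Standard inertia-weight PSO: v ← 0.72·v + 1.49·r₁(pbest−x) + 1.49·r₂(gbest−x),
x ← clamp(x+v), zero initial velocities, uniform initial positions. These
constants are conventional constriction-equivalent defaults and are exposed
in the run configuration. The ranked-count dimension flies continuously and
is rounded only when a particle is evaluated, keeping the update rule
uniform across dimensions. One particle is pinned to the documented default
(c_lib = −0.1, q\* = 0.05, c_lab = 0.5, k = min(1000, n_detected)), so the
final result is never worse than the default pipeline. Ties for the global
best keep the earliest particle in (iteration, index) order; with a fixed
seed the whole search, including the locked panel, is reproducible
bit-for-bit. Fitness is the evaluation-series AUC (Mann–Whitney pair
counting, ties ½).

The clustering variant swarms a single dimension (the FDR threshold, other
parameters at defaults, default budget 200 particles × 12 iterations) with
fitness −log₁₀ of the cluster–class association p, passed through a
monotone clip to [0, 1] (divide by 300 after capping) to satisfy the
unit-interval fitness contract.

## Evaluation

- **AUC**: Mann–Whitney pair counting; verified against trapezoidal ROC
  area. 95% CI by stratified percentile bootstrap (2,000 resamples,
  seeded); the interval is clipped to [0, 1] and widened if needed to
  contain the point estimate.
- **Confusion tables**: full-precision rates internally; displayed rates
  are rounded to whole percents. An absent class makes its rate NA with a
  warning rather than an exception.
- **Shuffled-label control**: permute training+evaluation labels, re-run
  the entire optimization, score the untouched validation series with true
  labels; report median and IQR over shuffles. This is the permutation null
  for the whole pipeline, selection included.
- **Shuffled-training control**: re-draw the training/evaluation split with
  labels intact and re-optimize; a split-robustness check, expected to stay
  near the unshuffled validation AUC. Redraws that collapse a class are
  skipped and the effective count reported.
- **Signature overlap**: exact Venn cells for 2–3 named transcript sets;
  per-set unique fractions formatted `unique/total (pct%)`.

## Clustering

Samples are clustered on 1 − Pearson correlation of Z-scored columns
(complete linkage, SciPy) and cut into exactly two groups; Z-scoring uses
sample sd (ddof = 1) with constant rows mapped to zero. The
cluster–class association is a two-sided Fisher exact test, verified
against full enumeration of tables with fixed margins. Fisher exact is the
package's choice of association test; an empty cluster returns p = 1 with a
warning. Heatmap support is limited to exporting the ordered Z-matrix,
linkage and leaf order; drawing is left to the caller.

## Synthetic cohorts

The generator emulates a two-class platelet RNA-seq study: default 3,799
transcripts, 57 cases + 103 controls (38/103 flagged former patients),
series fractions (55, 52, 53)/160 — the cohort geometry the package's
defaults are modeled on. Counts are gamma-Poisson (negative binomial,
var = μ + αμ², default α = 0.2); baseline relative abundances are
log-normal across transcripts (σ = 1.5, a heavy tail typical of expression
data); library sizes are log-normal (median 7.5×10⁵ spliced reads,
log-sd 0.25). A chosen subset of transcripts (default 100) carries a
planted group effect with random sign and gamma-distributed magnitude
(shape 8) around the configured mean |log₂FC| (default 2). A disjoint 5%
of transcripts responds to age or gender instead (strength 0.5 log₂ units
per SD of age, or per gender class), so demographic confounding is present
but, by design, uninformative about the class: ages and genders are drawn
from identical distributions in both classes. This balance-by-construction
emulates a matched cohort; it is a stand-in, not a matching algorithm, and
a class-wise balance report is emitted instead. Former-sarcoma controls are
statistically identical to healthy controls — the flag exists for
reporting strata only. All randomness flows from one seed through a
hierarchical seed-spawning scheme, so any stage can be re-run independently
and cohorts are bit-reproducible.

What the synthetic cohorts do **not** capture: isoform/splice-graph
structure, batch or plate effects beyond library size, overdispersion
heterogeneity across transcripts, and any real platelet biology. Passing
tests therefore demonstrate the statistical machinery (calibration under
the null, recovery of planted signal, leakage-free validation), not
clinical performance on real cohorts.

## Problem sizes in tests and the acceptance run

Unit and property tests use cohorts of 300–4,000 transcripts and 40–160
samples, with swarm budgets of 4–10 particles × 1–3 iterations — sizes
chosen so the full suite exercises every code path, including ten-seed
null-calibration and signal-recovery sweeps, in well under a minute. The
acceptance script runs the full default design (3,799 × 160) with the full
100 × 10 swarm, a 40 × 6 clustering swarm, and 50-iteration controls at a
6 × 2 budget (the reduced control budget is recorded in its output). These
are the package's standard demonstration sizes; larger studies only change
the input matrix.

## Known limitations

- Two classes only; no histologic-subtype or stage modeling.
- The FDR dimension is searched uniformly on its raw scale, which favors
  large thresholds at initialization; the pinned default particle
  guarantees the conventional q\* = 0.05 setting is always considered.
- Platt calibration is fitted on resubstitution decision values; with small
  separable training series the score distribution saturates near 0/1, so
  the 0.5 cutoff can be conservative even when ranking is perfect.
- Under label shuffling most particles select nothing and score 0.5
  exactly, so the permutation null can collapse to a point mass at 0.5 on
  low-dimensional cohorts.
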