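# Methods

## Problem setting

A patient-derived xenograft (PDX) screen treats engrafted human tumours with
anti-cancer agents and records, for every PDX–treatment pair, the percentage
tumour-volume change relative to treatment start (%ΔTVol) every 3–4 days,
together with gene-level molecular profiles of the untreated tumour. The
modelling task is binary: predict whether a PDX is *sensitive* (responder) or
*resistant* (non-responder) to a treatment from one molecular profile, for one
cancer type at a time. Cohorts are small (tens of PDXs) while profiles carry
tens of thousands of gene-level features, so the central statistical problem
is severe dimensionality, and the central methodological risk is optimistic
performance estimation.

## Feature encodings

Four profiles are supported, each one gene-level feature per gene:

* **SNV** — 1 iff at least one somatic single-nucleotide variant was detected
  in the gene region, 0 (wild type) otherwise. Collapsing all variants of a
  gene into one binary feature keeps the matrix dense enough to learn from.
* **CN** — the real-valued copy number, used as provided.
* **CNA** — binarised copy number: 1 iff the gene is strongly amplified
  (cn ≥ 8), moderately amplified (5 ≤ cn < 8) or deleted (cn ≤ 0.8). The band
  edges are configuration (`CnaThresholds`), with exactly these boundary
  semantics as the default.
* **GEX** — FPKM expression values, used as provided (no log transform or
  normalisation; the tool models whatever scale the screen reports).

A merged profile concatenates several profiles over their common samples,
prefixing feature ids with the profile kind so the same gene contributes
distinct features from each profile.

Duplicate gene rows within an input table are resolved by keeping the row
whose values deviate most in absolute terms from the table median — a
deterministic rule that favours the more informative of the duplicates.
Sample identifiers are matched case-sensitively after whitespace trimming.

## Response classification

Two statistics summarise a %ΔTVol series, both restricted to post-baseline
observations at day ≥ `min_day` (default 10):

* *BestResponse* — the minimum %ΔTVol;
* *BestAvgResponse* — the minimum over eligible days *t* of the running mean
  of %ΔTVol from the start of the eligibility window up to *t*.

The eligibility day applies to **both** the start of the averaging window and
the minimum search; the day-0 baseline (0% by definition) never enters either
statistic. A series may omit the explicit day-0 point (the baseline is implied
by the definition of %ΔTVol); if present, it must be 0.

Categories follow mRECIST-like rules with strict comparisons, falling through
CR → PR → SD → PD:

| category | BestResponse | BestAvgResponse |
|----------|--------------|-----------------|
| CR       | < −95        | < −40           |
| PR       | < −50        | < −20           |
| SD       | < 35         | < 30            |
| PD       | otherwise    |                 |

Boundary values land in the less responsive class. All thresholds are a
configurable `ResponseRuleSet`; the table above is only the default. CR/PR/SD
collapse to *sensitive*, PD to *resistant*. When a retrieved (precomputed)
category disagrees with one recalculated from the raw series, the recalculated
one wins, so every pair is categorised under one set of rules; disagreements
are flagged and countable. A series with a single eligible point is
categorised from that point and logged as low-support.

## Metrics and their NA conventions

With positives = sensitive PDXs, performance is summarised by the Matthews
correlation coefficient

MCC = (TP·TN − FP·FN) / √((TP+FN)(FN+TN)(TN+FP)(FP+TP)),

which is **NA** whenever a marginal sum is zero (a model that never predicts
one class has no defined MCC). Precision is NA when TP+FP = 0, recall NA when
TP+FN = 0; F1 is the harmonic mean, defined as 0 when PR = RC = 0 and NA when
either input is NA. NA values propagate — they are never coerced to 0 — and
medians over replicates are taken over the non-NA values only (all-NA stays
NA). ROC curves enumerate all distinct score thresholds with trapezoidal AUC;
a hard 0/1 predictor yields a single intermediate point and
AUC = (TPR + 1 − FPR)/2; single-class truth has NA AUC.

Fisher's exact test is two-sided by the "sum of all tables no more likely
than the observed" rule, with the φ coefficient as effect size (φ > 0 ⇔
alteration enriched among sensitive PDXs). The unpaired t-test is Welch
(unequal variances) by default, configurable to pooled. Degenerate features —
constant within a training fold — receive p = 1 and rank last. Model
comparisons are classical paired t-tests on matched replicate (or matched
per-treatment) MCC vectors, one- or two-sided.

## Models

**RF-all.** A random forest over all features of the profile: 1000 trees by
default, m_try = ⌊√(#features)⌋, trees grown to purity, no per-case tuning
(tuning buys little at these sizes and costs replicate budget). Class
imbalance is counterbalanced by weighting: the minority class receives the
majority-class *proportion* as its per-sample weight and vice versa, entering
both the split impurity and the leaf votes. The sensitivity score of a test
PDX is the fraction of trees voting sensitive; the decision threshold is 0.5
(configurable). Evaluated by standard leave-one-out cross-validation (LOOCV).

**RF-OMC.** The optimal-model-complexity wrapper: (i) rank features on the
training fold by univariate association (Fisher for binary, Welch for
real-valued profiles, ascending p; ties by |effect| descending then feature
id); (ii) for every candidate subset — top-2, top-3, …, top-⌊n/2⌋ features
plus one candidate with all features — run an inner LOOCV of the forest on
that subset and record its MCC; (iii) select the candidate with the highest
inner MCC and refit on the whole training fold. The n/2 cap keeps at least
two training samples per considered feature. NA inner MCC loses to any
numeric value; exact ties go to the smaller subset (the all-features candidate
counting as the largest), and the minimum candidate size is 2. Features are
ranked **once per outer training fold** and reused across that fold's inner
splits; this is leakage-free with respect to the outer estimate because the
outer test sample is excluded from the ranking, and a stricter
re-rank-per-inner-fold mode is available by flag. Performance is estimated by
**nested LOOCV**: the whole selection runs inside each outer training fold, so
the held-out PDX never influences ranking, subset choice or training. Every
selection is recorded in a trace (candidate sizes, inner MCCs, chosen subset,
training-fold sample ids) that tests use to audit leakage.

**Single-gene marker.** Per training fold, a two-sided Fisher test per gene;
the lowest-p gene among sensitising ones (φ > 0) becomes the marker, and the
held-out PDX is predicted sensitive iff it carries an SNV in that gene. A fold
without any sensitising gene predicts resistant (no marker ⇒ no sensitivity
call). After evaluation, the final marker is recalculated on all samples so it
is ready for forthcoming tumours. Genes mutated in none or all training
samples carry p = 1 and are never electable.

**Random controls.** (a) A prior-probability model: per fold, predict
sensitive iff a uniform draw falls below the training-fold sensitive
proportion; one MCC per full pass, 10 replicates sharing the forests' seed
list. (b) RF on a uniformly drawn feature subset of the same size as an OMC
selection, 10 replicates — the control showing that OMC subsets are not
merely small but informative.

## Replication and aggregation

Stochastic models run 10 independent (nested) LOOCV passes with one fixed seed
list shared across model families, so paired per-seed comparisons are valid;
every reported metric is the replicate median. The benchmark planner
enumerates algorithm × cancer-type × treatment × profile × replicate grids
(the default 2×2×13×4×10 grid is 2080 LOOCV runs). The best predictor per
case is the argmax of median MCC over model × profile, ties resolving toward
fewer features (single-gene < RF-OMC < RF-all), matching the toolkit's bias
toward concise, clinically implementable gene lists. A case below the
inclusion threshold (default 35 PDXs, pure configuration) or with one response
class is flagged, not silently dropped.

## The forest implementation

Model selection evaluates a full inner LOOCV per candidate subset per outer
fold — order 10⁵ forest fits per replicated experiment, each on a few dozen
samples. The package therefore ships a compact CART/gini forest compiled with
numba (bootstrap per tree, random feature subsets of size m_try per split,
class-weighted impurity and votes, trees grown to purity) whose fused
LOOCV kernel recomputes class weights per training fold. A
scikit-learn-backed implementation of the identical contract is provided both
as an alternative backend and as the independent cross-check in the test
suite; the two agree qualitatively (strong MCC on planted signal, chance on
permuted labels) while the native kernel is ~3 orders of magnitude faster per
fit at these sizes. All fits are deterministic functions of (data, config,
seed); per-fold seeds derive from the replicate seed plus the fold index,
kept below 2³¹.

## Synthetic cohorts

The generator emulates the screen's data shapes: binary mutation matrices,
non-negative CN/GEX matrices, response categories consistent with the class,
and %ΔTVol curves. Defaults describe the conditions used throughout the
recovery experiments: 40 PDXs, prevalence 0.5, 500 binary features at
background alteration rate 0.1, three planted sensitivity markers at odds
ratio 20, 100 real-valued features, and expression shifts of 1.5 SD for
planted real features — strong enough for subset recovery at n = 40, the
regime the tool targets. Planted binary features draw class-conditional
alteration rates implying the requested odds ratio; planted real features are
class-shifted Gaussians (clipped at 0 to respect the value domain); noise
features are class-independent. Volume curves are piecewise-linear trends
(plateau reached around the eligibility day) plus Gaussian noise, rejected and
resampled until the curve sits strictly inside the requested category's region
with a ≥ 5-percentage-point margin. Label permutation provides the matching
null fixture.

What the generator does **not** emulate: co-mutation and co-expression
structure, mutational signatures, batch effects, measurement dropout, or
inter-treatment correlation. Passing the synthetic experiments therefore
demonstrates the machinery (encoding, ranking, selection, nesting, baselines,
metric conventions) — not that any particular real screen is predictable.

## Experiment sizes used by the test suite

The replicated experiments run at desk scale, chosen as the smallest sizes at
which the studied effects are unambiguous: signal recovery on the default
cohort (n = 40, 500 binary features of which 3 planted, 100-tree forests,
10 seeds)
and selection-bias demonstration on label-permuted cohorts (n = 30, 300
binary features, 10 permutation seeds). On one CPU these complete in roughly
five and two minutes respectively.

## Known limitations

* The univariate filter ignores feature cooperativity; a feature predictive
  only in combination can be ranked away. The permutation-importance ranking
  backend partially addresses this at much higher cost and is exposed for
  comparison only. (That backend measures importance by prediction-accuracy
  decrease under feature permutation on the training fold via scikit-learn,
  rather than per-tree out-of-bag noising.)
* LOOCV MCC on small cohorts is high-variance; single replicates of the null
  model can reach |MCC| > 0.5, which is why all conclusions rest on replicate
  medians and paired tests.
* The prior-probability baseline is not exactly zero-mean under LOOCV: the
  training-fold prior is anti-correlated with the held-out label (removing a
  sensitive PDX lowers the fold's sensitive proportion), giving an expected
  MCC of about −0.03 on a balanced 40-PDX case. This is a property of the
  baseline protocol, not a defect of the forests it calibrates.
* No multiple-testing correction is applied to the per-gene p-values: they
  are used for ranking, not inference.
* Samples missing from one profile are intersected away per case; the dropped
  ids are recorded on the `CaseDataset`.
* No survival endpoints, dose modelling, genome-coordinate handling or
  expression normalisation.
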