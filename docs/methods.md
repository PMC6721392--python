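# Methods

## The stratification model

`mixstrat` operationalizes a dual-pathway model of dementia. Two disease
processes progress independently: an amyloid/tau neurodegenerative pathway,
read out in CSF as elevated phosphorylated tau (Ptau) and a lowered
amyloid-beta 42/40 ratio, and a vascular pathway of small-vessel
white-matter injury, read out on DTI as elevated mean diffusivity (MD).
Patients are placed on each axis separately and the cross of the two
dichotomies yields the biological diagnosis: both positive is mixed
dementia (MX), CSF only is AD, DTI only is SIVD, neither is benign
leukoaraiosis (LA). Multi-infarct dementia (MI) lies outside the quadrant
scheme and is triggered directly by a documented infarct, which overrides
the axes.

The alternative feature-matrix classifier binarizes nine features
(hyperreflexia, imbalance, executive deficit, memory deficit, WMH on
FLAIR, high MD on DTI, amyloid positivity, Ptau positivity, high albumin
index) and scores each candidate label by the number of features matching
its expected ±-sign column; the argmax wins, with ties resolved by the
fixed precedence MX > SIVD > AD > LA — the dual-pathology label first
because missing it carries the largest treatment cost. This matcher is
equivalent to a Hamming-distance minimizer over the sign columns, which
the test suite verifies exhaustively.

## Thresholds

No numeric cut-points are published for any biomarker — the axes are
qualitative ("high/low") — so every cut is a package default, configurable
in `Thresholds`:

| parameter | default | units | rationale |
|---|---|---|---|
| `md_z_high` | 2.0 | z | separates the vascular groups (group means ≈ 2.9–3.2) from AD/LA (≈ 0.7–1.0) |
| `ptau_high` | 68 | pg/mL | between the AD/MX group means (≈ 88–119) and the LA/SIVD/control means (≈ 46–56) |
| `ab_ratio_low` | 0.07 | — | midpoint of the generator's normal (0.10) and Alzheimer (0.05) ratio regimes |
| `t_memory_low`, `t_executive_low` | 40 | T-score | one population SD below the T-score mean of 50 |
| `albumin_index_high` | 6.5 | — | between the generator's intact-barrier (≈ 5.2–5.5) and leaky-barrier (≈ 7.5–8.2) regimes; used only by the feature matcher |
| `ad_axis_rule` | `either` | — | Ptau high OR ratio low; both analytes mark Alzheimer pathology and either suffices. `both`, `ptau_only`, `amyloid_only` available |

Boundary convention: a value exactly at a cut is positive (`>=` for high
cuts, `<=` for low cuts).

## Composite scoring

Domain composites are arithmetic means of the available test T-scores
within a domain (missing tests dropped; a configurable minimum of one test
per domain), and the overall composite is the mean of the available domain
composites, reported with the number of contributing domains. Raw-to-T
conversion from normative tables is out of scope; the pipeline ingests
T-scores. The MD z-score is `(md − m) / s` with `m`, `s` the control
sample mean and SD (n−1 denominator); the control reference requires at
least two finite values with nonzero spread. An optional per-scanner batch
split of the reference is possible by fitting one reference per batch; the
package does not harmonize across scanners.

## The synthetic cohort

The generator emulates the study's five biological groups (plus controls)
at their published group sizes — SIVD 53, AD 25, MX 22, MI 18, LA 29, and
25 controls (the control count is a package default; it is not published).
For seven variables (age, T-memory, T-executive, MD z, MMP-1, MMP-10,
Ptau) the per-group (mean, SD) pairs are the published summaries. The
remaining variables are package defaults chosen to respect the qualitative
orderings the study reports: the amyloid ratio low in AD/MX (0.05 ± 0.015)
and normal elsewhere (0.10 ± 0.02); MMP-3 elevated in MX but not AD; the
albumin index elevated in the vascular/mixed groups; the three unpublished
cognitive domains tracking the executive scores per group. Binary signs
follow the feature matrix: "+" groups get probability 0.8, "−" groups 0.2,
controls near zero. MI has no published summary column at all; its
continuous parameters are invented vascular-like values and its infarct
probability is 1.0 (0.0 in all other groups), so the infarct flag defines
the group.

Sampling: each continuous variable is drawn independently from a normal
truncated to its valid range (T-scores [0, 100], Ptau > 0, ratio in
(0, 1), age ≥ 0) by rejection, with at most 1000 redraw rounds before a
hard error. One-sided truncation would otherwise inflate the retained
mean — for MX Ptau (118.86 ± 57.82, ≈2% of mass below zero) by about
+2.9 pg/mL — so the sampler first solves for a shifted location μ′ such
that the truncated normal's mean equals the configured group mean
(Brent root-finding on the truncated-normal mean; skipped when the
truncated mass is < 1e-10). This keeps the generator calibrated: sample
means at n = 10,000 recover every configured cell within three standard
errors. MMPs and the albumin index are left unbounded Gaussians; clamping
them at zero would de-calibrate groups whose SD is large relative to the
mean (AD MMP-10 by ≈ +11 units).

Clinical labels are drawn per record from a row-stochastic confusion
matrix P(clinical | biological): identity except that biological-MX
patients present clinically as MX/AD/SIVD with probabilities 9/22, 8/22,
5/22 and one of 18 MI patients presents as SIVD. With the default sizes
the expected clinical margins are exactly 59/33/9/17/29 — the published
clinical counts. The matrix is a documented construction, not a fit.

What the generator does **not** emulate: within-group covariance (all
variables independent given the group — real Ptau and memory scores are
correlated), longitudinal change, scanner batch effects, item-level test
responses, and non-Gaussian shapes (real MMP distributions are
right-skewed). Passing tests therefore demonstrate the correctness of the
pipeline's arithmetic and logic under the published marginal
distributions, not classifier performance on real patients.

## Statistics

Group comparisons use the Kruskal–Wallis omnibus test (tie-corrected H,
chi-square approximation with k−1 df) per variable and two-sided pairwise
Mann–Whitney U-tests, exact when both groups have n ≤ 20 and the pooled
sample is tie-free, otherwise the normal approximation with tie and
continuity corrections. U is oriented to the first sample. Family-wise
correction is Holm step-down by default (uniformly more powerful than
Bonferroni at the same FWER; Bonferroni available), with the family
defined as the pairs within one variable, not across variables. Degenerate
input in which every observation is identical returns H = 0 with p = 1.0
by convention. Note the chi-square p is an approximation: at very small n
it can differ noticeably from an exact permutation p (for k = 2 the exact
permutation test coincides with the exact Mann–Whitney test, which the
package already provides).

## Pipeline and reporting

`run_pipeline` simulates or ingests a patient table, validates it
(ingest), adds the overall cognitive composite, classifies every row
(rows with missing required fields become `UNCLASSIFIED` with a recorded
reason), and assembles: the labeled table; the clinical-vs-biological
contingency table with margins over rows whose clinical and predicted
labels are among the five patient categories (controls excluded, matching
the 147-patient study table); the per-group summary over the predicted
labels with controls kept as their own column; Holm-corrected pairwise
tests; and a YAML manifest echoing the package version, seed, thresholds
and counts. All outputs are plain delimited text. Determinism: the cohort
seed feeds a `SeedSequence` spawned once per group plus once for the
clinical relabeling, so identical configuration yields byte-identical
tables.

## Problem sizes and known limitations

Calibration checks run at n = 10,000 per group (standard errors small
enough that a 3-SE band is a meaningful test but cheap to simulate);
cohort-level checks run at the study sizes (147 + 25). Classifier-recovery
checks use a "well-separated" parameter variant (`well_separated_group_
params`: SDs × 0.25, sign probabilities sharpened to 0.95/0.05). This is
deliberate: at the published SDs the groups genuinely overlap (e.g. the
SIVD MD z-score 2.94 ± 2.12 straddles the 2.0 cut), and the dichotomy
recovers only ≈ 70% of generator labels — a property of the published
distributions, not a bug. The ≥ 90% recovery figure is therefore a
configuration property of the low-noise variant, verifying the rule logic
rather than claiming clinical accuracy. Other limitations: thresholds are
package choices and should be re-derived (e.g. by ROC) before any use on
real data; the confusion model reproduces margins, not the unpublished
patient-level clinical→biological flow; the rejection sampler errors out
by design when nearly all of a configured distribution lies outside the
valid range.
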