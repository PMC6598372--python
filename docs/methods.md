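# Methods

## Measurement model

Each marker assay is a methylation-specific qPCR on bisulfite-converted
urine DNA; it amplifies only methylated template, and the quantification
cycle Cq decreases with the number of methylated copies.  Signals are
reported on the transformed scale `max(0, max_cycles − Cq)` with
`max_cycles = 32`, so 0 means no amplification and larger values mean
more methylation; the range observed in urine DNA is 0–15.  The
transform is strictly decreasing in Cq on (0, 32] and clamps to 0
beyond.  Signals above 15 are retained with a warning rather than
clamped: the 0–15 range is an empirical observation, not a physical
bound.  In Cq-valued input files an empty cell or the token
`Undetermined` denotes no amplification (the usual instrument-export
convention); in signal-valued files a literal 0 does.

A per-sample boolean QC flag records whether the imprinted-gene control
assay (STIM1) recovered amplifiable DNA; no Cq threshold is imposed here
because the flag is a wet-lab judgement, and `qc_filter` simply
partitions samples on it.

Patients initially biopsy-negative but diagnosed on follow-up can be
moved into the case group at load time through a `followup_diagnosis`
metadata column; this is on by default, matching how the validation
cohort was analysed (three such patients).

## Scoring and the threshold rule

A marker is positive iff its signal is strictly greater than zero,
regardless of magnitude — the deliberate choice that folds analytical
false positives (e.g. incomplete deamination) into the per-marker rates
instead of hand-picked cutoffs.  The two cumulative statistics per
sample are the count of positive markers (`nof32`, 0–32) and the average
methylation (sum of all 32 signals divided by 32, zero markers
included).  The threshold rule "`t`of32" calls a sample positive when at
least `t` markers are positive, which makes case-positive counts
non-increasing and control-negative counts non-decreasing in `t`.

## Diagnostic metrics

Sensitivity, specificity, PPV and NPV come straight from the 2×2 table;
predictive values use the cohort's own prevalence (no Bayes adjustment)
and are undefined ("na" in reports) when their denominator is zero.
Confidence intervals are Wald, `p ± z·√(p(1−p)/n)` with `z` fixed at
1.96, and are *not* truncated to [0, 1]; this reproduces published
interval bounds such as an upper limit of 1.02 for 28/30.  Report tables
round half-up to 2 decimals; all internal values keep full precision.

Two published NPV cells in the validation cohort's threshold table (the
9of32 and 10of32 DRE rows, printed 0.84 and 0.85) disagree with direct
computation from their own counts (0.846 and 0.841 — apparently
transposed); this package implements the direct formula and does not
special-case those cells.

## ROC and AUC

AUC uses the Mann–Whitney convention with half credit for ties:
`[#(case > control) + ½·#(case = control)] / (n_case · n_control)`.
On integer counts this is deterministic and equals the trapezoidal area
under the empirical ROC over all unique thresholds (asserted to 1e−12 in
tests, and cross-checked against scikit-learn's `roc_auc_score`).
`reconstruct_pmf` inverts a cumulative at-or-above count table
(`pmf(c) = S(c) − S(c+1)`, `pmf(0) = n − S(1)`) so that published
per-threshold tables can be converted into per-sample distributions;
re-accumulation reproduces the input exactly, and the inversion rejects
non-monotone input.

Applied to the validation cohort's DRE table this yields case support
3–31 with median 16, control support 0–17 with median 5, and AUC
1549.5/1764 ≈ 0.878, consistent with the published AUC range (0.87–0.91)
whose per-curve assignment to statistic and sample type is not printed.
Under the same conventions the FV reconstruction gives medians 15.5 and
6 versus the published text's 16 and 5 — an artefact of the unprinted
median convention — so only the DRE medians are pinned in tests.

## Group and paired comparisons

Grading groups follow the CAPRA risk score: 0 = negative biopsy, 1 = low
risk (CAPRA ≤ 2), 2 = elevated risk (CAPRA ≥ 3).  Group comparisons (0
vs 1+2, 1 vs 2) use the two-sided Wilcoxon rank-sum test: exact
enumeration when both groups have ≤ 10 observations without ties,
otherwise the normal approximation with tie correction; the continuity
correction is off by default (a documented flag toggles it), matching
the common default of R's `wilcox.test` with `correct = FALSE`
behaviour under ties.  When every pooled value is identical the p-value
is 1 by construction.  Box-plot summaries use linear-interpolation
("type 7") quartiles and the even-n median convention; both conventions
are stated because the hinge values are test surfaces.

The paired DRE-vs-FV analysis uses only patients with both sample
types, differences oriented DRE − FV, and the one-sample t test
(`t = mean/(sd/√n)`, df = n−1) with a 95% t interval, run per marker and
for both cumulative statistics.  Zero-variance differences are treated
as the limit: p = 1 when the common difference is 0, p → 0 otherwise.

Case PSA summaries apply the extreme-outlier rule: iteratively drop the
maximum while it exceeds twice the maximum of the remaining values.
Gleason score and positive-core counts are dichotomized at ≤ 7 / > 7 and
≤ 3 / > 3 with the boundary in the lower bin.

## Synthetic cohort generator

The generator emulates the validation study's design so the whole
pipeline is testable without patient data.  Defaults are the study
conditions: 42 cases and 52 controls; sample availability drawn per
patient with probabilities 58/94 (both types), 27/94 (DRE only), 7/94
(FV only), the remainder having no usable sample — reproducing ~85 DRE
and ~65 FV samples with ~58 paired patients; cases assigned to the
elevated-risk group with probability 18/33.  PSA and age are drawn from
normals at the published case/control means and SDs (7.1 ± 3.3 vs
5.6 ± 2.7 ng/mL; 67.1 ± 7.1 vs 63.9 ± 7.6 years), truncated to plausible
ranges.

Marker positivity is Bernoulli with class- and sample-type-conditional
probabilities.  The 13 new markers use their published rates (p_case =
observed sensitivity, p_control = 1 − specificity, per sample type);
the 19 legacy markers, whose rates are not republished with this panel,
use mid-range defaults p_case = 0.52, p_control = 0.13 chosen so the
expected cumulative counts match the published cohort medians (16
positive markers in cases, 5 in controls).

Markers are **not** independent by default: a per-patient latent "tumor
burden" scalar z ~ N(0, 1.1) is added to every marker's log-odds.  This
is essential, not cosmetic — independent draws concentrate the case
count distribution far too tightly (10of32 sensitivity ≈ 0.99), whereas
observed per-sample counts span 3–31 in cases and 0–17 in controls.  The
sd of 1.1 was calibrated once against that published dispersion; at
large n it reproduces the published DRE operating point (sensitivity
0.83, specificity 0.77 at 10of32; AUC 0.88).  Setting
`tumor_burden_sd = 0` recovers independent markers, which is also the
configuration used for parameter-recovery tests since the latent
mixture shifts marginal rates away from their nominal values.

Elevated-risk cases get an additive log-odds boost (`group2_shift`,
default +0.75) on their DRE draws only, encoding the finding that
grading groups separate in DRE but not FV methylation.  Paired FV
samples copy each DRE positivity call with probability
`paired_agreement` (default 0.8 — a modeling choice; no quantitative
DRE/FV concordance is published) and redraw otherwise.  Positive
signals are uniform on (0.5, 15]; magnitudes only affect the
average-methylation statistic, so the default targets range fidelity.
Identical configs and seeds yield byte-for-byte identical cohorts.

What the generator does *not* emulate: qPCR chemistry and bisulfite
conversion failure, marker-specific signal-magnitude distributions,
realistic inter-marker correlation structure beyond a single shared
factor, and any PSA–methylation dependence (PSA is drawn independently
of marker state, so the generator cannot reproduce the published PSA
AUC of 0.688).  Passing tests therefore validate the statistical
machinery, not biological fidelity per marker.

## Quantities not reproducible from printed summaries

The published exact Wilcoxon p-values (0.001, 0.005, 0.4578, 0.647),
the PSA ROC, the identity of the five paired-significant markers, and
the assignment of the AUC range endpoints to specific curves all depend
on the per-sample data of the study's supplementary file, which this
package does not bundle.  They are covered instead by synthetic
substitutes: planted paired shifts in five markers are recovered at
p < 0.05, and the grading-group shift yields significant DRE group
comparisons on generated cohorts.

## Problem sizes and numerical choices

Deterministic checks (table cells, interval bounds, reconstruction,
AUC) run on the published counts themselves (36/49 DRE, 30/35 FV).
Monte-Carlo checks use generated cohorts of 200–800 samples per class,
and parameter recovery uses 10,000 samples per class with a 4-SE
binomial tolerance per marker.  Equality of the trapezoid and pairwise
AUC routes is asserted to 1e−12; published-value reproductions are
asserted at the printed precision (2 decimals, half-up).
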