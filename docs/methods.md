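# Methods

## The model

`cindexlab` evaluates a composite biomarker score for predicting
microbiologically documented infection at the onset of a fever episode in
haematological patients. For episode *i* with serum values PCT_i, CRP_i and
IL6_i,

    CIndex_i = PCT_i / PCT̂ + CRP_i / CRP̂ + IL6_i / IL6̂ ,

where the hatted denominators are reference means. Dividing each marker by
its mean puts three quantities whose raw scales differ by orders of
magnitude (PCT around 1 of its unit, IL-6 in the hundreds) on a common
dimensionless footing, so the unweighted sum is meaningful; no coefficients
are fitted. Two exact identities follow and are used as tests: an episode
at the mean of every marker scores 3, and a cohort normalized by its own
pooled means has average score exactly 3 (each normalized column has mean 1).

Reference means default to the analyzed cohort's own pooled means — both
outcome groups together, since at fever onset the outcome is unknown. For
deployment on new episodes an external set of means (from a large,
demographically homogeneous reference sample) can be supplied instead; the
report records which source was used. No outlier exclusion is applied, and
a biomarker value of 0 is legal input (assays report below-detection
results as small or zero values); only a column whose *mean* is zero is
rejected, because the normalization is then undefined.

## Synthetic cohorts

Raw episode-level data for the motivating cohort were not deposited; only
per-group descriptive statistics (N, mean, median, SD, Q1, Q3) for each
biomarker are available. The generator converts those summaries into a
simulatable model so the whole pipeline is exercisable end to end.

**Distribution family.** Every published cell shows mean well above median
— strong right skew, typical of inflammatory markers — so each
(biomarker, group) cell is modelled as a two-parameter lognormal, the most
parsimonious right-skewed family identifiable from two summary numbers.
Two fits are available:

* *Moment matching* (default): `sigma² = ln(1 + sd²/mean²)`,
  `mu = ln(mean) − sigma²/2`. Exactly invertible; the fitted analytic mean
  and SD reproduce the targets to 1e-9 relative.
* *Quantile matching* (fallback): `mu = ln(median)`,
  `sigma = |ln(quartile/median)| / z₀.₇₅` with `z₀.₇₅ ≈ 0.67449`.

**Default configuration.** 51 episodes split 40 (no infection) / 11
(documented infection), matching the published design. Five of the six
cells are moment-fitted to their published (mean, SD). The IL-6/infection
cell is quantile-fitted to (median 189.00, Q1 93.45) because its printed SD
(0.04, against a mean of 325.81) is internally impossible; the quantile
fit's implied analytic mean is ≈326, within 2% of the printed mean, which
the fit report and an acceptance test verify rather than silently assume —
evidence that the SD cell, not the mean, is the typo. The PCT/infection
cell's printed summaries (mean 19.05, SD 36.45, median 0.79) are mutually
inconsistent with *any* two-parameter family (the moment fit implies a
median near 8.8); the moment fit is retained, since the mean is the
quantity the composite index normalizes by, and the discrepancy is flagged
in the fit report.

**What the simulation does not emulate.** Biomarkers are drawn
independently within an episode — the published tables carry no correlation
information, and inventing a copula would be unfalsifiable. Real
inflammatory markers are positively correlated, and patient-level
clustering (the 51 episodes came from 34 patients) is likewise not
simulated. Consequently simulated between-group separation is *cleaner*
than clinical reality: large-sample AUCs of the default specs run
0.79–0.96, well above the 0.66–0.79 observed on the real cohort, and
passing tests demonstrate correctness of the estimators, not clinical
performance. Reproducing the original cohort's AUCs, cut-offs and p-values
is out of reach without the raw data; the test suite substitutes exact
oracle equivalences (below).

**Seeding.** One integer seed per simulation; each (biomarker, group) cell
draws from its own `numpy` substream keyed by (seed, biomarker index, group
index), so a cell's draws are independent of sampling order and of the
other cells' sizes. Identical configs give bit-identical cohorts.

## Statistics

* **Descriptive rows**: arithmetic mean; midpoint median for even n; sample
  SD (n−1 denominator, 0 for a single value); quartiles by linear
  interpolation of order statistics (quantile p at position 1+(n−1)p, the
  common scientific-software default — the convention is recorded in the
  report since the published tables do not state one).
* **Group comparison**: two-sided Wilcoxon–Mann–Whitney. For pooled
  n1+n2 ≤ 12 the p-value is exact, enumerating all C(n1+n2, n1) label
  assignments of the pooled midranks; this stays valid under ties, and the
  permutation distribution of U is symmetric about n1·n2/2 (negating the
  pooled values maps U to n1·n2 − U over the same assignment set), so the
  two-sided p counts assignments at least as extreme as observed. The
  threshold 12 keeps enumeration under a thousand terms and covers the
  scale of the motivating infection group (n = 11). Above it, the normal
  approximation with tie correction and continuity correction
  (scipy) is used; both routes are labelled in the output. α = 0.05 is
  reported as the conventional significance level, never used to filter.

## ROC analysis

Decision rule: `score ≥ cut-off ⇒ predicted infection`, with candidate
cut-offs at the distinct observed scores plus a sentinel above the maximum
(so the curve is anchored at (0,0) and (1,1)). The ≥ convention and the
observed-value (not midpoint) cut-off scale match how clinical thresholds
are quoted; both choices are written into the report's decisions log. AUC
is the trapezoidal area, which on this threshold grid equals the
tie-corrected rank probability (#{pos > neg} + ½·#{pos = neg})/(n_pos·n_neg);
a brute-force pairwise oracle enforces that identity to 1e-12 in the tests.

The reported operating point maximizes Youden's J = sensitivity +
specificity − 1. Ties on J are broken toward higher sensitivity — in this
clinical setting a missed infection is the costly error — then toward the
lower threshold. J is a rational number with denominator n_pos·n_neg, so
candidates are ranked in exact integer arithmetic (TP/FP counts), not on
float curve coordinates, making the selection immune to last-ulp noise.
With a binary outcome and a scalar composite score, "multi-marker ROC"
reduces to ordinary binary ROC on the composite, and is implemented as
such. No confidence intervals on AUC are produced.

Degenerate input (all scores identical) yields a two-point curve where
every operating point has J = 0; under the sensitivity-favoring tie-break
the selected cut-off is the single observed value (sensitivity 1,
specificity 0).

## Pipeline and outputs

`run_analysis` is deterministic in its inputs and produces: 12 descriptive
rows (four markers × total/infection/no-infection), four rank tests, four
ROC operating-point rows in fixed order (PCT, CRP, IL-6, CIndex), full ROC
point lists, per-episode scores and a long-form distribution table (raw and
mean-normalized values per marker per group, the data behind density and
violin plots; the composite score is normalized by 3, its value at the
per-marker means). Every convention above is embedded in the report's
`decisions` block so each number is re-derivable from the cohort CSV alone.
Rendering plots is deliberately out of scope: the exported tables are the
interface, and any plotting layer can consume them.

## Problem sizes and tolerances

Closed-form round trips are asserted at 1e-9 relative, float identities
(AUC vs rank oracle, component sums) at 1e-12. Monte-Carlo checks use
100 000 draws per cell, where the sample mean of the widest default spec
has a relative standard error under 0.6%, comfortably inside the 1–3-SE
bands asserted. Exact-test oracles enumerate instances up to pooled n = 10
(property tests) and n = 20 (one asymptotic-vs-exact comparison).

## Known limitations

* Lognormality is an assumption of convenience; the published summaries
  cannot distinguish it from gamma or Weibull alternatives (not offered).
* Independent markers and independent episodes overstate separability, as
  discussed above.
* Units are carried as opaque annotations and never converted: the printed
  assay units for PCT (mg/mL) and the CRP normal limit (1 ng/mL) conflict
  with usual clinical ranges, and no conversion can be justified from the
  source material. All analysis is unit-free by construction.
* The infection label is taken as given (a positive culture); the package
  does not adjudicate clinical definitions.
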