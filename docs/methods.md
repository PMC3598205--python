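# Methods

This note documents the models, statistical conventions and design
choices behind `ddirate`, and what the bundled tests do and do not
demonstrate.

## The decision model and its engine

A decision model is a rooted graph of binary question nodes; each node
names a `yes` and a `no` target, which is either another node or a
terminal severity rating `A`–`E` (coded 1–5). The engine
(`ddirate.engine`) interprets any such configuration; the bundled
`epha-dm-v1` model is data, not code.

Two structural devices deserve explanation:

* **OR-composite nodes.** The apparent-interaction question set (AIA)
  accepts either of two sub-questions — published evidence, or a
  plausible mechanism — as sufficient to proceed. It is modelled as a
  single `any_of` node that short-circuits on the first "yes" and counts
  as one step on a decision path. The AND-coupled alternative question
  set (ATE) needs no special node: its two sub-questions are chained
  ordinary nodes whose "no" branches exit to the same rating, and each
  "no" exit is a distinct decision path.
* **Question-sharing duplicated nodes.** The downstream subtree
  ACT → SUR → ATE → RBR appears twice, once per SAE branch, because an
  increased serious-adverse-event risk escalates the terminal severity
  (easy surveillance: B vs C; unfavourable risk–benefit: D vs E). The
  duplicated node instances share *question ids*, so a rater still
  answers each clinical question at most once; answer sets are keyed by
  question id. This yields 1 + 6 + 6 = 13 decision paths over 8 distinct
  questions.

The published drawing of the model fixes the question order and the
13-path/5-rating counts but not every branch target; the bundled wiring
is the unique reconstruction we found that satisfies all textual
constraints (the rating definitions, the path and rating counts, and
every worked example: the corrected roxithromycin–simvastatin rating B,
digoxin–alprazolam D, fluconazole–fluvastatin D, and the
citalopram–tramadol class of complex-monitoring D ratings). If a
different wiring is preferred it can be supplied as a YAML file without
touching the engine.

`rate_case` is a pure function of (configuration, answers). Answers to
questions not visited on the path are ignored with a logged notice —
raters only answer along the path, so leftover answers are expected, not
errors. A missing answer for a visited question is an error naming that
question. Every trace records the visited nodes, the consumed answers
and the enumerated path id; replaying the consumed answers reproduces
the trace (tested exhaustively over all 2^8 complete assignments).

Path enumeration is depth-first with "yes" explored before "no", giving
a stable ordering (path 0 is the all-yes path to E; the last path is
"no apparent interaction" → A). The DOT rendering merges node instances
by question id (8 decision diamonds) and draws one terminal box per
enumerated path (13 leaf edges), which matches how the model is drawn by
hand; a supplied trace is highlighted in red.

## Rating scales

All three scales — the decision model's A–E, a clinical expert's
conventional five-category severity scale, and Micromedex's
unknown/minor/moderate/major/contraindicated — are coded 1–5 in category
order and aligned position-wise for cross-tabulation. Micromedex
"unknown" sits in slot 1 (as the validation tables do) but carries a
*missing* flag: absence of information is not evidence of safety, and
downstream analyses use the flag to exclude those cases rather than
score them as disagreements. Labels are matched case-insensitively and
canonicalized on output.

## Agreement statistics

* **Cohen's kappa** `(Po − Pe)/(1 − Pe)` with `Po = trace/n` and
  `Pe = Σ rᵢcᵢ/n²`; the weighted form uses weight-averaged `Po_w`, `Pe_w`.
  Linear weights `1 − |i−j|/(k−1)` are the default: adjacent-category
  disagreements are clinically less serious than two-or-more-category
  ones, and the linear scheme is the one under which the bundled
  validation's weighted kappas reproduce exactly. Quadratic weights are
  available but non-default. Kappa on a table whose marginals are
  concentrated in one category (`Pe = 1`) is undefined and flagged
  rather than computed. Negative kappa is mathematically possible and is
  returned with the interpretation band "less than chance"; positive
  values get Altman's bands (0.01–0.20 slight, 0.21–0.40 fair, 0.41–0.60
  moderate, 0.61–0.80 substantial, 0.81–1 perfect).
* **Kappa standard errors** use the Fleiss–Cohen–Everitt asymptotic
  large-sample formula (the identity-weight special case covers the
  unweighted statistic), with a `small_sample` flag below n = 20.
  The resulting `kappa ± 1.96·SE` intervals reproduce three of the four
  validation-study intervals exactly and the lower bound of the fourth
  (0.611; our upper bound is 0.774 against a printed 0.744, consistent
  with a digit transposition in the source). Because the original
  interval method is unstated, these intervals are reported as
  informational and never asserted in tests.
* **Bland–Altman** statistics are computed on per-case code differences
  expanded from the cell counts, sign convention row rater − column
  rater (positive = the model rates more severely). SD uses the n−1
  denominator; limits of agreement are `d̄ ± 1.96·SD`; the CI on `d̄`
  uses `1.96·SD/√n`. These conventions reproduce all printed limits at
  printed rounding.
* **Wilson score intervals** are computed closed-form with z = 1.96
  (the conventional two-decimal quantile; statsmodels' z = 1.95996…
  agrees to ~1e-5 and serves as the test oracle). The lower bound is
  exactly 0 at x = 0.
* **Masking** zeroes excluded cells and reduces n; count conservation
  (`n = n_masked + Σ masked`) is property-tested.
* **Display rounding** is half-up (0.125 → 0.13, 9.5% → 10%), matching
  the reported values; full-precision numbers are always retained on the
  result objects, and rounding is applied only at the reporting edge.

## The bundled validation study

`ddirate.study` ships the two aggregate 5×5 tables (n = 200) and the
documented masks, verifies their marginals and mask totals on load, and
`run_validation` recomputes: both kappas, concordance (156/200 and
94/200) with Wilson CIs, Bland–Altman full (0.13 [−0.8, 1.05]; 0.9
[−1.6, 3.4]) and post-exclusion (n = 113, −0.02 [−0.89, 0.85]), and
residual non-systematic disagreement rates (14/200 and 19/200 with their
Wilson CIs). Each is compared with the reported value at its printed
rounding.

Known caveats:

* The expert-vs-Micromedex comparison (89 agreements; Bland–Altman 0.8,
  [−1.5, 3.1]) is *not* recomputed: its joint table was never published
  and cannot be reconstructed from the two bundled tables' marginals.
  The report says so explicitly rather than fabricating a joint
  distribution.
* The post-exclusion DM-vs-MMX set still contains one two-category
  discrepancy (the fluconazole–fluvastatin cell, model D vs database
  minor), although the original narrative describes the remaining
  differences as at most one category; the printed limits of agreement
  only reproduce with that case included, so it is included. The result
  object exposes `max_abs_difference` (= 2) rather than asserting the
  narrative claim.
* Post-exclusion kappa is computed and reported but has no published
  reference value, so it is never asserted.
* `expand_fixture` turns the aggregate tables into synthetic per-case
  records (synthetic ids and drug labels, shuffled cell assignment);
  pairwise cross-tabulation of its output reproduces both tables
  exactly, but the three-way joint distribution it implies is arbitrary
  — it must not be used to compute expert-vs-Micromedex statistics.

## Synthetic data generator

`simulate_pair` draws, per case: an agreement coin with probability
θ, a common category and two independent categories from the marginal π,
then a missing-rating coin (rate for rater B; requires a scale with a
missing label) and a one-step downward offset coin (systematic severity
understatement, floored at category 1). Under the pure mixture
(no missing, no offset) `Po = θ + (1−θ)Σπ²` and `Pe = Σπ²`, so the
population unweighted kappa equals θ exactly — an analytic recovery
target that the tests verify at three θ values within three sampling
standard errors at n = 10,000. The default π is the observed severity
marginal of the bundled validation sample (0.105, 0.06, 0.27, 0.465,
0.10); defaults of n = 200 cases match the validation design.

What the generator does *not* emulate: ordinal correlation structure in
disagreements (independent redraws scatter symmetrically, unlike real
raters who disagree mostly by one category), case-mix heterogeneity, and
any pharmacological content (drug names are synthetic labels). Passing
recovery tests therefore demonstrates the statistics and the
generator's own consistency, not rater behaviour on real DDIs.

## Numerical and interface choices

* All statistics are exact integer/float computations on desk-scale
  tables; there is no optimisation or iteration anywhere, and the full
  validation re-analysis runs in well under a second.
* Fixed problem sizes: exhaustive engine checks cover all 256 complete
  answer assignments; property tests use 25–40 random tables with
  n ≤ 50 against per-case oracles at 1e-12; parameter recovery uses
  n = 10,000 per θ.
* Configuration documents are YAML (JSON being a subset); unknown fields
  are rejected loudly, `yes`/`no` mapping keys are accepted in quoted or
  bare (boolean) YAML form, and every load runs full structural
  validation: dangling targets, cycles, unreachable nodes, undeclared or
  unreachable ratings.
* CLI exit codes: 0 success, 1 input/domain error, 2 validation-study
  mismatch (so `ddirate validate-study` can gate a CI pipeline);
  argument-parsing errors follow click's convention.
* Randomness: every stochastic component (record expansion shuffle,
  simulator) takes an explicit seed and uses a single `numpy` Generator
  with a documented draw order.
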