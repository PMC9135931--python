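# Methods

## Scope and data model

`brainfa` analyzes gas-chromatography fatty-acid profiles of total lipids
from human brain gray matter, expressed in mol%: the molar share of each of
25 acyl species (14:0 through 24:6n-3) among all quantified species of a
sample. A profile therefore lives on the 100-mol% simplex ("closure"), which
induces negative dependence among its parts; every operation in the package
either respects that constraint explicitly or is invariant to it.

Species are parsed from the shorthand `C:D[n-S]` (carbons : double bonds,
omega series). Both the hyphenated (`22:6n-3`) and compact (`22:6n3`)
spellings are accepted because both occur in published tables; the canonical
form is hyphenated. The parser accepts any even chain length from 12 to 26
and 0-6 double bonds; the study panel is the fixed 25-species tuple
`brainfa.PANEL`. Species *missing* from a profile are distinct from species
at 0 mol% and invalidate index computation — silently zero-filling would
bias the chain-length and unsaturation indexes downward.

Thirteen region codes map to the anatomical sampling sites (e.g.
`occipital` = occipital cortex areas 17-18, `vermis` = upper cerebellar
vermis); the vocabulary is closed to keep cross-table joins reliable.

## Membrane indexes

For a closed profile with mol% `x_f`:

* **ACL** (average chain length) `= Σ_f carbons(f) · x_f / 100` — carbon
  atoms per chain, grouping by chain length only.
* **Class totals**: SFA (0 double bonds), MUFA (1), PUFA (≥ 2), with PUFA
  split into n-3 and n-6 series; UFA = MUFA + PUFA; plus the SFA/UFA ratio
  (undefined, reported as NaN, when UFA = 0).
* **DBI** (double bond index) `= Σ_k k · Σ_{f: db(f)=k} x_f`, k = 1..6 —
  double bonds per 100 chains.
* **PI** (peroxidizability index): the same class sums weighted
  0.025/1/2/4/6/8 for mono- through hexaenoic chains — an empirical
  susceptibility score for lipid peroxidation in which monoenes count almost
  nothing and each additional double bond roughly doubles the weight.

Class membership is always computed from the parsed double-bond count,
never from a hard-coded species list, so the operators remain valid for
extended panels. All of these except SFA/UFA are linear in the mol% vector,
so the mean of per-subject indexes equals the index of the mean profile;
this licenses validating the published group-level index values against the
published group mean compositions, which the acceptance suite does for all
26 region × group cells. Ratio-type quantities (SFA/UFA, the activity
surrogates below) are computed per subject and then averaged, because the
mean of ratios is not the ratio of means; the packaged reference table's
PbOx rows visibly follow the per-subject convention.

## Activity surrogates

Desaturase, elongase and peroxisomal beta-oxidation activities are
estimated as mol% ratios of a biosynthetic product to its immediate
substrate (e.g. D9D(n-9) = 18:1n-9/18:0; PbOx = 22:6n-3/24:6n-3). The
built-in table has 17 entries (5 desaturase, 11 elongase, 1 peroxisomal)
and custom tables can be loaded from YAML/JSON. These are surrogate
indices, not enzymatic rates. A ratio is reported as NaN when its
denominator is below 1e-6 mol% — real compositions bottom out around
0.02 mol%, so the threshold only guards degenerate synthetic input.
The overlap between the Elovl2-5 (n-3) and Elovl2 (n-3) definitions is
reproduced as conventionally published, without reassigning enzymes.

## Statistics

* **Group split**: middle-aged = age < 60 y, elderly = age ≥ 60 y. The
  reference cohort has no donor at exactly 60; the ≥ convention is this
  package's documented tie-break.
* **Two-sample t-test**: pooled-variance Student test by default (Welch
  available), two-sided, via `scipy.stats.ttest_ind`. `t_from_summary`
  reconstructs the test from printed mean ± SEM and n — the Welch variant
  works on the SEMs directly; the pooled variant rebuilds SDs as
  SEM·√n — useful for sanity-checking published star codings, with the
  caveat that SEM-only reconstruction inherits the table's rounding.
* **Percent change** is reported for the elderly relative to the
  middle-aged group, rounded to integer percent at the reporting layer.
* **BH-FDR**: Benjamini-Hochberg step-up q-values (via statsmodels) with
  discoveries at q ≤ Q, default Q = 0.10. The adjustment family is all
  variables reported within one region (25 species + 10 indexes + PbOx in
  the comparison pipeline), matching how the regional result tables are
  organized; activities form their own per-region family when analyzed.
  NaN p-values pass through without counting toward the family size.
* **Spearman correlation with age**: rho on average ranks; p from the
  t-approximation `t = rho·√((n-2)/(1-rho²))`, replaced by the exact
  two-sided permutation p (full enumeration of rank orders) for n ≤ 9,
  where the t-approximation is least reliable and enumeration (≤ 9! orders)
  is cheap. Constant variables and n < 3 yield NaN.
* **Cross-region matrices**: per-subject indexes are matched by subject id
  across regions; Spearman rho per region pair with pairwise-complete
  deletion, undefined below 3 shared subjects; symmetric, unit diagonal.
* **Star coding**: `*`/`**`/`***` at raw p < 0.05/0.01/0.001, reported
  separately from FDR survivors, since pre-adjustment stars and
  post-adjustment discoveries answer different questions.

## Reference templates

The packaged fixture (`brainfa/data/reference_templates.csv`) transcribes
published group-level summaries for the 13 regions: mean ± SEM mol% of all
25 species per age group (middle-aged n = 9, elderly n = 8), the printed
index rows, the pre-FDR star codings, and the FDR-adjusted significance
column. The transcription was validated mechanically: every cell's
composition closes to 100 ± 1 mol% (group means of closed data re-closed
only up to rounding), and every printed linear index is reproduced from the
printed species means within 0.1 (ACL, class totals) / 0.5 (DBI, PI) —
the worst-case propagation of ±0.005 per-cell rounding. Printed SEMs of
0.00 reflect rounding, not zero variance.

## Synthetic cohorts

The simulator emulates the structure the analysis assumes, so every
pipeline stage is testable without access to per-subject data (which were
never deposited).

* **Noise model**: logistic-normal-style. Per-species abundances are drawn
  log-normally around the template means and the vector is closed to
  100 mol%. This guarantees positivity and closure — the two structural
  facts of the data — at the cost of small compensatory coupling among
  species, which real compositions share.
* **SEM calibration**: the target per-subject SD of species *f* is
  `SEM_f · √n`; the log-scale SD is that divided by the mean (delta
  method). The calibration is approximate under closure (within ±20% for
  species ≥ 0.1 mol%). Printed SEMs of 0.00 are floored at 0.005 (half the
  printed resolution); log-SDs are capped at 1.0 because a few sub-0.1 mol%
  template cells carry SEMs as large as their means, which would otherwise
  explode the calibration.
* **Mean calibration**: closing a vector of independent log-normals biases
  closed-scale means slightly (a ratio expectation). Pre-closure means are
  therefore adjusted once per template by an internal fixed-seed Monte-Carlo
  loop (200,000 draws, 4 common-random-number iterations, cached), making
  the closed composition mean-unbiased for the renormalized template. The
  internal stream never touches the user's generator, so seed determinism
  of the output is unaffected.
* **Age effects**: optional per-species linear slopes on log abundance
  (units 1/year), centred at a reference age (default 60) and injected
  before closure, so one species' trend induces small anti-trends
  elsewhere — mirroring real compositional coupling.
* **Ages** default to uniform on 40-80 y (the reference cohort's range);
  the 17 actual donor ages are available as `STUDY_AGES` and reproduce the
  9/8 group split. Donors are shared across regions (same id, age, sex,
  post-mortem delay; independent regional profiles), so cross-region
  correlation analyses are well defined. Sex is drawn 12:5 male:female and
  post-mortem delay uniformly on 2-14.7 h, matching the reference cohort's
  margins.

What the simulator does **not** emulate: between-species covariance beyond
closure coupling (only marginal SEMs are published, so the log-scale
covariance is diagonal), sex/post-mortem-delay confounding, and any
nonlinearity of age trends (e.g. breakpoints). Passing calibration tests
therefore demonstrates correctness of the pipeline under these stated
conditions, not fidelity to every feature of real cohorts.

## Test problem sizes

The statistical engines are validated against independent oracles
(exhaustive BH step-up scan on 1,000 random p-vectors; full permutation
enumeration of Spearman p at n ≤ 7; closed-form t-test recomputation to
1e-10). Simulator calibration uses 200 seeded null replicates of a
17-donor, one-region cohort for p-value uniformity and FDR control, 50
replicates at n = 100 for slope-recovery power, and a single n = 10,000
draw for mean recovery — sizes chosen to make Monte-Carlo error small
relative to the tolerances being checked while keeping the default test
run fast.

## Known limitations

* Published per-subject data are unavailable, so printed t/rho/p values
  cannot be reproduced exactly; tests against the reference table are
  limited to quantities recomputable from group means (indexes, percent
  changes, ratio orderings) and to star-pattern consistency checks.
* The SEM-only t reconstruction and the ratio-of-means activity ordering
  are surrogates; both are documented as such where used.
* `validate`-level closure tolerance (default τ = 1.0 mol%) is permissive
  by design for transcribed group means; per-subject experimental exports
  typically close much tighter.
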