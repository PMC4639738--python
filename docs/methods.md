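# Methods

## Data model

The unit of observation is a *scan*: an instantaneous record, taken at a
fixed interval, of which unordered pairs of adults in one group are within
arm's reach (*passive close proximity*) and which ordered groomer->groomee
pairs are grooming (*grooming given*). A group-period (one group observed
over one period, e.g. the year after re-socialisation vs the second year of
group life) is a sequence of scans; the roster carries each individual's
group, sex, age class (mature = females 13-33 y / males 16-33 y; old >
33 y) and deprivation class (ND zoo-born non-deprived, EMD wild-caught
early maternally deprived, ELD/LLD ex-laboratory early/late long-term
deprived, LMD late maternally deprived).

Every individual is assumed observable in every scan of its group-period:
edge weights are computed against a single per-group-period scan count. The
number of scans for a group-period is the largest scan index present in the
table, so scans in which nothing was observed still count in the
denominator (an explicit `none` marker row preserves trailing empty scans
across round trips).

## Networks and measures

Proximity yields an undirected weighted network with
`w_ij = 100 x (#scans with pair {i,j}) / n_scans`; grooming yields a
directed network with `w_ij = 100 x (#scans in which i grooms j) / n_scans`
(grooming *given*, i.e. out-edges; in-strength is available but not
analysed). Weights stay on the percent scale throughout.

Per individual and behaviour:

* **vertex strength centrality** `s_i / (N-1)`, with `s_i` the sum of
  incident (undirected) or outgoing (directed) weights — the mean percent
  of scans spent per potential partner, comparable across group sizes;
* **edge weight disparity** `Y2(i) = sum_j (w_ij / s_i)^2`, which equals
  `1/(N-1)` for a perfectly even spread and 1 for a single partner, and its
  **deviation** `dY2 = Y2 - 1/(N-1)`, comparable across groups.

`Y2` is undefined when `s_i = 0` (an animal that never groomed has no
grooming distribution); such rows are flagged and excluded listwise from
disparity models and tests while keeping their zero strength centrality.
Ratios are formed from exact integer scan counts, so the equal-spread
identity `dY2 = 0` holds exactly in floating point.

## Statistical pipeline

For each behaviour x period x measure the full fixed structure is
`age_class + sex + deprivation_class + sex:deprivation_class` with a random
intercept per group, fitted as a normal linear mixed model (identity link)
by maximum likelihood (statsmodels `MixedLM`). ML rather than REML is used
wherever models with different fixed structures are compared; the selected
model is refitted by REML for coefficient reporting.

Model comparison uses the small-sample corrected AIC,
`AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)`, with `k` = fixed-effect columns
(after alias removal) + 2 variance parameters; `k` is held at that count
even when the group variance lands on the zero boundary so candidates stay
comparable. Backward selection removes, at each step, the single term whose
removal lowers AICc most, subject to marginality (an interaction is removed
before the main effects it involves); ties break toward the higher-order
term and then alphabetically, and the ledger records every candidate AICc
at every step. Selection stops when no removal lowers AICc.

Per-term tests are marginal (type-III-style) Wald F tests on a sum-to-zero
coded design, with the residual df `n - rank(X)` as denominator df.
Aliased design columns — e.g. an empty sex x class cell after the
non-groomers of one class drop out — are removed greedily left-to-right,
shrinking the affected term's numerator df, which is how reduced
interaction dfs arise in unbalanced subsets. Degenerate inputs are handled
closed-form: a response that is an exact linear function of the design (or
constant) returns the least-squares coefficients with ~0 residual
variance, F = 0 for vanishing terms, without raising. Singular fits
(group variance on the zero boundary, where the ML solution coincides with
the ordinary linear fit) are flagged, never raised; the optimiser chain is
the statsmodels default followed by Powell and Nelder-Mead, accepting the
first finite log-likelihood.

"Group size as random effect" is implemented as a random intercept per
group identity (group size is constant within a group, so the two
groupings coincide unless two groups share a size); `random_by:
group_size` switches to grouping by the size value.

Post-hoc comparisons are two-sided Mann-Whitney U tests (U reported with
the `min(U_a, U_b)` convention): exact by full null enumeration when there
are no ties and `n_a * n_b <= 400`, otherwise the normal approximation with
tie and continuity correction. Families per measure-period: (i) all pairs
of eligible deprivation classes, always; (ii) female vs male when sex was
retained; (iii) within-sex class pairs when the interaction was retained.
Holm-Bonferroni correction is applied within each family. Classes with
fewer than `min_class_n = 3` non-missing values are excluded from models
and tests (the conventional exclusion of a 2-animal class). Whether the
correction family should instead span all periods is not determinable from
standard practice alone; per-measure-per-period was chosen and is the
documented behaviour.

## Synthetic generator

The generator emulates the study design: 41 adults in 4 groups (two
sanctuary groups of 9 = 5 ELD + 4 LLD; two zoo groups of 12 and 11 mixing
EMD and ND; 27 females / 14 males), 500 scans per group-period, two
periods. Behaviour is driven by three per-class parameters:

| parameter | meaning | defaults (ELD / LLD / EMD / ND) |
|---|---|---|
| sigma_c in [0,1] | dyad (i,j) in proximity with prob. sigma_i sigma_j | 0.15 / 0.25 / 0.55 / 0.60 |
| gamma_c in [0,1] | individual grooms in a scan with prob. gamma_i | 0.05 / 0.20 / 0.20 / 0.35 |
| kappa_c > 0 | total Dirichlet concentration of the stable partner-preference vector pi_i (drawn once per individual; small kappa = one or two preferred partners) | 0.3 / 0.5 / 2.0 / 8.0 |

Realised per-individual rates are the class rates jittered on the logit
scale (`gamma_logit_sd = 0.6`, `sigma_logit_sd = 0.25`; 0 and 1 are fixed
points). Without heterogeneity, within-class variance is purely binomial
and every class pair separates completely at 500 scans — unlike real
animals. The grooming SD was calibrated by simulation so that the default
conditions reproduce the intended contrast structure (the strong
ELD-vs-ND grooming deficit detectable, the mild LLD-vs-ND difference
mostly not), while leaving the class-level rates at their stated values.

Per scan, each dyad is in proximity independently; each individual grooms
with its own probability and picks one partner from its preference vector.
Grooming and proximity are independent, consecutive scans are independent
(no temporal autocorrelation), and there are no dominance dynamics or
immatures. Expected values under the realised traits are available as a
recovery oracle: grooming strength centrality `100 gamma_i/(N-1)`, grooming
disparity `sum_j pi_ij^2`, proximity weight `100 sigma_i sigma_j`.

What passing recovery tests shows — and does not. The generator produces
stable preferences, independent dyads, and logit-normal individual
variation; real chimpanzee data add reciprocity, temporal correlation,
kinship and rank structure, and observation error. Parameter recovery
therefore validates the pipeline's arithmetic and its statistical
calibration under the stated design, not the ethological realism of any
particular dataset.

## Validation experiments and problem sizes

* Metric agreement: 100 random instances (N <= 8, <= 50 scans) against a
  brute-force raw-count recomputation, tolerance 1e-12.
* Exact tests: every sample split with `n_a + n_b <= 12` against full
  enumeration over all labelings; Holm against hand-computed step-down
  values.
* Pattern recovery: 200 seeded pipeline passes at the default conditions;
  the class-median orderings (ELD lowest grooming strength centrality, ND
  lowest grooming dY2, ELD/LLD highest proximity dY2) and the
  ELD-vs-ND-significant / LLD-vs-ND-not post-hoc contrast are each
  expected in at least 80% of runs.
* Null calibration: 500 passes with behaviourally identical classes; the
  Holm-adjusted significant fraction at alpha = 0.05 stays at or below
  0.07.
* Selection: 200 seeds with a 2-residual-SD class deficit (plus a 0.25-SD
  group intercept) — the class term retained in >= 90%, a null age term
  dropped in >= 80%, marginality never violated; the marginal F for the
  class term in the generating model is significant in >= 95%.

These sizes keep a full validation pass in the low minutes on one core
while leaving the Monte-Carlo error of each rate near or below one
percentage point (binomial SE at p = 0.9, n = 200 is about 2 points).

## Known limitations

* With four groups the random-intercept variance is weakly identified and
  frequently estimated at the boundary; fits are flagged `singular` and
  coincide with the ordinary linear model there.
* Marginal (type-III-style) F tests on unbalanced data differ from
  sequential tests; software that reports sequential sums of squares will
  not match term-by-term.
* The asymptotic Mann-Whitney branch is approximate for very small tied
  samples; the exact branch covers every untied case up to
  `n_a * n_b = 400`.
* Visibility correction (per-individual scan denominators) is accepted in
  the data model but off by default; all weights share the group-period
  denominator.
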